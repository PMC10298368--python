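"""Exception types shared across the package."""

from __future__ import annotations


class ValidationError(ValueError):
    """A field value violates its invariant; the message names the field."""


class DomainError(RuntimeError):
    """A contract violation identified by a short machine-readable code.

    Codes in use: ``irp-missing``, ``no-endoscopy``, ``insufficient-data``,
    ``empty-report``, ``not-a-report``, ``degenerate-table``,
    ``events-outside-duration``, ``unknown-label``, ``infeasible-margins``,
    ``label-absent``, ``missing-references``, ``incomplete-record``,
    ``age-outside-bands``.
    """

    def __init__(self, code: str, detail: str = ""):
        self.code = code
        self.detail = detail
        super().__init__(f"{code}: {detail}" if detail else code)
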