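"""Mining of copy-pasted pH-impedance report text into canonical parameters.

The dialect is line-oriented: section title lines (optionally decorated with
brackets, dashes or ``#`` marks) followed by ``Label: value [unit]`` lines.
Matching is tolerant of the noise real copy-paste produces — case, diacritics,
repeated whitespace, CRLF line endings, blank lines, decimal commas
("4,2" → 4.2, the source clinics export in Turkish/Dutch locales). Unknown
lines are skipped with a logged issue, never fatally: the parser's contract
is that ``|values| + |missing|`` always equals the schema size.

The parameter list itself lives in a schema data file
(``data/schema_48.yaml``, 48 entries by default) so other ambulatory-system
dialects can be described without code changes.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources

import yaml

from ._util import raise_validation
from .errors import DomainError

__all__ = [
    "ParameterSpec",
    "ParameterSchema",
    "ReportRecord",
    "ParseIssue",
    "default_schema",
    "load_schema",
    "parse_report",
    "render_report",
]

VALUE_KINDS = ("percent", "count", "seconds", "score")

_NUMBER_RE = re.compile(r"^([-+]?\d+(?:[.,]\d+)?(?:[eE][-+]?\d+)?)\s*(.*)$")


def _normalize(text: str) -> str:
    """Casefold, strip diacritics, collapse whitespace."""
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    return " ".join(text.casefold().split())


def _strip_decoration(line: str) -> str:
    return line.strip().strip("#=[]-—:· ").strip()


@dataclass(frozen=True)
class ParameterSpec:
    key: str
    label: str
    unit: str
    kind: str
    section: str

    def __post_init__(self):
        if self.kind not in VALUE_KINDS:
            raise_validation("kind", self.kind, f"must be one of {VALUE_KINDS}")


@dataclass(frozen=True)
class ParameterSchema:
    name: str
    sections: tuple[tuple[str, str], ...]  # (id, title) in render order
    entries: tuple[ParameterSpec, ...]

    def __post_init__(self):
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise_validation("entries", "duplicate keys", "canonical keys must be unique")
        section_ids = {sid for sid, _ in self.sections}
        for e in self.entries:
            if e.section not in section_ids:
                raise_validation("section", e.section, "not a declared section")

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(e.key for e in self.entries)

    def by_key(self, key: str) -> ParameterSpec:
        return next(e for e in self.entries if e.key == key)


@dataclass(frozen=True)
class ParseIssue:
    line_no: int
    code: str  # unknown-key | bad-number | duplicate-key | missing-section
    detail: str


@dataclass(frozen=True)
class ReportRecord:
    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, int] = field(default_factory=dict)
    missing: tuple[str, ...] = ()


def load_schema(source) -> ParameterSchema:
    """Load a schema from a YAML mapping, file path, or open stream."""
    if isinstance(source, dict):
        raw = source
    elif hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    return ParameterSchema(
        name=raw.get("name", "unnamed"),
        sections=tuple((s["id"], s["title"]) for s in raw["sections"]),
        entries=tuple(ParameterSpec(**e) for e in raw["entries"]),
    )


_DEFAULT: ParameterSchema | None = None


def default_schema() -> ParameterSchema:
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("refluxdx.data").joinpath("schema_48.yaml").read_text(
            encoding="utf-8"
        )
        _DEFAULT = load_schema(yaml.safe_load(text))
    return _DEFAULT


def parse_report(
    text: str, schema: ParameterSchema | None = None
) -> tuple[ReportRecord, list[ParseIssue]]:
    """Extract canonical parameters from copy-pasted report text.

    Returns the record plus a list of non-fatal issues. Raises
    :class:`DomainError` ``empty-report`` for empty/whitespace text and
    ``not-a-report`` when no section header is recognizable at all.
    """
    schema = schema or default_schema()
    if not text or not text.strip():
        raise DomainError("empty-report", "input text is empty")

    section_titles = {_normalize(title): sid for sid, title in schema.sections}
    section_titles.update({_normalize(sid): sid for sid, _ in schema.sections})
    labels = {_normalize(e.label): e for e in schema.entries}

    values: dict[str, float] = {}
    provenance: dict[str, int] = {}
    issues: list[ParseIssue] = []
    seen_section = False

    for line_no, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.strip()
        if not line:
            continue
        if _normalize(_strip_decoration(line)) in section_titles:
            seen_section = True
            continue
        if ":" not in line:
            issues.append(ParseIssue(line_no, "unknown-key", f"no key-value separator: {line!r}"))
            continue
        label_part, value_part = line.split(":", 1)
        spec = labels.get(_normalize(label_part))
        if spec is None:
            issues.append(ParseIssue(line_no, "unknown-key", label_part.strip()))
            continue
        if not seen_section:
            issues.append(
                ParseIssue(line_no, "missing-section", f"{spec.key} before any section header")
            )
        if spec.key in values:
            issues.append(ParseIssue(line_no, "duplicate-key", spec.key))
            continue
        m = _NUMBER_RE.match(value_part.strip())
        if m is None:
            issues.append(
                ParseIssue(line_no, "bad-number", f"{spec.key}: {value_part.strip()!r}")
            )
            continue
        number, unit_part = m.groups()
        if unit_part and _normalize(unit_part) != _normalize(spec.unit):
            issues.append(
                ParseIssue(
                    line_no,
                    "bad-number",
                    f"{spec.key}: unit {unit_part!r} != schema {spec.unit!r}",
                )
            )
        values[spec.key] = float(number.replace(",", "."))
        provenance[spec.key] = line_no

    if not seen_section:
        raise DomainError("not-a-report", "no recognizable section header")

    missing = tuple(k for k in schema.keys if k not in values)
    return ReportRecord(values=values, provenance=provenance, missing=missing), issues


def _format_value(value: float, kind: str) -> str:
    if kind == "count" and float(value).is_integer():
        return str(int(value))
    return repr(float(value))  # shortest round-trip representation


def render_report(record: ReportRecord, schema: ParameterSchema | None = None) -> str:
    """Emit the documented dialect; exact inverse of :func:`parse_report`."""
    schema = schema or default_schema()
    if record.missing:
        raise DomainError("incomplete-record", f"missing keys: {list(record.missing)}")
    absent = [k for k in schema.keys if k not in record.values]
    if absent:
        raise DomainError("incomplete-record", f"missing keys: {absent}")

    lines: list[str] = []
    for sid, title in schema.sections:
        lines.append(title)
        for e in schema.entries:
            if e.section != sid:
                continue
            val = _format_value(record.values[e.key], e.kind)
            suffix = f" {e.unit}" if e.unit else ""
            lines.append(f"{e.label}: {val}{suffix}")
        lines.append("")
    return "\n".join(lines)
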