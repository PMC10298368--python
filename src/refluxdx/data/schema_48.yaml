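# Default pH-impedance report dialect: 48 canonical parameters in 8 sections.
# Other ambulatory-system dialects can be described by swapping this file;
# the parser is schema-driven and has no parameter names in code.
name: ph-impedance-48
sections:
  - id: acid-exposure
    title: Acid Exposure
  - id: impedance-counts
    title: Impedance Reflux Episodes
  - id: proximal-extent
    title: Proximal Extent
  - id: bolus-exposure
    title: Bolus Exposure
  - id: bolus-clearance
    title: Bolus Clearance
  - id: symptom-analysis
    title: Symptom Analysis
  - id: study-metadata
    title: Study Metadata
  - id: composites
    title: Composite Scores
entries:
  - {key: aet_total, label: Total acid exposure, unit: "%", kind: percent, section: acid-exposure}
  - {key: aet_upright, label: Upright acid exposure, unit: "%", kind: percent, section: acid-exposure}
  - {key: aet_recumbent, label: Recumbent acid exposure, unit: "%", kind: percent, section: acid-exposure}
  - {key: acid_episodes_total, label: Acid episodes total, unit: "", kind: count, section: acid-exposure}
  - {key: acid_episodes_upright, label: Acid episodes upright, unit: "", kind: count, section: acid-exposure}
  - {key: acid_episodes_recumbent, label: Acid episodes recumbent, unit: "", kind: count, section: acid-exposure}
  - {key: acid_episodes_long, label: Episodes longer than 5 min, unit: "", kind: count, section: acid-exposure}
  - {key: longest_acid_episode_s, label: Longest acid episode, unit: s, kind: seconds, section: acid-exposure}
  - {key: demeester_score, label: DeMeester score, unit: "", kind: score, section: acid-exposure}
  - {key: reflux_acid_total, label: Acid reflux episodes total, unit: "", kind: count, section: impedance-counts}
  - {key: reflux_acid_upright, label: Acid reflux episodes upright, unit: "", kind: count, section: impedance-counts}
  - {key: reflux_acid_recumbent, label: Acid reflux episodes recumbent, unit: "", kind: count, section: impedance-counts}
  - {key: reflux_weakly_acid_total, label: Weakly acid reflux episodes total, unit: "", kind: count, section: impedance-counts}
  - {key: reflux_weakly_acid_upright, label: Weakly acid reflux episodes upright, unit: "", kind: count, section: impedance-counts}
  - {key: reflux_weakly_acid_recumbent, label: Weakly acid reflux episodes recumbent, unit: "", kind: count, section: impedance-counts}
  - {key: reflux_weakly_alkaline_total, label: Weakly alkaline reflux episodes total, unit: "", kind: count, section: impedance-counts}
  - {key: reflux_weakly_alkaline_upright, label: Weakly alkaline reflux episodes upright, unit: "", kind: count, section: impedance-counts}
  - {key: reflux_weakly_alkaline_recumbent, label: Weakly alkaline reflux episodes recumbent, unit: "", kind: count, section: impedance-counts}
  - {key: reflux_nonacid_total, label: Nonacid reflux episodes total, unit: "", kind: count, section: impedance-counts}
  - {key: reflux_nonacid_upright, label: Nonacid reflux episodes upright, unit: "", kind: count, section: impedance-counts}
  - {key: reflux_nonacid_recumbent, label: Nonacid reflux episodes recumbent, unit: "", kind: count, section: impedance-counts}
  - {key: proximal_total, label: Proximal episodes total, unit: "", kind: count, section: proximal-extent}
  - {key: proximal_upright, label: Proximal episodes upright, unit: "", kind: count, section: proximal-extent}
  - {key: proximal_recumbent, label: Proximal episodes recumbent, unit: "", kind: count, section: proximal-extent}
  - {key: bolus_exposure_total, label: Bolus exposure total, unit: "%", kind: percent, section: bolus-exposure}
  - {key: bolus_exposure_upright, label: Bolus exposure upright, unit: "%", kind: percent, section: bolus-exposure}
  - {key: bolus_exposure_recumbent, label: Bolus exposure recumbent, unit: "%", kind: percent, section: bolus-exposure}
  - {key: bolus_clearance_total_s, label: Median bolus clearance total, unit: s, kind: seconds, section: bolus-clearance}
  - {key: bolus_clearance_upright_s, label: Median bolus clearance upright, unit: s, kind: seconds, section: bolus-clearance}
  - {key: bolus_clearance_recumbent_s, label: Median bolus clearance recumbent, unit: s, kind: seconds, section: bolus-clearance}
  - {key: heartburn_count, label: Heartburn events, unit: "", kind: count, section: symptom-analysis}
  - {key: heartburn_si, label: Heartburn symptom index, unit: "%", kind: percent, section: symptom-analysis}
  - {key: heartburn_sap, label: Heartburn symptom association probability, unit: "%", kind: percent, section: symptom-analysis}
  - {key: heartburn_ssi, label: Heartburn symptom sensitivity index, unit: "%", kind: percent, section: symptom-analysis}
  - {key: regurgitation_count, label: Regurgitation events, unit: "", kind: count, section: symptom-analysis}
  - {key: regurgitation_si, label: Regurgitation symptom index, unit: "%", kind: percent, section: symptom-analysis}
  - {key: regurgitation_sap, label: Regurgitation symptom association probability, unit: "%", kind: percent, section: symptom-analysis}
  - {key: regurgitation_ssi, label: Regurgitation symptom sensitivity index, unit: "%", kind: percent, section: symptom-analysis}
  - {key: chest_pain_count, label: Chest pain events, unit: "", kind: count, section: symptom-analysis}
  - {key: chest_pain_si, label: Chest pain symptom index, unit: "%", kind: percent, section: symptom-analysis}
  - {key: chest_pain_sap, label: Chest pain symptom association probability, unit: "%", kind: percent, section: symptom-analysis}
  - {key: chest_pain_ssi, label: Chest pain symptom sensitivity index, unit: "%", kind: percent, section: symptom-analysis}
  - {key: recording_duration_s, label: Recording duration, unit: s, kind: seconds, section: study-metadata}
  - {key: meal_time_s, label: Meal time excluded, unit: s, kind: seconds, section: study-metadata}
  - {key: supine_time_s, label: Supine time, unit: s, kind: seconds, section: study-metadata}
  - {key: sensor_channels, label: Impedance channels, unit: "", kind: count, section: study-metadata}
  - {key: reflux_episodes_all, label: Total reflux episodes, unit: "", kind: count, section: composites}
  - {key: acid_clearance_mean_s, label: Mean acid clearance time, unit: s, kind: seconds, section: composites}
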