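# Six-phase dietary P schedule for a market pig, 27-180 days of age.
# diet_p_pct is total P, % as-fed; BW ranges are informational metadata.
phases:
  - {label: phase1, age_start: 27, age_end: 39, bw_low: 7.0, bw_high: 11.0, diet_p_pct: 0.64}
  - {label: phase2, age_start: 40, age_end: 66, bw_low: 11.0, bw_high: 25.0, diet_p_pct: 0.58}
  - {label: phase3, age_start: 67, age_end: 94, bw_low: 25.0, bw_high: 45.0, diet_p_pct: 0.51}
  - {label: phase4, age_start: 95, age_end: 117, bw_low: 45.0, bw_high: 65.0, diet_p_pct: 0.46}
  - {label: phase5, age_start: 118, age_end: 138, bw_low: 65.0, bw_high: 85.0, diet_p_pct: 0.43}
  - {label: phase6, age_start: 139, age_end: 180, bw_low: 85.0, bw_high: 121.5, diet_p_pct: 0.40}
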