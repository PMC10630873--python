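# Default indicator registry: the 21 laboratory indicators of the ACLF panel.
#
# Reference intervals are standard adult intervals (editable data, not code);
# the normal-range correction (C value) measures relative distance to the
# nearer bound.  ref_low/ref_high may each be omitted (open-ended interval),
# but not both.  The four liver-panel indicators gate the D/E modification.
# An optional per-indicator `scheme` overrides the default molecular_beta
# threshold scheme for the magnitude score.

indicators:
  - {name: hemoglobin,                 units: g/L,       ref_low: 130,    ref_high: 175,   is_liver_panel: false}
  - {name: white_blood_cell,           units: 1e9/L,     ref_low: 3.5,    ref_high: 9.5,   is_liver_panel: false}
  - {name: red_blood_cell,             units: 1e12/L,    ref_low: 4.3,    ref_high: 5.8,   is_liver_panel: false}
  - {name: platelet,                   units: 1e9/L,     ref_low: 125,    ref_high: 350,   is_liver_panel: false}
  - {name: thrombocytocrit,            units: "%",       ref_low: 0.11,   ref_high: 0.28,  is_liver_panel: false}
  - {name: activated_partial_thromboplastin_time, units: s, ref_low: 25,  ref_high: 37,    is_liver_panel: false}
  - {name: prothrombin_time,           units: s,         ref_low: 11,     ref_high: 14,    is_liver_panel: false}
  - {name: thrombin_time,              units: s,         ref_low: 14,     ref_high: 21,    is_liver_panel: false}
  - {name: fibrinogen,                 units: g/L,       ref_low: 2,      ref_high: 4,     is_liver_panel: false}
  - {name: international_normalized_ratio, units: ratio, ref_low: 0.8,    ref_high: 1.2,   is_liver_panel: false}
  - {name: uric_acid,                  units: umol/L,    ref_low: 208,    ref_high: 428,   is_liver_panel: false}
  - {name: creatinine,                 units: umol/L,    ref_low: 59,     ref_high: 104,   is_liver_panel: false}
  - {name: urea,                       units: mmol/L,    ref_low: 2.8,    ref_high: 7.6,   is_liver_panel: false}
  - {name: glucose,                    units: mmol/L,    ref_low: 3.9,    ref_high: 6.1,   is_liver_panel: false}
  - {name: alanine_aminotransferase,   units: U/L,       ref_low: 7,      ref_high: 40,    is_liver_panel: true}
  - {name: aspartate_aminotransferase, units: U/L,       ref_low: 13,     ref_high: 35,    is_liver_panel: true}
  - {name: total_bilirubin,            units: umol/L,    ref_low: 3.4,    ref_high: 21,    is_liver_panel: true}
  - {name: conjugated_bilirubin,       units: umol/L,                     ref_high: 6.8,   is_liver_panel: true}
  - {name: unconjugated_bilirubin,     units: umol/L,    ref_low: 1.7,    ref_high: 14,    is_liver_panel: false}
  - {name: cholinesterase,             units: U/L,       ref_low: 4300,   ref_high: 13200, is_liver_panel: false}
  - {name: gamma_glutamyl_transferase, units: U/L,       ref_low: 10,     ref_high: 60,    is_liver_panel: false}
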