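# Discretization thresholds for the 11 routine blood tests monitored
# under thiopurine therapy. Three rules are study facts:
#   - neutrophils: one count below 1.0 G/L defines neutropenia
#   - hemoglobin: one result below 9.0 g/100 mL defines moderate-to-severe anemia
#   - glycemia: hyperglycemia requires TWO results above the high threshold
# Every other numeric limit is a conventional adult reference value
# (source: common hospital laboratory ranges), NOT taken from the study,
# and is expected to be overridden by a site-specific table.
tests:
  leukocytes:
    label: Leukocyte count
    units: G/L
    low: 4.0
    high: 10.0
  neutrophils:
    label: Neutrophil count
    units: G/L
    low: 1.0          # study fact
    high: 7.5
  rbc:
    label: Red blood cell count
    units: T/L
    low: 4.0
    high: 5.7
  hemoglobin:
    label: Hemoglobin
    units: g/100mL
    low: 9.0          # study fact
    high: 17.0
  mcv:
    label: Mean corpuscular volume
    units: fL
    low: 80.0
    high: 100.0
  platelets:
    label: Platelet count
    units: G/L
    low: 150.0
    high: 450.0
  glycemia:
    label: Glycemia
    units: g/L
    low: 0.7
    high: 1.26
    min_high_occurrences: 2   # study fact
  alp:
    label: Alkaline phosphatase
    units: U/L
    low: 40.0
    high: 130.0
  alt:
    label: Alanine aminotransferase
    units: U/L
    low: null         # low threshold not clinically relevant
    high: 40.0
  ast:
    label: Aspartate aminotransferase
    units: U/L
    low: null
    high: 40.0
  ggt:
    label: Gamma glutamyl-transpeptidase
    units: U/L
    low: null
    high: 60.0
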