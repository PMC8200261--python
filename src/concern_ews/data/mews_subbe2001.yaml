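# Modified Early Warning Score (MEWS) component point table.
# Provenance: Subbe CP, Kruger M, Rutherford P, Gemmel L. Validation of a
# modified Early Warning Score in medical admissions. QJM 2001;94:521-6.
# Urine output is omitted (not charted hourly in this pipeline's streams).
#
# Each component lists ascending lower band edges; points[i] applies to
# values in [edges[i-1], edges[i]) with open ends below edges[0] and at or
# above edges[-1].
version: mews-subbe2001-v1
max_score: 14
components:
  sbp:
    edges: [71, 81, 101, 200]
    points: [3, 2, 1, 0, 2]
  hr:
    edges: [41, 51, 101, 111, 130]
    points: [2, 1, 0, 1, 2, 3]
  rr:
    edges: [9, 15, 21, 30]
    points: [2, 0, 1, 2, 3]
  temp:
    edges: [35.0, 38.5]
    points: [2, 0, 2]
  avpu:
    A: 0
    V: 1
    P: 2
    U: 3
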