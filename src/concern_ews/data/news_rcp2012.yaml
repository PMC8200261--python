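# National Early Warning Score (NEWS) component point table.
# Provenance: Royal College of Physicians. National Early Warning Score
# (NEWS): Standardising the assessment of acute-illness severity in the
# NHS. London: RCP, 2012.
#
# Each component lists ascending lower band edges; points[i] applies to
# values in [edges[i-1], edges[i]) with open ends below edges[0] and at or
# above edges[-1].  Temperature edges use .05 offsets so one-decimal
# readings band per the published table (35.1-36.0 -> 1, etc.).
version: news-rcp2012-v1
max_score: 20
components:
  rr:
    edges: [9, 12, 21, 25]
    points: [3, 1, 0, 2, 3]
  spo2:
    edges: [92, 94, 96]
    points: [3, 2, 1, 0]
  supplemental_o2:
    yes_points: 2
    no_points: 0
  temp:
    edges: [35.05, 36.05, 38.05, 39.05]
    points: [3, 1, 0, 1, 2]
  sbp:
    edges: [91, 101, 111, 220]
    points: [3, 2, 1, 0, 3]
  hr:
    edges: [41, 51, 91, 111, 131]
    points: [3, 1, 0, 1, 2, 3]
  consciousness:
    A: 0
    V: 3
    P: 3
    U: 3
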