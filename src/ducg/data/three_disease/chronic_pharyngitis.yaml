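# Chronic pharyngitis sub-DUCG (three-disease toy knowledge base).
# Prior 0.09 is the authored disease incidence; no risk-factor triple, so
# the raw prior passes through unchanged.  Link strengths are synthetic.
name: chronic_pharyngitis
variables:
  - {id: B12, kind: B, states: 2, label: "Chronic pharyngitis", prior: [0.91, 0.09]}
  - {id: X22, kind: X, states: 2, label: "Cough"}
  - {id: X44, kind: X, states: 2, label: "Throat itching"}
  - {id: X45, kind: X, states: 2, label: "Foreign body sensation in throat"}
  - {id: X51, kind: X, states: 2, label: "Dry throat"}
  - {id: X85, kind: X, states: 2, label: "Bilateral sore throat"}
links:
  - {child: X22, parent: B12, weight: 1.0, strength: {1: [0.0, 0.3]}}
  - {child: X44, parent: B12, weight: 1.0, strength: {1: [0.0, 0.6]}}
  - {child: X45, parent: B12, weight: 1.0, strength: {1: [0.0, 0.7]}}
  - {child: X51, parent: B12, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B12, weight: 1.0, strength: {1: [0.0, 0.6]}}
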