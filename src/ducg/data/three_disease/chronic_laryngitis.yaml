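# Chronic laryngitis sub-DUCG (three-disease toy knowledge base).
# Prior 0.04 is the authored disease incidence; link strengths are
# synthetic, drawn once and committed.
name: chronic_laryngitis
variables:
  - {id: B11, kind: B, states: 2, label: "Chronic laryngitis", prior: [0.96, 0.04]}
  - {id: BX11, kind: BX, states: 2, label: "Chronic laryngitis under risk factors"}
  - {id: SG11, kind: SG, states: 2, label: "Chronic laryngitis risk gate"}
  - {id: X5, kind: X, states: 2, label: "Subacute stage"}
  - {id: X52, kind: X, states: 2, label: "Male sex"}
  - {id: X21, kind: X, states: 2, label: "Hoarseness"}
  - {id: X23, kind: X, states: 2, label: "Expectoration"}
  - {id: X44, kind: X, states: 2, label: "Throat itching"}
  - {id: X85, kind: X, states: 2, label: "Bilateral sore throat"}
  - {id: X153, kind: X, states: 2, label: "Vocal cord edema"}
links:
  - {child: X21, parent: BX11, weight: 1.0, strength: {1: [0.0, 0.8]}}
  - {child: X23, parent: BX11, weight: 1.0, strength: {1: [0.0, 0.4]}}
  - {child: X44, parent: BX11, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: BX11, weight: 1.0, strength: {1: [0.0, 0.65]}}
  - {child: X153, parent: BX11, weight: 1.0, strength: {1: [0.0, 0.45]}}
gates:
  - gate: SG11
    rows:
      - {state: 1, expr: "X52=1 and X5=1"}
    remnant: 0
sa_factors:
  - {disease: B11, bx: BX11, gate: SG11, factors: [1, 3]}
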