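# Laryngopharyngeal reflux (LPR) sub-DUCG.
#
# The base incidence Pr{B23,1} = 0.03, the risk-factor gate on a history of
# reflux esophagitis (X74) and the SA multiplier 10 are authored values of
# the clinical model; manifestation link strengths are synthetic stand-ins
# chosen once and committed (the original per-link strengths are not
# published), so downstream golden tests stay stable.
name: lpr
variables:
  - {id: B23, kind: B, states: 2, label: "Laryngopharyngeal reflux", prior: [0.97, 0.03]}
  - {id: BX23, kind: BX, states: 2, label: "LPR incidence under risk factors"}
  - {id: SG23, kind: SG, states: 2, label: "LPR risk-factor gate"}
  - {id: X74, kind: X, states: 2, label: "History of reflux esophagitis"}
  - {id: X21, kind: X, states: 2, label: "Hoarseness"}
  - {id: X22, kind: X, states: 2, label: "Cough"}
  - {id: X45, kind: X, states: 2, label: "Foreign body sensation in throat"}
  - {id: X85, kind: X, states: 2, label: "Bilateral sore throat"}
  - {id: X150, kind: X, states: 2, label: "Throat clearing"}
  - {id: X153, kind: X, states: 2, label: "Vocal cord edema"}
  - {id: X158, kind: X, states: 2, label: "Pharyngeal pH monitoring positive"}
  - {id: SX160, kind: SX, states: 2, label: "Proton pump inhibitors are effective"}
links:
  - {child: X21, parent: BX23, weight: 1.0, strength: {1: [0.0, 0.6]}}
  - {child: X22, parent: BX23, weight: 1.0, strength: {1: [0.0, 0.35]}}
  - {child: X45, parent: BX23, weight: 1.0, strength: {1: [0.0, 0.55]}}
  - {child: X85, parent: BX23, weight: 1.0, strength: {1: [0.0, 0.7]}}
  - {child: X150, parent: BX23, weight: 1.0, strength: {1: [0.0, 0.65]}}
  - {child: X153, parent: BX23, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X158, parent: BX23, weight: 1.0, strength: {1: [0.0, 0.8]}}
  - {child: SX160, parent: BX23, weight: 1.0, strength: {1: [0.0, 0.9]}}
gates:
  - gate: SG23
    rows:
      - {state: 1, expr: "X74=1"}
    remnant: 0
sa_factors:
  - {disease: B23, bx: BX23, gate: SG23, factors: [1, 10]}
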