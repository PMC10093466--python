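# Structure-only skeleton of the 27-disease sore-throat knowledge base.
# Disease ids and labels follow the published disease list (indices reach
# B28 with no B21); priors and the single shared placeholder manifestation
# are synthetic scaffolding for structural tests.
name: sore_throat_skeleton
variables:
  - {id: B1, kind: B, states: 2, label: "Acute tonsillitis", prior: [0.99, 0.01]}
  - {id: B2, kind: B, states: 2, label: "Acute pharyngitis", prior: [0.99, 0.01]}
  - {id: B3, kind: B, states: 2, label: "Acute epiglottitis", prior: [0.99, 0.01]}
  - {id: B4, kind: B, states: 2, label: "Acute laryngitis", prior: [0.99, 0.01]}
  - {id: B5, kind: B, states: 2, label: "Pharyngeal burn", prior: [0.99, 0.01]}
  - {id: B6, kind: B, states: 2, label: "Glossopharyngeal neuralgia", prior: [0.99, 0.01]}
  - {id: B7, kind: B, states: 2, label: "Peritonsillar abscess", prior: [0.99, 0.01]}
  - {id: B8, kind: B, states: 2, label: "Pharyngeal foreign body", prior: [0.99, 0.01]}
  - {id: B9, kind: B, states: 2, label: "Chronic tonsillitis", prior: [0.99, 0.01]}
  - {id: B10, kind: B, states: 2, label: "Cancer of the larynx", prior: [0.99, 0.01]}
  - {id: B11, kind: B, states: 2, label: "Chronic laryngitis", prior: [0.99, 0.01]}
  - {id: B12, kind: B, states: 2, label: "Chronic pharyngitis", prior: [0.99, 0.01]}
  - {id: B13, kind: B, states: 2, label: "Tonsil carcinoma", prior: [0.99, 0.01]}
  - {id: B14, kind: B, states: 2, label: "Styloid process syndrome", prior: [0.99, 0.01]}
  - {id: B15, kind: B, states: 2, label: "Infectious mononucleosis", prior: [0.99, 0.01]}
  - {id: B16, kind: B, states: 2, label: "Throat ulcers", prior: [0.99, 0.01]}
  - {id: B17, kind: B, states: 2, label: "Closed laryngeal trauma", prior: [0.99, 0.01]}
  - {id: B18, kind: B, states: 2, label: "Carcinoma of hypopharynx", prior: [0.99, 0.01]}
  - {id: B19, kind: B, states: 2, label: "Peritonsillitis", prior: [0.99, 0.01]}
  - {id: B20, kind: B, states: 2, label: "Laryngeal tuberculosis", prior: [0.99, 0.01]}
  - {id: B22, kind: B, states: 2, label: "Tonsil lymphoma", prior: [0.99, 0.01]}
  - {id: B23, kind: B, states: 2, label: "Laryngopharyngeal reflux", prior: [0.99, 0.01]}
  - {id: B24, kind: B, states: 2, label: "Laryngeal syphilis", prior: [0.99, 0.01]}
  - {id: B25, kind: B, states: 2, label: "Pharyngeal syphilis", prior: [0.99, 0.01]}
  - {id: B26, kind: B, states: 2, label: "Pharyngeal tuberculosis", prior: [0.99, 0.01]}
  - {id: B27, kind: B, states: 2, label: "Upper respiratory tract infection", prior: [0.99, 0.01]}
  - {id: B28, kind: B, states: 2, label: "Coronary heart disease", prior: [0.99, 0.01]}
  - {id: X85, kind: X, states: 2, label: "Sore throat (placeholder manifestation)"}
links:
  - {child: X85, parent: B1, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B2, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B3, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B4, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B5, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B6, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B7, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B8, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B9, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B10, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B11, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B12, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B13, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B14, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B15, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B16, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B17, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B18, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B19, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B20, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B22, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B23, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B24, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B25, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B26, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B27, weight: 1.0, strength: {1: [0.0, 0.5]}}
  - {child: X85, parent: B28, weight: 1.0, strength: {1: [0.0, 0.5]}}
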