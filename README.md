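# ducg — causal knowledge bases and chain-reasoning differential diagnosis

`ducg` implements the Dynamic Uncertain Causality Graph (DUCG) formalism for
computer-aided differential diagnosis of a chief complaint: declarative,
modular disease knowledge bases; risk-factor logic gates that rescale disease
incidence; a four-step chain-reasoning engine that ranks disease hypotheses
with exact posteriors; per-hypothesis graphical explanations; and an accuracy
evaluation harness. It is aimed at clinical decision-support researchers who
need an *interpretable* probabilistic diagnostic engine whose every number
can be traced back along causal paths — unlike CPT-based Bayesian networks,
a DUCG is authored from expert knowledge and epidemiology, not trained.

## The model

A knowledge base is a directed acyclic graph of multi-state variables: `B`
disease roots with prior distributions, `X` manifestations (state 0 = normal),
`SX` gold-standard manifestations, and `D` default causes. Uncertain
causality from parent *i* onto child *n* is a **weighted functional event**

```
F_nk;ij = (r_i / r_n) · A_nk;ij ,   r_n = Σ_i r_i ,
```

where the virtual causation event `A_nk;ij` fires with probability `a[k][j]`
(parent state *j* independently causes child state *k*) and the weights `r`
normalise the influence of multiple parents. Given its parents, a child takes
abnormal state *k* with probability `Σ_i (r_i/r_n)·a[k][j_i]` and the normal
state with the residual mass.

Risk factors act on incidence, not through causal links: a logic gate `SG`
maps risk-factor state combinations to gate states via an ordered
specification table (first match wins, with a remnant default row), and an
`SA` factor vector rescales the disease prior per gate state into the
conditional root `BX`. Example: a base incidence of 0.03 with risk-factor
multiplier 10 gives `Pr{BX=1} = 10 × 0.03 = 0.3`.

Inference runs in four steps: **simplify** (prune variables and diseases
irrelevant under the evidence `E = E′E″`), **decompose** (single-fault
hypothesis views, one per abnormal state of each surviving disease),
**expand** (evidence events unwind backwards into sums of products over root
events and functional events — see `ducg.expansion`), and **calculate**:

```
ζ_kj = Pr{H_kj · E},     h_kj = ζ_kj / Σ ζ     (ranked descending)
```

Abnormal evidence with no causal path from a hypothesis is *isolated* and
multiplies that hypothesis's ζ by a small default-cause leak (default 0.01);
normal evidence on linked manifestations acts as negative evidence through
residual normal-state mass. A brute-force enumeration oracle
(`ducg.oracle`) recomputes every ζ on small graphs and the test suite holds
the engine to agreement within 1e-9.

## Worked example

The packaged three-disease knowledge base (chronic laryngitis B11, chronic
pharyngitis B12, laryngopharyngeal reflux B23, priors 0.04 / 0.09 / 0.03)
diagnoses a patient with hoarseness, foreign-body sensation, itching, throat
clearing and sore throat, with cough observed normal:

```python
from ducg import fixtures, diagnose, Evidence

kb = fixtures.three_disease_kb()
case = Evidence.from_mapping(
    {"X85": 1, "X21": 1, "X45": 1, "X44": 1, "X150": 1,
     "X5": 1, "X52": 1, "X51": 0, "X22": 0, "X23": 0}
)
for entry in diagnose(kb, case).entries:
    print(entry.hypothesis, f"{entry.posterior:.2%}")
```

or equivalently `ducg diagnose kb3.yaml case.yaml --explain text`, which
prints:

```
B23,1  posterior=92.9099%  zeta=3.09684e-10
B11,1  posterior=4.6802%  zeta=1.56e-11
B12,1  posterior=2.4099%  zeta=8.0325e-12
hypothesis: B23,1
explained abnormal evidence:
  X21 = 1
  X45 = 1
  X85 = 1
  X150 = 1
isolated abnormal evidence:
  X5 = 1
  X44 = 1
  X52 = 1
...
```

Reflux ranks first because it explains throat clearing (X150), which the
other two diseases would have to write off as isolated evidence; throat
itching (X44) is in turn isolated for reflux. The ζ values are joint
probabilities `Pr{hypothesis ∧ evidence}`; the posteriors normalise them.
`ducg suggest` then ranks the unobserved manifestations by one-step expected
entropy reduction — here it proposes the reflux gold standard first:

```
SX160  gain=0.137839  Proton pump inhibitors are effective
X158   gain=0.098724  Pharyngeal pH monitoring positive
X153   gain=0.005037  Vocal cord edema
```

Other commands: `ducg validate` (CI-friendly, exit code 2 on errors),
`ducg verify` (engine vs brute-force oracle), `ducg simulate` (sample
labelled cases from the generative semantics) and `ducg evaluate` (top-1
accuracy tables over labelled case files).

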