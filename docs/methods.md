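# Methods

## Model

A DUCG knowledge base is a DAG of multi-state variables; state 0 always
denotes the normal/negative state. Disease roots (`B`) carry prior
distributions summing to 1 (tolerance 1e-12). A causal link stores a
per-parent intensity `r_i > 0` and a strength matrix `a[k][j] ∈ [0, 1]` over
(child state `k ≥ 1`, parent state `j`); the row for the child's normal
state is implied residual mass and must be zero, and the column for a normal
parent state defaults to zero (normal states cause nothing unless a strength
is explicitly authored). Two soundness constraints are validated: per parent
state, `Σ_{k≥1} a[k][j] ≤ 1` (the causation draw is a categorical), and for
every joint parent-state combination the weighted abnormal mass
`Σ_{k≥1} Σ_i (r_i/r)·a[k][j_i] ≤ 1` (checked exhaustively up to 4096
combinations per child, by seeded sampling beyond that).

Generative semantics: each child draws its cause from one parent with
probability `r_i / r` (`r` summed over the parents present in the graph at
hand, so pruning a parent automatically renormalises the weights), and given
the selected parent's state `j` takes abnormal state `k` with probability
`a[k][j]`, normal with the residual. Marginally this yields
`Pr{X = k | parents} = Σ_i (r_i/r)·a[k][j_i]`, which is what the evaluator
uses directly.

Risk factors feed an ordered logic-gate specification table (boolean
expressions over variable-state literals; first matching row wins, a single
remnant row otherwise; unobserved risk factors default to state 0). The SA
factor vector rescales each abnormal prior mass by the factor of the
realised gate state; the remnant factor is forced to 1. The rescaled mass is
clipped so the total abnormal mass never exceeds 1 (multi-state priors are
renormalised only when the total overflows); the normal state takes the
residual. With all factors 1 the rescaled prior equals the raw prior
exactly.

## Single-fault worlds and ζ

Diseases are treated as mutually exclusive single-fault worlds: the
hypothesis space is {disease k in abnormal state j} ∪ {all normal}, and

ζ_kj = Pr{H_kj} · Pr{E | root k = j, every other disease root = 0} · leak^m

with no cross-disease prior factors. Two consequences motivate this choice:
with empty evidence the posteriors equal the normalised (risk-adjusted)
priors exactly, and summing ζ over all hypotheses plus the all-normal world
(weighted `1 − Σ` prior mass) obeys the law of total probability — both are
enforced by tests. `Pr{E | ·}` is computed exactly by marginalising hidden
ancestor variables and D-type defaults through enumeration over the pruned
evidence-relevant subgraph; `m` counts isolated abnormal observations
(no causal path from the hypothesis root or any D-type default), each
contributing the default-cause leak factor (default 0.01, configurable).
Exogenous context variables — observed variables with no causal parents,
typically risk factors — contribute factor 1 when normal; when abnormal they
are isolated for every hypothesis that cannot reach them, so their leak
factors cancel in the posterior and their real effect flows through the
gate/SA prior rescaling.

Posteriors are `h = ζ / Σζ`, ranked descending with ties broken by ascending
variable index then state; an all-zero ζ vector yields an empty, flagged
ranking. A gold-standard (`SX`) manifestation observed abnormal flags every
hypothesis that can causally reach it, but never overrides the posterior —
the ranking stays probabilistic even with gold-standard evidence.

## Simplification rules

R1 iteratively removes unobserved manifestations with no observed descendant
(descendants computed over causal links plus gate wiring, so risk factors
survive while their disease does) and inert `C`-type classifiers. R2 removes
disease roots with no directed path to any abnormal evidence, together with
their BX/SG/SA machinery; gate tables survive with their gate variable even
when unobserved risk factors were pruned, since expressions evaluate missing
parents as state 0. R3 records deterministic contradictions — a strength-1
link into a child observed in a different state excludes the parent state —
and is deliberately restricted to sole-parent links, because under the
weighted-mixture semantics a diluted (`r_i/r < 1`) deterministic link does
not force the child's state; in that restricted form the structural shortcut
provably agrees with the exact ζ computation. R1/R2 never change any ζ
(barren-node and irrelevant-root removal are exact marginalisations); both
are applied to fixpoint.

## Symbolic expansion

`ducg.expansion` implements the backward sum-of-products expansion with
three atom types (root events, rational-weighted parent selectors, causation
events) and exactly three exclusion rules: one state per root variable, one
selector per child, one outcome per (child, parent, parent-state) causation
draw, plus idempotent absorption of repeated atoms. Normal-state events
expand as one minus the abnormal expansions, producing signed terms whose
cancellations *require* that no stronger state-consistency rule be imposed.
The test suite checks idempotence (`S·S = S`), exclusivity
(`S_k · S_{k≠k'} = 0`), and numeric agreement of the symbolic route with
both the generative evaluator and the brute-force oracle to 1e-9. The
production ζ path is the generative evaluator; the expansion also backs the
explanation module's term-level reporting.

## Oracle

The oracle enumerates, in topological order, every root state, every
per-child parent selection, and every causation outcome, with no
factorisation shortcuts, refusing (never truncating) beyond a configurable
cap of 20 atomic events (root states + nonzero strength entries). It shares
only the leak *convention* with the engine, not code paths, and is invariant
to variable declaration order.

## Suggestion of further consultations

The next-question mechanism is one-step value of information: each
unobserved manifestation is scored by the expected reduction in posterior
Shannon entropy over its outcome states, with outcome probabilities taken
from the current single-fault mixture (each outcome re-runs the full
pipeline, so pruning stays consistent). Ties break by ascending variable
index; suggestions stop when fewer than two hypotheses remain plausible or
one exceeds the confirmation threshold (default 0.99). The choice of
criterion is this package's own; any admissible scoring of consultations
would slot in at the same interface.

## Fixtures and the synthetic-data generator

The packaged laryngopharyngeal-reflux module carries the published base
incidence 0.03, gate trigger (reflux-esophagitis history present) and SA
multiplier 10; the three-disease toy KB carries the published priors
0.04 / 0.09 / 0.03 and the shared-symptom structure of the worked case; the
27-disease skeleton reproduces the published disease roster and indices
(which reach B28 with no B21). Per-link causal strengths for these fixtures
are **synthetic**: the source model's strength parameters are not published,
so values were chosen once as clinically plausible sensitivities
(0.3–0.9), committed, and never regenerated — golden tests depend on them.
Consequently the packaged fixtures reproduce the published *arithmetic*
(prior rescaling, accuracy formula, roster) but not the published case
posteriors, which depend on the unpublished 354-variable parameterisation.

`random_kb` builds one sub-DUCG per disease and merges them: binary
variables, priors ~ U(0.01, 0.1), weights ~ U(0.5, 2), strengths drawn from
a configurable range, optional hidden chain variables to exercise
marginalisation. `sample_cases` draws the fault proportionally to abnormal
prior mass and simulates top-down through the selector/causation semantics.
What passing tests show is therefore *self-consistency* — the engine
recovers the generating fault from its own generative model — and numeric
correctness against enumeration; they do not show clinical accuracy on real
cases, which would require the full expert-authored knowledge base. Problem
sizes used by the verification battery: 100 random KBs of ≤ 12 atomic
events (2 diseases, hidden chain, partial observation) for oracle
equivalence, and one 6-disease informative KB (three unique strong
manifestations per disease, strengths 0.8–0.95) with 500 fully observed
sampled cases for the ≥ 90% top-1 self-consistency criterion.

## Numerical choices and limitations

Probability comparisons use absolute tolerance 1e-9; priors must sum to 1
within 1e-12; residual masses are clamped at 0 against float underflow.
Hidden-state marginalisation is exponential in the number of unobserved
ancestors of the evidence — acceptable for authored clinical KBs where
evidence chains are shallow, but not a scalable exact-inference engine.
Causal loops, continuous/fuzzy evidence, RG-type recursion gates (rejected
at load time) and multi-fault joint hypotheses are out of scope; sequential
consultation is handled by re-running diagnosis with accumulated evidence.
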