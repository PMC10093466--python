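"""Chain-reasoning inference for DUCG knowledge bases.

The algorithm runs in four steps:

1. **Simplification** — prune variables and causalities that are irrelevant
   under the current evidence ``E = E' E''`` (abnormal and normal partitions).
2. **Decomposition** — under the single-fault assumption, split the
   simplified graph into per-hypothesis views in which exactly one disease
   root is abnormal and every other disease root is fixed to state 0.
3. **Expansion** — evidence events expand backwards along the causal chains
   into sums of products over root events and weighted functional events
   (see :mod:`ducg.expansion`).
4. **Probability calculation** — the joint ``zeta = Pr{H, E}`` per
   hypothesis, normalised into posteriors ``h = zeta / sum(zeta)`` and ranked.

The numeric path used by :func:`evaluate` computes ``zeta`` directly under
the generative semantics implied by the weighted functional events: given
its parents' states ``j_i``, a child takes abnormal state ``k`` with
probability ``sum_i (r_i / r) a_i[k][j_i]`` and the normal state with the
residual mass.  Diseases are treated as mutually exclusive single-fault
worlds, so ``zeta = Pr{H} * Pr{E | only H abnormal}`` with no cross-disease
prior factors; abnormal evidence with no causal path from the hypothesis
(isolated evidence) contributes a small default-cause leak factor instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from . import kb_model as km
from .kb_model import (
    CausalLink,
    CompleteDUCG,
    KnowledgeBase,
    Variable,
    causal_digraph,
    compute_bx_prior,
    effective_root,
    sa_for_disease,
    var_index,
)

__all__ = [
    "Evidence",
    "EvidenceError",
    "Hypothesis",
    "DiagnosisConfig",
    "SimplifiedDUCG",
    "DecomposedView",
    "DiagnosisEntry",
    "DiagnosisResult",
    "simplify",
    "decompose",
    "evaluate",
    "posterior",
    "diagnose",
    "suggest_next",
]


class EvidenceError(km.KBError):
    """Evidence refers to unknown, unobservable, or out-of-range states."""


@dataclass(frozen=True)
class Evidence:
    """A patient case: mapping of observed variable id to state index.

    ``abnormal`` (E', states != 0) and ``normal`` (E'', state 0) partitions
    are derived views.
    """

    observations: tuple[tuple[str, int], ...]

    @classmethod
    def from_mapping(cls, obs: Mapping[str, int]) -> "Evidence":
        items = tuple(sorted(((str(v), int(s)) for v, s in obs.items()),
                             key=lambda it: (var_index(it[0]), it[0])))
        return cls(observations=items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.observations)

    @property
    def abnormal(self) -> dict[str, int]:
        return {v: s for v, s in self.observations if s != 0}

    @property
    def normal(self) -> dict[str, int]:
        return {v: s for v, s in self.observations if s == 0}

    def with_observation(self, var: str, state: int) -> "Evidence":
        obs = self.as_dict()
        obs[var] = state
        return Evidence.from_mapping(obs)

    def __len__(self) -> int:
        return len(self.observations)


def validate_evidence(kb: KnowledgeBase, ev: Evidence) -> None:
    for var, state in ev.observations:
        v = kb.variables.get(var)
        if v is None:
            raise EvidenceError(f"evidence names unknown variable {var}")
        if v.kind not in km.OBSERVABLE_KINDS:
            raise EvidenceError(
                f"{var} is {v.kind}-type and not directly observable"
            )
        if not 0 <= state < v.n_states:
            raise EvidenceError(
                f"{var}: observed state {state} out of range 0..{v.n_states - 1}"
            )


@dataclass(frozen=True, order=True)
class Hypothesis:
    """A candidate root cause: one disease in one abnormal state."""

    disease: str
    state: int

    @property
    def sort_key(self) -> tuple[int, int]:
        return (var_index(self.disease), self.state)

    def __str__(self) -> str:
        return f"{self.disease},{self.state}"


@dataclass(frozen=True)
class DiagnosisConfig:
    """Tunables of the reasoning engine.

    ``leak`` is the default-cause probability credited to isolated abnormal
    evidence; ``confirmation_threshold`` stops further-question suggestions
    once one hypothesis is effectively confirmed; ``path_cap`` bounds the
    causal paths enumerated per explained evidence item.
    """

    leak: float = 0.01
    confirmation_threshold: float = 0.99
    top_k: int | None = None
    path_cap: int = 10


# ---------------------------------------------------------------------------
# Step 1: simplification
# ---------------------------------------------------------------------------

@dataclass
class SimplifiedDUCG:
    """Evidence-reduced knowledge base plus bookkeeping from pruning."""

    kb: CompleteDUCG
    excluded_root_states: frozenset[tuple[str, int]] = frozenset()
    no_abnormal_evidence: bool = False
    removed: tuple[str, ...] = ()


def _restrict(kb: CompleteDUCG, keep: set[str]) -> CompleteDUCG:
    return CompleteDUCG(
        name=kb.name,
        variables={vid: v for vid, v in kb.variables.items() if vid in keep},
        links=tuple(l for l in kb.links if l.child in keep and l.parent in keep),
        # gate tables survive with their gate variable even when unobserved
        # risk factors were pruned: expressions treat missing parents as 0
        gates={gid: g for gid, g in kb.gates.items() if gid in keep},
        sa_factors=tuple(
            sa
            for sa in kb.sa_factors
            if sa.disease in keep and sa.bx in keep and sa.gate in keep
        ),
        provenance={vid: src for vid, src in kb.provenance.items() if vid in keep},
    )


def simplify(kb: CompleteDUCG, ev: Evidence) -> SimplifiedDUCG:
    """Remove variables and causalities unrelated to the current evidence.

    R1 drops unobserved manifestation variables with no observed descendant
    (and inert C-type classifiers).  R2 drops disease roots with no directed
    path to any abnormal evidence, together with their BX/SG/SA machinery.
    R3 records deterministic contradictions: a sole-parent link with strength
    1 into a child observed in a different state rules out that parent state
    (for a root parent this removes the hypothesis state).  Weight ratios are
    implicitly renormalised because ``r`` is always summed over surviving
    parents.
    """
    validate_evidence(kb, ev)
    observed = set(ev.as_dict())
    abnormal = set(ev.abnormal)
    keep = set(kb.variables)

    changed = True
    while changed:
        changed = False
        sub = _restrict(kb, keep)
        g = km.structural_digraph(sub)
        # R1: barren manifestations and inert classifiers.
        for vid in list(keep):
            v = kb.variables[vid]
            if v.kind == "C":
                keep.discard(vid)
                changed = True
                continue
            if v.kind in km.OBSERVABLE_KINDS and vid not in observed:
                if not (nx.descendants(g, vid) & observed):
                    keep.discard(vid)
                    changed = True
        if changed:
            continue
        # R2: diseases that explain no abnormal evidence.
        if abnormal:
            for d in sub.disease_roots():
                root = effective_root(sub, d)
                reach = nx.descendants(g, root) | {root}
                if not (reach & abnormal):
                    sa = sa_for_disease(sub, d)
                    keep.discard(d)
                    if sa is not None:
                        keep.discard(sa.bx)
                        keep.discard(sa.gate)
                    changed = True

    reduced = _restrict(kb, keep)

    # R3: deterministic contradictions from strength-1 sole-parent links.
    excluded: set[tuple[str, int]] = set()
    bx_to_disease = {sa.bx: sa.disease for sa in reduced.sa_factors}
    for var, state in ev.observations:
        links = km.parents_of(reduced, var)
        if len(links) != 1:
            continue
        l = links[0]
        for j in range(1, l.n_parent_states):
            for k in range(1, l.n_child_states):
                if l.a(k, j) == 1.0 and state != k:
                    pv = reduced.variables[l.parent]
                    if pv.kind in ("B", "BX"):
                        disease = bx_to_disease.get(l.parent, l.parent)
                        excluded.add((disease, j))

    return SimplifiedDUCG(
        kb=reduced,
        excluded_root_states=frozenset(excluded),
        no_abnormal_evidence=not abnormal,
        removed=tuple(sorted(set(kb.variables) - keep)),
    )


# ---------------------------------------------------------------------------
# Step 2: decomposition
# ---------------------------------------------------------------------------

@dataclass
class DecomposedView:
    """A single-hypothesis view of the simplified graph.

    ``root`` is the causal root carrying the disease's links (its BX if a
    risk-factor triple exists); ``prior`` is the risk-adjusted prior vector;
    every other disease's effective root in ``fixed_roots`` is held at 0.
    """

    hypothesis: Hypothesis
    kb: CompleteDUCG
    root: str
    prior: np.ndarray
    fixed_roots: dict[str, int]

    def causal_graph(self) -> nx.DiGraph:
        return causal_digraph(self.kb)


def decompose(simplified: SimplifiedDUCG, ev: Evidence) -> list[DecomposedView]:
    """One view per abnormal state of each surviving disease root."""
    kb = simplified.kb
    views: list[DecomposedView] = []
    diseases = sorted(kb.disease_roots(), key=var_index)
    for d in diseases:
        prior = compute_bx_prior(kb, d, ev.as_dict())
        root = effective_root(kb, d)
        others = {
            effective_root(kb, o): 0 for o in diseases if o != d
        }
        n_states = kb.variables[d].n_states
        for state in range(1, n_states):
            if (d, state) in simplified.excluded_root_states:
                continue
            views.append(
                DecomposedView(
                    hypothesis=Hypothesis(disease=d, state=state),
                    kb=kb,
                    root=root,
                    prior=prior,
                    fixed_roots=dict(others),
                )
            )
    views.sort(key=lambda v: v.hypothesis.sort_key)
    return views


# ---------------------------------------------------------------------------
# Step 4: probability calculation
# ---------------------------------------------------------------------------

def child_state_probability(
    links: Sequence[CausalLink], state: int, parent_states: Mapping[str, int]
) -> float:
    """``Pr{child = state | parents}`` under the weighted-mixture semantics."""
    r_total = sum(l.weight_r for l in links)
    if state >= 1:
        return sum(
            (l.weight_r / r_total) * l.a(state, parent_states[l.parent]) for l in links
        )
    abnormal = sum(
        (l.weight_r / r_total) * l.a(k, parent_states[l.parent])
        for l in links
        for k in range(1, l.n_child_states)
    )
    return max(0.0, 1.0 - abnormal)


def reachable_from_causes(view: DecomposedView) -> set[str]:
    """Variables causally reachable from the hypothesis root or any default
    (D-type) cause present in the view."""
    g = view.causal_graph()
    sources = [view.root] + [
        v.id for v in view.kb.variables.values() if v.kind == "D"
    ]
    out: set[str] = set()
    for s in sources:
        if s in g:
            out |= nx.descendants(g, s) | {s}
    return out


def isolated_evidence(view: DecomposedView, ev: Evidence) -> list[str]:
    reach = reachable_from_causes(view)
    return [v for v in ev.abnormal if v not in reach]


def evaluate(
    view: DecomposedView, ev: Evidence, leak: float = 0.01
) -> float:
    """Joint probability ``zeta = Pr{H, E}`` on one decomposed view.

    Exact under the generative semantics: the hypothesis prior mass, times
    the probability of all observations given the single fault (hidden
    ancestor states and D-type defaults marginalised by enumeration), times
    ``leak`` per isolated abnormal observation.
    """
    if not 0.0 <= leak < 1.0:
        raise ValueError("leak must lie in [0, 1)")
    kb = view.kb
    prior_mass = float(view.prior[view.hypothesis.state])
    if prior_mass == 0.0:
        return 0.0

    isolated = set(isolated_evidence(view, ev))
    factor = prior_mass * (leak ** len(isolated))
    if factor == 0.0:
        return 0.0

    obs = {v: s for v, s in ev.observations if v not in isolated}
    g = view.causal_graph()
    needed: set[str] = set()
    for v in obs:
        if v in g:
            needed |= nx.ancestors(g, v) | {v}

    fixed: dict[str, int] = {view.root: view.hypothesis.state}
    fixed.update(view.fixed_roots)
    for vid in needed:
        var = kb.variables[vid]
        if vid in obs:
            fixed.setdefault(vid, obs[vid])
        elif var.kind != "D" and g.in_degree(vid) == 0:
            fixed.setdefault(vid, 0)  # exogenous, unobserved: assumed normal

    hidden = sorted(
        (v for v in needed if v not in fixed),
        key=var_index,
    )
    links_by_child = {
        v: km.parents_of(kb, v) for v in needed if g.in_degree(v) > 0
    }

    order = [v for v in nx.topological_sort(g) if v in needed]

    def local_prob(vid: str, assignment: dict[str, int]) -> float:
        var = kb.variables[vid]
        state = assignment[vid]
        if vid == view.root or vid in view.fixed_roots:
            return 1.0  # conditioned by the single-fault world
        links = links_by_child.get(vid)
        if links:
            parent_states = {
                l.parent: assignment.get(l.parent, fixed.get(l.parent, 0))
                for l in links
            }
            return child_state_probability(links, state, parent_states)
        if var.kind == "D":
            return var.prior[state] if var.prior else (1.0 if state == 0 else 0.0)
        return 1.0 if state == 0 else 0.0  # exogenous context variable

    def recurse(idx: int, assignment: dict[str, int], acc: float) -> float:
        if acc == 0.0:
            return 0.0
        if idx == len(order):
            return acc
        vid = order[idx]
        if vid in fixed:
            assignment[vid] = fixed[vid]
            val = recurse(idx + 1, assignment, acc * local_prob(vid, assignment))
            del assignment[vid]
            return val
        total = 0.0
        for s in range(kb.variables[vid].n_states):
            assignment[vid] = s
            total += recurse(idx + 1, assignment, acc * local_prob(vid, assignment))
            del assignment[vid]
        return total

    return factor * recurse(0, {}, 1.0)


@dataclass
class DiagnosisEntry:
    hypothesis: Hypothesis
    zeta: float
    posterior: float
    gold_standard: bool = False
    interpretation: object | None = None


@dataclass
class DiagnosisResult:
    """Ranked hypotheses with joint probabilities and posteriors."""

    entries: list[DiagnosisEntry]
    flags: tuple[str, ...] = ()
    evidence: Evidence | None = None
    simplified: SimplifiedDUCG | None = None

    def top(self, k: int | None = None) -> list[DiagnosisEntry]:
        return self.entries[: k or len(self.entries)]

    @property
    def best(self) -> DiagnosisEntry | None:
        return self.entries[0] if self.entries else None

    def to_dict(self) -> dict:
        return {
            "flags": list(self.flags),
            "ranking": [
                {
                    "disease": e.hypothesis.disease,
                    "state": e.hypothesis.state,
                    "zeta": e.zeta,
                    "posterior": e.posterior,
                    "gold_standard": e.gold_standard,
                }
                for e in self.entries
            ],
        }


def posterior(zetas: Mapping[Hypothesis, float]) -> DiagnosisResult:
    """Normalise joint probabilities into ranked posteriors (descending,
    ties broken by ascending variable index then state)."""
    if not zetas:
        raise ValueError("posterior requires at least one hypothesis")
    for h, z in zetas.items():
        if z < 0:
            raise ValueError(f"negative zeta for {h}: {z}")
    total = sum(zetas.values())
    if total == 0.0:
        return DiagnosisResult(entries=[], flags=("no-hypothesis-explains-evidence",))
    entries = [
        DiagnosisEntry(hypothesis=h, zeta=z, posterior=z / total)
        for h, z in zetas.items()
    ]
    entries.sort(key=lambda e: (-e.posterior, e.hypothesis.sort_key))
    return DiagnosisResult(entries=entries)


def diagnose(
    kb: CompleteDUCG,
    ev: Evidence,
    config: DiagnosisConfig | None = None,
) -> DiagnosisResult:
    """Run the four inference steps and attach explanation payloads."""
    from . import explanation  # local import: explanation builds on this module

    config = config or DiagnosisConfig()
    simplified = simplify(kb, ev)
    views = decompose(simplified, ev)
    if not views:
        return DiagnosisResult(
            entries=[],
            flags=("no-surviving-hypotheses",),
            evidence=ev,
            simplified=simplified,
        )
    zetas = {v.hypothesis: evaluate(v, ev, leak=config.leak) for v in views}
    result = posterior(zetas)
    result.evidence = ev
    result.simplified = simplified

    view_by_h = {v.hypothesis: v for v in views}
    gold_vars = {
        v
        for v, s in ev.abnormal.items()
        if kb.variables[v].kind == "SX"
    }
    for entry in result.entries:
        view = view_by_h[entry.hypothesis]
        entry.interpretation = explanation.interpret(
            view, ev, path_cap=config.path_cap
        )
        if gold_vars:
            g = view.causal_graph()
            reach = nx.descendants(g, view.root) if view.root in g else set()
            if gold_vars & reach:
                entry.gold_standard = True
    if any(e.gold_standard for e in result.entries):
        result.flags = result.flags + ("gold-standard-confirmed",)
    if simplified.no_abnormal_evidence:
        result.flags = result.flags + ("no-abnormal-evidence",)
    if config.top_k is not None:
        result.entries = result.entries[: config.top_k]
    return result


# ---------------------------------------------------------------------------
# Next-question suggestion (one-step value of information)
# ---------------------------------------------------------------------------

def _entropy(ps: Iterable[float]) -> float:
    return -sum(p * math.log(p) for p in ps if p > 0.0)


def _zeta_map(
    kb: CompleteDUCG, ev: Evidence, config: DiagnosisConfig
) -> dict[Hypothesis, float]:
    simplified = simplify(kb, ev)
    views = decompose(simplified, ev)
    return {v.hypothesis: evaluate(v, ev, leak=config.leak) for v in views}


def suggest_next(
    kb: CompleteDUCG,
    ev: Evidence,
    current: DiagnosisResult | None = None,
    top_m: int = 5,
    config: DiagnosisConfig | None = None,
) -> list[tuple[str, float]]:
    """Rank unobserved manifestations by one-step expected reduction in
    posterior entropy (value of information under the current posterior
    mixture).  Returns an empty list when fewer than two hypotheses remain
    plausible or one hypothesis exceeds the confirmation threshold.
    """
    config = config or DiagnosisConfig()
    if current is None:
        current = diagnose(kb, ev, config)
    nonzero = [e for e in current.entries if e.posterior > 0.0]
    if len(nonzero) < 2:
        return []
    if max(e.posterior for e in nonzero) >= config.confirmation_threshold:
        return []
    h_current = _entropy(e.posterior for e in nonzero)

    observed = set(ev.as_dict())
    has_parents = {l.child for l in kb.links}
    candidates = sorted(
        (
            v.id
            for v in kb.variables.values()
            if v.kind in km.OBSERVABLE_KINDS
            and v.id not in observed
            and v.id in has_parents
        ),
        key=var_index,
    )

    scores: list[tuple[str, float]] = []
    for cand in candidates:
        n_states = kb.variables[cand].n_states
        outcome_mass: list[float] = []
        outcome_entropy: list[float] = []
        for s in range(n_states):
            zetas = _zeta_map(kb, ev.with_observation(cand, s), config)
            total = sum(zetas.values())
            outcome_mass.append(total)
            if total > 0:
                outcome_entropy.append(_entropy(z / total for z in zetas.values()))
            else:
                outcome_entropy.append(0.0)
        mass = sum(outcome_mass)
        if mass == 0.0:
            continue
        expected = sum(
            (m / mass) * h for m, h in zip(outcome_mass, outcome_entropy)
        )
        scores.append((cand, h_current - expected))
    scores.sort(key=lambda it: (-round(it[1], 12), var_index(it[0])))
    return scores[:top_m]
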