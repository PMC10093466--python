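"""Packaged knowledge bases and seeded generators.

Ships three authored fixtures — the laryngopharyngeal-reflux sub-DUCG, a
three-disease toy knowledge base (chronic laryngitis / chronic pharyngitis /
LPR with priors 0.04 / 0.09 / 0.03), and the 27-disease structural skeleton
— plus reproducible random KB and case generators used for engine-vs-oracle
verification and self-consistency accuracy simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import kb_model as km
from .inference import Evidence
from .kb_model import (
    CausalLink,
    CompleteDUCG,
    SubDUCG,
    Variable,
    load_kb,
    load_subducg,
    merge_subgraphs,
    strength_matrix,
)


def _data_path(*parts: str) -> Path:
    return Path(resources.files("ducg").joinpath("data", *parts))  # type: ignore[arg-type]


def lpr_subducg() -> SubDUCG:
    """The laryngopharyngeal reflux disease module (risk-factor gate, SA
    multiplier 10 on the base incidence 0.03, PPI-response gold standard)."""
    return load_subducg(_data_path("lpr.yaml"))


def three_disease_kb() -> CompleteDUCG:
    """Three merged disease modules sharing manifestations; priors are
    0.04 (chronic laryngitis), 0.09 (chronic pharyngitis), 0.03 (LPR)."""
    return load_kb(_data_path("three_disease"))


def sore_throat_skeleton() -> CompleteDUCG:
    """Structure-only skeleton with the full 27-disease roster."""
    return load_kb(_data_path("sore_throat_skeleton.yaml"))


@dataclass(frozen=True)
class FixtureSpec:
    """Size and parameter ranges for a seeded random knowledge base.

    Identical spec (including seed) always regenerates an identical KB.
    ``n_unique`` manifestations per disease are linked to that disease only;
    ``n_shared`` manifestations are linked to each disease independently
    with probability ``link_density``.  ``chain_depth`` inserts that many
    hidden intermediate variables on the first unique manifestation of the
    first disease, exercising marginalisation over unobserved ancestors.
    """

    name: str = "random"
    seed: int = 0
    n_diseases: int = 3
    n_unique: int = 1
    n_shared: int = 2
    link_density: float = 0.6
    chain_depth: int = 0
    prior_range: tuple[float, float] = (0.01, 0.1)
    weight_range: tuple[float, float] = (0.5, 2.0)
    strength_range: tuple[float, float] = (0.3, 0.9)


def small_oracle_spec(seed: int) -> FixtureSpec:
    """A spec whose KBs stay within the brute-force oracle's default cap."""
    return FixtureSpec(
        name=f"oracle-{seed}",
        seed=seed,
        n_diseases=2,
        n_unique=1,
        n_shared=1,
        link_density=1.0,
        chain_depth=1,
    )


def informative_spec(seed: int) -> FixtureSpec:
    """Diseases distinguishable by three strong unique manifestations each;
    the regime in which top-1 self-consistency accuracy should be high."""
    return FixtureSpec(
        name=f"informative-{seed}",
        seed=seed,
        n_diseases=6,
        n_unique=3,
        n_shared=4,
        link_density=0.5,
        strength_range=(0.8, 0.95),
        prior_range=(0.01, 0.05),
    )


def random_kb(spec: FixtureSpec) -> CompleteDUCG:
    """Generate a reproducible random KB by building one sub-DUCG per
    disease and merging them."""
    if spec.n_diseases < 1:
        raise ValueError("n_diseases must be >= 1")
    if spec.n_unique < 0 or spec.n_shared < 0 or spec.chain_depth < 0:
        raise ValueError("size parameters must be non-negative")
    if not 0.0 <= spec.link_density <= 1.0:
        raise ValueError("link_density must lie in [0, 1]")
    if spec.n_unique == 0 and spec.n_shared == 0:
        raise ValueError("each disease needs at least one manifestation")
    rng = np.random.default_rng(spec.seed)

    def draw(lo_hi: tuple[float, float]) -> float:
        return round(float(rng.uniform(*lo_hi)), 6)

    shared_ids = [f"X{200 + j}" for j in range(spec.n_shared)]
    parts: list[SubDUCG] = []
    for i in range(spec.n_diseases):
        did = f"B{i + 1}"
        p1 = draw(spec.prior_range)
        variables: dict[str, Variable] = {
            did: Variable(id=did, kind="B", n_states=2, prior=(1.0 - p1, p1))
        }
        links: list[CausalLink] = []

        def add_link(child: str, parent: str) -> None:
            links.append(
                CausalLink(
                    child=child,
                    parent=parent,
                    weight_r=draw(spec.weight_range),
                    strength=strength_matrix(2, 2, {1: [0.0, draw(spec.strength_range)]}),
                )
            )

        for m in range(spec.n_unique):
            xid = f"X{100 + i * 10 + m}"
            variables[xid] = Variable(id=xid, kind="X", n_states=2)
            source = did
            if i == 0 and m == 0:
                for c in range(spec.chain_depth):
                    mid = f"X{500 + c}"
                    variables[mid] = Variable(id=mid, kind="X", n_states=2)
                    add_link(mid, source)
                    source = mid
            add_link(xid, source)
        for sid in shared_ids:
            if rng.uniform() < spec.link_density:
                variables[sid] = Variable(id=sid, kind="X", n_states=2)
                add_link(sid, did)
        if not links:  # ensure the disease explains something
            sid = shared_ids[0]
            variables[sid] = Variable(id=sid, kind="X", n_states=2)
            add_link(sid, did)
        parts.append(
            SubDUCG(
                name=f"{spec.name}-{did}",
                variables=variables,
                links=tuple(links),
                gates={},
                sa_factors=(),
            )
        )
    return merge_subgraphs(parts)


def sample_cases(
    kb: CompleteDUCG,
    n: int,
    seed: int,
    observe: float = 1.0,
) -> list[tuple[Evidence, str]]:
    """Draw labelled cases from the KB's generative semantics.

    Each case fixes a single disease (drawn proportionally to abnormal prior
    mass) in one abnormal state, samples every consequence variable top-down
    — per child first the parent-selection event by weight, then the
    causation outcome given the selected parent's state — and reports a
    fraction ``observe`` of the manifestations as evidence together with the
    generating disease.
    """
    if not 0.0 < observe <= 1.0:
        raise ValueError("observe must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    diseases = sorted(kb.disease_roots(), key=km.var_index)
    masses = []
    for d in diseases:
        prior = kb.variables[d].prior
        assert prior is not None
        masses.append(sum(prior[1:]))
    weights = np.asarray(masses) / sum(masses)

    g = km.causal_digraph(kb)
    import networkx as nx

    topo = list(nx.topological_sort(g))
    links_by_child: dict[str, list[CausalLink]] = {}
    for l in kb.links:
        links_by_child.setdefault(l.child, []).append(l)
    manifest = sorted(
        (v.id for v in kb.variables.values()
         if v.kind in km.OBSERVABLE_KINDS and v.id in links_by_child),
        key=km.var_index,
    )

    cases: list[tuple[Evidence, str]] = []
    for _ in range(n):
        d = diseases[int(rng.choice(len(diseases), p=weights))]
        prior = kb.variables[d].prior
        assert prior is not None
        abnormal = np.asarray(prior[1:])
        state = 1 + int(rng.choice(len(abnormal), p=abnormal / abnormal.sum()))
        assignment: dict[str, int] = {}
        for dd in diseases:
            assignment[km.effective_root(kb, dd)] = state if dd == d else 0
        for vid in topo:
            if vid in assignment:
                continue
            links = links_by_child.get(vid)
            if not links:
                assignment[vid] = 0
                continue
            r_total = sum(l.weight_r for l in links)
            pick = links[
                int(rng.choice(len(links), p=[l.weight_r / r_total for l in links]))
            ]
            j = assignment[pick.parent]
            probs = [pick.a(k, j) for k in range(1, pick.n_child_states)]
            residual = max(0.0, 1.0 - sum(probs))
            outcome = int(rng.choice(pick.n_child_states, p=[residual] + probs))
            assignment[vid] = outcome
        kept = [v for v in manifest if observe >= 1.0 or rng.uniform() < observe]
        if not kept:
            kept = [manifest[0]]
        cases.append(
            (Evidence.from_mapping({v: assignment[v] for v in kept}), d)
        )
    return cases
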