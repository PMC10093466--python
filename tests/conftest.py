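"""Shared fixtures: packaged knowledge bases and small hand-built graphs."""

from __future__ import annotations

import pytest

from ducg import fixtures as fx
from ducg.kb_model import (
    CausalLink,
    CompleteDUCG,
    SubDUCG,
    Variable,
    assert_valid,
    strength_matrix,
)


def make_kb(
    priors: dict[str, tuple[float, ...]],
    links: list[tuple[str, str, float, float]] | list[tuple[str, str, float, dict]],
    n_states: dict[str, int] | None = None,
    name: str = "hand",
) -> CompleteDUCG:
    """Build a tiny KB from shorthand.

    ``priors`` maps root ids to prior vectors; ``links`` are
    ``(child, parent, weight, a)`` where ``a`` is either the single strength
    a[1][1] of a binary/binary link or a sparse ``{child_state: row}`` dict.
    """
    n_states = n_states or {}
    variables: dict[str, Variable] = {}
    for vid, prior in priors.items():
        kind = "D" if vid.startswith("D") else "B"
        variables[vid] = Variable(
            id=vid, kind=kind, n_states=len(prior), prior=tuple(prior)
        )
    built: list[CausalLink] = []
    for child, parent, weight, a in links:
        for vid in (child, parent):
            if vid not in variables:
                kind = "SX" if vid.startswith("SX") else "X"
                variables[vid] = Variable(
                    id=vid, kind=kind, n_states=n_states.get(vid, 2)
                )
    for child, parent, weight, a in links:
        nc = variables[child].n_states
        np_ = variables[parent].n_states
        rows = a if isinstance(a, dict) else {1: [0.0] * (np_ - 1) + [float(a)]}
        built.append(
            CausalLink(
                child=child,
                parent=parent,
                weight_r=weight,
                strength=strength_matrix(nc, np_, rows),
            )
        )
    kb = CompleteDUCG(
        name=name,
        variables=variables,
        links=tuple(built),
        gates={},
        sa_factors=(),
        provenance={vid: (name,) for vid in variables},
    )
    assert_valid(kb)
    return kb


@pytest.fixture(scope="session")
def lpr():
    return fx.lpr_subducg()


@pytest.fixture(scope="session")
def lpr_kb():
    from ducg.kb_model import merge_subgraphs

    return merge_subgraphs([fx.lpr_subducg()])


@pytest.fixture(scope="session")
def kb3():
    return fx.three_disease_kb()


@pytest.fixture(scope="session")
def skeleton():
    return fx.sore_throat_skeleton()


@pytest.fixture
def single_link_kb():
    """One disease (p=0.1) causing one manifestation with strength 0.8."""
    return make_kb({"B1": (0.9, 0.1)}, [("X2", "B1", 1.0, 0.8)])


@pytest.fixture
def chain_kb():
    """Deterministic-topology chain B1 -> X2 -> X3 with unit weights."""
    return make_kb(
        {"B1": (0.9, 0.1)},
        [("X2", "B1", 1.0, 0.7), ("X3", "X2", 1.0, 0.6)],
    )


@pytest.fixture
def two_parent_kb():
    """X3 caused by B1 (r=3) and B2 (r=1); carries weight ratios 3/4, 1/4."""
    return make_kb(
        {"B1": (0.9, 0.1), "B2": (0.8, 0.2)},
        [("X3", "B1", 3.0, 0.8), ("X3", "B2", 1.0, 0.5)],
    )
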