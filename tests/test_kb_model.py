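"""Knowledge-base types, validation, merging, risk-factor rescaling, I/O."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_kb
from ducg import fixtures as fx
from ducg.inference import child_state_probability
from ducg.kb_model import (
    CausalLink,
    KBParseError,
    KBValidationError,
    MergeConflictError,
    SubDUCG,
    Variable,
    compute_bx_prior,
    kb_to_dict,
    load_kb,
    load_subducg,
    merge_subgraphs,
    save_kb,
    strength_matrix,
    subducg_from_dict,
    validate_kb,
)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def test_lpr_fixture_loads_with_published_prior(lpr):
    assert lpr.variables["B23"].prior == (0.97, 0.03)
    assert [f for f in validate_kb(lpr) if f.level == "error"] == []


def test_empty_kb_rejected(tmp_path):
    p = tmp_path / "empty.yaml"
    p.write_text("name: empty\nvariables: []\n")
    with pytest.raises(KBValidationError, match="disease"):
        load_subducg(p)


def test_dangling_link_rejected(tmp_path):
    p = tmp_path / "dangle.yaml"
    p.write_text(
        "name: dangle\n"
        "variables:\n"
        "  - {id: B1, kind: B, states: 2, prior: [0.9, 0.1]}\n"
        "links:\n"
        "  - {child: X999, parent: B1, weight: 1.0, strength: {1: [0.0, 0.5]}}\n"
    )
    with pytest.raises(KBParseError, match="X999"):
        load_subducg(p)


def test_rg_type_flagged_at_load():
    doc = {
        "name": "rg",
        "variables": [
            {"id": "B1", "kind": "B", "states": 2, "prior": [0.9, 0.1]},
            {"id": "RG2", "states": 2},
        ],
    }
    with pytest.raises(KBParseError, match="RG"):
        subducg_from_dict(doc)


def test_malformed_prior_reports_field(tmp_path):
    p = tmp_path / "bad.yaml"
    p.write_text(
        "variables:\n  - {id: B1, kind: B, states: 2, prior: oops}\n"
    )
    with pytest.raises(KBParseError, match="prior"):
        load_subducg(p)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def test_strength_above_one_is_overflow_error():
    kb = make_kb({"B1": (0.9, 0.1)}, [])
    bad = kb_to_dict(kb)
    bad["variables"].append({"id": "X2", "kind": "X", "states": 2})
    bad["links"] = [
        {"child": "X2", "parent": "B1", "weight": 1.0, "strength": {1: [0.0, 1.2]}}
    ]
    sub = subducg_from_dict(bad)
    codes = {f.code for f in validate_kb(sub) if f.level == "error"}
    assert codes & {"cpt-overflow", "strength-overflow", "bad-strength"}


def test_weighted_two_parent_strengths_do_not_overflow():
    # 0.5 * 0.8 + 0.5 * 0.8 = 0.8 <= 1 under the r-weighted mixture
    kb = make_kb(
        {"B1": (0.9, 0.1), "B2": (0.9, 0.1)},
        [("X3", "B1", 1.0, 0.8), ("X3", "B2", 1.0, 0.8)],
    )
    assert [f for f in validate_kb(kb) if f.level == "error"] == []


def test_multistate_column_overflow_detected():
    sub = subducg_from_dict(
        {
            "name": "t",
            "variables": [
                {"id": "B1", "kind": "B", "states": 2, "prior": [0.9, 0.1]},
                {"id": "X2", "kind": "X", "states": 3},
            ],
            "links": [
                {
                    "child": "X2",
                    "parent": "B1",
                    "weight": 1.0,
                    "strength": {1: [0.0, 0.7], 2: [0.0, 0.6]},
                }
            ],
        }
    )
    assert any(f.code == "strength-overflow" for f in validate_kb(sub))


def test_cycle_detected():
    sub = subducg_from_dict(
        {
            "name": "cyc",
            "variables": [
                {"id": "B1", "kind": "B", "states": 2, "prior": [0.9, 0.1]},
                {"id": "X2", "kind": "X", "states": 2},
                {"id": "X3", "kind": "X", "states": 2},
            ],
            "links": [
                {"child": "X2", "parent": "X3", "weight": 1.0, "strength": {1: [0.0, 0.5]}},
                {"child": "X3", "parent": "X2", "weight": 1.0, "strength": {1: [0.0, 0.5]}},
            ],
        }
    )
    assert any(f.code == "cycle" for f in validate_kb(sub))


def test_sa_remnant_factor_must_be_one(lpr):
    doc = kb_to_dict(lpr)
    doc["sa_factors"][0]["factors"] = [2, 10]
    sub = subducg_from_dict(doc)
    assert any(f.code == "sa-remnant" for f in validate_kb(sub))


def test_disease_without_manifestations_warns():
    kb = make_kb(
        {"B1": (0.9, 0.1), "B2": (0.8, 0.2)}, [("X3", "B1", 1.0, 0.5)]
    )
    warnings_ = [f for f in validate_kb(kb) if f.level == "warning"]
    assert any("B2" in f.message for f in warnings_)


@pytest.mark.parametrize("fixture_name", ["lpr_kb", "kb3"])
def test_implied_child_distributions_are_probability_vectors(fixture_name, request):
    # For every joint parent-state assignment, the mixture plus residual
    # normal mass must form a probability vector (checked exhaustively).
    kb = request.getfixturevalue(fixture_name)
    by_child: dict[str, list[CausalLink]] = {}
    for l in kb.links:
        by_child.setdefault(l.child, []).append(l)
    for child, links in by_child.items():
        sizes = [kb.variables[l.parent].n_states for l in links]
        for combo in np.ndindex(*sizes):
            ps = {l.parent: int(j) for l, j in zip(links, combo)}
            probs = [
                child_state_probability(links, k, ps)
                for k in range(kb.variables[child].n_states)
            ]
            assert all(p >= -1e-12 for p in probs)
            assert abs(sum(probs) - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def test_shared_manifestation_union_of_links(kb3):
    incoming = [l for l in kb3.links if l.child == "X85"]
    assert len(incoming) == 3  # hoarse throat shared by all three diseases
    incoming21 = [l for l in kb3.links if l.child == "X21"]
    assert {l.parent for l in incoming21} == {"BX11", "BX23"}
    assert set(kb3.provenance["X85"]) == {
        "chronic_laryngitis",
        "chronic_pharyngitis",
        "lpr",
    }


def test_merge_single_is_identity(lpr):
    merged = merge_subgraphs([lpr])
    assert merged.variables == lpr.variables
    assert merged.links == lpr.links
    assert merged.gates == lpr.gates
    assert merged.sa_factors == lpr.sa_factors


def test_merge_commutative_and_associative():
    parts = [
        fx.load_subducg(p)
        for p in sorted(
            (fx._data_path("three_disease")).glob("*.yaml")
        )
        if p.name != "index.yaml"
    ]
    a, b, c = parts
    ab_c = merge_subgraphs([merge_and_wrap(a, b), c])
    a_bc = merge_subgraphs([a, merge_and_wrap(b, c)])
    forward = merge_subgraphs([a, b, c])
    backward = merge_subgraphs([c, b, a])
    for other in (backward, ab_c, a_bc):
        assert forward.variables == other.variables
        assert forward.links == other.links
        assert forward.gates == other.gates
        assert forward.sa_factors == other.sa_factors


def merge_and_wrap(x: SubDUCG, y: SubDUCG) -> SubDUCG:
    m = merge_subgraphs([x, y])
    return SubDUCG(
        name=f"{x.name}+{y.name}",
        variables=m.variables,
        links=m.links,
        gates=m.gates,
        sa_factors=m.sa_factors,
    )


def test_merge_conflict_names_both_sources(lpr):
    other = SubDUCG(
        name="conflicting",
        variables={
            "B9": Variable(id="B9", kind="B", n_states=2, prior=(0.9, 0.1)),
            "X21": Variable(id="X21", kind="X", n_states=3),  # clashes with lpr
        },
        links=(
            CausalLink(
                child="X21",
                parent="B9",
                weight_r=1.0,
                strength=strength_matrix(3, 2, {1: [0.0, 0.5]}),
            ),
        ),
        gates={},
        sa_factors=(),
    )
    with pytest.raises(MergeConflictError) as exc:
        merge_subgraphs([lpr, other])
    assert "lpr" in str(exc.value) and "conflicting" in str(exc.value)


# ---------------------------------------------------------------------------
# Risk-factor prior rescaling
# ---------------------------------------------------------------------------

def test_bx_prior_risk_present(lpr):
    prior = compute_bx_prior(lpr, "B23", {"X74": 1})
    assert prior[1] == pytest.approx(0.3)
    assert prior[0] == pytest.approx(0.7)


def test_bx_prior_risk_absent(lpr):
    assert compute_bx_prior(lpr, "B23", {"X74": 0})[1] == pytest.approx(0.03)
    assert compute_bx_prior(lpr, "B23", {})[1] == pytest.approx(0.03)


def test_bx_prior_clipped_at_one(lpr):
    doc = kb_to_dict(lpr)
    doc["sa_factors"][0]["factors"] = [1, 50]
    sub = subducg_from_dict(doc)
    prior = compute_bx_prior(sub, "B23", {"X74": 1})
    assert prior[1] == pytest.approx(1.0)
    assert prior[0] == pytest.approx(0.0)


def test_bx_prior_passthrough_without_triple(kb3):
    assert tuple(compute_bx_prior(kb3, "B12", {"X74": 1})) == (0.91, 0.09)


def test_bx_prior_all_factors_one_equals_raw(lpr):
    doc = kb_to_dict(lpr)
    doc["sa_factors"][0]["factors"] = [1, 1]
    sub = subducg_from_dict(doc)
    assert tuple(compute_bx_prior(sub, "B23", {"X74": 1})) == (0.97, 0.03)


# ---------------------------------------------------------------------------
# Round-trips
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("suffix", [".yaml", ".json"])
def test_kb_roundtrip(tmp_path, kb3, suffix):
    out = tmp_path / f"kb{suffix}"
    save_kb(kb3, out)
    again = load_kb(out)
    assert again.variables == kb3.variables
    assert again.links == kb3.links
    assert again.gates == kb3.gates
    assert again.sa_factors == kb3.sa_factors


@pytest.mark.parametrize("seed", range(5))
def test_random_kb_roundtrip(tmp_path, seed):
    kb = fx.random_kb(fx.FixtureSpec(seed=seed, n_diseases=3, chain_depth=1))
    out = tmp_path / "kb.yaml"
    save_kb(kb, out)
    again = load_kb(out)
    assert again.variables == kb.variables
    assert again.links == kb.links
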