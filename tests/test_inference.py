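"""The four reasoning steps: simplification, decomposition, evaluation,
posterior ranking, plus the engine's probabilistic invariants."""

from __future__ import annotations

import pytest

from conftest import make_kb
from ducg.inference import (
    DiagnosisConfig,
    Evidence,
    EvidenceError,
    Hypothesis,
    decompose,
    diagnose,
    evaluate,
    posterior,
    simplify,
    suggest_next,
)
from ducg.kb_model import kb_to_dict, subducg_from_dict


def ev(**obs) -> Evidence:
    return Evidence.from_mapping(obs)


# ---------------------------------------------------------------------------
# Step 1: simplification
# ---------------------------------------------------------------------------

def test_unrelated_disease_removed():
    kb = make_kb(
        {"B1": (0.9, 0.1), "B2": (0.8, 0.2)},
        [("X3", "B1", 1.0, 0.5), ("X4", "B2", 1.0, 0.5)],
    )
    s = simplify(kb, ev(X3=1))
    assert "B2" not in s.kb.variables
    assert "B1" in s.kb.variables
    assert "X4" not in s.kb.variables  # barren once B2 is gone


def test_no_evidence_keeps_roots_drops_leaves():
    kb = make_kb(
        {"B1": (0.9, 0.1)}, [("X2", "B1", 1.0, 0.5), ("X3", "X2", 1.0, 0.5)]
    )
    s = simplify(kb, ev())
    assert s.no_abnormal_evidence
    assert "B1" in s.kb.variables
    assert "X2" not in s.kb.variables and "X3" not in s.kb.variables


def test_three_disease_case_keeps_all_diseases(kb3):
    symptoms = ev(X85=1, X21=1, X45=1, X44=1, X150=1, X5=1, X52=1, X51=0, X22=0, X23=0)
    s = simplify(kb3, symptoms)
    assert set(s.kb.disease_roots()) == {"B11", "B12", "B23"}
    # every observed variable survives simplification
    assert set(symptoms.as_dict()) <= set(s.kb.variables)


def test_risk_factor_machinery_survives_for_relevant_disease(kb3):
    s = simplify(kb3, ev(X21=1))
    # X21 is reachable from chronic laryngitis and LPR; pharyngitis goes
    assert "B12" not in s.kb.variables
    assert {"B11", "BX11", "SG11", "B23", "BX23", "SG23"} <= set(s.kb.variables)


def test_unknown_evidence_variable_rejected(kb3):
    with pytest.raises(EvidenceError):
        simplify(kb3, ev(X999=1))


def test_root_not_observable(kb3):
    with pytest.raises(EvidenceError):
        simplify(kb3, ev(B11=1))


def test_deterministic_contradiction_excludes_hypothesis_state():
    kb = make_kb(
        {"B1": (0.9, 0.1), "B2": (0.8, 0.2)},
        [("X3", "B1", 1.0, 1.0), ("X4", "B1", 1.0, 0.5), ("X4", "B2", 1.0, 0.5)],
    )
    # X3 is deterministically caused by B1 state 1; observing it normal
    # while other abnormal evidence remains rules the state out.
    s = simplify(kb, ev(X3=0, X4=1))
    assert ("B1", 1) in s.excluded_root_states
    hyps = [v.hypothesis for v in decompose(s, ev(X3=0, X4=1))]
    assert Hypothesis("B1", 1) not in hyps
    assert Hypothesis("B2", 1) in hyps


# ---------------------------------------------------------------------------
# Step 2: decomposition
# ---------------------------------------------------------------------------

def test_one_view_per_surviving_disease(kb3):
    symptoms = ev(X85=1, X21=1, X45=1)
    views = decompose(simplify(kb3, symptoms), symptoms)
    assert [v.hypothesis for v in views] == [
        Hypothesis("B11", 1),
        Hypothesis("B12", 1),
        Hypothesis("B23", 1),
    ]
    for v in views:
        assert set(v.fixed_roots) == {
            r for r in ("BX11", "B12", "BX23") if r != v.root
        }


def test_multistate_disease_yields_state_hypotheses():
    sub = subducg_from_dict(
        {
            "name": "m",
            "variables": [
                {"id": "B1", "kind": "B", "states": 3, "prior": [0.8, 0.15, 0.05]},
                {"id": "X2", "kind": "X", "states": 2},
            ],
            "links": [
                {
                    "child": "X2",
                    "parent": "B1",
                    "weight": 1.0,
                    "strength": {1: [0.0, 0.5, 0.9]},
                }
            ],
        }
    )
    from ducg.kb_model import merge_subgraphs

    kb = merge_subgraphs([sub])
    views = decompose(simplify(kb, ev(X2=1)), ev(X2=1))
    assert [v.hypothesis for v in views] == [Hypothesis("B1", 1), Hypothesis("B1", 2)]


def test_no_surviving_roots_gives_empty_hypotheses():
    kb = make_kb({"B1": (0.9, 0.1)}, [("X2", "B1", 1.0, 0.5), ("X3", "X2", 1.0, 0.4)])
    # remove the disease by contradicting reachability: evidence abnormal on
    # a variable B1 cannot reach after pruning is impossible here, so build
    # an isolated observation instead
    kb2 = make_kb(
        {"B1": (0.9, 0.1)},
        [("X2", "B1", 1.0, 0.5), ("X9", "X8", 1.0, 0.4)],
    )
    s = simplify(kb2, ev(X9=1))
    assert s.kb.disease_roots() == []
    assert decompose(s, ev(X9=1)) == []


# ---------------------------------------------------------------------------
# Step 4: evaluation and posteriors
# ---------------------------------------------------------------------------

def test_single_link_abnormal(single_link_kb):
    e = ev(X2=1)
    (view,) = decompose(simplify(single_link_kb, e), e)
    assert evaluate(view, e) == pytest.approx(0.1 * 0.8)


def test_single_link_normal(single_link_kb):
    e = ev(X2=0)
    (view,) = decompose(simplify(single_link_kb, e), e)
    assert evaluate(view, e) == pytest.approx(0.1 * 0.2)


def test_hidden_intermediate_marginalised(chain_kb):
    e = ev(X3=1)
    (view,) = decompose(simplify(chain_kb, e), e)
    # X2 unobserved: zeta = p * a12 * a23 (X2 normal contributes nothing)
    assert evaluate(view, e) == pytest.approx(0.1 * 0.7 * 0.6)


def test_weight_ratios_mix_parents(two_parent_kb):
    e = ev(X3=1)
    views = decompose(simplify(two_parent_kb, e), e)
    z = {v.hypothesis.disease: evaluate(v, e) for v in views}
    assert z["B1"] == pytest.approx(0.1 * (0.75 * 0.8))
    assert z["B2"] == pytest.approx(0.2 * (0.25 * 0.5))


def test_posterior_normalisation_example():
    res = posterior({Hypothesis("B1", 1): 0.03, Hypothesis("B2", 1): 0.01})
    assert [e.posterior for e in res.entries] == pytest.approx([0.75, 0.25])
    assert res.entries[0].hypothesis.disease == "B1"


def test_posterior_single_hypothesis_is_one():
    res = posterior({Hypothesis("B7", 1): 1e-9})
    assert res.entries[0].posterior == 1.0


def test_posterior_all_zero_flagged():
    res = posterior({Hypothesis("B1", 1): 0.0})
    assert res.entries == []
    assert "no-hypothesis-explains-evidence" in res.flags


def test_posterior_rejects_negative():
    with pytest.raises(ValueError):
        posterior({Hypothesis("B1", 1): -0.1})


# ---------------------------------------------------------------------------
# Full pipeline invariants
# ---------------------------------------------------------------------------

def test_no_evidence_limit_equals_normalised_priors(kb3):
    res = diagnose(kb3, ev())
    post = {e.hypothesis.disease: e.posterior for e in res.entries}
    total = 0.04 + 0.09 + 0.03
    assert post["B12"] == pytest.approx(0.09 / total)
    assert post["B11"] == pytest.approx(0.04 / total)
    assert post["B23"] == pytest.approx(0.03 / total)
    assert [e.hypothesis.disease for e in res.entries] == ["B12", "B11", "B23"]
    assert "no-abnormal-evidence" in res.flags


def test_posteriors_sum_to_one(kb3):
    res = diagnose(kb3, ev(X21=1, X85=1, X22=0))
    assert sum(e.posterior for e in res.entries) == pytest.approx(1.0, abs=1e-9)


def test_negative_evidence_never_increases_zeta(kb3):
    base = ev(X21=1, X85=1)
    res = diagnose(kb3, base)
    z0 = {e.hypothesis.disease: e.zeta for e in res.entries}
    res2 = diagnose(kb3, base.with_observation("X44", 0))
    z1 = {e.hypothesis.disease: e.zeta for e in res2.entries}
    for d in z1:  # X44 links to B11 and B12 with a > 0
        assert z1[d] <= z0[d] + 1e-15


def test_isolated_evidence_multiplies_by_exactly_leak(kb3):
    cfg = DiagnosisConfig(leak=0.01)
    base = ev(X21=1)
    z0 = {e.hypothesis.disease: e.zeta for e in diagnose(kb3, base, cfg).entries}
    # X51 (dry throat) is a manifestation of chronic pharyngitis only, and
    # B12 was already pruned by X21; for the surviving hypotheses it is
    # isolated abnormal evidence.
    z1 = {
        e.hypothesis.disease: e.zeta
        for e in diagnose(kb3, base.with_observation("X51", 1), cfg).entries
    }
    for d in ("B11", "B23"):
        assert z1[d] == pytest.approx(cfg.leak * z0[d], rel=1e-12)


def test_risk_factor_scales_prior_mass_tenfold(lpr_kb):
    base = ev(X21=1)
    with_risk = ev(X21=1, X74=1)
    (v0,) = decompose(simplify(lpr_kb, base), base)
    (v1,) = decompose(simplify(lpr_kb, with_risk), with_risk)
    assert v1.prior[1] == pytest.approx(10 * v0.prior[1])


def test_gold_standard_flagged(lpr_kb):
    res = diagnose(lpr_kb, ev(SX160=1, X21=1))
    assert res.entries[0].gold_standard
    assert "gold-standard-confirmed" in res.flags
    res2 = diagnose(lpr_kb, ev(X21=1))
    assert not res2.entries[0].gold_standard


def test_leak_validation(single_link_kb):
    e = ev(X2=1)
    (view,) = decompose(simplify(single_link_kb, e), e)
    with pytest.raises(ValueError):
        evaluate(view, e, leak=1.0)


# ---------------------------------------------------------------------------
# Next-question suggestion
# ---------------------------------------------------------------------------

@pytest.fixture
def discriminating_kb():
    """Two diseases sharing one manifestation; X10 discriminates them."""
    return make_kb(
        {"B1": (0.9, 0.1), "B2": (0.9, 0.1)},
        [
            ("X9", "B1", 1.0, 0.5),
            ("X9", "B2", 1.0, 0.5),
            ("X10", "B1", 1.0, 0.9),
            ("X11", "B1", 1.0, 0.5),
            ("X11", "B2", 1.0, 0.5),
        ],
    )


def test_discriminator_ranked_first(discriminating_kb):
    ranked = suggest_next(discriminating_kb, ev(X9=1))
    assert ranked[0][0] == "X10"
    assert ranked[0][1] > 0


def test_all_observed_returns_empty(discriminating_kb):
    ranked = suggest_next(discriminating_kb, ev(X9=1, X10=0, X11=1))
    assert ranked == []


def test_symmetric_candidates_tie_in_index_order():
    kb = make_kb(
        {"B1": (0.9, 0.1), "B2": (0.9, 0.1)},
        [
            ("X9", "B1", 1.0, 0.5),
            ("X9", "B2", 1.0, 0.5),
            ("X12", "B1", 1.0, 0.6),
            ("X12", "B2", 1.0, 0.6),
            ("X11", "B1", 1.0, 0.6),
            ("X11", "B2", 1.0, 0.6),
        ],
    )
    ranked = suggest_next(kb, ev(X9=1))
    assert [v for v, _ in ranked] == ["X11", "X12"]
    assert ranked[0][1] == pytest.approx(ranked[1][1], abs=1e-12)


def test_confirmed_hypothesis_suppresses_suggestions(discriminating_kb):
    cfg = DiagnosisConfig(confirmation_threshold=0.5)
    assert suggest_next(discriminating_kb, ev(X10=1), config=cfg) == []
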