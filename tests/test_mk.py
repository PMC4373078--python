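import numpy as np
import pytest
from scipy.linalg import expm

from _oracles import enum_mk
from conftest import random_small_tree_newick
from melinvade.mk import (MkFit, call_invasions, fit_mk,
                          marginal_ancestral_states, mk_loglik,
                          transition_matrix)
from melinvade.phylo import RegionCoding, tree_from_string


def make_fit(tree, coding, q):
    k = len(coding.states)
    return MkFit(q=q, log_likelihood=0.0, n_states=k,
                 states=list(coding.states), root_prior=np.full(k, 1 / k))


def test_transition_matrix_is_matrix_exponential():
    for k in (2, 3, 5):
        for q, t in [(0.0, 1.0), (0.3, 0.7), (2.0, 0.1)]:
            gen = np.full((k, k), q)
            np.fill_diagonal(gen, -(k - 1) * q)
            assert np.allclose(transition_matrix(k, q, t), expm(gen * t),
                               atol=1e-12)
            assert np.allclose(transition_matrix(k, q, t).sum(axis=1), 1.0)


def test_rate_zero_two_identical_tips():
    t = tree_from_string("(A:1,B:1);")
    coding = RegionCoding(["X", "Y"], {"A": "X", "B": "X"})
    assert mk_loglik(t, coding, 0.0) == pytest.approx(-np.log(2))


def test_loglik_invariant_under_state_relabeling(four_tip_tree):
    states = ["X", "Y", "Z"]
    coding = RegionCoding(states, {"A": "X", "B": "Y", "C": "Z", "D": "X"})
    swapped = RegionCoding(states, {"A": "Z", "B": "Y", "C": "X", "D": "Z"})
    for q in (0.1, 0.7, 2.0):
        assert mk_loglik(four_tip_tree, coding, q) == pytest.approx(
            mk_loglik(four_tip_tree, swapped, q), abs=1e-12)


def test_four_tip_enumeration_oracle(four_tip_tree):
    coding = RegionCoding(["X", "Y", "Z"],
                          {"A": "X", "B": "Y", "C": "Z", "D": "X"})
    ll_o, marg_o = enum_mk(four_tip_tree, coding, 0.3)
    assert mk_loglik(four_tip_tree, coding, 0.3) == pytest.approx(ll_o,
                                                                  abs=1e-9)
    anc = marginal_ancestral_states(four_tip_tree, coding,
                                    make_fit(four_tip_tree, coding, 0.3))
    for nid, expected in marg_o.items():
        assert np.allclose(anc.probs[nid], expected, atol=1e-9)


def test_randomized_small_trees_match_enumeration():
    rng = np.random.default_rng(77)
    for _ in range(15):
        n_tips = int(rng.integers(2, 7))
        k = int(rng.integers(2, 4))
        t = tree_from_string(random_small_tree_newick(rng, n_tips))
        states = [f"S{i}" for i in range(k)]
        coding = RegionCoding(states, {
            lab: states[int(rng.integers(0, k))] for lab in t.tip_labels})
        q = float(rng.uniform(0.05, 1.5))
        ll_o, marg_o = enum_mk(t, coding, q)
        assert mk_loglik(t, coding, q) == pytest.approx(ll_o, abs=1e-9)
        anc = marginal_ancestral_states(t, coding, make_fit(t, coding, q))
        for nid, expected in marg_o.items():
            assert np.allclose(anc.probs[nid], expected, atol=1e-9)


def test_marginals_are_probability_vectors(four_tip_tree):
    coding = RegionCoding(["X", "Y"], {"A": "X", "B": "Y", "C": "Y", "D": "X"})
    fit = fit_mk(four_tip_tree, coding)
    anc = marginal_ancestral_states(four_tip_tree, coding, fit)
    for v in anc.probs.values():
        assert np.all(v >= 0)
        assert v.sum() == pytest.approx(1.0, abs=1e-9)


def test_symmetric_cherry_root_is_even():
    t = tree_from_string("(A:1,B:1);")
    coding = RegionCoding(["X", "Y"], {"A": "X", "B": "Y"})
    anc = marginal_ancestral_states(t, coding, make_fit(t, coding, 0.4))
    assert np.allclose(anc.probs["N0"], [0.5, 0.5], atol=1e-12)


def test_monomorphic_data_boundary_fit(four_tip_tree):
    coding = RegionCoding(["X", "Y"],
                          {"A": "X", "B": "X", "C": "X", "D": "X"})
    fit = fit_mk(four_tip_tree, coding)
    assert fit.at_lower_bound
    anc = marginal_ancestral_states(four_tip_tree, coding, fit)
    for v in anc.probs.values():
        assert v[0] > 0.999


def test_fitted_rate_is_local_optimum(four_tip_tree):
    coding = RegionCoding(["X", "Y"], {"A": "X", "B": "Y", "C": "Y", "D": "X"})
    fit = fit_mk(four_tip_tree, coding)
    for q in (fit.q / 2, 2 * fit.q):
        assert fit.log_likelihood >= mk_loglik(four_tip_tree, coding, q) - 1e-9


def test_saturation_limit_marginals_uniform(four_tip_tree):
    coding = RegionCoding(["X", "Y", "Z"],
                          {"A": "X", "B": "Y", "C": "Z", "D": "X"})
    q = 1e3 / four_tip_tree.height()
    anc = marginal_ancestral_states(four_tip_tree, coding,
                                    make_fit(four_tip_tree, coding, q))
    for v in anc.probs.values():
        assert np.allclose(v, 1 / 3, atol=1e-3)


def test_likelihood_continuous_in_rate(four_tip_tree):
    coding = RegionCoding(["X", "Y"], {"A": "X", "B": "Y", "C": "Y", "D": "X"})
    for q in (0.05, 0.3, 1.2):
        a = mk_loglik(four_tip_tree, coding, q)
        b = mk_loglik(four_tip_tree, coding, q + 1e-6)
        assert abs(a - b) < 1e-4


def test_negative_rate_and_uncoded_tip_rejected(four_tip_tree):
    coding = RegionCoding(["X", "Y"], {"A": "X", "B": "Y", "C": "Y", "D": "X"})
    with pytest.raises(ValueError, match="non-negative"):
        mk_loglik(four_tip_tree, coding, -0.1)
    partial = RegionCoding(["X", "Y"], {"A": "X", "B": "Y", "C": "Y"})
    with pytest.raises(ValueError, match="uncoded"):
        mk_loglik(four_tip_tree, partial, 0.1)


def test_invasion_call_rule_on_given_marginals():
    # the flagging rule itself, decoupled from the fit: E's parent is
    # confidently Asian -> flagged with source Asia; at 0.97 Africa -> not
    from melinvade.mk import AncestralStates
    t = tree_from_string("((E:1,B:1):1,C:2);")
    coding = RegionCoding(["Africa", "Asia"],
                          {"E": "Africa", "B": "Asia", "C": "Asia"})
    parent_of_e = t.node_ids[t.parent[t.node_ids.index("E")]]
    root = t.node_ids[t.root_index]
    anc = AncestralStates(states=["Africa", "Asia"], probs={
        parent_of_e: np.array([0.02, 0.98]), root: np.array([0.3, 0.7])})
    calls, clades = call_invasions(t, coding, anc, "Africa", threshold=0.9)
    (call,) = calls
    assert call.tip_label == "E" and call.flagged
    assert call.inferred_source == "Asia"
    assert call.confidence == pytest.approx(0.98)
    assert len(clades) == 1 and clades[0].tips == ["E"]

    anc.probs[parent_of_e] = np.array([0.97, 0.03])
    calls, clades = call_invasions(t, coding, anc, "Africa", threshold=0.9)
    assert not calls[0].flagged and clades == []


def test_invasion_call_full_pipeline_isolated_tip():
    # one African tip nested in a 9-tip Asian backbone: the fitted model
    # prefers a single recent change, so E's parent reconstructs as Asia
    t = tree_from_string(
        "((((E:0.4,B:0.05):0.5,(C:0.3,D:0.3):0.25):0.5,"
        "((F:0.6,G:0.6):0.45,(H:0.5,I:0.5):0.55):0.2):0.3,(J:1.2,K:1.2):0.35);")
    assignment = {lab: "Asia" for lab in t.tip_labels}
    assignment["E"] = "Africa"
    coding = RegionCoding(["Africa", "Asia"], assignment)
    fit = fit_mk(t, coding)
    anc = marginal_ancestral_states(t, coding, fit)
    calls, clades = call_invasions(t, coding, anc, "Africa", threshold=0.9)
    by_tip = {c.tip_label: c for c in calls}
    assert set(by_tip) == {"E"}  # non-focal tips never appear
    assert by_tip["E"].flagged
    assert by_tip["E"].inferred_source == "Asia"
    assert len(clades) == 1 and clades[0].tips == ["E"]


def test_invasion_call_respects_threshold_and_focal_membership():
    t = tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
    coding = RegionCoding(["Africa", "Asia"],
                          {"A": "Africa", "B": "Africa", "C": "Africa",
                           "D": "Asia"})
    fit = fit_mk(t, coding)
    anc = marginal_ancestral_states(t, coding, fit)
    calls, clades = call_invasions(t, coding, anc, "Africa", threshold=0.9)
    # mostly-African data: ancestry is reconstructed African, nothing flagged
    assert not any(c.flagged for c in calls)
    assert clades == []
    with pytest.raises(ValueError, match="threshold"):
        call_invasions(t, coding, anc, "Africa", threshold=0.4)
    with pytest.raises(ValueError, match="focal"):
        call_invasions(t, coding, anc, "Atlantis", threshold=0.9)
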