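import math

import numpy as np
import pytest

import barcodelim as bl
from barcodelim.gmyc import (
    COALESCENT,
    DIVERSIFICATION,
    GMYCError,
    _fit_schedule,
    build_schedule,
    extract_entities,
    fit_gmyc_multiple,
    fit_gmyc_null,
    fit_gmyc_single,
    waiting_time_loglik,
)
from barcodelim.synthetic import (
    simulate_coalescent_tree,
    simulate_delimitation_benchmark,
)
from barcodelim.trees import node_ages, tree_from_string


def _assign_all(tree, kind):
    return {nd: kind for nd in tree.preorder_internal_node_iter()}


def _balanced_two_species():
    return tree_from_string(
        "((a1:0.01,a2:0.01):0.99,(b1:0.02,b2:0.02):0.98);")


# ----------------------------------------------------------------------
# schedule construction
# ----------------------------------------------------------------------

def test_all_coalescent_gives_one_species():
    t = tree_from_string("((a:1,b:1):1,(c:0.5,d:0.5):1.5);")
    sched = build_schedule(t, _assign_all(t, COALESCENT))
    assert len(sched.cluster_nodes) == 1
    assert sched.singleton_tips == []
    assert sched.x.sum() == pytest.approx(2.0)


def test_all_diversification_gives_singletons():
    t = tree_from_string("((a:1,b:1):1,(c:0.5,d:0.5):1.5);")
    sched = build_schedule(t, _assign_all(t, DIVERSIFICATION))
    assert sched.cluster_nodes == []
    assert sorted(sched.singleton_tips) == ["a", "b", "c", "d"]
    # pure-Yule lineage counts 2,3,4 across the three intervals
    assert list(sched.div_counts) == [2, 3, 4]
    assert list(sched.coal_pair_sums) == [0, 0, 0]


def test_two_species_threshold_between_root_and_cherries():
    t = _balanced_two_species()
    assignment = {}
    for nd in t.preorder_internal_node_iter():
        age = max(node_ages(t)[id(nd)], 0)
        assignment[nd] = DIVERSIFICATION if age > 0.5 else COALESCENT
    sched = build_schedule(t, assignment)
    assert len(sched.cluster_nodes) == 2
    # rootward interval carries 2 between-species lineages
    assert sched.div_counts[0] == 2


def test_inconsistent_assignment_raises():
    t = tree_from_string("(((a:1,b:1):1,c:2):1,d:3);")
    nodes = list(t.preorder_internal_node_iter())
    assignment = {nd: COALESCENT for nd in nodes}
    assignment[nodes[-1]] = DIVERSIFICATION  # div node below coal root
    with pytest.raises(GMYCError, match="inconsistent"):
        build_schedule(t, assignment)


# ----------------------------------------------------------------------
# waiting-time likelihood
# ----------------------------------------------------------------------

def test_single_interval_exponential_density():
    t = tree_from_string("(a:1.5,b:1.5);")
    # n=2: a single interval with one coalescent event at the root
    sched = build_schedule(t, _assign_all(t, COALESCENT))
    lam, p = 0.7, 1.0
    b = lam * 2.0 ** p  # n(n-1) = 2
    expected = math.log(b) - b * 1.5
    assert waiting_time_loglik(sched, 0.0, 1.0, lam, p) == pytest.approx(expected)


def test_zero_hazard_event_returns_minus_inf():
    t = tree_from_string("(a:1.5,b:1.5);")
    sched = build_schedule(t, _assign_all(t, COALESCENT))
    assert waiting_time_loglik(sched, 1.0, 1.0, 0.0, 1.0) == -math.inf


def test_pure_yule_profile_matches_closed_form_mle():
    """With p_div fixed at 1 the Yule rate MLE is (n-2)/sum(k_i x_i)."""
    for seed in range(5):
        t = bl.simulate_yule_tree(12, 1.3, seed)
        sched = build_schedule(t, _assign_all(t, DIVERSIFICATION))
        n = 12
        denom = float(sched.div_counts @ sched.x)
        lam_hat = (n - 2) / denom
        ll_hat = waiting_time_loglik(sched, lam_hat, 1.0, 0.0, 1.0)
        for lam in (lam_hat * 0.8, lam_hat * 1.25):
            assert waiting_time_loglik(sched, lam, 1.0, 0.0, 1.0) < ll_hat
        # the free profile fit can only do better than the p=1 slice
        ll_free, _ = _fit_schedule(sched)
        assert ll_free >= ll_hat - 1e-9


def test_loglik_invariant_to_tip_relabelling_within_species():
    t1 = _balanced_two_species()
    t2 = tree_from_string(
        "((a2:0.01,a1:0.01):0.99,(b2:0.02,b1:0.02):0.98);")
    ages = node_ages(t1)
    assign1 = {nd: (DIVERSIFICATION if ages[id(nd)] > 0.5 else COALESCENT)
               for nd in t1.preorder_internal_node_iter()}
    ages2 = node_ages(t2)
    assign2 = {nd: (DIVERSIFICATION if ages2[id(nd)] > 0.5 else COALESCENT)
               for nd in t2.preorder_internal_node_iter()}
    s1 = build_schedule(t1, assign1)
    s2 = build_schedule(t2, assign2)
    args = (0.9, 1.1, 30.0, 0.8)
    assert waiting_time_loglik(s1, *args) == pytest.approx(
        waiting_time_loglik(s2, *args))


# ----------------------------------------------------------------------
# model fits
# ----------------------------------------------------------------------

def test_nesting_of_null_single_multiple():
    for seed in (1, 5, 9):
        tree, _ = simulate_delimitation_benchmark(seed, separation=50.0)
        f0 = fit_gmyc_null(tree)
        f1 = fit_gmyc_single(tree)
        f2 = fit_gmyc_multiple(tree)
        assert f0.log_likelihood <= f1.log_likelihood + 1e-6
        assert f1.log_likelihood <= f2.log_likelihood + 1e-6
        assert f1.null_log_likelihood == pytest.approx(f0.log_likelihood)


def test_threshold_beyond_root_reproduces_null():
    tree = simulate_coalescent_tree(12, 0.01, 3)
    f0 = fit_gmyc_null(tree)
    f1 = fit_gmyc_single(tree)
    # the rootward-most candidate is the all-coalescent configuration
    assert f1.log_likelihood >= f0.log_likelihood - 1e-9
    assert f0.n_entities == 1 and f0.n_clusters == 1


def test_single_threshold_recovers_benchmark_species():
    hits = 0
    for seed in range(8):
        tree, part = simulate_delimitation_benchmark(1000 + seed)
        fit = fit_gmyc_single(tree)
        hits += fit.n_clusters == 5 and fit.n_entities == 5
        assert 1 <= fit.n_entities <= len(tree.leaf_nodes())
        assert fit.confidence_range[0] <= fit.n_clusters <= fit.confidence_range[1]
    assert hits >= 7


def test_null_data_rarely_rejected():
    non_rejections = 0
    for seed in range(10):
        tree = simulate_coalescent_tree(25, 0.01, 3000 + seed)
        fit = fit_gmyc_single(tree)
        non_rejections += fit.p_value >= 0.05
    assert non_rejections >= 8


def test_entity_count_monotone_in_threshold():
    from barcodelim.gmyc import _TreeData, _schedule_from_mask, _single_candidate_mask

    tree, _ = simulate_delimitation_benchmark(4)
    data = _TreeData(tree)
    entities = []
    for j in range(1, data.n_tips + 1):
        sched = _schedule_from_mask(data, _single_candidate_mask(data, j))
        entities.append(len(sched.cluster_nodes) + len(sched.singleton_tips))
    assert all(b >= a for a, b in zip(entities, entities[1:]))


def test_multiple_threshold_two_depth_regimes():
    """Species with 10x different coalescent depths: the multiple-threshold
    fit reports distinct per-lineage switch times, never falls below the
    single-threshold likelihood, and its gain over one global switch on
    globally separated data is not significant."""
    sp = bl.simulate_yule_tree(5, 1.0, 4000)
    ages = [a for a in node_ages(sp).values() if a > 0]
    base = min(ages) / 200.0
    thetas = [base, base, base * 10, base * 10, base]
    tree, part = bl.simulate_species_coalescents(sp, 5, thetas, 5000)
    single = fit_gmyc_single(tree)
    multi = fit_gmyc_multiple(tree)
    assert multi.log_likelihood >= single.log_likelihood - 1e-9
    assert single.n_clusters == 5
    assert multi.n_clusters == 5
    assert len(multi.thresholds) >= 2
    assert len(set(multi.thresholds)) == len(multi.thresholds)
    assert multi.p_value >= 0.05


def test_extract_entities_listing():
    tree, _ = simulate_delimitation_benchmark(6)
    fit = fit_gmyc_single(tree)
    rows = extract_entities(fit)
    tips = [r[0] for r in rows]
    assert sorted(tips) == sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    assert len({r[1] for r in rows}) == fit.n_entities
    kinds = {r[2] for r in rows}
    assert kinds <= {"cluster", "singleton"}


def test_cluster_membership_stable_under_tiny_jitter():
    """Near-polytomies of identical sequences must not flip cluster
    membership when node heights move by <= 1e-9 of the root height."""
    base = ("((((a1:{x1},a2:{x1}):{y1},(a3:{x3},a4:{x3}):{y2}):{za},"
            "(b1:0.004,b2:0.004):0.996):0.005,(c1:0.005,c2:0.005):1.0);")

    def make(eps):
        x1, x3 = 1e-6 + eps, 2e-6 + eps
        return tree_from_string(base.format(
            x1=repr(x1), x3=repr(x3),
            y1=repr(3e-6 - x1), y2=repr(3e-6 - x3),
            za=repr(1.0 - 3e-6)))

    fits = [fit_gmyc_single(make(e)) for e in (0.0, 1e-9, -1e-9)]
    clusters = [sorted(map(tuple, f.clusters)) for f in fits]
    assert clusters[0] == clusters[1] == clusters[2]


def test_polytomy_rejected():
    t = tree_from_string("((a:1,b:1,c:1):1,d:2);")
    with pytest.raises(Exception, match="polytomy"):
        fit_gmyc_single(t)
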