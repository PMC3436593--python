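import io
import itertools
import math

import dendropy
import numpy as np
import pytest

import barcodelim as bl
from barcodelim.alignment import alignment_from_dict
from barcodelim.distances import DistanceError, DistanceMatrix, distance_matrix
from barcodelim.likelihood import TreeLikelihood
from barcodelim.trees import (
    TreeError,
    _bipartitions,
    is_ultrametric,
    ltt,
    neighbor_joining,
    nj_bootstrap,
    node_ages,
    read_newick,
    strict_clock_lr_test,
    tree_from_string,
    write_newick,
)


# ----------------------------------------------------------------------
# Newick I/O and ultrametric utilities
# ----------------------------------------------------------------------

def test_parse_ultrametric_three_tips():
    t = tree_from_string("((a:1,b:1):1,c:2);")
    assert len(t.leaf_nodes()) == 3
    assert is_ultrametric(t)
    ages = node_ages(t)
    assert max(ages.values()) == pytest.approx(2.0)


def test_non_ultrametric_detected():
    t = tree_from_string("((a:1,b:2):1,c:2);")
    assert not is_ultrametric(t)


def test_parse_error_raises():
    with pytest.raises(TreeError):
        tree_from_string("((a:1,b:1:1,c:2);")


def test_newick_roundtrip_on_simulated_trees(tmp_path):
    for seed in range(10):
        t = bl.simulate_yule_tree(6, 1.0, seed)
        path = tmp_path / f"t{seed}.nwk"
        write_newick(t, path)
        again = read_newick(path)
        taxa = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
        assert _bipartitions(again, taxa) == _bipartitions(t, taxa)
        ages_a = sorted(node_ages(t).values())
        ages_b = sorted(node_ages(again).values())
        assert np.allclose(ages_a, ages_b, atol=1e-9)


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

def _quartet_matrix(split_ab_len, limbs):
    """Additive quartet distances for topology ab|cd."""
    la, lb, lc, ld = limbs
    vals = np.zeros((4, 4))
    d = {
        ("a", "b"): la + lb,
        ("a", "c"): la + split_ab_len + lc,
        ("a", "d"): la + split_ab_len + ld,
        ("b", "c"): lb + split_ab_len + lc,
        ("b", "d"): lb + split_ab_len + ld,
        ("c", "d"): lc + ld,
    }
    taxa = ["a", "b", "c", "d"]
    for (x, y), v in d.items():
        i, j = taxa.index(x), taxa.index(y)
        vals[i, j] = vals[j, i] = v
    return DistanceMatrix(taxa, vals)


def _brute_force_quartet(dm):
    """Oracle: pick the quartet split by the four-point condition."""
    t = dm.taxa
    sums = {
        frozenset([t[0], t[1]]): dm.get(t[0], t[1]) + dm.get(t[2], t[3]),
        frozenset([t[0], t[2]]): dm.get(t[0], t[2]) + dm.get(t[1], t[3]),
        frozenset([t[0], t[3]]): dm.get(t[0], t[3]) + dm.get(t[1], t[2]),
    }
    return min(sums, key=sums.get)


@pytest.mark.parametrize("seed", range(10))
def test_nj_recovers_additive_quartets(seed):
    rng = np.random.default_rng(seed)
    dm = _quartet_matrix(rng.uniform(0.5, 2.0),
                         rng.uniform(0.2, 1.5, size=4))
    tree = neighbor_joining(dm)
    taxa = frozenset(dm.taxa)
    bips = _bipartitions(tree, taxa)
    assert len(bips) == 1
    split = next(iter(bips))
    pair = _brute_force_quartet(dm)
    assert split in (pair, taxa - pair)


def test_nj_three_taxa_closed_form():
    vals = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]])
    tree = neighbor_joining(DistanceMatrix(list("abc"), vals))
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx(1.0)
    assert lengths["b"] == pytest.approx(2.0)
    assert lengths["c"] == pytest.approx(3.0)


def test_nj_matches_dendropy_on_simulated_data():
    sp = bl.simulate_yule_tree(6, 1.0, 11)
    aln = bl.simulate_alignment(sp, bl.SubstitutionModel.jc69(), 2000, 12)
    dm = distance_matrix(aln, method="jc69")
    mine = neighbor_joining(dm)
    csv = "," + ",".join(dm.taxa) + "\n" + "\n".join(
        t + "," + ",".join(str(v) for v in dm.values[i])
        for i, t in enumerate(dm.taxa))
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO(csv), delimiter=",")
    taxa = frozenset(dm.taxa)
    assert _bipartitions(mine, taxa) == _bipartitions(pdm.nj_tree(), taxa)


def test_nj_recovers_clock_tree_topology():
    sp = bl.simulate_yule_tree(7, 1.0, 21)
    ages = node_ages(sp)
    taxa = [lf.taxon.label for lf in sp.leaf_node_iter()]
    pdc = sp.phylogenetic_distance_matrix()
    vals = np.zeros((7, 7))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                d = pdc.distance(
                    sp.taxon_namespace.get_taxon(a),
                    sp.taxon_namespace.get_taxon(b))
                vals[i, j] = vals[j, i] = d
    tree = neighbor_joining(DistanceMatrix(taxa, vals))
    tset = frozenset(taxa)
    assert _bipartitions(tree, tset) == _bipartitions(sp, tset)


def test_nj_rejects_saturated_matrix():
    vals = np.array([[0, 1, math.inf], [1, 0, 1], [math.inf, 1, 0.0]])
    with pytest.raises(DistanceError, match="saturated"):
        neighbor_joining(DistanceMatrix(list("abc"), vals))


# ----------------------------------------------------------------------
# pruning likelihood
# ----------------------------------------------------------------------

def _brute_force_loglik(aln, tree, model):
    nodes = list(tree.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    tips = {nd.taxon.label: nd for nd in tree.leaf_node_iter()}
    eigen = model.eigen()
    cats = model.gamma_category_rates()
    pi = model.pi
    code = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
    total = 0.0
    for site in range(aln.masked_length):
        obs = {t: code.get(aln.row(t)[site:site + 1].tobytes()) for t in tips}
        lik = 0.0
        for rho in cats:
            for states in itertools.product(range(4), repeat=len(internals)):
                st = {id(internals[i]): s for i, s in enumerate(states)}
                for t, nd in tips.items():
                    st[id(nd)] = obs[t]
                pr = pi[st[id(tree.seed_node)]]
                for nd in nodes:
                    if nd is tree.seed_node or st[id(nd)] is None:
                        continue
                    P = model.transition_matrix(
                        (nd.edge.length or 0.0) * rho, eigen)
                    pr *= P[st[id(nd.parent_node)], st[id(nd)]]
                lik += pr / len(cats)
        lik *= 1.0 - model.p_inv
        if model.p_inv > 0:
            vals = [v for v in obs.values() if v is not None]
            lik += model.p_inv * (pi[vals[0]] if len(set(vals)) == 1
                                  else (1.0 if not vals else 0.0))
        total += math.log(lik)
    return total


@pytest.mark.parametrize("model_name", ["jc", "gtr_ig"])
def test_pruning_matches_exhaustive_state_sum(model_name):
    model = (bl.SubstitutionModel.jc69() if model_name == "jc" else
             bl.SubstitutionModel.gtr([0.3, 0.2, 0.25, 0.25],
                                      [1.5, 4, 0.7, 1.2, 6, 1],
                                      p_inv=0.1, alpha=0.7))
    tree = tree_from_string("((a:0.1,b:0.25):0.05,(c:0.3,d:0.12):0.07);")
    aln = alignment_from_dict(
        {"a": "ACGT", "b": "ACCA", "c": "AGGT", "d": "ATGT"})
    engine = TreeLikelihood(aln, tree, model)
    assert engine.log_likelihood() == pytest.approx(
        _brute_force_loglik(aln, tree, model), abs=1e-9)


def test_two_taxon_single_site_closed_form():
    model = bl.SubstitutionModel.jc69()
    t = 0.3
    tree = tree_from_string(f"(a:{t / 2},b:{t / 2});")
    aln = alignment_from_dict({"a": "A", "b": "G"})
    # pi_A * P_AG(t) with JC's off-diagonal (1 - exp(-4t/3))/4
    expected = math.log(0.25 * (1 - math.exp(-4 * t / 3)) / 4)
    engine = TreeLikelihood(aln, tree, model)
    assert engine.log_likelihood() == pytest.approx(expected, abs=1e-10)


def test_likelihood_invariant_under_rerooting():
    model = bl.SubstitutionModel.gtr([0.3, 0.2, 0.25, 0.25],
                                     [1.5, 4, 0.7, 1.2, 6, 1], alpha=0.7)
    aln = alignment_from_dict(
        {"a": "ACGT", "b": "ACCA", "c": "AGGT", "d": "ATGT"})
    t1 = tree_from_string("((a:0.1,b:0.25):0.05,(c:0.3,d:0.12):0.07);")
    l1 = TreeLikelihood(aln, t1, model).log_likelihood()
    t2 = t1.clone(depth=1)
    nd = t2.find_node_with_taxon_label("c")
    t2.reroot_at_edge(nd.edge, length1=0.1, length2=0.2,
                      update_bipartitions=False)
    l2 = TreeLikelihood(aln, t2, model).log_likelihood()
    assert l1 == pytest.approx(l2, abs=1e-9)


def test_all_gap_taxon_leaves_likelihood_unchanged():
    model = bl.SubstitutionModel.gtr([0.3, 0.2, 0.25, 0.25],
                                     [1.5, 4, 0.7, 1.2, 6, 1], alpha=0.7)
    base = alignment_from_dict(
        {"a": "ACGT", "b": "ACCA", "c": "AGGT", "d": "ATGT"})
    t1 = tree_from_string("((a:0.1,b:0.25):0.05,(c:0.3,d:0.12):0.07);")
    l1 = TreeLikelihood(base, t1, model).log_likelihood()
    withe = alignment_from_dict(
        {"a": "ACGT", "b": "ACCA", "c": "AGGT", "d": "ATGT", "e": "----"})
    t2 = tree_from_string(
        "((a:0.1,b:0.25):0.05,(c:0.3,d:0.12):0.07,e:0.4);")
    l2 = TreeLikelihood(withe, t2, model).log_likelihood()
    assert l1 == pytest.approx(l2, abs=1e-9)


# ----------------------------------------------------------------------
# strict clock LR test
# ----------------------------------------------------------------------

def _clock_dataset(seed, accelerate=False):
    sp = bl.simulate_yule_tree(8, 1.0, seed)
    for nd in sp.preorder_node_iter():
        if nd.edge.length:
            nd.edge.length *= 0.15
    if accelerate:
        next(sp.leaf_node_iter()).edge.length *= 5
    model = bl.SubstitutionModel.k80(kappa=2.0)
    aln = bl.simulate_alignment(sp, model, 1000, seed + 7)
    topo = neighbor_joining(distance_matrix(aln, method="jc69"))
    return aln, topo, model


def test_clock_test_nesting_and_fields():
    aln, topo, model = _clock_dataset(301)
    res = strict_clock_lr_test(aln, topo, model)
    assert res.logL_clock <= res.logL_free + 1e-6
    assert res.df == 6
    assert 0.0 <= res.p_value <= 1.0
    assert res.lr == pytest.approx(
        2 * (res.logL_free - res.logL_clock), abs=1e-9)


def test_clock_test_rejects_rate_accelerated_branch():
    rejections = 0
    for seed in range(500, 506):
        aln, topo, model = _clock_dataset(seed, accelerate=True)
        res = strict_clock_lr_test(aln, topo, model)
        rejections += res.p_value < 0.05
    assert rejections >= 5


def test_clock_test_calibrated_under_true_clock():
    rejections = 0
    for seed in range(300, 306):
        aln, topo, model = _clock_dataset(seed)
        res = strict_clock_lr_test(aln, topo, model)
        rejections += res.p_value < 0.05
    assert rejections <= 1


# ----------------------------------------------------------------------
# LTT
# ----------------------------------------------------------------------

def test_ltt_balanced_and_caterpillar():
    bal = tree_from_string("((a:1,b:1):1,(c:1,d:1):1);")
    curve = ltt(bal)
    assert curve.counts == [2, 3, 4]  # two cherries at equal height split ties
    cat = tree_from_string("(((a:1,b:1):1,c:2):1,d:3);")
    assert ltt(cat).counts == [2, 3, 4]
    assert ltt(cat).times == [-3.0, -2.0, -1.0]


def test_ltt_step_count_and_errors():
    for seed in range(3):
        t = bl.simulate_yule_tree(9, 1.0, seed)
        curve = ltt(t)
        assert len(curve.counts) == 8
        assert curve.counts[0] == 2 and curve.counts[-1] == 9
        assert all(b >= a for a, b in zip(curve.counts, curve.counts[1:]))
    with pytest.raises(TreeError, match="ultrametric"):
        ltt(tree_from_string("((a:1,b:2):1,c:2);"))


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------

def test_bootstrap_reproducible_and_bounded():
    sp = bl.simulate_yule_tree(6, 1.0, 31)
    aln = bl.simulate_alignment(sp, bl.SubstitutionModel.jc69(), 800, 32)
    r1 = nj_bootstrap(aln, method="jc69", n_replicates=25, seed=9)
    r2 = nj_bootstrap(aln, method="jc69", n_replicates=25, seed=9)
    assert r1.support == r2.support
    assert all(0.0 <= v <= 100.0 for v in r1.support.values())


def test_bootstrap_high_support_on_clean_data():
    # deep split between two tight clades -> near-100% support
    t = tree_from_string(
        "(((a:0.01,b:0.01):0.5,(c:0.01,d:0.01):0.5):0.0,e:0.51);")
    aln = bl.simulate_alignment(t, bl.SubstitutionModel.jc69(), 2000, 5)
    res = nj_bootstrap(aln, method="jc69", n_replicates=50, seed=1)
    sup = res.support_for({"a", "b"})
    assert sup is not None and sup >= 95.0
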