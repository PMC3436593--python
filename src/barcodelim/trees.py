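"""Tree utilities: Newick I/O, neighbor joining, clock test, LTT curves.

Trees are dendropy :class:`~dendropy.Tree` objects throughout. Two length
conventions coexist: inference trees carry expected substitutions per site,
clock (ultrametric) trees carry relative time with tips at age 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.stats import chi2

from .alignment import Alignment
from .distances import DistanceMatrix, DistanceError, distance_matrix
from .likelihood import TreeLikelihood
from .models import SubstitutionModel


class TreeError(ValueError):
    pass


# -- Newick I/O ---------------------------------------------------------

def read_newick(path) -> dendropy.Tree:
    """Read one Newick tree; internal labels are kept as node annotations."""
    try:
        return dendropy.Tree.get(path=str(path), schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeError(f"failed to parse Newick file {path}: {exc}") from exc


def tree_from_string(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"failed to parse Newick string: {exc}") from exc


def write_newick(tree: dendropy.Tree, path=None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


# -- ultrametric utilities ---------------------------------------------

def node_ages(tree: dendropy.Tree) -> dict:
    """Age (time before present) per node: max path length to a tip below.

    For an ultrametric tree this is the node height; tips get age 0.
    Returns a dict keyed by node id."""
    ages: dict[int, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            ages[id(nd)] = 0.0
        else:
            ages[id(nd)] = max(
                ages[id(ch)] + (ch.edge.length or 0.0) for ch in nd.child_nodes()
            )
    return ages


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    """True if all root-to-tip path lengths agree within rel_tol * depth."""
    depths = []
    for lf in tree.leaf_node_iter():
        d, nd = 0.0, lf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(d)
    depth = max(depths)
    if depth == 0:
        return True
    return (depth - min(depths)) <= rel_tol * depth


def check_binary(tree: dendropy.Tree) -> None:
    for nd in tree.preorder_internal_node_iter():
        nch = len(nd.child_nodes())
        if nd is tree.seed_node:
            if nch != 2:
                raise TreeError("tree must be rooted and strictly bifurcating")
        elif nch != 2:
            raise TreeError("tree contains a polytomy; resolve it first")


@dataclass
class LTTCurve:
    """Lineage-through-time steps, ordered from the root to the present.

    ``times`` are relative times before present with negative sign (0 =
    present, matching the convention of plotting time into the past);
    ``counts[i]`` is the number of lineages from ``times[i]`` onward."""

    times: list[float]
    counts: list[int]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time\tlineages\n")
            for t, c in zip(self.times, self.counts):
                fh.write(f"{t:.10g}\t{c}\n")


def ltt(tree: dendropy.Tree, rel_tol: float = 1e-6) -> LTTCurve:
    """LTT curve of a binary ultrametric tree: one step per internal node."""
    if not is_ultrametric(tree, rel_tol):
        raise TreeError("LTT requires an ultrametric tree")
    check_binary(tree)
    ages = node_ages(tree)
    internal = sorted(
        (ages[id(nd)] for nd in tree.preorder_internal_node_iter()),
        reverse=True,
    )
    counts = list(range(2, len(internal) + 2))
    return LTTCurve(times=[-a for a in internal], counts=counts)


# -- neighbor joining ---------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; deterministic lexicographic tie-break.

    Negative branch lengths are clamped to zero (the deficit is recorded in
    the tree's ``nj_negative_deficit`` attribute). Saturated entries raise.
    """
    if dm.n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    if dm.any_saturated() or not np.isfinite(dm.condensed()).all():
        raise DistanceError(
            "distance matrix contains saturated/non-finite entries; "
            "use a richer model or remove the offending taxa"
        )
    taxon_ns = dendropy.TaxonNamespace(dm.taxa)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes = []
    for t in dm.taxa:
        nd = dendropy.Node(taxon=taxon_ns.get_taxon(t))
        nodes.append(nd)
    labels = list(dm.taxa)  # smallest original label per cluster (tie-break)
    d = dm.values.copy()
    active = list(range(dm.n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                if q[a, b] <= qmin + 1e-12:
                    ia, ib = active[a], active[b]
                    key = tuple(sorted((labels[ia], labels[ib])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        ia, ib = active[a], active[b]
        dij = sub[a, b]
        limb_a = 0.5 * dij + (rowsum[a] - rowsum[b]) / (2.0 * (r - 2))
        limb_b = dij - limb_a
        parent = dendropy.Node()
        parent.add_child(nodes[ia])
        parent.add_child(nodes[ib])
        nodes[ia].edge.length = clamp(limb_a)
        nodes[ib].edge.length = clamp(limb_b)
        new_index = len(nodes)
        nodes.append(parent)
        labels.append(min(labels[ia], labels[ib]))
        newd = np.zeros(len(nodes))
        row = np.zeros((1, d.shape[1]))
        d = np.vstack([d, row])
        d = np.hstack([d, np.zeros((d.shape[0], 1))])
        for k in active:
            if k in (ia, ib):
                continue
            dk = 0.5 * (d[ia, k] + d[ib, k] - dij)
            d[new_index, k] = d[k, new_index] = max(dk, 0.0)
        active = [k for k in active if k not in (ia, ib)] + [new_index]
    # resolve the final three clusters around an unrooted central node
    i, j, k = active
    center = dendropy.Node()
    for idx in (i, j, k):
        center.add_child(nodes[idx])
    nodes[i].edge.length = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    nodes[j].edge.length = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    nodes[k].edge.length = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    tree.seed_node = center
    tree.nj_negative_deficit = deficit
    tree.is_rooted = False
    return tree


# -- strict clock likelihood-ratio test ---------------------------------

@dataclass
class ClockTestResult:
    logL_free: float
    logL_clock: float
    lr: float
    df: int
    p_value: float


def _initial_heights(tree: dendropy.Tree) -> dict[int, float]:
    """Mean tip-path length below each node, as starting clock heights."""
    below: dict[int, tuple[float, int]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = (0.0, 1)
        else:
            tot, cnt = 0.0, 0
            for ch in nd.child_nodes():
                s, c = below[id(ch)]
                tot += s + c * (ch.edge.length or 0.0)
                cnt += c
            below[id(nd)] = (tot, cnt)
    return {k: s / c for k, (s, c) in below.items()}


def _set_clock_lengths(tree: dendropy.Tree, increments: np.ndarray,
                       internal: list) -> None:
    heights: dict[int, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            heights[id(nd)] = 0.0
    for i, nd in enumerate(internal):
        hmax = max(heights[id(ch)] for ch in nd.child_nodes())
        heights[id(nd)] = hmax + max(increments[i], 0.0)
        for ch in nd.child_nodes():
            ch.edge.length = heights[id(nd)] - heights[id(ch)]


def strict_clock_lr_test(aln: Alignment, topology: dendropy.Tree,
                         model: SubstitutionModel,
                         outgroup: str | None = None) -> ClockTestResult:
    """Likelihood-ratio test of a strict molecular clock on a fixed topology.

    The free model optimises all 2n-3 branch lengths of the unrooted
    topology; the clock model optimises n-1 node heights on a rooted version
    (midpoint rooting by default, an outgroup taxon if supplied). LR is
    referred to chi^2 with n-2 degrees of freedom.
    """
    n = len(topology.leaf_nodes())
    if n < 3:
        raise TreeError("clock test needs at least 3 taxa")
    free_tree = topology.clone(depth=1)
    free_tree.deroot()
    engine = TreeLikelihood(aln, free_tree, model)
    logl_free = engine.optimize_branch_lengths()

    clock_tree = free_tree.clone(depth=1)
    if outgroup is not None:
        og = clock_tree.find_node_with_taxon_label(outgroup)
        if og is None:
            raise TreeError(f"outgroup taxon not found: {outgroup}")
        clock_tree.reroot_at_edge(og.edge, update_bipartitions=False)
    else:
        clock_tree.reroot_at_midpoint(update_bipartitions=False)
    # ensure strictly bifurcating root with exactly 2 children
    if len(clock_tree.seed_node.child_nodes()) > 2:
        ch = clock_tree.seed_node.child_nodes()[0]
        clock_tree.reroot_at_edge(ch.edge, update_bipartitions=False)

    internal = [nd for nd in clock_tree.postorder_internal_node_iter()]
    heights0 = _initial_heights(clock_tree)
    x0 = []
    hts = {id(nd): 0.0 for nd in clock_tree.leaf_node_iter()}
    for nd in internal:
        hmax_child = max(heights0[id(ch)] for ch in nd.child_nodes())
        x0.append(max(heights0[id(nd)] - hmax_child, 1e-8))
    x0 = np.asarray(x0)
    clock_engine = TreeLikelihood(aln, clock_tree, model)

    from scipy.optimize import minimize

    def neg(x: np.ndarray) -> float:
        _set_clock_lengths(clock_tree, x, internal)
        try:
            return -clock_engine.log_likelihood()
        except Exception:
            return 1e300

    res = minimize(neg, x0, method="L-BFGS-B",
                   bounds=[(0.0, 20.0)] * len(x0),
                   options={"maxiter": 500, "ftol": 1e-10})
    logl_clock = -float(res.fun)
    if logl_clock > logl_free + 0.01:
        raise RuntimeError(
            "clock optimum exceeds free optimum; branch-length optimisation "
            f"failed (free={logl_free:.4f}, clock={logl_clock:.4f})"
        )
    logl_clock = min(logl_clock, logl_free)
    lr = 2.0 * (logl_free - logl_clock)
    df = n - 2
    return ClockTestResult(logl_free, logl_clock, lr, df,
                           float(chi2.sf(lr, df)))


# -- NJ bootstrap --------------------------------------------------------

def _bipartitions(tree: dendropy.Tree, all_taxa: frozenset) -> set[frozenset]:
    """Internal-edge splits, canonicalised to the side not containing the
    lexicographically smallest taxon (orientation-independent)."""
    ref = min(all_taxa)
    out = set()
    below: dict[int, frozenset] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset([nd.taxon.label])
        else:
            below[id(nd)] = frozenset().union(*(below[id(c)] for c in nd.child_nodes()))
    for nd in tree.preorder_node_iter():
        side = below[id(nd)]
        if nd is tree.seed_node or len(side) < 2 or len(all_taxa - side) < 2:
            continue
        if ref in side:
            side = all_taxa - side
        out.add(side)
    return out


@dataclass
class BootstrapResult:
    tree: dendropy.Tree
    support: dict[frozenset, float]  # percentage per original bipartition
    n_effective: int
    n_dropped: int

    def support_for(self, taxa) -> float | None:
        all_taxa = frozenset(
            lf.taxon.label for lf in self.tree.leaf_node_iter())
        side = frozenset(taxa)
        if min(all_taxa) in side:
            side = all_taxa - side
        return self.support.get(side)


def nj_bootstrap(aln: Alignment, method: str = "k2p_closed",
                 model: SubstitutionModel | None = None,
                 n_replicates: int = 100, seed: int = 0) -> BootstrapResult:
    """Site-resampled NJ bootstrap support for the full-data NJ tree.

    Replicates whose resampled distance matrix contains saturated entries
    are dropped and counted in ``n_dropped``.
    """
    if n_replicates < 1:
        raise TreeError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    base_dm = distance_matrix(aln, method=method, model=model)
    base_tree = neighbor_joining(base_dm)
    all_taxa = frozenset(aln.taxa)
    base_bips = _bipartitions(base_tree, all_taxa)
    hits = {b: 0 for b in base_bips}
    rows = aln.masked_rows()
    n_sites = rows.shape[1]
    dropped = 0
    effective = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep = Alignment(list(aln.taxa), rows[:, cols])
        try:
            dm = distance_matrix(rep, method=method, model=model)
            t = neighbor_joining(dm)
        except (DistanceError, TreeError):
            dropped += 1
            continue
        effective += 1
        for b in _bipartitions(t, all_taxa):
            if b in hits:
                hits[b] += 1
    if effective == 0:
        raise TreeError("all bootstrap replicates failed")
    support = {b: 100.0 * h / effective for b, h in hits.items()}
    return BootstrapResult(base_tree, support, effective, dropped)
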