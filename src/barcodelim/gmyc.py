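"""General mixed Yule-coalescent (GMYC) species delimitation.

The model reads a rooted binary ultrametric tree as the realisation of two
branching processes separated by one or more switch times (thresholds):
rootward of a threshold, lineages speciate under a generalised Yule process
with hazard ``lambda_div * k**p_div`` (k = number of between-species
lineages); tipward, lineages within each delimited species coalesce with
pooled hazard ``lambda_coal * (sum_j n_j*(n_j - 1))**p_coal``. The waiting
times between successive branching events are exponential with the pooled
piecewise-constant hazard; maximising their summed log-likelihood over all
candidate thresholds (the observed node heights) delimits species as the
maximal subtrees younger than the chosen threshold.

Bookkeeping convention: a diversification event is generated by the hazard
of the interval rootward of it (forward-time Yule waiting), a coalescent
event by the hazard of the interval tipward of it (backward-time Kingman
waiting); the integrated hazard runs over every interval from the root to
the present. This reduces exactly to the Yule likelihood when every node is
a speciation and to the Kingman likelihood when every node is a
coalescence, and it makes the log-likelihood separable in the two parameter
pairs for any temporally consistent assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .trees import TreeError, check_binary, is_ultrametric, node_ages

_P_BOUNDS = (-3.0, 8.0)
DIVERSIFICATION = "diversification"
COALESCENT = "coalescent"


class GMYCError(ValueError):
    pass


# ----------------------------------------------------------------------
# tree digest
# ----------------------------------------------------------------------

class _TreeData:
    """Integer-rank digest of a binary ultrametric tree.

    Internal nodes are ranked 1..n-1 by decreasing age (pre-order index
    breaks exact ties so a parent always outranks its children); tips carry
    the sentinel rank n. Interval i runs from the i-th oldest node down to
    the next node (or the present), so a branch above a node with rank r and
    parent rank q crosses intervals q..r-1 — exact integer logic, immune to
    floating-point ties from near-polytomies.
    """

    def __init__(self, tree) -> None:
        if not is_ultrametric(tree):
            raise GMYCError("GMYC requires an ultrametric tree")
        check_binary(tree)
        ages = node_ages(tree)
        order = {id(nd): i for i, nd in enumerate(tree.preorder_node_iter())}
        internal = [nd for nd in tree.preorder_internal_node_iter()]
        if not internal:
            raise GMYCError("tree has no internal nodes")
        internal.sort(key=lambda nd: (-ages[id(nd)], order[id(nd)]))
        self.nodes = internal
        self.n_tips = len(internal) + 1
        n = self.n_tips
        self.rank = {id(nd): i + 1 for i, nd in enumerate(internal)}
        self.heights = np.array([ages[id(nd)] for nd in internal])
        bounds = np.concatenate([self.heights, [0.0]])
        # x[i] = length of interval i+1 (0-based storage)
        self.x = np.maximum(bounds[:-1] - bounds[1:], 0.0)
        self.tips = [lf for lf in tree.leaf_node_iter()]
        self.tip_labels = [lf.taxon.label for lf in self.tips]
        # branches: (parent_rank, child_rank, node) for every non-root node
        self.branches = []
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            r = self.rank[id(nd)] if not nd.is_leaf() else n
            q = self.rank[id(nd.parent_node)]
            self.branches.append((q, r, nd))
        # children ranks per internal node, tips below per internal node
        self.tips_below: dict[int, list[str]] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                self.tips_below[id(nd)] = [nd.taxon.label]
            else:
                acc: list[str] = []
                for ch in nd.child_nodes():
                    acc.extend(self.tips_below[id(ch)])
                self.tips_below[id(nd)] = acc
        self.root = tree.seed_node

    def n_intervals(self) -> int:
        return self.n_tips - 1


# ----------------------------------------------------------------------
# waiting-time schedule
# ----------------------------------------------------------------------

@dataclass
class WaitingTimeSchedule:
    """Per-interval lineage bookkeeping for one div/coal assignment.

    ``x``: interval lengths, root to present (sum = root height).
    ``div_counts``: between-species lineage count per interval.
    ``coal_pair_sums``: sum_j n_ij*(n_ij - 1) per interval.
    ``events``: one ``(kind, hazard_argument)`` per branching event carrying
    a log-hazard term (the root only when it is a coalescence).
    """

    x: np.ndarray
    div_counts: np.ndarray
    coal_pair_sums: np.ndarray
    events: list[tuple[str, float]]
    cluster_nodes: list = field(default_factory=list)
    singleton_tips: list[str] = field(default_factory=list)


def _schedule_from_mask(data: _TreeData, coal_mask: np.ndarray) -> WaitingTimeSchedule:
    """Assignment given as a boolean per internal rank (True = coalescent).

    Temporal consistency (no diversification node below a coalescent node)
    must hold; violations raise naming the offending pair.
    """
    n = data.n_tips
    nint = data.n_intervals()
    coal_of = {}
    for i, nd in enumerate(data.nodes):
        coal_of[id(nd)] = bool(coal_mask[i])
    for nd in data.nodes:
        p = nd.parent_node
        if p is not None and coal_of[id(p)] and not coal_of[id(nd)]:
            raise GMYCError(
                "inconsistent assignment: diversification node below "
                f"coalescent node (ranks {data.rank[id(p)]} -> {data.rank[id(nd)]})"
            )
    # cluster roots: coalescent nodes whose parent is diversification (or root)
    cluster_nodes = []
    species_of: dict[int, int] = {}
    for nd in data.nodes:  # rank order: parents before children
        if not coal_of[id(nd)]:
            continue
        p = nd.parent_node
        if p is None or not coal_of[id(p)]:
            species_of[id(nd)] = len(cluster_nodes)
            cluster_nodes.append(nd)
        else:
            species_of[id(nd)] = species_of[id(p)]
    n_species = len(cluster_nodes)
    div_counts = np.zeros(nint)
    sp_counts = np.zeros((max(n_species, 1), nint))
    for q, r, nd in data.branches:
        lo, hi = q - 1, r - 1  # 0-based interval slice [lo, hi)
        parent_coal = coal_of[id(nd.parent_node)]
        if parent_coal:
            sp_counts[species_of[id(nd.parent_node)], lo:hi] += 1
        else:
            div_counts[lo:hi] += 1
    coal_pair_sums = (sp_counts * (sp_counts - 1.0)).sum(axis=0)
    events: list[tuple[str, float]] = []
    for i, nd in enumerate(data.nodes):
        m = i + 1  # rank
        if coal_of[id(nd)]:
            events.append((COALESCENT, float(coal_pair_sums[m - 1])))
        elif m >= 2:
            events.append((DIVERSIFICATION, float(div_counts[m - 2])))
    singles = []
    for lf in data.tips:
        if not coal_of[id(lf.parent_node)]:
            singles.append(lf.taxon.label)
    return WaitingTimeSchedule(
        x=data.x.copy(), div_counts=div_counts, coal_pair_sums=coal_pair_sums,
        events=events, cluster_nodes=cluster_nodes, singleton_tips=singles,
    )


def build_schedule(tree, assignment: dict) -> WaitingTimeSchedule:
    """Public schedule builder; ``assignment`` maps internal dendropy nodes
    to ``"diversification"`` or ``"coalescent"``."""
    data = _TreeData(tree)
    mask = np.zeros(len(data.nodes), dtype=bool)
    for i, nd in enumerate(data.nodes):
        kind = assignment.get(nd)
        if kind is None:
            raise GMYCError(f"no assignment for internal node rank {i + 1}")
        if kind not in (DIVERSIFICATION, COALESCENT):
            raise GMYCError(f"unknown class: {kind}")
        mask[i] = kind == COALESCENT
    return _schedule_from_mask(data, mask)


def waiting_time_loglik(schedule: WaitingTimeSchedule, lambda_div: float,
                        p_div: float, lambda_coal: float, p_coal: float) -> float:
    """Log-likelihood of the schedule under fixed rate parameters.

    Classes with zero lineages contribute nothing to the hazard; an event
    whose class hazard is zero yields -inf rather than an exception.
    """
    if lambda_div < 0 or lambda_coal < 0:
        raise GMYCError("rates must be non-negative")
    k = schedule.div_counts
    c = schedule.coal_pair_sums
    hazard = np.zeros_like(schedule.x)
    mask = k > 0
    hazard[mask] += lambda_div * np.power(k[mask], p_div)
    mask = c > 0
    hazard[mask] += lambda_coal * np.power(c[mask], p_coal)
    ll = -float(hazard @ schedule.x)
    for kind, arg in schedule.events:
        rate = (lambda_div * arg ** p_div if kind == DIVERSIFICATION
                else lambda_coal * arg ** p_coal if arg > 0 else 0.0)
        if rate <= 0:
            return -math.inf
        ll += math.log(rate)
    return ll


# ----------------------------------------------------------------------
# profile maximum likelihood
# ----------------------------------------------------------------------

def _profile_class(event_args: np.ndarray, interval_args: np.ndarray,
                   x: np.ndarray) -> tuple[float, float, float]:
    """Maximise E*log(lam) + p*sum(log A_ev) - lam*sum(A_i^p x_i) over
    (lam, p); lam has a closed form given p. Returns (logL, lam, p)."""
    n_events = event_args.size
    active = interval_args > 0
    if n_events == 0:
        return 0.0, 0.0, math.nan
    log_ev = np.log(event_args)
    a = interval_args[active]
    xs = x[active]
    log_a = np.log(a)

    def value(p: float) -> float:
        w = float(np.exp(p * log_a) @ xs)
        if w <= 0:
            return -math.inf
        return n_events * (math.log(n_events / w) - 1.0) + p * float(log_ev.sum())

    res = minimize_scalar(lambda p: -value(p), bounds=_P_BOUNDS,
                          method="bounded", options={"xatol": 1e-7})
    p_hat = float(res.x)
    w = float(np.exp(p_hat * log_a) @ xs)
    lam_hat = n_events / w
    return value(p_hat), lam_hat, p_hat


def _fit_schedule(schedule: WaitingTimeSchedule) -> tuple[float, dict]:
    div_ev = np.array([a for kind, a in schedule.events
                       if kind == DIVERSIFICATION], dtype=float)
    coal_ev = np.array([a for kind, a in schedule.events
                        if kind == COALESCENT], dtype=float)
    if (coal_ev == 0).any():
        return -math.inf, {}
    ll_d, lam_d, p_d = _profile_class(div_ev, schedule.div_counts, schedule.x)
    ll_c, lam_c, p_c = _profile_class(coal_ev, schedule.coal_pair_sums, schedule.x)
    params = {"lambda_div": lam_d, "p_div": p_d,
              "lambda_coal": lam_c, "p_coal": p_c}
    return ll_d + ll_c, params


# ----------------------------------------------------------------------
# model fits
# ----------------------------------------------------------------------

@dataclass
class GMYCFit:
    """Fit summary for one GMYC model (null, single or multiple threshold)."""

    mode: str
    thresholds: list[float]  # negative relative times before present
    parameters: dict
    log_likelihood: float
    null_log_likelihood: float
    lr: float
    lr_df: int
    p_value: float
    clusters: list[list[str]]
    singletons: list[str]
    confidence_range: tuple[int, int]  # min-max cluster count within 2 logL

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_entities(self) -> int:
        return len(self.clusters) + len(self.singletons)


def _entities_from_schedule(schedule: WaitingTimeSchedule, data: _TreeData):
    clusters = [sorted(data.tips_below[id(nd)]) for nd in schedule.cluster_nodes]
    singletons = sorted(schedule.singleton_tips)
    return clusters, singletons


def _single_candidate_mask(data: _TreeData, j: int) -> np.ndarray:
    """Threshold just rootward of the rank-j node: ranks >= j coalescent.
    j = n (beyond the youngest node) makes every node a diversification."""
    mask = np.zeros(len(data.nodes), dtype=bool)
    mask[j - 1:] = True
    return mask


def fit_gmyc_null(tree) -> GMYCFit:
    """Coalescent-only model: every branching event is a coalescence."""
    data = _TreeData(tree)
    sched = _schedule_from_mask(data, np.ones(len(data.nodes), dtype=bool))
    ll, params = _fit_schedule(sched)
    clusters, singles = _entities_from_schedule(sched, data)
    return GMYCFit("null", [], params, ll, ll, 0.0, 0, 1.0,
                   clusters, singles, (1, 1))


def fit_gmyc_single(tree) -> GMYCFit:
    """Single-threshold GMYC over all candidate node-height thresholds.

    The candidate maximising the profile log-likelihood is selected; the LR
    against the coalescent-only null is referred to chi^2(3). The confidence
    range is the min-max cluster count over candidates within 2 logL units
    of the maximum.
    """
    data = _TreeData(tree)
    n = data.n_tips
    if n < 3:
        raise GMYCError("GMYC needs at least 3 tips")
    results = []
    for j in range(1, n + 1):
        sched = _schedule_from_mask(data, _single_candidate_mask(data, j))
        ll, params = _fit_schedule(sched)
        results.append((ll, j, sched, params))
    null_ll = results[0][0]  # j=1: everything coalescent
    best = max(results, key=lambda r: r[0])
    ll, j, sched, params = best
    clusters, singles = _entities_from_schedule(sched, data)
    lo = hi = len(clusters)
    for rll, _, rsched, _ in results:
        if ll - rll <= 2.0:
            k = len(rsched.cluster_nodes)
            lo, hi = min(lo, k), max(hi, k)
    lr = 2.0 * (ll - null_ll)
    threshold = -data.heights[j - 1] if j <= n - 1 else 0.0
    return GMYCFit("single", [float(threshold)], params, ll, null_ll,
                   lr, 3, float(chi2.sf(lr, 3)), clusters, singles, (lo, hi))


def _mask_from_cluster_roots(data: _TreeData, roots: set) -> np.ndarray:
    mask = np.zeros(len(data.nodes), dtype=bool)
    inside: dict[int, bool] = {}
    for nd in data.nodes:  # parents first
        p = nd.parent_node
        flag = (id(nd) in roots) or (p is not None and inside.get(id(p), False))
        inside[id(nd)] = flag
    for i, nd in enumerate(data.nodes):
        mask[i] = inside[id(nd)]
    return mask


def fit_gmyc_multiple(tree, tol: float = 1e-4, max_iter: int = 200) -> GMYCFit:
    """Multiple-threshold GMYC by greedy local search.

    Starting from the single-threshold optimum, one species subtree at a
    time is split at its root or merged with its sister entity; the proposal
    with the largest log-likelihood gain is accepted until no proposal
    improves by more than ``tol``. Ties are broken toward fewer thresholds.
    The LR against the single-threshold model uses df = number of extra
    thresholds.
    """
    single = fit_gmyc_single(tree)
    data = _TreeData(tree)
    label_to_tip = {lf.taxon.label: lf for lf in data.tips}
    # reconstruct cluster-root set of the single optimum
    roots: set[int] = set()
    node_by_tipset = {frozenset(data.tips_below[id(nd)]): nd for nd in data.nodes}
    root_nodes: dict[int, object] = {}
    for cl in single.clusters:
        nd = node_by_tipset[frozenset(cl)]
        roots.add(id(nd))
        root_nodes[id(nd)] = nd

    def evaluate(rts: set[int]):
        sched = _schedule_from_mask(data, _mask_from_cluster_roots(data, rts))
        ll, params = _fit_schedule(sched)
        return ll, sched, params

    current_ll, current_sched, current_params = evaluate(roots)
    visited = [(current_ll, current_sched)]

    def n_thresholds(rts: set[int]) -> int:
        hs = {round(data.heights[data.rank[r] - 1], 12) for r in rts}
        return len(hs)

    for _ in range(max_iter):
        proposals: list[tuple[float, int, set[int]]] = []
        # split: replace a cluster root by its internal children
        for rid in sorted(roots, key=lambda r: data.rank[r]):
            nd = root_nodes[rid]
            new = set(roots)
            new.discard(rid)
            for ch in nd.child_nodes():
                if not ch.is_leaf():
                    new.add(id(ch))
                    root_nodes[id(ch)] = ch
            proposals.append((0.0, 0, new))
        # merge: a diversification node whose children subtrees are entities
        coal_mask = _mask_from_cluster_roots(data, roots)
        coal_ids = {id(nd) for i, nd in enumerate(data.nodes) if coal_mask[i]}
        for nd in data.nodes:
            if id(nd) in coal_ids:
                continue
            ok = True
            for ch in nd.child_nodes():
                if ch.is_leaf():
                    continue
                if id(ch) not in roots:
                    ok = False
                    break
            if not ok:
                continue
            new = set(roots)
            for ch in nd.child_nodes():
                new.discard(id(ch))
            new.add(id(nd))
            root_nodes[id(nd)] = nd
            proposals.append((0.0, 0, new))
        best = None
        for _, _, cand in proposals:
            ll, sched, params = evaluate(cand)
            key = (ll, -n_thresholds(cand))
            if best is None or key > best[0]:
                best = (key, cand, ll, sched, params)
        if best is None or best[2] - current_ll <= tol:
            break
        _, roots, current_ll, current_sched, current_params = best
        visited.append((current_ll, current_sched))

    current_ll = max(current_ll, single.log_likelihood)
    clusters, singles = _entities_from_schedule(current_sched, data)
    heights = sorted({round(float(data.heights[data.rank[r] - 1]), 12)
                      for r in roots}, reverse=True)
    thresholds = [-h for h in heights]
    lo = hi = len(clusters)
    for ll, sched in visited:
        if current_ll - ll <= 2.0:
            k = len(sched.cluster_nodes)
            lo, hi = min(lo, k), max(hi, k)
    lr = 2.0 * (current_ll - single.log_likelihood)
    df = max(len(thresholds) - 1, 0)
    p = float(chi2.sf(lr, df)) if df > 0 else 1.0
    return GMYCFit("multiple", thresholds, current_params, current_ll,
                   single.null_log_likelihood, lr, df, p,
                   clusters, singles, (lo, hi))


def extract_entities(fit: GMYCFit) -> list[tuple[str, int, str]]:
    """Deterministic (tip, entity id, kind) listing; clusters first, each
    sorted by its smallest member, then singletons alphabetically."""
    rows: list[tuple[str, int, str]] = []
    eid = 0
    for cl in sorted(fit.clusters, key=lambda c: c[0]):
        eid += 1
        for tip in cl:
            rows.append((tip, eid, "cluster"))
    for tip in fit.singletons:
        eid += 1
        rows.append((tip, eid, "singleton"))
    return rows


def write_entities_tsv(fit: GMYCFit, path) -> None:
    with open(path, "w") as fh:
        fh.write("tip\tentity\tkind\n")
        for tip, eid, kind in extract_entities(fit):
            fh.write(f"{tip}\t{eid}\t{kind}\n")
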