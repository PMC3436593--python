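"""Entropy-based substitution-saturation test (Iss against Iss.c).

The index of substitution saturation Iss is the mean of sitewise nucleotide
entropies divided by the full-saturation entropy expected from the global
base frequencies; it approaches 0 for invariant data and 1 when every site
is an independent draw from the base composition. Iss is compared against
critical values Iss.c — the Iss level at which tree reconstruction starts
to fail — tabulated separately for symmetric and asymmetric reference
topologies and for OTU counts of 4, 8, 16 and 32; data sets with more taxa
are evaluated on random 32-OTU subsamples.

The shipped Iss.c table is *synthetic*: it is re-derived by this package's
own simulation routine (:func:`regenerate_critical_table`), which evolves
sequences on symmetric/asymmetric model trees over a depth gradient and
interpolates Iss at the depth where neighbor joining still recovers the
true topology in 95% of replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.stats import t as t_dist

from .alignment import Alignment

VALID_N_OTU = (4, 8, 16, 32)
_TABLE_RESOURCE = "iss_critical_synthetic.tsv"


class SaturationError(ValueError):
    pass


def _gapfree_columns(rows: np.ndarray) -> np.ndarray:
    gap = (rows == b"-") | (rows == b"?")
    return ~gap.any(axis=0)


def _column_entropies(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-column entropies (bits) of gap-free columns; N is ignored within
    a column. Returns (entropies, base counts 4xm, n columns excluded)."""
    keep = _gapfree_columns(rows)
    sub = rows[:, keep]
    counts = np.stack([(sub == b).sum(axis=0) for b in (b"A", b"C", b"G", b"T")])
    totals = counts.sum(axis=0)
    usable = totals > 0
    n_excluded = int((~keep).sum() + (~usable).sum())
    counts = counts[:, usable].astype(float)
    totals = totals[usable].astype(float)
    freqs = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return -terms.sum(axis=0), counts, n_excluded


def sitewise_entropy(aln: Alignment) -> np.ndarray:
    """Entropy in bits per usable column (gapped columns excluded)."""
    ent, _, _ = _column_entropies(aln.masked_rows())
    return ent


def _remove_invariant(entropies: np.ndarray, counts: np.ndarray,
                      p_inv: float) -> tuple[np.ndarray, np.ndarray]:
    """Drop round(p_inv * m) constant columns, allocated across the four
    constant-column types proportionally to their abundance."""
    m = entropies.size
    n_remove = int(round(p_inv * m))
    if n_remove <= 0:
        return entropies, counts
    const = entropies < 1e-12
    const_base = counts.argmax(axis=0)
    keep = np.ones(m, dtype=bool)
    avail = [np.flatnonzero(const & (const_base == b)) for b in range(4)]
    n_avail = np.array([a.size for a in avail], dtype=float)
    if n_avail.sum() == 0:
        return entropies, counts
    n_remove = min(n_remove, int(n_avail.sum()))
    quota = n_remove * n_avail / n_avail.sum()
    take = np.floor(quota).astype(int)
    rema = quota - take
    for b in np.argsort(-rema):
        if take.sum() >= n_remove:
            break
        if take[b] < n_avail[b]:
            take[b] += 1
    for b in range(4):
        keep[avail[b][: take[b]]] = False
    return entropies[keep], counts[:, keep]


def _iss_of_rows(rows: np.ndarray, p_inv: float) -> tuple[float, float, int]:
    """(Iss, standard error, m columns used); H_full from global base
    frequencies of the retained columns."""
    entropies, counts, _ = _column_entropies(rows)
    entropies, counts = _remove_invariant(entropies, counts, p_inv)
    m = entropies.size
    if m == 0 or entropies.max() < 1e-12:
        return 0.0, 0.0, m
    freqs = counts.sum(axis=1)
    freqs = freqs / freqs.sum()
    h_full = -float(np.sum(np.where(freqs > 0, freqs * np.log2(freqs), 0.0)))
    if h_full <= 0:
        return 0.0, 0.0, m
    iss = float(entropies.mean()) / h_full
    se = float(entropies.std(ddof=1)) / (h_full * math.sqrt(m)) if m > 1 else 0.0
    return iss, se, m


# ----------------------------------------------------------------------
# critical-value table
# ----------------------------------------------------------------------

_table_cache: dict | None = None


def _load_table(path=None) -> dict:
    global _table_cache
    if path is None and _table_cache is not None:
        return _table_cache
    if path is None:
        src = resources.files("barcodelim.data") / _TABLE_RESOURCE
        text = src.read_text()
    else:
        text = Path(path).read_text()
    table: dict[tuple[int, str], list[tuple[float, float]]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("n_otu"):
            continue
        n_otu, length, topo, issc = line.split("\t")
        table.setdefault((int(n_otu), topo), []).append(
            (float(length), float(issc)))
    for key in table:
        table[key].sort()
    if path is None:
        _table_cache = table
    return table


def critical_iss(n_otu: int, n_sites: int, topology: str,
                 table_path=None) -> float:
    """Iss.c for (n_otu, sequence length, topology in {sym, asym}),
    log-length-interpolated between tabulated lengths and clamped outside."""
    if n_otu not in VALID_N_OTU:
        raise SaturationError(f"n_otu must be one of {VALID_N_OTU}")
    if topology not in ("sym", "asym"):
        raise SaturationError("topology must be 'sym' or 'asym'")
    rows = _load_table(table_path).get((n_otu, topology))
    if not rows:
        raise SaturationError(f"no critical values for n_otu={n_otu}")
    lengths = np.array([r[0] for r in rows])
    vals = np.array([r[1] for r in rows])
    return float(np.interp(math.log(max(n_sites, 1)), np.log(lengths), vals))


# ----------------------------------------------------------------------
# the test
# ----------------------------------------------------------------------

@dataclass
class SaturationResult:
    iss: float
    se_iss: float
    iss_c_sym: float
    iss_c_asym: float
    p_sym: float
    p_asym: float
    n_otu_used: int
    n_resamples: int
    m_sites: int
    verdict_sym: str
    verdict_asym: str

    def verdict_sentence(self) -> str:
        return (
            f"Iss = {self.iss:.3f} vs Iss.c(sym) = {self.iss_c_sym:.3f} "
            f"(P = {self.p_sym:.3g}): {self.verdict_sym}; "
            f"vs Iss.c(asym) = {self.iss_c_asym:.3f} "
            f"(P = {self.p_asym:.3g}): {self.verdict_asym}."
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for k in ("iss", "se_iss", "iss_c_sym", "iss_c_asym",
                      "p_sym", "p_asym", "n_otu_used", "n_resamples",
                      "m_sites"):
                fh.write(f"{k}={getattr(self, k)}\n")
            fh.write(f"verdict={self.verdict_sentence()}\n")


def _verdict(iss: float, iss_c: float, p: float) -> str:
    if p < 0.05:
        return ("saturation low; data useful" if iss < iss_c
                else "severe saturation; data useless for phylogeny")
    return "difference not significant; data quality poor"


def iss_test(aln: Alignment, p_inv: float = 0.0, n_otu: int = 32,
             n_resamples: int = 100, seed: int = 0,
             table_path=None) -> SaturationResult:
    """Substitution-saturation test of a (masked) alignment.

    ``p_inv`` is the externally estimated proportion of invariable sites
    (see the model-estimation module); the corresponding share of constant
    columns is removed before averaging entropies. Data sets with more than
    ``n_otu`` taxa are evaluated on ``n_resamples`` random ``n_otu``-taxon
    subsamples (seeded) and the subsampled Iss values are averaged. The
    observed Iss is compared against Iss.c for symmetric and asymmetric
    topologies with a two-sided one-sample t-test based on the sitewise
    entropy spread.
    """
    if aln.n_taxa < 4:
        raise SaturationError("saturation test needs at least 4 taxa")
    if n_otu not in VALID_N_OTU:
        raise SaturationError(f"n_otu must be one of {VALID_N_OTU}")
    if not 0.0 <= p_inv < 1.0:
        raise SaturationError("p_inv must lie in [0, 1)")
    rows = aln.masked_rows()
    if aln.n_taxa <= n_otu:
        iss, se, m = _iss_of_rows(rows, p_inv)
        n_used, n_res = aln.n_taxa, 1
    else:
        rng = np.random.default_rng(seed)
        vals, ses, ms = [], [], []
        for _ in range(n_resamples):
            idx = rng.choice(aln.n_taxa, size=n_otu, replace=False)
            i, s, m_i = _iss_of_rows(rows[np.sort(idx)], p_inv)
            vals.append(i)
            ses.append(s)
            ms.append(m_i)
        iss, se, m = float(np.mean(vals)), float(np.mean(ses)), int(np.mean(ms))
        n_used, n_res = n_otu, n_resamples
    n_eval = min(aln.n_taxa, n_otu)
    if m == 0 or iss == 0.0:
        return SaturationResult(0.0, 0.0, math.nan, math.nan, math.nan,
                                math.nan, n_used, n_res, m,
                                "no signal", "no signal")
    issc_sym = critical_iss(n_eval if n_eval in VALID_N_OTU else n_otu,
                            m, "sym", table_path)
    issc_asym = critical_iss(n_eval if n_eval in VALID_N_OTU else n_otu,
                             m, "asym", table_path)
    df = max(m - 1, 1)
    if se > 0:
        p_sym = 2.0 * float(t_dist.sf(abs(iss - issc_sym) / se, df))
        p_asym = 2.0 * float(t_dist.sf(abs(iss - issc_asym) / se, df))
    else:
        p_sym = p_asym = 0.0
    return SaturationResult(iss, se, issc_sym, issc_asym, p_sym, p_asym,
                            n_used, n_res, m,
                            _verdict(iss, issc_sym, p_sym),
                            _verdict(iss, issc_asym, p_asym))


# ----------------------------------------------------------------------
# empirical re-derivation of Iss.c
# ----------------------------------------------------------------------

def _reference_tree(n_otu: int, depth: float, topology: str):
    """Ultrametric reference topologies: 'sym' = balanced binary (n a power
    of two), 'asym' = caterpillar with equally spaced splits."""
    import dendropy

    labels = [f"t{i + 1}" for i in range(n_otu)]
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    if topology == "sym":
        levels = int(round(math.log2(n_otu)))
        if 2 ** levels != n_otu:
            raise SaturationError("symmetric topology needs a power-of-two n_otu")
        edge = depth / levels

        def build(label_slice):
            if len(label_slice) == 1:
                return dendropy.Node(taxon=ns.get_taxon(label_slice[0]))
            nd = dendropy.Node()
            half = len(label_slice) // 2
            for sl in (label_slice[:half], label_slice[half:]):
                ch = build(sl)
                nd.add_child(ch)
                ch.edge.length = edge
            return nd

        for sl in (labels[: n_otu // 2], labels[n_otu // 2:]):
            ch = build(sl)
            root.add_child(ch)
            ch.edge.length = edge
    else:
        # ultrametric caterpillar: splits equally spaced in time
        step = depth / (n_otu - 1)
        cur = root
        for i in range(n_otu - 2):
            height = depth - i * step  # height of cur
            tip = dendropy.Node(taxon=ns.get_taxon(labels[i]))
            tip.edge.length = height
            inner = dendropy.Node()
            inner.edge.length = step
            cur.add_child(tip)
            cur.add_child(inner)
            cur = inner
        for lab in labels[-2:]:
            tip = dendropy.Node(taxon=ns.get_taxon(lab))
            tip.edge.length = step
            cur.add_child(tip)
    tree.is_rooted = True
    return tree


def regenerate_critical_table(
    n_otus=(4, 8, 16, 32),
    lengths=(200, 400, 800, 1600, 3200),
    depths=(0.0125, 0.025, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8),
    n_replicates: int = 30,
    recovery_target: float = 0.95,
    seed: int = 20120824,
    out_path=None,
) -> list[tuple[int, int, str, float]]:
    """Re-derive Iss.c by simulation (slow; minutes at the default sizes).

    For each (n_otu, length, topology) sequences evolve under JC69 on the
    reference tree over a depth gradient; the mean fraction of true
    bipartitions recovered by neighbor joining is tracked, and Iss.c is the
    mean Iss interpolated at the depth where that fraction crosses
    ``recovery_target``.
    """
    from .distances import distance_matrix
    from .models import SubstitutionModel
    from .synthetic import simulate_alignment
    from .trees import _bipartitions, neighbor_joining

    rng = np.random.default_rng(seed)
    model = SubstitutionModel.jc69()
    rows_out: list[tuple[int, int, str, float]] = []
    for n_otu in n_otus:
        for topo in ("sym", "asym"):
            true_tree = _reference_tree(n_otu, 1.0, topo)
            all_taxa = frozenset(
                lf.taxon.label for lf in true_tree.leaf_node_iter())
            true_bips = _bipartitions(true_tree, all_taxa)
            for length in lengths:
                mean_iss, recovery = [], []
                for depth in depths:
                    tree = _reference_tree(n_otu, depth, topo)
                    iss_vals, rec = [], []
                    for _ in range(n_replicates):
                        aln = simulate_alignment(tree, model, length, rng)
                        iss_vals.append(_iss_of_rows(aln.rows, 0.0)[0])
                        try:
                            dm = distance_matrix(aln, method="jc69")
                            nj = neighbor_joining(dm)
                            found = _bipartitions(nj, all_taxa)
                            rec.append(len(true_bips & found)
                                       / max(len(true_bips), 1))
                        except Exception:
                            rec.append(0.0)
                    mean_iss.append(float(np.mean(iss_vals)))
                    recovery.append(float(np.mean(rec)))
                issc = _interpolate_critical(mean_iss, recovery, recovery_target)
                rows_out.append((n_otu, length, topo, issc))
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("n_otu\tlength\ttopology\tiss_c\n")
            for n_otu, length, topo, issc in rows_out:
                fh.write(f"{n_otu}\t{length}\t{topo}\t{issc:.4f}\n")
    return rows_out


def _interpolate_critical(mean_iss, recovery, target) -> float:
    """Iss at the saturation-side (deep-end) crossing of the recovery target.

    Shallow trees can fail for lack of signal rather than saturation, so the
    target is taken relative to the best recovery the configuration attains
    and the crossing is searched tipward of that maximum.
    """
    best = int(np.argmax(recovery))
    eff = target * recovery[best]
    for i in range(best + 1, len(recovery)):
        if recovery[i - 1] >= eff > recovery[i]:
            lo, hi = recovery[i - 1], recovery[i]
            w = (lo - eff) / (lo - hi)
            return mean_iss[i - 1] + w * (mean_iss[i] - mean_iss[i - 1])
    return mean_iss[-1]  # never degrades within the grid
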