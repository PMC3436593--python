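"""Pairwise genetic distances: p-distance, K2P closed form, and model-based ML.

Corrected distances are expressed in expected substitutions per site and are
open to infinity; pairs whose estimate hits the upper search bound (or whose
closed-form logarithm argument is non-positive) are flagged *saturated*
rather than silently truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment, BASES, MISSING_CHARS
from .models import SubstitutionModel

#: Upper bound of the ML distance search (substitutions per site).
MAX_DISTANCE = 10.0

_MISSING_BYTES = frozenset(bytes([c]) for c in b"N-?")

# Transition pairs (A<->G, C<->T) as index pairs into ACGT.
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}


class DistanceError(ValueError):
    pass


class PairwiseDistance(NamedTuple):
    value: float
    saturated: bool = False


def _as_bytes_row(seq) -> np.ndarray:
    if isinstance(seq, (str, bytes)):
        s = seq.upper().replace("U", "T") if isinstance(seq, str) else seq
        if isinstance(s, str):
            s = s.encode("ascii")
        return np.frombuffer(s, dtype="S1").copy()
    return np.asarray(seq, dtype="S1")


def _missing_mask(row: np.ndarray) -> np.ndarray:
    return (row == b"N") | (row == b"-") | (row == b"?")


def p_distance(a, b, mode: str = "pairwise_deletion") -> float:
    """Proportion of divergent positions between two aligned rows.

    ``total_length`` counts mismatches plus columns where exactly one
    row is gapped/missing, divided by the total (masked) alignment length.
    ``pairwise_deletion`` drops every column containing a gap or N in either
    row and divides by the remaining length.
    """
    ra, rb = _as_bytes_row(a), _as_bytes_row(b)
    if ra.shape != rb.shape:
        raise DistanceError("rows differ in length")
    miss_a, miss_b = _missing_mask(ra), _missing_mask(rb)
    if mode == "total_length":
        both_present = ~miss_a & ~miss_b
        mismatch = both_present & (ra != rb)
        one_gapped = miss_a ^ miss_b
        return float((mismatch | one_gapped).sum()) / ra.size
    if mode == "pairwise_deletion":
        keep = ~miss_a & ~miss_b
        n = int(keep.sum())
        if n == 0:
            raise DistanceError("no usable columns after pairwise deletion")
        return float((ra[keep] != rb[keep]).sum()) / n
    raise DistanceError(f"unknown p-distance mode: {mode}")


def pair_counts(a, b) -> np.ndarray:
    """4x4 site-pattern count matrix (rows: seq a, cols: seq b) over ACGT,
    pairwise-deleting columns with any gap/N."""
    ra, rb = _as_bytes_row(a), _as_bytes_row(b)
    if ra.shape != rb.shape:
        raise DistanceError("rows differ in length")
    keep = ~_missing_mask(ra) & ~_missing_mask(rb)
    ia = np.searchsorted(np.frombuffer(BASES, dtype="S1"), ra[keep])
    ib = np.searchsorted(np.frombuffer(BASES, dtype="S1"), rb[keep])
    counts = np.zeros((4, 4), dtype=float)
    np.add.at(counts, (ia, ib), 1.0)
    return counts


def k2p_distance(a, b) -> PairwiseDistance:
    """Kimura two-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    P and Q are the transition and transversion proportions after pairwise
    deletion. A non-positive logarithm argument flags the pair saturated.
    """
    counts = pair_counts(a, b)
    n = counts.sum()
    if n == 0:
        raise DistanceError("no usable columns after pairwise deletion")
    p_trans = sum(counts[i, j] for i, j in _TRANSITIONS) / n
    q_transv = (counts.sum() - np.trace(counts)
                - sum(counts[i, j] for i, j in _TRANSITIONS)) / n
    arg1 = 1.0 - 2.0 * p_trans - q_transv
    arg2 = 1.0 - 2.0 * q_transv
    if arg1 <= 0.0 or arg2 <= 0.0:
        return PairwiseDistance(math.inf, saturated=True)
    d = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    return PairwiseDistance(max(d, 0.0), saturated=False)


def jc69_distance(a, b) -> PairwiseDistance:
    """Jukes-Cantor closed form -3/4 ln(1 - 4p/3) (used as an oracle and for
    the NJ starting tree of parameter estimation)."""
    p = p_distance(a, b, mode="pairwise_deletion")
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return PairwiseDistance(math.inf, saturated=True)
    return PairwiseDistance(max(-0.75 * math.log(arg), 0.0), False)


def _pair_log_likelihood(t: float, counts: np.ndarray,
                         model: SubstitutionModel, eigen, cat_rates) -> float:
    """Two-sequence log-likelihood sum_xy N_xy log f_xy(t) with the +I+Gamma
    mixture f_xy(t) = p_inv pi_x 1{x=y} + (1-p_inv)/ncat sum_c pi_x P_xy(t rho_c)."""
    pi = model.pi
    f = np.zeros((4, 4))
    for rho in cat_rates:
        f += model.transition_matrix(t * rho, eigen)
    f *= (1.0 - model.p_inv) / len(cat_rates)
    f *= pi[:, None]
    if model.p_inv > 0:
        f[np.diag_indices(4)] += model.p_inv * pi
    with np.errstate(divide="ignore"):
        logf = np.log(f)
    mask = counts > 0
    if np.any(np.isneginf(logf[mask])):
        return -math.inf
    return float((counts[mask] * logf[mask]).sum())


def ml_pairwise_distance(a, b, model: SubstitutionModel,
                         max_distance: float = MAX_DISTANCE,
                         profile_rates: bool = False) -> PairwiseDistance:
    """Maximum-likelihood pairwise distance under a fully specified model.

    The branch length t >= 0 maximising the two-sequence likelihood is found
    by bounded unimodal search to absolute tolerance 1e-8; an optimum within
    one part in 10^3 of the upper bound is reported as saturated. With
    ``profile_rates`` the model's free exchangeabilities are jointly
    maximised per pair (e.g. kappa under K80, for which the joint optimum
    coincides with the K2P closed form).
    """
    counts = pair_counts(a, b)
    if counts.sum() == 0:
        raise DistanceError("no usable columns after pairwise deletion")
    if np.trace(counts) == counts.sum():
        return PairwiseDistance(0.0, False)
    cat_rates = model.gamma_category_rates()

    def best_t(mod: SubstitutionModel) -> tuple[float, float]:
        eigen = mod.eigen()

        def neg(t: float) -> float:
            ll = _pair_log_likelihood(t, counts, mod, eigen, cat_rates)
            return 1e300 if not math.isfinite(ll) else -ll

        res = minimize_scalar(neg, bounds=(0.0, max_distance),
                              method="bounded", options={"xatol": 1e-8})
        return float(res.x), float(res.fun)

    n_free = model.n_free_rate_params()
    if profile_rates and n_free > 0:
        from scipy.optimize import minimize

        def neg_rates(logr: np.ndarray) -> float:
            mod = model.with_free_rates(np.exp(logr))
            return best_t(mod)[1]

        res = minimize(neg_rates, np.log(model.free_rates()),
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9,
                                "maxiter": 400})
        model = model.with_free_rates(np.exp(res.x))
    t_hat, fun = best_t(model)
    if not math.isfinite(fun) or fun >= 1e300:
        raise DistanceError("non-finite likelihood for sequence pair")
    if t_hat >= max_distance * (1.0 - 1e-3):
        return PairwiseDistance(math.inf, saturated=True)
    return PairwiseDistance(max(t_hat, 0.0), False)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix tagged with the producing model."""

    taxa: list[str]
    values: np.ndarray
    model_tag: str = ""
    units: str = "expected substitutions per site"
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise DistanceError("matrix shape does not match taxa")
        if self.saturated is None:
            self.saturated = ~np.isfinite(self.values)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        finite = self.values[np.isfinite(self.values)]
        if (finite < -1e-12).any():
            raise DistanceError("negative distance")
        if not np.allclose(np.nan_to_num(self.values, posinf=1e30),
                           np.nan_to_num(self.values.T, posinf=1e30)):
            raise DistanceError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise DistanceError("non-zero diagonal")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values (i<j) in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def any_saturated(self) -> bool:
        iu = np.triu_indices(self.n, k=1)
        return bool(self.saturated[iu].any())


def distance_matrix(aln: Alignment, method: str = "k2p_closed",
                    model: SubstitutionModel | None = None) -> DistanceMatrix:
    """All n(n-1)/2 pairwise distances of a masked alignment.

    ``method``: ``p`` (uncorrected, pairwise deletion), ``p_total`` (the
    total-length definition), ``k2p_closed``, ``jc69`` or ``ml`` (requires a
    fully parameterised ``model``).
    """
    rows = aln.masked_rows()
    n = aln.n_taxa
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    if method == "ml":
        if model is None:
            raise DistanceError("method 'ml' requires a model")
        tag = _model_tag(model)
        units = "expected substitutions per site"
    elif method in ("p", "p_total"):
        tag, units = "p-distance", "proportion"
    elif method == "k2p_closed":
        tag, units = "K2P", "expected substitutions per site"
    elif method == "jc69":
        tag, units = "JC69", "expected substitutions per site"
    else:
        raise DistanceError(f"unknown distance method: {method}")
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if method == "p":
                    d = PairwiseDistance(p_distance(rows[i], rows[j]), False)
                elif method == "p_total":
                    d = PairwiseDistance(
                        p_distance(rows[i], rows[j], "total_length"), False)
                elif method == "k2p_closed":
                    d = k2p_distance(rows[i], rows[j])
                elif method == "jc69":
                    d = jc69_distance(rows[i], rows[j])
                else:
                    d = ml_pairwise_distance(rows[i], rows[j], model)
            except DistanceError as exc:
                raise DistanceError(
                    f"pair ({aln.taxa[i]}, {aln.taxa[j]}): {exc}") from exc
            values[i, j] = values[j, i] = d.value
            saturated[i, j] = saturated[j, i] = d.saturated
    return DistanceMatrix(list(aln.taxa), values, model_tag=tag, units=units,
                          saturated=saturated)


def _model_tag(model: SubstitutionModel) -> str:
    tag = model.family
    if model.p_inv > 0:
        tag += "+I"
    if model.alpha is not None:
        tag += "+G"
    return tag


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square TSV with a taxon header row and column; inf marks saturation."""
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(dm.taxa) + "\n")
        for i, t in enumerate(dm.taxa):
            vals = "\t".join(
                "inf" if not math.isfinite(v) else f"{v:.10g}"
                for v in dm.values[i]
            )
            fh.write(f"{t}\t{vals}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    taxa = lines[0].split("\t")[1:]
    values = np.array(
        [[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]]
    )
    return DistanceMatrix(taxa, values)
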