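"""Model-parameter estimation on a fixed NJ topology, and AIC model ranking.

The estimation protocol mirrors common distance-software practice: a
Jukes-Cantor distance matrix gives a neighbor-joining topology, on which
branch lengths and the free substitution parameters are optimised jointly
(coordinate ascent, fixed starting values, deterministic given the data).
Base frequencies are taken empirically from the alignment by default; full
ML estimation of the frequencies can be switched on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .alignment import Alignment
from .distances import distance_matrix
from .likelihood import TreeLikelihood
from .models import SubstitutionModel, ModelError

_PINV_CAP = 0.99
_ALPHA_BOUNDS = (0.02, 100.0)
_RATE_BOUNDS = (1e-4, 100.0)


class EstimationError(RuntimeError):
    pass


@dataclass
class ModelFit:
    model: SubstitutionModel
    tree: object
    log_likelihood: float
    k: int  # free parameters incl. branch lengths
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.log_likelihood


def empirical_base_frequencies(aln: Alignment) -> np.ndarray:
    rows = aln.masked_rows()
    counts = np.array([
        (rows == b"A").sum(), (rows == b"C").sum(),
        (rows == b"G").sum(), (rows == b"T").sum(),
    ], dtype=float)
    counts += 0.5  # guard against absent bases
    return counts / counts.sum()


def _initial_model(family: str, pi, with_inv: bool, with_gamma: bool) -> SubstitutionModel:
    base = SubstitutionModel(family, pi=pi) if family in ("TIM2", "GTR", "F81", "HKY85") \
        else SubstitutionModel(family)
    if family in ("K80", "HKY85"):
        base = base.with_free_rates([2.0])
    elif family == "TIM2":
        base = base.with_free_rates([1.0, 2.0, 2.0])
    elif family == "GTR":
        base = base.with_free_rates([1.0, 2.0, 1.0, 1.0, 2.0])
    return replace(base,
                   p_inv=0.1 if with_inv else 0.0,
                   alpha=1.0 if with_gamma else None)


def _pack(model: SubstitutionModel, ml_frequencies: bool) -> tuple[np.ndarray, list]:
    names: list[str] = []
    vals: list[float] = []
    for i, r in enumerate(model.free_rates()):
        names.append(f"rate{i}")
        vals.append(math.log(r))
    if model.p_inv > 0:
        names.append("p_inv")
        vals.append(model.p_inv)
    if model.alpha is not None:
        names.append("alpha")
        vals.append(math.log(model.alpha))
    if ml_frequencies and model.family in ("F81", "HKY85", "TIM2", "GTR"):
        for i in range(3):
            names.append(f"logpi{i}")
            vals.append(math.log(model.pi[i] / model.pi[3]))
    return np.asarray(vals), names


def _unpack(x: np.ndarray, names: list, template: SubstitutionModel) -> SubstitutionModel:
    model = template
    rates = [math.exp(v) for n, v in zip(names, x) if n.startswith("rate")]
    if rates:
        model = model.with_free_rates(rates)
    kw = {}
    for n, v in zip(names, x):
        if n == "p_inv":
            kw["p_inv"] = min(max(v, 0.0), _PINV_CAP)
        elif n == "alpha":
            kw["alpha"] = min(max(math.exp(v), _ALPHA_BOUNDS[0]), _ALPHA_BOUNDS[1])
    logpis = [v for n, v in zip(names, x) if n.startswith("logpi")]
    if logpis:
        raw = np.exp(np.array(logpis + [0.0]))
        kw["pi"] = raw / raw.sum()
    return replace(model, **kw)


def _bounds(names: list) -> list[tuple[float, float]]:
    out = []
    for n in names:
        if n.startswith("rate"):
            out.append((math.log(_RATE_BOUNDS[0]), math.log(_RATE_BOUNDS[1])))
        elif n == "p_inv":
            out.append((0.0, _PINV_CAP))
        elif n == "alpha":
            out.append((math.log(_ALPHA_BOUNDS[0]), math.log(_ALPHA_BOUNDS[1])))
        else:
            out.append((-10.0, 10.0))
    return out


def _has_variable_columns(aln: Alignment) -> bool:
    rows = aln.masked_rows()
    for col in rows.T:
        bases = {c for c in col.tobytes() if c in b"ACGT"}
        if len(bases) > 1:
            return True
    return False


def fit_substitution_model(aln: Alignment, family: str,
                           with_inv: bool = False, with_gamma: bool = False,
                           ml_frequencies: bool = False,
                           tol: float = 1e-6, max_rounds: int = 30) -> ModelFit:
    """Joint branch-length and parameter estimation on the JC-NJ topology."""
    if aln.n_taxa < 4:
        raise EstimationError("model estimation needs at least 4 taxa")
    from .trees import neighbor_joining  # deferred: trees imports distances

    dm = distance_matrix(aln, method="jc69")
    if dm.any_saturated():
        # only a starting topology: cap saturated entries at a large value
        vals = dm.values.copy()
        finite = vals[np.isfinite(vals)]
        cap = 2.0 * finite.max() if finite.max() > 0 else 5.0
        vals[~np.isfinite(vals)] = cap
        from .distances import DistanceMatrix
        dm = DistanceMatrix(dm.taxa, vals, model_tag="JC69-capped")
    tree = neighbor_joining(dm)
    pi = (np.full(4, 0.25) if family in ("JC69", "K80")
          else empirical_base_frequencies(aln))
    model = _initial_model(family, pi, with_inv, with_gamma)
    if not _has_variable_columns(aln):
        # degenerate data: the likelihood is flat in every parameter and the
        # invariable-site proportion sits at its boundary
        if with_inv:
            model = replace(model, p_inv=_PINV_CAP)
        engine = TreeLikelihood(aln, tree, model)
        k = model.n_free_params() + (2 * aln.n_taxa - 3)
        return ModelFit(model=model, tree=tree,
                        log_likelihood=engine.log_likelihood(), k=k,
                        converged=True)
    engine = TreeLikelihood(aln, tree, model)
    logl = engine.optimize_branch_lengths(max_rounds=3)
    x, names = _pack(model, ml_frequencies)
    converged = False
    for _ in range(max_rounds):
        prev = logl
        if len(names) > 0:
            def neg(v: np.ndarray) -> float:
                engine.model = _unpack(v, names, model)
                try:
                    engine.refresh_model()
                    return -engine.log_likelihood()
                except (ModelError, Exception):
                    return 1e300
            res = minimize(neg, x, method="L-BFGS-B", bounds=_bounds(names),
                           options={"maxiter": 60, "ftol": 1e-9})
            x = res.x
            model = _unpack(x, names, model)
            engine.model = model
            engine.refresh_model()
        logl = engine.optimize_branch_lengths(max_rounds=2)
        if abs(logl - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
    if not converged and max_rounds > 1:
        raise EstimationError(
            f"estimation did not converge for {family} "
            f"(last logL {logl:.4f}, params {dict(zip(names, x))})"
        )
    n = aln.n_taxa
    k = model.n_free_params() + (2 * n - 3)
    return ModelFit(model=model, tree=tree, log_likelihood=logl, k=k,
                    converged=converged)


def estimate_model_parameters(aln: Alignment, family: str,
                              with_inv: bool = False, with_gamma: bool = False,
                              **kwargs) -> SubstitutionModel:
    """Convenience wrapper returning only the fitted model."""
    return fit_substitution_model(aln, family, with_inv, with_gamma, **kwargs).model


_VARIANTS = {"plain": (False, False), "I": (True, False),
             "G": (False, True), "IG": (True, True)}


def rank_models_aic(aln: Alignment,
                    families=("JC69", "K80", "F81", "HKY85", "TIM2", "GTR"),
                    variants=("plain", "I", "G", "IG")) -> list[dict]:
    """AIC table over the candidate model family x {+I, +G} grid.

    Returns dicts with keys ``model, family, variant, logL, k, AIC``, sorted
    ascending by AIC (ties broken by smaller k). Candidates that fail
    estimation are reported with ``error`` set and sorted last.
    """
    rows: list[dict] = []
    for fam in families:
        for var in variants:
            with_inv, with_gamma = _VARIANTS[var]
            name = fam + {"plain": "", "I": "+I", "G": "+G", "IG": "+I+G"}[var]
            try:
                fit = fit_substitution_model(aln, fam, with_inv, with_gamma)
            except Exception as exc:
                rows.append({"model": name, "family": fam, "variant": var,
                             "logL": math.nan, "k": math.nan,
                             "AIC": math.inf, "error": str(exc)})
                continue
            rows.append({"model": name, "family": fam, "variant": var,
                         "logL": fit.log_likelihood, "k": fit.k,
                         "AIC": fit.aic, "error": None})
    rows.sort(key=lambda r: (r["AIC"], r["k"] if not math.isnan(r["k"]) else 1e9))
    return rows


def write_model_parameters(model: SubstitutionModel, path) -> None:
    """Flat key=value text block for a fitted model."""
    with open(path, "w") as fh:
        fh.write(f"family={model.family}\n")
        for base, p in zip("ACGT", model.pi):
            fh.write(f"pi_{base}={p:.6f}\n")
        from .models import RATE_ORDER
        for name, r in zip(RATE_ORDER, model.rates):
            fh.write(f"r_{name}={r:.6f}\n")
        fh.write(f"p_inv={model.p_inv:.6f}\n")
        fh.write(f"alpha={'none' if model.alpha is None else f'{model.alpha:.6f}'}\n")
        fh.write(f"n_cat={model.n_cat}\n")
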