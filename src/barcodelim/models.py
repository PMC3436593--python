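"""Reversible nucleotide substitution models (JC69 ... GTR, +I, +Gamma).

A model is the pair (exchangeabilities r, base frequencies pi) defining the
instantaneous rate matrix Q_ij = r_ij * pi_j (i != j), optionally augmented
with a proportion of invariable sites p_inv and discrete-gamma among-site
rate variation with shape alpha. Family constraints (which of the six
exchangeabilities are tied) follow the standard model hierarchy:

=======  ==========================================  ==============
family   exchangeability pattern (AC,AG,AT,CG,CT,GT) base freqs
=======  ==========================================  ==============
JC69     all equal                                   uniform
K80      AG=CT=kappa, others 1                       uniform
F81      all equal                                   free
HKY85    AG=CT=kappa, others 1                       free
TIM2     AC=AT, CG=GT, AG and CT free                free
GTR      all free (GT fixed to 1 as scale)           free
=======  ==========================================  ==============

Q is normalised so that -sum_i pi_i Q_ii = 1; with p_inv > 0 the matrix is
further scaled by 1/(1 - p_inv) so that branch lengths remain expected
substitutions per site averaged over all sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as _gamma_dist

RATE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
FAMILIES = ("p", "JC69", "K80", "F81", "HKY85", "TIM2", "GTR")

# Tying pattern per family: group index per exchangeability, one rate per group.
# The last group is fixed to 1 as the scale during estimation.
_TYING = {
    "JC69": (0, 0, 0, 0, 0, 0),
    "F81": (0, 0, 0, 0, 0, 0),
    "K80": (1, 0, 1, 1, 0, 1),
    "HKY85": (1, 0, 1, 1, 0, 1),
    "TIM2": (0, 1, 0, 3, 2, 3),
    "GTR": (0, 1, 2, 3, 4, 5),
}
# Whether base frequencies are constrained to be uniform.
_UNIFORM_PI = {"JC69": True, "K80": True, "F81": False, "HKY85": False,
               "TIM2": False, "GTR": False}


class ModelError(ValueError):
    pass


@dataclass
class SubstitutionModel:
    """A fully parameterised substitution model.

    ``rates`` is always the expanded 6-vector in :data:`RATE_ORDER` order;
    constructors enforce the family tying pattern. ``alpha=None`` means no
    among-site rate variation.
    """

    family: str
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    p_inv: float = 0.0
    alpha: float | None = None
    n_cat: int = 4

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelError(f"unknown model family: {self.family}")
        self.pi = np.asarray(self.pi, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.family == "p":
            return
        if self.pi.shape != (4,) or (self.pi <= 0).any():
            raise ModelError("pi must be 4 positive frequencies")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ModelError("pi must sum to 1")
        if self.rates.shape != (6,) or (self.rates < 0).any():
            raise ModelError("rates must be 6 non-negative exchangeabilities")
        if not 0.0 <= self.p_inv < 1.0:
            raise ModelError("p_inv must lie in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ModelError("gamma shape alpha must be positive")
        if _UNIFORM_PI[self.family] and not np.allclose(self.pi, 0.25):
            raise ModelError(f"{self.family} requires uniform base frequencies")
        tying = _TYING[self.family]
        for a in range(6):
            for b in range(6):
                if tying[a] == tying[b] and not np.isclose(
                    self.rates[a], self.rates[b]
                ):
                    raise ModelError(
                        f"{self.family} ties rates {RATE_ORDER[a]} and "
                        f"{RATE_ORDER[b]}"
                    )

    # -- constructors ---------------------------------------------------
    @classmethod
    def jc69(cls, p_inv: float = 0.0, alpha: float | None = None) -> "SubstitutionModel":
        return cls("JC69", p_inv=p_inv, alpha=alpha)

    @classmethod
    def k80(cls, kappa: float = 2.0, p_inv: float = 0.0,
            alpha: float | None = None) -> "SubstitutionModel":
        r = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls("K80", rates=r, p_inv=p_inv, alpha=alpha)

    @classmethod
    def f81(cls, pi, p_inv: float = 0.0, alpha: float | None = None) -> "SubstitutionModel":
        return cls("F81", pi=np.asarray(pi, float), p_inv=p_inv, alpha=alpha)

    @classmethod
    def hky85(cls, pi, kappa: float = 2.0, p_inv: float = 0.0,
              alpha: float | None = None) -> "SubstitutionModel":
        r = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls("HKY85", pi=np.asarray(pi, float), rates=r,
                   p_inv=p_inv, alpha=alpha)

    @classmethod
    def tim2(cls, pi, r_ac: float = 1.0, r_ag: float = 2.0, r_ct: float = 2.0,
             p_inv: float = 0.0, alpha: float | None = None) -> "SubstitutionModel":
        r = np.array([r_ac, r_ag, r_ac, 1.0, r_ct, 1.0])
        return cls("TIM2", pi=np.asarray(pi, float), rates=r,
                   p_inv=p_inv, alpha=alpha)

    @classmethod
    def gtr(cls, pi, rates, p_inv: float = 0.0,
            alpha: float | None = None) -> "SubstitutionModel":
        return cls("GTR", pi=np.asarray(pi, float),
                   rates=np.asarray(rates, float), p_inv=p_inv, alpha=alpha)

    # -- free-parameter plumbing for estimation -------------------------
    def n_free_rate_params(self) -> int:
        return len(set(_TYING[self.family])) - 1

    def free_rates(self) -> np.ndarray:
        """Group rates except the scale group (fixed to 1), estimation order."""
        tying = _TYING[self.family]
        groups = sorted(set(tying))
        scale_group = groups[-1]
        scale = self.rates[tying.index(scale_group)]
        vals = []
        for g in groups[:-1]:
            vals.append(self.rates[tying.index(g)] / scale)
        return np.array(vals)

    def with_free_rates(self, values) -> "SubstitutionModel":
        tying = _TYING[self.family]
        groups = sorted(set(tying))
        rates = np.empty(6)
        values = np.asarray(values, float)
        if values.shape != (len(groups) - 1,):
            raise ModelError("wrong number of free rate parameters")
        group_rate = {g: values[i] for i, g in enumerate(groups[:-1])}
        group_rate[groups[-1]] = 1.0
        for i, g in enumerate(tying):
            rates[i] = group_rate[g]
        return replace(self, rates=rates)

    def n_free_params(self) -> int:
        """Substitution-process parameter count (excludes branch lengths)."""
        k = self.n_free_rate_params()
        if not _UNIFORM_PI[self.family]:
            k += 3
        if self.p_inv > 0:
            k += 1
        if self.alpha is not None:
            k += 1
        return k

    # -- rate matrix and transition probabilities -----------------------
    def q_matrix(self) -> np.ndarray:
        """Normalised instantaneous rate matrix (see module docstring)."""
        if self.family == "p":
            raise ModelError("p-distance has no rate matrix")
        r = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), rate in zip(idx, self.rates):
            r[i, j] = r[j, i] = rate
        q = r * self.pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(self.pi, np.diag(q))
        if mu <= 0:
            raise ModelError("degenerate rate matrix (all rates zero)")
        q /= mu
        if self.p_inv > 0:
            q /= 1.0 - self.p_inv
        return q

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via the pi-symmetrised form.

        Returns ``(eigenvalues, right, left)`` with
        ``P(t) = right @ diag(exp(lam t)) @ left``.
        """
        q = self.q_matrix()
        sp = np.sqrt(self.pi)
        b = (sp[:, None] * q) / sp[None, :]
        lam, u = np.linalg.eigh((b + b.T) / 2.0)
        right = u / sp[:, None]
        left = u.T * sp[None, :]
        return lam, right, left

    def transition_matrix(self, t: float, eigen=None) -> np.ndarray:
        """P(t) = exp(Qt); ``eigen`` may be a cached :meth:`eigen` result."""
        if eigen is None:
            eigen = self.eigen()
        lam, right, left = eigen
        p = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def gamma_category_rates(self) -> np.ndarray:
        """Mean rates of ``n_cat`` equal-probability gamma slices, mean 1.

        With ``alpha=None`` a single unit-rate category is returned.
        """
        if self.alpha is None:
            return np.ones(1)
        a = float(self.alpha)
        k = self.n_cat
        edges = _gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # E[X; X in slice] for Gamma(a, 1/a) via the shape-(a+1) cdf.
        cdf_up = _gamma_dist.cdf(edges, a + 1.0, scale=1.0 / a)
        means = k * np.diff(cdf_up)
        return means / means.mean()
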