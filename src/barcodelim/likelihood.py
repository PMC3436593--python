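"""Felsenstein pruning likelihood with +I and discrete-gamma rate mixtures.

Works on dendropy trees whose edge lengths are expected substitutions per
site. Site patterns are compressed once per (alignment, tip-order) pair.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .models import SubstitutionModel

_CODE = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
MISSING_CODE = 4


class LikelihoodError(ValueError):
    pass


def encode_patterns(aln: Alignment, taxa: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Compress the masked alignment (restricted to ``taxa``, in order) into
    unique site patterns. Returns ``(patterns, counts)`` with patterns of
    shape ``(n_patterns, n_taxa)`` over codes A=0..T=3, missing=4."""
    rows = aln.subset(taxa).masked_rows()
    codes = np.full(rows.shape, MISSING_CODE, dtype=np.int8)
    for ch, c in _CODE.items():
        codes[rows == ch] = c
    patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
    return patterns, counts.astype(float)


class TreeLikelihood:
    """Pruning log-likelihood of an alignment on a (possibly unrooted) tree.

    The tree's seed node acts as the pruning root; for reversible models the
    value is invariant to its placement. Edge lengths are read live from the
    tree, so callers may mutate ``node.edge.length`` between evaluations.
    """

    def __init__(self, aln: Alignment, tree, model: SubstitutionModel) -> None:
        self.tree = tree
        self.model = model
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        missing = set(tips) - set(aln.taxa)
        if missing:
            raise LikelihoodError(f"tree tips absent from alignment: {sorted(missing)}")
        self.tip_order = tips
        self.patterns, self.counts = encode_patterns(aln, tips)
        self._postorder = list(tree.postorder_node_iter())
        self._node_index = {id(nd): i for i, nd in enumerate(self._postorder)}
        self._tip_partials = {}
        npat = self.patterns.shape[0]
        eye5 = np.vstack([np.eye(4), np.ones(4)])  # missing row = all-ones
        for k, label in enumerate(tips):
            self._tip_partials[label] = eye5[self.patterns[:, k]]
        # invariant-site indicator: pattern compatible with constant state x
        obs = self.patterns[:, :, None]  # (npat, ntip, 1)
        ok = (obs == np.arange(4)[None, None, :]) | (obs == MISSING_CODE)
        self._inv_ok = ok.all(axis=1).astype(float)  # (npat, 4)
        self.refresh_model()

    def refresh_model(self) -> None:
        """Re-cache the eigensystem after a model-parameter change."""
        self._eigen = self.model.eigen()
        self._cat_rates = self.model.gamma_category_rates()

    def log_likelihood(self) -> float:
        model = self.model
        pi = model.pi
        root_partial = self._root_partial()  # (ncat, npat, 4)
        site_lik = (root_partial @ pi).mean(axis=0)  # (npat,)
        site_lik *= 1.0 - model.p_inv
        if model.p_inv > 0:
            site_lik += model.p_inv * (self._inv_ok @ pi)
        if not np.all(site_lik > 0):
            bad = int(np.argmin(site_lik))
            raise LikelihoodError(
                f"non-positive site likelihood for pattern {self.patterns[bad]}"
            )
        return float(self.counts @ np.log(site_lik))

    def _edge_pmats_t(self, t: float) -> np.ndarray:
        """(ncat, 4, 4) transposed transition matrices P(t*rho_c).T."""
        lam, right, left = self._eigen
        expd = np.exp(np.outer(self._cat_rates * t, lam))  # (ncat, 4)
        p = (right[None, :, :] * expd[:, None, :]) @ left  # (ncat, 4, 4)
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return np.ascontiguousarray(p.transpose(0, 2, 1))

    def _root_partial(self) -> np.ndarray:
        ncat = len(self._cat_rates)
        partials: dict[int, np.ndarray] = {}
        for nd in self._postorder:
            if nd.is_leaf():
                tp = self._tip_partials[nd.taxon.label]  # (npat, 4)
                p = np.broadcast_to(tp, (ncat,) + tp.shape)
            else:
                p = None
                for ch in nd.child_nodes():
                    pmats_t = self._edge_pmats_t(ch.edge.length or 0.0)
                    # (ncat, npat, 4) @ (ncat, 4, 4): sum over child states
                    contrib = partials.pop(id(ch)) @ pmats_t
                    p = contrib if p is None else p * contrib
            partials[id(nd)] = p
        return partials[id(self._postorder[-1])]

    # -- branch-length optimisation -------------------------------------
    def optimizable_edges(self):
        root = self.tree.seed_node
        return [nd.edge for nd in self.tree.preorder_node_iter() if nd is not root]

    def optimize_branch_lengths(self, tol: float = 1e-6, max_rounds: int = 10,
                                max_len: float = 20.0) -> float:
        """Round-robin Brent optimisation of every edge length until the
        log-likelihood improvement falls below ``tol``. Returns final logL."""
        edges = self.optimizable_edges()
        for e in edges:
            if e.length is None or e.length < 1e-9:
                e.length = 1e-9
        current = self.log_likelihood()
        for _ in range(max_rounds):
            for e in edges:
                def neg(x, edge=e):
                    edge.length = x
                    try:
                        return -self.log_likelihood()
                    except LikelihoodError:
                        return 1e300
                res = minimize_scalar(neg, bounds=(1e-9, max_len),
                                      method="bounded",
                                      options={"xatol": 1e-7})
                e.length = float(res.x)
            new = self.log_likelihood()
            if new - current < tol:
                current = max(new, current)
                break
            current = new
        return current


def two_sequence_log_likelihood(counts4x4: np.ndarray, t: float,
                                model: SubstitutionModel) -> float:
    """Closed-path two-sequence logL used by tests as a cross-check."""
    from .distances import _pair_log_likelihood
    return _pair_log_likelihood(t, counts4x4, model,
                                model.eigen(), model.gamma_category_rates())
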