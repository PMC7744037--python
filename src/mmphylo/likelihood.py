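"""Compound-state pruning likelihood.

The observed-data likelihood of an alignment under a Markov-modulated
model is the product over sites of

    sum_{(k,s)} psi_k pi_ks L^R(k, s),

where L^R is the partial likelihood at the root, computed by Felsenstein
pruning over the KS compound states: at a tip the partial is 1 for every
compound state whose character component is compatible with the observed
symbol (the hidden model category is integrated out), and at an internal
node it is the product over children of P(t_child) applied to the child
partials. Transition probabilities come from the matrix exponential of
the compound generator Lambda.

With discrete-gamma ASRV the per-site likelihood is the equal-weight
average over categories, each category rescaling branch time (the whole of
Lambda — substitution and switching rates alike) by its rate.

Pruning cost is O(N L K^2 S^2) after the per-branch exponentials; site
patterns are deduplicated so L counts unique columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import MatrixExponentiator
from .errors import ValidationError
from .mmm import CompoundModel, MMMSpec, compose_compound_generator
from .phylo import Alignment, Tree, match_tree_alignment

_RESCALE_THRESHOLD = 1e-100


def transition_matrix(model: CompoundModel, t: float, rate_scalar: float = 1.0) -> np.ndarray:
    """Row-stochastic ``expm(rate_scalar * t * Lambda)``."""
    if t < 0:
        raise ValidationError("elapsed time t must be nonnegative")
    if rate_scalar <= 0:
        raise ValidationError("rate_scalar must be positive")
    return MatrixExponentiator(model.generator).expm(rate_scalar * t)


def site_pattern_compression(alignment: Alignment):
    """Collapse identical alignment columns.

    Returns ``(patterns, weights, inverse)`` where ``patterns`` is a
    (n_taxa, n_patterns) character array of the unique columns, ``weights``
    their multiplicities and ``inverse`` maps each original site to its
    pattern. The likelihood over weighted patterns equals the uncompressed
    likelihood exactly.
    """
    if alignment.n_sites == 0:
        raise ValidationError("empty alignment: no sites to compress")
    mat = np.array([list(s) for s in alignment.sequences])  # (n_taxa, L)
    patterns, inverse, counts = np.unique(
        mat, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(float), inverse.ravel()


@dataclass
class LikelihoodResult:
    """Total and per-site log-likelihoods, plus ASRV category posteriors."""

    log_likelihood: float
    site_log_likelihoods: np.ndarray
    category_posteriors: np.ndarray | None = None  # (n_sites, n_categories)

    def __float__(self) -> float:
        return self.log_likelihood


class LikelihoodEvaluator:
    """Reusable pruning engine bound to one (tree, alignment) pair.

    Construction pays the data-dependent costs once (taxon matching,
    pattern compression, tip indicator masks); :meth:`log_likelihood` can
    then be called repeatedly with different parameterizations, which is
    what the optimizer and the MCMC sampler do.
    """

    def __init__(self, alignment: Alignment, tree: Tree, *,
                 compress: bool = True, on_unknown: str = "error"):
        self.tree = tree
        self.alignment = alignment
        order = match_tree_alignment(tree, alignment)
        tip_part = alignment.tip_partials(on_unknown=on_unknown)[order]  # tree-tip order
        if compress and alignment.n_sites > 0:
            _, self.weights, self.inverse = site_pattern_compression(alignment)
            n_pat = int(self.inverse.max()) + 1
            first_site = np.zeros(n_pat, dtype=int)
            first_site[self.inverse[::-1]] = np.arange(alignment.n_sites - 1, -1, -1)
            self.tip_partials = tip_part[:, first_site, :]  # (n_tips, n_pat, S)
        else:
            self.weights = np.ones(alignment.n_sites)
            self.inverse = np.arange(alignment.n_sites)
            self.tip_partials = tip_part
        self.n_patterns = self.tip_partials.shape[1]
        self._tip_row = {int(v): i for i, v in enumerate(tree.tip_nodes)}
        self._tiled_tips: dict[int, np.ndarray] = {}

    def _tiled(self, k: int) -> np.ndarray:
        """Tip partials replicated across the K model blocks, cached."""
        if k not in self._tiled_tips:
            self._tiled_tips[k] = np.tile(self.tip_partials, (1, 1, k))
        return self._tiled_tips[k]

    # -- core pruning over one rate category ------------------------------

    def _pattern_logliks(self, compound: CompoundModel, rates: np.ndarray,
                         expm: MatrixExponentiator) -> np.ndarray:
        """Pattern log-likelihoods for every rate category at once.

        Categories ride along as a leading batch axis of the partials, so
        one pruning sweep serves the whole ASRV mixture. Returns
        (n_categories, n_patterns).
        """
        tree = self.tree
        k = compound.n_models
        n_cat = rates.size
        tiled = self._tiled(k)
        n_branch = tree.n_nodes - 1
        # all (category, branch) transition matrices in one batched exponential
        ts = np.multiply.outer(rates, tree.branch_lengths[:-1]).ravel()
        p_all = expm.expm_batch(ts).reshape(n_cat, n_branch,
                                            compound.n_compound, compound.n_compound)
        p_all = np.ascontiguousarray(p_all.transpose(1, 0, 3, 2))  # (branch, cat, C, C) pre-transposed
        partial = [None] * tree.n_nodes
        scale = np.zeros((n_cat, self.n_patterns))
        for v in tree.postorder():
            if tree.is_tip(v):
                partial[v] = np.broadcast_to(
                    tiled[self._tip_row[v]], (n_cat, self.n_patterns, k * compound.n_states)
                )
                continue
            acc = None
            for child in tree.children[v]:
                term = partial[child] @ p_all[child]
                acc = term if acc is None else acc * term
                partial[child] = None  # free memory
            mx = acc.max(axis=2)
            if (mx < _RESCALE_THRESHOLD).any():
                low = (mx < _RESCALE_THRESHOLD) & (mx > 0)
                acc[low] /= mx[low, None]
                scale[low] += np.log(mx[low])
            partial[v] = acc
        site_lik = partial[tree.root] @ compound.stationary
        with np.errstate(divide="ignore"):
            return np.where(site_lik > 0, np.log(np.maximum(site_lik, 1e-320)), -np.inf) + scale

    def log_likelihood(self, spec: MMMSpec, *, per_site: bool = True) -> LikelihoodResult:
        compound = compose_compound_generator(spec)
        if compound.n_states != len(self.alignment.alphabet):
            raise ValidationError(
                "model alphabet size does not match the alignment alphabet"
            )
        expm = MatrixExponentiator(compound.generator)
        if spec.asrv is None:
            pat_log = self._pattern_logliks(compound, np.ones(1), expm)[0]
            cat_post = None
        else:
            rates = np.asarray(spec.asrv.category_rates, dtype=float)
            logw = np.log(spec.asrv.category_weights)
            per_cat = self._pattern_logliks(compound, rates, expm).T  # (n_pat, n_cat)
            shifted = per_cat + logw
            m = shifted.max(axis=1)
            safe_m = np.where(np.isfinite(m), m, 0.0)
            pat_log = safe_m + np.log(np.exp(shifted - safe_m[:, None]).sum(axis=1))
            with np.errstate(invalid="ignore"):
                cat_post = np.exp(per_cat + logw - pat_log[:, None])
        total = float(self.weights @ pat_log)
        site_logs = pat_log[self.inverse] if per_site else None
        posts = cat_post[self.inverse] if cat_post is not None else None
        return LikelihoodResult(total, site_logs, posts)


def tree_log_likelihood(alignment: Alignment, tree: Tree, spec: MMMSpec, *,
                        compress: bool = True) -> LikelihoodResult:
    """One-shot pruning log-likelihood (see :class:`LikelihoodEvaluator`)."""
    return LikelihoodEvaluator(alignment, tree, compress=compress).log_likelihood(spec)
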