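"""Hidden model-state reconstruction at a fixed tree and parameterization.

Two complementary summaries of where the compound chain spent its time:

- the *joint MAP realization*: per site, the single most probable
  assignment of compound states (model, character) to every node, found by
  max-product dynamic programming over the tree with the stationary
  distribution as the root weight;
- *marginal model posteriors*: per site and node, the posterior
  distribution over the hidden model category, from an inside-outside
  computation.

From a realization, switch counting treats the model state of a branch as
the model index at its child node, so a per-site switch count is the
number of edges whose endpoints disagree in model index. A switch that
occurs and reverts inside one edge is invisible to this summary. Expected
per-model dwell times on each branch, conditional on the endpoint states,
are available as an optional refinement (computed exactly via the Van
Loan block-exponential integral).

With ASRV, the joint MAP also maximizes over the site's rate category,
and marginal posteriors average over categories with their per-site
posterior weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ._linalg import MatrixExponentiator
from .errors import ValidationError
from .likelihood import LikelihoodEvaluator
from .mmm import MMMSpec, compose_compound_generator
from .phylo import Alignment, Tree

_LOG_ZERO = -1e30  # sentinel for impossible states in max-product DP


@dataclass
class HiddenRealization:
    """Per-site, per-node compound-state assignment with its joint score."""

    node_states: np.ndarray  # (n_nodes, n_sites) compound indices
    joint_log_prob: np.ndarray  # (n_sites,)
    n_models: int
    n_states: int
    categories: np.ndarray | None = None  # per-site ASRV category of the MAP

    def model_states(self) -> np.ndarray:
        return self.node_states // self.n_states

    def char_states(self) -> np.ndarray:
        return self.node_states % self.n_states


@dataclass
class SwitchSummary:
    """Counting summaries of a hidden realization."""

    per_site_switches: np.ndarray  # (n_sites,) edges with discordant models
    histogram: np.ndarray  # histogram of per-site counts
    n_non_switching_sites: int
    branch_proportions: np.ndarray | None = None  # (n_edges, K) rows sum to 1
    model_site_totals: np.ndarray | None = None  # (K,) sites per root... model at child nodes
    dwell_times: np.ndarray | None = None  # (n_edges, n_sites, K) expected time


def _log_transition_tables(compound, tree: Tree, rate: float) -> list[np.ndarray]:
    expm = MatrixExponentiator(compound.generator)
    tables = [None] * tree.n_nodes
    for v, t in tree.edges():
        p = expm.expm(rate * t)
        with np.errstate(divide="ignore"):
            tables[v] = np.where(p > 0, np.log(np.maximum(p, 1e-300)), _LOG_ZERO)
    return tables


def _map_one_category(tree, compound, tip_log, log_p):
    """Max-product DP for all patterns under one rate category.

    ``tip_log``: dict node -> (n_pat, C) log tip indicators.
    Returns (scores (n_pat,), states (n_nodes, n_pat)).
    """
    c = compound.n_compound
    n_pat = next(iter(tip_log.values())).shape[0]
    msg = [None] * tree.n_nodes  # up-message of child v: (n_pat, C_parent)
    back = [None] * tree.n_nodes  # argmax child state: (n_pat, C_parent)
    subtree = [None] * tree.n_nodes
    for v in tree.postorder():
        if tree.is_tip(v):
            subtree[v] = tip_log[v]
        else:
            acc = np.zeros((n_pat, c))
            for ch in tree.children[v]:
                acc += msg[ch]
            subtree[v] = acc
        if v != tree.root:
            # scores[pat, parent, child] = logP[parent, child] + subtree[pat, child]
            scores = log_p[v][None, :, :] + subtree[v][:, None, :]
            back[v] = scores.argmax(axis=2)
            msg[v] = scores.max(axis=2)
    with np.errstate(divide="ignore"):
        root_w = np.where(compound.stationary > 0,
                          np.log(np.maximum(compound.stationary, 1e-300)), _LOG_ZERO)
    root_scores = subtree[tree.root] + root_w[None, :]
    best_root = root_scores.argmax(axis=1)
    best_score = root_scores.max(axis=1)
    states = np.zeros((tree.n_nodes, n_pat), dtype=int)
    states[tree.root] = best_root
    for v in tree.preorder():
        if v == tree.root:
            continue
        parent_states = states[tree.parent[v]]
        states[v] = back[v][np.arange(n_pat), parent_states]
    return best_score, states


def joint_map_realization(alignment: Alignment, tree: Tree, spec: MMMSpec) -> HiddenRealization:
    """Jointly most probable compound states at all nodes, per site.

    Ties break toward the lowest compound index (lowest model, then lowest
    character), which the model-major index order makes deterministic.
    """
    ev = LikelihoodEvaluator(alignment, tree)
    compound = compose_compound_generator(spec)
    k, s = compound.n_models, compound.n_states
    tip_log = {}
    for i, v in enumerate(tree.tip_nodes):
        tp = np.tile(ev.tip_partials[i], (1, k))
        with np.errstate(divide="ignore"):
            tip_log[int(v)] = np.where(tp > 0, 0.0, _LOG_ZERO)
    if spec.asrv is None:
        score, states = _map_one_category(
            tree, compound, tip_log, _log_transition_tables(compound, tree, 1.0)
        )
        cats = None
    else:
        logw = np.log(spec.asrv.category_weights)
        all_scores, all_states = [], []
        for ci, r in enumerate(spec.asrv.category_rates):
            sc, st = _map_one_category(
                tree, compound, tip_log,
                _log_transition_tables(compound, tree, float(r)),
            )
            all_scores.append(sc + logw[ci])
            all_states.append(st)
        all_scores = np.stack(all_scores)  # (n_cat, n_pat)
        best_cat = all_scores.argmax(axis=0)
        score = all_scores.max(axis=0)
        n_pat = best_cat.size
        states = np.zeros((tree.n_nodes, n_pat), dtype=int)
        for ci in range(len(all_states)):
            sel = best_cat == ci
            states[:, sel] = all_states[ci][:, sel]
        cats = best_cat[ev.inverse]
    inv = ev.inverse
    return HiddenRealization(states[:, inv], score[inv], k, s, categories=cats)


def count_model_switches(realization: HiddenRealization, tree: Tree) -> SwitchSummary:
    """Per-site number of edges whose endpoint model indices differ."""
    models = realization.model_states()
    if models.shape[0] != tree.n_nodes:
        raise ValidationError("realization does not cover every tree node")
    diffs = np.zeros(models.shape[1], dtype=int)
    for v in range(tree.n_nodes - 1):
        diffs += models[v] != models[tree.parent[v]]
    hist = np.bincount(diffs, minlength=1)
    return SwitchSummary(diffs, hist, int((diffs == 0).sum()))


def branch_model_proportions(realization: HiddenRealization, tree: Tree) -> SwitchSummary:
    """Per-edge fraction of sites assigned to each model at the child node."""
    models = realization.model_states()
    k = realization.n_models
    n_edges = tree.n_nodes - 1
    props = np.zeros((n_edges, k))
    for v in range(n_edges):
        props[v] = np.bincount(models[v], minlength=k) / models.shape[1]
    totals = np.zeros(k, dtype=int)
    # per-model site totals: majority model across nodes for each site
    maj = np.array([
        np.bincount(models[:, i], minlength=k).argmax() for i in range(models.shape[1])
    ])
    for m in range(k):
        totals[m] = int((maj == m).sum())
    base = count_model_switches(realization, tree)
    base.branch_proportions = props
    base.model_site_totals = totals
    return base


def marginal_model_posteriors(alignment: Alignment, tree: Tree, spec: MMMSpec) -> np.ndarray:
    """Posterior P(model k | data) per node and site, shape (n_nodes, n_sites, K).

    Inside-outside over compound states; with ASRV the per-category node
    marginals are averaged with the site's posterior category weights.
    """
    ev = LikelihoodEvaluator(alignment, tree)
    compound = compose_compound_generator(spec)
    k, s = compound.n_models, compound.n_states
    rates = [1.0] if spec.asrv is None else list(spec.asrv.category_rates)
    weights = np.array([1.0]) if spec.asrv is None else spec.asrv.category_weights

    n_pat = ev.n_patterns
    per_cat_marg = []  # (n_nodes, n_pat, K) per category
    per_cat_lik = []  # (n_pat,) pattern likelihood per category
    for r in rates:
        expm = MatrixExponentiator(compound.generator)
        p_mat = [None] * tree.n_nodes
        for v, t in tree.edges():
            p_mat[v] = expm.expm(float(r) * t)
        up = [None] * tree.n_nodes
        for v in tree.postorder():
            if tree.is_tip(v):
                row = list(tree.tip_nodes).index(v)
                up[v] = np.tile(ev.tip_partials[row], (1, k))
            else:
                acc = np.ones((n_pat, compound.n_compound))
                for ch in tree.children[v]:
                    acc *= up[ch] @ p_mat[ch].T
                up[v] = acc
        down = [None] * tree.n_nodes
        down[tree.root] = np.tile(compound.stationary, (n_pat, 1))
        for v in tree.preorder():
            for ch in tree.children[v]:
                prod = down[v].copy()
                for sib in tree.children[v]:
                    if sib != ch:
                        prod *= up[sib] @ p_mat[sib].T
                down[ch] = prod @ p_mat[ch]
        marg = np.zeros((tree.n_nodes, n_pat, k))
        lik = (up[tree.root] * down[tree.root]).sum(axis=1)
        for v in range(tree.n_nodes):
            joint = up[v] * down[v]  # (n_pat, C), proportional to state marginal
            marg[v] = joint.reshape(n_pat, k, s).sum(axis=2)
        per_cat_marg.append(marg)
        per_cat_lik.append(lik)
    lik = np.stack(per_cat_lik, axis=1)  # (n_pat, n_cat)
    cat_post = lik * weights[None, :]
    cat_post /= cat_post.sum(axis=1, keepdims=True)
    marg = np.zeros((tree.n_nodes, n_pat, k))
    for ci in range(len(rates)):
        m = per_cat_marg[ci]
        m = m / np.maximum(m.sum(axis=2, keepdims=True), 1e-300)
        marg += m * cat_post[None, :, ci, None]
    return marg[:, ev.inverse, :]


def branch_dwell_times(realization: HiddenRealization, tree: Tree, spec: MMMSpec) -> np.ndarray:
    """Expected time spent in each model on each edge, per site.

    Conditional on the realization's endpoint compound states (a, b) of an
    edge of length t, the expectation of the time the chain spends in
    model k is the Van Loan integral

        [expm(t [[Lambda, B_k], [0, Lambda]])]_{upper right}[a, b] / P_ab(t),

    with B_k the diagonal indicator of model k's block. Shape returned:
    (n_edges, n_sites, K); rows sum to the branch length. With ASRV the
    site's MAP category rescales the branch time.
    """
    compound = compose_compound_generator(spec)
    c = compound.n_compound
    k, s = compound.n_models, compound.n_states
    lam = compound.generator
    n_sites = realization.node_states.shape[1]
    n_edges = tree.n_nodes - 1
    out = np.zeros((n_edges, n_sites, k))
    cats = realization.categories
    rates = np.ones(n_sites)
    if cats is not None and spec.asrv is not None:
        rates = spec.asrv.category_rates[cats]
    expm_cache: dict[float, tuple] = {}
    for v, t in tree.edges():
        for site in range(n_sites):
            tt = t * rates[site]
            key = round(tt, 12)
            if key not in expm_cache:
                p = scipy.linalg.expm(lam * tt) if tt > 0 else np.eye(c)
                integrals = []
                for m in range(k):
                    b = np.zeros((c, c))
                    idx = np.arange(m * s, (m + 1) * s)
                    b[idx, idx] = 1.0
                    if tt > 0:
                        big = np.zeros((2 * c, 2 * c))
                        big[:c, :c] = lam
                        big[c:, c:] = lam
                        big[:c, c:] = b
                        integrals.append(scipy.linalg.expm(big * tt)[:c, c:])
                    else:
                        integrals.append(np.zeros((c, c)))
                expm_cache[key] = (p, integrals)
            p, integrals = expm_cache[key]
            a, bstate = realization.node_states[tree.parent[v], site], realization.node_states[v, site]
            pab = p[a, bstate]
            if pab <= 0:
                continue
            for m in range(k):
                out[v, site, m] = integrals[m][a, bstate] / pab
    return out
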