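"""Independent reference implementations used as test oracles.

Everything here is deliberately written by the most direct route available
(element-wise assembly, exhaustive enumeration, quadrature, truncated
series) and shares no code path with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.linalg import null_space
from scipy.stats import gamma as gamma_dist


def assemble_q_elementwise(sym_rates, freqs):
    """Reversible generator from Q_ij = pi_j * R_ij, then unit-rate rescale.

    ``sym_rates`` is given as a full symmetric matrix here (distinct input
    convention from the package's condensed vector).
    """
    r = np.asarray(sym_rates, dtype=float)
    pi = np.asarray(freqs, dtype=float)
    s = pi.size
    q = np.empty((s, s))
    for i in range(s):
        for j in range(s):
            if i != j:
                q[i, j] = pi[j] * r[i, j]
    for i in range(s):
        q[i, i] = -sum(q[i, j] for j in range(s) if j != i)
    mu = sum(-q[i, i] * pi[i] for i in range(s))
    return q / mu


def sym_matrix_from_condensed(vec, s):
    """Expand the package's condensed upper-triangle order to a matrix."""
    m = np.zeros((s, s))
    it = iter(vec)
    for i in range(s):
        for j in range(i + 1, s):
            m[i, j] = m[j, i] = next(it)
    return m


def gamma_category_means_quadrature(alpha, n):
    """Conditional category means of Gamma(alpha, alpha) by numerical quadrature."""
    bounds = gamma_dist.ppf(np.arange(n + 1) / n, a=alpha, scale=1.0 / alpha)
    bounds[0], bounds[-1] = 0.0, np.inf
    means = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        val, _ = quad(lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1.0 / alpha),
                      lo, hi, limit=200)
        means.append(val * n)  # divide by the 1/n category mass
    return np.array(means)


def stationary_nullspace(rate_matrix):
    """Normalized left null vector via scipy's SVD null space."""
    ns = null_space(np.asarray(rate_matrix, dtype=float).T)
    assert ns.shape[1] == 1, "expected a one-dimensional null space"
    v = ns[:, 0]
    v = v / v.sum()
    return v


def compound_generator_entrywise(components, multipliers, phi, psi=None,
                                 normalize=True):
    """Lambda built entry-by-entry from the (k,s) -> (k',s') transition rules."""
    k = len(components)
    s = components[0].shape[0] if isinstance(components[0], np.ndarray) else components[0].generator.shape[0]
    qs = [c if isinstance(c, np.ndarray) else c.generator for c in components]
    rho = np.asarray(multipliers, dtype=float).copy()
    if normalize:
        assert psi is not None
        rho = rho / float(np.asarray(psi) @ rho)
    lam = np.zeros((k * s, k * s))
    for ka in range(k):
        for sa in range(s):
            for kb in range(k):
                for sb in range(s):
                    a, b = ka * s + sa, kb * s + sb
                    if ka == kb and sa != sb:
                        lam[a, b] = rho[ka] * qs[ka][sa, sb]
                    elif ka != kb and sa == sb:
                        lam[a, b] = phi[ka, kb]
                    elif a != b:
                        lam[a, b] = 0.0
    for a in range(k * s):
        lam[a, a] = -sum(lam[a, b] for b in range(k * s) if b != a)
    return lam


def expm_series(q, t, terms=60):
    """Truncated Taylor series with scaling-and-squaring, independent of scipy."""
    q = np.asarray(q, dtype=float)
    norm = np.abs(q * t).sum(axis=1).max()
    squarings = max(0, int(np.ceil(np.log2(max(norm, 1e-12)))) + 2)
    a = q * (t / 2**squarings)
    p = np.eye(q.shape[0])
    term = np.eye(q.shape[0])
    for i in range(1, terms):
        term = term @ a / i
        p = p + term
    for _ in range(squarings):
        p = p @ p
    return p


def jc_transition_closed_form(t):
    """4-state equal-rate transition probabilities (unit-rate normalized)."""
    p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    p_diff = (1.0 - p_same) / 3.0
    p = np.full((4, 4), p_diff)
    np.fill_diagonal(p, p_same)
    return p


# ---------------------------------------------------------------------------
# standard (single-model) pruning, written recursively
# ---------------------------------------------------------------------------

def reference_standard_pruning(tip_partials, tree, q, pi, rates=None, weights=None,
                               expm=None):
    """Per-site log-likelihoods under one substitution model.

    ``tip_partials``: (n_tips, n_sites, S) indicators in tree tip order.
    Optional ``rates``/``weights`` mix discrete rate categories.
    """
    import scipy.linalg

    expm = expm or (lambda m: scipy.linalg.expm(m))
    rates = [1.0] if rates is None else list(rates)
    weights = [1.0] if weights is None else list(weights)
    n_sites = tip_partials.shape[1]
    tip_row = {int(v): i for i, v in enumerate(tree.tip_nodes)}

    def partial(v, site, p_cache):
        if tree.is_tip(v):
            return tip_partials[tip_row[v], site]
        out = np.ones(len(pi))
        for ch in tree.children[v]:
            out = out * (p_cache[ch] @ partial(ch, site, p_cache))
        return out

    total = np.zeros(n_sites)
    for site in range(n_sites):
        lik = 0.0
        for r, w in zip(rates, weights):
            p_cache = {v: expm(q * (r * t)) for v, t in tree.edges()}
            lik += w * float(pi @ partial(tree.root, site, p_cache))
        total[site] = np.log(lik)
    return total


# ---------------------------------------------------------------------------
# exhaustive enumeration over compound states
# ---------------------------------------------------------------------------

def _compound_setup(tree, spec):
    import scipy.linalg

    from mmphylo.mmm import compose_compound_generator

    comp = compose_compound_generator(spec)
    rates = [1.0] if spec.asrv is None else list(spec.asrv.category_rates)
    weights = [1.0] if spec.asrv is None else list(spec.asrv.category_weights)
    p_by_rate = [
        {v: scipy.linalg.expm(comp.generator * (r * t)) for v, t in tree.edges()}
        for r in rates
    ]
    return comp, rates, weights, p_by_rate


def _tip_allowed(alignment, tree, comp):
    from mmphylo.phylo import match_tree_alignment

    order = match_tree_alignment(tree, alignment)
    tp = alignment.tip_partials()[order]
    allowed = {}
    for i, v in enumerate(tree.tip_nodes):
        allowed[int(v)] = [
            np.nonzero(np.tile(tp[i, site], comp.n_models))[0]
            for site in range(alignment.n_sites)
        ]
    return allowed


def enumeration_loglik(alignment, tree, spec):
    """Sum over all compound-state assignments to every node, per site.

    Exhaustive: a probability is evaluated for every joint assignment of a
    compound state to every node (tips restricted to their compatible
    states). The assignment grid is laid out as one numpy axis per node so
    the full C^(n_internal) enumeration stays affordable.
    """
    comp, rates, weights, p_by_rate = _compound_setup(tree, spec)
    allowed = _tip_allowed(alignment, tree, comp)
    c = comp.n_compound
    n_nodes = tree.n_nodes
    total = 0.0
    for site in range(alignment.n_sites):
        lik = 0.0
        for w, p_cache in zip(weights, p_by_rate):
            choices = [
                np.asarray(allowed[v][site]) if tree.is_tip(v) else np.arange(c)
                for v in range(n_nodes)
            ]
            def axis(v, arr1d):
                shape = [1] * n_nodes
                shape[v] = arr1d.size
                return arr1d.reshape(shape)

            prob = axis(tree.root, comp.stationary[choices[tree.root]])
            for v, _t in tree.edges():
                pv = p_cache[v][np.ix_(choices[tree.parent[v]], choices[v])]
                # child axis (v) precedes the parent axis in postorder, so
                # transpose to (child, parent) before reshaping onto the grid
                shape = [1] * n_nodes
                shape[tree.parent[v]] = choices[tree.parent[v]].size
                shape[v] = choices[v].size
                prob = prob * pv.T.reshape(shape)
            lik += w * prob.sum()
        total += np.log(lik)
    return total


def enumeration_joint_map(alignment, tree, spec):
    """Most probable compound assignment per site by brute-force maximization.

    Returns (states (n_nodes, n_sites), log_prob (n_sites,)). Ties break
    toward the lexicographically smallest assignment in node order
    (root-first preorder would differ; this matches scanning assignments
    in ascending index order and keeping strict improvements only).
    """
    comp, rates, weights, p_by_rate = _compound_setup(tree, spec)
    allowed = _tip_allowed(alignment, tree, comp)
    c = comp.n_compound
    n_sites = alignment.n_sites
    best_states = np.zeros((tree.n_nodes, n_sites), dtype=int)
    best_logp = np.full(n_sites, -np.inf)
    for site in range(n_sites):
        for w, p_cache in zip(weights, p_by_rate):
            choices = [
                allowed[v][site] if tree.is_tip(v) else range(c)
                for v in range(tree.n_nodes)
            ]
            for assign in itertools.product(*choices):
                p = w * comp.stationary[assign[tree.root]]
                for v, _t in tree.edges():
                    p *= p_cache[v][assign[tree.parent[v]], assign[v]]
                if p > 0 and np.log(p) > best_logp[site] + 1e-12:
                    best_logp[site] = np.log(p)
                    best_states[:, site] = assign
    return best_states, best_logp


def enumeration_model_marginals(alignment, tree, spec):
    """Per-node, per-site model posteriors by exhaustive summation."""
    comp, rates, weights, p_by_rate = _compound_setup(tree, spec)
    allowed = _tip_allowed(alignment, tree, comp)
    c = comp.n_compound
    s = comp.n_states
    n_sites = alignment.n_sites
    out = np.zeros((tree.n_nodes, n_sites, comp.n_models))
    for site in range(n_sites):
        for w, p_cache in zip(weights, p_by_rate):
            choices = [
                allowed[v][site] if tree.is_tip(v) else range(c)
                for v in range(tree.n_nodes)
            ]
            for assign in itertools.product(*choices):
                p = w * comp.stationary[assign[tree.root]]
                for v, _t in tree.edges():
                    p *= p_cache[v][assign[tree.parent[v]], assign[v]]
                for v in range(tree.n_nodes):
                    out[v, site, assign[v] // s] += p
    out /= out.sum(axis=2, keepdims=True)
    return out


def edge_scan_switch_counts(model_states, tree):
    """Per-site switch counts by scanning every edge independently."""
    n_sites = model_states.shape[1]
    counts = []
    for site in range(n_sites):
        n = 0
        for v, _t in tree.edges():
            if model_states[v, site] != model_states[tree.parent[v], site]:
                n += 1
        counts.append(n)
    return np.array(counts)
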