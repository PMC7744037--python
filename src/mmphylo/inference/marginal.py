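"""Stepping-stone estimation of the log marginal likelihood.

The marginal likelihood Z = integral L(theta) p(theta) dtheta is written
as a telescoping product of ratios between adjacent power posteriors
p_beta ~ L^beta p. With a ladder 0 = beta_0 < ... < beta_n = 1 chosen as
quantiles of a Beta(0.3, 1) distribution (concentrating rungs near the
prior, where the integrand varies fastest), each ratio is estimated by
importance sampling from the lower rung:

    Z_{j+1} / Z_j  ~=  mean over samples of  L(theta)^(beta_{j+1} - beta_j).

Chains warm-start from the previous rung's final state. The Monte Carlo
standard error is assembled per rung via the delta method (treating
samples as independent after thinning, which understates error for
poorly mixing chains; the per-rung breakdown is reported so divergent
rungs are visible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ..errors import ValidationError
from ..likelihood import LikelihoodEvaluator
from ..mmm import MMMSpec
from ..phylo import Alignment, Tree
from .mcmc import _BlockSampler
from .parameters import build_parameter_set
from .priors import PriorSet, default_priors


@dataclass
class MarginalLikelihood:
    """Stepping-stone estimate with its per-rung decomposition."""

    log_ml: float
    step_contributions: np.ndarray
    betas: np.ndarray
    standard_error: float
    step_standard_errors: np.ndarray
    model_name: str = ""

    def __float__(self) -> float:
        return self.log_ml


@dataclass
class LogBayesFactor:
    """log BF = log Z_a - log Z_b; positive favors model a."""

    value: float
    standard_error: float

    def __float__(self) -> float:
        return self.value


def beta_schedule(n_steps: int, shape: float = 0.3) -> np.ndarray:
    """Beta(shape, 1)-quantile ladder from 0 to 1 inclusive."""
    return (np.arange(n_steps + 1) / n_steps) ** (1.0 / shape)


def stepping_stone_logml(
    alignment: Alignment,
    tree: Tree,
    spec: MMMSpec,
    priors: PriorSet | None = None,
    n_steps: int = 16,
    chain_length: int = 1000,
    burnin: int = 250,
    thin: int = 1,
    seed: int = 0,
    *,
    free: list[str] | None = None,
    rw_scales: dict | None = None,
    evaluator: LikelihoodEvaluator | None = None,
) -> MarginalLikelihood:
    """Estimate the log marginal likelihood of ``spec`` by stepping-stone.

    ``chain_length`` and ``burnin`` are per rung; samples are the thinned
    post-burn-in states. The rung at beta = 1 is not sampled (it is never
    an importance-sampling source).
    """
    if n_steps < 8:
        raise ValidationError("stepping-stone requires n_steps >= 8")
    if chain_length <= burnin:
        raise ValidationError("chain_length must exceed burnin")
    ps = build_parameter_set(spec, free=free)
    if priors is None:
        priors = default_priors(ps)
    if evaluator is None:
        evaluator = LikelihoodEvaluator(alignment, tree)
    rng = np.random.default_rng(seed)
    betas = beta_schedule(n_steps)
    sampler = _BlockSampler(evaluator, ps, priors, rng, rw_scales)

    contributions = np.zeros(n_steps)
    step_se = np.zeros(n_steps)
    for j in range(n_steps):
        beta = betas[j]
        d_beta = betas[j + 1] - beta
        sampler.adapt(beta, burnin)  # burn-in doubles as proposal-scale tuning
        logl = []
        for it in range(chain_length - burnin):
            sampler.step(beta)
            if it % thin == 0:
                logl.append(sampler.loglik)
        logl = np.array(logl)
        n = logl.size
        shifted = d_beta * (logl - logl.max())
        log_mean = logsumexp(shifted) - np.log(n)
        contributions[j] = d_beta * logl.max() + log_mean
        w = np.exp(shifted - log_mean)  # self-normalized weights, mean 1
        step_se[j] = float(w.std(ddof=1) / np.sqrt(n)) if n > 1 else np.inf
        if step_se[j] > 1.0:
            warnings.warn(
                f"stepping-stone rung {j} (beta={beta:.4g}) has high variance "
                f"(relative SE {step_se[j]:.2f}); per-rung SEs: "
                f"{np.round(step_se[:j + 1], 3).tolist()}",
                RuntimeWarning,
                stacklevel=2,
            )
    # relative SE of each ratio translates to absolute SE on the log scale
    total_se = float(np.sqrt(np.sum(step_se**2)))
    return MarginalLikelihood(
        float(contributions.sum()), contributions, betas, total_se, step_se,
        model_name=spec.name or spec.canonical_name(),
    )


def log_bayes_factor(a: MarginalLikelihood, b: MarginalLikelihood) -> LogBayesFactor:
    """Difference of log marginal likelihoods with combined standard error."""
    return LogBayesFactor(
        a.log_ml - b.log_ml,
        float(np.hypot(a.standard_error, b.standard_error)),
    )
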