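"""Metropolis-within-blocks MCMC over MMM parameters.

The sampler works in the unconstrained parameter space (log for positive
blocks, stick-breaking for simplexes), targeting

    beta * logL(theta(y)) + log p(theta(y)) + log|J(y)|,

so that ``beta = 1`` is the posterior and ``beta = 0`` the prior — the
power posteriors needed by stepping-stone estimation. Each iteration picks
one block uniformly and proposes either a Gaussian random walk on its
unconstrained coordinates or an independence draw from its prior (whose
acceptance ratio reduces to the likelihood ratio to the power beta); the
mixture keeps mixing healthy both near the prior and near a concentrated
posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ValidationError
from ..likelihood import LikelihoodEvaluator
from ..mmm import MMMSpec
from ..phylo import Alignment, Tree
from .parameters import ParameterSet, build_parameter_set
from .priors import PriorSet, default_priors

_PRIOR_PROPOSAL_PROB = 0.3
_DEFAULT_RW_SCALE = 0.25


@dataclass
class McmcTrace:
    """Thinned samples with log-likelihood/log-prior columns."""

    parameter_labels: list[str]
    samples: np.ndarray  # (n_samples, n_parameters) natural scale
    iterations: np.ndarray
    log_likelihood: np.ndarray
    log_prior: np.ndarray
    acceptance_rates: dict[str, float]
    seed: int
    beta: float = 1.0
    final_state: ParameterSet | None = field(default=None, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=self.parameter_labels)
        df.insert(0, "iteration", self.iterations)
        df["log_likelihood"] = self.log_likelihood
        df["log_prior"] = self.log_prior
        return df

    def column(self, label: str) -> np.ndarray:
        return self.samples[:, self.parameter_labels.index(label)]


class _BlockSampler:
    """Shared machinery for posterior and power-posterior chains."""

    def __init__(self, evaluator: LikelihoodEvaluator, ps: ParameterSet,
                 priors: PriorSet, rng: np.random.Generator,
                 rw_scales: dict | None = None,
                 prior_proposal_prob: float = _PRIOR_PROPOSAL_PROB):
        priors.validate_against(ps)
        self.evaluator = evaluator
        self.priors = priors
        self.rng = rng
        self.state = ps
        self.free_names = [b.name for b in ps.free_blocks()]
        if not self.free_names:
            raise ValidationError("no free parameter blocks to sample")
        self.rw_scales = {n: _DEFAULT_RW_SCALE for n in self.free_names}
        if rw_scales:
            self.rw_scales.update(rw_scales)
        self.prior_proposal_prob = prior_proposal_prob
        self.loglik = self._loglik(ps)
        if not np.isfinite(self.loglik):
            raise ValidationError("log-likelihood not finite at the initial state")
        self.logprior = priors.log_prior(ps)
        self.proposed = {n: 0 for n in self.free_names}
        self.accepted = {n: 0 for n in self.free_names}

    def _loglik(self, ps: ParameterSet) -> float:
        return self.evaluator.log_likelihood(ps.to_spec(), per_site=False).log_likelihood

    def _block(self, ps: ParameterSet, name: str):
        for b in ps.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def step(self, beta: float) -> None:
        name = self.free_names[int(self.rng.integers(len(self.free_names)))]
        self.proposed[name] += 1
        block = self._block(self.state, name)
        # near the prior, independence proposals from the prior mix far better
        # than a random walk; near the posterior the reverse holds
        p_prior = max(self.prior_proposal_prob, np.exp(-beta * 100.0))
        accepted = False
        used_rw = False
        if self.rng.random() < p_prior:
            # independence proposal from the prior: prior and Jacobian cancel
            new_val = self.priors.sample_block_value(block, self.rng)
            cand = self.state.with_block_value(name, new_val)
            try:
                cand_ll = self._loglik(cand)
            except ValidationError:
                return name, used_rw, accepted
            if not np.isfinite(cand_ll) and beta > 0:
                return name, used_rw, accepted
            log_alpha = beta * (cand_ll - self.loglik) if beta > 0 else 0.0
        else:
            used_rw = True
            y = block.to_unconstrained()
            y_new = y + self.rng.normal(0.0, self.rw_scales[name], size=y.size)
            new_block = block.with_unconstrained(y_new)
            cand = self.state.with_block_value(name, new_block.value)
            try:
                cand_ll = self._loglik(cand) if beta > 0 else self.loglik
            except ValidationError:
                return name, used_rw, accepted
            if not np.isfinite(cand_ll) and beta > 0:
                return name, used_rw, accepted
            d_prior = (self.priors[name].log_pdf(
                           new_block.value if block.kind == "simplex"
                           else new_block.value[new_block.free])
                       - self.priors[name].log_pdf(
                           block.value if block.kind == "simplex"
                           else block.value[block.free]))
            d_jac = new_block.log_jacobian() - block.log_jacobian()
            if not np.isfinite(d_prior):
                return name, used_rw, accepted
            log_alpha = beta * (cand_ll - self.loglik) + d_prior + d_jac
        if np.log(self.rng.random()) < log_alpha:
            accepted = True
            self.accepted[name] += 1
            self.state = cand
            if beta > 0:
                self.loglik = cand_ll
            else:
                self.loglik = self._loglik(cand)
            self.logprior = self.priors.log_prior(cand)
        return name, used_rw, accepted

    def adapt(self, beta: float, n_iterations: int, *, target: float = 0.3,
              window: int = 25) -> None:
        """Burn-in scale adaptation: steer each block's random-walk scale
        toward the target acceptance rate at the current rung.

        Power posteriors range from prior-wide (large steps needed) to
        posterior-narrow (small steps); a fixed scale mixes poorly
        somewhere along the ladder. Adaptation runs only during burn-in,
        so the sampling phase remains a valid fixed-kernel chain.
        """
        acc = {n: 0 for n in self.free_names}
        prop = {n: 0 for n in self.free_names}
        for i in range(n_iterations):
            name, used_rw, accepted = self.step(beta)
            if used_rw:
                prop[name] += 1
                acc[name] += accepted
            if (i + 1) % window == 0:
                for n in self.free_names:
                    if prop[n] >= 5:
                        rate = acc[n] / prop[n]
                        self.rw_scales[n] *= float(np.exp(0.6 * (rate - target)))
                        self.rw_scales[n] = float(np.clip(self.rw_scales[n], 0.01, 3.0))
                        acc[n], prop[n] = 0, 0

    def acceptance_rates(self) -> dict[str, float]:
        return {
            n: self.accepted[n] / max(1, self.proposed[n]) for n in self.free_names
        }


def run_mcmc(
    alignment: Alignment,
    tree: Tree,
    spec: MMMSpec,
    priors: PriorSet | None = None,
    chain_length: int = 10000,
    thin: int = 10,
    seed: int = 0,
    *,
    beta: float = 1.0,
    free: list[str] | None = None,
    start: ParameterSet | None = None,
    rw_scales: dict | None = None,
    prior_proposal_prob: float = _PRIOR_PROPOSAL_PROB,
    evaluator: LikelihoodEvaluator | None = None,
) -> McmcTrace:
    """Sample the (power-)posterior of the free parameters of ``spec``.

    Reproducible given ``seed``. ``beta`` tempers the likelihood
    contribution (1 = posterior, 0 = prior).
    """
    if chain_length < 2 * thin:
        raise ValidationError("chain_length must be at least 2 * thin")
    ps = start if start is not None else build_parameter_set(spec, free=free)
    if priors is None:
        priors = default_priors(ps)
    if evaluator is None:
        evaluator = LikelihoodEvaluator(alignment, tree)
    rng = np.random.default_rng(seed)
    sampler = _BlockSampler(evaluator, ps, priors, rng, rw_scales,
                            prior_proposal_prob=prior_proposal_prob)

    rows, its, lls, lps = [], [], [], []
    for it in range(1, chain_length + 1):
        sampler.step(beta)
        if it % thin == 0:
            rows.append(sampler.state.natural_vector())
            its.append(it)
            lls.append(sampler.loglik)
            lps.append(sampler.logprior)
    return McmcTrace(
        ps.labels(),
        np.array(rows),
        np.array(its),
        np.array(lls),
        np.array(lps),
        sampler.acceptance_rates(),
        seed,
        beta=beta,
        final_state=sampler.state,
    )
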