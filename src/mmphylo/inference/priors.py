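"""Prior distributions over parameter blocks.

Defaults follow common Bayesian phylogenetics practice: flat Dirichlet on
frequency simplexes, diffuse Gamma(0.5, 1) on switching rates and GTR
exchangeabilities, Lognormal(0, 1) on the HKY kappa, Exponential with
mean 3 on the gamma shape, Lognormal(0, 1) on free rate multipliers.
All are overridable per block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from ..errors import ValidationError
from .parameters import ParameterSet


class Prior:
    """Interface: vectorized log-density and sampling for one block."""

    def log_pdf(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError

    def marginal_cdf(self, x: np.ndarray) -> np.ndarray:
        """CDF of a single coordinate (used by calibration checks)."""
        raise NotImplementedError


@dataclass
class GammaPrior(Prior):
    shape: float = 0.5
    rate: float = 1.0

    def log_pdf(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            return -np.inf
        # closed form; scipy.stats dispatch is too slow for sampler loops
        const = self.shape * np.log(self.rate) - gammaln(self.shape)
        return float(np.sum((self.shape - 1) * np.log(x) - self.rate * x + const))

    def sample(self, rng, size):
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)

    def marginal_cdf(self, x):
        return stats.gamma.cdf(x, a=self.shape, scale=1.0 / self.rate)


@dataclass
class LognormalPrior(Prior):
    mu: float = 0.0
    sigma: float = 1.0

    def log_pdf(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            return -np.inf
        z = (np.log(x) - self.mu) / self.sigma
        return float(np.sum(-np.log(x * self.sigma) - 0.5 * np.log(2 * np.pi)
                            - 0.5 * z * z))

    def sample(self, rng, size):
        return rng.lognormal(self.mu, self.sigma, size=size)

    def marginal_cdf(self, x):
        return stats.lognorm.cdf(x, s=self.sigma, scale=np.exp(self.mu))


@dataclass
class ExponentialPrior(Prior):
    rate: float = 1.0 / 3.0

    def log_pdf(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            return -np.inf
        return float(np.sum(np.log(self.rate) - self.rate * x))

    def sample(self, rng, size):
        return rng.exponential(1.0 / self.rate, size=size)

    def marginal_cdf(self, x):
        return stats.expon.cdf(x, scale=1.0 / self.rate)


@dataclass
class DirichletPrior(Prior):
    concentration: np.ndarray = None  # type: ignore[assignment]
    dim: int = 4

    def __post_init__(self):
        if self.concentration is None:
            self.concentration = np.ones(self.dim)
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.dim = self.concentration.size

    def log_pdf(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0) or abs(x.sum() - 1.0) > 1e-8:
            return -np.inf
        const = gammaln(self.concentration.sum()) - gammaln(self.concentration).sum()
        return float(const + np.sum((self.concentration - 1) * np.log(x / x.sum())))

    def sample(self, rng, size):
        # size is the simplex dimension here; one draw per call
        return rng.dirichlet(self.concentration)

    def marginal_cdf(self, x):
        a0 = self.concentration.sum()
        return stats.beta.cdf(x, self.concentration[0], a0 - self.concentration[0])


class PriorSet:
    """Mapping block name -> prior, with joint log-density and sampling."""

    def __init__(self, priors: dict[str, Prior]):
        self.priors = dict(priors)

    def __getitem__(self, name: str) -> Prior:
        return self.priors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.priors

    def validate_against(self, ps: ParameterSet) -> None:
        missing = [b.name for b in ps.free_blocks() if b.name not in self.priors]
        if missing:
            raise ValidationError(f"no prior specified for free blocks: {missing}")

    def log_prior(self, ps: ParameterSet) -> float:
        total = 0.0
        for b in ps.free_blocks():
            x = b.value if b.kind == "simplex" else b.value[b.free]
            total += self.priors[b.name].log_pdf(x)
        return total

    def sample_block_value(self, block, rng: np.random.Generator) -> np.ndarray:
        """Fresh prior draw for the free entries of ``block``.

        Fixed entries of a partially-free positive block keep their values.
        """
        draw = np.atleast_1d(self.priors[block.name].sample(rng, block.value.size))
        if block.kind == "simplex":
            return draw
        val = block.value.copy()
        val[block.free] = draw[: int(block.free.sum())]
        return val

    def sample(self, ps: ParameterSet, rng: np.random.Generator) -> ParameterSet:
        out = ps
        for b in ps.free_blocks():
            out = out.with_block_value(b.name, self.sample_block_value(b, rng))
        return out


def default_priors(ps: ParameterSet) -> PriorSet:
    """BEAST-style default priors for every free block of ``ps``."""
    spec = ps.template
    priors: dict[str, Prior] = {}
    for b in ps.free_blocks():
        if b.name.startswith("freqs"):
            priors[b.name] = DirichletPrior(dim=b.value.size)
        elif b.name.startswith("rates"):
            if spec.family == "HKY":
                priors[b.name] = LognormalPrior(0.0, 1.0)
            else:
                priors[b.name] = GammaPrior(0.5, 1.0)
        elif b.name == "switching":
            priors[b.name] = GammaPrior(0.5, 1.0)
        elif b.name == "multipliers":
            priors[b.name] = LognormalPrior(0.0, 1.0)
        elif b.name == "alpha":
            priors[b.name] = ExponentialPrior(1.0 / 3.0)
        else:
            raise ValidationError(f"no default prior for block {b.name!r}")
    return PriorSet(priors)
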