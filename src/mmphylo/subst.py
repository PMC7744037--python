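"""Component substitution models and discrete-gamma rate variation.

A component model is a time-reversible CTMC on an ordered character
alphabet, parameterized by symmetric exchangeabilities R_{i<->j} and a
stationary frequency vector pi, with off-diagonal rates

    Q_ij = pi_j * R_{i<->j},   i != j.

After assembly the generator is rescaled so that the expected number of
substitutions per unit time at stationarity equals one,
``-sum_s Q_ss pi_s = 1``, which makes branch lengths and the per-component
rate multipliers of a Markov-modulated model directly interpretable.

Among-site rate variation (ASRV) is the standard mean-one discrete-gamma
mixture: n equal-weight categories, each represented by its conditional
mean (or optionally median) rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .errors import ValidationError

NUCLEOTIDES = ("A", "C", "G", "T")
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

_SIMPLEX_TOL = 1e-12


def _pair_index(i: int, j: int, n: int) -> int:
    """Index of unordered pair (i<j) in row-major upper-triangle order."""
    return i * n - i * (i + 1) // 2 + (j - i - 1)


@dataclass(frozen=True)
class SubstitutionModel:
    """A normalized reversible CTMC over ``state_labels``.

    Attributes
    ----------
    state_labels : tuple of str
        Ordered character symbols (length S).
    sym_rates : ndarray, shape (S*(S-1)/2,)
        Relative exchangeabilities in row-major upper-triangle order,
        e.g. for nucleotides (AC, AG, AT, CG, CT, GT).
    frequencies : ndarray, shape (S,)
        Stationary distribution pi.
    generator : ndarray, shape (S, S)
        Rate matrix Q after normalization to one expected substitution
        per unit time.
    """

    state_labels: tuple[str, ...]
    sym_rates: np.ndarray
    frequencies: np.ndarray
    generator: np.ndarray
    name: str = "custom"

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def rate_matrix_entry(self, i: int, j: int) -> float:
        return float(self.generator[i, j])

    def __eq__(self, other) -> bool:  # structural equality for sharing checks
        return (
            isinstance(other, SubstitutionModel)
            and self.state_labels == other.state_labels
            and np.array_equal(self.sym_rates, other.sym_rates)
            and np.array_equal(self.frequencies, other.frequencies)
        )


def build_substitution_model(
    sym_rates,
    frequencies,
    labels=NUCLEOTIDES,
    name: str = "custom",
) -> SubstitutionModel:
    """Assemble and normalize a reversible substitution model.

    Parameters
    ----------
    sym_rates : array-like, length S*(S-1)/2
        Nonnegative exchangeabilities, at least one positive.
    frequencies : array-like, length S
        Strictly positive stationary frequencies summing to one.
    labels : sequence of str
        The character alphabet; defaults to nucleotides.

    Raises
    ------
    ValidationError
        On a non-simplex frequency vector, all-zero rates, or a dimension
        mismatch; the message names the offending field.
    """
    labels = tuple(labels)
    s = len(labels)
    if s < 2:
        raise ValidationError("state_labels must contain at least 2 symbols")
    if len(set(labels)) != s:
        raise ValidationError("state_labels must be unique")
    freqs = np.asarray(frequencies, dtype=float)
    rates = np.asarray(sym_rates, dtype=float)
    if freqs.shape != (s,):
        raise ValidationError(
            f"frequencies has length {freqs.size}, expected {s} for {s} states"
        )
    n_pairs = s * (s - 1) // 2
    if rates.shape != (n_pairs,):
        raise ValidationError(
            f"sym_rates has length {rates.size}, expected {n_pairs} for {s} states"
        )
    if abs(freqs.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValidationError(
            f"frequencies must sum to 1 (got {freqs.sum():.12g})"
        )
    if np.any(freqs <= 0):
        raise ValidationError("frequencies must all be strictly positive")
    if np.any(rates < 0):
        raise ValidationError("sym_rates must be nonnegative")
    if not np.any(rates > 0):
        raise ValidationError("sym_rates must contain at least one positive rate")

    q = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            r = rates[_pair_index(i, j, s)]
            q[i, j] = freqs[j] * r
            q[j, i] = freqs[i] * r
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(np.diag(q) @ freqs)
    if mu <= 0:
        raise ValidationError("model has zero total substitution rate")
    q /= mu
    return SubstitutionModel(labels, rates, freqs, q, name=name)


def jc(labels=NUCLEOTIDES) -> SubstitutionModel:
    """Jukes-Cantor style model: equal rates, uniform frequencies."""
    s = len(labels)
    return build_substitution_model(
        np.ones(s * (s - 1) // 2), np.full(s, 1.0 / s), labels, name="JC"
    )


def hky(kappa: float, frequencies) -> SubstitutionModel:
    """HKY85: transitions (A<->G, C<->T) at rate kappa, transversions at 1."""
    if kappa < 0:
        raise ValidationError("kappa must be nonnegative")
    rates = np.ones(6)
    rates[_pair_index(0, 2, 4)] = kappa  # A<->G
    rates[_pair_index(1, 3, 4)] = kappa  # C<->T
    return build_substitution_model(rates, frequencies, NUCLEOTIDES, name="HKY")


def gtr(sym_rates, frequencies) -> SubstitutionModel:
    """General time-reversible nucleotide model; rates (AC, AG, AT, CG, CT, GT)."""
    return build_substitution_model(sym_rates, frequencies, NUCLEOTIDES, name="GTR")


@dataclass(frozen=True)
class ASRVModel:
    """Discrete-gamma among-site rate variation with mean rate one."""

    shape: float
    n_categories: int
    category_rates: np.ndarray
    category_weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.category_weights is None:
            object.__setattr__(
                self,
                "category_weights",
                np.full(self.n_categories, 1.0 / self.n_categories),
            )

    @property
    def mean_rate(self) -> float:
        return float(self.category_rates @ self.category_weights)


def discrete_gamma(alpha: float, n: int, *, use_median: bool = False) -> ASRVModel:
    """Mean-one discrete-gamma ASRV with ``n`` equal-weight categories.

    Categories are the equal-probability slices of a Gamma(alpha, alpha)
    distribution (mean 1). By default each category is represented by its
    conditional mean, computed in closed form from the regularized
    incomplete gamma function; with ``use_median=True`` the category
    medians are used instead and rescaled to overall mean one.

    Results are memoized: samplers re-request the same discretization for
    every likelihood evaluation between shape updates.
    """
    return _discrete_gamma_cached(float(alpha), int(n), bool(use_median))


@lru_cache(maxsize=4096)
def _discrete_gamma_cached(alpha: float, n: int, use_median: bool) -> ASRVModel:
    if alpha <= 0:
        raise ValidationError("alpha must be strictly positive")
    n = int(n)
    if n < 1:
        raise ValidationError("n_categories must be at least 1")
    if n == 1:
        return ASRVModel(alpha, 1, np.ones(1))
    if use_median:
        quantiles = (np.arange(n) + 0.5) / n
        rates = gamma_dist.ppf(quantiles, a=alpha, scale=1.0 / alpha)
        rates *= n / rates.sum()
    else:
        bounds = gamma_dist.ppf(np.arange(1, n) / n, a=alpha, scale=1.0 / alpha)
        # E[X; X <= b] for X ~ Gamma(alpha, rate alpha) is gammainc(alpha+1, alpha*b)
        cum = np.concatenate([[0.0], gammainc(alpha + 1, alpha * bounds), [1.0]])
        rates = n * np.diff(cum)
    if np.any(np.diff(rates) < 0):  # ties only in the alpha -> inf limit
        raise ValidationError("category rates are not increasing")
    return ASRVModel(alpha, n, rates)
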