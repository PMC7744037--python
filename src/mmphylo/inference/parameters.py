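"""Free-parameter vectors over MMM specifications.

A :class:`ParameterSet` decomposes a model into named blocks — one block
per distinct exchangeability set, per distinct frequency set, plus the
rate multipliers, the switching rates and the ASRV shape — and maps them
to and from an unconstrained real vector: positive blocks through log,
simplex blocks through stick-breaking. Optimizers and samplers work in
the unconstrained space; the log-Jacobian of the transform is available
so MCMC in transformed coordinates targets the intended density.

Identifiability conventions, applied when building the free mask:
- rate multipliers are fixed (all 1) whenever ASRV is superimposed;
- with rate normalization on, the overall scale of the multipliers is
  redundant, so the first multiplier is held fixed in ML fits;
- the overall scale of GTR exchangeabilities is redundant after generator
  normalization, so the last exchangeability is held fixed in ML fits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, logit

from functools import lru_cache

from ..errors import ValidationError
from ..mmm import MMMSpec, build_switching_process
from ..subst import build_substitution_model, discrete_gamma, gtr, hky


@lru_cache(maxsize=8192)
def _component_cached(family: str, labels: tuple, rates_bytes: bytes,
                      freqs_bytes: bytes, n_pairs: int):
    """Memoized component build: block samplers re-request unchanged
    components on every proposal."""
    freqs = np.frombuffer(freqs_bytes)
    if family == "HKY":
        return hky(float(np.frombuffer(rates_bytes)[0]), freqs)
    if family == "GTR":
        return gtr(np.frombuffer(rates_bytes), freqs)
    if family == "JC":
        return build_substitution_model(np.ones(n_pairs), freqs, labels, name="JC")
    return build_substitution_model(np.frombuffer(rates_bytes), freqs, labels,
                                    name=family)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _simplex_to_unconstrained(p: np.ndarray) -> np.ndarray:
    """Stan-style stick-breaking: simplex of length S -> R^(S-1)."""
    s = p.size
    y = np.empty(s - 1)
    remaining = 1.0
    for i in range(s - 1):
        z = p[i] / remaining
        y[i] = logit(z) + np.log(s - 1 - i)
        remaining -= p[i]
    return y


def _unconstrained_to_simplex(y: np.ndarray) -> np.ndarray:
    s = y.size + 1
    p = np.empty(s)
    remaining = 1.0
    for i in range(s - 1):
        z = expit(y[i] - np.log(s - 1 - i))
        p[i] = z * remaining
        remaining -= p[i]
    p[-1] = remaining
    return p


def _simplex_log_jacobian(y: np.ndarray) -> float:
    """log|d p / d y| of the inverse stick-breaking map."""
    s = y.size + 1
    total = 0.0
    remaining = 1.0
    for i in range(s - 1):
        z = expit(y[i] - np.log(s - 1 - i))
        total += np.log(z) + np.log1p(-z) + np.log(remaining)
        remaining -= z * remaining
    return total


@dataclass(frozen=True)
class Block:
    """One named parameter block with its transform and free mask."""

    name: str
    kind: str  # "positive" | "simplex"
    value: np.ndarray
    free: np.ndarray  # boolean mask; simplex blocks are all-free or all-fixed

    @property
    def n_free(self) -> int:
        if self.kind == "simplex":
            return (self.value.size - 1) if self.free.any() else 0
        return int(self.free.sum())

    def to_unconstrained(self) -> np.ndarray:
        if self.n_free == 0:
            return np.empty(0)
        if self.kind == "simplex":
            return _simplex_to_unconstrained(self.value)
        return np.log(self.value[self.free])

    def with_unconstrained(self, y: np.ndarray) -> "Block":
        if self.n_free == 0:
            return self
        if self.kind == "simplex":
            return replace(self, value=_unconstrained_to_simplex(y))
        v = self.value.copy()
        v[self.free] = np.exp(y)
        return replace(self, value=v)

    def log_jacobian(self) -> float:
        if self.n_free == 0:
            return 0.0
        if self.kind == "simplex":
            return _simplex_log_jacobian(self.to_unconstrained())
        return float(np.log(self.value[self.free]).sum())


@dataclass(frozen=True)
class ParameterSet:
    """Named blocks plus the template spec they parameterize."""

    blocks: tuple[Block, ...]
    template: MMMSpec

    def __getitem__(self, name: str) -> np.ndarray:
        for b in self.blocks:
            if b.name == name:
                return b.value
        raise KeyError(name)

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def free_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.n_free > 0]

    def free_vector(self) -> np.ndarray:
        parts = [b.to_unconstrained() for b in self.blocks if b.n_free > 0]
        return np.concatenate(parts) if parts else np.empty(0)

    def with_free_vector(self, x: np.ndarray) -> "ParameterSet":
        x = np.asarray(x, dtype=float)
        new_blocks = []
        pos = 0
        for b in self.blocks:
            n = b.n_free
            if n:
                new_blocks.append(b.with_unconstrained(x[pos:pos + n]))
                pos += n
            else:
                new_blocks.append(b)
        if pos != x.size:
            raise ValidationError(
                f"free vector has {x.size} entries, expected {pos}"
            )
        return ParameterSet(tuple(new_blocks), self.template)

    def with_block_value(self, name: str, value: np.ndarray) -> "ParameterSet":
        new = tuple(
            replace(b, value=np.asarray(value, dtype=float)) if b.name == name else b
            for b in self.blocks
        )
        return ParameterSet(new, self.template)

    def log_jacobian(self) -> float:
        return sum(b.log_jacobian() for b in self.blocks)

    def labels(self) -> list[str]:
        """One label per natural-scale entry, block-major."""
        out = []
        for b in self.blocks:
            if b.value.size == 1:
                out.append(b.name)
            else:
                out += [f"{b.name}[{i}]" for i in range(b.value.size)]
        return out

    def natural_vector(self) -> np.ndarray:
        return np.concatenate([b.value for b in self.blocks])

    # -- spec reconstruction ---------------------------------------------

    def to_spec(self) -> MMMSpec:
        t = self.template
        s = t.n_states
        n_pairs = s * (s - 1) // 2
        rate_sets: dict[int, np.ndarray] = {}
        freq_sets: dict[int, np.ndarray] = {}
        rho = t.multipliers
        switch_rates = t.switching.off_diagonal()
        alpha = None if t.asrv is None else t.asrv.shape
        for b in self.blocks:
            if b.name.startswith("rates"):
                rate_sets[int(b.name[5:])] = b.value
            elif b.name.startswith("freqs"):
                freq_sets[int(b.name[5:])] = b.value
            elif b.name == "multipliers":
                rho = b.value
            elif b.name == "switching":
                switch_rates = b.value
            elif b.name == "alpha":
                alpha = float(b.value[0])
        comps = []
        for ri, fi in zip(t.rate_set_index, t.freq_set_index):
            f = freq_sets[fi]
            f = np.ascontiguousarray(f / f.sum())  # guard round-off for the simplex check
            r = rate_sets.get(ri)
            comps.append(_component_cached(
                t.family, t.state_labels,
                b"" if r is None else np.ascontiguousarray(r).tobytes(),
                f.tobytes(), n_pairs,
            ))
        switching = build_switching_process(
            switch_rates, t.n_models, t.switching.structure,
            stationary=None if _irreducible_rates(switch_rates) else t.switching.stationary,
            allow_reducible=not _irreducible_rates(switch_rates),
        )
        asrv = None
        if t.asrv is not None:
            asrv = discrete_gamma(alpha, t.asrv.n_categories)
        return MMMSpec(tuple(comps), rho, switching, asrv=asrv, name=t.name,
                       normalize_rates=t.normalize_rates,
                       rate_set_index=t.rate_set_index,
                       freq_set_index=t.freq_set_index, family=t.family)


def _irreducible_rates(rates: np.ndarray) -> bool:
    return bool(np.all(np.asarray(rates) > 0))


# ---------------------------------------------------------------------------
# block construction from a spec
# ---------------------------------------------------------------------------

def _rate_set_value(spec: MMMSpec, comp_idx: int) -> np.ndarray | None:
    c = spec.components[comp_idx]
    if spec.family == "HKY":
        return np.array([c.sym_rates[1]])  # kappa = A<->G entry
    if spec.family == "JC":
        return None
    return c.sym_rates.astype(float).copy()


def build_parameter_set(spec: MMMSpec, *, free: list[str] | None = None,
                        ml_identifiability: bool = False) -> ParameterSet:
    """Decompose ``spec`` into named blocks.

    ``free`` optionally restricts which blocks are free (by name); all
    others are fixed at their current values. ``ml_identifiability`` also
    pins the redundant scale coordinates (first multiplier, last GTR
    exchangeability) that a likelihood-only fit cannot identify.
    """
    blocks: list[Block] = []
    seen_rate, seen_freq = set(), set()
    for comp, (ri, fi) in enumerate(zip(spec.rate_set_index, spec.freq_set_index)):
        if ri not in seen_rate:
            seen_rate.add(ri)
            val = _rate_set_value(spec, comp)
            if val is not None:
                mask = np.ones(val.size, dtype=bool)
                if ml_identifiability and spec.family == "GTR":
                    mask[-1] = False
                blocks.append(Block(f"rates{ri}", "positive", val, mask))
        if fi not in seen_freq:
            seen_freq.add(fi)
            val = spec.components[comp].frequencies.astype(float).copy()
            blocks.append(Block(f"freqs{fi}", "simplex", val,
                                np.ones(val.size, dtype=bool)))
    rho = spec.multipliers.astype(float).copy()
    if spec.n_models > 1:
        if spec.asrv is not None:
            rho_mask = np.zeros(rho.size, dtype=bool)  # identifiability rule
        else:
            rho_mask = np.ones(rho.size, dtype=bool)
            if ml_identifiability and spec.normalize_rates:
                rho_mask[0] = False
            rho_mask &= rho > 0  # a structurally silent component stays silent
        blocks.append(Block("multipliers", "positive", rho, rho_mask))
    if spec.n_models > 1:
        sw = spec.switching.off_diagonal()
        blocks.append(Block("switching", "positive", sw,
                            np.ones(sw.size, dtype=bool)))
    if spec.asrv is not None:
        blocks.append(Block("alpha", "positive",
                            np.array([float(spec.asrv.shape)]),
                            np.ones(1, dtype=bool)))
    if free is not None:
        unknown = set(free) - {b.name for b in blocks}
        if unknown:
            raise ValidationError(f"unknown free blocks: {sorted(unknown)}")
        blocks = [
            b if b.name in free else replace(b, free=np.zeros(b.value.size, dtype=bool))
            for b in blocks
        ]
    return ParameterSet(tuple(blocks), spec)
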