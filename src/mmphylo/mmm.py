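"""Markov-modulated model (MMM) construction.

An MMM couples K component substitution models through a K-state
model-switching CTMC Phi. The compound process lives on the KS states
(k, s) = (model, character) and has generator

    Lambda = sum_k E_kk (x) (rho_k Q_k)  +  Phi (x) I_S,

where (x) is the Kronecker product, E_kk the k-th diagonal indicator, and
rho_k a per-component rate multiplier. From state (k, s) the process either
substitutes within model k at rate rho_k Q^(k)_{s s'}, or switches model
(k -> k', keeping s) at rate phi_{kk'}. The stationary distribution is
Pi_Lambda = (psi_1 pi_11, ..., psi_K pi_KS) with Psi the stationary
distribution of Phi.

Model shorthand follows the MMM(M)_{ijkl} notation: M the component family
(JC/HKY/GTR), i the number of distinct exchangeability sets, j the number
of distinct frequency sets, k (optional) the number of rate multipliers
(omitted means all rho fixed at 1 with ASRV superimposed), and l either T
(symmetric/triangular Phi) or A (asymmetric Phi).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from ._linalg import is_irreducible, stationary_distribution
from .errors import ModelParseError, ValidationError
from .subst import ASRVModel, SubstitutionModel, build_substitution_model, discrete_gamma

__all__ = [
    "SwitchingProcess",
    "MMMSpec",
    "MMMTemplate",
    "CompoundModel",
    "build_switching_process",
    "compose_compound_generator",
    "compound_stationary",
    "parse_model_notation",
    "covarion_preset",
    "load_spec",
    "save_spec",
    "spec_from_dict",
    "spec_to_dict",
]


# ---------------------------------------------------------------------------
# switching process
# ---------------------------------------------------------------------------

def _offdiag_pairs(k: int, structure: str):
    """Ordered (i, j) pairs matching the flat off-diagonal rate layout."""
    if structure == "symmetric":
        return [(i, j) for i in range(k) for j in range(i + 1, k)]
    return [(i, j) for i in range(k) for j in range(k) if i != j]


@dataclass(frozen=True)
class SwitchingProcess:
    """The K-state model-switching CTMC Phi with stationary weights Psi."""

    n_models: int
    rates: np.ndarray  # K x K generator, rows sum to 0
    structure: str  # "symmetric" | "asymmetric"
    stationary: np.ndarray  # Psi

    def off_diagonal(self) -> np.ndarray:
        """Flat off-diagonal rates in the canonical pair order."""
        return np.array([self.rates[i, j] for i, j in _offdiag_pairs(self.n_models, self.structure)])

    @property
    def expected_switch_rate(self) -> float:
        """Stationary rate of model switches, sum_k psi_k * (-Phi_kk)."""
        return float(-self.stationary @ np.diag(self.rates))


def build_switching_process(
    off_diagonal_rates,
    n_models: int,
    structure: str = "symmetric",
    *,
    stationary=None,
    allow_reducible: bool = False,
) -> SwitchingProcess:
    """Assemble Phi from its flat off-diagonal rates.

    ``structure="symmetric"`` expects K(K-1)/2 rates filling both phi_ij and
    phi_ji; ``"asymmetric"`` expects K(K-1) rates in row-major order. The
    diagonal is fixed so rows sum to zero and Psi is solved as the
    normalized left null vector.

    A reducible chain (some psi_k undefined or zero) raises unless
    ``allow_reducible`` is set, in which case explicit ``stationary``
    weights must be supplied (used e.g. for the zero-switching limit,
    where Psi plays the role of fixed mixture weights).
    """
    k = int(n_models)
    if k < 1:
        raise ValidationError("n_models must be >= 1")
    if structure not in ("symmetric", "asymmetric"):
        raise ValidationError("structure must be 'symmetric' or 'asymmetric'")
    rates = np.asarray(off_diagonal_rates, dtype=float).ravel()
    pairs = _offdiag_pairs(k, structure)
    if rates.size != len(pairs):
        raise ValidationError(
            f"expected {len(pairs)} off-diagonal rates for K={k} {structure}, got {rates.size}"
        )
    if np.any(rates < 0):
        raise ValidationError("switching rates must be nonnegative")
    phi = np.zeros((k, k))
    for r, (i, j) in zip(rates, pairs):
        phi[i, j] = r
        if structure == "symmetric":
            phi[j, i] = r
    np.fill_diagonal(phi, -phi.sum(axis=1))

    if k == 1:
        psi = np.ones(1)
    elif k == 2 and rates.min() > 0:
        # closed form: psi proportional to (phi_21, phi_12)
        p21, p12 = phi[1, 0], phi[0, 1]
        psi = np.array([p21, p12]) / (p12 + p21)
    elif np.all(rates > 0) or is_irreducible(phi):  # all-positive: trivially irreducible
        psi = stationary_distribution(phi)
    else:
        if not allow_reducible:
            raise ValidationError("switching process not irreducible")
        if stationary is None:
            raise ValidationError(
                "reducible switching process requires explicit stationary weights"
            )
        psi = np.asarray(stationary, dtype=float)
        if psi.shape != (k,) or abs(psi.sum() - 1.0) > 1e-10 or np.any(psi < 0):
            raise ValidationError("stationary weights must be a length-K simplex vector")
    if stationary is not None and (np.all(rates > 0) or is_irreducible(phi)):
        given = np.asarray(stationary, dtype=float)
        if np.abs(given - psi).max() > 1e-8:
            raise ValidationError("supplied stationary weights conflict with Phi")
    return SwitchingProcess(k, phi, structure, psi)


# ---------------------------------------------------------------------------
# full model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MMMSpec:
    """A fully parameterized Markov-modulated model.

    ``rate_set_index``/``freq_set_index`` record which components share an
    exchangeability or frequency set (indices into the distinct sets, per
    component), which determines the canonical notation string and the free
    parameterization used by inference.
    """

    components: tuple[SubstitutionModel, ...]
    multipliers: np.ndarray
    switching: SwitchingProcess
    asrv: ASRVModel | None = None
    name: str | None = None
    normalize_rates: bool = True
    rate_set_index: tuple[int, ...] | None = None
    freq_set_index: tuple[int, ...] | None = None
    family: str = "custom"

    def __post_init__(self):
        k = len(self.components)
        if k != self.switching.n_models:
            raise ValidationError(
                f"{k} components but switching process has {self.switching.n_models} models"
            )
        rho = np.asarray(self.multipliers, dtype=float)
        object.__setattr__(self, "multipliers", rho)
        if rho.shape != (k,):
            raise ValidationError("multipliers must have one entry per component")
        if np.any(rho < 0):
            raise ValidationError("multipliers must be nonnegative")
        labels = self.components[0].state_labels
        if any(c.state_labels != labels for c in self.components):
            raise ValidationError("all components must share one character alphabet")
        if self.asrv is not None and not np.allclose(rho, 1.0):
            raise ValidationError(
                "relative rate multipliers must all be fixed to 1 when ASRV is "
                "superimposed (identifiability)"
            )
        if self.rate_set_index is None:
            object.__setattr__(self, "rate_set_index", _infer_sharing(self.components, "sym_rates"))
        if self.freq_set_index is None:
            object.__setattr__(self, "freq_set_index", _infer_sharing(self.components, "frequencies"))

    @property
    def n_models(self) -> int:
        return len(self.components)

    @property
    def n_states(self) -> int:
        return self.components[0].n_states

    @property
    def state_labels(self) -> tuple[str, ...]:
        return self.components[0].state_labels

    def canonical_name(self) -> str:
        """The MMM(M)_{ijkl} string implied by the sharing structure."""
        i = len(set(self.rate_set_index))
        j = len(set(self.freq_set_index))
        letter = "T" if self.switching.structure == "symmetric" else "A"
        fam = self.family if self.family != "custom" else "?"
        if self.asrv is not None:
            return f"MMM({fam})_{i}{j}{letter}"
        k = self.n_models
        return f"MMM({fam})_{i}{j}{k}{letter}"

    def with_asrv(self, alpha: float, n_categories: int = 4) -> "MMMSpec":
        return replace(self, asrv=discrete_gamma(alpha, n_categories))


def _infer_sharing(components, attr) -> tuple[int, ...]:
    seen: list[np.ndarray] = []
    idx = []
    for c in components:
        arr = getattr(c, attr)
        for i, s in enumerate(seen):
            if np.array_equal(arr, s):
                idx.append(i)
                break
        else:
            idx.append(len(seen))
            seen.append(arr)
    return tuple(idx)


# ---------------------------------------------------------------------------
# compound generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundModel:
    """The realized KS x KS generator Lambda with stationary Pi_Lambda.

    Compound indexing is model-major: index(k, s) = k * S + s, so the
    within-model blocks are contiguous.

    ``stationary`` is the exact stationary distribution of Lambda (its
    normalized left null vector). When every component shares one
    frequency vector this equals the product form
    (psi_1 pi_1, ..., psi_K pi_K); when component frequencies differ the
    product form is *not* stationary — switching events carry characters
    between blocks whose equilibria disagree, so the marginal character
    distribution within block k is pulled away from pi_k. The product
    form remains available as :func:`product_form_stationary`. For a
    reducible switching process (e.g. the zero-switching limit) the
    stationary distribution is not unique and the product form with the
    supplied mixture weights is used.
    """

    generator: np.ndarray
    stationary: np.ndarray
    n_models: int
    n_states: int
    state_labels: tuple[str, ...]
    effective_multipliers: np.ndarray

    def compound_index(self, model: int, state: int) -> int:
        return model * self.n_states + state

    def model_of(self, index: int) -> int:
        return index // self.n_states

    def state_of(self, index: int) -> int:
        return index % self.n_states

    @property
    def n_compound(self) -> int:
        return self.n_models * self.n_states

    def compound_labels(self) -> list[tuple[int, str]]:
        return [
            (k, self.state_labels[s])
            for k in range(self.n_models)
            for s in range(self.n_states)
        ]


def compose_compound_generator(spec: MMMSpec) -> CompoundModel:
    """Build Lambda from a model specification.

    With ``spec.normalize_rates`` (default) the multipliers are rescaled so
    that sum_k psi_k rho_k = 1, making branch lengths measure expected
    substitutions per site at stationarity (model switches do not change
    characters and are not counted).
    """
    k, s = spec.n_models, spec.n_states
    psi = spec.switching.stationary
    rho = spec.multipliers.astype(float).copy()
    if spec.normalize_rates:
        mean_rate = float(psi @ rho)
        if mean_rate <= 0:
            raise ValidationError(
                "cannot normalize: stationary mean substitution rate is zero"
            )
        rho /= mean_rate
    lam = np.zeros((k * s, k * s))
    for m, comp in enumerate(spec.components):
        lam[m * s:(m + 1) * s, m * s:(m + 1) * s] = rho[m] * comp.generator
    lam += np.kron(spec.switching.rates, np.eye(s))
    product = np.concatenate([psi[m] * spec.components[m].frequencies for m in range(k)])
    shared_freqs = all(
        np.array_equal(c.frequencies, spec.components[0].frequencies)
        for c in spec.components[1:]
    )
    if k == 1 or shared_freqs:
        stat = product  # product form is exact under shared equilibria
    elif np.all(spec.switching.off_diagonal() > 0) or is_irreducible(spec.switching.rates):
        stat = stationary_distribution(lam, tol=1e-8)
    else:
        # reducible switching: no unique stationary law; psi acts as
        # fixed mixture weights over the blocks
        stat = product
    return CompoundModel(lam, stat, k, s, spec.state_labels, rho)


def compound_stationary(model: CompoundModel) -> np.ndarray:
    """Exact stationary distribution of Lambda, model-major order."""
    return model.stationary


def product_form_stationary(spec: MMMSpec) -> np.ndarray:
    """The product-form vector (psi_1 pi_11, ..., psi_K pi_KS).

    Coincides with the stationary distribution of the compound generator
    exactly when all components share one frequency vector; otherwise it
    is only an approximation to it.
    """
    psi = spec.switching.stationary
    return np.concatenate([
        psi[m] * spec.components[m].frequencies for m in range(spec.n_models)
    ])


# ---------------------------------------------------------------------------
# notation parsing
# ---------------------------------------------------------------------------

_NOTATION_RE = re.compile(r"^MMM\((?P<fam>[A-Za-z0-9]+)\)_?(?P<sub>[0-9]+[TAta])$")
_FAMILIES = {"JC": 0, "HKY": 1, "GTR": 6}  # family -> free exchangeabilities


@dataclass(frozen=True)
class MMMTemplate:
    """Parsed MMM(M)_{ijkl} notation: structure with unset numeric parameters."""

    family: str
    n_models: int
    n_rate_sets: int
    n_freq_sets: int
    n_multipliers: int | None  # None: rho fixed at 1, ASRV superimposed
    structure: str  # "symmetric" | "asymmetric"
    name: str

    @property
    def asrv_required(self) -> bool:
        return self.n_multipliers is None

    def rate_set_index(self) -> tuple[int, ...]:
        return _spread_sets(self.n_rate_sets, self.n_models)

    def freq_set_index(self) -> tuple[int, ...]:
        return _spread_sets(self.n_freq_sets, self.n_models)

    def n_switch_rates(self) -> int:
        k = self.n_models
        return k * (k - 1) // 2 if self.structure == "symmetric" else k * (k - 1)

    def instantiate(
        self,
        *,
        rate_sets=None,
        freq_sets,
        switch_rates,
        multipliers=None,
        alpha: float | None = None,
        n_categories: int = 4,
        labels=None,
        normalize_rates: bool = True,
    ) -> MMMSpec:
        """Fill in numeric parameters to obtain a full :class:`MMMSpec`.

        ``rate_sets`` holds one exchangeability vector per distinct rate set
        (for HKY a single kappa each; for JC it is ignored); ``freq_sets``
        one frequency simplex per distinct frequency set.
        """
        from .subst import NUCLEOTIDES, hky, jc, gtr

        labels = tuple(labels) if labels is not None else NUCLEOTIDES
        freq_sets = [np.asarray(f, dtype=float) for f in freq_sets]
        if len(freq_sets) != self.n_freq_sets:
            raise ValidationError(
                f"model {self.name} needs {self.n_freq_sets} frequency sets, got {len(freq_sets)}"
            )
        if self.family == "JC":
            rate_sets = [None] * self.n_rate_sets
        else:
            if rate_sets is None or len(rate_sets) != self.n_rate_sets:
                raise ValidationError(
                    f"model {self.name} needs {self.n_rate_sets} exchangeability sets"
                )
        comps = []
        for ri, fi in zip(self.rate_set_index(), self.freq_set_index()):
            f = freq_sets[fi]
            if self.family == "HKY":
                kappa = float(np.asarray(rate_sets[ri]).ravel()[0])
                comps.append(hky(kappa, f))
            elif self.family == "GTR":
                comps.append(gtr(np.asarray(rate_sets[ri], dtype=float), f))
            elif self.family == "JC":
                comps.append(jc(labels) if np.allclose(f, 1 / len(labels)) else
                             build_substitution_model(np.ones(len(labels) * (len(labels) - 1) // 2), f, labels, name="JC"))
            else:
                comps.append(build_substitution_model(np.asarray(rate_sets[ri], dtype=float), f, labels))
        switching = build_switching_process(switch_rates, self.n_models, self.structure)
        if self.asrv_required:
            if alpha is None:
                raise ValidationError(
                    f"model {self.name} superimposes ASRV: alpha is required"
                )
            rho = np.ones(self.n_models)
            asrv = discrete_gamma(alpha, n_categories)
        else:
            if multipliers is None:
                raise ValidationError(f"model {self.name} needs {self.n_multipliers} multipliers")
            rho = np.asarray(multipliers, dtype=float)
            if rho.size != self.n_models:
                raise ValidationError("multipliers length must equal the number of components")
            asrv = None if alpha is None else discrete_gamma(alpha, n_categories)
            if asrv is not None and not np.allclose(rho, 1.0):
                raise ValidationError(
                    "relative rate multipliers must all be fixed to 1 when ASRV is "
                    "superimposed (identifiability)"
                )
        return MMMSpec(
            tuple(comps), rho, switching, asrv=asrv, name=self.name,
            normalize_rates=normalize_rates,
            rate_set_index=self.rate_set_index(),
            freq_set_index=self.freq_set_index(),
            family=self.family,
        )


def _spread_sets(n_sets: int, k: int) -> tuple[int, ...]:
    """Map K components onto n distinct parameter sets.

    n_sets == 1 shares a single set; n_sets == K gives each component its
    own; intermediate counts give components 1..n-1 their own set and pool
    the remainder into the last (the only unambiguous general rule).
    """
    if n_sets == 1:
        return (0,) * k
    return tuple(min(i, n_sets - 1) for i in range(k))


def parse_model_notation(name: str) -> MMMTemplate:
    """Parse an MMM(M)_{ijkl} string into a structural template.

    Grammar: ``MMM(M)`` with M in {JC, HKY, GTR}, an optional underscore,
    two or three digits (i = #exchangeability sets, j = #frequency sets,
    optional k = #multipliers; omitted k means all rho = 1 with ASRV
    superimposed), then T (symmetric) or A (asymmetric). Subscripts are
    single digits, so K > 9 requires an explicit config instead.
    """
    text = name.strip()
    m = _NOTATION_RE.match(text)
    if not m:
        # locate the first offending character for the error message
        prefix = "MMM("
        pos = 0
        for pos, (a, b) in enumerate(zip(text, prefix)):
            if a != b:
                break
        else:
            pos = min(len(text), len(prefix))
        raise ModelParseError(f"malformed model notation {name!r}", position=pos)
    fam = m.group("fam").upper()
    if fam not in _FAMILIES:
        raise ModelParseError(
            f"unknown component family {m.group('fam')!r} (expected JC, HKY or GTR)",
            position=4,
        )
    sub = m.group("sub")
    digits, letter = sub[:-1], sub[-1].upper()
    if len(digits) not in (2, 3):
        raise ModelParseError(
            f"expected 2 or 3 subscript digits in {name!r}, found {len(digits)}",
            position=text.index(sub),
        )
    counts = [int(d) for d in digits]
    k = max(counts)
    if k < 1:
        raise ModelParseError("subscript digits must be >= 1", position=text.index(sub))
    for pos_d, c in enumerate(counts):
        if c not in (1, k):
            raise ModelParseError(
                f"subscript {digits} inconsistent with a single K={k}: "
                f"each count must be 1 or K",
                position=text.index(sub) + pos_d,
            )
    i, j = counts[0], counts[1]
    n_mult = counts[2] if len(counts) == 3 else None
    structure = "symmetric" if letter == "T" else "asymmetric"
    return MMMTemplate(fam, k, i, j, n_mult, structure, f"MMM({fam})_{digits}{letter}")


# ---------------------------------------------------------------------------
# covarion preset
# ---------------------------------------------------------------------------

def covarion_preset(
    base: SubstitutionModel, s_on_off: float, s_off_on: float
) -> MMMSpec:
    """Two-state covarion model: the base process plus a silent 'off' copy.

    Component 1 is ``base`` with multiplier 1; component 2 shares its
    parameters but has multiplier 0, so in the off state only switching
    events occur. Rate normalization is disabled so the generator keeps the
    classic covarion block form

        [[Q - s_on_off I,  s_on_off I ],
         [ s_off_on I,    -s_off_on I ]].
    """
    if s_on_off <= 0 or s_off_on <= 0:
        raise ValidationError("covarion switching rates must be strictly positive")
    switching = build_switching_process(
        [s_on_off, s_off_on], 2, "asymmetric"
    )
    return MMMSpec(
        (base, base),
        np.array([1.0, 0.0]),
        switching,
        name=f"covarion({base.name})",
        normalize_rates=False,
        rate_set_index=(0, 0),
        freq_set_index=(0, 0),
        family=base.name,
    )


# ---------------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------------

def spec_to_dict(spec: MMMSpec) -> dict:
    d = {
        "name": spec.name or spec.canonical_name(),
        "family": spec.family,
        "state_labels": list(spec.state_labels),
        "components": [
            {
                "sym_rates": [float(x) for x in c.sym_rates],
                "frequencies": [float(x) for x in c.frequencies],
            }
            for c in spec.components
        ],
        "multipliers": [float(x) for x in spec.multipliers],
        "switching": {
            "structure": spec.switching.structure,
            "rates": [float(x) for x in spec.switching.off_diagonal()],
        },
        "normalize_rates": spec.normalize_rates,
    }
    if spec.asrv is not None:
        d["asrv"] = {"alpha": float(spec.asrv.shape), "n_categories": int(spec.asrv.n_categories)}
    return d


def spec_from_dict(d: dict) -> MMMSpec:
    labels = tuple(d.get("state_labels", ("A", "C", "G", "T")))
    comps = tuple(
        build_substitution_model(c["sym_rates"], c["frequencies"], labels,
                                 name=d.get("family", "custom"))
        for c in d["components"]
    )
    sw = d["switching"]
    reducible_ok = "stationary" in sw
    switching = build_switching_process(
        sw["rates"], len(comps), sw.get("structure", "symmetric"),
        stationary=sw.get("stationary"), allow_reducible=reducible_ok,
    )
    asrv = None
    if d.get("asrv"):
        asrv = discrete_gamma(d["asrv"]["alpha"], d["asrv"].get("n_categories", 4))
    return MMMSpec(
        comps,
        np.asarray(d.get("multipliers", np.ones(len(comps))), dtype=float),
        switching,
        asrv=asrv,
        name=d.get("name"),
        normalize_rates=bool(d.get("normalize_rates", True)),
        family=d.get("family", "custom"),
    )


def save_spec(spec: MMMSpec, path) -> None:
    path = str(path)
    d = spec_to_dict(spec)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_spec(path) -> MMMSpec:
    path = str(path)
    with open(path) as fh:
        d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return spec_from_dict(d)
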