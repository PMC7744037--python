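"""Canonical synthetic study conditions and random-model generators.

The benchmark parameterizations emulate the empirical regimes the model
family was designed for: two nucleotide processes with strongly divergent
GC content (a GC-rich and an AT-rich component), distinct
transition/transversion ratios, asymmetric switching at rates comparable
to a fraction of a substitution per site, and gamma rate variation across
sites. They are the fixed reference conditions for the simulation-based
checks (parameter recovery, generative-model selection); the random-spec
generator drives the property-based tests.
"""

from __future__ import annotations

import numpy as np

from .mmm import MMMSpec, parse_model_notation
from .phylo import Tree, random_tree
from .subst import gtr, hky, jc

#: GC-rich component frequencies (A, C, G, T)
GC_RICH = np.array([0.10, 0.40, 0.40, 0.10])
#: AT-rich component frequencies
AT_RICH = np.array([0.40, 0.10, 0.10, 0.40])
#: asymmetric switching rates (phi_12, phi_21), substitutions time scale
SWITCH_RATES = (0.4, 0.2)
#: gamma shape for among-site rate variation
GAMMA_SHAPE = 0.5
#: distinct transition/transversion ratios of the two HKY components
KAPPAS = (4.0, 8.0)
#: distinct GTR exchangeability sets (AC, AG, AT, CG, CT, GT)
GTR_RATES_1 = np.array([1.0, 4.0, 0.7, 0.9, 5.0, 1.0])
GTR_RATES_2 = np.array([2.0, 8.0, 0.4, 1.5, 3.0, 1.0])
#: frequencies of the single-process GTR generator
GTR_FREQS = np.array([0.30, 0.20, 0.25, 0.25])


def hky22a_spec(*, asrv: bool = True) -> MMMSpec:
    """MMM(HKY)_22A under the benchmark conditions."""
    template = parse_model_notation("MMM(HKY)_22A")
    return template.instantiate(
        rate_sets=[[KAPPAS[0]], [KAPPAS[1]]],
        freq_sets=[GC_RICH, AT_RICH],
        switch_rates=list(SWITCH_RATES),
        alpha=GAMMA_SHAPE if asrv else None,
        multipliers=None if asrv else np.ones(2),
    )


def gtr22a_spec(*, asrv: bool = True) -> MMMSpec:
    """MMM(GTR)_22A under the benchmark conditions."""
    template = parse_model_notation("MMM(GTR)_22A")
    return template.instantiate(
        rate_sets=[GTR_RATES_1, GTR_RATES_2],
        freq_sets=[GC_RICH, AT_RICH],
        switch_rates=list(SWITCH_RATES),
        alpha=GAMMA_SHAPE if asrv else None,
        multipliers=None if asrv else np.ones(2),
    )


def gtr_spec(*, asrv: bool = True) -> MMMSpec:
    """Single-component GTR (+ optional gamma ASRV) generator."""
    from .mmm import build_switching_process

    comp = gtr(GTR_RATES_1, GTR_FREQS)
    switching = build_switching_process([], 1, "symmetric")
    spec = MMMSpec((comp,), np.ones(1), switching, name="GTR", family="GTR")
    return spec.with_asrv(GAMMA_SHAPE) if asrv else spec


def benchmark_tree(n_taxa: int, seed: int, *, mean_branch_length: float = 0.15) -> Tree:
    """Random rooted tree used by the simulation-study panels."""
    return random_tree(n_taxa, np.random.default_rng(seed),
                       mean_branch_length=mean_branch_length)


def random_spec(rng: np.random.Generator, *, max_models: int = 3,
                families=("JC", "HKY", "GTR"), allow_asrv: bool = False) -> MMMSpec:
    """A random valid model specification (used by property-based tests)."""
    from .mmm import MMMSpec, build_switching_process

    k = int(rng.integers(1, max_models + 1))
    family = str(rng.choice(list(families)))
    comps = []
    for _ in range(k):
        freqs = rng.dirichlet(np.full(4, 5.0))
        if family == "JC":
            comps.append(jc())
        elif family == "HKY":
            comps.append(hky(float(rng.lognormal(1.0, 0.4)), freqs))
        else:
            comps.append(gtr(rng.gamma(2.0, 1.0, size=6), freqs))
    structure = "symmetric" if rng.random() < 0.5 else "asymmetric"
    n_rates = k * (k - 1) // 2 if structure == "symmetric" else k * (k - 1)
    switching = build_switching_process(
        rng.gamma(2.0, 0.3, size=n_rates) + 0.01, k, structure
    )
    use_asrv = allow_asrv and rng.random() < 0.5
    rho = np.ones(k) if use_asrv else rng.gamma(3.0, 0.4, size=k) + 0.05
    spec = MMMSpec(tuple(comps), rho, switching, family=family)
    if use_asrv:
        spec = spec.with_asrv(float(rng.uniform(0.3, 2.0)))
    return spec
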