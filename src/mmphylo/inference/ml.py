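"""Maximum-likelihood fitting on a fixed tree.

Quasi-Newton (L-BFGS-B) optimization of the pruning log-likelihood in the
unconstrained parameter space; deterministic given the start point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ..errors import ValidationError
from ..likelihood import LikelihoodEvaluator
from ..mmm import MMMSpec
from ..phylo import Alignment, Tree
from .parameters import ParameterSet, build_parameter_set


@dataclass
class MLFit:
    """Result of :func:`fit_ml`."""

    estimates: ParameterSet
    log_likelihood: float
    converged: bool
    n_evaluations: int
    message: str = ""

    @property
    def spec(self) -> MMMSpec:
        return self.estimates.to_spec()


def fit_ml(
    alignment: Alignment,
    tree: Tree,
    spec: MMMSpec,
    *,
    free: list[str] | None = None,
    start: ParameterSet | None = None,
    settings: dict | None = None,
) -> MLFit:
    """Maximize the tree likelihood over the free blocks of ``spec``.

    ``spec`` supplies both the model structure and the starting values
    (unless ``start`` overrides them). ``free`` names the blocks to
    optimize; by default every block is free subject to the
    identifiability rules (multipliers pinned under ASRV, redundant scale
    coordinates pinned).
    """
    settings = dict(settings or {})
    evaluator = settings.pop("evaluator", None) or LikelihoodEvaluator(alignment, tree)
    ps = start if start is not None else build_parameter_set(
        spec, free=free, ml_identifiability=True
    )
    x0 = ps.free_vector()
    if x0.size == 0:
        res = evaluator.log_likelihood(spec, per_site=False)
        return MLFit(ps, res.log_likelihood, True, 1, "no free parameters")

    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            ll = evaluator.log_likelihood(
                ps.with_free_vector(x).to_spec(), per_site=False
            ).log_likelihood
        except (ValidationError, FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    f0 = objective(x0)
    if not np.isfinite(f0) or f0 >= 1e12:
        raise ValidationError(
            "log-likelihood is not finite at the starting point; rescale the "
            "starting parameters (e.g. smaller switching rates or multipliers)"
        )
    opt = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={
            "maxiter": settings.get("maxiter", 500),
            "ftol": settings.get("ftol", 1e-10),
            "gtol": settings.get("gtol", 1e-6),
        },
    )
    best = ps.with_free_vector(opt.x)
    logl = -float(opt.fun)
    if logl < -f0 - 1e-6:  # optimizer must not end below its start
        best, logl = ps, -f0
    return MLFit(best, logl, bool(opt.success), n_eval, str(opt.message))
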