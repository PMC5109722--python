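"""Recalibration fit: match the homogeneous-mixing prevalence curve to a target.

Given a mean prevalence curve from the network simulation with input
parameters ``(r0_c, mu_c)``, find the homogeneous-mixing pair ``(r0_h, mu_h)``
whose mean curve minimizes the cumulative squared difference, via
Levenberg-Marquardt on the pointwise residual vector.  The objective is
stochastic (each evaluation regenerates the homogeneous ensemble), so common
random numbers are used: one fixed block of realization seeds is drawn per fit
call and reused at every evaluation, making the objective a deterministic,
piecewise-smooth function of the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import homosir
from .netsir import PrevalenceCurve, _as_rng

__all__ = ["FitResult", "objective", "truncate_after_peak", "fit"]

# fit domain (per-day rates); enforced by clipping inside the evaluation
R0_BOUNDS = (0.5, 10.0)
MU_BOUNDS = (0.01, 10.0)


@dataclass(frozen=True)
class FitResult:
    """Fitted homogeneous-mixing parameters and optimizer diagnostics."""

    r0_h: float
    mu_h: float
    objective: float
    n_iterations: int
    converged: bool


def objective(curve_h: PrevalenceCurve, curve_c: PrevalenceCurve) -> float:
    """Cumulative squared difference between two curves on the target grid."""
    vals_h = curve_h.resample(curve_c.t)
    return float(np.sum((vals_h - curve_c.prevalence) ** 2))


def truncate_after_peak(curve: PrevalenceCurve, n_nodes: int) -> PrevalenceCurve:
    """Drop the pure-noise tail: keep up to the first post-peak dip below 0.5/N."""
    v = curve.prevalence
    peak = int(np.argmax(v))
    below = np.nonzero(v[peak:] < 0.5 / n_nodes)[0]
    end = peak + int(below[0]) + 1 if len(below) else len(v)
    return PrevalenceCurve(
        t=curve.t[:end],
        prevalence=v[:end],
        n_realizations=curve.n_realizations,
        final_sizes=curve.final_sizes,
    )


def fit(
    target: PrevalenceCurve,
    n_nodes: int,
    init: tuple[float, float],
    n_real_per_eval: int = 10_000,
    rng=None,
    xtol: float = 1e-3,
    max_nfev: int = 200,
) -> FitResult:
    """Fit ``(r0_h, mu_h)`` of the homogeneous model to a target curve.

    Parameters are optimized in log space (positivity) and clipped to the fit
    domain ``r0 in [0.5, 10]``, ``mu in [0.01, 10] / day``; the Jacobian is a
    forward finite difference with relative step 0.05.  ``init`` is typically
    the ``(r0_c, mu_c)`` of the target simulation.

    Raises ``ValueError`` for a degenerate target (no mass beyond the seed).
    """
    rng = _as_rng(rng)
    if len(target.t) < 3 or np.all(target.prevalence[1:] == 0):
        raise ValueError("degenerate target curve: no mass beyond the seed")
    target = truncate_after_peak(target, n_nodes)
    if len(target.t) < 3:
        raise ValueError("target curve too short to fit")
    grid = target.t
    crn_seed = int(rng.integers(0, 2**31 - 1))

    def residuals(x: np.ndarray) -> np.ndarray:
        r0 = float(np.clip(np.exp(x[0]), *R0_BOUNDS))
        mu = float(np.clip(np.exp(x[1]), *MU_BOUNDS))
        curve_h = homosir.average_prevalence_h(
            n_nodes, r0, mu, n_real_per_eval,
            np.random.default_rng(crn_seed), grid=grid,
        )
        return curve_h.prevalence - target.prevalence

    # Multi-start: the CRN objective is piecewise-smooth but can stall LM on a
    # plateau; a second start with faster turnover is enough in practice.
    starts = [
        (init[0], init[1]),
        (1.2 * init[0], 1.6 * init[1]),
    ]
    best = None
    total_nfev = 0
    for r0_0, mu_0 in starts:
        x0 = np.log([
            np.clip(r0_0, *R0_BOUNDS),
            np.clip(mu_0, *MU_BOUNDS),
        ])
        res = least_squares(
            residuals, x0, method="lm", diff_step=0.05, xtol=xtol, max_nfev=max_nfev
        )
        total_nfev += int(res.nfev)
        if best is None or res.cost < best.cost:
            best = res
    return FitResult(
        r0_h=float(np.clip(np.exp(best.x[0]), *R0_BOUNDS)),
        mu_h=float(np.clip(np.exp(best.x[1]), *MU_BOUNDS)),
        objective=float(np.sum(best.fun**2)),
        n_iterations=total_nfev,
        converged=bool(best.status > 0),
    )
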