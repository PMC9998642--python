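"""Sigmoidal D50 model of ALSFRS-R decline.

Each patient's ALSFRS-R trajectory is abstracted by a two-parameter
logistic decay

    ALSFRS-R(t) = 48 / (1 + exp((t - D50) / dx)),

where ``D50`` (months) is the turning point — the time from symptom
onset at which half of full motor function (ALSFRS-R = 24) is lost —
and ``dx`` (months) sets the steepness of decline. D50 measures disease
*aggressiveness*; the normalized coordinate

    rD50 = t / (2 * D50)

measures disease *accumulation* (0 at onset, 0.5 at the point of 50%
functional loss), comparable across patients of very different
aggressiveness. Patients stratify into aggressiveness subgroups by D50
(high < 20, intermediate 20-40, low >= 40 months) and into rD50 phases
(I < 0.25, II 0.25-0.5, III/IV >= 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .cohort_io import AlsfrsObservation

__all__ = [
    "FULL_SCALE",
    "D50Fit",
    "sigmoid_value",
    "fit_d50",
    "compute_rd50",
    "classify_phase",
    "classify_aggressiveness",
    "fit_cohort",
]

FULL_SCALE = 48.0

D50_BOUNDS = (0.1, 600.0)
DX_BOUNDS = (0.1, 120.0)
#: multiplicative jitters on the D50 start value for multi-start refits
_MULTISTART_FACTORS = (1.0, 0.5, 1.5, 0.75, 1.25)


@dataclass(frozen=True)
class D50Fit:
    """Fitted sigmoid parameters and diagnostics for one patient."""

    d50: float
    dx: float
    rss: float
    n_obs: int
    converged: bool
    identifiable: bool


def sigmoid_value(t_months, d50: float, dx: float):
    """Model ALSFRS-R at time ``t_months`` (vectorized over ``t_months``).

    Strictly decreasing in t, with asymptotes 48 (t -> -inf) and 0
    (t -> +inf) and value exactly 24 at t = d50.
    """
    if d50 <= 0 or dx <= 0:
        raise ValueError(f"d50 and dx must be positive, got d50={d50}, dx={dx}")
    t = np.asarray(t_months, dtype=float)
    with np.errstate(over="ignore"):  # deep-saturation exp overflow -> 0
        out = FULL_SCALE / (1.0 + np.exp((t - d50) / dx))
    return float(out) if np.isscalar(t_months) else out


def compute_rd50(t_months: float, d50: float) -> float:
    """Disease-accumulation coordinate: t normalized so onset is 0 and
    the 50% functional-loss point (t = D50) is 0.5."""
    if d50 <= 0:
        raise ValueError(f"d50 must be positive, got {d50}")
    if t_months < 0:
        raise ValueError(f"t_months must be non-negative, got {t_months}")
    return t_months / (2.0 * d50)


def classify_phase(rd50: float) -> str:
    """rD50 phase: I [0, 0.25), II [0.25, 0.5), III/IV [0.5, inf)."""
    if rd50 < 0:
        raise ValueError(f"rd50 must be non-negative, got {rd50}")
    if rd50 < 0.25:
        return "I"
    if rd50 < 0.5:
        return "II"
    return "III_IV"


def classify_aggressiveness(d50: float) -> str:
    """Aggressiveness subgroup: high [0, 20), intermediate [20, 40),
    low [40, inf) months."""
    if d50 < 0:
        raise ValueError(f"d50 must be non-negative, got {d50}")
    if d50 < 20:
        return "high"
    if d50 < 40:
        return "intermediate"
    return "low"


def _as_arrays(
    observations: Sequence[AlsfrsObservation] | tuple,
) -> tuple[np.ndarray, np.ndarray]:
    if len(observations) and isinstance(observations[0], AlsfrsObservation):
        t = np.array([o.t_months for o in observations], dtype=float)
        y = np.array([o.score for o in observations], dtype=float)
    else:
        t, y = (np.asarray(a, dtype=float) for a in observations)
    order = np.argsort(t)
    return t[order], y[order]


def _initial_d50(t: np.ndarray, y: np.ndarray) -> float:
    # first piecewise-linear crossing of the half-scale level
    half = FULL_SCALE / 2.0
    for i in range(len(t) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
            return float(t[i] + (half - y0) * (t[i + 1] - t[i]) / (y1 - y0))
    return float(t[-1])


def fit_d50(observations) -> D50Fit:
    """Least-squares fit of the sigmoid to one patient's trajectory.

    Accepts a sequence of :class:`AlsfrsObservation` or a ``(t, scores)``
    pair of arrays. Requires at least two observations. Bounded
    nonlinear least squares with a piecewise-linear initial guess for
    D50 and up to five multi-starts jittering that guess before
    declaring non-convergence. Trajectories with no strict decline are
    flagged ``identifiable=False`` (the fit is still attempted so the
    parameters are reported, but downstream analyses drop the patient).
    """
    t, y = _as_arrays(observations)
    if len(t) < 2:
        raise ValueError(f"need at least 2 observations, got {len(t)}")
    identifiable = bool(np.any(np.diff(y) < 0))

    span = max(float(t[-1] - t[0]), 1.0)
    dx0 = min(max(span / 4.0, DX_BOUNDS[0] * 2), DX_BOUNDS[1] * 0.5)
    d50_init = min(max(_initial_d50(t, y), D50_BOUNDS[0] * 2), D50_BOUNDS[1] * 0.5)

    def residuals(params):
        d50, dx = params
        with np.errstate(over="ignore"):  # exp overflow -> model value 0
            return FULL_SCALE / (1.0 + np.exp((t - d50) / dx)) - y

    best = None
    for factor in _MULTISTART_FACTORS:
        x0 = (
            np.clip(d50_init * factor, *D50_BOUNDS),
            np.clip(dx0, *DX_BOUNDS),
        )
        result = least_squares(
            residuals,
            x0=x0,
            bounds=([D50_BOUNDS[0], DX_BOUNDS[0]], [D50_BOUNDS[1], DX_BOUNDS[1]]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or result.cost < best.cost:
            best = result
        if result.success and result.cost < 1e-20 * max(len(t), 1):
            break
    assert best is not None
    d50_hat, dx_hat = best.x
    return D50Fit(
        d50=float(d50_hat),
        dx=float(dx_hat),
        rss=float(2.0 * best.cost),
        n_obs=len(t),
        converged=bool(best.success),
        identifiable=identifiable,
    )


def fit_cohort(records: Iterable) -> "pd.DataFrame":
    """Fit every patient; returns the d50_fits table (one row per patient)
    with subgroup labels for identifiable, converged fits."""
    import pandas as pd

    rows = []
    for record in records:
        fit = fit_d50(record.observations)
        usable = fit.converged and fit.identifiable
        rows.append(
            {
                "patient_id": record.patient_id,
                "d50": fit.d50,
                "dx": fit.dx,
                "rss": fit.rss,
                "n_obs": fit.n_obs,
                "converged": fit.converged,
                "identifiable": fit.identifiable,
                "subgroup": classify_aggressiveness(fit.d50) if usable else "",
                "rd50_at_munix": compute_rd50(record.panel.t_munix_months, fit.d50)
                if usable
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
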