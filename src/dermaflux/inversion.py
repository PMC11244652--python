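"""Least-squares estimation of barrier permeability and gel diffusivity.

The estimation mirrors a two-stage procedure: gel diffusivity D is obtained
first from devices with acellular (barrier-free) channels by fitting the
semi-infinite erfc solution to concentration time-courses measured at several
distances from the vessel boundary; endothelial permeability P is then fitted
with D held fixed, by matching the forward barrier-diffusion simulation to the
measured central-polygon trace.

Both fits minimize the plain (unweighted) sum of squared residuals over the
log of the parameter with bounded scalar minimization (Brent); a weighting
hook is provided but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .transport import (
    ConcentrationSeries,
    TransportDomain,
    TransportParams,
    erfc_profile,
    simulate_transport,
)

DEFAULT_P_BOUNDS_UM_S = (1e-3, 1e3)
DEFAULT_D_BOUNDS_UM2_S = (0.1, 1e4)
#: relative convergence tolerance on the parameter
DEFAULT_XTOL_REL = 1e-3
DEFAULT_MAX_EVALS = 100
#: SSE increase (relative to signal power) below which the objective counts as flat
FLATNESS_REL_TOL = 1e-4


class FitError(ValueError):
    """Invalid input to an inverse fit."""


@dataclass
class FitResult:
    """Outcome of a bounded scalar least-squares inversion."""

    parameter: str
    estimate: float
    sse: float
    bounds: tuple[float, float]
    n_evaluations: int
    converged: bool
    flat_objective: bool = False
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    scenario_id: str | None = None
    label: str | None = None   # e.g. which dye the fit refers to

    @property
    def relative_error(self) -> Callable[[float], float]:
        return lambda truth: abs(self.estimate - truth) / truth


def _minimize_log_scale(
    objective: Callable[[float], float],
    bounds: tuple[float, float],
    max_evals: int = DEFAULT_MAX_EVALS,
) -> tuple[float, float, int]:
    """Bounded scalar minimization of objective(theta) over log10(theta)."""
    lo, hi = bounds
    if not 0 < lo < hi:
        raise FitError(f"bounds must satisfy 0 < lo < hi, got {bounds}")
    n_evals = 0

    def wrapped(u: float) -> float:
        nonlocal n_evals
        n_evals += 1
        return objective(10.0**u)

    xatol = DEFAULT_XTOL_REL / np.log(10.0)
    res = minimize_scalar(
        wrapped,
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": xatol, "maxiter": max_evals},
    )
    return float(10.0**res.x), float(res.fun), n_evals


def _flatness_probe(
    objective: Callable[[float], float],
    estimate: float,
    sse_min: float,
    bounds: tuple[float, float],
    signal_power: float,
) -> bool:
    """True when moving the parameter 4x either way barely changes the SSE.

    All-zero observations carry no signal at all, so they are flat by
    definition (the optimizer just runs the parameter into a bound).
    """
    if signal_power <= 0:
        return True
    scale = signal_power
    for factor in (0.25, 4.0):
        probe = float(np.clip(estimate * factor, *bounds))
        if probe == estimate:
            continue
        if (objective(probe) - sse_min) / scale > FLATNESS_REL_TOL:
            return False
    return True


def fit_permeability(
    observed_times_s: Sequence[float],
    observed_trace: Sequence[float],
    domain: TransportDomain,
    d_fixed_um2_s: float,
    roi: str = "central",
    c_lumen: float = 1.0,
    bounds: tuple[float, float] = DEFAULT_P_BOUNDS_UM_S,
    weights: Sequence[float] | None = None,
    max_evals: int = DEFAULT_MAX_EVALS,
    scenario_id: str | None = None,
    label: str | None = None,
) -> FitResult:
    """Estimate barrier permeability P (um/s) from an ROI mean-intensity trace.

    The model trace is produced by :func:`simulate_transport` on ``domain``
    with diffusivity held at ``d_fixed_um2_s``; the sum of squared residuals
    against ``observed_trace`` is minimized over log10(P) within ``bounds``.
    A flat objective (e.g. an all-zero trace) is reported via
    ``converged=False`` / ``flat_objective=True`` rather than raised.
    """
    t = np.asarray(observed_times_s, dtype=float)
    obs = np.asarray(observed_trace, dtype=float)
    if t.shape != obs.shape or t.size < 3:
        raise FitError("need >= 3 (time, value) observation pairs")
    if d_fixed_um2_s <= 0:
        raise FitError("D must be > 0")
    w = np.ones_like(obs) if weights is None else np.asarray(weights, dtype=float)

    # t = 0 carries no information and the simulator starts from zero anyway
    sim_times = t[t > 0]
    keep = t > 0

    def model_trace(p: float) -> np.ndarray:
        params = TransportParams(
            d_um2_s=d_fixed_um2_s,
            p_um_s=p,
            c_lumen=c_lumen,
            duration_s=float(sim_times[-1]),
            output_times_s=sim_times,
        )
        series = simulate_transport(domain, params)
        return series.roi_traces[roi]

    def objective(p: float) -> float:
        r = model_trace(p) - obs[keep]
        return float(np.sum(w[keep] * r * r))

    estimate, sse, n_evals = _minimize_log_scale(objective, bounds, max_evals)
    signal_power = float(np.sum(obs[keep] ** 2))
    flat = _flatness_probe(objective, estimate, sse, bounds, signal_power)
    residuals = np.full_like(obs, np.nan)
    residuals[keep] = model_trace(estimate) - obs[keep]
    return FitResult(
        parameter="P_um_s",
        estimate=estimate,
        sse=sse,
        bounds=bounds,
        n_evaluations=n_evals,
        converged=not flat,
        flat_objective=flat,
        residuals=residuals,
        scenario_id=scenario_id,
        label=label,
    )


def fit_diffusivity(
    observed: pd.DataFrame | Mapping[str, Sequence[float]],
    c0: float = 1.0,
    bounds: tuple[float, float] = DEFAULT_D_BOUNDS_UM2_S,
    weights: Sequence[float] | None = None,
    max_evals: int = DEFAULT_MAX_EVALS,
    scenario_id: str | None = None,
    label: str | None = None,
) -> FitResult:
    """Estimate gel diffusivity D (um^2/s) from acellular-channel data.

    ``observed`` holds columns ``time_s``, ``distance_um``, ``value``:
    concentration time-courses at >= 3 distances from the vessel boundary.
    The erfc solution of the diffusion equation (constant surface
    concentration ``c0``) is fitted jointly to all (x, t) observations over
    log10(D).  All-zero observations pin the estimate at the lower bound with
    ``converged=False``.
    """
    df = pd.DataFrame(observed)
    for col in ("time_s", "distance_um", "value"):
        if col not in df:
            raise FitError(f"observations missing column {col!r}")
    if np.any(df["distance_um"] <= 0):
        raise FitError("distances must be strictly positive")
    if np.any(df["time_s"] <= 0):
        raise FitError("observation times must be strictly positive")
    n_dist = df["distance_um"].nunique()
    if n_dist < 3:
        raise FitError(f"need >= 3 distinct distances, got {n_dist}")
    if df.groupby("distance_um")["time_s"].nunique().min() < 2:
        raise FitError("need >= 2 time points per distance")

    x = df["distance_um"].to_numpy(dtype=float)
    t = df["time_s"].to_numpy(dtype=float)
    obs = df["value"].to_numpy(dtype=float)
    w = np.ones_like(obs) if weights is None else np.asarray(weights, dtype=float)

    def objective(d: float) -> float:
        r = erfc_profile(x, t, d, c0) - obs
        return float(np.sum(w * r * r))

    estimate, sse, n_evals = _minimize_log_scale(objective, bounds, max_evals)
    flat = _flatness_probe(objective, estimate, sse, bounds, float(np.sum(obs**2)))
    return FitResult(
        parameter="D_um2_s",
        estimate=estimate,
        sse=sse,
        bounds=bounds,
        n_evaluations=n_evals,
        converged=not flat,
        flat_objective=flat,
        residuals=erfc_profile(x, t, estimate, c0) - obs,
        scenario_id=scenario_id,
        label=label,
    )


def joint_recovery_report(truth, fits: Sequence[FitResult]) -> pd.DataFrame:
    """Tabulate fitted parameters against a synthetic scenario's ground truth.

    ``truth`` is a :class:`dermaflux.synth.GroundTruth`; every fit must carry
    the same ``scenario_id``.  Returns a DataFrame with columns
    (parameter, truth, estimate, relative_error, converged).
    """
    rows = []
    for fit in fits:
        if fit.scenario_id is not None and fit.scenario_id != truth.scenario_id:
            raise FitError(
                f"fit scenario {fit.scenario_id!r} does not match truth "
                f"{truth.scenario_id!r}"
            )
        true_value = truth.lookup_parameter(fit.parameter, fit.label)
        rows.append(
            {
                "parameter": fit.parameter,
                "label": fit.label,
                "truth": true_value,
                "estimate": fit.estimate,
                "relative_error": abs(fit.estimate - true_value) / true_value,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["parameter", "label", "truth", "estimate", "relative_error", "converged"],
    )
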