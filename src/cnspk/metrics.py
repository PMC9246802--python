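"""Steady-state detection, PK summary metrics and target engagement.

Chronic oral dosing is simulated interval by interval until the
interdose AUC of every CNS compartment changes by less than a stated
tolerance (0.5% by default) between consecutive intervals, with at least
five terminal plasma half-lives simulated.  The final interval is
re-indexed to time post dose and summarised per compartment: Cmax, Cmin,
Tmax, interdose AUC, terminal half-life from the log-linear tail, and
the peak-to-trough fluctuation ratio Cmax:Cmin.

Target engagement compares an unbound concentration profile with an
unbound in-vitro IC50: the fraction of the interdose interval spent at
or above the IC50, all crossing times (linear interpolation between grid
points), and the onset of the "drug-free" period -- the final downward
crossing after which the concentration does not recover within the
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cnsmodel import COMPARTMENTS, CnsModel, simulate_cns
from .plasma import ConcProfile, DoseRegimen, PlasmaModel, make_plasma_solution

__all__ = [
    "PkMetrics",
    "EngagementSummary",
    "run_to_steady_state",
    "compute_metrics",
    "engagement",
    "SteadyStateError",
]


class SteadyStateError(RuntimeError):
    """Interdose AUC did not converge within the allowed dose count."""


@dataclass(frozen=True)
class PkMetrics:
    """Summary metrics of one compartment over one interdose interval."""

    compartment: str
    cmax: float  # ng/mL
    cmin: float  # ng/mL
    tmax: float  # min post dose
    auc_tau: float  # ng*min/mL
    half_life: float | None  # min; None when the tail is not log-linear
    fluctuation: float  # cmax / cmin


@dataclass(frozen=True)
class EngagementSummary:
    """Position of a profile relative to an unbound IC50."""

    compartment: str
    ic50: float  # ng/mL
    fraction_above: float  # of the interdose interval
    crossings: tuple[tuple[float, str], ...]  # (time, "down"/"up")
    drug_free_onset: float | None  # min post dose, or None
    flag: str  # "always-above" / "dips-below" / "always-below"


def _quadratic_refine(
    t: np.ndarray, c: np.ndarray, idx: int
) -> tuple[float, float]:
    """Refine an extremum with a local parabola through three points."""
    if idx == 0 or idx == len(t) - 1:
        return float(t[idx]), float(c[idx])
    t0, t1, t2 = t[idx - 1], t[idx], t[idx + 1]
    c0, c1, c2 = c[idx - 1], c[idx], c[idx + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (c1 - c0) + t1 * (c0 - c2) + t0 * (c2 - c1)) / denom
    b = (t2 * t2 * (c0 - c1) + t1 * t1 * (c2 - c0) + t0 * t0 * (c1 - c2)) / denom
    if a == 0.0:
        return float(t1), float(c1)
    tv = -b / (2.0 * a)
    if not (min(t0, t2) <= tv <= max(t0, t2)):
        return float(t1), float(c1)
    cv = a * tv * tv + b * tv + (c0 - a * t0 * t0 - b * t0)
    return float(tv), float(cv)


def compute_metrics(profile: ConcProfile, compartment: str) -> PkMetrics:
    """Summarise one compartment of a single-interval profile."""
    t = profile.times - profile.times[0]
    c = profile.conc[compartment]
    if len(t) < 50:
        raise ValueError("metrics need at least 50 grid points per interval")
    imax = int(np.argmax(c))
    imin = int(np.argmin(c))
    tmax, cmax = _quadratic_refine(t, c, imax)
    _, cmin = _quadratic_refine(t, c, imin)
    cmin = max(cmin, 0.0)
    auc = float(np.trapezoid(c, t))
    half_life = _terminal_half_life(t, c, tmax)
    if np.allclose(c, c[0], rtol=1e-12, atol=0.0):
        tmax = 0.0  # constant profile: the peak time is degenerate
    fluctuation = cmax / cmin if cmin > 0 else math.inf
    return PkMetrics(
        compartment=compartment, cmax=cmax, cmin=cmin, tmax=tmax,
        auc_tau=auc, half_life=half_life, fluctuation=fluctuation,
    )


def _terminal_half_life(
    t: np.ndarray, c: np.ndarray, tmax: float
) -> float | None:
    """Least-squares log-linear fit on the last 30% of the interval."""
    tail_start = max(tmax, t[-1] - 0.3 * (t[-1] - t[0]))
    mask = t >= tail_start
    if mask.sum() < 3:
        return None
    ct = c[mask]
    if np.any(ct <= 0.0):
        return None
    slope = np.polyfit(t[mask], np.log(ct), 1)[0]
    if slope >= 0.0:
        return None
    return float(math.log(2.0) / -slope)


def _threshold_crossings(
    t: np.ndarray, c: np.ndarray, threshold: float
) -> list[tuple[float, str]]:
    """Linear-interpolated crossing times of ``c`` against a threshold."""
    out: list[tuple[float, str]] = []
    above = c >= threshold
    for i in range(len(t) - 1):
        if above[i] != above[i + 1]:
            frac = (threshold - c[i]) / (c[i + 1] - c[i])
            tc = float(t[i] + frac * (t[i + 1] - t[i]))
            out.append((tc, "down" if above[i] else "up"))
    return out


def engagement(
    profile: ConcProfile, compartment: str, ic50: float,
    drug_free_floor: float | None = None,
) -> EngagementSummary:
    """Compare one compartment's profile against an unbound IC50.

    By default "drug-free" means below the IC50; passing
    ``drug_free_floor`` (ng/mL, e.g. 0.01) instead derives the drug-free
    onset from the final crossing below that absolute concentration.
    """
    if not (ic50 > 0):
        raise ValueError("ic50 must be positive")
    t = profile.times - profile.times[0]
    c = profile.conc[compartment]
    above = c >= ic50
    crossings: list[tuple[float, str]] = []
    time_above = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        a0, a1 = above[i], above[i + 1]
        if a0 and a1:
            time_above += dt
        elif a0 != a1:
            # linear interpolation of the crossing point
            frac = (ic50 - c[i]) / (c[i + 1] - c[i])
            tc = t[i] + frac * dt
            if a0:
                time_above += tc - t[i]
                crossings.append((float(tc), "down"))
            else:
                time_above += t[i + 1] - tc
                crossings.append((float(tc), "up"))
    fraction = time_above / (t[-1] - t[0])
    drug_free = None
    onset_crossings = crossings
    if drug_free_floor is not None:
        onset_crossings = _threshold_crossings(t, c, drug_free_floor)
    if onset_crossings and onset_crossings[-1][1] == "down":
        drug_free = onset_crossings[-1][0]
    if np.all(above):
        flag = "always-above"
    elif not np.any(above):
        flag = "always-below"
    else:
        flag = "dips-below"
    return EngagementSummary(
        compartment=compartment, ic50=ic50, fraction_above=float(fraction),
        crossings=tuple(crossings), drug_free_onset=drug_free, flag=flag,
    )


def run_to_steady_state(
    model: CnsModel,
    plasma_model: PlasmaModel,
    regimen: DoseRegimen,
    points_per_interval: int = 721,
    auc_tol: float = 0.005,
    max_intervals: int = 200,
    min_half_lives: float = 5.0,
    rtol: float = 1e-8,
) -> ConcProfile:
    """Dose until interdose AUCs converge; return the final interval.

    The returned profile is re-indexed to time post dose and flagged
    ``at_steady_state`` in its metadata.  A regimen with ``n_doses=1``
    returns the first interval, flagged not at steady state.
    """
    tau = regimen.interval
    sol = make_plasma_solution(
        plasma_model, DoseRegimen(dose=regimen.dose, interval=tau, n_doses=None)
    )
    single_dose = regimen.n_doses == 1
    if single_dose:
        sol = make_plasma_solution(plasma_model, regimen)
    t_half = plasma_model.terminal_half_life
    y0 = np.zeros(len(COMPARTMENTS))
    prev_auc: np.ndarray | None = None
    intervals = 0
    converged = False
    profile: ConcProfile | None = None
    while intervals < max_intervals:
        grid = np.linspace(intervals * tau, (intervals + 1) * tau, points_per_interval)
        profile = simulate_cns(model, sol, grid, y0=y0, rtol=rtol)
        y0 = profile.metadata["final_state"]
        intervals += 1
        if single_dose:
            break
        if regimen.n_doses is not None and intervals >= regimen.n_doses:
            break  # finite regimen: return its last interval
        auc = np.array(
            [np.trapezoid(profile.conc[name], grid) for name in COMPARTMENTS]
        )
        if prev_auc is not None and intervals * tau >= min_half_lives * t_half:
            scale = np.maximum(np.abs(auc), 1e-300)
            rel = np.abs(auc - prev_auc) / scale
            nonzero = auc > 0
            if not np.any(nonzero) or np.max(rel[nonzero]) < auc_tol:
                converged = True
                break
        prev_auc = auc
    else:
        raise SteadyStateError(
            f"interdose AUC did not converge within {max_intervals} intervals "
            f"for {model.drug.name!r}"
        )
    assert profile is not None
    shifted = ConcProfile(
        times=profile.times - profile.times[0],
        conc=dict(profile.conc),
        metadata={
            **profile.metadata,
            "intervals_simulated": intervals,
            "at_steady_state": converged,
            "interval_min": tau,
            "regimen": regimen,
        },
    )
    return shifted
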