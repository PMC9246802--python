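"""Empirical plasma PK: closed-form oral 1-/2-compartment models.

Plasma is the forcing function of the CNS model: drug mass transported
into the CNS is a negligible fraction of the body burden, so there is no
feedback from the CNS to plasma, and the same plasma profile can be fed
to every population to isolate CNS physiology effects.

The shipped plasma parameters are apparent values already corrected for
plasma protein binding, i.e. the simulated concentrations are *unbound*
plasma concentrations in ng/mL.  Multi-dose profiles are superpositions
of identical single-dose solutions at the dosing interval; the
superposition sums are evaluated in closed form (geometric series), so a
profile with hundreds of doses costs the same as a single dose.

The single-dose solution is a sum of exponentials: the Bateman function
for one compartment with first-order absorption (with the ``t exp(-kt)``
limit when ka and ke coincide), and a three-exponential solution from the
eigenvalues of the depot/central/peripheral system for two compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "PlasmaModel",
    "DoseRegimen",
    "ConcProfile",
    "PlasmaSolution",
    "load_plasma",
    "load_regimen",
    "simulate_plasma",
    "plasma_closed_form_check",
]

MG_TO_NG = 1.0e6


@dataclass(frozen=True)
class PlasmaModel:
    """Oral 1- or 2-compartment plasma model (unbound, apparent scale)."""

    cl_cen: float  # mL/min apparent clearance
    v_cen: float  # mL
    ka: float  # 1/min first-order absorption
    q_cen_per1: float = 0.0  # mL/min inter-compartmental clearance
    v_per1: float = 0.0  # mL
    f_rel: float = 1.0  # relative bioavailability
    n_compartments: int = 1

    def __post_init__(self) -> None:
        for name in ("cl_cen", "v_cen", "ka"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if self.n_compartments == 1 and (self.q_cen_per1 or self.v_per1):
            raise ValueError(
                "a 1-compartment model must have q_cen_per1 = v_per1 = 0"
            )
        if self.n_compartments == 2 and not (self.q_cen_per1 > 0 and self.v_per1 > 0):
            raise ValueError("a 2-compartment model needs positive Q and V_per1")

    @property
    def ke(self) -> float:
        """Elimination rate constant from the central compartment, 1/min."""
        return self.cl_cen / self.v_cen

    @property
    def terminal_half_life(self) -> float:
        """ln2 over the smallest disposition rate constant, min."""
        rates = _disposition_rates(self)
        return math.log(2.0) / min(rates)


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated oral dosing: ``dose`` mg every ``interval`` min."""

    dose: float  # mg
    interval: float  # min
    n_doses: int | None = None  # None = keep dosing indefinitely
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not (self.interval > 0):
            raise ValueError("interval must be positive")
        if self.n_doses is not None and self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")


@dataclass
class ConcProfile:
    """Time-stamped unbound concentrations per compartment.

    ``times`` is a strictly increasing grid in minutes; ``conc`` maps a
    compartment label to an array of concentrations in ng/mL.
    """

    times: np.ndarray
    conc: dict[str, np.ndarray]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing 1-D grid")
        for k, v in self.conc.items():
            arr = np.asarray(v, dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"conc[{k!r}] does not match the time grid")
            self.conc[k] = arr

    @property
    def compartments(self) -> list[str]:
        return list(self.conc)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: time_min, compartment, conc_ng_per_ml."""
        frames = [
            pd.DataFrame(
                {"time_min": self.times, "compartment": k, "conc_ng_per_ml": v}
            )
            for k, v in self.conc.items()
        ]
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Exponential-sum machinery
# ---------------------------------------------------------------------------

_DEGENERATE_RTOL = 1e-9


def _disposition_rates(m: PlasmaModel) -> list[float]:
    if m.n_compartments == 1:
        return [m.ke]
    k10 = m.cl_cen / m.v_cen
    k12 = m.q_cen_per1 / m.v_cen
    k21 = m.q_cen_per1 / m.v_per1
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return [alpha, beta]


def _single_dose_terms(m: PlasmaModel, dose_mg: float) -> list[tuple[float, float, int]]:
    """Terms (coef, rate, power): C(t) = sum coef * t**power * exp(-rate*t)."""
    amount = m.f_rel * dose_mg * MG_TO_NG
    if amount == 0.0:
        return []
    ka = m.ka
    if m.n_compartments == 1:
        ke = m.ke
        if abs(ka - ke) <= _DEGENERATE_RTOL * max(ka, ke):
            # ka -> ke limit of the Bateman function
            return [(amount * ka / m.v_cen, ke, 1)]
        a = amount * ka / (m.v_cen * (ka - ke))
        return [(a, ke, 0), (-a, ka, 0)]
    alpha, beta = _disposition_rates(m)
    k21 = m.q_cen_per1 / m.v_per1
    rates = [alpha, beta, ka]
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(rates[i] - rates[j]) <= _DEGENERATE_RTOL * max(rates[i], rates[j]):
                raise ValueError(
                    "degenerate rate constants in the 2-compartment model; "
                    "perturb the parameters"
                )
    pref = amount * ka / m.v_cen
    terms = [
        (pref * (k21 - alpha) / ((ka - alpha) * (beta - alpha)), alpha, 0),
        (pref * (k21 - beta) / ((ka - beta) * (alpha - beta)), beta, 0),
        (pref * (k21 - ka) / ((alpha - ka) * (beta - ka)), ka, 0),
    ]
    return terms


def _superposed_term(
    t: np.ndarray, coef: float, rate: float, power: int, tau: float,
    n_doses: int | None,
) -> np.ndarray:
    """Closed-form sum of a term over doses at 0, tau, 2*tau, ..."""
    out = np.zeros_like(t)
    pos = t >= 0.0
    if not np.any(pos):
        return out
    tp = t[pos]
    m = np.floor(tp / tau).astype(int)  # index of most recent dose
    if n_doses is not None:
        m = np.minimum(m, n_doses - 1)
    u = tp - m * tau  # time since most recent counted dose
    rho = math.exp(-rate * tau)
    n = m + 1  # number of doses contributing
    if abs(1.0 - rho) < 1e-14:
        g0 = n.astype(float)
        g1 = 0.5 * n * (n - 1.0)
    else:
        rho_n = rho ** n
        g0 = (1.0 - rho_n) / (1.0 - rho)
        g1 = rho * (1.0 - n * rho ** (n - 1) + (n - 1) * rho_n) / (1.0 - rho) ** 2
    decay = np.exp(-rate * u)
    if power == 0:
        val = coef * decay * g0
    elif power == 1:
        val = coef * decay * (u * g0 + tau * g1)
    else:  # pragma: no cover - only powers 0/1 are generated
        raise ValueError("unsupported polynomial order")
    out[pos] = val
    return out


@dataclass(frozen=True)
class PlasmaSolution:
    """Callable closed-form plasma profile under repeated dosing."""

    terms: tuple[tuple[float, float, int], ...]
    tau: float
    n_doses: int | None = None

    def conc(self, t: float | np.ndarray) -> np.ndarray | float:
        """Unbound plasma concentration (ng/mL) at time(s) ``t`` (min)."""
        arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(arr)
        for coef, rate, power in self.terms:
            out += _superposed_term(arr, coef, rate, power, self.tau, self.n_doses)
        out = np.maximum(out, 0.0)
        if np.isscalar(t) or np.ndim(t) == 0:
            return float(out[0])
        return out

    __call__ = conc


def make_plasma_solution(m: PlasmaModel, r: DoseRegimen) -> PlasmaSolution:
    """Closed-form multi-dose solution for a model/regimen pair."""
    return PlasmaSolution(
        terms=tuple(_single_dose_terms(m, r.dose)),
        tau=r.interval,
        n_doses=r.n_doses,
    )


def simulate_plasma(
    m: PlasmaModel, r: DoseRegimen, grid: Sequence[float] | np.ndarray
) -> ConcProfile:
    """Evaluate the unbound plasma profile on a time grid (min)."""
    grid = np.asarray(grid, dtype=float)
    sol = make_plasma_solution(m, r)
    return ConcProfile(
        times=grid,
        conc={"plasma": np.asarray(sol.conc(grid))},
        metadata={"model": m, "regimen": r, "scale": "unbound"},
    )


def _simulate_plasma_ode(
    m: PlasmaModel, r: DoseRegimen, grid: np.ndarray
) -> np.ndarray:
    """Numerical reference solution (dose events as depot increments)."""
    n_states = 2 if m.n_compartments == 1 else 3
    ke = m.ke

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty_like(y)
        dy[0] = -m.ka * y[0]
        if n_states == 2:
            dy[1] = m.ka * y[0] - ke * y[1]
        else:
            k12 = m.q_cen_per1 / m.v_cen
            k21 = m.q_cen_per1 / m.v_per1
            dy[1] = m.ka * y[0] - (ke + k12) * y[1] + k21 * y[2] * 1.0
            dy[2] = k12 * y[1] - k21 * y[2]
        return dy

    t_end = grid[-1]
    n_doses = r.n_doses if r.n_doses is not None else int(t_end // r.interval) + 1
    dose_times = [k * r.interval for k in range(n_doses) if k * r.interval <= t_end]
    amount = m.f_rel * r.dose * MG_TO_NG

    y = np.zeros(n_states)
    out = np.zeros_like(grid)
    for i, t0 in enumerate(dose_times):
        y[0] += amount
        t1 = dose_times[i + 1] if i + 1 < len(dose_times) else t_end
        if t1 <= t0:
            continue
        last = i + 1 == len(dose_times)
        mask = (grid >= t0) & ((grid <= t1) if last else (grid < t1))
        idx = np.nonzero(mask)[0]
        t_eval = np.unique(np.append(grid[idx], t1))
        res = solve_ivp(
            rhs, (t0, t1), y, t_eval=t_eval, method="LSODA",
            rtol=1e-11, atol=1e-6,
        )
        if not res.success:  # pragma: no cover
            raise RuntimeError(f"plasma ODE integration failed: {res.message}")
        pos = np.searchsorted(res.t, grid[idx])
        out[idx] = res.y[1, pos]
        y = res.y[:, -1]
    return out / m.v_cen


def plasma_closed_form_check(
    m: PlasmaModel, r: DoseRegimen, n_points: int = 400
) -> float:
    """Max relative deviation between analytic and numerical solutions.

    Used as a solver-verification contract: the two independent routes to
    the same profile must agree to ~1e-8 relative (normalised by the peak
    concentration).
    """
    horizon = (r.n_doses or 3) * r.interval
    grid = np.linspace(0.0, horizon, n_points)
    analytic = np.asarray(make_plasma_solution(m, r).conc(grid))
    numeric = _simulate_plasma_ode(m, r, grid)
    scale = max(analytic.max(), 1e-300)
    return float(np.max(np.abs(analytic - numeric)) / scale)


# ---------------------------------------------------------------------------
# Shipped plasma models and clinical regimens
# ---------------------------------------------------------------------------

_PLASMA_REGISTRY: dict[str, dict[str, Any]] = {
    # apparent (unbound) parameters; mL, mL/min, 1/min
    "donepezil": dict(cl_cen=2048.0, v_cen=391_000.0, ka=0.022),
    "galantamine": dict(
        cl_cen=192.0, v_cen=157_000.0, ka=0.051,
        q_cen_per1=510.0, v_per1=59_000.0, n_compartments=2,
    ),
    "memantine": dict(cl_cen=228.0, v_cen=194_000.0, ka=0.005),
    "rivastigmine": dict(
        cl_cen=3333.0, v_cen=236_000.0, ka=0.052,
        # F = 1.4 for the 6 mg dose, relative to the 1-5 mg range
        f_rel=1.4,
    ),
    "semagacestat": dict(cl_cen=846.0, v_cen=71_700.0, ka=0.012),
}

_REGIMEN_REGISTRY: dict[str, dict[str, float]] = {
    "donepezil": dict(dose=10.0, interval=1440.0),  # once daily
    "galantamine": dict(dose=10.0, interval=720.0),  # twice daily
    "memantine": dict(dose=20.0, interval=1440.0),
    "rivastigmine": dict(dose=6.0, interval=720.0),
    "semagacestat": dict(dose=140.0, interval=1440.0),
}


def load_plasma(name: str) -> PlasmaModel:
    """Plasma model of a registry drug."""
    key = name.lower()
    if key not in _PLASMA_REGISTRY:
        raise KeyError(
            f"no plasma model for {name!r}; available: {sorted(_PLASMA_REGISTRY)}"
        )
    return PlasmaModel(**_PLASMA_REGISTRY[key])


def load_regimen(name: str, n_doses: int | None = None) -> DoseRegimen:
    """Clinical dosing regimen of a registry drug."""
    key = name.lower()
    if key not in _REGIMEN_REGISTRY:
        raise KeyError(
            f"no regimen for {name!r}; available: {sorted(_REGIMEN_REGISTRY)}"
        )
    return DoseRegimen(n_doses=n_doses, **_REGIMEN_REGISTRY[key])
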