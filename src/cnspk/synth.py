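"""Synthetic drugs and noisy observations for end-to-end testing.

The generator draws physically plausible random small molecules (at
most one acidic and one basic group, lipophilicity, size, binding and
Kpuu targets within realistic CNS-drug ranges) and emulates sparse
bioanalytical sampling of a concentration profile with multiplicative
log-normal noise, the standard error model for CV-characterised assays
of positive concentrations.  Everything is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .drugs import DrugProperties
from .plasma import ConcProfile

__all__ = ["SyntheticSpec", "generate_drug", "generate_observations"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ranges and noise settings of the synthetic generator."""

    logp_range: tuple[float, float] = (-1.0, 5.0)
    mw_range: tuple[float, float] = (150.0, 600.0)
    pka_acid_range: tuple[float, float] = (3.0, 11.0)
    pka_base_range: tuple[float, float] = (5.0, 12.0)
    p_acid: float = 0.3  # probability of an acidic group
    p_base: float = 0.5  # probability of a basic group
    fu_range: tuple[float, float] = (0.01, 1.0)
    kpuu_range: tuple[float, float] = (0.1, 5.0)
    ic50_range: tuple[float, float] = (1.0, 1000.0)  # ng/mL
    cv: float = 0.2  # assay coefficient of variation
    schedule: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.linspace(30.0, 1440.0, 12))
    )


def generate_drug(spec: SyntheticSpec | None = None, seed: int = 0) -> DrugProperties:
    """Draw one random, internally consistent drug record."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    pka_acid = None
    pka_base = None
    if rng.random() < spec.p_acid:
        pka_acid = float(rng.uniform(*spec.pka_acid_range))
    if rng.random() < spec.p_base:
        pka_base = float(rng.uniform(*spec.pka_base_range))
    lo, hi = spec.fu_range
    fu_p = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    fu_b = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    klo, khi = spec.kpuu_range

    def kpuu(lo: float = klo) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(khi))))

    kpuu_bbb = kpuu()
    # physical consistency: lumbar CSF drains brain ECF through the CSF
    # chain, so its unbound ratio cannot sit far below the brain's
    lumbar_floor = min(max(klo, 0.4 * kpuu_bbb), 0.9 * khi)
    return DrugProperties(
        name=f"synthetic-{seed}",
        mw=float(rng.uniform(*spec.mw_range)),
        logp=float(rng.uniform(*spec.logp_range)),
        pka_acid=pka_acid,
        pka_base=pka_base,
        fu_p=fu_p,
        fu_b=fu_b,
        kpuu_bbb=kpuu_bbb,
        kpuu_lv=kpuu(),
        kpuu_lumbar=kpuu(lumbar_floor),
        ic50=float(np.exp(rng.uniform(*np.log(spec.ic50_range)))),
        target="synthetic target",
    )


def generate_observations(
    profile: ConcProfile,
    schedule: Sequence[float],
    cv: float = 0.2,
    seed: int = 0,
    compartment: str = "csf_sas",
) -> pd.DataFrame:
    """Sample a profile at the given times with log-normal assay noise.

    The noise is multiplicative with the stated coefficient of variation
    and unit geometric mean; the interpolated truth is kept alongside the
    observations for recovery tests.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.min() < profile.times[0] or schedule.max() > profile.times[-1]:
        raise ValueError("sampling schedule extends beyond the profile span")
    truth = np.interp(schedule, profile.times, profile.conc[compartment])
    rng = np.random.default_rng(seed)
    if cv > 0:
        sigma = np.sqrt(np.log(1.0 + cv * cv))
        noise = np.exp(rng.normal(0.0, sigma, size=schedule.shape))
        observed = truth * noise
    else:
        observed = truth.copy()
    return pd.DataFrame(
        {
            "time_min": schedule,
            "compartment": compartment,
            "observed_ng_per_ml": observed,
            "truth_ng_per_ml": truth,
        }
    )
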