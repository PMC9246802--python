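"""The two application case studies of the CNS simulator.

Case study 1 asks whether, under the clinical dosing regimens, the four
marketed Alzheimer's drugs (donepezil, galantamine, memantine,
rivastigmine) reach their unbound in-vitro IC50 at the CNS target sites
(brain ECF/ICF) and at the clinical sampling site (subarachnoid CSF) in
mild-AD patients at steady state.

Case study 2 examines semagacestat, a gamma-secretase inhibitor that
failed in the clinic: the peak-to-trough fluctuation of its steady-state
profile differs by orders of magnitude between brain ECF/ICF and the
subarachnoid CSF, so the brain enters a drug-free period (below the
IC50 of 5.4 ng/mL) about half a day after each dose while the CSF stays
above the IC50 throughout -- a caution against reading target
engagement off lumbar CSF samples.
"""

from __future__ import annotations

import pandas as pd

from .drugs import load_drug
from .metrics import compute_metrics, engagement
from .plasma import ConcProfile
from .workflow import ELDERLY_AGE, steady_state_run

__all__ = ["case_study_1", "case_study_2", "TARGET_COMPARTMENTS"]

#: compartments reported in both case studies
TARGET_COMPARTMENTS = ("brain_ecf", "brain_icf", "csf_sas")

MARKETED_DRUGS = ("donepezil", "galantamine", "memantine", "rivastigmine")


def _summarise(
    profile: ConcProfile, ic50: float, compartments=TARGET_COMPARTMENTS
) -> list[dict]:
    rows = []
    for comp in compartments:
        m = compute_metrics(profile, comp)
        e = engagement(profile, comp, ic50)
        rows.append(
            dict(
                compartment=comp,
                cmax_ng_per_ml=m.cmax,
                cmin_ng_per_ml=m.cmin,
                tmax_min=m.tmax,
                auc_tau=m.auc_tau,
                fluctuation=m.fluctuation,
                half_life_min=m.half_life,
                ic50_ng_per_ml=ic50,
                fraction_above_ic50=e.fraction_above,
                drug_free_onset_min=e.drug_free_onset,
                flag=e.flag,
            )
        )
    return rows


def case_study_1(
    population: str = "AD",
    age: float = ELDERLY_AGE,
    points_per_interval: int = 721,
    profiles: dict[str, ConcProfile] | None = None,
) -> pd.DataFrame:
    """Steady-state metrics and IC50 engagement of the marketed drugs.

    Returns one row per drug x compartment.  Pre-computed steady-state
    profiles can be passed in to avoid re-simulation.
    """
    rows = []
    for name in MARKETED_DRUGS:
        d = load_drug(name)
        profile = (profiles or {}).get(name) or steady_state_run(
            d, population, age=age, points_per_interval=points_per_interval
        )
        for row in _summarise(profile, d.ic50):
            row.update(drug=name, target=d.target, population=population.upper())
            rows.append(row)
        if d.ic50_secondary is not None:
            for row in _summarise(profile, d.ic50_secondary):
                row.update(
                    drug=name, target=d.target_secondary,
                    population=population.upper(),
                )
                rows.append(row)
    cols = [
        "drug", "target", "population", "compartment", "cmax_ng_per_ml",
        "cmin_ng_per_ml", "tmax_min", "auc_tau", "fluctuation",
        "half_life_min", "ic50_ng_per_ml", "fraction_above_ic50",
        "drug_free_onset_min", "flag",
    ]
    return pd.DataFrame(rows)[cols]


def case_study_2(
    age: float = ELDERLY_AGE,
    points_per_interval: int = 721,
    profiles: dict[str, ConcProfile] | None = None,
) -> pd.DataFrame:
    """Semagacestat fluctuation and gamma-secretase engagement, CHY vs AD.

    One row per population x compartment with the peak-to-trough ratio,
    the engagement fraction, the drug-free onset and the position flag.
    """
    d = load_drug("semagacestat")
    rows = []
    for population in ("CHY", "AD"):
        profile = (profiles or {}).get(population) or steady_state_run(
            d, population, age=age, points_per_interval=points_per_interval
        )
        for row in _summarise(profile, d.ic50):
            row.update(drug=d.name, population=population)
            rows.append(row)
    cols = [
        "drug", "population", "compartment", "cmax_ng_per_ml",
        "cmin_ng_per_ml", "fluctuation", "ic50_ng_per_ml",
        "fraction_above_ic50", "drug_free_onset_min", "flag",
    ]
    return pd.DataFrame(rows)[cols]
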