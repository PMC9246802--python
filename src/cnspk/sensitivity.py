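"""One-at-a-time (OAT) sensitivity analysis of the AD model.

Each physiological parameter is perturbed in isolation -- two- and
ten-fold up and down for volumes, flows, areas and multipliers; plus or
minus one and two pH units for compartment pH values -- the model is
rebuilt with the asymmetry factors held fixed (re-calibrating would
cancel barrier-parameter perturbations by construction), run to steady
state, and the percent change of Cmax, Tmax, terminal half-life and
interdose AUC at brain ECF, brain ICF and subarachnoid CSF relative to
the unperturbed run is reported.  Perturbations that make the
physiology invalid (e.g. an ECF fraction >= 1) are recorded as skipped,
not fatal.
"""

from __future__ import annotations

import pandas as pd

from .cnsmodel import build_model
from .drugs import DrugProperties, load_drug
from .metrics import compute_metrics, run_to_steady_state
from .physiology import PhysiologySet, validate_physiology
from .plasma import load_plasma, load_regimen
from .workflow import ELDERLY_AGE, calibrated_factors, population_physiologies

__all__ = ["oat_sensitivity", "SCALE_PARAMETERS", "PH_PARAMETERS"]

#: parameters perturbed multiplicatively
SCALE_PARAMETERS = (
    "brain_volume", "f_ecf", "v_microvasc", "f_phospholipid", "v_lysosome",
    "v_lv", "v_tfv", "v_cm", "v_sas", "q_cbf_total", "q_ecf_bulk", "q_csf",
    "sa_bbb", "sa_bcsfb", "f_paracellular_bbb", "f_paracellular_bcsfb",
)
#: parameters perturbed additively, in pH units
PH_PARAMETERS = ("ph_plasma", "ph_ecf", "ph_icf", "ph_lyso", "ph_csf")

_METRIC_FIELDS = ("cmax", "tmax", "half_life", "auc_tau")
_COMPARTMENTS = ("brain_ecf", "brain_icf", "csf_sas")


def _perturb(p: PhysiologySet, name: str, factor: float) -> PhysiologySet:
    if name in PH_PARAMETERS:
        return p.with_(**{name: getattr(p, name) + factor})
    changes = {name: getattr(p, name) * factor}
    if name == "f_ecf":
        changes["f_icf"] = 1.0 - changes["f_ecf"]
    if name == "brain_volume":
        # keep the normalised-CBF bookkeeping consistent
        changes["q_cbf_norm"] = p.q_cbf_total / (
            changes["brain_volume"] * p.brain_density / 100.0
        )
    if name == "q_cbf_total":
        changes["q_cbf_norm"] = changes["q_cbf_total"] / (p.brain_mass / 100.0)
    return p.with_(**changes)


def _metric_row(profile) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for comp in _COMPARTMENTS:
        m = compute_metrics(profile, comp)
        for f in _METRIC_FIELDS:
            out[f"{f}@{comp}"] = getattr(m, f)
    return out


def _pct(new: float | None, ref: float | None) -> float | None:
    if new is None or ref is None or ref == 0:
        return None
    return 100.0 * (new - ref) / ref


def oat_sensitivity(
    drug: DrugProperties | str,
    population: str = "AD",
    parameters: tuple[str, ...] | None = None,
    scale_factors: tuple[float, ...] = (2.0, 10.0, 0.5, 0.1),
    ph_deltas: tuple[float, ...] = (1.0, 2.0, -1.0, -2.0),
    age: float = ELDERLY_AGE,
    plasma_model=None,
    regimen=None,
    points_per_interval: int = 361,
    rtol: float = 1e-7,
) -> pd.DataFrame:
    """OAT perturbation table, sorted by the largest absolute %change.

    One row per parameter x factor with the %change of every metric at
    brain ECF, brain ICF and subarachnoid CSF; skipped perturbations
    carry the violation message in the ``skipped`` column.
    """
    d = load_drug(drug) if isinstance(drug, str) else drug
    pops = population_physiologies(age=age)
    p_ref = pops.get(population)
    af = calibrated_factors(d, age=age)
    pm = plasma_model or load_plasma(d.name)
    reg = regimen or load_regimen(d.name)

    def run(p: PhysiologySet):
        model = build_model(p, d, af=af, calibrate=False)
        return run_to_steady_state(
            model, pm, reg, points_per_interval=points_per_interval, rtol=rtol
        )

    ref_metrics = _metric_row(run(p_ref))

    if parameters is None:
        parameters = SCALE_PARAMETERS + PH_PARAMETERS
    rows = []
    for name in parameters:
        factors = ph_deltas if name in PH_PARAMETERS else scale_factors
        for factor in factors:
            row: dict = {"parameter": name, "factor": factor, "skipped": None}
            try:
                p_new = _perturb(p_ref, name, factor)
            except (ValueError, TypeError) as exc:
                row["skipped"] = str(exc)
                rows.append(row)
                continue
            problems = validate_physiology(p_new)
            if problems:
                row["skipped"] = "; ".join(problems)
                rows.append(row)
                continue
            metrics = _metric_row(run(p_new))
            for key, ref_value in ref_metrics.items():
                row[f"pct_{key}"] = _pct(metrics[key], ref_value)
            rows.append(row)
    df = pd.DataFrame(rows)
    pct_cols = [c for c in df.columns if c.startswith("pct_")]
    df["max_abs_pct"] = df[pct_cols].abs().max(axis=1, skipna=True)
    return df.sort_values("max_abs_pct", ascending=False, ignore_index=True)
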