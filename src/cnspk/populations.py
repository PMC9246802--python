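"""Population translation: healthy young -> healthy elderly -> Alzheimer's.

The reference physiology describes a cognitively healthy young adult
(CHY).  Two translations are provided:

* :func:`apply_aging` turns a CHY set into a cognitively healthy elderly
  (CHE) set at a given age.  Yearly percentage rates compound
  multiplicatively from the onset of senescence (60 years by default):
  the brain shrinks at 0.401%/year while the ventricles (3.45%/year),
  cisterna magna (1.09%/year) and subarachnoid space (0.78%/year) expand;
  the phospholipid binding phase declines piecewise linearly (-10% over
  ages 60-80, a further -8% over 80-100); brain-ECF bulk flow falls by
  33% on top of atrophy; the BBB surface area is atrophy-corrected and
  reduced by 10%; intracellular pH drifts down 0.001 units/year.
  Normalised cerebral blood flow is age-invariant, so total CBF is
  recomputed on the shrunken brain, and the microvascular volume
  preserves the young microvasculature-to-CBF ratio.

* :func:`apply_ad` turns a CHE set into a mild Alzheimer's (AD) set using
  fold changes relative to the age-matched elderly: 5% lower brain
  volume, 40% higher ECF volume fraction, 10% lower phospholipid
  fraction, 39% larger ventricles, 21% larger extraventricular CSF, 15%
  lower normalised CBF and ECF bulk flow (both atrophy-corrected),
  atrophy-corrected BBB surface area increased by 11.23%, a 4.4-fold
  increase of BBB paracellular transport, unchanged BCSFB paracellular
  transport and CSF flow, and a +0.018 pH-unit shift of lumbar CSF.

The AD fold changes are CHE-relative and therefore not composable;
applying them twice raises.  Only mild AD is parameterised: moderate and
severe disease stages lack quantitative physiology and are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .physiology import PhysiologySet, validate_physiology

__all__ = [
    "AgingRates",
    "AdFoldChanges",
    "PopulationLabel",
    "apply_aging",
    "apply_ad",
    "build_population",
    "UnsupportedSeverityError",
]

SEVERITIES = ("questionable", "mild", "moderate", "severe")


class UnsupportedSeverityError(ValueError):
    """Requested an AD severity for which no physiology is parameterised."""


@dataclass(frozen=True)
class AgingRates:
    """Yearly rates and band totals of CNS aging past the onset age."""

    brain_shrinkage_rate: float = 0.401  # %/year
    ventricle_expansion_rate: float = 3.45  # %/year (lateral + 3rd/4th)
    cm_expansion_rate: float = 1.09  # %/year cisterna magna
    sas_expansion_rate: float = 0.78  # %/year subarachnoid space
    ecf_fraction_change: float = -16.0  # total % over senescence
    phospholipid_decline_60_80: float = 10.0  # % over ages 60-80
    phospholipid_decline_80_100: float = 8.0  # further % over ages 80-100
    ecf_bulk_flow_decline: float = 33.0  # % beyond atrophy
    bbb_sa_decline: float = 10.0  # % beyond atrophy
    icf_ph_drift: float = -0.001  # pH units/year (signed)
    onset_age: float = 60.0  # years
    compounding: bool = True  # False: linear accumulation of %/year rates

    def __post_init__(self) -> None:
        if self.onset_age < 0:
            raise ValueError("onset_age must be non-negative")


@dataclass(frozen=True)
class AdFoldChanges:
    """Mild-AD fold changes relative to age-matched healthy elderly."""

    brain_volume_factor: float = 0.95
    ecf_fraction_factor: float = 1.40
    phospholipid_factor: float = 0.90
    ventricle_factor: float = 1.39
    extraventricular_factor: float = 1.21
    cbf_norm_factor: float = 0.85
    ecf_bulk_flow_factor: float = 0.85
    bbb_sa_factor: float = 1.1123
    bbb_paracellular_factor: float = 4.4
    bcsfb_paracellular_factor: float = 1.0
    transporter_factors: Mapping[str, float] = field(default_factory=dict)
    lumbar_csf_ph_shift: float = 0.018  # pH units, added to CSF pH
    brain_ph_shift: float = 0.0  # ECF/ICF shift; reported range 0 to +0.009

    def __post_init__(self) -> None:
        for name in (
            "brain_volume_factor", "ecf_fraction_factor", "phospholipid_factor",
            "ventricle_factor", "extraventricular_factor", "cbf_norm_factor",
            "ecf_bulk_flow_factor", "bbb_sa_factor", "bbb_paracellular_factor",
            "bcsfb_paracellular_factor",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be a positive multiplier")

    @classmethod
    def identity(cls) -> "AdFoldChanges":
        """All-unity fold changes (no disease effect)."""
        return cls(
            brain_volume_factor=1, ecf_fraction_factor=1,
            phospholipid_factor=1, ventricle_factor=1,
            extraventricular_factor=1, cbf_norm_factor=1,
            ecf_bulk_flow_factor=1, bbb_sa_factor=1,
            bbb_paracellular_factor=1, bcsfb_paracellular_factor=1,
            lumbar_csf_ph_shift=0.0, brain_ph_shift=0.0,
        )


@dataclass(frozen=True)
class PopulationLabel:
    """Population selector: CHY, CHE or (mild) AD at a representative age."""

    population: str  # one of {"CHY", "CHE", "AD"}
    age: float = 70.0  # years
    severity: str | None = None  # for AD; defaults to "mild"

    def __post_init__(self) -> None:
        pop = self.population.upper()
        if pop not in ("CHY", "CHE", "AD"):
            raise ValueError(f"unknown population {self.population!r}")
        object.__setattr__(self, "population", pop)
        if pop == "AD" and self.severity is None:
            object.__setattr__(self, "severity", "mild")
        if self.severity is not None and self.severity not in SEVERITIES:
            raise ValueError(f"unknown AD severity {self.severity!r}")


def _compound(rate_percent_per_year: float, years: float,
              compounding: bool = True) -> float:
    """value(age)/value(onset): multiplicative compounding by default,
    with a linear alternative for comparison."""
    if compounding:
        return (1.0 + rate_percent_per_year / 100.0) ** years
    return max(1.0 + rate_percent_per_year / 100.0 * years, 0.0)


def _phospholipid_factor(age: float, r: AgingRates) -> float:
    """Piecewise-linear decline between the reported band endpoints."""
    lo = min(max(age - r.onset_age, 0.0), 20.0) / 20.0  # fraction of 60-80 band
    hi = min(max(age - (r.onset_age + 20.0), 0.0), 20.0) / 20.0
    f = 1.0 - (r.phospholipid_decline_60_80 / 100.0) * lo
    f *= 1.0 - (r.phospholipid_decline_80_100 / 100.0) * hi
    return f


def apply_aging(
    p: PhysiologySet, age: float, rates: AgingRates | None = None
) -> PhysiologySet:
    """Translate a CHY physiology to the healthy-elderly state at ``age``.

    Ages at or below the onset age return the input unchanged (no elapsed
    senescence).  Negative ages are a domain error.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative (got {age!r})")
    r = rates or AgingRates()
    if age <= r.onset_age:
        return p
    years = age - r.onset_age

    brain_volume = p.brain_volume * _compound(-r.brain_shrinkage_rate, years, r.compounding)
    atrophy = brain_volume / p.brain_volume
    f_ecf = p.f_ecf * (1.0 + r.ecf_fraction_change / 100.0)
    q_cbf_total = p.q_cbf_norm * (brain_volume * p.brain_density) / 100.0
    mv_ratio = p.v_microvasc / p.q_cbf_total  # preserved from the young state

    aged = p.with_(
        brain_volume=brain_volume,
        f_ecf=f_ecf,
        f_icf=1.0 - f_ecf,
        f_phospholipid=p.f_phospholipid * _phospholipid_factor(age, r),
        v_lv=p.v_lv * _compound(r.ventricle_expansion_rate, years, r.compounding),
        v_tfv=p.v_tfv * _compound(r.ventricle_expansion_rate, years, r.compounding),
        v_cm=p.v_cm * _compound(r.cm_expansion_rate, years, r.compounding),
        v_sas=p.v_sas * _compound(r.sas_expansion_rate, years, r.compounding),
        q_cbf_total=q_cbf_total,
        v_microvasc=mv_ratio * q_cbf_total,
        q_ecf_bulk=p.q_ecf_bulk * atrophy * (1.0 - r.ecf_bulk_flow_decline / 100.0),
        sa_bbb=p.sa_bbb * atrophy * (1.0 - r.bbb_sa_decline / 100.0),
        ph_icf=p.ph_icf + r.icf_ph_drift * years,
        label="CHE",
        age=age,
        provenance={**p.provenance, "_translation": f"aging to {age} y"},
    )
    problems = validate_physiology(aged)
    if problems:
        raise ValueError("aging produced invalid physiology: " + "; ".join(problems))
    return aged


def apply_ad(
    p: PhysiologySet, folds: AdFoldChanges | None = None
) -> PhysiologySet:
    """Translate an age-matched CHE physiology to mild AD.

    The fold changes are relative to the elderly state; applying them to a
    set already labelled AD raises, because the translation does not
    compose with itself.
    """
    if p.label == "AD":
        raise ValueError(
            "physiology is already an AD set; the CHE-relative fold changes "
            "are not composable"
        )
    f = folds or AdFoldChanges()

    f_ecf = p.f_ecf * f.ecf_fraction_factor
    if f_ecf >= 1.0:
        raise ValueError(
            f"AD ECF fraction {f_ecf:.3f} >= 1; fold change not applicable"
        )
    brain_volume = p.brain_volume * f.brain_volume_factor
    atrophy = brain_volume / p.brain_volume
    q_cbf_norm = p.q_cbf_norm * f.cbf_norm_factor
    q_cbf_total = q_cbf_norm * (brain_volume * p.brain_density) / 100.0
    mv_ratio = p.v_microvasc / p.q_cbf_total
    transporters = {
        k: v * f.transporter_factors.get(k, 1.0)
        for k, v in p.transporter_activity.items()
    }

    ad = p.with_(
        brain_volume=brain_volume,
        f_ecf=f_ecf,
        f_icf=1.0 - f_ecf,
        f_phospholipid=p.f_phospholipid * f.phospholipid_factor,
        v_lv=p.v_lv * f.ventricle_factor,
        v_tfv=p.v_tfv * f.ventricle_factor,
        v_cm=p.v_cm * f.extraventricular_factor,
        v_sas=p.v_sas * f.extraventricular_factor,
        q_cbf_norm=q_cbf_norm,
        q_cbf_total=q_cbf_total,
        v_microvasc=mv_ratio * q_cbf_total,
        q_ecf_bulk=p.q_ecf_bulk * f.ecf_bulk_flow_factor * atrophy,
        sa_bbb=p.sa_bbb * atrophy * f.bbb_sa_factor,
        f_paracellular_bbb=p.f_paracellular_bbb * f.bbb_paracellular_factor,
        f_paracellular_bcsfb=p.f_paracellular_bcsfb * f.bcsfb_paracellular_factor,
        transporter_activity=transporters,
        ph_ecf=p.ph_ecf + f.brain_ph_shift,
        ph_icf=p.ph_icf + f.brain_ph_shift,
        ph_csf=p.ph_csf + f.lumbar_csf_ph_shift,
        label="AD",
        provenance={**p.provenance, "_translation": "mild AD fold changes"},
    )
    problems = validate_physiology(ad)
    if problems:
        raise ValueError("AD translation produced invalid physiology: " + "; ".join(problems))
    return ad


def build_population(
    label: PopulationLabel | str,
    base: PhysiologySet | None = None,
    rates: AgingRates | None = None,
    folds: AdFoldChanges | None = None,
) -> PhysiologySet:
    """Dispatch identity / aging / aging + AD from a CHY base set."""
    from .physiology import default_physiology

    if isinstance(label, str):
        label = PopulationLabel(label)
    base = base or default_physiology()
    if label.population == "CHY":
        return base
    aged = apply_aging(base, label.age, rates)
    if aged is base:
        # no elapsed senescence; still relabel for clarity
        aged = base.with_(label="CHE", age=label.age)
    if label.population == "CHE":
        return aged
    if label.severity not in (None, "mild"):
        raise UnsupportedSeverityError(
            f"only mild AD is parameterised (requested {label.severity!r}); "
            "quantitative physiology for moderate/severe disease is unavailable"
        )
    return apply_ad(aged, folds)
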