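"""Drug parameter records, ionization arithmetic and partition conversions.

A :class:`DrugProperties` record holds the physicochemical and biological
inputs the CNS model needs for one small molecule: molecular weight,
lipophilicity (logP), the most acidic pKa and the pKa of the most basic
conjugate acid ("pKb"), unbound fractions in plasma and brain, the
unbound partition-coefficient targets at the three measurable interfaces
(Kpuu,BBB at brain ECF; Kpuu,LV at ventricular CSF; Kpuu,lumbar at the
lumbar sampling site), the unbound in-vitro IC50 of the drug's target,
and transporter annotations used for rat-to-human scaling of active
transport.

Ionization follows Henderson-Hasselbalch with at most one acidic and one
basic group; for an ampholyte the neutral fraction is the product of the
two monoprotic factors.

The shipped registry covers the five drugs studied in the Alzheimer's
use case: donepezil, galantamine and rivastigmine (cholinesterase
inhibitors), memantine (NMDA-receptor antagonist) and semagacestat
(gamma-secretase inhibitor).  Registry IC50 values are already on the
unbound scale as published; :func:`ic50_unbound` is a helper for new
drugs whose IC50 is reported on the total scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import pandas as pd

from .physiology import PhysiologySet

__all__ = [
    "DrugProperties",
    "fraction_neutral",
    "kp_to_kpuu",
    "scale_asymmetry_species",
    "load_drug",
    "registry_names",
    "registry_table",
    "ic50_unbound",
    "DrugLookupError",
]


class DrugLookupError(KeyError):
    """Requested drug is not in the shipped registry."""


@dataclass(frozen=True)
class DrugProperties:
    """Physicochemical and biological parameters of one drug."""

    name: str
    mw: float  # g/mol
    logp: float
    pka_acid: float | None  # most acidic pKa; None = no acidic group
    pka_base: float | None  # pKa of the conjugate acid of the most basic group
    fu_p: float  # unbound fraction in plasma
    fu_b: float  # unbound fraction in brain homogenate
    kpuu_bbb: float  # unbound brain-ECF : plasma target
    kpuu_lv: float  # unbound ventricular CSF : plasma target
    kpuu_lumbar: float  # unbound lumbar CSF : plasma target
    ic50: float  # ng/mL, unbound scale
    ic50_secondary: float | None = None  # ng/mL, secondary target if any
    target: str = ""
    target_secondary: str = ""
    kpuu_bbb_species: str = "human"  # species the Kpuu,BBB value comes from
    transporter_substrate: Mapping[str, bool] = field(default_factory=dict)
    species_scaling: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.mw > 0):
            raise ValueError("mw must be positive")
        for name in ("fu_p", "fu_b"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1] (got {v!r})")
        for name in ("kpuu_bbb", "kpuu_lv", "kpuu_lumbar", "ic50"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        for k, v in self.species_scaling.items():
            if not (v > 0):
                raise ValueError(f"species_scaling[{k!r}] must be positive")

    def with_(self, **changes: Any) -> "DrugProperties":
        return replace(self, **changes)


def fraction_neutral(ph: float, d: DrugProperties) -> float:
    """Neutral (un-ionized) fraction of the drug at the given pH.

    Henderson-Hasselbalch for monoprotic groups: a base is neutral with
    probability 1/(1+10^(pKb-pH)), an acid with 1/(1+10^(pH-pKa)); an
    ampholyte multiplies the two factors; a molecule without ionizable
    groups is fully neutral.
    """
    if not (0.0 <= ph <= 14.0):
        raise ValueError(f"pH outside [0, 14]: {ph!r}")
    f = 1.0
    if d.pka_base is not None:
        f *= 1.0 / (1.0 + 10.0 ** (d.pka_base - ph))
    if d.pka_acid is not None:
        f *= 1.0 / (1.0 + 10.0 ** (ph - d.pka_acid))
    return f


def kp_to_kpuu(kp_total: float, d: DrugProperties, p: PhysiologySet) -> float:
    """Convert a total brain:plasma ratio (Kp) to unbound Kpuu at the BBB.

    The total ratio is corrected for plasma protein binding (fu_p), brain
    tissue binding (fu_b) and the unequal distribution of the charged
    species between ECF and ICF at pH-partition equilibrium::

        Kpuu = Kp * (fu_b / fu_p) / D,
        D = f_ecf + f_icf * R,   R = fn(pH_ecf) / fn(pH_icf)

    where ``fn`` is the neutral fraction and ``R`` is the unbound ICF:ECF
    concentration ratio of the drug.
    """
    if not (kp_total > 0):
        raise ValueError("kp_total must be positive")
    if d.fu_b is None or d.fu_p is None:  # defensive; dataclass requires them
        raise ValueError("fu_b and fu_p are required for the Kp -> Kpuu conversion")
    r_icf_ecf = fraction_neutral(p.ph_ecf, d) / fraction_neutral(p.ph_icf, d)
    dilution = p.f_ecf + p.f_icf * r_icf_ecf
    return kp_total * (d.fu_b / d.fu_p) / dilution


def scale_asymmetry_species(
    af: float,
    direction: str,
    scaling: Mapping[str, float] | float,
) -> tuple[float, str]:
    """Scale a rat-derived asymmetry factor to human transporter expression.

    ``af`` is the directional magnitude (>= 1 by convention) and
    ``direction`` is ``"influx"`` or ``"efflux"``.  The magnitude is
    multiplied by the product of the applicable human:rat expression
    ratios; if it drops below 1 the direction flips and the magnitude is
    reciprocated, so that the returned factor is again >= 1.
    """
    if direction not in ("influx", "efflux"):
        raise ValueError(f"direction must be 'influx' or 'efflux' (got {direction!r})")
    if af < 1:
        raise ValueError("asymmetry factor magnitudes are reported >= 1")
    if isinstance(scaling, Mapping):
        product = 1.0
        for k, v in scaling.items():
            if not (v > 0):
                raise ValueError(f"non-positive expression ratio for {k!r}")
            product *= v
    else:
        product = float(scaling)
        if not (product > 0):
            raise ValueError("non-positive expression ratio")
    scaled = af * product
    if scaled >= 1.0:
        return scaled, direction
    flipped = "influx" if direction == "efflux" else "efflux"
    return 1.0 / scaled, flipped


def ic50_unbound(ic50_total: float, fu_b: float) -> float:
    """Correct a total-concentration IC50 for brain non-specific binding."""
    return ic50_total * fu_b


# ---------------------------------------------------------------------------
# Shipped registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, dict[str, Any]] = {
    "donepezil": dict(
        mw=379.49, logp=4.14, pka_acid=17.02, pka_base=8.62,
        fu_p=0.07, fu_b=0.107,
        kpuu_bbb=0.482, kpuu_lv=1.8, kpuu_lumbar=1.8,
        ic50=0.57, target="acetylcholinesterase",
        kpuu_bbb_species="rat",
        transporter_substrate={"pgp": True, "bcrp": True, "cht": True},
        # human:rat brain-microvessel expression ratios of the transporters
        # the drug is a substrate of (P-gp 0.22, BCRP 1.1)
        species_scaling={"pgp": 0.22, "bcrp": 1.1},
    ),
    "galantamine": dict(
        mw=287.35, logp=1.16, pka_acid=14.81, pka_base=8.58,
        fu_p=0.83, fu_b=0.333,
        kpuu_bbb=0.826, kpuu_lv=1.2, kpuu_lumbar=1.2,
        ic50=55.0, target="acetylcholinesterase",
        kpuu_bbb_species="human",
        transporter_substrate={},
        species_scaling={},
    ),
    "memantine": dict(
        mw=179.3, logp=3.31, pka_acid=None, pka_base=10.7,
        fu_p=0.55, fu_b=0.071,
        kpuu_bbb=2.0, kpuu_lv=0.89, kpuu_lumbar=0.89,
        ic50=109.0, target="NMDA receptor",
        # rat Kpuu; human brain:plasma ratios are similar, so the
        # expression scaling is unity
        kpuu_bbb_species="rat",
        transporter_substrate={"octn1": True},
        species_scaling={},
    ),
    "rivastigmine": dict(
        mw=250.3, logp=2.45, pka_acid=None, pka_base=8.89,
        fu_p=0.6, fu_b=0.376,
        kpuu_bbb=0.733, kpuu_lv=0.663, kpuu_lumbar=0.663,
        ic50=857.2, target="acetylcholinesterase",
        ic50_secondary=9.3, target_secondary="butyrylcholinesterase",
        kpuu_bbb_species="human",
        transporter_substrate={"cht": True},
        species_scaling={},
    ),
    "semagacestat": dict(
        mw=361.4, logp=0.44, pka_acid=11.91, pka_base=-3.7,
        fu_p=0.382, fu_b=0.413,
        kpuu_bbb=0.55,  # assumed equal to Kpuu,lumbar
        kpuu_lv=0.55, kpuu_lumbar=0.55,
        ic50=5.4, target="gamma-secretase",
        kpuu_bbb_species="human",
        transporter_substrate={},
        species_scaling={},
    ),
}


def registry_names() -> list[str]:
    """Names of the drugs shipped with the package."""
    return sorted(_REGISTRY)


def load_drug(name_or_config: str | Mapping[str, Any]) -> DrugProperties:
    """Load a drug record from the shipped registry or a full config.

    Raises
    ------
    DrugLookupError
        If a name is given that is not in the registry.
    """
    if isinstance(name_or_config, str):
        key = name_or_config.lower()
        if key not in _REGISTRY:
            raise DrugLookupError(
                f"unknown drug {name_or_config!r}; shipped registry: "
                f"{', '.join(registry_names())}"
            )
        return DrugProperties(name=key, **_REGISTRY[key])
    config = dict(name_or_config.get("drug", name_or_config))
    name = config.pop("name", None)
    if name is None:
        raise ValueError("drug config requires a 'name' field")
    if not config and name.lower() in _REGISTRY:
        return load_drug(name)
    return DrugProperties(name=name, **config)


def registry_table() -> pd.DataFrame:
    """The shipped registry as a flat table (one row per drug)."""
    rows = []
    for name in registry_names():
        d = load_drug(name)
        rows.append(
            dict(
                name=d.name, mw=d.mw, logp=d.logp, pka_acid=d.pka_acid,
                pka_base=d.pka_base, fu_p=d.fu_p, fu_b=d.fu_b,
                kpuu_bbb=d.kpuu_bbb, kpuu_lv=d.kpuu_lv,
                kpuu_lumbar=d.kpuu_lumbar, ic50_ng_per_ml=d.ic50,
                target=d.target, kpuu_bbb_species=d.kpuu_bbb_species,
            )
        )
    return pd.DataFrame(rows)
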