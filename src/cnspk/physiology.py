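"""CNS physiological parameter sets.

A :class:`PhysiologySet` collects the anatomical and physiological
quantities that govern small-molecule distribution in the human CNS:
compartment volumes (brain tissue, microvascular blood, the four CSF
spaces), fluid flows (cerebral blood flow, brain-ECF bulk flow, CSF
production), barrier surface areas (BBB, BCSFB), membrane-integrity
multipliers, transporter activities and compartment pH values.

All internal units are fixed: volumes in mL, flows in mL/min, surface
areas in cm2, masses in g, pH in pH units.  Converters, if any, belong at
the I/O boundary.

The shipped default describes a cognitively healthy young adult (CHY).
The two fractions printed for healthy brain tissue are 0.2 (extracellular)
and 0.8 (intracellular), and the phospholipid binding phase is 5% of brain
volume; the remaining defaults are standard adult human values from the
physiology literature and every field carries a provenance label so that
users can audit or override them field by field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

__all__ = [
    "PhysiologySet",
    "FIELD_UNITS",
    "default_physiology",
    "load_physiology",
    "validate_physiology",
    "physiology_to_config",
    "save_physiology",
    "physiology_table",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """A structured configuration is missing or malformed."""


#: units of every numeric PhysiologySet field (for table export)
FIELD_UNITS: dict[str, str] = {
    "brain_volume": "mL",
    "f_ecf": "-",
    "f_icf": "-",
    "v_microvasc": "mL",
    "f_phospholipid": "-",
    "v_lysosome": "mL",
    "v_lv": "mL",
    "v_tfv": "mL",
    "v_cm": "mL",
    "v_sas": "mL",
    "q_cbf_norm": "mL/min/100g",
    "q_cbf_total": "mL/min",
    "q_ecf_bulk": "mL/min",
    "q_csf": "mL/min",
    "sa_bbb": "cm2",
    "sa_bcsfb": "cm2",
    "f_bcsfb_lv": "-",
    "f_paracellular_bbb": "-",
    "f_paracellular_bcsfb": "-",
    "ph_plasma": "pH",
    "ph_ecf": "pH",
    "ph_icf": "pH",
    "ph_lyso": "pH",
    "ph_csf": "pH",
    "brain_density": "g/mL",
}


@dataclass(frozen=True)
class PhysiologySet:
    """Complete CNS physiological parameter vector for one population.

    The set is immutable; population translations return new instances.
    ``label`` records the population the values describe (``CHY``,
    ``CHE`` or ``AD``) and ``age`` the representative age in years.
    """

    # volumes and composition
    brain_volume: float  # mL total brain tissue
    f_ecf: float  # extracellular fraction of brain volume
    f_icf: float  # intracellular fraction of brain volume
    v_microvasc: float  # mL brain microvascular blood
    f_phospholipid: float  # phospholipid (binding phase) fraction of brain
    v_lysosome: float  # mL
    v_lv: float  # mL lateral ventricles
    v_tfv: float  # mL third + fourth ventricle
    v_cm: float  # mL cisterna magna
    v_sas: float  # mL subarachnoid space incl. lumbar CSF
    # flows
    q_cbf_norm: float  # mL/min/100 g brain
    q_cbf_total: float  # mL/min
    q_ecf_bulk: float  # mL/min brain-ECF bulk flow
    q_csf: float  # mL/min CSF production (constant along the CSF chain)
    # barriers
    sa_bbb: float  # cm2
    sa_bcsfb: float  # cm2 total; split between LV- and TFV-facing portions
    f_bcsfb_lv: float  # fraction of sa_bcsfb facing the lateral ventricles
    f_paracellular_bbb: float  # multiplier on BBB paracellular clearance
    f_paracellular_bcsfb: float  # multiplier on BCSFB paracellular clearance
    # transporters
    transporter_activity: Mapping[str, float]  # relative activity, 1 = CHY
    # pH
    ph_plasma: float
    ph_ecf: float
    ph_icf: float
    ph_lyso: float
    ph_csf: float
    # conversions
    brain_density: float  # g/mL
    # metadata
    label: str = "CHY"
    age: float = 35.0  # years
    provenance: Mapping[str, str] = field(default_factory=dict, compare=False)

    @property
    def brain_mass(self) -> float:
        """Brain mass in g."""
        return self.brain_volume * self.brain_density

    @property
    def v_ecf(self) -> float:
        return self.f_ecf * self.brain_volume

    @property
    def v_icf(self) -> float:
        return self.f_icf * self.brain_volume

    def with_(self, **changes: Any) -> "PhysiologySet":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


# Default CHY parameter values with per-field provenance.  Values printed
# in the primary literature for healthy tissue composition are labelled
# "literature-primary"; the remainder are standard adult human physiology
# ("literature-default") and fully overridable.
_CHY_DEFAULTS: dict[str, Any] = {
    "brain_volume": 1400.0,  # adult brain ~1.4 L
    "f_ecf": 0.2,
    "f_icf": 0.8,
    "v_microvasc": 35.0,  # ~2.5% of brain volume
    "f_phospholipid": 0.05,
    "v_lysosome": 11.2,  # ~1% of cellular volume
    "v_lv": 22.5,
    "v_tfv": 7.5,
    "v_cm": 7.5,
    "v_sas": 175.0,  # cranial + spinal subarachnoid CSF incl. lumbar
    "q_cbf_norm": 48.0,  # mL/min/100 g, stable in healthy adults
    "q_cbf_total": 48.0 * 1400.0 * 1.045 / 100.0,  # 702.24 mL/min
    "q_ecf_bulk": 0.2,
    "q_csf": 0.35,  # ~500 mL/day
    "sa_bbb": 150_000.0,  # ~15 m2
    "sa_bcsfb": 75_000.0,  # ~half of the BBB area
    "f_bcsfb_lv": 0.5,
    "f_paracellular_bbb": 1.0,
    "f_paracellular_bcsfb": 1.0,
    "transporter_activity": {"pgp": 1.0, "bcrp": 1.0, "cht": 1.0, "octn1": 1.0},
    "ph_plasma": 7.4,
    "ph_ecf": 7.3,
    "ph_icf": 7.0,
    "ph_lyso": 5.0,
    "ph_csf": 7.3,
    "brain_density": 1.045,
    "label": "CHY",
    "age": 35.0,
}

_CHY_PROVENANCE: dict[str, str] = {
    "brain_volume": "literature-default",
    "f_ecf": "literature-primary",
    "f_icf": "literature-primary",
    "v_microvasc": "literature-default",
    "f_phospholipid": "literature-primary",
    "v_lysosome": "literature-default",
    "v_lv": "literature-default",
    "v_tfv": "literature-default",
    "v_cm": "literature-default",
    "v_sas": "literature-default",
    "q_cbf_norm": "literature-default",
    "q_cbf_total": "derived: q_cbf_norm x brain_mass / 100",
    "q_ecf_bulk": "literature-default",
    "q_csf": "literature-default",
    "sa_bbb": "literature-default",
    "sa_bcsfb": "literature-default",
    "f_bcsfb_lv": "package-default",
    "f_paracellular_bbb": "reference = 1",
    "f_paracellular_bcsfb": "reference = 1",
    "transporter_activity": "reference = 1",
    "ph_plasma": "standard physiology",
    "ph_ecf": "standard physiology",
    "ph_icf": "standard physiology",
    "ph_lyso": "standard physiology",
    "ph_csf": "standard physiology",
    "brain_density": "literature-default",
}

_REQUIRED_FIELDS = [
    f.name
    for f in dataclasses.fields(PhysiologySet)
    if f.name not in ("label", "age", "provenance")
]


def default_physiology() -> PhysiologySet:
    """The shipped cognitively-healthy-young (CHY) parameter set."""
    return PhysiologySet(provenance=dict(_CHY_PROVENANCE), **_CHY_DEFAULTS)


def validate_physiology(p: PhysiologySet) -> list[str]:
    """Check all physiological invariants; return the list of violations.

    Reporting only -- the input is never mutated and no exception is
    raised.  An empty list means the set is internally consistent.
    """
    problems: list[str] = []
    positive = [
        "brain_volume", "v_microvasc", "v_lysosome", "v_lv", "v_tfv",
        "v_cm", "v_sas", "q_cbf_norm", "q_cbf_total", "q_ecf_bulk",
        "q_csf", "sa_bbb", "sa_bcsfb", "brain_density",
    ]
    for name in positive:
        v = getattr(p, name)
        if not (v > 0):
            problems.append(f"{name} must be strictly positive (got {v!r})")
    for name in ("f_paracellular_bbb", "f_paracellular_bcsfb"):
        if not (getattr(p, name) > 0):
            problems.append(f"{name} must be strictly positive")
    if not (0 < p.f_ecf < 1):
        problems.append(f"f_ecf must lie in (0, 1) (got {p.f_ecf!r})")
    if not (0 < p.f_phospholipid < 1):
        problems.append("f_phospholipid must lie in (0, 1)")
    if not (0 < p.f_bcsfb_lv < 1):
        problems.append("f_bcsfb_lv must lie in (0, 1)")
    if abs(p.f_ecf + p.f_icf - 1.0) > 1e-9:
        problems.append(
            "brain ECF and ICF volume fractions do not sum to 1 "
            f"(f_ecf={p.f_ecf!r}, f_icf={p.f_icf!r})"
        )
    for name in ("ph_plasma", "ph_ecf", "ph_icf", "ph_lyso", "ph_csf"):
        v = getattr(p, name)
        if not (4.0 <= v <= 9.0):
            problems.append(f"{name} outside the physiological range [4, 9]")
    expected_cbf = p.q_cbf_norm * p.brain_mass / 100.0
    if abs(p.q_cbf_total - expected_cbf) > 1e-3 * expected_cbf:
        problems.append(
            "q_cbf_total inconsistent with q_cbf_norm x brain_mass/100 "
            f"({p.q_cbf_total:.4g} vs {expected_cbf:.4g})"
        )
    for k, v in p.transporter_activity.items():
        if not (v > 0):
            problems.append(f"transporter_activity[{k!r}] must be positive")
    return problems


def _coerce_config(config: Mapping[str, Any]) -> dict[str, Any]:
    section = config.get("physiology", config)
    if not isinstance(section, Mapping):
        raise ConfigurationError("[physiology] section is not a mapping")
    return dict(section)


def load_physiology(config: str | Path | Mapping[str, Any] | None = None) -> PhysiologySet:
    """Load and validate a :class:`PhysiologySet`.

    Parameters
    ----------
    config
        ``None`` for the shipped CHY defaults, a mapping (optionally with a
        ``physiology`` section), or a path to a YAML file.  Fields not
        present in the config fall back to the CHY defaults and are
        labelled accordingly in the provenance map.

    Raises
    ------
    ConfigurationError
        If a required field is missing or the file is malformed.
    ValueError
        If the resulting set violates a physiological invariant.
    """
    if config is None:
        return default_physiology()
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raise ConfigurationError(f"empty configuration file: {config}")
        values = _coerce_config(raw)
    else:
        values = _coerce_config(config)

    provenance = dict(values.pop("provenance", {}))
    merged = dict(_CHY_DEFAULTS)
    unknown = set(values) - set(merged)
    if unknown:
        raise ConfigurationError(
            f"unknown physiology field(s): {sorted(unknown)}"
        )
    for name, v in values.items():
        merged[name] = v
        provenance.setdefault(name, "user-config")
    for name in _REQUIRED_FIELDS:
        if merged.get(name) is None:
            raise ConfigurationError(f"missing required physiology field: {name}")
        provenance.setdefault(name, _CHY_PROVENANCE.get(name, "package-default"))

    p = PhysiologySet(provenance=provenance, **merged)
    problems = validate_physiology(p)
    if problems:
        raise ValueError("invalid physiology: " + "; ".join(problems))
    return p


def physiology_to_config(p: PhysiologySet) -> dict[str, Any]:
    """Serialise a set into the nested-mapping config dialect."""
    body = {
        name: getattr(p, name)
        for name in _REQUIRED_FIELDS + ["label", "age"]
    }
    body["transporter_activity"] = dict(p.transporter_activity)
    body["provenance"] = dict(p.provenance)
    return {"physiology": body}


def save_physiology(p: PhysiologySet, path: str | Path) -> None:
    """Write a set to a YAML file that :func:`load_physiology` can reload."""
    with open(path, "w") as fh:
        yaml.safe_dump(physiology_to_config(p), fh, sort_keys=True)


def physiology_table(p: PhysiologySet) -> pd.DataFrame:
    """Tabulate the parameter set as name/value/units/provenance rows."""
    rows = []
    for name in _REQUIRED_FIELDS:
        value = getattr(p, name)
        if isinstance(value, Mapping):
            for k, v in value.items():
                rows.append(
                    (f"{name}.{k}", v, "-", p.provenance.get(name, ""))
                )
            continue
        rows.append(
            (name, value, FIELD_UNITS.get(name, ""), p.provenance.get(name, ""))
        )
    return pd.DataFrame(rows, columns=["name", "value", "units", "provenance"])
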