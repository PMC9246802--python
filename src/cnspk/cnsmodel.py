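"""The 9-compartment CNS distribution model.

States are drug amounts (ng) in eight CNS compartments -- microvascular
blood, brain ECF, brain ICF, lysosomes, and the four CSF spaces (lateral
ventricles, third+fourth ventricle, cisterna magna, subarachnoid space)
-- driven by the unbound plasma concentration as a forcing function (the
ninth, plasma, compartment).  The system is linear; every transport
route is a clearance (mL/min) acting on unbound concentrations:

* **Paracellular** diffusion across the BBB and BCSFB: symmetric,
  carried by both ionized and neutral species, with an aqueous-diffusion
  molecular-weight scaling ``P_para ~ mw**(-1/3)`` and the population's
  barrier-integrity multiplier.
* **Transcellular** diffusion across barriers and cell membranes:
  carried by the neutral species only (pH-partition hypothesis), with a
  log-linear lipophilicity/size permeability map
  ``log10 P_trans = a + b*logP - c*log10(mw/mw_ref)``.
* **Active transport** at the BBB and BCSFB: directional asymmetry
  factors (AF >= 1) multiplying the influx or efflux transcellular
  clearance, calibrated by root finding so that the steady-state unbound
  compartment:plasma ratio under a constant infusion reproduces the
  drug's Kpuu target.
* **Fluid flows**: cerebral blood flow between plasma and the
  microvascular compartment; brain-ECF bulk flow draining to the CSF;
  CSF production flowing along LV -> TFV -> CM -> SAS and leaving to
  venous blood (the CSF sink), which is the only irreversible CNS
  elimination route.
* **Tissue binding**: instantaneous equilibrium binding to brain
  phospholipids enlarges the apparent intracellular volume; the binding
  capacity is derived from the brain unbound fraction and rescales in
  proportion to the population's phospholipid fraction.

The exact permeability coefficients are package design parameters (kept
in :class:`ModelOptions`); the asymmetry-factor calibration absorbs
barrier-level error by construction, so steady-state compartment ratios
are robust to the map while absolute equilibration rates are sensitive
to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .drugs import DrugProperties, fraction_neutral, scale_asymmetry_species
from .physiology import PhysiologySet, validate_physiology
from .plasma import ConcProfile, PlasmaSolution

__all__ = [
    "COMPARTMENTS",
    "ModelOptions",
    "AsymmetryFactors",
    "CnsModel",
    "passive_clearances",
    "calibrate_af",
    "build_model",
    "simulate_cns",
    "steady_state_ratios",
    "CalibrationError",
]

#: CNS state compartments, in state-vector order
COMPARTMENTS = (
    "microvascular",
    "brain_ecf",
    "brain_icf",
    "lysosome",
    "csf_lv",
    "csf_tfv",
    "csf_cm",
    "csf_sas",
)
_IDX = {name: i for i, name in enumerate(COMPARTMENTS)}

#: phospholipid volume fraction at which brain unbound fractions are measured
PHOSPHOLIPID_REF = 0.05


class CalibrationError(RuntimeError):
    """An asymmetry-factor target is unreachable within the allowed range."""


@dataclass(frozen=True)
class ModelOptions:
    """Numerical and structural choices of the assembled ODE system."""

    # transcellular permeability map, cm/min:
    # log10 P = intercept + logp_slope*logP - mw_exp*log10(mw/mw_ref)
    p_trans_intercept: float = -3.9
    p_trans_logp_slope: float = 0.35
    p_trans_mw_exp: float = 1.0
    mw_ref: float = 350.0
    # paracellular permeability at the reference molecular weight, cm/min;
    # anchored to the brain uptake clearance of paracellular markers
    # (sucrose/mannitol scale, ~0.5 mL/min per brain at the healthy BBB)
    p_para_ref: float = 3.0e-6
    # effective exchange areas of brain cell and lysosomal membranes,
    # cm2 per mL of brain tissue
    mem_area_per_ml: float = 1070.0
    lyso_area_per_ml: float = 107.0
    # routing of brain-ECF bulk flow into the CSF chain
    bulk_flow_route: str = "csf_cm"  # one of {"csf_lv", "csf_cm", "csf_sas"}
    # asymmetry-factor calibration
    af_max: float = 1.0e6
    af_tol: float = 1.0e-3  # relative tolerance on the Kpuu target

    def __post_init__(self) -> None:
        if self.bulk_flow_route not in ("csf_lv", "csf_cm", "csf_sas"):
            raise ValueError(f"unknown bulk flow route {self.bulk_flow_route!r}")


@dataclass(frozen=True)
class AsymmetryFactors:
    """Directional active-transport multipliers per barrier (all >= 1)."""

    af_in_ecf: float = 1.0
    af_ef_ecf: float = 1.0
    af_in_lv: float = 1.0
    af_ef_lv: float = 1.0
    af_in_tfv: float = 1.0
    af_ef_tfv: float = 1.0

    def __post_init__(self) -> None:
        for barrier in ("ecf", "lv", "tfv"):
            a_in = getattr(self, f"af_in_{barrier}")
            a_ef = getattr(self, f"af_ef_{barrier}")
            if a_in < 1 or a_ef < 1:
                raise ValueError("asymmetry factors are reported >= 1")
            if a_in > 1 + 1e-12 and a_ef > 1 + 1e-12:
                raise ValueError(
                    f"at most one direction may exceed 1 at barrier {barrier!r}"
                )


def p_transcellular(d: DrugProperties, opt: ModelOptions) -> float:
    """Transcellular permeability of the neutral species, cm/min."""
    log10p = (
        opt.p_trans_intercept
        + opt.p_trans_logp_slope * d.logp
        - opt.p_trans_mw_exp * math.log10(d.mw / opt.mw_ref)
    )
    return 10.0 ** log10p


def p_paracellular(d: DrugProperties, opt: ModelOptions) -> float:
    """Paracellular (aqueous pore) permeability, cm/min; ~ mw**(-1/3)."""
    return opt.p_para_ref * (opt.mw_ref / d.mw) ** (1.0 / 3.0)


def passive_clearances(
    p: PhysiologySet, d: DrugProperties, opt: ModelOptions | None = None
) -> dict[str, float]:
    """Passive clearance terms (mL/min) of every transport route.

    Transcellular entries are *potential* clearances P_trans x SA; the
    neutral-fraction weight of the donor side and any asymmetry factor
    are applied when the mass-balance matrix is assembled.
    """
    opt = opt or ModelOptions()
    pt = p_transcellular(d, opt)
    pp = p_paracellular(d, opt)
    sa_lv = p.sa_bcsfb * p.f_bcsfb_lv
    sa_tfv = p.sa_bcsfb * (1.0 - p.f_bcsfb_lv)
    return {
        "cl_para_bbb": p.f_paracellular_bbb * pp * p.sa_bbb,
        "cl_trans_bbb": pt * p.sa_bbb,
        "cl_para_bcsfb_lv": p.f_paracellular_bcsfb * pp * sa_lv,
        "cl_trans_bcsfb_lv": pt * sa_lv,
        "cl_para_bcsfb_tfv": p.f_paracellular_bcsfb * pp * sa_tfv,
        "cl_trans_bcsfb_tfv": pt * sa_tfv,
        "cl_mem_ecf_icf": pt * opt.mem_area_per_ml * p.brain_volume,
        "cl_mem_icf_lyso": pt * opt.lyso_area_per_ml * p.brain_volume,
    }


@dataclass(frozen=True)
class CnsModel:
    """Assembled linear CNS system for one drug and one physiology."""

    physiology: PhysiologySet
    drug: DrugProperties
    options: ModelOptions
    af: AsymmetryFactors
    vapp: np.ndarray  # apparent volumes per compartment, mL
    matrix: np.ndarray  # 8x8 generator acting on amounts (via Cu = A/Vapp)
    input_clearance: float  # mL/min from plasma into the microvascular state

    def rhs(self, cp_of_t: Callable[[float], float]) -> Callable:
        M = self.matrix
        b = np.zeros(len(COMPARTMENTS))

        def f(t: float, y: np.ndarray) -> np.ndarray:
            b[0] = self.input_clearance * cp_of_t(t)
            return M @ y + b

        return f

    def unbound(self, amounts: np.ndarray) -> np.ndarray:
        """Convert amounts (ng) to unbound concentrations (ng/mL)."""
        return amounts / self.vapp

    def clearance_table(self) -> pd.DataFrame:
        """Inspectable table of every nonzero inter-compartment clearance."""
        rows = []
        for i, src in enumerate(COMPARTMENTS):
            for j, dst in enumerate(COMPARTMENTS):
                if i == j:
                    continue
                cl = self.matrix[j, i] * self.vapp[i]
                if cl != 0.0:
                    rows.append((src, dst, cl))
            out_total = -self.matrix[i, i] * self.vapp[i]
            to_others = sum(r[2] for r in rows if r[0] == src)
            sink = out_total - to_others
            if sink > 1e-12 * max(out_total, 1.0):
                rows.append((src, "outside_cns", sink))
        return pd.DataFrame(rows, columns=["from", "to", "cl_ml_per_min"])


def _apparent_volumes(p: PhysiologySet, d: DrugProperties) -> np.ndarray:
    """Apparent distribution volume per compartment (mL of unbound conc).

    Tissue binding: the brain-homogenate unbound fraction fu_b defines a
    binding capacity (1/fu_b - 1) referenced to the healthy phospholipid
    fraction; the bound pool sits in the intracellular compartment and
    scales with the population's phospholipid fraction.
    """
    k_bind = (1.0 / d.fu_b - 1.0) * (p.f_phospholipid / PHOSPHOLIPID_REF)
    v = np.empty(len(COMPARTMENTS))
    v[_IDX["microvascular"]] = p.v_microvasc
    v[_IDX["brain_ecf"]] = p.v_ecf
    v[_IDX["brain_icf"]] = p.v_icf + k_bind * p.brain_volume
    v[_IDX["lysosome"]] = p.v_lysosome
    v[_IDX["csf_lv"]] = p.v_lv
    v[_IDX["csf_tfv"]] = p.v_tfv
    v[_IDX["csf_cm"]] = p.v_cm
    v[_IDX["csf_sas"]] = p.v_sas
    return v


def _assemble_matrix(
    p: PhysiologySet,
    d: DrugProperties,
    opt: ModelOptions,
    af: AsymmetryFactors,
    closed_system: bool = False,
) -> tuple[np.ndarray, float]:
    """Mass-balance generator M (on amounts) and the plasma input clearance.

    ``closed_system=True`` removes the plasma exchange and the CSF sink,
    yielding a conservative system used for mass-balance verification.
    """
    n = len(COMPARTMENTS)
    vapp = _apparent_volumes(p, d)
    cl = passive_clearances(p, d, opt)
    fn = {
        "plasma": fraction_neutral(p.ph_plasma, d),
        "ecf": fraction_neutral(p.ph_ecf, d),
        "icf": fraction_neutral(p.ph_icf, d),
        "lyso": fraction_neutral(p.ph_lyso, d),
        "csf": fraction_neutral(p.ph_csf, d),
    }
    M = np.zeros((n, n))

    def add(src: str, dst: str, clearance: float) -> None:
        i, j = _IDX[src], _IDX[dst]
        M[i, i] -= clearance / vapp[i]
        M[j, i] += clearance / vapp[i]

    def remove(src: str, clearance: float) -> None:
        i = _IDX[src]
        M[i, i] -= clearance / vapp[i]

    # BBB: microvascular blood <-> brain ECF
    add("microvascular", "brain_ecf", cl["cl_para_bbb"])
    add("brain_ecf", "microvascular", cl["cl_para_bbb"])
    add("microvascular", "brain_ecf", cl["cl_trans_bbb"] * fn["plasma"] * af.af_in_ecf)
    add("brain_ecf", "microvascular", cl["cl_trans_bbb"] * fn["ecf"] * af.af_ef_ecf)

    # BCSFB: microvascular blood <-> ventricular CSF
    for csf, tag, a_in, a_ef in (
        ("csf_lv", "lv", af.af_in_lv, af.af_ef_lv),
        ("csf_tfv", "tfv", af.af_in_tfv, af.af_ef_tfv),
    ):
        add("microvascular", csf, cl[f"cl_para_bcsfb_{tag}"])
        add(csf, "microvascular", cl[f"cl_para_bcsfb_{tag}"])
        add("microvascular", csf, cl[f"cl_trans_bcsfb_{tag}"] * fn["plasma"] * a_in)
        add(csf, "microvascular", cl[f"cl_trans_bcsfb_{tag}"] * fn["csf"] * a_ef)

    # brain cell membrane: ECF <-> ICF (neutral species)
    add("brain_ecf", "brain_icf", cl["cl_mem_ecf_icf"] * fn["ecf"])
    add("brain_icf", "brain_ecf", cl["cl_mem_ecf_icf"] * fn["icf"])
    # lysosomal membrane: ICF <-> lysosome
    add("brain_icf", "lysosome", cl["cl_mem_icf_lyso"] * fn["icf"])
    add("lysosome", "brain_icf", cl["cl_mem_icf_lyso"] * fn["lyso"])

    # brain-ECF bulk flow into the CSF chain
    add("brain_ecf", opt.bulk_flow_route, p.q_ecf_bulk)
    # CSF flow: production at LV, chain to SAS, sink to venous blood
    q = p.q_csf
    chain = ["csf_lv", "csf_tfv", "csf_cm", "csf_sas"]
    carried = {name: q for name in chain}
    # bulk flow joins the chain at its routing point and is carried along
    route_idx = chain.index(opt.bulk_flow_route) if opt.bulk_flow_route in chain else None
    if route_idx is not None:
        for name in chain[route_idx:]:
            carried[name] += p.q_ecf_bulk
    for up, down in zip(chain[:-1], chain[1:]):
        add(up, down, carried[up])
    if not closed_system:
        remove("csf_sas", carried["csf_sas"])  # absorption to venous blood

    # cerebral blood flow: plasma <-> microvascular blood
    input_clearance = p.q_cbf_total
    if not closed_system:
        remove("microvascular", p.q_cbf_total)
    else:
        input_clearance = 0.0
    return M, input_clearance


def _build(
    p: PhysiologySet,
    d: DrugProperties,
    opt: ModelOptions,
    af: AsymmetryFactors,
    closed_system: bool = False,
) -> CnsModel:
    M, input_cl = _assemble_matrix(p, d, opt, af, closed_system=closed_system)
    return CnsModel(
        physiology=p, drug=d, options=opt, af=af,
        vapp=_apparent_volumes(p, d), matrix=M, input_clearance=input_cl,
    )


def steady_state_ratios(model: CnsModel, cp: float = 1.0) -> dict[str, float]:
    """Unbound compartment:plasma ratios under a constant plasma infusion.

    Solves the linear steady state ``M A = -b`` directly; no time
    integration is involved.
    """
    b = np.zeros(len(COMPARTMENTS))
    b[0] = model.input_clearance * cp
    amounts = np.linalg.solve(model.matrix, -b)
    cu = model.unbound(amounts)
    return {name: cu[i] / cp for i, name in enumerate(COMPARTMENTS)}


# barrier -> (AF field stem, compartment whose steady-state ratio is targeted)
_BARRIER_TARGETS = {
    "bbb": ("ecf", "brain_ecf"),
    "bcsfb_lv": ("lv", "csf_lv"),
    # the lumbar Kpuu is measured at the sampling site (subarachnoid CSF);
    # the calibrated factor sits at the TFV-facing barrier upstream of it
    "bcsfb_tfv": ("tfv", "csf_sas"),
}


def _af_from_x(x: float) -> tuple[float, float]:
    """Signed log parametrisation -> (af_in, af_ef), both >= 1."""
    if x >= 0:
        return math.exp(x), 1.0
    return 1.0, math.exp(-x)


def calibrate_af(
    p: PhysiologySet,
    d: DrugProperties,
    barrier: str,
    kpuu_target: float,
    af: AsymmetryFactors | None = None,
    opt: ModelOptions | None = None,
) -> AsymmetryFactors:
    """Calibrate the directional asymmetry factor of one barrier.

    Finds the AF such that, under a constant unit unbound plasma
    infusion, the steady-state unbound concentration ratio of the
    barrier's target compartment equals ``kpuu_target``.  Other barriers'
    factors are taken from ``af`` and held fixed.

    Raises
    ------
    CalibrationError
        If the target is unreachable with AF <= ``opt.af_max``; the
        message reports the achievable range.
    """
    if kpuu_target <= 0:
        raise ValueError("kpuu_target must be positive")
    if barrier not in _BARRIER_TARGETS:
        raise ValueError(f"unknown barrier {barrier!r}; use one of {sorted(_BARRIER_TARGETS)}")
    opt = opt or ModelOptions()
    af = af or AsymmetryFactors()
    stem, compartment = _BARRIER_TARGETS[barrier]

    def ratio_at(x: float) -> float:
        a_in, a_ef = _af_from_x(x)
        trial = replace(af, **{f"af_in_{stem}": a_in, f"af_ef_{stem}": a_ef})
        model = _build(p, d, opt, trial)
        return steady_state_ratios(model)[compartment]

    xmax = math.log(opt.af_max)
    resid = lambda x: ratio_at(x) - kpuu_target  # noqa: E731
    r_lo, r_hi = resid(-xmax), resid(xmax)
    if not (r_lo <= 0.0 <= r_hi):
        lo, hi = ratio_at(-xmax), ratio_at(xmax)
        raise CalibrationError(
            f"Kpuu target {kpuu_target:g} at barrier {barrier!r} is outside the "
            f"achievable steady-state range [{lo:.3g}, {hi:.3g}] for AF <= {opt.af_max:g}"
        )
    x = brentq(resid, -xmax, xmax, xtol=1e-12, rtol=8.9e-16)
    # verify to the stated relative tolerance
    achieved = ratio_at(x)
    if abs(achieved / kpuu_target - 1.0) > opt.af_tol:  # pragma: no cover
        raise CalibrationError(
            f"calibration at {barrier!r} converged to ratio {achieved:.6g} "
            f"!= target {kpuu_target:.6g}"
        )
    a_in, a_ef = _af_from_x(x)
    return replace(af, **{f"af_in_{stem}": a_in, f"af_ef_{stem}": a_ef})


def calibrate_all(
    p: PhysiologySet, d: DrugProperties, opt: ModelOptions | None = None
) -> AsymmetryFactors:
    """Calibrate all three barriers against the drug's Kpuu targets.

    The BBB factor is calibrated first (its steady state is independent
    of the CSF barriers), species-scaled if the Kpuu,BBB value is
    rat-derived, then the ventricular and TFV-facing barriers are
    calibrated downstream.
    """
    opt = opt or ModelOptions()
    af = calibrate_af(p, d, "bbb", d.kpuu_bbb, opt=opt)
    if d.kpuu_bbb_species != "human" and d.species_scaling:
        if af.af_in_ecf > 1.0:
            mag, direction = scale_asymmetry_species(
                af.af_in_ecf, "influx", d.species_scaling
            )
        else:
            mag, direction = scale_asymmetry_species(
                af.af_ef_ecf, "efflux", d.species_scaling
            )
        if direction == "influx":
            af = replace(af, af_in_ecf=mag, af_ef_ecf=1.0)
        else:
            af = replace(af, af_in_ecf=1.0, af_ef_ecf=mag)
    af = calibrate_af(p, d, "bcsfb_lv", d.kpuu_lv, af=af, opt=opt)
    af = calibrate_af(p, d, "bcsfb_tfv", d.kpuu_lumbar, af=af, opt=opt)
    return af


def build_model(
    p: PhysiologySet,
    d: DrugProperties,
    opt: ModelOptions | None = None,
    af: AsymmetryFactors | None = None,
    calibrate: bool = True,
    closed_system: bool = False,
) -> CnsModel:
    """Assemble the CNS model, calibrating asymmetry factors by default.

    Passing ``af`` reuses previously calibrated factors (e.g. factors
    calibrated on the AD physiology applied to a healthy model, or held
    fixed during sensitivity perturbations).
    """
    problems = validate_physiology(p)
    if problems:
        raise ValueError("invalid physiology: " + "; ".join(problems))
    opt = opt or ModelOptions()
    if af is None:
        af = calibrate_all(p, d, opt) if calibrate else AsymmetryFactors()
    return _build(p, d, opt, af, closed_system=closed_system)


def simulate_cns(
    model: CnsModel,
    plasma: PlasmaSolution | ConcProfile | Callable[[float], float],
    grid: np.ndarray,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcProfile:
    """Integrate the CNS system over ``grid`` driven by a plasma profile.

    Returns unbound concentrations (ng/mL) for the eight CNS compartments
    plus the plasma forcing itself.  The final state vector (amounts, ng)
    is stored in ``metadata['final_state']`` for chained integrations.
    """
    grid = np.asarray(grid, dtype=float)
    if isinstance(plasma, ConcProfile):
        times, conc = plasma.times, plasma.conc["plasma"]
        if grid[0] < times[0] - 1e-9 or grid[-1] > times[-1] + 1e-9:
            raise ValueError("plasma profile does not cover the simulation grid")
        cp_of_t = lambda t: float(np.interp(t, times, conc))  # noqa: E731
        cp_grid = np.interp(grid, times, conc)
    elif isinstance(plasma, PlasmaSolution):
        cp_of_t = lambda t: plasma.conc(t)  # noqa: E731
        cp_grid = np.asarray(plasma.conc(grid))
    else:
        cp_of_t = plasma
        cp_grid = np.array([plasma(t) for t in grid], dtype=float)

    y0 = np.zeros(len(COMPARTMENTS)) if y0 is None else np.asarray(y0, dtype=float)
    res = solve_ivp(
        model.rhs(cp_of_t), (grid[0], grid[-1]), y0,
        t_eval=grid, method="LSODA", rtol=rtol, atol=atol,
    )
    if not res.success:
        eigs = np.linalg.eigvals(model.matrix)
        stiffness = abs(eigs.real.min()) / max(abs(eigs.real.max()), 1e-300)
        worst = COMPARTMENTS[int(np.argmin(np.diag(model.matrix)))]
        raise RuntimeError(
            f"CNS integration failed: {res.message} "
            f"(stiffness ratio {stiffness:.3g}, fastest compartment {worst!r})"
        )
    amounts = res.y
    conc_out: dict[str, np.ndarray] = {
        name: np.maximum(amounts[i] / model.vapp[i], 0.0)
        for i, name in enumerate(COMPARTMENTS)
    }
    conc_out["plasma"] = cp_grid
    return ConcProfile(
        times=grid,
        conc=conc_out,
        metadata={
            "drug": model.drug.name,
            "population": model.physiology.label,
            "scale": "unbound",
            "final_state": amounts[:, -1],
        },
    )
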