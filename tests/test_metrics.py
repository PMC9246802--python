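"""PK summary metrics, engagement arithmetic and steady-state detection."""

import math

import numpy as np
import pytest

from cnspk.metrics import compute_metrics, engagement, run_to_steady_state
from cnspk.plasma import ConcProfile, DoseRegimen, load_plasma
from cnspk.workflow import build_population_model

MG_TO_NG = 1.0e6


def profile_from(times, values, name="probe"):
    return ConcProfile(times=np.asarray(times), conc={name: np.asarray(values)})


def test_constant_profile_metrics():
    t = np.linspace(0.0, 720.0, 100)
    m = compute_metrics(profile_from(t, np.full_like(t, 5.0)), "probe")
    assert m.fluctuation == pytest.approx(1.0)
    assert m.tmax == 0.0
    assert m.auc_tau == pytest.approx(5.0 * 720.0)


def test_monoexponential_decay_closed_forms():
    """fluctuation = exp(k*tau) and half-life = ln2/k, within 0.5%."""
    k, tau = 0.004, 720.0
    t = np.linspace(0.0, tau, 2000)
    m = compute_metrics(profile_from(t, 100.0 * np.exp(-k * t)), "probe")
    assert m.fluctuation == pytest.approx(math.exp(k * tau), rel=5e-3)
    assert m.half_life == pytest.approx(math.log(2.0) / k, rel=5e-3)
    assert m.cmax == pytest.approx(100.0, rel=1e-6)


def test_triangular_peak_located_by_refinement():
    t = np.linspace(0.0, 100.0, 101)
    c = np.where(t <= 40.0, t, 80.0 - t)
    m = compute_metrics(profile_from(t, c), "probe")
    assert m.tmax == pytest.approx(40.0, abs=1.0)
    assert m.cmax == pytest.approx(40.0, abs=0.5)


def test_nonpositive_tail_reports_undefined_half_life():
    t = np.linspace(0.0, 100.0, 60)
    c = np.maximum(50.0 - t, 0.0)
    m = compute_metrics(profile_from(t, c), "probe")
    assert m.half_life is None


class TestEngagement:
    def test_entirely_above_and_below(self):
        t = np.linspace(0.0, 100.0, 80)
        high = engagement(profile_from(t, np.full_like(t, 10.0)), "probe", 1.0)
        assert high.fraction_above == 1.0
        assert high.flag == "always-above"
        assert high.crossings == ()
        low = engagement(profile_from(t, np.full_like(t, 0.1)), "probe", 1.0)
        assert low.fraction_above == 0.0
        assert low.flag == "always-below"

    def test_exponential_crossing_at_half_interval(self):
        """C0/IC50 = exp(k*tau/2) puts the crossing exactly at tau/2."""
        k, tau, ic50 = 0.005, 1000.0, 2.0
        c0 = ic50 * math.exp(k * tau / 2.0)
        t = np.linspace(0.0, tau, 4000)
        e = engagement(profile_from(t, c0 * np.exp(-k * t)), "probe", ic50)
        assert e.fraction_above == pytest.approx(0.5, abs=1e-3)
        assert e.drug_free_onset == pytest.approx(tau / 2.0, abs=0.5)
        assert e.flag == "dips-below"

    def test_fraction_above_monotone_in_ic50(self, semagacestat_ad):
        fractions = [
            engagement(semagacestat_ad, "brain_ecf", ic50).fraction_above
            for ic50 in (0.01, 0.1, 1.0, 5.4, 50.0, 500.0, 5000.0)
        ]
        assert fractions == sorted(fractions, reverse=True)
        assert all(0.0 <= f <= 1.0 for f in fractions)

    def test_crossings_alternate(self, semagacestat_ad):
        e = engagement(semagacestat_ad, "brain_ecf", 5.4)
        kinds = [kind for _, kind in e.crossings]
        for a, b in zip(kinds, kinds[1:]):
            assert a != b


class TestSteadyState:
    def test_plasma_auc_identity_at_steady_state(self, pops):
        """Interdose plasma AUC converges to F*dose/CL within 0.5%."""
        model = build_population_model("donepezil", "AD", populations=pops)
        pm = load_plasma("donepezil")
        reg = DoseRegimen(dose=10.0, interval=1440.0)
        profile = run_to_steady_state(model, pm, reg)
        auc = np.trapezoid(profile.conc["plasma"], profile.times)
        assert auc == pytest.approx(10.0 * MG_TO_NG / pm.cl_cen, rel=5e-3)
        assert profile.metadata["at_steady_state"]

    def test_single_dose_flagged_not_at_steady_state(self, pops):
        model = build_population_model("semagacestat", "AD", populations=pops)
        profile = run_to_steady_state(
            model, load_plasma("semagacestat"),
            DoseRegimen(dose=140.0, interval=1440.0, n_doses=1),
        )
        assert profile.metadata["at_steady_state"] is False
        assert profile.metadata["intervals_simulated"] == 1

    def test_short_half_life_converges_within_few_intervals(self, semagacestat_ad):
        """Plasma t1/2 ~1 h against a 24 h interval: negligible accumulation."""
        assert semagacestat_ad.metadata["intervals_simulated"] <= 4

    def test_metrics_stable_under_grid_refinement(self, pops, semagacestat_ad):
        from cnspk.workflow import steady_state_run

        fine = steady_state_run(
            "semagacestat", "AD", populations=pops, points_per_interval=1501
        )
        for comp in ("brain_ecf", "csf_sas"):
            coarse_m = compute_metrics(semagacestat_ad, comp)
            fine_m = compute_metrics(fine, comp)
            assert fine_m.cmax == pytest.approx(coarse_m.cmax, rel=1e-3)
            assert fine_m.auc_tau == pytest.approx(coarse_m.auc_tau, rel=1e-3)


def test_absolute_drug_free_floor(semagacestat_ad):
    """The drug-free onset can use an absolute floor instead of the IC50."""
    by_ic50 = engagement(semagacestat_ad, "brain_ecf", 5.4)
    by_floor = engagement(semagacestat_ad, "brain_ecf", 5.4, drug_free_floor=0.01)
    assert by_floor.drug_free_onset > by_ic50.drug_free_onset
    assert by_floor.fraction_above == by_ic50.fraction_above  # IC50 unchanged
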