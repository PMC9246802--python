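"""Ionization arithmetic, partition conversions and the drug registry."""

import pytest
from hypothesis import given, settings, strategies as st

from cnspk.drugs import (
    DrugLookupError,
    DrugProperties,
    fraction_neutral,
    kp_to_kpuu,
    load_drug,
    registry_names,
    scale_asymmetry_species,
)


def make_drug(**kw) -> DrugProperties:
    base = dict(
        name="probe", mw=300.0, logp=1.0, pka_acid=None, pka_base=None,
        fu_p=1.0, fu_b=1.0, kpuu_bbb=1.0, kpuu_lv=1.0, kpuu_lumbar=1.0,
        ic50=10.0,
    )
    base.update(kw)
    return DrugProperties(**base)


class TestFractionNeutral:
    def test_no_ionizable_groups(self):
        d = make_drug()
        for ph in (0.0, 7.4, 14.0):
            assert fraction_neutral(ph, d) == 1.0

    def test_strong_base_at_physiological_ph(self):
        """pKb 10.7 at pH 7.4: 1/(1+10^3.3), about 5e-4."""
        d = make_drug(pka_base=10.7)
        assert fraction_neutral(7.4, d) == pytest.approx(
            1.0 / (1.0 + 10.0 ** 3.3), rel=1e-12
        )

    def test_half_ionization_at_pka(self):
        assert fraction_neutral(8.6, make_drug(pka_base=8.6)) == pytest.approx(0.5)
        assert fraction_neutral(4.5, make_drug(pka_acid=4.5)) == pytest.approx(0.5)

    def test_limits(self):
        base = make_drug(pka_base=9.0)
        acid = make_drug(pka_acid=5.0)
        assert fraction_neutral(14.0, base) > 0.999
        assert fraction_neutral(14.0, acid) < 1e-8
        assert fraction_neutral(0.0, acid) > 0.999

    def test_ampholyte_is_product_of_factors(self):
        d = make_drug(pka_acid=10.0, pka_base=6.0)
        expected = (1.0 / (1.0 + 10.0 ** (6.0 - 7.0))) * (
            1.0 / (1.0 + 10.0 ** (7.0 - 10.0))
        )
        assert fraction_neutral(7.0, d) == pytest.approx(expected, rel=1e-12)

    @given(
        pka=st.floats(2.0, 12.0),
        ph1=st.floats(0.0, 14.0),
        ph2=st.floats(0.0, 14.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ph_for_monoprotic_base(self, pka, ph1, ph2):
        d = make_drug(pka_base=pka)
        lo, hi = sorted((ph1, ph2))
        f_lo, f_hi = fraction_neutral(lo, d), fraction_neutral(hi, d)
        assert 0.0 < f_lo <= 1.0
        assert f_lo <= f_hi


class TestKpToKpuu:
    def test_neutral_unbound_drug_is_identity(self, chy):
        assert kp_to_kpuu(3.7, make_drug(), chy) == pytest.approx(3.7)

    def test_binding_correction(self, chy):
        d = make_drug(fu_p=0.5, fu_b=0.05)
        assert kp_to_kpuu(10.0, d, chy) == pytest.approx(1.0)

    def test_base_accumulates_intracellularly(self, chy):
        """For a base, ICF:ECF > 1, so D > 1 and Kpuu < Kp*fu_b/fu_p."""
        d = make_drug(pka_base=8.6, fu_p=0.5, fu_b=0.05)
        kpuu = kp_to_kpuu(10.0, d, chy)
        assert kpuu < 10.0 * 0.05 / 0.5

    def test_scale_equivariance(self, chy):
        d = make_drug(pka_base=9.0, fu_p=0.3, fu_b=0.1)
        assert kp_to_kpuu(4.0, d, chy) == pytest.approx(
            2.0 * kp_to_kpuu(2.0, d, chy), rel=1e-12
        )


class TestSpeciesScaling:
    def test_unit_scaling_is_identity(self):
        assert scale_asymmetry_species(2.5, "efflux", {"pgp": 1.0}) == (2.5, "efflux")

    def test_scaling_without_flip(self):
        mag, direction = scale_asymmetry_species(4.0, "efflux", 0.5)
        assert (mag, direction) == (2.0, "efflux")

    def test_rat_efflux_flips_to_human_influx(self):
        """Rat efflux AF 1/0.482 scaled by 0.22 x 1.1 flips to influx ~2."""
        mag, direction = scale_asymmetry_species(
            1.0 / 0.482, "efflux", {"pgp": 0.22, "bcrp": 1.1}
        )
        assert direction == "influx"
        assert mag == pytest.approx(2.0, abs=0.15)

    def test_reciprocal_scaling_round_trips(self):
        """Applying a map and its reciprocal restores the factor as long
        as the intermediate magnitude stays on the same side of unity."""
        mag1, dir1 = scale_asymmetry_species(3.0, "influx", {"a": 0.5})
        mag2, dir2 = scale_asymmetry_species(mag1, dir1, {"a": 2.0})
        assert (mag2, dir2) == (pytest.approx(3.0), "influx")

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            scale_asymmetry_species(2.0, "efflux", {"pgp": 0.0})
        with pytest.raises(ValueError):
            scale_asymmetry_species(2.0, "sideways", {})


class TestRegistry:
    def test_registry_contents(self):
        assert registry_names() == [
            "donepezil", "galantamine", "memantine", "rivastigmine",
            "semagacestat",
        ]

    def test_memantine_record(self):
        d = load_drug("memantine")
        assert d.mw == 179.3
        assert d.logp == 3.31
        assert d.kpuu_bbb == 2.0
        assert d.ic50 == 109.0

    def test_semagacestat_record(self):
        d = load_drug("semagacestat")
        assert d.kpuu_lumbar == 0.55
        assert d.ic50 == 5.4

    def test_rivastigmine_secondary_target(self):
        d = load_drug("rivastigmine")
        assert d.ic50 == 857.2
        assert d.ic50_secondary == 9.3
        assert d.target_secondary == "butyrylcholinesterase"

    def test_unknown_drug_names_the_registry(self):
        with pytest.raises(DrugLookupError, match="memantine"):
            load_drug("aspirin")

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            make_drug(fu_p=0.0)
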