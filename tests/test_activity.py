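import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgpbind import (
    ActivityProfile,
    AvailabilityScenario,
    IAAPAssay,
    apparent_atpase,
    apparent_competitive,
    atpase_velocity,
    available_protein,
    build_binding_model,
    iaap_bound_fraction,
    iaap_curve,
    iaap_displacement,
    solve_speciation,
)
from pgpbind.speciation import SpeciationState


def _state(p_free, pl, l_water=0.0, l_bilayer=0.0):
    pl = np.asarray(pl, float)
    return SpeciationState(
        l_water=l_water,
        l_bilayer=l_bilayer,
        p_free=p_free,
        pl=pl,
        l_total=l_water + l_bilayer + float(np.dot(np.arange(1, pl.size + 1), pl)),
        p_total=p_free + float(pl.sum()),
    )


class TestAtpaseVelocity:
    def test_zero_ligand_returns_basal(self):
        m = build_binding_model(3, 5e-6)
        state = solve_speciation(0.0, 6e-9, 1.9e4, 6.5e-5, m)
        v = atpase_velocity(state, ActivityProfile(vi=[300.0, 200.0, 50.0]))
        assert v == pytest.approx(100.0, rel=1e-12)

    def test_occupancy_independent_profile_is_flat(self):
        m = build_binding_model(2, 5e-6)
        profile = ActivityProfile(vi=[100.0, 100.0])
        for lt in (0.0, 1e-6, 50e-6):
            state = solve_speciation(lt, 6e-9, 0.0, 0.0, m)
            assert atpase_velocity(state, profile) == pytest.approx(100.0, rel=1e-12)

    def test_equal_thirds_weighted_mean(self):
        state = _state(p_free=1 / 3, pl=[1 / 3, 1 / 3])
        v = atpase_velocity(state, ActivityProfile(vi=[500.0, 100.0]))
        assert v == pytest.approx((100 + 500 + 100) / 3, rel=1e-9)

    def test_bounded_by_profile_extremes(self):
        m = build_binding_model(4, 3e-6)
        profile = ActivityProfile(vi=[400.0, 250.0, 80.0, 10.0])
        for lt in np.logspace(-7, -4, 12):
            state = solve_speciation(lt, 6e-9, 1.9e4, 6.5e-5, m)
            v = atpase_velocity(state, profile)
            assert 10.0 - 1e-9 <= v <= 400.0 + 1e-9

    def test_no_protein_is_an_error(self):
        state = _state(p_free=0.0, pl=[0.0])
        with pytest.raises(ValueError):
            atpase_velocity(state, ActivityProfile(vi=[100.0]))


class TestApparentAtpase:
    def test_limits(self):
        assert apparent_atpase(0.0, 100.0, 734.0, 84e-6) == pytest.approx(100.0)
        big = apparent_atpase(1e3, 100.0, 500.0, 1e-5, v2=30.0, k2=2e-5)
        assert big == pytest.approx(30.0, rel=1e-3)

    def test_single_site_midpoint(self):
        """At S = K1 the activation-only model sits halfway: (100+734)/2."""
        assert apparent_atpase(84e-6, 100.0, 734.0, 84e-6) == pytest.approx(417.0)


class TestAvailableProtein:
    def test_no_ligand_everything_available(self):
        state = _state(p_free=5e-9, pl=[0.0, 0.0, 0.0])
        for sc in AvailabilityScenario:
            assert available_protein(state, sc) == pytest.approx(5e-9)

    def test_fully_saturated_nothing_available(self):
        state = _state(p_free=0.0, pl=[0.0, 0.0, 1e-9])
        for sc in AvailabilityScenario:
            assert available_protein(state, sc) == 0.0

    def test_partial_occupancy_sums(self):
        state = _state(p_free=1.0, pl=[2.0, 3.0, 4.0])
        assert available_protein(state, "any_bound") == pytest.approx(1.0)
        assert available_protein(state, "all_but_one") == pytest.approx(3.0)
        assert available_protein(state, "full_only") == pytest.approx(6.0)

    def test_small_n_fallback_warns(self):
        state = _state(p_free=1.0, pl=[2.0])
        with pytest.warns(RuntimeWarning):
            assert available_protein(state, "all_but_one") == pytest.approx(1.0)


class TestIAAPBinding:
    def test_no_available_protein_no_binding(self, iaap_assay):
        assert iaap_bound_fraction(iaap_assay, 0.0) == 0.0

    def test_assay_conditions_bound_fraction(self, iaap_assay):
        """5 nM tracer, 59 nM protein, Kd 412 nM: ~12.4% of tracer bound."""
        assert iaap_bound_fraction(iaap_assay, 59e-9) == pytest.approx(0.124, abs=5e-4)

    def test_stoichiometric_limit(self):
        assay = IAAPAssay(iaap_total=5e-9, kd_iaap=1e-18)
        assert iaap_bound_fraction(assay, 59e-9) == pytest.approx(1.0, abs=1e-6)

    @given(
        log_it=st.floats(-10, -7),
        log_kd=st.floats(-9, -5),
        log_p=st.floats(-12, -6),
    )
    @settings(max_examples=150, deadline=None)
    def test_root_always_a_fraction(self, log_it, log_kd, log_p):
        assay = IAAPAssay(iaap_total=10.0**log_it, kd_iaap=10.0**log_kd)
        f = iaap_bound_fraction(assay, 10.0**log_p)
        assert 0.0 <= f <= 1.0

    def test_monotone_in_protein_and_kd(self, iaap_assay):
        fr = [iaap_bound_fraction(iaap_assay, p) for p in np.linspace(0, 2e-7, 12)]
        assert np.all(np.diff(fr) > 0)
        fr_kd = [
            iaap_bound_fraction(IAAPAssay(iaap_total=5e-9, kd_iaap=kd), 59e-9)
            for kd in np.logspace(-8, -5, 12)
        ]
        assert np.all(np.diff(fr_kd) < 0)


class TestDisplacement:
    def test_endpoints(self):
        assert iaap_displacement(1e-9, 1e-9) == 0.0
        assert iaap_displacement(0.0, 1e-9) == 100.0

    def test_halving(self, iaap_assay):
        ip0 = 0.124 * iaap_assay.iaap_total
        assert iaap_displacement(ip0 / 2, ip0) == pytest.approx(50.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            iaap_displacement(0.0, 0.0)


class TestApparentCompetitive:
    def test_half_displacement_point(self, iaap_assay):
        ki = 4e-6
        s50 = ki * (1 + iaap_assay.iaap_total / iaap_assay.kd_iaap)
        assert apparent_competitive(s50, ki, iaap_assay) == pytest.approx(50.0)
        assert apparent_competitive(0.0, ki, iaap_assay) == 0.0

    def test_tracer_correction_is_small(self, iaap_assay):
        """I_T/Kd ~ 1.2%: 4.05 uM is close to the 50% point for Ki = 4 uM."""
        assert apparent_competitive(4.05e-6, 4e-6, iaap_assay) == pytest.approx(50.0, abs=0.2)

    def test_full_model_reduces_to_competitive_in_dilute_limit(self, iaap_assay):
        """n=1, no bilayer, protein << ligand: the exact chain collapses onto the
        apparent competitive curve once Ki absorbs the tracer-occupancy factor."""
        kd = 5e-6
        model = build_binding_model(1, kd)
        assay = IAAPAssay(iaap_total=iaap_assay.iaap_total, kd_iaap=iaap_assay.kd_iaap,
                          scenario="any_bound")
        ki = kd / (1 + assay.iaap_total / assay.kd_iaap)
        s = ki * np.logspace(-1.5, 1.5, 25)
        full = iaap_curve(s, model, assay, p_total=1e-12, kp_w_lb=0.0, v_lb=0.0)
        approx = apparent_competitive(s, ki, assay)
        assert np.max(np.abs(full - approx) / approx) < 0.01
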