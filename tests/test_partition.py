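import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgpbind import (
    AmphiphileRecord,
    MembranePreparation,
    PartitionCoefficientSet,
    check_aggregation,
    close_cycle,
    distribute_dilute,
    series_regression,
    whole_membrane_kp,
)


class TestCloseCycle:
    def test_bilayer_to_protein_ratio_nbd_c4(self):
        """KP(Lb->P) is the cycle ratio: 6.9e4 / 3.9e2 ~ 177 for the C4 amphiphile."""
        s = PartitionCoefficientSet.from_w_values(1.4e3, 3.9e2, 6.9e4, "pgp_only")
        assert s.kp_lb_p == pytest.approx(176.9, abs=0.05)

    def test_all_proteins_closure(self, atpase_prep):
        """Splitting the whole-membrane KP recovers the protein term near 7.0e2."""
        s = close_cycle(5.7e2, 3.9e2, atpase_prep, "all_proteins")
        assert s.kp_w_p == pytest.approx(7.0e2, rel=0.01)
        assert s.kp_lb_p == pytest.approx(s.kp_w_p / 3.9e2, rel=1e-12)

    def test_round_trip_reproduces_whole_membrane_kp(self, atpase_prep):
        s = close_cycle(5.7e2, 3.9e2, atpase_prep, "all_proteins")
        assert whole_membrane_kp(s, atpase_prep) == pytest.approx(5.7e2, rel=1e-12)

    def test_degenerate_cycle_vanishing_protein_volume(self):
        """With v_p -> 0 and KP(W->M) = KP(W->Lb) the protein term stays finite."""
        prep = MembranePreparation(protein_conc=0.107, pgp_conc=1e-15)
        s = close_cycle(3.9e2, 3.9e2, prep, "pgp_only")
        assert s.kp_w_p == pytest.approx(3.9e2, rel=1e-6)

    def test_negative_numerator_clips_to_zero_with_flag(self, atpase_prep):
        with pytest.warns(RuntimeWarning):
            s = close_cycle(1.0e2, 3.9e2, atpase_prep, "all_proteins")
        assert s.kp_w_p == 0.0
        assert s.protein_term_clipped

    def test_inconsistent_set_rejected(self):
        with pytest.raises(ValueError, match="kp_lb_p"):
            PartitionCoefficientSet(1.4e3, 3.9e2, 6.9e4, 5.0, "pgp_only")


class TestDistributeDilute:
    def test_bilayer_fraction_atpase_conditions(self, atpase_prep):
        """NBD-C8 at ATPase dilution: ~55% in the bilayer when protein is excluded."""
        kps = PartitionCoefficientSet.from_w_values(1.9e4, 1.9e4, 0.0, "all_proteins")
        d = distribute_dilute(kps, atpase_prep, 50e-6)
        assert d.frac_bilayer == pytest.approx(1.236 / 2.236, rel=1e-3)

    def test_pl_to_ligand_iaap_conditions(self, iaap_prep):
        """NBD-C8 at 50 uM / 1 mg/mL: ~16.5 phospholipids per bilayer amphiphile."""
        kps = PartitionCoefficientSet.from_w_values(1.9e4, 1.9e4, 0.0, "all_proteins")
        d = distribute_dilute(kps, iaap_prep, 50e-6)
        assert d.pl_to_ligand == pytest.approx(16.5, abs=0.1)

    def test_no_membrane_affinity_stays_in_water(self, atpase_prep):
        kps = PartitionCoefficientSet.from_w_values(1e-300, 1e-300, 0.0, "all_proteins")
        d = distribute_dilute(kps, atpase_prep, 1e-6)
        assert d.frac_water == pytest.approx(1.0, abs=1e-12)
        assert d.conc_water == pytest.approx(1e-6, rel=1e-12)

    @given(
        kp_lb=st.floats(1e-2, 1e6), kp_p=st.floats(0.0, 1e6),
        lt=st.floats(1e-9, 1e-3),
    )
    @settings(max_examples=100, deadline=None)
    def test_fractions_sum_to_one_and_are_dilution_invariant(self, kp_lb, kp_p, lt):
        prep = MembranePreparation(protein_conc=0.107, pgp_conc=6e-9)
        kps = PartitionCoefficientSet.from_w_values(
            max(kp_lb, 1e-6), kp_lb, kp_p, "all_proteins"
        )
        d1 = distribute_dilute(kps, prep, lt)
        d2 = distribute_dilute(kps, prep, 10 * lt)
        assert d1.frac_water + d1.frac_bilayer + d1.frac_protein == pytest.approx(1.0, abs=1e-12)
        assert d1.frac_bilayer == pytest.approx(d2.frac_bilayer, rel=1e-12)
        assert d1.pl_to_ligand == pytest.approx(10 * d2.pl_to_ligand, rel=1e-9)


class TestAggregation:
    def test_c8_above_cac_flags(self):
        rec = AmphiphileRecord(id="NBD-C8", cac_25c=1e-6)
        chk = check_aggregation(rec, 21e-6)
        assert chk.flag is True and chk.margin == pytest.approx(21.0)

    def test_c4_below_cac_does_not_flag(self):
        rec = AmphiphileRecord(id="NBD-C4", cac_25c=250e-6)
        chk = check_aggregation(rec, 60e-6)
        assert chk.flag is False

    def test_zero_concentration(self):
        chk = check_aggregation(AmphiphileRecord(id="x", cac_25c=1e-6), 0.0)
        assert chk.flag is False and chk.margin == 0.0

    def test_unknown_cac_gives_unknown_flag(self):
        chk = check_aggregation(AmphiphileRecord(id="NBD-C6"), 1e-6)
        assert chk.flag is None


class TestSeriesRegression:
    def test_clogd_series(self):
        """Computed LogD of the homologous series: 0.445 per carbon, 0.28 intercept."""
        r = series_regression([(4, 2.06), (6, 2.95), (8, 3.84)])
        assert r.slope == pytest.approx(0.445, abs=1e-12)
        assert r.intercept == pytest.approx(0.28, abs=1e-12)

    def test_popc_series_slope(self):
        r = series_regression([(4, 2.99), (6, 3.79), (8, 4.67)])
        assert r.slope == pytest.approx(0.42, abs=1e-12)

    def test_translation_invariance_of_slope(self):
        base = [(4, 2.0), (6, 3.0), (8, 4.1)]
        shifted = [(n, y + 5.0) for n, y in base]
        assert series_regression(base).slope == pytest.approx(
            series_regression(shifted).slope, rel=1e-12
        )

    def test_collinear_input_r2_is_one(self):
        r = series_regression([(4, 1.0), (6, 2.0), (8, 3.0), (10, 4.0)])
        assert r.r2 == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            series_regression([(4, 1.0), (6, 2.0)])
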