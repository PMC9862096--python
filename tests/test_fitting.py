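import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from pgpbind import (
    ActivityProfile,
    DoseResponsePoint,
    IAAPAssay,
    ModelSpec,
    NoiseModel,
    fit_dose_response,
    gen_atpase_curve,
    gen_iaap_curve,
    nbd_preset,
    profile_confidence,
    scan_site_count,
    with_seed,
)
from pgpbind.fitting import profile_interval_from_chi2


def _atpase_truth(n=2, kd=5e-6, vi=(500.0, 100.0), noise=0.0, seed=0):
    t = nbd_preset("NBD-C8", n_sites=n, kd=kd, noise=NoiseModel(relative_sd=noise), seed=seed)
    return replace(t, profile=ActivityProfile(vi=np.asarray(vi, float)))


def _spec_for(truth, kind="atpase", assay=None):
    vf = truth.prep.volume_fractions()
    return ModelSpec(
        kind=kind,
        n_sites=truth.model.n_sites,
        p_total=truth.prep.pgp_conc,
        kp_w_lb=truth.kp_w_lb,
        v_lb=vf.v_lb,
        assay=assay,
    )


class TestFitDoseResponse:
    def test_noise_free_atpase_recovery_is_exact(self):
        truth = _atpase_truth()
        sim = gen_atpase_curve(truth)
        fit = fit_dose_response(sim.points, _spec_for(truth))
        assert fit.chi2 < 1e-12
        assert fit.kd == pytest.approx(5e-6, rel=1e-6)
        assert fit.params["v1"] == pytest.approx(500.0, rel=1e-6)
        assert fit.params["v2"] == pytest.approx(100.0, rel=1e-6)

    def test_iaap_kd_recovery_over_seeds(self):
        """Noisy displacement curves refit at the true n recover Kd within 30%."""
        base = nbd_preset("NBD-C8", assay_kind="iaap", n_sites=5, kd=5e-6)
        assay = IAAPAssay(scenario="all_but_one")
        spec = _spec_for(base, kind="iaap", assay=assay)
        for seed in range(20):
            sim = gen_iaap_curve(with_seed(base, 4000 + seed), assay=assay)
            fit = fit_dose_response(sim.points, spec)
            assert fit.kd == pytest.approx(5e-6, rel=0.30)

    def test_too_few_points_rejected(self):
        truth = _atpase_truth()
        sim = gen_atpase_curve(truth)
        with pytest.raises(ValueError):
            fit_dose_response(sim.points[:3], _spec_for(truth))

    def test_kp_from_beta1_identity(self):
        truth = _atpase_truth()
        fit = fit_dose_response(gen_atpase_curve(truth).points, _spec_for(truth))
        assert fit.kp_from_beta1 == pytest.approx(truth.model.n_sites / fit.kd / 142.0, rel=1e-9)


class TestScanSiteCount:
    def test_single_row_scan_equals_direct_fit(self):
        truth = _atpase_truth(n=1, vi=(500.0,))
        sim = gen_atpase_curve(truth)
        spec = _spec_for(truth)
        scan = scan_site_count(sim.points, spec, n_max=1)
        fit = fit_dose_response(sim.points, spec)
        assert scan.table.shape[0] == 1
        assert scan.table.chi2[0] == pytest.approx(fit.chi2, rel=1e-6, abs=1e-15)
        assert scan.best_n() == 1

    def test_chi2_drops_at_true_site_count(self):
        """IAAP data generated with n=3 show a sharp chi2 minimum at n=3."""
        base = nbd_preset("NBD-C8", assay_kind="iaap", n_sites=3, kd=5e-6, seed=1000)
        assay = IAAPAssay(scenario="all_but_one")
        sim = gen_iaap_curve(base, assay=assay)
        scan = scan_site_count(sim.points, _spec_for(base, "iaap", assay), n_max=5)
        assert scan.best_n() == 3
        chi2 = scan.table.set_index("n").chi2
        assert chi2[1] > 10 * chi2[3] and chi2[2] > 5 * chi2[3]

    def test_kp_beta1_increases_with_n_at_fixed_kd(self):
        base = nbd_preset("NBD-C8", assay_kind="iaap", n_sites=3, kd=5e-6, seed=1000)
        assay = IAAPAssay(scenario="all_but_one")
        sim = gen_iaap_curve(base, assay=assay)
        scan = scan_site_count(sim.points, _spec_for(base, "iaap", assay), n_max=4)
        implied_beta1 = scan.table.kp_beta1 * 142.0
        assert np.allclose(implied_beta1, scan.table.n / scan.table.kd, rtol=1e-9)


class TestProfileConfidence:
    def test_matches_linear_regression_oracle(self):
        """On an exactly quadratic chi2 surface the profile interval equals the
        closed-form t-based standard-error interval of the slope."""
        rng = np.random.default_rng(5)
        x = np.linspace(0.0, 10.0, 12)
        y = 2.0 + 0.7 * x + 0.3 * rng.standard_normal(x.size)
        res = stats.linregress(x, y)
        resid = y - (res.intercept + res.slope * x)
        chi2_min = float(np.sum(resid**2))
        sxx = float(np.sum((x - x.mean()) ** 2))
        nu = x.size - 2
        level = 0.75

        def chi2_profile(b):  # intercept re-optimised in closed form
            return chi2_min + sxx * (b - res.slope) ** 2

        threshold = chi2_min * (1 + stats.f.ppf(level, 1, nu) / nu)
        lo, hi = profile_interval_from_chi2(
            chi2_profile, est=res.slope, threshold=threshold, step=res.stderr / 2
        )
        t = stats.t.ppf(0.5 + level / 2, nu)
        se = np.sqrt(chi2_min / nu / sxx)
        assert lo == pytest.approx(res.slope - t * se, abs=0.02 * se)
        assert hi == pytest.approx(res.slope + t * se, abs=0.02 * se)

    def test_level_zero_collapses_to_estimate(self):
        truth = _atpase_truth(noise=0.02, seed=3)
        sim = gen_atpase_curve(truth)
        spec = _spec_for(truth)
        fit = fit_dose_response(sim.points, spec)
        lo, hi = profile_confidence(sim.points, spec, fit, "log10_kd", level=0.0)
        assert lo == hi == fit.params["log10_kd"]

    def test_interval_contains_estimate_and_widens_with_level(self):
        truth = _atpase_truth(noise=0.02, seed=7)
        sim = gen_atpase_curve(truth)
        spec = _spec_for(truth)
        fit = fit_dose_response(sim.points, spec)
        lo50, hi50 = profile_confidence(sim.points, spec, fit, "log10_kd", level=0.50)
        lo90, hi90 = profile_confidence(sim.points, spec, fit, "log10_kd", level=0.90)
        assert lo90 <= lo50 <= fit.params["log10_kd"] <= hi50 <= hi90

    def test_one_sided_when_profile_flat_on_one_side(self):
        def chi2_profile(v):
            return 1.0 + (100.0 * max(0.0, v - 1.0)) ** 2

        lo, hi = profile_interval_from_chi2(chi2_profile, est=1.0, threshold=2.0, step=0.5)
        assert lo == -np.inf
        assert np.isfinite(hi)
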