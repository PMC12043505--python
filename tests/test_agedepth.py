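"""Non-monotonic age-depth regression, imputation and reversal diagnostics."""

import numpy as np
import pytest

import phasecal as pc
from phasecal.agedepth import AgeDepthPriors, monotone_baseline_slope


@pytest.fixture(scope="module")
def core_curve():
    return pc.simulate_calibration_curve((8000, 800), wiggle_amplitude=12,
                                         wiggle_period=650, sigma=8, seed=31)


def _mcmc(seed=0, iters=4000, burn=1500):
    return pc.McmcSettings(chains=2, iterations=iters, burn_in=burn,
                           thin=2, seed=seed)


def _noiseless_core(curve, n=10, lab_sigma=5.0):
    cfg = pc.CoreSimConfig(beta0=2000.0, beta1=500.0, sigma_eps=0.0,
                           depths=tuple(np.linspace(0.5, 5.0, n)),
                           lab_sigma=lab_sigma, seed=8)
    return pc.simulate_core(cfg, curve)


def test_exact_line_recovery(core_curve):
    core, truth = _noiseless_core(core_curve)
    fit = pc.fit_age_depth(core, core_curve, mcmc=_mcmc(1))
    b0 = fit.beta0_samples.ravel()
    b1 = fit.beta1_samples.ravel()
    assert abs(b0.mean() - 2000.0) < 2.0 * b0.std()
    assert abs(b1.mean() - 500.0) < 2.0 * b1.std()


def test_posterior_invariant_to_sample_order(core_curve):
    core, _ = _noiseless_core(core_curve)
    fit1 = pc.fit_age_depth(core, core_curve, mcmc=_mcmc(2, 1500, 500))
    rng = np.random.default_rng(0)
    permuted = list(core)
    rng.shuffle(permuted)
    fit2 = pc.fit_age_depth(permuted, core_curve, mcmc=_mcmc(2, 1500, 500))
    assert np.array_equal(fit1.beta1_samples, fit2.beta1_samples)
    assert np.array_equal(fit1.theta_samples, fit2.theta_samples)


def test_imputation_properties(core_curve):
    core, _ = _noiseless_core(core_curve)
    fit = pc.fit_age_depth(core, core_curve, mcmc=_mcmc(3))
    depths = [float(core[0].depth_m), 2.75, float(core[-1].depth_m)]
    imp = pc.impute_depth_ages(fit, depths, force=True)
    # predictive variance >= line variance at every depth
    for d, rec in imp.items():
        assert rec["draws"].var() >= rec["line_variance"]
    # at a dated depth, predictive mean ~ that sample's latent age posterior
    th0 = fit.theta_samples[:, :, 0].ravel()
    se = imp[depths[0]]["draws"].std() / np.sqrt(200.0)  # generous MC se
    assert abs(imp[depths[0]]["mean"] - th0.mean()) < max(3 * se, 30.0)
    # midpoint of two dated depths on the line ~ average of its neighbours
    mid = imp[2.75]["mean"]
    assert abs(mid - (2000.0 + 500.0 * 2.75)) < 50.0
    with pytest.raises(pc.ValidationError):
        pc.impute_depth_ages(fit, [], force=True)


def test_interval_width_monotone_in_sigma_prior_scale(core_curve):
    """With exact-line data and few samples, shrinking the sigma_eps prior
    scale shrinks the imputed predictive spread toward the line."""
    core, _ = _noiseless_core(core_curve, n=5, lab_sigma=30.0)
    sds = []
    for scale in (5.0, 50.0, 500.0):
        fit = pc.fit_age_depth(core, core_curve,
                               priors=AgeDepthPriors(sigma_eps_scale=scale),
                               mcmc=_mcmc(4))
        line_var = (fit.beta0_samples + fit.beta1_samples * 2.75).var()
        sds.append(np.sqrt(line_var + (fit.sigma_eps_samples ** 2).mean()))
    assert sds[0] < sds[1] < sds[2]


def test_lab_error_inflation_widens_imputed_intervals(core_curve):
    core, _ = _noiseless_core(core_curve, lab_sigma=20.0)
    inflated = [pc.CoreSample(s.lab_code, s.depth_m,
                              pc.Determination(s.lab_code, s.det.c14_age,
                                               s.det.c14_sigma * 4.0))
                for s in core]
    depths = [1.0, 2.5, 4.0]
    w = {}
    for name, c in (("base", core), ("x4", inflated)):
        fit = pc.fit_age_depth(c, core_curve, mcmc=_mcmc(5))
        imp = pc.impute_depth_ages(fit, depths, force=True, seed=7)
        w[name] = [imp[d]["hpd95"][1] - imp[d]["hpd95"][0] for d in depths]
    for a, b in zip(w["base"], w["x4"]):
        assert b > a


def test_depth_unit_rescaling_is_exact(core_curve):
    core, _ = _noiseless_core(core_curve)
    core_cm = [pc.CoreSample(s.lab_code, s.depth_m * 100.0, s.det)
               for s in core]
    pr_m = AgeDepthPriors(beta1_mean=0.0, beta1_sd=10000.0)
    pr_cm = AgeDepthPriors(beta1_mean=0.0, beta1_sd=100.0)
    fit_m = pc.fit_age_depth(core, core_curve, priors=pr_m,
                             mcmc=_mcmc(6, 1500, 500))
    fit_cm = pc.fit_age_depth(core_cm, core_curve, priors=pr_cm,
                              mcmc=_mcmc(6, 1500, 500))
    assert np.allclose(fit_cm.beta1_samples * 100.0, fit_m.beta1_samples,
                       rtol=1e-9, atol=1e-9)


def test_count_reversals(core_curve):
    core, _ = _noiseless_core(core_curve)
    assert pc.count_reversals(core, core_curve) == 0
    # hand-built 4-sample core with one swapped pair
    ages = [2500.0, 3000.0, 2800.0, 3500.0]
    swapped = [pc.CoreSample(f"H{i}", 1.0 + i,
                             pc.Determination(f"H{i}", a, 5.0))
               for i, a in enumerate(ages)]
    assert pc.count_reversals(swapped, core_curve) == 1
    # random cores: equals a brute-force pairwise scan on calibrated means
    rng = np.random.default_rng(12)
    for _ in range(3):
        n = 8
        ages = rng.uniform(2000, 6000, n)
        core_r = [pc.CoreSample(f"R{i}", 0.5 * (i + 1),
                                pc.Determination(f"R{i}", float(a), 30.0))
                  for i, a in enumerate(ages)]
        grid = pc.CalendarGrid(core_curve.calbp_max - 5,
                               core_curve.calbp_min + 5, 5)
        means = [pc.point_summaries(
            pc.calibrate_terrestrial(s.det, core_curve, grid))[0]
            for s in core_r]
        brute = sum(1 for i in range(n - 1) if means[i + 1] < means[i])
        assert pc.count_reversals(core_r, core_curve) == brute


def test_disturbed_core_single_replicate(core_curve):
    """One disturbed core: slope interval covers truth; the monotone
    baseline is visibly biased by the redeposited samples."""
    cfg = pc.CoreSimConfig(beta0=2000.0, beta1=500.0, sigma_eps=100.0,
                           depths=tuple(np.linspace(0.2, 6.0, 12)),
                           redeposit_fraction=2 / 12, redeposit_shift=800.0,
                           lab_sigma=40.0, seed=77)
    core, truth = pc.simulate_core(cfg, core_curve)
    assert truth["redeposited"].sum() == 2
    fit = pc.fit_age_depth(core, core_curve, mcmc=_mcmc(9))
    from phasecal.summaries import hpd_from_draws
    lo, hi = hpd_from_draws(fit.beta1_samples, 0.95)
    assert lo <= 500.0 <= hi
    base = monotone_baseline_slope(core, core_curve, n_boot=200, seed=5)
    assert base["hi"] - base["lo"] < hi - lo  # overconfident foil


def test_validation_errors(core_curve):
    core, _ = _noiseless_core(core_curve)
    with pytest.raises(pc.ValidationError):
        pc.fit_age_depth(core[:2], core_curve)
    flat = [pc.CoreSample(f"F{i}", 1.0, pc.Determination(f"F{i}", 3000.0, 30.0))
            for i in range(4)]
    with pytest.raises(pc.ValidationError):
        pc.fit_age_depth(flat, core_curve)
    far = [pc.CoreSample(f"X{i}", float(i), pc.Determination(f"X{i}", 30000.0, 30.0))
           for i in range(4)]
    with pytest.raises(pc.CurveRangeError):
        pc.fit_age_depth(far, core_curve)
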