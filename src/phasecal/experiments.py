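"""Seeded recovery experiments on synthetic data with known truth.

Each function simulates replicate datasets, runs the corresponding inference
on each, and reports frequentist recovery summaries (coverage of true
parameters, bias, detection rates).  Replicates are executed through the
batched samplers so a 100-replicate study costs little more than a single
fit.  These studies are the package's own validation evidence and are rerun
verbatim by ``scripts/acceptance.py``.

Problem sizes are desk-scale by design: around 10²–10³ retained draws per
chain and two chains per replicate, which keeps each study in the tens of
seconds while leaving Monte-Carlo error well inside the decision bands used
in the test suite (see docs/methods.md).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from ._kernel import PhaseKernel, PhaseStructure
from .agedepth import _AgeDepthKernel, monotone_baseline_slope
from .calibrate import CalendarGrid, calibrate_terrestrial
from .curves import CalibrationCurve, Determination
from .phase import OutlierSpec
from .reservoir import _ReservoirKernel
from .simulate import (
    CoreSimConfig,
    SiteSimConfig,
    simulate_calibration_curve,
    simulate_core,
    simulate_paired_reservoir,
    simulate_phased_site,
)
from .summaries import hpd_from_draws


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def _batch_range(x: np.ndarray, sig: np.ndarray, curve: CalibrationCurve,
                 pad: float = 500.0, step: float = 5.0) -> Tuple[float, float]:
    """Union of per-date 99.9 % calibrated supports across a batch, padded.

    Mirrors the default overall-range rule of ``build_model`` for batched
    datasets sharing one curve.
    """
    grid = np.arange(curve.calbp_min + step, curve.calbp_max - step, step)
    mu, sc = curve.interp_unchecked(grid)
    old, young = -np.inf, np.inf
    for xi, si in zip(x.ravel(), sig.ravel()):
        var = si * si + sc * sc
        ll = -0.5 * np.log(var) - (xi - mu) ** 2 / (2 * var)
        w = np.exp(ll - ll.max())
        c = np.cumsum(w / w.sum())
        young = min(young, grid[np.searchsorted(c, 0.0005)])
        old = max(old, grid[min(np.searchsorted(c, 0.9995), grid.size - 1)])
    return (min(old + pad, curve.calbp_max - step),
            max(young - pad, curve.calbp_min + step))


def _study_curve(seed: int = 3) -> CalibrationCurve:
    """The mildly wiggly terrestrial curve used across the phase studies."""
    return simulate_calibration_curve((11000, 5000), wiggle_amplitude=15.0,
                                      wiggle_period=600.0, sigma=8.0, seed=seed)


# --------------------------------------------------------------------------
def calibration_oracle_check(n_cases: int = 100, seed: int = 0) -> Dict:
    """Single-date calibration vs an independent brute-force oracle.

    For each case a fresh random wiggly curve and a random date are drawn;
    the calibrated density is compared cell-wise with a direct normalised
    Gaussian-likelihood sum computed by an independent code path, and (on an
    identity curve) with the closed-form Gaussian posterior.
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_cases):
        curve = simulate_calibration_curve(
            (10000, 2000), wiggle_amplitude=float(rng.uniform(0, 60)),
            wiggle_period=float(rng.uniform(200, 1500)),
            sigma=float(rng.uniform(2, 25)), seed=int(rng.integers(2 ** 31)),
            noise_amplitude=float(rng.uniform(0, 30)))
        x = float(rng.uniform(3500, 8500))
        s = float(rng.uniform(15, 80))
        det = Determination("case", x, s)
        grid = CalendarGrid(9800.0, 2200.0, 1.0)
        dens = calibrate_terrestrial(det, curve, grid)
        # brute-force oracle: per-cell Gaussian pdf, normalised directly
        theta = grid.values()
        mu, sc = curve(theta)
        sd = np.sqrt(s * s + sc * sc)
        pdf = np.exp(-0.5 * ((x - mu) / sd) ** 2) / sd
        pdf = pdf / pdf.sum()
        max_err = max(max_err, float(np.abs(dens.density - pdf).max()))
    # closed form on a linear curve with constant (negligible) curve error
    from .simulate import identity_curve
    ident = identity_curve((12000, 2000))
    det = Determination("cf", 7000.0, 50.0)
    grid = CalendarGrid(8000.0, 6000.0, 1.0)
    dens = calibrate_terrestrial(det, ident, grid)
    theta = grid.values()
    gauss = np.exp(-0.5 * ((theta - 7000.0) / 50.0) ** 2)
    gauss /= gauss.sum()
    gauss_err = float(np.abs(dens.density - gauss).max())
    return {"max_abs_cell_error": max_err, "gaussian_closed_form_error": gauss_err,
            "n": n_cases}


# --------------------------------------------------------------------------
def phase_start_recovery(n_sites: int = 100, seed: int = 0,
                         n_dates: int = 30, lab_sigma: float = 40.0,
                         span: Tuple[float, float] = (8500.0, 7500.0),
                         chains: int = 2, iterations: int = 8000,
                         burn_in: int = 1500, thin: int = 2) -> Dict:
    """Coverage and bias of the start boundary over replicate sites.

    Each replicate is a single uniform-boundary phase with ``n_dates`` dates
    drawn uniformly in the true span and observed through the study curve.
    """
    curve = _study_curve()
    seeds = _spawn_seeds(seed, n_sites)
    xs, sgs = [], []
    for s in seeds:
        cfg = SiteSimConfig(phase_truths=(span,), dates_per_phase=n_dates,
                            lab_sigma=lab_sigma, seed=int(s))
        table, _ = simulate_phased_site(cfg, curve)
        xs.append([r.c14_age for r in table])
        sgs.append([r.c14_sigma for r in table])
    x = np.asarray(xs)
    sg = np.asarray(sgs)
    rng_all = _batch_range(x, sg, curve)
    st = PhaseStructure([{"idx": np.arange(n_dates), "btype": "uniform"}],
                        contiguous=True)
    kern = PhaseKernel(x, sg, np.zeros(n_dates, bool), curve, None, st,
                       rng_all, outlier=None)
    store = kern.run(chains=chains, iterations=iterations, burn_in=burn_in,
                     thin=thin, seed=seed + 1)
    start = store["bounds"][:, :, :, 0]           # (B, C, T)
    covered = 0
    biases = []
    for b in range(n_sites):
        lo, hi = hpd_from_draws(start[b], 0.95)
        covered += int(lo <= span[0] <= hi)
        biases.append(start[b].mean() - span[0])
    return {"coverage_pct": 100.0 * covered / n_sites,
            "mean_bias_yr": float(np.mean(biases)),
            "mean_abs_bias_yr": float(np.abs(np.mean(biases))),
            "n": n_sites}


# --------------------------------------------------------------------------
def outlier_detection(n_sites: int = 100, seed: int = 0, n_dates: int = 20,
                      shift: float = 1000.0, lab_sigma: float = 40.0,
                      span: Tuple[float, float] = (8500.0, 7500.0),
                      chains: int = 2, iterations: int = 4000,
                      burn_in: int = 1500, thin: int = 2) -> Dict:
    """Detection of one injected +shift outlier, and false alarms on clean data.

    Reports the rate (over replicates) at which the injected date attains the
    maximum posterior outlier probability, and the rate at which clean
    replicates keep every posterior outlier probability at or below 0.15.
    """
    curve = _study_curve()
    out = OutlierSpec()
    results = {}
    for arm in ("injected", "clean"):
        seeds = _spawn_seeds(seed + (0 if arm == "injected" else 7), n_sites)
        xs, sgs, inj = [], [], []
        for s in seeds:
            cfg = SiteSimConfig(
                phase_truths=(span,), dates_per_phase=n_dates,
                lab_sigma=lab_sigma, seed=int(s),
                inject_outlier_shift=shift if arm == "injected" else None)
            table, truth = simulate_phased_site(cfg, curve)
            xs.append([r.c14_age for r in table])
            sgs.append([r.c14_sigma for r in table])
            if arm == "injected":
                inj.append(int(np.argmax(truth["is_outlier"])))
        x = np.asarray(xs)
        sg = np.asarray(sgs)
        rng_all = _batch_range(x, sg, curve)
        # "sigma" boundaries, as in a site model whose phase tails may
        # overlap; tails cover edge dates so the outlier component only
        # fires on genuinely extreme ones
        st = PhaseStructure([{"idx": np.arange(n_dates), "btype": "sigma"}],
                            contiguous=True)
        kern = PhaseKernel(x, sg, np.zeros(n_dates, bool), curve, None, st,
                           rng_all, outlier=out)
        store = kern.run(chains=chains, iterations=iterations, burn_in=burn_in,
                         thin=thin, seed=seed + 13)
        p = store["phi"].mean(axis=(1, 2))        # (B, N) posterior P(outlier)
        if arm == "injected":
            inj = np.asarray(inj)
            top = (np.argmax(p, axis=1) == inj)
            results["injected_top_rate_pct"] = 100.0 * float(top.mean())
            results["injected_p_mean"] = float(p[np.arange(n_sites), inj].mean())
        else:
            ok = (p.max(axis=1) <= 0.15)
            results["clean_max_le_015_pct"] = 100.0 * float(ok.mean())
            results["clean_mean_p"] = float(p.mean())
    results["n"] = n_sites
    return results


# --------------------------------------------------------------------------
def delta_r_recovery(n_reps: int = 100, seed: int = 0,
                     true_delta_r: float = 150.0, n_contexts: int = 5,
                     n_terr: int = 2, n_marine: int = 3,
                     lab_sigma: float = 35.0, halfwidth: float = 1000.0,
                     n_null: int = 20, chains: int = 2, iterations: int = 3000,
                     burn_in: int = 1000, thin: int = 2) -> Dict:
    """ΔR recovery: 95 % HPD coverage of the true offset, plus a null arm."""
    terr = simulate_calibration_curve((11000, 5000), wiggle_amplitude=12.0,
                                      wiggle_period=700.0, sigma=8.0, seed=21)
    mar = simulate_calibration_curve((11000, 5000), wiggle_amplitude=10.0,
                                     wiggle_period=900.0, sigma=10.0, seed=22,
                                     kind="marine")

    def batch(n, dr, seed0):
        seeds = _spawn_seeds(seed0, n)
        xs, sgs = [], []
        marine_mask, ctx_idx = None, None
        for s in seeds:
            pairs, _ = simulate_paired_reservoir(
                n_contexts, n_terr, n_marine, dr, terr, mar,
                lab_sigma=lab_sigma, seed=int(s))
            x, sg, mm, ci = [], [], [], []
            for c, p in enumerate(pairs):
                for d in p.terrestrial + p.marine:
                    x.append(d.c14_age)
                    sg.append(d.c14_sigma)
                    mm.append(d.material == "marine")
                    ci.append(c)
            xs.append(x)
            sgs.append(sg)
            marine_mask, ctx_idx = mm, ci
        x = np.asarray(xs)
        sg = np.asarray(sgs)
        lo = max(terr.calbp_min, mar.calbp_min)
        hi = min(terr.calbp_max, mar.calbp_max)
        th_range = (min(x.max() + halfwidth + 500, hi - 1),
                    max(x.min() - halfwidth - 500, lo + 1))
        kern = _ReservoirKernel(x, sg, marine_mask, ctx_idx, n_contexts,
                                terr, mar, halfwidth, th_range)
        dr_draws, _ = kern.run(chains=chains, iterations=iterations,
                               burn_in=burn_in, thin=thin, seed=seed0 + 1)
        return dr_draws

    dr_draws = batch(n_reps, true_delta_r, seed)
    covered = 0
    means = []
    for b in range(n_reps):
        lo, hi = hpd_from_draws(dr_draws[b], 0.95)
        covered += int(lo <= true_delta_r <= hi)
        means.append(dr_draws[b].mean())
    null_draws = batch(n_null, 0.0, seed + 101)
    null_means = null_draws.reshape(n_null, -1).mean(axis=1)
    return {"coverage_pct": 100.0 * covered / n_reps,
            "posterior_mean": float(np.mean(means)),
            "null_mean": float(null_means.mean()),
            "null_mean_se": float(null_means.std() / np.sqrt(n_null)),
            "n": n_reps}


# --------------------------------------------------------------------------
def agedepth_recovery(n_reps: int = 100, seed: int = 0,
                      n_redeposited: int = 2, n_samples: int = 12,
                      chains: int = 2, iterations: int = 4000,
                      burn_in: int = 1500, thin: int = 2,
                      n_boot: int = 200) -> Dict:
    """Slope recovery on disturbed cores vs the monotone baseline.

    Replicate cores follow a true line (β0=2000, β1=500 yr/m, σ_ε=100) with
    ``n_redeposited`` of ``n_samples`` samples shifted +800 yr (old material
    moved up).  Reports 95 % coverage of β1 for the Bayesian regression and
    for the monotone-interpolation baseline, and the fraction of imputation
    depths where predictive variance exceeds line variance.
    """
    curve = simulate_calibration_curve((8000, 800), wiggle_amplitude=12.0,
                                       wiggle_period=650.0, sigma=8.0, seed=31)
    from .agedepth import AgeDepthPriors
    seeds = _spawn_seeds(seed, n_reps)
    cores = []
    xs, sgs = [], []
    depths = tuple(np.linspace(0.2, 6.0, n_samples))
    for s in seeds:
        cfg = CoreSimConfig(beta0=2000.0, beta1=500.0, sigma_eps=100.0,
                            depths=depths,
                            redeposit_fraction=n_redeposited / n_samples,
                            redeposit_shift=800.0, lab_sigma=40.0, seed=int(s))
        core, _ = simulate_core(cfg, curve)
        cores.append(core)
        xs.append([c.det.c14_age for c in core])
        sgs.append([c.det.c14_sigma for c in core])
    x = np.asarray(xs)
    sg = np.asarray(sgs)
    kern = _AgeDepthKernel(x, sg, np.asarray(depths), curve, AgeDepthPriors())
    b, s_eps, th = kern.run(chains=chains, iterations=iterations,
                            burn_in=burn_in, thin=thin, seed=seed + 3)
    cov_bayes = 0
    cov_base = 0
    for r in range(n_reps):
        lo, hi = hpd_from_draws(b[r, :, :, 1], 0.95)
        cov_bayes += int(lo <= 500.0 <= hi)
        base = monotone_baseline_slope(cores[r], curve, n_boot=n_boot,
                                       seed=int(seeds[r]) % (2 ** 31))
        cov_base += int(base["lo"] <= 500.0 <= base["hi"])
    # predictive-variance law on the first replicate
    b0 = b[0, :, :, 0].ravel()
    b1 = b[0, :, :, 1].ravel()
    se = s_eps[0].ravel()
    rng = np.random.default_rng(seed + 5)
    var_ok = 0
    test_depths = np.linspace(0.0, 6.5, 14)
    for d in test_depths:
        line = b0 + b1 * d
        pred = line + se * rng.standard_normal(line.size)
        var_ok += int(pred.var() >= line.var())
    return {"bayes_coverage_pct": 100.0 * cov_bayes / n_reps,
            "baseline_coverage_pct": 100.0 * cov_base / n_reps,
            "predictive_var_ok_frac": var_ok / test_depths.size,
            "n": n_reps}


# --------------------------------------------------------------------------
def determinism_check(seed: int = 0) -> Dict:
    """Every sampler reruns bit-identically from a fixed seed."""
    curve = _study_curve()
    cfg = SiteSimConfig(dates_per_phase=8, seed=seed)
    table, _ = simulate_phased_site(cfg, curve)
    x = np.array([[r.c14_age for r in table]])
    sg = np.array([[r.c14_sigma for r in table]])
    st = PhaseStructure([{"idx": np.arange(8), "btype": "sigma"}],
                        contiguous=True)
    rng_all = _batch_range(x, sg, curve)
    runs = []
    for _ in range(2):
        kern = PhaseKernel(x, sg, np.zeros(8, bool), curve, None, st, rng_all,
                           outlier=OutlierSpec())
        store = kern.run(chains=2, iterations=600, burn_in=200, thin=1,
                         seed=seed + 17)
        runs.append(store)
    same_phase = (np.array_equal(runs[0]["bounds"], runs[1]["bounds"])
                  and np.array_equal(runs[0]["theta"], runs[1]["theta"])
                  and np.array_equal(runs[0]["phi"], runs[1]["phi"]))
    # age-depth sampler
    core_cfg = CoreSimConfig(seed=seed)
    curve2 = simulate_calibration_curve((8000, 800), sigma=8.0, seed=31)
    core, _ = simulate_core(core_cfg, curve2)
    from .agedepth import AgeDepthPriors, fit_age_depth
    from .phase import McmcSettings
    fits = [fit_age_depth(core, curve2,
                          mcmc=McmcSettings(chains=2, iterations=1200,
                                            burn_in=400, thin=1, seed=seed + 19))
            for _ in range(2)]
    same_ad = np.array_equal(fits[0].beta1_samples, fits[1].beta1_samples)
    return {"identical": float(same_phase and same_ad), "n": 2}
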