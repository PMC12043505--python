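"""Marine reservoir (ΔR) estimation and propagation."""

import numpy as np
import pytest
from scipy import stats

import phasecal as pc
from phasecal.reservoir import _ReservoirKernel


@pytest.fixture(scope="module")
def curves():
    terr = pc.simulate_calibration_curve((11000, 5000), wiggle_amplitude=12,
                                         wiggle_period=700, sigma=8, seed=21)
    mar = pc.simulate_calibration_curve((11000, 5000), wiggle_amplitude=10,
                                        wiggle_period=900, sigma=10, seed=22,
                                        kind="marine")
    return terr, mar


def _mcmc(seed=0):
    return pc.McmcSettings(chains=2, iterations=3000, burn_in=1000,
                           thin=2, seed=seed)


def test_null_delta_r_recovery(curves):
    terr, mar = curves
    pairs, _ = pc.simulate_paired_reservoir(5, 2, 3, 0.0, terr, mar, seed=1)
    post = pc.estimate_delta_r(pairs, terr, mar, mcmc=_mcmc(2))
    assert abs(post.mean) < 3.0 * post.sd
    assert np.all(np.abs(post.samples) <= post.prior_halfwidth)


def test_offset_recovered_when_curves_identical():
    """Marine curve equal to the terrestrial one: the posterior centres on
    the simulated shell offset."""
    terr = pc.simulate_calibration_curve((11000, 5000), wiggle_amplitude=12,
                                         wiggle_period=700, sigma=8, seed=21)
    mar = pc.CalibrationCurve("m", terr.knots_calbp, terr.knots_c14,
                              terr.knots_sigma, kind="marine")
    pairs, _ = pc.simulate_paired_reservoir(5, 2, 3, 150.0, terr, mar, seed=3)
    post = pc.estimate_delta_r(pairs, terr, mar, mcmc=_mcmc(4))
    assert abs(post.mean - 150.0) < 3.0 * post.sd


def test_sd_shrinks_with_more_contexts(curves):
    """Posterior sd for 5 contexts beats 1 context (paired sign test over
    50 replicates)."""
    terr, mar = curves

    def batch_sd(n_ctx, seed0):
        xs, sgs = [], []
        marine, ctx = None, None
        rng = np.random.default_rng(seed0)
        for _ in range(50):
            pairs, _ = pc.simulate_paired_reservoir(
                n_ctx, 2, 3, 150.0, terr, mar, seed=int(rng.integers(2 ** 31)))
            x, sg, mm, ci = [], [], [], []
            for c, p in enumerate(pairs):
                for d in p.terrestrial + p.marine:
                    x.append(d.c14_age)
                    sg.append(d.c14_sigma)
                    mm.append(d.material == "marine")
                    ci.append(c)
            xs.append(x)
            sgs.append(sg)
            marine, ctx = mm, ci
        x = np.asarray(xs)
        kern = _ReservoirKernel(x, np.asarray(sgs), marine, ctx, n_ctx,
                                terr, mar, 1000.0,
                                (x.max() + 1500, x.min() - 1500))
        dr, _ = kern.run(chains=2, iterations=2500, burn_in=800, thin=2,
                         seed=seed0)
        return dr.reshape(50, -1).std(axis=1)

    sd1 = batch_sd(1, 100)
    sd5 = batch_sd(5, 100)
    wins = int((sd5 < sd1).sum())
    assert stats.binomtest(wins, 50, 0.5, alternative="greater").pvalue < 0.05


def test_screening_drops_low_agreement_samples(curves):
    terr, mar = curves
    pairs, _ = pc.simulate_paired_reservoir(4, 2, 3, 150.0, terr, mar, seed=9)
    # sabotage one shell far beyond what DeltaR can absorb coherently
    bad = pairs[0].marine[0]
    pairs[0].marine[0] = pc.Determination(bad.lab_code, bad.c14_age + 900.0,
                                          bad.c14_sigma, material="marine",
                                          context_id=bad.context_id)
    post = pc.estimate_delta_r(pairs, terr, mar, mcmc=_mcmc(6))
    assert any(code == bad.lab_code for code, _ in post.excluded)
    assert all(a < 60.0 for _, a in post.excluded)


def test_divergence_error_names_contexts(curves):
    terr, mar = curves
    pairs, _ = pc.simulate_paired_reservoir(2, 2, 2, 0.0, terr, mar, seed=5)
    # marine dates implying a reservoir offset far outside the prior box
    pairs[1] = pc.PairedContext(
        context_id=pairs[1].context_id,
        terrestrial=pairs[1].terrestrial,
        marine=[pc.Determination(d.lab_code, d.c14_age + 5000.0, d.c14_sigma,
                                 material="marine", context_id=d.context_id)
                for d in pairs[1].marine])
    with pytest.raises(pc.DivergenceError):
        pc.estimate_delta_r(pairs, terr, mar, prior_halfwidth=500.0,
                            mcmc=_mcmc(7), screen=False)


def test_apply_delta_r(curves):
    terr, mar = curves
    shells = pc.DateTable(rows=[
        pc.Determination(f"S{i}", 8000.0 + 15 * i, 40.0, material="marine")
        for i in range(49)])
    grid = pc.CalendarGrid(10200.0, 5800.0, 5.0)
    dr0 = pc.DeltaRPosterior(samples=np.zeros(10), prior_halfwidth=1000.0,
                             mean=0.0, sd=0.0, hpd95=(0.0, 0.0))
    densities, summary = pc.apply_delta_r(shells, mar, dr0, grid)
    assert len(densities) == 49
    assert summary["n_shells"] == 49
    assert summary["oldest_mean_calbp"] > summary["youngest_mean_calbp"]
    # degenerate DeltaR at 0 equals the plain marine calibration
    plain = pc.calibrate_marine(shells.rows[0], mar, 0.0, 0.0, grid)
    assert np.array_equal(densities[0].density, plain.density)
    with pytest.raises(pc.ValidationError):
        pc.apply_delta_r(pc.DateTable(rows=[pc.Determination("T", 8000, 40)]),
                         mar, dr0, grid)


def test_paired_context_validation():
    with pytest.raises(pc.ValidationError):
        pc.PairedContext("c", [], [pc.Determination("M", 8000, 40,
                                                    material="marine")])
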