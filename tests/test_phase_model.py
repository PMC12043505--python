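"""Phase-model construction, prior, posterior sampling and reports."""

import numpy as np
import pytest
from scipy import stats

import phasecal as pc
from phasecal.phase import boundary_estimates, boundary_labels


def _members(table):
    return [r.lab_code for r in table]


# -------------------------------------------------------------- build_model
def test_three_contiguous_phases_have_four_boundaries(wiggly):
    rows = [pc.Determination(f"L{i}", 7600.0 + 30 * i, 40.0) for i in range(33)]
    table = pc.DateTable(rows=rows)
    phases = [
        pc.PhaseSpec("V", members=[f"L{i}" for i in range(0, 11)]),
        pc.PhaseSpec("IV", members=[f"L{i}" for i in range(11, 22)]),
        pc.PhaseSpec("III", members=[f"L{i}" for i in range(22, 33)]),
    ]
    model = pc.build_model(table, phases[::-1], wiggly, contiguous=True)
    assert len(boundary_labels(model)) == 4


def test_build_model_validation_errors(wiggly, single_phase_site):
    table, _ = single_phase_site
    codes = _members(table)
    with pytest.raises(pc.ValidationError):
        pc.build_model(table, [], wiggly)
    with pytest.raises(pc.ValidationError, match="both"):
        pc.build_model(table, [pc.PhaseSpec("a", members=codes[:5]),
                               pc.PhaseSpec("b", members=codes[4:8])], wiggly)
    with pytest.raises(pc.ValidationError, match="unknown"):
        pc.build_model(table, [pc.PhaseSpec("a", members=["nope"])], wiggly)
    with pytest.raises(pc.ValidationError):
        pc.PhaseSpec("empty", members=[])
    marine_table = pc.DateTable(rows=[
        pc.Determination("M1", 8500.0, 40.0, material="marine"),
        pc.Determination("T1", 8000.0, 40.0)])
    with pytest.raises(pc.ValidationError, match="delta_r"):
        pc.build_model(marine_table, [pc.PhaseSpec("p", members=["M1", "T1"])],
                       wiggly)


# ------------------------------------------------------------- log posterior
def test_log_posterior_matches_single_date_calibration(wiggly):
    """With pinned wide boundaries and one date, lp(theta) differences equal
    the single-date calibration log-density differences."""
    det = pc.Determination("D", 8200.0, 45.0)
    table = pc.DateTable(rows=[det])
    phases = [pc.PhaseSpec("p", boundary_type="uniform", members=["D"],
                           fixed_start=9400.0, fixed_end=7000.0)]
    model = pc.build_model(table, phases, wiggly, outlier=None,
                           overall_range=(9500.0, 6900.0))
    grid = pc.CalendarGrid(9300.0, 7100.0, 20.0)
    dens = pc.calibrate_terrestrial(det, wiggly, grid)
    logd = np.log(dens.density)
    thetas = grid.values()
    lps = np.array([
        pc.log_posterior({"theta": [th], "bounds": [9400.0, 7000.0]}, model)
        for th in thetas])
    delta = (lps - lps[0]) - (logd - logd[0])
    assert np.abs(delta).max() < 1e-9


def test_log_posterior_outside_uniform_phase_is_minus_inf(wiggly):
    det = pc.Determination("D", 8200.0, 45.0)
    table = pc.DateTable(rows=[det])
    phases = [pc.PhaseSpec("p", boundary_type="uniform", members=["D"])]
    model = pc.build_model(table, phases, wiggly, outlier=None)
    lp = pc.log_posterior({"theta": [8600.0], "bounds": [8500.0, 8000.0]}, model)
    assert lp == -np.inf


def test_wider_pinned_span_lowers_event_factor(wiggly):
    det = pc.Determination("D", 8200.0, 45.0)
    table = pc.DateTable(rows=[det])

    def lp(start, end):
        phases = [pc.PhaseSpec("p", boundary_type="uniform", members=["D"],
                               fixed_start=start, fixed_end=end)]
        model = pc.build_model(table, phases, wiggly, outlier=None,
                               overall_range=(9500.0, 6900.0))
        return pc.log_posterior({"theta": [8200.0], "bounds": [start, end]},
                                model)

    vals = [lp(8200 + w, 8200 - w) for w in (200.0, 400.0, 800.0)]
    assert vals[0] > vals[1] > vals[2]


# ------------------------------------------------------ prior predictive span
def test_prior_predictive_span_is_uniform(wiggly, single_phase_site):
    table, _ = single_phase_site
    model = pc.build_model(
        table, [pc.PhaseSpec("p", boundary_type="uniform",
                             members=_members(table))],
        wiggly, outlier=None, overall_range=(9200.0, 6800.0))
    spans = pc.prior_predictive_span(model, draws=10000, seed=2)["p"]
    R = 9200.0 - 6800.0
    ks = stats.kstest(spans / R, "uniform")
    assert ks.pvalue > 0.01
    # correction independent of n: a 1-member phase draws the same spans
    one = pc.build_model(
        table, [pc.PhaseSpec("p", boundary_type="uniform",
                             members=_members(table)[:1])],
        wiggly, outlier=None, overall_range=(9200.0, 6800.0))
    spans_one = pc.prior_predictive_span(one, draws=10000, seed=2)["p"]
    assert np.array_equal(spans, spans_one)
    # seed determinism
    again = pc.prior_predictive_span(model, draws=10000, seed=2)["p"]
    assert np.array_equal(spans, again)


# ---------------------------------------------------------------- posterior
def test_seeded_runs_are_bit_identical(wiggly, single_phase_site, quick_mcmc):
    table, _ = single_phase_site
    model = pc.build_model(
        table, [pc.PhaseSpec("p", boundary_type="uniform",
                             members=_members(table))], wiggly, outlier=None)
    r1 = pc.sample_posterior(model, quick_mcmc)
    r2 = pc.sample_posterior(model, quick_mcmc)
    for lab in r1.boundary_samples:
        assert np.array_equal(r1.boundary_samples[lab], r2.boundary_samples[lab])


def test_single_phase_start_recovery(wiggly, single_phase_site, quick_mcmc):
    table, truth = single_phase_site
    model = pc.build_model(
        table, [pc.PhaseSpec("p", boundary_type="uniform",
                             members=_members(table))], wiggly, outlier=None)
    res = pc.sample_posterior(model, quick_mcmc)
    start = res.boundary_samples["start p"].ravel()
    assert abs(start.mean() - 8500.0) < 3.0 * start.std()
    # uniform-phase invariant holds draw by draw
    ev = np.stack([res.event_samples[c] for c in _members(table)], axis=-1)
    s = res.boundary_samples["start p"]
    e = res.boundary_samples["end p"]
    assert np.all(s >= ev.max(axis=-1))
    assert np.all(e <= ev.min(axis=-1))


def test_event_marginal_matches_calibration_when_unconstrained(wiggly):
    """Single pinned phase spanning the whole range, no outliers: each event's
    marginal posterior equals its own calibration (TV < 0.02)."""
    rows = [pc.Determination("A", 8300.0, 45.0),
            pc.Determination("B", 7900.0, 50.0),
            pc.Determination("C", 7400.0, 40.0)]
    table = pc.DateTable(rows=rows)
    old, young = 9200.0, 6600.0
    phases = [pc.PhaseSpec("p", boundary_type="uniform", members=["A", "B", "C"],
                           fixed_start=old, fixed_end=young)]
    model = pc.build_model(table, phases, wiggly, outlier=None,
                           overall_range=(old, young))
    res = pc.sample_posterior(model, pc.McmcSettings(
        chains=4, iterations=11000, burn_in=1000, thin=2, seed=9))
    grid = pc.CalendarGrid(old, young, 15.0)
    for code in ("A", "B", "C"):
        draws = res.event_samples[code].ravel()
        assert draws.size == 20000
        hist = pc.density_from_samples(draws, grid)
        calib = pc.calibrate_terrestrial(table.get(code), wiggly, grid)
        tv = 0.5 * np.abs(hist.density - calib.density).sum()
        assert tv < 0.02


def test_boundary_estimates_reports(wiggly, single_phase_site, quick_mcmc):
    table, _ = single_phase_site
    model = pc.build_model(
        table, [pc.PhaseSpec("p", boundary_type="uniform",
                             members=_members(table))], wiggly, outlier=None)
    res = pc.sample_posterior(model, quick_mcmc)
    df = boundary_estimates(res)
    assert len(df) == 2
    for _, row in df.iterrows():
        raw = res.boundary_samples[row["boundary"]].ravel()
        assert row["mean_calbp"] == pytest.approx(raw.mean(), abs=1e-9)
        assert row["median_calbp"] == pytest.approx(np.median(raw), abs=1e-9)
        assert row["mean_ka"] == round(raw.mean() / 1000.0, 1)
    # degenerate draws: zero-width interval, mean == median
    res.boundary_samples = {"b": np.full((2, 50), 8000.0)}
    df = boundary_estimates(res)
    assert df.loc[0, "mean_calbp"] == df.loc[0, "median_calbp"] == 8000.0
    assert df.loc[0, "hpd95_older"] == df.loc[0, "hpd95_younger"]


def test_three_phase_contiguous_run_reports_four_boundaries(wiggly):
    cfg = pc.SiteSimConfig(
        phase_truths=((8500.0, 8200.0), (8200.0, 7900.0), (7900.0, 7500.0)),
        dates_per_phase=8, lab_sigma=40.0, seed=23)
    table, _ = pc.simulate_phased_site(cfg, wiggly)
    phases = [pc.PhaseSpec(f"P{j}", boundary_type="sigma",
                           members=[r.lab_code for r in table
                                    if r.phase_id == f"phase{j}"])
              for j in range(3)]
    model = pc.build_model(table, phases, wiggly, outlier=None, contiguous=True)
    res = pc.sample_posterior(model, pc.McmcSettings(
        chains=2, iterations=2500, burn_in=1000, thin=2, seed=4))
    df = boundary_estimates(res)
    assert len(df) == 4
    # boundaries ordered older -> younger in every draw
    b = np.stack([res.boundary_samples[lab] for lab in df["boundary"]], -1)
    assert np.all(np.diff(b, axis=-1) <= 0)
    assert "rhat" in res.diagnostics.columns
    assert len(res.diagnostics) == 4
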