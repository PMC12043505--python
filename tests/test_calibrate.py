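"""Single-date calibration, HPD sets, summaries and the agreement index."""

import numpy as np
import pytest

import phasecal as pc


def _brute_force(det, curve, grid, dr_mean=0.0, dr_sigma=0.0):
    """Independent normalised-likelihood sum (plain loop over cells)."""
    theta = grid.values()
    out = np.empty(theta.size)
    for i, th in enumerate(theta):
        mu, sc = curve(th)
        var = det.c14_sigma ** 2 + sc ** 2 + dr_sigma ** 2
        out[i] = np.exp(-0.5 * (det.c14_age - mu - dr_mean) ** 2 / var) \
            / np.sqrt(var)
    return out / out.sum()


def test_identity_curve_gives_gaussian_posterior(identity):
    det = pc.Determination("X", 7000.0, 50.0)
    grid = pc.CalendarGrid(8000.0, 6000.0, 1.0)
    dens = pc.calibrate_terrestrial(det, identity, grid)
    theta = grid.values()
    gauss = np.exp(-0.5 * ((theta - 7000.0) / 50.0) ** 2)
    gauss /= gauss.sum()
    assert np.abs(dens.density - gauss).max() < 1e-12


def test_matches_brute_force_on_wiggly_curve(wiggly):
    det = pc.Determination("X", 8200.0, 45.0)
    grid = pc.CalendarGrid(9500.0, 7000.0, 5.0)
    dens = pc.calibrate_terrestrial(det, wiggly, grid)
    oracle = _brute_force(det, wiggly, grid)
    assert np.abs(dens.density - oracle).max() < 1e-12


def test_marine_path_enforced(wiggly):
    shells = [pc.Determination(f"S-{i}", 8000.0, 40.0, material="marine")
              for i in range(49)]
    grid = pc.CalendarGrid(9500.0, 7000.0, 5.0)
    for det in shells:
        with pytest.raises(pc.ValidationError):
            pc.calibrate_terrestrial(det, wiggly, grid)


def test_marine_reduces_to_terrestrial_at_zero_delta_r():
    curve = pc.identity_curve((12000, 2000), kind="marine")
    grid = pc.CalendarGrid(8000.0, 6000.0, 1.0)
    det_m = pc.Determination("S", 7000.0, 50.0, material="marine")
    det_t = pc.Determination("T", 7000.0, 50.0, material="terrestrial")
    terr_curve = pc.identity_curve((12000, 2000))
    marine = pc.calibrate_marine(det_m, curve, 0.0, 0.0, grid)
    terrestrial = pc.calibrate_terrestrial(det_t, terr_curve, grid)
    assert np.array_equal(marine.density, terrestrial.density)


def test_delta_r_shifts_posterior_older_compensated():
    curve = pc.identity_curve((12000, 2000), kind="marine")
    grid = pc.CalendarGrid(8000.0, 6000.0, 1.0)
    det = pc.Determination("S", 7000.0, 50.0, material="marine")
    base = pc.calibrate_marine(det, curve, 0.0, 0.0, grid)
    shifted = pc.calibrate_marine(det, curve, 100.0, 0.0, grid)
    m0 = pc.point_summaries(base)[0]
    m1 = pc.point_summaries(shifted)[0]
    assert abs((m1 - m0) - (-100.0)) < 0.5


def test_marine_brute_force(wiggly):
    curve = pc.CalibrationCurve("m", wiggly.knots_calbp, wiggly.knots_c14 + 300,
                                wiggly.knots_sigma * 1.5, kind="marine")
    det = pc.Determination("S", 8400.0, 35.0, material="marine")
    grid = pc.CalendarGrid(9500.0, 7000.0, 5.0)
    dens = pc.calibrate_marine(det, curve, 150.0, 30.0, grid)
    oracle = _brute_force(det, curve, grid, dr_mean=150.0, dr_sigma=30.0)
    assert np.abs(dens.density - oracle).max() < 1e-12


def test_degenerate_posterior_raises(identity):
    det = pc.Determination("X", 11900.0, 5.0)
    grid = pc.CalendarGrid(3000.0, 2500.0, 1.0)
    with pytest.raises(pc.DegeneratePosteriorError):
        pc.calibrate_terrestrial(det, identity, grid)


# ----------------------------------------------------------------- HPD sets
def _gaussian_density(mean=7000.0, sd=50.0, step=1.0):
    grid = pc.CalendarGrid(mean + 6 * sd, mean - 6 * sd, step)
    theta = grid.values()
    p = np.exp(-0.5 * ((theta - mean) / sd) ** 2)
    return pc.CalibratedDensity(grid, p / p.sum())


def test_hpd_gaussian_two_sigma():
    dens = _gaussian_density()
    hpd = pc.hpd_intervals(dens, 0.954)
    assert len(hpd.intervals) == 1
    older, younger = hpd.intervals[0]
    assert abs(older - (7000 + 2 * 50)) <= 2.0
    assert abs(younger - (7000 - 2 * 50)) <= 2.0
    assert hpd.attained >= 0.954


def test_hpd_bimodal_matches_threshold_oracle():
    grid = pc.CalendarGrid(7400.0, 6600.0, 1.0)
    theta = grid.values()
    p = (np.exp(-0.5 * ((theta - 7200) / 40) ** 2)
         + np.exp(-0.5 * ((theta - 6800) / 40) ** 2))
    dens = pc.CalibratedDensity(grid, p / p.sum())
    hpd = pc.hpd_intervals(dens, 0.9)
    assert len(hpd.intervals) == 2
    # oracle: scan density thresholds for the smallest superlevel set >= 0.9
    d = dens.density
    best = None
    for thr in np.unique(d)[::-1]:
        mask = d >= thr
        if d[mask].sum() >= 0.9:
            best = mask
            break
    chosen = np.zeros(d.size, bool)
    for older, younger in hpd.intervals:
        chosen |= (theta <= older) & (theta >= younger)
    assert np.array_equal(chosen, best)


def test_hpd_level_one_covers_support():
    dens = _gaussian_density()
    hpd = pc.hpd_intervals(dens, 1.0)
    assert hpd.attained == pytest.approx(1.0)
    nz = dens.calbp()[dens.density > 0]
    assert hpd.intervals[0][0] >= nz.max()
    assert hpd.intervals[-1][1] <= nz.min()


# ----------------------------------------------------------- point summaries
def test_point_summaries_symmetric_and_hand_value():
    dens = _gaussian_density()
    mean, median, mode = pc.point_summaries(dens)
    assert mean == pytest.approx(7000.0, abs=0.01)
    assert median == pytest.approx(7000.0, abs=1.0)
    assert mode == pytest.approx(7000.0, abs=0.01)
    tri = pc.CalibratedDensity(pc.CalendarGrid(3000.0, 2998.0, 1.0),
                               np.array([0.2, 0.5, 0.3]))
    mean, _, _ = pc.point_summaries(tri)
    # hand arithmetic: 0.2*3000 + 0.5*2999 + 0.3*2998
    assert mean == pytest.approx(2998.9, abs=1e-9)


def test_point_summaries_match_brute_force(wiggly):
    det = pc.Determination("X", 8200.0, 45.0)
    grid = pc.CalendarGrid(9500.0, 7000.0, 5.0)
    dens = pc.calibrate_terrestrial(det, wiggly, grid)
    theta = grid.values()
    mean, median, mode = pc.point_summaries(dens)
    assert mean == pytest.approx(float((dens.density * theta).sum()), abs=1e-9)
    csum = np.cumsum(dens.density)
    assert median == theta[np.searchsorted(csum, 0.5)]
    assert mode == theta[np.argmax(dens.density)]


def test_grid_refinement_stability(wiggly):
    det = pc.Determination("X", 8200.0, 45.0)
    d5 = pc.calibrate_terrestrial(det, wiggly, pc.CalendarGrid(9500, 7000, 5))
    d1 = pc.calibrate_terrestrial(det, wiggly, pc.CalendarGrid(9500, 7000, 1))
    for a, b in zip(pc.point_summaries(d5), pc.point_summaries(d1)):
        assert abs(a - b) < 5.0


# ----------------------------------------------------------- agreement index
def test_agreement_self_is_100():
    dens = _gaussian_density()
    assert pc.agreement_index(dens, dens) == pytest.approx(100.0)


def test_agreement_vanishes_without_overlap():
    grid = pc.CalendarGrid(8000.0, 6000.0, 1.0)
    theta = grid.values()
    a = np.exp(-0.5 * ((theta - 7700) / 30) ** 2)
    b = np.exp(-0.5 * ((theta - 6300) / 30) ** 2)
    da = pc.CalibratedDensity(grid, a / a.sum())
    db = pc.CalibratedDensity(grid, b / b.sum())
    assert pc.agreement_index(da, db) < 1e-6


def test_agreement_half_overlap_matches_direct_sum():
    grid = pc.CalendarGrid(8000.0, 6000.0, 1.0)
    theta = grid.values()
    a = np.exp(-0.5 * ((theta - 7050) / 60) ** 2)
    b = np.exp(-0.5 * ((theta - 6950) / 60) ** 2)
    da = pc.CalibratedDensity(grid, a / a.sum())
    db = pc.CalibratedDensity(grid, b / b.sum())
    direct = 100.0 * sum(pa * pb for pa, pb in zip(da.density, db.density)) \
        / sum(pa * pa for pa in da.density)
    assert pc.agreement_index(da, db) == pytest.approx(direct, abs=1e-9)


def test_agreement_grid_step_invariance():
    vals = {}
    for step in (1.0, 5.0):
        grid = pc.CalendarGrid(8000.0, 6000.0, step)
        theta = grid.values()
        a = np.exp(-0.5 * ((theta - 7050) / 60) ** 2)
        b = np.exp(-0.5 * ((theta - 6950) / 60) ** 2)
        vals[step] = pc.agreement_index(
            pc.CalibratedDensity(grid, a / a.sum()),
            pc.CalibratedDensity(grid, b / b.sum()))
    assert vals[1.0] == pytest.approx(vals[5.0], rel=1e-6)


def test_agreement_requires_shared_grid():
    da = _gaussian_density()
    db = _gaussian_density(step=2.0)
    with pytest.raises(pc.GridMismatchError):
        pc.agreement_index(da, db)


def test_density_mass_always_one(wiggly):
    for x, s in [(6000, 20), (7500, 60), (9000, 120)]:
        det = pc.Determination("X", float(x), float(s))
        dens = pc.calibrate_terrestrial(det, wiggly,
                                        pc.CalendarGrid(10500, 5500, 5))
        assert dens.density.sum() == pytest.approx(1.0, abs=1e-9)
        assert (dens.density >= 0).all()


def test_density_export_two_columns(tmp_path, identity):
    det = pc.Determination("X", 7000.0, 50.0)
    dens = pc.calibrate_terrestrial(det, identity, pc.CalendarGrid(7500, 6500, 5))
    p = tmp_path / "dens.csv"
    dens.export(p)
    lines = p.read_text().strip().splitlines()
    assert lines[0] == "calbp,mass"
    assert len(lines) == dens.grid.n_cells + 1
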