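"""Single-date radiocarbon calibration and density summaries.

Calibration inverts the curve: for a measurement x ± σ and a curve μc(θ) with
error σc(θ), the calendar-age posterior under a uniform prior on the grid is

    p(θ | x, σ) ∝ N(x; μc(θ), sqrt(σ² + σc(θ)²)) Δθ

evaluated on a regular calendar grid and normalised to unit mass.  Marine
samples add the local reservoir offset ΔR (¹⁴C yr): the likelihood mean gains
ΔR and its variance gains σ_ΔR².

Also provided: highest-posterior-density (HPD) sets, point summaries, and the
OxCal-style agreement index A used for screening (A < 60 % flags conflict
between a date's own calibration and its modelled posterior).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.special import logsumexp

from .curves import CalibrationCurve, Determination
from .errors import (
    DegeneratePosteriorError,
    GridMismatchError,
    ValidationError,
)

#: screening threshold for the agreement index, percent
A_INDEX_THRESHOLD = 60.0

#: grid steps (yr): single-date reporting vs inside-MCMC proposal tables
DEFAULT_STEP_SINGLE = 1.0
DEFAULT_STEP_MCMC = 5.0


@dataclass(frozen=True)
class CalendarGrid:
    """Regular calendar-age grid, cal BP decreasing toward the present.

    ``start_calbp`` is the oldest cell, ``end_calbp`` the youngest bound;
    cells sit at start, start − step, ... while ≥ end.
    """

    start_calbp: float
    end_calbp: float
    step_yr: float = DEFAULT_STEP_SINGLE

    def __post_init__(self) -> None:
        if self.start_calbp <= self.end_calbp:
            raise ValidationError("grid start_calbp must exceed end_calbp")
        if self.step_yr < 1:
            raise ValidationError("grid step_yr must be >= 1")

    @property
    def n_cells(self) -> int:
        return int(np.floor((self.start_calbp - self.end_calbp) / self.step_yr)) + 1

    def values(self) -> np.ndarray:
        return self.start_calbp - self.step_yr * np.arange(self.n_cells)


@dataclass
class CalibratedDensity:
    """Normalised posterior mass per cell of a calendar grid."""

    grid: CalendarGrid
    density: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.size != self.grid.n_cells:
            raise ValidationError("density length does not match grid")
        if np.any(self.density < 0):
            raise ValidationError("density mass must be >= 0")
        if abs(float(self.density.sum()) - 1.0) > 1e-9:
            raise ValidationError("density must sum to 1 within 1e-9")

    def calbp(self) -> np.ndarray:
        return self.grid.values()

    def export(self, path) -> None:
        """Two-column delimited text: cal BP, probability mass."""
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("calbp,mass\n")
            for th, p in zip(self.calbp(), self.density):
                fh.write(f"{float(th)!r},{float(p)!r}\n")


@dataclass
class HpdSet:
    """HPD interval set: disjoint [older, younger] cal BP pairs."""

    level: float
    intervals: Tuple[Tuple[float, float], ...]
    attained: float


def _loglik_on_grid(x: float, sigma: float, curve: CalibrationCurve,
                    grid: CalendarGrid, shift_mean: float = 0.0,
                    extra_var: float = 0.0) -> np.ndarray:
    theta = grid.values()
    mu, sc = curve(theta)  # raises CurveRangeError if grid exceeds support
    var = sigma * sigma + sc * sc + extra_var
    return -0.5 * np.log(2.0 * np.pi * var) - (x - (mu + shift_mean)) ** 2 / (2.0 * var)


def _normalise(loglik: np.ndarray, grid: CalendarGrid) -> CalibratedDensity:
    logz = float(logsumexp(loglik))
    if not np.isfinite(logz) or logz < np.log(1e-300):
        raise DegeneratePosteriorError(
            "total likelihood mass below 1e-300: date incompatible with grid"
        )
    dens = np.exp(loglik - logz)
    dens /= dens.sum()
    return CalibratedDensity(grid=grid, density=dens)


def calibrate_terrestrial(det: Determination, curve: CalibrationCurve,
                          grid: CalendarGrid) -> CalibratedDensity:
    """Calibrate a terrestrial determination against a terrestrial curve."""
    if det.material != "terrestrial":
        raise ValidationError(
            f"{det.lab_code}: material {det.material!r} requires the marine "
            "calibration path (calibrate_marine)"
        )
    if curve.kind != "terrestrial":
        raise ValidationError(f"curve {curve.name!r} is not terrestrial")
    ll = _loglik_on_grid(det.c14_age, det.c14_sigma, curve, grid)
    return _normalise(ll, grid)


def calibrate_marine(det: Determination, curve: CalibrationCurve,
                     delta_r_mean: float, delta_r_sigma: float,
                     grid: CalendarGrid) -> CalibratedDensity:
    """Calibrate a marine determination with reservoir offset ΔR ± σ_ΔR."""
    if det.material != "marine":
        raise ValidationError(f"{det.lab_code}: material must be marine")
    if delta_r_sigma < 0:
        raise ValidationError("delta_r_sigma must be >= 0")
    ll = _loglik_on_grid(det.c14_age, det.c14_sigma, curve, grid,
                         shift_mean=delta_r_mean,
                         extra_var=delta_r_sigma * delta_r_sigma)
    return _normalise(ll, grid)


def hpd_intervals(dens: CalibratedDensity, level: float) -> HpdSet:
    """Smallest set of grid cells (by descending mass) reaching ``level``.

    Contiguous selected cells are merged; each interval is reported as
    [older bound, younger bound] padded by half a grid step.
    """
    if not (0.0 < level <= 1.0):
        raise ValidationError("level must be in (0, 1]")
    p = dens.density
    theta = dens.calbp()
    # deterministic tie-break: higher mass first, then older cell
    order = np.lexsort((-theta, -p))
    csum = np.cumsum(p[order])
    k = int(np.searchsorted(csum, level - 1e-12)) + 1
    if level >= 1.0:
        chosen = np.flatnonzero(p > 0)
    else:
        chosen = np.sort(order[:k])
    attained = float(p[chosen].sum())
    half = dens.grid.step_yr / 2.0
    intervals = []
    start = prev = chosen[0]
    for idx in chosen[1:]:
        if idx == prev + 1:
            prev = idx
            continue
        intervals.append((float(theta[start] + half), float(theta[prev] - half)))
        start = prev = idx
    intervals.append((float(theta[start] + half), float(theta[prev] - half)))
    return HpdSet(level=level, intervals=tuple(intervals), attained=attained)


def point_summaries(dens: CalibratedDensity) -> Tuple[float, float, float]:
    """(mean, median, mode) in cal BP.  Mode ties break toward older ages."""
    p = dens.density
    theta = dens.calbp()
    mean = float(np.dot(p, theta))
    csum = np.cumsum(p)
    median = float(theta[np.searchsorted(csum, 0.5)])
    mode = float(theta[int(np.argmax(p))])  # theta decreasing ⇒ first max is oldest
    return mean, median, mode


def agreement_index(unmodelled: CalibratedDensity,
                    modelled: CalibratedDensity) -> float:
    """OxCal-style agreement A = 100 · Σ(p_post p_prior) / Σ(p_prior²), percent.

    A = 100 when the modelled posterior equals the date's own calibration and
    falls toward 0 as the two stop overlapping.
    """
    ga, gb = unmodelled.grid, modelled.grid
    if (ga.start_calbp, ga.end_calbp, ga.step_yr) != (
            gb.start_calbp, gb.end_calbp, gb.step_yr):
        raise GridMismatchError("agreement_index requires a shared grid")
    prior = unmodelled.density
    post = modelled.density
    return float(100.0 * np.dot(post, prior) / np.dot(prior, prior))


def density_from_samples(samples: np.ndarray, grid: CalendarGrid) -> CalibratedDensity:
    """Bin posterior draws onto a calendar grid as a normalised mass function."""
    theta = grid.values()
    step = grid.step_yr
    edges = np.concatenate(([theta[0] + step / 2.0], theta - step / 2.0))[::-1]
    counts, _ = np.histogram(samples, bins=edges)
    counts = counts[::-1].astype(float)
    total = counts.sum()
    if total == 0:
        raise ValidationError("no samples fall inside the grid")
    return CalibratedDensity(grid=grid, density=counts / total)
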