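"""Bayesian multi-phase chronological models.

Dated events are grouped into ordered depositional phases delimited by start
and end boundaries.  Two boundary treatments are supported:

``uniform``
    Events are uniform between the phase boundaries, which the events may not
    cross.  The joint prior carries a span correction so that the implied
    prior on the phase span is flat on (0, R), R being the overall model
    range — without it, adding events squeezes the boundaries toward the
    dated extremes.

``sigma``
    Events follow a plateau between the boundaries with Gaussian tails of
    scale τ outside, τ given a half-Normal prior.  Tails let the event
    distributions of abutting phases overlap, reflecting sedimentary
    fuzziness at physical phase boundaries; the reported boundary is the
    plateau edge.

A general outlier model can accompany the phases: each date carries a prior
probability (default 0.05) of a heavy-tailed calendar-scale shift
t·10^u (t ~ Student-t, u ~ Uniform over an exponent range), yielding per-date
posterior outlier probabilities.  Posterior sampling is Metropolis-within-
Gibbs with burn-in-only step adaptation, so retained draws are reproducible
bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._kernel import PhaseKernel, PhaseStructure
from .calibrate import (
    CalendarGrid,
    CalibratedDensity,
    density_from_samples,
    hpd_intervals,
)
from .curves import CalibrationCurve, DateTable
from .diagnostics import effective_sample_size, split_rhat
from .errors import UnsupportedOperationError, ValidationError

RHAT_FLAG_THRESHOLD = 1.05


@dataclass
class OutlierSpec:
    """General outlier model: shift = t · 10^u calendar years."""

    prior_prob: float = 0.05
    t_df: float = 5.0
    log10_scale_range: Tuple[float, float] = (0.0, 4.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prior_prob < 1.0:
            raise ValidationError("prior_prob must be in [0, 1)")
        if self.t_df <= 0:
            raise ValidationError("t_df must be > 0")
        lo, hi = self.log10_scale_range
        if lo >= hi:
            raise ValidationError("log10_scale_range must be ordered")


@dataclass
class PhaseSpec:
    """One phase: its boundary treatment and member lab codes.

    ``fixed_start`` / ``fixed_end`` pin a boundary at a known calendar age
    (the pinned boundary is excluded from sampling and from the span
    correction).
    """

    phase_id: str
    boundary_type: str = "sigma"
    members: Sequence[str] = ()
    fixed_start: Optional[float] = None
    fixed_end: Optional[float] = None

    def __post_init__(self) -> None:
        if self.boundary_type not in ("sigma", "uniform"):
            raise ValidationError("boundary_type must be 'sigma' or 'uniform'")
        if not self.members:
            raise ValidationError(f"phase {self.phase_id!r} has no members")


@dataclass
class McmcSettings:
    chains: int = 4
    iterations: int = 20000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    step_scales: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValidationError("iterations must exceed burn_in")
        if self.chains < 2:
            raise ValidationError("at least 2 chains are required")


@dataclass
class ModelSpec:
    """Validated phase model: ordered phases (older → younger) over a table."""

    phases: List[PhaseSpec]
    overall_range: Tuple[float, float]
    outlier: Optional[OutlierSpec]
    contiguous: bool
    dates: DateTable
    curves: Dict[str, CalibrationCurve]
    delta_r: Optional[Tuple[float, float]] = None
    tau_scale: float = 100.0

    @property
    def event_order(self) -> List[str]:
        return [code for ph in self.phases for code in ph.members]


def build_model(dates: DateTable,
                phases: Sequence[PhaseSpec],
                curves: Union[CalibrationCurve, Dict[str, CalibrationCurve]],
                outlier: Optional[OutlierSpec] = None,
                contiguous: bool = True,
                delta_r: Optional[Tuple[float, float]] = None,
                overall_range: Optional[Tuple[float, float]] = None,
                tau_scale: float = 100.0) -> ModelSpec:
    """Validate a phase layout against a date table and fix the model range.

    ``overall_range`` defaults to the union of the members' 99.9 % single-date
    calibrated supports padded by 500 yr (clipped to curve support).
    """
    if isinstance(curves, CalibrationCurve):
        curves = {"terrestrial": curves}
    phases = list(phases)
    if not phases:
        raise ValidationError("at least one phase is required")
    seen: Dict[str, str] = {}
    for ph in phases:
        for code in ph.members:
            try:
                det = dates.get(code)
            except KeyError:
                raise ValidationError(f"unknown lab_code in phase "
                                      f"{ph.phase_id!r}: {code!r}") from None
            if code in seen:
                raise ValidationError(
                    f"{code!r} assigned to both {seen[code]!r} and {ph.phase_id!r}")
            seen[code] = ph.phase_id
            if det.material == "marine":
                if delta_r is None:
                    raise ValidationError(
                        f"marine date {code!r} requires a delta_r (mean, sigma)")
                if "marine" not in curves:
                    raise ValidationError("marine dates require a marine curve")

    model = ModelSpec(phases=phases, overall_range=(0.0, 0.0), outlier=outlier,
                      contiguous=contiguous, dates=dates, curves=curves,
                      delta_r=delta_r, tau_scale=tau_scale)
    if overall_range is None:
        overall_range = _default_overall_range(model)
    model.overall_range = (float(max(overall_range)), float(min(overall_range)))
    return model


def _support_bounds(curves: Dict[str, CalibrationCurve]) -> Tuple[float, float]:
    lo = max(c.calbp_min for c in curves.values())
    hi = min(c.calbp_max for c in curves.values())
    return lo, hi


def _default_overall_range(model: ModelSpec, pad: float = 500.0,
                           step: float = 5.0) -> Tuple[float, float]:
    lo, hi = _support_bounds(model.curves)
    grid = np.arange(lo + step, hi - step, step)
    old = -np.inf
    young = np.inf
    drm, drs = model.delta_r if model.delta_r else (0.0, 0.0)
    for code in model.event_order:
        det = model.dates.get(code)
        if det.material == "marine":
            curve = model.curves["marine"]
            mu, sc = curve.interp_unchecked(grid)
            mu = mu + drm
            var = det.c14_sigma ** 2 + sc ** 2 + drs ** 2
        else:
            curve = model.curves["terrestrial"]
            mu, sc = curve.interp_unchecked(grid)
            var = det.c14_sigma ** 2 + sc ** 2
        ll = -0.5 * np.log(var) - (det.c14_age - mu) ** 2 / (2 * var)
        ll -= ll.max()
        w = np.exp(ll)
        w /= w.sum()
        c = np.cumsum(w)
        young_i = grid[np.searchsorted(c, 0.0005)]
        old_i = grid[min(np.searchsorted(c, 0.9995), grid.size - 1)]
        old = max(old, old_i)
        young = min(young, young_i)
    return (min(old + pad, hi - step), max(young - pad, lo + step))


def _kernel_from_model(model: ModelSpec, prop_step: float = 5.0) -> PhaseKernel:
    order = model.event_order
    dets = [model.dates.get(c) for c in order]
    x = np.array([[d.c14_age for d in dets]])
    sig = np.array([[d.c14_sigma for d in dets]])
    marine = np.array([d.material == "marine" for d in dets])
    pos = {c: i for i, c in enumerate(order)}
    st_phases = [{"idx": np.array([pos[c] for c in ph.members]),
                  "btype": ph.boundary_type} for ph in model.phases]
    fixed: Dict[int, float] = {}
    P = len(model.phases)
    for j, ph in enumerate(model.phases):
        si = j if model.contiguous else 2 * j
        ei = j + 1 if model.contiguous else 2 * j + 1
        if ph.fixed_start is not None:
            if si in fixed and fixed[si] != ph.fixed_start:
                raise ValidationError("conflicting fixed values at a shared boundary")
            fixed[si] = float(ph.fixed_start)
        if ph.fixed_end is not None:
            if ei in fixed and fixed[ei] != ph.fixed_end:
                raise ValidationError("conflicting fixed values at a shared boundary")
            fixed[ei] = float(ph.fixed_end)
    structure = PhaseStructure(st_phases, model.contiguous, fixed=fixed)
    drm, drs = model.delta_r if model.delta_r else (0.0, 0.0)
    return PhaseKernel(
        x, sig, marine,
        terr_curve=model.curves.get("terrestrial"),
        mar_curve=model.curves.get("marine"),
        structure=structure, overall_range=model.overall_range,
        outlier=model.outlier, dr_mean=drm, dr_sig=drs,
        tau_scale=model.tau_scale, prop_step=prop_step)


def boundary_labels(model: ModelSpec) -> List[str]:
    ids = [ph.phase_id for ph in model.phases]
    if model.contiguous:
        labels = [f"start {ids[0]}"]
        labels += [f"{a}/{b}" for a, b in zip(ids[:-1], ids[1:])]
        labels.append(f"end {ids[-1]}")
        return labels
    out = []
    for pid in ids:
        out += [f"start {pid}", f"end {pid}"]
    return out


@dataclass
class PhaseModelResult:
    """Posterior draws and reports from one phase-model run."""

    boundary_samples: Dict[str, np.ndarray]          # label -> (chains, draws)
    event_samples: Dict[str, np.ndarray]             # lab_code -> (chains, draws)
    outlier_prob: Optional[Dict[str, float]]
    agreement: Dict[str, float]                      # lab_code -> A-index %
    diagnostics: pd.DataFrame                        # per-boundary rhat / ess
    flagged: bool
    seed: int
    model: ModelSpec
    tau_samples: Optional[np.ndarray] = None


def log_posterior(state: Dict, model: ModelSpec) -> float:
    """Joint log density (up to a constant) of one full state; -inf off-support.

    ``state`` keys: theta (N,) in model event order, bounds (Kb,), and
    optionally tau, phi, t, u.
    """
    kern = _kernel_from_model(model)
    st = kern.st

    def as3(v, width):
        return np.asarray(v, dtype=float).reshape(1, 1, width)

    theta = as3(state["theta"], kern.N)
    bounds = as3(state["bounds"], st.n_bounds)
    tau = as3(state.get("tau", np.full(st.n_tau, model.tau_scale / 2)), st.n_tau)
    phi = as3(state.get("phi", np.zeros(kern.N)), kern.N)
    t = as3(state.get("t", np.zeros(kern.N)), kern.N)
    u = as3(state.get("u", np.zeros(kern.N)), kern.N)
    if model.outlier is None:
        phi = np.zeros_like(phi)
    return float(kern.log_posterior(theta, bounds, tau, phi, t, u)[0, 0])


def sample_posterior(model: ModelSpec,
                     mcmc: Optional[McmcSettings] = None) -> PhaseModelResult:
    """Draw from the phase-model posterior; see module docstring for the kernel."""
    mcmc = mcmc or McmcSettings()
    kern = _kernel_from_model(model)
    store = kern.run(chains=mcmc.chains, iterations=mcmc.iterations,
                     burn_in=mcmc.burn_in, thin=mcmc.thin, seed=mcmc.seed,
                     step_scales=mcmc.step_scales)
    labels = boundary_labels(model)
    bsamp = {lab: store["bounds"][0, :, :, k] for k, lab in enumerate(labels)}
    order = model.event_order
    esamp = {code: store["theta"][0, :, :, i] for i, code in enumerate(order)}
    out_prob = None
    if model.outlier is not None:
        out_prob = {code: float(store["phi"][0, :, :, i].mean())
                    for i, code in enumerate(order)}
    # agreement: each date's own calibration vs its modelled event density,
    # both as masses on the kernel's shared proposal grid
    agreement = {}
    g = kern.grid_asc
    edges = np.concatenate((g - kern.prop_step / 2.0, [g[-1] + kern.prop_step / 2.0]))
    for i, code in enumerate(order):
        prior = np.exp(kern.logq[0, i])
        draws = store["theta"][0, :, :, i].ravel()
        counts, _ = np.histogram(draws, bins=edges)
        post = counts / max(counts.sum(), 1)
        agreement[code] = float(100.0 * np.dot(post, prior) / np.dot(prior, prior))
    rows = []
    for lab, arr in bsamp.items():
        rows.append({"boundary": lab, "rhat": split_rhat(arr),
                     "ess": effective_sample_size(arr)})
    diag = pd.DataFrame(rows)
    flagged = bool((diag["rhat"] > RHAT_FLAG_THRESHOLD).any())
    tau = store["tau"][0] if kern.st.n_tau else None
    return PhaseModelResult(boundary_samples=bsamp, event_samples=esamp,
                            outlier_prob=out_prob, agreement=agreement,
                            diagnostics=diag, flagged=flagged, seed=mcmc.seed,
                            model=model, tau_samples=tau)


def _sample_hpd(samples: np.ndarray, level: float,
                step: float = 5.0) -> Tuple[float, float]:
    """Outermost HPD envelope of a draw set (older, younger)."""
    lo, hi = float(samples.min()), float(samples.max())
    if hi - lo < step:
        return hi, lo
    grid = CalendarGrid(start_calbp=hi + step, end_calbp=lo - step, step_yr=step)
    dens = density_from_samples(samples, grid)
    hpd = hpd_intervals(dens, level)
    older = max(iv[0] for iv in hpd.intervals)
    younger = min(iv[1] for iv in hpd.intervals)
    return older, younger


def boundary_estimates(result: PhaseModelResult,
                       levels: Sequence[float] = (0.68, 0.95)) -> pd.DataFrame:
    """Per-boundary mean / median / HPD table, cal BP plus display ka."""
    rows = []
    for lab, arr in result.boundary_samples.items():
        flat = arr.ravel()
        if flat.size == 0:
            raise ValidationError("empty boundary samples")
        row = {"boundary": lab,
               "mean_calbp": float(flat.mean()),
               "median_calbp": float(np.median(flat)),
               "mean_ka": round(float(flat.mean()) / 1000.0, 1)}
        for lv in levels:
            older, younger = _sample_hpd(flat, lv)
            pct = int(round(lv * 100))
            row[f"hpd{pct}_older"] = older
            row[f"hpd{pct}_younger"] = younger
        rows.append(row)
    return pd.DataFrame(rows)


def outlier_report(result: PhaseModelResult) -> pd.DataFrame:
    """Per-sample posterior outlier probability and agreement index."""
    if result.outlier_prob is None:
        raise UnsupportedOperationError(
            "outlier model was disabled for this run")
    rows = [{"lab_code": code, "p_outlier": p,
             "agreement": result.agreement[code]}
            for code, p in result.outlier_prob.items()]
    return pd.DataFrame(rows)


def prior_predictive_span(model: ModelSpec, draws: int = 10000,
                          seed: int = 0) -> Dict[str, np.ndarray]:
    """Sample phase spans from the prior alone (uniform boundaries only).

    Under the span-uniform construction each phase's span is Uniform(0, R)
    a priori, independent of how many dates the phase contains; multi-phase
    layouts are sampled by rejection against the ordering constraints.
    """
    if any(ph.boundary_type != "uniform" for ph in model.phases):
        raise ValidationError("prior_predictive_span requires uniform boundaries")
    rng = np.random.default_rng(seed)
    old, young = model.overall_range
    R = old - young
    P = len(model.phases)
    out = {ph.phase_id: [] for ph in model.phases}
    got = 0
    while got < draws:
        m = max(draws - got, 1000)
        s = rng.uniform(0.0, R, size=(m, P))
        e = young + rng.uniform(0.0, 1.0, size=(m, P)) * (R - s)
        a = e + s
        ok = np.ones(m, dtype=bool)
        for j in range(P - 1):
            ok &= (a[:, j] >= a[:, j + 1]) & (e[:, j] >= e[:, j + 1])
            ok &= e[:, j] >= a[:, j + 1]  # phases ordered older -> younger
        take = min(int(ok.sum()), draws - got)
        idx = np.flatnonzero(ok)[:take]
        for j, ph in enumerate(model.phases):
            out[ph.phase_id].append(s[idx, j])
        got += take
    return {k: np.concatenate(v) for k, v in out.items()}
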