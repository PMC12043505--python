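"""Synthetic-data generators with known truth.

Everything the inference modules consume can be generated here: smooth wiggly
calibration curves, multi-phase occupation sites observed through a curve with
lab error, paired charcoal/shell contexts sharing a latent event age but
offset by a true ΔR, and sediment cores with broadly linear accumulation plus
redeposition (age reversals).  Every generator is a pure function of its
configuration and seed, and each returns a truth record holding every latent
variable so recovery metrics need no hidden state.

Conditions emulated (and their defaults) follow the structure of a small
Mediterranean shell-midden excavation: a few ordered depositional phases a few
centuries long, AMS lab errors of a few tens of ¹⁴C years, a regional marine
reservoir offset of order 10²  ¹⁴C years, a small fraction of redeposited or
intrusive samples with heavy-tailed calendar shifts, and cores accumulating a
few hundred calendar years per metre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .curves import CalibrationCurve, DateTable, Determination
from .errors import ValidationError


@dataclass
class SiteSimConfig:
    """Truth for a phased occupation site.

    phase_truths are (start, end) pairs in cal BP, older → younger, start >
    end.  Outliers receive Student-t(5) calendar shifts scaled by
    ``outlier_shift_scale`` before being mapped through the curve, matching
    the heavy-tailed family assumed by the general outlier model.  Setting
    ``inject_outlier_shift`` forces one deterministic shifted date instead of
    random outliers — used for controlled detection experiments.
    ``inject_outlier_index`` picks the victim within the flattened table; the
    default −1 selects the first-phase date whose true age lies closest to
    the phase midpoint, so the shifted age always falls clearly outside the
    phase (a shift applied at a phase edge can land back inside and would
    not constitute an outlier at all).
    """

    phase_truths: Sequence[Tuple[float, float]] = ((8500.0, 7500.0),)
    dates_per_phase: int = 30
    lab_sigma: float = 40.0
    outlier_fraction: float = 0.0
    outlier_shift_scale: float = 500.0
    marine_fraction: float = 0.0
    true_delta_r: float = 150.0
    inject_outlier_shift: Optional[float] = None
    inject_outlier_index: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        for start, end in self.phase_truths:
            if start <= end:
                raise ValidationError("phase start (older) must exceed end in cal BP")
        for frac in (self.outlier_fraction, self.marine_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("fractions must be within [0, 1]")
        if self.lab_sigma <= 0:
            raise ValidationError("lab_sigma must be > 0")


@dataclass
class CoreSimConfig:
    """Truth for a sediment core: θ(d) = beta0 + beta1·d + N(0, sigma_eps).

    A ``redeposit_fraction`` of samples receives ``redeposit_shift`` extra
    calendar years (positive = older material moved up the core), which is
    what breaks monotonicity in the observed age–depth relation.
    """

    beta0: float = 2000.0
    beta1: float = 500.0
    sigma_eps: float = 100.0
    depths: Sequence[float] = field(default_factory=lambda: tuple(np.linspace(0.2, 6.0, 12)))
    redeposit_fraction: float = 0.0
    redeposit_shift: float = 800.0
    lab_sigma: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        if d.size and not np.all(np.diff(d) > 0):
            raise ValidationError("depths must be strictly increasing")
        if not 0.0 <= self.redeposit_fraction <= 1.0:
            raise ValidationError("redeposit_fraction must be within [0, 1]")
        if self.lab_sigma <= 0 or self.sigma_eps < 0:
            raise ValidationError("lab_sigma > 0 and sigma_eps >= 0 required")


def simulate_calibration_curve(range_calbp: Tuple[float, float],
                               wiggle_amplitude: float = 0.0,
                               wiggle_period: float = 500.0,
                               sigma: float = 10.0,
                               seed: int = 0,
                               noise_amplitude: float = 0.0,
                               kind: str = "terrestrial",
                               name: Optional[str] = None) -> CalibrationCurve:
    """Synthetic curve μc(θ) = θ + A·sin(2πθ/P) + smooth seeded noise.

    Knots at every calendar year across ``range_calbp`` (old, young); constant
    1σ curve error ``sigma``.  The smooth noise term interpolates coarse
    seeded Gaussian knots (every 200 yr) so the curve stays differentiable-
    looking at the 1-yr grid.
    """
    old, young = float(max(range_calbp)), float(min(range_calbp))
    if not (0.0 <= young < old < 60000.0):
        raise ValidationError("range must lie within (0, 60000) cal BP")
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    theta = np.arange(old, young - 0.5, -1.0)
    mu = theta.copy()
    if wiggle_amplitude:
        mu = mu + wiggle_amplitude * np.sin(2.0 * np.pi * theta / wiggle_period)
    if noise_amplitude:
        rng = np.random.default_rng(seed)
        coarse = np.arange(young, old + 200.0, 200.0)
        vals = rng.normal(0.0, noise_amplitude, size=coarse.size)
        mu = mu + np.interp(theta, coarse, vals)
    if not np.all(np.isfinite(mu)):
        raise ValidationError("curve values non-finite; reduce amplitudes")
    return CalibrationCurve(
        name=name or f"synthetic-{kind}-s{seed}",
        knots_calbp=theta,
        knots_c14=mu,
        knots_sigma=np.full(theta.size, float(sigma)),
        kind=kind,
    )


def identity_curve(range_calbp: Tuple[float, float], sigma: float = 1e-6,
                   kind: str = "terrestrial") -> CalibrationCurve:
    """μc(θ) = θ with (near-)zero curve error; handy for closed-form checks."""
    old, young = float(max(range_calbp)), float(min(range_calbp))
    theta = np.arange(old, young - 0.5, -1.0)
    return CalibrationCurve(name=f"identity-{kind}", knots_calbp=theta,
                            knots_c14=theta.copy(),
                            knots_sigma=np.full(theta.size, float(sigma)),
                            kind=kind)


def _observe(rng: np.ndarray, theta: np.ndarray, curve: CalibrationCurve,
             lab_sigma: float, delta_r: float = 0.0) -> np.ndarray:
    """CRA = Normal(μc(θ) + ΔR, sqrt(lab_sigma² + σc²)); θ assumed in support."""
    mu, sc = curve(theta)
    return rng.normal(mu + delta_r, np.sqrt(lab_sigma ** 2 + sc ** 2))


def simulate_phased_site(cfg: SiteSimConfig,
                         terrestrial_curve: CalibrationCurve,
                         marine_curve: Optional[CalibrationCurve] = None
                         ) -> Tuple[DateTable, Dict]:
    """Draw a phased site: true θ uniform within each phase, CRAs via curve.

    Latent θ values are clipped into curve support if a shift pushes them out;
    clipping is recorded in the truth record, never applied to the CRA.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.marine_fraction > 0 and marine_curve is None:
        raise ValidationError("marine_fraction > 0 requires a marine curve")
    for start, end in cfg.phase_truths:
        if start > terrestrial_curve.calbp_max or end < terrestrial_curve.calbp_min:
            raise ValidationError("phase truth outside curve support")

    rows: List[Determination] = []
    truth = {"theta_true": [], "shift": [], "is_outlier": [], "is_marine": [],
             "phase": [], "clipped": [], "true_delta_r": cfg.true_delta_r,
             "config": cfg}
    idx = 0
    for j, (start, end) in enumerate(cfg.phase_truths):
        n = cfg.dates_per_phase
        theta = rng.uniform(end, start, size=n)
        is_out = rng.random(n) < cfg.outlier_fraction
        shifts = np.where(
            is_out, rng.standard_t(5.0, size=n) * cfg.outlier_shift_scale, 0.0)
        is_marine = rng.random(n) < cfg.marine_fraction
        inject_local = None
        if cfg.inject_outlier_shift is not None:
            if cfg.inject_outlier_index < 0:
                if j == 0 and n > 0:
                    inject_local = int(np.argmin(
                        np.abs(theta - 0.5 * (start + end))))
            elif idx <= cfg.inject_outlier_index < idx + n:
                inject_local = cfg.inject_outlier_index - idx
        for i in range(n):
            shift = float(shifts[i])
            outlier = bool(is_out[i])
            if inject_local is not None and i == inject_local:
                shift, outlier = float(cfg.inject_outlier_shift), True
            th_obs = theta[i] + shift
            lo = (marine_curve if is_marine[i] else terrestrial_curve).calbp_min
            hi = (marine_curve if is_marine[i] else terrestrial_curve).calbp_max
            clipped = not (lo <= th_obs <= hi)
            th_obs = float(np.clip(th_obs, lo, hi))
            if is_marine[i]:
                cra = _observe(rng, np.array([th_obs]), marine_curve,
                               cfg.lab_sigma, cfg.true_delta_r)[0]
                material = "marine"
            else:
                cra = _observe(rng, np.array([th_obs]), terrestrial_curve,
                               cfg.lab_sigma)[0]
                material = "terrestrial"
            rows.append(Determination(
                lab_code=f"SIM-{idx:04d}", c14_age=float(cra),
                c14_sigma=cfg.lab_sigma, material=material,
                phase_id=f"phase{j}"))
            truth["theta_true"].append(float(theta[i]))
            truth["shift"].append(shift)
            truth["is_outlier"].append(outlier)
            truth["is_marine"].append(bool(is_marine[i]))
            truth["phase"].append(j)
            truth["clipped"].append(clipped)
            idx += 1
    for key in ("theta_true", "shift", "is_outlier", "is_marine", "phase", "clipped"):
        truth[key] = np.asarray(truth[key])
    return DateTable(rows=rows, provenance=f"simulate_phased_site(seed={cfg.seed})"), truth


def simulate_paired_reservoir(n_contexts: int,
                              n_terrestrial: int,
                              n_marine: int,
                              true_delta_r: float,
                              terrestrial_curve: CalibrationCurve,
                              marine_curve: CalibrationCurve,
                              lab_sigma: float = 35.0,
                              age_range: Tuple[float, float] = (8600.0, 7600.0),
                              seed: int = 0):
    """Paired contexts: one latent θ_c per context shared by both materials."""
    from .reservoir import PairedContext  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    old, young = float(max(age_range)), float(min(age_range))
    pairs = []
    truth = {"theta_c": [], "true_delta_r": float(true_delta_r)}
    for c in range(n_contexts):
        th = float(rng.uniform(young, old))
        truth["theta_c"].append(th)
        terr = [Determination(
            lab_code=f"CTX{c}-T{i}",
            c14_age=float(_observe(rng, np.array([th]), terrestrial_curve, lab_sigma)[0]),
            c14_sigma=lab_sigma, material="terrestrial", context_id=f"ctx{c}")
            for i in range(n_terrestrial)]
        mar = [Determination(
            lab_code=f"CTX{c}-M{i}",
            c14_age=float(_observe(rng, np.array([th]), marine_curve, lab_sigma,
                                   true_delta_r)[0]),
            c14_sigma=lab_sigma, material="marine", context_id=f"ctx{c}")
            for i in range(n_marine)]
        pairs.append(PairedContext(context_id=f"ctx{c}", terrestrial=terr, marine=mar))
    truth["theta_c"] = np.asarray(truth["theta_c"])
    return pairs, truth


def simulate_core(cfg: CoreSimConfig, curve: CalibrationCurve):
    """Sediment core with linear accumulation plus optional redeposition."""
    from .agedepth import CoreSample  # local import avoids a cycle

    rng = np.random.default_rng(cfg.seed)
    depths = np.asarray(cfg.depths, dtype=float)
    n = depths.size
    theta = cfg.beta0 + cfg.beta1 * depths + rng.normal(0.0, cfg.sigma_eps, size=n)
    n_red = int(round(cfg.redeposit_fraction * n))
    red_idx = rng.choice(n, size=n_red, replace=False) if n_red else np.array([], int)
    theta = theta.copy()
    theta[red_idx] += cfg.redeposit_shift
    clipped = (theta < curve.calbp_min) | (theta > curve.calbp_max)
    theta_clipped = np.clip(theta, curve.calbp_min, curve.calbp_max)
    cra = _observe(rng, theta_clipped, curve, cfg.lab_sigma)
    samples = [CoreSample(
        lab_code=f"CORE-{i:03d}", depth_m=float(depths[i]),
        det=Determination(lab_code=f"CORE-{i:03d}", c14_age=float(cra[i]),
                          c14_sigma=cfg.lab_sigma, material="terrestrial",
                          depth_m=float(depths[i])))
        for i in range(n)]
    truth = {"theta_true": theta_clipped, "redeposited": np.isin(np.arange(n), red_idx),
             "clipped": clipped, "beta0": cfg.beta0, "beta1": cfg.beta1,
             "sigma_eps": cfg.sigma_eps, "config": cfg}
    return samples, truth
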