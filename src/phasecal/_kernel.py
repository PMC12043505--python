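"""Batched Metropolis-within-Gibbs kernel for the phase model.

The kernel vectorises over a batch axis B (independent datasets with the same
phase structure — used for replicate recovery studies) and a chain axis C.
State per walker (b, c):

    theta  (N,)   latent calendar event ages, cal BP
    bounds (Kb,)  phase boundaries (contiguous: P+1 shared; else 2 per phase)
    tau    (J,)   tail scales of the "sigma" phases
    phi    (N,)   outlier indicators;  t, u: shift magnitude/scale exponents

Updates: random-walk Metropolis for theta / bounds / tau / (t, u), an
occasional independence proposal for theta drawn from each date's own
calibration density (precomputed once), exact prior redraws of (t, u) where
phi = 0, and a Gibbs flip for phi from its full conditional Bernoulli.
Proposal scales adapt during burn-in only, so retained draws come from a
fixed kernel and a fixed seed reproduces them bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .errors import InitializationError

TWO_PI = 2.0 * np.pi
SQRT_TWO_PI = np.sqrt(2.0 * np.pi)


class PhaseStructure:
    """Immutable phase bookkeeping: member indices and boundary wiring."""

    def __init__(self, phases, contiguous, fixed=None):
        # phases: list of dicts {idx: int array, btype: 'uniform'|'sigma'}
        self.contiguous = bool(contiguous)
        self.n_phases = len(phases)
        self.member_idx = [np.asarray(p["idx"], dtype=int) for p in phases]
        self.btypes = [p["btype"] for p in phases]
        if self.contiguous:
            self.n_bounds = self.n_phases + 1
            self.start_of = np.arange(self.n_phases)
            self.end_of = np.arange(self.n_phases) + 1
        else:
            self.n_bounds = 2 * self.n_phases
            self.start_of = 2 * np.arange(self.n_phases)
            self.end_of = 2 * np.arange(self.n_phases) + 1
        self.sigma_phase = np.array([bt == "sigma" for bt in self.btypes])
        self.tau_index = np.cumsum(self.sigma_phase) - 1  # valid where sigma
        self.n_tau = int(self.sigma_phase.sum())
        # per-event wiring
        n_ev = sum(len(m) for m in self.member_idx)
        self.n_events = n_ev
        self.ev_start = np.empty(n_ev, dtype=int)
        self.ev_end = np.empty(n_ev, dtype=int)
        self.ev_uniform = np.empty(n_ev, dtype=bool)
        self.ev_tau = np.zeros(n_ev, dtype=int)
        for j, m in enumerate(self.member_idx):
            self.ev_start[m] = self.start_of[j]
            self.ev_end[m] = self.end_of[j]
            self.ev_uniform[m] = self.btypes[j] == "uniform"
            if self.sigma_phase[j]:
                self.ev_tau[m] = self.tau_index[j]
        # fixed boundaries: dict boundary index -> value
        self.fixed = dict(fixed or {})
        self.free_bounds = [k for k in range(self.n_bounds) if k not in self.fixed]
        # a phase contributes the 1/(R - span) correction only if at least one
        # of its boundaries is free (for pinned phases it is a constant)
        self.phase_free = [
            (self.start_of[j] not in self.fixed) or (self.end_of[j] not in self.fixed)
            for j in range(self.n_phases)
        ]


class PhaseKernel:
    """Sampler for B independent datasets sharing one phase structure."""

    def __init__(self, x, sig, marine, terr_curve, mar_curve, structure,
                 overall_range, outlier=None, dr_mean=0.0, dr_sig=0.0,
                 tau_scale=100.0, prop_step=5.0, grid_pad=200.0):
        self.x = np.atleast_2d(np.asarray(x, dtype=float))          # (B, N)
        self.sig = np.atleast_2d(np.asarray(sig, dtype=float))      # (B, N)
        self.B, self.N = self.x.shape
        marine = np.asarray(marine, dtype=bool)
        if marine.ndim == 1:
            marine = np.broadcast_to(marine, (self.B, self.N))
        self.marine = marine
        self.any_marine = bool(marine.any())
        self.terr = terr_curve
        self.mar = mar_curve
        self.dr_mean = float(dr_mean)
        self.dr_sig = float(dr_sig)
        self.st = structure
        if structure.n_events != self.N:
            raise ValueError("phase structure does not cover every date")
        self.old, self.young = float(max(overall_range)), float(min(overall_range))
        self.R = self.old - self.young
        self.outlier = outlier  # OutlierSpec or None
        self.tau_scale = float(tau_scale)
        # ---- per-date calibration tables (proposal density + init medians)
        lo = self.young - grid_pad
        hi = self.old + grid_pad
        lo = max(lo, terr_curve.calbp_min)
        hi = min(hi, terr_curve.calbp_max)
        if mar_curve is not None:
            lo = max(lo, mar_curve.calbp_min)
            hi = min(hi, mar_curve.calbp_max)
        self.grid_asc = np.arange(lo, hi + prop_step / 2.0, prop_step)
        self.prop_step = float(prop_step)
        self._build_proposal_tables()

    # ------------------------------------------------------------------ setup
    def _build_proposal_tables(self):
        g = self.grid_asc                                    # (G,)
        mu_t, sg_t = self.terr.interp_unchecked(g)
        mu = np.broadcast_to(mu_t, (self.B, self.N, g.size)).copy()
        s2 = np.broadcast_to(sg_t ** 2, (self.B, self.N, g.size)).copy()
        if self.any_marine:
            mu_m, sg_m = self.mar.interp_unchecked(g)
            mu[self.marine] = mu_m + self.dr_mean
            s2[self.marine] = sg_m ** 2 + self.dr_sig ** 2
        var = self.sig[..., None] ** 2 + s2
        ll = -0.5 * np.log(TWO_PI * var) - (self.x[..., None] - mu) ** 2 / (2 * var)
        ll -= ll.max(axis=-1, keepdims=True)
        q = np.exp(ll)
        q /= q.sum(axis=-1, keepdims=True)
        with np.errstate(divide="ignore"):
            self.logq = np.log(q)                            # (B, N, G)
        self.cdfq = np.cumsum(q, axis=-1)
        med_idx = np.argmax(self.cdfq >= 0.5, axis=-1)
        self.theta_med = self.grid_asc[med_idx]              # (B, N)

    # ------------------------------------------------------------- likelihood
    def meas_loglik(self, theta_eff):
        """(B, C, N) measurement log-likelihood; -inf outside curve support."""
        mu_t, sg_t = self.terr.interp_unchecked(theta_eff)
        mu, s2 = mu_t, sg_t ** 2
        if self.any_marine:
            mu_m, sg_m = self.mar.interp_unchecked(theta_eff)
            m3 = self.marine[:, None, :]
            mu = np.where(m3, mu_m + self.dr_mean, mu_t)
            s2 = np.where(m3, sg_m ** 2 + self.dr_sig ** 2, sg_t ** 2)
        var = self.sig[:, None, :] ** 2 + s2
        ll = -0.5 * np.log(TWO_PI * var) - (self.x[:, None, :] - mu) ** 2 / (2 * var)
        return np.where(np.isfinite(ll), ll, -np.inf)

    # ------------------------------------------------------------ phase prior
    def event_logprior(self, theta, bounds, tau):
        """Per-event phase-prior density term (B, C, N)."""
        st = self.st
        S = bounds[..., st.ev_start]
        E = bounds[..., st.ev_end]
        span = S - E
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.full(theta.shape, -np.inf)
            uni = st.ev_uniform
            if uni.any():
                inside = (theta[..., uni] <= S[..., uni]) & (theta[..., uni] >= E[..., uni])
                lp = np.where(inside & (span[..., uni] > 0),
                              -np.log(span[..., uni]), -np.inf)
                out[..., uni] = lp
            sig = ~uni
            if sig.any():
                t = tau[..., st.ev_tau[sig]]
                z = span[..., sig] + SQRT_TWO_PI * t
                d = (np.clip(E[..., sig] - theta[..., sig], 0.0, None)
                     + np.clip(theta[..., sig] - S[..., sig], 0.0, None))
                lp = -np.log(z) - d * d / (2.0 * t * t)
                lp = np.where((t > 0) & (span[..., sig] >= 0), lp, -np.inf)
                out[..., sig] = lp
        return out

    def bounds_logprior(self, bounds, tau):
        """Boundary ordering / support / span-correction / tau-prior (B, C)."""
        st = self.st
        ok = np.all((bounds <= self.old) & (bounds >= self.young), axis=-1)
        if st.contiguous:
            ok &= np.all(np.diff(bounds, axis=-1) <= 0, axis=-1)
        else:
            starts = bounds[..., st.start_of]
            ends = bounds[..., st.end_of]
            ok &= np.all(starts - ends >= 0, axis=-1)
            if st.n_phases > 1:
                ok &= np.all(np.diff(starts, axis=-1) <= 0, axis=-1)
                ok &= np.all(np.diff(ends, axis=-1) <= 0, axis=-1)
                for j in range(st.n_phases - 1):
                    # uniform phases do not overlap; sigma tails may
                    if st.btypes[j] == "uniform" and st.btypes[j + 1] == "uniform":
                        ok &= ends[..., j] >= starts[..., j + 1]
        total = np.zeros(bounds.shape[:-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            for j in range(st.n_phases):
                span = bounds[..., st.start_of[j]] - bounds[..., st.end_of[j]]
                if st.btypes[j] == "uniform" and st.phase_free[j]:
                    # span-uniform correction: marginal prior span ~ U(0, R)
                    corr = np.where(span < self.R, -np.log(self.R - span), -np.inf)
                    total = total + corr
                if st.sigma_phase[j]:
                    t = tau[..., st.tau_index[j]]
                    total = total + np.where(
                        t > 0, -t * t / (2.0 * self.tau_scale ** 2), -np.inf)
        return np.where(ok, total, -np.inf)

    def outlier_logprior(self, phi, t, u):
        if self.outlier is None:
            return 0.0
        o = self.outlier
        p = o.prior_prob
        lo, hi = o.log10_scale_range
        with np.errstate(divide="ignore"):
            lp = np.where(phi, np.log(p), np.log1p(-p))
        lp = lp - 0.5 * (o.t_df + 1.0) * np.log1p(t * t / o.t_df)
        lp = lp + np.where((u >= lo) & (u <= hi), -np.log(hi - lo), -np.inf)
        return lp.sum(axis=-1)

    def log_posterior(self, theta, bounds, tau, phi, t, u):
        """Full joint log density up to a constant; -inf outside support."""
        shift = phi * t * 10.0 ** u if self.outlier is not None else 0.0
        ll = self.meas_loglik(theta + shift).sum(axis=-1)
        elp = self.event_logprior(theta, bounds, tau).sum(axis=-1)
        blp = self.bounds_logprior(bounds, tau)
        olp = self.outlier_logprior(phi, t, u) if self.outlier is not None else 0.0
        return ll + elp + blp + olp

    # ------------------------------------------------------------------- init
    def init_state(self, chains, rng):
        B, C, N = self.B, chains, self.N
        st = self.st
        for attempt in range(1000):
            theta = self.theta_med[:, None, :] + rng.normal(0.0, 5.0, (B, C, N))
            bounds = np.empty((B, C, st.n_bounds))
            mx = np.stack([theta[..., m].max(-1) for m in st.member_idx], -1)
            mn = np.stack([theta[..., m].min(-1) for m in st.member_idx], -1)
            if st.contiguous:
                bounds[..., 0] = mx[..., 0] + 50.0
                for j in range(1, st.n_phases):
                    bounds[..., j] = 0.5 * (mn[..., j - 1] + mx[..., j])
                bounds[..., st.n_phases] = mn[..., st.n_phases - 1] - 50.0
            else:
                bounds[..., st.start_of] = mx + 50.0
                bounds[..., st.end_of] = mn - 50.0
            bounds += rng.normal(0.0, 2.0, bounds.shape)
            bounds = np.clip(bounds, self.young + 1e-3, self.old - 1e-3)
            if st.contiguous:
                bounds = np.minimum.accumulate(bounds, axis=-1)
            for k, v in st.fixed.items():
                bounds[..., k] = v
            # keep events strictly inside uniform phases
            for j in range(st.n_phases):
                if st.btypes[j] != "uniform":
                    continue
                m = st.member_idx[j]
                s = bounds[..., st.start_of[j]][..., None]
                e = bounds[..., st.end_of[j]][..., None]
                theta[..., m] = np.clip(theta[..., m], e + 1e-6, s - 1e-6)
            tau = np.full((B, C, st.n_tau), 0.5 * self.tau_scale)
            if self.outlier is not None:
                phi = np.zeros((B, C, N))
                t = rng.standard_t(self.outlier.t_df, (B, C, N))
                lo, hi = self.outlier.log10_scale_range
                u = rng.uniform(lo, hi, (B, C, N))
            else:
                phi = np.zeros((B, C, N))
                t = np.zeros((B, C, N))
                u = np.zeros((B, C, N))
            lp = self.log_posterior(theta, bounds, tau, phi, t, u)
            if np.all(np.isfinite(lp)):
                return dict(theta=theta, bounds=bounds, tau=tau, phi=phi, t=t, u=u)
        raise InitializationError(
            "no finite-posterior starting state after 1000 attempts")

    # -------------------------------------------------------------------- run
    def run(self, chains=2, iterations=4000, burn_in=1000, thin=2, seed=0,
            step_scales=None, indep_every=4, adapt_every=50):
        # -inf minus -inf inside rejected-move deltas is expected; the nan
        # compares False and the move is rejected
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            return self._run(chains, iterations, burn_in, thin, seed,
                             step_scales, indep_every, adapt_every)

    def _run(self, chains, iterations, burn_in, thin, seed,
             step_scales, indep_every, adapt_every):
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        rng = np.random.default_rng(seed)
        B, C, N = self.B, chains, self.N
        st = self.st
        state = self.init_state(chains, rng)
        theta, bounds = state["theta"], state["bounds"]
        tau, phi, t, u = state["tau"], state["phi"], state["t"], state["u"]
        have_out = self.outlier is not None

        scales = {
            "theta": np.full((B, 1, 1), 40.0), "bounds": np.full((B, 1), 40.0),
            "tau": np.full((B, 1), 0.4 * self.tau_scale),
            "t": np.full((B, 1, 1), 1.0), "u": np.full((B, 1, 1), 0.4),
        }
        if step_scales:
            for k, v in step_scales.items():
                scales[k][...] = v
        acc = {k: np.zeros(B) for k in scales}
        tries = {k: 1e-12 for k in scales}

        shift = phi * t * 10.0 ** u if have_out else np.zeros_like(theta)
        ll_cur = self.meas_loglik(theta + shift)
        elp_cur = self.event_logprior(theta, bounds, tau)
        blp_cur = self.bounds_logprior(bounds, tau)

        n_keep = (iterations - burn_in + thin - 1) // thin
        store = {
            "theta": np.empty((B, C, n_keep, N)),
            "bounds": np.empty((B, C, n_keep, st.n_bounds)),
            "tau": np.empty((B, C, n_keep, st.n_tau)),
            "phi": np.empty((B, C, n_keep, N), dtype=np.int8),
        }
        kept = 0
        bi = np.arange(B)[:, None, None]
        ni = np.arange(N)[None, None, :]

        for it in range(iterations):
            # --- theta: elementwise random walk
            prop = theta + scales["theta"] * rng.standard_normal((B, C, N))
            ll_p = self.meas_loglik(prop + shift)
            elp_p = self.event_logprior(prop, bounds, tau)
            dlp = (ll_p + elp_p) - (ll_cur + elp_cur)
            a = np.log(rng.random((B, C, N))) < dlp
            theta = np.where(a, prop, theta)
            ll_cur = np.where(a, ll_p, ll_cur)
            elp_cur = np.where(a, elp_p, elp_cur)
            acc["theta"] += a.mean(axis=(1, 2))
            tries["theta"] += 1

            # --- theta: independence proposal from the calibration density.
            # The proposal is over the effective age z = theta + shift (that
            # is what the data constrain), mapped back to theta.
            if it % indep_every == 0:
                uu = rng.random((B, C, N))
                idx = (self.cdfq[:, None, :, :] < uu[..., None]).sum(axis=-1)
                idx = np.minimum(idx, self.grid_asc.size - 1)
                z = (self.grid_asc[idx]
                     + rng.uniform(-0.5, 0.5, (B, C, N)) * self.prop_step)
                prop = z - shift
                logq_p = self.logq[bi, ni, idx]
                icur = np.rint((theta + shift - self.grid_asc[0])
                               / self.prop_step).astype(int)
                inrange = (icur >= 0) & (icur < self.grid_asc.size)
                icur = np.clip(icur, 0, self.grid_asc.size - 1)
                logq_c = np.where(inrange, self.logq[bi, ni, icur], -np.inf)
                ll_p = self.meas_loglik(prop + shift)
                elp_p = self.event_logprior(prop, bounds, tau)
                dlp = (ll_p + elp_p - logq_p) - (ll_cur + elp_cur - logq_c)
                dlp = np.where(np.isfinite(logq_c), dlp, -np.inf)
                a = np.log(rng.random((B, C, N))) < dlp
                theta = np.where(a, prop, theta)
                ll_cur = np.where(a, ll_p, ll_cur)
                elp_cur = np.where(a, elp_p, elp_cur)

            # --- boundaries, one coordinate at a time
            for k in st.free_bounds:
                bprop = bounds.copy()
                bprop[..., k] = bounds[..., k] + scales["bounds"] * \
                    rng.standard_normal((B, C))
                elp_p = self.event_logprior(theta, bprop, tau)
                blp_p = self.bounds_logprior(bprop, tau)
                dlp = (elp_p.sum(-1) + blp_p) - (elp_cur.sum(-1) + blp_cur)
                a = np.log(rng.random((B, C))) < dlp
                bounds = np.where(a[..., None], bprop, bounds)
                elp_cur = np.where(a[..., None], elp_p, elp_cur)
                blp_cur = np.where(a, blp_p, blp_cur)
                acc["bounds"] += a.mean(axis=1) / max(len(st.free_bounds), 1)
            tries["bounds"] += 1

            # --- sigma-phase tail scales
            if st.n_tau:
                tprop = tau + scales["tau"][..., None] * \
                    rng.standard_normal((B, C, st.n_tau))
                elp_p = self.event_logprior(theta, bounds, tprop)
                blp_p = self.bounds_logprior(bounds, tprop)
                dlp = (elp_p.sum(-1) + blp_p) - (elp_cur.sum(-1) + blp_cur)
                a = np.log(rng.random((B, C))) < dlp
                tau = np.where(a[..., None], tprop, tau)
                elp_cur = np.where(a[..., None], elp_p, elp_cur)
                blp_cur = np.where(a, blp_p, blp_cur)
                acc["tau"] += a.mean(axis=1)
                tries["tau"] += 1

            # --- outlier machinery
            if have_out:
                o = self.outlier
                lo, hi = o.log10_scale_range
                off = phi == 0
                if off.any():  # exact conditional = prior when the shift is unused
                    t = np.where(off, rng.standard_t(o.t_df, (B, C, N)), t)
                    u = np.where(off, rng.uniform(lo, hi, (B, C, N)), u)
                ll1 = self.meas_loglik(theta + t * 10.0 ** u)
                tp = t + scales["t"] * rng.standard_normal((B, C, N))
                up = u + scales["u"] * rng.standard_normal((B, C, N))
                ll1_p = self.meas_loglik(theta + tp * 10.0 ** up)
                dprior = (-0.5 * (o.t_df + 1.0)
                          * (np.log1p(tp * tp / o.t_df) - np.log1p(t * t / o.t_df)))
                dlp = (ll1_p - ll1) + dprior
                dlp = np.where((up >= lo) & (up <= hi), dlp, -np.inf)
                a = (np.log(rng.random((B, C, N))) < dlp) & (phi == 1)
                t = np.where(a, tp, t)
                u = np.where(a, up, u)
                ll1 = np.where(a, ll1_p, ll1)
                acc["t"] += (a & (phi == 1)).sum(axis=(1, 2)) / \
                    np.maximum((phi == 1).sum(axis=(1, 2)), 1)
                tries["t"] += 1
                # Gibbs flip of phi from its full conditional
                ll0 = self.meas_loglik(theta)
                logit = np.log(o.prior_prob / (1.0 - o.prior_prob)) + ll1 - ll0
                pflip = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
                phi = (rng.random((B, C, N)) < pflip).astype(float)
                shift = phi * t * 10.0 ** u
                ll_cur = np.where(phi == 1, ll1, ll0)

                # blame-shift: move (t, u) jointly with theta while keeping
                # theta + shift (hence the likelihood) fixed — lets a flagged
                # date slide into its phase while the shift absorbs the rest.
                flagged = phi == 1
                if flagged.any():
                    use_prior = rng.random((B, C, N)) < 0.5
                    t_rw = t + scales["t"] * rng.standard_normal((B, C, N))
                    u_rw = u + scales["u"] * rng.standard_normal((B, C, N))
                    t_pr = rng.standard_t(o.t_df, (B, C, N))
                    u_pr = rng.uniform(lo, hi, (B, C, N))
                    tp = np.where(use_prior, t_pr, t_rw)
                    up = np.where(use_prior, u_pr, u_rw)
                    shift_p = tp * 10.0 ** up
                    theta_p = theta + shift - shift_p
                    elp_p = self.event_logprior(theta_p, bounds, tau)
                    dprior = (-0.5 * (o.t_df + 1.0)
                              * (np.log1p(tp * tp / o.t_df)
                                 - np.log1p(t * t / o.t_df)))
                    # prior-draw proposals cancel the (t, u) prior exactly
                    dlp = elp_p - elp_cur + np.where(use_prior, 0.0, dprior)
                    dlp = np.where((up >= lo) & (up <= hi), dlp, -np.inf)
                    a = (np.log(rng.random((B, C, N))) < dlp) & flagged
                    theta = np.where(a, theta_p, theta)
                    t = np.where(a, tp, t)
                    u = np.where(a, up, u)
                    elp_cur = np.where(a, elp_p, elp_cur)
                    shift = phi * t * 10.0 ** u

            # --- burn-in-only adaptation
            if it < burn_in and (it + 1) % adapt_every == 0:
                for k, target in (("theta", 0.35), ("bounds", 0.30),
                                  ("tau", 0.30), ("t", 0.25)):
                    rate = acc[k] / tries[k]
                    fac = np.exp(0.8 * (rate - target))
                    if k in ("theta", "t"):
                        scales[k] *= fac[:, None, None]
                        if k == "t":
                            scales["u"] *= fac[:, None, None]
                    else:
                        scales[k] *= fac[:, None]
                    acc[k][:] = 0.0
                    tries[k] = 1e-12

            if it >= burn_in and (it - burn_in) % thin == 0:
                store["theta"][:, :, kept] = theta
                store["bounds"][:, :, kept] = bounds
                store["tau"][:, :, kept] = tau
                store["phi"][:, :, kept] = phi.astype(np.int8)
                kept += 1

        for k in store:
            store[k] = store[k][:, :, :kept]
        store["scales"] = {k: v.copy() for k, v in scales.items()}
        return store
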