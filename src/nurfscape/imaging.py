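"""Chromatin-binding kinetics from single-molecule tracks and FRAP traces.

Single-particle tracking movies (500 ms frames by default) yield per-
molecule *dwell times*: the span of frames over which a bound molecule is
detected.  Trackers split a track when a molecule is missed for a frame,
so fragments separated by a single skipped frame (and a small spatial
jump) are re-linked first.  Dwells are summarized as an uncorrected
survival curve S(t) — the fraction of dwells at least t — and fitted with
a two-exponential mixture

    S(t) = f * exp(-t/tau1) + (1 - f) * exp(-t/tau2),   tau1 <= tau2,

whose mixture mean ``f*tau1 + (1-f)*tau2`` is the mean residence time.

Dwell conventions: with frame interval dt, an n-frame track spans
``n * dt`` by the inclusive convention (default) or ``(n - 1) * dt`` by
the span convention.  For an exponential dwell discretized to frames the
span convention makes the survival curve exact on the frame grid
(S(k*dt) equals the true survivor function), whereas the inclusive
convention shifts it by one frame; the residence-time pipeline therefore
fits under the span convention.

FRAP traces are fitted with single-exponential recovery
``I(t) = I_inf - (I_inf - I_0) * exp(-k t)``; the recovery half-life is
``ln 2 / k`` and the mobile fraction ``(I_inf - I_0)/(baseline - I_0)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "link_skipped_frames",
    "dwell_times",
    "survival_curve",
    "TwoExponentialSurvival",
    "fit_two_exponential",
    "FrapRecovery",
    "fit_frap",
    "bound_unbound_ratio",
]

TRACK_COLUMNS = ["track_id", "frame", "x", "y"]


def _track_summary(tracks: pd.DataFrame) -> pd.DataFrame:
    g = tracks.sort_values(["track_id", "frame"]).groupby("track_id", sort=True)
    first = g.first()
    last = g.last()
    return pd.DataFrame(
        {
            "first_frame": first["frame"],
            "last_frame": last["frame"],
            "first_x": first["x"],
            "first_y": first["y"],
            "last_x": last["x"],
            "last_y": last["y"],
        }
    )


def link_skipped_frames(
    tracks: pd.DataFrame, max_gap: int = 1, max_jump: float = 2.0
) -> tuple[pd.DataFrame, int]:
    """Re-join track fragments split by skipped detection frames.

    Fragment pairs whose end and start are separated by at most
    ``max_gap + 1`` frames and at most ``max_jump`` distance are merged
    greedily nearest-first (distance ties resolve to the earlier fragment
    id).  Each fragment end / start participates in at most one merge, but
    chains A->B->C are allowed.  Returns ``(linked_tracks, n_merged)``;
    linked tracks reuse the id of their earliest fragment.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if tracks.empty:
        return tracks.copy(), 0
    summ = _track_summary(tracks)
    ids = summ.index.to_numpy()
    first_frame = summ["first_frame"].to_numpy()
    last_frame = summ["last_frame"].to_numpy()
    fx, fy = summ["first_x"].to_numpy(), summ["first_y"].to_numpy()
    lx, ly = summ["last_x"].to_numpy(), summ["last_y"].to_numpy()
    # candidate pairs via a frame join: ends at frame f against starts at
    # frame f + dframe, distances vectorized, then filtered by max_jump
    start_order = np.argsort(first_frame, kind="stable")
    sorted_first = first_frame[start_order]
    candidates = []
    for dframe in range(1, max_gap + 2):
        target = last_frame + dframe
        lo = np.searchsorted(sorted_first, target, side="left")
        hi = np.searchsorted(sorted_first, target, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        ends_rep = np.repeat(np.arange(len(ids)), counts)
        starts_idx = start_order[
            np.concatenate([np.arange(l, h) for l, h in zip(lo, hi) if h > l])
        ]
        dist = np.hypot(fx[starts_idx] - lx[ends_rep], fy[starts_idx] - ly[ends_rep])
        ok = (dist <= max_jump) & (ends_rep != starts_idx)
        for d, i, j in zip(dist[ok], ends_rep[ok], starts_idx[ok]):
            candidates.append((float(d), ids[i], ids[j]))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    next_of: dict = {}
    has_prev: set = set()
    used_end: set = set()
    for dist, tid_e, tid_s in candidates:
        if tid_e in used_end or tid_s in has_prev:
            continue
        next_of[tid_e] = tid_s
        used_end.add(tid_e)
        has_prev.add(tid_s)
    # resolve chains to their root id
    root = {}
    for tid in ids:
        if tid in has_prev:
            continue
        cur = tid
        while True:
            root[cur] = tid
            if cur in next_of:
                cur = next_of[cur]
            else:
                break
    out = tracks.copy()
    out["track_id"] = out["track_id"].map(root)
    out = out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    return out, len(next_of)


def dwell_times(
    tracks: pd.DataFrame,
    frame_interval: float = 0.5,
    n_frames: int | None = None,
    convention: str = "inclusive",
) -> pd.DataFrame:
    """Per-track chromatin dwell times.

    The dwell of a track spanning frames [f0, f1] is
    ``(f1 - f0 + 1) * frame_interval`` under the ``"inclusive"`` convention
    (a single detection counts one interval) or ``(f1 - f0) *
    frame_interval`` under ``"span"``.  Tracks touching the first or last
    movie frame (``n_frames`` given, frames 0-indexed) are flagged
    censored: their true dwell is only bounded below.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if convention not in ("inclusive", "span"):
        raise ValueError("convention must be 'inclusive' or 'span'")
    g = tracks.groupby("track_id", sort=True)["frame"]
    first = g.min()
    last = g.max()
    spanned = (last - first + (1 if convention == "inclusive" else 0)).astype(float)
    dwell = spanned * frame_interval
    censored = pd.Series(False, index=first.index)
    if n_frames is not None:
        censored = (first == 0) | (last == n_frames - 1)
    return pd.DataFrame(
        {
            "track_id": first.index,
            "first_frame": first.to_numpy(),
            "last_frame": last.to_numpy(),
            "dwell_s": dwell.to_numpy(),
            "censored": censored.to_numpy(),
        }
    ).reset_index(drop=True)


def survival_curve(
    dwells, frame_interval: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Uncorrected survival curve on the frame-interval grid.

    ``S(t)`` is the fraction of dwells at least ``t``; censored dwells (if
    present in a DataFrame input) are included at their observed length —
    the "uncorrected" convention.  Returns ``(t, S)`` with
    ``t = 0, dt, 2dt, ...`` up to the longest dwell; ``S(0) = 1`` and S is
    non-increasing.
    """
    if isinstance(dwells, pd.DataFrame):
        values = dwells["dwell_s"].to_numpy(dtype=float)
    else:
        values = np.asarray(dwells, dtype=float)
    if len(values) == 0:
        raise ValueError("no dwells")
    # the grid runs a few frames past the longest dwell: the empirical
    # survivor function is exactly zero there, which anchors fits of
    # fast-dissociating populations whose dwell range spans few frames
    t = np.arange(0, values.max() + 4.5 * frame_interval, frame_interval)
    S = (values[None, :] >= t[:, None] - 1e-9).mean(axis=1)
    return t, S


def _two_exp(t, f, tau1, tau2):
    return f * np.exp(-t / tau1) + (1.0 - f) * np.exp(-t / tau2)


class TwoExponentialSurvival(BaseEstimator):
    """Least-squares two-exponential fit of a survival curve.

    Canonicalized so ``tau1_ <= tau2_`` (the fit is label-symmetric:
    swapping ``(f, tau1)`` with ``(1-f, tau2)`` leaves the curve
    unchanged).  When the two time constants collapse within
    ``collapse_tol`` (relative), the fit falls back to a single
    exponential with ``f_ = 1``.

    Fitted attributes: ``f_``, ``tau1_``, ``tau2_``, ``mean_residence_``
    (= f*tau1 + (1-f)*tau2, s), ``rss_``, ``converged_``,
    ``single_exponential_``.
    """

    def __init__(self, collapse_tol: float = 0.05, maxfev: int = 20000):
        self.collapse_tol = collapse_tol
        self.maxfev = maxfev

    def fit(self, t, S):
        t = np.asarray(t, dtype=float).ravel()
        S = np.asarray(S, dtype=float).ravel()
        if len(np.unique(t)) < 6:
            raise ValueError("need at least 6 distinct time points")
        tmax = t.max()
        # area under S approximates the mean dwell; seeds the slow tau
        mean0 = max(np.trapezoid(S, t), t[1] if len(t) > 1 else 1.0)
        starts = [
            (0.5, max(mean0 / 10, 1e-3), mean0 * 2),
            (0.8, max(mean0 / 30, 1e-3), mean0),
            (0.2, mean0, mean0 * 3),
        ]
        best = None
        for p0 in starts:
            try:
                popt, _ = curve_fit(
                    _two_exp,
                    t,
                    S,
                    p0=p0,
                    bounds=([0.0, 1e-6, 1e-6], [1.0, tmax * 100, tmax * 100]),
                    maxfev=self.maxfev,
                )
            except RuntimeError:
                continue
            resid = S - _two_exp(t, *popt)
            rss = float(resid @ resid)
            if best is None or rss < best[1]:
                best = (popt, rss)
        if best is None:
            self.converged_ = False
            self.f_ = self.tau1_ = self.tau2_ = self.mean_residence_ = self.rss_ = float("nan")
            self.single_exponential_ = False
            return self
        (f, tau1, tau2), rss = best
        if tau1 > tau2:
            f, tau1, tau2 = 1.0 - f, tau2, tau1
        self.single_exponential_ = False
        if abs(tau2 - tau1) / tau2 < self.collapse_tol or f in (0.0, 1.0):
            # degenerate mixture: refit a single exponential
            try:
                popt1, _ = curve_fit(
                    lambda tt, tau: np.exp(-tt / tau),
                    t,
                    S,
                    p0=[max(mean0, 1e-3)],
                    bounds=([1e-6], [tmax * 100]),
                    maxfev=self.maxfev,
                )
                tau = float(popt1[0])
                f, tau1, tau2 = 1.0, tau, tau
                resid = S - np.exp(-t / tau)
                rss = float(resid @ resid)
                self.single_exponential_ = True
            except RuntimeError:
                pass
        self.converged_ = True
        self.f_ = float(f)
        self.tau1_ = float(tau1)
        self.tau2_ = float(tau2)
        self.mean_residence_ = float(f * tau1 + (1.0 - f) * tau2)
        self.rss_ = rss
        return self

    def predict(self, t):
        if not getattr(self, "converged_", False):
            raise AttributeError("no converged fit available")
        return _two_exp(np.asarray(t, dtype=float), self.f_, self.tau1_, self.tau2_)


def fit_two_exponential(t, S, **kwargs) -> TwoExponentialSurvival:
    """Functional wrapper over :class:`TwoExponentialSurvival`."""
    return TwoExponentialSurvival(**kwargs).fit(t, S)


class FrapRecovery(BaseEstimator):
    """Single-exponential FRAP recovery fit.

    ``fit(times, intensities)`` takes the full trace; points at negative
    times are the pre-bleach baseline (its mean is used unless
    ``baseline`` is passed), points at t >= 0 are fitted with
    ``I(t) = I_inf - (I_inf - I_0) exp(-k t)``.

    Fitted attributes: ``t_half_`` (s), ``mobile_fraction_``, ``i0_``,
    ``i_inf_``, ``k_``, ``baseline_``, ``immobile_``, ``converged_``.
    """

    def __init__(self, baseline: float | None = None, maxfev: int = 20000):
        self.baseline = baseline
        self.maxfev = maxfev

    def fit(self, times, intensities):
        times = np.asarray(times, dtype=float).ravel()
        I = np.asarray(intensities, dtype=float).ravel()
        pre = times < 0
        post = ~pre
        if self.baseline is not None:
            baseline = float(self.baseline)
        elif pre.any():
            baseline = float(I[pre].mean())
        else:
            raise ValueError("no pre-bleach points and no explicit baseline")
        t, y = times[post], I[post]
        if len(t) < 5:
            raise ValueError("need at least 5 post-bleach points")
        i0_0 = float(y[np.argmin(t)])
        iinf_0 = float(y[np.argsort(t)[-max(3, len(t) // 10) :]].mean())
        self.immobile_ = False
        self.converged_ = False
        self.baseline_ = baseline
        # "no recovery within noise": tolerance from the pre-bleach scatter,
        # floored to guard floating-point round-off on noise-free traces
        noise_tol = max(
            2.0 * float(I[pre].std()) if pre.any() else 0.0, 1e-6 * abs(baseline)
        )
        if iinf_0 <= i0_0 + noise_tol:
            self.immobile_ = True
            self.t_half_ = self.mobile_fraction_ = self.i0_ = self.i_inf_ = self.k_ = float("nan")
            return self
        # initial rate from time to half recovery
        half_level = i0_0 + 0.5 * (iinf_0 - i0_0)
        above = t[y >= half_level]
        t_half0 = float(above.min()) if len(above) else max(t.max() / 4, 1e-3)
        k0 = np.log(2) / max(t_half0, 1e-3)

        def model(tt, i_inf, i0, k):
            return i_inf - (i_inf - i0) * np.exp(-k * tt)

        try:
            popt, _ = curve_fit(
                model,
                t,
                y,
                p0=[iinf_0, i0_0, k0],
                bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=self.maxfev,
            )
        except RuntimeError:
            self.t_half_ = self.mobile_fraction_ = self.i0_ = self.i_inf_ = self.k_ = float("nan")
            return self
        i_inf, i0, k = map(float, popt)
        if i_inf <= i0:
            self.immobile_ = True
            self.t_half_ = self.mobile_fraction_ = float("nan")
            self.i0_, self.i_inf_, self.k_ = i0, i_inf, k
            return self
        self.converged_ = True
        self.i0_, self.i_inf_, self.k_ = i0, i_inf, k
        self.t_half_ = float(np.log(2) / k)
        denom = baseline - i0
        self.mobile_fraction_ = float((i_inf - i0) / denom) if denom > 0 else float("nan")
        return self

    def predict(self, times):
        if not getattr(self, "converged_", False):
            raise AttributeError("no converged fit available")
        tt = np.asarray(times, dtype=float)
        return self.i_inf_ - (self.i_inf_ - self.i0_) * np.exp(-self.k_ * tt)


def fit_frap(times, intensities, **kwargs) -> FrapRecovery:
    """Functional wrapper over :class:`FrapRecovery`."""
    return FrapRecovery(**kwargs).fit(times, intensities)


def bound_unbound_ratio(band_intensities, nucleoplasm_intensities) -> float:
    """Bound/unbound ratio: mean chromatin-band over mean nucleoplasm signal.

    Returns NaN when the nucleoplasm mean is zero (undefined ratio);
    raises on an empty compartment.
    """
    band = np.asarray(band_intensities, dtype=float)
    nuc = np.asarray(nucleoplasm_intensities, dtype=float)
    if band.size == 0 or nuc.size == 0:
        raise ValueError("each compartment needs at least one intensity")
    if nuc.mean() == 0:
        return float("nan")
    return float(band.mean() / nuc.mean())
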