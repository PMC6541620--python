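"""Trajectory analytics: speeds, MSD, random-walk test, decay kinetics.

A cell's speed is the mean step displacement per unit time over uniform
10-minute sampling.  The mean-squared displacement

    MSD(tau) = < |r(t + tau) − r(t)|^2 >

is time-averaged over all ordered same-track pairs (overlapping
windows), then averaged over the ensemble.  For a pure 2D random walk
MSD is linear in lag with slope 4D, so an ordinary least-squares fit
with R^2 ~ 1 is the operational test for total random movement; the
log–log slope alpha separates diffusive (alpha ~ 1) from ballistic
(alpha ~ 2) and confined motion.

Washout/inhibition kinetics are summarised by fitting the hourly running
average speed to an exponential approach to a plateau parameterised by
its literal half-life:

    S(t) = S_inf + (S0 − S_inf) · 2^(−(t − t_drug) / t_half)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .io_core import CellQuantError, Track


class MotilityError(CellQuantError):
    pass


@dataclass(frozen=True)
class SpeedSeries:
    """Hourly running-average speed of one track (or a condition mean)."""

    track_id: str
    window_centres_h: np.ndarray
    speeds_um_per_h: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.window_centres_h, dtype=float)
        s = np.asarray(self.speeds_um_per_h, dtype=float)
        if t.size != s.size:
            raise ValueError("window centres and speeds differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("window centres must be increasing")
        if np.any(s < 0):
            raise ValueError("speeds must be >= 0")
        object.__setattr__(self, "window_centres_h", t)
        object.__setattr__(self, "speeds_um_per_h", s)


@dataclass(frozen=True)
class MSDResult:
    """Ensemble MSD curve with optional linear-fit summary."""

    lags_h: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags_h, dtype=float)
        msd = np.asarray(self.msd_um2, dtype=float)
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(msd < 0):
            raise ValueError("msd must be >= 0")
        object.__setattr__(self, "lags_h", lags)
        object.__setattr__(self, "msd_um2", msd)
        object.__setattr__(self, "n_pairs", np.asarray(self.n_pairs, dtype=int))


@dataclass(frozen=True)
class DecayFit:
    """Half-life fit of a decaying speed series."""

    s0_um_per_h: float
    s_inf_um_per_h: float
    half_life_h: float
    residual_norm: float
    identifiable: bool = True


@dataclass(frozen=True)
class MotionClassification:
    label: str  # diffusive | superdiffusive | subdiffusive
    alpha: float
    r_squared_linear: float
    degenerate: bool = False


def _step_speeds(track: Track) -> np.ndarray:
    disp = np.hypot(np.diff(track.xs), np.diff(track.ys))
    return disp / track.dt_h


def average_speed(track: Track) -> float:
    """Mean step speed (µm/h) over the whole track."""
    return float(_step_speeds(track).mean())


def running_average_speed(track: Track, window_h: float = 1.0) -> SpeedSeries:
    """Per-window mean step speed, windows tiled from the track start.

    Steps are assigned to windows by their midpoint time; a trailing
    partial window is dropped.
    """
    if window_h < track.dt_h:
        raise MotilityError(
            f"window {window_h} h shorter than sampling interval {track.dt_h} h"
        )
    span = track.times[-1] - track.times[0]
    n_windows = int(np.floor(span / window_h + 1e-9))
    if n_windows < 1:
        raise MotilityError("track shorter than one window")
    speeds = _step_speeds(track)
    mids = (track.times[:-1] + track.times[1:]) / 2 - track.times[0]
    centres, means = [], []
    for i in range(n_windows):
        sel = (mids >= i * window_h) & (mids < (i + 1) * window_h)
        if not sel.any():
            continue
        centres.append(track.times[0] + (i + 0.5) * window_h)
        means.append(speeds[sel].mean())
    return SpeedSeries(
        track_id=track.track_id,
        window_centres_h=np.array(centres),
        speeds_um_per_h=np.array(means),
    )


def mean_speed_series(series: list[SpeedSeries]) -> SpeedSeries:
    """Average several per-track running series on their common windows."""
    if not series:
        raise MotilityError("no speed series given")
    common = series[0].window_centres_h
    for s in series[1:]:
        n = min(common.size, s.window_centres_h.size)
        common = common[:n]
    stackd = np.vstack([s.speeds_um_per_h[: common.size] for s in series])
    return SpeedSeries(
        track_id="mean",
        window_centres_h=common,
        speeds_um_per_h=stackd.mean(axis=0),
    )


def msd(
    tracks: list[Track],
    max_lag_fraction: float = 0.25,
    overlapping: bool = True,
) -> MSDResult:
    """Ensemble time-averaged MSD.

    For each lag k·dt up to ``max_lag_fraction`` of the shortest track,
    the per-track time average over all ordered pairs (overlapping
    windows by default; ``overlapping=False`` uses disjoint pairs only)
    is computed, then averaged across tracks.
    """
    if not tracks:
        raise MotilityError("empty track list")
    dt = tracks[0].dt_h
    for tr in tracks:
        if abs(tr.dt_h - dt) > 1e-9:
            raise MotilityError("tracks have differing sampling intervals")
    n_min = min(tr.n_points for tr in tracks)
    max_lag = max(1, int(np.floor(max_lag_fraction * (n_min - 1))))
    lags = np.arange(1, max_lag + 1) * dt
    msd_vals = np.zeros(max_lag)
    n_pairs = np.zeros(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        per_track = []
        for tr in tracks:
            pos = tr.positions
            if overlapping:
                d = pos[k:] - pos[:-k]
            else:
                sub = pos[::k]
                d = sub[1:] - sub[:-1]
            if d.shape[0] == 0:
                continue
            per_track.append(np.mean(np.sum(d * d, axis=1)))
            n_pairs[k - 1] += d.shape[0]
        msd_vals[k - 1] = float(np.mean(per_track))
    return MSDResult(lags_h=lags, msd_um2=msd_vals, n_pairs=n_pairs)


def fit_msd_linear(result: MSDResult) -> MSDResult:
    """OLS fit of MSD on lag (with intercept); returns the annotated result.

    R^2 is the standard coefficient of determination; R^2 ~ 1 with a
    positive slope is the signature of a pure random walk.
    """
    if result.lags_h.size < 3:
        raise MotilityError("need at least 3 lags for a linear fit")
    fit = stats.linregress(result.lags_h, result.msd_um2)
    return replace(
        result,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def estimate_diffusion(tracks: list[Track], n_fit_lags: int = 4) -> float:
    """Diffusion coefficient D (µm²/h) from the short-lag MSD slope.

    For noise-free uniformly sampled tracks the variance of the fitted
    slope is minimised by regressing on only the first few lags, where
    the time-averaged MSD has the most independent pairs; the default of
    4 lags follows that standard practice.  D = slope / 4 for 2D motion.
    """
    if n_fit_lags < 2:
        raise MotilityError("need at least 2 lags to fit a slope")
    n_min = min(tr.n_points for tr in tracks)
    frac = min(1.0, (n_fit_lags + 0.5) / max(1, n_min - 1))
    result = msd(tracks, max_lag_fraction=frac)
    if result.lags_h.size < n_fit_lags:
        raise MotilityError("tracks too short for the requested number of fit lags")
    fit = stats.linregress(result.lags_h[:n_fit_lags], result.msd_um2[:n_fit_lags])
    return float(fit.slope / 4.0)


def classify_motion(result: MSDResult, tol: float = 0.1) -> MotionClassification:
    """Classify motion by the log–log slope alpha of MSD vs lag.

    diffusive if |alpha − 1| <= tol, superdiffusive if alpha > 1 + tol,
    subdiffusive otherwise.  Non-positive MSD values are excluded from
    the log fit; if fewer than 3 remain the result is flagged degenerate
    (e.g. stationary cells).
    """
    pos = result.msd_um2 > 0
    if pos.sum() < 3:
        return MotionClassification(
            label="subdiffusive", alpha=float("nan"), r_squared_linear=0.0, degenerate=True
        )
    lin = fit_msd_linear(result) if result.r_squared is None else result
    loglog = stats.linregress(np.log(result.lags_h[pos]), np.log(result.msd_um2[pos]))
    alpha = float(loglog.slope)
    if abs(alpha - 1) <= tol:
        label = "diffusive"
    elif alpha > 1 + tol:
        label = "superdiffusive"
    else:
        label = "subdiffusive"
    return MotionClassification(
        label=label, alpha=alpha, r_squared_linear=float(lin.r_squared)
    )


def fit_speed_decay(series: SpeedSeries, t_drug_h: float = 0.0) -> DecayFit:
    """Fit post-treatment speeds to a half-life decay towards a plateau.

    Nonlinear least squares of
    ``S(t) = S_inf + (S0 − S_inf) · 2^(−(t − t_drug)/t_half)`` on windows
    at or after ``t_drug_h``.  A near-constant series leaves the
    half-life unidentifiable and is flagged rather than fitted.
    """
    sel = series.window_centres_h >= t_drug_h - 1e-9
    t = series.window_centres_h[sel] - t_drug_h
    s = series.speeds_um_per_h[sel]
    if t.size < 4:
        raise MotilityError("need at least 4 post-treatment windows")
    span = float(s.max() - s.min())
    if span < 1e-9 * max(1.0, float(s.max())):
        return DecayFit(
            s0_um_per_h=float(s.mean()),
            s_inf_um_per_h=float(s.mean()),
            half_life_h=float("nan"),
            residual_norm=0.0,
            identifiable=False,
        )

    def model(tt, s0, s_inf, t_half):
        return s_inf + (s0 - s_inf) * np.exp2(-tt / t_half)

    p0 = [float(s[0]), float(s[-1]), max(float(t[-1]) / 4, 1e-3)]
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            s,
            p0=p0,
            bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise MotilityError(f"decay fit did not converge: {exc}") from exc
    resid = s - model(t, *popt)
    return DecayFit(
        s0_um_per_h=float(popt[0]),
        s_inf_um_per_h=float(popt[1]),
        half_life_h=float(popt[2]),
        residual_norm=float(np.linalg.norm(resid)),
    )
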