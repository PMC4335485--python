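"""Per-subject HRF estimation from the photic-burst run.

The full-field burst run (one stimulated volume followed by eleven blank
volumes, repeated ten times) yields an impulse-response estimate: trials
are outlier-rejected and averaged, then a three-parameter double-gamma
(response delay, undershoot delay, response:undershoot ratio, plus a
nuisance amplitude) is fitted by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .forward_model import HRFParams

__all__ = [
    "PhoticRun",
    "HRFFit",
    "trial_average",
    "fit_hrf",
    "select_responsive_vertices",
    "estimate_hrf",
]


@dataclass
class PhoticRun:
    """Photic-burst data: (vertices, T) series and the 10 burst onsets."""

    series: np.ndarray
    trial_onsets: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=int)
        gaps = np.diff(self.trial_onsets)
        if len(gaps) and not np.all(gaps == gaps[0]):
            raise ValueError("trial onsets must be evenly spaced")


@dataclass
class HRFFit:
    """Fitted HRF with diagnostics."""

    params: HRFParams
    amplitude: float
    residual_norm: float
    converged: bool
    reliable: bool


def select_responsive_vertices(
    series: np.ndarray, n_trials: int, quantile: float = 0.9
) -> np.ndarray:
    """Indices of visually responsive vertices: top decile of spectral
    power at the burst repetition frequency (``n_trials`` cycles/run)."""
    series = np.atleast_2d(series)
    coeff = series @ np.exp(
        -2j * np.pi * n_trials * np.arange(series.shape[1]) / series.shape[1]
    )
    power = np.abs(coeff) ** 2
    return np.flatnonzero(power >= np.quantile(power, quantile))


def trial_average(
    run: PhoticRun, outlier_sd: float = 1.5
) -> np.ndarray:
    """Vertex-averaged, outlier-rejected mean epoch across trials.

    The series is averaged over vertices, cut into epochs at the trial
    onsets, and at each epoch time-point values departing more than
    ``outlier_sd`` standard deviations from the across-trial mean are
    excluded before averaging the remaining trials.
    """
    if len(run.trial_onsets) < 2:
        raise ValueError("need at least two trials")
    epoch_len = int(np.diff(run.trial_onsets)[0])
    mean_series = run.series.mean(axis=0)
    epochs = np.stack(
        [mean_series[o : o + epoch_len] for o in run.trial_onsets if o + epoch_len <= len(mean_series)]
    )
    mu = epochs.mean(axis=0)
    sd = epochs.std(axis=0, ddof=0)
    keep = np.abs(epochs - mu) <= outlier_sd * np.where(sd > 0, sd, np.inf)
    counts = keep.sum(axis=0)
    if np.any(counts == 0):
        bad = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"all trials rejected at epoch time-point {bad}")
    return np.where(keep, epochs, 0.0).sum(axis=0) / counts


def _epoch_model(t: np.ndarray, rd: float, ud: float, ratio: float, amp: float) -> np.ndarray:
    peak = stats.gamma.pdf(t, a=rd + 1.0, scale=1.0)
    under = stats.gamma.pdf(t, a=ud + 1.0, scale=1.0)
    h = peak - under / ratio
    m = np.max(np.abs(h))
    return amp * h / m if m > 0 else h


def fit_hrf(
    avg_epoch: np.ndarray,
    dt: float,
    start: HRFParams | None = None,
    reliable_amp: float = 0.05,
) -> HRFFit:
    """Least-squares double-gamma fit to an averaged burst epoch.

    Free parameters: response delay, undershoot delay, amplitude ratio,
    and a nuisance amplitude.  Non-convergence or a near-zero amplitude
    is flagged on the returned fit rather than raised.
    """
    avg_epoch = np.asarray(avg_epoch, dtype=float)
    if len(avg_epoch) < 11:
        raise ValueError("epoch too short to constrain the double gamma")
    t = np.arange(len(avg_epoch)) * dt
    start = start or HRFParams(dt=dt)
    amp0 = float(np.max(np.abs(avg_epoch)))

    def objective(p: np.ndarray) -> float:
        rd, ud, ratio, amp = p
        if rd <= 0 or ud <= 0 or ratio <= 0:
            return np.inf
        return float(np.sum((avg_epoch - _epoch_model(t, rd, ud, ratio, amp)) ** 2))

    x0 = np.array([start.response_delay, start.undershoot_delay, start.ratio, amp0 or 1.0])
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options=dict(xatol=1e-4, fatol=1e-6, maxiter=4000),
    )
    rd, ud, ratio, amp = res.x
    rd, ud, ratio = abs(rd), abs(ud), abs(ratio)
    params = HRFParams(response_delay=rd, undershoot_delay=ud, ratio=ratio, dt=dt)
    return HRFFit(
        params=params,
        amplitude=float(amp),
        residual_norm=float(np.sqrt(res.fun)) if np.isfinite(res.fun) else np.inf,
        converged=bool(res.success),
        reliable=bool(res.success and abs(amp) > reliable_amp),
    )


def estimate_hrf(series: np.ndarray, trial_onsets: np.ndarray, dt: float) -> HRFFit:
    """Full photic pipeline: responsive-vertex pooling, trial averaging,
    double-gamma fitting."""
    series = np.atleast_2d(series)
    n_trials = len(trial_onsets)
    idx = select_responsive_vertices(series, n_trials)
    run = PhoticRun(series=series[idx], trial_onsets=np.asarray(trial_onsets))
    return fit_hrf(trial_average(run), dt)
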