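"""Gaussian pRF encoding model: from aperture masks to predicted BOLD.

The population receptive field of a cortical vertex is modeled as an
isotropic 2D Gaussian in visual space with four parameters: center
(x0, y0), spread sigma, and signal amplitude beta.  The neural response
at each volume is the sum of Gaussian weights falling inside the binary
stimulus aperture; the BOLD prediction is that series convolved with a
double-gamma hemodynamic response function and scaled by beta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .stimulus import ApertureSequence

__all__ = [
    "GaussianPRF",
    "HRFParams",
    "gaussian_weights",
    "neural_prediction",
    "neural_prediction_dog",
    "double_gamma",
    "convolve_neural",
    "bold_prediction",
    "bold_prediction_runs",
]


@dataclass(frozen=True)
class GaussianPRF:
    """2D Gaussian population receptive field (degrees of visual angle)."""

    x0: float
    y0: float
    sigma: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma hemodynamic response parameters.

    The three free shape parameters follow the standard double-gamma
    parameterization: the delay of the positive response peak, the delay
    of the undershoot peak (both in seconds from stimulus onset), and the
    response:undershoot amplitude ratio.  ``dt`` is the sampling interval
    of the generated kernel.
    """

    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    ratio: float = 6.0
    dt: float = 2.55

    def __post_init__(self) -> None:
        if self.response_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("delays must be positive")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def gaussian_weights(
    prf: GaussianPRF | Tuple[float, float, float],
    grid: Tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Unit-peak Gaussian receptive-field weights over the visual grid.

    ``w(x, y) = exp(-((x - x0)^2 + (y - y0)^2) / (2 sigma^2))``
    """
    if isinstance(prf, GaussianPRF):
        x0, y0, sigma = prf.x0, prf.y0, prf.sigma
    else:
        x0, y0, sigma = prf
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x, y = grid
    return np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma**2))


def neural_prediction(prf: GaussianPRF, apertures: ApertureSequence) -> np.ndarray:
    """Per-volume sum of Gaussian weights inside the binary aperture.

    Blank volumes (all-zero masks) give exactly zero.
    """
    w = gaussian_weights(prf, apertures.grid()).ravel()
    return apertures.flat_masks() @ w


def neural_prediction_dog(
    prf: GaussianPRF,
    surround_sigma: float,
    surround_amp: float,
    apertures: ApertureSequence,
) -> np.ndarray:
    """Difference-of-Gaussians neural response (center minus surround).

    Used as a ground-truth generator to probe how surround suppression
    biases plain-Gaussian sigma estimates; never fitted.
    """
    if surround_sigma <= prf.sigma:
        raise ValueError("surround must be broader than the center")
    if not 0 <= surround_amp < 1:
        raise ValueError("surround_amp must be in [0, 1)")
    grid = apertures.grid()
    masks = apertures.flat_masks()
    center = masks @ gaussian_weights((prf.x0, prf.y0, prf.sigma), grid).ravel()
    surround = masks @ gaussian_weights((prf.x0, prf.y0, surround_sigma), grid).ravel()
    return center - surround_amp * surround


def double_gamma(params: HRFParams, duration: float = 32.0) -> np.ndarray:
    """Sampled double-gamma HRF kernel, normalized to unit peak.

    ``h(t) = g(t; response_delay) - g(t; undershoot_delay) / ratio`` with
    each component a gamma density of unit scale whose mode sits exactly
    at its delay (shape = delay + 1), so ``h(0) = 0`` and the kernel peaks
    at ``response_delay``.
    """
    if duration < params.response_delay:
        raise ValueError("duration must cover the response peak")
    t = np.arange(0.0, duration + params.dt / 2, params.dt)
    peak = stats.gamma.pdf(t, a=params.response_delay + 1.0, scale=1.0)
    under = stats.gamma.pdf(t, a=params.undershoot_delay + 1.0, scale=1.0)
    h = peak - under / params.ratio
    return h / np.max(h)


def _convolve_run(neural: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(neural, kernel)[: len(neural)]


def convolve_neural(neural: np.ndarray, hrf: HRFParams) -> np.ndarray:
    """Convolve an arbitrary neural series with the HRF, truncated to its
    own length (used for difference-of-Gaussians ground-truth simulation)."""
    return _convolve_run(np.asarray(neural, dtype=float), double_gamma(hrf))


def bold_prediction(
    prf: GaussianPRF, apertures: ApertureSequence, hrf: HRFParams
) -> np.ndarray:
    """Predicted BOLD series: causal convolution of the neural response
    with the HRF kernel, truncated to the run length and scaled by beta."""
    kernel = double_gamma(hrf)
    return prf.beta * _convolve_run(neural_prediction(prf, apertures), kernel)


def bold_prediction_runs(
    prf: GaussianPRF, runs: Sequence[ApertureSequence], hrf: HRFParams
) -> np.ndarray:
    """Concatenated predictions over several runs, convolved per run so
    hemodynamic responses do not bleed across run boundaries."""
    kernel = double_gamma(hrf)
    parts = [
        prf.beta * _convolve_run(neural_prediction(prf, run), kernel) for run in runs
    ]
    return np.concatenate(parts)
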