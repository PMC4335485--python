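"""Synthetic cortical sheet and BOLD simulation.

Builds a ground-truth test bed for the whole pipeline: a sheet of
vertices with a retinotopic gradient (eccentricity log-spaced along one
sheet axis, polar angle uniform along the other, pRF size growing
linearly with eccentricity at ROI-specific intercept/slope), and a
forward simulation of percent-signal-change BOLD under any aperture
sequence with AR(1) Gaussian noise at a configurable contrast-to-noise
ratio.

The generator emulates the large-scale organization the fitting stages
rely on; it does not model cortical folding, draining veins, or
physiological noise structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.signal import fftconvolve as signal_fftconvolve

from .containers import CorticalSheet, DataMatrix
from .forward_model import HRFParams, double_gamma
from .stimulus import ApertureSequence

__all__ = ["NoiseSpec", "RoiSpec", "make_sheet", "simulate_bold", "make_dog_truth"]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise for the BOLD simulation.

    ``cnr`` is the per-vertex peak of the noiseless prediction divided by
    the noise standard deviation.  ``ar1_rho`` sets mild temporal
    autocorrelation of the kind surviving standard fMRI preprocessing.
    ``cnr = inf`` disables noise.
    """

    cnr: float = 3.0
    ar1_rho: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cnr <= 0:
            raise ValueError("cnr must be positive")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")


@dataclass(frozen=True)
class RoiSpec:
    """Linear sigma-vs-eccentricity law of one simulated visual area."""

    name: str
    sigma_intercept: float
    sigma_slope: float


DEFAULT_ROIS = (
    RoiSpec("V1", 0.5, 0.25),
    RoiSpec("V2", 0.7, 0.35),
    RoiSpec("V3", 0.9, 0.45),
)


def _roi_grid_shape(n: int) -> tuple[int, int]:
    """Near-square block shape; the last row may be partially filled."""
    rows = max(1, int(np.round(np.sqrt(n))))
    return rows, int(np.ceil(n / rows))


def make_sheet(
    n_vertices: int,
    rois: Sequence[RoiSpec] = DEFAULT_ROIS,
    max_ecc: float = 9.0,
    seed: int = 0,
    spacing_mm: float = 1.0,
    ecc_min: float = 0.5,
    ecc_max_frac: float = 0.95,
    beta: float = 1.0,
) -> CorticalSheet:
    """Regular-grid cortical sheet with ground-truth retinotopy.

    Vertices are split evenly across ROIs; within each ROI block they lie
    on a regular grid with eccentricity log-spaced along rows (emulating
    cortical magnification) and polar angle uniform along columns.  Per
    vertex, ``sigma = intercept + slope * eccentricity``; positions get a
    small seeded jitter so that pRF centers are not grid-aligned.
    Adjacent ROI blocks are stitched edge-to-edge so the sheet graph is
    connected.
    """
    if not rois:
        raise ValueError("at least one ROI required")
    per_roi = n_vertices // len(rois)
    if per_roi < 16:
        raise ValueError("need at least 16 vertices per ROI")
    rng = np.random.default_rng(seed)
    rows, cols = _roi_grid_shape(per_roi)

    coords, labels, records = [], [], []
    row_idx, col_idx = [], []
    ecc_levels = np.geomspace(ecc_min, ecc_max_frac * max_ecc, rows)
    angles = np.arange(cols) * (360.0 / cols)
    for b, roi in enumerate(rois):
        x_off = b * (cols + 2) * spacing_mm  # 2-column gap between ROI blocks
        placed = 0
        for i in range(rows):
            for j in range(cols):
                if placed == per_roi:
                    break
                placed += 1
                ecc = ecc_levels[i] * np.exp(rng.normal(0.0, 0.03))
                ang = angles[j] + rng.normal(0.0, 2.0)
                ecc = min(ecc, max_ecc)
                sigma = roi.sigma_intercept + roi.sigma_slope * ecc
                if sigma <= 0:
                    raise ValueError(
                        f"ROI {roi.name}: sigma law non-positive at ecc {ecc:.2f}"
                    )
                coords.append((x_off + j * spacing_mm, i * spacing_mm))
                labels.append(roi.name)
                records.append(
                    dict(
                        x0=ecc * np.cos(np.deg2rad(ang)),
                        y0=ecc * np.sin(np.deg2rad(ang)),
                        sigma=sigma,
                        beta=beta,
                        ecc=ecc,
                    )
                )
                row_idx.append(i)
                col_idx.append(j)

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    graph = sparse.lil_matrix((n, n))
    index = {}
    for v, (b, i, j) in enumerate(
        (v // per_roi, row_idx[v], col_idx[v]) for v in range(n)
    ):
        index[(b, i, j)] = v
    for (b, i, j), v in index.items():
        for bi, ii, jj in ((b, i + 1, j), (b, i, j + 1)):
            u = index.get((bi, ii, jj))
            if u is not None:
                d = float(np.linalg.norm(coords[v] - coords[u]))
                graph[v, u] = graph[u, v] = d
        # stitch the last column of one ROI block to the first of the next
        if j == cols - 1 and (b + 1, i, 0) in index:
            u = index[(b + 1, i, 0)]
            d = float(np.linalg.norm(coords[v] - coords[u]))
            graph[v, u] = graph[u, v] = d

    truth = pd.DataFrame(records)
    map_params = pd.DataFrame(
        [dict(roi=r.name, sigma_intercept=r.sigma_intercept, sigma_slope=r.sigma_slope) for r in rois]
    )
    return CorticalSheet(
        vertex_coords=coords,
        neighbor_graph=graph.tocsr(),
        roi_label=np.asarray(labels),
        truth=truth,
        map_params=map_params,
    )


def make_dog_truth(
    sheet: CorticalSheet, surround_ratio: float = 2.0, surround_amp: float = 0.2
) -> CorticalSheet:
    """Replace the sheet's Gaussian truth with difference-of-Gaussians.

    Surround sigma is ``surround_ratio`` times the center sigma; the
    surround subtracts ``surround_amp`` times its aperture sum from the
    neural response.  ``surround_amp * surround_ratio**2`` (the surround's
    share of the receptive-field volume) must stay below 1 so that
    suppression weakens responses without inverting them.
    """
    if surround_ratio <= 1:
        raise ValueError("surround_ratio must exceed 1")
    if not 0 <= surround_amp < 1:
        raise ValueError("surround_amp must be in [0, 1)")
    if surround_amp * surround_ratio**2 >= 1:
        raise ValueError(
            "surround volume exceeds the center's: require "
            "surround_amp * surround_ratio**2 < 1"
        )
    truth = sheet.truth.copy()
    truth["surround_sigma"] = truth["sigma"] * surround_ratio
    truth["surround_amp"] = surround_amp
    return CorticalSheet(
        vertex_coords=sheet.vertex_coords,
        neighbor_graph=sheet.neighbor_graph,
        roi_label=sheet.roi_label,
        truth=truth,
        map_params=sheet.map_params,
    )


def _truth_neural_matrix(truth: pd.DataFrame, run: ApertureSequence) -> np.ndarray:
    """(V, T) neural responses of all ground-truth pRFs to one run."""
    x, y = run.grid()
    xf, yf = x.ravel(), y.ravel()
    x0 = truth["x0"].to_numpy()[:, None]
    y0 = truth["y0"].to_numpy()[:, None]
    sig = truth["sigma"].to_numpy()[:, None]
    beta = truth["beta"].to_numpy()[:, None]
    d2 = (xf[None, :] - x0) ** 2 + (yf[None, :] - y0) ** 2
    w = np.exp(-d2 / (2.0 * sig**2))
    if "surround_sigma" in truth.columns:
        ss = truth["surround_sigma"].to_numpy()[:, None]
        amp = truth["surround_amp"].to_numpy()[:, None]
        w = w - amp * np.exp(-d2 / (2.0 * ss**2))
    return beta * (w @ run.flat_masks().T)


def simulate_bold(
    sheet: CorticalSheet,
    runs: Sequence[ApertureSequence] | ApertureSequence,
    hrf: HRFParams,
    noise: NoiseSpec = NoiseSpec(),
) -> DataMatrix:
    """Forward-simulate percent-signal-change BOLD for every vertex.

    The noiseless prediction is the ground-truth neural response
    convolved with the HRF per run; AR(1) Gaussian noise is added with a
    standard deviation of (per-vertex peak prediction) / cnr.  Vertices
    whose pRF is never stimulated get noise scaled by the median peak of
    the stimulated vertices.
    """
    if isinstance(runs, ApertureSequence):
        runs = [runs]
    if sheet.truth is None:
        raise ValueError("sheet carries no ground truth")
    kernel = double_gamma(hrf)
    parts = []
    for run in runs:
        neurals = _truth_neural_matrix(sheet.truth, run)
        t = neurals.shape[1]
        # convolve all vertices at once, causal truncation to the run length
        full = signal_fftconvolve(neurals, kernel[None, :], axes=1)[:, :t]
        parts.append(full)
    signal = np.concatenate(parts, axis=1)

    peaks = np.max(np.abs(signal), axis=1)
    ref = np.median(peaks[peaks > 0]) if np.any(peaks > 0) else 1.0
    sds = np.where(peaks > 0, peaks, ref) / noise.cnr
    if not np.isfinite(noise.cnr):
        return DataMatrix(series=signal, tr_s=runs[0].tr_s, sheet=sheet)

    rng = np.random.default_rng(noise.seed)
    v, t = signal.shape
    white = rng.standard_normal((v, t))
    eps = np.empty_like(white)
    eps[:, 0] = white[:, 0]
    rho = noise.ar1_rho
    scale = np.sqrt(1.0 - rho**2)
    for k in range(1, t):
        eps[:, k] = rho * eps[:, k - 1] + scale * white[:, k]
    series = signal + eps * sds[:, None]
    return DataMatrix(series=series, tr_s=runs[0].tr_s, sheet=sheet)
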