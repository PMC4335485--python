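"""Coarse-to-fine estimation of Gaussian pRF parameters per vertex.

Stage one ("coarse fit") correlates each vertex's surface-smoothed time
series against an exhaustive grid of HRF-convolved model predictions:
candidate centers on a 2.4-degree lattice within the stimulated field and
34 exponentially spaced sigma levels from 0.32 to 32 degrees.  Stage two
("fine fit") refines the winning candidate on the unsmoothed series with
a Nelder-Mead simplex search over (x0, y0, sigma, beta), minimizing the
squared residuals.

Goodness of fit is the squared Pearson correlation at the coarse stage
(scale-free) and 1 - SS_res/SS_tot at the fine stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .containers import DataMatrix
from .forward_model import HRFParams, double_gamma
from .stimulus import ApertureSequence

__all__ = [
    "SearchGrid",
    "build_search_grid",
    "smooth_on_sheet",
    "coarse_fit",
    "fine_fit",
    "fit_prf",
]

COARSE_R2_MIN = 0.05  # inclusion threshold for fine fitting
ANALYSIS_R2_MIN = 0.1  # downstream vertex-selection threshold

SIGMA_RANGE = (0.32, 32.0)
N_SIGMA = 34
CENTER_STEP_DEG = 2.4


def _as_runs(runs: Sequence[ApertureSequence] | ApertureSequence) -> list:
    return [runs] if isinstance(runs, ApertureSequence) else list(runs)


@dataclass
class SearchGrid:
    """Exhaustive candidate set with precomputed unit-amplitude predictions.

    Candidates are ordered by (sigma, center radius) ascending, so the
    first index hit by an argmax is the preferred tie-break (smallest
    sigma, then most foveal center).
    """

    params: np.ndarray  # (C, 3): x0, y0, sigma
    predictions: np.ndarray  # (C, T), HRF-convolved, unit amplitude
    run_slices: list

    @property
    def n_candidates(self) -> int:
        return self.params.shape[0]


def _center_candidates(max_ecc: float, step: float) -> np.ndarray:
    offsets = np.arange(0.0, max_ecc + 1e-9, step)
    return np.unique(np.concatenate([-offsets, offsets]))


def _run_slices(runs: Sequence[ApertureSequence]) -> list:
    slices, start = [], 0
    for run in runs:
        slices.append(slice(start, start + run.n_volumes))
        start += run.n_volumes
    return slices


def _convolve_segments(neural: np.ndarray, kernel: np.ndarray, slices: list) -> np.ndarray:
    """Causal convolution applied independently within each run segment.

    ``neural`` is (..., T); convolution never bleeds across run borders.
    """
    from scipy.signal import fftconvolve

    out = np.empty_like(neural)
    for sl in slices:
        seg = neural[..., sl]
        n = seg.shape[-1]
        if seg.ndim > 1:
            out[..., sl] = fftconvolve(seg, kernel[None, :], axes=-1)[..., :n]
        else:
            out[..., sl] = np.convolve(seg, kernel)[:n]
    return out


def build_search_grid(
    runs: Sequence[ApertureSequence] | ApertureSequence,
    hrf: HRFParams,
    max_ecc: float | None = None,
    step: float = CENTER_STEP_DEG,
    sigma_range: Tuple[float, float] = SIGMA_RANGE,
    n_sigma: int = N_SIGMA,
) -> SearchGrid:
    """Build the three-dimensional (x0, y0, sigma) search space and one
    HRF-convolved prediction per candidate.

    Center candidates step by 2.4 degrees within the stimulated bounds;
    sigma levels are exponentially spaced (34 levels, 0.32-32 degrees by
    default).
    """
    runs = _as_runs(runs)
    if not runs:
        raise ValueError("no aperture runs given")
    cfg = runs[0].cfg
    max_ecc = max_ecc if max_ecc is not None else cfg.max_eccentricity_deg
    centers = _center_candidates(max_ecc, step)
    if centers.size == 0:
        raise ValueError("empty candidate bounds")
    sigmas = np.geomspace(sigma_range[0], sigma_range[1], n_sigma)

    xx, yy = np.meshgrid(centers, centers)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= max_ecc + 1e-9]
    radius = np.hypot(pts[:, 0], pts[:, 1])
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0], radius))]

    params = np.concatenate(
        [np.column_stack([pts, np.full(len(pts), s)]) for s in sigmas]
    )
    # order by (sigma, radius): sigma blocks are already contiguous & ascending
    x, y = cfg.grid()
    xf, yf = x.ravel(), y.ravel()
    masks = np.concatenate([run.flat_masks() for run in runs])  # (T, P)
    slices = _run_slices(runs)
    kernel = double_gamma(hrf)

    preds = np.empty((params.shape[0], masks.shape[0]))
    chunk = max(1, int(2e7 // masks.shape[1]))
    for lo in range(0, params.shape[0], chunk):
        p = params[lo : lo + chunk]
        d2 = (xf[None, :] - p[:, 0:1]) ** 2 + (yf[None, :] - p[:, 1:2]) ** 2
        w = np.exp(-d2 / (2.0 * p[:, 2:3] ** 2))
        preds[lo : lo + chunk] = w @ masks.T
    preds = _convolve_segments(preds, kernel, slices)
    return SearchGrid(params=params, predictions=preds, run_slices=slices)


def smooth_on_sheet(data: DataMatrix, fwhm_mm: float) -> DataMatrix:
    """Gaussian smoothing along the cortical sheet's neighbor graph.

    Each time-point is smoothed with weights exp(-d^2 / (2 sd^2)) on
    geodesic (graph shortest-path) distances, sd = fwhm / 2.355, with
    per-vertex weight normalization; ``fwhm_mm = 0`` is the identity.
    Vertices unreachable from the rest of the sheet keep their own values
    and trigger a warning.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0 or data.sheet is None:
        if fwhm_mm > 0:
            warnings.warn("no sheet geometry available; data left unsmoothed")
        return DataMatrix(series=data.series.copy(), tr_s=data.tr_s, sheet=data.sheet,
                          vertex_ids=data.vertex_ids)
    sd = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    graph = data.sheet.neighbor_graph
    dists = sparse.csgraph.dijkstra(graph, directed=False, limit=3.0 * sd)
    w = np.exp(-(dists**2) / (2.0 * sd**2))
    w[~np.isfinite(dists)] = 0.0
    np.fill_diagonal(w, 1.0)
    isolated = w.sum(axis=1) <= 1.0 + 1e-12
    if np.any(isolated) and graph.shape[0] > 1:
        n_comp, _ = sparse.csgraph.connected_components(graph, directed=False)
        if n_comp > 1:
            warnings.warn(f"{int(isolated.sum())} vertices have no neighbors in smoothing range")
    w /= w.sum(axis=1, keepdims=True)
    return DataMatrix(series=w @ data.series, tr_s=data.tr_s, sheet=data.sheet,
                      vertex_ids=data.vertex_ids)


def _standardize_rows(a: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    z = (a - mu) / np.where(sd > 0, sd, 1.0)
    return z, ok


def coarse_fit(
    series: np.ndarray, grid: SearchGrid, r2_min: float = COARSE_R2_MIN
) -> pd.DataFrame:
    """Exhaustive correlation search over the candidate grid.

    Returns one row per vertex: the argmax-correlation candidate, its
    squared correlation ``r2_coarse``, and an ``included`` flag that is
    False for vertices with non-positive best correlation, squared
    correlation at or below ``r2_min``, or zero-variance series.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[1] != grid.predictions.shape[1]:
        raise ValueError("series length does not match grid predictions")
    zs, ok_s = _standardize_rows(series)
    zp, ok_p = _standardize_rows(grid.predictions)
    r = (zs @ zp.T) / series.shape[1]
    r[:, ~ok_p] = -np.inf
    best = np.argmax(r, axis=1)  # first max: smallest sigma, most foveal
    r_best = r[np.arange(len(best)), best]
    included = ok_s & (r_best > 0) & (r_best**2 > r2_min)
    out = pd.DataFrame(
        dict(
            vertex_id=np.arange(series.shape[0]),
            x0=grid.params[best, 0],
            y0=grid.params[best, 1],
            sigma=grid.params[best, 2],
            r2_coarse=np.where(ok_s, r_best**2, 0.0),
            candidate=best,
            included=included,
        )
    )
    return out


def _prepare_runs(runs: Sequence[ApertureSequence]):
    cfg = runs[0].cfg
    x, y = cfg.grid()
    masks = np.concatenate([run.flat_masks() for run in runs])
    return x.ravel(), y.ravel(), masks, _run_slices(runs)


def fine_fit(
    series: np.ndarray,
    coarse: pd.DataFrame,
    runs: Sequence[ApertureSequence] | ApertureSequence,
    hrf: HRFParams,
    xatol: float = 1e-4,
    fatol: float = 1e-4,
) -> pd.DataFrame:
    """Nelder-Mead refinement of (x0, y0, sigma, beta) per included vertex.

    Starts from the coarse candidate with beta initialized by least-
    squares projection of the starting prediction onto the unsmoothed
    series; invalid sigma <= 0 is repelled by an infinite objective.
    Non-converged vertices retain the coarse parameters and are flagged.
    """
    runs = _as_runs(runs)
    series = np.atleast_2d(np.asarray(series, dtype=float))
    xf, yf, masks, slices = _prepare_runs(runs)
    kernel = double_gamma(hrf)
    t_total = masks.shape[0]
    if series.shape[1] != t_total:
        raise ValueError("series length does not match apertures")

    def predict(p: np.ndarray) -> np.ndarray:
        w = np.exp(-((xf - p[0]) ** 2 + (yf - p[1]) ** 2) / (2.0 * p[2] ** 2))
        neural = masks @ w
        out = np.empty(t_total)
        for sl in slices:
            seg = neural[sl]
            out[sl] = np.convolve(seg, kernel)[: len(seg)]
        return out

    rows = []
    for _, row in coarse.iterrows():
        v = int(row["vertex_id"])
        y = series[v]
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if not row["included"]:
            rows.append(
                dict(vertex_id=v, x0=row["x0"], y0=row["y0"], sigma=row["sigma"],
                     beta=np.nan, r2_coarse=row["r2_coarse"], r2_fine=np.nan,
                     converged=False, included=False)
            )
            continue
        start = np.array([row["x0"], row["y0"], row["sigma"]])
        base = predict(start)
        denom = float(base @ base)
        beta0 = float(base @ y) / denom if denom > 0 else 1.0

        def objective(p: np.ndarray) -> float:
            if p[2] <= 0:
                return np.inf
            return float(np.sum((y - p[3] * predict(p[:3])) ** 2))

        x0 = np.concatenate([start, [beta0]])
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options=dict(xatol=xatol, fatol=fatol, maxiter=400 * 4, maxfev=400 * 4),
        )
        if res.success and np.isfinite(res.fun) and res.x[2] > 0:
            xf_, yf_, sig_, beta_ = res.x
            sse = res.fun
            converged = True
        else:
            xf_, yf_, sig_ = start
            beta_ = beta0
            sse = objective(x0)
            converged = False
        r2 = 1.0 - sse / ss_tot if ss_tot > 0 else np.nan
        rows.append(
            dict(vertex_id=v, x0=xf_, y0=yf_, sigma=sig_, beta=beta_,
                 r2_coarse=row["r2_coarse"], r2_fine=r2, converged=converged,
                 included=True)
        )
    return pd.DataFrame(rows)


def fit_prf(
    data: DataMatrix,
    runs: Sequence[ApertureSequence] | ApertureSequence,
    hrf: HRFParams,
    grid: SearchGrid | None = None,
    fwhm_mm: float = 8.3,
    coarse_r2: float = COARSE_R2_MIN,
    **grid_kwargs,
) -> pd.DataFrame:
    """Full two-stage pipeline: smooth, coarse grid search, fine simplex.

    The coarse stage sees the surface-smoothed series; the fine stage
    refines on the unsmoothed series.  Returns the per-vertex fit table.
    """
    runs = _as_runs(runs)
    if grid is None:
        grid = build_search_grid(runs, hrf, **grid_kwargs)
    smoothed = smooth_on_sheet(data, fwhm_mm)
    coarse = coarse_fit(smoothed.series, grid, r2_min=coarse_r2)
    fits = fine_fit(data.series, coarse, runs, hrf)
    fits["ecc"] = np.hypot(fits["x0"], fits["y0"])
    return fits
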