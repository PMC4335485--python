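"""Cross-validated comparison of pRF models across stimulus conditions.

A pRF table fitted on one stimulus condition predicts the observed
series of a held-out condition through the known apertures of that
condition.  Per-vertex Pearson correlations between prediction and
observation are Fisher z-transformed, averaged within regions of
interest, and compared between training conditions with paired t-tests.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forward_model import HRFParams, double_gamma
from .prf_fitting import _as_runs, _prepare_runs
from .stimulus import ApertureSequence

__all__ = ["predict_heldout", "fisher_z_scores", "compare_training_conditions"]

logger = logging.getLogger(__name__)


def predict_heldout(
    fits: pd.DataFrame,
    target_runs: Sequence[ApertureSequence] | ApertureSequence,
    hrf: HRFParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict held-out series from trained pRF parameters.

    Returns (vertex_ids, predictions) where predictions has shape
    (n_usable_vertices, T) over the target apertures.  Vertices with
    missing or non-positive sigma are skipped (count logged).
    """
    runs = _as_runs(target_runs)
    xf, yf, masks, slices = _prepare_runs(runs)
    kernel = double_gamma(hrf)
    usable = fits.dropna(subset=["x0", "y0", "sigma", "beta"])
    usable = usable[usable["sigma"] > 0]
    skipped = len(fits) - len(usable)
    if skipped:
        logger.info("predict_heldout: skipped %d vertices without usable fits", skipped)
    x0 = usable["x0"].to_numpy()[:, None]
    y0 = usable["y0"].to_numpy()[:, None]
    sig = usable["sigma"].to_numpy()[:, None]
    beta = usable["beta"].to_numpy()[:, None]
    w = np.exp(-((xf[None, :] - x0) ** 2 + (yf[None, :] - y0) ** 2) / (2 * sig**2))
    neural = w @ masks.T
    preds = np.empty_like(neural)
    for sl in slices:
        seg = neural[:, sl]
        n = seg.shape[1]
        from scipy.signal import fftconvolve

        preds[:, sl] = fftconvolve(seg, kernel[None, :], axes=1)[:, :n]
    return usable["vertex_id"].to_numpy(), beta * preds


def fisher_z_scores(
    predictions: np.ndarray,
    observed: np.ndarray,
    roi_labels: np.ndarray | Sequence[str],
) -> pd.DataFrame:
    """Per-vertex Fisher z of the prediction/observation correlation,
    with ROI means.

    ``|r| = 1`` is clipped just inside the open interval before atanh and
    flagged in the ``clipped`` column.
    """
    predictions = np.atleast_2d(predictions)
    observed = np.atleast_2d(observed)
    if predictions.shape != observed.shape:
        raise ValueError("prediction/observation shape mismatch")
    p = predictions - predictions.mean(axis=1, keepdims=True)
    o = observed - observed.mean(axis=1, keepdims=True)
    denom = np.sqrt((p**2).sum(axis=1) * (o**2).sum(axis=1))
    r = np.where(denom > 0, (p * o).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
    clipped = np.abs(r) >= 1.0
    r = np.clip(r, -(1 - 1e-7), 1 - 1e-7)
    z = np.arctanh(r)
    return pd.DataFrame(dict(roi=np.asarray(roi_labels), r=r, z=z, clipped=clipped))


def roi_mean_z(vertex_table: pd.DataFrame) -> pd.Series:
    return vertex_table.groupby("roi")["z"].mean()


def compare_training_conditions(z_table: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test of ROI-mean z between two training conditions.

    ``z_table`` is long-form with columns (roi, condition, pair, z) where
    ``pair`` identifies the pairing unit (subject x hemisphere).  Returns
    one row per ROI with the mean z per condition, their difference
    (first minus second condition in sorted order), t, df and p.
    """
    required = {"roi", "condition", "pair", "z"}
    if not required.issubset(z_table.columns):
        raise ValueError(f"z_table must have columns {sorted(required)}")
    conditions = sorted(z_table["condition"].unique())
    if len(conditions) != 2:
        raise ValueError("exactly two training conditions required")
    rows = []
    for roi, sub in z_table.groupby("roi"):
        wide = sub.pivot_table(index="pair", columns="condition", values="z")
        wide = wide.dropna()
        if len(wide) < 2:
            raise ValueError(f"ROI {roi}: need at least 2 complete pairs")
        a, b = wide[conditions[0]], wide[conditions[1]]
        t, p = stats.ttest_rel(a, b)
        rows.append(
            dict(
                roi=roi,
                condition_a=conditions[0],
                condition_b=conditions[1],
                mean_z_a=a.mean(),
                mean_z_b=b.mean(),
                z_difference=a.mean() - b.mean(),
                t=float(t),
                df=len(wide) - 1,
                p=float(p),
            )
        )
    return pd.DataFrame(rows)
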