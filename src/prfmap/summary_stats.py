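"""Downstream comparisons over fitted pRF tables.

Thresholding of fits, the mean-luminance truncation control, pRF size
versus eccentricity curves and slopes, and the comparison of model-based
against phase-encoded eccentricity estimates on a normalized scale.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataMatrix
from .stimulus import ApertureSequence

__all__ = [
    "threshold_fits",
    "truncate_blanks",
    "bin_sigma_by_eccentricity",
    "sigma_ecc_slope",
    "compare_slopes",
    "compare_ecc_estimates",
    "goodness_of_fit_anova",
]


def threshold_fits(fits: pd.DataFrame, r2_min: float = 0.1, column: str = "r2_fine") -> pd.DataFrame:
    """Vertices with goodness of fit strictly greater than ``r2_min``."""
    out = fits[fits[column] > r2_min].copy()
    out.attrs["n_surviving"] = len(out)
    return out


def _blank_segments(is_blank: np.ndarray) -> list:
    """Contiguous runs of blank volumes as (start, stop) index pairs."""
    segs, start = [], None
    for i, b in enumerate(is_blank):
        if b and start is None:
            start = i
        elif not b and start is not None:
            segs.append((start, i))
            start = None
    if start is not None:
        segs.append((start, len(is_blank)))
    return segs


def truncate_blanks(
    apertures: ApertureSequence, data: DataMatrix, keep: int = 24
) -> Tuple[ApertureSequence, DataMatrix]:
    """Drop blank volumes beyond ``keep``, keeping the final blank segment.

    Earlier blank segments are removed first (the first trial's blank
    goes, the terminal one stays), trimming apertures and data in step so
    they remain aligned.
    """
    if apertures.n_volumes != data.n_volumes:
        raise ValueError("apertures and data have different lengths")
    n_blank = int(apertures.is_blank.sum())
    if n_blank < keep:
        raise ValueError(f"run has only {n_blank} blank volumes, fewer than keep={keep}")
    drop = np.zeros(apertures.n_volumes, dtype=bool)
    to_drop = n_blank - keep
    for start, stop in _blank_segments(apertures.is_blank):
        if to_drop <= 0:
            break
        take = min(stop - start, to_drop)
        drop[start : start + take] = True
        to_drop -= take
    keep_mask = ~drop
    new_ap = ApertureSequence(
        masks=apertures.masks[keep_mask],
        tr_s=apertures.tr_s,
        condition=apertures.condition,
        direction=apertures.direction,
        is_blank=apertures.is_blank[keep_mask],
        cfg=apertures.cfg,
    )
    new_data = DataMatrix(
        series=data.series[:, keep_mask], tr_s=data.tr_s, sheet=data.sheet,
        vertex_ids=data.vertex_ids,
    )
    return new_ap, new_data


def bin_sigma_by_eccentricity(
    fits: pd.DataFrame, bin_deg: float = 1.0, max_ecc: float | None = None
) -> pd.DataFrame:
    """Mean sigma (and SEM) in half-open 1-degree eccentricity bins.

    Expects a thresholded fit table with ``x0``, ``y0``, ``sigma`` and
    optionally ``roi`` and ``subject`` columns.  The SEM is computed
    across participants when a ``subject`` column is present, otherwise
    across vertices.  Empty bins are absent from the output rather than
    reported as zero.
    """
    df = fits.copy()
    df["ecc"] = np.hypot(df["x0"], df["y0"])
    if max_ecc is not None:
        df = df[df["ecc"] <= max_ecc]
    df["bin"] = np.floor(df["ecc"] / bin_deg).astype(int)
    group_cols = [c for c in ("roi",) if c in df.columns] + ["bin"]
    rows = []
    for key, sub in df.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        if "subject" in sub.columns and sub["subject"].nunique() > 1:
            per_subj = sub.groupby("subject")["sigma"].mean()
            mean, sem = per_subj.mean(), per_subj.sem()
            n = per_subj.size
        else:
            mean, sem = sub["sigma"].mean(), sub["sigma"].sem()
            n = len(sub)
        rec = dict(zip(group_cols, key))
        b = rec.pop("bin")
        rec.update(
            bin_lo=b * bin_deg, bin_hi=(b + 1) * bin_deg,
            mean_sigma=mean, sem_sigma=sem, n=n,
        )
        if "roi" in group_cols:
            rec["roi"] = key[0]
        rows.append(rec)
    return pd.DataFrame(rows).sort_values(["bin_lo"]).reset_index(drop=True)


def sigma_ecc_slope(fits: pd.DataFrame) -> float:
    """OLS slope of sigma against eccentricity for one fit table."""
    ecc = np.hypot(fits["x0"], fits["y0"])
    if len(fits) < 3:
        raise ValueError("need at least 3 vertices")
    if np.ptp(ecc) == 0:
        raise ValueError("degenerate eccentricity variance")
    slope, _ = np.polyfit(ecc, fits["sigma"], 1)
    return float(slope)


def compare_slopes(slope_table: pd.DataFrame) -> pd.DataFrame:
    """Paired comparison of sigma-vs-eccentricity slopes between conditions.

    ``slope_table`` is long-form with columns (subject, roi, condition,
    slope), two conditions.  Returns per-ROI mean slope difference
    (first minus second in sorted condition order), SEM, t, df, p.
    """
    conditions = sorted(slope_table["condition"].unique())
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    rows = []
    for roi, sub in slope_table.groupby("roi"):
        wide = sub.pivot_table(index="subject", columns="condition", values="slope").dropna()
        if len(wide) < 2:
            raise ValueError(f"ROI {roi}: need at least 2 subjects")
        diff = wide[conditions[0]] - wide[conditions[1]]
        t, p = stats.ttest_rel(wide[conditions[0]], wide[conditions[1]])
        rows.append(
            dict(
                roi=roi,
                mean_slope_difference=diff.mean(),
                sem_slope_difference=diff.sem(),
                t=float(t),
                df=len(wide) - 1,
                p=float(p),
            )
        )
    return pd.DataFrame(rows)


def compare_ecc_estimates(
    prf_fits: pd.DataFrame,
    phase_map: pd.DataFrame,
    max_ecc: float,
    r2_min: float = 0.05,
) -> Tuple[pd.DataFrame, np.ndarray, float]:
    """Model-based vs phase-encoded eccentricity on a normalized scale.

    Merges the two estimates on ``vertex_id`` (pRF rows thresholded at
    ``r2_fine > r2_min``), normalizes both by the maximum stimulated
    eccentricity, fits a degree-2 polynomial of the phase estimate as a
    function of the pRF estimate, and reports the signed mean discrepancy
    (phase minus pRF, normalized units).
    """
    fits = prf_fits[prf_fits["r2_fine"] > r2_min].copy()
    fits["prf_ecc"] = np.hypot(fits["x0"], fits["y0"])
    merged = fits.merge(
        phase_map[["vertex_id", "eccentricity_deg"]], on="vertex_id", how="inner"
    )
    if len(merged) < 10:
        raise ValueError("fewer than 10 shared vertices")
    merged["prf_ecc_norm"] = merged["prf_ecc"] / max_ecc
    merged["phase_ecc_norm"] = merged["eccentricity_deg"] / max_ecc
    poly = np.polyfit(merged["prf_ecc_norm"], merged["phase_ecc_norm"], 2)
    discrepancy = float((merged["phase_ecc_norm"] - merged["prf_ecc_norm"]).mean())
    return merged, poly, discrepancy


def goodness_of_fit_anova(r2_table: pd.DataFrame) -> pd.DataFrame:
    """Repeated-measures ANOVA of per-subject mean goodness of fit.

    ``r2_table`` is long-form with columns (subject, condition, r2);
    standard reporting machinery via statsmodels' AnovaRM.
    """
    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(data=r2_table, depvar="r2", subject="subject", within=["condition"]).fit()
    return res.anova_table
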