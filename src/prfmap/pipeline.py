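"""Stage orchestration: stimuli -> simulate -> fit-hrf -> fit-prf ->
phase-encode -> crossval -> report, with versioned outputs and JSON
manifests so every number in a report traces back to a configuration."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np

from . import io
from .forward_model import HRFParams
from .hrf_estimation import estimate_hrf
from .phase_encoded import analyze_wedge_ring
from .prf_fitting import fit_prf
from .stimulus import photic_sequence, session_schedule
from .synthetic import NoiseSpec, make_sheet, simulate_bold

logger = logging.getLogger(__name__)

STAGES = ("stimuli", "simulate", "fit-hrf", "fit-prf", "phase-encode", "report")


class MissingDependencyError(RuntimeError):
    """A stage's required input is absent; names the stage to run first."""


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingDependencyError(
            f"missing input {path.name}; run the '{producer}' stage first"
        )
    return path


def run_pipeline(config: dict, stages: Iterable[str], out_dir: str | Path) -> dict:
    """Execute the requested pipeline stages on the demo synthetic sheet.

    Returns a manifest dict keyed by stage.  Deterministic given the
    config seed: identical seeds reproduce byte-identical simulated
    series.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest: dict = {}
    cfg = io.carrier_config_from(config)
    design = io.design_from(config)
    seed = int(config.get("seed", 0))
    fitting = config.get("fitting", {})
    noise_cfg = config.get("noise", {})

    ap_path = out / "apertures.h5"
    photic_path = out / "photic.h5"
    data_path = out / "series.h5"
    photic_data_path = out / "photic_series.h5"
    hrf_path = out / "hrf.yaml"
    fits_path = out / "fits.tsv"
    phase_path = out / "phase.tsv"

    if "stimuli" in stages:
        runs = session_schedule(cfg, design)
        io.save_apertures(ap_path, runs)
        io.save_apertures(photic_path, photic_sequence(cfg))
        manifest["stimuli"] = io.write_manifest(
            out / "manifest_stimuli.json", "stimuli",
            dict(max_ecc=cfg.max_eccentricity_deg, seed=seed),
            [ap_path, photic_path],
        )

    if "simulate" in stages:
        _require(ap_path, "stimuli")
        runs = io.load_apertures(ap_path)
        sheet = make_sheet(
            n_vertices=int(config.get("n_vertices", 48)),
            max_ecc=cfg.max_eccentricity_deg,
            seed=seed,
        )
        hrf_true = HRFParams(dt=runs[0].tr_s)
        noise = NoiseSpec(
            cnr=float(noise_cfg.get("cnr", 3.0)),
            ar1_rho=float(noise_cfg.get("ar1_rho", 0.2)),
            seed=seed,
        )
        data = simulate_bold(sheet, runs, hrf_true, noise)
        io.save_data_matrix(data_path, data)
        photic = io.load_apertures(photic_path)[0]
        pdata = simulate_bold(sheet, photic, hrf_true, noise)
        io.save_data_matrix(photic_data_path, pdata)
        io.save_table(out / "ground_truth.tsv", sheet.truth.assign(roi=sheet.roi_label))
        manifest["simulate"] = io.write_manifest(
            out / "manifest_simulate.json", "simulate",
            dict(seed=seed, cnr=noise.cnr, ar1_rho=noise.ar1_rho),
            [data_path, photic_data_path, out / "ground_truth.tsv"],
        )

    if "fit-hrf" in stages:
        _require(photic_data_path, "simulate")
        pdata = io.load_data_matrix(photic_data_path)
        onsets = np.arange(10) * 12
        fit = estimate_hrf(pdata.series, onsets, pdata.tr_s)
        io.save_hrf(hrf_path, fit.params)
        manifest["fit-hrf"] = io.write_manifest(
            out / "manifest_fit_hrf.json", "fit-hrf",
            dict(converged=fit.converged, amplitude=fit.amplitude),
            [hrf_path],
        )

    if "fit-prf" in stages:
        _require(data_path, "simulate")
        _require(hrf_path, "fit-hrf")
        data = io.load_data_matrix(data_path)
        runs = io.load_apertures(ap_path)
        hrf = io.load_hrf(hrf_path)
        fits = fit_prf(
            data, runs, hrf,
            fwhm_mm=float(fitting.get("fwhm_mm", 8.3)),
            coarse_r2=float(fitting.get("coarse_r2", 0.05)),
            n_sigma=int(fitting.get("n_sigma", 34)),
        )
        io.save_table(fits_path, fits)
        manifest["fit-prf"] = io.write_manifest(
            out / "manifest_fit_prf.json", "fit-prf",
            dict(fwhm_mm=fitting.get("fwhm_mm", 8.3)),
            [fits_path],
        )

    if "phase-encode" in stages:
        _require(data_path, "simulate")
        data = io.load_data_matrix(data_path)
        runs = io.load_apertures(ap_path)
        idx = [i for i, r in enumerate(runs) if r.condition == "wedge_ring"]
        if len(idx) < 2:
            raise MissingDependencyError("need two wedge-ring runs; run 'stimuli' with the full schedule")
        starts = np.cumsum([0] + [r.n_volumes for r in runs])
        segs = [data.series[:, starts[i] : starts[i] + runs[i].n_volumes] for i in idx[:2]]
        if runs[idx[0]].direction == "cw_expand":
            fwd, rev = segs
        else:
            rev, fwd = segs
        phase = analyze_wedge_ring(fwd, rev, design, cfg.max_eccentricity_deg)
        io.save_table(phase_path, phase)
        manifest["phase-encode"] = io.write_manifest(
            out / "manifest_phase.json", "phase-encode", {}, [phase_path]
        )

    if "report" in stages:
        _require(fits_path, "fit-prf")
        from .summary_stats import bin_sigma_by_eccentricity, threshold_fits

        fits = io.load_table(fits_path)
        surv = threshold_fits(fits, float(fitting.get("analysis_r2", 0.1)))
        curve = bin_sigma_by_eccentricity(surv, max_ecc=cfg.max_eccentricity_deg)
        io.save_table(out / "sigma_by_ecc.tsv", curve)
        manifest["report"] = io.write_manifest(
            out / "manifest_report.json", "report",
            dict(n_surviving=len(surv)),
            [out / "sigma_by_ecc.tsv"],
        )

    return manifest
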