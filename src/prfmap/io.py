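"""File formats: HDF5 containers for masks and time series, TSV tables,
YAML configuration, and JSON run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import sparse

from .containers import CorticalSheet, DataMatrix
from .forward_model import HRFParams
from .stimulus import ApertureSequence, CarrierConfig, StimulusDesign

__all__ = [
    "save_apertures",
    "load_apertures",
    "save_data_matrix",
    "load_data_matrix",
    "save_table",
    "load_table",
    "save_hrf",
    "load_hrf",
    "load_config",
    "write_manifest",
    "load_nifti_series",
]


def _cfg_attrs(cfg: CarrierConfig) -> dict:
    return dict(
        max_eccentricity_deg=cfg.max_eccentricity_deg,
        pixels_per_degree=cfg.pixels_per_degree,
        phase_step_ms=cfg.phase_step_ms,
        n_phase_steps=cfg.n_phase_steps,
        rotation_deg=cfg.rotation_deg,
        edge_band_px=cfg.edge_band_px,
    )


def save_apertures(path: str | Path, runs: Sequence[ApertureSequence] | ApertureSequence) -> None:
    """Write aperture sequences to HDF5 (masks as packed bits)."""
    if isinstance(runs, ApertureSequence):
        runs = [runs]
    with h5py.File(path, "w") as f:
        for i, run in enumerate(runs):
            g = f.create_group(f"run{i:02d}")
            packed = np.packbits(run.masks.astype(np.uint8), axis=None)
            g.create_dataset("masks_packed", data=packed, compression="gzip")
            g.attrs["shape"] = run.masks.shape
            g.create_dataset("is_blank", data=run.is_blank.astype(np.uint8))
            g.attrs["tr_s"] = run.tr_s
            g.attrs["condition"] = run.condition
            g.attrs["direction"] = run.direction
            for k, v in _cfg_attrs(run.cfg).items():
                g.attrs[f"cfg_{k}"] = v


def load_apertures(path: str | Path) -> List[ApertureSequence]:
    runs = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            shape = tuple(g.attrs["shape"])
            n = int(np.prod(shape))
            masks = np.unpackbits(g["masks_packed"][...], count=n).reshape(shape).astype(bool)
            cfg = CarrierConfig(
                max_eccentricity_deg=float(g.attrs["cfg_max_eccentricity_deg"]),
                pixels_per_degree=float(g.attrs["cfg_pixels_per_degree"]),
                phase_step_ms=float(g.attrs["cfg_phase_step_ms"]),
                n_phase_steps=int(g.attrs["cfg_n_phase_steps"]),
                rotation_deg=float(g.attrs["cfg_rotation_deg"]),
                edge_band_px=int(g.attrs["cfg_edge_band_px"]),
            )
            runs.append(
                ApertureSequence(
                    masks=masks,
                    tr_s=float(g.attrs["tr_s"]),
                    condition=str(g.attrs["condition"]),
                    direction=str(g.attrs["direction"]),
                    is_blank=g["is_blank"][...].astype(bool),
                    cfg=cfg,
                )
            )
    return runs


def save_data_matrix(path: str | Path, data: DataMatrix) -> None:
    """Write a vertices-by-time container (plus sheet geometry) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("series", data=data.series, compression="gzip")
        f.attrs["tr_s"] = data.tr_s
        f.create_dataset("vertex_ids", data=data.vertex_ids)
        if data.sheet is not None:
            g = f.create_group("sheet")
            g.create_dataset("vertex_coords", data=data.sheet.vertex_coords)
            coo = data.sheet.neighbor_graph.tocoo()
            g.create_dataset("graph_row", data=coo.row)
            g.create_dataset("graph_col", data=coo.col)
            g.create_dataset("graph_len", data=coo.data)
            g.create_dataset(
                "roi_label", data=np.asarray(data.sheet.roi_label, dtype="S16")
            )
            if data.sheet.truth is not None:
                tg = g.create_group("truth")
                for col in data.sheet.truth.columns:
                    tg.create_dataset(col, data=data.sheet.truth[col].to_numpy())


def load_data_matrix(path: str | Path) -> DataMatrix:
    with h5py.File(path, "r") as f:
        series = f["series"][...]
        tr = float(f.attrs["tr_s"])
        vertex_ids = f["vertex_ids"][...]
        sheet = None
        if "sheet" in f:
            g = f["sheet"]
            coords = g["vertex_coords"][...]
            n = coords.shape[0]
            graph = sparse.coo_matrix(
                (g["graph_len"][...], (g["graph_row"][...], g["graph_col"][...])),
                shape=(n, n),
            ).tocsr()
            truth = None
            if "truth" in g:
                truth = pd.DataFrame({k: g["truth"][k][...] for k in g["truth"]})
            sheet = CorticalSheet(
                vertex_coords=coords,
                neighbor_graph=graph,
                roi_label=g["roi_label"][...].astype(str),
                truth=truth,
            )
    return DataMatrix(series=series, tr_s=tr, sheet=sheet, vertex_ids=vertex_ids)


def save_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_hrf(path: str | Path, hrf: HRFParams) -> None:
    Path(path).write_text(
        yaml.safe_dump({k: float(v) for k, v in asdict(hrf).items()})
    )


def load_hrf(path: str | Path) -> HRFParams:
    return HRFParams(**yaml.safe_load(Path(path).read_text()))


def load_config(path: str | Path) -> dict:
    """Load a pipeline YAML config into nested dicts with defaults applied."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = dict(display={}, design={}, fitting={}, noise={}, paths={}, seed=0)
    cfg.update(raw)
    return cfg


def carrier_config_from(cfg: dict) -> CarrierConfig:
    return CarrierConfig(**cfg.get("display", {}))


def design_from(cfg: dict) -> StimulusDesign:
    return StimulusDesign(**cfg.get("design", {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, stage: str, params: dict, outputs: Sequence[str | Path]) -> dict:
    """JSON manifest recording a stage's parameters and output checksums."""
    manifest = dict(
        stage=stage,
        parameters=params,
        outputs={str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
    )
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def load_nifti_series(nifti_path: str | Path, sampling: pd.DataFrame, tr_s: float) -> DataMatrix:
    """Sample a 4D NIfTI volume at voxel coordinates into a DataMatrix.

    ``sampling`` must have integer columns i, j, k (one row per vertex).
    Surface projection itself is out of scope; this reader covers the
    case where a vertex-to-voxel lookup already exists.
    """
    import nibabel as nib

    img = nib.load(str(nifti_path))
    vol = np.asarray(img.dataobj)
    ijk = sampling[["i", "j", "k"]].to_numpy(dtype=int)
    series = vol[ijk[:, 0], ijk[:, 1], ijk[:, 2], :]
    return DataMatrix(series=series.astype(float), tr_s=tr_s)
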