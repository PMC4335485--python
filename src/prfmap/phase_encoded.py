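"""Traveling-wave (phase-encoded) analysis of wedge-and-ring runs.

Each vertex's series is reduced to the discrete Fourier coefficient at
the two fundamental frequencies: 6 cycles/run for the rotating wedge
(polar angle) and 8 cycles/run for the expanding/contracting ring
(eccentricity).  Hemodynamic lag is cancelled by combining runs cycling
in opposite directions (reversed-run phases are negated before circular
averaging), after which phase decodes to visual-field position.

Phase convention: the stored phase is the argument of the DFT
coefficient ``sum_t y_t exp(-2 pi i f t / T)`` wrapped to [0, 2 pi); a
response peaking later in the cycle yields a larger ``(-phase) mod 2 pi``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend as _detrend

from .stimulus import StimulusDesign, effective_log_min

__all__ = [
    "PhaseMap",
    "to_percent_change",
    "fundamental_phase",
    "combine_directions",
    "decode_coordinates",
    "analyze_wedge_ring",
]

POLAR_CYCLES = 6
ECC_CYCLES = 8


@dataclass
class PhaseMap:
    """Per-vertex phase and power at the two fundamental frequencies."""

    phase_polar: np.ndarray
    phase_ecc: np.ndarray
    power_polar: np.ndarray
    power_ecc: np.ndarray
    direction: str = "cw_expand"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                vertex_id=np.arange(len(self.phase_polar)),
                phase_polar=self.phase_polar,
                phase_ecc=self.phase_ecc,
                power_polar=self.power_polar,
                power_ecc=self.power_ecc,
            )
        )


def to_percent_change(series: np.ndarray) -> np.ndarray:
    """De-trend and express as percent change of the series mean.

    The linear trend and mean are removed and the residual is scaled by
    100 / mean; the output has zero mean.  Raises for near-zero-mean
    input, where percent change is undefined (series already expressed in
    percent units should skip this step).
    """
    arr = np.asarray(series, dtype=float)
    one_d = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] <= 2:
        raise ValueError("series too short")
    mean = arr.mean(axis=1)
    if np.any(np.abs(mean) < 1e-9 * np.maximum(1.0, arr.std(axis=1))):
        raise ValueError("series mean is ~0; percent change undefined")
    out = _detrend(arr, axis=1, type="linear") / mean[:, None] * 100.0
    return out[0] if one_d else out


def fundamental_phase(series: np.ndarray, n_cycles: int) -> tuple:
    """(phase, power) of the DFT coefficient at exactly ``n_cycles``/run.

    Phase is wrapped to [0, 2 pi); power is the squared coefficient
    magnitude.  Blank tail volumes must be removed beforehand so that the
    stimulus completes an integer number of cycles over the series.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    t = series.shape[1]
    if int(n_cycles) != n_cycles or not 0 < n_cycles < t / 2:
        raise ValueError("n_cycles must be a positive integer below Nyquist")
    basis = np.exp(-2j * np.pi * n_cycles * np.arange(t) / t)
    coeff = series @ basis
    phase = np.angle(coeff) % (2 * np.pi)
    power = np.abs(coeff) ** 2
    if phase.size == 1:
        return float(phase[0]), float(power[0])
    return phase, power


def circular_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * np.asarray(a)) + np.exp(1j * np.asarray(b))) % (2 * np.pi)


def combine_directions(map_fwd: PhaseMap, map_rev: PhaseMap) -> PhaseMap:
    """Cancel hemodynamic lag by combining opposite-direction runs.

    In the reversed run the stimulus visits each position at the
    time-reversed moment, so its phase is the negative of the forward
    stimulus phase plus the same lag; negating reversed phases and
    circularly averaging leaves the lag-free stimulus phase.
    """
    if len(map_fwd.phase_polar) != len(map_rev.phase_polar):
        raise ValueError("phase maps cover different vertices")
    return PhaseMap(
        phase_polar=circular_mean(map_fwd.phase_polar, -map_rev.phase_polar),
        phase_ecc=circular_mean(map_fwd.phase_ecc, -map_rev.phase_ecc),
        power_polar=(map_fwd.power_polar + map_rev.power_polar) / 2.0,
        power_ecc=(map_fwd.power_ecc + map_rev.power_ecc) / 2.0,
        direction=map_fwd.direction,
    )


def decode_coordinates(
    pmap: PhaseMap, design: StimulusDesign, max_ecc: float
) -> pd.DataFrame:
    """Decode combined phases into polar angle and eccentricity.

    The wedge advances clockwise (decreasing polar angle) from the
    positive x-axis in the reference direction, so the polar angle maps
    linearly onto the cycle fraction; the ring expands along the
    log-spaced schedule, so eccentricity decodes through
    ``e = e_min * (e_max / e_min) ** u`` with u the cycle fraction.
    """
    u_pol = (-np.asarray(pmap.phase_polar)) % (2 * np.pi) / (2 * np.pi)
    u_ecc = (-np.asarray(pmap.phase_ecc)) % (2 * np.pi) / (2 * np.pi)
    polar = (-360.0 * u_pol) % 360.0  # clockwise rotation in the reference run
    e_min = effective_log_min(design, max_ecc)
    ecc = e_min * (max_ecc / e_min) ** u_ecc
    out = pmap.as_frame()
    out["polar_angle_deg"] = polar
    out["eccentricity_deg"] = ecc
    return out


def analyze_wedge_ring(
    series_fwd: np.ndarray,
    series_rev: np.ndarray,
    design: StimulusDesign,
    max_ecc: float,
    n_blank: int | None = None,
) -> pd.DataFrame:
    """Full phase-encoded pipeline on a pair of opposite-direction runs.

    Terminal blank volumes are removed, each run is linearly de-trended,
    phases at the two fundamentals are extracted per run, combined across
    directions, and decoded to visual-field coordinates.
    """
    n_blank = design.volumes_per_blank if n_blank is None else n_blank
    maps = []
    for series, direction in ((series_fwd, "cw_expand"), (series_rev, "ccw_contract")):
        series = np.atleast_2d(np.asarray(series, dtype=float))
        if n_blank:
            series = series[:, :-n_blank]
        series = _detrend(series, axis=1, type="linear")
        ph_p, pw_p = fundamental_phase(series, POLAR_CYCLES)
        ph_e, pw_e = fundamental_phase(series, ECC_CYCLES)
        maps.append(
            PhaseMap(
                phase_polar=np.atleast_1d(ph_p),
                phase_ecc=np.atleast_1d(ph_e),
                power_polar=np.atleast_1d(pw_p),
                power_ecc=np.atleast_1d(pw_e),
                direction=direction,
            )
        )
    combined = combine_directions(maps[0], maps[1])
    return decode_coordinates(combined, design, max_ecc)
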