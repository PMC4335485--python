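"""Visual stimulus generation for retinotopic mapping.

Three traveling-wave aperture configurations are produced on a common
visual-field pixel grid: size-invariant bars, eccentricity-scaled
("logarithmic") bars, and a simultaneous wedge-and-ring stimulus, plus a
full-field photic-burst run used for hemodynamic response estimation.

The carrier is a dynamic high-contrast ripple pattern; the encoding model
only ever sees the binary aperture masks, so the carrier exists for
inspection/rendering while :class:`ApertureSequence` is the modeling
currency.

Coordinate convention: x rightward, y upward, degrees of visual angle,
origin at fixation.  Polar angle is measured counterclockwise from the
positive x-axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = [
    "CarrierConfig",
    "StimulusDesign",
    "ApertureSequence",
    "PhaseSchedule",
    "carrier_frame",
    "phase_schedule",
    "bar_sequence",
    "wedge_ring_sequence",
    "photic_sequence",
    "session_schedule",
    "fixation_events",
]

TR_S = 2.55  # seconds per acquired volume; apertures advance once per TR

BAR_DIRECTIONS = (0, 45, 90, 135)
WEDGE_RING_DIRECTIONS = ("cw_expand", "ccw_contract")


@dataclass(frozen=True)
class CarrierConfig:
    """Geometry and timing of the carrier pattern and the rendering grid.

    Parameters
    ----------
    max_eccentricity_deg:
        Radius of the stimulated disc (9 or 16 degrees in the two display
        setups).
    pixels_per_degree:
        Resolution of the square rendering grid.
    phase_step_ms:
        Duration of one carrier phase step.
    n_phase_steps:
        Number of equal steps taking the carrier phase from 0 to 4*pi
        (even, so one 2*pi cycle is an integer number of steps).
    rotation_deg:
        Overall pattern orientation for the current trial condition
        (0 for cardinal bars, 45 for oblique bars, wedge angle for the
        wedge-and-ring condition).
    edge_band_px:
        Width in pixels of the blurred fringe at the edge of the disc,
        within which contrast ramps linearly to zero.
    """

    max_eccentricity_deg: float = 16.0
    pixels_per_degree: float = 4.0
    phase_step_ms: float = 32.0
    n_phase_steps: int = 72
    rotation_deg: float = 0.0
    edge_band_px: int = 12

    def __post_init__(self) -> None:
        if self.max_eccentricity_deg <= 0:
            raise ValueError("max_eccentricity_deg must be positive")
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")
        if self.n_phase_steps <= 0 or self.n_phase_steps % 2:
            raise ValueError("n_phase_steps must be positive and even")

    @property
    def grid_size(self) -> int:
        return int(round(2 * self.max_eccentricity_deg * self.pixels_per_degree))

    def grid(self) -> Tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate arrays (X, Y) in degrees.

        Row 0 is the top of the image (largest y), matching image
        conventions while keeping y pointing upward in visual space.
        """
        n = self.grid_size
        step = 1.0 / self.pixels_per_degree
        r = self.max_eccentricity_deg
        xs = -r + (np.arange(n) + 0.5) * step
        ys = r - (np.arange(n) + 0.5) * step
        return np.meshgrid(xs, ys)


@dataclass(frozen=True)
class StimulusDesign:
    """Timing and geometry shared by the aperture sequences.

    Widths and eccentricities are given for the 16-degree display; the
    9-degree display scales all geometry by 9/16 while volume counts are
    unchanged.
    """

    bar_width_deg: float = 2.70
    log_min_ecc_deg: float = 0.06
    wedge_width_deg: float = 18.0
    wedge_cycles_per_run: int = 6
    ring_cycles_per_run: int = 8
    volumes_per_sweep: int = 24
    volumes_per_blank: int = 24
    ring_overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "bar_width_deg",
            "log_min_ecc_deg",
            "wedge_width_deg",
            "wedge_cycles_per_run",
            "ring_cycles_per_run",
            "volumes_per_sweep",
            "volumes_per_blank",
            "ring_overlap_frac",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.wedge_ring_stimulation_volumes % self.wedge_cycles_per_run:
            raise ValueError("wedge cycles must divide the stimulation segment")
        if self.wedge_ring_stimulation_volumes % self.ring_cycles_per_run:
            raise ValueError("ring cycles must divide the stimulation segment")

    @property
    def bar_run_volumes(self) -> int:
        """Two trials of (sweep + orthogonal sweep + blank): 144 volumes."""
        return 2 * (2 * self.volumes_per_sweep + self.volumes_per_blank)

    @property
    def wedge_ring_stimulation_volumes(self) -> int:
        # the composite run matches the bar-run length but carries a single
        # terminal blank block: 144 - 24 = 120 stimulation volumes
        return self.bar_run_volumes - self.volumes_per_blank

    @property
    def wedge_volumes_per_revolution(self) -> int:
        return self.wedge_ring_stimulation_volumes // self.wedge_cycles_per_run

    @property
    def ring_volumes_per_cycle(self) -> int:
        return self.wedge_ring_stimulation_volumes // self.ring_cycles_per_run


@dataclass(eq=False)
class ApertureSequence:
    """Per-volume binary visual-field masks plus timing.

    ``masks`` has shape (T, H, W) over the rendering grid of ``cfg``;
    ``is_blank`` marks mean-luminance volumes (their masks are all zero).
    """

    masks: np.ndarray
    tr_s: float
    condition: str
    direction: str
    is_blank: np.ndarray
    cfg: CarrierConfig

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.is_blank = np.asarray(self.is_blank, dtype=bool)
        if self.masks.shape[0] != self.is_blank.shape[0]:
            raise ValueError("masks and is_blank length mismatch")

    @property
    def n_volumes(self) -> int:
        return self.masks.shape[0]

    def grid(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.cfg.grid()

    def flat_masks(self, dtype=np.float64) -> np.ndarray:
        """Masks reshaped to (T, n_pixels) as floats, for linear algebra."""
        t = self.masks.shape[0]
        return self.masks.reshape(t, -1).astype(dtype)

    def concat(self, other: "ApertureSequence") -> "ApertureSequence":
        if self.cfg.grid_size != other.cfg.grid_size:
            raise ValueError("grid mismatch")
        return ApertureSequence(
            masks=np.concatenate([self.masks, other.masks]),
            tr_s=self.tr_s,
            condition=f"{self.condition}+{other.condition}",
            direction=f"{self.direction}+{other.direction}",
            is_blank=np.concatenate([self.is_blank, other.is_blank]),
            cfg=self.cfg,
        )


@dataclass(frozen=True)
class PhaseSchedule:
    theta: np.ndarray
    delta: np.ndarray
    cycle_s: float


def phase_schedule(cfg: CarrierConfig) -> PhaseSchedule:
    """Carrier phase/spatial-frequency schedule over one presentation.

    theta advances uniformly over [0, 4*pi) in ``n_phase_steps`` steps;
    delta = sin(theta)/4 + 1/2 modulates the pattern's spatial frequency.
    One 2*pi phase cycle lasts (n_phase_steps/2) * phase_step_ms.
    """
    theta = np.arange(cfg.n_phase_steps) * (4 * np.pi / cfg.n_phase_steps)
    delta = np.sin(theta) / 4.0 + 0.5
    cycle_s = (cfg.n_phase_steps / 2) * cfg.phase_step_ms / 1000.0
    return PhaseSchedule(theta=theta, delta=delta, cycle_s=cycle_s)


def carrier_frame(t_index: int, cfg: CarrierConfig) -> np.ndarray:
    """Render one carrier frame as luminance in [0, 1].

    The underlying pattern is
    ``I(x, y) = sqrt(x^2 + y^2) * cos(2*pi*(sin(d)*pi*x/180 + cos(d)*pi*y/180)**4 + theta)``
    rectified to binary black/white (the non-negative radial prefactor
    only gates the sign of the cosine), bounded by the stimulated disc
    (outside pixels at mean luminance 0.5) and blurred linearly to mean
    luminance over the ``edge_band_px`` fringe.
    """
    if not 0 <= t_index < cfg.n_phase_steps:
        raise ValueError("t_index outside the phase schedule")
    sched = phase_schedule(cfg)
    theta = sched.theta[t_index]
    delta = sched.delta[t_index]
    x, y = cfg.grid()
    if cfg.rotation_deg:
        a = np.deg2rad(cfg.rotation_deg)
        x, y = x * np.cos(a) + y * np.sin(a), -x * np.sin(a) + y * np.cos(a)
    r = np.hypot(x, y)
    arg = 2 * np.pi * (np.sin(delta) * np.pi * x / 180.0 + np.cos(delta) * np.pi * y / 180.0) ** 4 + theta
    intensity = r * np.cos(arg)
    frame = np.where(intensity > 0, 1.0, 0.0)

    r_true = np.hypot(*cfg.grid())  # fringe follows display geometry, not rotation
    rmax = cfg.max_eccentricity_deg
    band_deg = cfg.edge_band_px / cfg.pixels_per_degree
    contrast = np.clip((rmax - r_true) / band_deg, 0.0, 1.0)
    frame = 0.5 + (frame - 0.5) * contrast
    frame[r_true > rmax] = 0.5
    return frame


def _disc_mask(cfg: CarrierConfig) -> np.ndarray:
    x, y = cfg.grid()
    return np.hypot(x, y) <= cfg.max_eccentricity_deg


def _blank_block(cfg: CarrierConfig, n: int) -> np.ndarray:
    g = cfg.grid_size
    return np.zeros((n, g, g), dtype=bool)


def effective_log_min(design: StimulusDesign, max_ecc: float) -> float:
    """Foveal minimum eccentricity for the current display.

    Geometry is stated for the 16-degree display and scales uniformly for
    the smaller display, so all aperture geometry is an exact similarity
    transform between display sizes.
    """
    return design.log_min_ecc_deg * max_ecc / 16.0


def eccentricity_scaled_width(
    center_ecc: np.ndarray | float, design: StimulusDesign, max_ecc: float
) -> np.ndarray:
    """Bar width under logarithmic eccentricity scaling.

    The width grows in proportion to the local spacing of a log-uniform
    eccentricity grid running from the foveal minimum to the display edge
    in ``volumes_per_sweep`` steps, i.e. proportionally to eccentricity
    itself, floored at the foveal minimum width.
    """
    e_min = effective_log_min(design, max_ecc)
    ecc = np.abs(np.asarray(center_ecc, dtype=float))
    kappa = np.log(max_ecc / e_min) / design.volumes_per_sweep
    return np.maximum(e_min, ecc * kappa)


def _bar_sweep_masks(
    direction_deg: float,
    sweep_sign: int,
    scaled: bool,
    design: StimulusDesign,
    cfg: CarrierConfig,
) -> np.ndarray:
    """One 24-volume sweep of the bar along ``direction_deg``."""
    n = design.volumes_per_sweep
    rmax = cfg.max_eccentricity_deg
    x, y = cfg.grid()
    disc = np.hypot(x, y) <= rmax
    a = np.deg2rad(direction_deg)
    proj = x * np.cos(a) + y * np.sin(a)  # position along the motion axis
    step = 2 * rmax / n
    centers = -rmax + step * (np.arange(n) + 0.5)
    if sweep_sign < 0:
        centers = centers[::-1]
    scale = rmax / 16.0  # widths stated for the 16-degree display
    masks = np.empty((n, cfg.grid_size, cfg.grid_size), dtype=bool)
    for k, c in enumerate(centers):
        if scaled:
            width = float(eccentricity_scaled_width(c, design, rmax))
        else:
            width = design.bar_width_deg * scale
        masks[k] = (np.abs(proj - c) <= width / 2) & disc
    return masks


def bar_sequence(
    direction: float,
    sweep_sign: int,
    scaled: bool,
    design: StimulusDesign,
    cfg: CarrierConfig,
) -> ApertureSequence:
    """One bar-stimulus run (144 volumes).

    A run holds two trials; each trial is a 24-volume sweep along
    ``direction``, a 24-volume sweep along the orthogonal direction, and a
    24-volume mean-luminance blank.  The second trial reverses the sweep
    direction.  ``scaled`` selects eccentricity-scaled bar widths.
    """
    if direction not in BAR_DIRECTIONS:
        raise ValueError(f"direction must be one of {BAR_DIRECTIONS}")
    if sweep_sign not in (-1, 1):
        raise ValueError("sweep_sign must be +1 or -1")
    ortho = (direction + 90) % 180
    blocks = []
    blank_flags = []
    for sign in (sweep_sign, -sweep_sign):
        for d in (direction, ortho):
            blocks.append(_bar_sweep_masks(d, sign, scaled, design, cfg))
            blank_flags.append(np.zeros(design.volumes_per_sweep, dtype=bool))
        blocks.append(_blank_block(cfg, design.volumes_per_blank))
        blank_flags.append(np.ones(design.volumes_per_blank, dtype=bool))
    condition = "bar_log" if scaled else "bar_invariant"
    axis = "cardinal" if direction in (0, 90) else "oblique"
    return ApertureSequence(
        masks=np.concatenate(blocks),
        tr_s=TR_S,
        condition=condition,
        direction=f"{axis}_{'fwd' if sweep_sign > 0 else 'rev'}",
        is_blank=np.concatenate(blank_flags),
        cfg=cfg,
    )


def ring_radii_schedule(design: StimulusDesign, max_ecc: float) -> np.ndarray:
    """(n_steps, 2) inner/outer radii of the expanding-ring steps.

    Radii are log-spaced between the foveal minimum and the display edge.
    Each annulus spans two adjacent intervals of a log grid with
    ``ring_volumes_per_cycle + 1`` intervals, so consecutive steps share
    half of their radial (log-domain) extent.
    """
    n = design.ring_volumes_per_cycle
    span = int(round(1.0 / (1.0 - design.ring_overlap_frac)))  # grid intervals per annulus
    bounds = np.geomspace(effective_log_min(design, max_ecc), max_ecc, n + span)
    return np.stack([bounds[:n], bounds[span : n + span]], axis=1)


def wedge_ring_sequence(
    direction: str, design: StimulusDesign, cfg: CarrierConfig
) -> ApertureSequence:
    """One simultaneous wedge-and-ring run (144 volumes).

    120 stimulation volumes (wedge: 6 revolutions of 20 volumes; ring: 8
    cycles of 15 steps) followed by 24 terminal blank volumes.  Each mask
    is the union of the wedge sector and the current annulus.
    ``cw_expand`` rotates the wedge clockwise while the ring expands;
    ``ccw_contract`` reverses both components.
    """
    if direction not in WEDGE_RING_DIRECTIONS:
        raise ValueError(f"direction must be one of {WEDGE_RING_DIRECTIONS}")
    reverse = direction == "ccw_contract"
    n_stim = design.wedge_cycles_per_run * design.wedge_volumes_per_revolution
    rmax = cfg.max_eccentricity_deg
    x, y = cfg.grid()
    r = np.hypot(x, y)
    disc = r <= rmax
    angle = np.rad2deg(np.arctan2(y, x)) % 360.0

    wedge_step = 360.0 / design.wedge_volumes_per_revolution
    radii = ring_radii_schedule(design, rmax)
    n_ring = design.ring_volumes_per_cycle

    masks = np.empty((n_stim + design.volumes_per_blank, cfg.grid_size, cfg.grid_size), dtype=bool)
    for t in range(n_stim):
        wsign = -1 if not reverse else 1  # clockwise = decreasing polar angle
        bisector = (wsign * wedge_step * t) % 360.0
        dist = np.abs((angle - bisector + 180.0) % 360.0 - 180.0)
        wedge = (dist <= design.wedge_width_deg / 2) & disc
        s = t % n_ring
        if reverse:
            s = n_ring - 1 - s
        inner, outer = radii[s]
        ring = (r >= inner) & (r <= outer)
        masks[t] = wedge | ring
    masks[n_stim:] = False
    is_blank = np.zeros(masks.shape[0], dtype=bool)
    is_blank[n_stim:] = True
    return ApertureSequence(
        masks=masks,
        tr_s=TR_S,
        condition="wedge_ring",
        direction=direction,
        is_blank=is_blank,
        cfg=cfg,
    )


def photic_sequence(cfg: CarrierConfig, n_trials: int = 10, volumes_per_trial: int = 12) -> ApertureSequence:
    """Photic-burst run for HRF estimation.

    Each of the ``n_trials`` repetitions shows the full stimulated disc
    for one volume followed by ``volumes_per_trial - 1`` blank volumes
    (120 volumes in total by default).
    """
    disc = _disc_mask(cfg)
    t_total = n_trials * volumes_per_trial
    masks = np.zeros((t_total, cfg.grid_size, cfg.grid_size), dtype=bool)
    is_blank = np.ones(t_total, dtype=bool)
    for k in range(n_trials):
        masks[k * volumes_per_trial] = disc
        is_blank[k * volumes_per_trial] = False
    return ApertureSequence(
        masks=masks,
        tr_s=TR_S,
        condition="photic",
        direction="full_field",
        is_blank=is_blank,
        cfg=cfg,
    )


def session_schedule(
    cfg: CarrierConfig, design: StimulusDesign | None = None
) -> List[ApertureSequence]:
    """The ten mapping runs of one scanning session.

    Two runs each of cardinal and oblique size-invariant bars, two each of
    cardinal and oblique eccentricity-scaled bars (the second run of each
    pair reverses sweep direction), and two wedge-and-ring runs in
    opposite directions — 1440 volumes in total.
    """
    design = design or StimulusDesign()
    runs = []
    for scaled in (False, True):
        for direction in (0, 45):
            for sign in (1, -1):
                runs.append(bar_sequence(direction, sign, scaled, design, cfg))
    for direction in WEDGE_RING_DIRECTIONS:
        runs.append(wedge_ring_sequence(direction, design, cfg))
    return runs


def fixation_events(
    duration_s: float, seed: int, bin_ms: float = 200.0, p_change: float = 0.05
) -> np.ndarray:
    """Fixation-dot color-change times (s) for the attention task.

    Each ``bin_ms`` bin flips the dot color with probability ``p_change``,
    never in two consecutive bins.  Plays no role in modeling.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(duration_s * 1000.0 / bin_ms)
    events = []
    previous = False
    for k in range(n_bins):
        change = (not previous) and (rng.random() < p_change)
        if change:
            events.append(k * bin_ms / 1000.0)
        previous = change
    return np.asarray(events)
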