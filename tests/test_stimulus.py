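"""Stimulus generation: carrier rectification, aperture geometry, timing."""

import numpy as np
import pytest

from prfmap import (
    CarrierConfig,
    bar_sequence,
    carrier_frame,
    phase_schedule,
    session_schedule,
    wedge_ring_sequence,
)
from prfmap.stimulus import (
    eccentricity_scaled_width,
    fixation_events,
    ring_radii_schedule,
)


class TestCarrier:
    def test_fixation_pixel_is_black(self):
        # ppd chosen so one pixel center lands exactly on the origin,
        # where the radial prefactor is zero and rectification maps
        # non-positive intensity to minimum luminance
        cfg = CarrierConfig(max_eccentricity_deg=9, pixels_per_degree=0.5, edge_band_px=1)
        x, y = cfg.grid()
        i, j = np.argwhere((x == 0) & (y == 0))[0]
        frame = carrier_frame(0, cfg)
        assert frame[i, j] == 0.0

    def test_outside_disc_is_mean_luminance(self, cfg9):
        frame = carrier_frame(3, cfg9)
        x, y = cfg9.grid()
        outside = np.hypot(x, y) > cfg9.max_eccentricity_deg
        assert np.all(frame[outside] == 0.5)

    def test_patterned_fraction_matches_disc_area(self):
        # over a square grid of side 2R, the disc covers pi/4 of the area
        cfg = CarrierConfig(max_eccentricity_deg=9, pixels_per_degree=8, edge_band_px=1)
        frame = carrier_frame(0, cfg)
        frac = np.mean(frame != 0.5)
        assert abs(frac - np.pi / 4) < 0.01

    def test_values_ternary_outside_fringe(self, cfg9):
        frame = carrier_frame(10, cfg9)
        x, y = cfg9.grid()
        r = np.hypot(x, y)
        band = cfg9.edge_band_px / cfg9.pixels_per_degree
        core = r <= cfg9.max_eccentricity_deg - band
        assert set(np.unique(frame[core])) <= {0.0, 0.5, 1.0}

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            CarrierConfig(pixels_per_degree=0)


class TestPhaseSchedule:
    def test_delta_at_zero_and_cycle_duration(self, cfg9):
        sched = phase_schedule(cfg9)
        assert sched.delta[0] == pytest.approx(0.5)
        assert round(sched.cycle_s, 2) == 1.15

    def test_delta_period_matches_theta_period(self, cfg9):
        # delta = sin(theta)/4 + 1/2 repeats every 2*pi of theta,
        # i.e. every n_phase_steps/2 steps over the 0..4*pi schedule
        sched = phase_schedule(cfg9)
        half = cfg9.n_phase_steps // 2
        np.testing.assert_allclose(sched.delta[:half], sched.delta[half:], atol=1e-12)

    def test_theta_uniform(self, cfg9):
        sched = phase_schedule(cfg9)
        steps = np.diff(sched.theta)
        np.testing.assert_allclose(steps, 4 * np.pi / cfg9.n_phase_steps)


class TestBarSequence:
    def test_run_arithmetic(self, bar_run):
        assert bar_run.n_volumes == 144
        assert int(bar_run.is_blank.sum()) == 48
        assert np.all(bar_run.masks[bar_run.is_blank] == 0)

    def test_masks_binary_and_bounded(self, bar_run, cfg9):
        x, y = cfg9.grid()
        outside = np.hypot(x, y) > cfg9.max_eccentricity_deg
        assert bar_run.masks.dtype == bool
        assert not bar_run.masks[:, outside].any()

    def test_opposite_signs_time_reverse_sweeps(self, cfg9, design):
        fwd = bar_sequence(0, 1, False, design, cfg9)
        rev = bar_sequence(0, -1, False, design, cfg9)
        n = design.volumes_per_sweep
        np.testing.assert_array_equal(fwd.masks[:n], rev.masks[:n][::-1])

    def test_scaled_widths_floor_and_monotone(self, design):
        max_ecc = 16.0
        centers = -max_ecc + 2 * max_ecc / 24 * (np.arange(24) + 0.5)
        widths = eccentricity_scaled_width(centers, design, max_ecc)
        # the scaling map bottoms out at the foveal minimum width
        assert eccentricity_scaled_width(0.0, design, max_ecc) == pytest.approx(
            design.log_min_ecc_deg
        )
        # widths strictly increase with |eccentricity| of the bar center
        pos = widths[12:]
        assert np.all(np.diff(pos) > 0)
        np.testing.assert_allclose(widths, widths[::-1])  # symmetric in |ecc|

    def test_display_scaling_is_exact_similarity(self, design):
        # same pixel count, geometry scaled by 9/16 -> identical masks
        small = CarrierConfig(max_eccentricity_deg=9, pixels_per_degree=2)
        large = CarrierConfig(max_eccentricity_deg=16, pixels_per_degree=2 * 9 / 16)
        for scaled in (False, True):
            a = bar_sequence(0, 1, scaled, design, small)
            b = bar_sequence(0, 1, scaled, design, large)
            np.testing.assert_array_equal(a.masks, b.masks)

    def test_unknown_direction_rejected(self, cfg9, design):
        with pytest.raises(ValueError):
            bar_sequence(30, 1, False, design, cfg9)


class TestWedgeRing:
    def test_run_arithmetic(self, wedge_ring_runs):
        run = wedge_ring_runs[0]
        assert run.n_volumes == 144
        assert int(run.is_blank.sum()) == 24
        assert np.all(run.is_blank[-24:])

    def test_wedge_component_period_20(self, cfg9, design):
        # subtract the reconstructed ring annulus; the remaining wedge
        # sector must repeat exactly every 20 volumes (one revolution)
        run = wedge_ring_sequence("cw_expand", design, cfg9)
        x, y = cfg9.grid()
        r = np.hypot(x, y)
        radii = ring_radii_schedule(design, cfg9.max_eccentricity_deg)
        n_ring = design.ring_volumes_per_cycle
        period = design.wedge_volumes_per_revolution
        assert period == 20
        for t in range(0, 120 - period, 7):
            ring_t = (r >= radii[t % n_ring, 0]) & (r <= radii[t % n_ring, 1])
            s = t + period
            ring_s = (r >= radii[s % n_ring, 0]) & (r <= radii[s % n_ring, 1])
            np.testing.assert_array_equal(
                run.masks[t] & ~ring_t & ~ring_s, run.masks[s] & ~ring_s & ~ring_t
            )

    def test_masks_are_wedge_union_ring(self, cfg9, design):
        run = wedge_ring_sequence("cw_expand", design, cfg9)
        x, y = cfg9.grid()
        r = np.hypot(x, y)
        radii = ring_radii_schedule(design, cfg9.max_eccentricity_deg)
        for t in (0, 7, 33):
            ring = (r >= radii[t % 15, 0]) & (r <= radii[t % 15, 1])
            assert np.all(run.masks[t][ring])  # ring fully contained

    def test_ring_area_increases_when_expanding(self, cfg9, design):
        radii = ring_radii_schedule(design, cfg9.max_eccentricity_deg)
        areas = np.pi * (radii[:, 1] ** 2 - radii[:, 0] ** 2)
        assert np.all(np.diff(areas) > 0)

    def test_ring_50pct_log_overlap(self, cfg9, design):
        radii = ring_radii_schedule(design, cfg9.max_eccentricity_deg)
        log_r = np.log(radii)
        # consecutive annuli share half their log-domain extent
        shared = log_r[:-1, 1] - log_r[1:, 0]
        extent = log_r[:, 1] - log_r[:, 0]
        np.testing.assert_allclose(shared / extent[:-1], 0.5, atol=1e-9)

    def test_reverse_direction_contracts(self, cfg9, design, wedge_ring_runs):
        # the reverse run steps the ring through the same annuli in the
        # opposite order: its per-volume mask areas (ring-dominated)
        # decrease over the first cycle while the forward run's increase
        fwd, rev = wedge_ring_runs
        areas_f = fwd.masks[:15].sum(axis=(1, 2))
        areas_r = rev.masks[:15].sum(axis=(1, 2))
        assert areas_f[-1] > areas_f[0]
        assert areas_r[-1] < areas_r[0]


class TestPhoticAndSession:
    def test_photic_arithmetic(self, photic_run_seq, cfg9):
        assert photic_run_seq.n_volumes == 120
        assert int((~photic_run_seq.is_blank).sum()) == 10
        x, y = cfg9.grid()
        disc = np.hypot(x, y) <= cfg9.max_eccentricity_deg
        for t in np.flatnonzero(~photic_run_seq.is_blank):
            np.testing.assert_array_equal(photic_run_seq.masks[t], disc)

    def test_session_totals(self, cfg9, design):
        runs = session_schedule(cfg9, design)
        assert len(runs) == 10
        assert sum(r.n_volumes for r in runs) == 1440
        wr = [r for r in runs if r.condition == "wedge_ring"]
        assert sum(r.n_volumes for r in wr) == 288
        assert {r.direction for r in wr} == {"cw_expand", "ccw_contract"}
        conditions = [r.condition for r in runs]
        assert conditions.count("bar_invariant") == 4
        assert conditions.count("bar_log") == 4


class TestFixationTask:
    def test_no_consecutive_changes_and_determinism(self):
        ev1 = fixation_events(300.0, seed=11)
        ev2 = fixation_events(300.0, seed=11)
        np.testing.assert_array_equal(ev1, ev2)
        assert np.all(np.diff(ev1) >= 0.4 - 1e-9)  # at least one bin apart
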