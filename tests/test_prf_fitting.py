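"""Coarse-to-fine pRF fitting: search grid, smoothing, both stages."""

import numpy as np
import pytest
from scipy import sparse

from prfmap import (
    DataMatrix,
    GaussianPRF,
    NoiseSpec,
    bold_prediction_runs,
    build_search_grid,
    coarse_fit,
    fine_fit,
    fit_prf,
    make_sheet,
    simulate_bold,
    smooth_on_sheet,
)
from prfmap.prf_fitting import _center_candidates


@pytest.fixture(scope="module")
def small_grid(bar_runs, hrf):
    return build_search_grid(bar_runs, hrf, n_sigma=8)


class TestSearchGrid:
    def test_candidate_count_and_ordering(self, small_grid):
        centers = _center_candidates(9.0, 2.4)
        xx, yy = np.meshgrid(centers, centers)
        in_disc = np.hypot(xx, yy) <= 9.0 + 1e-9
        assert small_grid.n_candidates == int(in_disc.sum()) * 8
        sig = small_grid.params[:, 2]
        assert np.all(np.diff(sig) >= 0)  # sigma blocks ascending
        # within each sigma block, center radius is non-decreasing
        for s in np.unique(sig):
            block = small_grid.params[sig == s]
            radius = np.hypot(block[:, 0], block[:, 1])
            assert np.all(np.diff(radius) >= -1e-9)

    def test_predictions_match_forward_model(self, small_grid, bar_runs, hrf):
        k = 57
        x0, y0, s = small_grid.params[k]
        prf = GaussianPRF(x0, y0, s, beta=1.0)
        expected = bold_prediction_runs(prf, bar_runs, hrf)
        np.testing.assert_allclose(small_grid.predictions[k], expected, atol=1e-8)

    def test_empty_runs_rejected(self, hrf):
        with pytest.raises(ValueError):
            build_search_grid([], hrf)


def _chain_sheet(n: int) -> sparse.csr_matrix:
    g = sparse.lil_matrix((n, n))
    for i in range(n - 1):
        g[i, i + 1] = g[i + 1, i] = 1.0
    return g.tocsr()


class TestSmoothing:
    def _data(self, series):
        from prfmap.containers import CorticalSheet

        n = series.shape[0]
        sheet = CorticalSheet(
            vertex_coords=np.column_stack([np.arange(n), np.zeros(n)]),
            neighbor_graph=_chain_sheet(n),
            roi_label=np.full(n, "V1"),
        )
        return DataMatrix(series=series, tr_s=2.55, sheet=sheet)

    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        data = self._data(rng.normal(size=(6, 20)))
        out = smooth_on_sheet(data, 0.0)
        np.testing.assert_array_equal(out.series, data.series)

    def test_constant_field_preserved_exactly(self):
        data = self._data(np.full((8, 5), 3.7))
        out = smooth_on_sheet(data, 4.0)
        np.testing.assert_allclose(out.series, 3.7)

    def test_smoothing_reduces_variance(self):
        rng = np.random.default_rng(1)
        data = self._data(rng.normal(size=(30, 10)))
        out = smooth_on_sheet(data, 5.0)
        assert out.series.var(axis=0).mean() < data.series.var(axis=0).mean()

    def test_disconnected_vertex_warns_and_keeps_value(self):
        from prfmap.containers import CorticalSheet

        g = _chain_sheet(4).tolil()
        g[2, 3] = g[3, 2] = 0.0  # isolate vertex 3
        sheet = CorticalSheet(
            vertex_coords=np.column_stack([np.arange(4), np.zeros(4)]),
            neighbor_graph=g.tocsr(),
            roi_label=np.full(4, "V1"),
        )
        data = DataMatrix(series=np.arange(8.0).reshape(4, 2), tr_s=2.55, sheet=sheet)
        with pytest.warns(UserWarning):
            out = smooth_on_sheet(data, 2.0)
        np.testing.assert_allclose(out.series[3], data.series[3])

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_on_sheet(self._data(np.zeros((3, 3))), -1.0)


class TestCoarseFit:
    def test_noiseless_pick_is_grid_optimum(self, small_grid, bar_runs, hrf):
        # a series generated from an exact grid candidate must select it
        k = 200
        series = 2.5 * small_grid.predictions[k] + 0.1
        out = coarse_fit(series, small_grid)
        assert int(out.loc[0, "candidate"]) == k
        assert out.loc[0, "r2_coarse"] == pytest.approx(1.0)
        assert bool(out.loc[0, "included"])

    def test_flat_and_anticorrelated_excluded(self, small_grid):
        flat = np.zeros(small_grid.predictions.shape[1])
        anti = -small_grid.predictions[10]
        out = coarse_fit(np.stack([flat, anti]), small_grid)
        assert not out["included"].any()

    def test_length_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError):
            coarse_fit(np.zeros(7), small_grid)


class TestFineFit:
    def test_noiseless_recovery_off_grid(self, bar_runs, hrf, small_grid):
        truth = GaussianPRF(x0=2.9, y0=-1.3, sigma=1.17, beta=1.8)
        series = bold_prediction_runs(truth, bar_runs, hrf)[None, :]
        coarse = coarse_fit(series, small_grid)
        fits = fine_fit(series, coarse, bar_runs, hrf)
        row = fits.iloc[0]
        assert row["converged"]
        assert row["x0"] == pytest.approx(2.9, abs=0.1)
        assert row["y0"] == pytest.approx(-1.3, abs=0.1)
        assert row["sigma"] == pytest.approx(1.17, abs=0.1)
        assert row["beta"] == pytest.approx(1.8, rel=0.1)
        assert row["r2_fine"] > 0.99

    def test_excluded_vertices_pass_through(self, bar_runs, hrf, small_grid):
        series = np.zeros((1, small_grid.predictions.shape[1]))
        coarse = coarse_fit(series, small_grid)
        fits = fine_fit(series, coarse, bar_runs, hrf)
        assert not fits.loc[0, "included"]
        assert np.isnan(fits.loc[0, "beta"])


class TestFitPRFEndToEnd:
    def test_recovers_synthetic_sheet(self, bar_runs, hrf):
        sheet = make_sheet(48, max_ecc=9.0, seed=7)
        data = simulate_bold(sheet, bar_runs, hrf, NoiseSpec(cnr=4.0, seed=7))
        fits = fit_prf(data, bar_runs, hrf, n_sigma=12)
        good = fits[fits["included"] & fits["converged"]]
        assert len(good) >= 30
        truth = sheet.truth.iloc[good["vertex_id"].to_numpy()]
        err = np.hypot(good["x0"].to_numpy() - truth["x0"].to_numpy(),
                       good["y0"].to_numpy() - truth["y0"].to_numpy())
        assert np.median(err) < 1.0
        assert "ecc" in fits.columns
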