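"""Summary statistics over fit tables and the truncation control."""

import numpy as np
import pandas as pd
import pytest

from prfmap import (
    DataMatrix,
    bin_sigma_by_eccentricity,
    compare_ecc_estimates,
    compare_slopes,
    sigma_ecc_slope,
    threshold_fits,
    truncate_blanks,
)
from prfmap.summary_stats import goodness_of_fit_anova


def _fits(ecc, sigma, **extra):
    n = len(ecc)
    return pd.DataFrame(
        dict(
            vertex_id=np.arange(n),
            x0=np.asarray(ecc, dtype=float),
            y0=np.zeros(n),
            sigma=np.asarray(sigma, dtype=float),
            r2_fine=np.full(n, 0.5),
            **extra,
        )
    )


class TestThreshold:
    def test_strictly_greater(self):
        fits = pd.DataFrame(dict(r2_fine=[0.05, 0.1, 0.100001, 0.9]))
        out = threshold_fits(fits, r2_min=0.1)
        assert len(out) == 2
        assert out.attrs["n_surviving"] == 2


class TestTruncateBlanks:
    def test_keeps_terminal_blanks(self, bar_run):
        n_vertex = 3
        data = DataMatrix(
            series=np.tile(np.arange(bar_run.n_volumes, dtype=float), (n_vertex, 1)),
            tr_s=bar_run.tr_s,
        )
        new_ap, new_data = truncate_blanks(bar_run, data, keep=24)
        assert new_ap.n_volumes == bar_run.n_volumes - 24
        assert int(new_ap.is_blank.sum()) == 24
        # the terminal blank block survives intact
        assert np.all(new_ap.is_blank[-24:])
        # data stays aligned with apertures: dropped indices are the
        # earliest blank volumes of the original run
        dropped = np.flatnonzero(bar_run.is_blank)[:24]
        expected = np.delete(np.arange(bar_run.n_volumes), dropped)
        np.testing.assert_array_equal(new_data.series[0], expected.astype(float))

    def test_too_few_blanks_rejected(self, bar_run):
        data = DataMatrix(series=np.zeros((1, bar_run.n_volumes)), tr_s=bar_run.tr_s)
        with pytest.raises(ValueError):
            truncate_blanks(bar_run, data, keep=100)

    def test_length_mismatch_rejected(self, bar_run):
        data = DataMatrix(series=np.zeros((1, 10)), tr_s=bar_run.tr_s)
        with pytest.raises(ValueError):
            truncate_blanks(bar_run, data)


class TestBinSigma:
    def test_known_bins(self):
        fits = _fits([0.5, 0.6, 1.5, 1.7, 5.2], [1.0, 2.0, 3.0, 5.0, 9.0])
        out = bin_sigma_by_eccentricity(fits, bin_deg=1.0)
        assert list(out["bin_lo"]) == [0.0, 1.0, 5.0]
        row0 = out[out["bin_lo"] == 0.0].iloc[0]
        assert row0["mean_sigma"] == pytest.approx(1.5)
        assert row0["n"] == 2
        # empty bins absent: nothing between 2 and 5 degrees
        assert 2.0 not in set(out["bin_lo"])

    def test_subject_level_sem(self):
        fits = pd.concat(
            [
                _fits([0.5] * 4, [1.0] * 4, subject="s1"),
                _fits([0.5] * 4, [2.0] * 4, subject="s2"),
            ]
        )
        out = bin_sigma_by_eccentricity(fits)
        assert out.iloc[0]["n"] == 2  # two subjects, not eight vertices
        assert out.iloc[0]["mean_sigma"] == pytest.approx(1.5)

    def test_max_ecc_filter(self):
        fits = _fits([1.0, 8.0], [1.0, 2.0])
        out = bin_sigma_by_eccentricity(fits, max_ecc=4.0)
        assert len(out) == 1


class TestSlopes:
    def test_exact_on_linear_data(self):
        ecc = np.linspace(0.5, 8, 40)
        fits = _fits(ecc, 0.5 + 0.25 * ecc)
        assert sigma_ecc_slope(fits) == pytest.approx(0.25)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            sigma_ecc_slope(_fits([1.0, 2.0], [1.0, 1.1]))
        with pytest.raises(ValueError):
            sigma_ecc_slope(_fits([2.0] * 5, [1.0] * 5))

    def test_compare_slopes_recovers_difference(self):
        rng = np.random.default_rng(4)
        rows = []
        for s in range(8):
            base = rng.normal(0.25, 0.01)
            rows.append(dict(subject=s, roi="V1", condition="invariant",
                             slope=base + 0.10 + rng.normal(0, 0.005)))
            rows.append(dict(subject=s, roi="V1", condition="scaled",
                             slope=base + rng.normal(0, 0.005)))
        out = compare_slopes(pd.DataFrame(rows))
        assert out.loc[0, "mean_slope_difference"] == pytest.approx(0.10, abs=0.01)
        assert out.loc[0, "p"] < 1e-4

    def test_compare_slopes_needs_two_conditions(self):
        df = pd.DataFrame(dict(subject=[0, 1], roi="V1", condition="a", slope=[0.1, 0.2]))
        with pytest.raises(ValueError):
            compare_slopes(df)


class TestCompareEcc:
    def test_known_offset(self):
        n = 40
        ecc = np.linspace(0.5, 8.0, n)
        fits = _fits(ecc, np.ones(n))
        phase = pd.DataFrame(
            dict(vertex_id=np.arange(n), eccentricity_deg=ecc + 0.9)
        )
        merged, poly, disc = compare_ecc_estimates(fits, phase, max_ecc=9.0)
        assert len(merged) == n
        assert disc == pytest.approx(0.1)  # 0.9 deg / 9 deg
        # the fitted polynomial reproduces the offset relation
        pred = np.polyval(poly, merged["prf_ecc_norm"])
        np.testing.assert_allclose(pred, merged["phase_ecc_norm"], atol=1e-6)

    def test_too_few_vertices_rejected(self):
        fits = _fits([1, 2, 3], [1, 1, 1])
        phase = pd.DataFrame(dict(vertex_id=[0, 1, 2], eccentricity_deg=[1, 2, 3.0]))
        with pytest.raises(ValueError):
            compare_ecc_estimates(fits, phase, max_ecc=9.0)


class TestAnova:
    def test_smoke_three_conditions(self):
        rng = np.random.default_rng(0)
        rows = [
            dict(subject=s, condition=c, r2=rng.normal(base, 0.01))
            for s in range(6)
            for c, base in (("a", 0.26), ("b", 0.17), ("c", 0.14))
        ]
        table = goodness_of_fit_anova(pd.DataFrame(rows))
        assert "F Value" in table.columns
        assert table["Pr > F"].iloc[0] < 0.01
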