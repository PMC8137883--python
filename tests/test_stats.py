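"""Series alignment, smoothing, effective df, alpha bracketing, correlations."""

import numpy as np
import pandas as pd
import pytest

from sedarich.stats import (
    ALPHA_LEVELS,
    align_series,
    alpha_level,
    effective_df,
    loess_smooth,
    spline_smooth,
    window_correlations,
)


class TestAlignSeries:
    def test_series_on_grid_unchanged(self):
        ages = np.arange(10.0, -0.1, -0.25)
        s = pd.Series(np.sin(ages), index=ages)
        out = align_series({"x": s}, step=0.25)
        np.testing.assert_allclose(out["x"].to_numpy(), s.to_numpy(), atol=1e-12)

    def test_linear_interpolation(self):
        s = pd.Series([0.0, 18.0], index=[18.0, 0.0])
        out = align_series({"x": s}, step=0.25)
        assert out.loc[9.0, "x"] == pytest.approx(9.0)

    def test_overlap_grid_length(self):
        a = pd.Series([1.0, 1.0], index=[14.0, 0.0])
        b = pd.Series([2.0, 2.0], index=[18.0, 3.6])
        out = align_series({"a": a, "b": b}, step=0.25)
        assert len(out) == 42                       # 14.0 down to 3.75
        assert out.index[0] == pytest.approx(14.0)
        assert out.index[-1] == pytest.approx(3.75)

    def test_empty_overlap_rejected(self):
        a = pd.Series([1.0, 1.0], index=[18.0, 10.0])
        b = pd.Series([2.0, 2.0], index=[5.0, 0.0])
        with pytest.raises(ValueError):
            align_series({"a": a, "b": b})


class TestSmoothers:
    ages = np.linspace(18, 0, 73)

    def test_loess_reproduces_constants(self):
        out = loess_smooth(self.ages, np.full_like(self.ages, 5.0))
        np.testing.assert_allclose(out, 5.0, atol=1e-9)

    def test_loess_reproduces_lines(self):
        y = 2.0 * self.ages + 1.0
        out = loess_smooth(self.ages, y)
        np.testing.assert_allclose(out, y, atol=1e-7)

    def test_loess_reduces_noise_rmse(self):
        rng = np.random.default_rng(0)
        truth = np.sin(self.ages / 3.0)
        noisy = truth + rng.normal(0, 0.4, truth.size)
        smooth = loess_smooth(self.ages, noisy, span=0.5)
        assert np.sqrt(np.mean((smooth - truth) ** 2)) < np.sqrt(np.mean((noisy - truth) ** 2))

    def test_loess_needs_five_points(self):
        with pytest.raises(ValueError):
            loess_smooth(np.arange(4.0), np.arange(4.0))

    def test_spline_reproduces_zeros(self):
        out = spline_smooth(self.ages, np.zeros_like(self.ages))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_spline_reproduces_lines(self):
        y = -3.0 * self.ages + 7.0
        out = spline_smooth(self.ages, y)
        np.testing.assert_allclose(out, y, atol=1e-6)

    def test_spline_monotone_near_onset(self):
        # zero-inflated step: smoother should rise through the onset with at
        # most small ringing
        y = np.where(self.ages > 3.6, 0.0, 1.0)
        out = spline_smooth(self.ages, y)
        near = (self.ages < 5.0) & (self.ages > 2.0)
        increments = np.diff(out[near])  # ages descend, so this runs old -> young
        assert (increments >= -0.05).all()


class TestEffectiveDf:
    def test_white_noise_keeps_nearly_all_df(self):
        rng = np.random.default_rng(1)
        n = 200
        adf = effective_df(rng.standard_normal(n), rng.standard_normal(n))
        assert abs(adf - (n - 2)) <= 25

    def test_strong_autocorrelation_shrinks_df(self):
        # cos(w t) has lag-1 autocorrelation ~ cos(w); choose cos(w) = 0.9
        n = 400
        t = np.arange(n)
        w = np.arccos(0.9)
        x = np.cos(w * t)
        y = np.cos(w * t + 1.0)
        adf = effective_df(x, y)
        expected = int(np.floor(n * (1 - 0.81) / (1 + 0.81))) - 2
        assert abs(adf - expected) <= 4

    def test_floor_prevents_degenerate_df(self):
        x = np.linspace(0, 1, 50)  # lag-1 autocorrelation near 1
        adf = effective_df(x, x)
        assert adf >= 1


class TestAlphaLevel:
    def test_perfect_correlation_reaches_strongest_level(self):
        assert alpha_level(1.0, 10) == 0.0005

    def test_zero_correlation_reaches_none(self):
        assert alpha_level(0.0, 10) is None

    def test_strong_rho_at_df_11(self):
        assert alpha_level(0.966, 11) == 0.0005

    def test_monotone_in_rho(self):
        rhos = np.linspace(0, 1, 51)
        levels = [alpha_level(r, 12) for r in rhos]
        coded = [2.0 if lv is None else lv for lv in levels]
        assert all(b <= a for a, b in zip(coded, coded[1:]))

    def test_negative_rho_uses_magnitude(self):
        assert alpha_level(-0.966, 11) == 0.0005


class TestWindowCorrelations:
    def make_aligned(self, rng=None):
        ages = np.arange(18.0, -0.1, -0.25)
        alpine = np.interp(ages, [0, 6, 12, 14, 18], [14, 10, 18, 0, 0])
        frame = pd.DataFrame(
            {
                "richness": 15 + 2 * alpine,
                "temperature": np.interp(ages, [0, 7, 15, 18], [0, 0.9, -5.5, -6]),
                "alpine_habitat": alpine,
                "forested_area": 18 - alpine,
                "total_habitat": np.interp(ages, [0, 13, 14, 18], [18, 18, 0, 0]),
                "glacier_decay": np.interp(ages, [0, 13, 14, 18], [0, 0, 18, 18]),
                "mgca": 2 + np.cos(ages / 3),
                "land_use": np.where(ages > 3.6, 0.0, 3.6 - ages),
            },
            index=pd.Index(ages, name="age"),
        )
        return frame

    def test_richness_equal_to_alpine_gives_rho_one(self):
        aligned = self.make_aligned()
        out = window_correlations(aligned, smoothed={})
        assert out.loc[("14-3.6", "alpine_habitat"), "rho"] == pytest.approx(1.0)
        assert out.loc[("10-0", "alpine_habitat"), "rho"] == pytest.approx(1.0)

    def test_spearman_invariant_under_monotone_transform(self):
        aligned = self.make_aligned()
        out1 = window_correlations(aligned, smoothed={})
        aligned2 = aligned.copy()
        aligned2["alpine_habitat"] = np.exp(aligned2["alpine_habitat"] / 5.0)
        out2 = window_correlations(aligned2, smoothed={})
        assert out1.loc[("10-0", "alpine_habitat"), "rho"] == pytest.approx(
            out2.loc[("10-0", "alpine_habitat"), "rho"]
        )

    def test_bonferroni_never_below_raw_p(self):
        from scipy import stats as sps

        aligned = self.make_aligned()
        out = window_correlations(aligned, smoothed={})
        sel = (aligned.index <= 10.0 + 1e-9) & (aligned.index >= -1e-9)
        sub = aligned.loc[sel]
        for pred in ("temperature", "mgca", "land_use"):
            raw = sps.spearmanr(sub["richness"], sub[pred]).pvalue
            assert out.loc[("10-0", pred), "p_adj"] >= raw - 1e-15

    def test_sub_window_keeps_perfect_monotone_rho(self):
        aligned = self.make_aligned()
        out = window_correlations(
            aligned,
            windows=((5.0, 2.0),),
            predictor_map={(5.0, 2.0): ("alpine_habitat",)},
            smoothed={},
        )
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_missing_predictor_rejected(self):
        aligned = self.make_aligned().drop(columns=["land_use"])
        with pytest.raises(KeyError):
            window_correlations(aligned, smoothed={})

    def test_adjusted_df_not_above_nominal(self):
        aligned = self.make_aligned()
        out = window_correlations(aligned)
        assert (out["adj_df"] <= out["df"]).all()
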