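"""Filters, conversions and compositing from daily records to windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fluxlue as fl
from fluxlue.preprocess import FilterThresholds
from fluxlue.synthdata import C_MOLAR_MASS


class TestPpfdConversion:
    def test_zero(self):
        assert fl.ppfd_from_shortwave(0.0) == 0.0

    def test_reference_value(self):
        # 200 W m-2 x 2.04e-6 mol J-1 x 86400 s
        assert fl.ppfd_from_shortwave(200.0) == pytest.approx(35.2512, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fl.ppfd_from_shortwave(-1.0)


class TestCloudinessIndex:
    @pytest.mark.parametrize(
        "s_t,s_o,expected", [(400.0, 400.0, 0.0), (0.0, 400.0, 1.0), (300.0, 400.0, 0.25)]
    )
    def test_values(self, s_t, s_o, expected):
        assert fl.cloudiness_index(s_t, s_o) == pytest.approx(expected)

    def test_zero_potential_flagged_nan(self):
        assert np.isnan(fl.cloudiness_index(0.0, 0.0))


class TestDiffuseTransmittance:
    def test_zero_at_clear_sky_bound(self):
        assert fl.diffuse_transmittance(0.889, 0.889) == pytest.approx(0.0, abs=1e-12)

    def test_all_diffuse_limit(self):
        t_t = 1e-6
        assert fl.diffuse_transmittance(t_t, 0.889) / t_t == pytest.approx(1.0, abs=1e-9)

    def test_hand_evaluated_point(self):
        # exponent 0.6*(1 - 0.889/0.5)/0.489 = -0.954601..., Td = 0.5*(1-e^x)
        expected = 0.5 * (1.0 - np.exp(0.6 * (1.0 - 0.889 / 0.5) / (0.889 - 0.4)))
        assert fl.diffuse_transmittance(0.5, 0.889) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.3075, abs=5e-4)

    @settings(derandomize=True, max_examples=50)
    @given(
        t_t=st.floats(1e-4, 1.0),
        b=st.floats(0.45, 1.0),
    )
    def test_bounded_by_total(self, t_t, b):
        td = fl.diffuse_transmittance(t_t, b)
        assert 0.0 <= td <= t_t

    def test_parameter_error(self):
        with pytest.raises(ValueError):
            fl.diffuse_transmittance(0.5, 0.4)
        with pytest.raises(ValueError):
            fl.diffuse_transmittance(0.0, 0.889)


class TestFitBristow:
    def test_noise_free_self_consistency(self):
        rng = np.random.default_rng(1)
        t_t = rng.uniform(0.1, 0.95, 200)
        t_d = fl.diffuse_transmittance(t_t, 0.75)
        b_hat, se, boundary = fl.fit_bristow(t_d, t_t)
        assert b_hat == pytest.approx(0.75, abs=1e-6)
        assert not boundary

    def test_noisy_recovery(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(50):
            t_t = rng.uniform(0.1, 0.95, 500)
            t_d = fl.diffuse_transmittance(t_t, 0.889) + rng.normal(0, 0.02, 500)
            b_hat, _, _ = fl.fit_bristow(t_d, t_t)
            hits += abs(b_hat - 0.889) < 0.02
        assert hits >= 47

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            fl.fit_bristow([0.1] * 5, [0.5] * 5)


class TestGapfillDiffuse:
    def _frame(self, ppfd_dif):
        return pd.DataFrame({
            "site_id": "A",
            "date": pd.to_datetime(["2001-06-01"]),
            "sw_in": [355.6],
            "sw_in_pot": [400.0],
            "ppfd_dif": [ppfd_dif],
        })

    def test_observed_untouched(self):
        out = fl.gapfill_diffuse(self._frame(123.0), 0.889)
        assert out["ppfd_dif"].iloc[0] == 123.0

    def test_filled_zero_at_clear_bound(self):
        out = fl.gapfill_diffuse(self._frame(np.nan), 0.889)
        assert out["ppfd_dif"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_fill_bounded_by_total(self, small_network):
        daily, _ = small_network
        site = daily[daily["ppfd_dif"].isna()].copy()
        out = fl.gapfill_diffuse(site, 0.889)
        filled = out["ppfd_dif"].to_numpy()
        total = out["sw_in"].to_numpy() * 2.04
        ok = np.isfinite(filled)
        assert (filled[ok] >= -1e-9).all()
        assert (filled[ok] <= total[ok] + 1e-6).all()


class TestInterpolateFapar:
    def test_constant_with_unity_point(self):
        dates = pd.date_range("2001-01-01", periods=20, freq="4D")
        values = np.full(20, 0.6)
        values[10] = 1.0  # saturated observation must be discarded
        out_dates = pd.date_range("2001-01-01", "2001-03-01", freq="D")
        daily = fl.interpolate_fapar(dates, values, out_dates)
        assert np.allclose(daily, 0.6, atol=1e-6)

    def test_outlier_removed_before_fit(self):
        dates = pd.date_range("2001-01-01", periods=30, freq="4D")
        rng = np.random.default_rng(0)
        values = 0.5 + rng.normal(0, 0.01, 30)
        values[15] = 0.5 + 5 * (np.percentile(values, 75) - np.percentile(values, 25))
        daily = fl.interpolate_fapar(dates, values, dates)
        assert daily.max() < 0.6

    def test_sinusoid_reconstruction(self):
        dates = pd.date_range("2001-01-01", periods=365, freq="D")
        doy = dates.dayofyear.to_numpy()
        curve = 0.45 + 0.3 * np.sin(2 * np.pi * doy / 365.0)
        obs_idx = np.arange(0, 365, 4)
        daily = fl.interpolate_fapar(dates[obs_idx], curve[obs_idx], dates)
        assert np.max(np.abs(daily - curve)) < 0.02

    def test_too_few_survivors(self):
        dates = pd.date_range("2001-01-01", periods=3, freq="10D")
        with pytest.raises(ValueError):
            fl.interpolate_fapar(dates, [0.5, 0.6, 0.55], dates)


class TestFilterSiteDays:
    def _toy(self):
        # 10 rows, 3 violating exactly one rule each
        df = pd.DataFrame({
            "gpp": [5.0] * 10,
            "gapfill_frac": [0.1] * 10,
            "ppfd": [30.0] * 10,
            "fapar": [0.5] * 10,
        })
        df.loc[1, "gapfill_frac"] = 0.6        # rule 1
        df.loc[4, "gpp"] = -0.3                # rule 2
        df.loc[7, "fapar"] = 0.001             # rule 3: absorbed light 0.03 < 0.1
        return df

    def test_counts_match_enumeration(self):
        out, audit = fl.filter_site_days(self._toy(), FilterThresholds())
        assert len(out) == 7
        assert audit["gapfill"] == 1
        assert audit["negative_gpp"] == 1
        assert audit["low_absorbed_light"] == 1
        assert audit["infeasible_lue"] == 0
        assert audit["retained"] == 7

    def test_exact_half_gapfilled_dropped(self):
        df = self._toy().iloc[:1].copy()
        df["gapfill_frac"] = 0.5
        out, audit = fl.filter_site_days(df, FilterThresholds())
        assert len(out) == 0 and audit["gapfill"] == 1

    def test_infeasible_lue_dropped(self):
        df = self._toy().iloc[:1].copy()
        df["gpp"] = 0.13 * 30.0 * 0.5 * C_MOLAR_MASS  # daily LUE 0.13 > 0.12
        out, audit = fl.filter_site_days(df, FilterThresholds())
        assert len(out) == 0 and audit["infeasible_lue"] == 1


class TestGrowingSeasonMask:
    def test_arithmetic_sequence(self):
        gpp = np.arange(100, dtype=float)
        mask = fl.growing_season_mask(gpp, FilterThresholds())
        # q05=4.95, q95=94.05 -> threshold 4.95 + 0.2*89.1 = 22.77
        assert mask.sum() == 100 - 23
        assert mask[23:].all() and not mask[:23].any()

    def test_constant_series_excluded(self):
        assert not fl.growing_season_mask(np.full(60, 5.0), FilterThresholds()).any()

    def test_too_short_series_excluded(self):
        assert not fl.growing_season_mask(np.arange(10.0), FilterThresholds()).any()

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0, 100), min_size=40, max_size=80, unique=True))
    def test_increasing_series_gives_suffix(self, values):
        gpp = np.sort(np.array(values))
        mask = fl.growing_season_mask(gpp, FilterThresholds())
        if mask.any():
            first = int(np.argmax(mask))
            assert mask[first:].all()


class TestComposeWindows:
    def _daily(self, n, gpp=6.0, sw_in=None, start="2001-06-01"):
        # sw_in chosen so daily PPFD = 30 mol m-2 d-1
        sw = sw_in if sw_in is not None else 30.0 / (2.04e-6 * 86400.0)
        return pd.DataFrame({
            "site_id": "A",
            "date": pd.date_range(start, periods=n, freq="D"),
            "gpp": gpp,
            "sw_in": sw,
            "sw_in_pot": 2.0 * sw,
            "ppfd_dif": 0.3 * sw * 2.04,
            "ta_day": 20.0,
            "vpd_day": 600.0,
            "soil_m": 0.8,
            "co2": 400.0,
            "elv": 100.0,
            "fapar": 0.5,
            "ppfd": 30.0,
        })

    def test_hand_example(self):
        comps = fl.compose_windows(self._daily(15), FilterThresholds())
        assert len(comps) == 1
        expected = (15 * 6.0 / C_MOLAR_MASS) / (15 * 30.0 * 0.5)
        assert comps["lue"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0333, abs=5e-5)

    def test_run_of_44_days_gives_two_windows(self):
        comps = fl.compose_windows(self._daily(44), FilterThresholds())
        assert len(comps) == 2
        assert (comps["n_days"] == 15).all()

    def test_gap_restarts_window_grid(self):
        a = self._daily(20, start="2001-06-01")
        b = self._daily(16, start="2001-07-15")  # 24 days after a's end: new run
        comps = fl.compose_windows(pd.concat([a, b]), FilterThresholds())
        assert len(comps) == 2

    def test_constant_forcing_means(self):
        comps = fl.compose_windows(self._daily(15), FilterThresholds())
        row = comps.iloc[0]
        assert row["temp"] == pytest.approx(20.0)
        assert row["vpd"] == pytest.approx(600.0)
        assert row["ci"] == pytest.approx(0.5)  # sw_in_pot = 2 sw_in
        assert row["fapar"] == pytest.approx(0.5)
        assert row["year"] == 2001


class TestPrepareComposites:
    def test_every_window_has_fifteen_days(self, small_composites):
        comps, audit = small_composites
        assert (comps["n_days"] == 15).all()
        assert (comps["lue"] > 0).all()
        assert comps["ci"].between(0, 1).all()
        assert audit["n_windows"] == len(comps)

    def test_bristow_refit_recovers_generator_value(self, small_composites):
        _, audit = small_composites
        assert audit["bristow"]["B"] == pytest.approx(0.889, abs=1e-3)

    def test_noise_free_window_closure(self, small_config):
        daily, truth = fl.generate_site_network(small_config.noise_free())
        comps, _ = fl.prepare_composites(daily, fapar_mode="observed")
        merged = daily.merge(truth[["site_id", "date", "lue_true"]], on=["site_id", "date"])
        merged["ppfd"] = fl.ppfd_from_shortwave(merged["sw_in"].to_numpy())
        for _, row in comps.head(25).iterrows():
            days = merged[
                (merged["site_id"] == row["site_id"])
                & (merged["date"] >= row["start_date"])
                & (merged["date"] < row["start_date"] + pd.Timedelta(days=15))
            ]
            assert len(days) == 15
            expected = (days["gpp"].sum() / C_MOLAR_MASS) / (
                days["ppfd"].sum() * days["fapar_obs"].mean()
            )
            assert row["lue"] == pytest.approx(expected, rel=1e-10)
            # identity closure against the generating truth
            truth_lue = (
                days["lue_true"] * days["fapar_obs"] * days["ppfd"]
            ).sum() / (days["ppfd"].sum() * days["fapar_obs"].mean())
            assert row["lue"] == pytest.approx(truth_lue, rel=1e-10)
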