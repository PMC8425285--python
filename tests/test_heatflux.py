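"""Surface heat-flux budget: bulk fluxes, radiation, closure calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from metabloom import heatflux, synth
from metabloom.constants import FluxParams
from metabloom.population import Hypsography

AREA = 6.66e7


def scalar_bulk_oracle(tair, rh, pressure, wind, tsurf, params=FluxParams()):
    """Independent straight-line transcription of the neutral bulk formulas
    with the same stability iteration, kept deliberately separate from the
    vectorized implementation."""
    esat = lambda t: 6.112 * math.exp(17.62 * t / (243.12 + t))  # noqa: E731
    q = lambda e, p: 0.622 * e / (p - 0.378 * e)  # noqa: E731
    ea, es = rh / 100 * esat(tair), esat(tsurf)
    qa, qs = q(ea, pressure), q(es, pressure)
    tv = (tair + 273.15) * (1 + 0.608 * qa)
    rho = pressure * 100 / (287.05 * tv)
    lv = 2.501e6 - 2370 * tsurf
    kappa = 0.4
    z = params.wind_height
    z0 = z * math.exp(-kappa / math.sqrt(params.c_dn))
    z0h = z * math.exp(-(kappa**2) / (params.c_hn * math.log(z / z0)))
    z0e = z * math.exp(-(kappa**2) / (params.c_en * math.log(z / z0)))
    cd, ch, ce = params.c_dn, params.c_hn, params.c_en
    for _ in range(params.max_iter):
        h = rho * 1005 * ch * wind * (tsurf - tair)
        e = rho * lv * ce * wind * (qs - qa)
        ustar = math.sqrt(cd) * wind
        hv = h + 0.61 * 1005 * (tsurf + 273.15) * e / lv
        if abs(hv) < 1e-9:
            break
        lmo = -rho * 1005 * tv * ustar**3 / (kappa * 9.81 * hv)
        zeta = max(min(z / lmo, 10.0), -10.0)
        if zeta < 0:
            x = (1 - 16 * zeta) ** 0.25
            pm = (
                2 * math.log((1 + x) / 2)
                + math.log((1 + x * x) / 2)
                - 2 * math.atan(x)
                + math.pi / 2
            )
            ph = 2 * math.log((1 + x * x) / 2)
        else:
            pm = ph = -5 * zeta
        cd_n = kappa**2 / (math.log(z / z0) - pm) ** 2
        ch_n = kappa * math.sqrt(cd_n) / (math.log(z / z0h) - ph)
        ce_n = kappa * math.sqrt(cd_n) / (math.log(z / z0e) - ph)
        delta = max(abs(cd_n - cd) / cd, abs(ch_n - ch) / ch, abs(ce_n - ce) / ce)
        cd, ch, ce = cd_n, ch_n, ce_n
        if delta < params.rtol:
            break
    h = rho * 1005 * ch * wind * (tsurf - tair)
    e = rho * lv * ce * wind * (qs - qa)
    return -e, -h


class TestBulkFluxes:
    def test_zero_gradients_zero_fluxes(self):
        q_lat, q_sen, conv = heatflux.bulk_turbulent_fluxes(15.0, 100.0, 980.0, 5.0, 15.0)
        assert q_lat == pytest.approx(0.0, abs=1e-9)
        assert q_sen == pytest.approx(0.0, abs=1e-9)
        assert conv

    def test_monotone_in_wind(self):
        f0 = heatflux.bulk_turbulent_fluxes(10.0, 70.0, 980.0, 0.0, 15.0)
        f5 = heatflux.bulk_turbulent_fluxes(10.0, 70.0, 980.0, 5.0, 15.0)
        assert abs(f0[0]) < abs(f5[0])
        assert abs(f0[1]) < abs(f5[1])

    def test_matches_scalar_oracle(self):
        cases = [
            (10.0, 70.0, 980.0, 3.0, 15.0),
            (20.0, 50.0, 1000.0, 7.0, 18.0),
            (2.0, 90.0, 960.0, 1.5, 5.0),
            (18.0, 60.0, 980.0, 4.0, 12.0),  # stable: air warmer than lake
        ]
        for case in cases:
            expect = scalar_bulk_oracle(*case)
            got = heatflux.bulk_turbulent_fluxes(*case)
            assert got[0] == pytest.approx(expect[0], abs=0.5)
            assert got[1] == pytest.approx(expect[1], abs=0.5)

    def test_evaporation_cools_the_lake(self):
        # warm lake under dry air: both turbulent fluxes are heat losses
        q_lat, q_sen, _ = heatflux.bulk_turbulent_fluxes(10.0, 50.0, 980.0, 4.0, 20.0)
        assert q_lat < 0 and q_sen < 0

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            heatflux.bulk_turbulent_fluxes(10.0, 150.0, 980.0, 3.0, 15.0)


class TestRadiativeFluxes:
    def test_linearity_in_calibration_constant(self):
        args = ("2015-06-01", 18.0, 70.0, 250.0, 20.0)
        _, lw1, _ = heatflux.radiative_fluxes(*args, a=1.0)
        _, lw2, _ = heatflux.radiative_fluxes(*args, a=2.0)
        assert lw2 == pytest.approx(2 * lw1)

    def test_no_sun_no_shortwave(self):
        sw, _, _ = heatflux.radiative_fluxes("2015-12-01", 5.0, 80.0, 0.0, 6.0)
        assert sw == 0.0

    def test_blackbody_balance(self):
        params = FluxParams(emissivity_water=1.0, atm_emissivity=1.0)
        _, lw_in, lw_out = heatflux.radiative_fluxes(
            "2015-06-01", 15.0, 70.0, 200.0, 15.0, params=params, a=1.0
        )
        assert lw_in == pytest.approx(lw_out)

    def test_albedo_scales_shortwave(self):
        sw, _, _ = heatflux.radiative_fluxes("2015-06-01", 15.0, 70.0, 300.0, 15.0)
        assert sw == pytest.approx(0.93 * 300.0)

    def test_summer_day_gains_winter_night_loses(self):
        fx = heatflux.compute_fluxes(
            pd.DataFrame(
                {
                    "date": [pd.Timestamp("2015-07-01"), pd.Timestamp("2015-01-05")],
                    "tair_c": [22.0, -5.0],
                    "rh_pct": [60.0, 55.0],
                    "pressure_hpa": [980.0, 980.0],
                    "wind_ms": [2.0, 4.0],
                    "swdown_wm2": [320.0, 10.0],
                    "tsurf_c": [21.0, 5.0],
                }
            )
        )
        assert fx.loc[0, "q_sw_net"] > 0
        assert fx.loc[0, "q_net"] > 0
        assert fx.loc[1, "q_net"] < 0


class TestHeatContent:
    def _hyps(self):
        tops = np.arange(120.0)
        return Hypsography(tops, tops + 1, np.full(120, 1e7))

    def test_uniform_warming_linearity(self):
        hyps = self._hyps()
        t1 = np.full(120, 5.0)
        t2 = np.full(120, 6.0)
        dh = heatflux.heat_content(t2, hyps) - heatflux.heat_content(t1, hyps)
        v = hyps.total_volume
        assert dh == pytest.approx(1000.0 * 4186.0 * v, rel=1e-3)

    def test_brute_force_summation(self, rng):
        from metabloom.physics import density

        hyps = self._hyps()
        t = rng.uniform(4.0, 20.0, 120)
        expected = sum(
            float(density(t[i], 0.0)) * 4186.0 * t[i] * hyps.volume[i]
            for i in range(120)
        )
        assert heatflux.heat_content(t, hyps) == pytest.approx(expected, rel=1e-12)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            heatflux.heat_content(np.ones(50), self._hyps())


class TestClosureCalibration:
    def test_noise_free_closure_and_recovery(self):
        met, h, area = synth.generate_closed_budget_meteo(
            n_days=730, a_true=1.02, seed=3
        )
        fx = heatflux.compute_fluxes(met, a=1.02)
        cum = float((fx["q_net"] * 86400 * area).sum())
        dh = float(h.iloc[-1] - h.iloc[0]) + float(
            fx["q_net"].iloc[0] * 86400 * area
        )  # H starts after the first day's integration
        assert cum == pytest.approx(dh, rel=1e-3)
        a_fit = heatflux.fit_longwave_constant(met, h, area)
        assert a_fit == pytest.approx(1.02, abs=1e-6)

    def test_recovery_under_observation_noise(self):
        met, h, area = synth.generate_closed_budget_meteo(
            n_days=730, a_true=1.02, noise_frac=0.02, seed=3
        )
        a_fit = heatflux.fit_longwave_constant(met, h, area)
        assert 1.00 <= a_fit <= 1.04

    def test_monotone_in_true_constant(self):
        fits = []
        for a_true in (0.9, 1.0, 1.1):
            met, h, area = synth.generate_closed_budget_meteo(
                n_days=365, a_true=a_true, seed=5
            )
            fits.append(heatflux.fit_longwave_constant(met, h, area))
        assert fits[0] < fits[1] < fits[2]

    def test_degenerate_series_rejected(self):
        met, h, area = synth.generate_closed_budget_meteo(n_days=30, seed=1)
        with pytest.raises(ValueError):
            heatflux.fit_longwave_constant(met, h.iloc[:1], area)


class TestSeasonalClimatology:
    def _daily(self, n_years=12, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.date_range("2009-01-01", periods=n_years * 365, freq="D")
        return pd.Series(rng.normal(0.0, 5.0, idx.size), index=idx)

    def test_constant_series_no_anomalies(self):
        idx = pd.date_range("2010-01-01", periods=3 * 365, freq="D")
        out = heatflux.seasonal_climatology(pd.Series(10.0, index=idx))
        assert (out["anomaly"] == 0.0).all()
        assert not out["flagged"].any()

    def test_injected_outlier_winter_flagged(self):
        # identical seasonal cycle every year, one winter shifted upward:
        # exactly that winter exceeds one SD of the winter means
        idx = pd.date_range("2009-01-01", periods=12 * 365, freq="D")
        s = pd.Series(
            np.cos(2 * np.pi * (idx.dayofyear - 200) / 365.0) * 50.0, index=idx
        )
        mask = (s.index >= "2014-12-01") & (s.index < "2015-03-01")
        s[mask] += 30.0
        out = heatflux.seasonal_climatology(s)
        djf = out[out.season == "DJF"]
        assert bool(djf.loc[djf.year == 2015, "flagged"].iloc[0])
        assert not djf.loc[djf.year != 2015, "flagged"].any()

    def test_december_assigned_to_following_winter(self):
        idx = pd.date_range("2010-12-01", "2010-12-31", freq="D")
        out = heatflux.seasonal_climatology(pd.Series(1.0, index=idx))
        assert set(out["year"]) == {2011}

    def test_anomalies_sum_to_zero_within_season(self):
        out = heatflux.seasonal_climatology(self._daily(seed=4))
        for sea, grp in out.groupby("season"):
            assert grp["anomaly"].sum() == pytest.approx(0.0, abs=1e-9)
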