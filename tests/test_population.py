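"""Population metrics: mass integration, growth, extremes, regime labels."""

import math

import numpy as np
import pandas as pd
import pytest

from metabloom import physics, population
from metabloom.population import Hypsography
from metabloom.synth import make_hypsography


@pytest.fixture(scope="module")
def hyps():
    return make_hypsography(total_volume=3.3e9)


@pytest.fixture(scope="module")
def flat_hyps():
    # 120 equal layers summing to 3.234e9 m³
    tops = np.arange(120.0)
    return Hypsography(tops, tops + 1, np.full(120, 3.234e9 / 120))


class TestDepthIntegratedMass:
    def test_uniform_concentration_conserves(self, flat_hyps):
        total, per, _ = population.depth_integrated_mass(np.ones(120), flat_hyps)
        assert total == pytest.approx(3.234, rel=1e-12)
        assert sum(per.values()) == pytest.approx(total, rel=1e-9)

    def test_all_zero(self, flat_hyps):
        total, per, _ = population.depth_integrated_mass(np.zeros(120), flat_hyps)
        assert total == 0.0
        assert all(v == 0.0 for v in per.values())

    def test_single_cell(self):
        tops = np.arange(120.0)
        hyps = Hypsography(tops, tops + 1, np.full(120, 5e7))
        c = np.zeros(120)
        c[37] = 10.0
        total, per, _ = population.depth_integrated_mass(c, hyps)
        assert total == pytest.approx(0.5)
        assert per["20-40m"] == pytest.approx(0.5)
        assert sum(v for k, v in per.items() if k != "20-40m") == 0.0

    def test_missing_cells_counted(self, flat_hyps):
        c = np.ones(120)
        c[10:13] = np.nan
        total, _, n_missing = population.depth_integrated_mass(c, flat_hyps)
        assert n_missing == 3
        assert total == pytest.approx(3.234 * 117 / 120)

    def test_grid_mismatch_rejected(self, flat_hyps):
        with pytest.raises(ValueError):
            population.depth_integrated_mass(np.ones(100), flat_hyps)

    def test_mass_conservation_random(self, hyps, rng):
        for _ in range(30):
            c = rng.gamma(1.0, 2.0, 120)
            total, per, _ = population.depth_integrated_mass(c, hyps)
            assert sum(per.values()) == pytest.approx(total, rel=1e-9)


class TestNetGrowthRate:
    def test_no_change(self):
        assert population.net_growth_rate(5.0, 5.0, "2020-01-01", "2020-01-15") == 0.0

    def test_doubling(self):
        mu = population.net_growth_rate(3.0, 6.0, "2020-06-01", "2020-06-15")
        assert mu == pytest.approx(math.log(2) / 14, abs=1e-12)

    def test_antisymmetry(self):
        a = population.net_growth_rate(2.0, 7.0, "2020-06-01", "2020-06-11")
        b = population.net_growth_rate(7.0, 2.0, "2020-06-01", "2020-06-11")
        assert a == pytest.approx(-b)

    def test_nonpositive_biomass_rejected(self):
        with pytest.raises(ValueError):
            population.net_growth_rate(0.0, 5.0, "2020-01-01", "2020-01-15")

    def test_telescoping(self, rng):
        # summed interval rates equal the endpoint log-ratio over elapsed days
        dates = pd.date_range("2015-01-01", periods=10, freq="13D")
        b = rng.uniform(1.0, 30.0, 10)
        total = sum(
            population.net_growth_rate(b[i], b[i + 1], dates[i], dates[i + 1])
            * (dates[i + 1] - dates[i]).days
            for i in range(9)
        )
        expected = math.log(b[-1] / b[0])
        assert total == pytest.approx(expected, rel=1e-10)


class TestChlMaxDepth:
    def test_gaussian_layer(self):
        z = np.arange(40.0)
        c = 20 * np.exp(-0.5 * ((z - 11) / 2.0) ** 2)
        depth, below = population.chl_max_depth(c, z)
        assert depth == 11.0 and not below

    def test_tie_breaks_shallow(self):
        c = np.zeros(20)
        c[5] = c[12] = 3.0
        depth, _ = population.chl_max_depth(c)
        assert depth == 5.0

    def test_below_detection_flag(self):
        depth, below = population.chl_max_depth(np.full(20, 0.01))
        assert below

    def test_all_zero_absent(self):
        depth, below = population.chl_max_depth(np.zeros(10))
        assert depth is None and below


class TestRegimeLabel:
    def _strat(self, valid, upper=8.0):
        return physics.StratificationSummary(
            n2_profile=np.zeros(5),
            z_mix=5.0,
            metalimnion_upper=upper if valid else None,
            metalimnion_center=11.0 if valid else None,
            metalimnion_lower=14.0 if valid else None,
            metalimnion_valid=valid,
            n2_max=3e-4,
        )

    def test_inside_metalimnion(self):
        assert population.regime_label(12.0, self._strat(True)) == "metalimnetic"

    def test_invalid_metalimnion_means_mixed(self):
        assert population.regime_label(12.0, self._strat(False)) == "mixed"

    def test_above_upper_boundary_mixed(self):
        assert population.regime_label(3.0, self._strat(True)) == "mixed"


class TestAnnualExtremes:
    def _series(self, year_vals):
        """Build a series with given (vernal_min, following_max) per year."""
        rows = {}
        for i, (vmin, vmax) in enumerate(year_vals):
            y = 2010 + i
            rows[pd.Timestamp(f"{y}-05-15")] = vmin
            rows[pd.Timestamp(f"{y}-11-15")] = vmax
        return pd.Series(rows).sort_index()

    def test_constructed_ratios(self):
        s = self._series([(1.0, 20.0), (2.0, 20.0)])
        out = population.annual_extremes(s)
        assert len(out) == 2
        first, second = out
        assert first.survival_ratio is None
        assert first.recovery_ratio == pytest.approx(1.0 / 20.0)
        assert second.survival_ratio == pytest.approx(2.0 / 20.0)

    def test_flat_series_unit_ratios(self):
        s = self._series([(5.0, 5.0), (5.0, 5.0), (5.0, 5.0)])
        for e in population.annual_extremes(s)[1:]:
            assert e.survival_ratio == pytest.approx(1.0)
            assert e.recovery_ratio == pytest.approx(1.0)

    def test_below_detection_floored_and_flagged(self):
        s = self._series([(1.0, 20.0), (0.001, 10.0)])
        out = population.annual_extremes(s, detection_floor=0.1)
        assert out[1].min_below_detection
        assert out[1].survival_ratio == pytest.approx(0.1 / 20.0)

    def test_short_series_empty(self):
        s = pd.Series({pd.Timestamp("2020-05-01"): 3.0})
        assert population.annual_extremes(s) == []

    def test_ratios_bounded(self, rng):
        dates = pd.date_range("2010-01-07", periods=6 * 26, freq="14D")
        s = pd.Series(rng.uniform(0.5, 30.0, dates.size), index=dates)
        for e in population.annual_extremes(s):
            if e.survival_ratio is not None:
                assert 0.0 <= e.survival_ratio <= 1.0
            assert 0.0 <= e.recovery_ratio <= 1.0
            assert e.following_max >= e.vernal_min


class TestCongruence:
    def test_sign_convention(self):
        zp = pd.Series({pd.Timestamp("2020-06-01"): 10.0, pd.Timestamp("2020-06-15"): 12.0})
        zb = pd.Series({pd.Timestamp("2020-06-01"): 10.0, pd.Timestamp("2020-06-15"): 10.0})
        dev = population.congruence_series(zp, zb)
        assert dev.iloc[0] == 0.0
        assert dev.iloc[1] == -2.0  # population below the comparison depth

    def test_absent_propagates(self):
        zp = pd.Series({pd.Timestamp("2020-06-01"): 8.0})
        other = pd.Series({pd.Timestamp("2020-07-01"): 14.0})
        dev = population.congruence_series(zp, other)
        assert dev.isna().all()


class TestScenarioRecovery:
    def test_regime_matches_generator_truth(self, default_tables, truth):
        pop = default_tables["population"].set_index("timestamp")
        match = (pop["regime"] == truth["regime_true"]).mean()
        assert match >= 0.95

    def test_survival_recovery(self, default_scenario, default_tables):
        ext = default_tables["extremes"]
        merged = ext.merge(default_scenario.truth_survival, on="bloom_year")
        merged = merged.dropna(subset=["survival_ratio", "survival_true"])
        assert len(merged) >= 10
        rel = (
            (merged["survival_ratio"] - merged["survival_true"])
            / merged["survival_true"]
        ).abs()
        assert rel.max() < 0.05

    def test_bimodal_growth_pattern(self, default_tables):
        g = default_tables["growth"].copy()
        doy = pd.to_datetime(g["t0"]).dt.dayofyear
        assert g.loc[(doy >= 166) & (doy < 274), "mu"].mean() > 0  # metalimnetic
        assert g.loc[doy >= 274, "mu"].mean() > 0  # autumn epilimnetic
        assert g.loc[doy < 95, "mu"].mean() <= 0  # winter mixing
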