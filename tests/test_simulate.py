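import numpy as np
import pandas as pd
import pytest

from icepools.io import load_campaign
from icepools.models import ic_profiles
from icepools.simulate import (
    SimConfig,
    sampling_days,
    simulate_bloom,
    simulate_campaign,
    simulate_currents,
    write_campaign,
)


class TestConfig:
    def test_sampling_grid_pattern(self):
        days = sampling_days(SimConfig(n_days=42))
        assert list(days[:5]) == [0, 3, 7, 10, 14]
        assert days[-1] <= 42
        assert len(sampling_days(SimConfig.grid_2010())) == 12

    def test_negative_midseason_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            SimConfig(n_days=60, chla_decline_rate=-2.0)
        with pytest.raises(ValueError, match="IC-N"):
            SimConfig(icN0=2.0, icN_trend=-0.15)

    def test_retention_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(retention_Si=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=5, retention_Si=0.2)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestCurrents:
    def test_zero_amplitudes_zero_series(self):
        cfg = SimConfig(a_m2=0.0, a_s2=0.0, current_noise_sd=0.0)
        cur = simulate_currents(cfg)
        assert np.allclose(cur["max_speed"], 0.0)

    def test_single_constituent_has_no_beat(self):
        cfg = SimConfig(a_s2=0.0, current_noise_sd=0.0)
        daily = simulate_currents(cfg)["max_speed"].to_numpy()
        assert daily.std() / daily.mean() < 0.05

    def test_spring_neap_beat_period(self):
        # 1/(1/12.00 - 1/12.42) h = 355 h ~ 14.8 days between spring maxima
        cfg = SimConfig(n_days=42, current_noise_sd=0.0)
        daily = simulate_currents(cfg)["max_speed"].to_numpy()
        peaks = [
            i
            for i in range(2, daily.size - 2)
            if daily[i] == daily[i - 2: i + 3].max()
        ]
        spacings = np.diff(peaks)
        spacings = spacings[spacings > 5]  # ignore flat-top neighbours
        assert len(spacings) >= 1
        assert all(13 <= s <= 17 for s in spacings)


class TestBloom:
    def test_zero_trends_and_noise_constant(self):
        cfg = SimConfig(
            chla_decline_rate=0.0, icN_trend=0.0, icSi_trend=0.0,
            noise_cv=0.0, process_sd_N=0.0, process_sd_Si=0.0,
            coupling_r=0.0, current_noise_sd=0.0,
        )
        state = simulate_bloom(cfg, simulate_currents(cfg))
        for _, g in state.groupby("site"):
            assert g["ic_chl_N"].nunique() == 1
            assert g["chla_mg_m3"].nunique() == 1

    def test_exponential_mode_log_ratio_linear(self):
        cfg = SimConfig(
            trend_mode="exponential", noise_cv=0.0, process_sd_N=0.0,
            process_sd_Si=0.0, coupling_r=0.0, current_noise_sd=0.0,
        )
        state = simulate_bloom(cfg, simulate_currents(cfg))
        g = state[state["site"] == "medium"]
        logratio = np.log(g["ic_chl_N"] / g["ic_chl_Si"])
        fit = np.polyfit(g["day"], logratio, 1)
        assert np.allclose(np.polyval(fit, g["day"]), logratio, atol=1e-9)

    def test_all_quantities_nonnegative(self):
        state = simulate_bloom(SimConfig(seed=3), simulate_currents(SimConfig(seed=3)))
        num = state.select_dtypes("number")
        assert (num >= 0).all().all()

    def test_null_coupling_residuals_uncorrelated(self):
        """With coupling off, detrended IC residuals are centred on zero
        correlation with the currents and bounded by the n=12 white-noise
        90% quantile (|r| < 0.58)."""
        from icepools.models import TidalTrendModel

        rs = []
        for seed in range(60):
            cfg = SimConfig.grid_2010(seed=seed, coupling_r=0.0)
            tidal = TidalTrendModel.from_tables(simulate_campaign(cfg)).fit()
            rs.append(tidal.residual_correlations[("ic_chl_N", 0)].r)
        rs = np.array(rs)
        assert abs(np.median(rs)) < 0.2
        assert np.mean(np.abs(rs) < 0.58) >= 0.85


class TestObservation:
    def test_noise_free_scrape_chain_inverts_exactly(self, noise_free_tables):
        prof = ic_profiles(noise_free_tables)
        truth = noise_free_tables.truth
        merged = prof.merge(truth, on=["date", "site"], suffixes=("", "_true"))
        assert np.allclose(merged["ic_chl_N"], merged["ic_chl_N_true"], rtol=1e-9)
        assert np.allclose(merged["ic_chl_Si"], merged["ic_chl_Si_true"], rtol=1e-9)
        assert np.allclose(merged["chla_mg_m3"], merged["chla_mg_m3_true"],
                           rtol=1e-9)

    def test_recovered_ic_unbiased_at_default_noise(self):
        """Multiplicative 10% noise leaves the recovered pool unbiased (<2%)."""
        ratios = []
        for seed in range(200):
            cfg = SimConfig(seed=seed, n_days=7)
            tables = simulate_campaign(cfg)
            prof = ic_profiles(tables).merge(
                tables.truth, on=["date", "site"], suffixes=("", "_true")
            )
            ratios.append((prof["ic_chl_N"] / prof["ic_chl_N_true"]).mean())
        assert abs(np.mean(ratios) - 1.0) < 0.02

    def test_noise_free_bulk_equals_background_plus_ic(self, noise_free_tables,
                                                       noise_free_config):
        cfg = noise_free_config
        bulk = noise_free_tables.bulk_melt.merge(
            noise_free_tables.truth, on=["date", "site"]
        )
        bg = cfg.water_column_N * bulk["bulk_salinity"] / cfg.water_salinity
        ic_bottom = bulk["ic_chl_N"] * bulk["chla_mg_m3"] / 1000.0
        assert np.allclose(bulk["no3no2_umol_l"] - bg,
                           cfg.retention_N * ic_bottom, rtol=1e-9)

    def test_bulk_nsi_exceeds_water_column(self, default_tables):
        bulk_nsi = (default_tables.bulk_melt["no3no2_umol_l"]
                    / default_tables.bulk_melt["sioh4_umol_l"]).mean()
        water_nsi = (default_tables.water_column["no3no2_umol_l"]
                     / default_tables.water_column["sioh4_umol_l"]).mean()
        assert bulk_nsi > water_nsi

    def test_counting_error_near_poisson_cv(self):
        ratios = []
        for seed in range(120):
            cfg = SimConfig(seed=seed, n_days=7)
            tables = simulate_campaign(cfg)
            cm = tables.core_melt.merge(tables.truth, on=["date", "site"])
            dil = cm["melted_ice_volume_l"] / (
                cm["melted_ice_volume_l"] + cm["fsw_volume_l"]
            )
            ratios.extend(cm["abundance_diluted_cells_l"]
                          / (cm["abundance_cells_l"] * dil))
        cv = np.std(ratios)
        assert 0.03 < cv < 0.07  # 1/sqrt(400) = 5%


class TestWriteCampaign:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=42)
        write_campaign(cfg, tmp_path / "a")
        write_campaign(cfg, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_row_counts_and_round_trip(self, tmp_path):
        cfg = SimConfig(seed=1)
        out = write_campaign(cfg, tmp_path / "camp")
        tables = load_campaign(out)
        n_expected = len(sampling_days(cfg)) * cfg.n_sites
        for df in (tables.scrape, tables.core_melt, tables.bulk_melt):
            assert len(df) == n_expected
        assert (out / "config.yaml").exists()
        # currents cover every day of the season
        assert len(tables.currents) == cfg.n_days + 1
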