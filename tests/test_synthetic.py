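import numpy as np
import pandas as pd
import pytest

from phenoshift import ingest, phenology, synthetic
from phenoshift.effect_sizes import compute_effect_sizes


class TestSimConfig:
    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="years"):
            synthetic.SimConfig(years=5)

    def test_wide_season_rejected(self):
        with pytest.raises(ValueError, match="width"):
            synthetic.SimConfig(sigma_season=100.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            synthetic.preset("atlantis-like")


class TestDeterminism:
    def test_identical_config_identical_tables(self):
        cfg = synthetic.preset("massbay-like", seed=42, taxa_per_group=1,
                               regions_per_estuary=1, stations_per_region=1)
        m1, c1, _ = synthetic.simulate(cfg)
        m2, c2, _ = synthetic.simulate(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_different_seed_different_tables(self):
        base = dict(taxa_per_group=1, regions_per_estuary=1,
                    stations_per_region=1)
        m1, _, _ = synthetic.simulate(synthetic.preset("massbay-like",
                                                       seed=1, **base))
        m2, _, _ = synthetic.simulate(synthetic.preset("massbay-like",
                                                       seed=2, **base))
        assert not m1["value"].equals(m2["value"])

    def test_effect_sets_deterministic(self):
        e1, t1 = synthetic.simulate_effect_sets(10, [0, 0, 0], [0.01] * 3,
                                                seed=5)
        e2, t2 = synthetic.simulate_effect_sets(10, [0, 0, 0], [0.01] * 3,
                                                seed=5)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.z, b.z)
        pd.testing.assert_frame_equal(t1, t2)


class TestSimulateClimate:
    def test_no_trend_no_noise_constant_annual_means(self):
        cfg = synthetic.SimConfig(b_CT_temperature=0.0, b_CT_salinity=0.0,
                                  sigma_climate=0.0, regions_per_estuary=1,
                                  stations_per_region=1, seed=0)
        climate, _ = synthetic.simulate_climate(cfg)
        annual = climate.groupby("year")["temperature"].mean()
        assert annual.std() == pytest.approx(0.0, abs=1e-12)

    def test_zero_seasonal_amplitude_constant_within_year(self):
        cfg = synthetic.SimConfig(temp_season_amplitude=0.0,
                                  sigma_climate=0.0, regions_per_estuary=1,
                                  stations_per_region=1)
        climate, _ = synthetic.simulate_climate(cfg)
        one_year = climate[climate["year"] == climate["year"].iloc[0]]
        assert one_year.groupby("station")["temperature"].std().max() \
            == pytest.approx(0.0, abs=1e-12)

    def test_trend_recovered_by_regression(self):
        """Annual-mean OLS slope recovers b_CT across seeds."""
        b = 0.05
        slopes = []
        for seed in range(25):
            cfg = synthetic.SimConfig(b_CT_temperature=b, years=30,
                                      regions_per_estuary=1,
                                      stations_per_region=1, seed=seed)
            climate, _ = synthetic.simulate_climate(cfg)
            annual = climate.groupby("year")["temperature"].mean()
            slopes.append(np.polyfit(annual.index, annual.to_numpy(), 1)[0])
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - b) < 3 * se + 1e-4


class TestSimulateAbundance:
    def test_no_drift_no_noise_constant_peak_month(self):
        cfg = synthetic.SimConfig(b_PT=0.0, b_PC=0.0, sigma_peak=0.0,
                                  sigma_obs=0.0, zero_inflation=0.0,
                                  sigma_climate=0.0, taxa_per_group=1,
                                  regions_per_estuary=1,
                                  stations_per_region=1, mu0=180.0, seed=3)
        monitoring, climate, _ = synthetic.simulate(cfg)
        pheno = phenology.extract_phenology(monitoring, climate)
        for _, grp in pheno.groupby(["taxon", "station"]):
            assert grp["peak_month"].nunique() == 1

    def test_full_zero_inflation_yields_no_phenology(self):
        cfg = synthetic.SimConfig(zero_inflation=1.0, taxa_per_group=1,
                                  regions_per_estuary=1,
                                  stations_per_region=1, seed=3)
        monitoring, climate, _ = synthetic.simulate(cfg)
        assert (monitoring["value"] == 0).all()
        pheno = phenology.extract_phenology(monitoring, climate)
        assert pheno.empty

    def test_drift_recovered_end_to_end(self):
        """Pipeline-extracted peak-vs-year OLS slope tracks b_PT = −1.5 d/yr
        at low noise over 40 years."""
        slopes = []
        for seed in range(15):
            cfg = synthetic.SimConfig(
                b_PT=-1.5, b_PC=0.0, years=40, sigma_peak=2.0, sigma_obs=0.1,
                zero_inflation=0.0, taxa_per_group=1, regions_per_estuary=1,
                stations_per_region=1, mu0=180.0, seed=seed)
            monitoring, climate, _ = synthetic.simulate(cfg)
            pheno = phenology.extract_phenology(monitoring, climate)
            for _, grp in pheno.groupby(["taxon", "station"]):
                slopes.append(np.polyfit(grp["year"], grp["peak_doy"], 1)[0])
        assert abs(np.mean(slopes) - (-1.5)) < 0.5

    def test_tables_pass_ingest_validation(self):
        cfg = synthetic.preset("sanfrancisco-like", taxa_per_group=2, seed=8)
        monitoring, climate, _ = synthetic.simulate(cfg)
        table, report = ingest.read_monitoring(monitoring)
        assert report.n_kept == len(monitoring) and not report.rejected
        _, creport = ingest.read_climate(climate)
        assert not creport.rejected
        filtered, log = ingest.filter_series(table)
        assert log["kept"].all()  # 30-year series all survive


class TestGenerativeConsistency:
    def test_pipeline_correlations_match_implied(self):
        """At 40 years and ~200 series with low noise, the mean pipeline
        PT/CT/PC correlations sit within 0.05 of the generative model's
        implied values."""
        cfg = synthetic.SimConfig(
            taxa_per_group=67, regions_per_estuary=1, stations_per_region=1,
            years=40, b_PT=-3.0, b_PC=-1.0, b_CT_temperature=0.05,
            sigma_peak=4.0, sigma_obs=0.05, sigma_climate=0.3,
            zero_inflation=0.0, seed=21)
        monitoring, climate, truth = synthetic.simulate(cfg)
        pheno = phenology.extract_phenology(monitoring, climate)
        effects = compute_effect_sizes(pheno, "temperature", "annual")
        assert len(effects) == 201
        est = pd.DataFrame([{"r_PT": e.triplet.p_PT, "r_CT": e.triplet.p_CT,
                             "r_PC": e.triplet.p_PC} for e in effects])
        implied = synthetic.implied_correlations(cfg)
        for key in ("r_PT", "r_CT", "r_PC"):
            assert est[key].mean() == pytest.approx(implied[key], abs=0.05), key

    def test_effect_sets_concentrate_at_beta_with_tiny_variance(self):
        effects, _ = synthetic.simulate_effect_sets(
            50, [-0.3, 0.4, -0.35], [0.0, 0.0, 0.0], n_range=(5000, 5000),
            seed=2)
        zs = np.stack([e.z for e in effects])
        assert np.allclose(zs.mean(axis=0), [-0.3, 0.4, -0.35], atol=0.01)
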