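"""Synthetic monitoring and water-quality tables with known ground truth.

The generator emulates the statistical structure the pipeline assumes in
real estuarine monitoring programs: monthly sampling over multidecadal
spans, a unimodal seasonal abundance curve per taxon (Gaussian on the
circle, so winter-peaking taxa exercise the calendar-boundary unwrap), a
linear drift in peak timing, climate covariates with linear trends plus a
seasonal cycle, lognormal observation noise with zero-inflated detection,
and a taxon × station × region × estuary hierarchy spanning fish,
zooplankton and phytoplankton.

The generative peak date for taxon j at station s in year y is

    μ_jy = μ0_j + b_PT · (y − ȳ) + b_PC · (c_sy − c̄_s) + N(0, σ_p²)

where c_sy is the realized annual mean of the driving covariate, so the
phenology–climate sensitivity b_PC acts through interannual climate
anomalies (which include the climate trend b_CT — mirroring the
collinearity the real analysis faces).  Monthly abundance is
A·exp(−d(mid-month, μ_jy)²/(2σ_s²)) with circular distance d, times
lognormal noise, zeroed with the detection-failure probability.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``: identical configs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .effect_sizes import CorrelationTriplet, build_block
from .phenology import month_mid_doy

YEAR = 365.25
MONTH_DAYS = YEAR / 12
# variance of the mid-month quantization error, treated as uniform dither
QUANTIZATION_VAR = MONTH_DAYS ** 2 / 12


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic estuary.

    Defaults describe one desk-scale estuary: 30 monitored years (the
    middle of the 10–49-year range of real programs), two regions of two
    stations, four taxa per trophic group, a modest phenological advance
    and a warming trend, with noise levels typical of monthly plankton and
    trawl indices.
    """

    estuary: str = "synthetic-bay"
    regions_per_estuary: int = 2
    stations_per_region: int = 2
    taxa_per_group: int = 4
    years: int = 30
    start_year: int = 1990

    # seasonal peak model (per taxon; baseline peak dates are drawn
    # uniformly over the year unless pinned via mu0)
    mu0: float | None = None           # baseline peak day-of-year
    sigma_season: float = 30.0         # seasonal width, days
    amplitude: float = 100.0           # peak monthly abundance

    # trends
    b_PT: float = -0.5                 # phenology drift, days/year
    b_CT_temperature: float = 0.03     # °C/year
    b_CT_salinity: float = 0.01        # PSU/year
    b_PC: float = -2.0                 # days per covariate unit (anomaly)
    driver: str = "temperature"        # covariate forcing phenology

    # climate baselines and seasonal cycle
    temp_baseline: float = 15.0
    sal_baseline: float = 22.0
    temp_season_amplitude: float = 6.0
    sal_season_amplitude: float = 2.0

    # noise
    sigma_obs: float = 0.3             # lognormal sd of abundance noise
    sigma_climate: float = 0.6         # monthly climate noise sd
    sigma_peak: float = 5.0            # peak-timing jitter, days
    zero_inflation: float = 0.05       # detection-failure probability

    seed: int = 0

    def __post_init__(self):
        if min(self.sigma_obs, self.sigma_climate, self.sigma_peak,
               self.zero_inflation) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.years < 10:
            raise ValueError("years < 10 would not pass the ingest filter")
        if self.sigma_season >= YEAR / 4:
            raise ValueError("seasonal width >= a quarter year: the monthly "
                             "peak is not identifiable")


TROPHIC_GROUPS = ("fish", "zooplankton", "phytoplankton")


def preset(name: str, **overrides) -> SimConfig:
    """Named study conditions; they differ in which covariate trend
    dominates and drives phenology (salinity in the San Francisco-like
    system, temperature elsewhere)."""
    presets = {
        "sanfrancisco-like": dict(estuary="sanfrancisco-like",
                                  b_CT_temperature=0.005,
                                  b_CT_salinity=0.06, b_PC=-8.0,
                                  driver="salinity"),
        "chesapeake-like": dict(estuary="chesapeake-like",
                                b_CT_temperature=0.04, b_CT_salinity=0.005,
                                b_PC=-2.0, driver="temperature"),
        "massbay-like": dict(estuary="massbay-like",
                             b_CT_temperature=0.03, b_CT_salinity=0.0,
                             b_PC=-1.5, driver="temperature"),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
    kwargs = dict(presets[name])
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@dataclass
class GroundTruth:
    """Generative parameters and their implied asymptotic correlations."""

    stations: pd.DataFrame = field(default_factory=pd.DataFrame)
    taxa: pd.DataFrame = field(default_factory=pd.DataFrame)


def _station_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for r in range(config.regions_per_estuary):
        for s in range(config.stations_per_region):
            rows.append({"estuary": config.estuary,
                         "region": f"region_{r + 1}",
                         "station": f"station_{r + 1}_{s + 1}"})
    return pd.DataFrame(rows)


def implied_correlations(config: SimConfig) -> dict[str, float]:
    """Asymptotic PT/CT/PC correlations of the generative model.

    Treats year as uniform over the span and propagates the variance of the
    annual-mean climate noise, the peak jitter, and the mid-month
    quantization of the extracted peak date.
    """
    Y = config.years
    var_t = (Y ** 2 - 1) / 12.0
    b_ct = {"temperature": config.b_CT_temperature,
            "salinity": config.b_CT_salinity}[config.driver]
    var_ca = config.sigma_climate ** 2 / 12.0      # annual mean of 12 months
    a = config.b_PT + config.b_PC * b_ct           # total phenology-time slope
    var_p = (a ** 2 * var_t + config.b_PC ** 2 * var_ca
             + config.sigma_peak ** 2 + QUANTIZATION_VAR)
    var_c = b_ct ** 2 * var_t + var_ca
    cov_pt = a * var_t
    cov_ct = b_ct * var_t
    cov_pc = a * b_ct * var_t + config.b_PC * var_ca
    return {
        "r_PT": cov_pt / np.sqrt(var_p * var_t),
        "r_CT": cov_ct / np.sqrt(var_c * var_t),
        "r_PC": cov_pc / np.sqrt(var_p * var_c),
    }


def simulate_climate(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Monthly temperature and salinity for every station.

    value = station baseline + trend·(year − mid) + seasonal sine + noise.
    """
    rng = np.random.default_rng(config.seed)
    stations = _station_table(config)
    years = np.arange(config.start_year, config.start_year + config.years)
    mid = years.mean()
    months = np.arange(1, 13)

    rows = []
    truth_rows = []
    for _, st in stations.iterrows():
        base_t = config.temp_baseline + rng.normal(0, 0.5)
        base_s = config.sal_baseline + rng.normal(0, 1.0)
        truth_rows.append({**st.to_dict(),
                           "temp_baseline": base_t, "sal_baseline": base_s,
                           "b_CT_temperature": config.b_CT_temperature,
                           "b_CT_salinity": config.b_CT_salinity})
        yy, mm = np.meshgrid(years, months, indexing="ij")
        phase = 2 * np.pi * (mm - 0.5) / 12 - np.pi / 2  # peak mid-summer
        temp = (base_t + config.b_CT_temperature * (yy - mid)
                + config.temp_season_amplitude * np.sin(phase)
                + rng.normal(0, config.sigma_climate, yy.shape))
        sal = (base_s + config.b_CT_salinity * (yy - mid)
               + config.sal_season_amplitude * np.sin(phase)
               + rng.normal(0, config.sigma_climate, yy.shape))
        rows.append(pd.DataFrame({
            "station": st["station"], "year": yy.ravel(), "month": mm.ravel(),
            "temperature": temp.ravel(), "salinity": sal.ravel()}))
    climate = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(stations=pd.DataFrame(truth_rows))
    return climate, truth


def simulate_abundance(config: SimConfig, climate: pd.DataFrame
                       ) -> tuple[pd.DataFrame, GroundTruth]:
    """Monthly abundance for every taxon × station, forced by the realized
    climate (the driving covariate's annual-mean anomaly)."""
    rng = np.random.default_rng(config.seed + 1)
    stations = _station_table(config)
    years = np.arange(config.start_year, config.start_year + config.years)
    mid = years.mean()

    annual = (climate.groupby(["station", "year"])[config.driver]
              .mean().unstack("year"))
    implied = implied_correlations(config)

    rows = []
    truth_rows = []
    for group in TROPHIC_GROUPS:
        for j in range(config.taxa_per_group):
            taxon = f"{group}_{j + 1}"
            mu0 = (config.mu0 if config.mu0 is not None
                   else float(rng.uniform(1, 365)))
            for _, st in stations.iterrows():
                station = st["station"]
                c = annual.loc[station, years].to_numpy()
                anomaly = c - c.mean()
                mu_y = (mu0 + config.b_PT * (years - mid)
                        + config.b_PC * anomaly
                        + rng.normal(0, config.sigma_peak, len(years)))
                truth_rows.append({
                    "taxon": taxon, "station": station,
                    "trophic_group": group, "mu0": mu0,
                    "b_PT": config.b_PT, "b_PC": config.b_PC,
                    "b_CT": {"temperature": config.b_CT_temperature,
                             "salinity": config.b_CT_salinity}[config.driver],
                    "driver": config.driver,
                    "true_peak_mean": float(np.mean(mu_y)), **implied})
                mids = np.array([[month_mid_doy(int(y), m)
                                  for m in range(1, 13)] for y in years],
                                dtype=float)                 # (years, 12)
                d = np.abs(mids - (mu_y[:, None] % YEAR))
                d = np.minimum(d, YEAR - d)                  # circular distance
                signal = config.amplitude * np.exp(
                    -d ** 2 / (2 * config.sigma_season ** 2))
                noise = (rng.lognormal(0, config.sigma_obs, d.shape)
                         if config.sigma_obs > 0 else np.ones(d.shape))
                detected = rng.random(d.shape) >= config.zero_inflation
                value = signal * noise * detected
                yy, mm = np.meshgrid(years, np.arange(1, 13), indexing="ij")
                rows.append(pd.DataFrame({
                    "estuary": st["estuary"], "region": st["region"],
                    "station": station, "taxon": taxon,
                    "trophic_group": group, "year": yy.ravel(),
                    "month": mm.ravel(), "value": value.ravel(),
                    "value_kind": "abundance"}))
    monitoring = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(taxa=pd.DataFrame(truth_rows))
    return monitoring, truth


def simulate(config: SimConfig
             ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (monitoring, climate, ground-truth) for one configuration."""
    climate, climate_truth = simulate_climate(config)
    monitoring, truth = simulate_abundance(config, climate)
    truth.stations = climate_truth.stations
    return monitoring, climate, truth


def simulate_effect_sets(m: int, beta_true, tau2_true, n_range=(10, 50),
                         seed: int = 0, sigma_from: str = "population"
                         ) -> tuple[list, pd.DataFrame]:
    """Draw effect-size triplets directly (test harness for the meta-model).

    True per-stratum effects come from MVN(beta_true, diag(tau2_true)) on
    the Fisher-z scale; observed triplets from MVN(true, Σ_i) with Σ_i the
    overlapping-correlation block at a year count n_i drawn uniformly from
    ``n_range``.

    ``sigma_from`` selects the correlations entering Σ_i: "population"
    (default) uses the correlations implied by the true fixed effects
    tanh(beta_true), keeping the GLS weights independent of the random
    effects so the estimator is exactly unbiased; "stratum" uses each
    stratum's own draw tanh(θ_i), which mimics the real pipeline (blocks
    estimated from the stratum's correlations) at the price of a small
    weight–effect correlation bias.
    """
    from .effect_sizes import EffectSizeTriplet  # local to avoid cycle noise

    beta_true = np.asarray(beta_true, dtype=float)
    tau2_true = np.asarray(tau2_true, dtype=float)
    if beta_true.shape != (3,) or tau2_true.shape != (3,):
        raise ValueError("beta_true and tau2_true must be 3-vectors")
    if (tau2_true < 0).any():
        raise ValueError("tau2_true must be non-negative")
    lo, hi = int(min(n_range)), int(max(n_range))
    if lo < 4:
        raise ValueError("n_range must stay >= 4")
    if sigma_from not in ("population", "stratum"):
        raise ValueError(f"unknown sigma_from {sigma_from!r}")

    rng = np.random.default_rng(seed)
    effects = []
    truth_rows = []
    for i in range(m):
        n = int(rng.integers(lo, hi + 1))
        theta = rng.normal(beta_true, np.sqrt(tau2_true))
        r = np.tanh(theta if sigma_from == "stratum" else beta_true)
        trip = CorrelationTriplet(p_PT=r[0], p_CT=r[1], p_PC=r[2], n=n)
        Sigma = build_block(trip)
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:  # PSD-boundary block
            L = np.linalg.cholesky(Sigma + 1e-10 * np.trace(Sigma) * np.eye(3))
        z_obs = theta + L @ rng.normal(size=3)
        effects.append(EffectSizeTriplet(
            z=z_obs, Sigma=Sigma, n=n, triplet=trip,
            stratum={"stratum": i, "taxon": f"taxon_{i}",
                     "station": f"station_{i}"}))
        truth_rows.append({"stratum": i, "n": n,
                           "theta_PT": theta[0], "theta_CT": theta[1],
                           "theta_PC": theta[2]})
    return effects, pd.DataFrame(truth_rows)
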