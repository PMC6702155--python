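"""Synthetic global soil-microbiome studies.

Generates complete studies — per-site daily weather, soil properties and
an ASV count table — with the statistical structure the downstream
analysis assumes, so that every stage of the pipeline can be exercised
and validated offline:

* a lognormal global species-abundance pool (most taxa globally rare);
* unimodal richness responses peaking at intermediate climatic water
  content (default 0.175) and near-neutral pH (default 7);
* a strong negative linear coupling between pH and soil wetness
  (climatically humid sites acidic, arid sites basic), calibrated to a
  target coefficient of determination (default 0.61);
* a suppression of globally rare taxa that strengthens with wetness
  above the richness peak, scaled by ``rare_sensitivity``;
* several samples per site sharing (almost) one coordinate so that
  0.1-degree aggregation is exercised.

All randomness flows from ``SimulationConfig.seed`` through keyed
`numpy` generator streams, so identical configurations reproduce
bit-identical studies regardless of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import SoilRecord, WeatherSeries, build_covariate_table
from .community import ASVTable

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "TrueParams",
    "simulate_weather",
    "simulate_soils",
    "simulate_community",
    "simulate_study",
]

# stream tags keeping the per-purpose RNG streams disjoint
_W, _SOIL, _PH, _POOL, _COMM = 1, 2, 3, 4, 5


@dataclass
class SimulationConfig:
    """Parameters of a synthetic study.

    The defaults mirror the observational conditions the pipeline is
    meant for: 320 sites spanning an aridity gradient, one to four
    samples per site (~2.5 on average, echoing the ~844 samples that
    aggregate to 320 sites), two years of daily weather, a pool of
    5,000 taxa sequenced at 10,000 reads per sample, richness peaking
    at CWC 0.175 and pH 7, and a pH–wetness coupling of R² = 0.61.
    """

    n_sites: int = 320
    samples_per_site_range: tuple[int, int] = (1, 4)
    n_days: int = 730
    species_pool_size: int = 5000
    read_depth: int = 10000
    richness_peak_cwc: float = 0.175
    richness_peak_ph: float = 7.0
    ph_coupling_r2: float = 0.61
    rare_sensitivity: float = 2.0
    seed: int = 0

    # secondary knobs (documented defaults; rarely moved)
    s_max: int | None = None             # richness scale at the joint optimum
                                         # (default: 40% of the species pool)
    log_richness_sd: float = 0.15        # lognormal noise on planted richness
    sad_sdlog: float = 2.0               # spread of the lognormal abundance pool
    rare_threshold: float = 5e-5         # global relative abundance cut for "rare"
    rare_penalty_slope: float = 4.0      # wetness-excess slope of rare suppression
    cwc_width: float = 0.12              # SD of the Gaussian CWC response
    ph_width: float = 1.5                # SD of the Gaussian pH response
    cwc_floor: float = 0.35              # response floor far from the CWC optimum
    ph_floor: float = 0.40               # response floor far from the pH optimum
    lat_range: tuple[float, float] = (-55.0, 65.0)
    lon_range: tuple[float, float] = (-180.0, 180.0)
    site_cluster_fraction: float = 0.15  # sites placed <0.03 deg from an earlier one
    archaea_fraction: float = 0.015
    unassigned_fraction: float = 0.005
    wet_day_prob_range: tuple[float, float] = (0.004, 0.60)
    rain_event_mean_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("need at least two sites")
        if self.species_pool_size < 10:
            raise ValueError("species pool must hold at least 10 taxa")
        if self.read_depth < 100:
            raise ValueError("read depth must be at least 100")
        if self.n_days < 365:
            raise ValueError("weather series must span at least one year")
        if not 0 < self.richness_peak_cwc < 1:
            raise ValueError("richness_peak_cwc must lie in (0, 1)")
        if not 0 < self.ph_coupling_r2 < 1:
            raise ValueError("ph_coupling_r2 must lie in (0, 1)")
        if self.rare_sensitivity < 1:
            raise ValueError("rare_sensitivity is a multiplier >= 1")
        lo, hi = self.samples_per_site_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid samples_per_site_range")


@dataclass
class TrueParams:
    """Generating quantities recorded for recovery checks."""

    pool_abundance: np.ndarray
    peak_cwc: float
    peak_ph: float
    cwc_width: float
    ph_width: float
    cwc_floor: float
    ph_floor: float
    s_max: int
    planted_richness: np.ndarray
    rare_taxa: np.ndarray

    def cwc_response(self, cwc) -> np.ndarray:
        return _bump(np.asarray(cwc, float), self.peak_cwc, self.cwc_width, self.cwc_floor)

    def ph_response(self, ph) -> np.ndarray:
        return _bump(np.asarray(ph, float), self.peak_ph, self.ph_width, self.ph_floor)


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    weather: dict[str, WeatherSeries]
    soils: dict[str, SoilRecord]
    coords: dict[str, tuple[float, float]]
    npp: dict[str, float]
    covariates: pd.DataFrame = field(repr=False)
    asv_table: ASVTable = field(repr=False)
    true_params: TrueParams = field(repr=False)


def _bump(x, peak, width, floor):
    """Unimodal Gaussian-shaped response with a distant floor."""
    return floor + (1.0 - floor) * np.exp(-0.5 * ((x - peak) / width) ** 2)


def _site_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def _site_profile(cfg: SimulationConfig, site_index: int) -> dict:
    """Latitude, longitude and aridity of a site (deterministic per seed)."""
    rng = np.random.default_rng([cfg.seed, _W, site_index, 0])
    lat = rng.uniform(*cfg.lat_range)
    lon = rng.uniform(*cfg.lon_range)
    if site_index > 0 and rng.random() < cfg.site_cluster_fraction:
        # snap next to an earlier site so some 0.1-degree cells host
        # samples from more than one site
        other = _site_profile(cfg, int(rng.integers(site_index)))
        lat = np.clip(other["lat"] + rng.uniform(-0.03, 0.03), -89.9, 89.9)
        lon = np.clip(other["lon"] + rng.uniform(-0.03, 0.03), -179.9, 179.9)
    aridity = rng.uniform(0.0, 1.0)
    return {"lat": float(lat), "lon": float(lon), "aridity": float(aridity)}


def simulate_weather(
    cfg: SimulationConfig,
    site_index: int,
    wet_day_prob: float | None = None,
    rain_amount_mm: float | None = None,
) -> WeatherSeries:
    """Daily weather series for one site.

    Wet days occur with a site-specific probability declining along the
    aridity gradient; wet-day amounts are gamma distributed (right
    skewed).  Temperature is a seasonal sinusoid around a
    latitude-dependent mean annual value and radiation a positive,
    latitude-dependent seasonal cycle.  ``wet_day_prob`` and a constant
    ``rain_amount_mm`` can be forced for degenerate scenarios.
    """
    if site_index < 0 or site_index >= cfg.n_sites:
        raise ValueError("site_index out of range")
    prof = _site_profile(cfg, site_index)
    rng = np.random.default_rng([cfg.seed, _W, site_index, 1])
    lat = prof["lat"]
    n = cfg.n_days
    lo, hi = cfg.wet_day_prob_range
    if wet_day_prob is None:
        # log-uniform along the aridity gradient: rainfall frequency
        # spans orders of magnitude between deserts and humid biomes
        p_wet = float(np.exp(np.log(lo) + (np.log(hi) - np.log(lo)) * (1.0 - prof["aridity"])))
    else:
        p_wet = wet_day_prob

    wet = rng.random(n) < p_wet
    if rain_amount_mm is None:
        amounts = rng.gamma(shape=0.7, scale=cfg.rain_event_mean_mm / 0.7, size=n)
    else:
        amounts = np.full(n, float(rain_amount_mm))
    precip = np.where(wet, amounts, 0.0)

    mat = 28.0 - 0.40 * abs(lat) + rng.normal(0.0, 1.5)
    t = np.arange(n)
    phase = 0.0 if lat >= 0 else np.pi
    season = np.sin(2 * np.pi * t / 365.25 - np.pi / 2 + phase)
    temp_amp = 2.0 + 0.30 * abs(lat)
    tmean = mat + temp_amp * season + rng.normal(0.0, 1.5, size=n)

    rad_mean = max(6.0, 27.0 - 0.22 * abs(lat))
    rad_amp = 0.14 * abs(lat)
    rad = np.maximum(0.3, rad_mean + rad_amp * season + rng.normal(0.0, 1.0, size=n))

    dates = pd.date_range("2000-01-01", periods=n, freq="D")
    return WeatherSeries(dates=dates, precip=precip, tmean=tmean, rad=rad)


def _texture_and_chem(cfg: SimulationConfig, site_index: int) -> dict:
    """Physical/chemical soil properties independent of pH."""
    rng = np.random.default_rng([cfg.seed, _SOIL, site_index])
    snd, slt, cly = rng.dirichlet([2.4, 2.0, 1.6])
    # renormalise so the stored fractions close exactly
    total = snd + slt + cly
    return {
        "SND": snd / total,
        "SLT": slt / total,
        "CLY": cly / total,
        "BLD": float(rng.uniform(1100.0, 1600.0)),
        "ORC": float(np.exp(rng.normal(2.5, 0.6))),
        "CEC": float(rng.uniform(5.0, 40.0)),
    }


def _ph_from_wetness(
    cfg: SimulationConfig, proxy: np.ndarray, noise_sd: float | None
) -> np.ndarray:
    """pH as a decreasing linear function of a wetness proxy.

    The deterministic part is ``8.4 - 6.5 * proxy``; the Gaussian noise
    SD is calibrated from the sample variance of the deterministic part
    so the realised coefficient of determination approaches
    ``cfg.ph_coupling_r2`` (noise_sd = 0 forces R² = 1).
    """
    det = 8.4 - 6.5 * proxy
    if noise_sd is None:
        r2 = cfg.ph_coupling_r2
        noise_sd = float(np.sqrt(np.var(det) * (1.0 - r2) / r2))
    rng = np.random.default_rng([cfg.seed, _PH])
    ph = det + rng.normal(0.0, noise_sd, size=proxy.size)
    return np.clip(ph, 3.2, 9.8)


def simulate_soils(
    cfg: SimulationConfig,
    cwc_proxy_per_site: np.ndarray,
    ph_noise_sd: float | None = None,
) -> list[SoilRecord]:
    """Soil records for all sites given a wetness proxy in (0, 1).

    Texture is Dirichlet (summing exactly to one), bulk density, carbon
    and CEC uniform/lognormal within plausible field ranges, and pH a
    noisy decreasing linear function of the proxy calibrated to the
    configured pH–wetness R².
    """
    proxy = np.asarray(cwc_proxy_per_site, dtype=float)
    if proxy.size != cfg.n_sites:
        raise ValueError("need one wetness proxy value per site")
    if np.any(proxy <= 0) or np.any(proxy >= 1):
        raise ValueError("wetness proxy values must lie strictly in (0, 1)")
    ph = _ph_from_wetness(cfg, proxy, ph_noise_sd)
    records = []
    for i in range(cfg.n_sites):
        phys = _texture_and_chem(cfg, i)
        records.append(SoilRecord(PH=float(ph[i]), **phys))
    return records


def _sample_ids(cfg: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Sample ids and their site indices (deterministic per seed)."""
    rng = np.random.default_rng([cfg.seed, _COMM, 0])
    lo, hi = cfg.samples_per_site_range
    per_site = rng.integers(lo, hi + 1, size=cfg.n_sites)
    ids, site_of = [], []
    for i, k in enumerate(per_site):
        for j in range(k):
            ids.append(f"S{i:04d}.{j}")
            site_of.append(i)
    return ids, np.asarray(site_of)


def simulate_community(cfg: SimulationConfig, covariates: pd.DataFrame) -> ASVTable:
    """ASV count table planted on the CWC and pH responses.

    A lognormal pool of ``species_pool_size`` taxa defines global
    relative abundances.  Each site realises ``round(s_max * f(CWC) *
    g(pH) * exp(eps))`` taxa, drawn without replacement with probability
    proportional to pool abundance; globally rare taxa (relative
    abundance below ``rare_threshold``) have their inclusion weight
    multiplied by a penalty decreasing linearly in ``CWC`` excess above
    the richness peak, scaled by ``rare_sensitivity``.  Reads are
    multinomial at ``read_depth`` per sample, and a small fraction of
    taxa carries ``Archaea`` / ``Unassigned`` labels for filter testing.
    """
    for colname in ("CWC", "PH"):
        if colname not in covariates.columns:
            raise KeyError(f"covariate table lacks required column {colname}")
    if len(covariates) != cfg.n_sites:
        raise ValueError("covariate table must have one row per site")

    pool_rng = np.random.default_rng([cfg.seed, _POOL])
    pool = pool_rng.lognormal(mean=0.0, sigma=cfg.sad_sdlog, size=cfg.species_pool_size)
    pool /= pool.sum()
    rare = pool < cfg.rare_threshold

    n_arch = int(round(cfg.archaea_fraction * cfg.species_pool_size))
    n_unas = int(round(cfg.unassigned_fraction * cfg.species_pool_size))
    labels = np.array(["Bacteria"] * cfg.species_pool_size, dtype=object)
    special = pool_rng.choice(cfg.species_pool_size, size=n_arch + n_unas, replace=False)
    labels[special[:n_arch]] = "Archaea"
    labels[special[n_arch:]] = "Unassigned"

    cwc = covariates["CWC"].to_numpy(dtype=float)
    ph = covariates["PH"].to_numpy(dtype=float)
    f = _bump(cwc, cfg.richness_peak_cwc, cfg.cwc_width, cfg.cwc_floor)
    g = _bump(ph, cfg.richness_peak_ph, cfg.ph_width, cfg.ph_floor)

    s_max = cfg.s_max if cfg.s_max is not None else int(0.4 * cfg.species_pool_size)
    rich_rng = np.random.default_rng([cfg.seed, _COMM, 1])
    eps = rich_rng.normal(0.0, cfg.log_richness_sd, size=cfg.n_sites)
    planted = np.round(s_max * f * g * np.exp(eps)).astype(int)
    planted = np.clip(planted, 10, cfg.species_pool_size)

    ids, site_of = _sample_ids(cfg)
    taxon_ids = [f"ASV{i:05d}" for i in range(cfg.species_pool_size)]
    counts = np.zeros((cfg.species_pool_size, len(ids)), dtype=np.int64)

    log_pool = np.log(pool)
    excess = np.maximum(0.0, cwc - cfg.richness_peak_cwc)
    for i in range(cfg.n_sites):
        srng = np.random.default_rng([cfg.seed, _COMM, 2, i])
        weights = log_pool.copy()
        penalty = max(1e-6, 1.0 - (cfg.rare_sensitivity - 1.0)
                      * cfg.rare_penalty_slope * excess[i])
        weights[rare] += np.log(penalty)
        # Gumbel top-k = weighted sampling without replacement
        keys = weights + srng.gumbel(size=cfg.species_pool_size)
        included = np.argpartition(-keys, planted[i] - 1)[: planted[i]]
        p_local = pool[included] / pool[included].sum()
        for j in np.flatnonzero(site_of == i):
            counts[included, j] = srng.multinomial(cfg.read_depth, p_local)

    coord_rng = np.random.default_rng([cfg.seed, _COMM, 3])
    meta_rows = []
    for sid, i in zip(ids, site_of):
        prof = _site_profile(cfg, int(i))
        meta_rows.append(
            {
                "sample": sid,
                "site": f"S{i:04d}",
                "lat": prof["lat"] + coord_rng.uniform(-0.02, 0.02),
                "lon": prof["lon"] + coord_rng.uniform(-0.02, 0.02),
                "depth_m": 0.1,
                "study": coord_rng.choice(["EMBL", "EMP", "ZHOU"]),
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("sample")
    table = ASVTable(
        counts=pd.DataFrame(counts, index=taxon_ids, columns=ids),
        kingdom=pd.Series(labels, index=taxon_ids, name="kingdom"),
        sample_meta=meta,
    )
    table.true_planted = planted  # attached for recovery checks
    return table


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Compose weather, soils and community into one synthetic study.

    Weather is generated per site; texture and climate determine AWC,
    PET, DRY and hence CWC; pH is then coupled to the realised CWC; the
    full covariate table is assembled through the climate module; and
    the community is planted on the realised CWC and pH values.
    """
    sites = _site_ids(cfg.n_sites)
    weather = {s: simulate_weather(cfg, i) for i, s in enumerate(sites)}
    coords = {
        s: (
            _site_profile(cfg, i)["lat"],
            _site_profile(cfg, i)["lon"],
        )
        for i, s in enumerate(sites)
    }

    # physical soil first, so AWC/CWC can be derived before pH coupling
    phys = [_texture_and_chem(cfg, i) for i in range(cfg.n_sites)]
    provisional = {
        s: SoilRecord(PH=7.0, **phys[i]) for i, s in enumerate(sites)
    }
    npp = {s: _miami_npp(weather[s]) for s in sites}
    cov0 = build_covariate_table(weather, provisional, npp, coords)
    cwc = cov0["CWC"].to_numpy()

    ph = _ph_from_wetness(cfg, cwc, noise_sd=None)
    soils = {
        s: SoilRecord(PH=float(ph[i]), **phys[i]) for i, s in enumerate(sites)
    }
    covariates = build_covariate_table(weather, soils, npp, coords)
    asv = simulate_community(cfg, covariates)
    pool_rng = np.random.default_rng([cfg.seed, _POOL])
    pool = pool_rng.lognormal(mean=0.0, sigma=cfg.sad_sdlog, size=cfg.species_pool_size)
    pool /= pool.sum()
    true = TrueParams(
        pool_abundance=pool,
        peak_cwc=cfg.richness_peak_cwc,
        peak_ph=cfg.richness_peak_ph,
        cwc_width=cfg.cwc_width,
        ph_width=cfg.ph_width,
        cwc_floor=cfg.cwc_floor,
        ph_floor=cfg.ph_floor,
        s_max=cfg.s_max if cfg.s_max is not None else int(0.4 * cfg.species_pool_size),
        planted_richness=np.asarray(asv.true_planted),
        rare_taxa=pool < cfg.rare_threshold,
    )
    return SyntheticStudy(
        config=cfg,
        weather=weather,
        soils=soils,
        coords=coords,
        npp=npp,
        covariates=covariates,
        asv_table=asv,
        true_params=true,
    )


def _miami_npp(series: WeatherSeries) -> float:
    """Net primary productivity proxy (g C m^-2 yr^-1), Miami-style:
    the minimum of a temperature- and a precipitation-limited term."""
    mat = float(np.mean(series.tmean))
    map_mm = float(np.mean(series.precip) * 365.25)
    npp_t = 3000.0 / (1.0 + np.exp(1.315 - 0.119 * mat))
    npp_p = 3000.0 * (1.0 - np.exp(-0.000664 * map_mm))
    return float(min(npp_t, npp_p) / 2.0)
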