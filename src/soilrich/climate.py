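"""Climatic and soil-hydrological covariates.

Derives the composite covariates used to explain soil bacterial richness
from per-site daily weather series and basic soil properties:

* **PET** — potential evapotranspiration (Jensen–Haise, temperature and
  shortwave radiation driven), clipped at zero.
* **DRY** — mean spacing in days between precipitation events, where an
  event is a day whose rainfall exceeds the daily-equivalent mean annual
  PET.
* **AWC** — available water capacity of the top metre of soil from a
  linear pedotransfer function of texture, organic carbon and bulk
  density.
* **CWC** — climatic water content: the time-averaged water content of a
  field-capacity store that refills fully at each rain event and is
  depleted exponentially by PET over a dry spell of length DRY.

The module also reduces covariate redundancy by hierarchical clustering
on Spearman-correlation distance (``1 - |rho_s|``) with a configurable
retention priority within clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = [
    "WeatherSeries",
    "SoilRecord",
    "ClusterReduction",
    "COVARIATE_NAMES",
    "DEFAULT_AWC_COEFFS",
    "DEFAULT_RETENTION_PRIORITY",
    "LATENT_HEAT_MJ_PER_KG",
    "DAYS_PER_YEAR",
    "pet_jensen_haise",
    "annual_pet",
    "detect_rain_events",
    "consecutive_dry_days",
    "awc_pedotransfer",
    "climatic_water_content",
    "build_covariate_table",
    "cluster_covariates",
]

#: latent heat of vaporisation used to convert MJ m^-2 day^-1 to mm/day
LATENT_HEAT_MJ_PER_KG = 2.45

#: mean Gregorian year length in days
DAYS_PER_YEAR = 365.25

#: the fifteen candidate covariates of the analysis
COVARIATE_NAMES = [
    "CWC", "PH", "MAT", "MAP", "PET", "DRY", "RAD", "NPP",
    "AWC", "BLD", "ORC", "SLT", "CLY", "SND", "CEC",
]

#: linear pedotransfer coefficients for AWC (volumetric fraction):
#: intercept, clay fraction, silt fraction, organic carbon (g kg^-1),
#: bulk density (kg m^-3).  A generic texture/carbon/density transfer;
#: AWC increases with clay, silt and carbon and decreases with packing.
DEFAULT_AWC_COEFFS = {
    "a0": 0.150,
    "a_cly": 0.30,
    "a_slt": 0.25,
    "a_orc": 0.002,
    "a_bld": -5.0e-5,
}

AWC_CLIP = (0.01, 0.45)

#: within-cluster retention order, most preferred first ("simpler
#: physical interpretation" made operational as an explicit list)
DEFAULT_RETENTION_PRIORITY = [
    "CWC", "PH", "MAT", "MAP", "PET", "DRY", "RAD", "NPP",
    "AWC", "SLT", "CLY", "ORC", "BLD", "CEC",
]


@dataclass
class WeatherSeries:
    """Daily weather at one site: precipitation (mm/day), mean air
    temperature (degC) and shortwave radiation (MJ m^-2 day^-1)."""

    dates: pd.DatetimeIndex
    precip: np.ndarray
    tmean: np.ndarray
    rad: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.precip = np.asarray(self.precip, dtype=float)
        self.tmean = np.asarray(self.tmean, dtype=float)
        self.rad = np.asarray(self.rad, dtype=float)
        n = len(self.dates)
        if not (len(self.precip) == len(self.tmean) == len(self.rad) == n):
            raise ValueError("weather vectors must have equal length")
        for name in ("precip", "tmean", "rad"):
            if np.any(~np.isfinite(getattr(self, name))):
                raise ValueError(f"missing or non-finite values in {name}")
        if np.any(self.precip < 0):
            raise ValueError("precipitation must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)


@dataclass
class SoilRecord:
    """Basic soil properties of one site.

    BLD kg m^-3, ORC g kg^-1, texture fractions (SND+SLT+CLY = 1),
    PH in pH units, CEC in cmol(+) kg^-1.
    """

    BLD: float
    ORC: float
    SLT: float
    CLY: float
    SND: float
    PH: float
    CEC: float

    def __post_init__(self) -> None:
        fracs = np.array([self.SND, self.SLT, self.CLY], dtype=float)
        if np.any(fracs < 0) or np.any(fracs > 1):
            raise ValueError("texture fractions must lie in [0, 1]")
        if abs(fracs.sum() - 1.0) > 1e-6:
            raise ValueError("SND + SLT + CLY must equal 1")
        if self.BLD <= 0:
            raise ValueError("bulk density must be positive")


@dataclass
class ClusterReduction:
    """Result of Spearman-distance covariate clustering."""

    distance: pd.DataFrame
    linkage: np.ndarray
    clusters: dict[str, int]
    retained: list[str]
    dropped: dict[str, str] = field(default_factory=dict)
    cut: float = 0.15


def pet_jensen_haise(tmean, rad):
    """Daily potential evapotranspiration (mm/day), Jensen–Haise.

    ``PET = max(0, (0.025 t + 0.08) * rad / lambda_w)`` with the latent
    heat lambda_w = 2.45 MJ kg^-1.  At very low temperatures the raw
    expression goes negative; such unphysical values are replaced by
    zero.
    """
    tmean = np.asarray(tmean, dtype=float)
    rad = np.asarray(rad, dtype=float)
    if np.any(rad < 0):
        raise ValueError("shortwave radiation must be non-negative")
    raw = (0.025 * tmean + 0.08) * rad / LATENT_HEAT_MJ_PER_KG
    return np.maximum(raw, 0.0)


def annual_pet(series: WeatherSeries) -> float:
    """Mean annual PET (mm/yr) by calendar aggregation.

    Daily PET is averaged within each of the 12 calendar months (pooled
    across years), the monthly means are averaged over the climatic
    year, and the resulting mean daily rate is scaled to a year.
    """
    daily = pet_jensen_haise(series.tmean, series.rad)
    monthly = pd.Series(daily, index=series.dates).groupby(series.dates.month).mean()
    return float(monthly.mean() * DAYS_PER_YEAR)


def detect_rain_events(series: WeatherSeries, pet_annual: float) -> np.ndarray:
    """Indices of days whose precipitation exceeds the PET threshold.

    A day is a rainfall event iff its precipitation exceeds the
    daily-equivalent mean annual PET (``pet_annual / 365.25``) — such
    events are expected to alter soil moisture conditions.
    """
    if pet_annual < 0:
        raise ValueError("annual PET must be non-negative")
    threshold = pet_annual / DAYS_PER_YEAR
    return np.flatnonzero(series.precip > threshold)


def consecutive_dry_days(events, n_days: int) -> float:
    """Mean spacing (days) between successive rainfall events.

    With fewer than two events the spacing is undefined and is capped at
    the series length (so DRY can exceed one year).  Events on
    consecutive days give a gap of one day; DRY is never below 1.
    """
    if n_days < 1:
        raise ValueError("series length must be at least one day")
    events = np.asarray(events, dtype=int)
    if events.size and (np.any(np.diff(events) <= 0) or events[0] < 0 or events[-1] >= n_days):
        raise ValueError("event indices must be sorted, unique and within range")
    if events.size < 2:
        return float(n_days)
    return float(max(np.diff(events).mean(), 1.0))


def awc_pedotransfer(soil: SoilRecord, coeffs: dict | None = None) -> float:
    """Available water capacity (volumetric fraction) of the top metre.

    Linear pedotransfer in clay, silt, organic carbon and bulk density
    only — soil chemistry (pH, CEC) is deliberately excluded so that AWC
    cannot leak chemical information into the wetness covariates.
    Clipped to [0.01, 0.45].
    """
    c = dict(DEFAULT_AWC_COEFFS)
    if coeffs:
        c.update(coeffs)
    raw = (
        c["a0"]
        + c["a_cly"] * soil.CLY
        + c["a_slt"] * soil.SLT
        + c["a_orc"] * soil.ORC
        + c["a_bld"] * soil.BLD
    )
    return float(np.clip(raw, *AWC_CLIP))


def climatic_water_content(
    awc: float, dry: float, pet_annual: float, depth: float = 1.0
) -> float:
    """Climatic water content (volumetric fraction).

    The top ``depth`` metres of soil refill to field capacity (AWC) at
    every rainfall event and are depleted exponentially by PET between
    events.  With drying rate ``k = (pet_annual/365.25) / (awc * depth
    * 1000)`` per day, CWC is the time average of the store over a dry
    spell of length DRY::

        CWC = awc * (1 - exp(-k * dry)) / (k * dry)

    For ``k * dry -> 0`` (no evaporative demand or instant re-wetting)
    the limit is AWC itself; CWC always lies in (0, awc].
    """
    if awc <= 0:
        raise ValueError("available water capacity must be positive")
    if dry < 0:
        raise ValueError("dry-spell length must be non-negative")
    if pet_annual < 0:
        raise ValueError("annual PET must be non-negative")
    k = (pet_annual / DAYS_PER_YEAR) / (awc * depth * 1000.0)
    kd = k * dry
    if kd < 1e-8:
        return float(awc)
    return float(awc * (1.0 - np.exp(-kd)) / kd)


def build_covariate_table(
    weather: dict[str, WeatherSeries],
    soils: dict[str, SoilRecord],
    npp: dict[str, float],
    coords: dict[str, tuple[float, float]],
    depth: float = 1.0,
    awc_coeffs: dict | None = None,
) -> pd.DataFrame:
    """Assemble the per-site table of all fifteen candidate covariates.

    MAT and RAD are series means, MAP the mean daily precipitation
    scaled to a 365.25-day year; PET, DRY, AWC and CWC follow the
    operations above.  Indexed by site id, with LAT/LON columns.
    """
    sites = sorted(weather)
    missing = [
        s
        for s in sites
        if s not in soils or s not in npp or s not in coords
    ] + [s for s in soils if s not in weather]
    if missing:
        raise KeyError(f"sites missing from one or more inputs: {sorted(set(missing))}")

    rows = []
    for site in sites:
        w = weather[site]
        soil = soils[site]
        pet_a = annual_pet(w)
        events = detect_rain_events(w, pet_a)
        dry = consecutive_dry_days(events, len(w))
        awc = awc_pedotransfer(soil, awc_coeffs)
        cwc = climatic_water_content(awc, dry, pet_a, depth=depth)
        lat, lon = coords[site]
        rows.append(
            {
                "SITE": site,
                "LAT": lat,
                "LON": lon,
                "CWC": cwc,
                "PH": soil.PH,
                "MAT": float(np.mean(w.tmean)),
                "MAP": float(np.mean(w.precip) * DAYS_PER_YEAR),
                "PET": pet_a,
                "DRY": dry,
                "RAD": float(np.mean(w.rad)),
                "NPP": float(npp[site]),
                "AWC": awc,
                "BLD": soil.BLD,
                "ORC": soil.ORC,
                "SLT": soil.SLT,
                "CLY": soil.CLY,
                "SND": soil.SND,
                "CEC": soil.CEC,
            }
        )
    return pd.DataFrame(rows).set_index("SITE")


def cluster_covariates(
    table: pd.DataFrame,
    cut: float = 0.15,
    priority: list[str] | None = None,
    drop: tuple[str, ...] = ("SND",),
) -> ClusterReduction:
    """Reduce covariate redundancy by Spearman-distance clustering.

    Pairwise distance is ``1 - |rho_s|``; covariates are merged by
    average linkage and the tree is cut at ``cut``.  Within each cluster
    a single covariate is retained according to ``priority``.  The sand
    fraction is removed beforehand: texture is compositional, so SND is
    fully determined by silt and clay.
    """
    if priority is None:
        priority = DEFAULT_RETENTION_PRIORITY
    cols = [c for c in COVARIATE_NAMES if c in table.columns]
    if len(table) < 3:
        raise ValueError("need at least three sites to estimate rank correlations")
    dropped: dict[str, str] = {}
    for d in drop:
        if d in cols:
            cols.remove(d)
            dropped[d] = "compositional closure (determined by SLT and CLY)"
    constant = [c for c in cols if table[c].nunique() <= 1]
    for c in constant:
        cols.remove(c)
        dropped[c] = "constant across sites"

    rho, _ = spearmanr(table[cols].to_numpy())
    rho = np.atleast_2d(rho)
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    dist_df = pd.DataFrame(dist, index=cols, columns=cols)

    linkage = average(squareform(dist, checks=False))
    labels = fcluster(linkage, t=cut, criterion="distance")
    clusters = dict(zip(cols, (int(v) for v in labels)))

    rank = {name: i for i, name in enumerate(priority)}
    retained = []
    for lab in sorted(set(labels)):
        members = [c for c in cols if clusters[c] == lab]
        keep = min(members, key=lambda c: rank.get(c, len(rank)))
        retained.append(keep)
        for m in members:
            if m != keep:
                dropped[m] = f"clustered with {keep} at distance cut {cut}"
    retained.sort(key=lambda c: rank.get(c, len(rank)))
    return ClusterReduction(
        distance=dist_df,
        linkage=linkage,
        clusters=clusters,
        retained=retained,
        dropped=dropped,
        cut=cut,
    )
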