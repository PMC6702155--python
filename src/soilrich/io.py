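"""Reading and writing the pipeline's on-disk formats.

Everything is plain text: one weather CSV per site (``date, precip_mm,
tmean_c, rad_mj_m2``), a single soils/covariates CSV, ASV tables as TSV
(taxa rows, sample columns) with a two-column taxonomy TSV, cluster
reductions as JSON, and prediction rasters as ESRI ASCII grids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import ClusterReduction, SoilRecord, WeatherSeries
from .community import ASVTable
from .stack import PredictionRaster

__all__ = [
    "write_weather", "read_weather",
    "write_soils", "read_soils",
    "write_asv_table", "read_asv_table",
    "write_study", "read_study",
    "write_clusters",
    "write_ascii_grid", "read_ascii_grid",
]

SOIL_COLUMNS = ["SITE", "LAT", "LON", "BLD", "ORC", "SLT", "CLY", "SND", "PH", "CEC", "NPP"]


def write_weather(series: WeatherSeries, path) -> None:
    df = pd.DataFrame(
        {
            "date": series.dates.strftime("%Y-%m-%d"),
            "precip_mm": series.precip,
            "tmean_c": series.tmean,
            "rad_mj_m2": series.rad,
        }
    )
    df.to_csv(path, index=False)


def read_weather(path) -> WeatherSeries:
    df = pd.read_csv(path, parse_dates=["date"])
    if df.isna().any().any():
        raise ValueError(f"missing values in weather file {path}")
    return WeatherSeries(
        dates=pd.DatetimeIndex(df["date"]),
        precip=df["precip_mm"].to_numpy(),
        tmean=df["tmean_c"].to_numpy(),
        rad=df["rad_mj_m2"].to_numpy(),
    )


def write_soils(soils: dict[str, SoilRecord], coords: dict, npp: dict, path) -> None:
    rows = []
    for site, rec in soils.items():
        lat, lon = coords[site]
        rows.append(
            {
                "SITE": site, "LAT": lat, "LON": lon,
                "BLD": rec.BLD, "ORC": rec.ORC, "SLT": rec.SLT, "CLY": rec.CLY,
                "SND": rec.SND, "PH": rec.PH, "CEC": rec.CEC, "NPP": npp[site],
            }
        )
    pd.DataFrame(rows, columns=SOIL_COLUMNS).to_csv(path, index=False)


def read_soils(path) -> tuple[dict[str, SoilRecord], dict, dict]:
    df = pd.read_csv(path)
    missing = [c for c in SOIL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"soil file lacks columns {missing}")
    soils, coords, npp = {}, {}, {}
    for _, row in df.iterrows():
        site = row["SITE"]
        soils[site] = SoilRecord(
            BLD=row["BLD"], ORC=row["ORC"], SLT=row["SLT"], CLY=row["CLY"],
            SND=row["SND"], PH=row["PH"], CEC=row["CEC"],
        )
        coords[site] = (float(row["LAT"]), float(row["LON"]))
        npp[site] = float(row["NPP"])
    return soils, coords, npp


def write_asv_table(table: ASVTable, counts_path, taxonomy_path, meta_path=None) -> None:
    table.counts.rename_axis("asv_id").to_csv(counts_path, sep="\t")
    table.kingdom.rename("kingdom").rename_axis("asv_id").to_csv(taxonomy_path, sep="\t")
    if meta_path is not None:
        table.sample_meta.rename_axis("sample").to_csv(meta_path, sep="\t")


def read_asv_table(counts_path, taxonomy_path, meta_path=None) -> ASVTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="asv_id")
    kingdom = pd.read_csv(taxonomy_path, sep="\t", index_col="asv_id")["kingdom"]
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    else:
        meta = pd.DataFrame(
            {"site": counts.columns, "lat": np.nan, "lon": np.nan},
            index=counts.columns,
        )
    return ASVTable(counts=counts, kingdom=kingdom, sample_meta=meta)


def write_study(study, out_dir) -> Path:
    """Write a synthetic study to a directory (weather/, soils.csv,
    covariates.csv, asv_counts.tsv, taxonomy.tsv, sample_meta.tsv)."""
    out = Path(out_dir)
    (out / "weather").mkdir(parents=True, exist_ok=True)
    for site, series in study.weather.items():
        write_weather(series, out / "weather" / f"{site}.csv")
    write_soils(study.soils, study.coords, study.npp, out / "soils.csv")
    study.covariates.to_csv(out / "covariates.csv")
    write_asv_table(
        study.asv_table,
        out / "asv_counts.tsv",
        out / "taxonomy.tsv",
        out / "sample_meta.tsv",
    )
    return out


def read_study(study_dir):
    """Read back the parts of a study directory needed downstream."""
    study_dir = Path(study_dir)
    weather = {
        p.stem: read_weather(p) for p in sorted((study_dir / "weather").glob("*.csv"))
    }
    soils, coords, npp = read_soils(study_dir / "soils.csv")
    covariates = pd.read_csv(study_dir / "covariates.csv", index_col="SITE")
    table = read_asv_table(
        study_dir / "asv_counts.tsv",
        study_dir / "taxonomy.tsv",
        study_dir / "sample_meta.tsv",
    )
    return {
        "weather": weather, "soils": soils, "coords": coords, "npp": npp,
        "covariates": covariates, "asv_table": table,
    }


def write_clusters(reduction: ClusterReduction, path) -> None:
    payload = {
        "cut": reduction.cut,
        "clusters": reduction.clusters,
        "retained": reduction.retained,
        "dropped": reduction.dropped,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_ascii_grid(raster: PredictionRaster, path) -> None:
    """Write an ESRI ASCII grid (plain-text georeferenced raster)."""
    values = raster.values
    nrows, ncols = values.shape
    cell = float(abs(raster.lon[1] - raster.lon[0])) if len(raster.lon) > 1 else 1.0
    xll = float(np.min(raster.lon) - cell / 2)
    yll = float(np.min(raster.lat) - cell / 2)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll}\n")
        fh.write(f"yllcorner {yll}\n")
        fh.write(f"cellsize {cell}\n")
        fh.write(f"nodata_value {raster.nodata}\n")
        np.savetxt(fh, values, fmt="%.4f")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    return values, header
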