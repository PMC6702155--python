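"""ASV-table processing and diversity estimation.

Implements the community side of the pipeline: taxonomic and singleton
filtering, rarefaction-depth grid search, repeated rarefaction with
averaging, Hill-number diversity, the rare/common log-ratio, spatial
aggregation of samples into 0.1-degree sites and between-biome rank-sum
comparisons.

The central container is :class:`ASVTable`: a taxa-by-samples count
matrix with a kingdom label per taxon and coordinates per sample.
Counts are integers before rarefaction averaging and real-valued after
(the element-wise mean over repeated rarefactions need not be integer).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import mannwhitneyu

__all__ = [
    "ASVTable",
    "GridSearchResult",
    "KINGDOMS",
    "RARE_THRESHOLD",
    "filter_taxa",
    "rarefy",
    "repeated_rarefaction",
    "grid_search_depth",
    "hill_diversity",
    "hill_profile",
    "rare_common_split",
    "log_ratio",
    "compute_diversity",
    "aggregate_sites",
    "compare_biomes",
]

KINGDOMS = ("Bacteria", "Archaea", "Unassigned")

#: global relative abundance below which a taxon counts as rare (0.005%)
RARE_THRESHOLD = 5e-5


@dataclass
class ASVTable:
    """Taxa-by-samples abundance table with taxonomy and sample metadata.

    ``counts`` has taxon ids as index and sample ids as columns;
    ``kingdom`` maps taxon id to its kingdom-level label; ``sample_meta``
    is indexed by sample id with at least ``site, lat, lon`` columns
    (``depth_m`` and ``study`` optional).
    """

    counts: pd.DataFrame
    kingdom: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if not self.counts.index.equals(self.kingdom.index):
            self.kingdom = self.kingdom.reindex(self.counts.index)
            if self.kingdom.isna().any():
                missing = self.kingdom.index[self.kingdom.isna()].tolist()
                raise ValueError(f"taxa without kingdom label: {missing[:5]}")
        extra = set(self.counts.columns) - set(self.sample_meta.index)
        if extra:
            raise ValueError(f"samples without metadata: {sorted(extra)[:5]}")
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_taxa(self, keep: pd.Index) -> "ASVTable":
        return ASVTable(self.counts.loc[keep], self.kingdom.loc[keep], self.sample_meta)

    def subset_samples(self, keep: list) -> "ASVTable":
        return ASVTable(self.counts[keep], self.kingdom, self.sample_meta.loc[keep])


@dataclass
class GridSearchResult:
    depth: int
    diagnostics: pd.DataFrame = field(repr=False)


def filter_taxa(table: ASVTable) -> tuple[ASVTable, dict[str, float]]:
    """Remove archaeal, kingdom-unassigned and globally singleton taxa.

    Archaea behave differently from bacteria and contribute only a small
    fraction of sequences; taxa that could not be assigned at kingdom
    level are unreliable; and taxa observed exactly once across all
    samples are likely residual errors.  Returns the filtered table and
    the fraction of taxa removed per rule.  Idempotent.
    """
    unknown = ~table.kingdom.isin(KINGDOMS)
    if unknown.any():
        raise ValueError(
            f"unknown kingdom labels for taxa: {table.kingdom.index[unknown].tolist()[:10]}"
        )
    n0 = table.n_taxa
    is_archaea = table.kingdom == "Archaea"
    is_unassigned = table.kingdom == "Unassigned"
    totals = table.counts.sum(axis=1)
    is_singleton = totals == 1
    removed = is_archaea | is_unassigned | is_singleton
    report = {
        "archaea": float(is_archaea.sum() / max(n0, 1)),
        "unassigned": float(is_unassigned.sum() / max(n0, 1)),
        "singletons": float((is_singleton & ~is_archaea & ~is_unassigned).sum() / max(n0, 1)),
        "retained": float((~removed).sum() / max(n0, 1)),
    }
    keep = table.counts.index[~removed]
    if len(keep) == 0:
        warnings.warn("all taxa removed by filtering; empty table returned")
    return table.subset_taxa(keep), report


def _rarefy_column(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``depth`` sequences without replacement from one sample."""
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def rarefy(table: ASVTable, depth: int, seed: int = 0) -> ASVTable:
    """Rarefy each sample to ``depth`` randomly drawn sequences.

    Sampling is multivariate hypergeometric (without replacement);
    samples with fewer than ``depth`` sequences are dropped with a
    warning.  Every retained column sums exactly to ``depth``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.counts.sum(axis=0)
    shallow = list(totals.index[totals < depth])
    if shallow:
        warnings.warn(f"dropping {len(shallow)} samples shallower than depth {depth}")
    kept = [c for c in table.counts.columns if c not in set(shallow)]
    out = {}
    for j, col in enumerate(kept):
        rng = np.random.default_rng([seed, 0, j])
        out[col] = _rarefy_column(table.counts[col].to_numpy(), depth, rng)
    counts = pd.DataFrame(out, index=table.counts.index)
    return ASVTable(counts, table.kingdom, table.sample_meta.loc[kept])


def repeated_rarefaction(
    table: ASVTable, depth: int, reps: int = 100, seed: int = 0
) -> ASVTable:
    """Average of ``reps`` independent rarefactions of the table.

    The averaged abundances are generally non-integer; averaging
    preserves the per-sample total, so every column still sums exactly
    to ``depth``.  Each (repetition, sample) pair uses an independent
    seeded stream, so the result does not depend on iteration order.
    """
    if reps < 1:
        raise ValueError("need at least one repetition")
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.counts.sum(axis=0)
    shallow = set(totals.index[totals < depth])
    if shallow:
        warnings.warn(f"dropping {len(shallow)} samples shallower than depth {depth}")
    kept = [c for c in table.counts.columns if c not in shallow]
    acc = np.zeros((table.n_taxa, len(kept)), dtype=float)
    raw = table.counts[kept].to_numpy().astype(np.int64)
    for rep in range(reps):
        for j in range(len(kept)):
            rng = np.random.default_rng([seed, rep + 1, j])
            acc[:, j] += _rarefy_column(raw[:, j], depth, rng)
    counts = pd.DataFrame(acc / reps, index=table.counts.index, columns=kept)
    return ASVTable(counts, table.kingdom, table.sample_meta.loc[kept])


def _expected_richness(counts: np.ndarray, depth: int) -> float:
    """Analytic expected richness of one sample under rarefaction.

    ``E[S] = sum_i 1 - C(C - c_i, d) / C(C, d)`` for sample total C and
    per-taxon counts c_i (hypergeometric inclusion probabilities).
    """
    c = counts[counts > 0].astype(np.int64)
    total = int(c.sum())
    if total < depth:
        return float("nan")
    # log C(total - c, depth) - log C(total, depth), guarded for c > total - depth
    keep = total - c >= depth
    log_miss = np.full(c.shape, -np.inf)
    tc = (total - c)[keep]
    log_miss[keep] = (
        gammaln(tc + 1)
        - gammaln(depth + 1)
        - gammaln(tc - depth + 1)
        - (gammaln(total + 1) - gammaln(depth + 1) - gammaln(total - depth + 1))
    )
    return float(np.sum(1.0 - np.exp(log_miss)))


def grid_search_depth(
    table: ASVTable,
    depths: list[int] | None = None,
) -> GridSearchResult:
    """Choose a rarefaction depth by grid search.

    For each candidate depth the diagnostics record the fraction of
    samples retained (total reads >= depth) and the mean analytic
    expected richness of retained samples.  The selected depth maximises
    ``retained_fraction * log(depth)`` — a documented trade-off between
    keeping samples and sampling each one deeply; the full diagnostic
    table is returned so other criteria can be applied.
    """
    if depths is None:
        depths = list(range(2500, 15001, 2500))
    depths = sorted(int(d) for d in depths)
    if not depths:
        raise ValueError("empty depth grid")
    totals = table.counts.sum(axis=0).to_numpy()
    raw = table.counts.to_numpy()
    rows = []
    for d in depths:
        retained = totals >= d
        frac = float(retained.mean()) if totals.size else 0.0
        if retained.any():
            mean_rich = float(
                np.mean([_expected_richness(raw[:, j], d) for j in np.flatnonzero(retained)])
            )
        else:
            mean_rich = float("nan")
        rows.append(
            {
                "depth": d,
                "n_retained": int(retained.sum()),
                "retained_fraction": frac,
                "mean_expected_richness": mean_rich,
                "score": frac * np.log(d),
            }
        )
    diag = pd.DataFrame(rows)
    best = diag.loc[diag["score"].idxmax(), "depth"]
    return GridSearchResult(depth=int(best), diagnostics=diag)


def hill_diversity(abund, q: float) -> float:
    """Hill number (effective species number) of order ``q``.

    With relative abundances p_i over the positive entries: q = 0 gives
    richness, q = 1 the exponential Shannon entropy (the q -> 1 limit),
    otherwise ``(sum p_i^q)^(1/(1-q))``.  Lower q weights rare taxa more.
    """
    a = np.asarray(abund, dtype=float)
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("diversity of an all-zero abundance vector is undefined")
    if q == 0:
        return float(a.size)
    p = a / a.sum()
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_profile(abund, q_orders) -> dict[float, float]:
    return {float(q): hill_diversity(abund, q) for q in q_orders}


def rare_common_split(table: ASVTable, threshold: float = RARE_THRESHOLD) -> pd.Series:
    """Flag each taxon rare (True) or common (False).

    Global relative abundance is the taxon's total across all samples
    divided by the grand total (computed on whatever table is passed —
    conventionally the averaged rarefied table); taxa strictly below
    ``threshold`` are rare.
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        raise ValueError("cannot split an empty table")
    totals = table.counts.sum(axis=1)
    rel = totals / totals.sum()
    return rel < threshold


def log_ratio(n_rare: float, n_common: float, correction: bool = True) -> float:
    """Log-ratio of rare to common species counts in one sample.

    Zero means a balanced sample (as many rare as common taxa), positive
    values an excess of rare taxa.  With ``correction`` a Haldane 1/2 is
    added to both counts so the ratio stays finite when one class is
    empty; when both counts are positive and ``correction`` is off the
    plain ``ln(n_rare / n_common)`` is returned.
    """
    if n_rare < 0 or n_common < 0:
        raise ValueError("counts must be non-negative")
    if correction:
        return float(np.log((n_rare + 0.5) / (n_common + 0.5)))
    return float(np.log(n_rare / n_common))


def compute_diversity(
    table: ASVTable,
    q_orders=(0.0, 1.0, 2.0),
    threshold: float = RARE_THRESHOLD,
    correction: bool = True,
) -> pd.DataFrame:
    """Per-sample diversity metrics on an (averaged) abundance table.

    A taxon is present in a sample iff its (mean) abundance is positive.
    Returns richness, Hill numbers for each requested order, rare and
    common presence counts and their log-ratio, indexed by sample id.
    """
    rare = rare_common_split(table, threshold)
    rows = {}
    for col in table.counts.columns:
        a = table.counts[col].to_numpy()
        present = a > 0
        n_rare = int(np.sum(present & rare.to_numpy()))
        n_common = int(np.sum(present & ~rare.to_numpy()))
        row = {"richness": float(present.sum())}
        for q in q_orders:
            row[f"hill_{q:g}"] = hill_diversity(a, q) if present.any() else 0.0
        row["n_rare"] = n_rare
        row["n_common"] = n_common
        row["log_ratio"] = log_ratio(n_rare, n_common, correction=correction)
        rows[col] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def aggregate_sites(sample_table: pd.DataFrame, cell: float = 0.1) -> pd.DataFrame:
    """Aggregate samples into ``cell``-degree grid cells ("sites").

    Cells are half-open with inclusive lower-left corner, keyed by
    ``(floor(lat/cell), floor(lon/cell))``.  Site metric values are the
    arithmetic means of the member samples, the representative
    coordinate is the member centroid, and ``n_samples`` records the
    member count.  ``sample_table`` must carry finite ``lat``/``lon``
    columns plus the metric columns to average.
    """
    lat = sample_table["lat"].to_numpy(dtype=float)
    lon = sample_table["lon"].to_numpy(dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("samples with non-finite coordinates")
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates outside [-90, 90] x [-180, 180]")
    numeric = sample_table.select_dtypes(include=[np.number]).copy()
    numeric["cell_lat"] = np.floor(lat / cell).astype(int)
    numeric["cell_lon"] = np.floor(lon / cell).astype(int)
    grouped = numeric.groupby(["cell_lat", "cell_lon"]).mean()
    grouped["n_samples"] = numeric.groupby(["cell_lat", "cell_lon"]).size()
    return grouped.reset_index()


def compare_biomes(values, labels) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between groups.

    Uses the exact null distribution for small untied samples and the
    tie-corrected normal approximation otherwise.  Returns one row per
    unordered group pair with group sizes and the p-value.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = {g: values[labels == g] for g in pd.unique(labels)}
    groups = {g: v for g, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("need at least two groups with two or more members")
    rows = []
    for a, b in itertools.combinations(groups, 2):
        res = mannwhitneyu(groups[a], groups[b], alternative="two-sided", method="auto")
        rows.append(
            {"group_a": a, "group_b": b, "n_a": groups[a].size, "n_b": groups[b].size,
             "p_value": float(res.pvalue)}
        )
    return pd.DataFrame(rows)
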