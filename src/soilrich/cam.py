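"""Causal additive model (CAM) structure learning with multi-split pruning.

Assumes each variable is generated as an additive smooth function of its
parents plus independent noise, with no hidden variables and no directed
cycles; under these assumptions the directed structure of a nonlinear
additive system is identifiable from observational data.

Structure search is a greedy edge insertion: repeatedly add the directed
edge that most improves the summed per-node penalized Gaussian
log-likelihood (additive regression of each node on its parents, small
unpenalized spline basis, BIC degree-of-freedom penalty) among edges not
creating a cycle, until no insertion improves the score.

Because the same data would otherwise be used both to select the graph
and to test it, pruning uses repeated sample splitting: on each split
the structure is learned on a random half and, on the other half, each
learned parent's contribution is tested by dropping its term from the
node's additive regression (F-test).  Per-edge p-values are aggregated
across splits by the quantile rule ``Q(gamma) = min(1, quantile_gamma
of p_b / gamma)`` at gamma = 0.5 (twice the median, capped at one);
splits where the edge was not learned contribute p = 1.  Edges with
aggregated p above the significance threshold are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .gam import _knots, bspline_design

__all__ = [
    "CausalGraph",
    "cam_order_search",
    "multisplit_prune",
    "direct_effects",
]


@dataclass
class CausalGraph:
    """Directed acyclic graph over covariates and the response."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    p_values: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha: float = 0.0005

    def parents(self, node: str) -> list[str]:
        return [a for a, b in self.edges if b == node]

    def to_dot(self) -> str:
        lines = ["digraph cam {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for a, b in self.edges:
            p = self.p_values.get((a, b))
            label = f' [label="p={p:.2g}"]' if p is not None else ""
            lines.append(f'  "{a}" -> "{b}"{label};')
        lines.append("}")
        return "\n".join(lines)


def _node_bases(data: pd.DataFrame, k: int) -> dict[str, np.ndarray]:
    """Centred unpenalized spline basis per variable (k-1 columns)."""
    bases = {}
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        B = bspline_design(x, _knots(x, k))
        B = B[:, 1:] - B[:, 1:].mean(axis=0)  # drop one column, centre
        bases[col] = B
    return bases


def _rss(y: np.ndarray, design: np.ndarray | None) -> float:
    yc = y - y.mean()
    if design is None or design.shape[1] == 0:
        return float(yc @ yc)
    beta, *_ = np.linalg.lstsq(design, yc, rcond=None)
    r = yc - design @ beta
    return float(r @ r)


def _stack(bases: dict[str, np.ndarray], parents: list[str]) -> np.ndarray | None:
    if not parents:
        return None
    return np.hstack([bases[p] for p in parents])


def _would_cycle(edges: set[tuple[str, str]], new: tuple[str, str]) -> bool:
    """True iff adding ``new`` creates a directed cycle (DFS from head)."""
    src, dst = new
    stack, seen = [dst], set()
    while stack:
        node = stack.pop()
        if node == src:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(b for a, b in edges if a == node)
    return False


def cam_order_search(
    data: pd.DataFrame,
    k: int = 6,
    max_parents: int = 4,
    bic_penalty: bool = True,
) -> CausalGraph:
    """Greedy edge-insertion search for the causal ordering.

    The score of a candidate edge i -> j is the gain in node j's
    Gaussian log-likelihood, ``n/2 * log(RSS_old / RSS_new)``, minus a
    BIC complexity charge of ``(log n)/2`` per added basis degree of
    freedom (the raw likelihood gain of an unpenalized regression is
    always positive, so the complexity charge is what makes "no
    positive gain" a meaningful stopping rule).  Insertion stops when
    no admissible edge has positive gain; edges creating a cycle or
    exceeding ``max_parents`` are inadmissible.  Deterministic given
    the data.
    """
    cols = [c for c in data.columns]
    keep = []
    for c in cols:
        if data[c].nunique() <= 1:
            warnings.warn(f"excluding constant column {c}")
        else:
            keep.append(c)
    data = data[keep]
    n, p = data.shape
    if p == 0:
        return CausalGraph(nodes=[], edges=[])
    if p > 1 and n <= 5 * p:
        warnings.warn(f"n = {n} is small for p = {p} variables (n > 5p recommended)")
    if np.any(~np.isfinite(data.to_numpy(dtype=float))):
        raise ValueError("missing or non-finite values in data")

    bases = _node_bases(data, k)
    df_term = next(iter(bases.values())).shape[1] if bases else 0
    y_arr = {c: data[c].to_numpy(dtype=float) for c in keep}
    parents: dict[str, list[str]] = {c: [] for c in keep}
    rss_now = {c: _rss(y_arr[c], None) for c in keep}
    edges: set[tuple[str, str]] = set()
    charge = (np.log(n) / 2.0) * df_term if bic_penalty else 0.0

    while True:
        best_gain, best_edge, best_rss = 0.0, None, None
        for j in keep:
            if len(parents[j]) >= max_parents:
                continue
            for i in keep:
                if i == j or i in parents[j] or (i, j) in edges:
                    continue
                if _would_cycle(edges, (i, j)):
                    continue
                rss_new = _rss(y_arr[j], _stack(bases, parents[j] + [i]))
                rss_new = max(rss_new, 1e-12)
                gain = 0.5 * n * np.log(rss_now[j] / rss_new) - charge
                if gain > best_gain:
                    best_gain, best_edge, best_rss = gain, (i, j), rss_new
        if best_edge is None:
            break
        i, j = best_edge
        edges.add(best_edge)
        parents[j].append(i)
        rss_now[j] = best_rss
    return CausalGraph(nodes=keep, edges=sorted(edges))


def _split_pvalues(
    train: pd.DataFrame, test: pd.DataFrame, k: int, max_parents: int
) -> dict[tuple[str, str], float]:
    """Learn structure on ``train``, test each learned parent on ``test``.

    For node j with learned parents P, each parent's p-value is the
    F-test of dropping its basis columns from the additive regression of
    j on P fitted to the held-out half.
    """
    graph = cam_order_search(train, k=k, max_parents=max_parents)
    bases = _node_bases(test, k)
    n = len(test)
    out: dict[tuple[str, str], float] = {}
    for j in graph.nodes:
        pars = graph.parents(j)
        if not pars:
            continue
        y = test[j].to_numpy(dtype=float)
        full = _stack(bases, pars)
        rss_full = _rss(y, full)
        df_full = full.shape[1] + 1
        if n - df_full < 2:
            for i in pars:
                out[(i, j)] = 1.0
            continue
        for i in pars:
            reduced = _stack(bases, [q for q in pars if q != i])
            rss_red = _rss(y, reduced)
            df_term = bases[i].shape[1]
            stat = ((rss_red - rss_full) / df_term) / (rss_full / (n - df_full))
            out[(i, j)] = float(f_dist.sf(max(stat, 0.0), df_term, n - df_full))
    return out


def multisplit_prune(
    data: pd.DataFrame,
    B: int = 100,
    alpha: float = 0.0005,
    k: int = 6,
    max_parents: int = 4,
    gamma: float = 0.5,
    seed: int = 0,
) -> CausalGraph:
    """Multi-split pruning of the CAM graph.

    ``B`` random 50/50 splits; structure is learned on one half and
    per-parent p-values computed on the other, then aggregated per edge
    by the gamma-quantile rule (splits where the edge was not learned
    contribute p = 1).  Edges with aggregated p <= ``alpha`` survive.
    The aggregation is a set operation over splits, so the result does
    not depend on split order.
    """
    if B < 2:
        raise ValueError("need at least two splits")
    if B < 20:
        warnings.warn("fewer than 20 splits gives unstable aggregated p-values")
    n = len(data)
    if n < 40:
        raise ValueError("multi-splitting needs at least 40 observations")
    half = n // 2
    all_p: dict[tuple[str, str], list[float]] = {}
    for b in range(B):
        rng = np.random.default_rng([seed, 7, b])
        perm = rng.permutation(n)
        train = data.iloc[perm[:half]].reset_index(drop=True)
        test = data.iloc[perm[half:]].reset_index(drop=True)
        pvals = _split_pvalues(train, test, k, max_parents)
        for edge, p in pvals.items():
            all_p.setdefault(edge, []).append(p)
    agg: dict[tuple[str, str], float] = {}
    for edge, ps in all_p.items():
        padded = np.ones(B)
        padded[: len(ps)] = sorted(ps)  # absent splits count p = 1
        padded.sort()
        q = np.quantile(padded, gamma)
        agg[edge] = float(min(1.0, q / gamma))
    edges = sorted(e for e, p in agg.items() if p <= alpha)
    return CausalGraph(nodes=list(data.columns), edges=edges, p_values=agg, alpha=alpha)


def direct_effects(graph: CausalGraph, response: str) -> list[str]:
    """Covariates linked to the response directly (its parents in the
    pruned graph), as opposed to those connected only via others."""
    if response not in graph.nodes:
        raise KeyError(f"response {response!r} not a node of the graph")
    return sorted(graph.parents(response))
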