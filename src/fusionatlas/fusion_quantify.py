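"""Normalized chimera expression, stage aggregation and correlation tests.

The expression unit for a chimeric RNA in one library is

    metric = log10( spanning_unique_reads / total_reads * 10^7 )

i.e. the depth-normalized spanning-read rate on a "reads per ten million"
scale, log-transformed. It is undefined at zero spanning reads (the record
is absent, not zero). The log base defaults to 10 and is configurable.

Developmental trend: distinct fusions of a chromosomal relation are counted
per library, averaged over replicates within each stage, and the stage means
are Pearson-correlated against day of differentiation (two-sided p from the
t distribution with n-2 df). The parent-vs-chimera question uses Spearman
rank correlation over paired (chimera metric, parental log expression)
observations, per fusion and pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fusion_classify import ClassifiedFusion
from .io_formats import FusionCall, SampleLibrary

__all__ = [
    "TrendResult",
    "CorrelationResult",
    "expression_metric",
    "expression_records",
    "stage_trend",
    "parent_chimera_correlation",
    "expression_heatmap_table",
]


@dataclass(frozen=True)
class TrendResult:
    r: float
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n_points: int
    flagged: str | None = None  # e.g. zero-variance counts


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n_pairs: int
    flagged: str | None = None


def expression_metric(
    spanning_unique_reads: int,
    total_reads: int,
    base: float = 10.0,
) -> float:
    """Normalized chimera expression; NaN signals "no evidence, undefined".

    ``log_base(su / total * 1e7)``; returns NaN when ``su == 0`` (the caller
    records the observation as absent) and raises when ``total <= 0``.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if spanning_unique_reads < 0:
        raise ValueError("spanning_unique_reads must be non-negative")
    if spanning_unique_reads == 0:
        return math.nan
    return math.log(spanning_unique_reads / total_reads * 1e7, base)


def expression_records(
    calls: Sequence[FusionCall],
    libraries: Sequence[SampleLibrary],
    base: float = 10.0,
) -> pd.DataFrame:
    """Tidy per-(fusion, sample) expression table.

    Columns: fusion_id, gene5, gene3, sample_id, stage_day,
    spanning_unique_reads, metric. Zero-read calls are retained with a NaN
    metric so downstream tables can distinguish absent from lowly expressed.
    """
    depth = {l.sample_id: l.total_reads for l in libraries}
    days = {l.sample_id: l.stage_day for l in libraries}
    rows = []
    for c in calls:
        if c.sample_id not in depth:
            raise KeyError(f"no library record for sample {c.sample_id!r}")
        rows.append(
            {
                "fusion_id": c.fusion_id,
                "gene5": c.gene5,
                "gene3": c.gene3,
                "sample_id": c.sample_id,
                "stage_day": days[c.sample_id],
                "spanning_unique_reads": c.spanning_unique_reads,
                "metric": expression_metric(c.spanning_unique_reads, depth[c.sample_id], base),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fusion_id", "gene5", "gene3", "sample_id", "stage_day",
            "spanning_unique_reads", "metric",
        ],
    )


# ---------------------------------------------------------------------------
# Developmental trend
# ---------------------------------------------------------------------------

def stage_trend(
    classified: Sequence[ClassifiedFusion],
    libraries: Sequence[SampleLibrary],
    relation: Literal["intra", "inter"] = "intra",
) -> TrendResult:
    """Pearson trend of distinct fusion counts against developmental day.

    Per library, distinct fusions (by fusion identity) of the requested
    chromosomal relation are counted; libraries of the same stage are
    averaged (replicate numbers may differ between stages), and the stage
    means are correlated with day. Needs >= 3 distinct stages.
    """
    if relation not in ("intra", "inter"):
        raise ValueError(f"relation must be 'intra' or 'inter', got {relation!r}")
    per_sample: dict[str, set[str]] = {l.sample_id: set() for l in libraries}
    day_of = {l.sample_id: l.stage_day for l in libraries}
    for c in classified:
        if c.chrom_relation == relation and c.call.sample_id in per_sample:
            per_sample[c.call.sample_id].add(c.call.fusion_id)

    by_stage: dict[int, list[int]] = {}
    for sample, fusions in per_sample.items():
        by_stage.setdefault(day_of[sample], []).append(len(fusions))
    if len(by_stage) < 3:
        raise ValueError(f"stage trend needs >= 3 distinct stages, got {len(by_stage)}")

    days = np.array(sorted(by_stage))
    means = np.array([np.mean(by_stage[d]) for d in days], dtype=float)

    if np.allclose(means, means[0]):
        return TrendResult(
            r=math.nan, r_squared=math.nan, p_value=math.nan,
            slope=0.0, intercept=float(means[0]), n_points=len(days),
            flagged="zero-variance counts",
        )
    res = stats.pearsonr(days, means)
    slope, intercept = np.polyfit(days, means, 1)
    r = float(res.statistic)
    return TrendResult(
        r=r, r_squared=r * r, p_value=float(res.pvalue),
        slope=float(slope), intercept=float(intercept), n_points=len(days),
    )


def stage_trend_permutation_p(
    classified: Sequence[ClassifiedFusion],
    libraries: Sequence[SampleLibrary],
    relation: Literal["intra", "inter"] = "intra",
    n_permutations: int = 999,
    seed: int = 0,
) -> float:
    """Permutation cross-check of the trend p-value (stage labels shuffled)."""
    base = stage_trend(classified, libraries, relation)
    rng = np.random.default_rng(seed)
    day_of = {l.sample_id: l.stage_day for l in libraries}
    hits = 0
    for _ in range(n_permutations):
        days = list(day_of.values())
        rng.shuffle(days)
        permuted = [
            SampleLibrary(l.sample_id, l.total_reads, d)
            for l, d in zip(libraries, days)
        ]
        r = stage_trend(classified, permuted, relation).r
        if not math.isnan(r) and abs(r) >= abs(base.r):
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Parent vs chimera correlation
# ---------------------------------------------------------------------------

def parent_chimera_correlation(
    expr: pd.DataFrame,
    parent_counts: pd.DataFrame,
    libraries: Sequence[SampleLibrary],
    base: float = 10.0,
    min_pairs: int = 4,
    parent_totals: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, CorrelationResult]:
    """Spearman correlation of chimera expression with parental expression.

    Parental expression uses the same normalization family as the chimera
    metric — ``log10(count / total * 1e7)`` — but with the parental
    quantification's own per-sample totals (the column sums of
    ``parent_counts``, overridable via ``parent_totals``): parental genes
    are counted by a separate alignment/quantification track, and
    normalizing both variables by one shared library total would correlate
    them through the common denominator alone. Each defined chimera
    observation contributes one pair per parental gene (5' and 3'). Returns
    per-(fusion, parent) correlations (pairs with >= ``min_pairs`` defined
    observations) and the pooled correlation over all pairs.
    """
    if parent_totals is None:
        parent_totals = parent_counts.sum(axis=0).to_dict()
    pairs: list[tuple[str, str, float, float]] = []  # fusion, parent, chimera, parent_expr
    for row in expr.itertuples(index=False):
        if math.isnan(row.metric):
            continue
        for parent in (row.gene5, row.gene3):
            if parent not in parent_counts.index:
                continue
            count = parent_counts.at[parent, row.sample_id]
            if count <= 0:
                continue
            pexpr = math.log(count / parent_totals[row.sample_id] * 1e7, base)
            pairs.append((row.fusion_id, parent, row.metric, pexpr))

    pair_df = pd.DataFrame(pairs, columns=["fusion_id", "parent", "chimera", "parent_expr"])
    if len(pair_df) < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} paired observations, got {len(pair_df)}"
        )

    per_rows = []
    for (fid, parent), grp in pair_df.groupby(["fusion_id", "parent"], sort=True):
        if len(grp) < min_pairs:
            continue
        rho, p, flag = _spearman(grp["chimera"].values, grp["parent_expr"].values)
        per_rows.append(
            {"fusion_id": fid, "parent": parent, "rho": rho, "p_value": p,
             "n_pairs": len(grp), "flagged": flag}
        )
    per_fusion = pd.DataFrame(
        per_rows, columns=["fusion_id", "parent", "rho", "p_value", "n_pairs", "flagged"]
    )

    rho, p, flag = _spearman(pair_df["chimera"].values, pair_df["parent_expr"].values)
    pooled = CorrelationResult(rho=rho, p_value=p, n_pairs=len(pair_df), flagged=flag)
    return per_fusion, pooled


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str | None]:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan, "constant vector"
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), None


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def expression_heatmap_table(
    expr: pd.DataFrame, group_by: Literal["isoform", "stage"] = "isoform"
) -> pd.DataFrame:
    """Fusion-isoform x stage matrix of mean metric values.

    Cells with no defined observation stay NaN (absent, not zero). Rows are
    ordered by total expression descending (NaN-safe), columns by day.
    """
    defined = expr.dropna(subset=["metric"])
    table = defined.pivot_table(
        index="fusion_id", columns="stage_day", values="metric", aggfunc="mean"
    )
    # re-add isoforms and stages with no defined cell at all
    missing = sorted(set(expr["fusion_id"]) - set(table.index))
    if missing:
        table = pd.concat(
            [table, pd.DataFrame(index=missing, columns=table.columns, dtype=float)]
        )
    all_stages = sorted(expr["stage_day"].dropna().unique())
    table = table.reindex(all_stages, axis=1)
    order = table.sum(axis=1, skipna=True).sort_values(ascending=False, kind="stable")
    table = table.loc[order.index]
    if group_by == "stage":
        table = table.T
    return table
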