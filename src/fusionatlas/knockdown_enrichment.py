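"""Statistics for the knockdown arm: differential expression, ORA, GSEA.

Differential expression is a deliberately simple, dependency-light test
matched to the downstream thresholding convention (|log2 fold change| > 1
and raw p < 0.05): per-gene Welch t-test on log2(CPM + 0.5) with
Benjamini-Hochberg FDR reported alongside the raw p-values.

Over-representation analysis (ORA) is the exact upper-tail hypergeometric
test of the overlap between a gene list and each gene set.

GSEA is implemented from scratch as the weighted Kolmogorov-Smirnov running
sum: walking the ranked gene list, set members increment the sum
proportionally to |score|^weight (normalized by the set total) and
non-members decrement by 1/(N - Nh); the enrichment score (ES) is the
maximal signed deviation. Because the intended designs have very few
samples per group, the null is built by gene-set label permutation (random
sets of matching size drawn from the ranked universe), not phenotype
permutation. NES divides ES by the mean |null ES| of matching sign;
empirical p-values use the same-signed null tail, and FDR follows the
standard pooled-null NES procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = [
    "DEResult",
    "EnrichmentResult",
    "differential_expression",
    "ora",
    "gsea",
    "enrichment_score",
    "marker_panel_table",
]

DEFAULT_LFC_CUT = 1.0
DEFAULT_P_CUT = 0.05


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEResult:
    gene: str
    log2_fold_change: float
    p_value: float
    fdr: float
    status: str  # 'up' | 'down' | 'ns'


def differential_expression(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    treatment: str = "knockdown",
    control: str = "control",
    lfc_cut: float = DEFAULT_LFC_CUT,
    p_cut: float = DEFAULT_P_CUT,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene log2 fold change and Welch t-test p on log2 CPM.

    ``counts`` is genes x samples (non-negative integers); ``groups`` maps
    each sample to its group label. Genes with all-zero counts are excluded
    from testing and returned separately. ``status`` applies the thresholds
    to the raw p-value (the convention of volcano-plot DEG calls); the BH
    FDR is reported alongside.
    """
    kd_samples = [s for s in counts.columns if groups.get(s) == treatment]
    ct_samples = [s for s in counts.columns if groups.get(s) == control]
    if len(kd_samples) < 2 or len(ct_samples) < 2:
        raise ValueError("each group needs >= 2 samples")
    mat = counts[kd_samples + ct_samples]
    if not np.issubdtype(mat.values.dtype, np.integer):
        if not np.allclose(mat.values, np.round(mat.values)):
            raise ValueError("counts must be integers")
    if (mat.values < 0).any():
        raise ValueError("counts must be non-negative")

    zero_mask = mat.sum(axis=1) == 0
    excluded = mat.index[zero_mask].tolist()
    mat = mat.loc[~zero_mask]

    cpm = mat / mat.sum(axis=0) * 1e6
    logcpm = np.log2(cpm + 0.5)
    kd, ct = logcpm[kd_samples].values, logcpm[ct_samples].values

    lfc = np.log2((cpm[kd_samples].mean(axis=1) + 0.5) / (cpm[ct_samples].mean(axis=1) + 0.5))
    tres = stats.ttest_ind(kd, ct, axis=1, equal_var=False)
    p = np.asarray(tres.pvalue, dtype=float)
    # zero variance in both groups: no evidence either way
    degenerate = np.isnan(p)
    p[degenerate & np.isclose(kd.mean(axis=1), ct.mean(axis=1))] = 1.0
    p = np.where(np.isnan(p), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]

    status = np.where(
        (p < p_cut) & (lfc > lfc_cut), "up",
        np.where((p < p_cut) & (lfc < -lfc_cut), "down", "ns"),
    )
    out = pd.DataFrame(
        {
            "gene": mat.index,
            "log2_fold_change": lfc.values,
            "p_value": p,
            "fdr": fdr,
            "status": status,
        }
    ).reset_index(drop=True)
    return out, excluded


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora(
    de_genes: Sequence[str],
    universe: Sequence[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``de_genes`` in each gene set.

    With a universe of M genes, K of them in the set and n DE genes of which
    k overlap the set, p is the upper-tail probability P(X >= k) of the
    hypergeometric distribution. Sets disjoint from the universe are skipped
    with a warning column rather than tested.
    """
    uni = set(universe)
    de = set(de_genes)
    if not de <= uni:
        raise ValueError("de_genes must be a subset of the universe")
    M, n = len(uni), len(de)
    rows = []
    for name, members in sets:
        in_uni = set(members) & uni
        K = len(in_uni)
        if K == 0:
            rows.append({"set": name, "set_size": 0, "overlap": 0,
                         "p_value": math.nan, "skipped": True})
            continue
        k = len(in_uni & de)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"set": name, "set_size": K, "overlap": k,
                     "p_value": p, "skipped": False})
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value", "skipped"])
    tested = ~df["skipped"]
    df["fdr"] = math.nan
    if tested.any():
        df.loc[tested, "fdr"] = multipletests(df.loc[tested, "p_value"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float
    set_size: int
    leading_edge: tuple[str, ...] = field(default=())


def enrichment_score(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0
) -> tuple[float, int]:
    """Weighted KS enrichment score of one set on a ranked score vector.

    ``scores`` must already be sorted in ranking order (descending);
    ``hit_mask`` marks set members. Returns (ES, index of the extremum).
    """
    n = len(scores)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("set must be a proper non-empty subset of the ranked list")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all member scores are exactly zero: fall back to unweighted
        hit_w = hit_mask.astype(float)
        denom = float(nh)
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~hit_mask) / (n - nh)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i]), i


def _null_es(
    scores: np.ndarray,
    set_size: int,
    weight: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES distribution for random sets of a given size (vectorized)."""
    n = len(scores)
    w = np.abs(scores) ** weight
    idx = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :set_size]
    hit = np.zeros((n_permutations, n), dtype=bool)
    np.put_along_axis(hit, idx, True, axis=1)
    hit_w = np.where(hit, w[None, :], 0.0)
    denom = hit_w.sum(axis=1, keepdims=True)
    denom[denom == 0] = set_size  # all-zero member scores: unweighted fallback
    p_hit = np.cumsum(hit_w, axis=1) / denom
    p_miss = np.cumsum(~hit, axis=1) / (n - set_size)
    dev = p_hit - p_miss
    i = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(n_permutations), i]


def gsea(
    ranking: pd.Series,
    sets: GeneSetCollection,
    n_permutations: int = 1000,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene set enrichment over a ranked gene list.

    ``ranking`` maps gene -> score (e.g. the DE log2 fold change); genes are
    ranked by descending score. Set-size bounds are applied after
    intersecting each set with the ranked universe. The permutation null
    (random same-size sets) is shared between sets of equal size, so the
    pooled-null FDR is well populated even with few sets.
    """
    ranking = ranking.sort_values(ascending=False, kind="mergesort")
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    n = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    kept: list[tuple[str, np.ndarray, int]] = []
    for name, members in sets:
        idx = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        if len(idx) < min_size or len(idx) > max_size:
            continue
        if len(idx) >= n:
            raise ValueError(f"set {name!r} covers the whole ranked list")
        kept.append((name, idx, len(idx)))

    null_by_size: dict[int, np.ndarray] = {}
    for _, _, size in kept:
        if size not in null_by_size:
            null_by_size[size] = _null_es(scores, size, weight, n_permutations, rng)

    results = []
    all_null_nes: list[np.ndarray] = []
    obs_nes: dict[str, float] = {}
    for name, idx, size in kept:
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es, peak = enrichment_score(scores, mask, weight)
        null = null_by_size[size]
        same_sign = null[null > 0] if es >= 0 else -null[null < 0]
        mean_same = same_sign.mean() if len(same_sign) else math.nan
        nes = es / mean_same if (mean_same and not math.isnan(mean_same)) else math.nan
        p = (float((same_sign >= abs(es)).sum()) + 1) / (len(same_sign) + 1)
        null_nes = np.concatenate([
            null[null > 0] / (null[null > 0].mean() if (null > 0).any() else 1.0),
            null[null < 0] / (abs(null[null < 0]).mean() if (null < 0).any() else 1.0),
        ])
        all_null_nes.append(null_nes)
        obs_nes[name] = nes
        if es >= 0:
            edge = tuple(genes[idx[idx <= peak]])
        else:
            edge = tuple(genes[idx[idx >= peak]])
        results.append(
            {"set": name, "set_size": size, "es": es, "nes": nes,
             "p_value": p, "leading_edge": ",".join(edge)}
        )

    df = pd.DataFrame(
        results, columns=["set", "set_size", "es", "nes", "p_value", "leading_edge"]
    )
    if len(df):
        pooled = np.concatenate(all_null_nes)
        obs = df["nes"].to_numpy()
        fdrs = []
        for nes in obs:
            if math.isnan(nes):
                fdrs.append(math.nan)
                continue
            if nes >= 0:
                null_frac = float((pooled >= nes).sum()) / max((pooled >= 0).sum(), 1)
                obs_frac = float((obs >= nes).sum()) / max((obs >= 0).sum(), 1)
            else:
                null_frac = float((pooled <= nes).sum()) / max((pooled < 0).sum(), 1)
                obs_frac = float((obs <= nes).sum()) / max((obs < 0).sum(), 1)
            fdrs.append(min(1.0, null_frac / obs_frac) if obs_frac > 0 else math.nan)
        df["fdr"] = fdrs
    else:
        df["fdr"] = []
    return df


# ---------------------------------------------------------------------------
# Marker panels
# ---------------------------------------------------------------------------

def marker_panel_table(
    de: pd.DataFrame, panels: GeneSetCollection
) -> pd.DataFrame:
    """Per-panel mean log2 fold change plus membership bookkeeping.

    Genes absent from the DE table are flagged (listed), never silently
    dropped; an empty intersection yields a flagged row with NaN mean.
    """
    by_gene = de.set_index("gene")["log2_fold_change"]
    rows = []
    for name, members in panels:
        present = [g for g in members if g in by_gene.index]
        missing = [g for g in members if g not in by_gene.index]
        mean_lfc = float(by_gene.loc[present].mean()) if present else math.nan
        rows.append(
            {
                "panel": name,
                "n_members": len(members),
                "n_present": len(present),
                "mean_lfc": mean_lfc,
                "missing_genes": ",".join(missing),
                "empty": len(present) == 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["panel", "n_members", "n_present", "mean_lfc", "missing_genes", "empty"],
    )
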