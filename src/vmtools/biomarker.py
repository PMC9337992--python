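"""Expression-sensitivity biomarker ranking and preranked GSEA.

Genes are ranked by the Pearson correlation between their (log-scale)
expression across cell lines and a per-line drug-sensitivity vector (AAC
by default; IC50 may be supplied instead).  The ranked statistic feeds a
weighted Kolmogorov-Smirnov preranked enrichment analysis: hits in a set
advance a running sum by |r|^p normalized over the set's hits, misses
retreat it by 1/(N - |S|), and the enrichment score is the extremum of the
running sum.  Significance comes from permuting gene labels of the ranked
statistic (the only permutation scheme available to a preranked input);
the normalized enrichment score (NES) divides the observed ES by the mean
magnitude of same-sign null scores, and false-discovery rates are
Benjamini-Hochberg across the tested sets.

Group-wise differential expression (sensitive vs resistant, treated vs
control) uses Welch's unequal-variance t-test per gene with BH adjustment.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .drug_response import SensitivityProfile

logger = logging.getLogger(__name__)

__all__ = [
    "RankedGeneList", "GseaResult", "correlate_sensitivity",
    "gsea_preranked", "group_differential", "top_pathways", "bh_adjust",
]


@dataclass
class RankedGeneList:
    """Genes ordered by correlation with sensitivity (rank 1 = highest r)."""

    table: pd.DataFrame       # index gene; columns r, rank
    n_lines: int
    metadata: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


@dataclass
class GseaResult:
    """Per-set ES/NES/p/FDR table plus leading-edge membership."""

    table: pd.DataFrame       # index set name; es, nes, p_value, fdr, set_size
    leading_edge: dict[str, list[str]]
    metadata: dict = field(default_factory=dict)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


# ------------------------------------------------------- ranking genes

def correlate_sensitivity(expr: pd.DataFrame,
                          sensitivity: SensitivityProfile | pd.Series,
                          metric: str = "aac") -> RankedGeneList:
    """Rank genes by Pearson correlation with a sensitivity vector.

    ``expr`` is genes x cell lines on a log scale.  Correlations use the
    lines shared between the matrix and the profile (>=3 required).  Genes
    with zero expression variance get r = 0 by convention and rank after
    every nonzero-variance gene; ties break lexicographically by gene
    identifier.
    """
    if isinstance(sensitivity, SensitivityProfile):
        if metric == "aac":
            vec = sensitivity.aac
        elif metric == "ic50":
            if sensitivity.ic50 is None:
                raise ValueError("profile has no IC50 values")
            vec = sensitivity.ic50.dropna()
        else:
            raise ValueError(f"unknown metric {metric!r}")
    else:
        vec = sensitivity.astype(float)
    shared = [c for c in expr.columns if c in vec.index]
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared cell lines, have {len(shared)}")
    x = expr[shared].to_numpy(dtype=float)
    s = vec[shared].to_numpy(dtype=float)
    s_c = s - s.mean()
    x_c = x - x.mean(axis=1, keepdims=True)
    denom = np.sqrt((x_c ** 2).sum(axis=1)) * np.sqrt((s_c ** 2).sum())
    num = x_c @ s_c
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    tab = pd.DataFrame({"r": r, "zero_var": denom == 0, "gene": expr.index},
                       index=expr.index)
    # r descending; zero-variance genes after all others; gene id tiebreak
    tab = tab.sort_values(["zero_var", "r", "gene"],
                          ascending=[True, False, True], kind="stable")
    tab["rank"] = np.arange(1, len(tab) + 1)
    return RankedGeneList(table=tab[["r", "rank"]], n_lines=len(shared),
                          metadata={"metric": metric, "lines": shared})


# ------------------------------------------------------------- GSEA core

def _es_running(r_abs_w: np.ndarray, hit_mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Enrichment score and running sum for one hit configuration.

    ``r_abs_w`` holds |r_i|^p for every position of the ranked list,
    ``hit_mask`` marks set members.  Hits add their weight normalized over
    hit weights; misses subtract 1/(N - |S|).  ES is the running-sum value
    of largest magnitude.
    """
    n = r_abs_w.size
    n_hit = int(hit_mask.sum())
    n_miss = n - n_hit
    w_hit = r_abs_w * hit_mask
    denom = w_hit.sum()
    if denom == 0:  # weight_p>0 with all-zero statistic inside the set
        w_hit = hit_mask.astype(float)
        denom = float(n_hit)
    steps = w_hit / denom - (~hit_mask) / n_miss
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def gsea_preranked(ranked: RankedGeneList, sets: dict[str, list[str]],
                   weight_p: float = 1.0, n_perm: int = 1000,
                   seed: int = 0, min_size: int = 2) -> GseaResult:
    """Preranked GSEA over a gene-set collection.

    Sets are intersected with the ranked universe; sets smaller than
    ``min_size`` after intersection, or spanning the whole universe (the
    miss step 1/(N-|S|) is undefined), are skipped with a warning.  The
    null distribution permutes hit positions (gene labels) with a seeded
    generator shared across sets so set-to-set comparisons use the same
    draws.  p is computed within the sign class of the observed ES:
    p = (1 + #{same-sign null >= |observed|}) / (#same-sign null + 1),
    which keeps null p-values uniform (the positive and negative running-sum
    extrema have different null scales, so pooling the classes would bias p).

    When the number of distinct hit configurations C(N, |S|) does not
    exceed ``n_perm``, the null is enumerated exhaustively instead of
    sampled, giving an exact permutation p (the observed configuration is
    one of those enumerated, so p > 0); the result metadata records which
    null was used per set.
    """
    genes = ranked.genes
    n = len(genes)
    r = ranked.table["r"].to_numpy(dtype=float)
    r_abs_w = np.abs(r) ** weight_p
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    leading: dict[str, list[str]] = {}
    for name, members in sets.items():
        hit_idx = sorted({pos[g] for g in members if g in pos})
        k = len(hit_idx)
        if k < min_size:
            warnings.warn(f"gene set {name!r} has {k} genes in the universe; skipped")
            logger.warning("set %s skipped: %d genes after intersection", name, k)
            continue
        if k == n:
            warnings.warn(f"gene set {name!r} spans the whole universe; skipped")
            logger.warning("set %s skipped: spans universe", name)
            continue
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[hit_idx] = True
        es, running = _es_running(r_abs_w, hit_mask)

        exhaustive = math.comb(n, k) <= n_perm
        if exhaustive:
            null_es = np.empty(math.comb(n, k))
            for b, combo in enumerate(itertools.combinations(range(n), k)):
                perm_mask = np.zeros(n, dtype=bool)
                perm_mask[list(combo)] = True
                null_es[b], _ = _es_running(r_abs_w, perm_mask)
        else:
            null_es = np.empty(n_perm)
            for b in range(n_perm):
                perm_mask = np.zeros(n, dtype=bool)
                perm_mask[rng.choice(n, size=k, replace=False)] = True
                null_es[b], _ = _es_running(r_abs_w, perm_mask)
        # p is computed within the sign class of the observed ES (the
        # positive and negative extrema have different null scales)
        same_sign = (null_es if es >= 0 else -null_es)
        same_sign = same_sign[same_sign > 0]
        n_ge = int(np.sum(same_sign >= abs(es)))
        if exhaustive:
            # the observed configuration is among those enumerated
            p = n_ge / max(1, same_sign.size)
        else:
            p = (1.0 + n_ge) / (same_sign.size + 1.0)
        mean_mag = float(np.mean(same_sign)) if same_sign.size else np.nan
        nes = es / mean_mag if (np.isfinite(mean_mag) and mean_mag > 0) else np.nan

        # leading edge: members at or before the extremum (positive ES) /
        # at or after it (negative ES)
        i_ext = int(np.argmax(np.abs(running)))
        if es >= 0:
            le = [genes[i] for i in hit_idx if i <= i_ext]
        else:
            le = [genes[i] for i in hit_idx if i >= i_ext]
        leading[name] = le
        rows.append({"set": name, "es": es, "nes": nes, "p_value": p,
                     "set_size": k, "null_exhaustive": exhaustive})

    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["es", "nes", "p_value", "set_size"])
    if len(table):
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["fdr"] = pd.Series(dtype=float)
    return GseaResult(table=table, leading_edge=leading,
                      metadata={"weight_p": weight_p, "n_perm": n_perm,
                                "seed": seed,
                                "statistic": "weighted-KS preranked",
                                "null": "gene-label permutation"})


# --------------------------------------------- group differential summary

def group_differential(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Welch t-test per gene between two groups of lines.

    ``labels`` maps line -> group; exactly two groups, each with >=2 lines.
    The input is assumed log-scale, so log2 fold change is the difference
    of group means (group A = first label in sorted order, minus group B).
    Returns a per-gene table with log2_fc, t_stat, p_value, fdr.
    """
    labels = labels[[c for c in labels.index if c in expr.columns]]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    a_cols = labels.index[labels == groups[0]]
    b_cols = labels.index[labels == groups[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs >=2 lines")
    a = expr[a_cols].to_numpy(dtype=float)
    b = expr[b_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    # zero-variance genes with equal means: no evidence of change
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    out = pd.DataFrame({"log2_fc": lfc, "t_stat": t, "p_value": p}, index=expr.index)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out


def top_pathways(gsea: GseaResult, k: int = 9) -> pd.DataFrame:
    """First ``k`` pathways by NES descending; ties by FDR ascending, then name."""
    if k < 1:
        raise ValueError("k must be >=1")
    tab = gsea.table.copy()
    if len(tab):
        tab = tab.reset_index(names="set")
        tab = tab.sort_values(["nes", "fdr", "set"],
                              ascending=[False, True, True],
                              kind="stable").set_index("set")
    return tab.head(k)
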