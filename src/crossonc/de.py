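"""Deletion-status differential expression and gene-set over-representation.

The DE stage mirrors the downstream analysis this platform feeds: per-gene
two-sample t tests between deletion-status groups (Welch by default, pooled
optionally), Benjamini–Hochberg FDR across genes, and significance at
``p < 0.05 AND q < 0.1``.  Over-representation of DE genes in gene sets uses a
one-sided Fisher exact (hypergeometric upper tail) against a user-supplied
background, replacing web-service enrichment with the same statistical core.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["welch_t", "bh_fdr", "differential_genes", "ora_fisher"]


def _t_arrays(
    A: np.ndarray, B: np.ndarray, pooled: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-sample t over rows of (genes x samples) group blocks.

    Rows with zero variance in both groups and equal means get t=0, p=1
    (retained, not dropped).
    """
    nA, nB = A.shape[1], B.shape[1]
    mA, mB = A.mean(axis=1), B.mean(axis=1)
    vA = A.var(axis=1, ddof=1)
    vB = B.var(axis=1, ddof=1)
    diff = mA - mB
    if pooled:
        sp2 = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
        se2 = sp2 * (1.0 / nA + 1.0 / nB)
        df = np.full_like(se2, float(nA + nB - 2))
    else:
        se2 = vA / nA + vB / nB
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((vA / nA) ** 2 / (nA - 1) + (vB / nB) ** 2 / (nB - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    degenerate = se2 <= 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    df = np.where(degenerate | ~np.isfinite(df), float(nA + nB - 2), df)
    p = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), df)
    )
    p = np.where(degenerate & (diff == 0), 1.0, p)
    return t, df, p


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Unequal-variance two-sample t with Welch–Satterthwaite df; two-sided p.

    Degenerate case (zero variance in both groups, equal means) returns
    ``(0, nA+nB-2, 1)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("values must be finite")
    t, df, p = _t_arrays(a[None, :], b[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotonised, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_genes(
    expr: pd.DataFrame,
    status: Mapping[str, str] | pd.Series,
    p_threshold: float = 0.05,
    q_threshold: float = 0.1,
    deleted_label: str = "deleted",
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-gene DE table between deletion-status groups.

    ``expr`` is genes x samples; ``status`` maps each sample column to
    ``deleted_label`` or anything else (wild type).  Output columns: group
    means, log fold-change (deleted - wild-type), t, df, p, q, ``neg_log10_p``
    (volcano y-axis) and ``significant`` (p < p_threshold AND q < q_threshold);
    rows ranked by p.
    """
    status = pd.Series(status)
    missing = [s for s in expr.columns if s not in status.index]
    if missing:
        raise ValueError(f"samples without status label: {missing[:5]}")
    lab = status.loc[list(expr.columns)]
    del_cols = list(expr.columns[(lab == deleted_label).to_numpy()])
    wt_cols = list(expr.columns[(lab != deleted_label).to_numpy()])
    if len(del_cols) < 2 or len(wt_cols) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(del_cols)} deleted / {len(wt_cols)} wild-type"
        )
    A = expr[del_cols].to_numpy(dtype=float)
    B = expr[wt_cols].to_numpy(dtype=float)
    t, df, p = _t_arrays(A, B, pooled=pooled)
    q = bh_fdr(p)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(np.maximum(p, np.finfo(float).tiny))
    out = pd.DataFrame(
        {
            "mean_deleted": A.mean(axis=1),
            "mean_wildtype": B.mean(axis=1),
            "lfc": A.mean(axis=1) - B.mean(axis=1),
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "neg_log10_p": nlp,
            "significant": (p < p_threshold) & (q < q_threshold),
        },
        index=expr.index,
    )
    return out.sort_values("p", kind="stable")


def ora_fisher(
    query: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of a query gene list.

    Sets are intersected with the background; the query must be a subset of
    the background.  p is the hypergeometric upper tail
    ``P(overlap >= observed)``; q is BH across sets; rows ranked by p.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background gene universe is empty")
    q_genes = set(query)
    stray = q_genes - bg
    if stray:
        raise ValueError(f"query genes not in background: {sorted(stray)[:5]}")
    N, n = len(bg), len(q_genes)
    rows = []
    for name, members in gene_sets.items():
        S = set(members) & bg
        K = len(S)
        k = len(S & q_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else 0.0
        rows.append((name, k, K, N, odds, p))
    df = pd.DataFrame(
        rows, columns=["gene_set", "overlap", "set_size", "background_size", "odds_ratio", "p"]
    ).set_index("gene_set")
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df.sort_values("p", kind="stable")
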