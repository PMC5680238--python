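"""AGO2-RIP differential association analysis.

Compares two conditions (e.g. the AGO2-immunoprecipitated fraction of
IL-1β-treated vs control cells, or RIP vs matched input) per miRNA
variant.  For each variant we report the M-A coordinates —
M = log2 fold change of condition B over A, A = mean log2 abundance —
a two-sided Fisher's exact p-value on pooled counts against library
sizes, a Benjamini-Hochberg q-value, and the candidate-selection flag:
mean count above a floor (default 1000 reads), |log2FC| >= 1 and
q <= 0.05.

Fisher's exact on pooled counts is an exact, replicate-free test; the
test is pluggable so a replicate-aware alternative (e.g. a negative
binomial model) can be swapped in when the design supports one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountTable, VariantKey

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class SelectionFilter:
    """Candidate filter: expressed above a floor, >=2-fold, significant."""

    min_mean_count: float = 1000.0
    min_abs_l2fc: float = 1.0
    max_q: float = 0.05


def ma_values(
    cpm_a: float | np.ndarray,
    cpm_b: float | np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[np.ndarray, np.ndarray]:
    """M-A coordinates: M = log2((b+c)/(a+c)), A = mean of the two log2s."""
    a = np.asarray(cpm_a, dtype=float)
    b = np.asarray(cpm_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("abundances must be nonnegative")
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    return lb - la, 0.5 * (la + lb)


def enrichment_test(
    count_a: int, count_b: int, libsize_a: int, libsize_b: int
) -> float:
    """Two-sided Fisher's exact test of a variant's proportion between libraries.

    The 2x2 table is [[count_a, libsize_a - count_a],
                      [count_b, libsize_b - count_b]].
    """
    if libsize_a <= 0 or libsize_b <= 0:
        raise ValueError("library sizes must be positive")
    if count_a > libsize_a or count_b > libsize_b:
        raise ValueError("counts cannot exceed library sizes")
    table = [[count_a, libsize_a - count_a], [count_b, libsize_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_enrichment(
    table: CountTable,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_total_count: float = 1.0,
    test: Callable[[int, int, int, int], float] = enrichment_test,
) -> pd.DataFrame:
    """Per-variant M/A, p and q for condition B vs condition A.

    Counts are pooled (summed) within each condition; M/A use
    CPM-scale means so M is a library-size-corrected log2 fold change.
    Variants whose pooled count across both conditions falls below
    ``min_total_count`` are dropped before testing (they carry no
    information and only dilute the BH correction).
    """
    counts = table.counts
    missing = [s for s in [*samples_a, *samples_b] if s not in counts.columns]
    if missing:
        raise ValueError(f"samples not in count table: {missing}")
    pooled_a = counts[list(samples_a)].sum(axis=1)
    pooled_b = counts[list(samples_b)].sum(axis=1)
    lib_a = float(pooled_a.sum())
    lib_b = float(pooled_b.sum())
    keep = (pooled_a + pooled_b) >= min_total_count
    pooled_a, pooled_b = pooled_a[keep], pooled_b[keep]

    # CPM-scale means for fold change / abundance coordinates
    cpm_a = pooled_a / lib_a * 1e6
    cpm_b = pooled_b / lib_b * 1e6
    M, A = ma_values(cpm_a.to_numpy(), cpm_b.to_numpy(), pseudocount)

    ia = np.rint(pooled_a.to_numpy()).astype(np.int64)
    ib = np.rint(pooled_b.to_numpy()).astype(np.int64)
    la = int(round(lib_a))
    lb = int(round(lib_b))
    p = np.array([test(a_i, b_i, la, lb) for a_i, b_i in zip(ia, ib)])
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "mean_count_a": cpm_a,
            "mean_count_b": cpm_b,
            "pooled_count_a": pooled_a,
            "pooled_count_b": pooled_b,
            "M": M,
            "A": A,
            "p": p,
            "q": q,
        },
        index=pooled_a.index,
    )


def select_candidates(
    records: pd.DataFrame, filt: SelectionFilter = SelectionFilter()
) -> pd.DataFrame:
    """Apply the candidate-selection filter; result sorted by |M| descending.

    Keeps variants with mean read count above the expression floor AND
    |log2FC| >= the fold-change floor AND q below the significance
    ceiling.  The expression floor is applied to raw read counts (the
    mean of the two pooled per-condition counts) when available, since
    "expressed at >N read count" refers to reads, not CPM.
    """
    if "pooled_count_a" in records.columns:
        mean_count = 0.5 * (records["pooled_count_a"] + records["pooled_count_b"])
    else:
        mean_count = 0.5 * (records["mean_count_a"] + records["mean_count_b"])
    mask = (
        (mean_count > filt.min_mean_count)
        & (records["M"].abs() >= filt.min_abs_l2fc)
        & (records["q"] <= filt.max_q)
    )
    out = records[mask].copy()
    out["selected"] = True
    return out.reindex(out["M"].abs().sort_values(ascending=False, kind="stable").index)


def write_enrichment_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", float_format="%.6g")
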