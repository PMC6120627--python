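"""Windowed differential methylation between two samples.

Methylation for each context is aggregated over non-overlapping 100-bp
windows anchored at coordinate 0 of each chromosome.  A window is tested
only when it holds at least five cytosines covered to the minimum depth in
both samples.  Read counts are pooled within the window and compared with a
two-sided Fisher exact test; Benjamini-Hochberg q-values are computed per
batch.  Calling rules are context-specific: CpG/CHG windows need an
absolute difference of at least 50 percentage points at q < 0.01, CHH
windows at least 15 points with the lower sample at or below 5% (non-CpG
methylation is low-level, so a large relative change matters at small
absolute differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests


class DmrError(ValueError):
    pass


@dataclass(frozen=True)
class DmrWindow:
    chrom: str
    start: int  # 0-based half-open window bounds
    end: int
    context: str
    n_cytosines: int
    level_a: float
    level_b: float
    p: float
    q: float
    is_dmr: bool


def build_windows(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    window: int = 100,
    min_cytosines: int = 5,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Per-context 100-bp window aggregates of two cytosine reports.

    Sites are matched on (chrom, pos, strand, context) and kept when both
    samples cover them to ``min_cov``.  Pooled methylated/unmethylated
    counts and the qualifying-cytosine count are returned per window;
    windows with fewer than ``min_cytosines`` qualifying sites are dropped.
    """
    key = ["chrom", "pos", "strand", "context"]
    a = sites_a[key + ["n_meth", "n_unmeth"]]
    b = sites_b[key + ["n_meth", "n_unmeth"]]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"))
    cov_a = merged["n_meth_a"] + merged["n_unmeth_a"]
    cov_b = merged["n_meth_b"] + merged["n_unmeth_b"]
    merged = merged[(cov_a >= min_cov) & (cov_b >= min_cov)].copy()
    merged["win"] = (merged["pos"] - 1) // window
    agg = (
        merged.groupby(["chrom", "context", "win"], as_index=False)
        .agg(
            n_cytosines=("pos", "size"),
            meth_a=("n_meth_a", "sum"),
            unmeth_a=("n_unmeth_a", "sum"),
            meth_b=("n_meth_b", "sum"),
            unmeth_b=("n_unmeth_b", "sum"),
        )
    )
    agg = agg[agg["n_cytosines"] >= min_cytosines].copy()
    agg["start"] = agg["win"] * window
    agg["end"] = agg["start"] + window
    agg["level_a"] = 100.0 * agg["meth_a"] / (agg["meth_a"] + agg["unmeth_a"])
    agg["level_b"] = 100.0 * agg["meth_b"] / (agg["meth_b"] + agg["unmeth_b"])
    return agg.drop(columns="win").reset_index(drop=True)


def test_window(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    """Two-sided Fisher exact p for one window's pooled 2x2 table."""
    if meth_a + unmeth_a == 0 or meth_b + unmeth_b == 0:
        raise DmrError("zero-total sample in window test")
    return float(
        stats.fisher_exact([[meth_a, unmeth_a], [meth_b, unmeth_b]], "two-sided")[1]
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


#: context -> (minimum |difference| in points, maximum low-side level or None)
DMR_RULES = {
    "CpG": (50.0, None),
    "CHG": (50.0, None),
    "CHH": (15.0, 5.0),
}


def call_dmrs(windows: pd.DataFrame, q_max: float = 0.01) -> pd.DataFrame:
    """Test window aggregates and flag DMRs with context-specific rules.

    Adds ``p``, ``q``, ``diff`` and ``is_dmr`` columns.  q-values are BH
    over all windows in the batch.
    """
    df = windows.copy().reset_index(drop=True)
    cache: dict = {}
    pvals = np.empty(len(df))
    for i, row in enumerate(
        df[["meth_a", "unmeth_a", "meth_b", "unmeth_b"]].itertuples(index=False)
    ):
        key = tuple(int(v) for v in row)
        if key not in cache:
            cache[key] = test_window(*key)
        pvals[i] = cache[key]
    df["p"] = pvals
    df["q"] = bh_adjust(pvals)
    df["diff"] = (df["level_a"] - df["level_b"]).abs()
    low = np.minimum(df["level_a"], df["level_b"])
    is_dmr = np.zeros(len(df), dtype=bool)
    for ctx, (min_diff, max_low) in DMR_RULES.items():
        m = (df["context"] == ctx).to_numpy()
        rule = (df["q"].to_numpy() < q_max) & (df["diff"].to_numpy() >= min_diff)
        if max_low is not None:
            rule &= low.to_numpy() <= max_low
        is_dmr |= m & rule
    df["is_dmr"] = is_dmr
    return df


def associate_features(dmrs: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Overlap DMR windows with annotation intervals (half-open, 0-based).

    ``annotation`` is BED-like with columns chrom, start, end, name and
    (optionally) ``feature`` in {gene, promoter}.  Each overlapping
    (DMR, feature) pair yields one row; a DMR may hit several features.
    """
    trees: dict = {}
    has_type = "feature" in annotation.columns
    for row in annotation.itertuples(index=False):
        if row.end <= row.start:
            continue
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, (row.name, row.feature if has_type else "gene")
        )
    rows = []
    for row in dmrs.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(row.start, row.end)):
            name, ftype = hit.data
            rows.append((row.chrom, row.start, row.end, row.context, name, ftype))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "context", "feature_name", "feature_type"]
    )


def promoters_from_genes(genes: pd.DataFrame, upstream: int = 2000) -> pd.DataFrame:
    """Derive promoter intervals as ``upstream`` bases before each gene TSS.

    Strand-aware; intervals are clipped at 0.  Used when no promoter track
    is supplied.
    """
    rows = []
    for g in genes.itertuples(index=False):
        strand = getattr(g, "strand", "+")
        if strand == "-":
            start, end = g.end, g.end + upstream
        else:
            start, end = max(0, g.start - upstream), g.start
        if end > start:
            rows.append((g.chrom, start, end, g.name, strand, "promoter"))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "strand", "feature"]
    )
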