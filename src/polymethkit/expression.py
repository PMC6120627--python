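"""Differential expression, triad allelic balance, and DMR-DE overlap.

Expression input is a gene-level matrix with replicate columns per
accession.  Differential expression between two accessions uses a Welch
t-test on log2(x+1) values with the additional requirement that the fold-
change direction is consistent in every replicate-versus-replicate
comparison — a deliberately conservative replicate-consistency rule that
substitutes for a full transcript-level model.

For homoeolog triads, per-subgenome expression is normalised so the three
shares sum to 100%; promoter methylation confined to one subgenome is
expected to depress that subgenome's share below one third.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionError(ValueError):
    pass


def de_test(
    expr: pd.DataFrame,
    group_a: list,
    group_b: list,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replicate-aware differential expression between two accessions.

    ``expr`` is genes x samples; ``group_a``/``group_b`` name the replicate
    columns of the two accessions (at least two each).  A gene is called DE
    when the Welch t-test on log2(x+1) gives p < ``alpha`` and every
    replicate of one accession is on the same side of every replicate of
    the other (direction consistency).  Degenerate zero-variance genes with
    equal means get p = 1.
    """
    for grp in (group_a, group_b):
        if len(grp) < 2:
            raise ExpressionError("need at least 2 replicates per accession")
    A = np.log2(expr[group_a].to_numpy(dtype=float) + 1.0)
    B = np.log2(expr[group_b].to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    degenerate = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    mean_diff = A.mean(axis=1) - B.mean(axis=1)
    # zero variance in both groups: equal means -> p = 1; unequal -> forced call
    p = np.where(degenerate & (mean_diff == 0), 1.0, p)
    forced = degenerate & (mean_diff != 0)
    p = np.where(forced, 0.0, p)
    consistent = (A.min(axis=1) > B.max(axis=1)) | (A.max(axis=1) < B.min(axis=1))
    out = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "log2_fold": mean_diff,
            "direction_consistent": consistent,
            "degenerate": forced,
        },
        index=expr.index,
    )
    out["is_de"] = (out["p"] < alpha) & out["direction_consistent"]
    return out


def normalize_shares(triads: pd.DataFrame) -> pd.DataFrame:
    """Normalise per-triad subgenome expression to shares summing to 100.

    ``triads`` needs columns triad, subgenome and expression (replicate
    means).  Triads with zero total are dropped.
    """
    df = triads.copy()
    totals = df.groupby("triad")["expression"].transform("sum")
    df = df[totals > 0].copy()
    df["share"] = 100.0 * df["expression"] / df.groupby("triad")["expression"].transform("sum")
    return df


def allelic_balance(
    triads: pd.DataFrame,
    min_triads: int = 2,
) -> dict:
    """Stratified triad expression shares by promoter-methylation class.

    ``triads`` needs columns triad, subgenome, expression, meth_class
    (e.g. tri / uni / none) and methylated_genome (the affected subgenome
    for uni triads, else empty/NaN).  Returns per-class mean shares and,
    for the uni class, a two-sample Welch t contrast between the methylated
    subgenome's share and the mean share of the other two, per triad.
    """
    shares = normalize_shares(triads)
    out: dict = {"class_mean_shares": {}}
    for cls, grp in shares.groupby("meth_class"):
        out["class_mean_shares"][cls] = (
            grp.groupby("subgenome")["share"].mean().to_dict()
        )
    uni = shares[shares["meth_class"] == "uni"]
    if len(uni["triad"].unique()) >= min_triads:
        meth_shares, other_shares = [], []
        for _, g in uni.groupby("triad"):
            target = g["methylated_genome"].iloc[0]
            m = g.loc[g["subgenome"] == target, "share"]
            o = g.loc[g["subgenome"] != target, "share"]
            if len(m) == 1 and len(o) == 2:
                meth_shares.append(float(m.iloc[0]))
                other_shares.append(float(o.mean()))
        out["uni_methylated_mean_share"] = float(np.mean(meth_shares))
        out["uni_other_mean_share"] = float(np.mean(other_shares))
        out["uni_n_triads"] = len(meth_shares)
        if np.allclose(meth_shares, other_shares):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(other_shares, meth_shares, equal_var=False)
        out["t_uni_contrast"] = float(t)
        out["p_uni_contrast"] = float(p)
    return out


def dmr_de_overlap(
    dmr_genes: set,
    de_genes: set,
    background_genes: set,
) -> dict:
    """Enrichment of differential expression among DMR-associated genes.

    ``overlap_pct`` is the share of DMR-associated genes that are DE;
    ``fold_enrichment`` divides that share by the background DE rate.
    """
    if len(dmr_genes) == 0:
        return {"overlap_pct": float("nan"), "fold_enrichment": float("nan"),
                "defined": False}
    overlap = len(dmr_genes & de_genes) / len(dmr_genes)
    background_rate = len(de_genes & background_genes) / max(len(background_genes), 1)
    return {
        "overlap_pct": 100.0 * overlap,
        "background_de_pct": 100.0 * background_rate,
        "fold_enrichment": overlap / background_rate if background_rate > 0 else float("inf"),
        "defined": True,
    }
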