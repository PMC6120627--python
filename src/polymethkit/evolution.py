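"""Ancestral methylation, deamination-driven SNPs, and methylation
conservation between a diploid ancestor and its descendant subgenome.

Spontaneous deamination of 5-methylcytosine yields thymine directly (an
unmethylated cytosine deaminates to uracil, which is repaired), so
ancestrally methylated cytosines accumulate C-to-T transitions faster than
unmethylated ones.  Given methylation calls on the ancestor and per-
accession homozygous alleles at the homologous descendant positions, the
enrichment is quantified per accession as the divergence fraction at
methylated versus unmethylated ancestor cytosines, compared by paired
t-tests across accessions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .methcall import METHYLATED, UNMETHYLATED


class EvolutionError(ValueError):
    pass


def deamination_enrichment(
    ancestor_calls: pd.DataFrame,
    accession_alleles: dict,
) -> dict:
    """Divergence enrichment at ancestrally methylated cytosines.

    ``ancestor_calls`` holds the ancestor's cytosines with columns chrom,
    pos, strand and status (from :func:`polymethkit.methcall.call_sites`);
    only methylated/unmethylated calls are informative.  Each entry of
    ``accession_alleles`` maps an accession id to a DataFrame of its
    homozygous alleles at those positions (columns chrom, pos, alt) —
    positions absent from the frame carry the ancestral base.

    Per accession: the fraction of ancestor cytosines carrying a different
    homozygous allele (divergence) and the fraction carrying the
    deamination product (T for plus-strand cytosines, A for minus-strand)
    are computed within the methylated and unmethylated strata.  Returns
    the per-accession table, the mean fold enrichment, and paired two-sided
    t-tests across accessions for both contrasts.
    """
    anc = ancestor_calls[ancestor_calls["status"].isin([METHYLATED, UNMETHYLATED])]
    if (anc["status"] == METHYLATED).sum() == 0:
        raise EvolutionError("no methylated ancestor cytosines")
    anc = anc[["chrom", "pos", "strand", "status"]].copy()

    rows = []
    for acc in sorted(accession_alleles):
        alleles = accession_alleles[acc]
        merged = anc.merge(
            alleles[["chrom", "pos", "alt"]], on=["chrom", "pos"], how="left"
        )
        divergent = merged["alt"].notna()
        deam_base = np.where(merged["strand"] == "+", "T", "A")
        is_ct = divergent & (merged["alt"] == deam_base)
        res = {"accession": acc}
        okstrata = True
        for status, tag in ((METHYLATED, "methylated"), (UNMETHYLATED, "unmethylated")):
            m = (merged["status"] == status).to_numpy()
            n = int(m.sum())
            if n == 0:
                okstrata = False
                break
            res[f"n_{tag}"] = n
            res[f"p_divergent_{tag}"] = float(divergent[m].mean())
            res[f"frac_ct_{tag}"] = float(is_ct[m].mean())
        if not okstrata:
            continue
        d_meth, d_un = res["p_divergent_methylated"], res["p_divergent_unmethylated"]
        res["fold"] = d_meth / d_un if d_un > 0 else np.nan
        rows.append(res)

    if not rows:
        raise EvolutionError("no accession with informative sites in both strata")
    table = pd.DataFrame(rows)

    out = {"per_accession": table}
    folds = table["fold"].dropna()
    out["mean_fold"] = float(folds.mean()) if len(folds) else float("nan")
    for a, b, name in (
        ("p_divergent_methylated", "p_divergent_unmethylated", "divergence"),
        ("frac_ct_methylated", "frac_ct_unmethylated", "ct_transition"),
    ):
        if len(table) >= 2 and not np.allclose(table[a], table[b]):
            t, p = stats.ttest_rel(table[a], table[b])
        else:
            t, p = 0.0, 1.0
        out[f"t_{name}"] = float(t)
        out[f"p_{name}"] = float(p)
    return out


def ancestral_conservation(
    ancestor_calls: pd.DataFrame,
    descendant_calls: pd.DataFrame,
) -> dict:
    """Methylation conservation between ancestor and descendant subgenome.

    Both inputs are called cytosine tables; only positions with a
    methylated or unmethylated call in both are compared.  Over
    ancestor-methylated sites: ``conserved_methylated`` + ``lost`` = 1;
    over ancestor-unmethylated sites: ``gained`` + ``conserved_unmethylated``
    = 1.  Fractions are returned in percent.
    """
    key = ["chrom", "pos", "strand"]
    a = ancestor_calls[ancestor_calls["status"].isin([METHYLATED, UNMETHYLATED])]
    d = descendant_calls[descendant_calls["status"].isin([METHYLATED, UNMETHYLATED])]
    merged = a[key + ["status"]].merge(
        d[key + ["status"]], on=key, suffixes=("_anc", "_desc")
    )
    if len(merged) == 0:
        raise EvolutionError("no shared covered positions")
    anc_meth = merged["status_anc"] == METHYLATED
    desc_meth = merged["status_desc"] == METHYLATED
    n_meth = int(anc_meth.sum())
    n_unmeth = int((~anc_meth).sum())
    out = {
        "n_shared": int(len(merged)),
        "n_ancestor_methylated": n_meth,
        "n_ancestor_unmethylated": n_unmeth,
    }
    out["conserved_methylated"] = (
        100.0 * float((anc_meth & desc_meth).sum()) / n_meth if n_meth else float("nan")
    )
    out["lost"] = 100.0 - out["conserved_methylated"] if n_meth else float("nan")
    out["gained"] = (
        100.0 * float((~anc_meth & desc_meth).sum()) / n_unmeth
        if n_unmeth
        else float("nan")
    )
    out["conserved_unmethylated"] = (
        100.0 - out["gained"] if n_unmeth else float("nan")
    )
    return out
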