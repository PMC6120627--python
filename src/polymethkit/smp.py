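"""Single methylation polymorphisms (SMPs) across a diversity panel.

An SMP is a strand-specific cytosine covered in every accession, carrying
the same underlying sequence in every accession (no SNP in the cytosine's
context window), and called methylated (code 100) in at least two
accessions and unmethylated (code 0) in at least two.  Intermediate
methylation is coded 50 ("heterozygous" epiallele) and does not disqualify
a site.  The resulting sites x accessions code matrix is the panel's
epigenotype and feeds the clustering and concordance analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methcall import METHYLATED, UNMETHYLATED, UNCOVERED

SITE_KEY = ["chrom", "pos", "strand", "context"]

CODE = {METHYLATED: 100, UNMETHYLATED: 0}


class SmpError(ValueError):
    pass


@dataclass
class SmpMatrix:
    """Sites x accessions epiallele codes in {0, 50, 100}.

    ``sites`` carries the site annotation (chrom, pos, strand, context) in
    the same row order as ``codes``; ``codes`` columns are accession ids.
    """

    sites: pd.DataFrame
    codes: pd.DataFrame

    @property
    def accessions(self) -> list:
        return list(self.codes.columns)

    def __len__(self) -> int:
        return len(self.codes)

    def write(self, path) -> None:
        pd.concat([self.sites.reset_index(drop=True),
                   self.codes.reset_index(drop=True)], axis=1).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SmpMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(sites=df[SITE_KEY].copy(), codes=df.drop(columns=SITE_KEY))


def identify_smps(
    panel_calls: dict,
    min_cov: int = 10,
    context_intact: pd.DataFrame | None = None,
) -> SmpMatrix:
    """Identify SMPs from per-accession called cytosine reports.

    ``panel_calls`` maps accession id -> DataFrame from
    :func:`polymethkit.methcall.call_sites` (columns chrom, pos, strand,
    context, coverage, status).  ``context_intact``, when given, is a
    DataFrame of (chrom, pos, strand) rows marking sites whose sequence
    context is unbroken in every accession; sites absent from it are
    excluded.  Needs at least 4 accessions (two methylated plus two
    unmethylated calls are otherwise impossible).
    """
    if len(panel_calls) < 4:
        raise SmpError("SMP identification needs at least 4 accessions")

    frames = []
    for acc, df in panel_calls.items():
        f = df[SITE_KEY + ["status"]].copy()
        f["accession"] = acc
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot_table(
        index=SITE_KEY, columns="accession", values="status", aggfunc="first",
        observed=True,
    )
    accs = sorted(panel_calls)
    wide = wide.reindex(columns=accs)

    # a site missing from one accession's report (e.g. the cytosine was
    # abolished by a SNP) or uncovered anywhere fails the coverage filter
    covered = wide.notna().all(axis=1) & (wide != UNCOVERED).all(axis=1)
    wide = wide[covered]

    codes = wide.apply(lambda col: col.map(CODE).fillna(50).astype(int))
    n_meth = (codes == 100).sum(axis=1)
    n_unmeth = (codes == 0).sum(axis=1)
    keep = (n_meth >= 2) & (n_unmeth >= 2)
    codes = codes[keep]

    sites = codes.index.to_frame(index=False)
    if context_intact is not None:
        ok = context_intact[["chrom", "pos", "strand"]].drop_duplicates()
        merged = sites.reset_index().merge(ok, on=["chrom", "pos", "strand"])
        idx = sorted(merged["index"])
        sites = sites.loc[idx].reset_index(drop=True)
        codes = codes.iloc[idx]

    codes = codes.reset_index(drop=True)
    codes.columns.name = None
    return SmpMatrix(sites=sites.reset_index(drop=True), codes=codes)


def accession_smps(matrix: SmpMatrix, accession: str) -> pd.DataFrame:
    """Sites where ``accession`` is coded 100 (its individual SMP set)."""
    if accession not in matrix.codes.columns:
        raise SmpError(f"unknown accession {accession!r}")
    mask = (matrix.codes[accession] == 100).to_numpy()
    return matrix.sites[mask].reset_index(drop=True)


def conservation_profile(matrix: SmpMatrix, high: float = 0.9, low: float = 0.1) -> dict:
    """Per-site methylation conservation and its extreme-frequency bins.

    ``fraction`` is, per site, the share of accessions coded 100 (percent).
    Summary bins report, per context and overall, the share of sites
    methylated in at least ``high`` of accessions and in fewer than ``low``.
    """
    if len(matrix) == 0:
        raise SmpError("empty SMP matrix")
    n_acc = matrix.codes.shape[1]
    frac = 100.0 * (matrix.codes == 100).sum(axis=1) / n_acc
    prof = matrix.sites.copy()
    prof["pct_methylated"] = frac.to_numpy()
    bins = {}
    groups = [("all", prof)] + [
        (ctx, prof[prof["context"] == ctx]) for ctx in sorted(prof["context"].unique())
    ]
    for name, g in groups:
        if len(g) == 0:
            continue
        bins[name] = {
            "n_sites": int(len(g)),
            "pct_high_conserved": float(
                100.0 * (g["pct_methylated"] >= 100.0 * high).mean()
            ),
            "pct_rare": float(100.0 * (g["pct_methylated"] < 100.0 * low).mean()),
        }
    return {"profile": prof, "bins": bins}


def gene_methylation_matrix(
    calls: dict,
    genes: pd.DataFrame,
    context: str = "CpG",
    min_sites: int = 1,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Gene x accession methylation presence (>=1 methylated body cytosine).

    ``genes`` is BED-like (chrom, start, end, name; half-open 0-based).  A
    gene counts as methylated in an accession when at least ``min_sites``
    of its body cytosines in ``context`` are called methylated.
    """
    accs = sorted(calls)
    out = pd.DataFrame(False, index=genes["name"].tolist(), columns=accs)
    for acc in accs:
        df = calls[acc]
        df = df[(df["context"] == context) & (df["status"] == METHYLATED)]
        for g in genes.itertuples(index=False):
            sub = df[(df["chrom"] == g.chrom) & (df["pos"] > g.start) & (df["pos"] <= g.end)]
            if len(sub) >= min_sites:
                out.at[g.name, acc] = True
    return out


def gene_methylation_groups(
    presence: pd.DataFrame,
    high_count: int = 90,
    low_count: int = 40,
    panel_size_reference: int = 105,
) -> dict:
    """Partition methylated genes by how many accessions they appear in.

    Count thresholds are stated for a reference panel size and scaled
    proportionally to the actual panel: high = present in >= high_count
    accessions, low = fewer than low_count, medium in between.  Genes with
    zero presence are excluded; the three groups partition the rest.
    """
    n_acc = presence.shape[1]
    hi = high_count * n_acc / panel_size_reference
    lo = low_count * n_acc / panel_size_reference
    counts = presence.sum(axis=1)
    counts = counts[counts >= 1]
    high = set(counts[counts >= hi].index)
    low = set(counts[counts < lo].index)
    medium = set(counts.index) - high - low
    return {"high": high, "medium": medium, "low": low, "counts": counts}


def family_methylation_profile(
    families: dict,
    presence: pd.DataFrame,
    min_mean_fraction: float = 0.25,
) -> pd.DataFrame:
    """Per-family, per-accession fraction of member genes methylated.

    ``families`` maps family id -> list of gene names (a partition of a
    gene subset).  Families whose across-accession mean fraction is at
    least ``min_mean_fraction`` are flagged as methylation-targeted.
    """
    rows = {}
    for fam, members in families.items():
        members = [g for g in members]
        if len(members) == 0:
            raise SmpError(f"family {fam!r} has no genes")
        sub = presence.loc[[g for g in members if g in presence.index]]
        if len(sub) != len(members):
            missing = set(members) - set(presence.index)
            raise SmpError(f"family {fam!r} has genes without presence rows: {missing}")
        rows[fam] = sub.mean(axis=0)
    prof = pd.DataFrame(rows).T
    prof.index.name = "family"
    prof["mean_fraction"] = prof.mean(axis=1)
    prof["flagged"] = prof["mean_fraction"] >= min_mean_fraction
    return prof
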