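"""Transposable-element family abundance and methylation summaries.

Off-target capture reads approximate shotgun sampling of the genome, so
the cumulative aligned base-space per TE family tracks that family's
genomic abundance.  Profiles are depth-normalised to a fixed total
(50 Mb by default) and compared against a reference accession: positive
differences mean the accession carries more of that family than the
reference.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TARGET = 50_000_000.0


class TeError(ValueError):
    pass


def normalize_te(counts: pd.DataFrame, total_target: float = DEFAULT_TARGET) -> pd.DataFrame:
    """Scale per-family aligned base counts to a fixed total base-space.

    ``counts`` needs columns family, te_class and bases.  Returns the
    profile with a ``normalized`` column summing to ``total_target``.
    """
    if (counts["bases"] < 0).any():
        raise TeError("negative base counts")
    total = float(counts["bases"].sum())
    if total <= 0:
        raise TeError("zero total base-space")
    out = counts.copy()
    out["normalized"] = out["bases"] * (total_target / total)
    return out


def compare_to_reference(
    profile: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Signed per-family base-space differences against the reference.

    Both inputs are normalised profiles.  Families missing on one side are
    treated as zero (with a warning).  Adds per-class aggregate rows under
    ``class_totals`` via :func:`class_differences`.
    """
    p = profile.set_index("family")
    r = reference.set_index("family")
    missing = set(p.index) ^ set(r.index)
    if missing:
        logger.warning("families missing on one side treated as 0: %s", sorted(missing))
    families = sorted(set(p.index) | set(r.index))
    rows = []
    for fam in families:
        acc_v = float(p["normalized"].get(fam, 0.0))
        ref_v = float(r["normalized"].get(fam, 0.0))
        cls = p["te_class"].get(fam, r["te_class"].get(fam, ""))
        rows.append((fam, cls, acc_v, ref_v, acc_v - ref_v))
    return pd.DataFrame(
        rows, columns=["family", "te_class", "accession", "reference", "difference"]
    )


def class_differences(comparison: pd.DataFrame) -> pd.Series:
    """Aggregate signed differences per top-level TE class.

    The top-level class is the part of ``te_class`` before the first
    semicolon-delimited subclass (e.g. ``DNA`` from ``DNA;TIR;CACTA``).
    """
    top = comparison["te_class"].str.split(";").str[0]
    return comparison.groupby(top)["difference"].sum()


def te_methylation(te_counts: pd.DataFrame) -> pd.DataFrame:
    """Pooled per-family, per-context methylation percentages.

    ``te_counts`` needs columns family, context, n_meth, n_unmeth —
    cytosine read counts aggregated over the reads aligned to each family.
    Zero-coverage (family, context) cells are excluded.
    """
    agg = te_counts.groupby(["family", "context"], as_index=False)[
        ["n_meth", "n_unmeth"]
    ].sum()
    cov = agg["n_meth"] + agg["n_unmeth"]
    kept = agg[cov > 0].copy()
    dropped = agg[cov == 0]
    for row in dropped.itertuples(index=False):
        logger.info("excluding zero-coverage family/context %s/%s", row.family, row.context)
    kept["pct_methylated"] = 100.0 * kept["n_meth"] / (kept["n_meth"] + kept["n_unmeth"])
    return kept.reset_index(drop=True)
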