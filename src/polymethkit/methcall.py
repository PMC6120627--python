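"""Per-cytosine methylation levels, three-way status calls, and bisulfite
conversion rate.

Levels are percentages of methylated reads at a single strand-specific
cytosine.  Status calls use context-dependent thresholds: CpG sites are
called methylated at >= 75% (CpG methylation in plants is near-binary),
CHG/CHH sites at >= 10% (non-CpG methylation is typically low-level), and
any context is called unmethylated below 1%.  Everything in between is
"intermediate" — retained but excluded from the methylated/unmethylated
classes, since intermediate levels likely reflect tissue-specific signal.
The conversion rate is estimated from the chloroplast, which carries no
methylation, so every methylated chloroplast read is a conversion failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
INTERMEDIATE = "intermediate"
UNCOVERED = "uncovered"

#: context -> minimum level (%) for a "methylated" call
METHYLATED_THRESHOLD = {"CpG": 75.0, "CHG": 10.0, "CHH": 10.0}
#: below this level (%) any context is "unmethylated"
UNMETHYLATED_THRESHOLD = 1.0


class MethylationError(ValueError):
    pass


@dataclass(frozen=True)
class CytosineSite:
    """One strand-specific cytosine with its bisulfite read counts."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        return methylation_level(self.n_meth, self.n_unmeth)


def methylation_level(n_meth, n_unmeth):
    """Percentage of methylated reads; scalar or elementwise on arrays.

    Raises :class:`MethylationError` for scalar zero coverage; array inputs
    get NaN at uncovered sites.
    """
    if np.isscalar(n_meth) and np.isscalar(n_unmeth):
        cov = n_meth + n_unmeth
        if cov <= 0:
            raise MethylationError("methylation level undefined at zero coverage")
        return 100.0 * n_meth / cov
    n_meth = np.asarray(n_meth, dtype=float)
    n_unmeth = np.asarray(n_unmeth, dtype=float)
    cov = n_meth + n_unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(cov > 0, 100.0 * n_meth / cov, np.nan)
    return level


def call_status(level, context, coverage, min_cov: int = 10):
    """Three-way status call for one site.

    Order of the rules: insufficient coverage -> uncovered; level < 1% ->
    unmethylated; level >= context threshold (75% CpG, 10% CHG/CHH) ->
    methylated; otherwise intermediate.
    """
    if coverage < min_cov:
        return UNCOVERED
    if level < UNMETHYLATED_THRESHOLD:
        return UNMETHYLATED
    if level >= METHYLATED_THRESHOLD[context]:
        return METHYLATED
    return INTERMEDIATE


def call_sites(report: pd.DataFrame, min_cov: int = 10) -> pd.DataFrame:
    """Vectorised status calls for a cytosine-report DataFrame.

    ``report`` needs columns chrom, pos, strand, context, n_meth, n_unmeth.
    Returns a copy with ``coverage``, ``level`` and ``status`` columns.
    """
    out = report.copy()
    cov = out["n_meth"].to_numpy() + out["n_unmeth"].to_numpy()
    level = methylation_level(out["n_meth"].to_numpy(), out["n_unmeth"].to_numpy())
    thr = out["context"].map(METHYLATED_THRESHOLD).to_numpy(dtype=float)
    status = np.full(len(out), INTERMEDIATE, dtype=object)
    with np.errstate(invalid="ignore"):
        status[level < UNMETHYLATED_THRESHOLD] = UNMETHYLATED
        status[level >= thr] = METHYLATED
    status[cov < min_cov] = UNCOVERED
    out["coverage"] = cov
    out["level"] = level
    out["status"] = status
    return out


def conversion_rate(chloroplast_sites: pd.DataFrame) -> float:
    """Bisulfite conversion rate (%) from chloroplast cytosine reports.

    The chloroplast genome is unmethylated, so the pooled fraction of
    unmethylated reads over all chloroplast cytosines estimates the
    conversion success rate.
    """
    n_unmeth = int(chloroplast_sites["n_unmeth"].sum())
    total = n_unmeth + int(chloroplast_sites["n_meth"].sum())
    if total == 0:
        raise MethylationError("no covered chloroplast cytosines")
    return 100.0 * n_unmeth / total
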