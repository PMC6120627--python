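"""Homoeolog coordinate translation and subgenome methylation classes.

An allohexaploid genome carries three related subgenomes (A, B, D).  A
one-to-one whole-genome alignment of A against B and A against D induces,
inside each aligned block, an exact coordinate translation that must respect
indels.  The map is stored as runs of gapless aligned segments
(a_start, t_start, length); translation inside a segment is an offset, and
positions falling in an indel or outside any block translate to nothing.
The A subgenome is the anchor frame: B <-> D translation composes through A.

On top of the map, homoeologous cytosine triples are classified as
tri-/bi-/uni-genome methylated.  Pairwise two-sided Fisher exact tests on
the (methylated, unmethylated) read counts, Benjamini-Hochberg corrected
across the whole batch, decide whether two subgenomes differ (q < 0.01 and
an absolute level difference of at least 50 percentage points).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .methcall import METHYLATED, call_status
from .genotype import context_window, classify_window

SUBGENOMES = ("A", "B", "D")

TRI = "tri"
BI = "bi"
UNI = "uni"
UNCLASSIFIED = "unclassified"


class MapError(ValueError):
    pass


@dataclass
class HomoeologMap:
    """Indel-aware one-to-one coordinate map A->B and A->D.

    ``segments[target]`` is a sorted list of ``(a_start, t_start, length)``
    gapless runs in 0-based coordinates.  Runs never overlap in either
    frame, so translation is bijective wherever it is defined.
    """

    segments: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {}
        for target, segs in self.segments.items():
            segs = sorted(segs)
            self.segments[target] = segs
            self._index[target] = {
                "a_starts": [s[0] for s in segs],
                "by_t": sorted((t, a, ln) for a, t, ln in segs),
            }
            self._index[target]["t_starts"] = [s[0] for s in self._index[target]["by_t"]]

    def translate(self, pos: int, frm: str = "A", to: str = "B") -> int | None:
        """Translate a 1-based position between subgenomes, or ``None``.

        ``None`` means the position falls outside every aligned block or
        inside an indel.  B<->D goes through the A anchor frame.
        """
        for label in (frm, to):
            if label not in SUBGENOMES:
                raise MapError(f"unknown subgenome label {label!r}")
        if frm == to:
            return pos
        if frm == "A":
            return self._from_a(pos, to)
        if to == "A":
            return self._to_a(pos, frm)
        mid = self._to_a(pos, frm)
        return None if mid is None else self._from_a(mid, to)

    def _from_a(self, pos: int, target: str) -> int | None:
        segs = self.segments.get(target, [])
        if not segs:
            return None
        p0 = pos - 1
        i = bisect.bisect_right(self._index[target]["a_starts"], p0) - 1
        if i < 0:
            return None
        a_start, t_start, length = segs[i]
        if p0 < a_start + length:
            return t_start + (p0 - a_start) + 1
        return None

    def _to_a(self, pos: int, source: str) -> int | None:
        idx = self._index.get(source)
        if idx is None:
            return None
        p0 = pos - 1
        i = bisect.bisect_right(idx["t_starts"], p0) - 1
        if i < 0:
            return None
        t_start, a_start, length = idx["by_t"][i]
        if p0 < t_start + length:
            return a_start + (p0 - t_start) + 1
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("A", a + 1, a + ln, tgt, t + 1, t + ln)
            for tgt, segs in sorted(self.segments.items())
            for a, t, ln in segs
        ]
        return pd.DataFrame(
            rows,
            columns=["sub_from", "from_start", "from_end", "sub_to", "to_start", "to_end"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HomoeologMap":
        segments: dict = {}
        for row in df.itertuples(index=False):
            ln = row.from_end - row.from_start + 1
            if row.to_end - row.to_start + 1 != ln:
                raise MapError("segment length mismatch between frames")
            segments.setdefault(row.sub_to, []).append(
                (row.from_start - 1, row.to_start - 1, ln)
            )
        return cls(segments)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "HomoeologMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def _pair_tests(counts: np.ndarray) -> np.ndarray:
    """Two-sided Fisher p for each row of (a_meth, a_unmeth, b_meth, b_unmeth)."""
    out = np.empty(len(counts))
    cache: dict = {}
    for i, (am, au, bm, bu) in enumerate(counts):
        key = (am, au, bm, bu)
        p = cache.get(key)
        if p is None:
            p = stats.fisher_exact([[am, au], [bm, bu]], alternative="two-sided")[1]
            cache[key] = p
        out[i] = p
    return out


def classify_sites(
    triples: pd.DataFrame,
    q_max: float = 0.01,
    min_diff: float = 50.0,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Classify homoeologous cytosine triples as tri/bi/uni-genome methylated.

    ``triples`` needs columns ``pos_A`` plus, for each subgenome X in A/B/D,
    ``meth_X`` and ``unmeth_X`` read counts, and a shared ``context``.
    Sites not covered to ``min_cov`` in all three subgenomes are skipped
    (returned with class ``unclassified`` and a reason).

    For each retained site the three pairwise two-sided Fisher tests are
    computed; BH correction runs across every test in the batch.  A pair
    differs when q < ``q_max`` and the absolute level difference is at least
    ``min_diff`` percentage points.  tri = methylated in all three; uni =
    methylated in exactly one subgenome and that subgenome differs from both
    others; bi = methylated in exactly two, each differing from the third.
    Anything inconsistent stays unclassified.
    """
    df = triples.copy().reset_index(drop=True)
    n = len(df)
    pairs = [("A", "B"), ("A", "D"), ("B", "D")]

    cov = {g: df[f"meth_{g}"].to_numpy() + df[f"unmeth_{g}"].to_numpy() for g in SUBGENOMES}
    level = {
        g: np.where(cov[g] > 0, 100.0 * df[f"meth_{g}"].to_numpy() / np.maximum(cov[g], 1), np.nan)
        for g in SUBGENOMES
    }
    ok = np.all([cov[g] >= min_cov for g in SUBGENOMES], axis=0)

    pvals = {}
    for x, y in pairs:
        counts = np.column_stack(
            [df[f"meth_{x}"], df[f"unmeth_{x}"], df[f"meth_{y}"], df[f"unmeth_{y}"]]
        ).astype(int)
        p = np.full(n, np.nan)
        if ok.any():
            p[ok] = _pair_tests(counts[ok])
        pvals[(x, y)] = p

    # BH across the whole batch of pairwise tests
    flat = np.concatenate([pvals[p][ok] for p in pairs])
    qflat = bh_adjust(flat) if flat.size else flat
    qvals = {}
    m = int(ok.sum())
    for i, pr in enumerate(pairs):
        q = np.full(n, np.nan)
        q[ok] = qflat[i * m : (i + 1) * m]
        qvals[pr] = q

    def pairkey(x, y):
        return (x, y) if (x, y) in qvals else (y, x)

    classes = np.full(n, UNCLASSIFIED, dtype=object)
    meth_sets = []
    for i in range(n):
        if not ok[i]:
            meth_sets.append("")
            continue
        ctx = df.at[i, "context"]
        meth = {
            g
            for g in SUBGENOMES
            if call_status(level[g][i], ctx, cov[g][i], min_cov) == METHYLATED
        }
        meth_sets.append("".join(sorted(meth)))

        def differs(x, y):
            q = qvals[pairkey(x, y)][i]
            return (q < q_max) and abs(level[x][i] - level[y][i]) >= min_diff

        if len(meth) == 3:
            classes[i] = TRI
        elif len(meth) == 1:
            (g,) = meth
            others = [o for o in SUBGENOMES if o != g]
            if all(differs(g, o) for o in others):
                classes[i] = UNI
        elif len(meth) == 2:
            (other,) = [o for o in SUBGENOMES if o not in meth]
            if all(differs(g, other) for g in meth):
                classes[i] = BI

    out = df.copy()
    out["covered"] = ok
    for g in SUBGENOMES:
        out[f"level_{g}"] = level[g]
    for x, y in pairs:
        out[f"q_{x}{y}"] = qvals[(x, y)]
    out["methylated_genomes"] = meth_sets
    out["genome_class"] = classes
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def homoeolog_snp_context(
    uni_sites: pd.DataFrame,
    sequences: dict,
    homoeolog_map: HomoeologMap,
) -> pd.DataFrame:
    """Flag uni-genome methylated sites whose context is SNP-differentiated.

    ``uni_sites`` needs columns ``pos_A``, ``strand`` and
    ``methylated_genomes`` (a single subgenome letter).  For each site, the
    trinucleotide context windows at the three homoeologous positions are
    compared: ``snp_differentiates`` is True when the methylated subgenome's
    context class differs from both of the other two, and ``creates_cpg``
    additionally requires the methylated subgenome to be CpG while both
    others are not.  Untranslatable sites are dropped.
    """
    rows = []
    for row in uni_sites.itertuples(index=False):
        meth_g = row.methylated_genomes
        if meth_g not in SUBGENOMES:
            continue
        positions = {}
        posA = int(row.pos_A)
        okflag = True
        for g in SUBGENOMES:
            p = homoeolog_map.translate(posA, "A", g)
            if p is None:
                okflag = False
                break
            positions[g] = p
        if not okflag:
            continue
        ctx = {}
        for g in SUBGENOMES:
            win = context_window(sequences[g], positions[g], row.strand)
            ctx[g] = classify_window(win) if win is not None else None
        others = [g for g in SUBGENOMES if g != meth_g]
        flag = ctx[meth_g] is not None and all(ctx[meth_g] != ctx[o] for o in others)
        creates_cpg = flag and ctx[meth_g] == "CpG" and all(ctx[o] != "CpG" for o in others)
        rows.append(
            (posA, row.strand, meth_g, ctx["A"], ctx["B"], ctx["D"], flag, creates_cpg)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pos_A", "strand", "methylated_genome",
            "context_A", "context_B", "context_D",
            "snp_differentiates", "creates_cpg",
        ],
    )


def class_conservation(
    meth_frac: pd.Series,
    strata: pd.Series,
) -> dict:
    """Compare per-site panel methylation conservation between class strata.

    ``meth_frac`` holds, per site, the fraction of accessions methylated
    (in percent); ``strata`` the site's tri/bi/uni class.  Returns summary
    quantiles per stratum and Welch t contrasts of tri against bi and uni.
    Raises on an empty stratum.
    """
    out: dict = {"strata": {}}
    groups = {}
    for s in (TRI, BI, UNI):
        vals = meth_frac[strata == s].to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"empty stratum {s!r}")
        groups[s] = vals
        out["strata"][s] = {
            "n": int(len(vals)),
            "median": float(np.median(vals)),
            "quantiles": {q: float(np.quantile(vals, q)) for q in (0.25, 0.5, 0.75)},
        }
    for other in (BI, UNI):
        if np.array_equal(groups[TRI], groups[other]):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(groups[TRI], groups[other], equal_var=False)
        out[f"t_tri_vs_{other}"] = float(t)
        out[f"p_tri_vs_{other}"] = float(p)
    return out
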