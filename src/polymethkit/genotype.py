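"""Homozygous SNP selection, accession-specific reference correction, and
strand-aware cytosine context derivation.

Bisulfite analysis of a diversity panel needs, per accession, (i) the set of
homozygous SNPs that distinguish it from the reference, (ii) a corrected
("accession-specific") reference built by substituting those alleles, and
(iii) the cytosine context (CpG / CHG / CHH) of every cytosine on both
strands, since a SNP within two bases downstream of a cytosine can change its
context class or abolish the cytosine altogether.  Only substitution SNPs are
applied; indels are never introduced so coordinates stay comparable across
accessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONTEXTS = ("CpG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenotypeError(ValueError):
    """Raised for inconsistent SNP sets or reference mismatches."""


@dataclass(frozen=True)
class SnpCall:
    """A per-accession substitution call against the reference.

    ``pos`` is 1-based.  ``alt_fraction`` is alternate-allele reads over
    depth; a call is flagged homozygous when the alternate allele is seen in
    at least 80% of reads at depth >= 5.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_fraction: float
    qual: float = 0.0
    homozygous: bool = False

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise GenotypeError(f"SNP at {self.chrom}:{self.pos} has depth < 1")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise GenotypeError(
                f"SNP at {self.chrom}:{self.pos} has alt_fraction outside [0, 1]"
            )


def filter_homozygous(
    snps,
    min_depth: int = 5,
    min_alt_frac: float = 0.8,
    min_qual: float = 30.0,
):
    """Return the homozygous subset of ``snps``, re-flagged.

    A call passes when depth >= ``min_depth``, alternate-allele fraction
    >= ``min_alt_frac`` and quality >= ``min_qual``.  Heterozygous and
    low-confidence calls are dropped (never applied to the reference).
    """
    kept = []
    for s in snps:
        if s.depth >= min_depth and s.alt_fraction >= min_alt_frac and s.qual >= min_qual:
            kept.append(
                SnpCall(
                    s.chrom, s.pos, s.ref, s.alt, s.depth, s.alt_fraction, s.qual,
                    homozygous=True,
                )
            )
    return kept


def correct_reference(reference: dict, snps) -> dict:
    """Apply homozygous substitution SNPs to ``reference`` sequences.

    Returns a new ``{chrom: sequence}`` dict differing from the input at
    exactly the SNP positions.  Raises :class:`GenotypeError` on duplicate
    positions or when a SNP's stated reference allele disagrees with the
    sequence.
    """
    out = {chrom: bytearray(seq.upper(), "ascii") for chrom, seq in reference.items()}
    seen: set = set()
    for s in snps:
        key = (s.chrom, s.pos)
        if key in seen:
            raise GenotypeError(f"two SNPs at the same position {s.chrom}:{s.pos}")
        seen.add(key)
        if s.chrom not in out:
            raise GenotypeError(f"SNP chromosome {s.chrom!r} absent from reference")
        seq = out[s.chrom]
        if not 1 <= s.pos <= len(seq):
            raise GenotypeError(f"SNP position {s.chrom}:{s.pos} outside reference")
        base = chr(seq[s.pos - 1])
        if base != s.ref.upper():
            raise GenotypeError(
                f"reference mismatch at {s.chrom}:{s.pos}: sequence has {base}, "
                f"SNP claims {s.ref}"
            )
        seq[s.pos - 1] = ord(s.alt.upper())
    return {chrom: seq.decode("ascii") for chrom, seq in out.items()}


def derive_contexts(sequence: str, chrom: str | None = None) -> pd.DataFrame:
    """Strand-aware context table for every cytosine in ``sequence``.

    Plus-strand cytosines are ``C`` bases read left-to-right; minus-strand
    cytosines are ``G`` bases read as ``C`` on the reverse complement, with
    the two-base lookahead running leftwards.  Cytosines whose lookahead
    falls off the sequence end, or whose lookahead contains an ambiguity
    code, get no context row.

    Returns a DataFrame with columns ``pos`` (1-based), ``strand`` and
    ``context``; ``chrom`` is prepended when given.
    """
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = len(arr)
    rows = []

    # plus strand: C at i; CpG needs arr[i+1], CHG/CHH need arr[i+2]
    c_idx = np.flatnonzero(arr == b"C")
    for i in c_idx:
        ctx = _context_plus(arr, i, n)
        if ctx is not None:
            rows.append((int(i) + 1, "+", ctx))

    g_idx = np.flatnonzero(arr == b"G")
    for i in g_idx:
        ctx = _context_minus(arr, i)
        if ctx is not None:
            rows.append((int(i) + 1, "-", ctx))

    df = pd.DataFrame(rows, columns=["pos", "strand", "context"])
    df = df.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)
    if chrom is not None:
        df.insert(0, "chrom", chrom)
    return df


def _context_plus(arr, i, n):
    if i + 1 >= n:
        return None
    nxt = arr[i + 1]
    if nxt == b"G":
        return "CpG"
    if nxt not in (b"A", b"C", b"T"):
        return None
    if i + 2 >= n:
        return None
    nxt2 = arr[i + 2]
    if nxt2 == b"G":
        return "CHG"
    if nxt2 in (b"A", b"C", b"T"):
        return "CHH"
    return None


def _context_minus(arr, i):
    # G at i is a cytosine on the reverse complement; lookahead runs leftwards
    # and a plus-strand C complements to G on the read strand.
    if i - 1 < 0:
        return None
    nxt = arr[i - 1]
    if nxt == b"C":
        return "CpG"
    if nxt not in (b"A", b"G", b"T"):
        return None
    if i - 2 < 0:
        return None
    nxt2 = arr[i - 2]
    if nxt2 == b"C":
        return "CHG"
    if nxt2 in (b"A", b"G", b"T"):
        return "CHH"
    return None


def context_window(sequence: str, pos: int, strand: str) -> str | None:
    """The strand-oriented trinucleotide starting at the cytosine.

    For a plus-strand cytosine at 1-based ``pos`` this is
    ``sequence[pos-1 : pos+2]``; for a minus-strand cytosine it is the
    reverse complement of ``sequence[pos-3 : pos]``.  Returns ``None`` when
    the window runs off the sequence end.
    """
    seq = sequence.upper()
    if strand == "+":
        window = seq[pos - 1 : pos + 2]
        return window if len(window) == 3 else None
    if strand == "-":
        if pos - 3 < 0:
            return None
        window = seq[pos - 3 : pos]
        return window.translate(_COMPLEMENT)[::-1]
    raise GenotypeError(f"unknown strand {strand!r}")


def classify_window(window: str) -> str | None:
    """Context class of a strand-oriented trinucleotide, or ``None``.

    ``None`` means the first base is not a cytosine (site abolished) or the
    window contains an ambiguity code.
    """
    if len(window) != 3 or window[0] != "C":
        return None
    if any(b not in "ACGT" for b in window):
        return None
    if window[1] == "G":
        return "CpG"
    if window[2] == "G":
        return "CHG"
    return "CHH"


@dataclass(frozen=True)
class ContextShift:
    """Outcome of substituting accession alleles into a cytosine's window."""

    changed: bool
    reference_context: str | None
    accession_context: str | None  # None when the cytosine is abolished

    @property
    def abolished(self) -> bool:
        return self.accession_context is None


def context_intact_sites(sites: pd.DataFrame, hom_snps_by_accession: dict,
                         reference_lengths: dict) -> pd.DataFrame:
    """Sites whose context window is SNP-free in every accession.

    ``sites`` needs columns chrom, pos (1-based) and strand; each entry of
    ``hom_snps_by_accession`` is an iterable of homozygous
    :class:`SnpCall`.  A site survives when no accession carries a
    homozygous substitution at the cytosine itself or the two downstream
    bases on its strand, so the cytosine context is identical panel-wide.
    """
    masks = {
        chrom: np.zeros(length, dtype=bool)
        for chrom, length in reference_lengths.items()
    }
    for snps in hom_snps_by_accession.values():
        for s in snps:
            if s.chrom in masks:
                masks[s.chrom][s.pos - 1] = True

    keep = np.zeros(len(sites), dtype=bool)
    for chrom, grp in sites.groupby("chrom"):
        mask = masks.get(chrom)
        if mask is None:
            continue
        p0 = grp["pos"].to_numpy() - 1
        plus = (grp["strand"] == "+").to_numpy()
        hit = np.zeros(len(grp), dtype=bool)
        for off in (0, 1, 2):
            idx = np.where(plus, p0 + off, p0 - off)
            valid = (idx >= 0) & (idx < len(mask))
            hit[valid] |= mask[idx[valid]]
        keep[grp.index.to_numpy()] = ~hit
    return sites.loc[keep, ["chrom", "pos", "strand"]].reset_index(drop=True)


def context_shift(reference_window: str, accession_window: str) -> ContextShift:
    """Compare the reference and accession trinucleotide of one cytosine.

    Both windows are strand-oriented (the cytosine first, then two
    downstream bases).  ``changed`` is True when the accession's context
    class differs from the reference's, including abolition of the cytosine
    (a substitution at the C itself), in which case the site must be
    excluded from methylation calling.
    """
    ref_ctx = classify_window(reference_window.upper())
    acc_ctx = classify_window(accession_window.upper())
    return ContextShift(changed=ref_ctx != acc_ctx,
                        reference_context=ref_ctx,
                        accession_context=acc_ctx)
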