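"""Readers and writers for the pipeline's external formats.

Conventions follow the upstream tools the tables come from: cytosine
reports are Bismark CX-style TSVs (1-based, one row per cytosine per
strand, contexts CpG/CHG/CHH, CpG sites never merged across strands),
variants are VCF v4.2, annotation is BED6 (0-based half-open), and
references are FASTA.  A YAML manifest ties an accession panel's files
together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]
VALID_CONTEXTS = {"CpG", "CHG", "CHH"}
VALID_STRANDS = {"+", "-"}


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- cytosine
def read_cytosine_report(path) -> pd.DataFrame:
    """Parse a Bismark CX-style cytosine report TSV.

    Columns: chrom, pos (1-based), strand (+/-), count methylated, count
    unmethylated, context.  Malformed rows raise :class:`FormatError`
    naming the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:3] == ["chrom", "pos", "strand"]:
                continue  # optional header
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 columns")
            chrom, pos, strand, n_meth, n_unmeth, context = parts[:6]
            try:
                pos_i, m_i, u_i = int(pos), int(n_meth), int(n_unmeth)
            except ValueError as err:
                raise FormatError(f"{path}: line {lineno}: non-integer field") from err
            if pos_i < 1:
                raise FormatError(f"{path}: line {lineno}: position must be >= 1")
            if m_i < 0 or u_i < 0:
                raise FormatError(f"{path}: line {lineno}: negative read count")
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}: line {lineno}: bad strand {strand!r}")
            if context not in VALID_CONTEXTS:
                raise FormatError(
                    f"{path}: line {lineno}: unknown context token {context!r}"
                )
            rows.append((chrom, pos_i, strand, m_i, u_i, context))
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    logger.info("read %d cytosine sites from %s", len(df), path)
    return df


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    df[REPORT_COLUMNS].to_csv(path, sep="\t", index=False, header=True)


# ------------------------------------------------------------------- FASTA
def read_fasta(path) -> dict:
    """Read FASTA into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------- VCF
def write_vcf(variants: pd.DataFrame, path, contigs: dict) -> None:
    """Write a per-accession VCF v4.2.

    ``variants`` needs columns chrom, pos (1-based), ref, alt, depth,
    alt_depth, qual, gt; ``contigs`` maps chromosome name to length.
    """
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.info.add("DP", 1, "Integer", "Read depth")
    header.info.add("AO", 1, "Integer", "Alternate allele observation count")
    header.add_sample("sample")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants.sort_values(["chrom", "pos"], kind="mergesort").itertuples(index=False):
            if v.pos < 1 or v.pos > contigs[v.chrom]:
                raise FormatError(f"variant {v.chrom}:{v.pos} outside reference")
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref, v.alt), qual=float(v.qual),
            )
            rec.info["DP"] = int(v.depth)
            rec.info["AO"] = int(v.alt_depth)
            gt = tuple(int(x) for x in str(v.gt).replace("|", "/").split("/"))
            rec.samples["sample"]["GT"] = gt
            out.write(rec)


def read_vcf(path) -> pd.DataFrame:
    """Read a per-accession VCF into the variant DataFrame dialect."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            gt = rec.samples[0]["GT"] if len(rec.samples) else (1, 1)
            gt_str = "/".join(str(x) for x in gt)
            rows.append(
                (
                    rec.contig,
                    rec.pos,
                    rec.ref,
                    rec.alts[0] if rec.alts else ".",
                    int(rec.info.get("DP", 0)),
                    int(rec.info.get("AO", 0)),
                    float(rec.qual) if rec.qual is not None else 0.0,
                    gt_str,
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_depth", "qual", "gt"]
    )


# --------------------------------------------------------------------- BED
def read_bed(path, reference_lengths: dict | None = None) -> pd.DataFrame:
    """Read BED6 annotation intervals (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if (df["end"] < df["start"]).any():
        raise FormatError(f"{path}: interval with end < start")
    if reference_lengths is not None:
        for row in df.itertuples(index=False):
            limit = reference_lengths.get(row.chrom)
            if limit is not None and row.end > limit:
                raise FormatError(
                    f"{path}: interval {row.chrom}:{row.start}-{row.end} outside reference"
                )
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------- manifest
@dataclass
class PanelManifest:
    """Paths of every per-accession file plus shared references."""

    reference: str
    annotation: str
    homoeolog_map: str
    accessions: dict = field(default_factory=dict)  # id -> {vcf, report, te_counts}
    ancestor_report: str | None = None
    reference_report: str | None = None
    te_reference: str | None = None
    expression: str | None = None
    origins: dict = field(default_factory=dict)  # id -> {region, latitude, longitude}

    def validate(self, base: Path | None = None) -> None:
        base = Path(base) if base else Path(".")
        paths = [self.reference, self.annotation, self.homoeolog_map]
        for acc, files in self.accessions.items():
            paths.extend(files.values())
        for p in paths:
            if p and not (base / p).exists():
                raise FormatError(f"manifest path does not exist: {p}")
        if len(set(self.accessions)) != len(self.accessions):
            raise FormatError("duplicate accession ids")

    def save(self, path) -> None:
        data = {
            "reference": self.reference,
            "annotation": self.annotation,
            "homoeolog_map": self.homoeolog_map,
            "accessions": self.accessions,
            "ancestor_report": self.ancestor_report,
            "reference_report": self.reference_report,
            "te_reference": self.te_reference,
            "expression": self.expression,
            "origins": self.origins,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PanelManifest":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


# ------------------------------------------------------------- panel on disk
def write_panel(panel, outdir, expression=None) -> PanelManifest:
    """Serialise a simulated panel to a directory and return its manifest.

    Layout: reference.fasta, annotation.bed, homoeolog_map.tsv,
    ancestor_report.tsv, te_reference.tsv, expression.tsv and one
    ``<accession>.vcf`` / ``<accession>.report.tsv`` / ``<accession>.te.tsv``
    trio per accession.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = panel.genome.chrom_sequences()
    write_fasta(seqs, outdir / "reference.fasta")
    write_bed(panel.truth.genes, outdir / "annotation.bed")
    panel.genome.homoeolog_map.write(outdir / "homoeolog_map.tsv")
    write_cytosine_report(panel.ancestor_report, outdir / "ancestor_report.tsv")
    write_cytosine_report(panel.reference_report, outdir / "reference_report.tsv")
    panel.te_reference.to_csv(outdir / "te_reference.tsv", sep="\t", index=False)
    contigs = {name: len(seq) for name, seq in seqs.items()}

    accessions = {}
    origins = {}
    for acc in panel.accessions:
        vcf_path = outdir / f"{acc}.vcf"
        report_path = outdir / f"{acc}.report.tsv"
        te_path = outdir / f"{acc}.te.tsv"
        write_vcf(panel.vcfs[acc], vcf_path, contigs)
        write_cytosine_report(panel.reports[acc], report_path)
        panel.te_counts[acc].to_csv(te_path, sep="\t", index=False)
        accessions[acc] = {
            "vcf": vcf_path.name,
            "report": report_path.name,
            "te_counts": te_path.name,
        }
        origins[acc] = {
            "region": str(panel.truth.regions[acc]),
            "latitude": float(panel.truth.coords.loc[acc, "y"]),
            "longitude": float(panel.truth.coords.loc[acc, "x"]),
        }

    expr_path = None
    if expression is not None:
        expr_path = "expression.tsv"
        expression.expr_matrix.to_csv(outdir / expr_path, sep="\t")
        expression.triads.to_csv(outdir / "triads.tsv", sep="\t", index=False)

    manifest = PanelManifest(
        reference="reference.fasta",
        annotation="annotation.bed",
        homoeolog_map="homoeolog_map.tsv",
        accessions=accessions,
        ancestor_report="ancestor_report.tsv",
        reference_report="reference_report.tsv",
        te_reference="te_reference.tsv",
        expression=expr_path,
        origins=origins,
    )
    manifest.save(outdir / "manifest.yaml")
    return manifest


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
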