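"""Synthetic allohexaploid diversity panel with full ground truth.

The generator emulates the data underlying a landrace methylation survey:
three subgenomes (A, B, D) derived from one common-ancestor sequence by
substitutions and short indels, an unmethylated chloroplast, a panel of
inbred accessions structured into ancestral populations with 2-D
geographic coordinates, per-cytosine methylation states with geography-
linked epialleles, bisulfite read counts drawn binomially at Poisson
coverage with incomplete conversion, a deamination mutation model in which
ancestrally methylated cytosines mutate several-fold faster and
preferentially to thymine, per-accession TE copy-number multipliers, and
triad expression in which promoter methylation confined to one subgenome
depresses that subgenome's expression share.

Every emitted table is consistent with the recorded :class:`GroundTruth`
under the stated sampling model, and a fixed seed fixes every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import derive_contexts, classify_window
from .subgenome import HomoeologMap

BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")

#: chromosome name per subgenome label
CHROM_OF = {"A": "chr1A", "B": "chr1B", "D": "chr1D"}
SUB_OF_CHROM = {v: k for k, v in CHROM_OF.items()}
CHLOROPLAST = "chloroplast"

TE_LIBRARY = [
    ("RLG_Gypsy", "Retro;LTR;Gypsy", 0.30),
    ("RLC_Copia", "Retro;LTR;Copia", 0.18),
    ("SINE_1", "Retro;SINE", 0.05),
    ("LINE_1", "Retro;LINE", 0.07),
    ("DTC_CACTA", "DNA;TIR;CACTA", 0.22),
    ("DTM_Mariner", "DNA;TIR;Mariner", 0.08),
    ("DTH_Harbinger", "DNA;TIR;Harbinger", 0.06),
    ("DHH_Helitron", "DNA;Helitron", 0.04),
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic panel.

    Defaults are the study conditions the generator emulates: ~98.7%
    bisulfite conversion, a roughly fourfold deamination-driven mutation
    excess at ancestrally methylated cytosines biased strongly to C-to-T,
    near-binary CpG methylation with low-level CHG/CHH methylation, and a
    two-population panel with geography-linked epialleles.
    """

    n_accessions: int = 20
    n_populations: int = 2
    subgenome_length: int = 20_000
    chloroplast_length: int = 8_000
    ancestor_divergence: float = 0.02  # substitutions per base per subgenome
    indel_rate: float = 0.001          # indel events per base
    panel_snp_rate: float = 0.003      # segregating SNPs per base
    epiallele_rate: float = 0.10       # polymorphic-methylation cytosines
    conversion_rate: float = 0.987
    mean_coverage: float = 30.0
    deamination_fold: float = 4.0
    deamination_base_rate: float = 0.005  # per-accession mutation rate, unmethylated stratum
    deamination_ct_bias: float = 0.96     # P(mutant allele is the deamination product)
    ancestral_retention: float = 0.837  # P(D methylated | ancestor methylated)
    ancestral_gain: float = 0.031       # P(D methylated | ancestor unmethylated)
    cpg_meth_high: float = 0.90    # read-level methylation of a methylated CpG
    chg_meth_mean: float = 0.40
    chh_meth_mean: float = 0.30
    cpg_meth_fraction: float = 0.40  # share of CpG sites ancestrally methylated
    chg_meth_fraction: float = 0.15
    chh_meth_fraction: float = 0.15
    epiallele_within_noise: float = 0.30  # ceiling of the geographic flip kernel
    geography_decay: float = 2.0          # exponential kernel length scale
    regions_per_population: int = 3
    heterozygous_rate: float = 0.03
    te_families: int = 8
    te_multiplier_sd: float = 0.10  # lognormal sd of per-family copy-number ratios
    n_genes: int = 30               # per subgenome
    n_triads: int = 60
    n_expr_replicates: int = 3
    n_de_genes: int = 10
    de_log2_fold: float = 1.0
    expr_noise_sd: float = 0.25     # log2-scale replicate noise
    uni_meth_share: float = 28.82   # expected share (%) of the promoter-methylated homoeolog
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "ancestor_divergence": self.ancestor_divergence,
            "indel_rate": self.indel_rate,
            "panel_snp_rate": self.panel_snp_rate,
            "epiallele_rate": self.epiallele_rate,
            "conversion_rate": self.conversion_rate,
            "deamination_base_rate": self.deamination_base_rate,
            "deamination_ct_bias": self.deamination_ct_bias,
            "ancestral_retention": self.ancestral_retention,
            "ancestral_gain": self.ancestral_gain,
            "cpg_meth_high": self.cpg_meth_high,
            "chg_meth_mean": self.chg_meth_mean,
            "chh_meth_mean": self.chh_meth_mean,
            "cpg_meth_fraction": self.cpg_meth_fraction,
            "chg_meth_fraction": self.chg_meth_fraction,
            "chh_meth_fraction": self.chh_meth_fraction,
            "epiallele_within_noise": self.epiallele_within_noise,
            "heterozygous_rate": self.heterozygous_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.deamination_fold < 1.0:
            raise ConfigError("deamination_fold must be >= 1")
        if self.subgenome_length < 1000:
            raise ConfigError("subgenome_length must be >= 1000")
        if self.indel_rate > 0 and self.subgenome_length * self.indel_rate < 1 and \
                self.subgenome_length < 3:
            raise ConfigError("sequence too short to place requested indels")
        if self.n_accessions < 1 or self.n_populations < 1:
            raise ConfigError("need at least one accession and one population")
        if self.n_populations > self.n_accessions:
            raise ConfigError("more populations than accessions")
        if self.mean_coverage <= 0:
            raise ConfigError("mean_coverage must be positive")


@dataclass
class Genome:
    """Reference sequences plus the true homoeolog coordinate map."""

    sequences: dict          # {"A": str, "B": str, "D": str, "chloroplast": str}
    homoeolog_map: HomoeologMap
    anc_maps: dict = field(default_factory=dict)  # subgenome -> anc->sub segments

    def chrom_sequences(self) -> dict:
        out = {CHROM_OF[g]: self.sequences[g] for g in ("A", "B", "D")}
        out[CHLOROPLAST] = self.sequences[CHLOROPLAST]
        return out


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    homoeolog_map: HomoeologMap
    population_labels: pd.Series            # accession -> population id
    regions: pd.Series                      # accession -> region label
    coords: pd.DataFrame                    # accession -> x, y
    sites: dict                             # subgenome -> site table (pos, strand, context)
    methylation_state: dict                 # subgenome -> sites x accessions bool array
    site_polymorphic: dict                  # subgenome -> bool array over sites
    site_context_broken: dict               # subgenome -> bool array over sites
    ancestor_methylation: np.ndarray        # over D sites
    te_multipliers: pd.DataFrame            # accessions x families
    genes: pd.DataFrame                     # BED-like gene annotation
    families: dict                          # family id -> gene names
    true_de_genes: set = field(default_factory=set)
    triad_classes: pd.DataFrame | None = None


def _random_seq(rng, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate_bases(rng, arr: np.ndarray, idx: np.ndarray) -> None:
    """Substitute a random different base at each index (in place)."""
    for i in idx:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]


def _derive_subgenome(rng, ancestor: np.ndarray, divergence: float, indel_rate: float):
    """One descendant sequence plus its ancestor->descendant segment map."""
    n = len(ancestor)
    seq = ancestor.copy()
    sub_idx = np.flatnonzero(rng.random(n) < divergence)
    _mutate_bases(rng, seq, sub_idx)

    events = []
    if indel_rate > 0:
        for p in np.flatnonzero(rng.random(n) < indel_rate):
            kind = "ins" if rng.random() < 0.5 else "del"
            length = int(rng.integers(1, 4))
            events.append((int(p), kind, length))
    events.sort()

    pieces = []
    segments = []  # (anc_start, sub_start, length)
    anc_cursor = 0
    sub_cursor = 0
    for p, kind, length in events:
        if p < anc_cursor:
            continue  # overlapping a previous deletion; skip
        if p > anc_cursor:
            run = seq[anc_cursor:p]
            pieces.append(run)
            segments.append((anc_cursor, sub_cursor, p - anc_cursor))
            sub_cursor += p - anc_cursor
            anc_cursor = p
        if kind == "del":
            anc_cursor = min(n, anc_cursor + length)
        else:
            ins = _random_seq(rng, length)
            pieces.append(ins)
            sub_cursor += length
    if anc_cursor < n:
        pieces.append(seq[anc_cursor:])
        segments.append((anc_cursor, sub_cursor, n - anc_cursor))
    out = np.concatenate(pieces) if pieces else np.empty(0, dtype="S1")
    return out, segments


def _compose_segments(segs_a, segs_b):
    """Intersect two ancestor->descendant maps into an A->B map."""
    out = []
    i = j = 0
    while i < len(segs_a) and j < len(segs_b):
        a0, sa, la = segs_a[i]
        b0, sb, lb = segs_b[j]
        lo = max(a0, b0)
        hi = min(a0 + la, b0 + lb)
        if hi > lo:
            out.append((sa + (lo - a0), sb + (lo - b0), hi - lo))
        if a0 + la <= b0 + lb:
            i += 1
        else:
            j += 1
    return out


def simulate_genome(cfg: SimConfig) -> Genome:
    """Three subgenomes from one ancestor, plus chloroplast and true map."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    ancestor = _random_seq(rng, cfg.subgenome_length)
    seqs = {}
    anc_maps = {}
    for g in ("A", "B", "D"):
        seqs[g], anc_maps[g] = _derive_subgenome(
            rng, ancestor, cfg.ancestor_divergence, cfg.indel_rate
        )
    segments = {
        "B": _compose_segments(anc_maps["A"], anc_maps["B"]),
        "D": _compose_segments(anc_maps["A"], anc_maps["D"]),
    }
    hmap = HomoeologMap(segments=segments)
    sequences = {g: seqs[g].tobytes().decode("ascii") for g in seqs}
    sequences[CHLOROPLAST] = _random_seq(rng, cfg.chloroplast_length).tobytes().decode("ascii")
    return Genome(sequences=sequences, homoeolog_map=hmap, anc_maps=anc_maps)


#: read-level methylation of a truly methylated site, by context
def _context_levels(cfg: SimConfig) -> dict:
    return {"CpG": cfg.cpg_meth_high, "CHG": cfg.chg_meth_mean, "CHH": cfg.chh_meth_mean}


def _context_fractions(cfg: SimConfig) -> dict:
    return {
        "CpG": cfg.cpg_meth_fraction,
        "CHG": cfg.chg_meth_fraction,
        "CHH": cfg.chh_meth_fraction,
    }


@dataclass
class PanelData:
    """In-memory synthetic panel: per-accession tables plus ground truth."""

    genome: Genome
    accessions: list
    reports: dict          # accession -> cytosine report DataFrame (incl. chloroplast)
    vcfs: dict             # accession -> variant DataFrame
    ancestor_report: pd.DataFrame  # the diploid D-progenitor's cytosine report
    reference_report: pd.DataFrame  # SNP-free reference-accession report
    te_counts: dict        # accession -> TE family base counts DataFrame
    te_reference: pd.DataFrame
    te_methylation: dict   # accession -> per-family/context cytosine counts
    truth: GroundTruth


def _assign_geography(cfg: SimConfig, rng):
    accs = [f"acc{i:03d}" for i in range(cfg.n_accessions)]
    pops = np.array([i % cfg.n_populations for i in range(cfg.n_accessions)])
    centers = np.column_stack(
        [10.0 * np.arange(cfg.n_populations), np.zeros(cfg.n_populations)]
    )
    region_centers = {}
    for p in range(cfg.n_populations):
        for r in range(cfg.regions_per_population):
            region_centers[(p, r)] = centers[p] + rng.normal(0, 1.5, size=2)
    region_idx = rng.integers(0, cfg.regions_per_population, size=cfg.n_accessions)
    regions = [f"pop{p}_r{r}" for p, r in zip(pops, region_idx)]
    coords = np.vstack(
        [
            region_centers[(p, r)] + rng.normal(0, 0.3, size=2)
            for p, r in zip(pops, region_idx)
        ]
    )
    return (
        accs,
        pd.Series(pops, index=accs, name="population"),
        pd.Series(regions, index=accs, name="region"),
        pd.DataFrame(coords, index=accs, columns=["x", "y"]),
        centers,
        region_idx,
    )


def simulate_panel(cfg: SimConfig, genome: Genome) -> PanelData:
    """Population-structured SNPs, methylation states, and read counts."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    accs, pops, regions, coords, pop_centers, region_idx = _assign_geography(cfg, rng)
    n_acc = cfg.n_accessions
    levels_by_ctx = _context_levels(cfg)
    fractions_by_ctx = _context_fractions(cfg)

    sites: dict = {}
    state: dict = {}
    polymorphic: dict = {}
    broken: dict = {}
    snp_tables = {acc: [] for acc in accs}
    report_parts = {acc: [] for acc in accs}
    ancestor_meth = None
    ancestor_parts = []
    reference_parts = []

    region_key = [f"{p}:{r}" for p, r in zip(pops.to_numpy(), region_idx)]
    unique_regions = sorted(set(region_key))
    region_of_acc = np.array([unique_regions.index(k) for k in region_key])
    # geographic flip probability per accession (shared per region by design)
    dist_to_center = np.linalg.norm(
        coords.to_numpy() - pop_centers[pops.to_numpy()], axis=1
    )
    flip_prob_acc = cfg.epiallele_within_noise * (
        1.0 - np.exp(-dist_to_center / cfg.geography_decay)
    )
    # one flip probability per region: the mean over its accessions
    flip_prob_region = np.array(
        [flip_prob_acc[region_of_acc == r].mean() for r in range(len(unique_regions))]
    )

    for g in ("A", "B", "D"):
        seq = genome.sequences[g]
        ctx = derive_contexts(seq)
        n_sites = len(ctx)
        pos = ctx["pos"].to_numpy()
        strand = ctx["strand"].to_numpy()
        context = ctx["context"].to_numpy()
        sites[g] = ctx

        frac = np.array([fractions_by_ctx[c] for c in context])
        if g == "D":
            # the D subgenome descends from a diploid ancestor whose
            # methylation is retained imperfectly and gained rarely
            ancestor_meth = rng.random(n_sites) < frac
            base_state = np.where(
                ancestor_meth,
                rng.random(n_sites) < cfg.ancestral_retention,
                rng.random(n_sites) < cfg.ancestral_gain,
            )
        else:
            base_state = rng.random(n_sites) < frac
        epi = rng.random(n_sites) < cfg.epiallele_rate

        pop_state = np.tile(base_state[:, None], (1, cfg.n_populations))
        pop_flip = rng.random((n_sites, cfg.n_populations)) < 0.5
        pop_state = np.where(epi[:, None], pop_state ^ pop_flip, pop_state)

        region_flip = (
            rng.random((n_sites, len(unique_regions))) < flip_prob_region[None, :]
        )
        S = pop_state[:, pops.to_numpy()]
        S = np.where(epi[:, None], S ^ region_flip[:, region_of_acc], S)
        state[g] = S
        polymorphic[g] = S.any(axis=1) & ~S.all(axis=1)

        # ---- panel SNPs (population-structured; on D, cytosine positions are
        # reserved for the deamination model) ----
        L = len(seq)
        is_cyt = np.zeros(L, dtype=bool)
        is_cyt[pos - 1] = True
        snp_cand = rng.random(L) < cfg.panel_snp_rate
        if g == "D":
            snp_cand &= ~is_cyt
        snp_pos = np.flatnonzero(snp_cand)
        F = 0.2
        p0 = rng.uniform(0.1, 0.9, size=len(snp_pos))
        pop_freq = rng.beta(
            p0[:, None] * (1 - F) / F, (1 - p0[:, None]) * (1 - F) / F,
            size=(len(snp_pos), cfg.n_populations),
        )
        hom_alt = rng.random((len(snp_pos), n_acc)) < pop_freq[:, pops.to_numpy()]
        het = (~hom_alt) & (rng.random((len(snp_pos), n_acc)) < cfg.heterozygous_rate)
        seq_arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        alt_alleles = np.empty(len(snp_pos), dtype="U1")
        for i, p in enumerate(snp_pos):
            choices = BASES[BASES != seq_arr[p]]
            alt_alleles[i] = choices[rng.integers(0, 3)].decode("ascii")

        # ---- deamination mutations at D cytosines ----
        deam_mut = np.zeros((n_sites, n_acc), dtype=bool)
        deam_allele = None
        if g == "D":
            mu = cfg.deamination_base_rate * np.where(
                ancestor_meth, cfg.deamination_fold, 1.0
            )
            deam_mut = rng.random((n_sites, n_acc)) < mu[:, None]
            product = np.where(strand == "+", "T", "A")
            deam_allele = np.empty((n_sites, n_acc), dtype="U1")
            use_ct = rng.random((n_sites, n_acc)) < cfg.deamination_ct_bias
            refbase = np.array(
                [seq[p - 1] for p in pos]
            )
            for i in range(n_sites):
                others = [b for b in "ACGT" if b != refbase[i] and b != product[i]]
                rand_others = rng.integers(0, len(others), size=n_acc)
                for a in range(n_acc):
                    if deam_mut[i, a]:
                        deam_allele[i, a] = (
                            product[i] if use_ct[i, a] else others[rand_others[a]]
                        )

        # ---- per-accession mutated-position masks and reports ----
        chrom = CHROM_OF[g]
        lvl_ctx = np.array([levels_by_ctx[c] for c in context])
        level = state[g] * lvl_ctx[:, None]
        cov = rng.poisson(cfg.mean_coverage, size=(n_sites, n_acc))
        p_meth = level + (1.0 - level) * (1.0 - cfg.conversion_rate)
        n_meth = rng.binomial(cov, p_meth)
        n_unmeth = cov - n_meth

        hom_mask_any = np.zeros(L, dtype=bool)
        for a, acc in enumerate(accs):
            mut_mask = np.zeros(L, dtype=bool)
            mut_base = np.empty(L, dtype="U1")
            hom_here = np.flatnonzero(hom_alt[:, a])
            mut_mask[snp_pos[hom_here]] = True
            mut_base[snp_pos[hom_here]] = alt_alleles[hom_here]
            depth = rng.poisson(cfg.mean_coverage, size=len(snp_pos)).clip(min=5)
            for i in np.flatnonzero(hom_alt[:, a] | het[:, a]):
                is_hom = bool(hom_alt[i, a])
                d = int(depth[i])
                alt_d = d if is_hom else max(1, int(rng.binomial(d, 0.5)))
                snp_tables[acc].append(
                    (chrom, int(snp_pos[i]) + 1, seq[snp_pos[i]], alt_alleles[i],
                     d, alt_d, 50.0, "1/1" if is_hom else "0/1")
                )
            if g == "D":
                for i in np.flatnonzero(deam_mut[:, a]):
                    p1 = int(pos[i])
                    mut_mask[p1 - 1] = True
                    mut_base[p1 - 1] = deam_allele[i, a]
                    d = max(5, int(rng.poisson(cfg.mean_coverage)))
                    snp_tables[acc].append(
                        (chrom, p1, seq[p1 - 1], deam_allele[i, a], d, d, 50.0, "1/1")
                    )
            hom_mask_any |= mut_mask

            report = _accession_report(
                chrom, seq, pos, strand, context, mut_mask, mut_base,
                n_meth[:, a], n_unmeth[:, a],
            )
            report_parts[acc].append(report)

        # context-broken flag: any accession's homozygous substitution inside
        # a site's strand-oriented window (the C and 2 downstream bases)
        broken[g] = _window_hit(pos, strand, hom_mask_any, L)

        # reference accession: the descendant base states with no panel
        # SNPs, serving as the comparison baseline for DMRs and conservation
        ref_level = base_state * lvl_ctx
        ref_cov = rng.poisson(cfg.mean_coverage, size=n_sites)
        ref_p = ref_level + (1.0 - ref_level) * (1.0 - cfg.conversion_rate)
        ref_meth = rng.binomial(ref_cov, ref_p)
        reference_parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": strand,
                    "n_meth": ref_meth,
                    "n_unmeth": ref_cov - ref_meth,
                    "context": context,
                }
            )
        )

        if g == "D":
            anc_level = ancestor_meth * lvl_ctx
            anc_cov = rng.poisson(cfg.mean_coverage, size=n_sites)
            anc_p = anc_level + (1.0 - anc_level) * (1.0 - cfg.conversion_rate)
            anc_meth_reads = rng.binomial(anc_cov, anc_p)
            ancestor_parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "n_meth": anc_meth_reads,
                        "n_unmeth": anc_cov - anc_meth_reads,
                        "context": context,
                    }
                )
            )

    # ---- chloroplast: fully unmethylated ----
    cp_seq = genome.sequences[CHLOROPLAST]
    cp_ctx = derive_contexts(cp_seq)
    cp_pos = cp_ctx["pos"].to_numpy()
    ref_cp_cov = rng.poisson(cfg.mean_coverage, size=len(cp_ctx))
    ref_cp_meth = rng.binomial(ref_cp_cov, 1.0 - cfg.conversion_rate)
    reference_parts.append(
        pd.DataFrame(
            {
                "chrom": CHLOROPLAST,
                "pos": cp_pos,
                "strand": cp_ctx["strand"].to_numpy(),
                "n_meth": ref_cp_meth,
                "n_unmeth": ref_cp_cov - ref_cp_meth,
                "context": cp_ctx["context"].to_numpy(),
            }
        )
    )
    for a, acc in enumerate(accs):
        cov = rng.poisson(cfg.mean_coverage, size=len(cp_ctx))
        n_meth = rng.binomial(cov, 1.0 - cfg.conversion_rate)
        report_parts[acc].append(
            pd.DataFrame(
                {
                    "chrom": CHLOROPLAST,
                    "pos": cp_pos,
                    "strand": cp_ctx["strand"].to_numpy(),
                    "n_meth": n_meth,
                    "n_unmeth": cov - n_meth,
                    "context": cp_ctx["context"].to_numpy(),
                }
            )
        )

    reports = {
        acc: pd.concat(parts, ignore_index=True) for acc, parts in report_parts.items()
    }
    vcf_cols = ["chrom", "pos", "ref", "alt", "depth", "alt_depth", "qual", "gt"]
    vcfs = {
        acc: pd.DataFrame(rows, columns=vcf_cols).sort_values(
            ["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        for acc, rows in snp_tables.items()
    }

    genes, families = _make_annotation(cfg, genome, rng)
    te_counts, te_reference, te_meth, te_mult = _make_te(cfg, rng, accs)

    truth = GroundTruth(
        homoeolog_map=genome.homoeolog_map,
        population_labels=pops,
        regions=regions,
        coords=coords,
        sites=sites,
        methylation_state=state,
        site_polymorphic=polymorphic,
        site_context_broken=broken,
        ancestor_methylation=ancestor_meth,
        te_multipliers=te_mult,
        genes=genes,
        families=families,
    )
    return PanelData(
        genome=genome,
        accessions=accs,
        reports=reports,
        vcfs=vcfs,
        ancestor_report=pd.concat(ancestor_parts, ignore_index=True),
        reference_report=pd.concat(reference_parts, ignore_index=True),
        te_counts=te_counts,
        te_reference=te_reference,
        te_methylation=te_meth,
        truth=truth,
    )


def _window_hit(pos, strand, mask, L):
    """True where any masked 0-based position falls in a site's context window."""
    p0 = pos - 1
    hit = np.zeros(len(pos), dtype=bool)
    plus = strand == "+"
    for off in (0, 1, 2):
        idx = np.where(plus, p0 + off, p0 - off)
        valid = (idx >= 0) & (idx < L)
        hit[valid] |= mask[idx[valid]]
    return hit


def _accession_report(chrom, seq, pos, strand, context, mut_mask, mut_base,
                      n_meth, n_unmeth) -> pd.DataFrame:
    """Apply an accession's substitutions to the site list.

    A substitution at the cytosine itself abolishes the site (dropped); a
    substitution in the 2-base downstream window re-derives the context.
    """
    L = len(seq)
    hit = _window_hit(pos, strand, mut_mask, L)
    keep = np.ones(len(pos), dtype=bool)
    new_context = context.copy()
    for i in np.flatnonzero(hit):
        p0 = int(pos[i]) - 1
        if strand[i] == "+":
            idx = [p0, p0 + 1, p0 + 2]
        else:
            idx = [p0, p0 - 1, p0 - 2]
        win = []
        okwin = True
        for k, j in enumerate(idx):
            if not 0 <= j < L:
                okwin = False
                break
            b = mut_base[j] if mut_mask[j] else seq[j]
            if strand[i] == "-":
                b = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(b, "N")
            win.append(b)
        if not okwin:
            # incomplete window: only the C itself matters
            if mut_mask[p0]:
                keep[i] = False
            continue
        ctx_new = classify_window("".join(win))
        if ctx_new is None:
            keep[i] = False
        else:
            new_context[i] = ctx_new
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos[keep],
            "strand": strand[keep],
            "n_meth": n_meth[keep],
            "n_unmeth": n_unmeth[keep],
            "context": new_context[keep],
        }
    )


def _make_annotation(cfg: SimConfig, genome: Genome, rng):
    """Non-overlapping gene intervals per subgenome plus family clusters."""
    rows = []
    gene_names = []
    for g in ("A", "B", "D"):
        L = len(genome.sequences[g])
        gene_len = max(200, L // (3 * cfg.n_genes))
        slots = np.linspace(0, L - gene_len - 1, cfg.n_genes).astype(int)
        for j, s in enumerate(slots):
            start = int(s + rng.integers(0, max(1, gene_len // 2)))
            end = min(L, start + gene_len)
            name = f"gene{g}{j:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((CHROM_OF[g], start, end, name, 0, strand))
            gene_names.append(name)
    genes = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    fam_size = 3
    families = {
        f"fam{k:03d}": gene_names[k * fam_size : (k + 1) * fam_size]
        for k in range((len(gene_names) + fam_size - 1) // fam_size)
    }
    families = {k: v for k, v in families.items() if v}
    return genes, families


#: pooled read-level methylation of TE-aligned cytosines, by context
TE_METH_RATES = {"CpG": 0.90, "CHG": 0.70, "CHH": 0.40}


def _make_te(cfg: SimConfig, rng, accs):
    lib = TE_LIBRARY[: cfg.te_families]
    fams = [f for f, _, _ in lib]
    classes = {f: c for f, c, _ in lib}
    weights = np.array([w for _, _, w in lib], dtype=float)
    weights = weights / weights.sum()
    base = weights * 5e7

    mult = pd.DataFrame(
        np.exp(rng.normal(0.0, cfg.te_multiplier_sd, size=(len(accs), len(fams)))),
        index=accs, columns=fams,
    )
    te_counts = {}
    te_meth = {}
    for acc in accs:
        depth_scale = rng.uniform(0.5, 2.0)
        bases = base * mult.loc[acc].to_numpy() * depth_scale
        te_counts[acc] = pd.DataFrame(
            {"family": fams, "te_class": [classes[f] for f in fams],
             "bases": np.round(bases).astype(np.int64)}
        )
        rows = []
        for f in fams:
            for ctx, rate in TE_METH_RATES.items():
                n = 1000
                k = int(rng.binomial(n, rate * cfg.conversion_rate + (1 - rate) * (1 - cfg.conversion_rate)))
                rows.append((f, ctx, k, n - k))
        te_meth[acc] = pd.DataFrame(rows, columns=["family", "context", "n_meth", "n_unmeth"])
    te_reference = pd.DataFrame(
        {"family": fams, "te_class": [classes[f] for f in fams],
         "bases": np.round(base).astype(np.int64)}
    )
    return te_counts, te_reference, te_meth, mult


@dataclass
class ExpressionData:
    """Triad shares plus a replicate DE matrix with planted truth."""

    triads: pd.DataFrame        # triad, subgenome, expression (replicate mean), meth_class, methylated_genome
    triad_replicates: pd.DataFrame
    expr_matrix: pd.DataFrame   # genes x samples
    groups: dict                # accession -> replicate column names
    true_de_genes: set


def simulate_expression(cfg: SimConfig, truth: GroundTruth | None = None) -> ExpressionData:
    """Triad expression with promoter-methylation imbalance plus DE genes.

    One third of triads are tri-genome promoter-methylated (balanced
    expression), one third uni-genome methylated (the affected subgenome's
    expected share is ``uni_meth_share``%), one third unmethylated
    (balanced).  Replicates carry lognormal noise of ``expr_noise_sd`` on
    the log2 scale; with zero noise the shares are exact.  A separate
    two-accession gene matrix plants ``n_de_genes`` differentially
    expressed genes at ``de_log2_fold``.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 2])
    subgenomes = ["A", "B", "D"]
    classes = ["tri", "uni", "none"]
    rows_mean = []
    rows_rep = []
    triad_rows = []
    uni_share = cfg.uni_meth_share
    other_share = (100.0 - uni_share) / 2.0
    for t in range(cfg.n_triads):
        cls = classes[t % 3]
        meth_g = subgenomes[rng.integers(0, 3)] if cls == "uni" else ""
        total = float(np.exp(rng.normal(np.log(300.0), 0.3)))
        shares = {g: 100.0 / 3.0 for g in subgenomes}
        if cls == "uni":
            shares = {g: (uni_share if g == meth_g else other_share) for g in subgenomes}
        triad_rows.append((f"triad{t:03d}", cls, meth_g))
        for g in subgenomes:
            mean_expr = total * shares[g] / 100.0
            reps = mean_expr * np.exp2(
                rng.normal(0.0, cfg.expr_noise_sd, size=cfg.n_expr_replicates)
            ) if cfg.expr_noise_sd > 0 else np.full(cfg.n_expr_replicates, mean_expr)
            for j, v in enumerate(reps):
                rows_rep.append((f"triad{t:03d}", g, j, float(v)))
            rows_mean.append(
                (f"triad{t:03d}", g, float(np.mean(reps)), cls, meth_g)
            )
    triads = pd.DataFrame(
        rows_mean,
        columns=["triad", "subgenome", "expression", "meth_class", "methylated_genome"],
    )
    triad_replicates = pd.DataFrame(
        rows_rep, columns=["triad", "subgenome", "replicate", "expression"]
    )

    n_genes = max(cfg.n_de_genes * 10, 100)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    de = set(rng.choice(gene_ids, size=cfg.n_de_genes, replace=False).tolist())
    base = np.exp(rng.normal(np.log(200.0), 0.5, size=n_genes))
    cols = {}
    groups = {"accA": [], "accB": []}
    for accession, shift in (("accA", 0.0), ("accB", cfg.de_log2_fold)):
        for j in range(cfg.n_expr_replicates):
            name = f"{accession}_rep{j}"
            groups[accession].append(name)
            mean = base * np.exp2(
                np.where([gid in de for gid in gene_ids], shift if accession == "accB" else 0.0, 0.0)
            )
            noise = (
                np.exp2(rng.normal(0.0, cfg.expr_noise_sd, size=n_genes))
                if cfg.expr_noise_sd > 0
                else 1.0
            )
            cols[name] = mean * noise
    expr = pd.DataFrame(cols, index=gene_ids)
    if truth is not None:
        truth.true_de_genes = de
        truth.triad_classes = pd.DataFrame(
            triad_rows, columns=["triad", "meth_class", "methylated_genome"]
        )
    return ExpressionData(
        triads=triads,
        triad_replicates=triad_replicates,
        expr_matrix=expr,
        groups=groups,
        true_de_genes=de,
    )
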