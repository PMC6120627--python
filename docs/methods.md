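# Methods

polymethkit analyses DNA-methylation diversity across a panel of inbred
allohexaploid accessions, starting from per-cytosine bisulfite read counts
and per-accession variant calls. This note records the models, thresholds,
numerical choices, and the assumptions behind the synthetic panel that the
test suite and the acceptance script run on.

## Calling model

Every strand-specific cytosine carries counts (n_meth, n_unmeth); the
methylation level is 100·n_meth/(n_meth+n_unmeth). Status calls use
context-dependent thresholds reflecting plant methylation biology:

| rule | default | rationale |
|---|---|---|
| methylated, CpG | level ≥ 75% | CpG methylation is near-binary in plants |
| methylated, CHG/CHH | level ≥ 10% | non-CpG methylation is low-level |
| unmethylated, any context | level < 1% | tolerates no more than trace signal |
| uncovered | coverage < 10 reads | SMP/DMR analyses; 5 reads for genotype summaries |

Levels between the bounds are *intermediate*: retained in outputs but
excluded from the methylated/unmethylated classes, since intermediate
levels likely reflect tissue-specific regulation that single-seedling data
cannot resolve. The <1% rule is applied uniformly across analyses
(configurable); one consequence, quantified below, is censoring of
truly-unmethylated sites when bisulfite conversion is imperfect.

The bisulfite conversion rate is estimated from the chloroplast, which
carries no methylation: the pooled fraction of converted chloroplast
cytosine reads. Sites are never merged across strands; both strands of a
CpG dyad are scored independently.

## SMPs

A single methylation polymorphism is a cytosine (i) covered to ≥10 reads
in *every* accession, (ii) with identical underlying sequence panel-wide —
operationalised as no homozygous SNP in any accession within the cytosine
and its two downstream bases on its strand (the context window), and
(iii) called methylated (code 100) in ≥2 accessions and unmethylated
(code 0) in ≥2. Intermediate calls are coded 50 and do not disqualify a
site. At least 4 accessions are required or the definition is
unsatisfiable. A gene counts as methylated in an accession when ≥1 CpG in
its body is called methylated (configurable); gene-group thresholds
(high ≥90, low <40 accessions) are stated for a 105-accession panel and
scale proportionally to the actual panel size.

## Subgenome methylation classes

Homoeologous positions are translated through an indel-aware one-to-one
map stored as gapless aligned segments, with the A subgenome as the anchor
frame (B↔D composes through A); translation inside a segment is an exact
offset and is bijective wherever defined. Classified triples use pairwise
two-sided Fisher exact tests on pooled read counts with
Benjamini–Hochberg correction across the whole batch; a pair differs when
q < 0.01 *and* the level difference is ≥50 points. tri = methylated in all
three subgenomes; uni = methylated in exactly one, which differs from both
others; bi = methylated in exactly two, each differing from the third;
anything inconsistent is left unclassified rather than forced. BH is used
instead of the SLIM correction some regional callers apply; BH is the
standard reproducible choice and the decision is visible in the output
metadata.

## DMRs

Methylation is pooled over non-overlapping 100-bp windows anchored at
coordinate 0 of each chromosome (the last partial window is kept if it
qualifies). A window is tested only with ≥5 cytosines covered ≥10× in
both samples; the pooled 2×2 table gets a two-sided Fisher test and BH
q-values per batch. Calls: CpG/CHG need |Δ| ≥ 50 points at q < 0.01; CHH
needs |Δ| ≥ 15 points with the lower sample ≤5% at q < 0.01 (the "low"
rule is applied to the window mean per sample). Pooled-count testing —
not per-cytosine averaging — matches regional-counting callers.
Promoters default to 2 kb upstream of the TSS, strand-aware, when no
promoter track is supplied.

## Deamination enrichment and ancestral conservation

5-methylcytosine deaminates to thymine directly, so ancestrally methylated
cytosines accumulate C→T (G→A on the minus strand) transitions faster.
Per accession, ancestor cytosines are stratified by the ancestor's
methylated/unmethylated call; the divergence fraction (any homozygous
non-ancestral allele; heterozygous calls excluded) and the
deamination-product fraction are computed per stratum, and paired
two-sided t-tests compare strata across accessions. The fold is the ratio
of divergence fractions, averaged over accessions.

Conservation between the ancestor and the descendant D subgenome compares
informative calls at shared positions against the reference accession.
**Censoring bias:** with conversion at 98.7% and 30× coverage, roughly a
third of truly-unmethylated sites carry ≥1 conversion-failure read, fail
the <1% rule, and drop to intermediate — while methylated sites are almost
always retained. Conditioning on informative calls therefore inflates
apparent conservation by ≈4 points at the default conversion rate. The
parameter-recovery experiment in the acceptance script runs at
conversion_rate = 1.0, where the estimator is unbiased up to small calling
losses; conversion-rate recovery itself is checked separately.

## Population structure

Accessions are clustered with complete linkage on Euclidean distances,
using SMP epiallele codes {0, 50, 100} directly as numeric features (or
SNP alternate-allele frequencies). SciPy's deterministic linkage supplies
tie-breaking. Cluster support is an in-package reimplementation of
multiscale-bootstrap AU values: sites are resampled at scales
0.5–1.4 × n_sites, z(r) = Φ⁻¹(1−BP(r)) is fitted by weighted least squares
to v·√r + c/√r, and AU = 1 − Φ(v − c). Clades present in all (or no)
replicates at every scale give a flat probit curve from which v and c are
not separable; these report AU 1 (or 0) directly. The Mantel statistic is
the Pearson correlation of upper-triangle distances with a one-sided
permutation p = (1 + #{r* ≥ r})/(n_perm + 1). The Wald–Wolfowitz runs test
uses the closed-form moments μ_R = 2n₁n₂/n + 1 and
σ²_R = 2n₁n₂(2n₁n₂−n)/(n²(n−1)). Geography concordance reports, per
region, the modal-cluster share and the fraction of regions with a ≥50%
majority; because two-accession regions pass the majority rule trivially,
permutation contrasts use the mean modal share, a finer summary of the
same quantity.

## Expression

Differential expression between two accessions is a Welch t-test on
log2(x+1) with the added requirement that every replicate of one accession
lies on the same side of every replicate of the other; a transcript-level
replicate model is deliberately not reproduced — the replicate-consistency
rule preserves the "all replicates agree" acceptance logic at gene level.
Triad expression is normalised so the three subgenome shares sum to 100%;
the uni-methylated contrast is a Welch t between the methylated
subgenome's share and the mean of the other two, per triad.

## TE profiles

Off-target reads approximate shotgun sampling, so per-family aligned
base-space ("cumulative coverage": summed aligned bases, not breadth)
tracks family abundance. Profiles are normalised to a fixed 50 Mb total
and compared to the reference accession as signed differences; per-class
aggregates split DNA transposons from retrotransposons. In a two-class
summary a gain on one side is exactly the other's loss.

## Synthetic panel: what it emulates and what it does not

The generator draws one ancestor sequence and derives subgenomes A, B, D
by substitutions (2%/lineage) and short indels (10⁻³/base, 1–3 bp),
recording the exact segment map as ground truth. Default panel: 20
accessions in 2 populations, 3 collection regions per population with 2-D
coordinates; Poisson(30) coverage truncated at zero per site; binomial
read sampling; conversion 98.7%. Methylation: a fraction of sites per
context is ancestrally methylated (CpG 40%, CHG/CHH 15%); methylated
sites read at level 0.90 (CpG), 0.40 (CHG), 0.30 (CHH) — the non-CpG
read-levels of *methylated* sites are moderate, while marginal per-context
methylation stays low because most non-CpG sites are unmethylated, giving
the bimodal CpG / low-CHH pattern. Epialleles (10% of sites) vary at the
population level and, within populations, at the region level: each
region's deviation probability follows an exponential geographic kernel,
noise·(1−exp(−d/ℓ)) with d the region's distance from its population
centre, so accessions collected together share epialleles. The D
subgenome descends from an explicit diploid ancestor with methylation
retention 83.7% and gain 3.1%; ancestrally methylated D cytosines mutate
per accession at 4× the base rate (0.5%), with the mutant allele being
the deamination product 96% of the time, and a mutated cytosine is
removed from the carrier's callable set. Panel SNPs are
population-structured (Balding–Nichols, F = 0.2); on D, cytosine
positions are reserved for the deamination model so the fourfold
parameter stays clean. A SNP-free reference accession (read from the
descendant base states) provides the comparison baseline, and a separate
ancestor report provides the progenitor's calls. Uni-methylated triads
express their methylated homoeolog at 28.82% versus 35.59% for each of
the other two; replicates carry log2-normal noise (σ = 0.25).

Not emulated: read-level errors beyond conversion failure, linkage
disequilibrium and recombination, within-accession (cell-to-cell)
methylation heterogeneity — states are binary per accession per site,
matching single-seedling sampling — strand-symmetric CpG dyad coupling,
and capture-efficiency overdispersion (coverage is plain Poisson).
Passing tests therefore demonstrate correctness of the estimators and
filters under this model, not robustness to alignment artefacts or
overdispersed real-world coverage.

## Problem sizes

The suite and acceptance script run at desk scale, chosen so each check is
statistically decisive: 20 k-base subgenomes (≈30 k cytosines) for SMP
checks at 20 accessions, 100 k-base subgenomes (≈50 k D cytosines) for
deamination recovery, 1000 null + 100 planted windows for DMR
calibration, exhaustive Fisher enumeration to table total 40 (134 030
tables), 1000 Mantel null replicates at 30 accessions, and 10 000
homoeolog round-trip positions. Every stochastic quantity is seeded; the
acceptance script derives all sub-seeds from its --seed argument.
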