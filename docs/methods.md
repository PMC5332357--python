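# Methods

This note records the models behind `mutseek`, the defaults that matter,
and the choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The mapping model

The package models a map-based cloning design for a monogenic recessive
trait induced by EMS mutagenesis:

* An inbred line is mutagenised; the resulting mutant line is homozygous
  for a set of G:C→A:T transitions (the canonical EMS spectrum) at a
  density of `ems_rate_per_kb` (default 0.3/kb, the density implied by
  ~1.1 × 10⁵ SNPs over a ~3.7 × 10⁸ bp genome in the emulated study).
* The mutant is crossed to its non-mutagenised parent; F1 plants are
  heterozygous at every induced site. A bulk of `bulk_size` (default 42)
  homozygous-recessive F2 plants is sequenced together with the parent,
  both against the same public reference.
* Among the bulk's 2 × 42 = 84 chromosomes, the mutant-parent allele is
  present with probability 1 at the causal locus and 1 − r at a site
  with recombination fraction r to it (a gamete carrying the causal
  allele carries the linked allele unless a crossover separated them);
  unlinked sites segregate at ½. The SNP index estimates this frequency
  from reads.

### Sequencing model

Depth per site is Poisson(`mean_depth`, default 30); alt reads are
Binomial(depth, true frequency). This is the simplest model consistent
with pooled short-read data; it ignores mapping bias, base-calling error
and over-dispersion. Zero-depth sites produce no record. The wild-type
parent table records induced sites as ref-homozygous and shares
`n_background_snps` (default 300) parental variants with the mutant pool;
the mutant-specific derivation removes any site where the parent shows
alt evidence (heterozygous parent calls are also treated as shared
background — the method is defined only for the homozygous contrast).

### Genome scale and the genetic map

The synthetic reference is 7 chromosomes × 500 kb (default), with genes
stamped into random sequence — a deliberate ~50-fold physical reduction
that keeps a full pipeline run under a second. The genetic map is a
constant `cm_per_kb` (default 0.2 cM/kb, ≈100 cM per chromosome).
The scale-down preserves the *genetic length* of a chromosome rather
than the per-bp crossover rate: what the bulk signal and the candidate
region's width depend on is the genetic distance profile along a
chromosome, and a 500-kb chromosome carrying a realistic ~100 cM behaves
like a real chromosome. (Keeping a real-genome rate of ~3 cM/Mb instead
would compress each synthetic chromosome to 1.5 cM — every site would be
effectively fully linked to the causal locus, the candidate region would
span whole chromosomes, and no filter cascade could isolate a unique
survivor.)

Genes default to 3 per chromosome with 900-bp CDS over 3 exons
(GT…AG introns of 200 bp). The causal gene — the middle gene of
chromosome 5, forward strand — instead mirrors the mapped candidate's
architecture: nine exons, a 1392-bp CDS (463 residues plus stop) with a
tryptophan codon (TGG) at position 157 placed in exon 2, so the planted
G→A at spliced-CDS position 470 creates the TAG stop. The gene density
is sparse relative to a real genome; it is chosen so that the expected
number of *additional* exonic non-synonymous fixed sites inside the
candidate region stays well below one, which is the regime in which the
cascade can end at a single SNP. The generator also draws its random
mutations outside the causal gene's CDS, so that CDS carries exactly the
one planted stop-gain — emulating a study design with a single causal
exonic lesion.

### What the generator does not emulate

Read-level artefacts (FASTQ, mapping error, duplicated regions), indels
and structural variants, interference-aware crossover placement along
the physical genome, population structure in the natural panel, and
realistic gene density. A pipeline that passes on this generator is
validated for its statistical logic and bookkeeping, not for robustness
to alignment noise or to gene-dense regions where several linked exonic
changes can co-occur (in real data the panel/resequencing comparison, not
the cascade alone, resolves those).

## Per-module notes

**Segregation.** χ² goodness of fit with arbitrary positive class
weights and no Yates correction — the uncorrected statistic is the
classical test for Mendelian ratios and reproduces the published
P-values (448:130 → χ² = 1.94, P = 0.164; 1038:318 → χ² = 1.73,
P = 0.188). Expected counts of zero are an error. The F3 progeny test
calls any segregating family heterozygous and an all-normal family of n
homozygous with misclassification probability (3/4)ⁿ; an all-mutant
family from a normal-phenotype parent is flagged inconsistent.

**SNP-index filter ("index = 1").** With 30× depth, literal equality to
1 is fragile (one mis-mapped read breaks it), so the fixation criterion
defaults to index ≥ 0.95 *and* ≥ 10 alt reads; strict equality is
available (`strict_index=True`). The candidate-region threshold on
window means defaults to 0.9 and is exposed — the emulated study did not
publish the exact bound it used. Regions are ranked by peak mean, then
span, then (chromosome, start) for deterministic ties.

**Marker simulation.** Markers are specified by Kosambi cM from the
trait locus on one chromosome arm. Gametes are generated by a Markov
walk along the ordered loci: each interval recombines independently with
probability `inverse_kosambi(Δd)`. The marker adjacent to the trait
therefore recombines at exactly the inverse-Kosambi rate of its
distance, and pairwise marker linkage reflects the map; recombination
fractions across several intervals follow the Markov composite rather
than the single-interval Kosambi value (interference between intervals
is not modelled). Distances ≥ 50 cM are a sentinel for "unlinked"
(independent chromosome, r = ½) — the literal inverse-Kosambi of 50 cM
(r = 0.38) would still be strongly detectable association.

**Linkage estimation.** Marker–trait r uses only mutant-class plants
(the trait locus is a fully penetrant recessive scored by phenotype):
among their 2n marker alleles each is recombinant with probability r,
giving the binomial MLE and LOD = log₁₀ L(r̂) − log₁₀ L(½). Marker–marker
r maximises the 3×3 F2 class-table likelihood numerically (coupling
phase). Grouping is single linkage at LOD ≥ 4.0; ordering minimises the
sum of adjacent Kosambi distances, exhaustively for ≤ 8 markers and by
greedy seriation from the most peripheral marker above that (adequate
for maps of a dozen markers; orientation of a group is arbitrary).
Missing genotypes are dropped pairwise.

**dCAPS design.** The search tries each enzyme, strand and placement of
the recognition pattern over the SNP; the pattern base at the SNP must
match exactly one allele, template bases beyond the primer must match
naturally, and at most one engineered primer substitution is allowed,
restricted to the primer's final five bases excluding the 3'-terminal
base (standard practice — a terminal mismatch would block extension).
Zero-mismatch solutions are natural CAPS. The amplicon end is chosen
(within 150–300 bp, the scale of the emulated 254-bp assay) so the
discriminating site is the only cut: the cut allele yields exactly two
fragments, the uncut allele one. Primer Tm is reported by the Wallace
2+4 rule, advisory only. Enzymes are plain data (name, IUPAC pattern,
top-strand cut offset) and user-extensible; DdeI (C^TNAG) ships first.

**Phylogeny.** Distances default to the protein p-distance with
pairwise gap deletion (the common default for distance-based protein
trees); Poisson correction −ln(1−p) and complete deletion are options.
NJ follows Saitou–Nei with the Q-criterion, deterministic lowest-index
tie-break, and negative branch estimates clamped to zero with the
deficit moved to the sibling edge (path lengths preserved, node
flagged). Bootstrap support is the percentage of column-resampled
replicate trees containing the same bipartition, canonicalised so the
result is invariant to leaf input order; replicates whose resampled
columns leave a pair with no comparable sites are skipped.

**Expression.** Technical replicates are averaged to one Ct per
biological replicate before analysis; ΔCt = Ct_target − Ct_reference;
fold = 2^−ΔΔCt with amplification efficiency fixed at 100% (the plain
2^−ΔΔCt method) by default; per-assay efficiencies can be supplied, in
which case the Pfaffl ratio E_t^ΔCt_t / E_r^ΔCt_r is used (it reduces
exactly to 2^−ΔΔCt at E = 2). The condition-level fold uses the mean
ΔCt, so the calibrator's fold is exactly 1 by construction. Comparisons are
two-sided Welch t-tests on per-replicate ΔCt (approximately normal,
unlike fold) at α = 0.01 by default; identical zero-variance vectors are
reported as P = 1. No multiple-testing correction is applied across
organs (contrasts are reported per organ, as in the emulated analysis).
Feedback classification: repressed/induced if significant with fold
below/above 1, unchanged otherwise, incomplete if a treatment arm is
missing.

## Randomness and reproducibility

One master seed drives everything. Each generator stage draws from
`numpy.random.default_rng(SeedSequence(seed, spawn_key=(k,)))` with a
fixed stage key (genome 0, EMS 1, depths 2, markers 3, panel 4, Ct 5,
proteins 6), so stages are independent streams and any stage can be
regenerated in isolation; all outputs are bit-reproducible given the
seed.

## Problem sizes used in the checks

The test suite exercises the defaults end to end: 100 seeded pipeline
runs for the recovery-rate property; 1,000 random SNPs against the
full-translation annotation oracle; 50 random additive matrices (≤ 10
taxa) for NJ; 200 replicates of 130 mutant plants for r-recovery;
1,000-column alignments and 1,000 bootstrap replicates in the worked
phylogeny example. These sizes were chosen so the whole suite completes
in well under a minute while keeping Monte-Carlo tolerances (±0.02 on
means) several standard errors wide.

## Known limitations

Single transcript per gene; no splice-site or UTR effect classes (exonic
non-CDS sites are `exonic_noncoding` and never pass the non-synonymous
filter); only substitution SNPs; codominant markers only (the emulated
study also used dominant markers, whose scoring it did not specify); qPCR efficiencies must be supplied by the user (no
standard-curve estimation from raw fluorescence); dCAPS design does not model primer thermodynamics or partial
digestion.
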