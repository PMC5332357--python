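# mutseek

Map an EMS-induced recessive mutation to a single causal nucleotide — the
computational chain of a forward-genetics map-based cloning study, as a
tested Python library.

`mutseek` is for plant geneticists and computational biologists who work
with bulked-segregant sequencing of mutant populations and want the whole
downstream analysis — segregation testing, SNP-index mapping, candidate
filtering, marker design, linkage maps, homolog phylogenies and qPCR
quantification — in one importable, seedable package. A synthetic-data
generator emulates the full study design (mutagenised line crossed to its
wild-type parent, a homozygous-recessive F2 bulk, a natural germplasm
panel), so every step runs end-to-end at desk scale with no downloads.

## The methods at its core

**SNP-index (MutMap) mapping.** A bulk of n homozygous-recessive F2
plants is sequenced along with the wild-type parent, both aligned to the
same public reference. After subtracting variants shared with the parent
(pre-existing background), each mutagen-induced site gets a SNP index

    SNP index = alt reads / (ref reads + alt reads),

the read fraction of the mutant allele in the bulk. Its expectation is 1
at the causal locus, 1 − r at a site with recombination fraction r to it,
and ½ at unlinked sites. Indices are smoothed with a moving window of
five consecutive SNPs shifted one SNP at a time, each window plotted at
the midpoint of its first and fifth member; runs of windows with mean
index above a threshold (default 0.9) delimit the candidate region.
Candidates are then filtered in a fixed cascade — in region, exonic,
non-synonymous, fixed in the bulk — and survivors are screened against a
natural panel: a truly mutagen-induced allele is carried by no panel line.

**Around it:** χ² goodness-of-fit tests against Mendelian ratios and
F3 progeny tests with misclassification probability (3/4)^n; strand-aware
variant-effect annotation against GFF3 gene models (codon,
synonymous/missense/stop-gained); CAPS/dCAPS assay design with in-silico
IUPAC restriction digestion; recombination-fraction ML estimates, the
Kosambi map function d = 25 ln((1+2r)/(1−2r)) and LOD-threshold linkage
grouping; Saitou–Nei neighbor joining with bootstrap bipartition support;
and 2^−ΔΔCt relative expression with Welch tests on ΔCt.

## Worked example

```python
from mutseek import SimulationConfig, run_pipeline

result = run_pipeline(SimulationConfig(seed=1))
```

The default configuration simulates a 7 × 500 kb genome, ~1050 EMS
transitions (0.3/kb), a 42-plant bulk at 30× depth and a 412-line panel.
`examples/02_mutmap_mapping.py` prints, for seed 1:

```
EMS mutations simulated:   1049
mutant-specific SNPs:      1049
top candidate region:      chr5:196348-311152 (peak window mean index 0.986)
filter cascade funnel:
  input            1049
  in_region        39
  exonic           1
  non_synonymous   1
  homozygous       1
surviving SNP:             chr5:249173 G>A, codon 157 TGG->TAG (stop_gained)
panel screen:              0/412 carriers -> unique
planted causal SNP:        chr5:249173 recovered uniquely: True
```

Reading: of 1049 mutagen-induced SNPs, 39 fall in the high-index region
on chromosome 5; exactly one is exonic, non-synonymous and fixed in the
bulk — a G→A at spliced-CDS position 470 converting tryptophan codon 157
(TGG) to a stop (TAG) — and no natural line carries it, so it is called
as the causal nonsense mutation. The other scripts in `examples/`
demonstrate segregation testing, BSA + linkage mapping, dCAPS design
(e.g. a DdeI assay whose cut allele gives 19 + 235 bp bands from a
254-bp amplicon while the uncut allele stays 254 bp), NJ phylogenies
with 1000 bootstraps, and ΔΔCt feedback analysis.

A thin CLI mirrors the library:

```bash
mutseek simulate --out data/ --seed 1
mutseek mutmap --mutant data/mutant_pool.vcf --wt data/wt_parent.vcf
mutseek segtest --obs 448,130 --ratio 3,1
mutseek njtree --alignment family.fasta --boot 1000 --seed 7
```

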