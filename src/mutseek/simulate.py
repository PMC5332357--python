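"""Synthetic-data generator for the whole mapping pipeline.

Generates every input the downstream modules need — a multi-chromosome
reference with gene models, an EMS mutation set carrying one planted
causal stop-gain SNP, pooled allele depths for a homozygous-recessive F2
bulk and its wild-type parent, F2 marker genotypes, natural-panel
genotypes, a simulated protein family for phylogeny, and qPCR Ct tables
— with the statistical structure of the emulated study design:

* EMS produces G:C -> A:T transitions at a density of 0.3 mutations/kb,
  drawn Poisson over the genome (the causal gene's CDS carries exactly
  one mutation: the planted stop-gain);
* the mutant bulk pools 42 homozygous-recessive F2 plants, so the
  mutant-allele frequency among the bulk's 84 chromosomes is 1 at the
  causal locus, decays with genetic distance along its chromosome
  (per-chromosome transmission probability 1 - r), and averages 0.5 at
  unlinked mutagen-induced sites;
* read depth per site is Poisson, alt reads Binomial(depth, frequency) —
  the simplest model consistent with pooled short-read data;
* the wild-type parent shares the background SNPs (variants against the
  public reference present in both parents) but is ref-homozygous at
  every EMS site;
* the natural panel is homozygous wild type at mutagen-induced sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, reverse_complement, site_key, translate_cds
from .config import SimulationConfig
from .linkage import inverse_kosambi
from .mutmap import VARIANT_COLUMNS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# structure of the causal gene, mirroring the study's candidate:
# nine exons, a 1392-bp CDS (463 residues + stop) with a tryptophan
# codon (TGG) at position 157 falling in the second exon.
CAUSAL_CDS_CODONS = 464
CAUSAL_N_EXONS = 9
CAUSAL_TRP_CODON = 157


class Mutation(NamedTuple):
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class CausalVariant:
    """The planted causal stop-gain SNP and its CDS geometry."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    cds_pos: int
    codon_number: int
    ref_codon: str
    alt_codon: str

    @property
    def key(self) -> str:
        return site_key(self.chrom, self.pos)


@dataclass
class SyntheticGenome:
    """Reference chromosomes plus their (single-transcript) gene models."""

    chromosomes: dict[str, str]
    gene_models: list[GeneModel]
    causal_gene_id: str

    @property
    def causal_gene(self) -> GeneModel:
        for g in self.gene_models:
            if g.gene_id == self.causal_gene_id:
                return g
        raise KeyError(self.causal_gene_id)

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def base(self, chrom: str, pos: int) -> str:
        return self.chromosomes[chrom][pos - 1]

    def validate(self) -> None:
        """Check gene-model invariants against the sequence."""
        for g in self.gene_models:
            if g.end > len(self.chromosomes[g.chrom]):
                raise ValueError(f"{g.gene_id} extends past {g.chrom}")
            g.check_frame()
            cds = g.spliced_cds(self.chromosomes)
            if not cds.startswith("ATG"):
                raise ValueError(f"{g.gene_id}: CDS does not start with ATG")
            if cds[-3:] not in _STOPS:
                raise ValueError(f"{g.gene_id}: CDS does not end with a stop codon")
            if len(translate_cds(cds)) != len(cds) // 3 - 1:
                raise ValueError(f"{g.gene_id}: internal stop codon")


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _split_lengths(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _design_cds(
    rng: np.random.Generator, n_codons: int, forced: Mapping[int, str] | None = None
) -> str:
    """ATG + random sense codons + one stop; ``forced`` pins codons."""
    forced = dict(forced or {})
    codons = ["ATG"]
    for c in range(2, n_codons):
        codons.append(forced.get(c) or _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))])
    codons.append(forced.get(n_codons) or ("TAA", "TAG", "TGA")[rng.integers(0, 3)])
    return "".join(codons)


def _intron(rng: np.random.Generator, length: int) -> str:
    if length < 4:
        raise ValueError("introns need at least 4 bp (GT...AG)")
    middle = _random_bases(rng, length - 4).tobytes().decode()
    return "GT" + middle + "AG"


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    center: int,
    strand: str,
    n_codons: int,
    n_exons: int,
    intron_len: int,
    exon_split: Sequence[int] | None = None,
    forced_codons: Mapping[int, str] | None = None,
) -> tuple[GeneModel, int, str]:
    """Return the gene model, its genomic start and its forward-strand seq."""
    cds = _design_cds(rng, n_codons, forced_codons)
    splits = list(exon_split) if exon_split else _split_lengths(len(cds), n_exons)
    if sum(splits) != len(cds):
        raise ValueError("exon split does not sum to CDS length")
    pieces: list[str] = []
    offsets: list[tuple[int, int]] = []  # 0-based [s, e) in transcription order
    cursor = 0
    cds_cursor = 0
    for i, seg in enumerate(splits):
        offsets.append((cursor, cursor + seg))
        pieces.append(cds[cds_cursor : cds_cursor + seg])
        cds_cursor += seg
        cursor += seg
        if i < len(splits) - 1:
            pieces.append(_intron(rng, intron_len))
            cursor += intron_len
    region = "".join(pieces)
    span = len(region)
    gene_start = max(1, center - span // 2)
    if strand == "+":
        exons = [(gene_start + s, gene_start + e - 1) for s, e in offsets]
        genomic = region
    else:
        exons = [(gene_start + span - e, gene_start + span - 1 - s) for s, e in offsets]
        genomic = reverse_complement(region)
    model = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)
    return model, gene_start, genomic


def simulate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Random chromosomes with evenly spaced genes stamped into them.

    Genes alternate strand; the causal gene (middle gene of the
    designated chromosome, forward strand) gets the nine-exon, 1392-bp
    CDS structure with TGG at codon 157.
    """
    rng = config.rng("genome")
    chromosomes: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    causal_gene_id = ""
    causal_chrom = config.chrom_names()[config.causal_chrom_index]
    causal_slot = config.genes_per_chromosome // 2
    gene_counter = 0
    for ci, chrom in enumerate(config.chrom_names()):
        seq = _random_bases(rng, config.chrom_length_bp)
        for gi in range(config.genes_per_chromosome):
            gene_counter += 1
            center = config.chrom_length_bp * (gi + 1) // (config.genes_per_chromosome + 1)
            is_causal = chrom == causal_chrom and gi == causal_slot
            if is_causal:
                split = [300, 300] + _split_lengths(3 * CAUSAL_CDS_CODONS - 600, 7)
                model, start, genomic = _build_gene(
                    rng,
                    gene_id=f"gene{gene_counter:03d}",
                    chrom=chrom,
                    center=center,
                    strand="+",
                    n_codons=CAUSAL_CDS_CODONS,
                    n_exons=CAUSAL_N_EXONS,
                    intron_len=config.intron_length_bp,
                    exon_split=split,
                    forced_codons={CAUSAL_TRP_CODON: "TGG"},
                )
                causal_gene_id = model.gene_id
            else:
                model, start, genomic = _build_gene(
                    rng,
                    gene_id=f"gene{gene_counter:03d}",
                    chrom=chrom,
                    center=center,
                    strand="+" if gene_counter % 2 else "-",
                    n_codons=config.gene_cds_codons,
                    n_exons=config.gene_n_exons,
                    intron_len=config.intron_length_bp,
                )
            if start + len(genomic) - 1 > config.chrom_length_bp:
                raise ValueError("gene does not fit inside its chromosome")
            seq[start - 1 : start - 1 + len(genomic)] = np.frombuffer(
                genomic.encode(), dtype=np.uint8
            )
            gene_models.append(model)
        chromosomes[chrom] = seq.tobytes().decode()
    genome = SyntheticGenome(
        chromosomes=chromosomes,
        gene_models=gene_models,
        causal_gene_id=causal_gene_id,
    )
    return genome


# ---------------------------------------------------------------------------
# EMS mutations
# ---------------------------------------------------------------------------

def plant_causal(genome: SyntheticGenome, gene: GeneModel | None = None) -> CausalVariant:
    """Pick the stop-gain site of the designated gene.

    Searches the spliced CDS for a codon that a single G->A or C->T
    transition converts to a stop (TGG codons, yielding TAG via the
    second position, are preferred — the canonical EMS nonsense change).
    """
    gene = gene or genome.causal_gene
    spliced = gene.spliced_cds(genome.chromosomes)
    candidates: list[tuple[int, int, str, str]] = []
    for c in range(1, len(spliced) // 3):  # exclude the terminal stop codon
        codon = spliced[3 * (c - 1) : 3 * c]
        for w, b in enumerate(codon):
            if b not in "GC":
                continue
            alt_b = "A" if b == "G" else "T"
            alt_codon = codon[:w] + alt_b + codon[w + 1 :]
            if alt_codon in _STOPS and codon not in _STOPS:
                candidates.append((c, w, codon, alt_codon))
    if not candidates:
        raise ValueError(
            f"gene {gene.gene_id}: no codon can be converted to a stop by a "
            "G->A/C->T transition; cannot plant a causal stop-gain SNP"
        )
    trp = [c for c in candidates if c[2] == "TGG" and c[3] == "TAG"]
    preferred = [c for c in trp if c[0] == CAUSAL_TRP_CODON]
    c, w, ref_codon, alt_codon = (preferred or trp or candidates)[0]
    cds_pos = 3 * (c - 1) + w + 1
    pos = gene.genomic_position_of(cds_pos)
    ref = genome.base(gene.chrom, pos)
    alt_b = alt_codon[w]
    alt = alt_b if gene.strand == "+" else _COMPLEMENT[alt_b]
    return CausalVariant(
        chrom=gene.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene_id=gene.gene_id,
        cds_pos=cds_pos,
        codon_number=c,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
    )


def simulate_ems_mutations(
    genome: SyntheticGenome, config: SimulationConfig
) -> tuple[list[Mutation], CausalVariant]:
    """Draw the EMS mutation set and plant the causal stop-gain.

    The count is Poisson(rate x genome kb); every mutation is a G->A or
    C->T transition at a distinct position.  The causal gene's CDS
    carries exactly one mutation — the plant — so random draws falling
    there are excluded.
    """
    rng = config.rng("ems")
    causal = plant_causal(genome)
    causal_gene = genome.causal_gene
    excluded = {
        p for s, e in causal_gene.cds for p in range(s, e + 1)
    }
    chrom_names = list(genome.chromosomes)
    candidate_pos: list[np.ndarray] = []
    for chrom in chrom_names:
        arr = np.frombuffer(genome.chromosomes[chrom].encode(), dtype=np.uint8)
        mask = (arr == ord("G")) | (arr == ord("C"))
        if chrom == causal_gene.chrom:
            idx = np.fromiter((p - 1 for p in excluded), dtype=np.int64)
            mask[idx] = False
        candidate_pos.append(np.flatnonzero(mask) + 1)  # 1-based
    counts = np.array([len(p) for p in candidate_pos])
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total_candidates = int(offsets[-1])
    n = int(rng.poisson(config.ems_rate_per_kb * genome.total_bp / 1000.0))
    n = min(n, total_candidates)
    picks = rng.choice(total_candidates, size=n, replace=False)
    mutations: list[Mutation] = []
    for flat in picks:
        ci = int(np.searchsorted(offsets, flat, side="right") - 1)
        pos = int(candidate_pos[ci][flat - offsets[ci]])
        chrom = chrom_names[ci]
        ref = genome.base(chrom, pos)
        alt = "A" if ref == "G" else "T"
        mutations.append(Mutation(chrom, pos, ref, alt))
    mutations.append(Mutation(causal.chrom, causal.pos, causal.ref, causal.alt))
    mutations.sort(key=lambda m: (m.chrom, m.pos))
    return mutations, causal


# ---------------------------------------------------------------------------
# Pooled allele depths
# ---------------------------------------------------------------------------

def simulate_bulk_depths(
    genome: SyntheticGenome,
    mutations: Sequence[Mutation],
    causal: CausalVariant,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site allele depths for the mutant bulk and the WT parent.

    The true mutant-allele frequency in the bulk is 1 at the causal
    site; at another EMS site with recombination fraction r to the
    causal locus it is Binomial(2 x bulk_size, 1 - r) / (2 x bulk_size)
    (each of the bulk's chromosomes carries the mutant-parent allele
    independently with probability 1 - r, given it carries the causal
    allele); unlinked sites use r = 0.5.  Read depth is
    Poisson(mean_depth) and alt reads Binomial(depth, frequency);
    zero-depth sites are dropped (no evidence, no record).  Shared
    parental background SNPs are alt-homozygous in both tables; the WT
    table records EMS sites as ref-homozygous (zero alt reads).
    """
    rng = config.rng("depths")
    n_chrom = 2 * config.bulk_size
    rows_mut: list[tuple] = []
    rows_wt: list[tuple] = []
    for m in mutations:
        if m.chrom == causal.chrom and m.pos == causal.pos:
            freq = 1.0
        else:
            if m.chrom == causal.chrom:
                cm = abs(m.pos - causal.pos) / 1000.0 * config.cm_per_kb
                r = inverse_kosambi(cm) if cm < 50 else 0.5
            else:
                r = 0.5
            freq = rng.binomial(n_chrom, 1.0 - r) / n_chrom
        depth = int(rng.poisson(config.mean_depth))
        if depth > 0:
            alt_d = int(rng.binomial(depth, freq))
            rows_mut.append((m.chrom, m.pos, m.ref, m.alt, depth - alt_d, alt_d))
        wt_depth = int(rng.poisson(config.mean_depth))
        if wt_depth > 0:
            rows_wt.append((m.chrom, m.pos, m.ref, m.alt, wt_depth, 0))
    # shared parental background: both parents alt-homozygous vs the reference
    taken = {(m.chrom, m.pos) for m in mutations}
    chrom_names = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chrom_names], dtype=float)
    placed = 0
    while placed < config.n_background_snps:
        ci = int(rng.choice(len(chrom_names), p=lengths / lengths.sum()))
        chrom = chrom_names[ci]
        pos = int(rng.integers(1, int(lengths[ci]) + 1))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        ref = genome.base(chrom, pos)
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        depth = int(rng.poisson(config.mean_depth))
        if depth > 0:
            rows_mut.append((chrom, pos, ref, alt, 0, depth))
        wt_depth = int(rng.poisson(config.mean_depth))
        if wt_depth > 0:
            rows_wt.append((chrom, pos, ref, alt, 0, wt_depth))
        placed += 1
    mutant = pd.DataFrame(rows_mut, columns=VARIANT_COLUMNS)
    wt = pd.DataFrame(rows_wt, columns=VARIANT_COLUMNS)
    for df in (mutant, wt):
        df.sort_values(["chrom", "pos"], inplace=True, ignore_index=True)
    return mutant, wt


# ---------------------------------------------------------------------------
# F2 marker genotypes
# ---------------------------------------------------------------------------

DEFAULT_MARKER_CM = {
    "SSR_0cM": 0.0,
    "SSR_1.1cM": 1.1,
    "SSR_5.5cM": 5.5,
    "SSR_8.9cM": 8.9,
    "SSR_unlinked": 50.0,
}


def simulate_marker_table(
    config: SimulationConfig,
    marker_cm: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """F2 individuals x markers genotype table plus phenotype column.

    Marker positions are given as Kosambi cM from the trait locus, all
    on one chromosome arm.  Gametes are drawn by Mendelian transmission
    along the ordered loci (trait at 0 cM, then markers by increasing
    distance): each interval recombines independently with per-gamete
    crossover probability equal to the inverse Kosambi of its length,
    so a marker adjacent to the trait recombines at exactly the
    inverse-Kosambi rate of its distance and pairwise marker linkage
    reflects the map.  Distances >= 50 cM are treated as unlinked
    (r = 0.5, an independent chromosome).  Phenotype is mutant iff the
    individual is homozygous recessive at the trait locus.  Codes:
    A = WT-parent homozygote, H = het, B = mutant-line homozygote.
    """
    marker_cm = dict(DEFAULT_MARKER_CM if marker_cm is None else marker_cm)
    for name, cm in marker_cm.items():
        if cm < 0:
            raise ValueError(f"marker {name}: negative map distance")
    rng = config.rng("markers")
    n = config.n_f2
    trait = rng.integers(0, 2, size=(2, n))  # 1 = mutant allele, per gamete
    code = np.array(["A", "H", "B"])
    alleles: dict[str, np.ndarray] = {}
    linked = sorted(
        ((cm, name) for name, cm in marker_cm.items() if cm < 50), key=lambda t: t[0]
    )
    prev_cm, prev_state = 0.0, trait
    for cm, name in linked:
        r = inverse_kosambi(cm - prev_cm)
        flips = rng.random((2, n)) < r
        state = prev_state ^ flips
        alleles[name] = state
        prev_cm, prev_state = cm, state
    for name, cm in marker_cm.items():
        if cm >= 50:
            alleles[name] = rng.integers(0, 2, size=(2, n))
    data = {name: code[alleles[name].sum(axis=0)] for name in marker_cm}
    data["phenotype"] = np.where(trait.sum(axis=0) == 2, "mutant", "normal")
    index = [f"F2_{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(data, index=index)


# ---------------------------------------------------------------------------
# Natural panel
# ---------------------------------------------------------------------------

def simulate_panel(
    config: SimulationConfig,
    sites: Sequence[str],
    n_background_loci: int = 20,
) -> pd.DataFrame:
    """Genotype table (mutant-allele dosage) for the natural panel.

    Every line is homozygous wild type (dosage 0) at each mutagen-induced
    site in ``sites`` — new mutations are absent from standing natural
    variation.  Optional background loci segregate at Hardy-Weinberg
    dosages with random allele frequencies, so the table is not
    trivially all-zero.
    """
    rng = config.rng("panel")
    n = config.n_panel
    data: dict[str, np.ndarray] = {}
    for key in sites:
        data[key] = np.zeros(n, dtype=int)
    for i in range(n_background_loci):
        maf = rng.uniform(0.05, 0.5)
        data[f"bg_{i + 1:02d}"] = rng.binomial(2, maf, size=n)
    index = [f"line_{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(data, index=index)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    config: SimulationConfig,
    target: str = "CsCYP85A1",
    reference: str = "UBI-ep",
    organs: Sequence[str] = ("leaf", "stem", "root"),
    genotypes: Sequence[str] = ("WT", "mutant"),
    treatments: Sequence[str] = ("mock", "BL"),
    fold_bl: Mapping[str, float] | None = None,
    n_bio: int = 3,
    n_tech: int = 3,
    noise_sd: float = 0.15,
    target_baseline_ct: float = 24.0,
    reference_ct: float = 18.0,
) -> pd.DataFrame:
    """Long-format Ct table: sample x gene x 3 biological x 3 technical reps.

    Ct = baseline - log2(true expression) + Normal noise (biological noise
    shared by a bio rep's technical reps, plus technical noise per well).
    The reference gene has constant expression everywhere.  ``fold_bl``
    gives the hormone-feedback effect: the target's expression under the
    BL (brassinolide) treatment relative to mock, per genotype — by
    default 4-fold repression in the WT and no change in the mutant,
    whose feedback loop is broken.
    """
    fold_bl = dict(fold_bl or {"WT": 0.25, "mutant": 1.0})
    rng = config.rng("ct")
    rows = []
    for organ in organs:
        for gt in genotypes:
            for tr in treatments:
                expr = 1.0 if tr == "mock" else fold_bl.get(gt, 1.0)
                sample = f"{organ}_{gt}_{tr}"
                condition = f"{gt}_{tr}"
                for b in range(1, n_bio + 1):
                    bio_noise_t = rng.normal(0, noise_sd) if noise_sd else 0.0
                    bio_noise_r = rng.normal(0, noise_sd) if noise_sd else 0.0
                    for t in range(1, n_tech + 1):
                        tech_t = rng.normal(0, noise_sd / 2) if noise_sd else 0.0
                        tech_r = rng.normal(0, noise_sd / 2) if noise_sd else 0.0
                        rows.append(
                            (sample, organ, gt, tr, condition, target, b, t,
                             target_baseline_ct - math.log2(expr) + bio_noise_t + tech_t)
                        )
                        rows.append(
                            (sample, organ, gt, tr, condition, reference, b, t,
                             reference_ct + bio_noise_r + tech_r)
                        )
    return pd.DataFrame(
        rows,
        columns=["sample", "organ", "genotype", "treatment", "condition",
                 "gene", "bio_rep", "tech_rep", "ct"],
    )


# ---------------------------------------------------------------------------
# Protein family for phylogeny
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_protein_family(
    n_taxa: int = 16,
    seq_len: int = 300,
    seed: int = 0,
    branch_range: tuple[float, float] = (0.02, 0.12),
):
    """Evolve a gap-free protein family down a random unrooted tree.

    Substitutions only (the alignment is the identity), each site
    replaced with probability 1 - exp(-branch length) by a uniformly
    chosen different residue.  Returns ``(names, sequences, true_tree)``
    where the true tree is a :class:`mutseek.phylo.PhyloTree`.
    """
    from .phylo import PhyloTree, TreeNode

    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(6,))
    )
    lo, hi = branch_range
    nodes = [TreeNode(name=f"taxon{i + 1:02d}", length=rng.uniform(lo, hi))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        child_j = nodes.pop(int(j))
        child_i = nodes.pop(int(i))
        nodes.append(
            TreeNode(children=[child_i, child_j], length=rng.uniform(lo, hi))
        )
    root = TreeNode(children=nodes)
    tree = PhyloTree(root)

    seqs: dict[str, str] = {}

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        bl = node.length or 0.0
        p_sub = 1.0 - math.exp(-bl)
        child_seq = seq.copy()
        hits = np.flatnonzero(rng.random(seq_len) < p_sub)
        for h in hits:
            choices = [a for a in range(20) if a != child_seq[h]]
            child_seq[h] = choices[rng.integers(0, 19)]
        if node.is_leaf():
            seqs[node.name] = "".join(_AA[a] for a in child_seq)
        else:
            for ch in node.children:
                evolve(ch, child_seq)

    root_seq = rng.integers(0, 20, seq_len)
    for ch in root.children:
        evolve(ch, root_seq)
    names = sorted(seqs)
    return names, [seqs[n] for n in names], tree
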