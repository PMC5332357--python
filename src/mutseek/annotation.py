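"""Variant-effect annotation against gene models, the candidate filter
cascade, and the natural-panel uniqueness screen.

Gene models carry one transcript each (the mapped trait is a single-gene
recessive locus; the study's candidate has a single annotated transcript).
Coordinates are 1-based inclusive throughout, the GFF3/VCF convention.
Splice-site and UTR effects are not modelled: a site inside an exon but
outside the CDS is labelled ``exonic_noncoding`` and does not count as
non-synonymous in the cascade.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .mutmap import VariantSite, CandidateRegion, passes_fixation_rule

NONSYNONYMOUS = frozenset({"missense", "stop_gained", "stop_lost", "start_lost"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A single-transcript protein-coding gene on the reference.

    ``exons`` and ``cds`` are lists of 1-based inclusive ``(start, end)``
    intervals in genomic order (sorted by start regardless of strand).
    If ``cds`` is omitted the exons are taken to be entirely coding.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.cds is None:
            self.cds = list(self.exons)
        else:
            self.cds = sorted(tuple(c) for c in self.cds)

    # -- geometry -----------------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def check_frame(self) -> None:
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {self.cds_length} is not a multiple of 3"
            )

    def cds_position_of(self, pos: int) -> int | None:
        """Map a genomic position to its 1-based spliced-CDS coordinate."""
        offset = 0  # 0-based offset from the genomic-leftmost CDS base
        for s, e in self.cds:
            if s <= pos <= e:
                offset += pos - s
                break
            offset += e - s + 1
        else:
            return None
        if self.strand == "+":
            return offset + 1
        return self.cds_length - offset

    def genomic_position_of(self, cds_pos: int) -> int:
        """Inverse of :meth:`cds_position_of`."""
        if not 1 <= cds_pos <= self.cds_length:
            raise ValueError(f"cds_pos {cds_pos} outside CDS of {self.gene_id}")
        offset = cds_pos - 1 if self.strand == "+" else self.cds_length - cds_pos
        for s, e in self.cds:
            seg = e - s + 1
            if offset < seg:
                return s + offset
            offset -= seg
        raise AssertionError("unreachable")

    def spliced_cds(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS in transcription order (reverse-complemented on '-')."""
        chrom = genome[self.chrom]
        seq = "".join(chrom[s - 1 : e] for s, e in self.cds)
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass
class EffectCall:
    """Predicted consequence of a single-nucleotide substitution."""

    site: VariantSite
    gene_id: str | None
    region: str  # exonic / exonic_noncoding / intronic / intergenic
    cds_pos: int | None = None
    codon_number: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    effect: str | None = None


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard nuclear code.

    Translation stops at the first stop codon; the returned protein
    excludes the stop, so a 1392-bp CDS with one terminal stop yields
    463 residues.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValueError(f"CDS contains non-ACGT characters: {sorted(bad)}")
    return str(Seq(cds).translate(to_stop=True))


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def _classify(codon_number: int, ref_aa: str, alt_aa: str) -> str:
    if ref_aa == alt_aa:
        return "synonymous"
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    if codon_number == 1 and ref_aa == "M":
        return "start_lost"
    return "missense"


class _GeneIndex:
    """Per-chromosome sorted interval lookup (genes assumed non-overlapping)."""

    def __init__(self, gene_models: Iterable[GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for g in sorted(gene_models, key=lambda g: (g.chrom, g.start)):
            starts, genes = self._by_chrom.setdefault(g.chrom, ([], []))
            starts.append(g.start)
            genes.append(g)

    def find(self, chrom: str, pos: int) -> GeneModel | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, genes = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and genes[i].contains(pos):
            return genes[i]
        return None


def annotate_effect(
    site: VariantSite,
    gene_models: Sequence[GeneModel] | _GeneIndex,
    genome: Mapping[str, str],
) -> EffectCall:
    """Annotate a SNP against gene models and the reference sequence.

    The genomic reference base at ``site.pos`` must equal ``site.ref``.
    For genes on the '-' strand the substituted base is complemented
    before codon translation.
    """
    chrom_seq = genome[site.chrom]
    if not 1 <= site.pos <= len(chrom_seq):
        raise ValueError(f"position {site.chrom}:{site.pos} outside the genome")
    if chrom_seq[site.pos - 1] != site.ref:
        raise ValueError(
            f"reference mismatch at {site.chrom}:{site.pos}: "
            f"genome has {chrom_seq[site.pos - 1]}, site says {site.ref}"
        )
    index = gene_models if isinstance(gene_models, _GeneIndex) else _GeneIndex(gene_models)
    gene = index.find(site.chrom, site.pos)
    if gene is None:
        return EffectCall(site=site, gene_id=None, region="intergenic")
    if not gene.in_cds(site.pos):
        region = "exonic_noncoding" if gene.in_exon(site.pos) else "intronic"
        return EffectCall(site=site, gene_id=gene.gene_id, region=region)
    gene.check_frame()
    cds_pos = gene.cds_position_of(site.pos)
    codon_number = math.ceil(cds_pos / 3)
    within = (cds_pos - 1) % 3
    cds_seq = gene.spliced_cds(genome)
    ref_codon = cds_seq[3 * (codon_number - 1) : 3 * codon_number]
    alt_base = site.alt if gene.strand == "+" else site.alt.translate(_COMPLEMENT)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    return EffectCall(
        site=site,
        gene_id=gene.gene_id,
        region="exonic",
        cds_pos=cds_pos,
        codon_number=codon_number,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect=_classify(codon_number, ref_aa, alt_aa),
    )


def build_gene_index(gene_models: Iterable[GeneModel]) -> _GeneIndex:
    """Pre-build the interval index when annotating many sites."""
    return _GeneIndex(gene_models)


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

@dataclass
class FunnelReport:
    """Per-stage survivor counts of the candidate filter cascade."""

    stages: list[tuple[str, int]]
    survivors: list[EffectCall]

    def __str__(self) -> str:  # human-readable funnel
        lines = [f"{name:<16} {n}" for name, n in self.stages]
        return "\n".join(lines)


def filter_cascade(
    effect_calls: Sequence[EffectCall],
    region: CandidateRegion,
    min_index: float = 0.95,
    min_alt_depth: int = 10,
    strict_index: bool = False,
) -> FunnelReport:
    """Apply the four candidate filters in fixed order.

    1. site inside the candidate region;
    2. exonic (within the CDS);
    3. non-synonymous (missense / stop_gained / stop_lost / start_lost);
    4. fixed in the mutant pool (the "SNP index = 1" criterion, applied as
       index >= ``min_index`` with >= ``min_alt_depth`` supporting reads, or
       literal equality when ``strict_index``).

    The fixed order keeps funnel reports comparable across runs.
    """
    calls = list(effect_calls)
    stages = [("input", len(calls))]
    calls = [
        c
        for c in calls
        if c.site.chrom == region.chrom and region.start <= c.site.pos <= region.end
    ]
    stages.append(("in_region", len(calls)))
    calls = [c for c in calls if c.region == "exonic"]
    stages.append(("exonic", len(calls)))
    calls = [c for c in calls if c.effect in NONSYNONYMOUS]
    stages.append(("non_synonymous", len(calls)))
    calls = [
        c
        for c in calls
        if passes_fixation_rule(
            c.site, min_index=min_index, min_alt_depth=min_alt_depth, strict=strict_index
        )
    ]
    stages.append(("homozygous", len(calls)))
    return FunnelReport(stages=stages, survivors=calls)


# ---------------------------------------------------------------------------
# Natural-panel uniqueness screen
# ---------------------------------------------------------------------------

@dataclass
class PanelScreenResult:
    site_key: str
    n_lines: int
    n_carriers: int
    verdict: str  # "unique" | "not_unique"


def site_key(chrom: str, pos: int) -> str:
    return f"{chrom}:{pos}"


def panel_uniqueness_screen(site: VariantSite | str, panel: pd.DataFrame) -> PanelScreenResult:
    """Count natural-panel lines carrying the mutant allele at a site.

    ``panel`` holds one row per line and one column per site (keys
    ``chrom:pos``), with values the mutant-allele dosage (0/1/2).  The
    verdict is ``unique`` iff no line carries the allele — the signature
    of a mutagen-induced, rather than standing, variant.
    """
    key = site if isinstance(site, str) else site_key(site.chrom, site.pos)
    if panel.shape[0] == 0:
        raise ValueError("panel table is empty")
    if key not in panel.columns:
        raise KeyError(f"site {key} absent from the panel genotype table")
    dosages = panel[key]
    n_carriers = int((dosages > 0).sum())
    return PanelScreenResult(
        site_key=key,
        n_lines=int(panel.shape[0]),
        n_carriers=n_carriers,
        verdict="unique" if n_carriers == 0 else "not_unique",
    )
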