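"""dCAPS/CAPS marker design and in-silico restriction digestion.

A CAPS assay genotypes a SNP that creates or destroys a natural
restriction site.  When no such site exists, a dCAPS assay engineers
one: a PCR primer carrying a small number of deliberate mismatches
(here at most one, placed in the primer's 3' tail but never at the
3'-terminal base, the standard practice that preserves extension)
completes an enzyme's recognition pattern on exactly one allele.
Digesting the amplicon then cuts one allele and not the other, e.g. a
254-bp amplicon cut after base 19 giving 19 + 235 bp bands for the
mutant allele and a single 254-bp band for the wild type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values

_IUPAC = {code: frozenset(bases) for code, bases in ambiguous_dna_values.items()}
_COMPLEMENT_CODE = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp_pattern(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT_CODE)[::-1]


def _revcomp_seq(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition pattern (IUPAC) plus top-strand cut offset from its start."""

    name: str
    pattern: str
    cut_offset: int

    def __post_init__(self) -> None:
        bad = [c for c in self.pattern.upper() if c not in _IUPAC]
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC codes {bad}")
        if not 0 <= self.cut_offset <= len(self.pattern):
            raise ValueError(f"{self.name}: cut offset outside the pattern")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def matches(self, seq: str, start: int) -> bool:
        if start < 0 or start + len(self.pattern) > len(seq):
            return False
        return all(
            seq[start + k] in _IUPAC[self.pattern[k]] for k in range(len(self.pattern))
        )


#: Common enzymes; DdeI (C^TNAG) is the one used in the emulated assay.
DEFAULT_ENZYMES: tuple[RestrictionEnzyme, ...] = (
    RestrictionEnzyme("DdeI", "CTNAG", 1),
    RestrictionEnzyme("EcoRI", "GAATTC", 1),
    RestrictionEnzyme("HindIII", "AAGCTT", 1),
    RestrictionEnzyme("HinfI", "GANTC", 1),
    RestrictionEnzyme("MseI", "TTAA", 1),
    RestrictionEnzyme("Sau3AI", "GATC", 0),
    RestrictionEnzyme("AluI", "AGCT", 2),
    RestrictionEnzyme("RsaI", "GTAC", 2),
    RestrictionEnzyme("TaqI", "TCGA", 1),
)

DDE_I = DEFAULT_ENZYMES[0]


# ---------------------------------------------------------------------------
# Scanning and digestion
# ---------------------------------------------------------------------------

def scan_cut_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All cut positions of an enzyme in a sequence, both orientations.

    A cut position ``c`` means the enzyme cuts after the 1-based base
    ``c``.  Recognition in reverse orientation (pattern on the bottom
    strand) cuts at the mirrored offset.  Physical sites matching in
    both orientations (palindromic patterns) are reported once, at the
    forward-orientation cut.  Cuts at the extreme ends (no fragment on
    one side) are dropped.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains invalid bases: {sorted(bad)}")
    length = len(enzyme.pattern)
    rc = RestrictionEnzyme(enzyme.name, _revcomp_pattern(enzyme.pattern), enzyme.cut_offset)
    cuts: set[int] = set()
    for i in range(len(seq) - length + 1):
        fwd = enzyme.matches(seq, i)
        rev = rc.matches(seq, i)
        if fwd:
            cuts.add(i + enzyme.cut_offset)
        elif rev:
            cuts.add(i + length - enzyme.cut_offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(amplicon: str, enzyme: RestrictionEnzyme) -> tuple[int, ...]:
    """Fragment lengths 5' to 3'; their sum equals the amplicon length."""
    if not amplicon:
        raise ValueError("amplicon is empty")
    cuts = scan_cut_sites(amplicon, enzyme)
    bounds = [0] + cuts + [len(amplicon)]
    return tuple(b - a for a, b in zip(bounds, bounds[1:]))


# ---------------------------------------------------------------------------
# Assay design
# ---------------------------------------------------------------------------

class NoAssayFoundError(Exception):
    """No enzyme/placement satisfies the design constraints."""

    def __init__(self, snp: tuple, n_enzymes: int, n_placements: int):
        self.snp = snp
        self.n_enzymes = n_enzymes
        self.n_placements = n_placements
        super().__init__(
            f"no CAPS/dCAPS assay found for SNP {snp} "
            f"({n_enzymes} enzymes, {n_placements} placements examined)"
        )


@dataclass(frozen=True)
class DcapsAssay:
    """A designed allele-discriminating digestion assay.

    ``primer`` is the forward primer 5'->3' in assay orientation with any
    engineered mismatches already substituted; ``mismatch_positions`` are
    its 0-based mismatched offsets.  ``fragments_ref``/``fragments_alt``
    are the predicted band patterns per allele; exactly one allele is
    cut.  ``orientation`` records whether the assay reads the reference
    forward strand ('+') or its reverse complement ('-').
    """

    snp_pos: int
    ref: str
    alt: str
    enzyme: RestrictionEnzyme
    assay_type: str            # "CAPS" | "dCAPS"
    orientation: str
    primer: str
    primer_start: int          # 1-based, assay orientation coordinates
    mismatch_positions: tuple[int, ...]
    amplicon_start: int
    amplicon_length: int
    fragments_ref: tuple[int, ...]
    fragments_alt: tuple[int, ...]
    cut_allele: str            # "ref" | "alt"
    tm_advisory: float

    def band_table(self) -> str:
        return (
            f"{self.enzyme.name} digestion of the {self.amplicon_length}-bp amplicon\n"
            f"  ref allele ({self.ref}): {' + '.join(map(str, self.fragments_ref))} bp\n"
            f"  alt allele ({self.alt}): {' + '.join(map(str, self.fragments_alt))} bp"
        )


def primer_tm(primer: str) -> float:
    """Advisory Wallace 2+4 rule melting temperature."""
    at = sum(primer.count(b) for b in "AT")
    gc = sum(primer.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


def _allele_bases(pattern_code: str, ref: str, alt: str) -> tuple[bool, bool]:
    allowed = _IUPAC[pattern_code]
    return ref in allowed, alt in allowed


def _try_orientation(
    seq: str,
    pos: int,
    ref: str,
    alt: str,
    enzymes: Sequence[RestrictionEnzyme],
    orientation: str,
    max_mismatch: int,
    primer_len: int,
    amplicon_range: tuple[int, int],
    mismatch_window: int,
) -> DcapsAssay | tuple[int, int]:
    """Search one strand orientation; return an assay or (n_enz, n_place)."""
    min_len, max_len = amplicon_range
    n_place = 0
    for enzyme in enzymes:
        pat = enzyme.pattern
        L = len(pat)
        for j in range(L):  # pattern index aligned with the SNP
            n_place += 1
            start = pos - j  # 1-based genomic start of the pattern
            if start < pos - primer_len + 1 or start + L - 1 > len(seq):
                continue
            hits_ref, hits_alt = _allele_bases(pat[j], ref, alt)
            if hits_ref == hits_alt:
                continue  # pattern does not discriminate the alleles
            # pattern bases downstream of the SNP are template, must match
            if not all(
                seq[start - 1 + k] in _IUPAC[pat[k]] for k in range(j + 1, L)
            ):
                continue
            # pattern bases upstream are covered by the primer tail;
            # engineer mismatches where the genome does not already match
            primer_start = pos - primer_len  # 1-based
            if primer_start < 1:
                continue
            mismatches: list[int] = []  # 0-based offsets within the primer
            ok = True
            for k in range(j):
                gpos = start + k
                if seq[gpos - 1] in _IUPAC[pat[k]]:
                    continue
                offset = gpos - primer_start  # 0-based within primer
                # allowed zone: final `mismatch_window` bases minus 3' terminus
                if not (primer_len - 1 - mismatch_window <= offset <= primer_len - 2):
                    ok = False
                    break
                mismatches.append(offset)
            if not ok or len(mismatches) > max_mismatch:
                continue
            primer = list(seq[primer_start - 1 : pos - 1])
            for off in mismatches:
                code = pat[(primer_start + off) - start]
                choices = sorted(_IUPAC[code] - {primer[off]})
                primer[off] = choices[0]
            primer_seq = "".join(primer)
            # choose the amplicon end: as long as allowed without a second
            # cut site on either allele downstream of the engineered one
            for amp_len in range(min(max_len, len(seq) - primer_start + 1), min_len - 1, -1):
                amp_end = primer_start + amp_len - 1
                if amp_end < start + L - 1:
                    break
                template = seq[pos : amp_end]  # after the SNP base
                base_amp = primer_seq  # engineered upstream part
                amp_ref = base_amp + ref + template
                amp_alt = base_amp + alt + template
                frags_ref = digest(amp_ref, enzyme)
                frags_alt = digest(amp_alt, enzyme)
                one_cut = (len(frags_ref) == 1) != (len(frags_alt) == 1)
                if not one_cut:
                    continue
                cut_allele = "ref" if len(frags_ref) > 1 else "alt"
                if len(frags_ref if cut_allele == "ref" else frags_alt) != 2:
                    continue  # stray natural site in the amplicon
                return DcapsAssay(
                    snp_pos=pos,
                    ref=ref,
                    alt=alt,
                    enzyme=enzyme,
                    assay_type="dCAPS" if mismatches else "CAPS",
                    orientation=orientation,
                    primer=primer_seq,
                    primer_start=primer_start,
                    mismatch_positions=tuple(mismatches),
                    amplicon_start=primer_start,
                    amplicon_length=amp_len,
                    fragments_ref=frags_ref,
                    fragments_alt=frags_alt,
                    cut_allele=cut_allele,
                    tm_advisory=primer_tm(primer_seq),
                )
    return len(enzymes), n_place


def design_dcaps(
    sequence: str,
    pos: int,
    ref: str,
    alt: str,
    enzymes: Sequence[RestrictionEnzyme] = DEFAULT_ENZYMES,
    max_mismatch: int = 1,
    primer_len: int = 25,
    amplicon_range: tuple[int, int] = (150, 300),
    mismatch_window: int = 5,
) -> DcapsAssay:
    """Design a CAPS or dCAPS assay discriminating a SNP's two alleles.

    For each enzyme and each placement of its recognition pattern over
    the SNP, the search checks whether the pattern base at the SNP
    matches exactly one allele, whether the template bases beyond the
    primer already fit the pattern, and whether at most ``max_mismatch``
    primer substitutions (restricted to the final ``mismatch_window``
    bases excluding the 3' terminus) complete it.  Zero-mismatch
    solutions are natural CAPS.  The amplicon end is chosen so the
    enzyme cuts the discriminated allele exactly once and the other not
    at all.  Both strand orientations are tried.  Raises
    :class:`NoAssayFoundError` when the search is exhausted.
    """
    sequence = sequence.upper()
    if not 1 <= pos <= len(sequence):
        raise ValueError("SNP position outside the sequence")
    if sequence[pos - 1] != ref.upper():
        raise ValueError(
            f"sequence has {sequence[pos - 1]} at position {pos}, expected ref {ref}"
        )
    total_place = 0
    for orientation in "+-":
        if orientation == "+":
            seq_o, pos_o, ref_o, alt_o = sequence, pos, ref.upper(), alt.upper()
        else:
            seq_o = _revcomp_seq(sequence)
            pos_o = len(sequence) - pos + 1
            ref_o = _revcomp_seq(ref.upper())
            alt_o = _revcomp_seq(alt.upper())
        result = _try_orientation(
            seq_o, pos_o, ref_o, alt_o, enzymes, orientation,
            max_mismatch, primer_len, amplicon_range, mismatch_window,
        )
        if isinstance(result, DcapsAssay):
            return result
        total_place += result[1]
    raise NoAssayFoundError((pos, ref, alt), len(enzymes), total_place)
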