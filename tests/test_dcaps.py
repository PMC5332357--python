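"""Restriction scanning, digestion arithmetic, and dCAPS/CAPS design."""

import re

import numpy as np
import pytest
from Bio.Restriction import DdeI
from Bio.Seq import Seq

from mutseek.dcaps import (
    DDE_I,
    DEFAULT_ENZYMES,
    NoAssayFoundError,
    RestrictionEnzyme,
    design_dcaps,
    digest,
    scan_cut_sites,
)

IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT", "R": "AG", "Y": "CT"}


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestScan:
    def test_manual_pattern_match(self):
        # C^TNAG inside AACTGAGAA: site CTGAG at base 3, cut after base 3
        assert scan_cut_sites("AACTGAGAA", DDE_I) == [3]

    def test_no_site(self):
        assert scan_cut_sites("AAAAAAAA", DDE_I) == []

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            scan_cut_sites("ACGTN", DDE_I)

    def test_palindromic_site_counted_once(self):
        """Brute force over both strands: each physical site appears once."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            seq = random_seq(rng, 300)
            cuts = scan_cut_sites(seq, DDE_I)
            assert cuts == sorted(set(cuts))
            # forward+reverse regex matches, deduplicated by start
            pat = re.compile("CT[ACGT]AG")
            starts = {m.start() for m in pat.finditer(seq)}
            rc = str(Seq(seq).reverse_complement())
            starts_rc = {len(seq) - m.start() - 5 for m in pat.finditer(rc)}
            assert len(cuts) == len(starts | starts_rc)

    def test_agrees_with_biopython_catalog(self):
        """Cut positions match Bio.Restriction's DdeI (which reports the
        first base after the cut) on random sequences."""
        rng = np.random.default_rng(8)
        for _ in range(25):
            seq = random_seq(rng, 400)
            ours = scan_cut_sites(seq, DDE_I)
            theirs = [p - 1 for p in DdeI.search(Seq(seq))]
            assert ours == sorted(theirs)


class TestDigest:
    def test_single_cut_after_base_19_of_254(self):
        """The worked assay arithmetic: one cut after base 19 of a 254-bp
        amplicon gives 19 + 235 bp; the uncut allele stays 254 bp."""
        cut_amp = ("AT" * 9) + "CTAAG" + ("AT" * 115) + "T"
        uncut_amp = ("AT" * 9) + "CAAAG" + ("AT" * 115) + "T"
        assert len(cut_amp) == len(uncut_amp) == 254
        assert digest(cut_amp, DDE_I) == (19, 235)
        assert digest(uncut_amp, DDE_I) == (254,)

    def test_two_cuts(self):
        # cuts after 10 and 20 in a 50-mer -> 10, 10, 30
        seq = ("A" * 9) + "CTTAG" + "AAAAA" + "CTTAG" + "A" * 26
        assert len(seq) == 50
        assert scan_cut_sites(seq, DDE_I) == [10, 20]
        assert digest(seq, DDE_I) == (10, 10, 30)

    def test_fragments_conserve_length(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            seq = random_seq(rng, int(rng.integers(50, 400)))
            for enz in DEFAULT_ENZYMES[:4]:
                assert sum(digest(seq, enz)) == len(seq)

    def test_empty_amplicon_rejected(self):
        with pytest.raises(ValueError):
            digest("", DDE_I)


class TestEnzymeDefinition:
    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme("bad", "CTZAG", 1)
        with pytest.raises(ValueError):
            RestrictionEnzyme("bad", "CTNAG", 9)


def brute_force_assay_exists(seq, pos, ref, alt, enzymes, primer_len=25,
                             amp_range=(150, 300), window=5, max_mm=1):
    """Independent exhaustive search over strands/enzymes/placements,
    using regex digestion, mirroring the published dCAPS principle."""

    def rc(s):
        return str(Seq(s).reverse_complement())

    def all_cuts(s, enz):
        out = set()
        L = len(enz.pattern)
        rcp = "".join(
            {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "R": "Y", "Y": "R"}[c]
            for c in reversed(enz.pattern)
        )
        for i in range(len(s) - L + 1):
            win = s[i : i + L]
            if all(b in IUPAC[p] for b, p in zip(win, enz.pattern)):
                out.add(i + enz.cut_offset)
            elif all(b in IUPAC[p] for b, p in zip(win, rcp)):
                out.add(i + L - enz.cut_offset)
        return {c for c in out if 0 < c < len(s)}

    for orient in (0, 1):
        if orient:
            seq_o, pos_o = rc(seq), len(seq) - pos + 1
            ref_o, alt_o = rc(ref), rc(alt)
        else:
            seq_o, pos_o, ref_o, alt_o = seq, pos, ref, alt
        for enz in enzymes:
            L = len(enz.pattern)
            for j in range(L):
                start = pos_o - j
                p_start = pos_o - primer_len
                if p_start < 1 or start < p_start or start + L - 1 > len(seq_o):
                    continue
                code = enz.pattern[j]
                in_ref, in_alt = ref_o in IUPAC[code], alt_o in IUPAC[code]
                if in_ref == in_alt:
                    continue
                if not all(
                    seq_o[start - 1 + k] in IUPAC[enz.pattern[k]]
                    for k in range(j + 1, L)
                ):
                    continue
                mms = []
                ok = True
                for k in range(j):
                    g = start + k
                    if seq_o[g - 1] in IUPAC[enz.pattern[k]]:
                        continue
                    off = g - p_start
                    if not (primer_len - 1 - window <= off <= primer_len - 2):
                        ok = False
                        break
                    mms.append((off, enz.pattern[k]))
                if not ok or len(mms) > max_mm:
                    continue
                primer = list(seq_o[p_start - 1 : pos_o - 1])
                for off, codep in mms:
                    primer[off] = sorted(set(IUPAC[codep]) - {primer[off]})[0]
                primer = "".join(primer)
                for amp_len in range(
                    min(amp_range[1], len(seq_o) - p_start + 1), amp_range[0] - 1, -1
                ):
                    end = p_start + amp_len - 1
                    if end < start + L - 1:
                        break
                    tail = seq_o[pos_o : end]
                    a_ref, a_alt = primer + ref_o + tail, primer + alt_o + tail
                    c_ref, c_alt = all_cuts(a_ref, enz), all_cuts(a_alt, enz)
                    if (len(c_ref) == 0) != (len(c_alt) == 0):
                        if max(len(c_ref), len(c_alt)) == 1:
                            return True
    return False


class TestDesign:
    def test_engineered_dcaps_on_transition_snp(self):
        """A G->A SNP given a flank that completes CTNAG only on the
        mutant allele yields a one-mismatch dCAPS assay."""
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 600)
        # plant ...C T [G] A G... around pos 300 with ref G, alt A:
        # pattern CTNAG hits both alleles at N; instead plant C T N A [G->A]
        # at the pattern's G so only the ref is cut -> discriminating
        pos = 300
        seq = seq[:295] + "CTTAG" + seq[300:]
        # SNP at the final G of the site: ref G cut, alt A uncut
        pos = 300
        ref, alt = "G", "A"
        assay = design_dcaps(seq, pos, ref, alt, (DDE_I,))
        assert assay.enzyme.name == "DdeI"
        assert len(assay.mismatch_positions) <= 1
        assert (len(assay.fragments_ref) == 1) != (len(assay.fragments_alt) == 1)
        assert sum(assay.fragments_ref) == assay.amplicon_length
        assert sum(assay.fragments_alt) == assay.amplicon_length

    def test_natural_caps_when_site_destroyed(self):
        """A SNP destroying an intact DdeI site gives a zero-mismatch CAPS."""
        rng = np.random.default_rng(6)
        # A/T background cannot form CTNAG except at the planted site
        seq = "".join("AT"[i] for i in rng.integers(0, 2, 600))
        seq = seq[:299] + "CTTAG" + seq[304:]
        pos = 300  # the C of the site; C->T destroys it
        assay = design_dcaps(seq, pos, "C", "T", (DDE_I,))
        assert assay.assay_type == "CAPS"
        assert assay.mismatch_positions == ()
        assert assay.cut_allele == "ref"

    def test_no_assay_found_is_structured(self):
        seq = "".join("AT"[i % 2] for i in range(400))
        with pytest.raises(NoAssayFoundError) as exc:
            design_dcaps(seq, 200, "T", "A", (DDE_I,))
        assert exc.value.n_enzymes == 1

    def test_returned_assays_discriminate_and_conserve_length(self):
        rng = np.random.default_rng(7)
        found = 0
        for _ in range(60):
            seq = random_seq(rng, 700)
            pos = int(rng.integers(320, 380))
            ref = seq[pos - 1]
            alt = {"G": "A", "C": "T", "A": "G", "T": "C"}[ref]
            try:
                assay = design_dcaps(seq, pos, ref, alt, DEFAULT_ENZYMES)
            except NoAssayFoundError:
                continue
            found += 1
            assert sum(assay.fragments_ref) == assay.amplicon_length
            assert sum(assay.fragments_alt) == assay.amplicon_length
            assert assay.fragments_ref != assay.fragments_alt
            cut = assay.fragments_ref if assay.cut_allele == "ref" else assay.fragments_alt
            uncut = assay.fragments_alt if assay.cut_allele == "ref" else assay.fragments_ref
            assert len(cut) >= 2 and len(uncut) == 1
        assert found > 10  # the search succeeds for a fair share of SNPs

    def test_agrees_with_exhaustive_search(self):
        """Found/not-found verdicts match an independent brute-force
        enumeration of every enzyme, strand and placement."""
        rng = np.random.default_rng(9)
        enzymes = (DDE_I, DEFAULT_ENZYMES[4])  # DdeI + MseI
        agree = 0
        for _ in range(100):
            seq = random_seq(rng, 700)
            pos = int(rng.integers(330, 370))
            ref = seq[pos - 1]
            alt = {"G": "A", "C": "T", "A": "G", "T": "C"}[ref]
            try:
                design_dcaps(seq, pos, ref, alt, enzymes)
                found = True
            except NoAssayFoundError:
                found = False
            expected = brute_force_assay_exists(seq, pos, ref, alt, enzymes)
            assert found == expected
            agree += 1
        assert agree == 100
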