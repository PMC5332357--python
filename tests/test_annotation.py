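"""Effect annotation vs a full-translation oracle; cascade; panel screen."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from mutseek.annotation import (
    GeneModel,
    annotate_effect,
    build_gene_index,
    filter_cascade,
    panel_uniqueness_screen,
    translate_cds,
)
from mutseek.mutmap import CandidateRegion, VariantSite
from mutseek.simulate import _build_gene


def make_gene(chrom_len=6000, strand="+", n_codons=120, n_exons=4, seed=0,
              forced=None, center=None):
    """Random gene stamped into a random chromosome."""
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, chrom_len))
    model, start, genomic = _build_gene(
        rng, "g1", "chr1", center or chrom_len // 2, strand,
        n_codons, n_exons, intron_len=60, forced_codons=forced,
    )
    chrom = seq[: start - 1] + genomic + seq[start - 1 + len(genomic):]
    return model, {"chr1": chrom}


def site_at(genome, pos, alt, chrom="chr1"):
    ref = genome[chrom][pos - 1]
    return VariantSite(chrom, pos, ref, alt, 0, 30)


def oracle_effect(gene, genome, pos, alt):
    """Independent classification by translating both full proteins."""
    chrom = genome[gene.chrom]
    mutated = {gene.chrom: chrom[: pos - 1] + alt + chrom[pos:]}

    def spliced(g_map):
        s = "".join(g_map[gene.chrom][a - 1 : b] for a, b in gene.cds)
        return str(Seq(s).reverse_complement()) if gene.strand == "-" else s

    ref_prot = str(Seq(spliced(genome)).translate())
    alt_prot = str(Seq(spliced(mutated)).translate())
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if not diffs:
        return "synonymous", None
    codon = diffs[0] + 1
    ra, aa = ref_prot[diffs[0]], alt_prot[diffs[0]]
    if ra != "*" and aa == "*":
        return "stop_gained", codon
    if ra == "*":
        return "stop_lost", codon
    if codon == 1 and ra == "M":
        return "start_lost", codon
    return "missense", codon


class TestAnnotateEffect:
    def test_study_geometry_stop_gain(self):
        """G->A at spliced-CDS position 470 of a CDS with TGG at codon 157
        gives codon 157, TGG->TAG, stop_gained."""
        gene, genome = make_gene(n_codons=464, n_exons=9, forced={157: "TGG"},
                                 chrom_len=9000, seed=3)
        pos = gene.genomic_position_of(470)
        alt = "A" if gene.strand == "+" else "T"
        call = annotate_effect(site_at(genome, pos, alt), [gene], genome)
        assert call.cds_pos == 470
        assert call.codon_number == 157
        assert (call.ref_codon, call.alt_codon) == ("TGG", "TAG")
        assert call.effect == "stop_gained"

    def test_wobble_synonymous(self):
        gene, genome = make_gene(n_codons=50, seed=5, forced={10: "GGG"})
        pos = gene.genomic_position_of(30)  # third base of codon 10
        alt = "A" if gene.strand == "+" else "T"
        call = annotate_effect(site_at(genome, pos, alt), [gene], genome)
        assert (call.ref_codon, call.alt_codon) == ("GGG", "GGA")
        assert call.effect == "synonymous"

    def test_regions_outside_cds(self):
        gene, genome = make_gene(n_codons=60, n_exons=3, seed=7)
        intron_pos = gene.exons[0][1] + 5
        call = annotate_effect(site_at(genome, intron_pos, "A" if genome["chr1"][intron_pos-1] != "A" else "T"), [gene], genome)
        assert call.region == "intronic" and call.effect is None
        call2 = annotate_effect(site_at(genome, 10, "A" if genome["chr1"][9] != "A" else "T"), [gene], genome)
        assert call2.region == "intergenic" and call2.gene_id is None

    def test_reference_mismatch_rejected(self):
        gene, genome = make_gene(seed=1)
        ref = genome["chr1"][99]
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match="reference mismatch"):
            annotate_effect(VariantSite("chr1", 100, wrong, "T", 0, 30), [gene], genome)

    def test_frame_violation_names_gene(self):
        gene = GeneModel("broken", "chr1", "+", exons=[(11, 20)])  # 10 bp CDS
        genome = {"chr1": "A" * 100}
        site = VariantSite("chr1", 15, "A", "G", 0, 30)
        with pytest.raises(ValueError, match="broken"):
            annotate_effect(site, [gene], genome)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_full_translation_oracle(self, strand):
        """Classification equals the diff of the full ref/alt proteins over
        many random genes, SNPs and both strands."""
        rng = np.random.default_rng(11 if strand == "+" else 13)
        n_checked = 0
        for trial in range(60):
            gene, genome = make_gene(
                strand=strand, n_codons=int(rng.integers(20, 90)),
                n_exons=int(rng.integers(1, 5)), seed=int(rng.integers(1e6)),
            )
            for _ in range(5):
                cds_pos = int(rng.integers(1, gene.cds_length + 1))
                pos = gene.genomic_position_of(cds_pos)
                ref = genome["chr1"][pos - 1]
                alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
                call = annotate_effect(site_at(genome, pos, alt), [gene], genome)
                expected_effect, expected_codon = oracle_effect(gene, genome, pos, alt)
                assert call.effect == expected_effect, (strand, trial, cds_pos)
                if expected_codon is not None:
                    assert call.codon_number == expected_codon
                assert call.codon_number == -(-call.cds_pos // 3)  # ceil
                n_checked += 1
        assert n_checked == 300

    def test_strand_round_trip(self):
        """A '-' strand gene annotates like its reverse complement laid on
        the '+' strand with mirrored coordinates."""
        gene, genome = make_gene(strand="-", n_codons=40, n_exons=2, seed=21)
        L = len(genome["chr1"])
        mirrored_genome = {"chr1": str(Seq(genome["chr1"]).reverse_complement())}
        mirrored_exons = [(L - e + 1, L - s + 1) for s, e in reversed(gene.exons)]
        mirrored = GeneModel("g1", "chr1", "+", exons=mirrored_exons)
        rng = np.random.default_rng(0)
        for _ in range(20):
            cds_pos = int(rng.integers(1, gene.cds_length + 1))
            pos = gene.genomic_position_of(cds_pos)
            ref = genome["chr1"][pos - 1]
            alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
            call = annotate_effect(site_at(genome, pos, alt), [gene], genome)
            m_pos = L - pos + 1
            m_alt = str(Seq(alt).reverse_complement())
            m_call = annotate_effect(
                site_at(mirrored_genome, m_pos, m_alt), [mirrored], mirrored_genome
            )
            assert (call.effect, call.codon_number, call.ref_codon, call.alt_codon) == (
                m_call.effect, m_call.codon_number, m_call.ref_codon, m_call.alt_codon
            )


class TestTranslateCds:
    def test_terminal_stop_excluded(self):
        assert translate_cds("ATGTAA") == "M"

    def test_1392bp_cds_gives_463_residues(self):
        rng = np.random.default_rng(9)
        sense = [c for c in
                 ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
                 if c not in {"TAA", "TAG", "TGA"}]
        cds = "ATG" + "".join(sense[i] for i in rng.integers(0, len(sense), 462)) + "TGA"
        assert len(cds) == 1392
        assert len(translate_cds(cds)) == 463

    def test_premature_stop_truncates(self):
        # stop at codon 157 of 464: 156 residues, ~66% of the protein lost
        rng = np.random.default_rng(10)
        sense = [c for c in
                 ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
                 if c not in {"TAA", "TAG", "TGA"}]
        codons = ["ATG"] + [sense[i] for i in rng.integers(0, len(sense), 462)] + ["TAA"]
        codons[156] = "TAG"  # codon 157
        prot = translate_cds("".join(codons))
        assert len(prot) == 156
        assert 1 - len(prot) / 463 == pytest.approx(0.663, abs=0.001)

    @pytest.mark.parametrize("bad", ["ATGNAA", "ATGA", "ATGXTA"])
    def test_invalid_cds_rejected(self, bad):
        with pytest.raises(ValueError):
            translate_cds(bad)


class TestFilterCascade:
    def region(self):
        return CandidateRegion("chr1", 1, 10_000, 1.0, 5)

    def call(self, pos, region_label, effect, alt_depth=30, ref_depth=0):
        site = VariantSite("chr1", pos, "G", "A", ref_depth, alt_depth)
        from mutseek.annotation import EffectCall

        return EffectCall(site=site, gene_id="g", region=region_label, effect=effect)

    def test_funnel_order_and_counts(self):
        calls = [
            self.call(100, "exonic", "stop_gained"),            # survives all
            self.call(200, "exonic", "synonymous"),             # dies at stage 3
            self.call(300, "intronic", None),                   # dies at stage 2
            self.call(20_000, "exonic", "missense"),            # dies at stage 1
            self.call(400, "exonic", "missense", 15, 15),       # dies at stage 4
        ]
        report = filter_cascade(calls, self.region())
        assert [n for _, n in report.stages] == [5, 4, 3, 2, 1]
        assert report.survivors[0].site.pos == 100

    def test_all_synonymous_stops_at_stage_three(self):
        calls = [self.call(p, "exonic", "synonymous") for p in (100, 200, 300)]
        report = filter_cascade(calls, self.region())
        assert dict(report.stages)["non_synonymous"] == 0

    def test_empty_region_stops_at_stage_one(self):
        region = CandidateRegion("chr9", 1, 100, 1.0, 5)
        calls = [self.call(100, "exonic", "missense")]
        report = filter_cascade(calls, region)
        assert dict(report.stages)["in_region"] == 0

    def test_default_run_funnel_ends_at_causal(self, pipeline_result):
        res = pipeline_result
        assert len(res.funnel.survivors) == 1
        s = res.funnel.survivors[0]
        assert (s.site.chrom, s.site.pos) == (res.causal.chrom, res.causal.pos)
        assert s.effect == "stop_gained"


class TestPanelScreen:
    def panel(self, n=412, carriers=0):
        dosage = np.zeros(n, dtype=int)
        dosage[:carriers] = 1
        return pd.DataFrame({"chr5:100": dosage},
                            index=[f"line_{i}" for i in range(n)])

    def test_clean_panel_unique(self):
        res = panel_uniqueness_screen("chr5:100", self.panel())
        assert (res.n_carriers, res.verdict) == (0, "unique")
        assert res.n_lines == 412

    def test_injected_carrier_flagged(self):
        res = panel_uniqueness_screen("chr5:100", self.panel(carriers=1))
        assert (res.n_carriers, res.verdict) == (1, "not_unique")

    def test_empty_panel_and_missing_site_raise(self):
        with pytest.raises(ValueError):
            panel_uniqueness_screen("chr5:100", self.panel(n=412).iloc[0:0])
        with pytest.raises(KeyError):
            panel_uniqueness_screen("chr9:999", self.panel())
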