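"""dCAPS marker design and in-silico digestion at the causal SNP.

Designs an allele-discriminating restriction assay for the planted
stop-gain SNP of a simulated run and predicts the band pattern of each
allele, then shows the published-style fragment arithmetic: a single
DdeI cut after base 19 of a 254-bp amplicon.
"""

from mutseek import DDE_I, SimulationConfig, design_dcaps, digest, run_pipeline

result = run_pipeline(SimulationConfig(seed=1))
causal = result.causal
chrom_seq = result.genome.chromosomes[causal.chrom]

assay = design_dcaps(chrom_seq, causal.pos, causal.ref, causal.alt)
print(f"designed {assay.assay_type} assay with {assay.enzyme.name} "
      f"({assay.enzyme.pattern}), {len(assay.mismatch_positions)} primer "
      f"mismatch(es), amplicon {assay.amplicon_length} bp")
print(assay.band_table())
print("# One allele is cut, the other is not: genotypes are read directly "
      "from the gel.\n")

amp_mut = ("AT" * 9) + "CTAAG" + ("AT" * 115) + "T"   # 254 bp, site at base 19
amp_wt = ("AT" * 9) + "CAAAG" + ("AT" * 115) + "T"    # site destroyed
print(f"DdeI digest, mutant allele: {digest(amp_mut, DDE_I)} bp")
print(f"DdeI digest, WT allele:     {digest(amp_wt, DDE_I)} bp")
print("# The classic pattern: 19 + 235 bp for the cut allele vs one "
      "254-bp band for the uncut allele.")
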