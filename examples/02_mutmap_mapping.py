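"""End-to-end bulked-segregant SNP-index mapping on synthetic data.

Simulates the full study design (EMS-mutagenised line, 42-plant
homozygous-recessive F2 bulk sequenced at ~30x against a 7-chromosome
reference), then maps the planted causal stop-gain SNP: mutant-specific
sites, 5-SNP sliding-window SNP indices, candidate region, effect
annotation, filter cascade, and the 412-line natural-panel screen.
"""

from mutseek import SimulationConfig, run_pipeline

result = run_pipeline(SimulationConfig(seed=1))

print(f"EMS mutations simulated:   {len(result.mutations)}")
print(f"mutant-specific SNPs:      {len(result.sites)}")
top = result.regions[0]
print(f"top candidate region:      {top.chrom}:{top.start}-{top.end} "
      f"(peak window mean index {top.peak_mean_index:.3f})")
print("filter cascade funnel:")
for stage, n in result.funnel.stages:
    print(f"  {stage:<16} {n}")
survivor = result.survivors[0]
print(f"surviving SNP:             {survivor.site.chrom}:{survivor.site.pos} "
      f"{survivor.site.ref}>{survivor.site.alt}, codon {survivor.codon_number} "
      f"{survivor.ref_codon}->{survivor.alt_codon} ({survivor.effect})")
screen = result.panel_screens[0]
print(f"panel screen:              {screen.n_carriers}/{screen.n_lines} carriers "
      f"-> {screen.verdict}")
print(f"planted causal SNP:        {result.causal.chrom}:{result.causal.pos} "
      f"recovered uniquely: {result.recovered}")
print("# The cascade keeps only exonic, non-synonymous SNPs fixed in the "
      "bulk inside the high-index region; the natural panel's lack of "
      "carriers marks the survivor as mutagen-induced rather than standing "
      "variation.")
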