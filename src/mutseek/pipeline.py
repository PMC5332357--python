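"""End-to-end mapping pipeline on synthetic data.

Chains the generator and the analysis modules: simulate the genome and
EMS mutations, sequence the bulk and parent in silico, derive
mutant-specific sites, smooth SNP indices, call the candidate region,
annotate effects, run the filter cascade, and screen survivors against
the natural panel.  ``recovered`` is True when the planted causal SNP is
the unique cascade survivor and is flagged unique in the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .annotation import (
    EffectCall,
    FunnelReport,
    PanelScreenResult,
    annotate_effect,
    build_gene_index,
    filter_cascade,
    panel_uniqueness_screen,
    site_key,
)
from .config import SimulationConfig
from .mutmap import (
    CandidateRegion,
    VariantSite,
    WindowPoint,
    call_candidate_region,
    derive_mutant_specific_sites,
    sliding_window,
)
from .simulate import (
    CausalVariant,
    Mutation,
    SyntheticGenome,
    simulate_bulk_depths,
    simulate_ems_mutations,
    simulate_genome,
    simulate_panel,
)


@dataclass
class PipelineResult:
    config: SimulationConfig
    genome: SyntheticGenome
    mutations: list[Mutation]
    causal: CausalVariant
    mutant_table: pd.DataFrame
    wt_table: pd.DataFrame
    sites: list[VariantSite]
    windows: list[WindowPoint]
    regions: list[CandidateRegion]
    funnel: FunnelReport | None
    survivors: list[EffectCall]
    panel: pd.DataFrame | None
    panel_screens: list[PanelScreenResult]

    @property
    def recovered(self) -> bool:
        """Planted SNP is the unique survivor and unique in the panel."""
        if len(self.survivors) != 1:
            return False
        s = self.survivors[0].site
        if (s.chrom, s.pos) != (self.causal.chrom, self.causal.pos):
            return False
        return all(sc.verdict == "unique" for sc in self.panel_screens)


def run_pipeline(
    config: SimulationConfig,
    window: int = 5,
    region_threshold: float = 0.9,
    min_index: float = 0.95,
    min_alt_depth: int = 10,
    screen_panel: bool = True,
) -> PipelineResult:
    """Run the full synthetic mapping pipeline for one configuration."""
    genome = simulate_genome(config)
    mutations, causal = simulate_ems_mutations(genome, config)
    mutant_table, wt_table = simulate_bulk_depths(genome, mutations, causal, config)
    sites = derive_mutant_specific_sites(mutant_table, wt_table)
    windows = sliding_window(sites, k=window)
    regions = call_candidate_region(windows, threshold=region_threshold)
    funnel = None
    survivors: list[EffectCall] = []
    if regions:
        region = regions[0]
        index = build_gene_index(genome.gene_models)
        calls = [annotate_effect(s, index, genome.chromosomes) for s in sites]
        funnel = filter_cascade(
            calls, region, min_index=min_index, min_alt_depth=min_alt_depth
        )
        survivors = funnel.survivors
    panel = None
    screens: list[PanelScreenResult] = []
    if screen_panel and survivors:
        keys = [site_key(c.site.chrom, c.site.pos) for c in survivors]
        panel = simulate_panel(config, keys)
        screens = [panel_uniqueness_screen(k, panel) for k in keys]
    return PipelineResult(
        config=config,
        genome=genome,
        mutations=mutations,
        causal=causal,
        mutant_table=mutant_table,
        wt_table=wt_table,
        sites=sites,
        windows=windows,
        regions=regions,
        funnel=funnel,
        survivors=survivors,
        panel=panel,
        panel_screens=screens,
    )


def recovery_rate(
    base_config: SimulationConfig, n_runs: int = 100, seed0: int = 0
) -> tuple[int, int]:
    """(# runs recovering the planted SNP uniquely, # runs) over seeds."""
    recovered = 0
    for i in range(n_runs):
        cfg = replace(base_config, seed=seed0 + i)
        if run_pipeline(cfg).recovered:
            recovered += 1
    return recovered, n_runs
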