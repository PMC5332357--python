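"""Small descriptive summaries used when reporting a mapping study."""

from __future__ import annotations


def mutation_frequency_percent(n_snps: int, genome_bp: int) -> float:
    """Genome-wide mutation frequency as a percentage of base pairs.

    111,490 induced SNPs over a 367-Mbp genome give 0.03%.
    """
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    if n_snps < 0:
        raise ValueError("SNP count must be non-negative")
    return 100.0 * n_snps / genome_bp


def mutations_per_kb(n_snps: int, genome_bp: int) -> float:
    """Mutation density per kb (0.3/kb for 111,490 SNPs over 367 Mbp)."""
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    return 1000.0 * n_snps / genome_bp


def marker_polymorphism_rate(n_polymorphic: int, n_screened: int) -> float:
    """Percent of screened markers polymorphic between two lines.

    283 of 2489 SSRs give 11.4%.
    """
    if n_screened <= 0:
        raise ValueError("number of screened markers must be positive")
    if not 0 <= n_polymorphic <= n_screened:
        raise ValueError("polymorphic count outside [0, screened]")
    return 100.0 * n_polymorphic / n_screened


def percent_of_wt(mutant_value: float, wt_value: float) -> float:
    """A mutant trait measurement as a percentage of the wild-type value."""
    if wt_value == 0:
        raise ValueError("wild-type value must be non-zero")
    return 100.0 * mutant_value / wt_value
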