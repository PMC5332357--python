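"""Modified-MutMap core: mutant-specific SNP derivation, SNP indices,
5-SNP sliding-window smoothing and candidate-region calling.

The classical MutMap approach aligns the mutant bulk against an assembly
of the pre-mutagenesis parent.  The modification implemented here (used
when no parental assembly exists) aligns both the mutant F2 bulk and the
wild-type parent line against the same public reference and subtracts the
shared variation: sites where the parent also carries the alternate
allele are pre-existing background, not mutagen-induced, and are removed
before SNP indices are computed.

The SNP index of a site is the fraction of bulk reads carrying the
mutant allele; in a bulk of homozygous-recessive F2 plants it approaches
1 at the causal locus and stays near 0.5 at unlinked mutagen-induced
sites.  Indices are smoothed with a moving window of five consecutive
SNPs, shifted one SNP at a time; each window is plotted at the midpoint
between its first and fifth member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_depth", "alt_depth"]


@dataclass(frozen=True)
class VariantSite:
    """One called site with mutant-pool allele depths.

    ``wt_state`` records the wild-type parent's call at this position
    against the same reference: ``ref`` (ref-homozygous), ``alt``
    (carries the alternate allele) or ``missing``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_depth: int
    alt_depth: int
    wt_state: str = "ref"

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("read depths must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def snp_index(self) -> float | None:
        """alt reads / total reads; undefined (None) at zero depth."""
        return compute_snp_index(self.ref_depth, self.alt_depth)


def compute_snp_index(ref_depth: int, alt_depth: int) -> float | None:
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("read depths must be non-negative")
    total = ref_depth + alt_depth
    if total == 0:
        logger.info("site with zero depth: SNP index undefined, excluded")
        return None
    return alt_depth / total


def passes_fixation_rule(
    site: VariantSite,
    min_index: float = 0.95,
    min_alt_depth: int = 10,
    strict: bool = False,
) -> bool:
    """Operational form of the "homozygous, SNP index = 1" criterion.

    With finite read depth, literal equality to 1 is fragile (a single
    mis-mapped read breaks it), so the default requires index >=
    ``min_index`` with at least ``min_alt_depth`` alt reads, preserving
    the intent — the mutant allele is fixed in the bulk.  ``strict``
    restores literal equality.
    """
    idx = site.snp_index
    if idx is None:
        return False
    if strict:
        return idx == 1.0 and site.alt_depth >= 1
    return idx >= min_index and site.alt_depth >= min_alt_depth


# ---------------------------------------------------------------------------
# Mutant-specific site derivation
# ---------------------------------------------------------------------------

def _check_table(df: pd.DataFrame, name: str) -> None:
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table lacks columns {missing}")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        where = df.loc[dup, ["chrom", "pos"]].iloc[0]
        raise ValueError(
            f"duplicate position in {name} table at {where['chrom']}:{where['pos']}"
        )


def derive_mutant_specific_sites(
    mutant: pd.DataFrame, wt: pd.DataFrame
) -> list[VariantSite]:
    """Subtract parental background from the mutant-pool variant table.

    Both tables must be called against the same reference build.  A site
    is retained when the mutant pool shows the alternate allele and the
    wild-type parent is ref-homozygous there (absent from the WT table,
    or listed with zero alt reads).  Any WT alt evidence — homozygous or
    heterozygous — marks shared parental background and removes the site.
    Zero-depth mutant sites carry no evidence and are dropped.
    """
    _check_table(mutant, "mutant")
    _check_table(wt, "wt")
    if len(mutant) and len(wt):
        if not (set(mutant["chrom"]) & set(wt["chrom"])):
            raise ValueError(
                "mutant and WT tables share no chromosome names; "
                "were they called against the same reference build?"
            )
    wt_alt = {
        (row.chrom, row.pos): row.alt_depth > 0
        for row in wt.itertuples()
    }
    sites: list[VariantSite] = []
    for row in mutant.itertuples():
        if row.alt_depth <= 0:
            continue
        if row.ref_depth + row.alt_depth == 0:
            continue
        has_wt_alt = wt_alt.get((row.chrom, row.pos))
        if has_wt_alt:
            continue  # shared parental background
        wt_state = "missing" if has_wt_alt is None else "ref"
        sites.append(
            VariantSite(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                ref_depth=int(row.ref_depth),
                alt_depth=int(row.alt_depth),
                wt_state=wt_state,
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


# ---------------------------------------------------------------------------
# Sliding window and candidate regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowPoint:
    """Mean SNP index of one window of consecutive SNPs on a chromosome."""

    chrom: str
    x: float                       # midpoint of first and last member position
    mean_index: float
    member_positions: tuple[int, ...]


def sliding_window(
    sites: Sequence[VariantSite], k: int = 5, step: int = 1
) -> list[WindowPoint]:
    """Moving-window mean of SNP indices, ``step`` SNPs at a time.

    Windows never span chromosomes; a chromosome with fewer than ``k``
    usable sites yields none.  Zero-depth sites are excluded.
    """
    if k < 1 or step < 1:
        raise ValueError("k and step must be >= 1")
    by_chrom: dict[str, list[VariantSite]] = {}
    for s in sites:
        if s.snp_index is None:
            continue
        by_chrom.setdefault(s.chrom, []).append(s)
    out: list[WindowPoint] = []
    for chrom in sorted(by_chrom):
        chrom_sites = sorted(by_chrom[chrom], key=lambda s: s.pos)
        n = len(chrom_sites)
        if n < k:
            continue
        idx = np.array([s.snp_index for s in chrom_sites])
        pos = np.array([s.pos for s in chrom_sites])
        means = np.convolve(idx, np.ones(k) / k, mode="valid")
        for i in range(0, n - k + 1, step):
            out.append(
                WindowPoint(
                    chrom=chrom,
                    x=(pos[i] + pos[i + k - 1]) / 2,
                    mean_index=float(means[i]),
                    member_positions=tuple(int(p) for p in pos[i : i + k]),
                )
            )
    return out


@dataclass(frozen=True)
class CandidateRegion:
    """A run of high-index windows delimiting the candidate interval."""

    chrom: str
    start: int
    end: int
    peak_mean_index: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")


def call_candidate_region(
    windows: Sequence[WindowPoint], threshold: float = 0.9
) -> list[CandidateRegion]:
    """Maximal runs of consecutive windows with mean index >= threshold.

    Region bounds are the first and last member SNP positions of the run.
    Regions are ranked by peak mean index, then span length, with ties
    broken by (chromosome name, start).
    """
    regions: list[CandidateRegion] = []
    by_chrom: dict[str, list[WindowPoint]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: w.x)
        run: list[WindowPoint] = []
        for w in ws + [None]:  # type: ignore[list-item]
            if w is not None and w.mean_index >= threshold:
                run.append(w)
                continue
            if run:
                positions = sorted({p for r in run for p in r.member_positions})
                regions.append(
                    CandidateRegion(
                        chrom=chrom,
                        start=positions[0],
                        end=positions[-1],
                        peak_mean_index=max(r.mean_index for r in run),
                        n_sites=len(positions),
                    )
                )
                run = []
    if not regions:
        logger.warning("no window reached mean SNP index %.2f", threshold)
    regions.sort(
        key=lambda r: (-r.peak_mean_index, -(r.end - r.start), r.chrom, r.start)
    )
    return regions


def windows_to_frame(windows: Iterable[WindowPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": w.chrom, "x": w.x, "mean_index": w.mean_index,
             "first": w.member_positions[0], "last": w.member_positions[-1]}
            for w in windows
        ]
    )


def regions_to_bed(regions: Iterable[CandidateRegion]) -> pd.DataFrame:
    """BED-compatible frame (0-based half-open coordinates)."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start - 1,
                "end": r.end,
                "name": f"candidate_{i + 1}",
                "score": round(r.peak_mean_index * 1000),
            }
            for i, r in enumerate(regions)
        ]
    )


def plot_snp_index(
    windows: Sequence[WindowPoint],
    path: str,
    threshold: float | None = 0.9,
) -> None:
    """Per-chromosome SNP-index curves (window means vs midpoint bp)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({w.chrom for w in windows})
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(8, 1.6 * max(len(chroms), 1)), sharey=True
    )
    if len(chroms) == 1:
        axes = [axes]
    for ax, chrom in zip(axes, chroms):
        ws = sorted((w for w in windows if w.chrom == chrom), key=lambda w: w.x)
        ax.plot([w.x / 1e6 for w in ws], [w.mean_index for w in ws], "r-", lw=0.8)
        if threshold is not None:
            ax.axhline(threshold, color="grey", ls="--", lw=0.6)
        ax.set_ylim(-0.05, 1.05)
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
    axes[-1].set_xlabel("position (Mb)")
    fig.suptitle("mean SNP index, 5-SNP moving window")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
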