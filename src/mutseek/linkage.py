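"""F2 linkage analysis: bulked-segregant marker screening, recombination
fraction estimation against a recessive trait locus, Kosambi map
distances, and LOD-threshold linkage grouping with marker ordering.

Genotype codes follow the usual F2 convention: ``A`` = homozygous for
the parent-1 (wild-type parent) allele, ``B`` = homozygous for the
parent-2 (mutant line) allele, ``H`` = heterozygous, ``-`` = missing.
The trait locus is treated as a fully penetrant recessive marker scored
by phenotype, so only mutant-class individuals (homozygous recessive at
the trait locus) inform the marker-trait recombination fraction: among
their 2n marker alleles, each is a recombinant with probability r.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

GENOTYPE_CODES = {"A", "H", "B", "-"}


# ---------------------------------------------------------------------------
# Kosambi mapping function
# ---------------------------------------------------------------------------

def kosambi_cm(r: float) -> float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM, for 0 <= r < 0.5."""
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def inverse_kosambi(cm: float) -> float:
    """Recombination fraction for a Kosambi distance: r = tanh(d/50)/2."""
    if cm < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * math.tanh(cm / 50.0)


# ---------------------------------------------------------------------------
# Marker-trait estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkageEstimate:
    """Recombination estimate for a marker pair or marker-trait pair."""

    pair: tuple[str, str]
    r_hat: float
    lod: float
    cm_kosambi: float
    n: int


def estimate_r_trait(
    mutant_genotypes: Sequence[str],
    marker: str = "marker",
    mutant_allele_code: str = "B",
) -> LinkageEstimate:
    """ML recombination fraction between a codominant marker and the trait.

    ``mutant_genotypes`` are the marker codes of the mutant-phenotype
    (homozygous recessive) individuals only.  With the mutant-line allele
    coded ``B``, every ``A`` allele in this class is a recombinant
    gamete; r_hat = (#recombinant alleles) / (2 n) is the binomial MLE,
    and LOD = log10 L(r_hat) - log10 L(0.5).
    """
    codes = [g for g in mutant_genotypes if g != "-"]
    bad = set(codes) - {"A", "H", "B"}
    if bad:
        raise ValueError(f"invalid genotype codes {sorted(bad)}")
    n = len(codes)
    if n == 0:
        raise ValueError("no mutant-class individuals with marker genotypes")
    other = "A" if mutant_allele_code == "B" else "B"
    k = sum(2 if g == other else 1 if g == "H" else 0 for g in codes)
    m = 2 * n
    r_hat = min(k / m, 0.5)
    # binomial log10 likelihood ratio vs r = 0.5
    def log10_lik(r: float) -> float:
        if r == 0:
            return -math.inf if k > 0 else 0.0
        if r == 1:
            return -math.inf if k < m else 0.0
        return k * math.log10(r) + (m - k) * math.log10(1 - r)

    if k / m >= 0.5:
        lod = 0.0  # estimate capped at independence
    else:
        lod = max(0.0, log10_lik(k / m) - m * math.log10(0.5))
    cm = kosambi_cm(r_hat) if r_hat < 0.5 else math.inf
    return LinkageEstimate(pair=(marker, "trait"), r_hat=r_hat, lod=lod, cm_kosambi=cm, n=n)


def _f2_class_probs(r: float) -> np.ndarray:
    """3x3 F2 genotype-class probabilities for two coupling-phase loci.

    Rows/cols index the dosage (0, 1, 2) of the parent-2 allele at each
    locus.  F1 gametes: parental haplotypes with probability (1-r)/2
    each, recombinant with r/2 each.
    """
    g = {
        (0, 0): (1 - r) / 2,  # a b
        (1, 1): (1 - r) / 2,  # A B
        (0, 1): r / 2,        # a B
        (1, 0): r / 2,        # A b
    }
    probs = np.zeros((3, 3))
    for (a1, b1), p1 in g.items():
        for (a2, b2), p2 in g.items():
            probs[a1 + a2, b1 + b2] += p1 * p2
    return probs


_DOSE = {"A": 0, "H": 1, "B": 2}


def estimate_r_pair(
    genotypes1: Sequence[str],
    genotypes2: Sequence[str],
    markers: tuple[str, str] = ("m1", "m2"),
) -> LinkageEstimate:
    """ML recombination fraction between two codominant F2 markers.

    Maximises the multinomial likelihood of the 3x3 genotype-class table
    over r (coupling phase assumed, as both markers descend from the
    same parental cross).  Individuals missing either genotype are
    dropped pairwise.
    """
    if len(genotypes1) != len(genotypes2):
        raise ValueError("genotype vectors differ in length")
    counts = np.zeros((3, 3))
    for g1, g2 in zip(genotypes1, genotypes2):
        if g1 == "-" or g2 == "-":
            continue
        counts[_DOSE[g1], _DOSE[g2]] += 1
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no individuals scored at both markers")

    def nll(r: float) -> float:
        p = _f2_class_probs(r)
        with np.errstate(divide="ignore"):
            logp = np.log(np.clip(p, 1e-300, None))
        return -float((counts * logp).sum())

    res = minimize_scalar(nll, bounds=(1e-6, 0.5), method="bounded")
    r_hat = float(min(res.x, 0.5))
    lod = max(0.0, (nll(0.5 - 1e-12) - nll(r_hat)) / math.log(10))
    cm = kosambi_cm(r_hat) if r_hat < 0.5 else math.inf
    return LinkageEstimate(pair=markers, r_hat=r_hat, lod=lod, cm_kosambi=cm, n=n)


# ---------------------------------------------------------------------------
# BSA marker pre-screen
# ---------------------------------------------------------------------------

def _bulk_alleles(table: pd.DataFrame, marker: str, members: Sequence[str]) -> set[str]:
    alleles: set[str] = set()
    for m in members:
        code = table.loc[m, marker]
        if code == "A":
            alleles.add("A")
        elif code == "B":
            alleles.add("B")
        elif code == "H":
            alleles.update("AB")
    return alleles


def bsa_screen(
    marker_table: pd.DataFrame,
    wt_bulk: Sequence[str],
    mutant_bulk: Sequence[str],
    markers: Sequence[str] | None = None,
) -> list[str]:
    """Markers whose inferred allele content differs between the bulks.

    Emulates pooled-DNA screening: a marker passes when the mutant bulk
    is fixed for a single parental allele while the WT bulk is mixed or
    fixed for the other — the pattern of a marker linked to the
    recessive locus.  ``marker_table`` is individuals x markers.
    """
    for member in list(wt_bulk) + list(mutant_bulk):
        if member not in marker_table.index:
            raise KeyError(f"bulk member {member!r} not in the genotype table")
    if markers is None:
        markers = [c for c in marker_table.columns if c != "phenotype"]
    passing = []
    for marker in markers:
        mut = _bulk_alleles(marker_table, marker, mutant_bulk)
        wt = _bulk_alleles(marker_table, marker, wt_bulk)
        if len(mut) == 1 and wt and wt != mut:
            passing.append(marker)
    return passing


# ---------------------------------------------------------------------------
# Linkage grouping and ordering
# ---------------------------------------------------------------------------

def _order_exhaustive(members: list[str], dist: Mapping[frozenset, float]) -> list[str]:
    best: tuple[float, list[str]] | None = None
    for perm in itertools.permutations(members):
        if perm[0] > perm[-1]:
            continue  # skip mirror-image orders
        cost = sum(
            dist.get(frozenset((a, b)), math.inf) for a, b in zip(perm, perm[1:])
        )
        key = (cost, list(perm))
        if best is None or key < best:
            best = key
    assert best is not None
    return best[1]


def _order_greedy(members: list[str], dist: Mapping[frozenset, float]) -> list[str]:
    # start from the most peripheral marker (largest distance to any other)
    start = max(
        sorted(members),
        key=lambda m: max(
            (dist.get(frozenset((m, o)), 0.0) for o in members if o != m), default=0.0
        ),
    )
    order = [start]
    remaining = set(members) - {start}
    while remaining:
        last = order[-1]
        nxt = min(
            sorted(remaining),
            key=lambda m: dist.get(frozenset((last, m)), math.inf),
        )
        order.append(nxt)
        remaining.remove(nxt)
    return order


def group_markers(
    estimates: Iterable[LinkageEstimate],
    lod_threshold: float = 4.0,
    exhaustive_max: int = 8,
) -> list[list[str]]:
    """Single-linkage grouping at a LOD threshold, with within-group ordering.

    Markers joined by any pairwise estimate with LOD >= threshold fall in
    one group (connected components of the linkage graph).  Within a
    group, ordering minimises the sum of adjacent Kosambi distances —
    exhaustively for small groups, by greedy seriation above
    ``exhaustive_max`` (adequate for maps of a dozen markers).  Groups
    are returned sorted by size (desc) then name; the result does not
    depend on marker input order.
    """
    import networkx as nx

    graph = nx.Graph()
    dist: dict[frozenset, float] = {}
    for est in estimates:
        a, b = est.pair
        graph.add_node(a)
        graph.add_node(b)
        dist[frozenset((a, b))] = est.cm_kosambi
        if est.lod >= lod_threshold:
            graph.add_edge(a, b)
    groups = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        if len(members) <= 2:
            ordered = members
        elif len(members) <= exhaustive_max:
            ordered = _order_exhaustive(members, dist)
        else:
            ordered = _order_greedy(members, dist)
        groups.append(ordered)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def map_table(
    groups: Sequence[Sequence[str]], estimates: Iterable[LinkageEstimate]
) -> pd.DataFrame:
    """Cumulative cM positions along each ordered group (TSV-ready)."""
    dist = {frozenset(e.pair): e.cm_kosambi for e in estimates}
    rows = []
    for gi, group in enumerate(groups, start=1):
        pos = 0.0
        for i, marker in enumerate(group):
            if i > 0:
                pos += dist.get(frozenset((group[i - 1], marker)), float("nan"))
            rows.append({"group": gi, "marker": marker, "cM": round(pos, 3)})
    return pd.DataFrame(rows)


def plot_linkage_map(map_df: pd.DataFrame, path: str) -> None:
    """Simple vertical linkage-map figure, one bar per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(map_df["group"].unique())
    fig, axes = plt.subplots(1, len(groups), figsize=(2.2 * len(groups), 5))
    if len(groups) == 1:
        axes = [axes]
    for ax, g in zip(axes, groups):
        sub = map_df[map_df["group"] == g]
        ax.vlines(0, 0, sub["cM"].max() or 1.0, color="k", lw=2)
        for _, row in sub.iterrows():
            ax.hlines(row["cM"], -0.08, 0.08, color="k", lw=1)
            ax.text(0.12, row["cM"], row["marker"], va="center", fontsize=8)
        ax.invert_yaxis()
        ax.set_title(f"group {g}")
        ax.set_xticks([])
        ax.set_xlim(-0.3, 1.2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
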