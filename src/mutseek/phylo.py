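"""Protein distances, neighbor-joining trees and bootstrap support.

Implements the Saitou-Nei neighbor-joining algorithm with a
deterministic tie-break (lowest index pair under the Q-criterion) and
the standard treatment of negative branch-length estimates: the length
is clamped to zero and the deficit moved to the sibling branch, so path
lengths through the joined pair are preserved; clamped nodes are
flagged.  Bootstrap support of an internal edge is the percentage of
column-resampled replicate trees containing the same leaf bipartition.

Distances default to the protein p-distance with pairwise deletion of
gap columns (the common default for distance-based protein trees); a
Poisson correction, -ln(1 - p), and complete deletion are selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

GAP_CHARS = frozenset("-.")


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    clamped: bool = False  # branch length was negative and clamped to 0

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


class PhyloTree:
    """An unrooted tree held as a trifurcating-rooted node structure."""

    def __init__(self, root: TreeNode):
        self.root = root

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf splits, one per internal edge.

        Each split is canonicalised as the side not containing the
        lexicographically smallest leaf, so the set is invariant to leaf
        input order and to the arbitrary rooting of the structure.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(ch) for ch in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = all_leaves - below if anchor in below else below
                splits.add(side)
            return below

        walk(self.root)
        return splits

    def _node_for_split(self, split: frozenset[str]) -> TreeNode | None:
        all_leaves = frozenset(self.leaf_names())

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(ch) for ch in node.children))
            if below == split or all_leaves - below == split:
                found.append(node)
            return below

        found: list[TreeNode] = []
        walk(self.root)
        for node in found:
            if node is not self.root:
                return node
        return None

    def to_newick(self, include_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                label = node.name or ""
            else:
                inner = ",".join(fmt(ch) for ch in node.children)
                label = f"({inner})"
                if include_support and node.support is not None:
                    label += f"{node.support:g}"
            if node.length is not None:
                label += f":{node.length:.6g}"
            return label

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class AlignedProteinSet:
    """Pre-aligned protein sequences (equal-length rows, '-' or '.' gaps)."""

    names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must all have the same length")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @classmethod
    def from_fasta(cls, path: str) -> "AlignedProteinSet":
        from Bio import SeqIO

        names, seqs = [], []
        for rec in SeqIO.parse(path, "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(names, seqs)

    def columns(self, idx: np.ndarray) -> "AlignedProteinSet":
        """Column-resampled copy (for bootstrap replicates)."""
        seqs = ["".join(s[i] for i in idx) for s in self.sequences]
        return AlignedProteinSet(list(self.names), seqs)


def pairwise_distance(
    aln: AlignedProteinSet,
    model: str = "p",
    gaps: str = "pairwise",
) -> np.ndarray:
    """Symmetric distance matrix over the alignment.

    ``model='p'``: mismatches / compared sites; ``model='poisson'``:
    -ln(1 - p).  ``gaps='pairwise'`` drops gap columns per pair,
    ``'complete'`` drops any column with a gap anywhere first.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if gaps not in ("pairwise", "complete"):
        raise ValueError(f"unknown gap handling {gaps!r}")
    mat = np.array([list(s) for s in aln.sequences])
    is_gap = np.isin(mat, list(GAP_CHARS))
    if gaps == "complete":
        keep = ~is_gap.any(axis=0)
        mat, is_gap = mat[:, keep], is_gap[:, keep]
    n = len(aln.names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(is_gap[i] | is_gap[j])
            n_valid = int(valid.sum())
            if n_valid == 0:
                raise ValueError(
                    f"no comparable sites between {aln.names[i]} and {aln.names[j]}"
                )
            p = float((mat[i, valid] != mat[j, valid]).sum() / n_valid)
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson correction undefined at p=1 for "
                        f"{aln.names[i]} vs {aln.names[j]}"
                    )
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return d


def percent_identity(aln: AlignedProteinSet, gaps: str = "pairwise") -> np.ndarray:
    """100 x (1 - p-distance) for every pair; 100 on the diagonal."""
    return 100.0 * (1.0 - pairwise_distance(aln, model="p", gaps=gaps))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: np.ndarray, names: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Iteratively joins the pair minimising
    Q(i,j) = (m - 2) d(i,j) - r_i - r_j, with ties broken by the lowest
    index pair; branch lengths follow the NJ formulas; the last three
    nodes are attached to an (unrooted) trifurcating root.  Exact on
    additive matrices.
    """
    d = np.asarray(dist, dtype=float)
    n = len(names)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match names")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if (d < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=str(nm)) for nm in names]
    d = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima: argmin scans row-major, i < j half
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        k = int(np.argmin(flat))
        i, j = int(iu[0][k]), int(iu[1][k])
        dij = d[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        vj = dij - vi
        clamped_i = clamped_j = False
        if vi < 0:
            vj, vi, clamped_i = vj + vi, 0.0, True
        if vj < 0:
            vi, vj, clamped_j = vi + vj, 0.0, True
            vi = max(vi, 0.0)
        ni, nj_ = nodes[i], nodes[j]
        ni.length, ni.clamped = float(vi), clamped_i
        nj_.length, nj_.clamped = float(vj), clamped_j
        new = TreeNode(children=[ni, nj_])
        du = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k_ for k_ in range(m) if k_ not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = du[keep]
        d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k_] for k_ in keep] + [new]

    # attach the last three with the three-leaf closed-form lengths
    (a, b, c) = nodes
    va = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    vb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    vc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, v in zip((a, b, c), (va, vb, vc)):
        node.clamped = v < 0
        node.length = float(max(v, 0.0))
    return PhyloTree(TreeNode(children=[a, b, c]))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: AlignedProteinSet,
    n_reps: int = 1000,
    seed: int | None = None,
    model: str = "p",
    gaps: str = "pairwise",
) -> PhyloTree:
    """NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement per replicate; the
    support of an internal edge is the percentage of replicate trees
    containing the same bipartition.  ``n_reps=0`` returns the tree
    without supports.  Reproducible given ``seed``.
    """
    if aln.length < 1:
        raise ValueError("alignment has no columns")
    tree = nj_tree(pairwise_distance(aln, model=model, gaps=gaps), aln.names)
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {split: 0 for split in tree.bipartitions()}
    for _ in range(n_reps):
        idx = rng.integers(0, aln.length, size=aln.length)
        rep = aln.columns(idx)
        try:
            rep_tree = nj_tree(pairwise_distance(rep, model=model, gaps=gaps), rep.names)
        except ValueError:
            continue  # e.g. a pair with no comparable resampled sites
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1
    for split, count in counts.items():
        node = tree._node_for_split(split)
        if node is not None:
            node.support = 100.0 * count / n_reps
    return tree
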