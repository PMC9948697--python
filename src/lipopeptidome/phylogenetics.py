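"""Distance matrices, neighbor joining, bootstrap and tree congruence.

Desk-scale phylogenetics for NRPS-concatenate vs rpoD comparisons:
pairwise identity distances (d = 1 - identity), neighbor joining
(delegated to scikit-bio), a site-resampling bootstrap over NJ, and
tree-vs-tree congruence scored by normalized Robinson-Foulds distance and
cophenetic correlation.  Leaves whose removal most improves the RF
agreement are reported as discordance (horizontal-gene-transfer)
candidates.  Externally computed newick trees can be read with
:func:`read_newick` for real-data use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode
from skbio.tree import nj as _skbio_nj

from ._align import sequence_identity

Split = frozenset  # frozenset({frozenset(side_a), frozenset(side_b)})


class TreeInputError(ValueError):
    """Invalid distance matrix or tree input."""


@dataclass
class CongruenceReport:
    """Topological and metric agreement between two trees."""

    normalized_rf: float
    cophenetic_correlation: float
    discordant_leaves: list[tuple[str, float]] = field(default_factory=list)
    shared_leaves: int = 0

    def __post_init__(self):
        if not 0.0 <= self.normalized_rf <= 1.0:
            raise ValueError("normalized RF must lie in [0, 1]")


# ---------------------------------------------------------------------------
# distances


def distance_matrix(
    sequences: Union[dict[str, str], Sequence[tuple[str, str]]],
    identity_fn: Optional[Callable[[str, str], float]] = None,
) -> DistanceMatrix:
    """Pairwise distance matrix ``d = 1 - fractional identity``.

    ``sequences`` maps taxon label -> sequence (dict or ordered pairs).
    """
    if isinstance(sequences, dict):
        items = list(sequences.items())
    else:
        items = list(sequences)
    labels = [k for k, _ in items]
    if len(labels) != len(set(labels)):
        raise TreeInputError("duplicate taxon labels")
    if len(labels) < 3:
        raise TreeInputError("need at least 3 taxa")
    fn = identity_fn or sequence_identity
    n = len(items)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - fn(items[i][1], items[j][1])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, labels)


def hamming_distance_matrix(aligned: dict[str, str]) -> DistanceMatrix:
    """p-distance matrix over pre-aligned, equal-length sequences."""
    labels = list(aligned)
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise TreeInputError("aligned sequences must have equal length")
    arr = np.array([list(aligned[k]) for k in labels])
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.mean(arr[i] != arr[j]))
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, labels)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining; negative branch lengths clamp to 0."""
    if not np.all(np.isfinite(dm.data)):
        raise TreeInputError("distance matrix contains non-finite entries")
    tree = _skbio_nj(dm, neg_as_zero=False)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(
            f"neighbor joining produced {clamped} negative branch length(s); "
            "clamped to 0",
            stacklevel=2,
        )
    return tree


# ---------------------------------------------------------------------------
# splits and Robinson-Foulds


def tree_splits(tree: TreeNode) -> set[Split]:
    """Non-trivial bipartitions induced by the tree's internal edges.

    Polytomies contribute only the splits they actually resolve.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    splits: set[Split] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({side, other}))
    return splits


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Unrooted Robinson-Foulds distance (symmetric split difference)."""
    return len(tree_splits(t1) ^ tree_splits(t2))


def normalized_rf(t1: TreeNode, t2: TreeNode) -> float:
    """RF / (2n - 6), the maximum for two unrooted binary trees on n leaves."""
    n = sum(1 for _ in t1.tips())
    denom = 2 * n - 6
    if denom <= 0:
        return 0.0
    return min(1.0, rf_distance(t1, t2) / denom)


def _with_lengths(tree: TreeNode) -> TreeNode:
    out = tree.copy()
    for node in out.traverse(include_self=False):
        if node.length is None:
            node.length = 1.0
    return out


def cophenetic_correlation(t1: TreeNode, t2: TreeNode) -> float:
    """Pearson correlation between the two path-length tip distance matrices."""
    d1 = _with_lengths(t1).tip_tip_distances()
    labels = list(d1.ids)
    d2 = _with_lengths(t2).tip_tip_distances().filter(labels)
    iu = np.triu_indices(len(labels), k=1)
    x, y = d1.data[iu], d2.filter(labels).data[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    aligned: dict[str, str],
    n_reps: int,
    seed: int,
) -> TreeNode:
    """NJ tree from aligned sequences with site-resampling bootstrap supports.

    Per-split support = fraction of replicate NJ trees containing the
    split; stored on internal nodes as ``node.support`` (float in [0, 1]).
    Seeded and reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = list(aligned)
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise TreeInputError("aligned sequences must have equal length")
    ncols = lengths.pop()
    arr = np.array([list(aligned[k]) for k in labels])
    tree = nj_tree(hamming_distance_matrix(aligned))

    rng = np.random.default_rng(seed)
    split_counts: dict[Split, int] = {}
    n = len(labels)
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, ncols)
        sub = arr[:, cols]
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.mean(sub[i] != sub[j]))
                mat[i, j] = mat[j, i] = d
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_tree = nj_tree(DistanceMatrix(mat, labels))
        for split in tree_splits(rep_tree):
            split_counts[split] = split_counts.get(split, 0) + 1

    all_tips = frozenset(labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        split = frozenset({side, all_tips - side})
        if len(side) >= 2 and len(all_tips - side) >= 2:
            node.support = split_counts.get(split, 0) / n_reps
            node.name = f"{node.support:g}"
    return tree


# ---------------------------------------------------------------------------
# congruence


def congruence(t1: TreeNode, t2: TreeNode) -> CongruenceReport:
    """Score topological agreement of two trees on their shared leaf set.

    Leaves outside the intersection are pruned with a warning.  The
    discordant-leaves ranking greedily scores each leaf by how much its
    removal improves the normalized RF distance (candidates for recent
    NRPS gene exchange between related species).
    """
    tips1 = {t.name for t in t1.tips()}
    tips2 = {t.name for t in t2.tips()}
    shared = tips1 & tips2
    if len(shared) < 4:
        raise TreeInputError(
            f"congruence undefined for {len(shared)} shared leaves (need >= 4)"
        )
    if shared != tips1 or shared != tips2:
        warnings.warn(
            f"pruning to {len(shared)} shared leaves", stacklevel=2
        )
        t1 = t1.shear(shared)
        t2 = t2.shear(shared)

    base = normalized_rf(t1, t2)
    corr = cophenetic_correlation(t1, t2)

    discordant: list[tuple[str, float]] = []
    if base > 0 and len(shared) >= 5:
        for leaf in sorted(shared):
            keep = shared - {leaf}
            sub_rf = normalized_rf(t1.shear(keep), t2.shear(keep))
            improvement = base - sub_rf
            if improvement > 0:
                discordant.append((leaf, improvement))
        discordant.sort(key=lambda t: (-t[1], t[0]))
    return CongruenceReport(
        normalized_rf=base,
        cophenetic_correlation=corr,
        discordant_leaves=discordant,
        shared_leaves=len(shared),
    )


# ---------------------------------------------------------------------------
# newick I/O


def read_newick(source) -> TreeNode:
    """Read a newick tree (quoted labels and internal support labels allowed)."""
    return TreeNode.read(source, format="newick")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(path, format="newick")


def read_distance_tsv(path) -> DistanceMatrix:
    """Read a square distance matrix (TSV or PHYLIP square dialect)."""
    import pandas as pd

    with open(path) as fh:
        first = fh.readline().split()
    if len(first) == 1 and first[0].isdigit():
        # PHYLIP square: first line is the taxon count
        df = pd.read_csv(
            path, sep=r"\s+", skiprows=1, header=None, index_col=0
        )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.values.astype(float), [str(i) for i in df.index])
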