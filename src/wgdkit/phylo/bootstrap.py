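"""Nonparametric bootstrap supports by site resampling."""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from ..alignment import Alignment
from .distance import p_distance_matrix, poisson_correct
from .model import SubstitutionModel
from .nj import neighbor_joining
from .tree import Node, bipartitions


def nj_builder(model: SubstitutionModel) -> Callable[[Alignment], Node]:
    """Distance(NJ) tree builder: Poisson-corrected p-distances + NJ."""

    def build(aln: Alignment) -> Node:
        P = p_distance_matrix(aln)
        D = np.vectorize(poisson_correct)(P)
        # cap saturated entries at twice the largest finite distance
        finite = D[np.isfinite(D)]
        cap = 2.0 * finite.max() if finite.size else 1.0
        D[~np.isfinite(D)] = cap
        return neighbor_joining(D, aln.names)

    return build


def bipartition_counts(
    aln: Alignment,
    builder: Callable[[Alignment], Node],
    n_replicates: int,
    seed: int = 0,
) -> dict[frozenset, int]:
    """Counts of bipartitions over site-resampled replicate trees."""
    rng = np.random.default_rng(seed)
    L = aln.n_sites
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        rep_tree = builder(aln.take_sites(idx))
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    return counts


def annotate_supports(
    tree: Node, counts: dict[frozenset, int], n_replicates: int
) -> Node:
    """Write bootstrap percentages onto a (copy of a) tree's internal nodes."""
    tree = tree.copy()
    all_names = frozenset(tree.leaf_names())
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        other = all_names - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: tuple(sorted(s)))
        node.support = 100.0 * counts.get(key, 0) / n_replicates
    return tree


def bootstrap_support(
    aln: Alignment,
    model: SubstitutionModel,
    builder: Optional[Callable[[Alignment], Node]] = None,
    n_replicates: int = 100,
    seed: int = 0,
    reference: Optional[Node] = None,
) -> Node:
    """Annotate the reference tree's bipartitions with bootstrap percentages.

    The reference defaults to the builder's tree on the original alignment.
    Support = percentage of site-resampled replicates whose tree contains the
    bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if builder is None:
        builder = nj_builder(model)
    if reference is None:
        reference = builder(aln)
    counts = bipartition_counts(aln, builder, n_replicates, seed)
    return annotate_supports(reference, counts, n_replicates)
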