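"""Neighbor joining (Saitou & Nei, with Studier-Keppler Q criterion) and
ordinary-least-squares branch lengths on a fixed topology.

Deterministic: ties in the Q matrix are broken by the smallest (i, j) index
pair.  Recovers additive metrics exactly.
"""

from __future__ import annotations

import numpy as np

from .tree import Node


def ls_branch_lengths(
    tree: Node, D: np.ndarray, names: list[str], floor: float = 1e-6
) -> Node:
    """Fit branch lengths on a fixed topology by least squares against a
    distance matrix (clamped non-negative).  Returns the same tree."""
    idx = {n: i for i, n in enumerate(names)}
    branches = [n for n in tree.postorder() if n.parent is not None]
    bidx = {id(n): k for k, n in enumerate(branches)}
    # edge sets on the path root->tip, as boolean membership vectors
    memb = {}
    for node in tree.preorder():
        if node.parent is None:
            memb[id(node)] = np.zeros(len(branches), dtype=bool)
        else:
            v = memb[id(node.parent)].copy()
            v[bidx[id(node)]] = True
            memb[id(node)] = v
    tips = tree.leaves()
    rows, y = [], []
    for a in range(len(tips)):
        for b in range(a + 1, len(tips)):
            rows.append(memb[id(tips[a])] ^ memb[id(tips[b])])
            y.append(D[idx[tips[a].name], idx[tips[b].name]])
    A = np.array(rows, dtype=float)
    sol, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
    for n in branches:
        n.length = float(max(sol[bidx[id(n)]], floor))
    return tree


def neighbor_joining(D: np.ndarray, names: list[str]) -> Node:
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or len(names) != n:
        raise ValueError("distance matrix / names mismatch")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes = [Node(name) for name in names]
    active = list(range(n))
    D = D.copy()

    if n == 1:
        return nodes[0]
    if n == 2:
        root = Node()
        nodes[0].length = nodes[1].length = D[0, 1] / 2.0
        root.add_child(nodes[0])
        root.add_child(nodes[1])
        return root

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic argmin: smallest (i, j) among ties
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ai, aj = min((int(i), int(j)) for i, j in ties if i < j)
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        new = Node()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        # distances to the new node
        newdist = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = newdist
        D[active, i] = newdist
        D[i, i] = 0.0
        nodes[i] = new
        active.remove(j)

    # final three-taxon star with the three-point formulas
    a, b, c = active
    root = Node()
    nodes[a].length = max(0.5 * (D[a, b] + D[a, c] - D[b, c]), 0.0)
    nodes[b].length = max(0.5 * (D[a, b] + D[b, c] - D[a, c]), 0.0)
    nodes[c].length = max(0.5 * (D[a, c] + D[b, c] - D[a, b]), 0.0)
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    root.add_child(nodes[c])
    return root
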