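"""Strict-clock node dating by constrained least squares.

Node ages (Ma) minimise sum over branches of (length - rate * duration)^2
subject to parent-older-than-child ordering and fossil-style calibration
bounds; the single global rate is profiled out analytically.  Tips are at
age 0.

The solver alternates a closed-form linear least-squares step for the ages
with the profiled-rate update; ordering violations are handled by an
active-set strategy that merges the offending parent/child ages into one
variable (the classic treatment of tree-ordered isotonic least squares),
and bound violations pin the age to the bound.  Deterministic, and
scale-invariant in branch lengths (the rate absorbs any global scaling)
provided at least one absolute calibration pins the timescale.
"""

from __future__ import annotations

import numpy as np

from .tree import Node


def _resolve_calibrations(tree: Node, calibrations: dict) -> dict[int, tuple]:
    out = {}
    for key, (lo, hi) in calibrations.items():
        node = tree.mrca(key)
        if node.is_leaf:
            raise ValueError("calibration resolves to a tip")
        lo = 0.0 if lo is None else float(lo)
        hi = np.inf if hi is None else float(hi)
        if lo > hi:
            raise ValueError("calibration has min > max")
        out[id(node)] = (lo, hi)
    return out


def _check_feasible(tree: Node, cal: dict[int, tuple]) -> None:
    # a descendant's lower bound may not exceed an ancestor's upper bound
    for node in tree.postorder():
        if id(node) not in cal:
            continue
        lo, _ = cal[id(node)]
        anc = node.parent
        while anc is not None:
            if id(anc) in cal and cal[id(anc)][1] < lo:
                raise ValueError(
                    "infeasible calibrations: descendant bound older than ancestor bound"
                )
            anc = anc.parent


class _Groups:
    """Union-find over age variables with optional pinned values."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.value: dict[int, float] = {}

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        vi, vj = self.value.get(ri), self.value.get(rj)
        self.parent[rj] = ri
        if vi is None and vj is not None:
            self.value[ri] = vj
        elif vi is not None and vj is not None:
            self.value[ri] = max(vi, vj)

    def pin(self, i: int, v: float) -> None:
        self.value[self.find(i)] = v


def date_nodes(tree: Node, calibrations: dict) -> Node:
    """Return a dated copy of a rooted tree.

    ``calibrations`` maps an iterable of tip names (the clade's MRCA is
    calibrated) to an ``(min_age, max_age)`` pair in Ma; ``None`` means
    unbounded on that side.  At least one calibration is required to pin
    the timescale.
    """
    if not calibrations:
        raise ValueError("at least one calibration required")
    if len(tree.children) < 2:
        raise ValueError("tree must be rooted")
    tree = tree.copy()
    cal = _resolve_calibrations(tree, calibrations)
    _check_feasible(tree, cal)

    internal = [n for n in tree.postorder() if not n.is_leaf]
    n_var = len(internal)
    index = {id(n): i for i, n in enumerate(internal)}
    # the position of the root along its edge is not identifiable under a
    # clock, so a binary root's two edges contribute one combined residual
    root_children = set(id(c) for c in tree.children) if len(tree.children) == 2 else set()
    A_rows, blen = [], []
    root_row = np.zeros(n_var)
    root_len = 0.0
    for node in tree.postorder():
        if node.parent is None:
            continue
        row = np.zeros(n_var)
        row[index[id(node.parent)]] = 1.0
        if not node.is_leaf:
            row[index[id(node)]] -= 1.0
        if id(node) in root_children:
            root_row += row
            root_len += node.length
            continue
        A_rows.append(row)
        blen.append(node.length)
    if root_children:
        A_rows.append(root_row)
        blen.append(root_len)
    A = np.array(A_rows)
    b = np.array(blen)
    edges = [
        (index[id(n.parent)], index[id(n)])
        for n in tree.postorder()
        if n.parent is not None and not n.is_leaf
    ]

    lo = np.zeros(n_var)
    hi = np.full(n_var, np.inf)
    groups = _Groups(n_var)
    for nid, (clo, chi) in cal.items():
        i = index[nid]
        lo[i], hi[i] = clo, chi
        if np.isfinite(chi) and clo == chi:
            groups.pin(i, clo)
    if not groups.value:
        # range calibrations only: pin the tightest midpoint to fix the scale
        nid, (clo, chi) = min(
            cal.items(), key=lambda kv: (kv[1][1] - kv[1][0])
        )
        mid = 0.5 * (clo + (chi if np.isfinite(chi) else clo * 2 or 1.0))
        groups.pin(index[nid], mid)

    # initial rate from mean root-to-tip path over the deepest pinned age
    depth = {}
    for node in tree.preorder():
        depth[id(node)] = (
            0.0 if node.parent is None else depth[id(node.parent)] + node.length
        )
    tip_depth = np.mean([depth[id(t)] for t in tree.leaves()])
    pin_ages = list(groups.value.values())
    r = max(tip_depth / max(max(pin_ages), 1e-12), 1e-12)

    t = np.zeros(n_var)
    for _outer in range(4 * n_var + 10):
        # collapse variables into groups
        reps = sorted({groups.find(i) for i in range(n_var)})
        rep_col = {rep: k for k, rep in enumerate(reps)}
        col = np.array([rep_col[groups.find(i)] for i in range(n_var)])
        Ag = np.zeros((A.shape[0], len(reps)))
        for i in range(n_var):
            Ag[:, col[i]] += A[:, i]
        fixed_mask = np.array([reps[k] in groups.value for k in range(len(reps))])
        fixed_vals = np.array(
            [groups.value.get(reps[k], 0.0) for k in range(len(reps))]
        )
        Af = Ag[:, ~fixed_mask]
        offset = Ag[:, fixed_mask] @ fixed_vals[fixed_mask]

        # substituting u = rate * age makes the profiled problem linear:
        # b ~ Af u + offset * rate, solved jointly in one least squares
        g = fixed_vals.copy()
        if Af.shape[1]:
            design = np.column_stack([Af, offset])
            sol, *_ = np.linalg.lstsq(design, b, rcond=None)
            r_hat = sol[-1]
            if r_hat > 1e-15:
                r = float(r_hat)
                g[~fixed_mask] = sol[:-1] / r
            else:  # degenerate: keep previous rate, solve ages only
                sol2, *_ = np.linalg.lstsq(Af, b / r - offset, rcond=None)
                g[~fixed_mask] = sol2
        else:
            dur = Ag @ g
            denom = float(dur @ dur)
            if denom > 0:
                r = max(float(b @ dur) / denom, 1e-12)
        t = g[col]

        changed = False
        for p, c in edges:
            if t[p] < t[c] - 1e-9:
                groups.union(p, c)
                changed = True
        for i in range(n_var):
            rep = groups.find(i)
            if rep in groups.value:
                continue
            if t[i] < lo[i] - 1e-9:
                groups.pin(i, lo[i])
                changed = True
            elif t[i] > hi[i] + 1e-9:
                groups.pin(i, hi[i])
                changed = True
        if not changed:
            break

    for n in internal:
        n.age = float(max(t[index[id(n)]], 0.0))
    for n in tree.postorder():
        if n.is_leaf:
            n.age = 0.0
    # squeeze out any residual ordering slack
    for n in tree.preorder():
        if n.parent is not None and not n.is_leaf and n.age > n.parent.age:
            n.age = n.parent.age
    return tree
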