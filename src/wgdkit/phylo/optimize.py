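"""Coordinate-ascent branch-length optimization.

Each sweep optimizes every branch in turn with Brent's method on the exact
one-dimensional likelihood (conditional likelihood vectors at both ends of
the branch are cached).  Within a sweep the cached vectors go slightly stale
as other branches move; a guard re-evaluates the full likelihood after each
sweep and falls back to per-branch fresh recomputation if the sweep failed to
improve, so the reported likelihood never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ..alignment import Alignment
from .likelihood import _tip_partial, log_likelihood
from .model import SubstitutionModel
from .tree import Node

MIN_BRANCH = 1e-8
MAX_BRANCH = 20.0


@dataclass
class OptimizeResult:
    tree: Node
    log_likelihood: float
    converged: bool
    sweeps: int


def _messages(tree, patterns, aln_index, model, rates):
    """Down (subtree) and up (rest-of-tree) conditional vectors per node."""
    n_pat = patterns.shape[1]
    n_cat = len(rates)
    down, dscale = {}, {}
    for node in tree.postorder():
        if node.is_leaf:
            tip = _tip_partial(patterns[aln_index[node.name]])
            down[id(node)] = np.repeat(tip[None], n_cat, axis=0)
            dscale[id(node)] = np.zeros((n_cat, n_pat))
            continue
        part = np.ones_like(down[id(node.children[0])])
        sc = np.zeros((n_cat, n_pat))
        for child in node.children:
            for c, r in enumerate(rates):
                P = model.transition(child.length * r)
                part[c] *= P @ down[id(child)][c]
            sc += dscale[id(child)]
        mx = part.max(axis=1)
        mx[mx == 0.0] = 1.0
        part /= mx[:, None, :]
        sc += np.log(mx)
        down[id(node)] = part
        dscale[id(node)] = sc

    up, uscale = {}, {}
    pi = model.frequencies
    for node in tree.preorder():
        for child in node.children:
            if node.parent is None:
                base = np.repeat(pi[None, :, None], n_cat, axis=0) * np.ones_like(
                    down[id(child)]
                )
                sc = np.zeros((n_cat, base.shape[2]))
            else:
                base = np.empty_like(down[id(child)])
                for c, r in enumerate(rates):
                    P = model.transition(node.length * r)
                    base[c] = P.T @ up[id(node)][c]
                sc = uscale[id(node)].copy()
            for sib in node.children:
                if sib is child:
                    continue
                for c, r in enumerate(rates):
                    P = model.transition(sib.length * r)
                    base[c] *= P @ down[id(sib)][c]
                sc += dscale[id(sib)]
            mx = base.max(axis=1)
            mx[mx == 0.0] = 1.0
            base /= mx[:, None, :]
            sc += np.log(mx)
            up[id(child)] = base
            uscale[id(child)] = sc
    return down, dscale, up, uscale


def _branch_lnl_fn(node, down, dscale, up, uscale, model, rates, weights):
    d, ds = down[id(node)], dscale[id(node)]
    u, us = up[id(node)], uscale[id(node)]
    n_cat = len(rates)

    def lnl(t: float) -> float:
        per_cat = np.empty((n_cat, d.shape[2]))
        for c, r in enumerate(rates):
            P = model.transition(t * r)
            lik = np.einsum("kp,kp->p", u[c], P @ d[c])
            per_cat[c] = np.log(np.clip(lik, 1e-300, None)) + ds[c] + us[c]
        if n_cat == 1:
            pat = per_cat[0]
        else:
            mx = per_cat.max(axis=0)
            pat = mx + np.log(np.mean(np.exp(per_cat - mx), axis=0))
        return float(pat @ weights)

    return lnl


def optimize_branch_lengths(
    tree: Node,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 100,
) -> OptimizeResult:
    """Optimize all branch lengths; returns a new tree and its lnL."""
    tree = tree.copy()
    patterns, weights, _ = aln.compress()
    aln_index = {n: i for i, n in enumerate(aln.names)}
    rates = model.category_rates()

    current = log_likelihood(tree, aln, model)
    converged = False
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        before = current
        saved = {id(n): n.length for n in tree.postorder()}
        _sweep_cached(tree, patterns, aln_index, model, rates, weights)
        new = log_likelihood(tree, aln, model)
        if new < before:
            # stale-cache sweep went backwards: restore and do an exact sweep
            for n in tree.postorder():
                n.length = saved[id(n)]
            new = _sweep_exact(
                tree, aln, patterns, aln_index, model, rates, weights, before
            )
        current = new
        if current - before < tol:
            converged = True
            break
    return OptimizeResult(tree, current, converged, sweeps)


def _optimize_one(node, fn):
    res = minimize_scalar(
        lambda t: -fn(t), bounds=(MIN_BRANCH, MAX_BRANCH), method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x), -float(res.fun)


def _sweep_cached(tree, patterns, aln_index, model, rates, weights):
    down, dscale, up, uscale = _messages(tree, patterns, aln_index, model, rates)
    for node in tree.postorder():
        if node.parent is None:
            continue
        fn = _branch_lnl_fn(node, down, dscale, up, uscale, model, rates, weights)
        t, val = _optimize_one(node, fn)
        if val >= fn(node.length):
            node.length = t


def _sweep_exact(tree, aln, patterns, aln_index, model, rates, weights, current):
    for node in tree.postorder():
        if node.parent is None:
            continue
        down, dscale, up, uscale = _messages(
            tree, patterns, aln_index, model, rates
        )
        fn = _branch_lnl_fn(node, down, dscale, up, uscale, model, rates, weights)
        old_val = fn(node.length)
        t, val = _optimize_one(node, fn)
        if val > old_val:
            node.length = t
            current = current + (val - old_val)
    return log_likelihood(tree, aln, model)
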