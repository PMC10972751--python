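"""Felsenstein pruning likelihood with site-pattern compression.

Gap states (-1) are treated as missing data (partial vector of ones).  Per-
pattern scaling keeps partials in floating range on large trees; discrete
gamma categories, when present, are averaged in log space.
"""

from __future__ import annotations

import numpy as np

from ..alignment import Alignment
from .model import N_STATES, SubstitutionModel
from .tree import Node


def _check_tree(tree: Node, aln: Alignment) -> None:
    names = tree.leaf_names()
    missing = [n for n in names if n not in aln.names]
    if missing:
        raise ValueError(f"tips missing from alignment: {missing}")
    for node in tree.postorder():
        if node.parent is not None and node.length < 0:
            raise ValueError("negative branch length")


def _tip_partial(codes: np.ndarray) -> np.ndarray:
    P = codes.shape[0]
    part = np.zeros((N_STATES, P))
    obs = codes >= 0
    part[:, ~obs] = 1.0
    part[codes[obs], np.nonzero(obs)[0]] = 1.0
    return part


def _category_pattern_loglik(
    tree: Node, patterns: np.ndarray, aln_index: dict, model: SubstitutionModel, rate: float
) -> np.ndarray:
    """Per-pattern log-likelihood for one rate category."""
    n_pat = patterns.shape[1]
    partials: dict[int, np.ndarray] = {}
    scale = np.zeros(n_pat)
    for node in tree.postorder():
        if node.is_leaf:
            partials[id(node)] = _tip_partial(patterns[aln_index[node.name]])
            continue
        part = np.ones((N_STATES, n_pat))
        for child in node.children:
            P = model.transition(child.length * rate)
            part *= P @ partials[id(child)]
        mx = part.max(axis=0)
        mx[mx == 0.0] = 1.0
        part /= mx
        scale += np.log(mx)
        partials[id(node)] = part
        for child in node.children:
            del partials[id(child)]
    root_part = partials[id(tree)]
    lik = model.frequencies @ root_part
    return np.log(np.clip(lik, 1e-300, None)) + scale


def pattern_log_likelihoods(
    tree: Node, aln: Alignment, model: SubstitutionModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(per-pattern lnL, pattern weights, site->pattern index)."""
    _check_tree(tree, aln)
    patterns, weights, inverse = aln.compress()
    aln_index = {n: i for i, n in enumerate(aln.names)}
    rates = model.category_rates()
    per_cat = np.stack(
        [
            _category_pattern_loglik(tree, patterns, aln_index, model, r)
            for r in rates
        ]
    )
    if len(rates) == 1:
        pat_lnl = per_cat[0]
    else:
        mx = per_cat.max(axis=0)
        pat_lnl = mx + np.log(np.mean(np.exp(per_cat - mx), axis=0))
    return pat_lnl, weights, inverse


def log_likelihood(tree: Node, aln: Alignment, model: SubstitutionModel) -> float:
    pat_lnl, weights, _ = pattern_log_likelihoods(tree, aln, model)
    return float(pat_lnl @ weights)


def site_log_likelihoods(
    tree: Node, aln: Alignment, model: SubstitutionModel
) -> np.ndarray:
    pat_lnl, _, inverse = pattern_log_likelihoods(tree, aln, model)
    return pat_lnl[inverse]
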