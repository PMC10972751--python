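"""Reading duplication history off paralogon trees and testing ancestral vs
lineage-specific rediploidization.

A node of a paralogon tree is a duplication iff its child clades share at
least one species (species-overlap rule); duplication nodes are assigned to
events by the lineages of their descendants: both cyclostomes and
gnathostomes on both sides = the shared vertebrate tetraploidization (1R),
gnathostome-only = the jawed-vertebrate allo-tetraploidization (2R_JV),
cyclostome-only = the cyclostome hexaploidization (2R_CY).

Rediploidization tests compare constrained tree topologies under the
ancestral model (cyclostome genes assigned to the two post-duplication
clades, jointly for chromosomally orthologous segments) against the
lineage-specific model (genes grouped by lineage), by RELL likelihood tests
at alpha = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .alignment import Alignment
from .paralogon import GNATHOSTOME_PARALOGONS, LabeledFamily
from .phylo.distance import distance_matrix
from .phylo.model import SubstitutionModel, poisson_model
from .phylo.nj import neighbor_joining
from .phylo.optimize import optimize_branch_lengths
from .phylo.toptest import topology_test
from .phylo.tree import Node

ONE_R_COPY1 = {"a1", "b1"}
ONE_R_COPY2 = {"a2", "b2"}


@dataclass
class SpeciesRoles:
    gnathostomes: set
    hagfish: set
    lamprey: set
    outgroup: set

    @property
    def cyclostomes(self) -> set:
        return self.hagfish | self.lamprey

    @classmethod
    def from_scenario(cls, scenario) -> "SpeciesRoles":
        gn, hf, lp, og = set(), set(), set(), set()
        for sp in scenario.species():
            c = scenario.species_class(sp)
            if c == "gnathostome":
                gn.add(sp)
            elif c == "outgroup":
                og.add(sp)
            elif "hagfish" in sp:
                hf.add(sp)
            else:
                lp.add(sp)
        return cls(gn, hf, lp, og)


def _tip_species(name: str) -> str:
    return name.split("|")[0]


# ---------------------------------------------------------------------------
# node classification
# ---------------------------------------------------------------------------


@dataclass
class NodeReading:
    node: Node
    kind: str  # duplication | speciation
    event: Optional[str]  # 1R | 2R_JV | 2R_CY | None
    support: Optional[float]
    age: Optional[float]


def classify_nodes(tree: Node, roles: SpeciesRoles) -> list[NodeReading]:
    """Annotate internal nodes as duplication/speciation and assign events.

    The tree must be rooted (two children at the root), tips named
    ``species|segment``.  Annotations are written onto the nodes and
    returned as a list of readings.
    """
    if len(tree.children) != 2:
        raise ValueError("tree must be rooted (binary root)")
    readings = []
    for node in tree.postorder():
        if node.is_leaf or node is tree:
            continue
        child_species = [
            {_tip_species(t) for t in c.leaf_names()} for c in node.children
        ]
        overlap = set.intersection(*child_species) if len(child_species) > 1 else set()
        below = set.union(*child_species)
        if overlap:
            node.kind = "duplication"
            cyc = below & roles.cyclostomes
            gna = below & roles.gnathostomes
            if cyc and gna and all(
                (cs & roles.cyclostomes) and (cs & roles.gnathostomes)
                for cs in child_species
            ):
                node.event = "1R"
            elif gna and not cyc and not (below & roles.outgroup):
                node.event = "2R_JV"
            elif cyc and not gna and not (below & roles.outgroup):
                node.event = "2R_CY"
            else:
                node.event = None
        else:
            node.kind = "speciation"
            node.event = None
        readings.append(
            NodeReading(node, node.kind, node.event, node.support, node.age)
        )
    return readings


def one_r_precedes_split(
    tree: Node, roles: SpeciesRoles, bp_threshold: float = 60.0
) -> tuple[bool, Optional[float]]:
    """Does a 1R duplication node precede the cyclostome-gnathostome
    speciation with bootstrap support above the threshold?

    A node labelled 1R by :func:`classify_nodes` has cyclostome and
    gnathostome descendants on both sides, i.e. it topologically precedes
    the speciation; the reading additionally requires BP > threshold when
    supports are present.
    """
    classify_nodes(tree, roles)
    best = None
    for node in tree.postorder():
        if getattr(node, "event", None) == "1R":
            if best is None or (node.support or 0) > (best.support or 0):
                best = node
    if best is None:
        return False, None
    if best.support is None:
        return True, None
    return bool(best.support > bp_threshold), best.support


# ---------------------------------------------------------------------------
# rediploidization family selection and topology enumeration
# ---------------------------------------------------------------------------


def meets_basic_redip_criteria(tree: Node) -> bool:
    """Criteria (i)-(iii) on a simulated family tree with ``species|label``
    tips: a gnathostome species retaining both 1R copies, at least one
    hagfish-like and one lamprey-like gene, and an outgroup gene."""
    by_species: dict[str, set] = {}
    for t in tree.leaves():
        sp, label = t.name.split("|")[:2]
        by_species.setdefault(sp, set()).add(label)
    has_both_1r = any(
        (labels & ONE_R_COPY1) and (labels & ONE_R_COPY2)
        for sp, labels in by_species.items()
        if sp not in ("outgroup", "hagfish_like", "lamprey_like")
    )
    return (
        has_both_1r
        and "hagfish_like" in by_species
        and "lamprey_like" in by_species
        and "outgroup" in by_species
    )


def _family_genes(family: LabeledFamily, roles: SpeciesRoles):
    """(gene, species, segment) triples for placed genes."""
    out = []
    for gene, key in family.rows.items():
        if key is None:
            continue
        out.append((gene, key[0], key[1]))
    return out


def select_redip_families(
    families: list[LabeledFamily],
    roles: SpeciesRoles,
    orthology: Optional[list] = None,
    max_topologies: int = 10,
) -> list[LabeledFamily]:
    """Families informative for the rediploidization test.

    Keeps families with (i) a gnathostome species retaining both 1R_1
    (alpha1/beta1) and 1R_2 (alpha2/beta2) copies, (ii) at least one hagfish
    and one lamprey gene, (iii) at least one outgroup gene, and (iv) at most
    ``max_topologies`` possible ancestral rediploidization topologies
    (evaluated by running the enumerator).
    """
    kept = []
    for fam in families:
        genes = _family_genes(fam, roles)
        by_species: dict[str, set] = {}
        for g, sp, seg in genes:
            by_species.setdefault(sp, set()).add(seg)
        crit1 = any(
            (segs & ONE_R_COPY1) and (segs & ONE_R_COPY2)
            for sp, segs in by_species.items()
            if sp in roles.gnathostomes
        )
        crit2 = any(sp in roles.hagfish for _, sp, _ in genes) and any(
            sp in roles.lamprey for _, sp, _ in genes
        )
        crit3 = any(sp in roles.outgroup for _, sp, _ in genes)
        if not (crit1 and crit2 and crit3):
            continue
        tops = enumerate_constrained_topologies(
            fam, roles, mode="ancestral", orthology=orthology
        )
        if 1 <= len(tops) <= max_topologies:
            kept.append(fam)
    return kept


def _merge_units(units: list, orthology: Optional[list]) -> list[frozenset]:
    """Group cyclostome (species, segment) units by orthology constraints."""
    groups = [frozenset({u}) for u in units]
    if not orthology:
        return groups
    for constraint in orthology:
        constraint = frozenset(constraint)
        linked = [g for g in groups if g & constraint]
        if len(linked) > 1:
            merged = frozenset().union(*linked)
            groups = [g for g in groups if not (g & constraint)] + [merged]
    return groups


def enumerate_constrained_topologies(
    family: LabeledFamily,
    roles: SpeciesRoles,
    mode: str = "ancestral",
    orthology: Optional[list] = None,
) -> list[Node]:
    """Constrained topologies for the 1R rediploidization test.

    Ancestral mode: gnathostome 1R_1 and 1R_2 copies anchor two clades;
    every assignment of cyclostome (species, segment) units to the two
    clades yields one topology, with chromosomally orthologous units
    (given by ``orthology`` as sets of (species, segment) pairs) assigned
    jointly.  Lineage-specific mode: a single topology grouping gnathostome
    genes and cyclostome genes into sister clades.  Outgroup genes attach
    outside.  Returned trees may contain multifurcations (resolved later
    against the data).
    """
    if mode not in ("ancestral", "lineage_specific"):
        raise ValueError("mode must be 'ancestral' or 'lineage_specific'")
    genes = _family_genes(family, roles)
    out_genes = [g for g, sp, _ in genes if sp in roles.outgroup]
    gn1 = [
        g
        for g, sp, seg in genes
        if sp in roles.gnathostomes and seg in ONE_R_COPY1
    ]
    gn2 = [
        g
        for g, sp, seg in genes
        if sp in roles.gnathostomes and seg in ONE_R_COPY2
    ]
    cyc = [
        (g, sp, seg) for g, sp, seg in genes if sp in roles.cyclostomes
    ]

    if mode == "lineage_specific":
        gn_all = gn1 + gn2
        cyc_all = [g for g, _, _ in cyc]
        if not gn_all or not cyc_all:
            return []
        return [_build_tree(out_genes, [gn_all, cyc_all])]

    if not cyc:
        return []  # no cyclostome genes: the family is uninformative
    units = sorted({(sp, seg) for _, sp, seg in cyc})
    groups = _merge_units(units, orthology)
    groups = sorted(groups, key=lambda g: sorted(g))
    seen = set()
    topologies = []
    for assignment in itertools.product((0, 1), repeat=len(groups)):
        slot_units: tuple[set, set] = (set(), set())
        for gi, slot in enumerate(assignment):
            slot_units[slot].update(groups[gi])
        key = (frozenset(slot_units[0]), frozenset(slot_units[1]))
        if key in seen:
            continue
        seen.add(key)
        clade1 = list(gn1) + [g for g, sp, seg in cyc if (sp, seg) in slot_units[0]]
        clade2 = list(gn2) + [g for g, sp, seg in cyc if (sp, seg) in slot_units[1]]
        if not clade1 or not clade2:
            continue
        topologies.append(_build_tree(out_genes, [clade1, clade2]))
    return topologies


def enumerate_cyclostome_pair_topologies(
    family: LabeledFamily,
    roles: SpeciesRoles,
    mode: str = "ancestral",
    hag_pair: Optional[tuple] = None,
    lam_pair: Optional[tuple] = None,
) -> list[Node]:
    """Constrained topologies for the post-2R_CY rediploidization test on a
    paralogous segment pair retained in the cyclostome lineages.

    ``hag_pair``/``lam_pair`` designate the two paralogous hagfish and
    lamprey segments under test (defaults: the family must carry exactly two
    segments per lineage).  Ancestral mode: the two possible cross-lineage
    groupings of hagfish and lamprey segments (each lineage's paralogous
    segments fall in different post-duplication clades); lineage-specific
    mode: genes grouped by lineage.  The family is informative only when at
    least three of the four designated segments carry genes.  All other
    genes (outgroup, gnathostomes, other cyclostome segments) form the
    unconstrained remainder.
    """
    genes = _family_genes(family, roles)
    by_seg: dict[tuple, list] = {}
    for g, sp, seg in genes:
        if sp in roles.cyclostomes:
            by_seg.setdefault((sp in roles.hagfish, seg), []).append(g)
    hag_segs = sorted(seg for (is_h, seg) in by_seg if is_h)
    lam_segs = sorted(seg for (is_h, seg) in by_seg if not is_h)
    if hag_pair is None:
        if len(hag_segs) != 2:
            return []
        hag_pair = tuple(hag_segs)
    if lam_pair is None:
        if len(lam_segs) != 2:
            return []
        lam_pair = tuple(lam_segs)
    h1g = by_seg.get((True, hag_pair[0]), [])
    h2g = by_seg.get((True, hag_pair[1]), [])
    l1g = by_seg.get((False, lam_pair[0]), [])
    l2g = by_seg.get((False, lam_pair[1]), [])
    n_present = sum(1 for g in (h1g, h2g, l1g, l2g) if g)
    if n_present < 3:
        return []
    designated = set(h1g + h2g + l1g + l2g)
    rest = [g for g, _, _ in genes if g not in designated]
    if mode == "lineage_specific":
        clades = [c for c in (h1g + h2g, l1g + l2g) if c]
        return [_build_tree(rest, clades)]
    tops = []
    for pairing in (
        (h1g + l1g, h2g + l2g),
        (h1g + l2g, h2g + l1g),
    ):
        clades = [c for c in pairing if c]
        if len(clades) == 2:
            tops.append(_build_tree(rest, clades))
    return tops


def _build_tree(outside: list[str], clades: list[list[str]]) -> Node:
    """Rooted constraint tree: (outside..., (clade1, clade2)).

    Internal structure branches start short (they are refined against the
    data); tip attachment branches start at a generic depth.
    """
    root = Node()
    for g in outside:
        root.add_child(Node(g, 0.1))
    inner = root.add_child(Node(None, 0.01))
    for clade in clades:
        if len(clade) == 1:
            inner.add_child(Node(clade[0], 0.1))
        else:
            cn = inner.add_child(Node(None, 0.01))
            for g in clade:
                cn.add_child(Node(g, 0.1))
    if len(root.children) == 1:
        root = root.suppress_unifurcations()
    return root


def _rooted_group_subtree(
    rows: list[str], D: np.ndarray, idx: dict, outside: list[str]
) -> Node:
    """Data-driven rooted resolution of a flat clade: NJ over the clade's
    rows plus an anchor pseudo-taxon (mean distance to the outside rows),
    rooted on the anchor edge."""
    m = len(rows)
    M = np.zeros((m + 1, m + 1))
    ridx = [idx[r] for r in rows]
    for i in range(m):
        for j in range(i + 1, m):
            M[i, j] = M[j, i] = D[ridx[i], ridx[j]]
    oidx = [idx[o] for o in outside]
    for i in range(m):
        M[i, m] = M[m, i] = float(np.mean(D[ridx[i], oidx]))
    sub = neighbor_joining(M, rows + ["@anchor"])
    rooted = sub.root_with_outgroup(["@anchor"])
    (keep,) = [
        c
        for c in rooted.children
        if not (c.is_leaf and c.name == "@anchor")
    ]
    keep.parent = None
    for n in keep.postorder():
        n.length = max(n.length, 1e-6)
    return keep


def resolve_multifurcations(
    tree: Node, D: np.ndarray, names: list[str]
) -> Node:
    """Resolve multifurcations of a constraint tree against the data.

    Flat clades (all-tip polytomies) are resolved by anchor-rooted neighbor
    joining on the distance matrix; mixed polytomies fall back to neighbor
    joining on group-average distances.  Constraint clade membership is
    never altered.  Branch lengths are then fitted to the distance matrix
    by least squares, giving the likelihood optimizer a near-converged
    start.
    """
    from .phylo.nj import ls_branch_lengths
    idx = {n: i for i, n in enumerate(names)}
    tree = tree.copy()
    all_names = set(names) & set(tree.leaf_names())

    def resolve(node: Node) -> Node:
        node.children = [resolve(c) for c in node.children]
        for c in node.children:
            c.parent = node
        limit = 3 if node.parent is None else 2
        if len(node.children) <= limit:
            return node
        outside = sorted(all_names - set(node.leaf_names()))
        if all(c.is_leaf for c in node.children) and outside:
            rows = [c.name for c in node.children]
            length = node.length
            new = _rooted_group_subtree(rows, D, idx, outside)
            node.children = []
            if new.is_leaf or len(new.children) == 0:
                node.add_child(new)
            else:
                for c in list(new.children):
                    node.add_child(c)
            node.length = length
            return node
        m = len(node.children)
        groups = [[idx[t] for t in c.leaf_names() if t in idx] for c in node.children]
        M = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                M[i, j] = M[j, i] = float(
                    np.mean(D[np.ix_(groups[i], groups[j])])
                )
        sub = neighbor_joining(M, [str(i) for i in range(m)])
        children = node.children
        node.children = []

        def graft(sn: Node) -> Node:
            if sn.is_leaf:
                orig = children[int(sn.name)]
                orig.length = max(sn.length, 1e-6)
                return orig
            g = Node(None, max(sn.length, 1e-6))
            for c in sn.children:
                g.add_child(graft(c))
            return g

        for c in sub.children:
            node.add_child(graft(c))
        return node

    resolved = resolve(tree)
    usable = set(resolved.leaf_names()) <= set(idx)
    return ls_branch_lengths(resolved, D, names) if usable else resolved


def candidate_cyclostome_pairs(tree: Node, roles: SpeciesRoles) -> Optional[dict]:
    """Identify the cyclostome homoeologous segment pair to test on a CLG
    paralogon tree, and whether its topology already shows the
    lineage-specific rediploidization pattern.

    Lineage-specific pattern: a cyclostome-only speciation node whose two
    children are within-lineage duplications (two hagfish segments sister to
    two lamprey segments).  Otherwise the youngest cyclostome duplication
    node with both lineages on both sides designates the (ancestral-looking)
    pair.  Returns {hag_pair, lam_pair, pattern, ages} or None.
    """
    classify_nodes(tree, roles)

    def segs(node: Node, species_set: set) -> list[str]:
        return sorted(
            {
                t.split("|", 1)[1]
                for t in node.leaf_names()
                if _tip_species(t) in species_set
            }
        )

    candidates = []
    for node in tree.postorder():
        if node.is_leaf or node is tree:
            continue
        below = {_tip_species(t) for t in node.leaf_names()}
        if not below <= roles.cyclostomes:
            continue
        hseg, lseg = segs(node, roles.hagfish), segs(node, roles.lamprey)
        if len(hseg) != 2 or len(lseg) != 2:
            continue
        # sister within-lineage duplications = the lineage-specific pattern
        pattern = "ancestral"
        if len(node.children) == 2:
            sp = [
                {_tip_species(t) for t in c.leaf_names()}
                for c in node.children
            ]
            if (sp[0] <= roles.hagfish and sp[1] <= roles.lamprey) or (
                sp[1] <= roles.hagfish and sp[0] <= roles.lamprey
            ):
                pattern = "lineage_specific"
        age = node.age if node.age is not None else np.inf
        candidates.append(
            (
                age,
                len(node.leaf_names()),
                {
                    "hag_pair": tuple(hseg),
                    "lam_pair": tuple(lseg),
                    "pattern": pattern,
                    "ages": {"clade": node.age},
                },
            )
        )
    if candidates:
        candidates.sort(key=lambda c: (c[0], c[1]))
        return candidates[0][2]
    return None


def detect_lineage_specific(
    tree: Node,
    roles: SpeciesRoles,
    margin: float = 5.0,
    aln: Optional[Alignment] = None,
    min_shared_sites: int = 50,
) -> Optional[dict]:
    """Divergence-time reading of lineage-specific rediploidization on a
    dated paralogon tree.

    Flags the tree when a cyclostome duplication node joins two (or more)
    segments of a *single* lineage at an age clearly younger than the tree's
    own hagfish-lamprey speciation ages - paralogue divergence inside one
    lineage after the split, the signature of independent rediploidization.
    When an alignment is given, the two sides of the duplication must share
    at least ``min_shared_sites`` resolved columns: rows with disjoint
    family coverage have no data constraining their relative placement and
    can collapse to spuriously young nodes.  Returns the within-lineage
    duplication ages per lineage, or None.
    """
    classify_nodes(tree, roles)
    splits = []
    for node in tree.postorder():
        if node.is_leaf or getattr(node, "kind", None) != "speciation":
            continue
        sp = [
            {_tip_species(t) for t in c.leaf_names()} for c in node.children
        ]
        if len(sp) == 2 and set.union(*sp) <= roles.cyclostomes:
            if (sp[0] <= roles.hagfish and sp[1] <= roles.lamprey) or (
                sp[1] <= roles.hagfish and sp[0] <= roles.lamprey
            ):
                if node.age is not None:
                    splits.append(node.age)
    if not splits:
        return None
    cutoff = float(np.mean(splits)) - margin
    found: dict[str, list] = {}
    for node in tree.postorder():
        if node.is_leaf or getattr(node, "event", None) != "2R_CY":
            continue
        below_sp = {_tip_species(t) for t in node.leaf_names()}
        segs = {t.split("|", 1)[1] for t in node.leaf_names()}
        if len(segs) < 2 or node.age is None or node.age >= cutoff:
            continue
        if aln is not None and len(node.children) == 2:
            shared = 0
            for a in node.children[0].leaf_names():
                for b in node.children[1].leaf_names():
                    if a in aln.names and b in aln.names:
                        shared = max(
                            shared,
                            int(
                                np.sum((aln.row(a) >= 0) & (aln.row(b) >= 0))
                            ),
                        )
            if shared < min_shared_sites:
                continue
        if below_sp <= roles.hagfish:
            found.setdefault("hagfish", []).append(node.age)
        elif below_sp <= roles.lamprey:
            found.setdefault("lamprey", []).append(node.age)
    if not found:
        return None
    return {
        "within_lineage_duplication_ages": found,
        "split_age": float(np.mean(splits)),
    }


# ---------------------------------------------------------------------------
# family-level likelihood test
# ---------------------------------------------------------------------------


@dataclass
class RediploidizationVerdict:
    family_id: str
    clg: int
    verdict: str  # ancestral | lineage_specific | inconclusive
    p_ancestral: list[float] = field(default_factory=list)
    p_lineage_specific: list[float] = field(default_factory=list)
    n_constrained_topologies: int = 0
    note: str = ""


def _decide(p_anc, p_ls, alpha, policy) -> str:
    if not p_anc or not p_ls:
        return "inconclusive"
    anc_ok = [p >= alpha for p in p_anc]
    ls_ok = [p >= alpha for p in p_ls]
    if policy == "unanimity":
        if any(anc_ok) and not any(ls_ok):
            return "ancestral"
        if any(ls_ok) and not any(anc_ok):
            return "lineage_specific"
        return "inconclusive"
    # majority: best surviving side wins
    if max(p_anc) > max(p_ls) and not any(ls_ok):
        return "ancestral"
    if max(p_ls) > max(p_anc) and not any(anc_ok):
        return "lineage_specific"
    return "inconclusive"


def test_family(
    family: LabeledFamily,
    roles: SpeciesRoles,
    model: Optional[SubstitutionModel] = None,
    alpha: float = 0.05,
    event: str = "1R",
    orthology: Optional[list] = None,
    n_rell: int = 1000,
    seed: int = 0,
    policy: str = "unanimity",
    hag_pair: Optional[tuple] = None,
    lam_pair: Optional[tuple] = None,
    max_sweeps: int = 5,
) -> RediploidizationVerdict:
    """Likelihood test of ancestral vs lineage-specific rediploidization.

    Builds the unconstrained tree (NJ + branch-length optimization),
    optimizes every constrained topology and runs the RELL topology test; a
    topology is rejected when significantly less likely than the best tree
    at ``alpha``.  Verdict = ancestral iff every lineage-specific topology
    is rejected and at least one ancestral topology survives (and
    symmetrically); otherwise inconclusive.
    """
    model = model or poisson_model()
    if event == "1R":
        anc = enumerate_constrained_topologies(
            family, roles, "ancestral", orthology
        )
        ls = enumerate_constrained_topologies(
            family, roles, "lineage_specific", orthology
        )
    elif event == "2R_CY":
        anc = enumerate_cyclostome_pair_topologies(
            family, roles, "ancestral", hag_pair, lam_pair
        )
        ls = enumerate_cyclostome_pair_topologies(
            family, roles, "lineage_specific", hag_pair, lam_pair
        )
    else:
        raise ValueError(f"unknown event {event!r}")
    if not anc or not ls:
        return RediploidizationVerdict(
            family.family_id, family.clg, "inconclusive",
            note="no constrained topologies",
        )

    genes = sorted(g for g, key in family.rows.items() if key is not None)
    aln = family.alignment.subset(genes)
    obs = aln.matrix >= 0
    hi = np.where(obs, aln.matrix, -1).max(axis=0)
    lo = np.where(obs, aln.matrix, 99).min(axis=0)
    if not np.any((hi > lo) & (lo < 99)):
        return RediploidizationVerdict(
            family.family_id, family.clg, "inconclusive",
            n_constrained_topologies=len(anc) + len(ls),
            note="no variable sites",
        )
    D = distance_matrix(aln, model, max_distance=10.0)
    unconstrained = neighbor_joining(D, aln.names)
    from .phylo.tree import patristic_distances

    Dp = patristic_distances(unconstrained, aln.names)
    candidates = []
    for top in [unconstrained] + anc + ls:
        resolved = resolve_multifurcations(top, Dp, aln.names)
        candidates.append(
            optimize_branch_lengths(resolved, aln, model, max_sweeps=max_sweeps).tree
        )
    result = topology_test(
        candidates, aln, model, n_rell=n_rell, seed=seed, alpha=alpha,
        method="kh",
    )
    p_anc = result.p_values[1 : 1 + len(anc)]
    p_ls = result.p_values[1 + len(anc) :]
    verdict = _decide(p_anc, p_ls, alpha, policy)
    return RediploidizationVerdict(
        family.family_id,
        family.clg,
        verdict,
        p_anc,
        p_ls,
        len(anc) + len(ls),
    )


def tally_by_clg(verdicts: Iterable[RediploidizationVerdict]) -> pd.DataFrame:
    """Per-CLG counts of ancestral / lineage-specific / inconclusive
    verdicts; column sums equal the number of tested families."""
    rows: dict[int, dict] = {}
    for v in verdicts:
        row = rows.setdefault(
            v.clg,
            {"clg": v.clg, "ancestral": 0, "lineage_specific": 0, "inconclusive": 0},
        )
        row[v.verdict] += 1
    return (
        pd.DataFrame(sorted(rows.values(), key=lambda r: r["clg"]))
        if rows
        else pd.DataFrame(
            columns=["clg", "ancestral", "lineage_specific", "inconclusive"]
        )
    )


# ---------------------------------------------------------------------------
# divergence-time distribution of cyclostome homoeologues
# ---------------------------------------------------------------------------


def divergence_time_distribution(
    dated_trees: list[Node],
    roles: SpeciesRoles,
    seed: int = 0,
) -> dict:
    """Ages of cyclostome (2R_CY) duplication nodes across dated paralogon
    trees, with a 1- vs 2-component Gaussian mixture summary (BIC-preferred).

    Refuses to fit a mixture on fewer than 4 ages.
    """
    ages = []
    for tree in dated_trees:
        classify_nodes(tree, roles)
        for node in tree.postorder():
            if getattr(node, "event", None) != "2R_CY" or node.age is None:
                continue
            # homoeologous-chromosome divergences: both post-duplication
            # sides must carry both cyclostome lineages (within-lineage
            # duplications are rediploidization artefacts, not 2R_CY ages)
            sides = [
                {_tip_species(t) for t in c.leaf_names()}
                for c in node.children
            ]
            if all(
                (s & roles.hagfish) and (s & roles.lamprey) for s in sides
            ):
                ages.append(float(node.age))
    out = {"ages": sorted(ages)}
    if len(ages) < 4:
        out["note"] = "too few ages for a mixture fit"
        return out
    X = np.array(ages).reshape(-1, 1)
    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(
            n_components=k,
            n_init=5,
            random_state=seed & 0x7FFFFFFF,
            covariance_type="full",
            reg_covar=1e-3,
        ).fit(X)
        fits[k] = gm
    bic1, bic2 = fits[1].bic(X), fits[2].bic(X)
    means2 = sorted(float(m) for m in fits[2].means_.ravel())
    out.update(
        {
            "mean_1": float(fits[1].means_.ravel()[0]),
            "means_2": means2,
            "bic_1": float(bic1),
            "bic_2": float(bic2),
            "preferred": 2 if bic2 < bic1 else 1,
        }
    )
    return out
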