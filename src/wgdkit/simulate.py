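"""Synthetic data generator: gene families, proteomes, karyotypes and paired
germline/soma depth tracks descending from a scripted evolutionary history,
with a machine-readable truth log.

Every operation is a pure function of its inputs and a seed.  Duplication
node ages in emitted gene trees equal the scheduled rediploidization (or
progenitor-divergence) ages exactly; gene loss is i.i.d. per copy per
terminal lineage; sequences are indel-free so per-family alignments are
columnwise by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .alignment import Alignment
from .phylo.model import SubstitutionModel, poisson_model
from .phylo.tree import Node, set_lengths_from_ages
from .scenario import (
    CYCLOSTOME_LABELS,
    GNATHOSTOME_LABELS,
    OUTGROUP_LABEL,
    EvolutionScenario,
    Split,
)


class AllCopiesLost(Exception):
    """Raised when gene loss removes every vertebrate copy of a family."""


# ---------------------------------------------------------------------------
# truth log
# ---------------------------------------------------------------------------


@dataclass
class TruthLog:
    """Ground truth for everything the simulator emits."""

    families: dict = field(default_factory=dict)  # family_id -> info
    chromosomes: dict = field(default_factory=dict)  # (species, chrom) -> [units]
    regions: list = field(default_factory=list)  # planted depth regions
    repeats: dict = field(default_factory=dict)  # repeat name -> copy count

    def gene_info(self) -> pd.DataFrame:
        rows = []
        for fam_id, info in self.families.items():
            for gene_id, g in info["genes"].items():
                rows.append(
                    {
                        "gene_id": gene_id,
                        "family_id": fam_id,
                        "species": g["species"],
                        "clg": info["clg"],
                        "label": g["label"],
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "families": self.families,
            "chromosomes": {
                f"{sp}:{ch}": units for (sp, ch), units in self.chromosomes.items()
            },
            "regions": self.regions,
            "repeats": self.repeats,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthLog":
        with open(path) as fh:
            payload = json.load(fh)
        chroms = {
            tuple(k.split(":", 1)): v for k, v in payload["chromosomes"].items()
        }
        return cls(
            families=payload["families"],
            chromosomes=chroms,
            regions=[tuple(r) for r in payload["regions"]],
            repeats=payload["repeats"],
        )


# ---------------------------------------------------------------------------
# gene-family trees
# ---------------------------------------------------------------------------


def _clade_universe(sp_node: Node, scenario: EvolutionScenario) -> frozenset:
    labels: set = set()
    for tip in sp_node.leaves():
        labels |= scenario.labels_for_species(tip.name)
    return frozenset(labels)


def _grow(
    sp_node: Node,
    labels: frozenset,
    age: float,
    splits: list[Split],
    scenario: EvolutionScenario,
) -> Node:
    # deepest split that fires on this branch segment, if any
    best = None
    for s in splits:
        if not (labels & s.side1 and labels & s.side2):
            continue
        if isinstance(s.age, dict):
            if not (sp_node.is_leaf and sp_node.name in s.age):
                continue
            fire = s.age[sp_node.name]
        else:
            fire = s.age
        if sp_node.age <= fire < age:
            if best is None or fire > best[1]:
                best = (s, fire)
    if best is not None:
        s, fire = best
        node = Node()
        node.age = fire
        node.kind = "duplication"
        node.event = s.event
        node.add_child(_grow(sp_node, labels & s.side1, fire, splits, scenario))
        node.add_child(_grow(sp_node, labels & s.side2, fire, splits, scenario))
        return node
    if sp_node.is_leaf:
        (label,) = labels
        tip = Node(f"{sp_node.name}|{label}")
        tip.age = 0.0
        tip.kind = "tip"
        return tip
    node = Node()
    node.age = sp_node.age
    node.kind = "speciation"
    for child in sp_node.children:
        child_labels = labels & _clade_universe(child, scenario)
        if child_labels:
            node.add_child(
                _grow(child, child_labels, sp_node.age, splits, scenario)
            )
    return node


def _prune(node: Node, keep: Callable[[Node], bool]) -> Optional[Node]:
    if node.is_leaf:
        return node if keep(node) else None
    kept = [p for p in (_prune(c, keep) for c in node.children) if p is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    new = Node(node.name)
    new.age, new.kind, new.event = node.age, node.kind, node.event
    for k in kept:
        new.add_child(k)
    return new


def simulate_family_tree(
    scenario: EvolutionScenario, clg: int, seed: int
) -> Node:
    """Simulate one dated gene-family tree for a CLG.

    Each WGD on the family's lineage creates duplicate subtrees whose
    divergence age equals the scheduled rediploidization (or progenitor
    divergence) age for that CLG.  Losses prune tips with probability
    1 - retention per duplication in the tip's history, independently per
    terminal lineage.  Raises :class:`AllCopiesLost` if no vertebrate copy
    survives (callers resample).
    """
    if not 0 <= clg < scenario.clg_count:
        raise ValueError(f"clg {clg} out of range [0, {scenario.clg_count})")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, clg])
    splits = scenario.splits_for_clg(clg)
    universe = _clade_universe(scenario.species_tree, scenario)
    full = _grow(
        scenario.species_tree, universe, float("inf"), splits, scenario
    )
    retention = {ev.name: ev.retention for ev in scenario.events}

    # survival probability per tip from its duplication ancestry
    surviving: set[str] = set()
    def walk(node: Node, events: tuple) -> None:
        if node.is_leaf:
            p = 1.0
            for e in events:
                p *= retention[e]
            if node.name.split("|")[0] == "outgroup" or rng.random() < p:
                surviving.add(node.name)
            return
        for c in node.children:
            walk(c, events + ((node.event,) if node.kind == "duplication" else ()))

    walk(full, ())
    pruned = _prune(full, lambda tip: tip.name in surviving)
    if pruned is None or all(
        t.name.startswith("outgroup") for t in pruned.leaves()
    ):
        raise AllCopiesLost(f"no vertebrate copy survived for CLG {clg}")
    set_lengths_from_ages(pruned)
    return pruned


@dataclass
class GeneFamilyRecord:
    """One simulated family: its dated tree and (optional) alignment."""

    family_id: str
    clg: int
    tree: Node
    alignment: Optional[Alignment] = None

    def species_of(self, tip_name: str) -> str:
        return tip_name.split("|")[0]

    def label_of(self, tip_name: str) -> str:
        return tip_name.split("|")[1]


def _requirement(
    name: Optional[str], scenario: EvolutionScenario
) -> Callable[[Node], bool]:
    if name is None:
        return lambda tree: True
    if name == "species_coverage":
        all_species = set(scenario.species())

        def check(tree: Node) -> bool:
            species = {t.name.split("|")[0] for t in tree.leaves()}
            return species == all_species

        return check
    if name == "redip_informative":
        from .wgd import meets_basic_redip_criteria

        return meets_basic_redip_criteria
    raise ValueError(f"unknown requirement {name!r}")


def simulate_families(
    scenario: EvolutionScenario,
    clg: int,
    n_families: int,
    seed: int,
    sites: int = 300,
    model: Optional[SubstitutionModel] = None,
    require: Optional[str] = None,
    max_tries: int = 200,
) -> list[GeneFamilyRecord]:
    """Simulate ``n_families`` informative families with sequences.

    ``require`` selects a rejection guard: ``None`` accepts any family with a
    surviving vertebrate copy; ``"species_coverage"`` requires every species
    to retain at least one gene; ``"redip_informative"`` requires the basic
    rediploidization-test criteria (gnathostome 1R_1+1R_2, both cyclostomes,
    outgroup).
    """
    model = model or poisson_model()
    ok = _requirement(require, scenario)
    out = []
    attempt = 0
    for i in range(n_families):
        tree = None
        for _ in range(max_tries):
            try:
                cand = simulate_family_tree(
                    scenario, clg, seed * 1_000_003 + attempt
                )
            except AllCopiesLost:
                cand = None
            attempt += 1
            if cand is not None and ok(cand):
                tree = cand
                break
        if tree is None:
            raise AllCopiesLost(
                f"could not draw an acceptable family for CLG {clg} "
                f"after {max_tries} tries"
            )
        fam_id = f"clg{clg:02d}_f{i:03d}"
        aln = evolve_sequences(
            tree, sites, model, scenario.rate, seed=seed * 7_919 + i
        )
        out.append(GeneFamilyRecord(fam_id, clg, tree, aln))
    return out


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def evolve_sequences(
    tree: Node,
    length: int,
    model: SubstitutionModel,
    rate: float,
    seed: int = 0,
) -> Alignment:
    """Evolve ungapped protein sequences down a dated tree.

    Branch durations are taken from node ages (Ma); the expected number of
    substitutions per branch is ``rate * duration`` per site.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    pi = model.frequencies
    states: dict[int, np.ndarray] = {
        id(tree): rng.choice(20, size=length, p=pi)
    }
    seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is not None:
            if node.age is None or node.parent.age is None:
                duration = node.length
            else:
                duration = node.parent.age - node.age
            if duration < 0:
                raise ValueError("negative branch duration (non-ultrametric tree)")
            parent_states = states[id(node.parent)]
            t = duration * rate
            if t == 0:
                child = parent_states.copy()
            else:
                P = model.transition(t)
                child = np.empty(length, dtype=np.int64)
                for s in range(20):
                    idx = parent_states == s
                    k = int(idx.sum())
                    if k:
                        child[idx] = rng.choice(20, size=k, p=P[s])
            states[id(node)] = child
        if node.is_leaf:
            seqs[node.name] = states[id(node)]
    names = list(seqs)
    mat = np.stack([seqs[n] for n in names]).astype(np.int8)
    return Alignment(names, mat)


# ---------------------------------------------------------------------------
# karyotypes
# ---------------------------------------------------------------------------


def default_fusion_plan(
    scenario: EvolutionScenario,
    seed: int = 0,
    species: str = "hagfish_like",
    min_units: int = 2,
    max_units: int = 6,
) -> dict:
    """Random fusion plan: group post-WGD units (CLG, segment label) into
    chromosomes of 2-6 units, never fusing two units of the same CLG."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 97])
    units = [
        (clg, lab)
        for clg in range(scenario.clg_count)
        for lab in CYCLOSTOME_LABELS
    ]
    order = list(rng.permutation(len(units)))
    pool = [units[i] for i in order]
    groups: list[list] = []
    while pool:
        size = int(rng.integers(min_units, max_units + 1))
        group: list = []
        rest: list = []
        for u in pool:
            if len(group) < size and all(u[0] != g[0] for g in group):
                group.append(u)
            else:
                rest.append(u)
        pool = rest
        groups.append(group)
    # fold a trailing singleton into the previous group if possible
    if len(groups) > 1 and len(groups[-1]) == 1:
        last = groups.pop()
        groups[-1].extend(last)
    return {species: groups}


def karyotype_from_families(
    scenario: EvolutionScenario,
    families: Sequence[GeneFamilyRecord],
    fusion_plan: Optional[dict] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Assign every surviving gene a (chromosome, position).

    Species without a fusion plan get one chromosome per post-WGD unit
    (outgroup: one per CLG); species with a plan get fused chromosomes.
    Within-chromosome gene order is shuffled.  Returns the gene map and the
    (species, chromosome) -> unit composition dict.
    """
    fusion_plan = fusion_plan or {}
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 131])
    known_units = {
        (clg, lab)
        for clg in range(scenario.clg_count)
        for lab in CYCLOSTOME_LABELS + GNATHOSTOME_LABELS + (OUTGROUP_LABEL,)
    }
    unit_to_chrom: dict[str, dict] = {}
    composition: dict = {}
    for sp in scenario.species():
        mapping = {}
        if sp in fusion_plan:
            for i, group in enumerate(fusion_plan[sp]):
                chrom = f"chr{i + 1}"
                for unit in group:
                    unit = tuple(unit)
                    if unit not in known_units:
                        raise ValueError(f"fusion plan references unknown unit {unit}")
                    mapping[unit] = chrom
                composition[(sp, chrom)] = [list(u) for u in group]
        unit_to_chrom[sp] = mapping

    # gather genes per (species, chromosome)
    genes: dict[tuple, list] = {}
    for fam in families:
        for tip in fam.tree.leaves():
            sp = fam.species_of(tip.name)
            label = fam.label_of(tip.name)
            unit = (fam.clg, label)
            mapping = unit_to_chrom[sp]
            if unit in mapping:
                chrom = mapping[unit]
            elif label == OUTGROUP_LABEL:
                chrom = f"chr{fam.clg + 1}"
            else:
                chrom = f"chr{fam.clg + 1}-{label}"
            gene_id = f"{fam.family_id}|{tip.name}"
            genes.setdefault((sp, chrom), []).append(
                (gene_id, fam.family_id, fam.clg, label)
            )
            key = (sp, chrom)
            if key not in composition:
                composition[key] = []
            if [fam.clg, label] not in composition[key]:
                composition[key].append([fam.clg, label])

    rows = []
    for (sp, chrom), glist in sorted(genes.items()):
        order = rng.permutation(len(glist))
        for pos, gi in enumerate(order):
            gene_id, fam_id, clg, label = glist[gi]
            rows.append(
                {
                    "gene_id": gene_id,
                    "species": sp,
                    "chromosome": chrom,
                    "start": pos * 1000,
                    "end": pos * 1000 + 900,
                    "family_id": fam_id,
                    "clg": clg,
                    "label": label,
                }
            )
    return pd.DataFrame(rows), composition


def simulate_karyotypes(
    scenario: EvolutionScenario,
    genes_per_clg: int = 40,
    fusion_plan: Optional[dict] = None,
    seed: int = 0,
    with_sequences: bool = False,
    sites: int = 300,
) -> tuple[pd.DataFrame, TruthLog, list[GeneFamilyRecord]]:
    """Simulate families for every CLG and lay them out on chromosomes."""
    if genes_per_clg < 1:
        raise ValueError("genes_per_clg must be >= 1")
    if fusion_plan is None:
        fusion_plan = default_fusion_plan(scenario, seed)
    families: list[GeneFamilyRecord] = []
    for clg in range(scenario.clg_count):
        if with_sequences:
            fams = simulate_families(
                scenario, clg, genes_per_clg, seed + clg * 10_007, sites=sites
            )
        else:
            fams = []
            attempt = 0
            for i in range(genes_per_clg):
                while True:
                    try:
                        tree = simulate_family_tree(
                            scenario, clg, seed + clg * 10_007 + attempt
                        )
                        attempt += 1
                        break
                    except AllCopiesLost:
                        attempt += 1
                fams.append(GeneFamilyRecord(f"clg{clg:02d}_f{i:03d}", clg, tree))
        families.extend(fams)
    gene_map, composition = karyotype_from_families(
        scenario, families, fusion_plan, seed
    )
    truth = TruthLog()
    for fam in families:
        truth.families[fam.family_id] = {
            "clg": fam.clg,
            "tree": fam.tree.newick(annotations=True),
            "genes": {
                f"{fam.family_id}|{tip.name}": {
                    "species": fam.species_of(tip.name),
                    "label": fam.label_of(tip.name),
                }
                for tip in fam.tree.leaves()
            },
        }
    truth.chromosomes = composition
    return gene_map, truth, families


# ---------------------------------------------------------------------------
# depth tracks and k-mer histograms
# ---------------------------------------------------------------------------

REGION_KINDS = ("germline_specific", "somatic", "high_copy_repeat")


def _nb_draw(rng, mean: np.ndarray, noise: float) -> np.ndarray:
    if noise == 0:
        return np.rint(mean).astype(np.int64)
    r = 1.0 / noise
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def _nb_mean_for_mode(mode: float, noise: float) -> float:
    """Negative-binomial mean whose distribution's mode is ``mode``.

    The NB mode is floor(mean (r-1)/r) for dispersion r = 1/noise, so the
    requested modal depth needs a slightly larger mean.
    """
    if noise <= 0:
        return float(mode)
    r = 1.0 / noise
    if r <= 1.0:
        return float(mode)
    return (mode + 0.5) * r / (r - 1.0)


def simulate_depth_tracks(
    contigs: dict,
    planted_regions: Iterable[tuple],
    modal_germ: int = 32,
    modal_soma: int = 54,
    noise: float = 0.05,
    seed: int = 0,
) -> tuple[dict, dict, list]:
    """Paired per-base depth tracks with planted germline-specific regions.

    Regions are (contig, start, end, kind, copy_ratio) with 0-based half-open
    coordinates.  ``germline_specific`` regions have soma depth ~0 and germ
    depth ~ modal_germ * copy_ratio; ``somatic`` regions elevate both samples
    by copy_ratio; ``high_copy_repeat`` elevates the germline only, keeping
    the soma at its modal depth.  Noise is negative-binomial with variance
    mean + noise * mean^2 (noise 0 = deterministic means).
    """
    if modal_germ <= 0 or modal_soma <= 0:
        raise ValueError("modal depths must be > 0")
    regions = [tuple(r) for r in planted_regions]
    by_contig: dict[str, list] = {}
    for contig, start, end, kind, ratio in regions:
        if kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {kind!r}")
        if contig not in contigs:
            raise ValueError(f"region on unknown contig {contig!r}")
        if not 0 <= start < end <= contigs[contig]:
            raise ValueError(f"region {contig}:{start}-{end} out of bounds")
        by_contig.setdefault(contig, []).append((start, end, kind, ratio))
    for contig, regs in by_contig.items():
        regs.sort()
        for (s1, e1, k1, _), (s2, e2, k2, _) in zip(regs, regs[1:]):
            if s2 < e1 and k1 != k2:
                raise ValueError(
                    f"overlapping planted regions of different kinds on {contig}"
                )

    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    germ, soma = {}, {}
    g_base = _nb_mean_for_mode(modal_germ, noise)
    s_base = _nb_mean_for_mode(modal_soma, noise)
    for contig, length in contigs.items():
        g_mean = np.full(length, g_base)
        s_mean = np.full(length, s_base)
        for start, end, kind, ratio in by_contig.get(contig, []):
            if kind == "germline_specific":
                g_mean[start:end] = g_base * ratio
                s_mean[start:end] = 0.0
            elif kind == "somatic":
                g_mean[start:end] = g_base * ratio
                s_mean[start:end] = s_base * ratio
            else:  # high_copy_repeat
                g_mean[start:end] = g_base * ratio
        germ[contig] = _nb_draw(rng, g_mean, noise)
        soma[contig] = _nb_draw(rng, s_mean, noise)
    return germ, soma, regions


def simulate_kmer_histogram(
    modal_copy: int,
    abundant_fraction: float = 0.01,
    seed: int = 0,
    n_kmers: int = 1_000_000,
) -> np.ndarray:
    """31-mer count histogram: unimodal around ``modal_copy`` plus a planted
    heavy tail of abundant k-mers.  ``histogram[c]`` = number of distinct
    k-mers observed ``c`` times."""
    if modal_copy < 1:
        raise ValueError("modal_copy must be >= 1")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    n_abundant = int(round(n_kmers * abundant_fraction))
    background = rng.poisson(modal_copy + 0.5, size=n_kmers - n_abundant)
    counts = [background[background > 0]]
    if n_abundant:
        tail = np.rint(modal_copy * rng.uniform(4.0, 40.0, size=n_abundant))
        counts.append(tail.astype(np.int64))
    allc = np.concatenate(counts)
    return np.bincount(allc)
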