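"""Scripted evolutionary scenarios: a dated species tree decorated with
whole-genome-duplication (WGD) events and per-CLG rediploidization schedules.

The default scenario encodes the inferred early-vertebrate history: a shared
auto-tetraploidization (1R) on the vertebrate stem whose paralogon divergence
(rediploidization) completed around 527 Ma, the cyclostome-gnathostome split
around 520 Ma, a gnathostome allo-tetraploidization (2R_JV) with progenitor
divergence around 508 Ma, a cyclostome two-step hexaploidization (2R_CY) with
homoeologue divergences around 511 and 493 Ma, and the hagfish-lamprey split
around 457 Ma.  One designated CLG undergoes lineage-specific
rediploidization of the shallow 2R_CY pair (divergence 431 Ma in the
hagfish-like lineage, 442 Ma in the lamprey-like lineage) instead of the
ancestral 493 Ma divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .phylo.tree import Node

GNATHOSTOME_LABELS = ("a1", "a2", "b1", "b2")  # alpha1, alpha2, beta1, beta2
CYCLOSTOME_LABELS = ("1a", "1b", "1c", "2a", "2b", "2c")
OUTGROUP_LABEL = "o"

#: pretty aliases used in output tables
LABEL_ALIASES = {"a1": "α1", "a2": "α2", "b1": "β1", "b2": "β2"}


@dataclass
class WGDEvent:
    """A polyploidization event on one branch of the species tree."""

    name: str
    kind: str  # auto_tetraploidy | allo_tetraploidy | hexaploidy_two_step
    lineage: str  # name of the species-tree node below the carrying branch
    time: float  # Ma; placement of the event itself
    progenitor_divergences: tuple[float, ...] = ()
    retention: float = 0.8

    def __post_init__(self):
        if self.kind not in (
            "auto_tetraploidy",
            "allo_tetraploidy",
            "hexaploidy_two_step",
        ):
            raise ValueError(f"unknown WGD kind {self.kind!r}")
        if self.kind == "allo_tetraploidy" and len(self.progenitor_divergences) != 1:
            raise ValueError("allo_tetraploidy needs exactly one progenitor divergence")
        if self.kind == "hexaploidy_two_step":
            if len(self.progenitor_divergences) != 2:
                raise ValueError("two-step hexaploidy needs two divergence ages")
            a, b = self.progenitor_divergences
            if not a > b:
                raise ValueError("hexaploidy divergence ages must be strictly ordered")
        if not 0 < self.retention <= 1:
            raise ValueError("retention must be in (0, 1]")


#: schedule value: an ancestral divergence age (float) or a per-species map
ScheduleAge = Union[float, dict]


@dataclass
class Split:
    """One scheduled copy divergence: partitions a label universe in two."""

    event: str
    side1: frozenset
    side2: frozenset
    age: ScheduleAge


@dataclass
class EvolutionScenario:
    species_tree: Node
    events: list[WGDEvent]
    clg_count: int = 17
    rate: float = 5e-4  # substitutions per site per Myr
    #: (event_name, clg, split_id) -> age or {species: age}
    rediploidization_times: dict = field(default_factory=dict)
    lineage_specific_clg: Optional[int] = None

    def __post_init__(self):
        if self.clg_count < 1:
            raise ValueError("clg_count must be >= 1")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        names = {
            n.name for n in self.species_tree.postorder() if n.name is not None
        }
        for ev in self.events:
            if ev.lineage not in names:
                raise ValueError(f"event lineage {ev.lineage!r} not in species tree")
            node = self.species_tree.find(ev.lineage)
            top = node.parent.age if node.parent else float("inf")
            if not node.age <= ev.time <= top:
                raise ValueError(
                    f"event {ev.name} time {ev.time} off its branch "
                    f"[{node.age}, {top}]"
                )
        self._check_schedule()

    # ------------------------------------------------------------------
    def _check_schedule(self) -> None:
        for (event, clg, _sid), age in self.rediploidization_times.items():
            ev = self.event(event)
            node = self.species_tree.find(ev.lineage)
            if isinstance(age, dict):
                continue  # lineage-specific: checked at simulation time
            if ev.kind == "auto_tetraploidy" and age > ev.time:
                # rediploidization happens after the duplication itself
                raise ValueError(
                    f"rediploidization {age} Ma predates its event {ev.name} "
                    f"({ev.time} Ma) for CLG {clg}"
                )
            if ev.kind != "auto_tetraploidy" and age < ev.time:
                # progenitor divergences precede the merger
                raise ValueError(
                    f"progenitor divergence {age} Ma postdates the merger of "
                    f"event {ev.name} ({ev.time} Ma) for CLG {clg}"
                )
            if age < node.age:
                raise ValueError(
                    f"ancestral rediploidization {age} Ma postdates the next "
                    f"speciation ({node.age} Ma) for CLG {clg}"
                )

    def event(self, name: str) -> WGDEvent:
        for ev in self.events:
            if ev.name == name:
                return ev
        raise KeyError(name)

    def speciation(self, which: str) -> float:
        """Age of a named split, e.g. ``"cyclostome-gnathostome"``."""
        key = which.replace("–", "-")
        table = {
            "cyclostome-gnathostome": "vertebrates",
            "hagfish-lamprey": "cyclostomes",
            "gnathostome-crown": "gnathostomes",
            "outgroup": None,
        }
        if key not in table:
            raise KeyError(which)
        node = (
            self.species_tree
            if table[key] is None
            else self.species_tree.find(table[key])
        )
        return node.age

    @property
    def hexaploidy_divergences(self) -> set[float]:
        ev = next(e for e in self.events if e.kind == "hexaploidy_two_step")
        return set(ev.progenitor_divergences)

    # ------------------------------------------------------------------
    def splits_for_clg(self, clg: int) -> list[Split]:
        """Scheduled copy divergences for one CLG, deepest first."""
        g = GNATHOSTOME_LABELS
        c = CYCLOSTOME_LABELS
        sched = self.rediploidization_times

        def age(event, sid, default):
            return sched.get((event, clg, sid), default)

        splits = [
            Split(
                "1R",
                frozenset({"a1", "b1", "1a", "1b", "1c"}),
                frozenset({"a2", "b2", "2a", "2b", "2c"}),
                age("1R", "1|2", 527.0),
            ),
            Split(
                "2R_JV",
                frozenset({"a1", "a2"}),
                frozenset({"b1", "b2"}),
                age("2R_JV", "a|b", 508.0),
            ),
            Split(
                "2R_CY",
                frozenset({"1a", "2a"}),
                frozenset({"1b", "1c", "2b", "2c"}),
                age("2R_CY", "a|bc", 511.0),
            ),
            Split(
                "2R_CY",
                frozenset({"1b", "2b"}),
                frozenset({"1c", "2c"}),
                age("2R_CY", "b|c", 493.0),
            ),
        ]
        return splits

    def species(self) -> list[str]:
        return self.species_tree.leaf_names()

    def species_class(self, species: str) -> str:
        gn = set(self.species_tree.find("gnathostomes").leaf_names())
        cy = set(self.species_tree.find("cyclostomes").leaf_names())
        if species in gn:
            return "gnathostome"
        if species in cy:
            return "cyclostome"
        return "outgroup"

    def labels_for_species(self, species: str) -> frozenset:
        cls = self.species_class(species)
        if cls == "gnathostome":
            return frozenset(GNATHOSTOME_LABELS)
        if cls == "cyclostome":
            return frozenset(CYCLOSTOME_LABELS)
        return frozenset({OUTGROUP_LABEL})


def _default_species_tree() -> Node:
    root = Node("root")
    root.age = 600.0
    out = root.add_child(Node("outgroup"))
    out.age = 0.0
    vert = root.add_child(Node("vertebrates"))
    vert.age = 520.0
    gnath = vert.add_child(Node("gnathostomes"))
    gnath.age = 456.0
    shark = gnath.add_child(Node("shark_like"))
    shark.age = 0.0
    neo = gnath.add_child(Node("neopterygian_crown"))
    neo.age = 430.0
    for sp in ("gar_like", "chicken_like"):
        tip = neo.add_child(Node(sp))
        tip.age = 0.0
    cyclo = vert.add_child(Node("cyclostomes"))
    cyclo.age = 457.0
    for sp in ("hagfish_like", "lamprey_like"):
        tip = cyclo.add_child(Node(sp))
        tip.age = 0.0
    for node in root.postorder():
        if node.parent is not None:
            node.length = node.parent.age - node.age
    return root


def default_scenario(
    clg_count: int = 17,
    lineage_specific_clg: int = 1,
    rate: float = 5e-4,
) -> EvolutionScenario:
    """The default early-vertebrate scenario (ages in Ma; see module docs)."""
    tree = _default_species_tree()
    events = [
        WGDEvent("1R", "auto_tetraploidy", "vertebrates", 530.0, (), 0.9),
        WGDEvent("2R_JV", "allo_tetraploidy", "gnathostomes", 500.0, (508.0,), 0.8),
        WGDEvent(
            "2R_CY", "hexaploidy_two_step", "cyclostomes", 490.0, (511.0, 493.0), 0.7
        ),
    ]
    sched: dict = {}
    for clg in range(clg_count):
        sched[("1R", clg, "1|2")] = 527.0
        sched[("2R_JV", clg, "a|b")] = 508.0
        sched[("2R_CY", clg, "a|bc")] = 511.0
        sched[("2R_CY", clg, "b|c")] = 493.0
    if lineage_specific_clg is not None:
        if not 0 <= lineage_specific_clg < clg_count:
            raise ValueError("lineage_specific_clg out of range")
        sched[("2R_CY", lineage_specific_clg, "b|c")] = {
            "hagfish_like": 431.0,
            "lamprey_like": 442.0,
        }
    return EvolutionScenario(
        species_tree=tree,
        events=events,
        clg_count=clg_count,
        rate=rate,
        rediploidization_times=sched,
        lineage_specific_clg=lineage_specific_clg,
    )
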