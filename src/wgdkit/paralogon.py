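"""Paralogon classification and per-CLG concatenated supermatrices.

Gnathostome genes are labelled with one of the four paralogons alpha1,
alpha2, beta1, beta2 (written a1/a2/b1/b2): the letter encodes the
allo-tetraploidy progenitor, the digit the 1R copy.  Cyclostome genes are
keyed by the chromosomal identity of the CLG derivative; non-vertebrate
outgroup genes by "out".  Families passing strict (>= 3 distinct gnathostome
paralogons) or relaxed (>= 2) selection are concatenated per CLG into a
supermatrix with one row per observed (species, segment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .alignment import GAP, Alignment

GNATHOSTOME_PARALOGONS = ("a1", "a2", "b1", "b2")
UNPLACED = "unplaced"
OUTGROUP_SEGMENT = "out"


def classify_paralogons(
    genes: pd.DataFrame, reference: pd.DataFrame
) -> pd.Series:
    """Label genes by looking up their chromosome segment in a reference.

    ``genes`` columns: gene_id, species, chromosome and (optionally) clg;
    ``reference`` columns: species, chromosome, label and optionally clg
    (for fused chromosomes carrying several CLG derivatives).  Genes on
    segments absent from the reference are labelled ``"unplaced"``.
    """
    with_clg = {}
    without_clg = {}
    has_clg = "clg" in reference.columns
    for row in reference.itertuples(index=False):
        if has_clg and not pd.isna(row.clg):
            with_clg[(row.species, row.chromosome, row.clg)] = row.label
        else:
            without_clg[(row.species, row.chromosome)] = row.label
    labels = []
    for row in genes.itertuples(index=False):
        clg = getattr(row, "clg", None)
        label = None
        if clg is not None:
            label = with_clg.get((row.species, row.chromosome, clg))
        if label is None:
            label = without_clg.get((row.species, row.chromosome), UNPLACED)
        labels.append(label)
    return pd.Series(labels, index=genes.index, name="label")


def select_families(
    family_labels: Mapping[str, Iterable[str]], mode: str = "strict"
) -> list[str]:
    """Family selection by gnathostome paralogon coverage.

    ``strict`` keeps families with >= 3 distinct gnathostome paralogons among
    {a1, a2, b1, b2}; ``relaxed`` keeps >= 2.  Returns kept family ids; the
    strict set is always a subset of the relaxed set.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError("mode must be 'strict' or 'relaxed'")
    need = 3 if mode == "strict" else 2
    kept = []
    for fam, labels in family_labels.items():
        distinct = set(labels) & set(GNATHOSTOME_PARALOGONS)
        if len(distinct) >= need:
            kept.append(fam)
    return kept


@dataclass
class LabeledFamily:
    """A gene family with per-gene (species, segment) row assignments."""

    family_id: str
    clg: int
    alignment: Alignment
    rows: dict  # tip/gene name -> (species, segment) or None to exclude

    def gnathostome_paralogons(self) -> set:
        return {
            seg
            for key in self.rows.values()
            if key is not None
            for seg in [key[1]]
            if seg in GNATHOSTOME_PARALOGONS
        }


@dataclass
class Supermatrix:
    clg: int
    alignment: Alignment  # row names "species|segment"
    partition: dict  # family_id -> (start, end)
    occupancy: dict  # row name -> non-gap fraction
    dropped_rows: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.alignment.n_sites

    def rows(self) -> list[tuple[str, str]]:
        return [tuple(n.split("|", 1)) for n in self.alignment.names]

    def extract(self, family_id: str) -> Alignment:
        start, end = self.partition[family_id]
        return Alignment(
            list(self.alignment.names),
            self.alignment.matrix[:, start:end],
        )


def build_supermatrix(
    clg: int,
    families: list[LabeledFamily],
    occupancy_threshold: float = 0.2,
) -> Supermatrix:
    """Concatenate family alignments keyed by (species, segment).

    Missing family x row blocks are gap-filled.  When a family has two genes
    on one segment (tandem duplicates), the copy with more resolved sites is
    kept (ties by gene name).  Rows with occupancy below the threshold are
    dropped with a warning.
    """
    for fam in families:
        if fam.clg != clg:
            raise ValueError(
                f"family {fam.family_id} belongs to CLG {fam.clg}, not {clg}"
            )
    row_keys: list[str] = []
    for fam in families:
        for key in fam.rows.values():
            if key is None:
                continue
            name = f"{key[0]}|{key[1]}"
            if name not in row_keys:
                row_keys.append(name)
    row_keys.sort()

    parts = []
    for fam in families:
        chosen: dict[str, str] = {}
        for gene, key in fam.rows.items():
            if key is None:
                continue
            name = f"{key[0]}|{key[1]}"
            if name in chosen:
                old = chosen[name]
                better = _resolved(fam.alignment, gene) > _resolved(
                    fam.alignment, old
                ) or (
                    _resolved(fam.alignment, gene)
                    == _resolved(fam.alignment, old)
                    and gene < old
                )
                if better:
                    chosen[name] = gene
            else:
                chosen[name] = gene
        mat = np.full((len(row_keys), fam.alignment.n_sites), GAP, dtype=np.int8)
        for i, name in enumerate(row_keys):
            if name in chosen:
                mat[i] = fam.alignment.row(chosen[name])
        parts.append(Alignment(list(row_keys), mat))

    aln, part_idx = Alignment.concat(parts, row_keys)
    partition = {
        fam.family_id: part_idx[k] for k, fam in enumerate(families)
    }
    occupancy = {
        name: float(np.mean(aln.matrix[i] != GAP))
        for i, name in enumerate(aln.names)
    }
    keep = [n for n in aln.names if occupancy[n] >= occupancy_threshold]
    dropped = [n for n in aln.names if n not in keep]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} low-occupancy rows from CLG {clg}: {dropped}"
        )
        aln = aln.subset(keep)
    return Supermatrix(clg, aln, partition, occupancy, dropped)


def _resolved(aln: Alignment, name: str) -> int:
    return int(np.sum(aln.row(name) != GAP))


def reference_from_composition(composition: Mapping, scenario) -> pd.DataFrame:
    """Build the chromosome-segment -> paralogon reference table from a
    karyotype composition map (as the analysis takes the prior gnathostome
    classification as input).

    Gnathostome chromosomes map to their paralogon label; cyclostome and
    outgroup chromosomes map to their own chromosomal identity.
    """
    rows = []
    for (species, chrom), units in composition.items():
        cls = scenario.species_class(species)
        for clg, label in units:
            if cls == "gnathostome":
                rows.append((species, chrom, clg, label))
            elif cls == "outgroup":
                rows.append((species, chrom, clg, OUTGROUP_SEGMENT))
            else:
                rows.append((species, chrom, clg, chrom))
    return pd.DataFrame(
        rows, columns=["species", "chromosome", "clg", "label"]
    )
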