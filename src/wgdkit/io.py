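"""Readers/writers for the plain-text formats shared across modules:
FASTA proteomes, gene-map TSV, bedGraph depth tracks, newick tree sets and
relaxed PHYLIP supermatrices."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import Alignment


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_gene_map(gene_map: pd.DataFrame, path) -> None:
    gene_map.to_csv(path, sep="\t", index=False)


def read_gene_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(track: Mapping[str, np.ndarray], path) -> None:
    """Run-length-encoded bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for contig in track:
            depths = np.asarray(track[contig])
            if depths.size == 0:
                continue
            changes = np.nonzero(np.diff(depths))[0] + 1
            starts = np.concatenate(([0], changes))
            ends = np.concatenate((changes, [len(depths)]))
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{int(depths[s])}\n")


def read_bedgraph(path, contig_lengths: Mapping[str, int] | None = None) -> dict:
    """Dense per-base depth arrays from a bedGraph file."""
    spans: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            contig, s, e, v = line.split()[:4]
            spans.setdefault(contig, []).append((int(s), int(e), float(v)))
    out = {}
    for contig, rows in spans.items():
        length = (
            contig_lengths[contig]
            if contig_lengths
            else max(e for _, e, _ in rows)
        )
        arr = np.zeros(length, dtype=np.int64)
        for s, e, v in rows:
            arr[s:e] = int(v)
        out[contig] = arr
    return out


def write_phylip(aln: Alignment, path) -> None:
    """Relaxed PHYLIP: name, space, sequence."""
    seqs = aln.to_dict()
    with open(path, "w") as fh:
        fh.write(f"{len(aln)} {aln.n_sites}\n")
        for name in aln.names:
            fh.write(f"{name.replace(' ', '_')}  {seqs[name]}\n")


def write_supermatrix(sm, prefix) -> None:
    """Write a supermatrix as relaxed PHYLIP + FASTA with its partition map
    and per-row occupancy as TSV (``<prefix>.phy/.fasta/.partitions.tsv``)."""
    prefix = str(prefix)
    write_phylip(sm.alignment, prefix + ".phy")
    write_fasta(sm.alignment.to_dict(), prefix + ".fasta")
    rows = [
        {"family_id": fam, "start": start, "end": end}
        for fam, (start, end) in sm.partition.items()
    ]
    pd.DataFrame(rows).to_csv(prefix + ".partitions.tsv", sep="\t", index=False)
    occ = pd.DataFrame(
        [{"row": k, "occupancy": v} for k, v in sm.occupancy.items()]
    )
    occ.to_csv(prefix + ".occupancy.tsv", sep="\t", index=False)


def write_trees(trees, path, annotations: bool = True) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.newick(annotations=annotations) + "\n")


def write_bed(regions, path) -> None:
    with open(path, "w") as fh:
        for contig, start, end, *rest in regions:
            extra = "\t" + "\t".join(str(r) for r in rest) if rest else ""
            fh.write(f"{contig}\t{start}\t{end}{extra}\n")


def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            out.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
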