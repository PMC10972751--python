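"""Ungapped/gapped protein alignment container backed by a numpy matrix."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = -1


class Alignment:
    """Rows of equal-length protein sequences; gap/missing encoded as -1."""

    def __init__(self, names: list[str], matrix: np.ndarray):
        if matrix.ndim != 2 or len(names) != matrix.shape[0]:
            raise ValueError("names/matrix shape mismatch")
        self.names = list(names)
        self.matrix = np.asarray(matrix, dtype=np.int8)
        self._index = {n: i for i, n in enumerate(self.names)}

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "Alignment":
        names = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        L = lengths.pop() if lengths else 0
        mat = np.full((len(names), L), GAP, dtype=np.int8)
        for i, n in enumerate(names):
            mat[i] = encode(seqs[n])
        return cls(names, mat)

    def to_dict(self) -> dict[str, str]:
        return {n: decode(self.matrix[i]) for i, n in enumerate(self.names)}

    # -- basic properties --------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.names)

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self._index[name]]

    def subset(self, names: Iterable[str]) -> "Alignment":
        names = list(names)
        idx = [self._index[n] for n in names]
        return Alignment(names, self.matrix[idx])

    def take_sites(self, idx: np.ndarray) -> "Alignment":
        return Alignment(self.names, self.matrix[:, idx])

    # -- pattern compression ----------------------------------------------
    def compress(self):
        """Unique site patterns, their weights and the site->pattern map."""
        cols = np.ascontiguousarray(self.matrix.T)
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        return patterns.T, counts.astype(float), inverse

    @staticmethod
    def concat(parts: list["Alignment"], all_names: list[str]) -> tuple["Alignment", dict]:
        """Concatenate columnwise over ``all_names``; absent rows are gaps.

        Returns the alignment and a partition map ``{index: (start, end)}``.
        """
        total = sum(p.n_sites for p in parts)
        mat = np.full((len(all_names), total), GAP, dtype=np.int8)
        partition = {}
        pos = 0
        for k, part in enumerate(parts):
            end = pos + part.n_sites
            for i, n in enumerate(all_names):
                if n in part._index:
                    mat[i, pos:end] = part.row(n)
            partition[k] = (pos, end)
            pos = end
        return Alignment(list(all_names), mat), partition


def encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for j, ch in enumerate(seq):
        out[j] = _CODE.get(ch, GAP)
    return out


def decode(row: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[v] if v >= 0 else "-" for v in row)
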