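"""Macrosynteny reconstruction: mutual-best-hit orthologs, chromosome-vs-
chromosome enrichment by one-sided Fisher's exact test (BH-corrected), and
per-bin CLG composition of chromosomes (20-gene bins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

# ---------------------------------------------------------------------------
# similarity search
# ---------------------------------------------------------------------------


def _kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def similarity_search(
    proteome_query: Mapping[str, str],
    proteome_target: Mapping[str, str],
    k: int = 5,
    rescore: bool = True,
) -> pd.DataFrame:
    """Shared-k-word similarity search with optional ungapped identity
    rescoring for equal-length candidate pairs.

    Returns a HitTable dataframe (query, target, score); queries with no
    shared k-word are absent.  The score is monotone in true homology on
    indel-free simulated proteomes below saturation.
    """
    if not proteome_query or not proteome_target:
        raise ValueError("empty proteome")
    index: dict[str, list[str]] = {}
    for name, seq in proteome_target.items():
        if not seq:
            warnings.warn(f"empty target sequence {name!r}; skipped")
            continue
        for kmer in _kmers(seq, k):
            index.setdefault(kmer, []).append(name)
    rows = []
    for qname, qseq in proteome_query.items():
        if not qseq:
            warnings.warn(f"empty query sequence {qname!r}; skipped")
            continue
        shared: dict[str, int] = {}
        for kmer in _kmers(qseq, k):
            for tname in index.get(kmer, ()):
                shared[tname] = shared.get(tname, 0) + 1
        for tname, count in shared.items():
            tseq = proteome_target[tname]
            if rescore and len(tseq) == len(qseq):
                ident = sum(a == b for a, b in zip(qseq, tseq))
                score = ident / len(qseq)
            else:
                score = count / max(len(qseq), len(tseq))
            rows.append((qname, tname, float(score)))
    return pd.DataFrame(rows, columns=["query", "target", "score"])


def _best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """Top hit per query; score ties broken by lexicographic target id."""
    best: dict[str, tuple[float, str]] = {}
    for q, t, s in hits.itertuples(index=False):
        cur = best.get(q)
        if cur is None or s > cur[0] or (s == cur[0] and t < cur[1]):
            best[q] = (s, t)
    return {q: t for q, (s, t) in best.items()}


def mutual_best_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame
) -> pd.DataFrame:
    """Reciprocal best hits: (a, b) kept iff b is a's unique top hit and a is
    b's unique top hit.  Deterministic via lexicographic tie-breaking."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = [
        (a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    return pd.DataFrame(sorted(pairs), columns=["gene_a", "gene_b"])


# ---------------------------------------------------------------------------
# Fisher enrichment between chromosomes
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentMatrix:
    table: pd.DataFrame  # chrom_a, chrom_b, count, p, p_adj, significant

    def significant_pairs(self) -> set[tuple[str, str]]:
        sig = self.table[self.table.significant]
        return set(zip(sig.chrom_a, sig.chrom_b))


def fisher_enrichment(
    memberships: pd.DataFrame, alpha: float = 0.05
) -> EnrichmentMatrix:
    """One-sided Fisher enrichment over a two-column membership frame.

    ``memberships`` has columns (group_a, group_b), one row per item; each
    (a, b) cell is tested for over-representation against the 2x2 margin
    table, with Benjamini-Hochberg correction across all cells.
    """
    ct = pd.crosstab(memberships.iloc[:, 0], memberships.iloc[:, 1])
    n = int(ct.values.sum())
    rows = []
    for a in ct.index:
        row_total = int(ct.loc[a].sum())
        for b in ct.columns:
            k = int(ct.loc[a, b])
            col_total = int(ct[b].sum())
            table = [
                [k, row_total - k],
                [col_total - k, n - row_total - col_total + k],
            ]
            _, p = fisher_exact(table, alternative="greater")
            rows.append((a, b, k, float(p)))
    df = pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "count", "p"])
    if len(df):
        reject, p_adj, _, _ = multipletests(df.p, alpha=alpha, method="fdr_bh")
        df["p_adj"] = p_adj
        df["significant"] = reject
    else:
        df["p_adj"] = []
        df["significant"] = []
    return EnrichmentMatrix(df)


def chromosome_association_test(
    pairs: pd.DataFrame,
    map_a: Mapping[str, str],
    map_b: Mapping[str, str],
    alpha: float = 0.05,
) -> EnrichmentMatrix:
    """Chromosome-vs-chromosome ortholog enrichment.

    ``pairs`` is an OrthologPairs frame (gene_a, gene_b); ``map_a``/``map_b``
    map gene id -> chromosome.  Every paired gene must be mapped.
    """
    missing = [g for g in pairs.gene_a if g not in map_a] + [
        g for g in pairs.gene_b if g not in map_b
    ]
    if missing:
        raise KeyError(f"genes without a chromosome assignment: {missing[:10]}")
    frame = pd.DataFrame(
        {
            "chrom_a": [map_a[g] for g in pairs.gene_a],
            "chrom_b": [map_b[g] for g in pairs.gene_b],
        }
    )
    return fisher_enrichment(frame, alpha=alpha)


# ---------------------------------------------------------------------------
# CLG assignment in 20-gene bins
# ---------------------------------------------------------------------------


def assign_clgs(
    gene_map: pd.DataFrame,
    reference: Mapping[str, object],
    bin_size: int = 20,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-bin CLG composition and chromosome-level CLG calls.

    ``gene_map`` needs columns (gene_id, chromosome, start); ``reference``
    maps gene id -> CLG.  Chromosome x CLG enrichment is tested by one-sided
    Fisher (BH across all chromosome x CLG cells); bins of ``bin_size``
    consecutive genes count only genes from significantly enriched CLGs.
    Chromosomes with no reference gene are flagged "unassigned".
    """
    mapped = gene_map[gene_map.gene_id.isin(reference)].copy()
    mapped["clg"] = [reference[g] for g in mapped.gene_id]
    calls: dict[str, object] = {}
    for chrom in gene_map.chromosome.unique():
        if chrom not in set(mapped.chromosome):
            calls[chrom] = "unassigned"
    if mapped.chromosome.nunique() < 2 or mapped.clg.nunique() < 2:
        # degenerate margins: no contrast to test, call what is observed
        for chrom, sub in mapped.groupby("chromosome"):
            calls[chrom] = sorted(set(sub.clg), key=str)
    else:
        enrich = fisher_enrichment(mapped[["chromosome", "clg"]], alpha=alpha)
        sig = enrich.significant_pairs()
        for chrom in mapped.chromosome.unique():
            calls[chrom] = sorted(
                {clg for (c, clg) in sig if c == chrom}, key=str
            )

    rows = []
    for chrom, sub in mapped.groupby("chromosome"):
        sub = sub.sort_values("start")
        enriched = set(calls[chrom]) if calls[chrom] != "unassigned" else set()
        clgs = list(sub.clg)
        for b0 in range(0, len(clgs), bin_size):
            chunk = clgs[b0 : b0 + bin_size]
            counts: dict = {}
            for clg in chunk:
                if clg in enriched:
                    counts[clg] = counts.get(clg, 0) + 1
            rows.append(
                {
                    "chromosome": chrom,
                    "bin": b0 // bin_size,
                    "n_genes": len(chunk),
                    "partial": len(chunk) < bin_size,
                    "composition": counts,
                }
            )
    return pd.DataFrame(rows), calls
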