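"""Detection of germline-specific and germline-enriched regions from paired
germline/soma depth tracks.

The scan mirrors a DifCover-style pipeline: per-base masking by modal-depth
rules, grouping of unmasked positions into discontiguous intervals of a fixed
number of valid bases (default 500), log2 enrichment scoring of interval mean
depths normalised by modal coverage (with minimum/maximum mean-depth clamps),
changepoint segmentation of the interval score sequence without smoothing,
and calling of germline-specific regions above a score threshold.  Repeat
span estimation and k-mer abundance thresholds follow the same depth-ratio
logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd


@dataclass
class ScanParams:
    """Parameters of the enrichment scan.

    ``v``: valid bases per interval.  ``lo_mode``: "fraction" masks positions
    below modal/3 in both samples, "absolute" below ``lo_abs`` in both.
    ``hi_multiple``: positions above hi_multiple x modal in both samples are
    masked.  ``a``/``b``: minimum mean-depth clamps (germ/soma); ``A``/``B``:
    maximum mean-depth clamps.  ``call_threshold``: log2 units for calling
    germline-specific segments.
    """

    v: int = 500
    lo_mode: str = "fraction"
    lo_abs: float = 10.0
    hi_multiple: float = 3.0
    a: float = 10.0
    b: float = 10.0
    A: float = 1e8
    B: float = 1e8
    call_threshold: float = 2.0

    def __post_init__(self):
        if self.v < 1:
            raise ValueError("v must be >= 1")
        if not (0 < self.a <= self.A) or not (0 < self.b <= self.B):
            raise ValueError("require 0 < a <= A and 0 < b <= B")
        if self.lo_mode not in ("fraction", "absolute"):
            raise ValueError("lo_mode must be 'fraction' or 'absolute'")


def modal_depth(track: np.ndarray) -> int:
    """Mode of depths over positions with depth >= 1 (ties -> smaller)."""
    track = np.asarray(track)
    if track.size == 0:
        raise ValueError("empty track")
    nz = track[track >= 1]
    if nz.size == 0:
        raise ValueError("all-zero depth track")
    counts = np.bincount(nz)
    return int(np.argmax(counts))


def mask_positions(
    germ: np.ndarray,
    soma: np.ndarray,
    params: ScanParams,
    modal_g: Optional[int] = None,
    modal_s: Optional[int] = None,
) -> np.ndarray:
    """Boolean mask: True = masked (excluded from intervals).

    Low-coverage masking requires *both* samples low (below modal/3 or the
    absolute cutoff); high-coverage masking requires both samples above
    hi_multiple x their modal depth.
    """
    germ = np.asarray(germ)
    soma = np.asarray(soma)
    if germ.shape != soma.shape:
        raise ValueError("germ/soma track length mismatch")
    modal_g = modal_depth(germ) if modal_g is None else modal_g
    modal_s = modal_depth(soma) if modal_s is None else modal_s
    if params.lo_mode == "fraction":
        low = (germ < modal_g / 3.0) & (soma < modal_s / 3.0)
    else:
        low = (germ < params.lo_abs) & (soma < params.lo_abs)
    high = (germ > params.hi_multiple * modal_g) & (
        soma > params.hi_multiple * modal_s
    )
    return low | high


@dataclass
class Interval:
    contig: str
    start: int
    end: int  # half-open; spans masked gaps
    valid: int
    partial: bool = False
    mean_germ: float = 0.0
    mean_soma: float = 0.0
    score: float = 0.0


def make_intervals(
    mask: np.ndarray, v: int = 500, contig: str = "contig"
) -> list[Interval]:
    """Greedy left-to-right grouping of unmasked positions into intervals of
    exactly ``v`` valid bases (the final interval may be partial)."""
    if v < 1:
        raise ValueError("v must be >= 1")
    valid_pos = np.nonzero(~np.asarray(mask))[0]
    out = []
    for i0 in range(0, len(valid_pos), v):
        chunk = valid_pos[i0 : i0 + v]
        out.append(
            Interval(
                contig=contig,
                start=int(chunk[0]),
                end=int(chunk[-1]) + 1,
                valid=len(chunk),
                partial=len(chunk) < v,
            )
        )
    return out


def interval_enrichment(
    intervals: list[Interval],
    germ: np.ndarray,
    soma: np.ndarray,
    params: ScanParams,
    mask: Optional[np.ndarray] = None,
    modal_g: Optional[int] = None,
    modal_s: Optional[int] = None,
) -> list[Interval]:
    """Score intervals: log2 of modal-normalised germ/soma mean-depth ratio.

    Means are over valid bases only; the germ mean is clamped to [a, A] and
    the soma mean to [b, B] before the ratio.  Intervals whose raw means are
    both below their minimum clamps are dropped.
    """
    germ = np.asarray(germ, dtype=float)
    soma = np.asarray(soma, dtype=float)
    modal_g = modal_depth(germ.astype(int)) if modal_g is None else modal_g
    modal_s = modal_depth(soma.astype(int)) if modal_s is None else modal_s
    if mask is None:
        mask = np.zeros(germ.shape, dtype=bool)
    valid = ~np.asarray(mask)
    out = []
    for iv in intervals:
        sel = valid[iv.start : iv.end]
        g = float(germ[iv.start : iv.end][sel].mean())
        s = float(soma[iv.start : iv.end][sel].mean())
        if g < params.a and s < params.b:
            continue
        gc = min(max(g, params.a), params.A)
        sc = min(max(s, params.b), params.B)
        score = float(np.log2((gc / modal_g) / (sc / modal_s)))
        out.append(
            Interval(
                iv.contig, iv.start, iv.end, iv.valid, iv.partial, g, s, score
            )
        )
    return out


# ---------------------------------------------------------------------------
# segmentation (binary max-t splitting with permutation testing)
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    contig: str
    start: int  # base coordinate (start of first interval)
    end: int  # base coordinate (end of last interval)
    n_intervals: int
    mean_score: float


def _max_t_segment(x: np.ndarray) -> tuple[int, int, float]:
    """Best interior segment (i, j) maximising the two-sample |t| between
    x[i:j] and the rest (the circular-binary-segmentation statistic; single
    edge splits are the i = 0 / j = n special cases)."""
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
    total, total2 = cs[-1], cs2[-1]
    i = np.arange(n)[:, None]
    j = np.arange(n + 1)[None, :]
    n1 = (j - i).astype(float)
    valid = n1 >= 1
    n1 = np.where(valid, n1, 1.0)
    n2 = n - n1
    valid &= n2 >= 1
    n2 = np.where(n2 >= 1, n2, 1.0)
    s1 = cs[j] - cs[i]
    q1 = cs2[j] - cs2[i]
    m1 = s1 / n1
    m2 = (total - s1) / n2
    ss = (q1 - n1 * m1**2) + ((total2 - q1) - n2 * m2**2)
    dof = max(n - 2, 1)
    denom = np.sqrt(np.maximum(ss / dof, 1e-300) * (1 / n1 + 1 / n2))
    t = np.where(valid, np.abs(m1 - m2) / denom, -1.0)
    flat = int(np.argmax(t))
    bi, bj = divmod(flat, n + 1)
    return bi, bj, float(t[bi, bj])


#: observed max-t values above this are treated as significant without
#: permutations (far beyond any permutation maximum at these sizes)
_T_SHORTCUT = 8.0


def _segment_significant(
    x: np.ndarray, t_obs: float, rng, n_perm: int, p_cut: float
) -> bool:
    if t_obs >= _T_SHORTCUT:
        return True
    limit = max(int(np.ceil(p_cut * n_perm)), 1)
    exceed = 0
    for _ in range(n_perm):
        _, _, t_p = _max_t_segment(rng.permutation(x))
        if t_p >= t_obs:
            exceed += 1
            if exceed >= limit:
                return False
    return exceed < limit


def _segment_recursive(
    x: np.ndarray, rng, n_perm: int, p_cut: float, min_segment: int, offset: int, cuts: list
) -> None:
    n = len(x)
    if n < 2 * min_segment:
        return
    i, j, t_obs = _max_t_segment(x)
    if t_obs <= 0.0:
        return
    if not _segment_significant(x, t_obs, rng, n_perm, p_cut):
        return
    new_cuts = [k for k in (i, j) if min_segment <= k <= n - min_segment]
    if not new_cuts:
        return
    cuts.extend(offset + k for k in new_cuts)
    bounds = [0] + new_cuts + [n]
    for lo, hi in zip(bounds, bounds[1:]):
        _segment_recursive(
            x[lo:hi], rng, n_perm, p_cut, min_segment, offset + lo, cuts
        )


def segment_scores(
    intervals: list[Interval],
    min_segment: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
    p_cut: float = 0.01,
) -> list[Segment]:
    """Recursive max-t binary splitting of the per-contig interval score
    sequence (no pre-smoothing); split accepted when the permutation p-value
    of the max-t statistic is < ``p_cut``.  Deterministic given the seed."""
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    segments: list[Segment] = []
    by_contig: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda i: i.start)
        x = np.array([iv.score for iv in ivs])
        cuts: list[int] = []
        _segment_recursive(x, rng, n_perm, p_cut, min_segment, 0, cuts)
        bounds = [0] + sorted(cuts) + [len(x)]
        for lo, hi in zip(bounds, bounds[1:]):
            segments.append(
                Segment(
                    contig=contig,
                    start=ivs[lo].start,
                    end=ivs[hi - 1].end,
                    n_intervals=hi - lo,
                    mean_score=float(x[lo:hi].mean()),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# calling and summaries
# ---------------------------------------------------------------------------


def call_germline_specific(
    segments: list[Segment],
    call_threshold: float = 2.0,
    gene_map: Optional[pd.DataFrame] = None,
) -> dict:
    """Merge adjacent above-threshold segments into germline-specific regions.

    Returns regions, total span and (optionally) the genes fully contained
    in called regions given an annotation with (gene_id, chromosome/contig,
    start, end) columns.
    """
    regions: list[tuple[str, int, int]] = []
    for seg in sorted(segments, key=lambda s: (s.contig, s.start)):
        if seg.mean_score < call_threshold:
            continue
        if regions and regions[-1][0] == seg.contig and regions[-1][2] >= seg.start:
            regions[-1] = (seg.contig, regions[-1][1], max(regions[-1][2], seg.end))
        else:
            regions.append((seg.contig, seg.start, seg.end))
    total = sum(e - s for _, s, e in regions)
    out = {"regions": regions, "total_bases": total}
    if gene_map is not None:
        contig_col = "contig" if "contig" in gene_map.columns else "chromosome"
        contained = []
        for row in gene_map.itertuples(index=False):
            c = getattr(row, contig_col)
            for rc, rs, re in regions:
                if rc == c and rs <= row.start and row.end <= re:
                    contained.append(row.gene_id)
                    break
        out["genes"] = contained
        out["n_genes"] = len(contained)
    return out


def repeat_span(
    profile: np.ndarray, modal_g: int = 32, min_depth: float = 10.0
) -> float:
    """Estimated genomic span of a repeat from its consensus depth profile:
    (mean germ depth over covered bases / modal depth) x covered bases,
    where covered means depth > ``min_depth``."""
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty profile")
    covered = profile > min_depth
    n = int(covered.sum())
    if n == 0:
        return 0.0
    return float(profile[covered].mean() / modal_g * n)


def select_abundant_repeats(
    table: pd.DataFrame,
    min_score: float = 10.0,
    min_span: float = 100_000.0,
) -> pd.DataFrame:
    """Highly abundant germline-specific repeats: enrichment score > 10 and
    estimated span > 100 kb."""
    return table[(table.score > min_score) & (table.span > min_span)]


def kmer_abundance_threshold(
    histogram: np.ndarray, factor: float = 3.0
) -> tuple[int, int]:
    """Abundance threshold = factor x modal k-mer copy number.

    Returns (threshold, number of distinct k-mers at or above it).  With the
    modal copy numbers of 24 (germline) and 40 (soma) the default factor
    gives thresholds of 72 and 120.
    """
    histogram = np.asarray(histogram)
    if histogram.size == 0 or histogram[1:].sum() == 0:
        raise ValueError("empty histogram")
    modal = int(np.argmax(histogram[1:]) + 1)
    threshold = int(round(factor * modal))
    abundant = int(histogram[threshold:].sum()) if threshold < len(histogram) else 0
    return threshold, abundant


def repeat_alignment_filter(alignments: pd.DataFrame) -> pd.DataFrame:
    """Keep read-repeat alignments covering > 80% of the repeat or with
    > 80% of read bases aligned."""
    rf = alignments["repeat_fraction"].to_numpy(dtype=float)
    qf = alignments["read_fraction"].to_numpy(dtype=float)
    if np.any((rf < 0) | (rf > 1) | (qf < 0) | (qf > 1)):
        raise ValueError("coverage fractions must be in [0, 1]")
    return alignments[(rf > 0.8) | (qf > 0.8)]


def somatic_repeat_windows(
    hits: pd.DataFrame,
    chromosomes: Optional[Iterable[str]] = None,
    window: int = 1_000_000,
    min_hits: int = 200,
    centromeric: bool = False,
) -> list[str]:
    """Repeat families with > ``min_hits`` alignments in some 1-Mb window.

    ``hits`` columns: family, contig, position.  With ``centromeric=True`` a
    family must exceed the threshold on *every* chromosome in
    ``chromosomes``; otherwise on at least one.
    """
    flagged = []
    for family, sub in hits.groupby("family"):
        per_chrom = {}
        for contig, csub in sub.groupby("contig"):
            pos = np.sort(csub.position.to_numpy())
            best = 0
            j = 0
            for i in range(len(pos)):
                while pos[i] - pos[j] >= window:
                    j += 1
                best = max(best, i - j + 1)
            per_chrom[contig] = best
        if centromeric:
            universe = set(chromosomes) if chromosomes else set(per_chrom)
            ok = all(per_chrom.get(c, 0) > min_hits for c in universe)
        else:
            ok = any(v > min_hits for v in per_chrom.values())
        if ok:
            flagged.append(family)
    return sorted(flagged)


# ---------------------------------------------------------------------------
# end-to-end scan
# ---------------------------------------------------------------------------


def scan(
    germ_tracks: Mapping[str, np.ndarray],
    soma_tracks: Mapping[str, np.ndarray],
    params: Optional[ScanParams] = None,
    seed: int = 0,
    n_perm: int = 1000,
) -> dict:
    """Full germline-enrichment scan over paired depth tracks.

    Returns modal depths, scored intervals, segments and called
    germline-specific regions.
    """
    params = params or ScanParams()
    all_g = np.concatenate([np.asarray(t) for t in germ_tracks.values()])
    all_s = np.concatenate([np.asarray(t) for t in soma_tracks.values()])
    modal_g = modal_depth(all_g)
    modal_s = modal_depth(all_s)
    intervals: list[Interval] = []
    for contig in germ_tracks:
        g = np.asarray(germ_tracks[contig])
        s = np.asarray(soma_tracks[contig])
        mask = mask_positions(g, s, params, modal_g, modal_s)
        ivs = make_intervals(mask, params.v, contig)
        intervals.extend(
            interval_enrichment(ivs, g, s, params, mask, modal_g, modal_s)
        )
    segments = segment_scores(intervals, seed=seed, n_perm=n_perm)
    calls = call_germline_specific(segments, params.call_threshold)
    return {
        "modal_germ": modal_g,
        "modal_soma": modal_s,
        "intervals": intervals,
        "segments": segments,
        "calls": calls,
    }
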