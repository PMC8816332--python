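"""Interval-set colocalization statistics.

Three levels of stringency:

* `intersect_sets` — plain overlap counts between two interval sets.
* `monte_carlo_overlap` — significance of the overlap by shuffling one
  set: each interval is relocated uniformly within its own chromosome,
  preserving length; p-values use the plus-one correction
  (1 + exceedances) / (n_shuffles + 1) and are computed separately for
  the intersection-count and bp-overlap statistics.
* `interval_stats_p` — an exact per-interval proximity p-value: the
  probability that a uniformly placed interval of the query's length
  within the domain lies at least as close to the reference set as the
  query does, computed by interval arithmetic rather than sampling.
  `coassociation` summarizes a whole query set as the proportion of its
  intervals with p below alpha, symmetrized across query/reference
  direction in `coassociation_matrix` and hierarchically clustered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from ._seeds import derive_rng
from .genome import GenomeIndex, GenomicInterval

__all__ = [
    "OverlapResult",
    "CoassociationMatrix",
    "intersect_sets",
    "monte_carlo_overlap",
    "interval_stats_p",
    "coassociation",
    "coassociation_matrix",
]


# ---------------------------------------------------------------------------
# merged-interval arithmetic helpers
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Per-chromosome (n, 2) arrays of merged, sorted, disjoint intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def _overlap_stats(
    starts: np.ndarray, ends: np.ndarray, merged: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per query interval: number of merged reference blocks hit, bp overlap."""
    if len(merged) == 0:
        z = np.zeros(len(starts), dtype=np.int64)
        return z, z.copy()
    b_s, b_e = merged[:, 0], merged[:, 1]
    b_cum = np.concatenate([[0], np.cumsum(b_e - b_s)])
    i0 = np.searchsorted(b_e, starts, side="right")
    i1 = np.searchsorted(b_s, ends, side="left")
    n_over = np.maximum(i1 - i0, 0)
    bp = np.zeros(len(starts), dtype=np.int64)
    hit = n_over > 0
    if hit.any():
        left = np.clip(starts[hit] - b_s[i0[hit]], 0, None)
        right = np.clip(b_e[i1[hit] - 1] - ends[hit], 0, None)
        bp[hit] = b_cum[i1[hit]] - b_cum[i0[hit]] - left - right
    return n_over, bp


def _count_and_bp(
    queries: Mapping[str, np.ndarray], refs: Mapping[str, np.ndarray]
) -> tuple[int, int]:
    """(#query intervals overlapping refs, total bp overlap)."""
    count = bp = 0
    for chrom, q in queries.items():
        r = refs.get(chrom)
        if r is None or len(r) == 0:
            continue
        n_over, bps = _overlap_stats(q[:, 0], q[:, 1], r)
        count += int(np.count_nonzero(n_over))
        bp += int(bps.sum())
    return count, bp


def _by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.asarray(sorted(v), dtype=np.int64) for c, v in by.items()}


# ---------------------------------------------------------------------------
# intersection and Monte-Carlo significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    n_overlap_a: int
    n_overlap_b: int
    bp_overlap: int
    p_count: float | None = None
    p_bp: float | None = None
    n_shuffles: int = 0
    seed: int | None = None


def intersect_sets(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    require: str = "any_overlap",
) -> tuple[list[tuple[int, int]], OverlapResult]:
    """Overlapping (i, j) index pairs and per-set overlap counts.

    `any_overlap`: >= 1 shared bp. `center`: center of the interval from
    one set inside an interval of the other (applied in each direction
    for the per-set counts; pairs use A centers in B).
    """
    if require not in ("any_overlap", "center"):
        raise ValueError(f"unknown mode {require!r}")
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: list[tuple[int, int]] = []
    hit_a: set[int] = set()
    hit_b: set[int] = set()
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        matches = (
            tree.overlap(iv.start, iv.end)
            if require == "any_overlap"
            else tree.at(iv.center)
        )
        for m in matches:
            pairs.append((i, m.data))
            hit_a.add(i)
            if require == "any_overlap":
                hit_b.add(m.data)
    if require == "center":
        trees_a: dict[str, IntervalTree] = {}
        for i, iv in enumerate(a):
            trees_a.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
        for j, iv in enumerate(b):
            t = trees_a.get(iv.chrom)
            if t is not None and t.at(iv.center):
                hit_b.add(j)
    _, bp = _count_and_bp(_by_chrom(a), merge_intervals(b))
    return sorted(pairs), OverlapResult(len(hit_a), len(hit_b), bp)


def monte_carlo_overlap(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    genome: GenomeIndex,
    n_shuffles: int = 999,
    seed: int = 0,
) -> OverlapResult:
    """Monte-Carlo significance of the overlap of A with B.

    A's intervals are relocated uniformly within their own chromosomes
    (lengths preserved, overlaps among shuffled intervals permitted).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    for iv in a:
        if len(iv) > genome.length(iv.chrom):
            raise ValueError(f"interval longer than chromosome: {iv}")
    refs = merge_intervals(b)
    queries = _by_chrom(a)
    obs_count, obs_bp = _count_and_bp(queries, refs)
    _, b_in_a = intersect_sets(b, a)
    rng = derive_rng(seed, "coloc.shuffle")
    lengths = {c: q[:, 1] - q[:, 0] for c, q in queries.items()}
    exceed_count = exceed_bp = 0
    for _ in range(n_shuffles):
        count = bp = 0
        for chrom, lens in lengths.items():
            l_chrom = genome.length(chrom)
            max_start = l_chrom - lens  # inclusive
            starts = (rng.random(len(lens)) * (max_start + 1)).astype(np.int64)
            r = refs.get(chrom)
            if r is None or len(r) == 0:
                continue
            n_over, bps = _overlap_stats(starts, starts + lens, r)
            count += int(np.count_nonzero(n_over))
            bp += int(bps.sum())
        exceed_count += count >= obs_count
        exceed_bp += bp >= obs_bp
    return OverlapResult(
        n_overlap_a=obs_count,
        n_overlap_b=b_in_a.n_overlap_a,
        bp_overlap=obs_bp,
        p_count=(1 + exceed_count) / (n_shuffles + 1),
        p_bp=(1 + exceed_bp) / (n_shuffles + 1),
        n_shuffles=n_shuffles,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# exact placement-null proximity statistic
# ---------------------------------------------------------------------------

def _distance(qs: int, qe: int, rs: int, re: int) -> int:
    """bp distance between half-open intervals (0 when overlapping or
    bookended)."""
    return max(0, rs - qe, qs - re)


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(windows):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_stats_p(
    query: GenomicInterval,
    reference: Sequence[GenomicInterval],
    domain: Sequence[GenomicInterval],
) -> float:
    """Exact p-value: fraction of placements of an interval of the
    query's length within the domain whose distance to the nearest
    reference interval is <= the query's observed distance.

    The domain is a set of intervals (e.g. whole chromosomes or promoter
    regions). Placements never cross domain-interval boundaries. An empty
    reference gives p = 1.
    """
    if not reference:
        return 1.0
    length = len(query)
    d_obs = min(
        (
            _distance(query.start, query.end, r.start, r.end)
            for r in reference
            if r.chrom == query.chrom
        ),
        default=None,
    )
    total = 0
    for d in domain:
        total += max(0, len(d) - length + 1)
    if total == 0:
        raise ValueError("domain admits no placement of the query length")
    if d_obs is None:
        return 1.0  # query's chromosome has no reference: nothing is closer
    # allowed start windows: s such that distance([s, s+len), ref) <= d_obs
    allowed: dict[str, list[tuple[int, int]]] = {}
    for r in reference:
        allowed.setdefault(r.chrom, []).append(
            (r.start - length - d_obs, r.end + d_obs + 1)
        )
    favourable = 0
    for d in domain:
        wins = allowed.get(d.chrom)
        if not wins:
            continue
        lo, hi = d.start, d.end - length + 1  # valid starts, half-open
        for ws, we in _merge_windows(wins):
            favourable += max(0, min(we, hi) - max(ws, lo))
    return min(1.0, max(favourable / total, 1.0 / total))


def domain_from_genome(genome: GenomeIndex) -> list[GenomicInterval]:
    return [GenomicInterval(n, 0, l) for n, l in genome.chromosomes]


def coassociation(
    query: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    domain: Sequence[GenomicInterval],
    alpha: float = 0.05,
) -> float:
    """Proportion of query intervals significantly close to the reference."""
    if not query:
        raise ValueError("empty query set")
    ps = [interval_stats_p(q, reference, domain) for q in query]
    return float(np.mean([p < alpha for p in ps]))


@dataclass
class CoassociationMatrix:
    values: pd.DataFrame  # symmetric, in [0, 1]
    linkage: np.ndarray
    order: list[str]  # leaf order from hierarchical clustering


def coassociation_matrix(
    sets: Mapping[str, Sequence[GenomicInterval]],
    domain: Sequence[GenomicInterval],
    alpha: float = 0.05,
) -> CoassociationMatrix:
    """Symmetrized coassociation over >= 2 peak sets with average-linkage
    hierarchical clustering on distance 1 - value."""
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need >= 2 sets")
    n = len(names)
    m = np.zeros((n, n))
    for i, qi in enumerate(names):
        for j, rj in enumerate(names):
            m[i, j] = coassociation(sets[qi], sets[rj], domain, alpha=alpha)
    sym = (m + m.T) / 2.0
    dist = np.clip(1.0 - sym, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(n, k=1)]
    link = hierarchy.linkage(condensed, method="average")
    order = [names[i] for i in hierarchy.leaves_list(link)]
    return CoassociationMatrix(
        values=pd.DataFrame(sym, index=names, columns=names),
        linkage=link,
        order=order,
    )
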