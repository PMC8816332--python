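"""Permutation-FDR peak calling on per-fragment log2 ratio tracks.

Candidate peaks are maximal runs of >= `min_fragments` consecutive
fragments whose score reaches a threshold (thresholds are score
quantiles). False discovery rates come from permuting the per-fragment
scores genome-wide: the shuffle preserves the exact score multiset and
the fragment-length structure, so runs of high scores that survive it are
exactly the runs that consecutive-fragment chance alone would produce.

For an observed peak of score s at threshold T,

    FDR(s) = (1 + #shuffled peaks at T with score >= s) / n_shuffles
             ------------------------------------------------------
                      #observed peaks at T with score >= s

The plus-one pseudo-exceedance keeps estimates away from zero at finite
shuffle counts. Estimates are monotonized q-value-style — a peak reports
the best FDR among the rejection sets {score >= s} containing it, so FDR
is non-increasing in score — and a threshold whose pooled shuffles
produce fewer than `min_null_peaks` peaks is treated as unassessable
(FDR = 1): with almost no null exceedances the ratio estimator is
dominated by the pseudo-count and would certify any singleton run.
Chromosome-end fragments participate in shuffling but never seed peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

from ._seeds import derive_rng
from .genome import GatcFragmentMap, GenomicInterval
from .signal import RatioTrack

__all__ = ["Peak", "PeakCallConfig", "candidate_peaks", "estimate_fdr", "call_peaks"]


@dataclass(frozen=True)
class Peak:
    """Run of enriched consecutive fragments."""

    chrom: str
    start: int
    end: int
    first_fragment: int
    last_fragment: int  # inclusive
    score: float
    summit: int  # fragment id with maximal score
    fdr: float | None = None
    name: str = "peak"

    @property
    def n_fragments(self) -> int:
        return self.last_fragment - self.first_fragment + 1

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               name=self.name, score=self.score)


@dataclass(frozen=True)
class PeakCallConfig:
    fdr_threshold: float = 0.05
    min_fragments: int = 2
    quantiles: tuple[float, ...] = (0.95, 0.99, 0.995, 0.999)
    n_shuffles: int = 100
    seed: int = 0
    max_gap: int = 0
    within_chromosome: bool = False
    score_stat: str = "mean"  # or "sum"
    min_null_peaks: int = 10


def _run_bounds(above: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and end (exclusive) indices of True runs."""
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def _scan_scores(
    scores: np.ndarray,
    fmap: GatcFragmentMap,
    threshold: float,
    min_fragments: int,
    max_gap: int,
    score_stat: str,
) -> list[tuple[int, int, float, int]]:
    """(first_fragment, last_fragment, peak score, summit) per run."""
    above = (scores >= threshold) & ~fmap.terminal & np.isfinite(scores)
    out: list[tuple[int, int, float, int]] = []
    for name in fmap.genome.names:
        off = fmap.offset(name)
        sub = above[off : off + fmap.n_fragments_in(name)]
        starts, ends = _run_bounds(sub)
        if max_gap > 0 and len(starts) > 1:
            merged_s, merged_e = [starts[0]], [ends[0]]
            for s, e in zip(starts[1:], ends[1:]):
                if s - merged_e[-1] <= max_gap:
                    merged_e[-1] = e
                else:
                    merged_s.append(s)
                    merged_e.append(e)
            starts, ends = np.asarray(merged_s), np.asarray(merged_e)
        for s, e in zip(starts, ends):
            if e - s < min_fragments:
                continue
            member = scores[off + s : off + e]
            stat = float(member.mean() if score_stat == "mean" else member.sum())
            summit = off + s + int(np.argmax(member))
            out.append((off + s, off + e - 1, stat, summit))
    return out


def candidate_peaks(
    track: RatioTrack | np.ndarray,
    fmap: GatcFragmentMap,
    threshold: float,
    min_fragments: int = 2,
    max_gap: int = 0,
    score_stat: str = "mean",
) -> list[Peak]:
    """Maximal runs of consecutive fragments with score >= threshold."""
    scores = track.scores if isinstance(track, RatioTrack) else np.asarray(track, float)
    if len(scores) != fmap.n_fragments:
        raise ValueError("track length != number of fragments")
    peaks = []
    for first, last, stat, summit in _scan_scores(
        scores, fmap, threshold, min_fragments, max_gap, score_stat
    ):
        peaks.append(
            Peak(
                chrom=fmap.chrom_name(first),
                start=int(fmap.starts[first]),
                end=int(fmap.ends[last]),
                first_fragment=first,
                last_fragment=last,
                score=stat,
                summit=summit,
            )
        )
    return peaks


def _shuffled_peak_scores(
    scores: np.ndarray,
    fmap: GatcFragmentMap,
    thresholds: np.ndarray,
    config: PeakCallConfig,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Pooled shuffled peak scores per threshold over all shuffles."""
    pools: list[list[float]] = [[] for _ in thresholds]
    for _ in range(config.n_shuffles):
        if config.within_chromosome:
            perm = scores.copy()
            for ci in range(len(fmap.genome.names)):
                mask = fmap.chrom_index == ci
                perm[mask] = rng.permutation(scores[mask])
        else:
            perm = rng.permutation(scores)
        for k, t in enumerate(thresholds):
            for _, _, stat, _ in _scan_scores(
                perm, fmap, float(t), config.min_fragments, config.max_gap, config.score_stat
            ):
                pools[k].append(stat)
    return [np.sort(np.asarray(p)) for p in pools]


def estimate_fdr(
    track: RatioTrack | np.ndarray,
    fmap: GatcFragmentMap,
    config: PeakCallConfig = PeakCallConfig(),
) -> list[Peak]:
    """Candidate peaks at every configured threshold, with estimated FDR.

    Overlapping candidates from different thresholds are all returned;
    `call_peaks` deduplicates. Reproducible under a fixed config seed.
    """
    if config.n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    scores = track.scores if isinstance(track, RatioTrack) else np.asarray(track, float)
    if len(scores) != fmap.n_fragments:
        raise ValueError("track length != number of fragments")
    eligible = scores[~fmap.terminal & np.isfinite(scores)]
    if len(eligible) == 0:
        return []
    thresholds = np.quantile(eligible, np.asarray(config.quantiles))
    rng = derive_rng(config.seed, "peaks.shuffle")
    pools = _shuffled_peak_scores(scores, fmap, thresholds, config, rng)

    out: list[Peak] = []
    for k, t in enumerate(thresholds):
        obs = candidate_peaks(scores, fmap, float(t), config.min_fragments,
                              config.max_gap, config.score_stat)
        if not obs:
            continue
        pool = pools[k]
        obs_scores = np.sort(np.asarray([p.score for p in obs]))
        order = np.argsort([-p.score for p in obs], kind="stable")
        raw = np.empty(len(obs))
        for idx in order:
            s = obs[idx].score
            if len(pool) < config.min_null_peaks:
                raw[idx] = 1.0
            else:
                n_null = len(pool) - np.searchsorted(pool, s, side="left")
                n_obs = len(obs_scores) - np.searchsorted(obs_scores, s, side="left")
                raw[idx] = min(1.0, (1.0 + n_null) / config.n_shuffles / max(n_obs, 1))
        # q-value monotonization: FDR(s) is the FDR of the whole rejection
        # set {score >= s}; each peak gets the best FDR among rejection
        # sets containing it, making FDR non-increasing in score.
        fdrs = np.empty(len(obs))
        running = 1.0
        for idx in order[::-1]:  # ascending score
            running = min(running, raw[idx])
            fdrs[idx] = running
        out.extend(replace(p, fdr=float(f)) for p, f in zip(obs, fdrs))
    return out


def call_peaks(
    track: RatioTrack | np.ndarray,
    fmap: GatcFragmentMap,
    config: PeakCallConfig = PeakCallConfig(),
) -> list[Peak]:
    """Significant peaks (fdr < fdr_threshold), deduplicated and named.

    Candidates from different thresholds that overlap are resolved by
    keeping the lowest-FDR (ties: highest score, then widest) candidate.
    Deterministic given the config seed.
    """
    cands = [p for p in estimate_fdr(track, fmap, config) if p.fdr < config.fdr_threshold]
    cands.sort(key=lambda p: (p.fdr, -p.score, -(p.end - p.start), p.chrom, p.start))
    accepted: list[Peak] = []
    for p in cands:
        if any(a.chrom == p.chrom and a.start < p.end and p.start < a.end for a in accepted):
            continue
        accepted.append(p)
    # candidates born at different thresholds can interleave out of order;
    # enforce FDR non-increasing in score across the final list by raising
    # (never lowering) the FDR of lower-scored peaks
    accepted.sort(key=lambda p: -p.score)
    running = 0.0
    monotone: list[Peak] = []
    for p in accepted:
        running = max(running, p.fdr)
        monotone.append(replace(p, fdr=running))
    chrom_order = {n: i for i, n in enumerate(fmap.genome.names)}
    monotone.sort(key=lambda p: (chrom_order[p.chrom], p.start))
    return [replace(p, name=f"peak_{i + 1}") for i, p in enumerate(monotone)]
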