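"""From aligned reads to normalized log2 DamID ratio tracks.

The quantification unit is the GATC fragment. Each read contributes one
count to the fragment containing its strand-adjusted 5' position (the
methylated GATC a DamID read starts from). TF-Dam counts are divided by
Dam-only control counts after per-library scaling, log2-transformed, and
the mode of the background score distribution is centred at zero: the
Dam-only control carries the same accessibility-driven methylation bias
as the fusion sample, so for the (vast) unbound majority of fragments the
ratio is a constant that the mode centring removes.

With n TF and m control replicates, all n x m pairwise ratio tracks are
computed and averaged into a single signal profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .genome import GatcFragmentMap, GenomeIndex, GenomicInterval

__all__ = [
    "FragmentCountTrack",
    "RatioTrack",
    "ReadQcReport",
    "count_reads_per_fragment",
    "normalize_ratio",
    "average_replicates",
    "pairwise_ratio_profile",
    "qc_reads",
    "binned_coverage_matrix",
    "sample_correlation",
    "sample_pca",
]


@dataclass
class FragmentCountTrack:
    """Integer read counts per fragment for one sample."""

    sample_id: str
    counts: np.ndarray
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def library_size(self) -> int:
        return int(self.counts.sum())


@dataclass
class RatioTrack:
    """Normalized log2(TF:dam / control:dam) score per fragment."""

    scores: np.ndarray
    tf_samples: tuple[str, ...] = ()
    control_samples: tuple[str, ...] = ()
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class ReadQcReport:
    """Post-sequencing QC: uncut adaptors, primer dimer, internal GATC."""

    n_reads: int
    fraction_start_gatc: float
    fraction_end_gatc: float
    fraction_adaptor: float
    mean_internal_gatc: float
    valid: bool = True


def count_reads_per_fragment(
    reads: Sequence[GenomicInterval], fmap: GatcFragmentMap, sample_id: str = "sample"
) -> FragmentCountTrack:
    """Assign each read to the fragment containing its 5' position.

    A 5' position exactly on a fragment boundary belongs to the fragment
    starting there. Reads on unknown chromosomes or beyond the chromosome
    end are rejected; the rejected count is reported on the track.
    """
    counts = np.zeros(fmap.n_fragments, dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    rejected = 0
    for r in reads:
        if r.chrom not in fmap.genome:
            rejected += 1
            continue
        p5 = r.five_prime()
        if p5 < 0 or p5 >= fmap.genome.length(r.chrom):
            rejected += 1
            continue
        by_chrom.setdefault(r.chrom, []).append(p5)
    for chrom, positions in by_chrom.items():
        ids = fmap.locate(chrom, np.asarray(positions, dtype=np.int64))
        np.add.at(counts, ids, 1)
    return FragmentCountTrack(sample_id, counts, n_rejected=rejected)


def _score_mode(scores: np.ndarray) -> float:
    """Mode of a score distribution by Gaussian kernel density on a grid."""
    if len(scores) == 0:
        return 0.0
    sd = float(np.std(scores))
    if sd < 1e-9 or len(scores) < 10:
        return float(np.median(scores))
    kde = stats.gaussian_kde(scores)
    lo, hi = float(scores.min()), float(scores.max())
    grid = np.linspace(lo, hi, 1024)
    return float(grid[int(np.argmax(kde(grid)))])


def normalize_ratio(
    tf: FragmentCountTrack,
    control: FragmentCountTrack,
    pseudocount: float = 0.5,
    min_count: int = 10,
    center: str = "mode",
) -> RatioTrack:
    """Per-fragment normalized log2 ratio of TF-Dam over Dam-only control.

    score_i = log2((tf_i/L_tf + c) / (ctrl_i/L_c + c)) - m, where L are
    library sizes, c = pseudocount / mean library size, and m centres the
    mode of the score distribution over well-covered fragments
    (tf_i + ctrl_i >= min_count) at zero. `center="median"` is a plain
    median-centring fallback.
    """
    if len(tf.counts) != len(control.counts):
        raise ValueError("mismatched fragment maps (count vectors differ in length)")
    l_tf, l_c = tf.library_size, control.library_size
    if l_tf <= 0 or l_c <= 0:
        raise ValueError("cannot normalize: empty library")
    c = pseudocount / ((l_tf + l_c) / 2.0)
    raw = np.log2(tf.counts / l_tf + c) - np.log2(control.counts / l_c + c)
    covered = (tf.counts + control.counts) >= min_count
    pool = raw[covered] if covered.any() else raw
    if center == "mode":
        m = _score_mode(pool)
    elif center == "median":
        m = float(np.median(pool))
    else:
        raise ValueError(f"unknown centering {center!r}")
    return RatioTrack(
        raw - m,
        tf_samples=(tf.sample_id,),
        control_samples=(control.sample_id,),
        normalization={
            "pseudocount_reads": pseudocount,
            "pseudocount_scaled": c,
            "min_count": min_count,
            "center": center,
            "offset": m,
            "library_sizes": (l_tf, l_c),
        },
    )


def average_replicates(ratios: Sequence[RatioTrack]) -> RatioTrack:
    """Arithmetic per-fragment mean of pairwise ratio tracks."""
    if not ratios:
        raise ValueError("no ratio tracks to average")
    n = len(ratios[0].scores)
    if any(len(r.scores) != n for r in ratios):
        raise ValueError("mismatched fragment maps across ratio tracks")
    scores = np.mean([r.scores for r in ratios], axis=0)
    tf = tuple(dict.fromkeys(s for r in ratios for s in r.tf_samples))
    ctrl = tuple(dict.fromkeys(s for r in ratios for s in r.control_samples))
    return RatioTrack(scores, tf_samples=tf, control_samples=ctrl,
                      normalization={"averaged_over": len(ratios)})


def pairwise_ratio_profile(
    tf_tracks: Sequence[FragmentCountTrack],
    control_tracks: Sequence[FragmentCountTrack],
    **kwargs,
) -> RatioTrack:
    """All pairwise TF x control ratio tracks, averaged into one profile."""
    if not tf_tracks or not control_tracks:
        raise ValueError("need >= 1 TF and >= 1 control replicate")
    pairs = [normalize_ratio(t, c, **kwargs) for t in tf_tracks for c in control_tracks]
    return average_replicates(pairs)


def qc_reads(sequences: Sequence[str], adaptor: str = "") -> ReadQcReport:
    """Read-level QC fractions; adaptor detection is an exact substring
    match of the first >=12 nt of the supplied adaptor."""
    n = len(sequences)
    if n == 0:
        return ReadQcReport(0, math.nan, math.nan, math.nan, math.nan, valid=False)
    if adaptor and len(adaptor) < 12:
        raise ValueError("adaptor prefix must be >= 12 nt")
    probe = adaptor[:].upper() if adaptor else ""
    start = end = has_adaptor = 0
    internal = 0
    for s in sequences:
        s = s.upper()
        if s.startswith("GATC"):
            start += 1
        if s.endswith("GATC"):
            end += 1
        if probe and probe in s:
            has_adaptor += 1
        # GATC occurrences strictly inside the read
        i = s.find("GATC", 1)
        while i != -1 and i + 4 < len(s):
            internal += 1
            i = s.find("GATC", i + 1)
    return ReadQcReport(
        n_reads=n,
        fraction_start_gatc=start / n,
        fraction_end_gatc=end / n,
        fraction_adaptor=(has_adaptor / n) if probe else 0.0,
        mean_internal_gatc=internal / n,
    )


def binned_coverage_matrix(
    read_sets: Sequence[Sequence[GenomicInterval]],
    genome: GenomeIndex,
    bin_size: int = 300,
) -> tuple[np.ndarray, list[GenomicInterval]]:
    """Read counts per fixed genomic bin per sample (bins x samples).

    Reads are assigned to the bin containing their 5' position; the last
    bin of each chromosome may be short. Returns the matrix and the bin
    intervals.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    bins: list[GenomicInterval] = []
    offsets: dict[str, int] = {}
    for name, length in genome.chromosomes:
        offsets[name] = len(bins)
        for s in range(0, length, bin_size):
            bins.append(GenomicInterval(name, s, min(s + bin_size, length)))
    mat = np.zeros((len(bins), len(read_sets)), dtype=np.int64)
    for j, reads in enumerate(read_sets):
        for r in reads:
            if r.chrom not in genome:
                continue
            p5 = r.five_prime()
            if 0 <= p5 < genome.length(r.chrom):
                mat[offsets[r.chrom] + p5 // bin_size, j] += 1
    return mat, bins


def sample_correlation(matrix: np.ndarray) -> np.ndarray:
    """Symmetric Pearson correlation between samples (columns).

    Zero-variance samples give NaN off-diagonal entries (undefined
    correlation); the diagonal is 1.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    sd = matrix.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(matrix, rowvar=False)
    bad = sd == 0
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def sample_pca(matrix: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component coordinates of samples (columns of `matrix`).

    Returns (coordinates: samples x n_components, explained variance
    ratio). Components are ordered by variance.
    """
    from sklearn.decomposition import PCA

    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = matrix.T  # samples as rows, bins as features
    n_components = min(n_components, x.shape[0], x.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x - x.mean(axis=0))
    return coords, pca.explained_variance_ratio_
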