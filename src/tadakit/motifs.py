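"""PWM scanning, top-peak selection, and k-mer enrichment.

The PWM scanner reports sites on both strands whose log-odds score
reaches a configurable fraction of the maximum achievable score. K-mer
enrichment is an explicitly simplified surrogate for full de novo motif
discovery: observed canonical k-mer counts in peak sequences are
compared against dinucleotide-preserving shuffles of the same sequences
(Altschul-Erickson doublet shuffle), yielding a z-score per k-mer.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_rng
from .genome import GenomicInterval

__all__ = [
    "Pwm",
    "MotifSite",
    "read_pwm",
    "top_peaks",
    "scan_pwm",
    "kmer_enrichment",
    "dinucleotide_shuffle",
    "inter_motif_mode_distance",
    "ModeDistance",
]

_BASES = "ACGT"
_IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSite:
    interval: GenomicInterval
    strand: str
    score: float


class Pwm:
    """Position weight matrix: base probabilities per position (4 x width).

    Log-odds use a pseudo-probability of 0.001 per cell against the
    background frequencies (default uniform).
    """

    PSEUDO = 1e-3

    def __init__(self, probs: np.ndarray, background: Sequence[float] | None = None):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError("probs must be 4 x width (rows A,C,G,T)")
        if probs.shape[1] < 4:
            raise ValueError("width must be >= 4")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("columns must sum to 1")
        self.probs = probs
        self.background = np.asarray(
            background if background is not None else [0.25] * 4, dtype=float
        )
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        p = probs + self.PSEUDO
        p /= p.sum(axis=0)
        self.log_odds = np.log2(p / self.background[:, None])

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @classmethod
    def from_consensus(cls, consensus: str, background=None) -> "Pwm":
        cols = []
        for ch in consensus.upper():
            allowed = _IUPAC.get(ch)
            if allowed is None:
                raise ValueError(f"invalid consensus symbol {ch!r}")
            col = np.zeros(4)
            for b in allowed:
                col[_BASES.index(b)] = 1.0 / len(allowed)
            cols.append(col)
        return cls(np.column_stack(cols), background=background)

    @classmethod
    def from_counts(cls, counts: np.ndarray, background=None) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        return cls(counts / counts.sum(axis=0), background=background)

    def reverse_complement(self) -> "Pwm":
        # A<->T, C<->G row swap plus column reversal
        return Pwm(self.probs[::-1, ::-1], background=self.background[::-1])


def read_pwm(path: str) -> Pwm:
    """Read a PWM from a whitespace matrix (positions x ACGT columns) or a
    TRANSFAC-style count block (rows `01 nA nC nG nT [consensus]`)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ">", "XX", "//", "ID", "BF", "DE")):
                continue
            fields = line.split()
            if fields[0].upper() in ("PO", "P0", "A", "C", "G", "T"):
                continue
            nums = []
            for f in fields:
                try:
                    nums.append(float(f))
                except ValueError:
                    break
            if len(nums) == 5 and fields[0].rstrip(".0").isdigit():
                nums = nums[1:]  # TRANSFAC position index column
            if len(nums) == 4:
                rows.append(nums)
    if not rows:
        raise ValueError(f"{path}: no PWM rows found")
    counts = np.asarray(rows).T  # to 4 x width
    return Pwm.from_counts(counts)


def top_peaks(peaks: Sequence, n: int = 200) -> list:
    """The n peaks with highest score, ties broken by genomic position."""
    return sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))[: n]


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray, threshold_abs: float) -> tuple[np.ndarray, np.ndarray]:
    w = lo.shape[1]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=int), np.empty(0)
    lo5 = np.vstack([lo, np.full((1, w), -1e9)])  # row 4: non-ACGT never matches
    scores = np.zeros(n)
    for j in range(w):
        scores += lo5[codes[j : j + n], j]
    hits = np.flatnonzero(scores >= threshold_abs)
    return hits, scores[hits]


def scan_pwm(
    sequences: Mapping[str, str],
    pwm: Pwm,
    score_threshold: float = 0.9,
    regions: Sequence[GenomicInterval] | None = None,
) -> list[MotifSite]:
    """Sites on both strands with log-odds >= threshold x max log-odds.

    `regions` restricts the scan; a region shorter than the PWM width
    yields no sites. Overlapping sites on opposite strands are both
    reported. Coordinates are always on the forward strand.
    """
    if not 0 < score_threshold <= 1:
        raise ValueError("score_threshold must be in (0, 1]")
    thr = score_threshold * pwm.max_score
    rc = pwm.reverse_complement()
    if regions is None:
        regions = [GenomicInterval(c, 0, len(s)) for c, s in sequences.items()]
    sites: list[MotifSite] = []
    for reg in regions:
        seq = sequences[reg.chrom][reg.start : reg.end]
        if len(seq) < pwm.width:
            continue
        codes = _encode(seq)
        for strand, mat in (("+", pwm.log_odds), ("-", rc.log_odds)):
            pos, scores = _scan_one_strand(codes, mat, thr)
            for p, s in zip(pos, scores):
                sites.append(
                    MotifSite(
                        GenomicInterval(reg.chrom, reg.start + int(p),
                                        reg.start + int(p) + pwm.width),
                        strand,
                        float(s),
                    )
                )
    sites.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.strand))
    return sites


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erickson)
# ---------------------------------------------------------------------------

def _reaches(v: str, last_edge: dict[str, str], target: str) -> bool:
    seen = set()
    while v != target:
        if v in seen or v not in last_edge:
            return False
        seen.add(v)
        v = last_edge[v]
    return True


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random sequence with the exact dinucleotide composition of `seq`."""
    s = seq.upper()
    if len(s) < 3:
        return s
    succ: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(s, s[1:]):
        succ[a].append(b)
    last = s[-1]
    verts = [v for v in succ if v != last]
    for _ in range(1000):
        chosen = {v: succ[v][rng.integers(len(succ[v]))] for v in verts}
        if all(_reaches(v, chosen, last) for v in verts):
            break
    else:  # pragma: no cover - tiny alphabet, effectively unreachable
        raise RuntimeError("doublet shuffle failed to connect")
    shuffled: dict[str, list[str]] = {}
    for v, edges in succ.items():
        edges = list(edges)
        if v in chosen:
            edges.remove(chosen[v])
        perm = [edges[i] for i in rng.permutation(len(edges))]
        if v in chosen:
            perm.append(chosen[v])
        shuffled[v] = perm
    out = [s[0]]
    ptr: dict[str, int] = defaultdict(int)
    for _ in range(len(s) - 1):
        v = out[-1]
        out.append(shuffled[v][ptr[v]])
        ptr[v] += 1
    return "".join(out)


def _canonical_kmer_counts(seqs: Sequence[str], k: int) -> Counter:
    counts: Counter = Counter()
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if any(c not in _BASES for c in kmer):
                continue
            counts[min(kmer, revcomp(kmer))] += 1
    return counts


def kmer_enrichment(
    sequences: Sequence[str],
    k: int = 6,
    n_shuffles: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Canonical k-mer enrichment against dinucleotide-preserving shuffles.

    Returns a DataFrame (kmer, observed, expected, sd, z) sorted by z
    descending; k-mers with degenerate null SD have z = NaN (flagged in
    the `degenerate` column).
    """
    if not 4 <= k <= 10:
        raise ValueError("k must be in [4, 10]")
    if n_shuffles < 1:
        raise ValueError("need >= 1 shuffle")
    if not sequences:
        raise ValueError("no sequences")
    rng = derive_rng(seed, "motifs.kmer_shuffle")
    obs = _canonical_kmer_counts(sequences, k)
    null_counts: dict[str, list[int]] = defaultdict(list)
    kmers = sorted(obs)
    for _ in range(n_shuffles):
        shuf = [dinucleotide_shuffle(s, rng) for s in sequences]
        c = _canonical_kmer_counts(shuf, k)
        for km in kmers:
            null_counts[km].append(c.get(km, 0))
    rows = []
    for km in kmers:
        null = np.asarray(null_counts[km], dtype=float)
        mu, sd = float(null.mean()), float(null.std(ddof=1)) if n_shuffles > 1 else 0.0
        degenerate = sd == 0
        z = float("nan") if degenerate else (obs[km] - mu) / sd
        rows.append((km, obs[km], mu, sd, z, degenerate))
    df = pd.DataFrame(rows, columns=["kmer", "observed", "expected", "sd", "z", "degenerate"])
    return df.sort_values("z", ascending=False, na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# inter-motif distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeDistance:
    bin_start: int
    bin_end: int
    mode: float  # bin midpoint
    n_pairs: int
    histogram: dict[int, int]  # bin_start -> count


def inter_motif_mode_distance(
    sites_a: Sequence[MotifSite],
    sites_b: Sequence[MotifSite],
    shared_peaks: Sequence[GenomicInterval],
    bin_size: int = 50,
) -> ModeDistance | None:
    """Mode of nearest-neighbor distances between A- and B-motif sites
    within shared peaks (binned; ties -> smaller distance). Returns None
    when no A-site has a B-site in its peak."""
    dists: list[int] = []
    for peak in shared_peaks:
        a_in = [s for s in sites_a if peak.overlaps(s.interval)]
        b_in = [s for s in sites_b if peak.overlaps(s.interval)]
        if not a_in or not b_in:
            continue
        for sa in a_in:
            dists.append(min(abs(sa.interval.center - sb.interval.center) for sb in b_in))
    if not dists:
        return None
    hist: dict[int, int] = defaultdict(int)
    for d in dists:
        hist[(d // bin_size) * bin_size] += 1
    best = min(hist.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return ModeDistance(
        bin_start=best,
        bin_end=best + bin_size,
        mode=best + bin_size / 2.0,
        n_pairs=len(dists),
        histogram=dict(sorted(hist.items())),
    )
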