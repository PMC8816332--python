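"""Genome coordinate system for DamID analysis.

DamID signal is quantified on *GATC fragments*: the intervals between
consecutive GATC cut positions of a genome. This module holds the genome
index, the fragment map (the pipeline's fundamental coordinate system),
gene models, and plain genomic intervals. All coordinates are 0-based
half-open internally; 1-based formats (GFF/GTF) are converted on I/O.

The Dam methyltransferase marks the adenine of GATC; the downstream DpnI
digestion cuts between the A and T (blunt, motif start + 2). We place
fragment boundaries at that cut position. Any consistent offset in [0, 4]
yields identical per-fragment read counts for reads longer than 4 bp,
because a read 5' end can only move across a boundary if the boundary
shifts past it, which a uniform offset applies to observed and simulated
reads alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeIndex",
    "GenomicInterval",
    "GeneModel",
    "GatcFragmentMap",
    "find_gatc_sites",
    "build_fragment_map",
]

GATC_CUT_OFFSET = 2  # DpnI blunt cut within GA^TC


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length")

    @classmethod
    def from_lengths(cls, lengths: Mapping[str, int] | Sequence[tuple[str, int]]) -> "GenomeIndex":
        items = lengths.items() if isinstance(lengths, Mapping) else lengths
        return cls(tuple((str(n), int(l)) for n, l in items))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, name: str) -> int:
        for n, l in self.chromosomes:
            if n == name:
                return l
        raise KeyError(name)

    def __contains__(self, name: object) -> bool:
        return any(n == name for n, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with optional BED-style decorations."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def five_prime(self) -> int:
        """Strand-adjusted 5' position (start for +/., end-1 for -)."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass(frozen=True)
class GeneModel:
    """Gene span of the largest transcript, with TSS/TES and exon structure.

    `tss` and `tes` are bp positions (0-based). For a + strand gene
    tss < tes; for a - strand gene tss > tes. Exons are half-open,
    non-overlapping, sorted by coordinate.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")
        lo, hi = self.body_start, self.body_end
        prev = lo
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: empty exon ({s},{e})")
            if s < prev:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            if s < lo or e > hi:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
            prev = e

    @property
    def body_start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def body_end(self) -> int:
        """Half-open end of the gene body."""
        return max(self.tss, self.tes) + 1

    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return tuple(out)

    def body_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.body_start, self.body_end,
                               name=self.gene_id, strand=self.strand)


def find_gatc_sites(sequence: str) -> list[int]:
    """0-based start positions of literal GATC matches (case-insensitive).

    The motif is its own reverse complement, so one strand scan suffices.
    N never matches.
    """
    seq = sequence.upper()
    sites: list[int] = []
    i = seq.find("GATC")
    while i != -1:
        sites.append(i)
        i = seq.find("GATC", i + 1)
    return sites


class GatcFragmentMap:
    """Ordered, non-overlapping GATC fragments tiling each chromosome.

    Fragments are intervals between consecutive cut positions
    (motif start + 2) plus the two terminal fragments of each chromosome.
    Fragment ids are global and sequential in chromosome order.
    """

    def __init__(self, genome: GenomeIndex, boundaries: Mapping[str, np.ndarray]):
        self.genome = genome
        self._boundaries: dict[str, np.ndarray] = {}
        starts, ends, chrom_idx, terminal = [], [], [], []
        offsets: dict[str, int] = {}
        total = 0
        for ci, (name, length) in enumerate(genome.chromosomes):
            b = np.asarray(boundaries[name], dtype=np.int64)
            if b[0] != 0 or b[-1] != length:
                raise ValueError(f"{name}: boundaries must span [0, {length}]")
            if np.any(np.diff(b) <= 0):
                raise ValueError(f"{name}: boundaries not strictly increasing")
            self._boundaries[name] = b
            n = len(b) - 1
            offsets[name] = total
            starts.append(b[:-1])
            ends.append(b[1:])
            chrom_idx.append(np.full(n, ci, dtype=np.int32))
            t = np.zeros(n, dtype=bool)
            t[0] = t[-1] = True
            terminal.append(t)
            total += n
        self._offsets = offsets
        self.starts = np.concatenate(starts)
        self.ends = np.concatenate(ends)
        self.chrom_index = np.concatenate(chrom_idx)
        self.terminal = np.concatenate(terminal)

    # -- basic accessors -------------------------------------------------
    @property
    def n_fragments(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def chrom_name(self, fragment_id: int) -> str:
        return self.genome.names[self.chrom_index[fragment_id]]

    def boundaries(self, chrom: str) -> np.ndarray:
        return self._boundaries[chrom]

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def n_fragments_in(self, chrom: str) -> int:
        return len(self._boundaries[chrom]) - 1

    def fragment(self, fragment_id: int) -> GenomicInterval:
        return GenomicInterval(
            self.chrom_name(fragment_id),
            int(self.starts[fragment_id]),
            int(self.ends[fragment_id]),
            name=f"frag_{fragment_id}",
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        return (self.fragment(i) for i in range(self.n_fragments))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GatcFragmentMap):
            return NotImplemented
        return self.genome == other.genome and all(
            np.array_equal(self._boundaries[n], other._boundaries[n])
            for n in self.genome.names
        )

    # -- coordinate queries ----------------------------------------------
    def locate(self, chrom: str, pos: int | np.ndarray) -> int | np.ndarray:
        """Global fragment id(s) containing position(s) on `chrom`.

        A position exactly on a boundary belongs to the fragment starting
        there. Positions outside [0, chrom length) raise.
        """
        b = self._boundaries[chrom]
        pos_arr = np.asarray(pos)
        if np.any(pos_arr < 0) or np.any(pos_arr >= b[-1]):
            raise ValueError(f"position out of range on {chrom}")
        idx = np.searchsorted(b, pos_arr, side="right") - 1
        out = idx + self._offsets[chrom]
        return int(out) if np.isscalar(pos) else out

    def overlapping(self, interval: GenomicInterval) -> np.ndarray:
        """Global fragment ids overlapping `interval` (>= 1 shared bp)."""
        b = self._boundaries[interval.chrom]
        lo = int(np.searchsorted(b, interval.start, side="right") - 1)
        hi = int(np.searchsorted(b, interval.end, side="left"))
        off = self._offsets[interval.chrom]
        return np.arange(off + max(lo, 0), off + hi)


def build_fragment_map(
    sequences: Mapping[str, str], genome: GenomeIndex | None = None
) -> GatcFragmentMap:
    """Digest `sequences` at GATC cut positions into a fragment map.

    A chromosome with no GATC site yields a single whole-chromosome
    fragment (terminal-flagged).
    """
    if not sequences:
        raise ValueError("need at least one chromosome")
    if genome is None:
        genome = GenomeIndex.from_lengths({n: len(s) for n, s in sequences.items()})
    boundaries = {}
    for name, length in genome.chromosomes:
        seq = sequences[name]
        if len(seq) != length:
            raise ValueError(f"{name}: sequence length {len(seq)} != index length {length}")
        cuts = np.asarray([p + GATC_CUT_OFFSET for p in find_gatc_sites(seq)], dtype=np.int64)
        boundaries[name] = np.concatenate([[0], cuts, [length]])
    return GatcFragmentMap(genome, boundaries)
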