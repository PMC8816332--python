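"""Peak-to-gene assignment and gene-set overlap statistics.

A peak is assigned to every gene (on either strand) whose window from
6 kb upstream of the TSS to 1 kb downstream of the TES contains the peak
center. Location relative to the gene uses the full peak span and the
gene's strand, with precedence TSS > TES > within-gene > up/downstream;
a within-gene peak is refined to intron-only/exon-only when its whole
span lies in introns/exons. Distances are signed in transcription
direction: negative = upstream of the TSS.

Gene-set overlaps are tested against a hypergeometric null on a fixed
sampling pool of annotated coding genes (default 20191).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, GenomeIndex, GenomicInterval

__all__ = [
    "AnnotationConfig",
    "PeakAssignment",
    "LOCATION_CLASSES",
    "assign_peaks_to_genes",
    "classify_location",
    "location_summary",
    "promoter_regions",
    "gene_set_overlap_test",
]

LOCATION_CLASSES = (
    "upstream",
    "overlapping_TSS",
    "within_gene",
    "intron_only",
    "exon_only",
    "overlapping_TES",
    "downstream",
)


@dataclass(frozen=True)
class AnnotationConfig:
    upstream_limit: int = 6000
    downstream_limit: int = 1000
    allow_multiple: bool = True


@dataclass(frozen=True)
class PeakAssignment:
    peak_name: str
    gene_id: str
    distance: int  # peak center to TSS, transcription-direction signed
    location: str


def _tss_distance(center: int, gene: GeneModel) -> int:
    """Signed distance from position to TSS; negative = upstream."""
    return center - gene.tss if gene.strand == "+" else gene.tss - center


def _in_window(center: int, gene: GeneModel, cfg: AnnotationConfig) -> bool:
    """Center within [TSS - up, TES + down] in transcription coordinates."""
    d_tss = _tss_distance(center, gene)
    d_tes = center - gene.tes if gene.strand == "+" else gene.tes - center
    return d_tss >= -cfg.upstream_limit and d_tes <= cfg.downstream_limit


def _covers(peak: GenomicInterval, pos: int) -> bool:
    return peak.start <= pos < peak.end


def _subset_of(peak: GenomicInterval, pieces: Iterable[tuple[int, int]]) -> bool:
    """True if every bp of the peak lies within the union of pieces."""
    pos = peak.start
    for s, e in sorted(pieces):
        if pos < s:
            break
        pos = max(pos, min(e, peak.end))
        if pos >= peak.end:
            return True
    return pos >= peak.end


def classify_location(peak: GenomicInterval, gene: GeneModel) -> str:
    if peak.chrom != gene.chrom:
        raise ValueError("peak and gene on different chromosomes")
    if _covers(peak, gene.tss):
        return "overlapping_TSS"
    if _covers(peak, gene.tes):
        return "overlapping_TES"
    if peak.start >= gene.body_start and peak.end <= gene.body_end:
        if _subset_of(peak, gene.exons):
            return "exon_only"
        if _subset_of(peak, gene.introns()):
            return "intron_only"
        return "within_gene"
    return "upstream" if _tss_distance(peak.center, gene) < 0 else "downstream"


def assign_peaks_to_genes(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    config: AnnotationConfig = AnnotationConfig(),
) -> tuple[list[PeakAssignment], list[GenomicInterval]]:
    """Assignments by the center-coordinate distance rule, plus the list
    of peaks no gene window contains (reported separately so every peak
    appears in exactly one of the two)."""
    assignments: list[PeakAssignment] = []
    unassigned: list[GenomicInterval] = []
    for i, p in enumerate(peaks):
        pname = p.name or f"peak_{i + 1}"
        hits = [
            g for g in genes
            if g.chrom == p.chrom and _in_window(p.center, g, config)
        ]
        if not hits:
            unassigned.append(p)
            continue
        if not config.allow_multiple:
            hits = [min(hits, key=lambda g: (abs(_tss_distance(p.center, g)), g.gene_id))]
        for g in hits:
            assignments.append(
                PeakAssignment(pname, g.gene_id, _tss_distance(p.center, g),
                               classify_location(p, g))
            )
    return assignments, unassigned


def location_summary(assignments: Sequence[PeakAssignment]) -> pd.Series:
    """Proportion of assignments per location class, plus the fraction of
    upstream assignments whose center lies within the first 2 kb."""
    if not assignments:
        raise ValueError("no assignments")
    counts = pd.Series(0.0, index=list(LOCATION_CLASSES))
    for a in assignments:
        counts[a.location] += 1
    props = counts / counts.sum()
    ups = [a for a in assignments if a.location == "upstream"]
    props["upstream_within_2kb"] = (
        float(np.mean([abs(a.distance) <= 2000 for a in ups])) if ups else float("nan")
    )
    return props


def promoter_regions(
    genes: Sequence[GeneModel],
    genome: GenomeIndex,
    upstream: int = 5000,
    downstream: int = 500,
) -> list[GenomicInterval]:
    """Strand-aware promoter windows (default 5 kb upstream to 500 bp
    downstream of the TSS), clipped at chromosome bounds."""
    out = []
    for g in genes:
        if g.strand == "+":
            s, e = g.tss - upstream, g.tss + downstream
        else:
            s, e = g.tss - downstream, g.tss + upstream
        length = genome.length(g.chrom)
        s, e = max(0, s), min(length, e)
        if s < e:
            out.append(GenomicInterval(g.chrom, s, e, name=f"{g.gene_id}_promoter",
                                       strand=g.strand))
    return out


def gene_set_overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    pool_size: int = 20191,
    method: str = "hypergeometric",
) -> tuple[int, float]:
    """Overlap size and upper-tail p-value of drawing |B| genes from a
    pool with |A| successes and seeing >= the observed overlap."""
    a, b = set(set_a), set(set_b)
    if len(a) > pool_size or len(b) > pool_size:
        raise ValueError("set larger than sampling pool")
    k = len(a & b)
    if method == "hypergeometric":
        p = float(stats.hypergeom.sf(k - 1, pool_size, len(a), len(b)))
    elif method == "fisher":
        table = [[k, len(a) - k], [len(b) - k, pool_size - len(a) - len(b) + k]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return k, min(p, 1.0)
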