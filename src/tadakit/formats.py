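"""Reading and writing the standard genomic text formats.

FASTA via pyfaidx, GFF3/GTF via gffutils, SAM/FASTQ via pysam; BED and
bedGraph are plain TSV handled directly. GFF/GTF 1-based inclusive
coordinates are converted to the internal 0-based half-open convention on
input. Gene spans follow the largest-transcript convention: the span of a
gene is min start / max end over its transcripts.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import GatcFragmentMap, GeneModel, GenomeIndex, GenomicInterval

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_bedgraph",
    "read_reads",
    "read_fastq",
    "write_peaks_bed",
]


class FormatError(ValueError):
    """Malformed input file; message carries the path and line number."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> tuple[GenomeIndex, dict[str, str]]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=False)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    genome = GenomeIndex.from_lengths({n: len(s) for n, s in seqs.items()})
    return genome, seqs


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / GTF gene models
# ---------------------------------------------------------------------------

def _gene_from_transcripts(gene_id, chrom, strand, spans, exons) -> GeneModel:
    start = min(s for s, _ in spans)
    end = max(e for _, e in spans)
    if strand == "+":
        tss, tes = start, end - 1
    else:
        tss, tes = end - 1, start
    merged: list[list[int]] = []
    for s, e in sorted(exons):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return GeneModel(gene_id, chrom, strand, tss, tes, tuple((s, e) for s, e in merged))


def read_gff(path: str | os.PathLike, genome: GenomeIndex | None = None) -> list[GeneModel]:
    """Parse gene models from GFF3 or GTF (dialect chosen by extension).

    Returns one GeneModel per gene, spanning the largest transcript; exons
    of all transcripts are merged. Unknown chromosomes are rejected when a
    genome index is supplied.
    """
    import gffutils

    path = str(path)
    is_gtf = path.lower().endswith(".gtf")
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        verbose=False,
        disable_infer_genes=not is_gtf,
        disable_infer_transcripts=not is_gtf,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if genome is not None and g.seqid not in genome:
            raise FormatError(f"{path}: gene {g.id} on unknown chromosome {g.seqid!r}")
        spans: list[tuple[int, int]] = []
        exons: list[tuple[int, int]] = []
        for t in db.children(g, level=1):
            if t.featuretype in ("exon", "CDS"):
                continue
            spans.append((t.start - 1, t.end))
            for ex in db.children(t, featuretype="exon"):
                exons.append((ex.start - 1, ex.end))
        if not spans:
            spans = [(g.start - 1, g.end)]
        if not exons:
            exons = list(spans)
        gene_id = g.attributes.get("gene_id", [g.id])[0]
        genes.append(_gene_from_transcripts(gene_id, g.seqid, g.strand, spans, exons))
    return genes


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(
    path: str | os.PathLike, genome: GenomeIndex | None = None
) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; malformed lines report line numbers."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if genome is not None and chrom not in genome:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, name=name, score=score, strand=strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def _fmt_score(x: float | None) -> str:
    if x is None:
        return "."
    return format(float(x), ".6g")


def write_bed(path: str | os.PathLike, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{_fmt_score(iv.score)}\t{iv.strand}\n"
            )


def write_bedgraph(
    path: str | os.PathLike, fmap: GatcFragmentMap, scores: Sequence[float] | np.ndarray
) -> None:
    """One bedGraph record per GATC fragment."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != fmap.n_fragments:
        raise ValueError("scores length != number of fragments")
    names = fmap.genome.names
    with open(path, "w") as fh:
        for i in range(fmap.n_fragments):
            fh.write(
                f"{names[fmap.chrom_index[i]]}\t{fmap.starts[i]}\t{fmap.ends[i]}\t"
                f"{scores[i]:.6f}\n"
            )


def read_bedgraph(path: str | os.PathLike) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), score=float(fields[3]))
            )
    return out


# ---------------------------------------------------------------------------
# Aligned reads (BED6 or SAM) and FASTQ
# ---------------------------------------------------------------------------

def read_reads(
    path: str | os.PathLike, genome: GenomeIndex | None = None
) -> list[GenomicInterval]:
    """Aligned single-end reads as intervals with strand.

    BED6 by default; `.sam` files go through pysam (unmapped records are
    skipped).
    """
    path = str(path)
    if path.lower().endswith(".sam"):
        import pysam

        reads = []
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    continue
                strand = "-" if rec.is_reverse else "+"
                reads.append(
                    GenomicInterval(
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end or rec.reference_start + rec.query_length,
                        name=rec.query_name,
                        strand=strand,
                    )
                )
        return reads
    return read_bed(path, genome=genome)


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    """(name, sequence) pairs from FASTQ or FASTA, via pysam."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        return [(rec.name, rec.sequence) for rec in fh]


def write_peaks_bed(path: str | os.PathLike, peaks: Iterable) -> None:
    """BED6+1: chrom, start, end, name, mean log2 score, '.', fdr."""
    with open(path, "w") as fh:
        for p in peaks:
            fdr = "." if p.fdr is None else f"{p.fdr:.6f}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:.4f}\t.\t{fdr}\n"
            )
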