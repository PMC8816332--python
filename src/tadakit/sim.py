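"""Synthetic targeted-DamID experiments with ground truth.

The generator emulates the data a TaDa sequencing experiment hands the
analysis pipeline: a multi-chromosome random genome (i.i.d. uniform
bases, so GATC spacing is geometric with mean 256 bp), non-overlapping
genes with TSS/TES/exon structure, a TF motif planted into the upstream
window of a chosen fraction of genes, and replicate read sets for TF-Dam
and Dam-only control samples.

Methylation is modeled at fragment resolution. Fragment i has propensity

    m_i = a_i * b * len_i * (e  if the fragment lies within `halo` bp of
                                a planted site, else 1)

for TF samples, and a_i * b * len_i for controls, where a_i is a
lognormal accessibility factor shared across *all* samples — the
confounder the Dam-only control exists to cancel. Read counts per
fragment are negative binomial with mean depth * m_i / sum(m) and a
configured dispersion; reads fall uniformly within their fragment with
random strand and fixed length. The whole simulation is a pure function
of the config (including its seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._seeds import derive_rng
from .genome import GatcFragmentMap, GeneModel, GenomeIndex, GenomicInterval, build_fragment_map
from .motifs import revcomp

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genome",
    "plant_binding",
    "simulate_reads",
    "simulate_experiment",
    "evaluate_recovery",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of one synthetic TaDa experiment.

    Defaults describe the package's standard study conditions: a
    scaled-down six-chromosome genome, ~30% of genes bound, 8-fold
    enrichment within 500 bp of a bound site, 500k reads per sample and
    2x2 replicates.
    """

    n_chromosomes: int = 6
    chromosome_length: int = 1_000_000
    n_genes: int = 60
    motif: str = "CACGTG"  # E-box consensus
    fraction_bound: float = 0.3
    binding_window: int = 2000  # bp upstream of TSS for planted sites
    background_rate: float = 1.0  # b, per fragment-bp
    enrichment: float = 8.0  # e, at fragments near bound sites
    halo: int = 500  # bp around a bound site that picks up enrichment
    accessibility_sigma: float = 0.4  # lognormal sd, shared across samples
    depth: int = 500_000  # reads per sample
    dispersion: float = 10.0  # negative binomial size; larger = less noise
    read_length: int = 75
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_bound <= 1:
            raise ValueError("fraction_bound must be in [0, 1]")
        for name in ("background_rate", "enrichment", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SimulationTruth:
    """Planted binding sites and generative state of one simulation."""

    config: SimulationConfig
    genome: GenomeIndex
    sequences: dict[str, str]
    genes: list[GeneModel]
    bound_sites: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    fragment_map: GatcFragmentMap | None = None
    accessibility: np.ndarray | None = None
    propensity_tf: np.ndarray | None = None
    propensity_control: np.ndarray | None = None

    def enriched_fragments(self) -> np.ndarray:
        """Boolean mask of fragments within `halo` bp of a bound site."""
        fmap = self.fragment_map
        if fmap is None:
            raise ValueError("fragment map not built (call plant_binding first)")
        mask = np.zeros(fmap.n_fragments, dtype=bool)
        halo = self.config.halo
        for site, _ in self.bound_sites:
            lo = max(0, site.start - halo)
            hi = min(self.genome.length(site.chrom), site.end + halo)
            mask[fmap.overlapping(GenomicInterval(site.chrom, lo, hi))] = True
        return mask

    def site_fragments(self) -> list[np.ndarray]:
        """Fragment ids overlapping each bound site (the planted fragments)."""
        assert self.fragment_map is not None
        return [self.fragment_map.overlapping(site) for site, _ in self.bound_sites]


def _make_genes(
    chrom: str, length: int, n: int, rng: np.random.Generator,
    margin: int = 5000, spacing: int = 8000,
) -> list[GeneModel]:
    """Non-overlapping genes with >= `spacing` bp between them."""
    gene_lens = rng.integers(1500, 4001, size=n)
    needed = int(gene_lens.sum()) + spacing * (n - 1) + 2 * margin
    if needed > length:
        raise ValueError(f"chromosome too short for {n} genes with {spacing} bp spacing")
    slack = length - needed
    # distribute slack as random extra gaps
    extra = rng.multinomial(slack, np.full(n, 1.0 / n))
    genes = []
    pos = margin
    for i in range(n):
        pos += int(extra[i])
        start = pos
        end = start + int(gene_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 6))
        # cut the body into alternating exon/intron pieces
        cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * n_exons - 2, replace=False))
        edges = np.concatenate([[start], cuts, [end]])
        exons = tuple((int(edges[2 * j]), int(edges[2 * j + 1])) for j in range(n_exons))
        tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
        genes.append(GeneModel(f"gene_{chrom}_{i + 1}", chrom, strand, tss, tes, exons))
        pos = end + spacing
    return genes


def simulate_genome(config: SimulationConfig) -> SimulationTruth:
    """Random genome and gene annotation; deterministic in the config."""
    rng = derive_rng(config.seed, "sim.genome")
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    per_chrom = _split_counts(config.n_genes, config.n_chromosomes)
    for ci in range(config.n_chromosomes):
        chrom = f"chr{['I', 'II', 'III', 'IV', 'V', 'X'][ci] if ci < 6 else ci + 1}"
        seq = _BASES[rng.integers(0, 4, size=config.chromosome_length)].tobytes().decode()
        sequences[chrom] = seq
        genes.extend(_make_genes(chrom, config.chromosome_length, per_chrom[ci], rng))
    genome = GenomeIndex.from_lengths({c: len(s) for c, s in sequences.items()})
    return SimulationTruth(config=config, genome=genome, sequences=sequences, genes=genes)


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def plant_binding(truth: SimulationTruth) -> SimulationTruth:
    """Write the motif consensus into the upstream window of a random
    fraction of genes, then build the fragment map from the final
    sequence (planting can create or destroy GATC sites)."""
    cfg = truth.config
    rng = derive_rng(cfg.seed, "sim.binding")
    n_bound = int(round(cfg.fraction_bound * len(truth.genes)))
    order = rng.permutation(len(truth.genes))[:n_bound]
    motif = cfg.motif.upper()
    w = len(motif)
    sites: list[tuple[GenomicInterval, str]] = []
    seqs = dict(truth.sequences)
    for gi in sorted(order):
        g = truth.genes[gi]
        offset = int(rng.integers(w, cfg.binding_window))  # bp upstream of TSS
        if g.strand == "+":
            start = g.tss - offset
            inserted = motif
        else:
            start = g.tss + offset - w + 1
            inserted = revcomp(motif)
        length = truth.genome.length(g.chrom)
        start = max(0, min(start, length - w))
        s = seqs[g.chrom]
        seqs[g.chrom] = s[:start] + inserted + s[start + w :]
        sites.append((GenomicInterval(g.chrom, start, start + w, name=g.gene_id,
                                      strand=g.strand), g.gene_id))
    fmap = build_fragment_map(seqs, truth.genome)
    return replace(
        truth, sequences=seqs, bound_sites=sites, fragment_map=fmap
    )


def _fragment_propensities(truth: SimulationTruth) -> SimulationTruth:
    cfg = truth.config
    fmap = truth.fragment_map
    assert fmap is not None
    rng = derive_rng(cfg.seed, "sim.accessibility")
    a = rng.lognormal(mean=0.0, sigma=cfg.accessibility_sigma, size=fmap.n_fragments)
    base = a * cfg.background_rate * fmap.lengths
    tf = base * np.where(truth.enriched_fragments(), cfg.enrichment, 1.0)
    truth.accessibility = a
    truth.propensity_tf = tf
    truth.propensity_control = base
    return truth


def simulate_counts(truth: SimulationTruth, condition: str, replicate: int) -> np.ndarray:
    """Negative-binomial read counts per fragment for one sample.

    Identical to counting the reads from `simulate_reads` (every read's
    5' end stays within its fragment); the array form skips per-read
    bookkeeping for large simulation sweeps.
    """
    cfg = truth.config
    if cfg.depth <= 0:
        raise ValueError("depth must be > 0")
    if condition not in ("tf", "control"):
        raise ValueError("condition must be 'tf' or 'control'")
    if truth.propensity_tf is None:
        _fragment_propensities(truth)
    m = truth.propensity_tf if condition == "tf" else truth.propensity_control
    mu = cfg.depth * m / m.sum()
    rng = derive_rng(cfg.seed, f"sim.reads.{condition}.{replicate}")
    r = cfg.dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate_reads(
    truth: SimulationTruth, condition: str, replicate: int
) -> list[GenomicInterval]:
    """One sample's aligned reads (BED-style intervals with strand).

    `condition` is "tf" or "control"; replicate numbering starts at 1.
    Counts per fragment are negative binomial around the scaled
    propensities; each read's 5' end is uniform within its fragment.
    """
    cfg = truth.config
    if cfg.depth <= 0:
        raise ValueError("depth must be > 0")
    if condition not in ("tf", "control"):
        raise ValueError("condition must be 'tf' or 'control'")
    if truth.propensity_tf is None:
        _fragment_propensities(truth)
    fmap = truth.fragment_map
    assert fmap is not None
    m = truth.propensity_tf if condition == "tf" else truth.propensity_control
    mu = cfg.depth * m / m.sum()
    rng = derive_rng(cfg.seed, f"sim.reads.{condition}.{replicate}")
    r = cfg.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    # place reads: 5' uniform within fragment, random strand, fixed length
    frag_ids = np.repeat(np.arange(fmap.n_fragments), counts)
    lens = fmap.lengths[frag_ids]
    p5 = fmap.starts[frag_ids] + (rng.random(len(frag_ids)) * lens).astype(np.int64)
    minus = rng.random(len(frag_ids)) < 0.5
    chrom_len = np.asarray([l for _, l in fmap.genome.chromosomes])[fmap.chrom_index[frag_ids]]
    starts = np.where(minus, np.maximum(p5 - cfg.read_length + 1, 0), p5)
    ends = np.where(minus, p5 + 1, np.minimum(p5 + cfg.read_length, chrom_len))
    names = fmap.genome.names
    sample = f"{condition}_rep{replicate}"
    return [
        GenomicInterval(names[fmap.chrom_index[f]], int(s), int(e),
                        name=f"{sample}_read_{i}", strand="-" if mi else "+")
        for i, (f, s, e, mi) in enumerate(zip(frag_ids, starts, ends, minus))
    ]


def simulate_experiment(config: SimulationConfig) -> tuple[SimulationTruth, dict[str, list[GenomicInterval]]]:
    """Full experiment: genome + planted binding + all replicate read sets."""
    truth = plant_binding(simulate_genome(config))
    samples = {}
    for cond in ("tf", "control"):
        for rep in range(1, config.n_replicates + 1):
            samples[f"{cond}_rep{rep}"] = simulate_reads(truth, cond, rep)
    return truth, samples


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float  # NaN when no peaks were called
    recall: float
    f1: float
    n_true_positive_peaks: int
    n_called: int
    n_sites: int


def evaluate_recovery(
    called_peaks: Sequence, truth: SimulationTruth, match: str = "enriched_span"
) -> RecoveryMetrics:
    """Precision/recall/F1 of called peaks against planted sites.

    A called peak is a true positive when it overlaps a site's span of
    enriched fragments — with `match="enriched_span"` (default) the
    fragments within the enrichment halo of the site, i.e. exactly where
    the generator placed excess signal; with `match="site_fragments"`
    only the fragments the motif itself touches. A site is recovered
    when some called peak overlaps its span.
    """
    fmap = truth.fragment_map
    assert fmap is not None
    halo = truth.config.halo if match == "enriched_span" else 0
    if match not in ("enriched_span", "site_fragments"):
        raise ValueError(f"unknown match mode {match!r}")
    site_spans = []
    for site, _ in truth.bound_sites:
        length = truth.genome.length(site.chrom)
        lo = max(0, site.start - halo)
        hi = min(length, site.end + halo)
        frag_ids = fmap.overlapping(GenomicInterval(site.chrom, lo, hi))
        site_spans.append(
            GenomicInterval(
                site.chrom,
                int(fmap.starts[frag_ids[0]]),
                int(fmap.ends[frag_ids[-1]]),
            )
        )
    peak_ivs = [
        p.interval() if hasattr(p, "interval") and callable(p.interval) else p
        for p in called_peaks
    ]
    tp_peaks = sum(1 for p in peak_ivs if any(p.overlaps(s) for s in site_spans))
    hit_sites = sum(1 for s in site_spans if any(p.overlaps(s) for p in peak_ivs))
    n_sites = len(site_spans)
    recall = hit_sites / n_sites if n_sites else math.nan
    precision = tp_peaks / len(peak_ivs) if peak_ivs else math.nan
    if peak_ivs and n_sites and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0 if peak_ivs or n_sites else math.nan
    return RecoveryMetrics(precision, recall, f1, tp_peaks, len(peak_ivs), n_sites)
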