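"""End-to-end workflow: signal -> peaks -> annotation, with a manifest.

One root seed drives every stochastic stage via named substreams
(peaks.shuffle, sim.reads.*, coloc.shuffle, ...); re-running with the
same config produces byte-identical deterministic outputs. A JSON run
manifest (resolved config, seeds, input checksums, version) is written
alongside every output set.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Mapping

from . import __version__
from ._seeds import derive_seed
from .annotate import AnnotationConfig, assign_peaks_to_genes, location_summary
from .formats import (
    read_fasta,
    read_gff,
    read_reads,
    write_bedgraph,
    write_peaks_bed,
)
from .genome import build_fragment_map
from .peaks import PeakCallConfig, call_peaks
from .signal import count_reads_per_fragment, pairwise_ratio_profile

__all__ = ["ConfigError", "DataError", "run_pipeline", "write_manifest"]


class ConfigError(ValueError):
    """Bad configuration; CLI exit code 2."""


class DataError(ValueError):
    """Bad or inconsistent input data; CLI exit code 3."""


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: Path,
    subcommand: str,
    config: Mapping,
    inputs: Mapping[str, str | Path],
    seed: int,
) -> Path:
    manifest = {
        "subcommand": subcommand,
        "tool": "tadakit",
        "version": __version__,
        "config": dict(config),
        "seed": seed,
        "substream_seeds": {
            name: derive_seed(seed, name)
            for name in ("peaks.shuffle", "coloc.shuffle", "sim.genome",
                         "sim.binding", "sim.accessibility")
        },
        "inputs": {k: {"path": str(p), "sha256": _checksum(p)} for k, p in inputs.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = Path(outdir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def _validate_sample_sheet(config: Mapping) -> tuple[list[str], list[str]]:
    try:
        tf = list(config["samples"]["tf"])
        ctrl = list(config["samples"]["control"])
    except (KeyError, TypeError) as exc:
        raise ConfigError(
            "config must define samples.tf and samples.control replicate lists"
        ) from exc
    if not tf or not ctrl:
        raise ConfigError("need >= 1 TF and >= 1 control replicate")
    return tf, ctrl


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Run signal -> peaks -> annotate on the files named in `config`.

    Required keys: fasta, gff, samples: {tf: [...], control: [...]}.
    Optional: seed (default 0), fdr (default 0.05), upstream/downstream
    assignment limits. Failure in any stage raises a stage-tagged error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tf_paths, ctrl_paths = _validate_sample_sheet(config)
    for key in ("fasta", "gff"):
        if key not in config:
            raise ConfigError(f"missing config key {key!r}")
        if not Path(config[key]).exists():
            raise ConfigError(f"{key} file not found: {config[key]}")
    for p in (*tf_paths, *ctrl_paths):
        if not Path(p).exists():
            raise ConfigError(f"sample file not found: {p}")
    seed = int(config.get("seed", 0))

    try:
        genome, seqs = read_fasta(config["fasta"])
        fmap = build_fragment_map(seqs, genome)
        genes = read_gff(config["gff"], genome=genome)
    except ConfigError:
        raise
    except Exception as exc:
        raise DataError(f"[genome] {exc}") from exc

    try:
        tf_tracks = [
            count_reads_per_fragment(read_reads(p, genome), fmap, sample_id=f"tf_{i + 1}")
            for i, p in enumerate(tf_paths)
        ]
        ctrl_tracks = [
            count_reads_per_fragment(read_reads(p, genome), fmap, sample_id=f"control_{i + 1}")
            for i, p in enumerate(ctrl_paths)
        ]
        ratio = pairwise_ratio_profile(tf_tracks, ctrl_tracks)
        write_bedgraph(outdir / "ratio.bedgraph", fmap, ratio.scores)
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"[signal] {exc}") from exc

    try:
        pk_cfg = PeakCallConfig(
            fdr_threshold=float(config.get("fdr", 0.05)),
            seed=derive_seed(seed, "pipeline.peaks"),
        )
        peaks = call_peaks(ratio, fmap, pk_cfg)
        write_peaks_bed(outdir / "peaks.bed", peaks)
    except Exception as exc:
        raise DataError(f"[peaks] {exc}") from exc

    try:
        ann_cfg = AnnotationConfig(
            upstream_limit=int(config.get("upstream", 6000)),
            downstream_limit=int(config.get("downstream", 1000)),
        )
        assignments, unassigned = assign_peaks_to_genes(
            [p.interval() for p in peaks], genes, ann_cfg
        )
        with open(outdir / "assignments.tsv", "w") as fh:
            fh.write("peak\tgene\tdistance\tlocation\n")
            for a in assignments:
                fh.write(f"{a.peak_name}\t{a.gene_id}\t{a.distance}\t{a.location}\n")
        if assignments:
            location_summary(assignments).to_csv(outdir / "location_summary.tsv", sep="\t",
                                                 header=False)
    except Exception as exc:
        raise DataError(f"[annotate] {exc}") from exc

    inputs = {"fasta": config["fasta"], "gff": config["gff"]}
    inputs.update({f"tf_{i + 1}": p for i, p in enumerate(tf_paths)})
    inputs.update({f"control_{i + 1}": p for i, p in enumerate(ctrl_paths)})
    write_manifest(outdir, "run", dict(config), inputs, seed)
    return {
        "n_fragments": fmap.n_fragments,
        "n_peaks": len(peaks),
        "n_assignments": len(assignments),
        "n_unassigned_peaks": len(unassigned),
        "outdir": str(outdir),
    }
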