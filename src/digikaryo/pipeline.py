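"""End-to-end pipeline: genome -> tag DB -> extraction -> mapping -> calls.

One configuration drives every stage and a manifest records the parameter
echo, the seed and a checksum of every output, so re-running with the same
configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from ._util import read_fasta, write_fasta
from .cnv import (
    DEFAULT_AMP_THRESHOLD,
    DEFAULT_DEL_THRESHOLD,
    DEFAULT_WINDOW,
    annotate_genes,
    call_amplicons,
    scan_windows,
    write_calls_bed,
    write_calls_table,
    write_windows,
)
from .extract import extract_tags, write_tag_counts
from .mapping import map_tags, write_locus_counts, write_report
from .simulate import CnvSegment, SimConfig, make_genome, segments_to_bed, simulate_tag_reads
from .tagdb import build_virtual_tags, write_tagdb

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and parameters for one run.

    Either provide ``genome`` (FASTA path; reads likewise) or leave them
    unset to simulate both from ``sim``.
    """

    outdir: str = "dk_run"
    genome: str | None = None
    reads: str | None = None
    annotation: str | None = None
    window: int = DEFAULT_WINDOW
    amp_threshold: float = DEFAULT_AMP_THRESHOLD
    del_threshold: float = DEFAULT_DEL_THRESHOLD
    dedup: bool = True
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if not self.del_threshold < 1.0 < self.amp_threshold:
            raise ValueError("thresholds must satisfy del_threshold < 1 < amp_threshold")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        sim_raw = raw.pop("sim", {})
        profile = [CnvSegment(**s) for s in sim_raw.pop("cnv_profile", [])]
        return cls(**raw, sim=SimConfig(**sim_raw, cnv_profile=profile))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write stage outputs and a manifest; return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.genome is not None:
            stage = "load-genome"
            genome = read_fasta(config.genome)
        else:
            stage = "simulate-genome"
            sim = config.sim
            sim.seed = config.seed
            genome, _truth = make_genome(sim)
            write_fasta(genome.items(), out / "genome.fa")
            if sim.cnv_profile:
                segments_to_bed(sim.cnv_profile, out / "truth.bed")

        stage = "build-tagdb"
        tagdb = build_virtual_tags(genome)
        write_tagdb(tagdb, out / "tagdb.tsv")

        if config.reads is not None:
            stage = "load-reads"
            reads = config.reads
        else:
            stage = "simulate-reads"
            read_list, tagdb = simulate_tag_reads(genome, config.sim, tagdb)
            write_fasta(read_list, out / "reads.fa")
            reads = read_list

        stage = "extract-tags"
        observed, report = extract_tags(reads, dedup=config.dedup)
        write_tag_counts(observed, out / "tags.tsv")
        report.to_json(out / "extraction.json")

        stage = "map-tags"
        counts = map_tags(observed, tagdb)
        write_locus_counts(counts, out / "counts.tsv")
        write_report(counts, out / "mapping.json")

        stage = "detect-cnv"
        windows = scan_windows(counts, tagdb, window=config.window)
        write_windows(windows, out / "windows.tsv")
        calls = call_amplicons(windows, config.amp_threshold, config.del_threshold)
        if config.annotation is not None:
            calls = annotate_genes(calls, config.annotation)
        write_calls_bed(calls, out / "calls.bed")
        write_calls_table(calls, out / "calls.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    files = sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "window": config.window,
            "amp_threshold": config.amp_threshold,
            "del_threshold": config.del_threshold,
            "dedup": config.dedup,
            "sim": {k: v for k, v in asdict(config.sim).items()},
        },
        "outputs": {name: _sha256(out / name) for name in files},
        "n_calls": len(calls),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    for name in files:
        if (out / name).stat().st_size == 0:
            raise RuntimeError(f"output {name} is empty")
    return manifest
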