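"""End-to-end orchestration: simulate (or load) -> mask -> search ->
classify -> windowed scan -> junction validation -> expression -> report.

One JSON config mirrors every module's parameter object; a machine-readable
manifest records parameters, per-stage record counts and versions so a run
can be audited and reproduced.  Reruns with the same config are
byte-identical apart from the manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .classify import calls_to_frame, classify_scaffolds
from .containers import ScaffoldSet, TruthSet
from .errors import PipelineError
from .evaluation import score_candidates, score_contaminants
from .expression import classify_expression, expression_to_frame
from .homology import ScoringParams, build_index, search_all, write_tabular
from .io import (write_bed, write_bedgraph, write_fasta, write_pairs,
                 write_truth)
from .junctions import support_to_frame, validate_junctions
from .mask import MaskParams, mask_scaffold_set
from .report import length_histogram, summarize_genera
from .scan import (ScanParams, candidates_to_bed, candidates_to_frame,
                   candidates_to_gff3, run_scan)
from .simulate import Simulation, SimulationConfig, simulate

log = logging.getLogger("lgtscreen")


@dataclass
class PipelineConfig:
    """Single source of truth for a full run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    scan: ScanParams = field(default_factory=ScanParams)
    mask: MaskParams = field(default_factory=MaskParams)
    min_cov: float = 0.5
    min_overhang: int = 20
    min_spanning: int = 1
    min_bridging: int = 1
    expression_t0: float = 0.0
    expression_t1: float = 1.0

    def to_json(self) -> str:
        return json.dumps({
            "simulation": dataclasses.asdict(self.simulation),
            "scoring": dataclasses.asdict(self.scoring),
            "scan": dataclasses.asdict(self.scan),
            "mask": dataclasses.asdict(self.mask),
            "min_cov": self.min_cov,
            "min_overhang": self.min_overhang,
            "min_spanning": self.min_spanning,
            "min_bridging": self.min_bridging,
            "expression_t0": self.expression_t0,
            "expression_t1": self.expression_t1,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        return cls(
            simulation=SimulationConfig(**raw.get("simulation", {})),
            scoring=ScoringParams(**raw.get("scoring", {})),
            scan=ScanParams(**raw.get("scan", {})),
            mask=MaskParams(**raw.get("mask", {})),
            **{k: raw[k] for k in ("min_cov", "min_overhang", "min_spanning",
                                   "min_bridging", "expression_t0",
                                   "expression_t1") if k in raw})

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())


@dataclass
class PipelineResult:
    """In-memory view of a finished run (files are also on disk)."""

    config: PipelineConfig
    simulation: Simulation
    calls: list
    candidates: list
    supports: list
    expression_calls: list
    genus_summary: object
    histogram: object
    manifest: dict
    recovery: object = None
    contaminants: object = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %-20s %6.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig,
                 outdir: str | os.PathLike | None = None,
                 write_timestamp: bool = True) -> PipelineResult:
    """Execute every stage on a simulated study; write all artifacts.

    With ``outdir=None`` nothing touches disk and only the in-memory result
    is returned.
    """
    counts: dict[str, int] = {}
    sim = _stage("simulate")(simulate)(config.simulation)
    counts["scaffolds"] = len(sim.genome)
    counts["truth_implants"] = len(sim.truth.implants)
    counts["truth_contaminants"] = len(sim.truth.contaminants)
    counts["pairs"] = len(sim.pairs)

    masked_donors, mask_ivs = _stage("mask")(mask_scaffold_set)(
        sim.donors, config.mask, mode="soft")
    masked_animal, _ = _stage("mask-animal")(mask_scaffold_set)(
        sim.host_reference, config.mask, mode="soft")
    counts["mask_intervals"] = len(mask_ivs)

    bact_index = _stage("index-bacterial")(build_index)(
        masked_donors, config.scoring, db_class="bacterial")
    animal_index = _stage("index-animal")(build_index)(
        masked_animal, config.scoring, db_class="animal")

    bact_hits = _stage("search-bacterial")(search_all)(
        sim.genome, bact_index, config.scoring)
    animal_hits = _stage("search-animal")(search_all)(
        sim.genome, animal_index, config.scoring)
    counts["bacterial_hits"] = len(bact_hits)
    counts["animal_hits"] = len(animal_hits)

    calls = _stage("classify-scaffolds")(classify_scaffolds)(
        sim.genome, bact_hits, animal_hits, min_cov=config.min_cov)
    counts["scaffold_calls"] = len(calls)

    candidates = _stage("scan")(run_scan)(
        calls, sim.genome, bact_index, animal_index, config.scoring,
        config.scan)
    counts["candidates"] = len(candidates)

    supports = _stage("validate-junctions")(validate_junctions)(
        candidates, sim.pairs, min_overhang=config.min_overhang,
        s=config.min_spanning, p=config.min_bridging,
        scaffold_lengths=sim.genome.lengths)
    for c, sup in zip(candidates, supports):
        c.junction = sup
    counts["supported_candidates"] = sum(s.supported for s in supports)

    expr_calls = _stage("annotate-expression")(classify_expression)(
        candidates, sim.expression, t0=config.expression_t0,
        t1=config.expression_t1)
    for c, e in zip(candidates, expr_calls):
        c.expression = e
    counts["differential_candidates"] = sum(e.differential for e in expr_calls)

    genus = summarize_genera(candidates)
    hist = length_histogram(candidates, bin=10)

    manifest = {
        "tool": "lgtscreen",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.simulation.seed,
        "parameters": json.loads(config.to_json()),
        "record_counts": counts,
    }

    result = PipelineResult(
        config=config, simulation=sim, calls=calls, candidates=candidates,
        supports=supports, expression_calls=expr_calls, genus_summary=genus,
        histogram=hist, manifest=manifest,
        recovery=score_candidates(candidates, sim.truth),
        contaminants=score_contaminants(calls, sim.truth))

    if outdir is not None:
        _write_outputs(result, Path(outdir), bact_hits, animal_hits,
                       mask_ivs, write_timestamp)
    return result


def _write_outputs(result: PipelineResult, outdir: Path, bact_hits,
                   animal_hits, mask_ivs, write_timestamp: bool) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    sim = result.simulation
    write_fasta(sim.genome, outdir / "genome.fa")
    write_fasta(sim.donors, outdir / "donors.fa")
    write_fasta(sim.host_reference, outdir / "animal_db.fa")
    write_truth(sim.truth, outdir / "truth_implants.bed",
                outdir / "truth_contaminants.tsv")
    write_pairs(sim.pairs, outdir / "pairs.tsv")
    for cond, track in sim.expression.items():
        write_bedgraph(track, outdir / f"coverage_{cond}.bedgraph")
    write_bed([(iv.scaffold, iv.start, iv.end) for iv in mask_ivs],
              outdir / "mask.bed")
    write_tabular(bact_hits, outdir / "hits_bacterial.tsv")
    write_tabular(animal_hits, outdir / "hits_animal.tsv")
    calls_to_frame(result.calls).to_csv(
        outdir / "scaffold_calls.tsv", sep="\t", index=False)
    candidates_to_frame(result.candidates).to_csv(
        outdir / "candidates.tsv", sep="\t", index=False)
    write_bed(candidates_to_bed(result.candidates), outdir / "candidates.bed")
    (outdir / "candidates.gff3").write_text(
        "\n".join(candidates_to_gff3(result.candidates)) + "\n")
    support_to_frame(result.supports).to_csv(
        outdir / "junction_support.tsv", sep="\t", index=False)
    expression_to_frame(result.expression_calls).to_csv(
        outdir / "expression.tsv", sep="\t", index=False)
    result.genus_summary.to_frame().to_csv(
        outdir / "genus_summary.tsv", sep="\t", index=False)
    result.histogram.to_frame().to_csv(
        outdir / "length_histogram.tsv", sep="\t", index=False)

    manifest = dict(result.manifest)
    if write_timestamp:
        manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
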