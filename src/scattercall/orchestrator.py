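"""Scatter-gather pipeline orchestration with three synchronization barriers.

The execution flow mirrors a two-pass splice-aware variant-calling pipeline:

    split FASTQ into chunks
    -> parallel mapping pass 1 per chunk
    -> BARRIER 1: merge splice-junction tables, rebuild the genome index once
    -> parallel mapping pass 2 per chunk
    -> BARRIER 2: route alignments into static regions, profile read counts,
       refine to a dynamic partition, re-route
    -> parallel per-region variant calling
    -> BARRIER 3: merge per-region VCFs into the final call set

External stages (aligner, index rebuild, caller) are pluggable command
templates, so real tools and the bundled mocks run through the identical
mechanism.  A single-machine worker pool stands in for cluster executors:
the contract is independent tasks separated by barriers, not any particular
scheduler.  Shard naming is deterministic ({stage}/{name}.{index:04d}) and
every external-stage shard leaves a ``.ok`` marker on success, so an
interrupted run resumes from its completed artifacts and — because every
internal computation is deterministic — produces the same final VCF as a
clean run.
"""

from __future__ import annotations

import itertools
import json
import os
import shlex
import string
import subprocess
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from .balance import (
    RegionProfile,
    dynamic_partition,
    static_partition,
)
from .errors import PipelineError, ValidationError
from .genome import ReferenceDict, load_reference_index
from .stage_io import merge_splice_junctions, merge_vcf, read_sam, route_sam, split_fastq

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline"]

STAGE_PLACEHOLDERS = {
    "map_pass1": {"input", "index", "output"},
    "index_rebuild": {"input", "output"},
    "map_pass2": {"input", "index", "output"},
    "per_region_call": {"input", "region_bed", "output"},
}
OPTIONAL_PLACEHOLDERS = {"input2", "index", "reference", "region_bed"}


@dataclass
class PipelineConfig:
    """Validated, normalized pipeline configuration."""

    reference_index: Path
    inputs: list[Path]
    index: Path  # initial genome index directory
    stages: dict[str, str]  # stage name -> command template
    workdir: Path
    num_regions: int = 1
    workers: int = 1
    n_chunks: int | None = None  # defaults to workers
    reference_fasta: Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chunks is None:
            # chunk count follows the available parallelism by default
            self.n_chunks = self.workers
        if self.n_chunks < 1 or self.num_regions < 1 or self.workers < 1:
            raise ValidationError("n_chunks, num_regions and workers must be >= 1")

    def snapshot(self) -> dict:
        d = asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()} | {
            "inputs": [str(p) for p in self.inputs]
        }


def _template_placeholders(template: str) -> set[str]:
    return {
        name
        for _, name, _, _ in string.Formatter().parse(template)
        if name is not None
    }


def validate_config(source: str | os.PathLike | dict) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline config file (or parsed dict).

    Checks that referenced paths exist and that every stage command template
    contains its required placeholders; fills defaults (``n_chunks``
    defaults to the worker count — one chunk per available thread).
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
        base = Path(source).parent
    else:
        raw, base = dict(source), Path(".")
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")

    def _path(key: str, required: bool = True) -> Path | None:
        if key not in raw or raw[key] is None:
            if required:
                raise ValidationError(f"config is missing required key {key!r}")
            return None
        p = Path(raw[key])
        if not p.is_absolute():
            p = base / p
        return p

    reference_index = _path("reference_index")
    index = _path("index")
    reference_fasta = _path("reference_fasta", required=False)
    inputs = raw.get("inputs") or []
    if not 1 <= len(inputs) <= 2:
        raise ValidationError("config must name 1 or 2 FASTQ inputs")
    input_paths = []
    for p in inputs:
        p = Path(p)
        if not p.is_absolute():
            p = base / p
        input_paths.append(p)

    for p in [reference_index, index, *input_paths] + (
        [reference_fasta] if reference_fasta else []
    ):
        if not Path(p).exists():
            raise ValidationError(f"configured path does not exist: {p}")

    stages = raw.get("stages") or {}
    for stage, required in STAGE_PLACEHOLDERS.items():
        if stage not in stages:
            raise ValidationError(f"config is missing stage command {stage!r}")
        present = _template_placeholders(stages[stage])
        missing = required - present
        if missing:
            raise ValidationError(
                f"stage {stage!r} template lacks placeholder(s): "
                + ", ".join(sorted("{%s}" % m for m in missing))
            )
        unknown = present - required - OPTIONAL_PLACEHOLDERS
        if unknown:
            raise ValidationError(
                f"stage {stage!r} template has unknown placeholder(s): "
                + ", ".join(sorted(unknown))
            )
        if len(input_paths) == 2 and stage in ("map_pass1", "map_pass2") and (
            "input2" not in present
        ):
            raise ValidationError(
                f"paired inputs configured but stage {stage!r} template lacks {{input2}}"
            )

    workers = int(raw.get("workers", 1))
    return PipelineConfig(
        reference_index=reference_index,
        inputs=input_paths,
        index=index,
        stages=dict(stages),
        workdir=_path("workdir") if "workdir" in raw else Path("scattercall_run"),
        num_regions=int(raw.get("num_regions", 1)),
        workers=workers,
        n_chunks=int(raw["n_chunks"]) if raw.get("n_chunks") is not None else None,
        reference_fasta=reference_fasta,
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class StageRecord:
    name: str
    status: str = "pending"  # pending | running | done | failed
    started: float | None = None
    finished: float | None = None
    shards: list[dict] = field(default_factory=list)
    info: dict = field(default_factory=dict)


@dataclass
class RunManifest:
    """Inventory of a pipeline run: stage status, artifacts, region counts."""

    config: dict
    stages: list[StageRecord] = field(default_factory=list)
    rslb: int | None = None
    rdlb: int | None = None
    n_reads_mapped: int | None = None
    n_reads_unmapped: int | None = None
    final_vcf: str | None = None
    status: str = "running"

    def stage(self, name: str) -> StageRecord:
        for s in self.stages:
            if s.name == name:
                return s
        rec = StageRecord(name)
        self.stages.append(rec)
        return rec

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "status": self.status,
            "config": self.config,
            "rslb": self.rslb,
            "rdlb": self.rdlb,
            "n_reads_mapped": self.n_reads_mapped,
            "n_reads_unmapped": self.n_reads_unmapped,
            "final_vcf": self.final_vcf,
            "stages": [asdict(s) for s in self.stages],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _run_command(cmd: str) -> subprocess.CompletedProcess:
    return subprocess.run(
        shlex.split(cmd), capture_output=True, text=True
    )


def _run_shards(
    manifest: RunManifest,
    stage: StageRecord,
    jobs: list[tuple[int, str, list[Path]]],  # (shard index, command, outputs)
    workers: int,
    manifest_path: Path,
) -> None:
    """Run external-command shards on the worker pool with resume markers."""
    stage.status = "running"
    stage.started = time.time()

    def one(job: tuple[int, str, list[Path]]) -> dict:
        idx, cmd, outputs = job
        marker = Path(str(outputs[0]) + ".ok")
        shard = {"index": idx, "cmd": cmd, "outputs": [str(o) for o in outputs]}
        if marker.exists() and all(o.exists() for o in outputs):
            shard["status"] = "done"
            shard["resumed"] = True
            return shard
        proc = _run_command(cmd)
        if proc.returncode != 0 or not all(o.exists() for o in outputs):
            shard["status"] = "failed"
            shard["returncode"] = proc.returncode
            shard["stderr"] = proc.stderr[-2000:]
        else:
            marker.touch()
            shard["status"] = "done"
        return shard

    with ThreadPoolExecutor(max_workers=workers) as pool:
        shards = list(pool.map(one, jobs))
    stage.shards = sorted(shards, key=lambda s: s["index"])
    stage.finished = time.time()
    failed = [s for s in shards if s["status"] == "failed"]
    if failed:
        stage.status = "failed"
        manifest.status = "failed"
        manifest.to_json(manifest_path)
        first = failed[0]
        raise PipelineError(
            f"stage {stage.name!r} failed on shard {first['index']} "
            f"(exit {first.get('returncode')}): {first.get('stderr', '')[:500]}"
        )
    stage.status = "done"


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full scatter-gather flow and return the run manifest.

    Aborts at the current barrier if any stage command exits nonzero; all
    intermediate artifacts are preserved and a rerun with the same config
    resumes from completed shards.  With deterministic stage commands,
    identical config and seed yield a byte-identical final VCF.
    """
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    manifest_path = wd / "manifest.json"
    manifest = RunManifest(config=config.snapshot())
    ref = load_reference_index(config.reference_index)

    def fmt(stage: str, **kw) -> str:
        kw.setdefault("reference", str(config.reference_fasta or ""))
        kw.setdefault("index", "")
        return config.stages[stage].format(**kw)

    # Static plan needs only the reference, so it is available from the start.
    static_plan = static_partition(ref, config.num_regions)
    manifest.rslb = static_plan.rslb

    # --- scatter: FASTQ chunking -------------------------------------------
    st = manifest.stage("split_fastq")
    st.status, st.started = "running", time.time()
    chunks = split_fastq(config.inputs, config.n_chunks, wd / "chunks")
    st.finished, st.status = time.time(), "done"
    st.info = {"n_chunks": len(chunks)}

    # --- mapping pass 1 -----------------------------------------------------
    pass1 = wd / "pass1"
    pass1.mkdir(exist_ok=True)
    jobs = []
    for i, chunk in enumerate(chunks):
        prefix = pass1 / f"chunk_{i:04d}"
        kw = {"input": chunk[0], "index": config.index, "output": prefix}
        if len(chunk) == 2:
            kw["input2"] = chunk[1]
        jobs.append(
            (i, fmt("map_pass1", **kw),
             [Path(str(prefix) + ".sam"), Path(str(prefix) + ".SJ.out.tab")])
        )
    _run_shards(manifest, manifest.stage("map_pass1"), jobs, config.workers, manifest_path)

    # --- barrier 1: merge splice junctions, rebuild index (once) ------------
    st = manifest.stage("merge_sj")
    st.status, st.started = "running", time.time()
    sj_inputs = [pass1 / f"chunk_{i:04d}.SJ.out.tab" for i in range(len(chunks))]
    sj_merged = wd / "SJ.merged.tab"
    rows = merge_splice_junctions(sj_inputs, sj_merged, ref)
    st.finished, st.status = time.time(), "done"
    st.info = {"n_junctions": len(rows), "output": str(sj_merged)}

    index2 = wd / "index2"
    _run_shards(
        manifest,
        manifest.stage("index_rebuild"),
        [(0, fmt("index_rebuild", input=sj_merged, index=config.index, output=index2),
          [index2])],
        1,  # strictly sequential step
        manifest_path,
    )

    # --- mapping pass 2 -----------------------------------------------------
    pass2 = wd / "pass2"
    pass2.mkdir(exist_ok=True)
    jobs = []
    for i, chunk in enumerate(chunks):
        prefix = pass2 / f"chunk_{i:04d}"
        kw = {"input": chunk[0], "index": index2, "output": prefix}
        if len(chunk) == 2:
            kw["input2"] = chunk[1]
        jobs.append((i, fmt("map_pass2", **kw), [Path(str(prefix) + ".sam")]))
    _run_shards(manifest, manifest.stage("map_pass2"), jobs, config.workers, manifest_path)

    # --- barrier 2: route, profile, dynamic refinement, re-route ------------
    st = manifest.stage("route_and_balance")
    st.status, st.started = "running", time.time()
    pass2_records = itertools.chain.from_iterable(
        read_sam(pass2 / f"chunk_{i:04d}.sam") for i in range(len(chunks))
    )
    static_dir = wd / "routed_static"
    static_route = route_sam(pass2_records, static_plan.region_set, static_dir)
    profile = RegionProfile(
        static_plan.region_set,
        static_route.counts,
        static_route.n_unmapped,
        static_route.positions,
    )
    dynamic_plan = dynamic_partition(profile)
    manifest.rdlb = dynamic_plan.rdlb
    manifest.n_reads_mapped = static_route.n_mapped
    manifest.n_reads_unmapped = static_route.n_unmapped

    static_records = itertools.chain.from_iterable(
        read_sam(static_route.files[i]) for i in sorted(static_route.files)
    )
    routed_dir = wd / "routed"
    dynamic_route = route_sam(static_records, dynamic_plan.region_set, routed_dir)
    if dynamic_route.n_mapped != static_route.n_mapped:
        raise PipelineError(
            "read conservation violated during re-routing: "
            f"{static_route.n_mapped} -> {dynamic_route.n_mapped}"
        )
    beds = wd / "beds"
    beds.mkdir(exist_ok=True)
    static_plan.region_set.to_bed(wd / "regions_static.bed")
    dynamic_plan.region_set.to_bed(wd / "regions_dynamic.bed")
    for region in dynamic_plan.region_set:
        with open(beds / f"region_{region.index:04d}.bed", "w") as fh:
            fh.write(f"{region.contig}\t{region.start}\t{region.end}\t{region.name}\n")
    st.finished, st.status = time.time(), "done"
    st.info = {
        "rslb": static_plan.rslb,
        "rdlb": dynamic_plan.rdlb,
        "n_mapped": static_route.n_mapped,
        "n_unmapped": static_route.n_unmapped,
        "per_region_counts": dynamic_route.counts,
    }

    # --- per-region variant calling ----------------------------------------
    vcf_dir = wd / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    jobs = []
    for region in dynamic_plan.region_set:
        out = vcf_dir / f"region_{region.index:04d}.vcf"
        jobs.append(
            (region.index,
             fmt(
                 "per_region_call",
                 input=dynamic_route.files[region.index],
                 region_bed=beds / f"region_{region.index:04d}.bed",
                 output=out,
             ),
             [out])
        )
    _run_shards(
        manifest, manifest.stage("per_region_call"), jobs, config.workers, manifest_path
    )

    # --- barrier 3: merge VCFs ----------------------------------------------
    st = manifest.stage("merge_vcf")
    st.status, st.started = "running", time.time()
    final_vcf = wd / "final.vcf"
    stats = merge_vcf(
        [vcf_dir / f"region_{r.index:04d}.vcf" for r in dynamic_plan.region_set],
        ref,
        final_vcf,
    )
    st.finished, st.status = time.time(), "done"
    st.info = stats | {"output": str(final_vcf)}

    manifest.final_vcf = str(final_vcf)
    manifest.status = "done"
    manifest.to_json(manifest_path)
    return manifest
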