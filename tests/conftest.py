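"""Shared fixtures: small synthetic references, reads, and mock stage commands."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

import scattercall as sc
from scattercall import simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_sam_line(
    qname: str,
    contig: str | None,
    pos: int,
    flag: int | None = None,
    seq: str = "ACGT",
) -> str:
    """A minimal valid SAM line (1-based pos; contig None means unmapped)."""
    if flag is None:
        flag = 0 if contig is not None else 0x4
    rname = contig if contig is not None else "*"
    return (
        f"{qname}\t{flag}\t{rname}\t{pos}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t"
        + "I" * len(seq)
    )


def stage_templates() -> dict[str, str]:
    """Command templates driving the bundled mock tools via the CLI."""
    py = sys.executable
    mod = f"{py} -m scattercall.cli"
    return {
        "map_pass1": f"{mod} mock-align {{input}} --index {{index}} --out {{output}}",
        "index_rebuild": f"{mod} mock-index {{input}} --index {{index}} --out {{output}}",
        "map_pass2": f"{mod} mock-align {{input}} --index {{index}} --out {{output}}",
        "per_region_call": (
            f"{mod} mock-call {{input}} --bed {{region_bed}} "
            f"--reference {{reference}} --out {{output}}"
        ),
    }


def boundary_guard(
    ref: sc.ReferenceDict, num_regions_values: tuple[int, ...], guard: int
) -> dict[str, list[tuple[int, int]]]:
    """Intervals within ``guard`` bp of any static region boundary.

    With uniformly sampled reads the dynamic balancer performs no splits
    (no region reaches twice the mean load), so keeping planted variants
    out of these bands keeps them at least one read length away from every
    region cut point of every tested partition.
    """
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for nr in num_regions_values:
        plan = sc.static_partition(ref, nr)
        for r in plan.region_set:
            for b in (r.start, r.end):
                forbidden.setdefault(r.contig, []).append(
                    (max(0, b - guard), b + guard)
                )
    return forbidden


@pytest.fixture(scope="session")
def small_ref(tmp_path_factory) -> dict:
    """A 2-contig 14 kb reference for fast unit tests."""
    out = tmp_path_factory.mktemp("smallref")
    fasta, fai = simulate.gen_reference([8000, 6000], seed=11, out_dir=out)
    return {"fasta": fasta, "fai": fai, "ref": sc.load_reference_index(fai)}


@pytest.fixture(scope="session")
def small_pipeline_fixture(tmp_path_factory, small_ref) -> dict:
    """Reads + truth for quick orchestrator tests (read length 50, 10x)."""
    out = tmp_path_factory.mktemp("smallreads")
    guard = boundary_guard(small_ref["ref"], (1, 2, 3), guard=60)
    truth = simulate.make_truth_set(
        small_ref["fasta"], 8, seed=11, fraction=1.0, read_length=50,
        coverage=10.0, forbidden=guard,
    )
    fastqs, truth_vcf = simulate.gen_reads(truth, out)
    index = simulate.init_index(small_ref["fai"], out / "index1")
    return {
        **small_ref,
        "truth": truth,
        "fastqs": fastqs,
        "truth_vcf": truth_vcf,
        "index": index,
    }


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory) -> dict:
    """The partition-invariance study: 2 contigs x 50 kb, 30x coverage,
    20 planted allele-fraction-1.0 SNVs clear of all tested region cuts."""
    out = tmp_path_factory.mktemp("study")
    fasta, fai = simulate.gen_reference([50000, 50000], seed=7, out_dir=out)
    ref = sc.load_reference_index(fai)
    guard = boundary_guard(ref, (1, 3, 7), guard=110)
    truth = simulate.make_truth_set(
        fasta, 20, seed=7, fraction=1.0, read_length=100, coverage=30.0,
        forbidden=guard,
    )
    fastqs, truth_vcf = simulate.gen_reads(truth, out / "reads")
    index = simulate.init_index(fai, out / "index1")
    return {
        "fasta": fasta,
        "fai": fai,
        "ref": ref,
        "truth": truth,
        "fastqs": fastqs,
        "truth_vcf": truth_vcf,
        "index": index,
    }


def pipeline_config(fx: dict, workdir: Path, **overrides) -> dict:
    cfg = {
        "reference_index": str(fx["fai"]),
        "reference_fasta": str(fx["fasta"]),
        "inputs": [str(p) for p in fx["fastqs"]],
        "index": str(fx["index"]),
        "num_regions": 3,
        "workers": 1,
        "workdir": str(workdir),
        "seed": 1,
        "stages": stage_templates(),
    }
    cfg.update(overrides)
    return cfg
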