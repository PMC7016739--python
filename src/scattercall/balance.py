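"""Two-stage genomic load balancing.

The genome is first partitioned *statically*, using only contig sizes: with a
requested region count ``num_regions`` the target region size is

    avg_size_static = total_genome_bp / num_regions

and a contig of length L is cut into ``k = max(1, floor(L / avg_size_static))``
equal pieces (remainder to the last piece).  Every contig keeps at least one
region, so the realized region count RsLB is >= max(num_regions, n_contigs)
and usually exceeds the request on real genomes, where many small contigs
each claim a region of their own.

After alignment, the observed per-region mapped-read counts refine the plan
*dynamically*: with total routed reads N over RsLB static regions the target
per-region load is

    avg_size_dynamic = N / RsLB

and a region holding n reads is split into ``k = floor(n / avg_size_dynamic)``
sub-regions when k >= 2, with cut points at read-count quantiles so that
sub-region loads differ by at most one read (plus ties at the cut
coordinate).  RNA-seq coverage is concentrated in expressed regions, so the
dynamic pass typically creates substantially more regions than the static
one and caps the maximum per-region load, which bounds the critical path of
the downstream per-region calling stage.

Averages are kept as exact rationals; flooring happens only when computing k,
so exact multiples never fall prey to float rounding.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .errors import RoutingError, ValidationError
from .genome import ReferenceDict, Region, RegionSet

__all__ = [
    "StaticPlan",
    "RegionProfile",
    "DynamicPlan",
    "BalanceReport",
    "avg_size_static",
    "static_partition",
    "profile_regions",
    "avg_size_dynamic",
    "dynamic_partition",
    "balance_report",
]


@dataclass
class StaticPlan:
    """Size-based partition of a reference into regions."""

    ref: ReferenceDict
    num_regions: int
    avg_size: Fraction
    region_set: RegionSet

    @property
    def rslb(self) -> int:
        """Number of regions actually created (>= the request)."""
        return len(self.region_set)


@dataclass
class RegionProfile:
    """Observed read load per region of a plan.

    ``positions`` optionally carries the sorted 0-based leftmost mapping
    positions of the reads in each region, which the dynamic partitioner
    needs to place quantile cuts.
    """

    region_set: RegionSet
    counts: list[int]
    unmapped: int = 0
    positions: list[list[int]] | None = None

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.region_set):
            raise ValidationError(
                f"{len(self.counts)} counts for {len(self.region_set)} regions"
            )
        if any(c < 0 for c in self.counts):
            raise ValidationError("negative region count")
        if self.positions is not None:
            for i, (c, p) in enumerate(zip(self.counts, self.positions)):
                if len(p) != c:
                    raise ValidationError(
                        f"region {i}: {len(p)} positions for count {c}"
                    )

    @property
    def total_reads(self) -> int:
        """Total routed reads (the dynamic balancer's numerator)."""
        return sum(self.counts)


@dataclass
class DynamicPlan:
    """Read-count-based refinement of a static plan."""

    profile: RegionProfile
    avg_size: Fraction
    region_set: RegionSet
    parents: list[int]  # static region index of each dynamic region

    @property
    def rslb(self) -> int:
        return len(self.profile.region_set)

    @property
    def rdlb(self) -> int:
        """Number of regions after dynamic refinement (>= RsLB)."""
        return len(self.region_set)


def avg_size_static(ref: ReferenceDict, num_regions: int) -> Fraction:
    """Target static region size in base pairs (exact rational)."""
    if num_regions < 1:
        raise ValidationError(f"num_regions must be >= 1, got {num_regions}")
    return Fraction(ref.total_size, num_regions)


def static_partition(ref: ReferenceDict, num_regions: int) -> StaticPlan:
    """Partition a reference by contig size alone.

    Each contig of length L yields ``max(1, floor(L / avg_size_static))``
    equal-length regions, remainder base pairs going to the last region of
    the contig.  Regions exactly tile the reference.
    """
    avg = avg_size_static(ref, num_regions)
    regions: list[Region] = []
    index = 0
    for name, length in ref.contigs:
        # floor of the exact ratio; capped at L so no piece is empty when
        # the requested region count exceeds the genome size
        k = max(1, min(length, int(Fraction(length) / avg)))
        base = length // k
        cursor = 0
        for piece in range(k):
            end = cursor + base if piece < k - 1 else length
            regions.append(Region(name, cursor, end, index))
            cursor = end
            index += 1
    region_set = RegionSet(regions, ref, level="static", requested=num_regions)
    return StaticPlan(ref, num_regions, avg, region_set)


def profile_regions(
    records: Iterable,
    plan: StaticPlan,
    keep_positions: bool = True,
) -> RegionProfile:
    """Count mapped reads per region of a static plan.

    ``records`` yields objects with ``contig`` (None when unmapped) and
    ``pos`` (1-based leftmost mapping position) attributes, e.g.
    :class:`scattercall.stage_io.SamRecord`.  Each mapped record increments
    exactly one region — the one containing its 0-based leftmost position.
    Unmapped records are tallied separately and excluded from the profile.
    """
    rs = plan.region_set
    counts = [0] * len(rs)
    positions: list[list[int]] | None = (
        [[] for _ in range(len(rs))] if keep_positions else None
    )
    unmapped = 0
    for rec in records:
        if rec.contig is None:
            unmapped += 1
            continue
        if rec.contig not in plan.ref:
            raise RoutingError(f"record on unknown contig {rec.contig!r}")
        pos0 = rec.pos - 1
        idx = rs.locate(rec.contig, pos0)
        counts[idx] += 1
        if positions is not None:
            positions[idx].append(pos0)
    if positions is not None:
        for p in positions:
            p.sort()
    return RegionProfile(rs, counts, unmapped, positions)


def avg_size_dynamic(profile: RegionProfile) -> Fraction:
    """Target per-region read load (exact rational): total reads / RsLB."""
    rslb = len(profile.region_set)
    if rslb < 1:
        raise ValidationError("profile has no regions")
    return Fraction(profile.total_reads, rslb)


def _quantile_cuts(positions: Sequence[int], k: int, start: int, end: int) -> list[int]:
    """Coordinate cut points splitting [start, end) into k read-balanced pieces.

    The j-th cut (j = 1..k-1) falls between the read ranked ceil(j*n/k)
    (1-based) and the next read, at the latter's start coordinate, so each
    piece holds n/k reads up to +-1 where positions are distinct.  A cut must
    lie strictly between two distinct read starts: when reads are tied across
    the quantile rank the cut shifts forward past the tie run (inflating the
    left piece by the run length), and a region whose reads all share one
    coordinate is never split.
    """
    import bisect

    n = len(positions)
    cuts: list[int] = []
    prev = start
    for j in range(1, k):
        idx = -(-j * n // k)  # ceil(j*n/k), 0-based rank of the "next" read
        if idx >= n:
            break
        if positions[idx] == positions[idx - 1]:
            # shift past the tie run to the next distinct coordinate
            idx = bisect.bisect_right(positions, positions[idx])
            if idx >= n:
                break
        c = positions[idx]
        if prev < c < end:
            cuts.append(c)
            prev = c
    return cuts


def dynamic_partition(
    profile: RegionProfile,
    positions: Sequence[Sequence[int]] | None = None,
) -> DynamicPlan:
    """Refine a static partition using observed read loads.

    A region with n reads is split into ``k = floor(n / avg_size_dynamic)``
    sub-regions when k >= 2, cutting at read-count quantiles; otherwise it is
    kept whole.  Every resulting region is wholly contained in exactly one
    parent region, sub-regions tile their parent exactly, and the refined
    count RdLB is >= RsLB.
    """
    if positions is None:
        positions = profile.positions
    if positions is None:
        raise ValidationError("per-region read positions are required")
    if len(positions) != len(profile.region_set):
        raise ValidationError("positions length does not match region count")
    for i, (c, p) in enumerate(zip(profile.counts, positions)):
        if len(p) != c:
            raise ValidationError(f"region {i}: {len(p)} positions for count {c}")

    avg = avg_size_dynamic(profile)
    total = profile.total_reads
    if avg == 0 and total > 0:
        raise ValidationError("zero target load with nonzero read counts")

    regions: list[Region] = []
    parents: list[int] = []
    index = 0
    for parent_idx, parent in enumerate(profile.region_set):
        n = profile.counts[parent_idx]
        k = int(Fraction(n) / avg) if avg > 0 else 1
        cuts: list[int] = []
        if k >= 2:
            cuts = _quantile_cuts(positions[parent_idx], k, parent.start, parent.end)
        bounds = [parent.start, *cuts, parent.end]
        for lo, hi in zip(bounds, bounds[1:]):
            regions.append(Region(parent.contig, lo, hi, index))
            parents.append(parent_idx)
            index += 1
    region_set = RegionSet(
        regions,
        profile.region_set.ref,
        level="dynamic",
        requested=profile.region_set.requested,
    )
    return DynamicPlan(profile, avg, region_set, parents)


@dataclass
class BalanceReport:
    """Deterministic summary of per-region load for before/after comparison."""

    values: list[int]
    kind: str  # "reads" or "bp"
    min: int
    max: int
    mean: float
    hist_counts: list[int]
    hist_edges: list[float]

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = json.dumps(
            {
                "kind": self.kind,
                "n_regions": len(self.values),
                "min": self.min,
                "max": self.max,
                "mean": self.mean,
                "values": self.values,
                "hist_counts": self.hist_counts,
                "hist_edges": self.hist_edges,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    def to_tsv(self, path: str | os.PathLike | None = None) -> str:
        lines = ["region\t" + self.kind]
        lines += [f"{i}\t{v}" for i, v in enumerate(self.values)]
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def balance_report(source, bins: int = 10) -> BalanceReport:
    """Summarize per-region load.

    ``source`` may be a :class:`RegionProfile` (read counts), a
    :class:`StaticPlan` / :class:`RegionSet` (region sizes in bp), or a bare
    sequence of counts.
    """
    if isinstance(source, RegionProfile):
        values, kind = list(source.counts), "reads"
    elif isinstance(source, StaticPlan):
        values, kind = [r.size for r in source.region_set], "bp"
    elif isinstance(source, DynamicPlan):
        values, kind = [r.size for r in source.region_set], "bp"
    elif isinstance(source, RegionSet):
        values, kind = [r.size for r in source], "bp"
    else:
        values, kind = [int(v) for v in source], "reads"
    if not values:
        return BalanceReport([], kind, 0, 0, 0.0, [], [])
    arr = np.asarray(values)
    hist, edges = np.histogram(arr, bins=bins)
    return BalanceReport(
        values,
        kind,
        int(arr.min()),
        int(arr.max()),
        float(arr.mean()),
        hist.tolist(),
        edges.tolist(),
    )
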