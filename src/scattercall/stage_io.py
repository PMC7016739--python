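"""Stage I/O: FASTQ chunking, splice-junction merging, SAM routing, VCF merging.

These are the data-movement computations at the pipeline's three
synchronization barriers.  Records are handled at the text level and carry
their verbatim source line, because the contracts here are byte-level:
concatenating FASTQ chunks reproduces the input exactly, routed SAM lines are
byte-identical to their source, and a merged VCF preserves data lines
verbatim.  Only the few fields the routing and merge rules need are parsed.
"""

from __future__ import annotations

import heapq
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import ParseError, RoutingError, ValidationError
from .genome import ReferenceDict, RegionSet

__all__ = [
    "SamRecord",
    "SpliceJunction",
    "VariantRecord",
    "read_sam",
    "read_sam_header",
    "read_vcf_records",
    "split_fastq",
    "merge_splice_junctions",
    "route_sam",
    "RouteResult",
    "merge_vcf",
]

FLAG_UNMAPPED = 0x4


@dataclass(frozen=True)
class SamRecord:
    """Minimal alignment record: just enough to route, plus the raw line."""

    qname: str
    flag: int
    contig: str | None  # None when unmapped
    pos: int  # 1-based leftmost mapping position (0 when unmapped)
    raw: str  # verbatim SAM line, no trailing newline

    @classmethod
    def from_line(cls, line: str, lineno: int | None = None) -> "SamRecord":
        raw = line.rstrip("\n")
        fields = raw.split("\t")
        if len(fields) < 11:
            raise ParseError(
                f"SAM record has {len(fields)} fields, expected >= 11", lineno
            )
        try:
            flag = int(fields[1])
            pos = int(fields[3])
        except ValueError:
            raise ParseError("non-integer FLAG or POS field", lineno) from None
        contig: str | None = fields[2]
        if flag & FLAG_UNMAPPED or contig == "*":
            contig = None
        return cls(fields[0], flag, contig, pos, raw)

    @property
    def is_mapped(self) -> bool:
        return self.contig is not None


@dataclass(frozen=True)
class SpliceJunction:
    """One row of a 9-column splice-junction table (SJ.out.tab layout).

    Intron coordinates are 1-based inclusive.  The key identifying a junction
    is (contig, intron_start, intron_end, strand, motif); support counts are
    additive across files while overhang and annotation status take the max.
    """

    contig: str
    intron_start: int
    intron_end: int
    strand: int  # 0 undefined, 1 +, 2 -
    motif: int  # 0-6
    annotated: int  # 0 novel, 1 annotated
    n_unique: int
    n_multi: int
    max_overhang: int

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValidationError(
                f"intron start {self.intron_start} > end {self.intron_end}"
            )

    @property
    def key(self) -> tuple:
        return (self.contig, self.intron_start, self.intron_end, self.strand, self.motif)

    @classmethod
    def from_line(cls, line: str, lineno: int | None = None) -> "SpliceJunction":
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise ParseError(
                f"splice-junction row has {len(fields)} columns, expected 9", lineno
            )
        try:
            ints = [int(f) for f in fields[1:]]
        except ValueError:
            raise ParseError("non-integer splice-junction column", lineno) from None
        return cls(fields[0], *ints)

    def to_line(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.contig,
                self.intron_start,
                self.intron_end,
                self.strand,
                self.motif,
                self.annotated,
                self.n_unique,
                self.n_multi,
                self.max_overhang,
            )
        )


@dataclass(frozen=True)
class VariantRecord:
    """A VCF data line reduced to its matching key plus the verbatim line."""

    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    raw: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


def read_sam_header(path: str | os.PathLike) -> list[str]:
    """Return the @-prefixed header lines of a SAM file (with newlines)."""
    header = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("@"):
                break
            header.append(line)
    return header


def read_sam(path: str | os.PathLike) -> Iterator[SamRecord]:
    """Iterate alignment records of a SAM file, skipping header lines."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("@") or not line.strip():
                continue
            yield SamRecord.from_line(line, i)


def read_vcf_records(path: str | os.PathLike) -> Iterator[VariantRecord]:
    """Iterate VCF data lines as variant records.

    Multi-allelic lines are split into one record per alt allele, each
    sharing the original raw line.
    """
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            raw = line.rstrip("\n")
            fields = raw.split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"VCF data line has {len(fields)} fields, expected >= 8", i
                )
            try:
                pos = int(fields[1])
            except ValueError:
                raise ParseError(f"non-integer POS {fields[1]!r}", i) from None
            ref = fields[3]
            if not ref:
                raise ParseError("empty REF allele", i)
            for alt in fields[4].split(","):
                if not alt:
                    raise ParseError("empty ALT allele", i)
                yield VariantRecord(fields[0], pos, ref, alt, raw)


# ---------------------------------------------------------------------------
# FASTQ chunking
# ---------------------------------------------------------------------------

def _fastq_records(path: str | os.PathLike) -> Iterator[list[str]]:
    """Yield 4-line FASTQ records (lines keep their newlines)."""
    with open(path) as fh:
        while True:
            block = [fh.readline() for _ in range(4)]
            if not block[0]:
                return
            if not all(block) :
                raise ParseError(
                    "truncated FASTQ record (file length not a multiple of 4 lines)"
                )
            if not block[0].startswith("@") or not block[2].startswith("+"):
                raise ParseError("malformed FASTQ record structure")
            yield block


def _count_fastq(path: str | os.PathLike) -> int:
    return sum(1 for _ in _fastq_records(path))


def split_fastq(
    inputs: Sequence[str | os.PathLike],
    n_chunks: int,
    out_dir: str | os.PathLike,
) -> list[tuple[Path, ...]]:
    """Split one (single-end) or two (paired-end) FASTQ files into chunks.

    Records are distributed in contiguous blocks of ``ceil(total/n_chunks)``
    records, so every chunk but possibly the last is full-sized and
    concatenating the chunks reproduces each input byte-identically.  Paired
    files are cut at identical record indices so mates stay aligned.
    Fewer than ``n_chunks`` files result when the input is too small.
    """
    if n_chunks < 1:
        raise ValidationError(f"n_chunks must be >= 1, got {n_chunks}")
    if not 1 <= len(inputs) <= 2:
        raise ValidationError(f"expected 1 or 2 FASTQ inputs, got {len(inputs)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    totals = [_count_fastq(p) for p in inputs]
    if len(set(totals)) > 1:
        raise ValidationError(
            f"paired FASTQ files have unequal record counts: {totals[0]} != {totals[1]}"
        )
    total = totals[0]
    chunk_size = -(-total // n_chunks) if total else 0

    chunk_paths: list[list[Path]] = []
    for mate, path in enumerate(inputs, start=1):
        paths: list[Path] = []
        writer = None
        written = 0
        try:
            for i, block in enumerate(_fastq_records(path)):
                if i % chunk_size == 0:
                    if writer:
                        writer.close()
                    out = out_dir / f"chunk_{len(paths):04d}.R{mate}.fastq"
                    writer = open(out, "w")
                    paths.append(out)
                writer.writelines(block)
                written += 1
        finally:
            if writer:
                writer.close()
        chunk_paths.append(paths)
    if total == 0:
        return []
    return [tuple(mates) for mates in zip(*chunk_paths)]


# ---------------------------------------------------------------------------
# Splice-junction merging
# ---------------------------------------------------------------------------

def merge_splice_junctions(
    inputs: Sequence[str | os.PathLike],
    out_path: str | os.PathLike,
    ref: ReferenceDict | None = None,
) -> list[SpliceJunction]:
    """Merge splice-junction tables into one, aggregating duplicate keys.

    Support counts (unique- and multi-mapping) are summed across files;
    the maximum overhang and the annotation flag take the maximum.  Output
    is sorted by (contig, intron_start, intron_end, strand, motif), contigs
    in reference dictionary order when ``ref`` is given, lexicographic
    otherwise — either way the merge is associative and input-order
    insensitive, byte for byte.
    """
    merged: dict[tuple, SpliceJunction] = {}
    for path in inputs:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                sj = SpliceJunction.from_line(line, i)
                prev = merged.get(sj.key)
                if prev is None:
                    merged[sj.key] = sj
                else:
                    merged[sj.key] = SpliceJunction(
                        *sj.key,
                        annotated=max(prev.annotated, sj.annotated),
                        n_unique=prev.n_unique + sj.n_unique,
                        n_multi=prev.n_multi + sj.n_multi,
                        max_overhang=max(prev.max_overhang, sj.max_overhang),
                    )

    if ref is not None:
        def contig_rank(name: str):
            return (ref.rank(name),)
    else:
        def contig_rank(name: str):
            return (name,)

    rows = sorted(
        merged.values(),
        key=lambda sj: (contig_rank(sj.contig), sj.intron_start, sj.intron_end,
                        sj.strand, sj.motif),
    )
    with open(out_path, "w") as fh:
        for sj in rows:
            fh.write(sj.to_line() + "\n")
    return rows


# ---------------------------------------------------------------------------
# SAM routing
# ---------------------------------------------------------------------------

@dataclass
class RouteResult:
    """Outcome of routing a SAM stream into per-region shards."""

    files: dict[int, Path]  # region index -> shard path
    overflow: Path  # unmapped records
    counts: list[int]  # mapped records per region
    positions: list[list[int]]  # sorted 0-based leftmost positions per region
    n_mapped: int = 0
    n_unmapped: int = 0


def route_sam(
    records: Iterable[SamRecord],
    region_set: RegionSet,
    out_dir: str | os.PathLike,
    prefix: str = "region",
) -> RouteResult:
    """Write each mapped record to the shard of the region containing its
    leftmost mapping position.

    A record belongs to exactly one region — the one covering its (0-based)
    start — regardless of how far it extends; reads overlapping a region
    boundary are deliberately attributed to the left region only.  Within a
    shard, records are sorted by (position, read name).  Unmapped records go
    to a dedicated overflow file.  Shard record counts sum to the mapped
    input count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = len(region_set)
    buckets: list[list[tuple[int, str, str]]] = [[] for _ in range(n)]
    overflow_lines: list[str] = []
    for rec in records:
        if not rec.is_mapped:
            overflow_lines.append(rec.raw)
            continue
        if rec.contig not in region_set.ref:
            raise RoutingError(f"record {rec.qname!r} on unknown contig {rec.contig!r}")
        idx = region_set.locate(rec.contig, rec.pos - 1)
        buckets[idx].append((rec.pos, rec.qname, rec.raw))

    files: dict[int, Path] = {}
    counts: list[int] = []
    positions: list[list[int]] = []
    for idx, bucket in enumerate(buckets):
        bucket.sort(key=lambda t: (t[0], t[1]))
        path = out_dir / f"{prefix}_{idx:04d}.sam"
        with open(path, "w") as fh:
            for _, _, raw in bucket:
                fh.write(raw + "\n")
        files[idx] = path
        counts.append(len(bucket))
        positions.append([pos - 1 for pos, _, _ in bucket])

    overflow = out_dir / f"{prefix}_unmapped.sam"
    with open(overflow, "w") as fh:
        for raw in overflow_lines:
            fh.write(raw + "\n")
    return RouteResult(
        files, overflow, counts, positions,
        n_mapped=sum(counts), n_unmapped=len(overflow_lines),
    )


# ---------------------------------------------------------------------------
# VCF merging
# ---------------------------------------------------------------------------

def _vcf_contig_lines(header: Sequence[str]) -> list[str]:
    return [l for l in header if l.startswith("##contig")]


def merge_vcf(
    inputs: Sequence[str | os.PathLike],
    ref: ReferenceDict,
    out_path: str | os.PathLike,
) -> dict[str, int]:
    """Merge per-region VCF files into one sorted, deduplicated VCF.

    The header is taken from the first input (all inputs must agree on their
    ##contig lines).  Data lines are sorted by (contig order in the
    reference, position); exact duplicates of the (contig, pos, ref, alt)
    key — which arise when adjacent regions both call a boundary variant —
    collapse to the first occurrence in input order.  Returns counts of
    records written and duplicates dropped.
    """
    if not inputs:
        raise ValidationError("no input VCF files to merge")
    header = None
    header_contigs = None
    keyed: dict[tuple, tuple[int, int, int, str]] = {}
    order = 0
    for path in inputs:
        with open(path) as fh:
            lines = fh.readlines()
        this_header = [l for l in lines if l.startswith("#")]
        contigs = _vcf_contig_lines(this_header)
        if header is None:
            header, header_contigs = this_header, contigs
        elif contigs != header_contigs:
            raise ValidationError(
                f"conflicting ##contig header lines in {path}"
            )
        for i, line in enumerate(lines, start=1):
            if line.startswith("#") or not line.strip():
                continue
            raw = line.rstrip("\n")
            fields = raw.split("\t")
            if len(fields) < 8:
                raise ParseError(f"VCF data line has {len(fields)} fields", i)
            contig, pos, ref_a, alt = fields[0], int(fields[1]), fields[3], fields[4]
            if contig not in ref:
                raise ValidationError(f"variant on contig {contig!r} absent from reference")
            key = (contig, pos, ref_a, alt)
            if key not in keyed:
                keyed[key] = (ref.rank(contig), pos, order, raw)
                order += 1
    records = sorted(keyed.values())
    total_in = 0
    for path in inputs:
        with open(path) as fh:
            total_in += sum(
                1 for l in fh if not l.startswith("#") and l.strip()
            )
    with open(out_path, "w") as fh:
        fh.writelines(header)
        for _, _, _, raw in records:
            fh.write(raw + "\n")
    return {
        "n_records": len(records),
        "n_inputs": len(inputs),
        "n_input_records": total_in,
        "n_duplicates": total_in - len(records),
    }
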