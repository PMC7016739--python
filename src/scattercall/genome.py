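"""Reference metadata and the genomic-interval data model.

Coordinates are 0-based half-open everywhere inside the toolkit; SAM/VCF
1-based positions are converted at the boundary where records are ingested.
Contig order is the file order of the reference index and defines the global
sort order of every downstream output (regions, routed SAM, merged VCF),
matching the dictionary-ordered convention of SAM and VCF.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

from .errors import ParseError, ValidationError

__all__ = [
    "ReferenceDict",
    "Region",
    "RegionSet",
    "load_reference_index",
    "regionset_from_bed",
]


@dataclass(frozen=True)
class ReferenceDict:
    """Ordered contig names and lengths of a reference genome.

    The total size in base pairs is the quantity the static load balancer
    divides by the requested region count.
    """

    contigs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate contig name(s): {', '.join(dup)}")
        for name, length in self.contigs:
            if length < 1:
                raise ValidationError(
                    f"contig {name!r} has non-positive length {length}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.contigs)

    @property
    def total_size(self) -> int:
        """Sum of all contig lengths in base pairs."""
        return sum(length for _, length in self.contigs)

    def length(self, contig: str) -> int:
        for name, length in self.contigs:
            if name == contig:
                return length
        raise KeyError(contig)

    def rank(self, contig: str) -> int:
        """Position of ``contig`` in the global sort order."""
        return self.names.index(contig)

    def __len__(self) -> int:
        return len(self.contigs)

    def __contains__(self, contig: str) -> bool:
        return contig in self.names

    def to_fai_lines(self) -> list[str]:
        """Render as minimal .fai-style lines (offset columns synthesized)."""
        lines = []
        offset = 0
        for name, length in self.contigs:
            lines.append(f"{name}\t{length}\t{offset}\t{length}\t{length + 1}")
            offset += length + len(name) + 3  # '>' + name + 2 newlines
        return lines


@dataclass(frozen=True, order=True)
class Region:
    """A contiguous half-open interval [start, end) on one contig."""

    contig: str
    start: int
    end: int
    index: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid region {self.contig}:{self.start}-{self.end}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end

    @property
    def name(self) -> str:
        return f"region_{self.index:04d}"


@dataclass
class RegionSet:
    """An ordered set of regions tiling a reference.

    ``level`` records whether the set came from static (size-based) or
    dynamic (read-count-based) load balancing; ``requested`` preserves the
    user's requested region count for provenance.  The number of regions
    actually created typically exceeds the request because every contig
    receives at least one region.
    """

    regions: list[Region]
    ref: ReferenceDict
    level: Literal["static", "dynamic"] = "static"
    requested: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check the exact-tiling and ordering invariants."""
        per_contig: dict[str, list[Region]] = {name: [] for name in self.ref.names}
        for r in self.regions:
            if r.contig not in per_contig:
                raise ValidationError(f"region on unknown contig {r.contig!r}")
            if r.end > self.ref.length(r.contig):
                raise ValidationError(
                    f"region {r.contig}:{r.start}-{r.end} exceeds contig length"
                )
            per_contig[r.contig].append(r)
        expected_order = [
            (self.ref.rank(r.contig), r.start) for r in self.regions
        ]
        if expected_order != sorted(expected_order):
            raise ValidationError("regions out of (contig order, start) order")
        for name, length in self.ref.contigs:
            regs = per_contig[name]
            if not regs:
                raise ValidationError(f"contig {name!r} has no regions")
            cursor = 0
            for r in regs:
                if r.start != cursor:
                    raise ValidationError(
                        f"gap or overlap on {name} at {cursor} (region starts {r.start})"
                    )
                cursor = r.end
            if cursor != length:
                raise ValidationError(
                    f"contig {name!r} tiled to {cursor}, length is {length}"
                )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    def locate(self, contig: str, pos: int) -> int:
        """Index of the region containing 0-based ``pos`` on ``contig``."""
        import bisect

        starts = self._starts().get(contig)
        if starts is None:
            raise KeyError(contig)
        positions, indices = starts
        if not (0 <= pos < self.ref.length(contig)):
            raise ValidationError(
                f"position {pos} out of bounds for contig {contig!r}"
            )
        i = bisect.bisect_right(positions, pos) - 1
        return indices[i]

    _starts_cache: dict | None = field(default=None, repr=False, compare=False)

    def _starts(self) -> dict[str, tuple[list[int], list[int]]]:
        if self._starts_cache is None:
            cache: dict[str, tuple[list[int], list[int]]] = {}
            for r in self.regions:
                positions, indices = cache.setdefault(r.contig, ([], []))
                positions.append(r.start)
                indices.append(r.index)
            self._starts_cache = cache
        return self._starts_cache

    def to_bed(self, path: str | os.PathLike) -> None:
        """Write the region set as BED (contig, start, end, region name)."""
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\n")


def _parse_fai(lines: Iterable[str]) -> list[tuple[str, int]]:
    contigs = []
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"expected >= 2 tab-separated fields, got {len(fields)}", i)
        try:
            length = int(fields[1])
        except ValueError:
            raise ParseError(f"non-integer contig length {fields[1]!r}", i) from None
        contigs.append((fields[0], length))
    return contigs


def _parse_dict(lines: Iterable[str]) -> list[tuple[str, int]]:
    contigs = []
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.startswith("@SQ"):
            continue
        tags = dict(
            f.split(":", 1) for f in line.split("\t")[1:] if ":" in f
        )
        if "SN" not in tags or "LN" not in tags:
            raise ParseError("@SQ line missing SN: or LN: tag", i)
        try:
            length = int(tags["LN"])
        except ValueError:
            raise ParseError(f"non-integer LN tag {tags['LN']!r}", i) from None
        contigs.append((tags["SN"], length))
    return contigs


def load_reference_index(
    path: str | os.PathLike, format: Literal["fai", "dict"] | None = None
) -> ReferenceDict:
    """Load contig names and lengths from a FASTA index or sequence dictionary.

    Parameters
    ----------
    path
        A ``.fai`` FASTA index (samtools faidx layout) or a ``.dict``
        sequence dictionary with ``@SQ`` lines.
    format
        ``"fai"`` or ``"dict"``; inferred from the file extension when
        omitted (``.dict`` means dictionary, anything else means ``.fai``).

    Returns
    -------
    ReferenceDict
        Contigs in file order with exact lengths.
    """
    if format is None:
        format = "dict" if str(path).endswith(".dict") else "fai"
    with open(path) as fh:
        lines = fh.readlines()
    if format == "fai":
        contigs = _parse_fai(lines)
    elif format == "dict":
        contigs = _parse_dict(lines)
    else:
        raise ValidationError(f"unknown reference index format {format!r}")
    if not contigs:
        raise ValidationError(f"no contigs found in {path}")
    return ReferenceDict(tuple(contigs))


def regionset_from_bed(
    path: str | os.PathLike,
    ref: ReferenceDict,
    level: Literal["static", "dynamic"] = "static",
) -> RegionSet:
    """Load a region set previously written as BED; tiling is re-validated."""
    regions = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"BED line has {len(fields)} fields, expected >= 3", i)
            try:
                regions.append(
                    Region(fields[0], int(fields[1]), int(fields[2]), len(regions))
                )
            except ValueError:
                raise ParseError("non-integer BED coordinates", i) from None
    return RegionSet(regions, ref, level=level)
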