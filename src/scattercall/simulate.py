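"""Synthetic data generation and deterministic mock stage tools.

Everything the pipeline consumes can be generated here at desk scale: a
random reference with its FASTA index, reads with planted SNVs (and the
matching truth VCF), a mock two-pass aligner, a mock index rebuilder, and a
mock region-local variant caller.  The mocks stand in for the external
aligner/caller stages behind the same command-template interface, so the
orchestration, barrier, and load-balancing logic is exercised end to end
with no external tools and no downloads.

Read names encode their true origin (``contig:start[:start2]:serial``), and
the mock aligner simply places each read at its encoded coordinate — no
alignment algorithmics are implemented, because the object under test is
the scatter-gather scaffold, not the aligner.  All generators are bitwise
deterministic per seed.

The mock caller is *region-local by construction*: it piles up only reads
that START inside its region and emits variants only at positions inside
its region.  This reproduces, in its cleanest form, the boundary behavior
of a pipeline that shards reads by starting map position — and it makes the
final merged VCF exactly independent of how the genome was partitioned,
which the test suite exploits as a monolithic-run oracle.
"""

from __future__ import annotations

import json
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyfaidx import Faidx, Fasta

from .errors import ParseError, ValidationError
from .genome import ReferenceDict, load_reference_index
from .stage_io import read_sam

__all__ = [
    "PlantedVariant",
    "TruthSet",
    "gen_reference",
    "make_truth_set",
    "gen_reads",
    "expected_read_count",
    "init_index",
    "mock_align",
    "mock_index_rebuild",
    "mock_call",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
_ALT_OF = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _contig_names(n: int) -> list[str]:
    return [f"chr{chr(ord('A') + i)}" for i in range(n)]


def gen_reference(
    contig_sizes: list[int],
    seed: int,
    out_dir: str | os.PathLike,
    names: list[str] | None = None,
    min_size: int = 1,
) -> tuple[Path, Path]:
    """Write a random uppercase A/C/G/T reference FASTA and its .fai index.

    Returns (fasta_path, fai_path).  Deterministic per seed, byte for byte.
    """
    if not contig_sizes:
        raise ValidationError("contig_sizes must be non-empty")
    if any(s < min_size for s in contig_sizes):
        raise ValidationError(f"all contig sizes must be >= {min_size}")
    if names is None:
        names = _contig_names(len(contig_sizes))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "reference.fa"
    rng = np.random.default_rng(seed)
    with open(fasta, "w") as fh:
        for name, size in zip(names, contig_sizes):
            fh.write(f">{name}\n")
            seq = rng.integers(0, 4, size=size)
            text = BASES[seq].tobytes().decode()
            for i in range(0, size, 60):
                fh.write(text[i : i + 60] + "\n")
    fai = Path(str(fasta) + ".fai")
    if fai.exists():
        fai.unlink()  # pyfaidx trusts a stale index
    Faidx(str(fasta)).close()
    return fasta, fai


@dataclass(frozen=True)
class PlantedVariant:
    """A SNV planted into simulated reads at a known allele fraction."""

    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    fraction: float  # per-read probability of carrying the alt base


@dataclass
class TruthSet:
    """A reference plus planted variants and read-simulation parameters."""

    fasta: Path
    fai: Path
    variants: list[PlantedVariant]
    read_length: int = 100
    coverage: float = 30.0
    seed: int = 0
    ref_dict: ReferenceDict = field(init=False)

    def __post_init__(self) -> None:
        self.ref_dict = load_reference_index(self.fai)
        genome = Fasta(str(self.fasta))
        for v in self.variants:
            if not (0 <= v.pos < self.ref_dict.length(v.contig)):
                raise ValidationError(
                    f"variant position {v.contig}:{v.pos} out of bounds"
                )
            actual = str(genome[v.contig][v.pos]).upper()
            if actual != v.ref:
                raise ValidationError(
                    f"variant ref {v.ref!r} does not match reference base "
                    f"{actual!r} at {v.contig}:{v.pos}"
                )
        genome.close()


def make_truth_set(
    fasta: str | os.PathLike,
    n_variants: int,
    seed: int,
    fraction: float = 1.0,
    read_length: int = 100,
    coverage: float = 30.0,
    forbidden: dict[str, list[tuple[int, int]]] | None = None,
) -> TruthSet:
    """Plant ``n_variants`` SNVs at positions clear of ``forbidden`` intervals.

    ``forbidden`` maps contig name to half-open 0-based intervals that
    variants must avoid (used to keep variants away from region boundaries).
    Positions are drawn without replacement, at least one read length apart
    from contig edges, deterministically per seed.
    """
    fasta = Path(fasta)
    fai = Path(str(fasta) + ".fai")
    ref = load_reference_index(fai)
    rng = np.random.default_rng(seed)
    genome = Fasta(str(fasta))

    allowed: list[tuple[str, int]] = []
    for name, length in ref.contigs:
        bad = sorted(forbidden.get(name, [])) if forbidden else []
        for pos in range(read_length, length - read_length):
            if any(lo <= pos < hi for lo, hi in bad):
                continue
            allowed.append((name, pos))
    if len(allowed) < n_variants:
        raise ValidationError(
            f"only {len(allowed)} allowed positions for {n_variants} variants"
        )
    picks = rng.choice(len(allowed), size=n_variants, replace=False)
    variants = []
    for i in sorted(picks):
        contig, pos = allowed[i]
        ref_base = str(genome[contig][pos]).upper()
        alt = _ALT_OF[ref_base][rng.integers(0, 3)]
        variants.append(PlantedVariant(contig, pos, ref_base, alt, fraction))
    genome.close()
    return TruthSet(fasta, fai, variants, read_length, coverage, seed)


def expected_read_count(truth: TruthSet) -> int:
    """Deterministic read count: sum over contigs of round(L*cov/read_len)."""
    return sum(
        int(round(length * truth.coverage / truth.read_length))
        for _, length in truth.ref_dict.contigs
    )


def _write_truth_vcf(truth: TruthSet, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in truth.ref_dict.contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = sorted(
            truth.variants, key=lambda v: (truth.ref_dict.rank(v.contig), v.pos)
        )
        for v in ordered:
            fh.write(f"{v.contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


def gen_reads(
    truth: TruthSet,
    out_dir: str | os.PathLike,
    paired: bool = False,
    insert: int = 50,
) -> tuple[list[Path], Path]:
    """Simulate reads from a truth set; returns (fastq paths, truth VCF path).

    Reads are sampled uniformly along each contig, ``round(L * coverage /
    read_length)`` per contig.  Each read overlapping a planted variant
    carries the alt base with the variant's allele fraction (one seeded
    Bernoulli draw per read-variant pair).  Read names encode the true
    origin: ``contig:start:serial`` (single-end) or
    ``contig:start1:start2:serial`` (paired, mate 2 a forward-strand read at
    ``start1 + read_length + insert``).
    """
    if truth.coverage <= 0:
        raise ValidationError("coverage must be > 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rl = truth.read_length
    rng = np.random.default_rng(truth.seed)
    genome = Fasta(str(truth.fasta))
    by_contig: dict[str, list[PlantedVariant]] = {}
    for v in truth.variants:
        by_contig.setdefault(v.contig, []).append(v)

    frag = 2 * rl + insert if paired else rl
    paths = [out_dir / "reads.R1.fastq"]
    if paired:
        paths.append(out_dir / "reads.R2.fastq")
    handles = [open(p, "w") for p in paths]
    serial = 0
    try:
        for name, length in truth.ref_dict.contigs:
            if length < frag:
                raise ValidationError(
                    f"contig {name} ({length} bp) shorter than fragment ({frag} bp)"
                )
            n_reads = int(round(length * truth.coverage / rl))
            if paired:
                n_reads = -(-n_reads // 2)  # fragments, two reads each
            starts = rng.integers(0, length - frag + 1, size=n_reads)
            contig_seq = str(genome[name][:]).upper()
            contig_vars = by_contig.get(name, [])
            for s1 in starts:
                s1 = int(s1)
                mate_starts = (s1, s1 + rl + insert) if paired else (s1,)
                qname = ":".join(
                    [name, *map(str, mate_starts), str(serial)]
                )
                for mate, (h, start) in enumerate(zip(handles, mate_starts), start=1):
                    seq = list(contig_seq[start : start + rl])
                    for v in contig_vars:
                        if start <= v.pos < start + rl:
                            if v.fraction >= 1.0 or rng.random() < v.fraction:
                                seq[v.pos - start] = v.alt
                    suffix = f"/{mate}" if paired else ""
                    h.write(f"@{qname}{suffix}\n{''.join(seq)}\n+\n{'I' * rl}\n")
                serial += 1
    finally:
        for h in handles:
            h.close()
        genome.close()
    truth_vcf = out_dir / "truth.vcf"
    _write_truth_vcf(truth, truth_vcf)
    return paths, truth_vcf


# ---------------------------------------------------------------------------
# Mock stage tools
# ---------------------------------------------------------------------------

def init_index(fai: str | os.PathLike, out_dir: str | os.PathLike) -> Path:
    """Create a mock genome index directory from a reference .fai."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shutil.copy(fai, out_dir / "contigs.fai")
    with open(out_dir / "meta.json", "w") as fh:
        json.dump({"generation": 1, "n_junctions": 0}, fh)
    return out_dir


def mock_index_rebuild(
    sj_path: str | os.PathLike,
    index_dir: str | os.PathLike,
    out_dir: str | os.PathLike,
) -> Path:
    """Mock of the sequential index-rebuild step between mapping passes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shutil.copy(Path(index_dir) / "contigs.fai", out_dir / "contigs.fai")
    with open(Path(index_dir) / "meta.json") as fh:
        meta = json.load(fh)
    with open(sj_path) as fh:
        n_junctions = sum(1 for line in fh if line.strip())
    with open(out_dir / "meta.json", "w") as fh:
        json.dump(
            {"generation": meta["generation"] + 1, "n_junctions": n_junctions}, fh
        )
    return out_dir


# Fixed per-contig junction template the mock aligner hashes reads into.
_N_JUNCTIONS = 5
_HASH_MULT = 2654435761  # Knuth multiplicative hash, deterministic across runs


def _junction_template(contig: str, length: int, rank: int) -> list[tuple[int, int, int, int]]:
    """(intron_start, intron_end, strand, motif) per junction slot (1-based)."""
    out = []
    for j in range(_N_JUNCTIONS):
        span = max(length - 400, 1)
        istart = 101 + (937 * (j + 1) * (rank + 1)) % span
        iend = istart + 80 + 15 * j
        out.append((istart, min(iend, length), j % 3, j % 7))
    return out


def _parse_origin(qname: str) -> tuple[str, list[int], int]:
    parts = qname.split(":")
    if len(parts) < 3:
        raise ParseError(f"read name {qname!r} does not encode an origin")
    try:
        starts = [int(p) for p in parts[1:-1]]
        serial = int(parts[-1])
    except ValueError:
        raise ParseError(f"read name {qname!r} does not encode an origin") from None
    return parts[0], starts, serial


def mock_align(
    fastq: str | os.PathLike,
    index_dir: str | os.PathLike,
    out_prefix: str | os.PathLike,
    fastq2: str | os.PathLike | None = None,
) -> tuple[Path, Path]:
    """Mock aligner: place each read at the coordinate encoded in its name.

    Writes ``<out_prefix>.sam`` (one primary record per read, header
    included) and ``<out_prefix>.SJ.out.tab`` (read origins hashed into a
    fixed per-contig junction set, so junction merging aggregates real
    counts).  Returns (sam_path, sj_path).  Deterministic; concatenating the
    outputs of any chunking of the input yields the same record multiset as
    a single run.
    """
    ref = load_reference_index(Path(index_dir) / "contigs.fai")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    sam_path = Path(str(out_prefix) + ".sam")
    sj_path = Path(str(out_prefix) + ".SJ.out.tab")

    inputs = [Path(fastq)] + ([Path(fastq2)] if fastq2 else [])
    sj_counts: dict[tuple, list[int]] = {}  # key -> [n_unique, n_multi, overhang]
    templates = {
        name: _junction_template(name, length, rank)
        for rank, (name, length) in enumerate(ref.contigs)
    }

    with open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in ref.contigs:
            sam.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        readers = [open(p) for p in inputs]
        try:
            while True:
                blocks = []
                for r in readers:
                    block = [r.readline() for _ in range(4)]
                    blocks.append(block)
                if not blocks[0][0]:
                    break
                for mate_i, block in enumerate(blocks):
                    header = block[0].rstrip("\n")
                    if not header.startswith("@"):
                        raise ParseError("malformed FASTQ record")
                    qname_full = header[1:].split()[0]
                    qname = qname_full
                    if qname.endswith("/1") or qname.endswith("/2"):
                        qname = qname[:-2]
                    contig, starts, _ = _parse_origin(qname)
                    if contig not in ref:
                        raise ParseError(
                            f"read {qname!r} names unknown contig {contig!r}"
                        )
                    seq = block[1].rstrip("\n")
                    qual = block[3].rstrip("\n")
                    start = starts[mate_i] if mate_i < len(starts) else starts[0]
                    pos = start + 1  # SAM is 1-based
                    if fastq2:
                        flag = 0x1 | 0x2 | (0x40 if mate_i == 0 else 0x80)
                        other = starts[1 - mate_i] if len(starts) > 1 else start
                        rnext, pnext = "=", other + 1
                    else:
                        flag, rnext, pnext = 0, "*", 0
                    sam.write(
                        f"{qname}\t{flag}\t{contig}\t{pos}\t60\t{len(seq)}M\t"
                        f"{rnext}\t{pnext}\t0\t{seq}\t{qual}\n"
                    )
                    # hash origin into the contig's fixed junction set
                    slot = (start * _HASH_MULT) % (2**32) % _N_JUNCTIONS
                    istart, iend, strand, motif = templates[contig][slot]
                    key = (contig, istart, iend, strand, motif)
                    entry = sj_counts.setdefault(key, [0, 0, 0])
                    entry[0] += 1
                    entry[1] += start % 3  # deterministic multi-mapper tally
                    entry[2] = max(entry[2], start % 40 + 1)
        finally:
            for r in readers:
                r.close()

    ranks = {name: i for i, name in enumerate(ref.names)}
    with open(sj_path, "w") as fh:
        for key in sorted(sj_counts, key=lambda k: (ranks[k[0]], k[1:])):
            contig, istart, iend, strand, motif = key
            n_uniq, n_multi, overhang = sj_counts[key]
            fh.write(
                f"{contig}\t{istart}\t{iend}\t{strand}\t{motif}\t0\t"
                f"{n_uniq}\t{n_multi}\t{overhang}\n"
            )
    return sam_path, sj_path


def mock_call(
    sam_path: str | os.PathLike,
    bed_path: str | os.PathLike,
    fasta: str | os.PathLike,
    out_vcf: str | os.PathLike,
    min_alt: int = 3,
    min_frac: float = 0.3,
) -> Path:
    """Mock region-local variant caller: naive pileup over region positions.

    Uses only the reads in the shard (which all start inside the region) and
    emits a variant at a region position where at least ``min_alt`` reads
    and at least ``min_frac`` of covering reads carry the same non-reference
    base.  Emits nothing outside the region.  Output is deterministic and
    carries no depth annotations, so identical call sets serialize to
    identical bytes regardless of sharding.
    """
    regions: list[tuple[str, int, int]] = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.split("\t")
            regions.append((f[0], int(f[1]), int(f[2])))
    if not regions:
        raise ValidationError(f"empty region BED {bed_path}")

    ref = load_reference_index(str(fasta) + ".fai")

    coverage: dict[tuple[str, int], int] = {}
    alt_counts: dict[tuple[str, int, str], int] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for contig, lo, hi in regions:
        spans.setdefault(contig, []).append((lo, hi))
    genome = Fasta(str(fasta))
    contig_seq = {c: str(genome[c][:]).upper() for c in spans}
    genome.close()

    for rec in read_sam(sam_path):
        if not rec.is_mapped:
            continue
        seq = rec.raw.split("\t")[9]
        start = rec.pos - 1
        contig_spans = spans.get(rec.contig, [])
        if not contig_spans:
            continue
        ref_seq = contig_seq[rec.contig][start : start + len(seq)]
        for i, base in enumerate(seq):
            p = start + i
            if not any(lo <= p < hi for lo, hi in contig_spans):
                continue
            coverage[(rec.contig, p)] = coverage.get((rec.contig, p), 0) + 1
            if i < len(ref_seq) and base != ref_seq[i] and base != "N":
                k = (rec.contig, p, base)
                alt_counts[k] = alt_counts.get(k, 0) + 1


    calls = []
    for (contig, p, base), n_alt in alt_counts.items():
        cov = coverage[(contig, p)]
        if n_alt >= min_alt and n_alt >= min_frac * cov:
            calls.append((ref.rank(contig), p, base, contig))
    calls.sort()

    with open(out_vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in ref.contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, p, base, contig in calls:
            ref_base = contig_seq[contig][p]
            fh.write(f"{contig}\t{p + 1}\t.\t{ref_base}\t{base}\t.\tPASS\t.\n")
    return Path(out_vcf)
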