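"""FASTQ chunking, splice-junction merging, SAM routing, VCF merging."""

import random

import pytest

from scattercall import (
    ReferenceDict,
    Region,
    RegionSet,
    merge_splice_junctions,
    merge_vcf,
    route_sam,
    split_fastq,
)
from scattercall.errors import ParseError, RoutingError, ValidationError
from scattercall.stage_io import SamRecord, read_sam

from conftest import make_sam_line


def write_fastq(path, names, seq="ACGTACGT"):
    with open(path, "w") as fh:
        for n in names:
            fh.write(f"@{n}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


class TestSplitFastq:
    def test_even_split(self, tmp_path):
        fq = write_fastq(tmp_path / "in.fastq", [f"r{i}" for i in range(100)])
        chunks = split_fastq([fq], 4, tmp_path / "out")
        assert len(chunks) == 4
        for (chunk,) in chunks:
            assert sum(1 for l in open(chunk) if l.startswith("@")) == 25

    def test_ceil_rule_last_chunk_smaller(self, tmp_path):
        fq = write_fastq(tmp_path / "in.fastq", [f"r{i}" for i in range(10)])
        chunks = split_fastq([fq], 3, tmp_path / "out")
        sizes = [
            sum(1 for l in open(c) if l.startswith("@")) for (c,) in chunks
        ]
        assert sizes == [4, 4, 2]

    def test_concatenation_reproduces_input_bytes(self, tmp_path):
        fq = write_fastq(tmp_path / "in.fastq", [f"read{i}" for i in range(17)])
        chunks = split_fastq([fq], 5, tmp_path / "out")
        concat = b"".join(open(c, "rb").read() for (c,) in chunks)
        assert concat == open(fq, "rb").read()

    def test_paired_chunks_share_record_boundaries(self, tmp_path):
        names = [f"frag{i}" for i in range(11)]
        r1 = write_fastq(tmp_path / "r1.fastq", [n + "/1" for n in names])
        r2 = write_fastq(tmp_path / "r2.fastq", [n + "/2" for n in names])
        chunks = split_fastq([r1, r2], 3, tmp_path / "out")
        for c1, c2 in chunks:
            n1 = [l.strip()[1:-2] for l in open(c1) if l.startswith("@")]
            n2 = [l.strip()[1:-2] for l in open(c2) if l.startswith("@")]
            assert n1 == n2

    def test_unequal_pair_lengths_rejected(self, tmp_path):
        r1 = write_fastq(tmp_path / "r1.fastq", ["a", "b"])
        r2 = write_fastq(tmp_path / "r2.fastq", ["a"])
        with pytest.raises(ValidationError, match="unequal"):
            split_fastq([r1, r2], 2, tmp_path / "out")

    def test_ragged_record_structure_rejected(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n")
        with pytest.raises(ParseError):
            split_fastq([p], 2, tmp_path / "out")

    def test_more_chunks_than_records(self, tmp_path):
        fq = write_fastq(tmp_path / "in.fastq", ["a", "b"])
        chunks = split_fastq([fq], 5, tmp_path / "out")
        assert len(chunks) == 2  # one record each; no empty chunks


SJ_ROWS = [
    "chrA\t100\t180\t1\t1\t0\t5\t1\t20",
    "chrA\t300\t400\t2\t2\t0\t2\t0\t15",
    "chrB\t50\t90\t1\t1\t0\t7\t2\t31",
]


class TestMergeSpliceJunctions:
    def test_disjoint_union(self, tmp_path):
        a = tmp_path / "a.tab"
        b = tmp_path / "b.tab"
        a.write_text("\n".join(SJ_ROWS[:2]) + "\n")
        b.write_text(SJ_ROWS[2] + "\n")
        out = tmp_path / "m.tab"
        rows = merge_splice_junctions([a, b], out)
        assert len(rows) == 3
        assert out.read_text().splitlines() == SJ_ROWS

    def test_duplicate_key_aggregation(self, tmp_path):
        a = tmp_path / "a.tab"
        b = tmp_path / "b.tab"
        a.write_text("chrA\t100\t180\t1\t1\t0\t5\t1\t20\n")
        b.write_text("chrA\t100\t180\t1\t1\t1\t7\t2\t31\n")
        out = tmp_path / "m.tab"
        (row,) = merge_splice_junctions([a, b], out)
        assert row.n_unique == 12 and row.n_multi == 3
        assert row.max_overhang == 31 and row.annotated == 1

    def test_empty_input_list_gives_empty_output(self, tmp_path):
        out = tmp_path / "m.tab"
        assert merge_splice_junctions([], out) == []
        assert out.read_text() == ""

    def test_merge_is_order_insensitive_byte_for_byte(self, tmp_path):
        files = []
        rnd = random.Random(3)
        for i in range(5):
            p = tmp_path / f"f{i}.tab"
            rows = rnd.sample(SJ_ROWS, k=rnd.randint(1, 3))
            p.write_text("".join(r + "\n" for r in rows))
            files.append(p)
        reference_bytes = None
        for trial in range(20):
            order = files[:]
            rnd.shuffle(order)
            out = tmp_path / f"out{trial}.tab"
            merge_splice_junctions(order, out)
            data = out.read_bytes()
            if reference_bytes is None:
                reference_bytes = data
            assert data == reference_bytes

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "bad.tab"
        p.write_text("chrA\t1\t2\t0\n")
        with pytest.raises(ParseError, match="columns"):
            merge_splice_junctions([p], tmp_path / "m.tab")


@pytest.fixture
def two_region_set():
    ref = ReferenceDict((("c", 200),))
    return RegionSet([Region("c", 0, 100, 0), Region("c", 100, 200, 1)], ref)


class TestRouteSam:
    def test_boundary_routing_by_leftmost_position(self, tmp_path, two_region_set):
        # 0-based starts {0, 99, 100, 199} over [0,100) and [100,200)
        records = [
            SamRecord.from_line(make_sam_line(f"r{i}", "c", pos))
            for i, pos in enumerate([1, 100, 101, 200])
        ]
        result = route_sam(records, two_region_set, tmp_path)
        assert result.counts == [2, 2]
        assert result.positions == [[0, 99], [100, 199]]

    def test_all_unmapped_go_to_overflow(self, tmp_path, two_region_set):
        records = [
            SamRecord.from_line(make_sam_line(f"r{i}", None, 0)) for i in range(3)
        ]
        result = route_sam(records, two_region_set, tmp_path)
        assert result.counts == [0, 0] and result.n_unmapped == 3
        assert sum(1 for _ in open(result.overflow)) == 3

    def test_record_line_roundtrips_byte_identically(self, tmp_path, two_region_set):
        line = make_sam_line("only", "c", 42, seq="ACGTN")
        result = route_sam(
            [SamRecord.from_line(line)], two_region_set, tmp_path
        )
        assert open(result.files[0]).read() == line + "\n"

    def test_shards_sorted_by_position_then_name(self, tmp_path, two_region_set):
        records = [
            SamRecord.from_line(make_sam_line(name, "c", pos))
            for name, pos in [("b", 50), ("a", 50), ("z", 5), ("c", 150)]
        ]
        result = route_sam(records, two_region_set, tmp_path)
        shard = [r.qname for r in read_sam(result.files[0])]
        assert shard == ["z", "a", "b"]

    def test_conservation_of_record_multiset(self, tmp_path, two_region_set):
        rnd = random.Random(5)
        records = [
            SamRecord.from_line(make_sam_line(f"r{i}", "c", rnd.randint(1, 200)))
            for i in range(500)
        ]
        result = route_sam(records, two_region_set, tmp_path)
        assert result.n_mapped == sum(result.counts) == 500
        routed = sorted(
            r.qname for i in result.files for r in read_sam(result.files[i])
        )
        assert routed == sorted(r.qname for r in records)

    def test_unknown_contig_raises(self, tmp_path, two_region_set):
        rec = SamRecord.from_line(make_sam_line("r", "chrX", 10))
        with pytest.raises(RoutingError, match="chrX"):
            route_sam([rec], two_region_set, tmp_path)


def write_vcf(path, rows, contigs=(("c1", 1000), ("c2", 1000))):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in rows:
            fh.write(r + "\n")
    return path


class TestMergeVcf:
    REF = ReferenceDict((("c1", 1000), ("c2", 1000)))

    def test_global_sort_across_region_files(self, tmp_path):
        a = write_vcf(tmp_path / "a.vcf", ["c1\t500\t.\tA\tT\t.\tPASS\t.",
                                           "c2\t10\t.\tG\tC\t.\tPASS\t."])
        b = write_vcf(tmp_path / "b.vcf", ["c1\t20\t.\tA\tG\t.\tPASS\t.",
                                           "c1\t900\t.\tT\tA\t.\tPASS\t.",
                                           "c2\t5\t.\tC\tG\t.\tPASS\t."])
        c = write_vcf(tmp_path / "c.vcf", ["c2\t999\t.\tA\tC\t.\tPASS\t."])
        out = tmp_path / "m.vcf"
        stats = merge_vcf([a, b, c], self.REF, out)
        assert stats["n_records"] == 6 and stats["n_duplicates"] == 0
        keys = [
            (l.split("\t")[0], int(l.split("\t")[1]))
            for l in open(out)
            if not l.startswith("#")
        ]
        assert keys == [("c1", 20), ("c1", 500), ("c1", 900),
                        ("c2", 5), ("c2", 10), ("c2", 999)]

    def test_exact_duplicate_key_collapsed_to_first(self, tmp_path):
        a = write_vcf(tmp_path / "a.vcf", ["c1\t100\t.\tA\tT\t50\tPASS\tfirst"])
        b = write_vcf(tmp_path / "b.vcf", ["c1\t100\t.\tA\tT\t99\tPASS\tsecond"])
        out = tmp_path / "m.vcf"
        stats = merge_vcf([a, b], self.REF, out)
        assert stats["n_duplicates"] == 1
        (line,) = [l for l in open(out) if not l.startswith("#")]
        assert "first" in line

    def test_header_taken_from_first_input(self, tmp_path):
        a = write_vcf(tmp_path / "a.vcf", [])
        b = write_vcf(tmp_path / "b.vcf", ["c1\t1\t.\tA\tT\t.\tPASS\t."])
        out = tmp_path / "m.vcf"
        merge_vcf([a, b], self.REF, out)
        header = [l for l in open(out) if l.startswith("##")]
        assert header == [l for l in open(a) if l.startswith("##")]

    def test_conflicting_contig_headers_rejected(self, tmp_path):
        a = write_vcf(tmp_path / "a.vcf", [])
        b = write_vcf(tmp_path / "b.vcf", [], contigs=(("cX", 5),))
        with pytest.raises(ValidationError, match="contig"):
            merge_vcf([a, b], self.REF, tmp_path / "m.vcf")

    def test_empty_input_list_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            merge_vcf([], self.REF, tmp_path / "m.vcf")
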