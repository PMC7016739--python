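"""Static and dynamic load balancing: worked examples and edge cases."""

from fractions import Fraction

import pytest

from scattercall import (
    ReferenceDict,
    RegionProfile,
    avg_size_dynamic,
    avg_size_static,
    balance_report,
    dynamic_partition,
    profile_regions,
    static_partition,
)
from scattercall.errors import RoutingError, ValidationError
from scattercall.stage_io import SamRecord

from conftest import make_sam_line


def recs(*placements):
    """SamRecords at given (contig, 1-based pos); contig None -> unmapped."""
    return [
        SamRecord.from_line(make_sam_line(f"r{i}", contig, pos))
        for i, (contig, pos) in enumerate(placements)
    ]


class TestAvgSizeStatic:
    @pytest.mark.parametrize(
        "contigs, n, expected",
        [
            ((("c", 1000),), 10, Fraction(100)),
            ((("c", 1000),), 1, Fraction(1000)),
            ((("a", 300), ("b", 100), ("c", 100)), 5, Fraction(100)),
            ((("c", 1000),), 3, Fraction(1000, 3)),  # stays exact, no rounding
        ],
    )
    def test_exact_rational_division(self, contigs, n, expected):
        assert avg_size_static(ReferenceDict(contigs), n) == expected

    def test_zero_regions_rejected(self):
        with pytest.raises(ValidationError):
            avg_size_static(ReferenceDict((("c", 10),)), 0)


class TestStaticPartition:
    def test_large_contig_split_small_ones_kept(self):
        ref = ReferenceDict((("a", 300), ("b", 100), ("c", 100)))
        plan = static_partition(ref, 5)
        assert plan.rslb == 5
        assert [(r.contig, r.start, r.end) for r in plan.region_set] == [
            ("a", 0, 100), ("a", 100, 200), ("a", 200, 300),
            ("b", 0, 100), ("c", 0, 100),
        ]

    def test_one_region_per_contig_when_none_exceeds_average(self):
        ref = ReferenceDict((("a", 100), ("b", 100), ("c", 100)))
        plan = static_partition(ref, 3)
        assert plan.rslb == 3
        assert all(r.size == 100 for r in plan.region_set)

    def test_single_contig_equal_quarters(self):
        plan = static_partition(ReferenceDict((("x", 1000),)), 4)
        assert [(r.start, r.end) for r in plan.region_set] == [
            (0, 250), (250, 500), (500, 750), (750, 1000)
        ]

    def test_realized_count_can_exceed_request(self):
        # avg = 270/2 = 135; the 250 bp contig stays whole (floor(250/135) = 1)
        # but each small contig still claims a region, so RsLB = 3 > 2.
        ref = ReferenceDict((("big", 250), ("s1", 10), ("s2", 10)))
        plan = static_partition(ref, 2)
        assert plan.rslb == 3
        assert plan.region_set[0].size == 250

    def test_remainder_goes_to_last_piece(self):
        plan = static_partition(ReferenceDict((("x", 1003),)), 4)
        sizes = [r.size for r in plan.region_set]
        assert sizes == [250, 250, 250, 253]
        assert sum(sizes) == 1003


class TestProfileRegions:
    def test_all_reads_in_first_region(self):
        plan = static_partition(ReferenceDict((("c", 300),)), 3)
        profile = profile_regions(recs(*[("c", 1)] * 10), plan)
        assert profile.counts == [10, 0, 0]
        assert profile.total_reads == 10

    def test_empty_stream_gives_zero_counts(self):
        plan = static_partition(ReferenceDict((("c", 300),)), 3)
        profile = profile_regions([], plan)
        assert profile.counts == [0, 0, 0] and profile.total_reads == 0

    def test_boundary_reads_assigned_by_leftmost_position(self):
        plan = static_partition(ReferenceDict((("c", 200),)), 2)
        # 1-based SAM positions 1, 100, 101, 200 = 0-based 0, 99, 100, 199
        profile = profile_regions(
            recs(("c", 1), ("c", 100), ("c", 101), ("c", 200)), plan
        )
        assert profile.counts == [2, 2]

    def test_unmapped_counted_separately(self):
        plan = static_partition(ReferenceDict((("c", 100),)), 1)
        profile = profile_regions(recs(("c", 5), (None, 0)), plan)
        assert profile.counts == [1] and profile.unmapped == 1

    def test_unknown_contig_raises_routing_error(self):
        plan = static_partition(ReferenceDict((("c", 100),)), 1)
        with pytest.raises(RoutingError, match="chrZ"):
            profile_regions(recs(("chrZ", 5)), plan)


class TestAvgSizeDynamic:
    @pytest.mark.parametrize(
        "counts, expected",
        [([400, 100, 100], Fraction(200)), ([0, 0], Fraction(0)), ([7], Fraction(7))],
    )
    def test_total_over_region_count(self, counts, expected):
        ref = ReferenceDict((("c", 1000 * len(counts)),))
        plan = static_partition(ref, len(counts))
        profile = RegionProfile(plan.region_set, counts)
        assert avg_size_dynamic(profile) == expected


class TestDynamicPartition:
    def _profile(self, counts, positions, contig_len=3000):
        ref = ReferenceDict((("c", contig_len),))
        plan = static_partition(ref, len(counts))
        return RegionProfile(plan.region_set, counts, positions=positions)

    def test_overloaded_region_split_at_read_quantiles(self):
        # region [0,1000) holds 400 reads spread uniformly; avg = 200 so it
        # splits in two halves of ~200 reads; the quiet regions stay whole.
        positions = [
            [i * 25 // 10 for i in range(400)],
            [1000 + i * 10 for i in range(100)],
            [2000 + i * 10 for i in range(100)],
        ]
        profile = self._profile([400, 100, 100], positions)
        plan = dynamic_partition(profile)
        assert plan.rdlb == 4
        split = [r for r in plan.region_set if r.start < 1000]
        assert len(split) == 2
        left = sum(1 for p in positions[0] if p < split[0].end)
        assert abs(left - 200) <= 1

    def test_uniform_load_leaves_partition_unchanged(self):
        positions = [
            [off + i * 10 for i in range(100)] for off in (0, 1000, 2000)
        ]
        profile = self._profile([100, 100, 100], positions)
        plan = dynamic_partition(profile)
        assert plan.rdlb == plan.rslb == 3
        assert [(r.start, r.end) for r in plan.region_set] == [
            (0, 1000), (1000, 2000), (2000, 3000)
        ]

    def test_all_reads_at_one_coordinate_keeps_region_whole(self):
        positions = [[500] * 400, [1000 + i for i in range(100)],
                     [2000 + i for i in range(100)]]
        profile = self._profile([400, 100, 100], positions)
        plan = dynamic_partition(profile)
        hot = [r for r in plan.region_set if r.start < 1000]
        assert len(hot) == 1 and (hot[0].start, hot[0].end) == (0, 1000)

    def test_zero_reads_everywhere_is_a_no_op(self):
        profile = self._profile([0, 0, 0], [[], [], []])
        plan = dynamic_partition(profile)
        assert plan.rdlb == 3

    def test_refinement_merges_back_to_static(self):
        positions = [
            [i * 25 // 10 for i in range(400)],
            [1000 + i * 10 for i in range(100)],
            [2000 + i * 10 for i in range(100)],
        ]
        profile = self._profile([400, 100, 100], positions)
        plan = dynamic_partition(profile)
        by_parent: dict[int, list] = {}
        for region, parent in zip(plan.region_set, plan.parents):
            by_parent.setdefault(parent, []).append(region)
        for parent_idx, children in by_parent.items():
            parent = profile.region_set[parent_idx]
            assert children[0].start == parent.start
            assert children[-1].end == parent.end


class TestBalanceReport:
    def test_max_load_drops_after_dynamic_split(self):
        positions = [
            [i * 25 // 10 for i in range(400)],
            [1000 + i * 10 for i in range(100)],
            [2000 + i * 10 for i in range(100)],
        ]
        ref = ReferenceDict((("c", 3000),))
        plan = static_partition(ref, 3)
        profile = RegionProfile(plan.region_set, [400, 100, 100], positions=positions)
        before = balance_report(profile)
        dyn = dynamic_partition(profile)
        after_counts = [
            sum(1 for p in positions[parent] if r.start <= p < r.end)
            for r, parent in zip(dyn.region_set, dyn.parents)
        ]
        after = balance_report(after_counts)
        assert before.max == 400
        assert after.max <= 200 + 1

    def test_single_region_max_equals_min_equals_total(self):
        rep = balance_report([42])
        assert rep.max == rep.min == 42

    def test_empty_report(self):
        rep = balance_report([])
        assert rep.values == [] and rep.hist_counts == []

    def test_tsv_and_json_serialization(self, tmp_path):
        rep = balance_report([1, 2, 3])
        assert "region\treads" in rep.to_tsv()
        rep.to_json(tmp_path / "r.json")
        import json

        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["max"] == 3 and loaded["n_regions"] == 3
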