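"""VCF concordance: TP/FP/FN classification and sensitivity/precision.

A scalable, region-parallel pipeline can call slightly different variants
than its monolithic baseline because reads are sorted into shards by their
starting map position, ignoring overlap across region boundaries.  This
module quantifies that concordance.  Variants match on the exact key
(contig, pos, ref, alt) after multi-allelic lines are split per alt allele;
TP are keys called by both pipelines, FP only by the pipeline under test,
FN only by the baseline, and

    sensitivity = TP / (TP + FN)        precision = TP / (TP + FP)

both reported as percentages to two decimals.  Matching is exact-key, not
haplotype-aware: tools that canonicalize equivalent complex representations
(as haplotype-aware comparators do) may count differently on such loci,
while the two metrics applied to given TP/FP/FN counts are exact.  FILTER
and genotype columns are ignored.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable

from .errors import UndefinedMetricError
from .stage_io import VariantRecord, read_vcf_records

__all__ = [
    "AccuracyReport",
    "classify_variants",
    "sensitivity",
    "precision",
    "evaluate",
]


@dataclass(frozen=True)
class AccuracyReport:
    """Concordance counts and metrics of a test VCF against a baseline."""

    tp: int
    fp: int
    fn: int
    sensitivity: float  # percent, two decimals
    precision: float  # percent, two decimals

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = json.dumps(
            {
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
                "sensitivity_pct": self.sensitivity,
                "precision_pct": self.precision,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    def to_tsv(self) -> str:
        return (
            "tp\tfp\tfn\tsensitivity_pct\tprecision_pct\n"
            f"{self.tp}\t{self.fp}\t{self.fn}\t{self.sensitivity:.2f}\t{self.precision:.2f}\n"
        )


def _keys(records: Iterable[VariantRecord]) -> set[tuple]:
    return {r.key for r in records}


def classify_variants(
    test: Iterable[VariantRecord], baseline: Iterable[VariantRecord]
) -> tuple[int, int, int]:
    """Exact-key confusion counts (tp, fp, fn) of test against baseline."""
    t, b = _keys(test), _keys(baseline)
    return len(t & b), len(t - b), len(b - t)


def sensitivity(tp: int, fn: int) -> float:
    """Fraction of baseline variants recovered, as a percent (two decimals)."""
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: tp + fn == 0")
    return round(100.0 * tp / (tp + fn), 2)


def precision(tp: int, fp: int) -> float:
    """Fraction of called variants confirmed, as a percent (two decimals)."""
    if tp + fp == 0:
        raise UndefinedMetricError("precision undefined: tp + fp == 0")
    return round(100.0 * tp / (tp + fp), 2)


def evaluate(
    test_vcf: str | os.PathLike, baseline_vcf: str | os.PathLike
) -> AccuracyReport:
    """Compare two VCF files and report concordance metrics."""
    tp, fp, fn = classify_variants(
        read_vcf_records(test_vcf), read_vcf_records(baseline_vcf)
    )
    return AccuracyReport(tp, fp, fn, sensitivity(tp, fn), precision(tp, fp))
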