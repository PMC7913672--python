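"""Read-redundancy assessment from unique molecular identifiers.

A duplicate is defined as a read carrying a UMI string already seen among
the aligned reads (exact string equality; optional Hamming-distance-1
clustering absorbs likely sequencing errors in the UMI itself, default
off).  The report includes the birthday-collision floor: with random
UMIs of length L, distinct molecules occasionally share a UMI by chance,
so the observable redundancy never falls below that floor; a warning flag
is raised when the read count approaches the 4^L UMI diversity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .align import AlignedReadSet
from .exceptions import ValidationError

__all__ = ["RedundancyReport", "assess_redundancy", "deduplicate"]


@dataclass
class RedundancyReport:
    """UMI duplicate accounting for one aligned read set."""

    total_reads: int
    distinct_umis: int
    duplicate_reads: int
    redundancy_fraction: float
    umi_count_histogram: dict[int, int]
    n_umis_with_N: int = 0
    expected_collision_redundancy: float = 0.0
    pcr_redundancy_estimate: float = 0.0
    diversity_warning: bool = False


def _expected_collision_redundancy(n: int, umi_length: int) -> float:
    """Baseline redundancy from random UMI collisions among n distinct molecules.

    E[distinct UMIs] = M (1 - (1 - 1/M)^n) with M = 4^L; the expected
    duplicate fraction is 1 - E[distinct]/n.
    """
    if n == 0 or umi_length == 0:
        return 0.0
    m = 4 ** umi_length
    expected_distinct = m * (1.0 - (1.0 - 1.0 / m) ** n)
    return 1.0 - expected_distinct / n


def _estimate_molecules(distinct: int, umi_length: int) -> float:
    """Invert E[distinct] = M(1 - (1 - 1/M)^x) to estimate molecule count.

    Corrects the distinct-UMI count for birthday collisions: at read depths
    approaching 4^L diversity the raw duplicate fraction overstates PCR
    redundancy, because distinct molecules share UMIs by chance.
    """
    import math

    m = 4 ** umi_length
    if distinct >= m:
        return float("inf")
    return math.log(1.0 - distinct / m) / math.log(1.0 - 1.0 / m)


def assess_redundancy(
    aligned: AlignedReadSet, cluster_1mm: bool = False
) -> RedundancyReport:
    """Count duplicate reads (same UMI) among the aligned reads.

    Reads with ``N`` in the UMI are excluded from the statistics and
    counted separately; a missing UMI on any read is an error.
    """
    umis: list[str] = []
    n_with_n = 0
    for read in aligned.reads:
        if read.umi is None:
            raise ValidationError(f"read {read.read_id} carries no UMI")
        if "N" in read.umi:
            n_with_n += 1
        else:
            umis.append(read.umi)
    counts = Counter(umis)
    if cluster_1mm and counts:
        counts = _cluster_one_mismatch(counts)
    total = len(umis)
    distinct = len(counts)
    duplicates = total - distinct
    umi_length = len(umis[0]) if umis else 0
    expected = _expected_collision_redundancy(total, umi_length)
    if total and umi_length:
        est_molecules = min(float(total), _estimate_molecules(distinct, umi_length))
        pcr_estimate = max(0.0, 1.0 - est_molecules / total)
    else:
        pcr_estimate = 0.0
    return RedundancyReport(
        total_reads=total,
        distinct_umis=distinct,
        duplicate_reads=duplicates,
        redundancy_fraction=duplicates / total if total else 0.0,
        umi_count_histogram=dict(Counter(counts.values())),
        n_umis_with_N=n_with_n,
        expected_collision_redundancy=expected,
        pcr_redundancy_estimate=pcr_estimate,
        diversity_warning=umi_length > 0 and total > 0.1 * 4 ** umi_length,
    )


def _cluster_one_mismatch(counts: Counter) -> Counter:
    """Greedy directional clustering: absorb UMIs at Hamming distance 1.

    UMIs are visited by descending count; a UMI is absorbed into an
    already-kept neighbour differing at exactly one position.
    """
    kept: dict[str, int] = {}
    alphabet = "ACGT"
    for umi, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        parent = None
        for i in range(len(umi)):
            for base in alphabet:
                if base == umi[i]:
                    continue
                neighbour = umi[:i] + base + umi[i + 1 :]
                if neighbour in kept:
                    parent = neighbour
                    break
            if parent:
                break
        if parent is None:
            kept[umi] = n
        else:
            kept[parent] += n
    return Counter(kept)


def deduplicate(aligned: AlignedReadSet) -> AlignedReadSet:
    """Optional pre-rates filter: keep the first read of every UMI.

    Off by default in the pipeline -- redundancy is reported, but rates are
    computed over all aligned reads.
    """
    seen: set[str] = set()
    kept = []
    for read in aligned.reads:
        if read.umi is None or read.umi not in seen:
            kept.append(read)
            if read.umi is not None:
                seen.add(read.umi)
    return AlignedReadSet(
        reference=aligned.reference,
        reads=kept,
        rejections=aligned.rejections,
        stats={**aligned.stats, "after_dedup": len(kept)},
    )


def report_table(report: RedundancyReport) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": [
                "total_reads", "distinct_umis", "duplicate_reads",
                "redundancy_fraction", "n_umis_with_N",
                "expected_collision_redundancy", "pcr_redundancy_estimate",
                "diversity_warning",
            ],
            "value": [
                report.total_reads, report.distinct_umis, report.duplicate_reads,
                report.redundancy_fraction, report.n_umis_with_N,
                report.expected_collision_redundancy, report.pcr_redundancy_estimate,
                report.diversity_warning,
            ],
        }
    )
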