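"""Location-independent per-family consensus coverage profiling.

Rather than calling individual insertion loci, this module counts how many
reads a library devotes to each TE family consensus and each immobile gene
(IGE) under the strict end-to-end mapping contract (soft-clipped reads count
as unmapped).  Counts are depth-normalized to reads per million mapped
library reads (RPM); "mean coverage" is reported both as mean per-base depth
and as the raw read count, since either convention appears in practice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mapping import AlignmentSet
from .stats import TestResult, rank_sum_test

__all__ = ["consensus_coverage_table", "coverage_ratio_test", "depth_vector"]


def consensus_coverage_table(alns: AlignmentSet) -> pd.DataFrame:
    """Per-target read counts, RPM and mean per-base coverage.

    One row per TE family and per IGE gene (plasmids included when present
    in the reference).  RPM is normalized by all mapped reads of the
    library; mean coverage is total aligned bases over target length.
    """
    if alns.mode != "consensus_end_to_end":
        raise ValueError("coverage profiling requires consensus_end_to_end alignments")
    if alns.n_pairs == 0:
        raise ValueError("empty alignment set")
    mapped = alns.mapped_reads
    if mapped == 0:
        raise ValueError("no mapped reads")
    index = alns.index
    counts = np.zeros(len(index.names), dtype=np.int64)
    bases = np.zeros(len(index.names), dtype=np.int64)
    for alist in (alns.a1, alns.a2):
        for a in alist:
            if a.mapped:
                counts[a.tid] += 1
                bases[a.tid] += a.alen
    rows = []
    for tid, name in enumerate(index.names):
        cat = index.categories[tid]
        if cat == "genome":
            continue
        length = len(index.seqs[tid])
        rows.append(
            {
                "target": name,
                "category": cat,
                "length": length,
                "reads": int(counts[tid]),
                "rpm": 1e6 * counts[tid] / mapped,
                "mean_coverage": bases[tid] / length,
                "library_mapped_reads": mapped,
            }
        )
    return pd.DataFrame(rows).set_index("target")


def depth_vector(alns: AlignmentSet, target: str) -> np.ndarray:
    """Per-base read depth along one consensus target."""
    index = alns.index
    tid = index.names.index(target)
    depth = np.zeros(len(index.seqs[tid]), dtype=np.int64)
    for alist in (alns.a1, alns.a2):
        for a in alist:
            if a.mapped and a.tid == tid:
                depth[a.pos : a.end] += 1
    return depth


def coverage_ratio_test(
    profile_aged: pd.DataFrame,
    profile_young: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Aged/young RPM ratio per target plus rank-sum test summaries.

    Targets with zero RPM in the young profile get a NaN ratio and a flag
    and are excluded from the tests.  Three rank-sum tests are reported:
    aged-vs-young RPMs across TE families, the same across IGE genes, and
    TE ratios versus gene ratios (is the TE shift larger than the gene
    baseline?).
    """
    if set(profile_aged.index) != set(profile_young.index):
        raise ValueError("profiles cover different target sets")
    young = profile_young.loc[profile_aged.index]
    table = pd.DataFrame(
        {
            "category": profile_aged["category"],
            "rpm_aged": profile_aged["rpm"],
            "rpm_young": young["rpm"],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["ratio"] = np.where(
            table["rpm_young"] > 0, table["rpm_aged"] / table["rpm_young"], np.nan
        )
    table["flagged_zero_young"] = table["rpm_young"] == 0

    tests: dict[str, TestResult] = {}
    for cat, label in (("TE", "te_rpm"), ("IGE", "gene_rpm")):
        sub = table[(table["category"] == cat) & ~table["flagged_zero_young"]]
        if len(sub) >= 2:
            tests[label] = rank_sum_test(sub["rpm_aged"], sub["rpm_young"])
    te_ratios = table.loc[(table["category"] == "TE") & ~table["flagged_zero_young"], "ratio"]
    gene_ratios = table.loc[(table["category"] == "IGE") & ~table["flagged_zero_young"], "ratio"]
    if len(te_ratios) >= 2 and len(gene_ratios) >= 2:
        tests["te_vs_gene_ratio"] = rank_sum_test(te_ratios, gene_ratios)
    return table, tests
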