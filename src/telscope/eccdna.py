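"""Quantitation of TE-derived extrachromosomal circular DNA (eccDNA).

An eccDNA-enriched library is counted against a *doubled-consensus* index:
each TE family consensus (and each spike-in plasmid) is concatenated
head-to-tail with itself, so a read crossing the circular junction maps
contiguously.  Alignments are canonicalized to ``start mod L``; a read is a
circular-junction read when its alignment covers the original end/start
boundary by at least ``m`` bases on each side.

Per family the module reports the raw read count ``x``, the library's total
aligned reads ``y``, the junction-spanning count ``j``, the depth
normalization ``rpm = (x/y) * 1e6`` and the spike-in normalized value
``v = ((x/y) * 1e6) / z`` where ``z`` aggregates the site-normalized
post-extraction plasmid counts per million aligned reads (spike-in
frequencies are depth-normalized exactly like the TE counts, so ``v`` is
invariant to subsampling).  The post-extraction plasmids share a backbone, so a read
matching ``k`` plasmid sites contributes ``1/k`` to each (mapping-site
normalization).  Pre-extraction plasmids (added before gDNA extraction) are
tracked separately: their ratio to the post-extraction set is the
extraction-recovery QC observable, and residual IGE reads measure leftover
linear DNA after exonuclease digestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .caller import _IntervalLookup
from .mapping import KmerIndex, _hash_str
from .simulate import PRE_EXTRACTION_REFERENCE, ReadPairs, ReferenceBundle, revcomp

__all__ = [
    "EccCount",
    "SpikeInCount",
    "EccQuantResult",
    "quantify_eccdna",
    "count_circle_reads",
    "count_spikeins",
    "spikein_normalize",
    "eccdna_aging_ratio",
    "spikein_qc",
]


@dataclass(frozen=True)
class EccCount:
    """Per-family eccDNA read accounting."""

    family: str
    x: int  # raw read count on the family
    y: int  # total aligned reads in the library
    z: float | None  # site-normalized post-extraction spike-in count per million aligned
    j: int  # circular-junction spanning reads (j <= x)

    @property
    def rpm_only(self) -> float:
        return 1e6 * self.x / self.y if self.y else 0.0

    @property
    def v(self) -> float | None:
        if self.z is None or self.z <= 0 or self.y <= 0:
            return None
        return spikein_normalize(self.x, self.y, self.z)


@dataclass(frozen=True)
class SpikeInCount:
    name: str
    role: str
    raw_reads: int  # reads with at least one site on this plasmid
    mean_sites: float  # mean mapping sites per read across all plasmids
    site_normalized: float  # sum over reads of (sites here / total sites)


@dataclass
class EccQuantResult:
    """Full per-library quantitation."""

    families: pd.DataFrame  # index family: x, j, rpm, v
    spikeins: pd.DataFrame  # index plasmid: role, raw_reads, mean_sites, site_normalized, rpm
    total_aligned: int  # y
    z: float | None
    ige_reads: int
    genome_reads: int

    def family_count(self, family: str) -> EccCount:
        row = self.families.loc[family]
        return EccCount(family, int(row["x"]), self.total_aligned, self.z, int(row["j"]))


def spikein_normalize(x: float, y: float, z: float) -> float:
    """Spike-in normalized read abundance ``((x/y) * 1e6) / z``."""
    if y <= 0:
        raise ValueError("total aligned reads y must be positive")
    if z <= 0:
        raise ValueError("spike-in count z must be positive")
    return (x / y) * 1e6 / z


def _doubled_index(seqs: dict[str, str], k: int) -> tuple[KmerIndex, dict[int, int]]:
    targets = {name: s + s for name, s in seqs.items()}
    idx = KmerIndex(targets, {n: "circle" for n in targets}, k=k)
    unit_len = {tid: len(idx.seqs[tid]) // 2 for tid in range(len(idx.names))}
    return idx, unit_len


def _all_circle_sites(idx: KmerIndex, unit_len: dict[int, int], seq: str, k: int) -> set[tuple[int, int, bool]]:
    """All verified placements of ``seq`` on a doubled index, canonicalized."""
    sites: set[tuple[int, int, bool]] = set()
    L = len(seq)
    for rev, s in ((False, seq), (True, revcomp(seq))):
        for tid, pos in idx.candidates(_hash_str(s, k)):
            t = idx.seqs[tid]
            if pos + L <= len(t) and t[pos : pos + L] == s:
                sites.add((tid, pos % unit_len[tid], rev))
    return sites


def _best_circle_hit(idx: KmerIndex, seq: str, k: int) -> tuple[int, int] | None:
    """Lowest-coordinate verified placement (canonical form on a doubled index)."""
    best = None
    L = len(seq)
    for s in (seq, revcomp(seq)):
        for tid, pos in idx.candidates(_hash_str(s, k)):
            t = idx.seqs[tid]
            if pos + L <= len(t) and t[pos : pos + L] == s:
                key = (idx.names[tid], pos)
                if best is None or key < best[0]:
                    best = (key, (tid, pos))
    return best[1] if best else None


def quantify_eccdna(
    reads: ReadPairs,
    bundle: ReferenceBundle,
    m: int = 10,
    k: int = 15,
) -> EccQuantResult:
    """Count an eccDNA library against families, spike-ins and the genome.

    Reads are assigned in priority order: spike-in plasmid (with 1/k
    mapping-site splitting), then best hit among doubled TE consensus and
    the linear genome.  Genome reads falling inside IGE intervals are
    tallied separately as the linear-contamination readout.
    """
    rl = reads.read_length
    junction_enabled = rl >= 2 * m
    if not junction_enabled:
        warnings.warn(f"read length {rl} < 2m = {2 * m}; junction detection disabled")

    fam_idx, fam_unit = _doubled_index(bundle.te_library, k)
    pla_idx, pla_unit = _doubled_index({p.name: p.seq for p in bundle.plasmids.values()}, k)
    genome_idx = KmerIndex(bundle.genome, {c: "genome" for c in bundle.genome}, k=k)
    ige_ann = _IntervalLookup(bundle.ige_intervals())

    x = {fam: 0 for fam in bundle.te_library}
    j = {fam: 0 for fam in bundle.te_library}
    raw = {p: 0 for p in bundle.plasmids}
    site_norm = {p: 0.0 for p in bundle.plasmids}
    sites_per_read = {p: [] for p in bundle.plasmids}
    y = 0
    ige_reads = 0
    genome_reads = 0

    for read_seq in _iter_reads(reads):
        plasmid_sites = _all_circle_sites(pla_idx, pla_unit, read_seq, k)
        if plasmid_sites:
            y += 1
            total_sites = len(plasmid_sites)
            per_plasmid: dict[int, int] = {}
            for tid, _pos, _rev in plasmid_sites:
                per_plasmid[tid] = per_plasmid.get(tid, 0) + 1
            for tid, n_sites in per_plasmid.items():
                name = pla_idx.names[tid]
                raw[name] += 1
                site_norm[name] += n_sites / total_sites
                sites_per_read[name].append(total_sites)
            continue
        fam_hit = _best_circle_hit(fam_idx, read_seq, k)
        if fam_hit is not None:
            tid, pos = fam_hit
            fam = fam_idx.names[tid]
            L = fam_unit[tid]
            y += 1
            x[fam] += 1
            if junction_enabled and pos <= L - m and pos + rl >= L + m:
                j[fam] += 1
            continue
        gen_hit = _best_circle_hit(genome_idx, read_seq, k)
        if gen_hit is not None:
            tid, pos = gen_hit
            y += 1
            genome_reads += 1
            chrom = genome_idx.names[tid]
            mid = pos + rl // 2
            if ige_ann.at(chrom, mid) is not None:
                ige_reads += 1

    post = [p for p in bundle.plasmids.values() if p.role == "post_extraction"]
    z_total = sum(site_norm[p.name] for p in post)
    # z is the depth-normalized spike-in count (site-normalized reads per
    # million aligned): plasmid frequencies are normalized by library depth
    # just like the TE counts, which makes v invariant to subsampling
    z: float | None = 1e6 * z_total / y if z_total > 0 and y > 0 else None
    if z is None:
        warnings.warn("no post-extraction spike-in reads; spike-in normalization withheld")

    fam_rows = []
    for fam in bundle.te_library:
        rpm = 1e6 * x[fam] / y if y else 0.0
        fam_rows.append(
            {
                "family": fam,
                "x": x[fam],
                "j": j[fam],
                "rpm": rpm,
                "v": rpm / z if z else np.nan,
            }
        )
    families = pd.DataFrame(fam_rows).set_index("family")

    spike_rows = []
    for p in bundle.plasmids.values():
        n_sites = sites_per_read[p.name]
        spike_rows.append(
            {
                "plasmid": p.name,
                "role": p.role,
                "raw_reads": raw[p.name],
                "mean_sites": float(np.mean(n_sites)) if n_sites else 0.0,
                "site_normalized": site_norm[p.name],
                "rpm": 1e6 * site_norm[p.name] / y if y else 0.0,
            }
        )
    spikeins = pd.DataFrame(spike_rows).set_index("plasmid")

    return EccQuantResult(families, spikeins, y, z, ige_reads, genome_reads)


def _iter_reads(reads: ReadPairs):
    for seq in reads.r1:
        yield seq
    for seq in reads.r2:
        yield seq


def count_circle_reads(reads: ReadPairs, bundle: ReferenceBundle, m: int = 10, k: int = 15) -> pd.DataFrame:
    """Per-family ``(x, j)`` counts against the doubled-consensus index."""
    return quantify_eccdna(reads, bundle, m=m, k=k).families[["x", "j"]]


def count_spikeins(reads: ReadPairs, bundle: ReferenceBundle, k: int = 15) -> tuple[list[SpikeInCount], float | None]:
    """Site-normalized spike-in counts plus the aggregate post-extraction z."""
    res = quantify_eccdna(reads, bundle, k=k)
    counts = [
        SpikeInCount(
            name,
            row["role"],
            int(row["raw_reads"]),
            float(row["mean_sites"]),
            float(row["site_normalized"]),
        )
        for name, row in res.spikeins.iterrows()
    ]
    return counts, res.z


def eccdna_aging_ratio(
    result_aged: EccQuantResult,
    result_young: EccQuantResult,
    mode: str = "spikein",
    preextraction_reference: str = PRE_EXTRACTION_REFERENCE,
) -> pd.DataFrame:
    """Per-family aged/young abundance ratios.

    ``mode`` selects the headline ratio column: ``rpm`` (library-depth
    normalization only), ``spikein`` (v ratios) or ``preextraction_plasmid``
    (RPM ratio further divided by the pre-extraction reference plasmid's RPM
    ratio).  RPM-only and spike-in ratios are always emitted side by side;
    families lacking a denominator are flagged.
    """
    if mode not in ("rpm", "spikein", "preextraction_plasmid"):
        raise ValueError(f"unknown mode {mode!r}")
    if set(result_aged.families.index) != set(result_young.families.index):
        raise ValueError("family universes differ between samples")
    aged = result_aged.families
    young = result_young.families.loc[aged.index]

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_rpm = np.where(young["rpm"] > 0, aged["rpm"] / young["rpm"], np.nan)
        ratio_spike = np.where(
            (young["v"] > 0) & np.isfinite(aged["v"]) & np.isfinite(young["v"]),
            aged["v"] / young["v"],
            np.nan,
        )
    table = pd.DataFrame(
        {
            "x_aged": aged["x"],
            "x_young": young["x"],
            "ratio_rpm": ratio_rpm,
            "ratio_spikein": ratio_spike,
        },
        index=aged.index,
    )
    if mode == "preextraction_plasmid":
        ref_aged = result_aged.spikeins.loc[preextraction_reference, "rpm"]
        ref_young = result_young.spikeins.loc[preextraction_reference, "rpm"]
        if ref_aged <= 0 or ref_young <= 0:
            raise ValueError("pre-extraction reference plasmid missing from a sample")
        table["ratio_preextraction"] = table["ratio_rpm"] / (ref_aged / ref_young)
        table["ratio"] = table["ratio_preextraction"]
    else:
        table["ratio"] = table["ratio_rpm"] if mode == "rpm" else table["ratio_spikein"]
    table["flagged"] = ~np.isfinite(table["ratio"])
    return table


def filter_by_circle_score(
    table: pd.DataFrame,
    circle_scores: pd.DataFrame,
    min_score: float = 50.0,
) -> pd.DataFrame:
    """Restrict a per-family table to families with an external circle score.

    ``circle_scores`` is a table from an external circle-discovery tool with
    columns ``family`` and ``circle_score``; the score itself is never
    computed here.  Families absent from the table or scoring below
    ``min_score`` are dropped.
    """
    if not {"family", "circle_score"} <= set(circle_scores.columns):
        raise ValueError("circle score table needs 'family' and 'circle_score' columns")
    keep = set(
        circle_scores.loc[circle_scores["circle_score"] > min_score, "family"]
    )
    return table.loc[[f for f in table.index if f in keep]]


@dataclass
class SpikeInQC:
    ratios: pd.DataFrame  # samples x post-extraction plasmids: post/pre-reference ratios
    cv: pd.Series  # per-plasmid coefficient of variation across samples
    ige_reads: pd.Series
    failed: dict[str, bool]
    flagged: pd.DataFrame  # ratio deviates more than 3x from the cross-sample median


def spikein_qc(
    results: Mapping[str, EccQuantResult],
    reference: str = PRE_EXTRACTION_REFERENCE,
) -> SpikeInQC:
    """Cross-sample spike-in consistency QC.

    For each sample, each post-extraction plasmid's site-normalized count is
    taken relative to the pre-extraction reference plasmid; consistent
    library prep gives near-constant ratios across samples (low CV).  A
    sample whose ratio departs more than 3-fold from the cross-sample median
    is flagged (e.g. an extraction-loss or over-spiking event).  Residual
    IGE read totals report leftover linear DNA.
    """
    rows = {}
    failed = {}
    ige = {}
    for sample, res in results.items():
        pre = res.spikeins.loc[reference, "site_normalized"]
        failed[sample] = pre <= 0
        post = res.spikeins[res.spikeins["role"] == "post_extraction"]
        rows[sample] = (
            post["site_normalized"] / pre if pre > 0 else post["site_normalized"] * np.nan
        )
        ige[sample] = res.ige_reads
    ratios = pd.DataFrame(rows).T
    ratios.index.name = "sample"
    mean = ratios.mean(axis=0)
    sd = ratios.std(axis=0, ddof=1) if len(ratios) > 1 else ratios.iloc[0] * 0.0
    cv = sd / mean.replace(0, np.nan)
    median = ratios.median(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = ratios / median
    flagged = (fold > 3.0) | (fold < 1.0 / 3.0)
    return SpikeInQC(ratios, cv, pd.Series(ige, name="ige_reads"), failed, flagged)
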