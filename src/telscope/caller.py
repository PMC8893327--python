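"""Non-reference TE insertion calling from two-sided junction evidence.

A new insertion in a pooled sample shows up in a ``genome_split`` alignment
as (a) split reads whose genomic segment abuts the junction while the
soft-clipped remainder maps to a TE consensus, and (b) discordant pairs with
one mate anchored uniquely in the genome and the other mate inside TE
sequence.  Evidence of one family is clustered per locus; a cluster becomes
a call only with at least ``min_total`` supporting reads **and** at least
``min_side`` reads on each flank of the junction — the two-sided rule that
suppresses one-sided chimeric artifacts.

Each accepted call gets a Coverage Ratio ``CR = i / (r + 1)`` where ``i`` is
the insertion-supporting read count and ``r`` the number of read pairs that
span the site cleanly (concordant, unclipped, no TE signal).  ``CR > 2``
marks deeply penetrant insertions; a rare insertion in a pool leaves most
haplotypes contributing reference-allele pairs, driving CR down.

Immobile gene elements (IGEs) are processed identically; any "insertion"
called against an IGE is, by construction, an artifact, so the IGE call rate
estimates the pipeline's false-positive rate.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mapping import Aln, AlignmentSet, _best_full_hit, _hash_str
from .simulate import ReferenceBundle, revcomp

__all__ = [
    "JunctionEvidence",
    "InsertionCall",
    "Landscape",
    "CallerParams",
    "gather_evidence",
    "cluster_and_call",
    "compute_cr",
    "attach_coverage_ratios",
    "call_insertions",
    "ige_fp_rate",
]


@dataclass(frozen=True)
class CallerParams:
    """Tunables of the insertion caller.

    ``window`` (cluster merge distance) defaults to insert mean + 2 SD of
    the default library model; ``max_fragment`` (concordance bound) to
    insert mean + 4 SD.  ``cr_span`` is the half-width around the junction a
    reference-allele pair must span cleanly; by default the read length.
    """

    min_total: int = 4
    min_side: int = 2
    min_clip: int = 15
    window: int = 420
    max_fragment: float = 490.0
    cr_span: int = 75


@dataclass(frozen=True)
class JunctionEvidence:
    chrom: str
    coord: int  # genomic coordinate estimate used for clustering
    side: str  # "L": genomic segment is the left flank; "R": right flank
    family: str
    category: str  # "TE" | "IGE"
    kind: str  # "split_read" | "discordant_pair"
    pair_index: int
    junction: int | None = None  # base-precise coordinate (split reads only)
    strand_vote: str | None = None


@dataclass
class InsertionCall:
    chrom: str
    position: int
    family: str
    orientation: str
    left_support: int
    right_support: int
    total_support: int
    category: str
    ref_reads: int | None = None
    cr: float | None = None
    cr_class: str | None = None

    def as_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "pos0": self.position,
            "family": self.family,
            "orient": self.orientation,
            "i_L": self.left_support,
            "i_R": self.right_support,
            "i": self.total_support,
            "r": self.ref_reads,
            "CR": self.cr,
            "cr_class": self.cr_class,
            "category": self.category,
        }


_CALL_COLUMNS = ["chrom", "pos0", "family", "orient", "i_L", "i_R", "i", "r", "CR", "cr_class", "category"]


@dataclass
class Landscape:
    """A sample's accepted TE insertion calls plus the separate IGE call list."""

    sample_id: str
    mapped_reads: int
    calls: list[InsertionCall]
    ige_calls: list[InsertionCall] = field(default_factory=list)

    @property
    def normalized_per_million(self) -> float:
        return 1e6 * len(self.calls) / self.mapped_reads

    def to_frame(self, which: str = "TE") -> pd.DataFrame:
        calls = self.calls if which == "TE" else self.ige_calls
        return pd.DataFrame([c.as_dict() for c in calls], columns=_CALL_COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        frames = [f for f in (self.to_frame("TE"), self.to_frame("IGE")) if not f.empty]
        df = pd.concat(frames, ignore_index=True) if frames else self.to_frame("TE")
        df.insert(0, "sample_id", self.sample_id)
        df.insert(1, "mapped_reads", self.mapped_reads)
        df.to_csv(path, sep="\t", index=False)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in sorted(self.calls, key=lambda c: (c.chrom, c.position)):
                fh.write(f"{c.chrom}\t{c.position}\t{c.position + 1}\t{c.family}\t{c.total_support}\t{c.orientation}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Landscape":
        df = pd.read_csv(path, sep="\t")
        calls, ige_calls = [], []
        for _, row in df.iterrows():
            call = InsertionCall(
                row["chrom"], int(row["pos0"]), row["family"], str(row["orient"]),
                int(row["i_L"]), int(row["i_R"]), int(row["i"]), row["category"],
                None if pd.isna(row["r"]) else int(row["r"]),
                None if pd.isna(row["CR"]) else float(row["CR"]),
                None if pd.isna(row["cr_class"]) else str(row["cr_class"]),
            )
            (calls if row["category"] == "TE" else ige_calls).append(call)
        return cls(
            str(df["sample_id"].iloc[0]) if len(df) else "sample",
            int(df["mapped_reads"].iloc[0]) if len(df) else 0,
            calls,
            ige_calls,
        )


class _IntervalLookup:
    """Point/interval queries against non-overlapping labelled intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[str]]] = {}
        per: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, label in intervals:
            per.setdefault(chrom, []).append((start, end, label))
        for chrom, ivls in per.items():
            ivls.sort()
            self._by_chrom[chrom] = (
                [s for s, _e, _l in ivls],
                [e for _s, e, _l in ivls],
                [l for _s, _e, l in ivls],
            )

    def at(self, chrom: str, pos: int) -> str | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, labels = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return labels[i]
        return None

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends, _labels = entry
        i = bisect.bisect_right(starts, end - 1) - 1
        return i >= 0 and start < ends[i]


def _classify_clip_target(
    alns: AlignmentSet,
    bundle: ReferenceBundle,
    hit: Aln,
    te_ann: _IntervalLookup,
    ige_ann: _IntervalLookup,
) -> tuple[str, str] | None:
    """Map a clip/mate placement to a (category, family-or-gene) label."""
    cat = alns.index.categories[hit.tid]
    name = alns.index.names[hit.tid]
    if cat == "TE":
        return "TE", name
    if cat == "IGE":
        return "IGE", name
    if cat == "genome":
        mid = hit.pos + hit.alen // 2
        fam = te_ann.at(name, mid)
        if fam is not None:
            return "TE", fam
        gene = ige_ann.at(name, mid)
        if gene is not None:
            return "IGE", gene
    return None


def gather_evidence(
    alns: AlignmentSet,
    bundle: ReferenceBundle,
    params: CallerParams = CallerParams(),
) -> list[JunctionEvidence]:
    """Collect split-read and discordant-pair junction evidence.

    Anchors (the genome-unique segment of the evidence) falling inside
    annotated pre-existing TE copies are excluded; without an annotation no
    exclusion is possible and every locus is eligible.
    """
    if alns.mode != "genome_split":
        raise ValueError("evidence gathering requires genome_split alignments")
    import warnings

    if not bundle.te_annotation:
        warnings.warn("no reference TE annotation; evidence at pre-existing copies not excluded")
    te_ann = _IntervalLookup(bundle.te_annotation)
    ige_ann = _IntervalLookup(bundle.ige_intervals())
    index = alns.index
    prio = {"genome": 0, "TE": 1, "IGE": 2, "plasmid": 3}
    k = index.k
    evidence: list[JunctionEvidence] = []

    for i in range(alns.n_pairs):
        pair = ((1, alns.a1[i], alns.a2[i]), (2, alns.a2[i], alns.a1[i]))
        # --- split reads ---------------------------------------------------
        # A junction read has a genome-unique segment and a TE/IGE-mapping
        # segment; either may be the primary alignment.  Case A: primary is
        # the clean genomic anchor, the clip labels the inserted element.
        # Case B: primary sits in TE/IGE territory (consensus or a
        # pre-existing copy) and the clip is the genome-unique flank.
        for mate, a, _other in pair:
            if not a.mapped or not a.is_clipped:
                continue
            clip_at_right = a.clip_right >= params.min_clip and a.clip_right >= a.clip_left
            if not clip_at_right and a.clip_left < params.min_clip:
                continue
            oseq = alns.oriented_seq(i, mate)
            if clip_at_right:
                clip_seq = oseq[a.clip_left + a.alen :]
            else:
                clip_seq = oseq[: a.clip_left]
            if len(clip_seq) < k:
                continue
            hit = _best_full_hit(
                index, prio, clip_seq, revcomp(clip_seq),
                _hash_str(clip_seq, k), _hash_str(revcomp(clip_seq), k),
            )
            if hit is None:
                continue
            a_cat = index.categories[a.tid]
            a_chrom = index.names[a.tid]
            a_clean = a_cat == "genome" and not te_ann.overlaps(a_chrom, a.pos, a.end)
            hit_cat = index.categories[hit.tid]
            hit_chrom = index.names[hit.tid]
            hit_clean = hit_cat == "genome" and not te_ann.overlaps(hit_chrom, hit.pos, hit.end)
            hit_label = _classify_clip_target(alns, bundle, hit, te_ann, ige_ann)
            vote = "+" if hit.rev == a.rev else "-"
            if a_clean and hit_label is not None:
                # case A: anchor = primary alignment
                category, family = hit_label
                if clip_at_right:
                    side, junction = "L", a.end
                else:
                    side, junction = "R", a.pos
                evidence.append(
                    JunctionEvidence(a_chrom, junction, side, family, category,
                                     "split_read", i, junction, vote)
                )
                continue
            a_label = _classify_clip_target(
                alns, bundle, Aln(a.tid, a.pos, a.rev, a.alen), te_ann, ige_ann
            )
            if a_label is not None and hit_clean:
                # case B: anchor = the genome-unique clip placement.  The
                # junction abuts the clip base adjacent to the aligned
                # segment; which genomic end that is depends on the clip
                # side and the strand the flank mapped on.
                category, family = a_label
                junction_at_end = (not clip_at_right) != hit.rev
                if junction_at_end:
                    side, junction = "L", hit.end
                else:
                    side, junction = "R", hit.pos
                evidence.append(
                    JunctionEvidence(hit_chrom, junction, side, family, category,
                                     "split_read", i, junction, vote)
                )
        # --- discordant pairs ---------------------------------------------
        a1, a2 = alns.a1[i], alns.a2[i]
        if not (a1.mapped and a2.mapped) or a1.is_clipped or a2.is_clipped:
            continue
        if _is_concordant(a1, a2, params.max_fragment):
            continue
        for _mate, anchor, other in pair:
            if index.categories[anchor.tid] != "genome":
                continue
            chrom = index.names[anchor.tid]
            if te_ann.overlaps(chrom, anchor.pos, anchor.end):
                continue
            label = _classify_clip_target(alns, bundle, other, te_ann, ige_ann)
            if label is None:
                continue
            category, family = label
            side = "L" if not anchor.rev else "R"
            coord = anchor.end if side == "L" else anchor.pos
            vote = "+" if other.rev != anchor.rev else "-"
            evidence.append(
                JunctionEvidence(chrom, coord, side, family, category,
                                 "discordant_pair", i, None, vote)
            )
    evidence.sort(key=lambda e: (e.category, e.family, e.chrom, e.coord))
    return evidence


def _is_concordant(a1: Aln, a2: Aln, max_fragment: float) -> bool:
    if not (a1.mapped and a2.mapped) or a1.tid != a2.tid or a1.rev == a2.rev:
        return False
    fwd, rev = (a1, a2) if not a1.rev else (a2, a1)
    frag = rev.end - fwd.pos
    return fwd.pos <= rev.pos and 0 < frag <= max_fragment


def cluster_and_call(
    evidence: Sequence[JunctionEvidence],
    params: CallerParams = CallerParams(),
) -> list[InsertionCall]:
    """Merge same-family evidence within ``window`` bp; apply the two-sided rule.

    Position is the median of split-read junction coordinates, falling back
    to the median of discordant-pair interval estimates; orientation by
    majority strand vote ('.' on a tie).
    """
    calls: list[InsertionCall] = []
    cluster: list[JunctionEvidence] = []

    def flush() -> None:
        if not cluster:
            return
        left = sum(e.side == "L" for e in cluster)
        right = len(cluster) - left
        if len(cluster) < params.min_total or min(left, right) < params.min_side:
            cluster.clear()
            return
        junctions = sorted(e.junction for e in cluster if e.junction is not None)
        if junctions:
            position = int(junctions[len(junctions) // 2])
        else:
            coords = sorted(e.coord for e in cluster)
            position = int(coords[len(coords) // 2])
        plus = sum(e.strand_vote == "+" for e in cluster)
        minus = sum(e.strand_vote == "-" for e in cluster)
        orient = "+" if plus > minus else "-" if minus > plus else "."
        e0 = cluster[0]
        calls.append(
            InsertionCall(e0.chrom, position, e0.family, orient, left, right,
                          len(cluster), e0.category)
        )
        cluster.clear()

    prev_key = None
    prev_coord = None
    for e in evidence:  # gather_evidence output is sorted
        key = (e.category, e.family, e.chrom)
        if key != prev_key or (prev_coord is not None and e.coord - prev_coord > params.window):
            flush()
        cluster.append(e)
        prev_key, prev_coord = key, e.coord
    flush()
    calls.sort(key=lambda c: (c.category, c.chrom, c.position, c.family))
    return calls


def compute_cr(insertion_reads: int, reference_reads: int) -> tuple[float, str]:
    """Coverage Ratio ``i / (r + 1)`` and its class (``gt2`` iff CR > 2)."""
    cr = insertion_reads / (reference_reads + 1)
    return cr, ("gt2" if cr > 2 else "le2")


def attach_coverage_ratios(
    calls: Sequence[InsertionCall],
    alns: AlignmentSet,
    params: CallerParams = CallerParams(),
) -> None:
    """Count clean spanning pairs per call and set CR in place.

    A pair counts toward ``r`` when both mates map the genome full-length
    (no clips), form a concordant pair, and the fragment covers the window
    ``[position - cr_span, position + cr_span]`` entirely.
    """
    index = alns.index
    frags: dict[str, list[tuple[int, int]]] = {}
    for a1, a2 in zip(alns.a1, alns.a2):
        if not _is_concordant(a1, a2, params.max_fragment):
            continue
        if a1.is_clipped or a2.is_clipped or index.categories[a1.tid] != "genome":
            continue
        fwd, rev = (a1, a2) if not a1.rev else (a2, a1)
        frags.setdefault(index.names[a1.tid], []).append((fwd.pos, rev.end))
    frag_arrays = {
        chrom: (np.array([s for s, _e in v]), np.array([e for _s, e in v]))
        for chrom, v in frags.items()
    }
    for call in calls:
        lo = call.position - params.cr_span
        hi = call.position + params.cr_span
        starts, ends = frag_arrays.get(call.chrom, (np.empty(0, int), np.empty(0, int)))
        r = int(np.count_nonzero((starts <= lo) & (ends >= hi)))
        call.ref_reads = r
        call.cr, call.cr_class = compute_cr(call.total_support, r)


def call_insertions(
    alns: AlignmentSet,
    bundle: ReferenceBundle,
    sample_id: str = "sample",
    params: CallerParams = CallerParams(),
) -> Landscape:
    """Full calling pipeline: evidence, clustering, two-sided filter, CR."""
    evidence = gather_evidence(alns, bundle, params)
    calls = cluster_and_call(evidence, params)
    attach_coverage_ratios(calls, alns, params)
    te_calls = [c for c in calls if c.category == "TE"]
    ige_calls = [c for c in calls if c.category == "IGE"]
    return Landscape(sample_id, alns.mapped_reads, te_calls, ige_calls)


def ige_fp_rate(landscape: Landscape) -> float:
    """IGE calls over all calls (TE + IGE); 0 when nothing was called."""
    denom = len(landscape.calls) + len(landscape.ige_calls)
    return len(landscape.ige_calls) / denom if denom else 0.0
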