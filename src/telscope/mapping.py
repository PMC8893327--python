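"""Read mapping against the combined reference, and depth matching.

The combined reference holds four target categories: genome chromosomes, TE
family consensus sequences, immobile-gene (IGE) sequences and spike-in
plasmids.  Two mapping contracts are provided:

``genome_split``
    best end-to-end placement with soft-clipped fallback: if a read has no
    full-length placement, its longest exactly-matching prefix or suffix is
    aligned and the remainder soft-clipped.  This preserves the junction
    evidence the insertion caller consumes.  Ties between targets prefer the
    genome.

``consensus_end_to_end``
    full-length placements only (no clipping); ties prefer consensus entries
    (TE/IGE/plasmid) over the genome.  This is the contract the per-family
    coverage profiler requires.

The mapper is an exact-seed mapper: a k-mer index over the reference with
full verification of every candidate.  It is sufficient for the synthetic
error-free libraries this package targets; a small number of substitutions
per read is tolerated through multi-offset seeding when ``max_mismatches``
is raised.  Multi-mapping reads take a single best hit, ties broken by
(category priority, target name, coordinate, strand) for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, ROUND_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np

from .simulate import ReadPairs, ReferenceBundle, revcomp

__all__ = [
    "KmerIndex",
    "Aln",
    "AlignmentSet",
    "DownsampleSpec",
    "align_reads",
    "downsample",
    "round_to_sig",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_PRIORITY = {
    "genome_split": {"genome": 0, "TE": 1, "IGE": 2, "plasmid": 3},
    "consensus_end_to_end": {"TE": 0, "IGE": 0, "plasmid": 0, "genome": 1},
}


def _hash_str(seq: str, k: int, offset: int = 0) -> int:
    h = 0
    for ch in seq[offset : offset + k]:
        h = (h << 2) | int(_CODE[ord(ch)])
    return h


class KmerIndex:
    """Sorted k-mer table over a set of named target sequences."""

    def __init__(self, targets: dict[str, str], categories: dict[str, str], k: int = 15):
        self.k = k
        self.names: list[str] = list(targets)
        self.seqs: list[str] = [targets[n] for n in self.names]
        self.categories: list[str] = [categories[n] for n in self.names]
        hashes: list[np.ndarray] = []
        tids: list[np.ndarray] = []
        positions: list[np.ndarray] = []
        for tid, seq in enumerate(self.seqs):
            if len(seq) < k:
                continue
            codes = _CODE[np.frombuffer(seq.encode("ascii"), np.uint8)]
            n = codes.size - k + 1
            h = np.zeros(n, np.uint64)
            for j in range(k):
                h = (h << np.uint64(2)) | codes[j : j + n].astype(np.uint64)
            hashes.append(h)
            tids.append(np.full(n, tid, np.int32))
            positions.append(np.arange(n, dtype=np.int64))
        h = np.concatenate(hashes)
        order = np.argsort(h, kind="stable")
        self._h = h[order]
        self._tid = np.concatenate(tids)[order]
        self._pos = np.concatenate(positions)[order]

    def candidates(self, h: int) -> list[tuple[int, int]]:
        lo = int(np.searchsorted(self._h, np.uint64(h), side="left"))
        if lo >= self._h.size or self._h[lo] != h:
            return []
        hi = int(np.searchsorted(self._h, np.uint64(h), side="right"))
        return list(zip(self._tid[lo:hi].tolist(), self._pos[lo:hi].tolist()))


def get_index(bundle: ReferenceBundle, k: int = 15) -> KmerIndex:
    """Combined-reference index, cached on the bundle."""
    cache = bundle.__dict__.setdefault("_index_cache", {})
    if k not in cache:
        targets: dict[str, str] = {}
        categories: dict[str, str] = {}
        for name, seq in bundle.iter_all_sequences():
            targets[name] = seq
            categories[name] = bundle.category_of(name)
        cache[k] = KmerIndex(targets, categories, k=k)
    return cache[k]


@dataclass(slots=True)
class Aln:
    """One read alignment; ``tid < 0`` means unmapped.

    Coordinates are on the forward strand of the target; ``rev`` records
    whether the read mapped as its reverse complement.  ``clip_left`` /
    ``clip_right`` are soft-clip lengths in target orientation.
    """

    tid: int = -1
    pos: int = 0
    rev: bool = False
    alen: int = 0
    clip_left: int = 0
    clip_right: int = 0
    nm: int = 0

    @property
    def mapped(self) -> bool:
        return self.tid >= 0

    @property
    def end(self) -> int:
        return self.pos + self.alen

    @property
    def is_clipped(self) -> bool:
        return self.clip_left > 0 or self.clip_right > 0


_UNMAPPED = Aln()


def _best_full_hit(
    index: KmerIndex,
    prio: dict[str, int],
    seq: str,
    rc: str,
    hf: int,
    hr: int,
) -> Aln | None:
    L = len(seq)
    best_key = None
    best = None
    for rev, s, h in ((False, seq, hf), (True, rc, hr)):
        for tid, pos in index.candidates(h):
            t = index.seqs[tid]
            if pos + L <= len(t) and t[pos : pos + L] == s:
                key = (prio[index.categories[tid]], index.names[tid], pos, rev)
                if best_key is None or key < best_key:
                    best_key = key
                    best = Aln(tid, pos, rev, L, 0, 0, 0)
    return best


def _best_mismatch_hit(
    index: KmerIndex,
    prio: dict[str, int],
    seq: str,
    rc: str,
    max_mm: int,
) -> Aln | None:
    k = index.k
    L = len(seq)
    offsets = sorted({0, k, 2 * k, L - k} & set(range(0, L - k + 1)))
    best_key = None
    best = None
    for rev, s in ((False, seq), (True, rc)):
        arr = np.frombuffer(s.encode("ascii"), np.uint8)
        for off in offsets:
            h = _hash_str(s, k, off)
            for tid, pos in index.candidates(h):
                start = pos - off
                t = index.seqs[tid]
                if start < 0 or start + L > len(t):
                    continue
                tarr = np.frombuffer(t[start : start + L].encode("ascii"), np.uint8)
                nm = int(np.count_nonzero(arr != tarr))
                if nm <= max_mm:
                    key = (nm, prio[index.categories[tid]], index.names[tid], start, rev)
                    if best_key is None or key < best_key:
                        best_key = key
                        best = Aln(tid, start, rev, L, 0, 0, nm)
    return best


def _best_split_hit(
    index: KmerIndex,
    prio: dict[str, int],
    seq: str,
    rc: str,
    hf: int,
    hr: int,
    hfe: int,
    hre: int,
    min_segment: int,
) -> Aln | None:
    """Longest exactly-matching prefix or suffix; remainder soft-clipped."""
    k = index.k
    L = len(seq)
    best_rank = None  # maximize segment length, then minimize tie-break key
    best = None
    for rev, s, h0, hend in ((False, seq, hf, hfe), (True, rc, hr, hre)):
        # prefix segment: seed at read start, extend right
        for tid, pos in index.candidates(h0):
            t = index.seqs[tid]
            limit = min(L, len(t) - pos)
            length = k
            while length < limit and t[pos + length] == s[length]:
                length += 1
            if length >= min_segment and length < L:
                key = (prio[index.categories[tid]], index.names[tid], pos, rev, 0)
                rank = (-length, key)
                if best_rank is None or rank < best_rank:
                    best_rank = rank
                    best = Aln(tid, pos, rev, length, 0, L - length, 0)
        # suffix segment: seed at read end, extend left
        for tid, pos in index.candidates(hend):
            t = index.seqs[tid]
            end = pos + k
            length = k
            while length < L and end - length - 1 >= 0 and t[end - length - 1] == s[L - length - 1]:
                length += 1
            if length >= min_segment and length < L:
                key = (prio[index.categories[tid]], index.names[tid], end - length, rev, 1)
                rank = (-length, key)
                if best_rank is None or rank < best_rank:
                    best_rank = rank
                    best = Aln(tid, end - length, rev, length, L - length, 0, 0)
    return best


@dataclass
class AlignmentSet:
    """Paired alignments of one library against the combined reference."""

    reads: ReadPairs
    index: KmerIndex
    mode: str
    a1: list[Aln]
    a2: list[Aln]

    @property
    def n_pairs(self) -> int:
        return len(self.reads)

    @property
    def total_reads(self) -> int:
        return 2 * len(self.reads)

    @property
    def mapped_reads(self) -> int:
        return sum(a.mapped for a in self.a1) + sum(a.mapped for a in self.a2)

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for alns in (self.a1, self.a2):
            for a in alns:
                if a.mapped:
                    cat = self.index.categories[a.tid]
                    counts[cat] = counts.get(cat, 0) + 1
        return counts

    def pair_mapped_counts(self) -> np.ndarray:
        """Mapped reads contributed by each pair (0, 1 or 2)."""
        return np.array(
            [int(x.mapped) + int(y.mapped) for x, y in zip(self.a1, self.a2)],
            dtype=np.int64,
        )

    def oriented_seq(self, i: int, mate: int) -> str:
        """Read sequence oriented to the target's forward strand."""
        seq = self.reads.r1[i] if mate == 1 else self.reads.r2[i]
        a = self.a1[i] if mate == 1 else self.a2[i]
        return revcomp(seq) if a.rev else seq

    def subset_pairs(self, keep: np.ndarray) -> "AlignmentSet":
        idx = np.flatnonzero(keep) if keep.dtype == bool else np.asarray(keep)
        return AlignmentSet(
            self.reads.subset(idx),
            self.index,
            self.mode,
            [self.a1[i] for i in idx],
            [self.a2[i] for i in idx],
        )

    # -- SAM/BAM ------------------------------------------------------------

    def to_bam(self, path: str | Path) -> Path:
        import pysam

        path = Path(path)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in zip(self.index.names, self.index.seqs)
            ],
        }
        records = []
        for i, (x, y) in enumerate(zip(self.a1, self.a2)):
            for mate, a, other in ((1, x, y), (2, y, x)):
                rec = pysam.AlignedSegment()
                rec.query_name = self.reads.names[i]
                flag = 0x1 | (0x40 if mate == 1 else 0x80)
                if not a.mapped:
                    flag |= 0x4
                if not other.mapped:
                    flag |= 0x8
                if a.rev:
                    flag |= 0x10
                if other.rev:
                    flag |= 0x20
                rec.flag = flag
                rec.query_sequence = self.oriented_seq(i, mate) if a.mapped else (
                    self.reads.r1[i] if mate == 1 else self.reads.r2[i]
                )
                rec.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(rec.query_sequence)
                )
                if a.mapped:
                    rec.reference_id = a.tid
                    rec.reference_start = a.pos
                    rec.mapping_quality = 60
                    cigar = []
                    if a.clip_left:
                        cigar.append((4, a.clip_left))
                    cigar.append((0, a.alen))
                    if a.clip_right:
                        cigar.append((4, a.clip_right))
                    rec.cigar = cigar
                    rec.set_tag("NM", a.nm)
                if other.mapped:
                    rec.next_reference_id = other.tid
                    rec.next_reference_start = other.pos
                records.append(rec)
        records.sort(key=lambda r: (r.reference_id if r.reference_id >= 0 else 1 << 30, r.reference_start))
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for rec in records:
                bam.write(rec)
        pysam.index(str(path))
        return path

    @classmethod
    def from_bam(cls, path: str | Path, bundle: ReferenceBundle, mode: str, k: int = 15) -> "AlignmentSet":
        import pysam

        index = get_index(bundle, k=k)
        tid_map = {name: t for t, name in enumerate(index.names)}
        pairs: dict[str, dict[int, tuple[Aln, str]]] = {}
        with pysam.AlignmentFile(str(path), "rb") as bam:
            for rec in bam:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                mate = 1 if rec.is_read1 else 2
                if rec.is_unmapped:
                    a = Aln()
                    seq = rec.query_sequence
                else:
                    cl = rec.cigartuples[0][1] if rec.cigartuples[0][0] == 4 else 0
                    cr = rec.cigartuples[-1][1] if rec.cigartuples[-1][0] == 4 else 0
                    alen = rec.query_alignment_length
                    a = Aln(
                        tid_map[rec.reference_name],
                        rec.reference_start,
                        rec.is_reverse,
                        alen,
                        cl,
                        cr,
                        int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    )
                    seq = revcomp(rec.query_sequence) if rec.is_reverse else rec.query_sequence
                pairs.setdefault(rec.query_name, {})[mate] = (a, seq)
        names, r1, r2, a1, a2 = [], [], [], [], []
        for name in pairs:
            entry = pairs[name]
            if 1 not in entry or 2 not in entry:
                continue
            names.append(name)
            a1.append(entry[1][0])
            r1.append(entry[1][1])
            a2.append(entry[2][0])
            r2.append(entry[2][1])
        return cls(ReadPairs(names, r1, r2), index, mode, a1, a2)


def _batch_first_last_hashes(seqs: Sequence[str], k: int):
    n = len(seqs)
    L = len(seqs[0])
    arr = np.frombuffer("".join(seqs).encode("ascii"), np.uint8).reshape(n, L)
    codes = _CODE[arr]
    rcodes = (3 - codes)[:, ::-1]
    out = []
    for c in (codes, rcodes):
        for start in (0, L - k):
            h = np.zeros(n, np.uint64)
            for j in range(start, start + k):
                h = (h << np.uint64(2)) | c[:, j].astype(np.uint64)
            out.append(h)
    return out  # fwd_first, fwd_last, rev_first, rev_last


def align_reads(
    reads: ReadPairs | tuple[str | Path, str | Path],
    bundle: ReferenceBundle,
    mode: str = "genome_split",
    k: int = 15,
    min_segment: int = 20,
    max_mismatches: int = 0,
) -> AlignmentSet:
    """Align a paired library against the combined reference.

    Returns an :class:`AlignmentSet`; each read carries at most one best
    placement with soft-clip information preserved (``genome_split``) or a
    full-length-only placement (``consensus_end_to_end``).
    """
    if mode not in _PRIORITY:
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(reads, ReadPairs):
        reads = ReadPairs.from_fastq(*reads)
    if len(reads) == 0:
        raise ValueError("empty read set")
    index = get_index(bundle, k=k)
    prio = _PRIORITY[mode]
    split = mode == "genome_split"

    alns: list[list[Aln]] = []
    for mate_reads in (reads.r1, reads.r2):
        uniform = len({len(s) for s in mate_reads}) == 1 and len(mate_reads[0]) >= k
        if uniform:
            hf, hfe, hr, hre = _batch_first_last_hashes(mate_reads, k)
        out: list[Aln] = []
        for i, seq in enumerate(mate_reads):
            rc = revcomp(seq)
            if uniform:
                h0, he, h0r, her = int(hf[i]), int(hfe[i]), int(hr[i]), int(hre[i])
            else:
                h0, he = _hash_str(seq, k), _hash_str(seq, k, len(seq) - k)
                h0r, her = _hash_str(rc, k), _hash_str(rc, k, len(rc) - k)
            a = _best_full_hit(index, prio, seq, rc, h0, h0r)
            if a is None and max_mismatches > 0:
                a = _best_mismatch_hit(index, prio, seq, rc, max_mismatches)
            if a is None and split:
                a = _best_split_hit(index, prio, seq, rc, h0, h0r, he, her, min_segment)
            out.append(a if a is not None else _UNMAPPED)
        alns.append(out)

    return AlignmentSet(reads, index, mode, alns[0], alns[1])


# ---------------------------------------------------------------------------
# depth matching
# ---------------------------------------------------------------------------


def round_to_sig(x: float, n: int = 4, mode: str = "up") -> float:
    """Round to ``n`` significant digits; ``mode='up'`` rounds away from zero.

    The depth-matching protocol rounds the mapped-read ratio *up* at the 4th
    significant digit (0.572135 -> 0.5722); nearest-rounding is available via
    ``mode='nearest'``.
    """
    if x <= 0:
        raise ValueError("x must be positive")
    d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(d.adjusted() - (n - 1))
    rounding = ROUND_UP if mode == "up" else ROUND_HALF_EVEN
    return float(d.quantize(q, rounding=rounding))


@dataclass(frozen=True)
class DownsampleSpec:
    """Record of a depth-matching subsample."""

    fraction: float
    seed: int
    mapped_low: int
    mapped_deep: int
    tolerance: float = 1e-4  # tolerated relative mapped-read difference after re-mapping


def downsample(
    reads: ReadPairs,
    mapped_low: int,
    mapped_deep: int,
    seed: int,
    rounding: str = "up",
) -> tuple[ReadPairs, DownsampleSpec]:
    """Subsample read pairs so mapped depth matches a shallower library.

    The keep fraction is ``mapped_low / mapped_deep`` rounded up to 4
    significant digits; each pair is kept independently with that
    probability under the seed, atomically (no orphan mates).
    """
    if mapped_low > mapped_deep:
        raise ValueError("mapped_low must be <= mapped_deep")
    if mapped_deep <= 0:
        raise ValueError("mapped_deep must be positive")
    if mapped_low == mapped_deep:
        spec = DownsampleSpec(1.0, seed, mapped_low, mapped_deep)
        return reads, spec
    f = round_to_sig(mapped_low / mapped_deep, 4, mode=rounding)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < f
    return reads.subset(keep), DownsampleSpec(f, seed, mapped_low, mapped_deep)
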