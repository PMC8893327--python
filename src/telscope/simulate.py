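"""Synthetic reference bundles, pooled samples and sequencing libraries.

Every downstream stage of the pipeline (mapping, insertion calling, coverage
profiling, landscape comparison, eccDNA quantitation) is exercised on data
produced here, so each generator is fully seeded and ships a truth table that
makes its output attributable: WGS read names encode the source haplotype and
fragment, eccDNA read names encode the source circle.

The pooled-sample model is a bag of ``2N`` haplotypes (``N`` individuals).
Penetrance of a planted insertion is its haplotype frequency; an entry with
penetrance ``p`` is carried by exactly ``round(p * 2N)`` haplotypes chosen by
a seeded draw.  There is no diploid pairing logic — the model mirrors pooled
whole-animal sequencing where only allele frequency is observable.

Coordinates are 0-based, half-open throughout; BED output follows the same
convention.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "revcomp",
    "random_dna",
    "Plasmid",
    "ReferenceBundle",
    "InsertionSite",
    "InsertionPlan",
    "SeqParams",
    "CirclePlan",
    "SampleModel",
    "ReadPairs",
    "build_reference",
    "plant_insertions",
    "random_insertion_plan",
    "simulate_wgs",
    "simulate_eccdna",
    "default_circle_plan",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length ``n``."""
    return _BASES[rng.integers(0, 4, int(n))].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# reference bundle
# ---------------------------------------------------------------------------

#: default spike-in roster: (name, length bp, role, relative abundance in ng)
#: four plasmids added after gDNA extraction at a 1000-fold concentration range,
#: plus two added before extraction whose recovery tracks extraction efficiency.
DEFAULT_PLASMIDS: tuple[tuple[str, int, str, float], ...] = (
    ("pUC19", 2700, "post_extraction", 1.0),
    ("pMaxGFP", 3500, "post_extraction", 0.1),
    ("pGSH0", 5200, "post_extraction", 0.01),
    ("pCENPm3", 6300, "post_extraction", 0.001),
    ("pGL3-DmPiwipro1", 7000, "pre_extraction", 0.08),
    ("pJDS246-CarhCas9", 11000, "pre_extraction", 0.05),
)

#: name of the pre-extraction plasmid used as the default QC reference
PRE_EXTRACTION_REFERENCE = "pGL3-DmPiwipro1"


@dataclass(frozen=True)
class Plasmid:
    """A spike-in plasmid: a shared backbone plus a unique insert."""

    name: str
    seq: str
    role: str  # "pre_extraction" | "post_extraction"
    abundance: float  # relative mass added to the prep

    @property
    def size(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceBundle:
    """Genome, TE consensus library, immobile-gene set and spike-in plasmids.

    ``ige_set`` maps gene name to ``(sequence, (chrom, start, end))``; IGE
    sequences are exact sub-intervals of the genome, tracked like TE consensus
    entries so that any "insertion" called against them measures the artifact
    rate.  ``te_annotation`` records the pre-existing full-length TE copies
    embedded in the genome (one per family by default) as
    ``(chrom, start, end, family)``.
    """

    genome: dict[str, str]
    te_library: dict[str, str]
    ige_set: dict[str, tuple[str, tuple[str, int, int]]]
    plasmids: dict[str, Plasmid]
    te_annotation: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names: list[str] = [*self.genome, *self.te_library, *self.ige_set, *self.plasmids]
        if len(set(names)) != len(names):
            raise ValueError("reference names must be unique across categories")
        for name, seq in self.iter_all_sequences():
            if not seq:
                raise ValueError(f"empty sequence: {name}")
            if not _ALPHABET.issuperset(seq):
                raise ValueError(f"non-ACGT characters in {name}")
        for gene, (seq, (chrom, start, end)) in self.ige_set.items():
            if chrom not in self.genome:
                raise ValueError(f"IGE {gene} on unknown chrom {chrom}")
            if not (0 <= start < end <= len(self.genome[chrom])):
                raise ValueError(f"IGE {gene} interval out of genome bounds")
            if len(seq) != end - start:
                raise ValueError(f"IGE {gene} sequence/interval length mismatch")

    def iter_all_sequences(self) -> Iterable[tuple[str, str]]:
        yield from self.genome.items()
        yield from self.te_library.items()
        for gene, (seq, _ivl) in self.ige_set.items():
            yield gene, seq
        for p in self.plasmids.values():
            yield p.name, p.seq

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.genome.values())

    def ige_intervals(self) -> list[tuple[str, int, int, str]]:
        return [(c, s, e, g) for g, (_q, (c, s, e)) in self.ige_set.items()]

    def category_of(self, target: str) -> str:
        if target in self.genome:
            return "genome"
        if target in self.te_library:
            return "TE"
        if target in self.ige_set:
            return "IGE"
        if target in self.plasmids:
            return "plasmid"
        raise KeyError(target)

    # -- serialization ------------------------------------------------------

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "genome.fa", self.genome)
        write_fasta(out / "te_library.fa", self.te_library)
        write_fasta(out / "ige.fa", {g: s for g, (s, _i) in self.ige_set.items()})
        write_fasta(out / "plasmids.fa", {p.name: p.seq for p in self.plasmids.values()})
        with open(out / "ige.bed", "w") as fh:
            for chrom, start, end, gene in self.ige_intervals():
                fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")
        with open(out / "te_annotation.bed", "w") as fh:
            for chrom, start, end, fam in self.te_annotation:
                fh.write(f"{chrom}\t{start}\t{end}\t{fam}\n")
        manifest = {
            "ige": {g: list(ivl) for g, (_s, ivl) in self.ige_set.items()},
            "plasmids": {
                p.name: {"role": p.role, "size": p.size, "abundance": p.abundance}
                for p in self.plasmids.values()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "ReferenceBundle":
        src = Path(in_dir)
        genome = read_fasta(src / "genome.fa")
        te_library = read_fasta(src / "te_library.fa")
        ige_seqs = read_fasta(src / "ige.fa")
        plasmid_seqs = read_fasta(src / "plasmids.fa")
        manifest = json.loads((src / "manifest.json").read_text())
        ige_set = {
            g: (ige_seqs[g], tuple(ivl)) for g, ivl in manifest["ige"].items()
        }
        plasmids = {
            name: Plasmid(name, plasmid_seqs[name], meta["role"], meta["abundance"])
            for name, meta in manifest["plasmids"].items()
        }
        te_annotation = []
        ann = src / "te_annotation.bed"
        if ann.exists():
            for line in ann.read_text().splitlines():
                chrom, start, end, fam = line.split("\t")
                te_annotation.append((chrom, int(start), int(end), fam))
        return cls(genome, te_library, ige_set, plasmids, te_annotation)


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _place_intervals(
    rng: np.random.Generator,
    chrom_len: int,
    lengths: Sequence[int],
    occupied: list[tuple[int, int]],
    margin: int = 200,
    edge: int = 5000,
    max_tries: int = 10000,
) -> list[tuple[int, int]]:
    """Sample non-overlapping intervals, rejecting overlap with ``occupied``."""
    placed: list[tuple[int, int]] = []
    taken = list(occupied)
    for length in lengths:
        for _ in range(max_tries):
            start = int(rng.integers(edge, chrom_len - edge - length))
            end = start + length
            if all(end + margin <= s or start >= e + margin for s, e in taken):
                placed.append((start, end))
                taken.append((start, end))
                break
        else:
            raise ValueError("could not place interval; genome too crowded")
    return placed


def build_reference(
    genome_length: int = 1_000_000,
    n_chroms: int = 1,
    n_te_families: int = 5,
    n_ige: int = 100,
    seed: int = 0,
    te_length: int = 5000,
    ige_length: int = 1500,
    backbone_length: int = 800,
    plasmid_spec: Sequence[tuple[str, int, str, float]] = DEFAULT_PLASMIDS,
) -> ReferenceBundle:
    """Build a deterministic synthetic reference bundle.

    Each TE family gets one full-length pre-existing copy embedded in the
    genome (recorded in ``te_annotation``), so consensus mapping competes with
    a genomic copy as it does for a real repeat.  IGEs are sub-intervals of
    the genome.  Spike-in plasmids share a common backbone so that multi-site
    read assignment is non-trivial.
    """
    per_chrom = genome_length // n_chroms
    if per_chrom < 100_000:
        raise ValueError("need at least 100 kb per chromosome")
    if n_te_families < 1 or n_ige < 0:
        raise ValueError("need at least one TE family")
    rng = np.random.default_rng(seed)

    te_library = {f"TE{i + 1}": random_dna(rng, te_length) for i in range(n_te_families)}

    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    genome_arrays = {c: bytearray(random_dna(rng, per_chrom), "ascii") for c in chrom_names}

    te_annotation: list[tuple[str, int, int, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for i, (fam, seq) in enumerate(te_library.items()):
        chrom = chrom_names[i % n_chroms]
        (ivl,) = _place_intervals(rng, per_chrom, [len(seq)], occupied[chrom])
        occupied[chrom].append(ivl)
        start, end = ivl
        genome_arrays[chrom][start:end] = seq.encode("ascii")
        te_annotation.append((chrom, start, end, fam))

    genome = {c: bytes(a).decode("ascii") for c, a in genome_arrays.items()}

    ige_set: dict[str, tuple[str, tuple[str, int, int]]] = {}
    per_chrom_n = [n_ige // n_chroms + (1 if i < n_ige % n_chroms else 0) for i in range(n_chroms)]
    gi = 0
    for chrom, n_here in zip(chrom_names, per_chrom_n):
        ivls = _place_intervals(rng, per_chrom, [ige_length] * n_here, occupied[chrom])
        occupied[chrom].extend(ivls)
        for start, end in ivls:
            gi += 1
            name = f"IGE{gi:03d}"
            ige_set[name] = (genome[chrom][start:end], (chrom, start, end))

    # the post-extraction cocktail shares one cloning backbone (multi-site
    # read assignment is non-trivial there); pre-extraction plasmids are
    # unrelated vectors with fully unique sequence
    backbone = random_dna(rng, backbone_length)
    plasmids = {}
    for name, size, role, abund in plasmid_spec:
        if role == "post_extraction":
            seq = backbone + random_dna(rng, size - backbone_length)
        else:
            seq = random_dna(rng, size)
        plasmids[name] = Plasmid(name, seq, role, abund)

    return ReferenceBundle(genome, te_library, ige_set, plasmids, te_annotation)


# ---------------------------------------------------------------------------
# insertion plans and pooled samples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InsertionSite:
    """One planned non-reference insertion.

    ``position`` is the 0-based genomic base of the 5' junction; the TE
    sequence is spliced in between ``position - 1`` and ``position``.
    ``truncation``, when given, is a half-open slice of the consensus.
    """

    chrom: str
    position: int
    family: str
    penetrance: float = 1.0
    orientation: str = "+"
    truncation: tuple[int, int] | None = None


@dataclass
class InsertionPlan:
    entries: list[InsertionSite]
    min_spacing: int = 150  # twice the default read length

    def validate(self, bundle: ReferenceBundle) -> None:
        by_chrom: dict[str, list[int]] = {}
        for e in self.entries:
            if e.chrom not in bundle.genome:
                raise ValueError(f"unknown chrom {e.chrom}")
            if not (0 <= e.position <= len(bundle.genome[e.chrom])):
                raise ValueError(f"position {e.position} outside {e.chrom}")
            if e.family not in bundle.te_library:
                raise ValueError(f"unknown TE family {e.family}")
            if not (0.0 < e.penetrance <= 1.0):
                raise ValueError("penetrance must be in (0, 1]")
            if e.orientation not in "+-":
                raise ValueError("orientation must be + or -")
            by_chrom.setdefault(e.chrom, []).append(e.position)
        for chrom, positions in by_chrom.items():
            positions.sort()
            for a, b in zip(positions, positions[1:]):
                if b - a < self.min_spacing:
                    raise ValueError(
                        f"insertions {a} and {b} on {chrom} closer than "
                        f"min_spacing={self.min_spacing}"
                    )


def random_insertion_plan(
    bundle: ReferenceBundle,
    n: int,
    penetrance: float | Sequence[float] = 1.0,
    seed: int = 0,
    min_spacing: int = 150,
    margin: int = 500,
    families: Sequence[str] | None = None,
) -> InsertionPlan:
    """Draw ``n`` well-separated insertion sites avoiding reference TE copies."""
    rng = np.random.default_rng(seed)
    fams = list(families or bundle.te_library)
    pens = (
        list(penetrance)
        if isinstance(penetrance, (list, tuple, np.ndarray))
        else [float(penetrance)] * n
    )
    if len(pens) != n:
        raise ValueError("penetrance list length must equal n")
    chroms = list(bundle.genome)
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, start, end, _fam in bundle.te_annotation:
        forbidden[chrom].append((start - margin, end + margin))
    entries: list[InsertionSite] = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = len(bundle.genome[chrom])
        for _ in range(10000):
            pos = int(rng.integers(5000, clen - 5000))
            if any(s <= pos < e for s, e in forbidden[chrom]):
                continue
            forbidden[chrom].append((pos - min_spacing, pos + min_spacing))
            entries.append(
                InsertionSite(chrom, pos, fams[i % len(fams)], pens[i], "+")
            )
            break
        else:
            raise ValueError("could not place insertion; genome too crowded")
    return InsertionPlan(entries, min_spacing=min_spacing)


@dataclass
class SampleModel:
    """A pooled population of ``2 * n_individuals`` haplotypes."""

    bundle: ReferenceBundle
    plan: InsertionPlan
    n_individuals: int
    carriers: list[np.ndarray]  # per plan entry, sorted haplotype indices
    seed: int = 0

    def __post_init__(self) -> None:
        self._hap_cache: dict[int, dict[str, str]] = {}

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_individuals

    def haplotype_entries(self, hap: int) -> list[InsertionSite]:
        return [
            e
            for e, carr in zip(self.plan.entries, self.carriers)
            if hap in carr  # carrier arrays are tiny; linear scan is fine
        ]

    def insertion_sequence(self, entry: InsertionSite) -> str:
        seq = self.bundle.te_library[entry.family]
        if entry.truncation is not None:
            seq = seq[entry.truncation[0] : entry.truncation[1]]
        if entry.orientation == "-":
            seq = revcomp(seq)
        return seq

    def haplotype(self, hap: int) -> dict[str, str]:
        """Haplotype sequences, with carried insertions spliced in."""
        if hap in self._hap_cache:
            return self._hap_cache[hap]
        out: dict[str, str] = {}
        entries = sorted(self.haplotype_entries(hap), key=lambda e: (e.chrom, e.position))
        for chrom, ref in self.bundle.genome.items():
            parts: list[str] = []
            prev = 0
            for e in entries:
                if e.chrom != chrom:
                    continue
                parts.append(ref[prev : e.position])
                parts.append(self.insertion_sequence(e))
                prev = e.position
            parts.append(ref[prev:])
            out[chrom] = "".join(parts)
        self._hap_cache[hap] = out
        return out

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for e, carr in zip(self.plan.entries, self.carriers):
            rows.append(
                {
                    "chrom": e.chrom,
                    "position": e.position,
                    "family": e.family,
                    "orientation": e.orientation,
                    "penetrance": e.penetrance,
                    "n_carriers": len(carr),
                    "carrier_frequency": len(carr) / self.n_haplotypes,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "position",
                "family",
                "orientation",
                "penetrance",
                "n_carriers",
                "carrier_frequency",
            ],
        )


def plant_insertions(
    bundle: ReferenceBundle,
    plan: InsertionPlan,
    n_individuals: int,
    seed: int = 0,
) -> SampleModel:
    """Assign each planned insertion to ``round(p * 2N)`` seeded haplotypes."""
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    plan.validate(bundle)
    rng = np.random.default_rng(seed)
    two_n = 2 * n_individuals
    carriers = []
    for e in plan.entries:
        k = min(int(round(e.penetrance * two_n)), two_n)
        carriers.append(np.sort(rng.choice(two_n, size=k, replace=False)))
    return SampleModel(bundle, plan, n_individuals, carriers, seed=seed)


# ---------------------------------------------------------------------------
# read containers
# ---------------------------------------------------------------------------


@dataclass
class ReadPairs:
    """Paired-end reads held in memory; FASTQ at the edges."""

    names: list[str]
    r1: list[str]
    r2: list[str]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.r1) == len(self.r2)):
            raise ValueError("names/r1/r2 must have equal length")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def read_length(self) -> int:
        return len(self.r1[0]) if self.r1 else 0

    def subset(self, keep: np.ndarray) -> "ReadPairs":
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return ReadPairs(
            [self.names[i] for i in idx],
            [self.r1[i] for i in idx],
            [self.r2[i] for i in idx],
        )

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        for path, reads, mate in ((path1, self.r1, 1), (path2, self.r2, 2)):
            opener = gzip.open if str(path).endswith(".gz") else open
            with opener(str(path), "wt") as fh:
                for name, seq in zip(self.names, reads):
                    fh.write(f"@{name}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")

    @classmethod
    def from_fastq(cls, path1: str | Path, path2: str | Path) -> "ReadPairs":
        import pysam

        names: list[str] = []
        r1: list[str] = []
        r2: list[str] = []
        with pysam.FastxFile(str(path1)) as fh1, pysam.FastxFile(str(path2)) as fh2:
            for e1, e2 in zip(fh1, fh2):
                name = e1.name
                if name.endswith("/1"):
                    name = name[:-2]
                names.append(name)
                r1.append(e1.sequence.upper())
                r2.append(e2.sequence.upper())
        if not names:
            raise ValueError(f"no reads in {path1}")
        return cls(names, r1, r2)


# ---------------------------------------------------------------------------
# WGS simulation
# ---------------------------------------------------------------------------


@dataclass
class SeqParams:
    """Paired-end sequencing parameters.

    The default library is error-free so that algorithmic behaviour can be
    tested in isolation; substitution errors and chimeric artifacts are
    opt-in.  Chimeric templates model PCR/template-switching artifacts: a
    genomic locus with a random foreign segment spliced into it, amplified
    into ``chimera_amplification`` read pairs, which is what lets an artifact
    accumulate junction support on both flanks of one locus.
    """

    read_length: int = 75
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    depth: float = 20.0
    error_rate: float = 0.0
    chimera_rate: float = 0.0
    chimera_amplification: int = 20
    chimera_segment: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for rate in (self.error_rate, self.chimera_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("rates must be in [0, 1)")

    @property
    def max_concordant_fragment(self) -> float:
        return self.insert_mean + 4.0 * self.insert_sd


def _fragment_lengths(rng: np.random.Generator, n: int, params: SeqParams) -> np.ndarray:
    ilen = np.rint(rng.normal(params.insert_mean, params.insert_sd, n)).astype(np.int64)
    return np.maximum(ilen, params.read_length)  # truncated normal, min = read length


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = bytearray(seq, "ascii")
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        arr[pos] = _BASES[(np.searchsorted(_BASES, arr[pos]) + rng.integers(1, 4)) % 4]
    return arr.decode("ascii")


def simulate_wgs(
    sample: SampleModel,
    params: SeqParams,
    out_dir: str | Path | None = None,
) -> tuple[ReadPairs, pd.DataFrame]:
    """Simulate a pooled paired-end WGS library from a sample model.

    The pair count is ``round(depth * genome_length / (2 * read_length))``.
    Fragments are drawn uniformly per haplotype; read 1 is the forward end of
    the fragment and read 2 the reverse complement of its other end.  Read
    names encode provenance (``p{i}:h{hap}:{chrom}:{start}:{len}`` for
    genuine fragments, ``p{i}:chim{t}:...`` for chimeric ones).
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    genome_length = sample.bundle.genome_length
    n_pairs = int(round(params.depth * genome_length / (2 * rl)))
    n_chim = int(round(params.chimera_rate * n_pairs))
    n_norm = n_pairs - n_chim
    two_n = sample.n_haplotypes

    names: list[str] = []
    r1: list[str] = []
    r2: list[str] = []

    hap_of_pair = rng.integers(0, two_n, n_norm)
    hap_counts = np.bincount(hap_of_pair, minlength=two_n)
    pair_id = 0
    for hap in range(two_n):
        m = int(hap_counts[hap])
        if m == 0:
            continue
        seqs = sample.haplotype(hap)
        chroms = list(seqs)
        lens = np.array([len(seqs[c]) for c in chroms], dtype=float)
        chrom_idx = rng.choice(len(chroms), size=m, p=lens / lens.sum())
        ilens = _fragment_lengths(rng, m, params)
        starts = rng.random(m)
        for ci, ilen, u in zip(chrom_idx, ilens, starts):
            chrom = chroms[ci]
            seq = seqs[chrom]
            ilen = int(min(ilen, len(seq)))
            start = int(u * (len(seq) - ilen + 1))
            frag = seq[start : start + ilen]
            a, b = frag[:rl], revcomp(frag[-rl:])
            if params.error_rate > 0:
                a = _mutate(a, rng, params.error_rate)
                b = _mutate(b, rng, params.error_rate)
            names.append(f"p{pair_id}:h{hap}:{chrom}:{start}:{ilen}")
            r1.append(a)
            r2.append(b)
            pair_id += 1

    if n_chim:
        genome = sample.bundle.genome
        chroms = list(genome)
        lens = np.array([len(genome[c]) for c in chroms], dtype=float)
        seg = params.chimera_segment
        n_templates = max(1, int(round(n_chim / params.chimera_amplification)))
        per_template = np.full(n_templates, n_chim // n_templates)
        per_template[: n_chim % n_templates] += 1
        for t in range(n_templates):
            ca = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
            cb = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
            a_pos = int(rng.integers(seg, len(genome[ca]) - seg))
            b_pos = int(rng.integers(0, len(genome[cb]) - seg))
            template = (
                genome[ca][a_pos - seg : a_pos]
                + genome[cb][b_pos : b_pos + seg]
                + genome[ca][a_pos : a_pos + seg]
            )
            ilens = _fragment_lengths(rng, int(per_template[t]), params)
            for ilen in ilens:
                ilen = int(min(ilen, len(template)))
                start = int(rng.integers(0, len(template) - ilen + 1))
                frag = template[start : start + ilen]
                a, b = frag[:rl], revcomp(frag[-rl:])
                if params.error_rate > 0:
                    a = _mutate(a, rng, params.error_rate)
                    b = _mutate(b, rng, params.error_rate)
                names.append(f"p{pair_id}:chim{t}:{ca}:{a_pos}:{cb}:{b_pos}:{start}:{ilen}")
                r1.append(a)
                r2.append(b)
                pair_id += 1

    reads = ReadPairs(names, r1, r2)
    truth = sample.truth_table()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        reads.write_fastq(out / "reads_1.fastq", out / "reads_2.fastq")
        truth.to_csv(out / "truth_insertions.tsv", sep="\t", index=False)
    return reads, truth


# ---------------------------------------------------------------------------
# eccDNA simulation
# ---------------------------------------------------------------------------


@dataclass
class CirclePlan:
    """Composition of an eccDNA-enriched library.

    ``circles`` lists ``(source, copies)`` where the source is a TE family
    (its consensus taken as a head-to-tail circle) or a spike-in plasmid.
    Read share per circle is proportional to ``copies * length``.
    ``extraction_loss`` multiplies the recovered amount of *pre-extraction*
    plasmids only (they are added before gDNA extraction, so they experience
    extraction losses; post-extraction plasmids do not) — their ratio is the
    QC observable.  ``linear_background_rate`` is the fraction of reads drawn
    from linear genome that survived the simulated exonuclease digestion.
    """

    circles: list[tuple[str, float]]
    linear_background_rate: float = 0.0
    extraction_loss: float = 1.0
    n_read_pairs: int = 100_000

    def validate(self, bundle: ReferenceBundle) -> None:
        if not self.circles:
            raise ValueError("empty circle plan")
        total = 0.0
        for source, copies in self.circles:
            if source not in bundle.te_library and source not in bundle.plasmids:
                raise ValueError(f"unknown circle source {source}")
            if copies < 0:
                raise ValueError("copies must be >= 0")
            total += copies
        if total == 0:
            raise ValueError("all-zero copy plan")
        if not (0.0 <= self.linear_background_rate < 1.0):
            raise ValueError("linear_background_rate must be in [0, 1)")
        if not (0.0 < self.extraction_loss <= 1.0):
            raise ValueError("extraction_loss must be in (0, 1]")


def default_circle_plan(
    bundle: ReferenceBundle,
    te_copies: float | Mapping[str, float] = 30.0,
    plasmid_scale: float = 55.0,
    **kwargs,
) -> CirclePlan:
    """Circle plan with all TE families plus the bundled spike-in roster.

    Plasmid copies are derived from each plasmid's relative mass abundance
    (copies proportional to mass / length), scaled so the most abundant
    spike-in contributes on the order of one TE family's read share.
    """
    circles: list[tuple[str, float]] = []
    for fam in bundle.te_library:
        copies = te_copies[fam] if isinstance(te_copies, Mapping) else te_copies
        circles.append((fam, float(copies)))
    for p in bundle.plasmids.values():
        circles.append((p.name, plasmid_scale * p.abundance / (p.size / 1000.0)))
    return CirclePlan(circles, **kwargs)


def simulate_eccdna(
    source: SampleModel | ReferenceBundle,
    plan: CirclePlan,
    params: SeqParams,
    out_dir: str | Path | None = None,
) -> tuple[ReadPairs, pd.DataFrame]:
    """Simulate an eccDNA-enriched paired-end library.

    Fragment start positions are uniform on each circle, so reads may span
    the head-to-tail junction; fragments longer than the circle are clipped
    to one full turn.  Linear background reads are drawn from the reference
    genome.  Read names encode the source circle (``p{i}:circ:{name}:{start}``)
    or background locus (``p{i}:lin:{chrom}:{start}``).
    """
    bundle = source.bundle if isinstance(source, SampleModel) else source
    plan.validate(bundle)
    rng = np.random.default_rng(params.seed)
    rl = params.read_length

    sources: list[str] = []
    seqs: list[str] = []
    weights: list[float] = []
    for name, copies in plan.circles:
        if name in bundle.te_library:
            seq = bundle.te_library[name]
            loss = 1.0
        else:
            p = bundle.plasmids[name]
            seq = p.seq
            loss = plan.extraction_loss if p.role == "pre_extraction" else 1.0
        sources.append(name)
        seqs.append(seq)
        weights.append(copies * len(seq) * loss)

    w = np.asarray(weights, dtype=float)
    n_bg = int(round(plan.linear_background_rate * plan.n_read_pairs))
    n_circ = plan.n_read_pairs - n_bg
    counts = rng.multinomial(n_circ, w / w.sum())

    names: list[str] = []
    r1: list[str] = []
    r2: list[str] = []
    pair_id = 0
    for name, seq, m in zip(sources, seqs, counts):
        if m == 0:
            continue
        if len(seq) < rl:
            raise ValueError(f"circle {name} shorter than read length")
        doubled = seq + seq
        L = len(seq)
        starts = rng.integers(0, L, m)
        ilens = np.minimum(_fragment_lengths(rng, m, params), L)
        for s, ilen in zip(starts, ilens):
            frag = doubled[s : s + int(ilen)]
            a, b = frag[:rl], revcomp(frag[-rl:])
            if params.error_rate > 0:
                a = _mutate(a, rng, params.error_rate)
                b = _mutate(b, rng, params.error_rate)
            names.append(f"p{pair_id}:circ:{name}:{int(s)}")
            r1.append(a)
            r2.append(b)
            pair_id += 1

    if n_bg:
        genome = bundle.genome
        chroms = list(genome)
        lens = np.array([len(genome[c]) for c in chroms], dtype=float)
        chrom_idx = rng.choice(len(chroms), size=n_bg, p=lens / lens.sum())
        ilens = _fragment_lengths(rng, n_bg, params)
        for ci, ilen in zip(chrom_idx, ilens):
            chrom = chroms[ci]
            seq = genome[chrom]
            ilen = int(min(ilen, len(seq)))
            start = int(rng.integers(0, len(seq) - ilen + 1))
            frag = seq[start : start + ilen]
            names.append(f"p{pair_id}:lin:{chrom}:{start}")
            r1.append(frag[:rl])
            r2.append(revcomp(frag[-rl:]))
            pair_id += 1

    reads = ReadPairs(names, r1, r2)
    total_w = w.sum()
    truth = pd.DataFrame(
        {
            "source": sources,
            "copies": [c for _n, c in plan.circles],
            "length": [len(s) for s in seqs],
            "weight": weights,
            "expected_share": w / total_w * (1 - plan.linear_background_rate),
            "pairs_drawn": counts,
        }
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        reads.write_fastq(out / "ecc_1.fastq", out / "ecc_2.fastq")
        truth.to_csv(out / "truth_circles.tsv", sep="\t", index=False)
    return reads, truth
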