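"""Depth-matched comparison of two TE landscapes.

Comparisons assume both libraries were brought to matched mapped depth (see
:func:`telscope.mapping.downsample`).  The module provides:

* a seeded bootstrap of the insertion-calling pipeline (downsample half the
  pairs, re-call, repeat) quantifying sampling noise of the landscape size;
* the common/unique partition of two call sets (same locus, same family,
  within a positional window);
* per-family composition with an "Others" bucket for rare families;
* the paired signed-rank and rank-sum tests applied to per-family unique
  insertion counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caller import CallerParams, Landscape, cluster_and_call, gather_evidence
from .mapping import AlignmentSet
from .simulate import ReferenceBundle
from .stats import TestResult, rank_sum_test, signed_rank_test

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "LandscapeComparison",
    "bootstrap_landscape",
    "classify_common_unique",
    "family_composition",
    "aging_tests",
    "cohort_difference_test",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Permutation settings; seeds are the iteration numbers ``1..n_perm``."""

    n_perm: int = 20
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")

    @property
    def seeds(self) -> list[int]:
        return list(range(1, self.n_perm + 1))


@dataclass
class BootstrapResult:
    values: np.ndarray  # insertions per million mapped reads, one per permutation
    mean: float
    sd: float
    ci95: tuple[float, float]
    cumulative_mean: np.ndarray
    config: BootstrapConfig
    normalization: str

    def normal_ci95(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.sd
        return (self.mean - half, self.mean + half)


def bootstrap_landscape(
    alns: AlignmentSet,
    bundle: ReferenceBundle,
    config: BootstrapConfig = BootstrapConfig(),
    params: CallerParams = CallerParams(),
    normalization: str = "library",
) -> BootstrapResult:
    """Bootstrap the normalized insertion count by seeded downsampling.

    For permutation ``k`` (seed ``k``), each read pair is kept atomically
    with probability ``fraction``; the caller is re-run on the kept pairs
    and the accepted TE call count recorded as insertions per million mapped
    reads.  With ``normalization="library"`` (default) the denominator is
    the full library's mapped read count, so the permutation values estimate
    sampling noise of the landscape itself around the full-data value; with
    ``"permutation"`` each value is normalized by the permutation's own
    mapped reads.
    """
    if normalization not in ("library", "permutation"):
        raise ValueError("normalization must be 'library' or 'permutation'")
    evidence = gather_evidence(alns, bundle, params)
    pair_mapped = alns.pair_mapped_counts()
    library_mapped = int(pair_mapped.sum())
    n_pairs = alns.n_pairs
    values = np.empty(config.n_perm)
    for i, seed in enumerate(config.seeds):
        if config.fraction >= 1.0:
            keep = np.ones(n_pairs, dtype=bool)
        else:
            rng = np.random.default_rng(seed)
            keep = rng.random(n_pairs) < config.fraction
        kept_evidence = [e for e in evidence if keep[e.pair_index]]
        calls = cluster_and_call(kept_evidence, params)
        n_calls = sum(c.category == "TE" for c in calls)
        mapped = library_mapped if normalization == "library" else int(pair_mapped[keep].sum())
        values[i] = 1e6 * n_calls / mapped
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if config.n_perm > 1 else 0.0
    ci = (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5)))
    cumulative = np.cumsum(values) / np.arange(1, config.n_perm + 1)
    return BootstrapResult(values, mean, sd, ci, cumulative, config, normalization)


# ---------------------------------------------------------------------------
# common / unique partition
# ---------------------------------------------------------------------------


@dataclass
class LandscapeComparison:
    """Partition of two call sets into common and sample-unique insertions."""

    sample_a: str
    sample_b: str
    common: pd.DataFrame  # columns from A suffixed _a, from B suffixed _b
    unique_a: pd.DataFrame
    unique_b: pd.DataFrame
    family_table: pd.DataFrame
    match_window: int

    @property
    def n_common(self) -> int:
        return len(self.common)

    def check_conservation(self, n_a: int, n_b: int) -> None:
        if self.n_common + len(self.unique_a) != n_a:
            raise AssertionError("partition does not conserve sample A calls")
        if self.n_common + len(self.unique_b) != n_b:
            raise AssertionError("partition does not conserve sample B calls")


def _call_frame(landscape: Landscape | pd.DataFrame) -> pd.DataFrame:
    if isinstance(landscape, Landscape):
        return landscape.to_frame("TE")
    return landscape.copy()


def classify_common_unique(
    landscape_a: Landscape | pd.DataFrame,
    landscape_b: Landscape | pd.DataFrame,
    match_window: int = 100,
    ratio_pseudocount: bool = True,
) -> LandscapeComparison:
    """Match calls between two samples and partition common/unique.

    Calls match iff same chromosome, same family and positions within
    ``match_window`` bp; matching is greedy nearest-first and one-to-one.
    The family table reports per-family call counts, per-million normalized
    counts when mapped depths are available, and B/A ratios (with an
    optional +1 pseudocount when a family is absent from one sample, in
    which case the ratio is flagged).
    """
    df_a = _call_frame(landscape_a).reset_index(drop=True)
    df_b = _call_frame(landscape_b).reset_index(drop=True)
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    groups_b: dict[tuple[str, str], list[int]] = {}
    for j, row in df_b.iterrows():
        groups_b.setdefault((row["chrom"], row["family"]), []).append(j)
    candidates: list[tuple[int, int, int, int]] = []
    for i, row in df_a.iterrows():
        for j in groups_b.get((row["chrom"], row["family"]), ()):
            dist = abs(int(row["pos0"]) - int(df_b.at[j, "pos0"]))
            if dist <= match_window:
                candidates.append((dist, int(row["pos0"]), i, j))
    for _dist, _pos, i, j in sorted(candidates):
        if i in matched_a or j in matched_b:
            continue
        matched_a.add(i)
        matched_b.add(j)
        pairs.append((i, j))
    common = pd.concat(
        [
            df_a.loc[[i for i, _j in pairs]].reset_index(drop=True).add_suffix("_a"),
            df_b.loc[[j for _i, j in pairs]].reset_index(drop=True).add_suffix("_b"),
        ],
        axis=1,
    )
    unique_a = df_a.loc[[i for i in df_a.index if i not in matched_a]].reset_index(drop=True)
    unique_b = df_b.loc[[j for j in df_b.index if j not in matched_b]].reset_index(drop=True)

    fams = sorted(set(df_a["family"]) | set(df_b["family"]))
    mapped_a = landscape_a.mapped_reads if isinstance(landscape_a, Landscape) else None
    mapped_b = landscape_b.mapped_reads if isinstance(landscape_b, Landscape) else None
    rows = []
    for fam in fams:
        n_a = int((df_a["family"] == fam).sum())
        n_b = int((df_b["family"] == fam).sum())
        row = {
            "family": fam,
            "n_a": n_a,
            "n_b": n_b,
            "unique_a": int((unique_a["family"] == fam).sum()),
            "unique_b": int((unique_b["family"] == fam).sum()),
            "common": int((common["family_a"] == fam).sum()),
        }
        norm_a = 1e6 * n_a / mapped_a if mapped_a else float(n_a)
        norm_b = 1e6 * n_b / mapped_b if mapped_b else float(n_b)
        row["norm_a"] = norm_a
        row["norm_b"] = norm_b
        if n_a > 0 and n_b > 0:
            row["ratio_b_over_a"] = norm_b / norm_a
            row["ratio_flagged"] = False
        elif ratio_pseudocount:
            pa = 1e6 * (n_a + 1) / mapped_a if mapped_a else n_a + 1
            pb = 1e6 * (n_b + 1) / mapped_b if mapped_b else n_b + 1
            row["ratio_b_over_a"] = pb / pa
            row["ratio_flagged"] = True
        else:
            row["ratio_b_over_a"] = np.nan
            row["ratio_flagged"] = True
        rows.append(row)
    family_table = pd.DataFrame(rows).set_index("family") if rows else pd.DataFrame()

    name_a = landscape_a.sample_id if isinstance(landscape_a, Landscape) else "A"
    name_b = landscape_b.sample_id if isinstance(landscape_b, Landscape) else "B"
    cmp = LandscapeComparison(name_a, name_b, common, unique_a, unique_b, family_table, match_window)
    cmp.check_conservation(len(df_a), len(df_b))
    return cmp


def family_composition(
    landscape: Landscape | pd.DataFrame,
    min_fraction: float = 0.01,
) -> pd.DataFrame:
    """Per-family percentage of calls; families below the threshold share are
    lumped into an "Others" bucket.  Percentages sum to 100."""
    df = _call_frame(landscape)
    if df.empty:
        return pd.DataFrame(columns=["count", "percent"])
    counts = df["family"].value_counts()
    total = counts.sum()
    major = counts[counts / total >= min_fraction]
    others = total - major.sum()
    out = major.to_frame("count")
    if others > 0:
        out.loc["Others"] = others
    out["percent"] = 100.0 * out["count"] / total
    out.index.name = "family"
    return out


def aging_tests(
    comparison: LandscapeComparison | pd.DataFrame,
    alternative: str = "two-sided",
    min_informative: int = 3,
) -> dict[str, TestResult]:
    """Paired signed-rank test of per-family unique insertion counts (B vs A).

    Refuses to test when fewer than ``min_informative`` families have a
    non-zero difference — a handful of informative pairs cannot reach
    meaningful significance and would only invite over-reading.
    """
    table = comparison.family_table if isinstance(comparison, LandscapeComparison) else comparison
    a = np.asarray(table["unique_a"], dtype=float)
    b = np.asarray(table["unique_b"], dtype=float)
    informative = int(np.count_nonzero(b - a))
    if informative < min_informative:
        raise ValueError(
            f"only {informative} informative family pairs (need >= {min_informative}); "
            "test refused"
        )
    return {"signed_rank_unique": signed_rank_test(b, a, alternative=alternative)}


def cohort_difference_test(
    diffs_experimental,
    diffs_control,
    alternative: str = "greater",
) -> TestResult:
    """One-tailed rank-sum test of grouped per-sample differences between two
    cohorts (e.g. mutant versus wild-type aging gains)."""
    return rank_sum_test(diffs_experimental, diffs_control, alternative=alternative)
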