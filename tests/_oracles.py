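"""Independent brute-force oracles used only by the tests.

These deliberately avoid the implementation paths they check: the Wilcoxon
oracles enumerate the full null distribution; the junction-support oracle
derives per-locus evidence counts from the simulator's read-name provenance
and haplotype coordinates, never touching the mapper or caller.
"""

from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata


def exact_signed_rank_p(diffs, alternative="two-sided"):
    """Signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    p_greater = ge / 2**n
    p_less = le / 2**n
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


def exact_rank_sum_p(x, y, alternative="two-sided"):
    """Rank-sum p by enumerating all group assignments of the pooled ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = x.size
    ranks = rankdata(np.concatenate([x, y]))
    w_obs = ranks[:nx].sum()
    ge = le = total = 0
    for idx in combinations(range(ranks.size), nx):
        w = ranks[list(idx)].sum()
        total += 1
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    p_greater = ge / total
    p_less = le / total
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


def truth_locus_support(sample, reads, min_clip=15):
    """Per-truth-locus junction support derived from read provenance.

    Returns ``{(chrom, position, family): {"L": n, "R": n}}`` counting, for
    each planted insertion, reads that cross a junction with at least
    ``min_clip`` bases on both sides (split evidence) and pairs with one
    read wholly in a flank and its mate wholly inside the inserted element
    (discordant evidence).
    """
    rl = reads.read_length
    junction_cache: dict[tuple[int, str], list] = {}

    def junctions(hap, chrom):
        key = (hap, chrom)
        if key not in junction_cache:
            entries = sorted(
                (e for e in sample.haplotype_entries(hap) if e.chrom == chrom),
                key=lambda e: e.position,
            )
            out = []
            offset = 0
            for e in entries:
                te_len = len(sample.insertion_sequence(e))
                lj = e.position + offset
                out.append((e, lj, lj + te_len))
                offset += te_len
            junction_cache[key] = out
        return junction_cache[key]

    support = {
        (e.chrom, e.position, e.family): {"L": 0, "R": 0} for e in sample.plan.entries
    }
    for name in reads.names:
        parts = name.split(":")
        if not parts[1].startswith("h"):
            continue  # chimeric fragment: no truth locus
        hap = int(parts[1][1:])
        chrom, start, ilen = parts[2], int(parts[3]), int(parts[4])
        r1 = (start, start + rl)
        r2 = (start + ilen - rl, start + ilen)
        for e, lj, rj in junctions(hap, chrom):
            key = (e.chrom, e.position, e.family)
            for s, t in (r1, r2):
                if s + min_clip <= lj <= t - min_clip:
                    support[key]["L"] += 1
                if s + min_clip <= rj <= t - min_clip:
                    support[key]["R"] += 1
            # discordant: one read wholly in a flank, mate wholly inside the TE
            if r1[1] <= lj and lj <= r2[0] and r2[1] <= rj:
                support[key]["L"] += 1
            if rj <= r2[0] and lj <= r1[0] and r1[1] <= rj:
                support[key]["R"] += 1
    return support


def oracle_accepts(support, min_total=4, min_side=2):
    """Two-sided acceptance rule applied to oracle support counts."""
    return {
        key: (c["L"] + c["R"] >= min_total and c["L"] >= min_side and c["R"] >= min_side)
        for key, c in support.items()
    }
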