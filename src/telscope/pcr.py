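"""Droplet-digital PCR and qPCR copy-number calculators.

ddPCR partitions a sample into ~20,000 droplets; target molecules follow a
Poisson distribution over droplets, so the mean occupancy is recovered from
the negative-droplet fraction as ``lambda = -ln(N_neg / N)`` and converted
to copies/µL through the droplet volume and dilution factor.  The 95% CI is
the binomial-delta interval on the negative fraction pushed through the log
transform — the standard open-form realization of the instrument software's
propagated Poisson interval.  Wells with fewer than 10,000 accepted droplets
are rejected as statistically unreliable; fully positive wells are saturated
and carry no point estimate.

TE copies per genome divide the TE concentration by *half* the measured
concentration of the diploid single-copy housekeeping gene Rp49, so a
single-copy-per-haploid target reads as 2 copies per diploid normalizer.

qPCR fold changes use 2^-ddCt with Rp49 normalization; replicate SDs are
propagated in quadrature through both dCt terms using SDs of the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DdpcrWell",
    "DdpcrResult",
    "ddpcr_concentration",
    "copies_per_genome",
    "ddct_fold",
    "DdctResult",
    "simulate_ddpcr_well",
]

_Z95 = 1.959963984540054
MIN_DROPLETS = 10_000


@dataclass(frozen=True)
class DdpcrWell:
    """One ddPCR well readout."""

    total_droplets: int
    positive_droplets: int
    droplet_volume_ul: float  # instrument-specific; no default exists
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.positive_droplets <= self.total_droplets):
            raise ValueError("positive droplets must be within [0, total]")
        if self.droplet_volume_ul <= 0:
            raise ValueError("droplet volume must be positive")
        if self.dilution <= 0:
            raise ValueError("dilution factor must be positive")


@dataclass(frozen=True)
class DdpcrResult:
    concentration: float  # copies/µL of the (diluted-corrected) input
    lam: float  # copies per droplet
    ci95: tuple[float, float]
    lam_ci95: tuple[float, float]
    saturated: bool
    well: DdpcrWell


def ddpcr_concentration(well: DdpcrWell, min_droplets: int = MIN_DROPLETS) -> DdpcrResult:
    """Poisson concentration estimate with a binomial-delta 95% CI.

    Raises ``ValueError`` for wells below the droplet-count floor; returns a
    result flagged ``saturated`` (NaN estimates) when every droplet is
    positive.
    """
    n = well.total_droplets
    if n < min_droplets:
        raise ValueError(
            f"well rejected: {n} droplets < required {min_droplets} for a stable "
            "Poisson estimate"
        )
    neg = n - well.positive_droplets
    scale = well.dilution / well.droplet_volume_ul
    if neg == 0:
        nan = float("nan")
        return DdpcrResult(nan, nan, (nan, nan), (nan, nan), True, well)
    p_hat = neg / n
    lam = -math.log(p_hat)
    se = math.sqrt(p_hat * (1.0 - p_hat) / n)
    p_hi = min(p_hat + _Z95 * se, 1.0)
    p_lo = max(p_hat - _Z95 * se, 0.5 / n)  # clip away from 0 to keep the log finite
    lam_lo = -math.log(p_hi)
    lam_hi = -math.log(p_lo)
    return DdpcrResult(
        scale * lam,
        lam,
        (scale * lam_lo, scale * lam_hi),
        (lam_lo, lam_hi),
        False,
        well,
    )


def copies_per_genome(
    te: DdpcrResult | float,
    rp49: DdpcrResult | float,
) -> tuple[float, tuple[float, float]]:
    """TE copies per genome: TE concentration over half the Rp49 concentration.

    When both arguments carry confidence intervals, the interval on the
    ratio is propagated to first order (relative half-widths in quadrature).
    """
    te_val, te_ci = _value_ci(te)
    rp_val, rp_ci = _value_ci(rp49)
    if rp_val is None or rp_val <= 0:
        raise ValueError("Rp49 concentration must be positive")
    copies = te_val / (rp_val / 2.0)
    rel2 = 0.0
    for val, ci in ((te_val, te_ci), (rp_val, rp_ci)):
        if ci is not None and val > 0:
            half = (ci[1] - ci[0]) / 2.0
            rel2 += (half / val) ** 2
    half = copies * math.sqrt(rel2)
    return copies, (copies - half, copies + half)


def _value_ci(x: DdpcrResult | float) -> tuple[float, tuple[float, float] | None]:
    if isinstance(x, DdpcrResult):
        if x.saturated:
            raise ValueError("saturated well carries no concentration estimate")
        return x.concentration, x.ci95
    return float(x), None


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DdctResult:
    fold: float
    ddct: float
    sd: float  # propagated SD of ddCt
    fold_interval: tuple[float, float]  # 2^-(ddct +/- sd)


def ddct_fold(
    panel: Mapping[str, Mapping[str, Sequence[float]]],
    experiment: str,
    control: str,
    target: str,
    housekeeping: str = "Rp49",
    min_replicates: int = 3,
) -> DdctResult:
    """2^-ddCt fold change of ``target`` in ``experiment`` versus ``control``.

    ``panel[condition][gene]`` holds replicate Ct values.  dCt per condition
    is mean(target Ct) - mean(housekeeping Ct); ddCt is their difference.
    SD is propagated in quadrature through all four replicate means.
    """
    means = {}
    variances = []
    for condition in (experiment, control):
        for gene in (target, housekeeping):
            try:
                cts = np.asarray(panel[condition][gene], dtype=float)
            except KeyError as err:
                raise ValueError(f"missing Ct series for {condition}/{gene}") from err
            if cts.size < min_replicates:
                raise ValueError(
                    f"{condition}/{gene}: {cts.size} replicates < required {min_replicates}"
                )
            if np.any(cts <= 0):
                raise ValueError("Ct values must be positive")
            means[(condition, gene)] = float(cts.mean())
            variances.append(float(cts.var(ddof=1)) / cts.size)  # SD of the mean
    dct_exp = means[(experiment, target)] - means[(experiment, housekeeping)]
    dct_ctl = means[(control, target)] - means[(control, housekeeping)]
    ddct = dct_exp - dct_ctl
    sd = math.sqrt(sum(variances))
    fold = 2.0 ** (-ddct)
    return DdctResult(fold, ddct, sd, (2.0 ** (-ddct - sd), 2.0 ** (-ddct + sd)))


# ---------------------------------------------------------------------------
# droplet simulation (truth-known fixture for recovery tests)
# ---------------------------------------------------------------------------


def simulate_ddpcr_well(
    lam: float,
    n_droplets: int,
    droplet_volume_ul: float,
    rng: np.random.Generator,
    dilution: float = 1.0,
) -> DdpcrWell:
    """Simulate droplet partitioning at true mean occupancy ``lam``.

    Each droplet is positive when it receives at least one molecule, i.e.
    with probability ``1 - exp(-lam)``.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    positive = int(rng.binomial(n_droplets, 1.0 - math.exp(-lam)))
    return DdpcrWell(n_droplets, positive, droplet_volume_ul, dilution)
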