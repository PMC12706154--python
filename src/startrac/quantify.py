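"""Partition-level quantification: gating, Poisson occupancy, concentration.

A dPCR well partitions the reaction into ~2 x 10^4 microchambers; target
molecules distribute across them Poisson-randomly. Each dye channel yields a
fluorescence amplitude per partition; gating splits these into negative and
positive clusters, the fraction of negatives gives the mean occupancy
``lambda = -ln(n_neg / n_total)``, and dividing by the partition volume
converts occupancy to copies per microlitre of reaction.

Gating uses exact 1-D two-means clustering (optimal single split of the
sorted amplitudes) with the threshold at the midpoint of the two cluster
means. A secondary positive cluster at intermediate amplitude — the
double-positive artifact a reference-gene SNV can produce — stays above the
threshold and is counted positive, leaving copy-number calls unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import NoSeparationError
from .platform import DEFAULT_PLATFORM, PlatformModel

__all__ = [
    "PartitionTable",
    "GatePolicy",
    "ChannelGate",
    "QuantResult",
    "two_means_1d",
    "gate_partitions",
    "estimate_lambda",
    "concentration",
    "quantify_table",
]

#: Fewer negative partitions than this flags the estimate as saturated:
#: the variance of lambda-hat explodes and quantification is censored.
SATURATION_FLOOR = 3


@dataclass
class PartitionTable:
    """Per-partition, per-channel data for one reaction well.

    ``channels`` maps channel keys (e.g. ``g.2851C``, ``ref``) to amplitude
    arrays in RFU, or to 0/1 gated-state arrays when ``gated`` is set in the
    metadata. All arrays must share one length (the valid partition count).
    """

    well_id: str
    channels: Mapping[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.well_id}: channel arrays differ in length")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(
                    f"{self.well_id}/{name}: amplitudes must be finite and >= 0"
                )

    @property
    def n_partitions(self) -> int:
        return len(next(iter(self.channels.values())))


@dataclass(frozen=True)
class GatePolicy:
    """How to split a channel's amplitudes into negatives and positives.

    ``auto-midpoint`` clusters amplitudes by 1-D two-means and thresholds at
    the midpoint of the cluster means; ``fixed-threshold`` uses
    ``threshold_rfu`` directly. When the two cluster means are closer than
    ``min_separation`` the channel is dominated by a single cluster (blank
    well, fully saturated well, or a minority class too small for two-means
    to isolate); the gate then falls back to ``single_cluster_boundary`` as
    a fixed threshold, so a blank well gates all-negative, a saturated one
    all-positive, and stray opposite-class partitions are still counted. A
    lone cluster sitting near the boundary itself raises
    :class:`~startrac.errors.NoSeparationError`. Amplitudes exactly at the
    threshold count positive.
    """

    mode: str = "auto-midpoint"
    threshold_rfu: float | None = None
    min_separation: float = 1000.0
    single_cluster_boundary: float = 2000.0

    def __post_init__(self) -> None:
        if self.mode not in ("auto-midpoint", "fixed-threshold"):
            raise ValueError(f"unknown gating mode {self.mode!r}")
        if self.mode == "fixed-threshold":
            if self.threshold_rfu is None or self.threshold_rfu <= 0:
                raise ValueError("fixed-threshold mode requires threshold_rfu > 0")


@dataclass(frozen=True)
class ChannelGate:
    """Gating outcome and cluster statistics for one channel."""

    channel: str
    n_pos: int
    n_neg: int
    threshold: float
    neg_mean: float
    pos_mean: float
    pos_sd: float
    pos_modes: int

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class QuantResult:
    """Occupancy and concentration estimate for one channel."""

    channel: str
    n_pos: int
    n_neg: int
    lambda_hat: float
    lambda_low: float
    lambda_high: float
    conc: float
    ci_low: float
    ci_high: float
    saturated_flag: bool = False
    empty_flag: bool = False

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg


def two_means_1d(x: np.ndarray) -> tuple[float, float, int]:
    """Exact 1-D two-means: optimal split of sorted values.

    Returns ``(mean_low, mean_high, n_low)`` minimising within-cluster sum
    of squares over all single split points. For one-dimensional data the
    two-means optimum is a contiguous split of the sorted sample, so a
    prefix-sum scan finds it exactly and deterministically.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    if n < 2 or xs[0] == xs[-1]:
        m = float(xs.mean())
        return m, m, n
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    k = np.arange(1, n)  # size of the low cluster
    sum_lo, sum_hi = csum[k - 1], csum[-1] - csum[k - 1]
    sq_lo, sq_hi = csq[k - 1], csq[-1] - csq[k - 1]
    cost = (sq_lo - sum_lo**2 / k) + (sq_hi - sum_hi**2 / (n - k))
    best = int(np.argmin(cost))
    n_lo = best + 1
    return float(sum_lo[best] / n_lo), float(sum_hi[best] / (n - n_lo)), n_lo


def _positive_modality(pos: np.ndarray, min_separation: float) -> int:
    """1 or 2 amplitude modes among positive partitions.

    Two modes are reported when a second two-means split of the positives
    separates by more than ``min_separation`` with both subclusters
    non-trivially populated — the double-positive artifact signature.
    """
    if len(pos) < 10:
        return 1
    m_lo, m_hi, n_lo = two_means_1d(pos)
    floor = max(5, int(0.02 * len(pos)))
    if (m_hi - m_lo) > min_separation and floor <= n_lo <= len(pos) - floor:
        return 2
    return 1


def _gate_channel(name: str, amp: np.ndarray, policy: GatePolicy) -> ChannelGate:
    if policy.mode == "fixed-threshold":
        thr = float(policy.threshold_rfu)
    else:
        m_lo, m_hi, _ = two_means_1d(amp)
        if (m_hi - m_lo) < policy.min_separation:
            # Single dominant cluster (blank, fully saturated, or one class
            # so small that two-means splits the big cluster instead): fall
            # back to the fixed boundary so stray opposite-class partitions
            # are still counted. A cluster sitting on the boundary itself is
            # genuinely ungateable.
            overall = float(amp.mean())
            margin = policy.min_separation / 2
            if abs(overall - policy.single_cluster_boundary) < margin:
                raise NoSeparationError(name, m_hi - m_lo, policy.min_separation)
            thr = policy.single_cluster_boundary
        else:
            thr = (m_lo + m_hi) / 2.0
    positive = amp >= thr  # tie at threshold counts positive
    n_pos = int(positive.sum())
    n_neg = len(amp) - n_pos
    pos_amp = amp[positive]
    neg_amp = amp[~positive]
    return ChannelGate(
        channel=name,
        n_pos=n_pos,
        n_neg=n_neg,
        threshold=thr,
        neg_mean=float(neg_amp.mean()) if n_neg else float("nan"),
        pos_mean=float(pos_amp.mean()) if n_pos else float("nan"),
        pos_sd=float(pos_amp.std()) if n_pos else float("nan"),
        pos_modes=_positive_modality(pos_amp, policy.min_separation) if n_pos else 0,
    )


def gate_partitions(
    table: PartitionTable, policy: GatePolicy | None = None
) -> dict[str, ChannelGate]:
    """Gate every channel of a well into positive/negative partition counts."""
    policy = policy or GatePolicy()
    if table.n_partitions < 100:
        raise ValueError(
            f"{table.well_id}: at least 100 partitions required, "
            f"got {table.n_partitions}"
        )
    if table.metadata.get("gated"):
        out = {}
        for name, states in table.channels.items():
            n_pos = int(np.count_nonzero(states))
            out[name] = ChannelGate(
                channel=name, n_pos=n_pos, n_neg=len(states) - n_pos,
                threshold=0.5, neg_mean=float("nan"), pos_mean=float("nan"),
                pos_sd=float("nan"), pos_modes=1 if n_pos else 0,
            )
        return out
    return {
        name: _gate_channel(name, amp, policy)
        for name, amp in table.channels.items()
    }


def estimate_lambda(
    n_pos: int, n_total: int, conf: float = 0.95
) -> tuple[float, float, float, bool, bool]:
    """Poisson occupancy from partition counts.

    Returns ``(lambda_hat, low, high, saturated_flag, empty_flag)``.
    ``lambda_hat = -ln(n_neg / n_total)``; the interval is a Wilson binomial
    interval on the negative fraction propagated through ``-ln``. With no
    negative partitions the estimate is censored at ``-ln(0.5 / n_total)``
    and flagged saturated (as are wells with fewer than 3 negatives, where
    the estimator's variance explodes).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise ValueError("n_pos must lie in [0, n_total]")
    n_neg = n_total - n_pos
    saturated = n_neg < SATURATION_FLOOR
    empty = n_pos == 0
    if n_neg == 0:
        lam = -np.log(0.5 / n_total)
    else:
        lam = -np.log(n_neg / n_total)
    p_lo, p_hi = proportion_confint(n_neg, n_total, alpha=1 - conf, method="wilson")
    high = float(-np.log(p_lo)) if p_lo > 0 else float("inf")
    low = float(-np.log(p_hi)) if p_hi < 1 else 0.0
    low = min(low, float(lam))
    return float(lam), low, high, saturated, empty


def concentration(
    lambda_hat: float,
    platform: PlatformModel = DEFAULT_PLATFORM,
    dilution: float = 1.0,
) -> float:
    """Convert occupancy to copies per microlitre of undiluted reaction."""
    if dilution <= 0:
        raise ValueError("dilution factor must be positive")
    return lambda_hat / platform.v_partition * dilution


def quantify_table(
    table: PartitionTable,
    policy: GatePolicy | None = None,
    platform: PlatformModel = DEFAULT_PLATFORM,
    conf: float = 0.95,
) -> dict[str, QuantResult]:
    """Gate a well and estimate occupancy and concentration per channel."""
    dilution = float(table.metadata.get("dilution", 1.0))
    results = {}
    for name, gate in gate_partitions(table, policy).items():
        lam, lo, hi, sat, empty = estimate_lambda(gate.n_pos, gate.n_total, conf)
        results[name] = QuantResult(
            channel=name,
            n_pos=gate.n_pos,
            n_neg=gate.n_neg,
            lambda_hat=lam,
            lambda_low=lo,
            lambda_high=hi,
            conc=concentration(lam, platform, dilution),
            ci_low=concentration(lo, platform, dilution),
            ci_high=concentration(hi, platform, dilution) if np.isfinite(hi) else float("inf"),
            saturated_flag=sat,
            empty_flag=empty,
        )
    return results
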