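"""Partition-level simulation of StarTRAC dPCR reactions.

The generator emulates the physical chain the instrument realises: restriction-
digested genomic DNA carrying an integer number of target copies per diploid
genome is loaded into ~2 x 10^4 microchambers; molecule counts per partition
are Poisson; occupied partitions fluoresce around a positive cluster mean and
empty ones around a negative mean. Two interference artifacts are modelled at
the amplitude level, matching how they present on the instrument:

* ``amplitude-suppression`` — an SNV under a probe suppresses the positive
  cluster (default to 0.25x of nominal), scatters it, and drops a fraction
  of occupied partitions to negative-like amplitude (partial drop-out), so
  downstream gating loses signal and the calculated CN falls out of window.
* ``double-positive`` — a reference-gene SNV splits the positive cluster,
  placing a fraction of occupied partitions at an intermediate amplitude;
  with midpoint gating both positive clusters stay above threshold and CN
  calls are unaffected.

Incomplete digestion is a linkage parameter: tandem copies on one haplotype
that remain joined co-segregate as a single molecule, lowering the number of
independent positives and hence the calculated CN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alleles import (
    AssayPlex,
    DiplotypeConfig,
    HaplotypeConfig,
    REF,
    REF_CHANNEL,
    VAR,
)
from .calling import CallPolicy, NO_CALL, calculated_cn, call_cn
from .platform import DEFAULT_PLATFORM, PlatformModel
from .quantify import GatePolicy, PartitionTable, quantify_table

__all__ = ["ChannelModel", "SimConfig", "simulate_sample", "cni_sweep"]

#: Haploid genome-equivalents per ng of genomic DNA. Chosen below the
#: theoretical ~303/ng so that 10 ng in a 10 uL reaction puts a 2-copy
#: target near the 100-500 copies/uL operating band (lambda ~ 0.1-0.3).
GENOMES_PER_NG = 250.0


@dataclass(frozen=True)
class ChannelModel:
    """Fluorescence amplitude model for one dye channel.

    Nominal clusters sit at ``neg_mean`` and ``pos_mean`` (RFU) with common
    scatter ``sd``. Under amplitude suppression the positive mean is scaled
    by ``suppression_factor``, its scatter by ``suppression_extra_sd``, and
    a fraction ``suppression_dropout`` of occupied partitions emit
    negative-like amplitude. The double-positive artifact moves a fraction
    ``double_cluster_fraction`` of occupied partitions to
    ``double_cluster_mean``.
    """

    neg_mean: float = 500.0
    pos_mean: float = 6000.0
    sd: float = 200.0
    suppression_factor: float = 0.25
    suppression_extra_sd: float = 3.0
    suppression_dropout: float = 0.4
    double_cluster_fraction: float = 0.3
    double_cluster_mean: float = 3500.0

    def __post_init__(self) -> None:
        if self.neg_mean >= self.pos_mean:
            raise ValueError("neg_mean must be below pos_mean")
        for name in ("suppression_dropout", "double_cluster_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """One simulated reaction: diplotype, plex, input mass, artifacts."""

    diplotype: DiplotypeConfig
    plex: AssayPlex
    dna_input_ng: float = 10.0
    genomes_per_ng: float = GENOMES_PER_NG
    digestion_completeness: float = 1.0
    interference: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dna_input_ng < 0:
            raise ValueError("dna_input_ng must be >= 0")
        if not 0.0 <= self.digestion_completeness <= 1.0:
            raise ValueError("digestion_completeness must lie in [0, 1]")
        for channel, mode in self.interference.items():
            if mode not in ("amplitude-suppression", "double-positive"):
                raise ValueError(f"unknown interference mode {mode!r} on {channel}")


def _haplotype_channel_copies(
    hap: HaplotypeConfig, plex: AssayPlex
) -> dict[str, int]:
    """Copies this haplotype contributes per channel (per genome)."""
    gt, extra = plex.gt_target, plex.extra_target
    counts = {gt.ref_label: 0, gt.var_label: 0, extra.var_label: 0}
    for copy in hap.gene_copies():
        sig = copy.effective_signal(gt)
        if sig == REF:
            counts[gt.ref_label] += 1
        elif sig == VAR:
            counts[gt.var_label] += 1
        if copy.effective_signal(extra) == VAR:
            counts[extra.var_label] += 1
    return counts


def _molecule_lambda(
    cfg: SimConfig, platform: PlatformModel
) -> dict[str, float]:
    """Mean independent molecules per partition for every channel.

    Diploid genome concentration is ``dna * genomes_per_ng / (2 * V)``; a
    channel seen on ``k`` tandem copies of one haplotype yields on average
    ``1 + (k - 1) * d`` separable fragments per genome, where ``d`` is the
    probability each tandem junction is cut. The 2-copy reference sits on
    two independent chromosomes and is never linked.
    """
    genome_conc = (cfg.dna_input_ng * cfg.genomes_per_ng
                   / (2.0 * platform.reaction_volume))
    d = cfg.digestion_completeness
    lam: dict[str, float] = {}
    for hap in (cfg.diplotype.hapA, cfg.diplotype.hapB):
        for channel, k in _haplotype_channel_copies(hap, cfg.plex).items():
            if k > 0:
                fragments = 1.0 + (k - 1) * d
                lam[channel] = lam.get(channel, 0.0) + fragments * genome_conc * platform.v_partition
            else:
                lam.setdefault(channel, 0.0)
    lam[REF_CHANNEL] = cfg.plex.ref_copies * genome_conc * platform.v_partition
    return lam


def simulate_sample(
    cfg: SimConfig,
    platform: PlatformModel = DEFAULT_PLATFORM,
    channel_model: ChannelModel | None = None,
    rng: np.random.Generator | None = None,
) -> PartitionTable:
    """Draw one well's partition amplitudes for a 4-plex reaction.

    Fully reproducible: all randomness flows from ``cfg.seed`` (or an
    explicitly supplied generator).
    """
    cm = channel_model or ChannelModel()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = platform.n_partitions
    channels: dict[str, np.ndarray] = {}
    for channel, lam in _molecule_lambda(cfg, platform).items():
        occupied = rng.poisson(lam, size=n) > 0
        amp = rng.normal(cm.neg_mean, cm.sd, size=n)
        mode = cfg.interference.get(channel)
        n_occ = int(occupied.sum())
        if n_occ:
            if mode == "amplitude-suppression":
                pos = rng.normal(cm.pos_mean * cm.suppression_factor,
                                 cm.sd * cm.suppression_extra_sd, size=n_occ)
                dropped = rng.random(n_occ) < cm.suppression_dropout
                pos[dropped] = rng.normal(cm.neg_mean, cm.sd, size=int(dropped.sum()))
            elif mode == "double-positive":
                pos = rng.normal(cm.pos_mean, cm.sd, size=n_occ)
                shifted = rng.random(n_occ) < cm.double_cluster_fraction
                pos[shifted] = rng.normal(cm.double_cluster_mean, cm.sd,
                                          size=int(shifted.sum()))
            else:
                pos = rng.normal(cm.pos_mean, cm.sd, size=n_occ)
            amp[occupied] = pos
        channels[channel] = np.clip(amp, 0.0, None)
    return PartitionTable(
        well_id=f"{cfg.diplotype.label}:{cfg.plex.name}:s{cfg.seed}",
        channels=channels,
        metadata={
            "sample": cfg.diplotype.label,
            "plex": cfg.plex.name,
            "dna_input_ng": cfg.dna_input_ng,
            "dilution": 1.0,
            "seed": cfg.seed,
        },
    )


def cni_sweep(
    cfg: SimConfig,
    input_series: Sequence[float],
    replicates: int = 3,
    seed: int | None = None,
    platform: PlatformModel = DEFAULT_PLATFORM,
    channel_model: ChannelModel | None = None,
    gate_policy: GatePolicy | None = None,
    call_policy: CallPolicy | None = None,
) -> pd.DataFrame:
    """Sweep DNA input and tabulate copy-number integrity.

    Runs simulate -> quantify -> call for every input level and replicate,
    returning a tidy table with one row per (input, replicate, target
    channel): calculated CN, integer call (NaN for NO_CALL), and target and
    reference concentrations in copies/uL. A 0-ng input yields empty wells
    and no calls.
    """
    if not len(input_series):
        raise ValueError("input_series must be non-empty")
    call_policy = call_policy or CallPolicy()
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for ng in input_series:
        for rep in range(replicates):
            rng = np.random.default_rng(root.integers(2**31))
            table = simulate_sample(
                replace(cfg, dna_input_ng=float(ng)), platform, channel_model, rng
            )
            quants = quantify_table(table, gate_policy, platform)
            ref = quants[REF_CHANNEL]
            for channel, q in quants.items():
                if channel == REF_CHANNEL:
                    continue
                if ref.conc > 0:
                    cn = calculated_cn(q.conc, ref.conc, call_policy)
                else:
                    cn = float("nan")  # reference failure (e.g. 0 ng input)
                call = call_cn(cn, call_policy) if np.isfinite(cn) else NO_CALL
                rows.append({
                    "dna_input_ng": float(ng),
                    "replicate": rep,
                    "target": channel,
                    "calculated_cn": cn,
                    "call": np.nan if call is NO_CALL else int(call),
                    "conc_target": q.conc,
                    "conc_ref": ref.conc,
                    "saturated": q.saturated_flag or ref.saturated_flag,
                    "empty": q.empty_flag,
                })
    return pd.DataFrame(rows)
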