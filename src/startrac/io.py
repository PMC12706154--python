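"""File formats, sample sheets, and the validation-cohort fixture tables.

Formats are deliberately plain: partition data as long-form CSV (one row per
partition-channel), quantification and CN results as TSV, interpretation
reports as JSON. The validation cohort — five copy-neutral and ten
structural-variant reference samples with consensus diplotypes — is encoded
here and drives the golden fixture files and the end-to-end tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .alleles import (
    AlleleRegistry,
    default_registry,
    expected_copy_vector,
    parse_diplotype,
)
from .calling import CNResult, NO_CALL
from .quantify import PartitionTable, QuantResult

__all__ = [
    "SampleSpec",
    "COPY_NEUTRAL_COHORT",
    "SV_COHORT",
    "write_partition_csv",
    "read_partition_csv",
    "quant_to_frame",
    "write_quant_tsv",
    "read_quant_tsv",
    "cn_to_frame",
    "write_cn_tsv",
    "read_cn_tsv",
    "read_sample_sheet",
    "write_fixture_tables",
    "candidates_for",
]


@dataclass(frozen=True)
class SampleSpec:
    """One sample-sheet row: identity, diplotype, assays, run parameters."""

    sample_id: str
    diplotype: str
    plexes: tuple[str, ...] = ()  # empty = full panel
    dna_input_ng: float = 10.0
    interference: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0


#: Copy-neutral (CN = 2) reference samples and the plexes each was assayed
#: with during validation.
COPY_NEUTRAL_COHORT: tuple[SampleSpec, ...] = (
    SampleSpec("NA17111", "*1/*1",
               ("CN_2851", "CN_1847", "CN_100", "CN_1022", "CN_3184", "CN_2989")),
    SampleSpec("NA18966", "*1/*2", ("CN_2851",)),
    SampleSpec("NA06991", "*1/*4", ("CN_1847", "CN_100")),
    SampleSpec("HG03313", "*29/*154", ("CN_1022", "CN_3184")),
    SampleSpec("NA19316", "*2/*158", ("CN_2989",)),
)

#: Structural-variant reference samples (duplications, multiplications,
#: hybrids) with their consensus diplotypes.
SV_COHORT: tuple[SampleSpec, ...] = (
    SampleSpec("NA19685", "*1/*2x2", ("CN_2851",)),
    SampleSpec("NA19920", "*1/*4x2", ("CN_2851", "CN_1847", "CN_100")),
    SampleSpec("NA24217", "*2/*41x3", ("CN_2851", "CN_2989")),
    SampleSpec("NA19224", "*2x2/*17", ("CN_2851", "CN_1022", "CN_3184")),
    SampleSpec("NA19109", "*2x2/*29", ("CN_3184",)),
    SampleSpec("NA17113", "*17x2/*45", ("CN_1022",)),
    SampleSpec("NA07439", "*4x2/*41", ("CN_1847", "CN_2989")),
    SampleSpec("NA23297", "*10x2/*17", ("CN_100", "CN_1022")),
    SampleSpec("NA21781", "*2x2/*68+*4", ("CN_2851", "CN_1847", "CN_100")),
    SampleSpec("NA23246", "*10x2/*36+*10", ("CN_100",)),
)


def candidates_for(diplotype_label: str) -> tuple[str, str]:
    """Candidate haplotype units: the diplotype label with multiplicities
    stripped (the prior unphased consensus genotype)."""
    import re

    hapA, hapB = diplotype_label.replace(" ", "").split("/")
    strip = lambda h: re.sub(r"x\d+", "", h)
    return strip(hapA), strip(hapB)


# ---------------------------------------------------------------------------
# partition CSV

def write_partition_csv(table: PartitionTable, path) -> None:
    """Long-form CSV: well_id, channel, partition_index, amplitude."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["well_id", "channel", "partition_index", "amplitude"])
        for channel, amp in table.channels.items():
            for i, a in enumerate(amp):
                w.writerow([table.well_id, channel, i, f"{a:.2f}"])


def read_partition_csv(path, metadata: dict | None = None) -> PartitionTable:
    df = pd.read_csv(path)
    required = {"well_id", "channel", "partition_index", "amplitude"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: partition CSV needs columns {sorted(required)}"
        )
    wells = df["well_id"].unique()
    if len(wells) != 1:
        raise ValueError(f"{path}: expected one well per file, found {len(wells)}")
    channels = {}
    for channel, grp in df.groupby("channel", sort=False):
        grp = grp.sort_values("partition_index")
        channels[str(channel)] = grp["amplitude"].to_numpy(dtype=float)
    return PartitionTable(str(wells[0]), channels, dict(metadata or {}))


# ---------------------------------------------------------------------------
# quant / CN tables

def quant_to_frame(quants: Mapping[str, QuantResult]) -> pd.DataFrame:
    rows = []
    for q in quants.values():
        rows.append({
            "channel": q.channel, "n_pos": q.n_pos, "n_neg": q.n_neg,
            "lambda_hat": q.lambda_hat, "conc": q.conc,
            "ci_low": q.ci_low, "ci_high": q.ci_high,
            "saturated": q.saturated_flag, "empty": q.empty_flag,
        })
    return pd.DataFrame(rows)


def write_quant_tsv(quants: Mapping[str, QuantResult], path) -> None:
    quant_to_frame(quants).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_quant_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "channel" not in df.columns or "conc" not in df.columns:
        raise ValueError(f"{path}: not a quantification TSV")
    return df


def cn_to_frame(results: Sequence[CNResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "target": r.target_label,
            "calculated_cn": round(r.calculated_cn, 2),
            "call": "NO_CALL" if r.call is NO_CALL else int(r.call),
            "flags": ";".join(sorted(r.flags)),
        })
    return pd.DataFrame(rows)


def write_cn_tsv(results: Sequence[CNResult], path) -> None:
    cn_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.2f")


def read_cn_tsv(path) -> dict:
    """Read a CN TSV back into a channel -> call/NO_CALL mapping."""
    df = pd.read_csv(path, sep="\t", dtype={"call": str})
    if "target" not in df.columns or "call" not in df.columns:
        raise ValueError(f"{path}: not a CN-result TSV")
    calls = {}
    for _, row in df.iterrows():
        call = row["call"]
        calls[row["target"]] = NO_CALL if str(call) == "NO_CALL" else int(call)
    return calls


# ---------------------------------------------------------------------------
# sample sheets and config

def _parse_interference(text: str) -> dict[str, str]:
    if not text or (isinstance(text, float) and np.isnan(text)):
        return {}
    out = {}
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        channel, _, mode = item.partition(":")
        if not mode:
            raise ValueError(f"interference spec {item!r} must be channel:mode")
        out[channel.strip()] = mode.strip()
    return out


def read_sample_sheet(path) -> list[SampleSpec]:
    """CSV with columns sample_id, diplotype[, plexes, dna_input_ng,
    interference, seed]. Plexes are semicolon-separated; interference is
    ``channel:mode`` pairs joined by semicolons."""
    df = pd.read_csv(path)
    if not {"sample_id", "diplotype"}.issubset(df.columns):
        raise ValueError(f"{path}: sample sheet needs sample_id and diplotype columns")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    specs = []
    for _, row in df.iterrows():
        plexes = ()
        if "plexes" in df.columns and isinstance(row.get("plexes"), str):
            plexes = tuple(p.strip() for p in row["plexes"].split(";") if p.strip())
        specs.append(SampleSpec(
            sample_id=str(row["sample_id"]),
            diplotype=str(row["diplotype"]),
            plexes=plexes,
            dna_input_ng=float(row.get("dna_input_ng", 10.0))
            if "dna_input_ng" in df.columns else 10.0,
            interference=_parse_interference(row.get("interference", ""))
            if "interference" in df.columns else {},
            seed=int(row.get("seed", 0)) if "seed" in df.columns else 0,
        ))
    return specs


def load_config(path) -> dict:
    """Load a YAML config of platform/gating/calling overrides."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return doc


# ---------------------------------------------------------------------------
# golden fixture tables

def _cohort_frame(
    cohort: Sequence[SampleSpec], registry: AlleleRegistry
) -> pd.DataFrame:
    rows = []
    for spec in cohort:
        config = parse_diplotype(spec.diplotype, registry)
        for plex_name in spec.plexes:
            plex = registry.plexes[plex_name]
            vec = expected_copy_vector(config, plex)
            gt = plex.gt_target
            rows.append({
                "sample": spec.sample_id,
                "diplotype": spec.diplotype,
                "plex": plex_name,
                "target": gt.label,
                "ref_copies": vec[gt.ref_label],
                "var_copies": vec[gt.var_label],
                "g4181C_copies": vec["g.4181C"],
            })
    return pd.DataFrame(rows)


def write_fixture_tables(out_dir, registry: AlleleRegistry | None = None) -> list[Path]:
    """Write the validation-cohort golden tables (forward-model expectations).

    Produces ``copy_neutral_cohort.tsv`` and ``sv_cohort.tsv`` with one row
    per sample-plex; deterministic byte-for-byte.
    """
    registry = registry or default_registry()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, cohort in (
        ("copy_neutral_cohort", COPY_NEUTRAL_COHORT),
        ("sv_cohort", SV_COHORT),
    ):
        path = out_dir / f"{name}.tsv"
        _cohort_frame(cohort, registry).to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
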