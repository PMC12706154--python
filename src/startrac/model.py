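"""Top-level modelling interface: :class:`StarTracModel` and results.

The model is built from partition-level data (one well per 4-plex) plus the
prior consensus genotype; ``fit()`` gates each channel, fits the Poisson
partition model (occupancy, concentration, Wilson intervals), computes
calculated CN against the 2-copy reference, resolves which star allele is
duplicated, and runs the g.4181C copy-control and interference diagnostics.
The returned :class:`StarTracResults` carries the estimates with their
uncertainties and renders a ``summary()`` table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alleles import (
    AlleleRegistry,
    P4181_CHANNEL,
    REF_CHANNEL,
    default_registry,
    parse_diplotype,
)
from .calling import CallPolicy, CNResult, NO_CALL, cn_result
from .errors import InconsistentCallsError
from .interpret import (
    InterferenceFlag,
    StarTracReport,
    flag_panel_interference,
    resolve_duplication,
)
from .platform import DEFAULT_PLATFORM, PlatformModel
from .quantify import GatePolicy, PartitionTable, quantify_table

__all__ = ["StarTracModel", "StarTracResults"]


@dataclass
class StarTracResults:
    """Fitted quantities for one sample across its assayed plexes."""

    sample_id: str
    quant: pd.DataFrame
    cn: pd.DataFrame
    calls: dict
    report: StarTracReport | None
    interference_flags: list[InterferenceFlag] = field(default_factory=list)
    inconsistency: dict | None = None

    def summary(self) -> str:
        lines = [f"StarTRAC results — sample {self.sample_id}", ""]
        if self.report is not None:
            configs = ", ".join(self.report.config_labels)
            tag = "unique" if self.report.unique else "ambiguous"
            lines.append(f"Consistent configuration(s): {configs} [{tag}]")
            if self.report.copy_control is not None:
                cc = self.report.copy_control
                lines.append(
                    "Copy control (g.4181C): expected "
                    f"{cc.expected}, observed {cc.observed} — "
                    + ("pass" if cc.passed else "FAIL")
                )
            if self.report.informative_plexes_used:
                lines.append(
                    "Informative plexes used: "
                    + ", ".join(sorted(self.report.informative_plexes_used))
                )
        elif self.inconsistency is not None:
            lines.append(
                "No consistent configuration; residual "
                f"{self.inconsistency} (closest candidate mismatch)"
            )
        lines.append("")
        lines.append(self.cn.to_string(index=False))
        if self.interference_flags:
            lines.append("")
            lines.append("Interference signatures:")
            for f in self.interference_flags:
                lines.append(f"  {f.channel}: {f.signature} — {f.detail}")
        return "\n".join(lines)


class StarTracModel:
    """Allele-specific CN model over one sample's multiplexed dPCR wells.

    Parameters
    ----------
    tables : mapping or sequence
        Plex name -> :class:`PartitionTable`, or a sequence of tables whose
        metadata carries ``plex``.
    candidates : (str, str), optional
        The two haplotype units of the prior consensus genotype; without
        them only quantification and CN calling are performed.
    """

    def __init__(
        self,
        tables: Mapping[str, PartitionTable] | Sequence[PartitionTable],
        candidates: tuple[str, str] | None = None,
        sample_id: str = "sample",
        registry: AlleleRegistry | None = None,
        gate_policy: GatePolicy | None = None,
        call_policy: CallPolicy | None = None,
        platform: PlatformModel = DEFAULT_PLATFORM,
        max_multiplicity: int = 5,
    ):
        if not isinstance(tables, Mapping):
            tables = {t.metadata["plex"]: t for t in tables}
        if not tables:
            raise ValueError("at least one partition table is required")
        self.tables = dict(tables)
        self.candidates = candidates
        self.sample_id = sample_id
        self.registry = registry or default_registry()
        self.gate_policy = gate_policy or GatePolicy()
        self.call_policy = call_policy or CallPolicy()
        self.platform = platform
        self.max_multiplicity = max_multiplicity

    @classmethod
    def from_simulation(
        cls,
        diplotype: str,
        plexes: Sequence[str] | None = None,
        dna_input_ng: float = 10.0,
        seed: int = 0,
        registry: AlleleRegistry | None = None,
        **model_kwargs,
    ) -> "StarTracModel":
        """Simulate a sample's wells and build a model over them."""
        from .io import candidates_for
        from .simulate import SimConfig, simulate_sample

        registry = registry or default_registry()
        config = parse_diplotype(diplotype, registry)
        names = list(plexes) if plexes else list(registry.plexes)
        root = np.random.default_rng(seed)
        tables = {}
        for name in names:
            rng = np.random.default_rng(root.integers(2**31))
            tables[name] = simulate_sample(
                SimConfig(diplotype=config, plex=registry.plexes[name],
                          dna_input_ng=dna_input_ng, seed=seed),
                rng=rng,
            )
        model_kwargs.setdefault("candidates", candidates_for(diplotype))
        model_kwargs.setdefault("sample_id", diplotype)
        return cls(tables, registry=registry, **model_kwargs)

    def fit(self) -> StarTracResults:
        """Quantify, call and interpret; returns :class:`StarTracResults`."""
        from .quantify import gate_partitions

        quant_rows = []
        cn_rows = []
        calls: dict[str, CNResult] = {}
        p4181_results: list[CNResult] = []
        flags: list[InterferenceFlag] = []
        for plex_name, table in self.tables.items():
            gates = gate_partitions(table, self.gate_policy)
            flags.extend(flag_panel_interference(gates))
            quants = quantify_table(table, self.gate_policy, self.platform)
            ref = quants[REF_CHANNEL]
            for channel, q in quants.items():
                quant_rows.append({
                    "plex": plex_name, "channel": channel, "n_pos": q.n_pos,
                    "lambda_hat": q.lambda_hat, "conc": q.conc,
                    "ci_low": q.ci_low, "ci_high": q.ci_high,
                })
                if channel == REF_CHANNEL:
                    continue
                res = cn_result(channel, q, ref, self.call_policy)
                cn_rows.append({
                    "plex": plex_name, "channel": channel,
                    "calculated_cn": round(res.calculated_cn, 2),
                    "call": "NO_CALL" if res.call is NO_CALL else int(res.call),
                    "flags": ";".join(sorted(res.flags)),
                })
                if channel == P4181_CHANNEL:
                    p4181_results.append(res)
                else:
                    calls[channel] = res

        if p4181_results:
            valid = [r.call for r in p4181_results if r.is_call]
            if valid:
                consensus = Counter(valid).most_common(1)[0][0]
                calls[P4181_CHANNEL] = next(
                    r for r in p4181_results if r.call == consensus
                )
            else:
                calls[P4181_CHANNEL] = p4181_results[0]

        report = None
        inconsistency = None
        if self.candidates is not None:
            panel = [self.registry.plexes[name] for name in self.tables]
            try:
                report = resolve_duplication(
                    calls, self.candidates, self.registry, panel,
                    self.max_multiplicity, self.sample_id,
                )
                report.interference_flags = flags
            except InconsistentCallsError as err:
                inconsistency = err.residual

        return StarTracResults(
            sample_id=self.sample_id,
            quant=pd.DataFrame(quant_rows),
            cn=pd.DataFrame(cn_rows),
            calls=calls,
            report=report,
            interference_flags=flags,
            inconsistency=inconsistency,
        )
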