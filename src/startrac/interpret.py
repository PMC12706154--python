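"""The inverse StarTRAC engine.

Given per-target integer CN calls and a prior unphased consensus genotype
(the candidate star alleles), enumerate all structural configurations —
which allele is duplicated or multiplied, where hybrids sit in tandem —
whose forward copy model reproduces every valid call; run the g.4181C
copy-control check; flag assay-interference signatures in the cluster
statistics; and annotate metabolizer activity.

The search is exhaustive over per-copy multiplicities up to
``max_multiplicity`` (the configuration space is tiny). Configurations the
calls cannot distinguish — e.g. ``*2x2/*17`` vs ``*2/*17x2`` under
non-informative plexes, or phase-equivalent hybrid tandems — are all
reported, with ``unique`` set accordingly; the engine reports ambiguity
rather than hiding it.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alleles import (
    AlleleRegistry,
    AssayPlex,
    DiplotypeConfig,
    HaplotypeConfig,
    P4181_CHANNEL,
    REF_CHANNEL,
    default_registry,
    expected_copy_vector,
    informative_assays,
)
from .calling import NO_CALL, CNResult
from .errors import ActivityError, InconsistentCallsError
from .quantify import ChannelGate

__all__ = [
    "StarTracReport",
    "InterferenceFlag",
    "CopyControl",
    "resolve_duplication",
    "copy_control_check",
    "flag_interference",
    "annotate_activity",
    "DEFAULT_ACTIVITY",
    "DEFAULT_PHENOTYPE_BANDS",
]


@dataclass(frozen=True)
class CopyControl:
    """g.4181C internal copy-control: expected vs observed variant copies."""

    expected: int
    observed: int
    passed: bool


@dataclass(frozen=True)
class InterferenceFlag:
    channel: str
    signature: str
    detail: str = ""


@dataclass
class StarTracReport:
    """Outcome of structural-variant resolution for one sample."""

    sample_id: str
    observed: dict
    candidate_alleles: tuple[str, str]
    consistent_configs: list[DiplotypeConfig]
    unique: bool
    informative_plexes_used: set[str]
    copy_control: CopyControl | None = None
    interference_flags: list[InterferenceFlag] = field(default_factory=list)

    @property
    def config_labels(self) -> list[str]:
        return [c.label for c in self.consistent_configs]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "observed": {k: (v if v is not NO_CALL else "NO_CALL")
                         for k, v in self.observed.items()},
            "candidate_alleles": list(self.candidate_alleles),
            "consistent_configs": self.config_labels,
            "unique": self.unique,
            "informative_plexes_used": sorted(self.informative_plexes_used),
            "copy_control": None if self.copy_control is None else {
                "expected_4181C": self.copy_control.expected,
                "observed_4181C": self.copy_control.observed,
                "pass": self.copy_control.passed,
            },
            "interference_flags": [
                {"channel": f.channel, "signature": f.signature, "detail": f.detail}
                for f in self.interference_flags
            ],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def _valid_calls(calls: Mapping) -> dict[str, int]:
    """Extract channel -> integer call, dropping NO_CALL entries."""
    out = {}
    for channel, value in calls.items():
        if isinstance(value, CNResult):
            if value.is_call:
                out[channel] = int(value.call)
        elif value is NO_CALL or value is None:
            continue
        else:
            out[channel] = int(value)
    return out


def _expected_for_channels(
    config: DiplotypeConfig, panel: Sequence[AssayPlex], channels: Iterable[str]
) -> dict[str, int]:
    expected: dict[str, int] = {}
    for plex in panel:
        vec = expected_copy_vector(config, plex)
        for ch, n in vec.items():
            if ch in expected and expected[ch] != n:  # pragma: no cover
                raise AssertionError(f"inconsistent expectation for {ch}")
            expected[ch] = n
    missing = set(channels) - expected.keys()
    if missing:
        raise ValueError(f"calls reference unknown channels: {sorted(missing)}")
    return expected


def _enumerate_configs(
    candidates: tuple[str, str],
    registry: AlleleRegistry,
    max_multiplicity: int,
) -> list[DiplotypeConfig]:
    """All diplotype configurations over the two candidate haplotype units.

    Each unit is a single allele name or a ``+``-joined tandem; every
    non-deleted gene copy's multiplicity runs 1..max_multiplicity (a *5
    unit stays a bare deletion). Duplicates that differ only by haplotype
    order are collapsed.
    """

    def unit_options(unit: str) -> list[HaplotypeConfig]:
        names = unit.replace(" ", "").split("+")
        alleles = [registry.allele(n) for n in names]
        ranges = [
            (1,) if a.deletion else tuple(range(1, max_multiplicity + 1))
            for a in alleles
        ]
        return [
            HaplotypeConfig(tuple(zip(alleles, mults)))
            for mults in itertools.product(*ranges)
        ]

    seen: set[frozenset] = set()
    configs = []
    for hapA in unit_options(candidates[0]):
        for hapB in unit_options(candidates[1]):
            key = frozenset({hapA.label, hapB.label})
            if key in seen:
                continue
            seen.add(key)
            configs.append(DiplotypeConfig(hapA, hapB))
    return configs


def _unit_alleles(unit: str) -> list[str]:
    return unit.replace(" ", "").split("+")


def resolve_duplication(
    calls: Mapping,
    candidates: tuple[str, str],
    registry: AlleleRegistry | None = None,
    panel: Sequence[AssayPlex] | None = None,
    max_multiplicity: int = 5,
    sample_id: str = "sample",
) -> StarTracReport:
    """Determine which candidate star allele is duplicated/multiplied.

    Parameters
    ----------
    calls : mapping
        Channel label (``g.2851C``, ``g.4181C``, ...) to integer call,
        :class:`CNResult`, or NO_CALL. NO_CALL entries contribute no
        constraint but are reported.
    candidates : (str, str)
        The two haplotype units of the prior consensus genotype; each is an
        allele name or a tandem label such as ``*68+*4``.

    Raises
    ------
    InconsistentCallsError
        If no enumerated configuration reproduces every valid call; the
        error carries the closest configuration's per-target residual.
    """
    registry = registry or default_registry()
    panel = list(panel) if panel is not None else registry.panel
    valid = _valid_calls(calls)
    constraint = {ch: n for ch, n in valid.items() if ch != REF_CHANNEL}

    matching = []
    best_residual: dict[str, int] | None = None
    best_label = ""
    for config in _enumerate_configs(candidates, registry, max_multiplicity):
        expected = _expected_for_channels(config, panel, constraint)
        residual = {ch: expected[ch] - n for ch, n in constraint.items()
                    if expected[ch] != n}
        if not residual:
            matching.append(config)
        else:
            size = sum(abs(v) for v in residual.values())
            if best_residual is None or size < sum(abs(v) for v in best_residual.values()):
                best_residual, best_label = residual, config.label
    if not matching:
        raise InconsistentCallsError(best_residual or {}, best_label)

    matching.sort(key=lambda c: c.label)

    # Which informative plexes actually contributed a valid call.
    allelesA = _unit_alleles(candidates[0])
    allelesB = _unit_alleles(candidates[1])
    informative: set[str] = set()
    for a in allelesA:
        for b in allelesB:
            informative |= informative_assays(
                registry.allele(a), registry.allele(b), panel
            )
    called_channels = set(constraint)
    used = {
        plex.name
        for plex in panel
        if plex.name in informative
        and called_channels & {plex.gt_target.ref_label, plex.gt_target.var_label,
                               P4181_CHANNEL}
    }

    copy_control = None
    if P4181_CHANNEL in valid:
        copy_control = copy_control_check(valid, matching, panel)

    observed = {
        ch: (v.call if isinstance(v, CNResult) else v) for ch, v in calls.items()
    }
    return StarTracReport(
        sample_id=sample_id,
        observed=observed,
        candidate_alleles=candidates,
        consistent_configs=matching,
        unique=len(matching) == 1,
        informative_plexes_used=used,
        copy_control=copy_control,
    )


def copy_control_check(
    calls: Mapping,
    consistent_configs: Sequence[DiplotypeConfig],
    panel: Sequence[AssayPlex] | None = None,
) -> CopyControl:
    """Check observed g.4181C copies against the forward model.

    Passes iff at least one consistent configuration predicts exactly the
    observed count; hybrid copies with a CYP2D7-derived exon 9 are excluded
    from the expectation by the forward model itself.
    """
    registry = default_registry()
    panel = list(panel) if panel is not None else registry.panel
    valid = _valid_calls(calls)
    if P4181_CHANNEL not in valid:
        raise ValueError("g.4181C call absent or invalid; copy-control unavailable")
    observed = valid[P4181_CHANNEL]
    expectations = []
    for config in consistent_configs:
        vec = expected_copy_vector(config, panel[0])
        expectations.append(vec[P4181_CHANNEL])
    passed = observed in expectations
    expected = observed if passed else expectations[0]
    return CopyControl(expected=expected, observed=observed, passed=passed)


#: Nominal positive-cluster amplitude and spread of an unimpaired channel.
NOMINAL_POS_MEAN = 6000.0
NOMINAL_POS_SD = 200.0


def flag_interference(
    gate: ChannelGate,
    nominal_pos_mean: float = NOMINAL_POS_MEAN,
    nominal_pos_sd: float = NOMINAL_POS_SD,
    is_reference: bool = False,
) -> InterferenceFlag | None:
    """Detect interference signatures in one channel's cluster statistics.

    ``amplitude-suppression``: the positive cluster sits below half its
    nominal amplitude with more than twice the nominal scatter — the
    signature of an SNV disrupting probe binding. ``reference-multimodal``:
    the reference channel shows more than two total modes (a secondary
    positive cluster); the recommendation is to confirm with an alternative
    reference gene assay.
    """
    if gate.n_pos == 0:
        return None
    if is_reference and gate.pos_modes > 1:
        return InterferenceFlag(
            channel=gate.channel,
            signature="reference-multimodal",
            detail=(
                "secondary positive cluster in the reference channel; "
                "consider an alternative reference gene assay"
            ),
        )
    if (gate.pos_mean < 0.5 * nominal_pos_mean
            and gate.pos_sd > 2.0 * nominal_pos_sd):
        return InterferenceFlag(
            channel=gate.channel,
            signature="amplitude-suppression",
            detail=(
                f"positive cluster at {gate.pos_mean:.0f} RFU "
                f"(nominal {nominal_pos_mean:.0f}) with sd {gate.pos_sd:.0f}; "
                "possible probe-binding disruption and partial drop-out"
            ),
        )
    return None


def flag_panel_interference(
    gates: Mapping[str, ChannelGate],
    nominal_pos_mean: float = NOMINAL_POS_MEAN,
    nominal_pos_sd: float = NOMINAL_POS_SD,
) -> list[InterferenceFlag]:
    """Apply :func:`flag_interference` across a well's channels."""
    flags = []
    for name, gate in gates.items():
        f = flag_interference(
            gate, nominal_pos_mean, nominal_pos_sd,
            is_reference=(name == REF_CHANNEL),
        )
        if f is not None:
            flags.append(f)
    return flags


#: Only the activity values forced by printed worked examples are shipped;
#: anything else must come from a user-supplied table (ClinPGx/CPIC).
DEFAULT_ACTIVITY: dict[str, float] = {"*1": 1.0, "*2": 1.0, "*4": 0.0}

#: (low, high, label) activity-score bands, boundaries inclusive.
DEFAULT_PHENOTYPE_BANDS: tuple[tuple[float, float, str], ...] = (
    (0.0, 0.0, "poor metabolizer"),
    (0.25, 1.0, "intermediate metabolizer"),
    (1.25, 2.25, "normal metabolizer"),
    (2.5, float("inf"), "ultrarapid metabolizer"),
)


def annotate_activity(
    config: DiplotypeConfig,
    activity_table: Mapping[str, float] | None = None,
    phenotype_bands: Sequence[tuple[float, float, str]] | None = None,
) -> tuple[float, str]:
    """Activity score (sum over gene copies) and metabolizer phenotype band.

    The activity score is the sum of per-allele activity values across all
    gene copies (multiplicities included; deletions contribute 0).
    """
    table = DEFAULT_ACTIVITY if activity_table is None else activity_table
    bands = DEFAULT_PHENOTYPE_BANDS if phenotype_bands is None else phenotype_bands
    score = 0.0
    for copy in config.gene_copies():
        if copy.name not in table:
            raise ActivityError(
                f"no activity value for allele {copy.name}; supply an "
                "activity_table covering every allele in the diplotype"
            )
        score += table[copy.name]
    for lo, hi, label in bands:
        if lo <= score <= hi:
            return score, label
    return score, "indeterminate"
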