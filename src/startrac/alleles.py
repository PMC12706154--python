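"""Star-allele definitions, diplotype configurations and the forward copy model.

CYP2D6 star alleles are haplotypes defined by core variants (PharmVar
nomenclature). A multiplexed dPCR panel interrogates seven such variants;
each 4-plex combines one genotyping (GT) target detecting both alleles, the
variant-only exon-9 target g.4181C, and a 2-copy reference gene assay. Given
a structural configuration of a diplotype — duplications (``*2x2``),
multiplications (``*41x3``), deletions (``*5``) and CYP2D6::CYP2D7 hybrid
copies in tandem arrangements (``*68+*4``) — this module predicts the
integer number of copies each dye channel should report.

Two silencing rules govern the forward model: a deleted haplotype
contributes nothing, and a gene copy whose region at a target is
CYP2D7-derived contributes nothing at that target (CYP2D6-specific assays do
not amplify pseudogene sequence).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

import yaml

from .errors import DiplotypeParseError, MatrixIncompleteError

__all__ = [
    "REGIONS",
    "REF",
    "VAR",
    "UNKNOWN",
    "SILENT",
    "VariantTarget",
    "AssayPlex",
    "StarAlleleDefinition",
    "HaplotypeConfig",
    "DiplotypeConfig",
    "AlleleRegistry",
    "expected_copy_vector",
    "informative_assays",
    "parse_diplotype",
    "render_diplotype",
    "default_registry",
]

#: Ordered gene regions of CYP2D6 (5'UTR through exon 9). Hybrid conversion
#: breakpoints are represented at region granularity.
REGIONS: tuple[str, ...] = (
    "utr5",
    "exon1", "intron1",
    "exon2", "intron2",
    "exon3", "intron3",
    "exon4", "intron4",
    "exon5", "intron5",
    "exon6", "intron6",
    "exon7", "intron7",
    "exon8", "intron8",
    "exon9",
)

REF = "REF"
VAR = "VAR"
UNKNOWN = "UNKNOWN"
#: Effective signal of a copy whose sequence at the target is CYP2D7-derived
#: or whose haplotype is deleted.
SILENT = "SILENT"

#: Channel key for the 2-copy reference gene assay.
REF_CHANNEL = "ref"
#: Channel key for the variant-only exon-9 assay.
P4181_CHANNEL = "g.4181C"


@dataclass(frozen=True)
class VariantTarget:
    """One interrogated genomic variant.

    Positions are 1-based on the NG_008376.4 reference with ATG = +1.
    """

    label: str
    position: int
    ref_allele: str
    var_allele: str
    region: str
    rsid: str | None = None
    dyes: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"{self.label}: position must be positive")
        if self.ref_allele == self.var_allele:
            raise ValueError(f"{self.label}: ref and var alleles must differ")
        if self.region not in REGIONS:
            raise ValueError(f"{self.label}: unknown gene region {self.region!r}")

    @property
    def region_index(self) -> int:
        return REGIONS.index(self.region)

    @property
    def ref_label(self) -> str:
        """Channel key for the reference allele, e.g. ``g.2851C``."""
        return f"g.{self.position}{self.ref_allele}"

    @property
    def var_label(self) -> str:
        """Channel key for the variant allele, e.g. ``g.2851T``."""
        return f"g.{self.position}{self.var_allele}"


@dataclass(frozen=True)
class AssayPlex:
    """One 4-plex reaction: GT target, g.4181C target, reference assay."""

    name: str
    gt_target: VariantTarget
    extra_target: VariantTarget
    reference: str = "RNaseP"
    ref_copies: int = 2

    def __post_init__(self) -> None:
        if len(set(self.channels)) != 4:
            raise ValueError(f"{self.name}: plex must expose 4 distinct channels")

    @property
    def channels(self) -> tuple[str, str, str, str]:
        """The four dye-channel keys: GT ref, GT var, g.4181C, reference."""
        return (
            self.gt_target.ref_label,
            self.gt_target.var_label,
            self.extra_target.var_label,
            REF_CHANNEL,
        )

    @property
    def dye_map(self) -> dict[str, str]:
        dyes = {}
        gt = self.gt_target.dyes
        if "ref" in gt:
            dyes[self.gt_target.ref_label] = gt["ref"]
        if "var" in gt:
            dyes[self.gt_target.var_label] = gt["var"]
        dyes[self.extra_target.var_label] = self.extra_target.dyes.get("var", "JUN")
        dyes[REF_CHANNEL] = "ABY"
        return dyes


@dataclass(frozen=True)
class StarAlleleDefinition:
    """Per-target variant status of one star allele plus hybrid-region origin.

    ``status`` maps target labels to REF/VAR; absent entries are UNKNOWN and
    raise when queried rather than being guessed. ``d7_regions`` lists gene
    regions derived from the CYP2D7 pseudogene; targets falling in those
    regions are silent. ``hatched`` marks targets whose variant is present on
    most but not all suballeles (the default suballele carries them);
    ``suballeles`` holds per-suballele status overrides.
    """

    name: str
    status: Mapping[str, str] = field(default_factory=dict)
    d7_regions: frozenset[str] = frozenset()
    deletion: bool = False
    hatched: frozenset[str] = frozenset()
    annotations: tuple[str, ...] = ()
    suballeles: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region in self.d7_regions:
            if region not in REGIONS:
                raise ValueError(f"{self.name}: unknown region {region!r}")
        for label, st in self.status.items():
            if st not in (REF, VAR, UNKNOWN):
                raise ValueError(f"{self.name}: invalid status {st!r} at {label}")

    def origin(self, region: str) -> str:
        """``D6`` or ``D7`` origin of a gene region on this allele."""
        return "D7" if region in self.d7_regions else "D6"

    def effective_signal(self, target: VariantTarget) -> str:
        """REF, VAR or SILENT signal this allele produces at ``target``.

        Raises
        ------
        MatrixIncompleteError
            If the allele's status at the target is UNKNOWN and no silencing
            rule (deletion, CYP2D7-derived region) applies.
        """
        if self.deletion:
            return SILENT
        if self.origin(target.region) == "D7":
            return SILENT
        st = self.status.get(target.label, UNKNOWN)
        if st == UNKNOWN:
            raise MatrixIncompleteError(self.name, target.label)
        return st

    def for_suballele(self, suballele: str) -> "StarAlleleDefinition":
        """Return a definition with this suballele's status overrides applied."""
        if suballele not in self.suballeles:
            raise KeyError(f"{self.name}: unknown suballele {suballele!r}")
        merged = dict(self.status)
        merged.update(self.suballeles[suballele])
        return StarAlleleDefinition(
            name=suballele,
            status=merged,
            d7_regions=self.d7_regions,
            deletion=self.deletion,
            hatched=self.hatched,
            annotations=self.annotations,
        )


@dataclass(frozen=True)
class HaplotypeConfig:
    """One haplotype: an ordered tandem of gene copies with multiplicities."""

    copies: tuple[tuple[StarAlleleDefinition, int], ...]

    def __post_init__(self) -> None:
        if not self.copies:
            raise ValueError("haplotype needs at least one (allele, multiplicity)")
        for allele, mult in self.copies:
            if mult < 1:
                raise ValueError(f"{allele.name}: multiplicity must be >= 1")

    @property
    def label(self) -> str:
        return "+".join(
            f"{a.name}x{m}" if m > 1 else a.name for a, m in self.copies
        )

    def gene_copies(self) -> Iterator[StarAlleleDefinition]:
        """Expand to individual gene copies; deleted copies contribute none."""
        for allele, mult in self.copies:
            if allele.deletion:
                continue
            for _ in range(mult):
                yield allele

    @property
    def n_gene_copies(self) -> int:
        return sum(1 for _ in self.gene_copies())


@dataclass(frozen=True)
class DiplotypeConfig:
    """Two haplotypes; phase beyond the haplotype split is not modelled."""

    hapA: HaplotypeConfig
    hapB: HaplotypeConfig

    @property
    def label(self) -> str:
        return f"{self.hapA.label}/{self.hapB.label}"

    def gene_copies(self) -> Iterator[StarAlleleDefinition]:
        yield from self.hapA.gene_copies()
        yield from self.hapB.gene_copies()

    @property
    def total_gene_copies(self) -> int:
        return self.hapA.n_gene_copies + self.hapB.n_gene_copies


def expected_copy_vector(
    diplotype: DiplotypeConfig, plex: AssayPlex
) -> dict[str, int]:
    """Predict integer copies per dye channel for one 4-plex reaction.

    Returns a map with four keys: the GT target's reference-allele and
    variant-allele channels, the variant-only ``g.4181C`` channel, and the
    2-copy ``ref`` reference channel. Each non-deleted, non-silenced gene
    copy contributes to exactly one of the two GT channels; the g.4181C
    channel counts copies that carry the variant and whose exon-9 region is
    CYP2D6-derived.
    """
    gt = plex.gt_target
    extra = plex.extra_target
    vector = {gt.ref_label: 0, gt.var_label: 0, extra.var_label: 0,
              REF_CHANNEL: plex.ref_copies}
    for copy in diplotype.gene_copies():
        sig = copy.effective_signal(gt)
        if sig == REF:
            vector[gt.ref_label] += 1
        elif sig == VAR:
            vector[gt.var_label] += 1
        sig4 = copy.effective_signal(extra)
        if sig4 == VAR:
            vector[extra.var_label] += 1
    return vector


def _signal_or_none(
    allele: StarAlleleDefinition, target: VariantTarget
) -> str | None:
    try:
        return allele.effective_signal(target)
    except MatrixIncompleteError:
        warnings.warn(
            f"allele {allele.name} has UNKNOWN status at {target.label}; "
            "excluded from informativeness comparison",
            stacklevel=3,
        )
        return None


def informative_assays(
    alleleA: StarAlleleDefinition,
    alleleB: StarAlleleDefinition,
    panel: Iterable[AssayPlex],
) -> set[str]:
    """Plexes whose signal pattern differentiates two candidate alleles.

    A plex is informative iff the two alleles differ in effective signal
    (REF/VAR/silenced) at its GT target or at g.4181C. Targets where either
    allele is UNKNOWN are excluded from the comparison with a warning.
    """
    informative: set[str] = set()
    for plex in panel:
        for target in (plex.gt_target, plex.extra_target):
            sigA = _signal_or_none(alleleA, target)
            sigB = _signal_or_none(alleleB, target)
            if sigA is not None and sigB is not None and sigA != sigB:
                informative.add(plex.name)
                break
    return informative


_COPY_RE = re.compile(r"^(?P<name>\*[\w.]+?)(?:x(?P<mult>\d+))?$")


class AlleleRegistry:
    """Registry of targets, plexes and star-allele definitions.

    Usually loaded from the packaged allele-matrix YAML via
    :func:`default_registry`; custom matrices (other alleles, suballele
    overrides) can be loaded with :meth:`from_yaml`.
    """

    def __init__(
        self,
        targets: Mapping[str, VariantTarget],
        plexes: Mapping[str, AssayPlex],
        alleles: Mapping[str, StarAlleleDefinition],
    ):
        self.targets = dict(targets)
        self.plexes = dict(plexes)
        self.alleles = dict(alleles)

    @property
    def panel(self) -> list[AssayPlex]:
        """All plexes, in registry order."""
        return list(self.plexes.values())

    def allele(self, name: str) -> StarAlleleDefinition:
        try:
            return self.alleles[name]
        except KeyError:
            raise DiplotypeParseError(
                f"unknown allele {name!r}; registered alleles: "
                f"{', '.join(sorted(self.alleles))}"
            ) from None

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "AlleleRegistry":
        targets = {}
        for label, spec in doc["targets"].items():
            targets[label] = VariantTarget(
                label=label,
                position=int(spec["position"]),
                ref_allele=spec["ref"],
                var_allele=spec["var"],
                region=spec["region"],
                rsid=spec.get("rsid"),
                dyes=spec.get("dyes", {}),
            )
        extra = targets["g.4181G>C"]
        plexes = {}
        for name, spec in doc["plexes"].items():
            plexes[name] = AssayPlex(
                name=name,
                gt_target=targets[spec["gt"]],
                extra_target=extra,
                reference=spec.get("reference", "RNaseP"),
            )
        alleles = {}
        for name, spec in doc["alleles"].items():
            spec = spec or {}
            d7 = set(spec.get("d7_regions", []))
            if "d7_after" in spec:
                idx = REGIONS.index(spec["d7_after"])
                d7.update(REGIONS[idx + 1:])
            alleles[name] = StarAlleleDefinition(
                name=name,
                status=dict(spec.get("targets", {})),
                d7_regions=frozenset(d7),
                deletion=bool(spec.get("deletion", False)),
                hatched=frozenset(spec.get("hatched", [])),
                annotations=tuple(spec.get("annotations", [])),
                suballeles={
                    k: dict(v) for k, v in spec.get("suballeles", {}).items()
                },
            )
        return cls(targets, plexes, alleles)

    @classmethod
    def from_yaml(cls, source) -> "AlleleRegistry":
        """Load from a YAML file path, YAML text, or an open stream."""
        if isinstance(source, (str, bytes)) and "\n" not in str(source):
            with open(source) as fh:
                return cls.from_mapping(yaml.safe_load(fh))
        return cls.from_mapping(yaml.safe_load(source))


_DEFAULT: AlleleRegistry | None = None


def default_registry() -> AlleleRegistry:
    """The packaged CYP2D6 allele matrix and 6-plex panel (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("startrac.data").joinpath("alleles.yaml").read_text()
        _DEFAULT = AlleleRegistry.from_yaml(text)
    return _DEFAULT


def parse_diplotype(
    label: str, registry: AlleleRegistry | None = None
) -> DiplotypeConfig:
    """Parse a diplotype label such as ``*2x2/*68+*4`` into a configuration.

    Grammar: two haplotypes separated by ``/``; each haplotype is one or
    more gene copies joined by ``+`` (tandem arrangements); each copy is a
    registered star-allele name with an optional ``xN`` multiplicity.
    """
    registry = registry or default_registry()
    parts = label.replace(" ", "").split("/")
    if len(parts) != 2:
        raise DiplotypeParseError(
            f"diplotype label must contain exactly one '/': {label!r}"
        )

    def parse_hap(text: str) -> HaplotypeConfig:
        copies = []
        for unit in text.split("+"):
            m = _COPY_RE.match(unit)
            if not m:
                raise DiplotypeParseError(f"cannot parse gene copy {unit!r}")
            allele = registry.allele(m.group("name"))
            mult = int(m.group("mult") or 1)
            if mult < 1:
                raise DiplotypeParseError(f"multiplicity must be >= 1 in {unit!r}")
            copies.append((allele, mult))
        return HaplotypeConfig(tuple(copies))

    return DiplotypeConfig(parse_hap(parts[0]), parse_hap(parts[1]))


def render_diplotype(config: DiplotypeConfig) -> str:
    """Inverse of :func:`parse_diplotype`: ``render(parse(s)) == s``."""
    return config.label
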