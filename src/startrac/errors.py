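"""Exception types shared across the package."""


class StarTracError(Exception):
    """Base class for all package-specific errors."""


class MatrixIncompleteError(StarTracError):
    """A star allele's status at a requested target is UNKNOWN.

    Raised instead of guessing: the allele matrix only encodes what the
    validation data force, so untested allele/target combinations must be
    surfaced explicitly.
    """

    def __init__(self, allele: str, target: str):
        self.allele = allele
        self.target = target
        super().__init__(
            f"allele {allele} has UNKNOWN status at target {target}; "
            "the allele matrix does not resolve this combination"
        )


class DiplotypeParseError(StarTracError):
    """A diplotype label could not be parsed against the allele registry."""


class NoSeparationError(StarTracError):
    """Positive and negative amplitude clusters cannot be separated."""

    def __init__(self, channel: str, separation: float, min_separation: float):
        self.channel = channel
        self.separation = separation
        super().__init__(
            f"channel {channel}: cluster means separated by "
            f"{separation:.0f} RFU (< {min_separation:.0f}); channel is ungateable"
        )


class ReferenceFailureError(StarTracError):
    """Reference-channel concentration is zero; calculated CN is undefined."""


class InconsistentCallsError(StarTracError):
    """No enumerated structural configuration reproduces the observed calls.

    Carries the per-target residual of the closest configuration — a signal
    of assay interference, wrong candidate alleles, or a novel structural
    variant.
    """

    def __init__(self, residual: dict, closest: str):
        self.residual = residual
        self.closest = closest
        super().__init__(
            f"no candidate configuration reproduces the observed calls; "
            f"closest is {closest} with per-target residual {residual}"
        )


class ActivityError(StarTracError):
    """An allele in the diplotype has no entry in the activity table."""
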