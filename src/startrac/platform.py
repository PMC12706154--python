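"""Digital-PCR platform geometry.

The partition array is modelled after a microchamber dPCR instrument:
~2 x 10^4 sub-nanolitre chambers loaded from a 10 uL reaction. Partition
count and volume are not published for the instrument, so the defaults are
chosen to place a 2-copy locus at 10 ng input inside the 100-500 copies/uL
operating band (lambda ~ 0.1-0.3) and are overridable everywhere they are
used.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PlatformModel:
    """Geometry of one dPCR reaction.

    Parameters
    ----------
    n_partitions : int
        Number of valid microchambers read out per well.
    v_partition : float
        Volume of one partition in microlitres (default 0.5 nL).
    reaction_volume : float
        Volume of the reaction mix in microlitres; concentrations are
        reported per microlitre of this (undiluted) reaction.
    """

    n_partitions: int = 20_480
    v_partition: float = 5.0e-4
    reaction_volume: float = 10.0

    def __post_init__(self) -> None:
        if self.n_partitions <= 0:
            raise ValueError("n_partitions must be positive")
        if self.v_partition <= 0:
            raise ValueError("v_partition must be positive")
        if self.reaction_volume <= 0:
            raise ValueError("reaction_volume must be positive")


DEFAULT_PLATFORM = PlatformModel()
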