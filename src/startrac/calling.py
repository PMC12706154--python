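"""Copy-number calculation against the 2-copy reference and the call rule.

Calculated CN is ``ref_copies x [target] / [reference]``; a call is valid
only when the calculated value lies within +/-0.25 of an integer (a CN call
of 2 requires a calculated CN between 1.75 and 2.25, boundaries inclusive).
Values outside every window are reported as NO_CALL with the raw calculated
CN preserved — they are never silently rounded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ReferenceFailureError
from .quantify import QuantResult

__all__ = ["NO_CALL", "CallPolicy", "CNResult", "calculated_cn", "call_cn",
           "cn_result"]


class _NoCall:
    """Singleton sentinel for an invalid (out-of-window) CN call."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NO_CALL"

    def __bool__(self) -> bool:
        return False


NO_CALL = _NoCall()


@dataclass(frozen=True)
class CallPolicy:
    """Valid-call window and reference configuration.

    ``half_width`` is the half-width of the valid window around each integer
    (default 0.25); ``ref_copies`` the copy number of the reference gene
    (default 2); ``max_cn`` the largest integer call considered.
    """

    half_width: float = 0.25
    ref_copies: int = 2
    max_cn: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.half_width < 0.5:
            raise ValueError("half_width must lie in (0, 0.5)")
        if self.ref_copies < 1:
            raise ValueError("ref_copies must be >= 1")


@dataclass(frozen=True)
class CNResult:
    """Calculated CN and integer call (or NO_CALL) for one target channel."""

    target_label: str
    calculated_cn: float
    call: object  # int or NO_CALL
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.call is not NO_CALL and not isinstance(self.call, (int,)):
            raise ValueError("call must be an int or NO_CALL")

    @property
    def is_call(self) -> bool:
        return self.call is not NO_CALL


def calculated_cn(
    conc_target: float, conc_ref: float, policy: CallPolicy | None = None
) -> float:
    """``ref_copies x conc_target / conc_ref`` (invariant to common scaling)."""
    policy = policy or CallPolicy()
    if conc_ref <= 0:
        raise ReferenceFailureError(
            "reference concentration is zero; calculated CN undefined"
        )
    return policy.ref_copies * conc_target / conc_ref


def call_cn(calculated: float, policy: CallPolicy | None = None):
    """Map a calculated CN to an integer call or NO_CALL.

    The valid region is exactly the union of closed windows
    ``[n - half_width, n + half_width]`` for integers ``0 <= n <= max_cn``.
    """
    policy = policy or CallPolicy()
    if calculated < 0:
        raise ValueError("calculated CN must be >= 0")
    n = int(round(calculated))
    if n > policy.max_cn or abs(calculated - n) > policy.half_width:
        return NO_CALL
    return n


def cn_result(
    target_label: str,
    target: QuantResult,
    reference: QuantResult,
    policy: CallPolicy | None = None,
) -> CNResult:
    """Build a :class:`CNResult` from target and reference quantifications.

    Flags carry quantification caveats forward: ``saturated`` when either
    channel hit the saturation floor, ``low-reference`` when the reference
    channel is empty or nearly so, ``out-of-window`` on NO_CALL.
    """
    policy = policy or CallPolicy()
    flags = set()
    if target.saturated_flag or reference.saturated_flag:
        flags.add("saturated")
    if reference.empty_flag or reference.n_pos < 50:
        flags.add("low-reference")
    cn = calculated_cn(target.conc, reference.conc, policy)
    call = call_cn(cn, policy)
    if call is NO_CALL:
        flags.add("out-of-window")
    return CNResult(
        target_label=target_label,
        calculated_cn=cn,
        call=call,
        flags=frozenset(flags),
    )
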