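"""Precision and information calculus for phase-ternary coding.

The refractory period bounds the maximum CAP frequency; with conduction
velocity ``v`` and maximum frequency ``f_max`` the refractory stretch of
membrane is ``v / f_max`` metres long and lasts ``1 / f_max`` seconds.
Subdividing the refractory window into ``k`` distinguishable phase positions
digitises the timing of a threshold relative to the blocking CAP; the
spacing of successive impulses then carries multi-valued (ternary by
default) information: ``n`` impulses span ``base**n`` distinguishable
states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError


@dataclass(frozen=True)
class DigitisationScheme:
    """Phase digitisation: ``subdivisions`` (k) bins per refractory window,
    information ``base`` per impulse (ternary by default)."""

    subdivisions: int = 12
    base: int = 3

    def __post_init__(self) -> None:
        if self.subdivisions < 1:
            raise ValidationError("subdivisions must be >= 1")
        if self.base < 2:
            raise ValidationError("base must be >= 2")


def refractory_metrics(velocity: float, max_frequency: float) -> tuple:
    """Refractory (distance m, time s) implied by velocity and max frequency.

    The maximum CAP frequency is set by the refractory period, so the
    refractory stretch of membrane is one phase length at that frequency:
    ``distance = velocity / max_frequency`` and ``time = 1 / max_frequency``
    (distance = velocity x time always holds).  At 0.3 m/s and 100 Hz this
    is 0.003 m and 10 ms.
    """
    if not (velocity > 0) or not math.isfinite(velocity):
        raise ValidationError(f"velocity must be positive, got {velocity!r}")
    if not (max_frequency > 0) or not math.isfinite(max_frequency):
        raise ValidationError(
            f"max_frequency must be positive, got {max_frequency!r}"
        )
    return velocity / max_frequency, 1.0 / max_frequency


def phase_index(
    offset: float,
    refractory_duration: float,
    scheme: DigitisationScheme = DigitisationScheme(),
) -> int:
    """Digitised phase bin of a threshold ``offset`` seconds into a window.

    Bins are half-open and left-closed: bin ``floor(offset * k / L)`` in
    ``[0, k-1]``.  ``offset`` is measured from the blocking CAP's threshold
    and must lie in ``[0, L)`` (outside that the threshold would not be
    inside the window at all).
    """
    if not (0 <= offset < refractory_duration):
        raise ValidationError(
            f"offset {offset!r} outside refractory window [0, {refractory_duration!r})"
        )
    idx = int(offset * scheme.subdivisions / refractory_duration)
    return min(idx, scheme.subdivisions - 1)


def states_per_window(n_impulses: int, base: int = 3) -> int:
    """Distinguishable states conveyed by ``n_impulses`` spacings: base**n.

    Two successive impulses under ternary coding convey base-9 information.
    """
    if n_impulses < 0:
        raise ValidationError("n_impulses must be >= 0")
    if base < 2:
        raise ValidationError("base must be >= 2")
    return base ** n_impulses


def trits_per_impulse(base: int = 3) -> float:
    """Information per impulse expressed in trits: log3(base).

    Exactly 1.0 for base 3.
    """
    if base < 2:
        raise ValidationError("base must be >= 2")
    if base == 3:
        return 1.0
    return math.log(base) / math.log(3)


def effective_clock_period(
    refractory_duration: float,
    scheme: DigitisationScheme = DigitisationScheme(),
) -> float:
    """Temporal resolution (s) of one phase subdivision: L / k.

    With L = 1 ms and k = 12 subdivisions this is ~83 us; reported as a
    derived quantity, not a constant.  Note that k distinguishable positions
    per window would carry log3(k) trits (~2.26 for k = 12), which is more
    than the one trit per impulse of pure ternary coding; both quantities
    are reported separately (see also :func:`trits_per_subdivided_window`).
    """
    if not (refractory_duration > 0):
        raise ValidationError("refractory_duration must be positive")
    return refractory_duration / scheme.subdivisions


def trits_per_subdivided_window(
    scheme: DigitisationScheme = DigitisationScheme(),
) -> float:
    """Trits carried by one window if all k subdivisions are distinguishable:
    log3(k)."""
    return math.log(scheme.subdivisions) / math.log(3)
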