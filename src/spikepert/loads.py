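"""Shoulder/elbow torque-load conditions and directional tuning.

The perturbation set consists of the 3 x 3 combinations of shoulder and
elbow torque in {flexor, null, extensor}.  The (null, null) combination is
the unloaded catch condition; the remaining eight loaded combinations span
eight directions of the joint-torque plane (shoulder torque on the x axis,
elbow torque on the y axis, flexor = +1, extensor = -1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

TORQUE_LEVELS = ("flexor", "null", "extensor")

_AXIS_VALUE = {"flexor": 1.0, "null": 0.0, "extensor": -1.0}


@dataclass(frozen=True, order=True)
class LoadCondition:
    """One shoulder/elbow torque combination.

    Parameters
    ----------
    shoulder, elbow : str
        Torque level on each joint, one of ``"flexor"``, ``"null"``,
        ``"extensor"``.
    magnitude_nm : float
        Torque magnitude in newton-metres applied on each non-null axis.
    """

    shoulder: str
    elbow: str
    magnitude_nm: float = field(default=0.24, compare=False)

    def __post_init__(self) -> None:
        for level in (self.shoulder, self.elbow):
            if level not in TORQUE_LEVELS:
                raise ValueError(f"unknown torque level {level!r}")
        if not self.is_null and self.magnitude_nm <= 0:
            raise ValueError("loaded conditions require magnitude_nm > 0")

    @property
    def is_null(self) -> bool:
        """True for the unloaded catch condition (null, null)."""
        return self.shoulder == "null" and self.elbow == "null"

    @property
    def torque_vector(self) -> tuple[float, float]:
        m = self.magnitude_nm
        return (_AXIS_VALUE[self.shoulder] * m, _AXIS_VALUE[self.elbow] * m)

    @property
    def angle_rad(self) -> float:
        """Direction of the torque vector in the shoulder-elbow plane."""
        if self.is_null:
            raise ValueError("the null condition has no torque direction")
        return math.atan2(_AXIS_VALUE[self.elbow], _AXIS_VALUE[self.shoulder])

    @property
    def key(self) -> tuple[str, str]:
        return (self.shoulder, self.elbow)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"S:{self.shoulder}/E:{self.elbow}"


def all_conditions(magnitude_nm: float = 0.24) -> list[LoadCondition]:
    """The nine load conditions in canonical order (shoulder axis fastest)."""
    return [
        LoadCondition(s, e, magnitude_nm)
        for e in TORQUE_LEVELS
        for s in TORQUE_LEVELS
    ]


def loaded_conditions(magnitude_nm: float = 0.24) -> list[LoadCondition]:
    """The eight non-null conditions, in canonical order."""
    return [c for c in all_conditions(magnitude_nm) if not c.is_null]


def cosine_tuning(angle_rad: float, preferred_rad: float, width: float = 1.0) -> float:
    """Broad cosine tuning of evoked amplitude over torque direction.

    ``((1 + cos(angle - preferred)) / 2) ** (1 / width)`` — a raised-cosine
    bump with range [0, 1], equal to 1 in the preferred direction and 0
    opposite to it.  ``width`` > 1 broadens the tuning, < 1 sharpens it.
    """
    if width <= 0:
        raise ValueError("tuning width must be positive")
    base = 0.5 * (1.0 + math.cos(angle_rad - preferred_rad))
    return float(base ** (1.0 / width))


def condition_tuning(
    condition: LoadCondition, preferred_rad: float, width: float = 1.0
) -> float:
    """Tuning weight of a load condition; the catch condition gets 0."""
    if condition.is_null:
        return 0.0
    return cosine_tuning(condition.angle_rad, preferred_rad, width)
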