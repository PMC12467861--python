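"""Locomotion-mode taxonomy.

Thirteen lower-limb locomotion modes: five steady-state gaits (level
walking, stair ascent/descent, ramp ascent/descent) and the eight
transition patterns between level walking and each of the other four.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ModeLabel",
    "MODE_CODES",
    "STEADY_CODES",
    "TRANSITION_CODES",
    "mode_index",
    "transition_endpoints",
]

#: Canonical ordering (transitions first, then steady modes), used for
#: confusion-matrix rows and one-hot layouts throughout the package.
MODE_CODES: tuple[str, ...] = (
    "LW-SA",
    "LW-SD",
    "LW-RA",
    "LW-RD",
    "RA-LW",
    "RD-LW",
    "SA-LW",
    "SD-LW",
    "LW",
    "SA",
    "SD",
    "RA",
    "RD",
)

STEADY_CODES: tuple[str, ...] = ("LW", "SA", "SD", "RA", "RD")
TRANSITION_CODES: tuple[str, ...] = tuple(
    c for c in MODE_CODES if c not in STEADY_CODES
)


@dataclass(frozen=True)
class ModeLabel:
    """A locomotion-mode label.

    Parameters
    ----------
    code : str
        One of the 13 canonical mode codes (e.g. ``"LW"``, ``"RD-LW"``).
    """

    code: str

    def __post_init__(self) -> None:
        if self.code not in MODE_CODES:
            raise ValueError(
                f"unknown locomotion mode {self.code!r}; "
                f"expected one of {MODE_CODES}"
            )

    @property
    def is_transition(self) -> bool:
        return self.code in TRANSITION_CODES

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def mode_index(code: str) -> int:
    """Position of ``code`` in the canonical mode ordering."""
    return MODE_CODES.index(code)


def transition_endpoints(code: str) -> tuple[str, str]:
    """Steady modes a transition connects, e.g. ``"RD-LW" -> ("RD", "LW")``.

    For a steady mode returns the mode twice.
    """
    if code in STEADY_CODES:
        return code, code
    a, b = code.split("-")
    return a, b
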