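"""Salmonid age nomenclature for scale-read life histories.

An age code like ``"1.2+"`` reads: one freshwater winter before smolting,
two completed sea winters, and marginal ("plus") growth at the scale edge
at capture.  Sea trout caught on their autumn spawning run essentially
always carry plus growth, but codes without the ``+`` are legal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_AGE_RE = re.compile(r"^(\d)\.(\d)(\+?)$")


class AgeCodeError(ValueError):
    """Raised for malformed age-code strings."""


@dataclass(frozen=True, order=True)
class AgeCode:
    """Freshwater/sea age of a fish, e.g. ``AgeCode(1, 2, True)`` == "1.2+".

    Attributes
    ----------
    fw_age : int
        Winters spent in freshwater before seaward migration (>= 1).
    sw_age : int
        Completed post-migration sea winters (>= 0).
    plus : bool
        Whether marginal (incomplete) growth is present at the scale edge.
    """

    fw_age: int
    sw_age: int
    plus: bool = False

    def __post_init__(self) -> None:
        if self.fw_age < 1:
            raise AgeCodeError(f"freshwater age must be >= 1, got {self.fw_age}")
        if self.sw_age < 0:
            raise AgeCodeError(f"sea age must be >= 0, got {self.sw_age}")

    def __str__(self) -> str:
        return f"{self.fw_age}.{self.sw_age}{'+' if self.plus else ''}"

    @property
    def n_completed_zones(self) -> int:
        """Number of completed annual growth zones (freshwater + sea)."""
        return self.fw_age + self.sw_age


def parse_age_code(code: str) -> AgeCode:
    """Parse an age-code string such as ``"1.2+"`` into an :class:`AgeCode`.

    The string round-trips: ``str(parse_age_code(s)) == s`` for any valid
    input.  Malformed strings raise :class:`AgeCodeError` naming the token.
    """
    m = _AGE_RE.match(code.strip())
    if m is None:
        raise AgeCodeError(f"malformed age code {code!r}: expected '<fw>.<sw>' with optional '+'")
    return AgeCode(fw_age=int(m.group(1)), sw_age=int(m.group(2)), plus=m.group(3) == "+")


def age_class_sequence(age: AgeCode) -> list[str]:
    """Completed-zone age classes in life order, e.g. 1.2+ -> [FW1, SW1, SW2]."""
    return [f"FW{k}" for k in range(1, age.fw_age + 1)] + [
        f"SW{k}" for k in range(1, age.sw_age + 1)
    ]


def environment_of(age_class: str) -> str:
    """Map an age class (FW1/FW2/SW1/...) to its environment."""
    if age_class.startswith("FW"):
        return "freshwater"
    if age_class.startswith("SW"):
        return "sea"
    raise ValueError(f"unknown age class {age_class!r}")
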