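"""Enzyme Commission (EC) number algebra.

EC numbers are four-level dotted identifiers ``class.subclass.subdivision.serial``
(e.g. ``5.4.4.2``): the first digit names one of six reaction classes
(1 oxidoreductases, 2 transferases, 3 hydrolases, 4 lyases, 5 isomerases,
6 ligases), the second and third digits refine the reaction chemistry, and the
fourth is a serial number addressing the substrate. Enzymes sharing the first
three digits (the *subdivision*) share the same reaction chemistry.

Partially specified numbers use ``-`` as a wildcard (e.g. ``1.-.-.-``); a
wildcard may only appear as a contiguous right suffix. Every grouping key used
by the downstream statistics derives from :func:`ec_key`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ECNumber",
    "ECParseError",
    "IncompleteAtLevel",
    "LEVELS",
    "LEVEL_DEPTH",
    "parse_ec",
    "ec_key",
    "same_at_level",
]

#: Grouping levels in order of increasing depth.
LEVELS = ("class", "subclass", "subdivision", "full")

#: Number of concrete digits each level requires.
LEVEL_DEPTH = {"class": 1, "subclass": 2, "subdivision": 3, "full": 4}

#: The classical six-class universe; translocases (class 7) are opt-in.
DEFAULT_MAX_CLASS = 6


class ECParseError(ValueError):
    """Raised for malformed or out-of-range EC strings."""


class IncompleteAtLevel(ValueError):
    """Raised when a grouping key is requested below an EC's wildcard depth."""


@dataclass(frozen=True, order=True)
class ECNumber:
    """An EC number with optional wildcard suffix.

    ``None`` encodes a wildcard position. Invariants enforced at construction:
    the class digit is a positive integer, all concrete digits are >= 1, and
    wildcards form a contiguous right suffix.
    """

    ec_class: int
    subclass: Optional[int] = None
    subdivision: Optional[int] = None
    serial: Optional[int] = None

    def __post_init__(self) -> None:
        if not isinstance(self.ec_class, int) or self.ec_class < 1:
            raise ECParseError(f"EC class digit must be a positive integer, got {self.ec_class!r}")
        digits = (self.subclass, self.subdivision, self.serial)
        seen_wildcard = False
        for name, value in zip(("subclass", "subdivision", "serial"), digits):
            if value is None:
                seen_wildcard = True
            else:
                if seen_wildcard:
                    raise ECParseError(
                        f"wildcard left of concrete digit: {name}={value} follows a '-'"
                    )
                if not isinstance(value, int) or value < 1:
                    raise ECParseError(f"EC {name} must be a positive integer, got {value!r}")

    @property
    def digits(self) -> tuple:
        return (self.ec_class, self.subclass, self.subdivision, self.serial)

    def depth(self) -> int:
        """Number of concrete (non-wildcard) leading digits, 1..4."""
        n = 0
        for d in self.digits:
            if d is None:
                break
            n += 1
        return n

    def is_complete_at(self, level: str) -> bool:
        return self.depth() >= _depth(level)

    def key(self, level: str) -> str:
        """Dotted prefix at *level*; raises :class:`IncompleteAtLevel` if wildcarded there."""
        d = _depth(level)
        if self.depth() < d:
            raise IncompleteAtLevel(f"{self} is incomplete at level {level!r}")
        return ".".join(str(x) for x in self.digits[:d])

    def __str__(self) -> str:
        return ".".join("-" if d is None else str(d) for d in self.digits)


def _depth(level: str) -> int:
    try:
        return LEVEL_DEPTH[level]
    except KeyError:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}") from None


def parse_ec(
    text: str,
    max_class: int = DEFAULT_MAX_CLASS,
    strip_preliminary: bool = False,
) -> ECNumber:
    """Parse an EC string such as ``"5.4.4.2"`` or ``"1.-.-.-"``.

    Parameters
    ----------
    text:
        Four dot-separated fields; ``-`` marks a wildcard, allowed only as a
        contiguous right suffix.
    max_class:
        Highest admissible class digit. Defaults to 6 (the classical
        universe); pass 7 to admit translocases.
    strip_preliminary:
        Preliminary serial numbers carry an ``n`` prefix (e.g. ``1.14.13.n9``).
        By default these are rejected; with this flag the prefix is stripped.
    """
    if not isinstance(text, str) or not text.strip():
        raise ECParseError(f"empty or non-string EC: {text!r}")
    fields = text.strip().split(".")
    if len(fields) != 4:
        raise ECParseError(f"expected four dot-separated fields, got {text!r}")
    parsed: list[Optional[int]] = []
    for i, field in enumerate(fields):
        field = field.strip()
        if field == "-":
            parsed.append(None)
            continue
        if field.startswith("n"):
            if not strip_preliminary:
                raise ECParseError(
                    f"preliminary EC field {field!r} in {text!r} (set strip_preliminary=True to accept)"
                )
            field = field[1:]
        if not field.isdigit():
            raise ECParseError(f"non-numeric EC field {fields[i]!r} in {text!r}")
        parsed.append(int(field))
    ec = ECNumber(*parsed)  # validates wildcard contiguity and positivity
    if ec.ec_class > max_class:
        raise ECParseError(
            f"EC class {ec.ec_class} out of range 1..{max_class} in {text!r}"
        )
    return ec


def ec_key(ec: ECNumber, level: str) -> str:
    """Grouping key of *ec* at *level* (e.g. ``ec_key(5.4.4.2, "subdivision") == "5.4.4"``)."""
    return ec.key(level)


def same_at_level(a: ECNumber, b: ECNumber, level: str) -> bool:
    """True iff *a* and *b* share the grouping key at *level*.

    Both numbers must be complete at *level*; :class:`IncompleteAtLevel`
    propagates otherwise.
    """
    return a.key(level) == b.key(level)
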