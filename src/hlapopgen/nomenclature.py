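"""HLA allele nomenclature at the four-digit level.

An allele designation such as ``A*1101`` or ``DRB1*0701`` carries a locus
name, a two-digit allele family (the serological group) and a two-digit
protein subtype.  Only this classic four-digit form is handled; modern
colon-delimited names, G/P ambiguity groups and expression suffixes are out
of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["AlleleName", "AlleleParseError", "parse_allele_name"]


class AlleleParseError(ValueError):
    """Raised when an allele designation cannot be parsed."""


_ALLELE_RE = re.compile(r"^(?:(?P<locus>[A-Za-z][A-Za-z0-9]*)\*)?(?P<digits>\d+)$")


@dataclass(frozen=True, order=True)
class AlleleName:
    """A four-digit HLA allele: locus, family (first field), protein (second).

    Rendering with ``str()`` reproduces the canonical ``LOCUS*FFPP`` form, so
    ``parse_allele_name(str(a)) == a`` for every valid name.
    """

    locus: str
    family: str
    protein: str

    def __post_init__(self) -> None:
        if len(self.family) != 2 or len(self.protein) != 2:
            raise AlleleParseError(
                f"family/protein fields must be two digits each, got "
                f"{self.family!r}/{self.protein!r}"
            )

    @property
    def code(self) -> str:
        """Four-digit code without the locus prefix (e.g. ``'1101'``)."""
        return self.family + self.protein

    def __str__(self) -> str:
        return f"{self.locus}*{self.code}"


def parse_allele_name(text: str, locus: str | None = None) -> AlleleName:
    """Parse ``LOCUS*FFPP`` (or bare ``FFPP`` with *locus* from context).

    Parameters
    ----------
    text:
        Allele designation, e.g. ``"A*1101"``.  A bare four-digit code is
        accepted when *locus* supplies the missing prefix.
    locus:
        Context locus used when *text* has no ``LOCUS*`` prefix.

    Raises
    ------
    AlleleParseError
        On a malformed designation: wrong digit count, missing locus, or
        characters outside the grammar.
    """
    m = _ALLELE_RE.match(text.strip())
    if m is None:
        raise AlleleParseError(f"malformed allele designation: {text!r}")
    digits = m.group("digits")
    if len(digits) != 4:
        raise AlleleParseError(
            f"allele {text!r}: expected a four-digit code, got {len(digits)} digit(s)"
        )
    parsed_locus = m.group("locus") or locus
    if parsed_locus is None:
        raise AlleleParseError(f"allele {text!r}: no locus prefix and no context locus")
    if locus is not None and m.group("locus") is not None and m.group("locus") != locus:
        raise AlleleParseError(
            f"allele {text!r}: locus prefix {m.group('locus')!r} conflicts with "
            f"context locus {locus!r}"
        )
    return AlleleName(locus=parsed_locus, family=digits[:2], protein=digits[2:])
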