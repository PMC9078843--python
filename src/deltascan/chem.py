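"""Signed elemental compositions and monoisotopic delta-mass arithmetic.

A delta mass produced by an open search is annotated with a *signed*
elemental composition: a gain or loss of atoms relative to the coding
residue. Compositions are written in a Unimod-like dialect::

    O            one oxygen                     (+15.994915 Da)
    O(2)         two oxygens                    (+31.989829 Da)
    C(-1)O       lose a carbon, gain an oxygen  (+3.994915 Da)
    H(11)C(6)NO(3)S(2)                          (+209.018035 Da)

An element symbol optionally followed by a signed integer count in
parentheses; a bare symbol means count +1; concatenation sums.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from types import MappingProxyType

from .errors import CompositionError, UnknownElementError

__all__ = [
    "MONOISOTOPIC_MASS",
    "ElementalComposition",
    "parse_composition",
    "format_composition",
    "monoisotopic_mass",
    "annotation_error",
]

#: Monoisotopic masses of the most abundant isotope, in Da (CODATA/IUPAC).
#: Carbon-12 defines the scale and is exactly 12.
MONOISOTOPIC_MASS: Mapping[str, float] = MappingProxyType({
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Mg": 23.98504170,
    "Fe": 55.93493750,
    "Zn": 63.92914220,
    "Cu": 62.92959750,
    "Mn": 54.93804510,
    "Ni": 57.93534290,
    "Co": 58.93319500,
    "Se": 79.91652130,
    "Li": 7.01600340,
    "B": 11.00930540,
    "Si": 27.97692653,
    "As": 74.92159650,
    "Mo": 95.96467930,
    "Al": 26.98153863,
    "Hg": 201.97064300,
})

_TOKEN = re.compile(r"([A-Z][a-z]?)(?:\((\s*[+-]?\d+\s*)\))?")


class ElementalComposition(Mapping):
    """Immutable signed element -> count map.

    Zero counts are normalized away, so two compositions are equal iff
    they describe the same net atom change. Supports ``+`` (merge),
    unary ``-`` (negation) and scalar ``*``.

    >>> parse_composition("C(-1)O(2)") == ElementalComposition({"O": 2, "C": -1})
    True
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for symbol, count in (counts or {}).items():
            if symbol not in MONOISOTOPIC_MASS:
                raise UnknownElementError(symbol)
            count = int(count)
            if count != 0:
                clean[symbol] = count
        # store in deterministic (sorted) order for stable formatting
        self._counts = dict(sorted(clean.items()))

    def __getitem__(self, symbol: str) -> int:
        return self._counts[symbol]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self._counts)
        for symbol, count in other.items():
            merged[symbol] = merged.get(symbol, 0) + count
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return self + (-other)

    def __neg__(self) -> "ElementalComposition":
        return ElementalComposition({s: -c for s, c in self._counts.items()})

    def __mul__(self, factor: int) -> "ElementalComposition":
        return ElementalComposition({s: c * factor for s, c in self._counts.items()})

    __rmul__ = __mul__

    def __repr__(self) -> str:
        return f"ElementalComposition({format_composition(self)!r})"


def parse_composition(text: str) -> ElementalComposition:
    """Parse a composition string into an :class:`ElementalComposition`.

    Raises
    ------
    CompositionError
        On empty input, an unknown element, or a malformed parenthetical;
        the error carries the 0-based position of the offending token.
    """
    if not isinstance(text, str):
        raise CompositionError(f"expected a string, got {type(text).__name__}")
    stripped = text.strip()
    if not stripped:
        raise CompositionError("empty composition string", 0)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(stripped):
        match = _TOKEN.match(stripped, pos)
        if match is None:
            raise CompositionError(
                f"malformed composition near {stripped[pos:pos + 8]!r}", pos
            )
        # the regex is longest-match: a lowercase letter after an uppercase
        # one is always consumed as a two-letter symbol ("Na"), so "NO"
        # tokenizes as N + O while "Cl" stays a single token.
        symbol, count_text = match.group(1), match.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise UnknownElementError(symbol, pos)
        count = 1 if count_text is None else int(count_text)
        counts[symbol] = counts.get(symbol, 0) + count
        pos = match.end()
    return ElementalComposition(counts)


def format_composition(comp: ElementalComposition) -> str:
    """Canonical string for a composition.

    Elements appear in Hill-like order (C, H, then alphabetical); a count
    of +1 is written as the bare symbol. ``parse_composition`` round-trips
    this form exactly.
    """
    def sort_key(symbol: str) -> tuple[int, str]:
        order = {"C": 0, "H": 1}
        return (order.get(symbol, 2), symbol)

    parts = []
    for symbol in sorted(comp, key=sort_key):
        count = comp[symbol]
        parts.append(symbol if count == 1 else f"{symbol}({count})")
    return "".join(parts)


def monoisotopic_mass(comp: ElementalComposition | Mapping[str, int]) -> float:
    """Signed monoisotopic mass of a composition, in Da.

    Additive over composition merge: ``mass(a + b) == mass(a) + mass(b)``
    up to float rounding.
    """
    if not isinstance(comp, ElementalComposition):
        comp = ElementalComposition(comp)
    return sum(MONOISOTOPIC_MASS[s] * c for s, c in comp.items())


def annotation_error(observed_delta: float, comp: ElementalComposition) -> float:
    """Observed delta mass minus the mass predicted by the annotation."""
    return observed_delta - monoisotopic_mass(comp)
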