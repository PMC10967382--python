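"""Elemental compositions and monoisotopic mass arithmetic.

All mass computation in the package funnels through :class:`ElementComposition`
and :func:`monoisotopic_mass`.  Atomic masses are the masses of the most
abundant isotope of each element, loaded once from a bundled reference table
so that every mass in the package is bit-reproducible.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Dict, Iterator, Mapping

__all__ = [
    "ATOMIC_MASSES",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementComposition",
    "monoisotopic_mass",
]

ELECTRON_MASS = 0.000548579909  # Da
PROTON_MASS = 1.00727646688  # Da, mass of H minus one electron


def _load_atomic_masses() -> Dict[str, float]:
    table: Dict[str, float] = {}
    text = resources.files("lipidshift.data").joinpath("atomic_masses.tsv").read_text()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        element, mass = line.split("\t")
        table[element] = float(mass)
    return table


ATOMIC_MASSES: Dict[str, float] = _load_atomic_masses()

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementComposition(Mapping[str, int]):
    """Immutable multiset of atoms; the unit of all mass arithmetic.

    Counts must be non-negative; zero-count elements are dropped so two
    compositions compare equal iff all stored counts are equal.  Signed
    deltas (e.g. adduct gains/losses) are represented as a pair of
    compositions (gain, loss) elsewhere.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: Dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for element, n in source.items():
                merged[element] = merged.get(element, 0) + int(n)
        for element, n in merged.items():
            if n < 0:
                raise ValueError(f"negative count for element {element!r}: {n}")
        self._counts = {e: n for e, n in sorted(merged.items()) if n != 0}

    @classmethod
    def from_formula(cls, formula: str) -> "ElementComposition":
        """Parse a Hill-notation formula string such as ``C36H72NO8P``."""
        if formula in ("", "-"):
            return cls()
        counts: Dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos or not match.group(1):
                break
            element, digits = match.groups()
            if element not in ATOMIC_MASSES:
                raise KeyError(f"unknown element symbol {element!r} in {formula!r}")
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def get(self, element: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(element, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementComposition):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        counts = dict(self._counts)
        for element, n in other.items():
            counts[element] = counts.get(element, 0) + n
        return ElementComposition(counts)

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        counts = dict(self._counts)
        for element, n in other.items():
            counts[element] = counts.get(element, 0) - n
        return ElementComposition(counts)

    def __mul__(self, k: int) -> "ElementComposition":
        if not isinstance(k, int) or k < 0:
            raise ValueError("composition may only be scaled by a non-negative integer")
        return ElementComposition({e: n * k for e, n in self._counts.items()})

    __rmul__ = __mul__

    def hill_formula(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        parts = []
        for element in ("C", "H"):
            n = self._counts.get(element, 0)
            if n:
                parts.append(element + (str(n) if n > 1 else ""))
        for element, n in self._counts.items():
            if element in ("C", "H"):
                continue
            parts.append(element + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementComposition({self.hill_formula()!r})"


def monoisotopic_mass(composition: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da: sum of count x most-abundant-isotope mass."""
    total = 0.0
    for element, n in composition.items():
        try:
            total += n * ATOMIC_MASSES[element]
        except KeyError:
            raise KeyError(f"no atomic mass for element symbol {element!r}") from None
    return total


CH2 = ElementComposition(C=1, H=2)
H2 = ElementComposition(H=2)
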