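"""Elemental formulas and nominal-mass isotope distribution arithmetic.

This module is the convolution engine behind everything downstream: a mass
isotopologue distribution (MID) is represented as a 1-D numpy vector
``m[0..k]`` of fractions over integer nominal mass shifts, and the natural
isotope pattern of a molecule is the discrete convolution of the per-atom
isotope distributions of its atoms.

Isotope abundances are bookkept by integer mass shift relative to the
lightest isotope, so 18O contributes at shift 2.  The shipped abundance
table uses IUPAC/CIAAW-style representative values and can be replaced
wholesale (e.g. with a zero-abundance table for testing, or a site-specific
calibration) -- every function that needs abundances accepts an
:class:`IsotopeTable`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SUPPORTED_ELEMENTS",
    "FormulaError",
    "ElementalFormula",
    "parse_formula",
    "IsotopeTable",
    "as_mid",
    "natural_mid",
    "convolve",
]

SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "P", "S")

#: Representative natural abundances, indexed by nominal mass shift.
_DEFAULT_ISOTOPES: dict[str, tuple[tuple[int, float], ...]] = {
    "C": ((0, 0.9893), (1, 0.0107)),
    "H": ((0, 0.999885), (1, 0.000115)),
    "N": ((0, 0.99636), (1, 0.00364)),
    "O": ((0, 0.99757), (1, 0.00038), (2, 0.00205)),
    "P": ((0, 1.0),),
    "S": ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)),
}


class FormulaError(ValueError):
    """Malformed or unsupported elemental formula."""


@dataclass(frozen=True)
class ElementalFormula:
    """Atom counts of a molecule over the supported elements.

    Counts are strictly positive; an element that is absent simply has no
    entry.  Instances are immutable value objects.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        if not counts:
            raise FormulaError("formula must contain at least one atom")
        for element, n in counts.items():
            if element not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element {element!r}")
            if not isinstance(n, (int, np.integer)) or n < 1:
                raise FormulaError(f"count for {element!r} must be a positive integer, got {n!r}")
        object.__setattr__(self, "counts", counts)

    def get(self, element: str) -> int:
        return self.counts.get(element, 0)

    def items(self) -> Iterable[tuple[str, int]]:
        return self.counts.items()

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in sorted(self.counts.items()))


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C3H7NO3"``.

    An omitted count means one atom.  Repeated element tokens are summed.
    Raises :class:`FormulaError` for unsupported elements, explicit zero
    counts and any text that is not element-count tokens.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"malformed formula {text!r}: cannot parse {text[pos:]!r}")
        element, digits = m.group(1), m.group(2)
        if element not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unsupported element {element!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {element!r} in formula {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return ElementalFormula(counts)


class IsotopeTable:
    """Per-element isotope abundances over integer nominal mass shifts.

    Per element the abundances must sum to one (within 1e-12) and the
    shift-0 entry must be present and the most abundant.
    """

    def __init__(self, entries: Mapping[str, Sequence[tuple[int, float]]]):
        dense: dict[str, np.ndarray] = {}
        for element, pairs in entries.items():
            if element not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element {element!r} in isotope table")
            pairs = list(pairs)
            shifts = [int(s) for s, _ in pairs]
            abundances = [float(a) for _, a in pairs]
            if len(set(shifts)) != len(shifts):
                raise ValueError(f"duplicate mass shift for element {element!r}")
            if any(s < 0 for s in shifts):
                raise ValueError(f"negative mass shift for element {element!r}")
            if any(a < 0 for a in abundances):
                raise ValueError(f"negative abundance for element {element!r}")
            if abs(sum(abundances) - 1.0) > 1e-12:
                raise ValueError(f"abundances for {element!r} must sum to 1")
            if 0 not in shifts:
                raise ValueError(f"element {element!r} lacks a shift-0 isotope")
            vec = np.zeros(max(shifts) + 1)
            for s, a in zip(shifts, abundances):
                vec[s] = a
            if vec[0] < vec.max():
                raise ValueError(f"shift-0 isotope of {element!r} must be the most abundant")
            dense[element] = vec
        self._dense = dense

    def elements(self) -> tuple[str, ...]:
        return tuple(self._dense)

    def distribution(self, element: str) -> np.ndarray:
        """Dense per-atom shift distribution ``[a0, a1, ...]`` (a copy)."""
        if element not in self._dense:
            raise KeyError(f"no isotope data for element {element!r}")
        return self._dense[element].copy()

    @classmethod
    def default(cls) -> "IsotopeTable":
        return cls(_DEFAULT_ISOTOPES)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IsotopeTable":
        """Load from a plain CSV with columns element, mass_shift, abundance."""
        import pandas as pd

        df = pd.read_csv(path)
        required = {"element", "mass_shift", "abundance"}
        if not required.issubset(df.columns):
            raise ValueError(f"isotope CSV must have columns {sorted(required)}")
        entries: dict[str, list[tuple[int, float]]] = {}
        for row in df.itertuples(index=False):
            entries.setdefault(str(row.element), []).append((int(row.mass_shift), float(row.abundance)))
        return cls(entries)


def as_mid(values: Sequence[float] | np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Validate and return a MID as a float vector.

    A valid MID has length >= 1, finite nonnegative entries, and sums to
    one within ``tol``.
    """
    vec = np.asarray(values, dtype=float)
    if vec.ndim != 1 or vec.size < 1:
        raise ValueError("MID must be a non-empty 1-D vector")
    if not np.all(np.isfinite(vec)):
        raise ValueError("MID contains non-finite entries")
    if np.any(vec < -tol):
        raise ValueError("MID contains negative fractions")
    total = float(vec.sum())
    if abs(total - 1.0) > tol:
        raise ValueError(f"MID fractions sum to {total}, expected 1")
    return np.clip(vec, 0.0, None)


def _power(dist: np.ndarray, n: int) -> np.ndarray:
    """n-fold self-convolution by binary exponentiation."""
    result = np.array([1.0])
    base = dist
    while n:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def natural_mid(
    formula: ElementalFormula,
    max_shift: int,
    isotopes: IsotopeTable | None = None,
    exclude: tuple[str, int] | None = None,
) -> np.ndarray:
    """Natural-abundance MID of ``formula``, truncated at ``max_shift``.

    ``exclude=(element, k)`` removes ``k`` atoms of ``element`` from the
    convolution (used to leave tracer positions out of the natural
    background).  The result is NOT renormalized after truncation: mass
    beyond ``max_shift`` is dropped, so a truncated result sums to < 1.
    Excluding every atom yields the delta distribution ``[1.0]``.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    table = isotopes if isotopes is not None else IsotopeTable.default()
    counts = dict(formula.items())
    if exclude is not None:
        element, k = exclude
        if counts.get(element, 0) < k:
            raise ValueError(
                f"cannot exclude {k} atoms of {element!r}: formula has {counts.get(element, 0)}"
            )
        counts[element] -= k
        if counts[element] == 0:
            del counts[element]
    acc = np.array([1.0])
    for element in sorted(counts):
        acc = np.convolve(acc, _power(table.distribution(element), counts[element]))
    return acc[: max_shift + 1].copy()


def convolve(a: Sequence[float], b: Sequence[float]) -> np.ndarray:
    """Discrete convolution of two valid MIDs; total mass is preserved."""
    return np.convolve(as_mid(a), as_mid(b))
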