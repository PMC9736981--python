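"""Elemental-formula algebra for small-molecule mass spectrometry.

Formulas are immutable maps from element symbol to a non-negative integer
count. Masses are monoisotopic, summed from a fixed packaged constants table
so that every computed value is bit-stable across platforms. Ion m/z values
for singly (de)protonated species carry the one-electron mass correction:

    m/z([M-H]-) = M - m(H) + m(e)        m/z([M+H]+) = M + m(H) - m(e)

i.e. the mass of the ion *including* its electron imbalance. This is the
convention high-resolution instruments report and the one under which the
reference metabolite table packaged with this library reproduces to five
decimal places.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, Mapping, Tuple


class FormulaError(ValueError):
    """Malformed formula string or infeasible formula arithmetic."""


def _load_masses() -> Dict[str, float]:
    table = {}
    text = resources.files("biotransid.data").joinpath("atomic_masses.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, mass = line.split("\t")
        table[symbol] = float(mass)
    return table


_MASSES: Dict[str, float] = _load_masses()
ELECTRON_MASS: float = _MASSES.pop("e-")

#: Elements accepted by the parser. Extensible via :func:`register_element`.
SUPPORTED_ELEMENTS = frozenset(_MASSES)

_HILL_FIRST = ("C", "H")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def register_element(symbol: str, monoisotopic_mass: float) -> None:
    """Extend the supported element table (e.g. P, Cl) for custom libraries."""
    if not re.fullmatch(r"[A-Z][a-z]?", symbol):
        raise FormulaError(f"invalid element symbol {symbol!r}")
    _MASSES[symbol] = float(monoisotopic_mass)
    global SUPPORTED_ELEMENTS
    SUPPORTED_ELEMENTS = frozenset(_MASSES)


class ElementalFormula(Mapping[str, int]):
    """An immutable elemental composition.

    Supports ``+``, ``-`` (raising :class:`FormulaError` if any count would
    go negative) and ``*`` by a non-negative integer. ``str()`` renders Hill
    notation (C, H, then remaining elements alphabetically); parsing the
    rendered string round-trips to an equal formula.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | Iterable[Tuple[str, int]] = ()):
        clean: Dict[str, int] = {}
        for symbol, n in dict(counts).items():
            if symbol not in _MASSES:
                raise FormulaError(f"unsupported element {symbol!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for element {symbol!r}")
            if n:
                clean[symbol] = n
        self._counts = clean
        self._hash = hash(frozenset(clean.items()))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a formula string such as ``C20H18O4`` or ``H2O``.

        Element symbols may appear in any order and repeat (counts add);
        an omitted count means 1. Unknown symbols or stray characters raise
        :class:`FormulaError` naming the offending token.
        """
        text = text.strip()
        if not text:
            return cls()
        counts: Dict[str, int] = {}
        pos = 0
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(
                    f"malformed formula {text!r}: unexpected {text[pos:match.start()]!r}"
                )
            pos = match.end()
            symbol, digits = match.groups()
            if symbol not in _MASSES:
                raise FormulaError(f"unsupported element {symbol!r} in {text!r}")
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        if pos != len(text):
            raise FormulaError(f"malformed formula {text!r}: unexpected {text[pos:]!r}")
        return cls(counts)

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return self._counts.get(symbol, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, symbol) -> bool:
        return symbol in self._counts

    # -- algebra -----------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for symbol, n in other._counts.items():
            counts[symbol] = counts.get(symbol, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for symbol, n in other._counts.items():
            new = counts.get(symbol, 0) - n
            if new < 0:
                raise FormulaError(
                    f"cannot remove {other.hill()} from {self.hill()}: "
                    f"element {symbol} would go negative"
                )
            counts[symbol] = new
        return ElementalFormula(counts)

    def __mul__(self, n: int) -> "ElementalFormula":
        if n < 0:
            raise FormulaError("formula multiplier must be non-negative")
        return ElementalFormula({s: c * n for s, c in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        return isinstance(other, ElementalFormula) and self._counts == other._counts

    def __hash__(self) -> int:
        return self._hash

    def hill(self) -> str:
        """Hill-notation string: C first, H second, then alphabetical."""
        parts = []
        rest = sorted(s for s in self._counts if s not in _HILL_FIRST)
        order = [s for s in _HILL_FIRST if s in self._counts] + rest
        for symbol in order:
            n = self._counts[symbol]
            parts.append(symbol if n == 1 else f"{symbol}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"


def parse_formula(text: str) -> ElementalFormula:
    """Parse ``text`` into an :class:`ElementalFormula` (see :meth:`parse`)."""
    return ElementalFormula.parse(text)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da; additive over formula sums."""
    return sum(_MASSES[s] * n for s, n in formula.items())


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged (de)protonation adduct.

    ``proton_delta`` protons are added to the neutral molecule and the ion
    carries ``charge_sign`` elementary charge. Only [M-H]- and [M+H]+ are
    shipped; the name uniquely determines the other fields.
    """

    name: str
    proton_delta: int
    charge_sign: int

    def __post_init__(self):
        if abs(self.charge_sign) != 1 or self.proton_delta not in (-1, 1):
            raise ValueError("only singly protonated/deprotonated adducts supported")


_H = "H"

ADDUCTS: Dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", proton_delta=-1, charge_sign=-1),
    "[M+H]+": AdductSpec("[M+H]+", proton_delta=+1, charge_sign=+1),
}


def get_adduct(name: str) -> AdductSpec:
    """Look up an adduct by name; tolerates the typographic minus sign."""
    key = name.replace("−", "-").replace("–", "-")
    try:
        return ADDUCTS[key]
    except KeyError:
        raise KeyError(f"unknown adduct {name!r}; supported: {sorted(ADDUCTS)}") from None


def ion_mz(neutral: ElementalFormula, adduct: AdductSpec | str) -> float:
    """m/z of the singly charged ion formed from ``neutral`` by ``adduct``.

    Includes the electron-mass correction: one electron mass is added for
    anions and subtracted for cations.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if adduct.proton_delta < 0 and neutral[_H] < 1:
        raise FormulaError(f"cannot deprotonate {neutral.hill()}: no hydrogen")
    mass = monoisotopic_mass(neutral) + adduct.proton_delta * _MASSES[_H]
    return mass - adduct.charge_sign * ELECTRON_MASS


def ion_formula_mz(ion: ElementalFormula, charge_sign: int) -> float:
    """m/z of a singly charged ion given its *ion* formula (e.g. a fragment).

    The formula already includes or excludes the transferred proton; only the
    electron-mass correction is applied.
    """
    if abs(charge_sign) != 1:
        raise ValueError("only singly charged ions supported")
    return monoisotopic_mass(ion) - charge_sign * ELECTRON_MASS


def rdb(formula: ElementalFormula) -> float:
    """Ring-and-double-bond equivalents: C + 1 + N/2 - H/2.

    O and S contribute nothing. For even-electron ion formulas the value is
    half-integer (e.g. 12.5 for C20H17O4-).
    """
    return formula["C"] + 1 + formula["N"] / 2 - formula["H"] / 2


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, (observed - theoretical)/theoretical * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class CompositionFilter:
    """Elemental-composition and unsaturation constraints for candidates.

    ``element_ranges`` maps element symbol to an inclusive (min, max) count;
    elements absent from a formula count 0, and elements absent from the map
    are unconstrained. ``rdb_range`` bounds ring-and-double-bond equivalents,
    ``max_ppm`` the MS1 mass tolerance used downstream.
    """

    element_ranges: Mapping[str, Tuple[int, int]]
    rdb_range: Tuple[float, float] = (3.0, 20.0)
    max_ppm: float = 10.0

    def __post_init__(self):
        for symbol, (lo, hi) in self.element_ranges.items():
            if lo > hi:
                raise ValueError(f"min > max for element {symbol}")
        if self.rdb_range[0] > self.rdb_range[1]:
            raise ValueError("min > max for RDB range")
        if self.max_ppm <= 0:
            raise ValueError("max_ppm must be positive")


def default_composition_filter(max_ppm: float = 10.0) -> CompositionFilter:
    """The search-space constraints used for metabolite prediction:
    C 5-40, H 5-60, O 2-20, S 0-2, N 0-3, RDB 3-20, 10 ppm."""
    return CompositionFilter(
        element_ranges={"C": (5, 40), "H": (5, 60), "O": (2, 20), "S": (0, 2), "N": (0, 3)},
        rdb_range=(3.0, 20.0),
        max_ppm=max_ppm,
    )


def passes_composition_filter(formula: ElementalFormula, comp: CompositionFilter) -> bool:
    """True iff every constrained element count and the RDB lie in range."""
    for symbol, (lo, hi) in comp.element_ranges.items():
        if not lo <= formula[symbol] <= hi:
            return False
    return comp.rdb_range[0] <= rdb(formula) <= comp.rdb_range[1]
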