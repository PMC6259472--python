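"""Element and isotope data, chemical formulas, and exact-mass arithmetic.

This module is the foundation of all mass calculations in the package:
a pinned isotope table (masses and natural abundances for H, D, C, N, O,
P), a :class:`ChemicalFormula` value type, a minimal formula parser, and
the exact/nominal mass and ppm-error operations used to design and
validate MRM transitions.

Deuterium is handled as its own element symbol ``D`` with a single
isotope at abundance 1.0: it is a *label* atom introduced by the tracer
and never participates in natural-abundance statistics.

Masses of cations follow the neutral-atom convention: the electron mass
is not subtracted, so the exact m/z of ``C5H9+`` is the plain sum of
atomic masses (69.0704 at 4 d.p.).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "Isotope",
    "IsotopeTable",
    "ChemicalFormula",
    "FormulaError",
    "load_isotope_table",
    "default_isotope_table",
    "parse_formula",
    "exact_mass",
    "nominal_mass",
    "ppm_error",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


@dataclass(frozen=True)
class Isotope:
    """A single isotope: exact mass in Da and natural abundance fraction."""

    mass: float
    abundance: float


class IsotopeTable:
    """Per-element isotope data.

    Maps an element symbol to its isotopes, ordered by increasing mass.
    The first (lightest) isotope of each element is the *principal*
    isotope used for monoisotopic mass; its integer mass number is used
    for nominal mass.

    Invariants enforced at construction: abundances of each element sum
    to 1 within 1e-9; masses strictly increase within an element; the
    label symbol ``D`` has exactly one isotope.
    """

    def __init__(self, isotopes: Mapping[str, list[Isotope]]):
        self._table: dict[str, tuple[Isotope, ...]] = {}
        for symbol, isos in isotopes.items():
            isos = sorted(isos, key=lambda i: i.mass)
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances for {symbol} sum to {total!r}, expected 1.0"
                )
            for a, b in zip(isos, isos[1:]):
                if not a.mass < b.mass:
                    raise ValueError(f"isotope masses for {symbol} not increasing")
            self._table[symbol] = tuple(isos)
        if "D" in self._table and len(self._table["D"]) != 1:
            raise ValueError("label symbol D must have exactly one isotope")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._table

    def __getitem__(self, symbol: str) -> tuple[Isotope, ...]:
        try:
            return self._table[symbol]
        except KeyError:
            raise FormulaError(f"unknown element symbol: {symbol!r}") from None

    def elements(self) -> Iterator[str]:
        return iter(self._table)

    def principal_mass(self, symbol: str) -> float:
        """Exact mass of the lightest isotope (the sole isotope for D)."""
        return self[symbol][0].mass

    def mass_number(self, symbol: str) -> int:
        """Integer mass number of the principal isotope (D counts as 2)."""
        return round(self[symbol][0].mass)

    def shift_distribution(self, symbol: str) -> list[tuple[int, float]]:
        """(mass-number shift vs principal, abundance) per isotope."""
        isos = self[symbol]
        base = round(isos[0].mass)
        return [(round(i.mass) - base, i.abundance) for i in isos]


def load_isotope_table(path) -> IsotopeTable:
    """Read an isotope table from a plain-text TSV file.

    Lines are ``element<TAB>mass<TAB>abundance``; ``#`` starts a comment.
    """
    table: dict[str, list[Isotope]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            symbol, mass, abundance = line.split("\t")
            table.setdefault(symbol, []).append(
                Isotope(mass=float(mass), abundance=float(abundance))
            )
    return IsotopeTable(table)


_DEFAULT_TABLE: IsotopeTable | None = None


def default_isotope_table() -> IsotopeTable:
    """The pinned isotope table shipped with the package (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("cklabel.data").joinpath("isotopes.tsv")
        with resources.as_file(ref) as path:
            _DEFAULT_TABLE = load_isotope_table(path)
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class ChemicalFormula:
    """An elemental composition plus an integer charge.

    ``counts`` maps element symbols (including the label symbol ``D``)
    to non-negative atom counts. Only charges 0 and +1 occur in this
    domain (protonated quasi-molecular ions and fragment cations).
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self):
        clean = {s: int(n) for s, n in self.counts.items() if n != 0}
        if any(n < 0 for n in clean.values()):
            raise FormulaError(f"negative atom count in {self.counts!r}")
        if not clean:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    def __hash__(self) -> int:
        return hash((frozenset(self.counts.items()), self.charge))

    # -- arithmetic ---------------------------------------------------

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for s, n in other.counts.items():
            merged[s] = merged.get(s, 0) + n
        return ChemicalFormula(merged, self.charge + other.charge)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for s, n in other.counts.items():
            merged[s] = merged.get(s, 0) - n
            if merged[s] < 0:
                raise FormulaError(
                    f"cannot remove {other} from {self}: {s} count would go negative"
                )
        return ChemicalFormula(merged, self.charge - other.charge)

    def protonated(self) -> "ChemicalFormula":
        """The [M+H]+ quasi-molecular ion of a neutral molecule."""
        merged = dict(self.counts)
        merged["H"] = merged.get("H", 0) + 1
        return ChemicalFormula(merged, self.charge + 1)

    def contains(self, other: "ChemicalFormula") -> bool:
        return all(self.counts.get(s, 0) >= n for s, n in other.counts.items())

    @property
    def atom_count(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        # Hill-ish ordering: C, H, D, then remaining symbols alphabetically
        order = ["C", "H", "D"]
        symbols = [s for s in order if s in self.counts]
        symbols += sorted(s for s in self.counts if s not in order)
        parts = [
            f"{s}{self.counts[s]}" if self.counts[s] > 1 else s for s in symbols
        ]
        return "".join(parts) + ("+" if self.charge == 1 else "")


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\+)|(\s+)|(.)")


def parse_formula(text: str, table: IsotopeTable | None = None) -> ChemicalFormula:
    """Parse a formula string like ``"C5H9+"`` or ``"C5 H3 D6 +"``.

    Repeated symbols are aggregated; a trailing ``+`` sets charge +1.
    Deuterium is written only as the symbol ``D`` (no bracket isotope
    syntax). Unknown element symbols are rejected by name.
    """
    if table is None:
        table = default_isotope_table()
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    charge = 0
    for match in _TOKEN.finditer(text.strip()):
        symbol, digits, plus, space, bad = match.groups()
        if space:
            continue
        if bad:
            raise FormulaError(f"unexpected character {bad!r} in formula {text!r}")
        if plus:
            if charge:
                raise FormulaError(f"multiple charge signs in {text!r}")
            charge = 1
            continue
        if symbol not in table:
            raise FormulaError(f"unknown element symbol: {symbol!r}")
        if charge:
            raise FormulaError(f"atoms after charge sign in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if not counts:
        raise FormulaError(f"no atoms in formula {text!r}")
    return ChemicalFormula(counts, charge)


def exact_mass(f: ChemicalFormula, table: IsotopeTable | None = None) -> float:
    """Monoisotopic mass in Da: principal-isotope mass summed over atoms.

    No electron-mass correction is applied for charged species, so for a
    cation this value is directly the calculated m/z.
    """
    if table is None:
        table = default_isotope_table()
    return sum(n * table.principal_mass(s) for s, n in f.counts.items())


def nominal_mass(f: ChemicalFormula, table: IsotopeTable | None = None) -> int:
    """Integer nominal mass: sum of principal mass numbers (D counts as 2)."""
    if table is None:
        table = default_isotope_table()
    return sum(n * table.mass_number(s) for s, n in f.counts.items())


def ppm_error(experimental: float, calculated: float) -> float:
    """Signed relative mass error in parts per million.

    ``(experimental - calculated) / calculated * 1e6``; the fidelity
    measure used to confirm a fragment's elemental composition.
    """
    if calculated <= 0:
        raise ValueError(f"calculated m/z must be positive, got {calculated!r}")
    return (experimental - calculated) / calculated * 1e6
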