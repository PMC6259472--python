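"""Natural isotopologue abundance patterns by per-element convolution.

A unit-resolution triple quadrupole sees isotopologues aggregated by
integer mass-number shift (+0, +1, +2, ... vs the monoisotopic species),
so the pattern of a formula is the convolution over its atoms of each
atom's shift distribution: for carbon, shift 1 with probability 0.0107
(13C); for oxygen, shifts 1 and 2 (17O, 18O); and so on.

Deuterium label atoms have a fixed mass and contribute a delta at shift
zero here — the constant +1-per-label offset is applied by callers (the
MRM ladder itself encodes it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import ChemicalFormula, IsotopeTable, default_isotope_table

__all__ = ["IsotopePattern", "natural_pattern", "relative_to_monoisotopic"]


@dataclass(frozen=True)
class IsotopePattern:
    """Relative abundances of mass-shift classes M+0 ... M+k.

    ``shifts[j]`` is the raw probability that a molecule of ``formula``
    carries heavy natural isotopes summing to a mass-number shift of
    exactly +j. Raw probabilities over the retained window sum to <= 1
    (the remainder lies beyond the truncation order ``k``).
    """

    formula: ChemicalFormula
    shifts: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.shifts) - 1

    @property
    def retained(self) -> float:
        """Total probability mass inside the truncated window."""
        return float(sum(self.shifts))


def _single_atom_poly(table: IsotopeTable, symbol: str, k: int) -> np.ndarray:
    poly = np.zeros(k + 1)
    for shift, abundance in table.shift_distribution(symbol):
        if shift <= k:
            poly[shift] += abundance
    return poly


def natural_pattern(
    f: ChemicalFormula, k: int = 3, table: IsotopeTable | None = None
) -> IsotopePattern:
    """Natural isotopologue pattern of ``f`` truncated at shift ``k``.

    Exact polynomial convolution of per-atom shift distributions,
    truncated at +k Da. Deterministic; D atoms contribute no variance
    (their fixed shift is handled by the transition ladder, not here).
    """
    if k < 0:
        raise ValueError(f"truncation order must be >= 0, got {k}")
    if table is None:
        table = default_isotope_table()
    pattern = np.zeros(k + 1)
    pattern[0] = 1.0
    for symbol, n in f.counts.items():
        single = _single_atom_poly(table, symbol, k)
        # n-fold self-convolution by exponentiation-by-squaring,
        # truncated to the window at every step
        power = single
        remaining = n
        while remaining:
            if remaining & 1:
                pattern = np.convolve(pattern, power)[: k + 1]
            remaining >>= 1
            if remaining:
                power = np.convolve(power, power)[: k + 1]
    return IsotopePattern(formula=f, shifts=tuple(float(p) for p in pattern))


def relative_to_monoisotopic(p: IsotopePattern) -> np.ndarray:
    """Abundance vector r with r[j] = p_j / p_0 (so r[0] = 1).

    The convenient form for building the natural-abundance correction
    matrix: r[j] is the signal expected in channel I_j per unit of
    monoisotopic signal.
    """
    if p.shifts[0] <= 0:
        raise ValueError("monoisotopic abundance p_0 must be positive")
    return np.asarray(p.shifts) / p.shifts[0]
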