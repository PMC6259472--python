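"""Shared fixtures and the independent isotope-enumeration oracle."""

from __future__ import annotations

import itertools
import math

import pytest

from cklabel.elements import ChemicalFormula, default_isotope_table


def _compositions(n: int, parts: int):
    """All tuples of `parts` non-negative ints summing to n."""
    if parts == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, parts - 1):
            yield (first, *rest)


def enumerate_pattern(f: ChemicalFormula, k: int) -> list[float]:
    """Brute-force isotopologue pattern by exhaustive enumeration.

    Enumerates, for every element, all ways of distributing its atoms
    over its isotopes; sums multinomial probabilities by total
    mass-number shift. Independent of the convolution implementation:
    pure Python, math.comb, no truncation during accumulation.
    """
    table = default_isotope_table()
    per_element = []
    for symbol, n in f.counts.items():
        isos = table.shift_distribution(symbol)
        options = []
        for counts in _compositions(n, len(isos)):
            coeff = math.factorial(n)
            prob = 1.0
            shift = 0
            for c, (s, a) in zip(counts, isos):
                coeff //= math.factorial(c)
                prob *= a**c
                shift += c * s
            options.append((shift, coeff * prob))
        per_element.append(options)

    shifts = [0.0] * (k + 1)
    for combo in itertools.product(*per_element):
        total_shift = sum(s for s, _ in combo)
        if total_shift <= k:
            prob = math.prod(p for _, p in combo)
            shifts[total_shift] += prob
    return shifts


@pytest.fixture(scope="session")
def isotope_table():
    return default_isotope_table()
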