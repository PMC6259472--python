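"""Registry of isoprenoid cytokinins, propionylation, and MRM transition design.

The registry covers the 11 compounds of the labeling study: the
isopentenyl (iP), trans-zeatin (tZ), cis-zeatin (cZ) and dihydrozeatin
(DHZ) families as free bases, ribosides, and riboside-5'-monophosphates.
cis/trans zeatin isomers share formulas and transitions and are
distinguished only by identity (chromatography separates them upstream).

Propionylation acylates every free hydroxyl with a propionyl residue
(C3H4O, +56 nominal Da): three on a riboside's sugar, plus one on a
hydroxylated (zeatin-type) side chain. Nucleotides are never derivatized
directly — they are dephosphorylated to ribosides by alkaline
phosphatase before analysis.

The diagnostic MRM transitions monitor the protonated riboside as the
precursor and its protonated base fragment (retaining any side-chain
propionyl, losing the sugar and its propionyls) as the product; the
isotopomer ladder I0..I3 adds +j Da to both ions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .elements import ChemicalFormula, nominal_mass, parse_formula

__all__ = [
    "Form",
    "CompoundRecord",
    "Transition",
    "TransitionSet",
    "REGISTRY",
    "get_compound",
    "propionylate",
    "diagnostic_transitions",
    "sidechain_fragment",
    "RIBOSE_RESIDUE",
    "PHOSPHATE_RESIDUE",
    "PROPIONYL_RESIDUE",
]

# residues added by ribosylation, phosphorylation and propionylation
RIBOSE_RESIDUE = parse_formula("C5H8O4")    # ribose condensation, +132
PHOSPHATE_RESIDUE = parse_formula("HPO3")   # 5'-monophosphate, +80
PROPIONYL_RESIDUE = parse_formula("C3H4O")  # per acylated hydroxyl, +56


class Form(str, Enum):
    BASE = "base"
    RIBOSIDE = "riboside"
    NUCLEOTIDE = "riboside-5'-monophosphate"


@dataclass(frozen=True)
class CompoundRecord:
    """One cytokinin of the study panel, with derivatization bookkeeping.

    ``formula`` is the neutral molecule in its current derivatization
    state. ``ribose_hydroxyls``/``sidechain_hydroxyls`` count *free*
    hydroxyls still available to propionylation.
    """

    abbreviation: str
    name: str
    form: Form
    formula: ChemicalFormula
    ribose_hydroxyls: int
    sidechain_hydroxyls: int
    derivatized: bool = False

    @property
    def free_hydroxyls(self) -> int:
        return self.ribose_hydroxyls + self.sidechain_hydroxyls

    @property
    def iP_type(self) -> bool:
        """True for compounds with the unhydroxylated isopentenyl chain."""
        return self.abbreviation.startswith("iP")

    def __str__(self) -> str:
        return ("pro-" if self.derivatized else "") + self.abbreviation


def _family(base_abbrev, base_name, base_formula, sidechain_oh):
    """Build base / riboside / nucleotide records for one side-chain type."""
    base = CompoundRecord(
        abbreviation=base_abbrev,
        name=base_name,
        form=Form.BASE,
        formula=base_formula,
        ribose_hydroxyls=0,
        sidechain_hydroxyls=sidechain_oh,
    )
    riboside = CompoundRecord(
        abbreviation=base_abbrev + "R",
        name=base_name + " riboside",
        form=Form.RIBOSIDE,
        formula=base_formula + RIBOSE_RESIDUE,
        ribose_hydroxyls=3,
        sidechain_hydroxyls=sidechain_oh,
    )
    nucleotide = CompoundRecord(
        abbreviation=base_abbrev + "MP",
        name=base_name + " riboside-5'-monophosphate",
        form=Form.NUCLEOTIDE,
        formula=base_formula + RIBOSE_RESIDUE + PHOSPHATE_RESIDUE,
        ribose_hydroxyls=2,  # 5'-OH is esterified by the phosphate
        sidechain_hydroxyls=sidechain_oh,
    )
    return base, riboside, nucleotide


_IP = parse_formula("C10H13N5")     # isopentenyladenine
_ZEATIN = parse_formula("C10H13N5O")
_DHZ = parse_formula("C10H15N5O")

REGISTRY: dict[str, CompoundRecord] = {
    c.abbreviation: c
    for c in (
        *_family("iP", "isopentenyladenine", _IP, sidechain_oh=0),
        *_family("tZ", "trans-zeatin", _ZEATIN, sidechain_oh=1),
        *_family("cZ", "cis-zeatin", _ZEATIN, sidechain_oh=1),
        *_family("DHZ", "dihydrozeatin", _DHZ, sidechain_oh=1)[:2],
    )
}


def get_compound(abbreviation: str) -> CompoundRecord:
    """Look up a registry compound; accepts a ``pro-`` prefix for the
    propionylated form."""
    key = abbreviation
    derivatized = False
    if key.startswith("pro-"):
        key = key[4:]
        derivatized = True
    # tolerate the common bare "ZR" shorthand for trans-zeatin riboside
    aliases = {"Z": "tZ", "ZR": "tZR", "ZMP": "tZMP"}
    key = aliases.get(key, key)
    try:
        record = REGISTRY[key]
    except KeyError:
        raise KeyError(
            f"unknown compound {abbreviation!r}; registry: {sorted(REGISTRY)}"
        ) from None
    return propionylate(record) if derivatized else record


def propionylate(c: CompoundRecord) -> CompoundRecord:
    """Acylate every free hydroxyl with a propionyl residue (+56 each).

    Nucleotides are rejected: in the workflow they are dephosphorylated
    by alkaline phosphatase and measured as ribosides, never derivatized
    as monophosphates. Re-derivatizing an already-propionylated record
    is rejected too (there are no free hydroxyls left).
    """
    if c.form is Form.NUCLEOTIDE:
        raise ValueError(
            f"{c.abbreviation}: nucleotides are dephosphorylated (alkaline "
            "phosphatase) and measured as ribosides; derivatize the riboside"
        )
    if c.derivatized:
        raise ValueError(f"{c}: already propionylated")
    n = c.free_hydroxyls
    formula = c.formula
    for _ in range(n):
        formula = formula + PROPIONYL_RESIDUE
    return replace(
        c,
        formula=formula,
        derivatized=True,
        ribose_hydroxyls=0,
        sidechain_hydroxyls=0,
    )


@dataclass(frozen=True)
class Transition:
    """One precursor -> product m/z pair at unit resolution."""

    isotopomer: int  # j in I_j
    precursor: int
    product: int

    def __str__(self) -> str:
        return f"{self.precursor}-{self.product}"


@dataclass(frozen=True)
class TransitionSet:
    """The I0..I_jmax diagnostic ladder for one (derivatized) riboside.

    ``product_formula`` is the product-ion composition (base fragment
    including any retained side-chain propionyl, charge +1) used
    downstream for natural-abundance correction.
    """

    analyte: str
    derivatized: bool
    transitions: tuple[Transition, ...]
    precursor_formula: ChemicalFormula
    product_formula: ChemicalFormula

    def __iter__(self):
        return iter(self.transitions)

    def __len__(self):
        return len(self.transitions)

    def pairs(self) -> list[tuple[int, int]]:
        return [(t.precursor, t.product) for t in self.transitions]


def diagnostic_transitions(
    c: CompoundRecord, derivatized: bool = False, j_max: int = 3
) -> TransitionSet:
    """Build the I0..I_jmax MRM ladder for a riboside analyte.

    Precursor: [M+H]+ of the (propionylated) riboside. Product: the
    protonated base fragment after neutral loss of the (propionylated)
    ribose; a zeatin-type side-chain propionyl stays on the fragment.
    The ladder shifts both ions by +j per isotopomer channel.
    """
    if c.form is not Form.RIBOSIDE:
        raise ValueError(
            f"{c.abbreviation}: diagnostic transitions are defined for "
            "ribosides only (free bases and nucleotides are not monitored)"
        )
    if j_max < 0:
        raise ValueError(f"j_max must be >= 0, got {j_max}")
    analyte = propionylate(c) if derivatized and not c.derivatized else c
    precursor_ion = analyte.formula.protonated()

    # neutral loss: the sugar with its propionyls; the side-chain
    # propionyl (if any) is retained on the base fragment
    neutral_loss = RIBOSE_RESIDUE
    if analyte.derivatized:
        for _ in range(3):
            neutral_loss = neutral_loss + PROPIONYL_RESIDUE
    product_ion = precursor_ion - neutral_loss

    p0, q0 = nominal_mass(precursor_ion), nominal_mass(product_ion)
    ladder = tuple(
        Transition(isotopomer=j, precursor=p0 + j, product=q0 + j)
        for j in range(j_max + 1)
    )
    return TransitionSet(
        analyte=str(analyte),
        derivatized=analyte.derivatized,
        transitions=ladder,
        precursor_formula=precursor_ion,
        product_formula=product_ion,
    )


# the six terminal-methyl hydrogens of the isopentenyl chain carry the
# deuterons in the D6-labeled standard
_SIDECHAIN = parse_formula("C5H9+")
_SIDECHAIN_D6 = parse_formula("C5H3D6+")


def sidechain_fragment(
    c: CompoundRecord, labeled: bool = False
) -> tuple[ChemicalFormula, int] | None:
    """The isoprenoid side-chain fragment cation, if the family has one.

    iP-type compounds shed a C5H9+ cation (m/z 69; m/z 75 for the
    D6-labeled side chain). No analogous fragment is defined for the
    hydroxylated (zeatin/dihydrozeatin) side chains.
    """
    if not c.iP_type:
        return None
    fragment = _SIDECHAIN_D6 if labeled else _SIDECHAIN
    return fragment, nominal_mass(fragment)
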