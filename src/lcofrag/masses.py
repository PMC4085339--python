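"""Elemental compositions and the dual nominal/monoisotopic mass contract.

The printed m/z values in the era's LCO literature are *nominal* integer
masses (lightest-isotope integer masses: C=12, H=1, N=14, O=16, Na=23);
the monoisotopic [M+H]+ of a ~1.1 kDa LCO is roughly 0.6 Da above its
nominal value and would round the other way.  This module therefore keeps
both scales side by side on every ion: table reproduction uses nominal
arithmetic with exact integer equality, real-spectrum matching uses
monoisotopic masses with a Da tolerance.

Conventions: charge is always +1 (no multiply charged LCO species are
modelled) and the electron mass (~0.0005 Da) is neglected, far below every
tolerance in use, so the proton adduct is treated as a hydrogen atom.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidChemistryError
from .structures import AcylChain, LCOStructure

__all__ = [
    "ElementalComposition",
    "IonMZ",
    "composition_of",
    "acyl_composition",
    "nominal_mass",
    "monoisotopic_mass",
    "precursor_mz",
    "ADDUCTS",
]

NOMINAL_MASSES = {"C": 12, "H": 1, "N": 14, "O": 16, "Na": 23}
MONOISOTOPIC_MASSES = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
}
_ELEMENTS = ("C", "H", "N", "O", "Na")


@dataclass(frozen=True)
class ElementalComposition:
    """Non-negative integer atom counts over C, H, N, O, Na."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    Na: int = 0

    def __post_init__(self) -> None:
        for el in _ELEMENTS:
            if getattr(self, el) < 0:
                raise InvalidChemistryError(
                    f"negative atom count {el}={getattr(self, el)}"
                )

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in _ELEMENTS}
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) - getattr(other, el) for el in _ELEMENTS}
        )

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) * k for el in _ELEMENTS}
        )

    __rmul__ = __mul__

    @property
    def nominal(self) -> int:
        return sum(getattr(self, el) * NOMINAL_MASSES[el] for el in _ELEMENTS)

    @property
    def monoisotopic(self) -> float:
        return sum(getattr(self, el) * MONOISOTOPIC_MASSES[el] for el in _ELEMENTS)

    @property
    def formula(self) -> str:
        """Hill-ish formula string, e.g. ``C32H54N4O21``."""
        parts = []
        for el in _ELEMENTS:
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


# Building blocks of the residue arithmetic (all as neutral compositions):
GLCNAC_RESIDUE = ElementalComposition(C=8, H=13, N=1, O=5)  # dehydro, nominal 203
WATER = ElementalComposition(H=2, O=1)
# Swapping the residue-1 N-acetyl for the fatty N-acyl removes a ketene
# equivalent (C2H2O, nominal 42) before the acyl chain is added:
N_ACETYL_KETENE = ElementalComposition(C=2, H=2, O=1)
CARBAMOYL_DELTA = ElementalComposition(C=1, H=1, N=1, O=1)  # +CHNO, nominal 43
O_ACETYL_DELTA = ElementalComposition(C=2, H=2, O=1)  # ester acetyl, nominal 42
METHYL_DELTA = ElementalComposition(C=1, H=2)  # +CH2, nominal 14
ACETIC_ACID = ElementalComposition(C=2, H=4, O=2)  # the CID neutral loss, 60
ADDUCTS = {
    "H": ElementalComposition(H=1),
    "Na": ElementalComposition(Na=1),
}


@dataclass(frozen=True)
class IonMZ:
    """A singly charged adduct ion on both mass scales."""

    adduct: str
    mz_nominal: int
    mz_mono: float
    charge: int = 1


def acyl_composition(chain: AcylChain) -> ElementalComposition:
    """Composition of the acyl group Cc H(2c-2-2d) O(1+h) as attached to
    the amine (i.e. the RC(=O)- part contributed to the molecule)."""
    h = 2 * chain.carbons - 2 - 2 * chain.double_bonds
    if h < 0:
        raise InvalidChemistryError(
            f"acyl C{chain.carbons}:{chain.double_bonds} would need {h} hydrogens"
        )
    return ElementalComposition(C=chain.carbons, H=h, O=1 + chain.hydroxyls)


def backbone_composition(n_residues: int) -> ElementalComposition:
    """Neutral chito-oligosaccharide of ``n_residues`` GlcNAc units
    (n residues + one water for the reducing-end/terminal OH pair)."""
    return GLCNAC_RESIDUE * n_residues + WATER


def composition_of(s: LCOStructure) -> ElementalComposition:
    """Elemental composition of the neutral LCO molecule."""
    comp = backbone_composition(s.backbone_length)
    comp = comp - N_ACETYL_KETENE + acyl_composition(s.acyl)
    if s.substituents.carbamoyl:
        comp = comp + CARBAMOYL_DELTA
    if s.substituents.o_acetyl:
        comp = comp + O_ACETYL_DELTA
    if s.substituents.methyl:
        comp = comp + METHYL_DELTA
    return comp


def nominal_mass(c: ElementalComposition) -> int:
    return c.nominal


def monoisotopic_mass(c: ElementalComposition) -> float:
    return c.monoisotopic


def _check_adduct(adduct: str) -> ElementalComposition:
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise InvalidChemistryError(
            f"unsupported adduct {adduct!r} (supported: {sorted(ADDUCTS)})"
        ) from None


def ion_mz(neutral: ElementalComposition, adduct: str) -> IonMZ:
    """m/z of the singly charged [neutral + adduct]+ ion."""
    ad = _check_adduct(adduct)
    ion = neutral + ad
    return IonMZ(adduct=adduct, mz_nominal=ion.nominal, mz_mono=ion.monoisotopic)


def precursor_mz(s: LCOStructure, adduct: str) -> IonMZ:
    """[M+H]+ or [M+Na]+ precursor m/z of a structure."""
    return ion_mz(composition_of(s), adduct)
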