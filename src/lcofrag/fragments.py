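"""B-series fragment prediction and the de-O-acetylation transform.

Under CID, LCOs fragment predominantly by glycosidic-bond cleavage with
charge retention on the non-reducing-terminal portion: the B-ion series.
Bk spans the k residues counted from the non-reducing terminus, so B ions
carry the acyl chain and carbamoyl (residue 1) and, for k >= 2, the
O-acetyl (residue 2); the reducing-terminal residue — and hence a
reducing-terminal methyl — never appears in a B ion.  Sodiated precursors
yield sodiated fragments (adduct retention).

O-acetylated species additionally show companions 60 m/z units below the
precursor and below every acetyl-containing B ion, from elimination of the
acetyl group as neutral acetic acid (C2H4O2).  Note the two distinct
constants: the acetyl *substituent* adds 42 (C2H2O, removed as such by
mild base), while the CID neutral *loss* is 60 (the ester leaves with the
ring proton as acetic acid).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import AnalysisPreconditionError
from .masses import (
    ACETIC_ACID,
    CARBAMOYL_DELTA,
    GLCNAC_RESIDUE,
    N_ACETYL_KETENE,
    O_ACETYL_DELTA,
    IonMZ,
    _check_adduct,
    acyl_composition,
    composition_of,
    ion_mz,
    precursor_mz,
)
from .structures import LCOStructure

__all__ = [
    "FragmentIon",
    "PredictedIonSet",
    "b_ions",
    "acetic_acid_companions",
    "de_O_acetylate",
    "predict_spectrum",
]


@dataclass(frozen=True)
class FragmentIon:
    """One predicted product ion: Bk, optionally minus acetic acid."""

    index: int
    adduct: str
    mz_nominal: int
    mz_mono: float
    acetic_acid_loss: bool = False
    series: str = "B"

    @property
    def label(self) -> str:
        loss = "-60" if self.acetic_acid_loss else ""
        return f"{self.series}{self.index}{loss}"


@dataclass(frozen=True)
class PredictedIonSet:
    """Precursor plus B-series fragments (and any acetic-acid-loss
    companions) for one structure/adduct."""

    structure: LCOStructure
    adduct: str
    precursor: IonMZ
    fragments: tuple[FragmentIon, ...]
    precursor_loss: IonMZ | None = None

    def labeled_ions(self) -> list[tuple[str, int, float]]:
        """All ions as (label, nominal m/z, monoisotopic m/z), precursor first."""
        out = [(f"[M+{self.adduct}]+", self.precursor.mz_nominal, self.precursor.mz_mono)]
        if self.precursor_loss is not None:
            out.append(
                (
                    f"[M+{self.adduct}]+-60",
                    self.precursor_loss.mz_nominal,
                    self.precursor_loss.mz_mono,
                )
            )
        out.extend((f.label, f.mz_nominal, f.mz_mono) for f in self.fragments)
        return out

    def nominal_ion_map(self) -> dict[int, tuple[str, ...]]:
        """Deduplicated nominal m/z -> labels of every ion landing there."""
        acc: dict[int, list[str]] = {}
        for label, nominal, _ in self.labeled_ions():
            acc.setdefault(nominal, []).append(label)
        return {mz: tuple(labels) for mz, labels in sorted(acc.items())}

    def nominal_mzs(self) -> set[int]:
        return {nominal for _, nominal, _ in self.labeled_ions()}

    def product_ions(self) -> list[tuple[str, int, float]]:
        """Non-precursor ions only (what a CID product-ion spectrum shows)."""
        return [
            (label, nom, mono)
            for label, nom, mono in self.labeled_ions()
            if not label.startswith("[M+") or label.endswith("-60")
        ]


def _b_composition(s: LCOStructure, k: int):
    """Neutral-fragment composition behind the Bk oxocarbenium ion:
    k dehydro-residues, residue 1 N-acyl swap + Cb, residue 2 OAc."""
    comp = GLCNAC_RESIDUE * k - N_ACETYL_KETENE + acyl_composition(s.acyl)
    if s.substituents.carbamoyl:
        comp = comp + CARBAMOYL_DELTA
    if k >= 2 and s.substituents.o_acetyl:
        comp = comp + O_ACETYL_DELTA
    return comp


def b_ions(s: LCOStructure, adduct: str) -> list[FragmentIon]:
    """B1 .. B(n-1) for a backbone of n residues, with adduct retention."""
    _check_adduct(adduct)
    if s.backbone_length < 2:
        raise AnalysisPreconditionError("B ions need a backbone of >= 2 residues")
    out = []
    for k in range(1, s.backbone_length):
        mz = ion_mz(_b_composition(s, k), adduct)
        out.append(
            FragmentIon(
                index=k, adduct=adduct, mz_nominal=mz.mz_nominal, mz_mono=mz.mz_mono
            )
        )
    return out


def acetic_acid_companions(ions: PredictedIonSet) -> PredictedIonSet:
    """Add the -60 acetic-acid-loss companions for an O-acetylated species.

    Companions are generated for the precursor and for every Bk that
    contains the O-acetylated residue (k >= 2); a structure without OAc is
    returned unchanged.
    """
    if not ions.structure.substituents.o_acetyl:
        return ions
    loss_nom = ACETIC_ACID.nominal
    loss_mono = ACETIC_ACID.monoisotopic
    prec_loss = IonMZ(
        adduct=ions.adduct,
        mz_nominal=ions.precursor.mz_nominal - loss_nom,
        mz_mono=ions.precursor.mz_mono - loss_mono,
    )
    companions = [
        replace(
            f,
            acetic_acid_loss=True,
            mz_nominal=f.mz_nominal - loss_nom,
            mz_mono=f.mz_mono - loss_mono,
        )
        for f in ions.fragments
        if f.index >= 2 and not f.acetic_acid_loss
    ]
    fragments = tuple(
        sorted(
            list(ions.fragments) + companions,
            key=lambda f: (f.index, f.acetic_acid_loss),
        )
    )
    return replace(ions, precursor_loss=prec_loss, fragments=fragments)


def de_O_acetylate(s: LCOStructure) -> LCOStructure:
    """Mild-base ester cleavage: remove the O-acetyl group (-42 on every
    precursor and every OAc-containing fragment)."""
    if not s.substituents.o_acetyl:
        raise AnalysisPreconditionError(
            f"{s.nomenclature} carries no O-acetyl group to remove"
        )
    return s.without_o_acetyl()


def predict_spectrum(s: LCOStructure, adduct: str) -> PredictedIonSet:
    """Full predicted ion set: precursor, B series, and -60 companions."""
    base = PredictedIonSet(
        structure=s,
        adduct=adduct,
        precursor=precursor_mz(s, adduct),
        fragments=tuple(b_ions(s, adduct)),
    )
    return acetic_acid_companions(base)
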