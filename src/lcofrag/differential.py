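"""Acetylation differential and base-treatment consistency inference.

Two inference procedures operate on *assigned structures*, not raw peaks
(structure assignment is the evidence level at which the biology is
argued):

* wild-type vs mutant comparison: O-acetylated structures in sample A are
  paired with their de-O-acetylated counterparts in sample B; losing every
  acetyl while the deacetylated backbones persist is the signature of a
  knocked-out acetyltransferase;
* base-treatment verification: mild base cleaves ester links, so an
  O-acetylated LCO must shift its precursor and every OAc-containing B ion
  down by exactly 42 while B1 is conserved and the -60 acetic-acid-loss
  companions disappear.

Structures identical except for the adduct are collapsed before pairing:
the adduct is an ionization artifact, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import AnalysisPreconditionError
from .fragments import de_O_acetylate, predict_spectrum
from .structures import LCOStructure

__all__ = [
    "Verdict",
    "SpeciesSet",
    "DifferentialReport",
    "BaseTreatmentCheck",
    "pair_by_acetyl",
    "acetylation_verdict",
    "verify_base_treatment",
]


class Verdict(str, Enum):
    ACETYLATION_LOST = "ACETYLATION_LOST"
    NO_CHANGE = "NO_CHANGE"
    INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class SpeciesSet:
    """Accepted (structure, adduct) annotations for one sample."""

    sample_id: str
    species: frozenset[tuple[LCOStructure, str]]

    @classmethod
    def from_pairs(cls, sample_id, pairs) -> "SpeciesSet":
        return cls(sample_id=sample_id, species=frozenset(pairs))

    def structures(self) -> frozenset[LCOStructure]:
        """Adduct-collapsed chemical species."""
        return frozenset(s for s, _ in self.species)


@dataclass(frozen=True)
class DifferentialReport:
    sample_a: str
    sample_b: str
    acetylated_in_a: int
    acetylated_in_b: int
    oac_pairs: tuple[tuple[LCOStructure, LCOStructure], ...]
    unpaired_a: tuple[LCOStructure, ...]
    unpaired_b: tuple[LCOStructure, ...]
    verdict: Verdict

    def to_dict(self) -> dict:
        return {
            "sample_a": self.sample_a,
            "sample_b": self.sample_b,
            "acetylated_in_a": self.acetylated_in_a,
            "acetylated_in_b": self.acetylated_in_b,
            "oac_pairs": [
                [a.nomenclature, b.nomenclature] for a, b in self.oac_pairs
            ],
            "unpaired_a": [s.nomenclature for s in self.unpaired_a],
            "unpaired_b": [s.nomenclature for s in self.unpaired_b],
            "verdict": self.verdict.value,
        }


def _verdict(acetyl_a: int, acetyl_b: int, n_pairs: int, min_acetylated: int) -> Verdict:
    if min_acetylated < 1:
        raise AnalysisPreconditionError("min_acetylated must be >= 1")
    if acetyl_a == 0 and acetyl_b == 0:
        return Verdict.NO_CHANGE
    if acetyl_a >= min_acetylated and acetyl_b == 0:
        return Verdict.ACETYLATION_LOST
    if acetyl_a == acetyl_b and n_pairs == 0:
        return Verdict.NO_CHANGE
    return Verdict.INCONCLUSIVE


def pair_by_acetyl(
    a: SpeciesSet, b: SpeciesSet, min_acetylated: int = 1
) -> DifferentialReport:
    """Pair O-acetylated structures in A with their exact de-O-acetylated
    counterparts in B and count acetylated species on both sides.

    Counting is at the distinct-structure level (adducts collapsed); each
    pair differs solely in the O-acetyl flag.  A pair records a *lost*
    acetylation: the acetylated form is absent from B while its
    deacetylated backbone persists there — an acetylated structure still
    present in B is not a loss.
    """
    structs_a = a.structures()
    structs_b = b.structures()
    oac_a = sorted(
        (s for s in structs_a if s.substituents.o_acetyl),
        key=lambda s: s.nomenclature,
    )
    oac_b = sorted(
        (s for s in structs_b if s.substituents.o_acetyl),
        key=lambda s: s.nomenclature,
    )
    pairs = tuple(
        (s, s.without_o_acetyl())
        for s in oac_a
        if s.without_o_acetyl() in structs_b and s not in structs_b
    )
    paired_a = {p[0] for p in pairs}
    return DifferentialReport(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        acetylated_in_a=len(oac_a),
        acetylated_in_b=len(oac_b),
        oac_pairs=pairs,
        unpaired_a=tuple(s for s in oac_a if s not in paired_a),
        unpaired_b=tuple(oac_b),
        verdict=_verdict(len(oac_a), len(oac_b), len(pairs), min_acetylated),
    )


def acetylation_verdict(r: DifferentialReport, min_acetylated: int = 1) -> Verdict:
    """Re-derive the verdict from a report's counts at a chosen evidence
    threshold (``min_acetylated`` acetylated species required in A)."""
    return _verdict(
        r.acetylated_in_a, r.acetylated_in_b, len(r.oac_pairs), min_acetylated
    )


@dataclass(frozen=True)
class BaseTreatmentCheck:
    structure: LCOStructure
    adduct: str
    before_ions: tuple[tuple[str, int, float], ...]
    after_ions: tuple[tuple[str, int, float], ...]
    precursor_shift: int
    b1_conserved: bool
    bk_shifts: tuple[tuple[int, int], ...]  # (k, nominal shift) for k >= 2
    losses_absent_after: bool
    consistent: bool
    observed_support: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.nomenclature,
            "adduct": self.adduct,
            "precursor_shift": self.precursor_shift,
            "b1_conserved": self.b1_conserved,
            "bk_shifts": list(self.bk_shifts),
            "losses_absent_after": self.losses_absent_after,
            "consistent": self.consistent,
            "observed_support": self.observed_support,
        }


def verify_base_treatment(
    s: LCOStructure,
    adduct: str,
    observed_before=None,
    observed_after=None,
    tolerance_da: float = 0.5,
) -> BaseTreatmentCheck:
    """Predict before/after base-treatment spectra for an O-acetylated
    structure and check the expected pattern: precursor −42, B1 conserved,
    every Bk (k >= 2) −42, no acetic-acid-loss companions after.

    When observed before/after peak lists (:class:`~.annotate.PeakList`)
    are supplied, the fraction of predicted ions supported by observed
    peaks (monoisotopic, within ``tolerance_da``) is recorded in
    ``observed_support``.
    """
    if not s.substituents.o_acetyl:
        raise AnalysisPreconditionError(
            f"{s.nomenclature} carries no O-acetyl group; nothing to verify"
        )
    after_s = de_O_acetylate(s)
    before = predict_spectrum(s, adduct)
    after = predict_spectrum(after_s, adduct)

    precursor_shift = after.precursor.mz_nominal - before.precursor.mz_nominal
    b_before = {f.index: f for f in before.fragments if not f.acetic_acid_loss}
    b_after = {f.index: f for f in after.fragments if not f.acetic_acid_loss}
    b1_conserved = b_before[1].mz_nominal == b_after[1].mz_nominal
    bk_shifts = tuple(
        (k, b_after[k].mz_nominal - b_before[k].mz_nominal)
        for k in sorted(b_before)
        if k >= 2
    )
    losses_absent_after = after.precursor_loss is None and not any(
        f.acetic_acid_loss for f in after.fragments
    )
    consistent = (
        precursor_shift == -42
        and b1_conserved
        and all(shift == -42 for _, shift in bk_shifts)
        and losses_absent_after
    )

    support: dict = {}
    for tag, ions, peaks in (
        ("before", before, observed_before),
        ("after", after, observed_after),
    ):
        if peaks is None:
            continue
        predicted = ions.labeled_ions()
        hit = sum(
            1
            for _, _, mono in predicted
            if any(abs(mz - mono) <= tolerance_da for mz, _ in peaks.peaks)
        )
        support[tag] = {"matched": hit, "predicted": len(predicted)}

    return BaseTreatmentCheck(
        structure=s,
        adduct=adduct,
        before_ions=tuple(before.labeled_ions()),
        after_ions=tuple(after.labeled_ions()),
        precursor_shift=precursor_shift,
        b1_conserved=b1_conserved,
        bk_shifts=bk_shifts,
        losses_absent_after=losses_absent_after,
        consistent=consistent,
        observed_support=support,
    )
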