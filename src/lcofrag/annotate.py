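"""Match observed precursor + CID peak lists against enumerated candidates.

Scoring counts predicted product ions (B ions and acetic-acid-loss
companions) that are matched by at least one observed peak; intensities
are carried through for reporting but never scored — assignments here, as
in manual LCO interpretation, argue from ion presence, not abundance.
Isobaric candidates (e.g. a protonated C20:3 species vs a sodiated C18:0
species at the same nominal precursor, which predict identical nominal
fragment series) are co-ranked and flagged, never tie-broken arbitrarily:
the chromatographic/biological context that resolves them is outside the
peak list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AnalysisPreconditionError, PeakListError
from .fragments import predict_spectrum
from .masses import precursor_mz
from .structures import LCOStructure, SearchSpace, enumerate_structures

__all__ = [
    "PeakList",
    "MatchParams",
    "CandidateAnnotation",
    "AnnotationResult",
    "annotate_precursor",
    "score_candidate",
    "annotate_spectrum",
]


@dataclass(frozen=True)
class PeakList:
    """Observed (m/z, intensity) pairs plus sample metadata; peaks are
    sorted ascending by m/z on construction."""

    peaks: tuple[tuple[float, float], ...]
    precursor_mz: float | None = None
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mz, intensity in self.peaks:
            if mz <= 0:
                raise PeakListError(f"non-positive m/z {mz}")
            if intensity < 0:
                raise PeakListError(f"negative intensity {intensity} at m/z {mz}")
        object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(mz for mz, _ in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class MatchParams:
    """Matching policy.

    ``tolerance_da`` is the monoisotopic window (default 0.5 Da,
    appropriate for unit-resolution instruments); ``nominal_mode`` switches
    to exact integer matching on nominal masses for reproducing printed
    tables.  ``min_fragment_matches`` defaults to 0 so precursor-only
    annotation is possible for sparse spectra.
    """

    tolerance_da: float = 0.5
    nominal_mode: bool = False
    adducts: tuple[str, ...] = ("H", "Na")
    min_fragment_matches: int = 0

    def __post_init__(self) -> None:
        if self.tolerance_da <= 0:
            raise ValueError("tolerance_da must be positive")
        if not self.adducts:
            raise ValueError("adducts must be non-empty")


@dataclass(frozen=True)
class CandidateAnnotation:
    structure: LCOStructure
    adduct: str
    matched_fragments: int
    predicted_fragments: int
    matched_losses: int
    score: int
    matched_peak_map: tuple[tuple[float, str], ...]


@dataclass(frozen=True)
class AnnotationResult:
    precursor_mz: float
    candidates: tuple[CandidateAnnotation, ...]
    ambiguity_flag: bool
    unmatched_peaks: tuple[tuple[float, float], ...]

    @property
    def top_candidates(self) -> tuple[CandidateAnnotation, ...]:
        """All candidates sharing the best score (the co-ranked set)."""
        if not self.candidates:
            return ()
        best = self.candidates[0].score
        return tuple(c for c in self.candidates if c.score == best)

    @property
    def accepted_species(self) -> tuple[CandidateAnnotation, ...]:
        """Co-ranked top candidates restricted to the fewest substituents.

        The isobar pairs that are genuinely indistinguishable (identical
        predicted ion series) carry the same substituent profile and are
        all retained; a more-decorated candidate that merely ties a
        plainer one on matched-ion count is dropped by parsimony.  This is
        the acceptance rule for downstream presence/absence inference
        (e.g. the acetylation differential).
        """
        top = self.top_candidates
        if not top:
            return ()
        fewest = min(c.structure.substituents.count for c in top)
        return tuple(c for c in top if c.structure.substituents.count == fewest)


def _matches(observed: float, predicted_nominal: int, predicted_mono: float,
             params: MatchParams) -> bool:
    if params.nominal_mode:
        return round(observed) == predicted_nominal
    return abs(observed - predicted_mono) <= params.tolerance_da


def annotate_precursor(
    mz: float, space: SearchSpace, params: MatchParams
) -> list[tuple[LCOStructure, str]]:
    """All (structure, adduct) pairs in the space whose precursor matches
    ``mz``; deterministic enumeration order, H before Na."""
    if mz <= 0:
        raise PeakListError(f"precursor m/z must be positive, got {mz}")
    out = []
    for s in enumerate_structures(space):
        for adduct in params.adducts:
            p = precursor_mz(s, adduct)
            if _matches(mz, p.mz_nominal, p.mz_mono, params):
                out.append((s, adduct))
    return out


def score_candidate(
    candidate: tuple[LCOStructure, str], peaks: PeakList, params: MatchParams
) -> CandidateAnnotation:
    """Count predicted product ions supported by the observed peaks.

    Each observed peak consumes at most one predicted ion — the nearest
    one within tolerance, ties resolved toward the lower predicted m/z —
    while a predicted ion may be confirmed by several peaks.  The score is
    the number of distinct predicted B/loss ions matched.
    """
    structure, adduct = candidate
    ions = predict_spectrum(structure, adduct)
    predicted = ions.product_ions()  # (label, nominal, mono), ascending index
    predicted = sorted(predicted, key=lambda t: t[1])
    matched_labels: set[str] = set()
    peak_map: list[tuple[float, str]] = []
    for obs_mz, _ in peaks.peaks:
        best: tuple[float, int, str] | None = None  # (distance, nominal, label)
        for label, nominal, mono in predicted:
            if not _matches(obs_mz, nominal, mono, params):
                continue
            ref = nominal if params.nominal_mode else mono
            key = (abs(obs_mz - ref), nominal, label)
            if best is None or key < best:
                best = key
        if best is not None:
            matched_labels.add(best[2])
            peak_map.append((obs_mz, best[2]))
    n_losses = sum(1 for lab in matched_labels if lab.endswith("-60"))
    score = len(matched_labels)
    return CandidateAnnotation(
        structure=structure,
        adduct=adduct,
        matched_fragments=score - n_losses,
        predicted_fragments=len(predicted),
        matched_losses=n_losses,
        score=score,
        matched_peak_map=tuple(peak_map),
    )


def annotate_spectrum(
    peaks: PeakList, space: SearchSpace, params: MatchParams
) -> AnnotationResult:
    """End-to-end assignment: precursor filter, fragment scoring, ranking.

    Candidates are ranked by (score desc, substituent count asc,
    nomenclature lexicographic); the ambiguity flag is set exactly when
    the top score is shared by two or more candidates.  Peaks matching no
    predicted ion of any co-ranked top candidate are reported unmatched.
    """
    if peaks.precursor_mz is None:
        raise AnalysisPreconditionError("peak list has no precursor m/z set")
    candidates = annotate_precursor(peaks.precursor_mz, space, params)
    annotations = [score_candidate(c, peaks, params) for c in candidates]
    annotations = [a for a in annotations if a.score >= params.min_fragment_matches]
    annotations.sort(
        key=lambda a: (-a.score, a.structure.substituents.count, a.structure.nomenclature)
    )
    ranked = tuple(annotations)
    ambiguous = len(ranked) >= 2 and ranked[0].score == ranked[1].score

    top = [a for a in ranked if ranked and a.score == ranked[0].score]
    explained: set[float] = set()
    for a in top:
        explained.update(mz for mz, _ in a.matched_peak_map)
    unmatched = tuple(p for p in peaks.peaks if p[0] not in explained)
    return AnnotationResult(
        precursor_mz=peaks.precursor_mz,
        candidates=ranked,
        ambiguity_flag=ambiguous,
        unmatched_peaks=unmatched,
    )
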