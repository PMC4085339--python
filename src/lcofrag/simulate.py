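"""Synthetic CID peak-list generator and parameter-recovery benchmark.

Emulates the spectra the annotator is built for: singly charged [M+H]+ or
[M+Na]+ LCO species whose product-ion spectra show B1-B3 ions, optional
-60 acetic-acid-loss companions, Gaussian m/z jitter, uniform decoy peaks,
and an optional arithmetic polymer ladder mimicking the strongly
UV-absorbing polymeric contaminant that co-elutes in real extracts.  The
generator does not model isotope envelopes, co-elution (peak-list merging
is available but off by default) or detector effects.

Everything is driven by one integer seed; a fixed seed reproduces peak
lists bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import AnnotationResult, MatchParams, PeakList, annotate_spectrum
from .errors import AnalysisPreconditionError
from .fragments import de_O_acetylate, predict_spectrum
from .structures import LCOStructure, SearchSpace, enumerate_structures

__all__ = [
    "SimConfig",
    "SyntheticExperiment",
    "generate_peaklist",
    "generate_experiment",
    "recovery_rate",
    "recovery_benchmark",
]


def _default_truth() -> tuple[LCOStructure, ...]:
    """Distinct wild-type structures from the published summary table."""
    from .published import WILD_TYPE, distinct_structures

    return tuple(distinct_structures(WILD_TYPE))


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    Defaults mirror the real acquisition regime: unit-resolution m/z
    jitter of 0.05 Da (1 sigma), 20 decoy peaks per spectrum over the
    fragment m/z range, sodiation more likely than protonation (the
    published species are predominantly [M+Na]+), log-normal intensities.
    """

    truth_structures: tuple[LCOStructure, ...] | None = None
    adduct_probs: tuple[tuple[str, float], ...] = (("H", 0.3), ("Na", 0.7))
    mz_jitter_sd: float = 0.05
    n_decoys: int = 20
    decoy_mz_range: tuple[float, float] = (400.0, 1250.0)
    polymer_ladder: tuple[float, float, int] | None = None  # (start, repeat, count)
    intensity_lognormal: tuple[float, float] = (8.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.adduct_probs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"adduct probabilities must sum to 1, got {total}")
        if self.mz_jitter_sd < 0:
            raise ValueError("mz_jitter_sd must be >= 0")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        lo, hi = self.decoy_mz_range
        if not lo < hi:
            raise ValueError("decoy_mz_range must be (low, high) with low < high")

    def resolve_truth(self) -> tuple[LCOStructure, ...]:
        return self.truth_structures if self.truth_structures else _default_truth()


@dataclass(frozen=True)
class SyntheticExperiment:
    wild_type: tuple[PeakList, ...]
    mutant: tuple[PeakList, ...]
    truth_wild_type: tuple[tuple[LCOStructure, str], ...]
    truth_mutant: tuple[tuple[LCOStructure, str], ...]


def _sample_adduct(cfg: SimConfig, rng: np.random.Generator) -> str:
    names = [a for a, _ in cfg.adduct_probs]
    probs = [p for _, p in cfg.adduct_probs]
    return str(rng.choice(names, p=probs))


def generate_peaklist(
    s: LCOStructure,
    adduct: str,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> PeakList:
    """One synthetic product-ion spectrum for a structure/adduct.

    Peaks sit at each predicted ion's monoisotopic m/z plus Gaussian
    jitter; decoys are uniform over ``decoy_mz_range``; the optional
    polymer ladder adds ``count`` peaks at ``start + k * repeat``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ions = predict_spectrum(s, adduct)
    mzs = [mono for _, _, mono in ions.labeled_ions()]
    mu, sigma = cfg.intensity_lognormal
    peaks = [
        (mz + rng.normal(0.0, cfg.mz_jitter_sd) if cfg.mz_jitter_sd else mz,
         float(rng.lognormal(mu, sigma)))
        for mz in mzs
    ]
    lo, hi = cfg.decoy_mz_range
    for _ in range(cfg.n_decoys):
        peaks.append((float(rng.uniform(lo, hi)), float(rng.lognormal(mu, sigma))))
    if cfg.polymer_ladder is not None:
        start, repeat, count = cfg.polymer_ladder
        for k in range(count):
            peaks.append((start + k * repeat, float(rng.lognormal(mu, sigma))))
    return PeakList(
        peaks=tuple(peaks),
        precursor_mz=ions.precursor.mz_mono,
        sample_id=sample_id or s.nomenclature,
        metadata={"truth": s.nomenclature, "adduct": adduct},
    )


def generate_experiment(cfg: SimConfig) -> SyntheticExperiment:
    """Paired wild-type/mutant peak lists with ground truth.

    Mutant truth is the wild-type truth with every O-acetyl removed
    (non-acetylated structures carried over unchanged) — the chemistry of
    an acetyltransferase knockout.  Requires at least one O-acetylated
    truth structure, otherwise there is no differential to detect.
    """
    truth = cfg.resolve_truth()
    if not any(s.substituents.o_acetyl for s in truth):
        raise AnalysisPreconditionError(
            "truth structures contain no O-acetylated species"
        )
    rng = np.random.default_rng(cfg.seed)

    mutant_truth: list[LCOStructure] = []
    for s in truth:
        t = de_O_acetylate(s) if s.substituents.o_acetyl else s
        if t not in mutant_truth:
            mutant_truth.append(t)

    def _spectra(structures, tag):
        assigned = [(s, _sample_adduct(cfg, rng)) for s in structures]
        lists = tuple(
            generate_peaklist(s, a, cfg, rng=rng, sample_id=f"{tag}-{i:03d}")
            for i, (s, a) in enumerate(assigned)
        )
        return lists, tuple(assigned)

    wt_lists, wt_truth = _spectra(truth, "wt")
    mut_lists, mut_truth = _spectra(mutant_truth, "mut")
    return SyntheticExperiment(
        wild_type=wt_lists,
        mutant=mut_lists,
        truth_wild_type=wt_truth,
        truth_mutant=mut_truth,
    )


def recovery_rate(
    truth: list[tuple[LCOStructure, str]] | list[LCOStructure],
    results: list[AnnotationResult],
) -> float:
    """Fraction of spectra whose true structure is among the co-ranked top
    candidates of its annotation."""
    if len(truth) != len(results):
        raise ValueError(
            f"truth ({len(truth)}) and results ({len(results)}) lengths differ"
        )
    if not truth:
        return 0.0
    hits = 0
    for t, res in zip(truth, results):
        true_structure = t[0] if isinstance(t, tuple) else t
        top_structures = {c.structure for c in res.top_candidates}
        hits += true_structure in top_structures
    return hits / len(truth)


def recovery_benchmark(
    n_spectra: int = 200,
    cfg: SimConfig | None = None,
    space: SearchSpace | None = None,
    params: MatchParams | None = None,
) -> float:
    """Sample structures from the search space, simulate one spectrum
    each, annotate, and return the recovery rate."""
    cfg = cfg or SimConfig(seed=42)
    space = space or SearchSpace()
    params = params or MatchParams()
    rng = np.random.default_rng(cfg.seed)
    pool = enumerate_structures(space)
    truth: list[tuple[LCOStructure, str]] = []
    results: list[AnnotationResult] = []
    for i in range(n_spectra):
        s = pool[int(rng.integers(len(pool)))]
        adduct = _sample_adduct(cfg, rng)
        peaks = generate_peaklist(s, adduct, cfg, rng=rng, sample_id=f"bench-{i:03d}")
        truth.append((s, adduct))
        results.append(annotate_spectrum(peaks, space, params))
    return recovery_rate(truth, results)


def annotate_experiment(
    exp: SyntheticExperiment,
    space: SearchSpace | None = None,
    params: MatchParams | None = None,
):
    """Annotate every spectrum of a synthetic experiment and collect the
    accepted (parsimonious co-ranked top) species per group.

    Returns a pair of :class:`~.differential.SpeciesSet` ready for
    :func:`~.differential.pair_by_acetyl`.
    """
    from .differential import SpeciesSet

    space = space or SearchSpace()
    params = params or MatchParams()

    def _collect(lists, tag):
        accepted = []
        for pl in lists:
            res = annotate_spectrum(pl, space, params)
            accepted.extend((c.structure, c.adduct) for c in res.accepted_species)
        return SpeciesSet.from_pairs(tag, accepted)

    return _collect(exp.wild_type, "wt"), _collect(exp.mutant, "mut")


def merge_peaklists(lists: list[PeakList], sample_id: str = "merged") -> PeakList:
    """Simulated co-elution: merge several peak lists into one fraction
    (precursor of the first list is kept)."""
    peaks: list[tuple[float, float]] = []
    for pl in lists:
        peaks.extend(pl.peaks)
    return PeakList(
        peaks=tuple(peaks),
        precursor_mz=lists[0].precursor_mz if lists else None,
        sample_id=sample_id,
        metadata={"merged_from": [pl.sample_id for pl in lists]},
    )
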