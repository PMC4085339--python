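# Methods

## Structure space

An LCO is modelled as (backbone length, acyl chain, substituent flags).
Backbone lengths 3–5 are supported (Roman numerals III–V in the
nomenclature); every published *N. galegae* species is a tetramer.
Substituent positions are fixed constants of the model rather than
per-structure data: carbamoyl on the non-reducing-terminal residue,
O-acetyl on the residue adjacent to it (position 2 from the
non-reducing end), methyl on the reducing-terminal residue. No observed
structure requires an alternative placement, and B-ion arithmetic only
depends on which residue a substituent sits on, not where within the
residue. Whether the reducing-terminal methyl is O- or N-linked is not
resolved by mass spectrometry; it is treated as a mass-only +CH₂ on the
reducing residue, which is all any prediction here depends on.

The default search space is tetramers with even C16–C22 acyl chains,
0–4 double bonds, at most one extra hydroxyl, and all three decorations
allowed — 320 structures, which cover every published assignment of
both strains. Odd chain lengths are representable but excluded from the
default bounds (none occur in the published data).

## Mass arithmetic

Two scales are kept on every ion. Nominal masses use integer
lightest-isotope masses (C 12, H 1, N 14, O 16, Na 23) and reproduce
printed table values under exact integer equality; monoisotopic masses
use standard isotope masses (H 1.0078250319, N 14.0030740052,
O 15.9949146221, Na 22.98976928) for tolerance matching of real
spectra. The two scales must not be mixed: the monoisotopic [M+H]⁺ of
the 1162 species is 1162.59, which would *round* to 1163, so rounding
monoisotopic values can never reproduce the printed integers. Charge is
fixed at +1 (no multiply charged species are modelled) and the electron
mass (~0.0005 Da) is neglected, two orders of magnitude below the
tightest tolerance in use.

Two distinct constants govern the acetyl chemistry and are deliberately
kept apart: the O-acetyl substituent adds 42 (C₂H₂O; removed as such by
mild base), while the CID neutral loss is 60 (acetic acid C₂H₄O₂,
taking a ring proton with it).

## Fragment model

Only B-series ions are predicted. Every published product ion is
explained by B ions plus −60 acetic-acid losses, and the instrument
regime gives no reason to model Y/C/Z or cross-ring cleavages; they are
an explicit non-goal, as are internal fragments and multiple sequential
losses. Fragments retain the precursor's adduct (the sodiated 1118
species yields B1 at 491, not 469). Loss companions are only generated
for ions that contain the O-acetylated residue: the precursor and Bk
with k ≥ 2.

## Annotation

Candidates whose precursor matches the query (exact nominal integer, or
monoisotopic within `tolerance_da`) are scored by the count of
predicted product ions matched by at least one observed peak. Each
observed peak consumes at most one predicted ion (nearest within
tolerance, ties toward the lower predicted m/z); a predicted ion may be
confirmed by several peaks. Intensities are never scored. The default
tolerance of 0.5 Da reflects unit-resolution instruments and is a
package default, not a literature value.

Ranking is (score desc, substituent count asc, nomenclature
lexicographic); the ambiguity flag is set exactly when the top score is
shared. For downstream presence/absence inference the accepted set per
spectrum is the co-ranked top restricted to the minimal substituent
count (`AnnotationResult.accepted_species`): genuinely
indistinguishable isobar pairs carry identical substituent profiles and
are all retained, while a more-decorated candidate that merely ties a
plainer one (typically via a decoy peak) is dropped by parsimony. This
is the same Occam principle as the ranking tie-break, applied to the
accepted set; without it a single chance decoy match can inject a
spurious O-acetylated species into a mutant sample and wreck the
differential.

## Differential inference

The wild-type/mutant comparison operates on assigned structure sets,
not raw peaks, with adducts collapsed first (the adduct is an
ionization artifact, not chemistry). An `oac_pair` records a *lost*
acetylation: the acetylated structure is absent from the comparison
sample while its exact de-O-acetylated backbone persists there. The
verdict is ACETYLATION_LOST when at least `min_acetylated` (default 1)
acetylated structures occur in sample A and none in sample B;
NO_CHANGE when both sides agree (equal counts, no lost pairs, or no
acetylation anywhere); otherwise INCONCLUSIVE. Presence/absence only:
the published evidence is qualitative, without replicates or abundance
comparison, so no statistics are attempted.

Base-treatment verification is a model-level theorem checked
exhaustively: for every O-acetylated structure and both adducts, the
de-O-acetylation transform must shift the precursor and every Bk
(k ≥ 2) by exactly −42, conserve B1, and leave no loss companions.
Observed before/after peak lists, when given, are matched against the
predictions and reported as supporting-ion counts.

## Synthetic data

The generator emulates the structure of the real acquisitions: one
product-ion spectrum per (structure, adduct), peaks at each predicted
ion's monoisotopic m/z plus Gaussian jitter (default sd 0.05 Da),
log-normal intensities (μ 8, σ 1 in log-space, arbitrary units), decoy
peaks uniform over 400–1250 m/z (default 20 per spectrum), and an
optional arithmetic polymer ladder (default repeat 44 Da) standing in
for the strongly UV-absorbing polymeric contaminant seen in real
extracts — its purpose is to stress unmatched-peak handling, not to
model a known polymer. Adducts are sampled at H:Na = 0.3:0.7,
reflecting the predominance of sodiated species in the published
spectra. The default truth set is the distinct published wild-type
structures; the mutant truth is derived by de-O-acetylating every
acetylated truth structure. One integer seed drives all randomness and
fixes the output bit for bit.

What the generator does **not** emulate: isotope envelopes, chemical
noise structure, co-elution (a merge helper exists but is off by
default), chromatography, detector saturation, and calibration drift.
Passing recovery benchmarks therefore demonstrates the soundness of the
annotation logic under calibrated noise, not performance on raw
instrument data.

Benchmark sizes: recovery is measured on 200 simulated spectra drawn
from the 320-structure default space (seconds of runtime); the
end-to-end wild-type/mutant verdict uses the published-truth experiment
(~20 spectra). The differential verdict is robust across seeds at
default noise.

## Numerical and interface choices

* Exact integer equality for nominal matching; 1e-6 Da determinism for
  monoisotopic sums (plain compensated summation is unnecessary at five
  atoms species).
* Deduplication of predicted ion sets happens on nominal m/z with all
  contributing labels retained, so provenance survives collisions.
* Enumeration order is fully deterministic (backbone, carbons, double
  bonds, hydroxyls, substituent flags), making every downstream ranking
  reproducible.
* MGF (Mascot generic format subset) is the peak-list interchange
  dialect, read and written via pyteomics; the two-column TSV dialect
  carries an optional `# precursor=` header. mzML/mzXML are out of
  scope; MGF is the documented extension point.
* Known typographical quirks of the printed record (a missing B1 cell
  in one row; one running-text fragment value contradicting both the
  table and the 203-increment rule) are documented in
  `lcofrag.published` and excluded from cell-level comparison rather
  than silently corrected.

## Limitations

Stereochemistry, linkage positions within a residue (C-6 vs C-4
O-acetylation), sulfate/fucose decorations of other rhizobia, negative
ion mode, and quantitative abundance inference are all out of scope.
Isobaric assignments are surfaced, not resolved; resolving them needs
orthogonal evidence (chromatographic position, biological context) that
a peak list does not contain.
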