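# lcofrag

Mass-spectrometric structure assignment for lipochitin oligosaccharides
(LCOs, rhizobial Nod factors): candidate enumeration, precursor and
B-series fragment m/z prediction, peak-list annotation, and the
wild-type-vs-mutant O-acetylation differential.

## The problem

Rhizobia signal to their legume hosts with Nod factors — chitin
oligomers of three to five β-1,4-linked GlcNAc residues whose
non-reducing-terminal residue carries a fatty N-acyl chain in place of
its N-acetyl group, decorated with small substituents (carbamoyl,
O-acetyl, methyl) that govern host specificity. Structures are read off
singly charged ESI/MALDI spectra: the [M+H]⁺ or [M+Na]⁺ precursor fixes
the composition, and CID product ions — dominated by glycosidic
cleavages with charge retention on the non-reducing end, the B series —
localize the acyl chain and the substituents along the backbone. This
package turns that manual interpretation into a reproducible pipeline,
aimed at analysts assigning LCO spectra and at anyone checking whether a
knocked-out transferase gene really removes its decoration.

## The model

All masses are computed on two scales. Nominal (integer,
lightest-isotope) arithmetic reproduces the printed literature values;
monoisotopic masses serve real-spectrum matching with a Da tolerance.
For a backbone of *n* residues with an acyl chain of *c* carbons, *d*
double bonds and *h* extra hydroxyls:

* neutral M = chitin backbone C₈ₙH₁₃ₙ₊₂NₙO₅ₙ₊₁ − C₂H₂O (N-acetyl
  removed) + CcH₂c₋₂₋₂dO₁₊h (N-acyl) + CHNO per carbamoyl + C₂H₂O per
  O-acetyl + CH₂ per methyl;
* Bk (k = 1 … n−1) sums the k non-reducing residues (residue 1 carries
  acyl + Cb, residue 2 the OAc) plus the adduct (+1 H, +23 Na nominal) —
  sodiated precursors give sodiated fragments;
* consecutive B ions step by 203 (plain GlcNAc) or 245 (O-acetylated
  residue); O-acetylated species add −60 acetic-acid-loss companions for
  the precursor and every Bk with k ≥ 2;
* mild base removes the ester-bound acetyl: precursor and every
  OAc-containing fragment shift by exactly −42 while B1 is conserved.

Annotation scores each precursor-compatible candidate by the number of
predicted product ions matched by observed peaks; isobars (e.g. a
protonated C20:3 species vs a sodiated C18:0 species at the same
nominal precursor, with identical fragment series) are co-ranked and
flagged, never tie-broken arbitrarily.

## Worked example

```bash
lcofrag predict "IV(C20:3, Cb, OAc)" --adduct H
```

```text
nomenclature,adduct,ion_label,nominal_mz,mono_mz
"IV(C20:3, Cb, OAc)",H,[M+H]+,1162,1162.587
"IV(C20:3, Cb, OAc)",H,[M+H]+-60,1102,1102.5659
"IV(C20:3, Cb, OAc)",H,B1,493,493.3278
"IV(C20:3, Cb, OAc)",H,B2,738,738.4177
"IV(C20:3, Cb, OAc)",H,B2-60,678,678.3966
"IV(C20:3, Cb, OAc)",H,B3,941,941.4971
"IV(C20:3, Cb, OAc)",H,B3-60,881,881.4759
```

This is the tetrameric, carbamoylated, O-acetylated C20:3 Nod factor:
the protonated molecule at nominal m/z 1162, B ions at 493/738/941
(B1→B2 steps by 245 because residue 2 carries the acetyl, B2→B3 by
203), and acetic-acid-loss companions 60 units below the precursor, B2
and B3. Feeding those product ions back in,

```bash
lcofrag annotate spectrum.tsv --nominal     # precursor 1162 + 6 fragments
```

returns two co-ranked candidates — IV(C20:3, Cb, OAc) as [M+H]⁺ and
IV(C18:0, Cb, OAc) as [M+Na]⁺ — with the ambiguity flag set: the two
are genuinely indistinguishable from this spectrum alone.

Other subcommands: `annotate` (MGF/TSV peak lists → ranked JSON
assignments), `diff` (two accepted-species CSVs → acetylation
differential verdict), `simulate` (synthetic wild-type/mutant
experiment with ground truth), `tables` (re-derive the packaged
published summary tables; prints `"mismatches": []`).

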