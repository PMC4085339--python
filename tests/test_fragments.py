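"""B-ion series, acetic-acid-loss companions, de-O-acetylation."""

import pytest
from pyteomics import mass as pyt_mass

from lcofrag import (
    AnalysisPreconditionError,
    acetic_acid_companions,
    b_ions,
    de_O_acetylate,
    parse_nomenclature,
    predict_spectrum,
)


@pytest.mark.parametrize(
    "nomenclature, adduct, expected",
    [
        ("IV(C20:3, Cb, OAc)", "H", [493, 738, 941]),
        ("IV(C18:1, Cb)", "Na", [491, 694, 897]),
        # reducing-terminal methyl is invisible to the B series
        ("IV(C18:0, Cb, CH3)", "Na", [493, 696, 899]),
        ("IV(C18:0, Cb)", "Na", [493, 696, 899]),
    ],
)
def test_b_ion_nominal_series(nomenclature, adduct, expected):
    ions = b_ions(parse_nomenclature(nomenclature), adduct)
    assert [f.mz_nominal for f in ions] == expected
    assert [f.index for f in ions] == [1, 2, 3]


def test_b_increment_rules(default_structures):
    """Consecutive B ions step by 203 over plain GlcNAc, 245 when the
    residue entered carries the O-acetyl (residue 2)."""
    for s in default_structures:
        for adduct in ("H", "Na"):
            series = b_ions(s, adduct)
            for prev, cur in zip(series, series[1:]):
                step = cur.mz_nominal - prev.mz_nominal
                if cur.index == 2 and s.substituents.o_acetyl:
                    assert step == 245
                else:
                    assert step == 203


def test_precursor_minus_last_b_ion(default_structures):
    """Precursor − B(n−1) = reducing residue + water: 221 plain, 235
    methylated."""
    for s in default_structures:
        ions = predict_spectrum(s, "Na")
        last_b = max(
            (f for f in ions.fragments if not f.acetic_acid_loss),
            key=lambda f: f.index,
        )
        gap = ions.precursor.mz_nominal - last_b.mz_nominal
        assert gap == (235 if s.substituents.methyl else 221)


def test_acetic_acid_companions_added():
    s = parse_nomenclature("IV(C20:3, Cb, OAc)")
    ions = predict_spectrum(s, "H")
    assert ions.precursor_loss is not None
    assert ions.precursor_loss.mz_nominal == 1102
    losses = {f.label: f.mz_nominal for f in ions.fragments if f.acetic_acid_loss}
    assert losses == {"B2-60": 678, "B3-60": 881}
    # mono shift is acetic acid exactly
    by_label = {f.label: f for f in ions.fragments}
    assert by_label["B2"].mz_mono - by_label["B2-60"].mz_mono == pytest.approx(
        60.0211, abs=1e-3
    )


def test_no_companions_without_acetyl():
    s = parse_nomenclature("IV(C18:1, Cb)")
    ions = predict_spectrum(s, "Na")
    assert ions.precursor_loss is None
    assert not any(f.acetic_acid_loss for f in ions.fragments)
    base = acetic_acid_companions(ions)
    assert base == ions


def test_companions_trimer_k2_rule():
    s = parse_nomenclature("III(C18:0, OAc)")
    ions = predict_spectrum(s, "H")
    assert ions.precursor_loss is not None
    assert {f.label for f in ions.fragments if f.acetic_acid_loss} == {"B2-60"}


@pytest.mark.parametrize(
    "before, adduct, prec_before, prec_after",
    [
        ("IV(C20:3, Cb, OAc)", "H", 1162, 1120),
        ("IV(C20:1, Cb, OAc)", "Na", 1188, 1146),
    ],
)
def test_de_o_acetylate_shift(before, adduct, prec_before, prec_after):
    s = parse_nomenclature(before)
    t = de_O_acetylate(s)
    assert not t.substituents.o_acetyl
    assert predict_spectrum(s, adduct).precursor.mz_nominal == prec_before
    assert predict_spectrum(t, adduct).precursor.mz_nominal == prec_after


def test_de_o_acetylate_requires_acetyl():
    with pytest.raises(AnalysisPreconditionError):
        de_O_acetylate(parse_nomenclature("IV(C18:1, Cb)"))


@pytest.mark.parametrize(
    "nomenclature, adduct, expected_set",
    [
        ("IV(C20:3, Cb, OAc)", "H", {1162, 1102, 941, 881, 738, 678, 493}),
        ("IV(C16:0, Cb)", "Na", {1092, 465, 668, 871}),
    ],
)
def test_predict_spectrum_nominal_sets(nomenclature, adduct, expected_set):
    ions = predict_spectrum(parse_nomenclature(nomenclature), adduct)
    assert ions.nominal_mzs() == expected_set


def test_sodiated_set_is_protonated_set_shifted(default_structures):
    for s in default_structures[::11]:
        h = predict_spectrum(s, "H")
        na = predict_spectrum(s, "Na")
        assert sorted(na.nominal_mzs()) == [mz + 22 for mz in sorted(h.nominal_mzs())]


def test_fragments_against_atom_level_oracle(default_structures):
    """Each Bk ion mass recomputed from independently assembled atom
    dictionaries (monomers + condensation waters, via pyteomics)."""
    water = {"H": 2, "O": 1}
    monomer = {"C": 8, "H": 15, "N": 1, "O": 6}
    acetic = {"C": 2, "H": 4, "O": 2}
    carbamic = {"C": 1, "H": 3, "N": 1, "O": 2}
    adduct_atoms = {"H": {"H": 1}, "Na": {"Na": 1}}

    def add(total, part, k=1):
        for el, n in part.items():
            total[el] = total.get(el, 0) + k * n

    for s in default_structures[::13]:
        c, d, h = s.acyl.carbons, s.acyl.double_bonds, s.acyl.hydroxyls
        fatty_acid = {"C": c, "H": 2 * c - 2 * d, "O": 2 + h}
        for adduct in ("H", "Na"):
            for frag in b_ions(s, adduct):
                k = frag.index
                atoms: dict = {}
                add(atoms, monomer, k)
                add(atoms, water, -k)      # k-1 glycosidic + 1 oxocarbenium
                add(atoms, acetic, -1)
                add(atoms, water, +1)
                add(atoms, fatty_acid)
                add(atoms, water, -1)
                if s.substituents.carbamoyl:
                    add(atoms, carbamic)
                    add(atoms, water, -1)
                if k >= 2 and s.substituents.o_acetyl:
                    add(atoms, acetic)
                    add(atoms, water, -1)
                add(atoms, adduct_atoms[adduct])
                oracle = pyt_mass.calculate_mass(
                    composition=pyt_mass.Composition(atoms)
                )
                assert frag.mz_mono == pytest.approx(oracle, abs=1e-4), (
                    s.nomenclature, adduct, frag.label
                )


def test_nominal_ion_map_retains_provenance():
    ions = predict_spectrum(parse_nomenclature("IV(C20:3, Cb, OAc)"), "H")
    ion_map = ions.nominal_ion_map()
    assert ion_map[493] == ("B1",)
    assert ion_map[1102] == ("[M+H]+-60",)
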