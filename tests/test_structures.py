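"""Nomenclature parsing/formatting and candidate enumeration."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcofrag import (
    AcylChain,
    LCOStructure,
    NomenclatureError,
    SearchSpace,
    SearchSpaceError,
    SubstituentSet,
    enumerate_structures,
    format_nomenclature,
    parse_nomenclature,
)


@pytest.mark.parametrize(
    "text, backbone, carbons, db, oh, cb, oac, me",
    [
        ("IV(C20:3, Cb, OAc)", 4, 20, 3, 0, True, True, False),
        ("IV(C18:1-OH, Cb)", 4, 18, 1, 1, True, False, False),
        ("V(C18:0)", 5, 18, 0, 0, False, False, False),
        ("IV(C18:0, Cb, CH_3_)", 4, 18, 0, 0, True, False, True),  # printed variant
        ("  III ( C16 : 0 ,Cb )  ", 3, 16, 0, 0, True, False, False),
    ],
)
def test_parse_nomenclature(text, backbone, carbons, db, oh, cb, oac, me):
    s = parse_nomenclature(text)
    assert s.backbone_length == backbone
    assert (s.acyl.carbons, s.acyl.double_bonds, s.acyl.hydroxyls) == (carbons, db, oh)
    assert (s.substituents.carbamoyl, s.substituents.o_acetyl, s.substituents.methyl) \
        == (cb, oac, me)


@pytest.mark.parametrize(
    "bad",
    [
        "XI(C18:0)",          # unsupported Roman numeral
        "IV(C18:0, Xx)",      # unknown substituent token
        "IV(C18)",            # missing double-bond token
        "IV(C18:9)",          # impossible unsaturation
        "IV(C18:0, Cb, Cb)",  # duplicate token
        "not a structure",
    ],
)
def test_parse_errors(bad):
    with pytest.raises(NomenclatureError):
        parse_nomenclature(bad)


@pytest.mark.parametrize(
    "structure, expected",
    [
        (
            LCOStructure(4, AcylChain(20, 3), SubstituentSet(carbamoyl=True, o_acetyl=True)),
            "IV(C20:3, Cb, OAc)",
        ),
        (
            LCOStructure(4, AcylChain(18, 0), SubstituentSet(carbamoyl=True, methyl=True)),
            "IV(C18:0, Cb, CH3)",
        ),
        (LCOStructure(5, AcylChain(18, 0)), "V(C18:0)"),
    ],
)
def test_format_nomenclature(structure, expected):
    assert format_nomenclature(structure) == expected


def test_roundtrip_over_default_space(default_structures):
    for s in default_structures:
        assert parse_nomenclature(format_nomenclature(s)) == s


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    backbone=st.integers(3, 5),
    carbons=st.integers(4, 30),
    db=st.integers(0, 6),
    oh=st.integers(0, 1),
    cb=st.booleans(),
    oac=st.booleans(),
    me=st.booleans(),
)
def test_roundtrip_random_structures(backbone, carbons, db, oh, cb, oac, me):
    if db > (carbons - 2) // 2:
        db = (carbons - 2) // 2
    s = LCOStructure(backbone, AcylChain(carbons, db, oh), SubstituentSet(cb, oac, me))
    assert parse_nomenclature(format_nomenclature(s)) == s


def _brute_force_count(space: SearchSpace) -> int:
    """Independent nested-loop enumeration of the same bounds."""
    n = 0
    for _ in space.backbone_lengths:
        for c in space.acyl_carbons:
            for d in range(space.max_double_bonds + 1):
                if d > (c - 2) // 2:
                    continue
                for _ in range(space.max_hydroxyls + 1):
                    for _ in [False, True] if space.allow_carbamoyl else [False]:
                        for _ in [False, True] if space.allow_o_acetyl else [False]:
                            for _ in [False, True] if space.allow_methyl else [False]:
                                n += 1
    return n


@pytest.mark.parametrize(
    "space",
    [
        SearchSpace(backbone_lengths={4}, acyl_carbons={18}, max_double_bonds=1,
                    max_hydroxyls=0),
        SearchSpace(),
        SearchSpace(backbone_lengths={3, 4, 5}, acyl_carbons={16, 17, 18},
                    max_double_bonds=2, allow_methyl=False),
    ],
)
def test_enumeration_size_matches_brute_force(space):
    out = enumerate_structures(space)
    assert len(out) == _brute_force_count(space)
    assert len(set(out)) == len(out)  # no duplicates
    assert out == sorted(
        out,
        key=lambda s: (
            s.backbone_length, s.acyl.carbons, s.acyl.double_bonds,
            s.acyl.hydroxyls, s.substituents,
        ),
    )


def test_small_space_cardinality():
    # 1 backbone x 1 carbon count x 2 unsaturation levels x 1 hydroxyl
    # level x 2x2x2 substituent flags
    space = SearchSpace(backbone_lengths={4}, acyl_carbons={18},
                        max_double_bonds=1, max_hydroxyls=0)
    assert len(enumerate_structures(space)) == 16


def test_singleton_space():
    space = SearchSpace(
        backbone_lengths={4}, acyl_carbons={18}, max_double_bonds=0,
        max_hydroxyls=0, allow_carbamoyl=False, allow_o_acetyl=False,
        allow_methyl=False,
    )
    assert enumerate_structures(space) == [parse_nomenclature("IV(C18:0)")]


def test_default_space_covers_published_structures(default_structures):
    from lcofrag.published import TABLE2

    pool = set(default_structures)
    for row in TABLE2:
        assert row.structure in pool, row.assignment


def test_empty_space_rejected():
    with pytest.raises(SearchSpaceError):
        SearchSpace(backbone_lengths=frozenset(), acyl_carbons={18})


def test_invalid_chain_constraints():
    with pytest.raises(ValueError):
        AcylChain(carbons=1)
    with pytest.raises(ValueError):
        AcylChain(carbons=18, double_bonds=9)
    with pytest.raises(ValueError):
        AcylChain(carbons=18, hydroxyls=2)
    with pytest.raises(ValueError):
        LCOStructure(6, AcylChain(18, 0))
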