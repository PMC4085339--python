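"""Lipochitin oligosaccharide (LCO) structure model.

An LCO / Nod factor is a short beta-1,4-linked chitin backbone of GlcNAc
residues whose non-reducing-terminal residue carries an N-linked fatty acyl
chain in place of its N-acetyl group.  Decorations considered here are the
ones relevant to *Neorhizobium galegae* Nod factors:

* a carbamoyl group (Cb) on the non-reducing-terminal residue,
* an O-acetyl group (OAc) on the residue adjacent to the non-reducing
  terminus (position 2 counted from the non-reducing end),
* a methyl group (Me) on the reducing-terminal residue.

Structures are named with the field's Roman-numeral convention, e.g.
``IV(C20:3, Cb, OAc)``: a tetramer with a C20 acyl chain bearing three
double bonds, carbamoylated and O-acetylated.  ``-OH`` after the acyl token
marks one additional hydroxyl on the chain, e.g. ``IV(C18:1-OH, Cb)``.

Substituent positions are fixed constants of the model, not per-structure
data: no alternative positions are ever needed for this structure space.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

from .errors import NomenclatureError, SearchSpaceError

__all__ = [
    "AcylChain",
    "SubstituentSet",
    "LCOStructure",
    "SearchSpace",
    "parse_nomenclature",
    "format_nomenclature",
    "enumerate_structures",
]

ROMAN_TO_INT = {"III": 3, "IV": 4, "V": 5}
INT_TO_ROMAN = {v: k for k, v in ROMAN_TO_INT.items()}


@dataclass(frozen=True, order=True)
class AcylChain:
    """A saturated-or-unsaturated fatty N-acyl chain, C{carbons}:{double_bonds},
    optionally carrying one extra hydroxyl (the ``-OH`` suffix)."""

    carbons: int
    double_bonds: int = 0
    hydroxyls: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be non-negative")
        if self.double_bonds > (self.carbons - 2) // 2:
            raise ValueError(
                f"C{self.carbons} chain cannot carry {self.double_bonds} double bonds"
            )
        if self.hydroxyls not in (0, 1):
            raise ValueError("hydroxyls must be 0 or 1")

    @property
    def token(self) -> str:
        """Nomenclature token, e.g. ``C20:3`` or ``C18:1-OH``."""
        oh = "-OH" if self.hydroxyls else ""
        return f"C{self.carbons}:{self.double_bonds}{oh}"


@dataclass(frozen=True, order=True)
class SubstituentSet:
    """Presence flags for the three backbone decorations; positions are
    model constants (Cb: residue 1, OAc: residue 2, Me: reducing residue)."""

    carbamoyl: bool = False
    o_acetyl: bool = False
    methyl: bool = False

    @property
    def count(self) -> int:
        return int(self.carbamoyl) + int(self.o_acetyl) + int(self.methyl)


@dataclass(frozen=True, order=True)
class LCOStructure:
    """An LCO: backbone length (GlcNAc residues), one N-acyl chain on the
    non-reducing-terminal residue, and a substituent set."""

    backbone_length: int
    acyl: AcylChain
    substituents: SubstituentSet = field(default_factory=SubstituentSet)

    def __post_init__(self) -> None:
        if not 3 <= self.backbone_length <= 5:
            raise ValueError(
                f"backbone_length must be in [3, 5], got {self.backbone_length}"
            )

    @property
    def nomenclature(self) -> str:
        return format_nomenclature(self)

    def without_o_acetyl(self) -> "LCOStructure":
        """Same structure with the O-acetyl flag cleared (no precondition)."""
        return replace(self, substituents=replace(self.substituents, o_acetyl=False))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.nomenclature


@dataclass(frozen=True)
class SearchSpace:
    """Bounds of the candidate enumeration.

    Defaults cover every structure the wild-type and mutant strains
    produced: tetrameric backbone, even C16-C22 chains with up to four
    unsaturations and at most one hydroxyl, all three decorations allowed.
    """

    backbone_lengths: frozenset[int] = frozenset({4})
    acyl_carbons: frozenset[int] = frozenset({16, 18, 20, 22})
    max_double_bonds: int = 4
    max_hydroxyls: int = 1
    allow_carbamoyl: bool = True
    allow_o_acetyl: bool = True
    allow_methyl: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "backbone_lengths", frozenset(self.backbone_lengths))
        object.__setattr__(self, "acyl_carbons", frozenset(self.acyl_carbons))
        if not self.backbone_lengths or not self.acyl_carbons:
            raise SearchSpaceError("search space axes must be non-empty")
        if self.max_double_bonds < 0 or self.max_hydroxyls < 0:
            raise SearchSpaceError("max_double_bonds/max_hydroxyls must be >= 0")


_NOMENCLATURE_RE = re.compile(
    r"""^\s*(?P<roman>[IVXLC]+)\s*\(\s*
        C\s*(?P<carbons>\d+)\s*:\s*(?P<double_bonds>\d+)\s*(?P<oh>-\s*OH)?
        (?P<rest>(?:\s*,[^,()]*)*)\s*\)\s*$""",
    re.VERBOSE,
)


def parse_nomenclature(text: str) -> LCOStructure:
    """Parse a structure string such as ``"IV(C20:3, Cb, OAc)"``.

    Accepts arbitrary internal whitespace and the printed-table variant
    ``CH_3_`` for the methyl token.  Raises :class:`NomenclatureError`
    naming the offending token on malformed input.
    """
    m = _NOMENCLATURE_RE.match(text)
    if m is None:
        raise NomenclatureError(f"malformed nomenclature string: {text!r}")
    roman = m.group("roman")
    if roman not in ROMAN_TO_INT:
        raise NomenclatureError(
            f"unsupported Roman numeral {roman!r} (expected one of "
            f"{sorted(ROMAN_TO_INT)})"
        )
    try:
        acyl = AcylChain(
            carbons=int(m.group("carbons")),
            double_bonds=int(m.group("double_bonds")),
            hydroxyls=1 if m.group("oh") else 0,
        )
    except ValueError as exc:
        raise NomenclatureError(f"invalid acyl chain in {text!r}: {exc}") from exc

    flags = {"Cb": False, "OAc": False, "CH3": False}
    rest = m.group("rest") or ""
    for raw in rest.split(","):
        token = raw.strip().replace("_", "")
        if not token:
            continue
        if token not in flags:
            raise NomenclatureError(f"unknown substituent token {token!r} in {text!r}")
        if flags[token]:
            raise NomenclatureError(f"duplicate substituent token {token!r} in {text!r}")
        flags[token] = True

    return LCOStructure(
        backbone_length=ROMAN_TO_INT[roman],
        acyl=acyl,
        substituents=SubstituentSet(
            carbamoyl=flags["Cb"], o_acetyl=flags["OAc"], methyl=flags["CH3"]
        ),
    )


def format_nomenclature(s: LCOStructure) -> str:
    """Canonical string form: Roman numeral, acyl token, then Cb, OAc, CH3.

    ``parse_nomenclature(format_nomenclature(s)) == s`` for every valid
    structure.
    """
    tokens = [s.acyl.token]
    if s.substituents.carbamoyl:
        tokens.append("Cb")
    if s.substituents.o_acetyl:
        tokens.append("OAc")
    if s.substituents.methyl:
        tokens.append("CH3")
    return f"{INT_TO_ROMAN[s.backbone_length]}({', '.join(tokens)})"


def enumerate_structures(space: SearchSpace) -> list[LCOStructure]:
    """All structures within ``space``, in a deterministic sorted order
    (backbone, carbons, double bonds, hydroxyls, substituent flags) with no
    duplicates."""
    flag_axes = [
        (False, True) if allowed else (False,)
        for allowed in (
            space.allow_carbamoyl,
            space.allow_o_acetyl,
            space.allow_methyl,
        )
    ]
    out: list[LCOStructure] = []
    for n, c, d, h, cb, oac, me in itertools.product(
        sorted(space.backbone_lengths),
        sorted(space.acyl_carbons),
        range(space.max_double_bonds + 1),
        range(space.max_hydroxyls + 1),
        *flag_axes,
    ):
        if d > (c - 2) // 2:
            continue
        out.append(
            LCOStructure(
                backbone_length=n,
                acyl=AcylChain(carbons=c, double_bonds=d, hydroxyls=h),
                substituents=SubstituentSet(carbamoyl=cb, o_acetyl=oac, methyl=me),
            )
        )
    if not out:
        raise SearchSpaceError("search space is empty after chemistry filtering")
    return out
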