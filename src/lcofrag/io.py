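"""Peak-list I/O (MGF and TSV dialects), tabular serialization, config.

MGF is the interchange dialect for CID peak lists (``BEGIN IONS`` /
``END IONS`` blocks, ``PEPMASS`` as the precursor m/z, ``TITLE`` as the
sample id), read and written through :mod:`pyteomics.mgf`.  The TSV
dialect is two whitespace-separated numeric columns (m/z, intensity) with
an optional ``# precursor=<mz>`` header comment.  mzML/mzXML are out of
scope by design; MGF is the documented extension point.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .annotate import AnnotationResult, MatchParams, PeakList
from .errors import ConfigError, PeakListError
from .fragments import PredictedIonSet
from .simulate import SimConfig
from .structures import (
    LCOStructure,
    SearchSpace,
    format_nomenclature,
    parse_nomenclature,
)

__all__ = [
    "read_peaklist",
    "read_peaklists",
    "write_peaklist",
    "ion_table",
    "structure_table",
    "annotation_to_dict",
    "annotation_table",
    "RunConfig",
]


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix == ".mgf":
        return "mgf"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise PeakListError(f"cannot infer peak-list format from {path.name!r}")


def _read_mgf(path: Path) -> list[PeakList]:
    out: list[PeakList] = []
    try:
        with _mgf.read(str(path)) as reader:
            for spectrum in reader:
                params = spectrum.get("params", {})
                pepmass = params.get("pepmass")
                precursor = float(pepmass[0]) if pepmass else None
                peaks = tuple(
                    zip(
                        (float(x) for x in spectrum["m/z array"]),
                        (float(x) for x in spectrum["intensity array"]),
                    )
                )
                out.append(
                    PeakList(
                        peaks=peaks,
                        precursor_mz=precursor,
                        sample_id=str(params.get("title", path.stem)),
                    )
                )
    except PeakListError:
        raise
    except Exception as exc:
        raise PeakListError(f"malformed MGF file {path}: {exc}") from exc
    if not out:
        raise PeakListError(f"no spectra found in {path}")
    return out


def _read_tsv(path: Path) -> list[PeakList]:
    precursor: float | None = None
    peaks: list[tuple[float, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        text = line.strip()
        if not text:
            continue
        if text.startswith("#"):
            body = text.lstrip("#").strip()
            if body.lower().startswith("precursor"):
                try:
                    precursor = float(body.split("=", 1)[1])
                except (IndexError, ValueError) as exc:
                    raise PeakListError(
                        f"{path}:{lineno}: malformed precursor header {text!r}"
                    ) from exc
            continue
        fields = text.split()
        if len(fields) < 2:
            raise PeakListError(f"{path}:{lineno}: expected two columns, got {text!r}")
        try:
            mz, intensity = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise PeakListError(f"{path}:{lineno}: non-numeric value in {text!r}") from exc
        peaks.append((mz, intensity))
    if not peaks:
        raise PeakListError(f"no peaks found in {path}")
    return [PeakList(peaks=tuple(peaks), precursor_mz=precursor, sample_id=path.stem)]


def read_peaklists(path, fmt: str | None = None) -> list[PeakList]:
    """All peak lists in a file (an MGF may hold several blocks)."""
    path = Path(path)
    if not path.exists():
        raise PeakListError(f"no such file: {path}")
    kind = _detect_format(path, fmt)
    if kind == "mgf":
        return _read_mgf(path)
    if kind == "tsv":
        return _read_tsv(path)
    raise PeakListError(f"unsupported peak-list format {kind!r}")


def read_peaklist(path, fmt: str | None = None) -> PeakList:
    """The single peak list in a file (first block of a multi-block MGF)."""
    return read_peaklists(path, fmt)[0]


def write_peaklist(pl: PeakList, path, fmt: str | None = None) -> None:
    path = Path(path)
    kind = _detect_format(path, fmt)
    if kind == "mgf":
        spectrum = {
            "m/z array": np.array([mz for mz, _ in pl.peaks]),
            "intensity array": np.array([i for _, i in pl.peaks]),
            "params": {
                "title": pl.sample_id,
                **({"pepmass": pl.precursor_mz} if pl.precursor_mz else {}),
            },
        }
        with _io.StringIO() as buf:
            _mgf.write([spectrum], buf)
            path.write_text(buf.getvalue())
    elif kind == "tsv":
        lines = []
        if pl.precursor_mz is not None:
            lines.append(f"# precursor={pl.precursor_mz:.4f}")
        lines.extend(f"{mz:.4f}\t{intensity:.4f}" for mz, intensity in pl.peaks)
        path.write_text("\n".join(lines) + "\n")
    else:
        raise PeakListError(f"unsupported peak-list format {kind!r}")


def ion_table(ion_sets: list[PredictedIonSet]) -> pd.DataFrame:
    """Predicted ions as a flat table (nomenclature, adduct, ion_label,
    nominal_mz, mono_mz)."""
    rows = [
        {
            "nomenclature": ions.structure.nomenclature,
            "adduct": ions.adduct,
            "ion_label": label,
            "nominal_mz": nominal,
            "mono_mz": round(mono, 4),
        }
        for ions in ion_sets
        for label, nominal, mono in ions.labeled_ions()
    ]
    return pd.DataFrame(rows)


def structure_table(structures: list[LCOStructure]) -> pd.DataFrame:
    rows = [
        {
            "nomenclature": s.nomenclature,
            "backbone": s.backbone_length,
            "acyl_carbons": s.acyl.carbons,
            "double_bonds": s.acyl.double_bonds,
            "hydroxyls": s.acyl.hydroxyls,
            "cb": s.substituents.carbamoyl,
            "oac": s.substituents.o_acetyl,
            "me": s.substituents.methyl,
        }
        for s in structures
    ]
    return pd.DataFrame(rows)


def annotation_to_dict(result: AnnotationResult) -> dict:
    return {
        "precursor_mz": result.precursor_mz,
        "ambiguity_flag": result.ambiguity_flag,
        "candidates": [
            {
                "structure": c.structure.nomenclature,
                "adduct": c.adduct,
                "score": c.score,
                "matched_fragments": c.matched_fragments,
                "matched_losses": c.matched_losses,
                "predicted_fragments": c.predicted_fragments,
                "matched_peaks": [
                    {"mz": mz, "ion": label} for mz, label in c.matched_peak_map
                ],
            }
            for c in result.candidates
        ],
        "unmatched_peaks": [
            {"mz": mz, "intensity": i} for mz, i in result.unmatched_peaks
        ],
    }


def annotation_table(results: list[AnnotationResult]) -> pd.DataFrame:
    """Flat summary mirroring the published table layout: parent ion,
    molecular species, fragment ions, structure assignment (co-ranked top
    candidates only, one row each)."""
    rows = []
    for res in results:
        for c in res.top_candidates:
            rows.append(
                {
                    "parent_ion": res.precursor_mz,
                    "molecular_species": f"[M+{c.adduct}]+",
                    "fragment_ions": ", ".join(
                        str(mz) for mz, _ in c.matched_peak_map
                    ),
                    "structure_assignment": c.structure.nomenclature,
                    "ambiguous": res.ambiguity_flag,
                }
            )
    return pd.DataFrame(rows)


# --- run configuration -----------------------------------------------------

_CONFIG_SECTIONS = ("search_space", "match", "simulation", "verbosity")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for a CLI run; round-trips through YAML
    losslessly and rejects unknown keys."""

    space: SearchSpace = dataclasses.field(default_factory=SearchSpace)
    match: MatchParams = dataclasses.field(default_factory=MatchParams)
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        sim = dataclasses.asdict(self.sim)
        sim["truth_structures"] = (
            [format_nomenclature(s) for s in self.sim.truth_structures]
            if self.sim.truth_structures
            else None
        )
        sim["adduct_probs"] = [list(p) for p in self.sim.adduct_probs]
        sim["decoy_mz_range"] = list(self.sim.decoy_mz_range)
        sim["intensity_lognormal"] = list(self.sim.intensity_lognormal)
        sim["polymer_ladder"] = (
            list(self.sim.polymer_ladder) if self.sim.polymer_ladder else None
        )
        return {
            "search_space": {
                "backbone_lengths": sorted(self.space.backbone_lengths),
                "acyl_carbons": sorted(self.space.acyl_carbons),
                "max_double_bonds": self.space.max_double_bonds,
                "max_hydroxyls": self.space.max_hydroxyls,
                "allow_carbamoyl": self.space.allow_carbamoyl,
                "allow_o_acetyl": self.space.allow_o_acetyl,
                "allow_methyl": self.space.allow_methyl,
            },
            "match": {
                "tolerance_da": self.match.tolerance_da,
                "nominal_mode": self.match.nominal_mode,
                "adducts": list(self.match.adducts),
                "min_fragment_matches": self.match.min_fragment_matches,
            },
            "simulation": sim,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(data) - set(_CONFIG_SECTIONS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

        def _section(name: str, allowed: set[str]) -> dict:
            section = data.get(name, {}) or {}
            if not isinstance(section, dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            bad = set(section) - allowed
            if bad:
                raise ConfigError(f"unknown keys in {name!r}: {sorted(bad)}")
            return section

        ss = _section(
            "search_space",
            {
                "backbone_lengths", "acyl_carbons", "max_double_bonds",
                "max_hydroxyls", "allow_carbamoyl", "allow_o_acetyl",
                "allow_methyl",
            },
        )
        space = SearchSpace(
            backbone_lengths=frozenset(ss.get("backbone_lengths", (4,))),
            acyl_carbons=frozenset(ss.get("acyl_carbons", (16, 18, 20, 22))),
            max_double_bonds=ss.get("max_double_bonds", 4),
            max_hydroxyls=ss.get("max_hydroxyls", 1),
            allow_carbamoyl=ss.get("allow_carbamoyl", True),
            allow_o_acetyl=ss.get("allow_o_acetyl", True),
            allow_methyl=ss.get("allow_methyl", True),
        )
        mp = _section(
            "match",
            {"tolerance_da", "nominal_mode", "adducts", "min_fragment_matches"},
        )
        match = MatchParams(
            tolerance_da=mp.get("tolerance_da", 0.5),
            nominal_mode=mp.get("nominal_mode", False),
            adducts=tuple(mp.get("adducts", ("H", "Na"))),
            min_fragment_matches=mp.get("min_fragment_matches", 0),
        )
        sc = _section(
            "simulation",
            {
                "truth_structures", "adduct_probs", "mz_jitter_sd", "n_decoys",
                "decoy_mz_range", "polymer_ladder", "intensity_lognormal",
                "seed",
            },
        )
        truth = sc.get("truth_structures")
        sim = SimConfig(
            truth_structures=(
                tuple(parse_nomenclature(t) for t in truth) if truth else None
            ),
            adduct_probs=tuple(
                (a, float(p)) for a, p in sc.get("adduct_probs", (("H", 0.3), ("Na", 0.7)))
            ),
            mz_jitter_sd=sc.get("mz_jitter_sd", 0.05),
            n_decoys=sc.get("n_decoys", 20),
            decoy_mz_range=tuple(sc.get("decoy_mz_range", (400.0, 1250.0))),
            polymer_ladder=(
                tuple(sc["polymer_ladder"]) if sc.get("polymer_ladder") else None
            ),
            intensity_lognormal=tuple(sc.get("intensity_lognormal", (8.0, 1.0))),
            seed=sc.get("seed", 0),
        )
        verbosity = data.get("verbosity", "INFO")
        return cls(space=space, match=match, sim=sim, verbosity=verbosity)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        return cls.from_dict(data or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
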