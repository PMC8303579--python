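"""Domain model for an Accurate Mass Retention Time (AMRT) metabolite library.

An AMRT library pairs each authentic standard with its precursor species,
retention time on a given column chemistry, and a reference MS2 spectrum
acquired at the compound's optimal collision energy.  This module holds the
core record types, the standards-manifest filters (scan-range and duplicate
screening), NIST-style MSP import/export, and merging of per-column
sub-libraries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd

__all__ = [
    "PROTON_MASS",
    "SODIUM_MASS",
    "POSITIVE",
    "NEGATIVE",
    "DEFAULT_ADDUCTS",
    "Compound",
    "PrecursorSpecies",
    "FragmentationSpectrum",
    "AMRTRecord",
    "FilterReport",
    "MSPParseError",
    "default_precursor_mz",
    "default_species",
    "filter_library",
    "write_msp",
    "read_msp",
    "merge_amrt",
    "read_manifest",
    "write_manifest",
]

#: Mass of a proton in Da, the shift for protonation/deprotonation at z=1.
PROTON_MASS = 1.007276
#: Mass shift for sodium adduct formation ([M+Na]+), Da.
SODIUM_MASS = 22.989218

POSITIVE = "positive"
NEGATIVE = "negative"

#: Adduct label -> (polarity, neutral-mass shift in Da) for singly charged ions.
DEFAULT_ADDUCTS: Mapping[str, tuple[str, float]] = {
    "[M+H]+": (POSITIVE, +PROTON_MASS),
    "[M+Na]+": (POSITIVE, +SODIUM_MASS),
    "[M-H]-": (NEGATIVE, -PROTON_MASS),
}

_DEFAULT_ADDUCT_BY_POLARITY = {POSITIVE: "[M+H]+", NEGATIVE: "[M-H]-"}


@dataclass(frozen=True)
class Compound:
    """One standards-library entry.

    ``structure_key`` is an opaque identifier for the chemical structure
    (e.g. a structure hash or normalised name) used for duplicate detection;
    two manifest rows with equal keys are treated as the same substance.
    """

    id: str
    name: str
    formula: str
    neutral_mass: float
    well: str = ""
    structure_key: str = ""

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"neutral_mass must be > 0, got {self.neutral_mass}")
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if not self.structure_key:
            object.__setattr__(self, "structure_key", self.name)


@dataclass(frozen=True)
class PrecursorSpecies:
    """An ionised species of a compound: adduct, polarity, m/z and charge."""

    adduct: str
    polarity: str
    mz: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("precursor m/z must be > 0")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def default_precursor_mz(neutral_mass: float, polarity: str) -> float:
    """m/z of the default singly charged species: [M+H]+ or [M-H]-."""
    if polarity == POSITIVE:
        return neutral_mass + PROTON_MASS
    if polarity == NEGATIVE:
        return neutral_mass - PROTON_MASS
    raise ValueError(f"unknown polarity {polarity!r}")


def default_species(compound: Compound, polarity: str) -> PrecursorSpecies:
    """The protonated (positive) or deprotonated (negative) species at z=1."""
    return PrecursorSpecies(
        adduct=_DEFAULT_ADDUCT_BY_POLARITY[polarity],
        polarity=polarity,
        mz=default_precursor_mz(compound.neutral_mass, polarity),
    )


class FragmentationSpectrum:
    """A centroided MS2 peak list at one polarity and collision energy.

    Peaks are stored as parallel numpy arrays sorted ascending by m/z;
    intensities are non-negative and in arbitrary units.
    """

    __slots__ = ("precursor", "energy", "mz", "intensity")

    def __init__(
        self,
        precursor: PrecursorSpecies,
        energy: float,
        peaks: Union[Sequence[tuple[float, float]], tuple[np.ndarray, np.ndarray]],
    ) -> None:
        self.precursor = precursor
        self.energy = float(energy)
        if isinstance(peaks, tuple) and len(peaks) == 2 and isinstance(peaks[0], np.ndarray):
            mz = np.asarray(peaks[0], dtype=float)
            intensity = np.asarray(peaks[1], dtype=float)
        else:
            arr = np.asarray(list(peaks), dtype=float).reshape(-1, 2)
            mz, intensity = arr[:, 0], arr[:, 1]
        if mz.shape != intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(intensity < 0):
            raise ValueError("intensities must be >= 0")
        order = np.argsort(mz, kind="stable")
        self.mz = mz[order]
        self.intensity = intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"FragmentationSpectrum(precursor={self.precursor.mz:.4f} "
            f"{self.precursor.polarity}, energy={self.energy}, n={len(self)})"
        )


@dataclass
class AMRTRecord:
    """The library unit: compound + species + column mode + RT + best-energy spectrum.

    ``rt`` is in minutes.  ``annotations`` holds extra header fields carried
    through MSP round trips (vendor comments and the like).
    """

    compound: Compound
    precursor: PrecursorSpecies
    column_mode: str  # "reversed_phase" | "hilic"
    rt: float
    best_energy: float
    spectrum: FragmentationSpectrum
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError("retention time must be >= 0")
        if self.column_mode not in ("reversed_phase", "hilic"):
            raise ValueError(f"unknown column_mode {self.column_mode!r}")
        if self.spectrum.energy != self.best_energy:
            raise ValueError(
                f"spectrum energy {self.spectrum.energy} != best_energy {self.best_energy}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.compound.id, self.precursor.polarity, self.column_mode)


OUT_OF_MASS_RANGE = "out_of_mass_range"
DUPLICATE = "duplicate"


@dataclass
class FilterReport:
    """Partition of a manifest into retained compounds and reasoned exclusions."""

    retained: list[Compound]
    excluded: list[tuple[Compound, str]]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def n_excluded_by(self, reason: str) -> int:
        return sum(1 for _, r in self.excluded if r == reason)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": c.id, "name": c.name, "neutral_mass": c.neutral_mass,
             "status": "retained", "reason": ""}
            for c in self.retained
        ] + [
            {"id": c.id, "name": c.name, "neutral_mass": c.neutral_mass,
             "status": "excluded", "reason": r}
            for c, r in self.excluded
        ]
        return pd.DataFrame(rows, columns=["id", "name", "neutral_mass", "status", "reason"])


def filter_library(
    manifest: Sequence[Compound],
    mass_range: tuple[float, float] = (70.0, 1000.0),
    polarities: Sequence[str] = (POSITIVE, NEGATIVE),
) -> FilterReport:
    """Screen a standards manifest against the scan range and for duplicates.

    A compound is retained iff at least one of its default precursor species
    (protonated in positive mode, deprotonated in negative) falls inside the
    inclusive ``mass_range`` — the instrument only observes species inside its
    scan window — and its ``structure_key`` has not occurred earlier in
    manifest order.  The first occurrence of each structure is the one kept.
    """
    low, high = mass_range
    if low >= high:
        raise ValueError(f"invalid mass range: low {low} >= high {high}")
    retained: list[Compound] = []
    excluded: list[tuple[Compound, str]] = []
    seen: set[str] = set()
    for compound in manifest:
        in_range = any(
            low <= default_precursor_mz(compound.neutral_mass, pol) <= high
            for pol in polarities
        )
        if not in_range:
            excluded.append((compound, OUT_OF_MASS_RANGE))
        elif compound.structure_key in seen:
            excluded.append((compound, DUPLICATE))
        else:
            retained.append(compound)
        seen.add(compound.structure_key)
    return FilterReport(retained=retained, excluded=excluded)


# ---------------------------------------------------------------------------
# MSP import/export
# ---------------------------------------------------------------------------

class MSPParseError(ValueError):
    """Raised when an MSP entry is malformed."""


_ION_MODE = {POSITIVE: "P", NEGATIVE: "N"}
_ION_MODE_INV = {"P": POSITIVE, "POSITIVE": POSITIVE, "N": NEGATIVE, "NEGATIVE": NEGATIVE}

# Header keys written by write_msp; anything else round-trips via annotations.
_KNOWN_KEYS = {
    "name", "formula", "precursormz", "precursor_type", "charge",
    "ion_mode", "collision_energy", "comment", "num peaks",
}


def write_msp(records: Sequence[AMRTRecord], destination: Union[str, Path, TextIO]) -> None:
    """Write records as NIST-style MSP text, one blank line between entries."""
    if not records:
        raise ValueError("no records to write")
    if hasattr(destination, "write"):
        _write_msp_handle(records, destination)  # type: ignore[arg-type]
    else:
        with open(destination, "w", encoding="utf-8") as handle:
            _write_msp_handle(records, handle)


def _write_msp_handle(records: Sequence[AMRTRecord], handle: TextIO) -> None:
    for i, rec in enumerate(records):
        if i:
            handle.write("\n")
        c = rec.compound
        comment = (
            f"RT={rec.rt:.4f} column={rec.column_mode} id={c.id} well={c.well} "
            f"structure_key={c.structure_key} neutral_mass={c.neutral_mass:.6f}"
        )
        handle.write(f"Name: {c.name}\n")
        handle.write(f"Formula: {c.formula}\n")
        handle.write(f"PrecursorMZ: {rec.precursor.mz:.6f}\n")
        handle.write(f"Precursor_type: {rec.precursor.adduct}\n")
        handle.write(f"Charge: {rec.precursor.charge}\n")
        handle.write(f"Ion_mode: {_ION_MODE[rec.precursor.polarity]}\n")
        handle.write(f"Collision_energy: {rec.best_energy:g}\n")
        handle.write(f"Comment: {comment}\n")
        for key, value in rec.annotations.items():
            handle.write(f"{key}: {value}\n")
        handle.write(f"Num Peaks: {len(rec.spectrum)}\n")
        for mz, inten in rec.spectrum.peaks:
            handle.write(f"{mz:.6f} {inten:.6f}\n")


_PEAK_RE = re.compile(r"^\s*([0-9.eE+-]+)[\s;,]+([0-9.eE+-]+)\s*$")


def read_msp(source: Union[str, Path, TextIO]) -> list[AMRTRecord]:
    """Parse NIST-style MSP text (the dialect of :func:`write_msp`).

    Unknown header fields are preserved in each record's ``annotations``.
    A peak count differing from ``Num Peaks`` or a malformed peak line raises
    :class:`MSPParseError`.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()  # type: ignore[union-attr]
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()

    records: list[AMRTRecord] = []
    header: dict[str, str] = {}
    extras: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    n_declared: int | None = None
    in_peaks = False

    def flush(line_no: int) -> None:
        nonlocal header, extras, peaks, n_declared, in_peaks
        if not header and not peaks:
            return
        name = header.get("name", "")
        if n_declared is None:
            raise MSPParseError(f"entry {name!r}: missing 'Num Peaks'")
        if len(peaks) != n_declared:
            raise MSPParseError(
                f"entry {name!r}: declared {n_declared} peaks but found {len(peaks)}"
            )
        records.append(_record_from_header(name, header, extras, peaks))
        header, extras, peaks, n_declared, in_peaks = {}, {}, [], None, False

    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if not line.strip():
            flush(line_no)
            continue
        if in_peaks:
            m = _PEAK_RE.match(line)
            if not m:
                raise MSPParseError(f"line {line_no}: malformed peak line {line!r}")
            peaks.append((float(m.group(1)), float(m.group(2))))
            continue
        if ":" not in line:
            raise MSPParseError(f"line {line_no}: expected 'Key: value', got {line!r}")
        key, _, value = line.partition(":")
        key_norm = key.strip().lower()
        value = value.strip()
        if key_norm == "num peaks":
            try:
                n_declared = int(value)
            except ValueError as exc:
                raise MSPParseError(f"line {line_no}: bad Num Peaks {value!r}") from exc
            in_peaks = True
        elif key_norm in _KNOWN_KEYS:
            header[key_norm] = value
        else:
            extras[key.strip()] = value
    flush(len(lines) + 1)
    return records


def _record_from_header(
    name: str, header: dict[str, str], extras: dict[str, str],
    peaks: list[tuple[float, float]],
) -> AMRTRecord:
    comment = dict(
        part.split("=", 1) for part in header.get("comment", "").split() if "=" in part
    )
    polarity = _ION_MODE_INV.get(header.get("ion_mode", "P").upper(), POSITIVE)
    precursor = PrecursorSpecies(
        adduct=header.get("precursor_type", _DEFAULT_ADDUCT_BY_POLARITY[polarity]),
        polarity=polarity,
        mz=float(header["precursormz"]),
        charge=int(header.get("charge", "1")),
    )
    energy = float(header.get("collision_energy", "0"))
    mz_mass = float(comment.get("neutral_mass", precursor.mz))
    compound = Compound(
        id=comment.get("id", name),
        name=name,
        formula=header.get("formula", ""),
        neutral_mass=mz_mass,
        well=comment.get("well", ""),
        structure_key=comment.get("structure_key", name),
    )
    return AMRTRecord(
        compound=compound,
        precursor=precursor,
        column_mode=comment.get("column", "reversed_phase"),
        rt=float(comment.get("RT", "0")),
        best_energy=energy,
        spectrum=FragmentationSpectrum(precursor, energy, peaks),
        annotations=dict(extras),
    )


def merge_amrt(
    rp_records: Sequence[AMRTRecord], hilic_records: Sequence[AMRTRecord]
) -> list[AMRTRecord]:
    """Union of two per-column sub-libraries, keyed on (compound, polarity, column).

    A compound characterised in both column modes keeps one record per mode
    (each with its own retention time).  A duplicate key within a single
    input is a validation error.
    """
    for label, recs in (("reversed-phase", rp_records), ("HILIC", hilic_records)):
        keys = [r.key for r in recs]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate record keys in {label} input: {dupes}")
    merged: dict[tuple[str, str, str], AMRTRecord] = {}
    for rec in list(rp_records) + list(hilic_records):
        merged.setdefault(rec.key, rec)
    return list(merged.values())


# ---------------------------------------------------------------------------
# Manifest I/O (delimited text)
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["id", "name", "formula", "neutral_mass", "well", "structure_key"]


def write_manifest(compounds: Iterable[Compound], path: Union[str, Path]) -> None:
    frame = pd.DataFrame(
        [
            {"id": c.id, "name": c.name, "formula": c.formula,
             "neutral_mass": c.neutral_mass, "well": c.well,
             "structure_key": c.structure_key}
            for c in compounds
        ],
        columns=_MANIFEST_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_manifest(path: Union[str, Path]) -> list[Compound]:
    frame = pd.read_csv(path, dtype={"id": str, "name": str, "formula": str,
                                     "well": str, "structure_key": str})
    missing = [c for c in ("name", "neutral_mass") if c not in frame.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    compounds = []
    for i, row in frame.iterrows():
        compounds.append(
            Compound(
                id=str(row.get("id", f"row{i}")),
                name=str(row["name"]),
                formula=str(row.get("formula", "")),
                neutral_mass=float(row["neutral_mass"]),
                well=str(row.get("well", "") or ""),
                structure_key=str(row.get("structure_key", "") or row["name"]),
            )
        )
    return compounds
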