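"""Shared fixtures: the default synthetic manifest and small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from amrtkit.library_model import (
    AMRTRecord,
    Compound,
    FragmentationSpectrum,
    PrecursorSpecies,
    filter_library,
)
from amrtkit.simulate import ManifestProfile, generate_manifest


@pytest.fixture(scope="session")
def default_manifest():
    """The MSMLS-like fixture manifest (default profile, seed 42)."""
    return generate_manifest(ManifestProfile())


@pytest.fixture(scope="session")
def retained_compounds(default_manifest):
    return filter_library(default_manifest).retained


def make_compound(i: int, mass: float, key: str | None = None) -> Compound:
    return Compound(
        id=f"T{i:03d}",
        name=f"test-{i:03d}",
        formula="C6H12O6",
        neutral_mass=mass,
        well=f"P1-A{i % 12 + 1:02d}",
        structure_key=key or f"TK{i:03d}",
    )


def make_record(
    i: int,
    mass: float = 180.063,
    rt: float = 5.0,
    polarity: str = "positive",
    column_mode: str = "reversed_phase",
    energy: float = 40.0,
    peaks=None,
) -> AMRTRecord:
    compound = make_compound(i, mass)
    shift = 1.007276 if polarity == "positive" else -1.007276
    precursor = PrecursorSpecies(
        adduct="[M+H]+" if polarity == "positive" else "[M-H]-",
        polarity=polarity,
        mz=mass + shift,
    )
    if peaks is None:
        rng = np.random.default_rng(i)
        frag_mz = np.sort(rng.uniform(50, mass - 20, 5))
        peaks = list(zip(frag_mz, rng.uniform(100, 1000, 5))) + [(precursor.mz, 500.0)]
    return AMRTRecord(
        compound=compound,
        precursor=precursor,
        column_mode=column_mode,
        rt=rt,
        best_energy=energy,
        spectrum=FragmentationSpectrum(precursor, energy, peaks),
    )
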