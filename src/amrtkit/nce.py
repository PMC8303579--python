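"""Collision-energy ladder and best-energy selection.

Reference MS2 spectra are acquired over a ladder of normalized collision
energies (NCE); the library keeps, per compound and polarity, the single
energy whose spectrum still contains the molecular ion while offering a rich,
balanced set of fragments.  Eligibility encodes the review criterion
(precursor present, enough fragments); among eligible energies the score
``n_fragments + normalized spectral entropy`` is maximised, with ties broken
toward the gentler (lower) energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .library_model import (
    DEFAULT_ADDUCTS,
    Compound,
    FragmentationSpectrum,
    PrecursorSpecies,
    POSITIVE,
)

__all__ = [
    "EnergyLadder",
    "EnergyScore",
    "ScoringParams",
    "BestEnergyResult",
    "NoIonizableSpeciesError",
    "energy_ladder",
    "choose_precursor_species",
    "score_spectrum",
    "select_best_energy",
]


@dataclass(frozen=True)
class EnergyLadder:
    """Inclusive arithmetic sequence of collision energies."""

    start: float
    stop: float
    step: float
    values: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"ladder step must be > 0, got {self.step}")
        if self.stop < self.start:
            raise ValueError(f"ladder stop {self.stop} < start {self.start}")
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        object.__setattr__(
            self, "values", tuple(self.start + i * self.step for i in range(n))
        )

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def __contains__(self, energy: float) -> bool:
        return any(abs(energy - v) < 1e-9 for v in self.values)


def energy_ladder(start: float, stop: float, step: float) -> EnergyLadder:
    """Build the NCE ladder ``start, start+step, ..., stop`` (inclusive)."""
    return EnergyLadder(start=start, stop=stop, step=step)


@dataclass(frozen=True)
class EnergyScore:
    """Per-energy evaluation of a fragmentation spectrum."""

    energy: float
    eligible: bool
    precursor_present: bool
    n_fragments: int
    score: float


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds operationalising 'molecular ion plus sufficient fragments'.

    ``ppm_tol``: match window for the precursor peak; ``intensity_floor``:
    relative intensity (fraction of base peak) below which a peak is ignored;
    ``min_fragments``: fragment count needed for an energy to be eligible.
    """

    ppm_tol: float = 10.0
    intensity_floor: float = 0.01
    min_fragments: int = 3


class NoIonizableSpeciesError(ValueError):
    """No candidate adduct of a compound matched any MS1 peak."""


def choose_precursor_species(
    ms1_peaks: Sequence[tuple[float, float]],
    compound: Compound,
    polarity: str,
    adducts: Optional[Mapping[str, float]] = None,
    ppm_tol: float = 10.0,
    presence_floor: float = 0.01,
) -> PrecursorSpecies:
    """Pick the precursor species to fragment from an MS1 survey peak list.

    The protonated (positive) / deprotonated (negative) molecular ion wins
    whenever its peak is found above the presence floor, regardless of other
    adducts' intensities; only when the molecular ion is absent does the most
    intense matching adduct from ``adducts`` take over.

    ``adducts`` maps adduct label to neutral-mass shift (Da) for the given
    polarity; defaults to the built-in adduct table.
    """
    if adducts is None:
        adducts = {
            label: shift
            for label, (pol, shift) in DEFAULT_ADDUCTS.items()
            if pol == polarity
        }
    default_label = "[M+H]+" if polarity == POSITIVE else "[M-H]-"
    if default_label not in adducts:
        raise ValueError(f"adduct set must include the molecular ion {default_label}")

    mz_arr = np.asarray([p[0] for p in ms1_peaks], dtype=float)
    int_arr = np.asarray([p[1] for p in ms1_peaks], dtype=float)
    base = int_arr.max() if int_arr.size else 0.0

    def matched_intensity(target_mz: float) -> float:
        if mz_arr.size == 0:
            return 0.0
        within = np.abs(mz_arr - target_mz) <= target_mz * ppm_tol * 1e-6
        return float(int_arr[within].max()) if within.any() else 0.0

    floor_abs = presence_floor * base
    default_mz = compound.neutral_mass + adducts[default_label]
    if base > 0 and matched_intensity(default_mz) >= floor_abs and matched_intensity(default_mz) > 0:
        return PrecursorSpecies(default_label, polarity, default_mz)

    best_label, best_intensity = None, 0.0
    for label, shift in adducts.items():
        target = compound.neutral_mass + shift
        if target <= 0:
            continue
        inten = matched_intensity(target)
        if inten > best_intensity:
            best_label, best_intensity = label, inten
    if best_label is None or best_intensity <= 0:
        raise NoIonizableSpeciesError(
            f"no ionizable species for {compound.id} in {polarity} mode"
        )
    return PrecursorSpecies(best_label, polarity, compound.neutral_mass + adducts[best_label])


def score_spectrum(
    spectrum: FragmentationSpectrum, params: ScoringParams = ScoringParams()
) -> EnergyScore:
    """Evaluate one spectrum: precursor presence, fragment count, score.

    The score is ``n_fragments + H/log(n)`` where ``H`` is the Shannon
    entropy of the fragment intensity distribution: richer and more balanced
    spectra score higher, and the entropy term (in [0, 1]) only arbitrates
    between energies with equal fragment counts.  Scale-invariant by
    construction (all thresholds are relative to the base peak).
    """
    if len(spectrum) == 0:
        return EnergyScore(spectrum.energy, False, False, 0, 0.0)
    base = spectrum.base_peak_intensity()
    if base <= 0:
        return EnergyScore(spectrum.energy, False, False, 0, 0.0)
    floor_abs = params.intensity_floor * base
    prec_mz = spectrum.precursor.mz
    tol = prec_mz * params.ppm_tol * 1e-6
    is_precursor = np.abs(spectrum.mz - prec_mz) <= tol
    above = spectrum.intensity >= floor_abs
    precursor_present = bool(np.any(is_precursor & above))
    frag_mask = above & ~is_precursor
    n_fragments = int(frag_mask.sum())
    if n_fragments > 1:
        p = spectrum.intensity[frag_mask]
        p = p / p.sum()
        entropy = float(-(p * np.log(p)).sum() / np.log(n_fragments))
    else:
        entropy = 0.0
    eligible = precursor_present and n_fragments >= params.min_fragments
    return EnergyScore(
        energy=spectrum.energy,
        eligible=eligible,
        precursor_present=precursor_present,
        n_fragments=n_fragments,
        score=n_fragments + entropy,
    )


@dataclass(frozen=True)
class BestEnergyResult:
    """Outcome of best-energy selection over a ladder of spectra."""

    best_energy: float
    eligible: bool  # False flags the choice for manual review
    table: tuple[EnergyScore, ...]


def select_best_energy(
    spectra_by_energy: Mapping[float, FragmentationSpectrum],
    params: ScoringParams = ScoringParams(),
) -> BestEnergyResult:
    """Select the best collision energy from per-energy spectra.

    Among eligible energies the highest score wins, ties going to the lowest
    energy (gentler fragmentation preserves the molecular ion).  If no energy
    is eligible the argmax-score energy is still reported but flagged
    ineligible for manual review.
    """
    if not spectra_by_energy:
        raise ValueError("no spectra supplied")
    table = tuple(
        score_spectrum(spectra_by_energy[e], params)
        for e in sorted(spectra_by_energy)
    )
    pool = [s for s in table if s.eligible]
    flagged_eligible = bool(pool)
    if not pool:
        pool = list(table)
    best = pool[0]
    for s in pool[1:]:
        if s.score > best.score:
            best = s
    return BestEnergyResult(best_energy=best.energy, eligible=flagged_eligible, table=table)
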