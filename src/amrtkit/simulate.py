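"""Seeded generators for every input the AMRT workflow consumes.

Four generators, all fully deterministic under their seeds:

* an MSMLS-like standards manifest (634 entries) with planted defects —
  compounds outside the 70–1000 m/z scan range, exact-structure duplicates —
  and a controlled isobaric-cluster structure whose largest cluster drives
  the non-isobaric mixture count;
* an energy-dependent fragmentation model with a planted optimal collision
  energy per compound (logistic precursor survival, Gaussian fragment
  breakdown curves peaking at the optimum);
* exponentially-modified-Gaussian (EMG) chromatographic peaks;
* full synthetic DDA runs (MS1 features plus triggered MS2 spectra) derived
  from a library, with jitter, dropout, and loop-count/exclusion emulation.

The models are intentionally simple — rich enough for parameter-recovery
and self-consistency tests, with no claim of physical realism.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .annotate import Feature
from .library_model import (
    AMRTRecord,
    Compound,
    FragmentationSpectrum,
    POSITIVE,
    default_species,
)
from .chromatography import Trace
from .nce import EnergyLadder, energy_ladder

__all__ = [
    "ManifestProfile",
    "FragModelParams",
    "PeakShapeParams",
    "LCRunParams",
    "SimulatedLCRun",
    "DDAParams",
    "SyntheticDDARun",
    "generate_manifest",
    "planted_optimal_energy",
    "simulate_fragmentation",
    "simulate_energy_ladder",
    "simulate_trace",
    "simulate_dda_run",
    "build_synthetic_library",
]


def _sub_rng(seed: int, *tokens) -> np.random.Generator:
    """Independent stream keyed on (seed, tokens); stable across processes."""
    keys = [seed & 0x7FFFFFFF]
    for tok in tokens:
        keys.append(zlib.crc32(str(tok).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(keys)


# ---------------------------------------------------------------------------
# Standards manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestProfile:
    """Shape of the synthetic standards plate set.

    Defaults mirror a commercial 7-plate standards library: 634 entries of
    which 5 fall outside the 70–1000 m/z scan window in both polarities and
    37 duplicate an earlier structure, leaving 592 analysable compounds.
    Neutral masses are drawn log-uniformly over [80, 950] Da in small
    isobaric clusters; exactly one cluster has ``largest_isobaric_cluster``
    members (pairwise within 1.5 Da), which pins the non-isobaric mixture
    count.
    """

    n_total: int = 634
    n_out_of_range: int = 5
    n_duplicates: int = 37
    mass_low: float = 80.0
    mass_high: float = 950.0
    largest_isobaric_cluster: int = 9
    isobaric_delta: float = 1.5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_out_of_range + self.n_duplicates >= self.n_total:
            raise ValueError("defects must not exhaust the manifest")
        if self.largest_isobaric_cluster < 1:
            raise ValueError("largest_isobaric_cluster must be >= 1")


def _cluster_masses(
    rng: np.random.Generator, profile: ManifestProfile, n_regular: int
) -> list[np.ndarray]:
    """Cluster neutral masses: one planted max cluster + minor clusters.

    Cluster centres keep >= 3 Da spacing and members span < 1.2 Da, so the
    gap between members of adjacent clusters exceeds ``isobaric_delta`` and
    every cluster is a clique: the largest isobaric clique is exactly the
    planted one.
    """
    k_max = profile.largest_isobaric_cluster
    max_minor = max(1, min(5, k_max - 1))
    sizes = [k_max]
    remaining = n_regular
    while remaining > 0:
        size = int(rng.integers(1, max_minor + 1))
        size = min(size, remaining)
        sizes.append(size)
        remaining -= size
    n_centers = len(sizes)
    min_gap = 3.0
    span = profile.mass_high - profile.mass_low
    slack = span - (n_centers - 1) * min_gap
    if slack <= 0:
        raise ValueError("mass range too narrow for the requested manifest")
    # log-uniform-ish placement with a hard minimum gap between centres
    u = np.sort(rng.random(n_centers))
    centers = profile.mass_low + u * slack + np.arange(n_centers) * min_gap
    rng.shuffle(sizes)
    clusters = []
    for center, size in zip(centers, sizes):
        if size == 1:
            clusters.append(np.array([center]))
        else:
            offsets = np.concatenate([[0.0], np.cumsum(rng.uniform(0.1, 1.1 / max(size - 1, 1), size - 1))])
            offsets = offsets / max(offsets.max(), 1e-9) * min(1.2, 0.15 * (size - 1) + 0.6)
            # rescale so the span stays < isobaric_delta while members differ
            offsets = offsets * (profile.isobaric_delta * 0.8) / max(offsets.max(), 1e-9) if size > 1 else offsets
            clusters.append(center + offsets)
    return clusters


def _fake_formula(rng: np.random.Generator, mass: float) -> str:
    c = max(1, int(mass // 18))
    h = max(2, int(mass // 9))
    o = int(rng.integers(0, 7))
    n = int(rng.integers(0, 4))
    parts = [f"C{c}", f"H{h}"]
    if n:
        parts.append(f"N{n}")
    if o:
        parts.append(f"O{o}")
    return "".join(parts)


def generate_manifest(profile: ManifestProfile = ManifestProfile()) -> list[Compound]:
    """Generate the synthetic standards manifest.

    Guarantees, by construction and self-validated before returning:

    * exactly ``n_total`` entries;
    * exactly ``n_out_of_range`` compounds whose default precursor m/z lies
      outside [70, 1000] in both polarities;
    * exactly ``n_duplicates`` entries sharing a structure_key with an
      earlier entry (each duplicating a distinct in-range original);
    * the defect classes are disjoint, so scan-range filtering plus
      duplicate removal retains ``n_total − n_out_of_range − n_duplicates``;
    * among retained compounds the largest set of pairwise-isobaric masses
      (within ``isobaric_delta``) has exactly ``largest_isobaric_cluster``
      members.
    """
    rng = _sub_rng(profile.seed, "manifest")
    n_regular = profile.n_total - profile.n_out_of_range - profile.n_duplicates
    clusters = _cluster_masses(rng, profile, n_regular - profile.largest_isobaric_cluster)
    masses = np.concatenate(clusters)

    n_low = (profile.n_out_of_range + 1) // 2
    n_high = profile.n_out_of_range - n_low
    # outside the scan range for both [M+H]+ and [M-H]-
    out_masses = np.concatenate([
        rng.uniform(40.0, 65.0, n_low),
        rng.uniform(1005.0, 1200.0, n_high),
    ])

    compounds: list[Compound] = []
    for i, mass in enumerate(masses):
        compounds.append(
            Compound(
                id=f"C{i + 1:04d}",
                name=f"compound-{i + 1:04d}",
                formula=_fake_formula(rng, mass),
                neutral_mass=float(mass),
                structure_key=f"SK{i + 1:04d}",
            )
        )
    for j, mass in enumerate(out_masses):
        compounds.append(
            Compound(
                id=f"X{j + 1:02d}",
                name=f"offrange-{j + 1:02d}",
                formula=_fake_formula(rng, mass),
                neutral_mass=float(mass),
                structure_key=f"SKX{j + 1:02d}",
            )
        )

    order = rng.permutation(len(compounds))
    manifest = [compounds[i] for i in order]

    # duplicates copy a distinct in-range original and are inserted after it
    original_pool = [c for c in manifest if c.id.startswith("C")]
    originals = list(rng.choice(len(original_pool), size=profile.n_duplicates, replace=False))
    for d, orig_idx in enumerate(originals):
        original = original_pool[orig_idx]
        dup = Compound(
            id=f"D{d + 1:02d}",
            name=original.name,
            formula=original.formula,
            neutral_mass=original.neutral_mass,
            structure_key=original.structure_key,
        )
        pos = next(i for i, c in enumerate(manifest) if c.id == original.id)
        insert_at = int(rng.integers(pos + 1, len(manifest) + 1))
        manifest.insert(insert_at, dup)

    # plate/well assignment in final order: 7 plates x 96 wells
    rows = "ABCDEFGH"
    out = []
    for i, c in enumerate(manifest):
        plate, slot = divmod(i, 96)
        well = f"P{plate + 1}-{rows[slot // 12]}{slot % 12 + 1:02d}"
        out.append(replace_well(c, well))

    _validate_manifest(out, profile)
    return out


def replace_well(compound: Compound, well: str) -> Compound:
    return Compound(
        id=compound.id,
        name=compound.name,
        formula=compound.formula,
        neutral_mass=compound.neutral_mass,
        well=well,
        structure_key=compound.structure_key,
    )


def _validate_manifest(manifest: Sequence[Compound], profile: ManifestProfile) -> None:
    from .library_model import filter_library, OUT_OF_MASS_RANGE, DUPLICATE

    report = filter_library(manifest)
    n_expected = profile.n_total - profile.n_out_of_range - profile.n_duplicates
    if (
        len(manifest) != profile.n_total
        or report.n_retained != n_expected
        or report.n_excluded_by(OUT_OF_MASS_RANGE) != profile.n_out_of_range
        or report.n_excluded_by(DUPLICATE) != profile.n_duplicates
    ):
        raise RuntimeError("manifest generation failed its planted-defect self-check")
    masses = np.sort([c.neutral_mass for c in report.retained])
    # largest isobaric clique = largest window of span < delta
    best = 0
    j = 0
    for i in range(len(masses)):
        while masses[i] - masses[j] >= profile.isobaric_delta:
            j += 1
        best = max(best, i - j + 1)
    if best != profile.largest_isobaric_cluster:
        raise RuntimeError(
            f"largest isobaric clique is {best}, expected {profile.largest_isobaric_cluster}"
        )


# ---------------------------------------------------------------------------
# Energy-dependent fragmentation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragModelParams:
    """Fragmentation simulator parameters.

    Each compound gets a planted optimal energy E* on the ladder.  The
    precursor survives collisional activation with probability
    ``1 / (1 + exp((E − E½)/s))`` with ``E½ = E* + survival_offset`` and
    slope ``s``; fragments follow Gaussian breakdown curves centred within
    ``frag_center_spread`` of E*.  Noise is multiplicative log-normal on
    every intensity plus Poisson-count spurious peaks below the presence
    floor.
    """

    ladder: EnergyLadder = field(default_factory=lambda: energy_ladder(10, 120, 10))
    survival_offset: float = 20.0
    survival_slope: float = 8.0
    n_frag_range: tuple[int, int] = (5, 9)
    frag_center_spread: float = 5.0
    frag_width_range: tuple[float, float] = (5.0, 8.0)
    frag_height_range: tuple[float, float] = (200.0, 800.0)
    precursor_height: float = 1000.0
    noise_sigma: float = 0.05
    spurious_rate: float = 1.0
    fixed_optimum: Optional[float] = None
    seed: int = 0


def _compound_frag_model(params: FragModelParams, compound: Compound, polarity: str):
    """Per-compound latent fragmentation parameters (energy-independent)."""
    rng = _sub_rng(params.seed, "fragmodel", compound.id, polarity)
    if params.fixed_optimum is not None:
        e_star = float(params.fixed_optimum)
    else:
        e_star = float(rng.choice(params.ladder.values))
    n_frag = int(rng.integers(params.n_frag_range[0], params.n_frag_range[1] + 1))
    species = default_species(compound, polarity)
    frag_mz = np.sort(rng.uniform(50.0, max(species.mz - 15.0, 55.0), n_frag))
    centers = e_star + rng.uniform(-params.frag_center_spread, params.frag_center_spread, n_frag)
    widths = rng.uniform(*params.frag_width_range, n_frag)
    heights = rng.uniform(*params.frag_height_range, n_frag)
    return e_star, species, frag_mz, centers, widths, heights


def planted_optimal_energy(
    compound: Compound, params: FragModelParams, polarity: str = POSITIVE
) -> float:
    """Ground-truth optimal collision energy the simulator planted."""
    return _compound_frag_model(params, compound, polarity)[0]


def simulate_fragmentation(
    compound: Compound,
    energy: float,
    params: FragModelParams = FragModelParams(),
    polarity: str = POSITIVE,
) -> FragmentationSpectrum:
    """One MS2 spectrum of ``compound`` at ``energy``.

    Deterministic under ``(params.seed, compound.id, polarity, energy)``.
    At E = E* the spectrum is eligible by construction: the precursor is well
    above the presence floor and every fragment's breakdown curve is within
    its central region.
    """
    if energy not in params.ladder:
        raise ValueError(f"energy {energy} not on the ladder {params.ladder.values}")
    e_star, species, frag_mz, centers, widths, heights = _compound_frag_model(
        params, compound, polarity
    )
    rng = _sub_rng(params.seed, "spectrum", compound.id, polarity, f"{energy:g}")

    e_half = e_star + params.survival_offset
    survival = 1.0 / (1.0 + np.exp((energy - e_half) / params.survival_slope))
    noise = lambda n: np.exp(rng.normal(0.0, params.noise_sigma, n))  # noqa: E731

    mzs = [species.mz * (1.0 + rng.normal(0.0, 1e-6))]
    intensities = [params.precursor_height * survival * float(noise(1)[0])]
    frag_int = heights * np.exp(-((energy - centers) ** 2) / (2.0 * widths**2)) * noise(len(frag_mz))
    for mz, inten in zip(frag_mz, frag_int):
        if inten > 1e-3:
            mzs.append(mz * (1.0 + rng.normal(0.0, 1e-6)))
            intensities.append(float(inten))

    # spurious peaks deliberately below the 1% presence floor
    n_spurious = int(rng.poisson(params.spurious_rate))
    base_guess = params.precursor_height
    for _ in range(n_spurious):
        mzs.append(float(rng.uniform(50.0, species.mz + 20.0)))
        intensities.append(float(rng.uniform(0.001, 0.005) * base_guess))

    return FragmentationSpectrum(species, energy, list(zip(mzs, intensities)))


def simulate_energy_ladder(
    compound: Compound,
    params: FragModelParams = FragModelParams(),
    polarity: str = POSITIVE,
) -> dict[float, FragmentationSpectrum]:
    """Spectra at every ladder energy for one compound."""
    return {
        energy: simulate_fragmentation(compound, energy, params, polarity)
        for energy in params.ladder
    }


# ---------------------------------------------------------------------------
# Chromatographic peak shapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakShapeParams:
    """EMG peak: Gaussian width ``sigma`` (s) convolved with exponential tail
    ``tau`` (s); ``tau = 0`` degenerates to a pure Gaussian.  ``rt`` is in
    minutes, sampling in Hz, baseline noise is additive Gaussian."""

    rt: float = 5.0
    sigma: float = 1.0
    tau: float = 0.0
    height: float = 1e6
    sampling_hz: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


def emg_profile(t: np.ndarray, rt_s: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-height EMG (or Gaussian when tau = 0) evaluated at times ``t`` (s)."""
    if tau <= 0:
        y = np.exp(-((t - rt_s) ** 2) / (2.0 * sigma**2))
    else:
        y = stats.exponnorm.pdf(t, K=tau / sigma, loc=rt_s, scale=sigma)
    m = y.max()
    return y / m if m > 0 else y


def simulate_trace(shape: PeakShapeParams = PeakShapeParams()) -> Trace:
    """Sample one EMG chromatographic peak as a Trace (times in seconds)."""
    rt_s = shape.rt * 60.0
    half_span = 6.0 * shape.sigma + 8.0 * shape.tau + 2.0
    dt = 1.0 / shape.sampling_hz
    t = np.arange(rt_s - half_span, rt_s + half_span + dt / 2, dt)
    y = shape.height * emg_profile(t, rt_s, shape.sigma, shape.tau)
    if shape.noise_sd > 0:
        rng = _sub_rng(shape.seed, "trace", f"{shape.rt:g}", f"{shape.sigma:g}")
        y = np.clip(y + rng.normal(0.0, shape.noise_sd, y.size), 0.0, None)
    return Trace(t, y)


@dataclass(frozen=True)
class LCRunParams:
    """Synthetic LC-MS1 run: one planted EMG peak per compound.

    Per compound the RT is drawn uniformly over ``rt_range_min`` and the peak
    shape from the sigma/tau ranges; ``tau_over_sigma`` (if set) fixes the
    tail-to-width ratio instead, which makes a whole condition systematically
    tail (poor symmetry).  ``found_fraction`` silently drops compounds to
    emulate analytes that do not elute.
    """

    rt_range_min: tuple[float, float] = (1.0, 14.0)
    sigma_range_s: tuple[float, float] = (0.9, 1.4)
    tau_range_s: tuple[float, float] = (0.0, 0.3)
    tau_over_sigma: Optional[float] = None
    height_range: tuple[float, float] = (5e5, 5e6)
    sampling_hz: float = 6.0
    found_fraction: float = 1.0
    seed: int = 0


class SimulatedLCRun:
    """Lazy MS1-scan view over planted chromatographic peaks.

    Satisfies the MS1Run protocol.  Scans cover the union of all peak
    supports on a uniform grid; each scan lists the m/z of every compound
    whose profile is non-negligible at that time.
    """

    def __init__(
        self,
        compounds: Sequence[Compound],
        polarity: str,
        params: LCRunParams = LCRunParams(),
    ) -> None:
        self.polarity = polarity
        self.params = params
        self.peaks: dict[str, PeakShapeParams] = {}
        self.planted_present: dict[str, bool] = {}
        for compound in compounds:
            rng = _sub_rng(params.seed, "lc", compound.id, polarity)
            present = bool(rng.random() < params.found_fraction)
            sigma = float(rng.uniform(*params.sigma_range_s))
            if params.tau_over_sigma is not None:
                tau = params.tau_over_sigma * sigma
            else:
                tau = float(rng.uniform(*params.tau_range_s))
            self.planted_present[compound.id] = present
            self.peaks[compound.id] = PeakShapeParams(
                rt=float(rng.uniform(*params.rt_range_min)),
                sigma=sigma,
                tau=tau,
                height=float(rng.uniform(*params.height_range)),
                sampling_hz=params.sampling_hz,
            )
        self._mz = {
            c.id: default_species(c, polarity).mz for c in compounds
        }
        self._scans: Optional[list[tuple[float, np.ndarray, np.ndarray]]] = None

    def ms1_scans(self) -> list[tuple[float, np.ndarray, np.ndarray]]:
        if self._scans is not None:
            return self._scans
        if not self.peaks:
            raise ValueError("run contains no compounds")
        dt = 1.0 / self.params.sampling_hz
        lo = min(
            p.rt * 60.0 - 6 * p.sigma - 8 * p.tau for p in self.peaks.values()
        )
        hi = max(
            p.rt * 60.0 + 6 * p.sigma + 8 * p.tau for p in self.peaks.values()
        )
        times = np.arange(lo - 2.0, hi + 2.0, dt)
        profiles = {}
        for cid, shape in self.peaks.items():
            if not self.planted_present[cid]:
                continue
            profiles[cid] = shape.height * emg_profile(
                times, shape.rt * 60.0, shape.sigma, shape.tau
            )
        scans = []
        ids = list(profiles)
        mz_arr = np.array([self._mz[cid] for cid in ids])
        for i, t in enumerate(times):
            if ids:
                inten = np.array([profiles[cid][i] for cid in ids])
                keep = inten > 1.0
                scans.append((float(t), mz_arr[keep], inten[keep]))
            else:
                scans.append((float(t), np.array([]), np.array([])))
        self._scans = scans
        return scans


# ---------------------------------------------------------------------------
# Synthetic DDA runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DDAParams:
    """Synthetic DDA sample-run parameters.

    Jitters perturb feature coordinates relative to the library record;
    ``rt_shift_min`` is a systematic shift (e.g. +0.6 min demotes every
    match below level 1).  MS2 triggering emulates a loop count of
    ``top_n`` precursors per cycle with dynamic exclusion: a feature can be
    fragmented only while eluting (``elution_halfwidth_min`` around its RT).
    """

    mz_jitter_ppm: float = 0.0
    rt_jitter_sd_min: float = 0.0
    rt_shift_min: float = 0.0
    dropout: float = 0.0
    spectrum_noise_sigma: float = 0.0
    top_n: int = 5
    cycle_s: float = 1.0
    elution_halfwidth_min: float = 0.25
    seed: int = 0


@dataclass
class SyntheticDDARun:
    """MS1 features (with triggered MS2 where acquired) plus bookkeeping."""

    features: list[Feature]
    polarity: str
    planted_ids: list[str]
    dropped_ids: list[str]


def simulate_dda_run(
    records: Sequence[AMRTRecord], params: DDAParams = DDAParams()
) -> SyntheticDDARun:
    """Simulate a DDA acquisition of a sample containing the library compounds.

    Per surviving record one MS1 feature is emitted at the record's m/z and
    RT plus jitter; MS2 spectra are granted cycle by cycle to the ``top_n``
    most intense co-eluting features not yet fragmented (dynamic exclusion
    keeps already-fragmented precursors off the list).  Deterministic under
    ``params.seed``.
    """
    polarities = {r.precursor.polarity for r in records}
    if len(polarities) != 1:
        raise ValueError("records must share one polarity")
    polarity = polarities.pop()
    rng = _sub_rng(params.seed, "dda", polarity)

    survivors: list[tuple[AMRTRecord, Feature]] = []
    dropped: list[str] = []
    for record in records:
        if rng.random() < params.dropout:
            dropped.append(record.compound.id)
            continue
        mz = record.precursor.mz * (1.0 + rng.normal(0.0, params.mz_jitter_ppm * 1e-6))
        rt = max(
            0.0,
            record.rt + params.rt_shift_min + rng.normal(0.0, params.rt_jitter_sd_min)
            if params.rt_jitter_sd_min > 0
            else record.rt + params.rt_shift_min,
        )
        intensity = float(rng.lognormal(mean=13.0, sigma=1.0))
        survivors.append((record, Feature(mz=mz, rt=rt, intensity=intensity,
                                          polarity=polarity, id=record.compound.id)))

    # MS2 triggering: loop-count-limited top-N per cycle with exclusion
    ms2_granted: dict[str, FragmentationSpectrum] = {}
    if survivors:
        starts = [f.rt - params.elution_halfwidth_min for _, f in survivors]
        ends = [f.rt + params.elution_halfwidth_min for _, f in survivors]
        t = min(starts)
        t_end = max(ends)
        cycle_min = params.cycle_s / 60.0
        while t <= t_end + cycle_min:
            eluting = [
                (record, feat)
                for (record, feat) in survivors
                if feat.id not in ms2_granted
                and feat.rt - params.elution_halfwidth_min <= t <= feat.rt + params.elution_halfwidth_min
            ]
            eluting.sort(key=lambda rf: -rf[1].intensity)
            for record, feat in eluting[: params.top_n]:
                ms2_granted[feat.id] = _jitter_spectrum(record.spectrum, params, rng)
            t += cycle_min

    features = [
        Feature(
            mz=f.mz, rt=f.rt, intensity=f.intensity, polarity=f.polarity,
            ms2=ms2_granted.get(f.id), id=f.id,
        )
        for _, f in survivors
    ]
    return SyntheticDDARun(
        features=features,
        polarity=polarity,
        planted_ids=[f.id for f in features],
        dropped_ids=dropped,
    )


def _jitter_spectrum(
    spectrum: FragmentationSpectrum, params: DDAParams, rng: np.random.Generator
) -> FragmentationSpectrum:
    mz = spectrum.mz * (1.0 + rng.normal(0.0, params.mz_jitter_ppm * 1e-6, len(spectrum)))
    if params.spectrum_noise_sigma > 0:
        inten = spectrum.intensity * np.exp(
            rng.normal(0.0, params.spectrum_noise_sigma, len(spectrum))
        )
    else:
        inten = spectrum.intensity.copy()
    return FragmentationSpectrum(spectrum.precursor, spectrum.energy, (mz, inten))


# ---------------------------------------------------------------------------
# End-to-end synthetic library
# ---------------------------------------------------------------------------

def build_synthetic_library(
    compounds: Sequence[Compound],
    params: FragModelParams = FragModelParams(),
    polarity: str = POSITIVE,
    column_mode: str = "reversed_phase",
    rt_range_min: tuple[float, float] = (1.0, 14.0),
    scoring=None,
) -> list[AMRTRecord]:
    """Simulate the whole library build: ladder spectra → best energy → RT.

    Retention times are drawn uniformly over the gradient window per
    compound (deterministic under the fragmentation seed); each record keeps
    the spectrum acquired at its selected best energy.
    """
    from .nce import ScoringParams, select_best_energy

    if scoring is None:
        scoring = ScoringParams()
    records = []
    for compound in compounds:
        spectra = simulate_energy_ladder(compound, params, polarity)
        result = select_best_energy(spectra, scoring)
        rng = _sub_rng(params.seed, "rt", compound.id, polarity, column_mode)
        rt = float(rng.uniform(*rt_range_min))
        records.append(
            AMRTRecord(
                compound=compound,
                precursor=spectra[result.best_energy].precursor,
                column_mode=column_mode,
                rt=rt,
                best_energy=result.best_energy,
                spectrum=spectra[result.best_energy],
            )
        )
    return records
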