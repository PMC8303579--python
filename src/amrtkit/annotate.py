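"""Feature annotation against the AMRT database with MSI confidence levels.

A DDA-run feature is matched to library records by accurate mass (ppm
window, same polarity); each candidate is scored on retention-time agreement
and MS2 spectral similarity (square-root-intensity cosine with greedy
fragment pairing).  MSI level 1 requires all three orthogonal pieces of
evidence against the authentic standard (mass + RT + MS2); mass + MS2
without RT gives level 2; anything less is unidentified (level 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .library_model import AMRTRecord, FragmentationSpectrum

__all__ = [
    "Feature",
    "Annotation",
    "MatchParams",
    "IdentificationSummary",
    "spectral_similarity",
    "assign_msi_level",
    "match_features",
    "summarize_identifications",
    "overlap_summary",
    "read_feature_table",
    "write_feature_table",
]


@dataclass(frozen=True)
class Feature:
    """An MS1 feature from a sample run, optionally with a triggered MS2."""

    mz: float
    rt: float  # minutes
    intensity: float
    polarity: str
    ms2: Optional[FragmentationSpectrum] = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("feature m/z must be > 0")
        if self.rt < 0:
            raise ValueError("feature rt must be >= 0")


@dataclass(frozen=True)
class MatchParams:
    """Identification thresholds.

    ``mass_ppm``: accurate-mass window; ``rt_tol_min``: RT agreement window
    (the same ±0.5 min used for inclusion-list scheduling); ``sim_threshold``
    and ``min_matched`` gate the MS2 evidence; ``frag_mz_tol`` is the
    fragment pairing tolerance in Da.
    """

    mass_ppm: float = 5.0
    rt_tol_min: float = 0.5
    sim_threshold: float = 0.7
    min_matched: int = 3
    frag_mz_tol: float = 0.01


@dataclass
class Annotation:
    """Outcome for one feature; ``record`` is None at level 4."""

    feature: Feature
    record: Optional[AMRTRecord]
    mass_error_ppm: float
    rt_error_min: float
    similarity: float
    matched_fragments: int
    msi_level: int
    shared_record: bool = False  # record also annotates another feature


def spectral_similarity(
    a: FragmentationSpectrum, b: FragmentationSpectrum, mz_tol: float = 0.01
) -> tuple[float, int]:
    """Cosine similarity on square-root intensities with greedy pairing.

    Candidate peak pairs within ``mz_tol`` are taken greedily in order of
    increasing m/z difference, each peak used at most once; the cosine is
    computed over the full peak vectors (unmatched peaks contribute to the
    norms only), so the result lies in [0, 1] and equals 1 only for matching
    spectra.  Symmetric and invariant to uniform intensity scaling.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    sa = np.sqrt(a.intensity)
    sb = np.sqrt(b.intensity)
    pairs = []
    for i, mza in enumerate(a.mz):
        lo = np.searchsorted(b.mz, mza - mz_tol)
        hi = np.searchsorted(b.mz, mza + mz_tol, side="right")
        for j in range(lo, hi):
            pairs.append((abs(mza - b.mz[j]), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    matched = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += sa[i] * sb[j]
        matched += 1
    norm = float(np.linalg.norm(sa) * np.linalg.norm(sb))
    return (dot / norm if norm > 0 else 0.0), matched


def assign_msi_level(mass_ok: bool, rt_ok: bool, ms2_ok: bool) -> int:
    """MSI confidence level from the three orthogonal evidence flags.

    Level 1 needs accurate mass plus RT plus MS2 against the authentic
    standard; level 2 keeps mass + MS2 (library-quality match without the
    orthogonal RT); everything else is unidentified (level 4).  Level 3
    (compound-class) is not assigned here.
    """
    if mass_ok and rt_ok and ms2_ok:
        return 1
    if mass_ok and ms2_ok:
        return 2
    return 4


def match_features(
    features: Sequence[Feature],
    amrt_db: Sequence[AMRTRecord],
    params: MatchParams = MatchParams(),
) -> list[Annotation]:
    """Annotate each feature against the AMRT database (one annotation each).

    Candidates share the feature's polarity and fall within the ppm window;
    the best candidate has the highest spectral similarity, ties broken by
    smaller |ΔRT| then record identity.  Records annotating more than one
    feature are flagged ``shared_record``.
    """
    if not amrt_db:
        raise ValueError("empty AMRT database")
    annotations: list[Annotation] = []
    for feature in features:
        best: Optional[tuple] = None
        for record in amrt_db:
            if record.precursor.polarity != feature.polarity:
                continue
            ppm = (feature.mz - record.precursor.mz) / record.precursor.mz * 1e6
            if abs(ppm) > params.mass_ppm:
                continue
            rt_err = feature.rt - record.rt
            if feature.ms2 is not None:
                sim, matched = spectral_similarity(
                    feature.ms2, record.spectrum, params.frag_mz_tol
                )
            else:
                sim, matched = 0.0, 0
            key = (-sim, abs(rt_err), record.compound.id, record.key)
            if best is None or key < best[0]:
                best = (key, record, ppm, rt_err, sim, matched)
        if best is None:
            annotations.append(
                Annotation(feature, None, np.nan, np.nan, 0.0, 0, 4)
            )
            continue
        _, record, ppm, rt_err, sim, matched = best
        ms2_ok = sim >= params.sim_threshold and matched >= params.min_matched
        rt_ok = abs(rt_err) <= params.rt_tol_min
        level = assign_msi_level(True, rt_ok, ms2_ok)
        if level == 4:
            annotations.append(
                Annotation(feature, None, ppm, rt_err, sim, matched, 4)
            )
        else:
            annotations.append(
                Annotation(feature, record, ppm, rt_err, sim, matched, level)
            )
    counts: dict[tuple, int] = {}
    for ann in annotations:
        if ann.record is not None:
            counts[ann.record.key] = counts.get(ann.record.key, 0) + 1
    for ann in annotations:
        if ann.record is not None and counts[ann.record.key] > 1:
            ann.shared_record = True
    return annotations


@dataclass
class IdentificationSummary:
    """Level-1 identification overlap across runs (machine-readable Venn)."""

    sets: dict[tuple, set]  # run label -> level-1 compound ids
    regions: dict[frozenset, int] = field(default_factory=dict)
    total: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": " & ".join("/".join(map(str, lab)) for lab in sorted(labels)),
                "n_labels": len(labels),
                "count": count,
            }
            for labels, count in sorted(
                self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["region", "n_labels", "count"])


def summarize_identifications(
    annotations_by_run: Mapping[tuple, Sequence[Annotation]],
) -> IdentificationSummary:
    """Count level-1 compounds per exclusive intersection region of the runs.

    Run labels are typically ``(column_mode, polarity)`` pairs.  For k runs
    all 2^k − 1 exclusive regions are reported (compounds level-1 in exactly
    that set of runs) plus the grand total of distinct compounds.
    """
    if not annotations_by_run:
        raise ValueError("no runs to summarize")
    sets = {
        label: {
            ann.record.compound.id
            for ann in anns
            if ann.msi_level == 1 and ann.record is not None
        }
        for label, anns in annotations_by_run.items()
    }
    return overlap_summary(sets)


def overlap_summary(sets: Mapping[tuple, set]) -> IdentificationSummary:
    """Exclusive-region counts (Venn arithmetic) over labelled id sets."""
    if not sets:
        raise ValueError("no sets to summarize")
    labels = list(sets)
    all_ids = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for mask in range(1, 2 ** len(labels)):
        subset = frozenset(
            labels[i] for i in range(len(labels)) if mask >> i & 1
        )
        inside = set(all_ids)
        for label in labels:
            if label in subset:
                inside &= sets[label]
            else:
                inside -= sets[label]
        regions[subset] = len(inside)
    return IdentificationSummary(sets=dict(sets), regions=regions, total=len(all_ids))


def write_feature_table(features: Sequence[Feature], path) -> None:
    pd.DataFrame(
        [
            {"id": f.id, "mz": f.mz, "rt": f.rt, "intensity": f.intensity,
             "polarity": f.polarity}
            for f in features
        ]
    ).to_csv(path, index=False)


def read_feature_table(path) -> list[Feature]:
    frame = pd.read_csv(path)
    return [
        Feature(
            mz=float(row["mz"]),
            rt=float(row["rt"]),
            intensity=float(row.get("intensity", 0.0)),
            polarity=str(row["polarity"]),
            id=str(row.get("id", i)),
        )
        for i, row in frame.iterrows()
    ]
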