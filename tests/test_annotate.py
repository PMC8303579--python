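"""Spectral similarity, MSI level assignment, and database matching."""

from __future__ import annotations

import numpy as np
import pytest

from amrtkit.annotate import (
    Feature,
    MatchParams,
    assign_msi_level,
    match_features,
    overlap_summary,
    spectral_similarity,
    summarize_identifications,
)
from amrtkit.library_model import FragmentationSpectrum, PrecursorSpecies

from conftest import make_record

PRECURSOR = PrecursorSpecies("[M+H]+", "positive", 181.070626)


def spec(peaks):
    return FragmentationSpectrum(PRECURSOR, 40.0, peaks)


class TestSpectralSimilarity:
    def test_identical_spectra_score_one(self):
        s = spec([(80.0, 100.0), (120.0, 300.0), (150.0, 50.0)])
        sim, matched = spectral_similarity(s, s)
        assert sim == pytest.approx(1.0)
        assert matched == 3

    def test_no_common_fragments_scores_zero(self):
        a = spec([(80.0, 100.0), (120.0, 300.0)])
        b = spec([(90.0, 100.0), (130.0, 300.0)])
        sim, matched = spectral_similarity(a, b)
        assert sim == 0.0 and matched == 0

    def test_hand_computed_sqrt_cosine(self):
        # sqrt intensities (2,1) vs (1,2): cosine = (2+2)/5 = 0.8
        a = spec([(100.0, 4.0), (200.0, 1.0)])
        b = spec([(100.0, 1.0), (200.0, 4.0)])
        sim, matched = spectral_similarity(a, b)
        assert sim == pytest.approx(0.8)
        assert matched == 2

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = spec(list(zip(np.sort(rng.uniform(50, 180, 8)), rng.uniform(10, 1000, 8))))
        b = spec(list(zip(np.sort(rng.uniform(50, 180, 6)), rng.uniform(10, 1000, 6))))
        ab, _ = spectral_similarity(a, b)
        ba, _ = spectral_similarity(b, a)
        assert ab == pytest.approx(ba)
        scaled = spec([(mz, 123.0 * i) for mz, i in a.peaks])
        sab, _ = spectral_similarity(scaled, b)
        assert sab == pytest.approx(ab)

    def test_empty_spectrum_scores_zero(self):
        assert spectral_similarity(spec([]), spec([(80.0, 1.0)])) == (0.0, 0)

    def test_matches_independent_greedy_cosine_oracle(self):
        """Cross-check against matchms CosineGreedy on sqrt-scaled spectra."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(42)
        for _ in range(20):
            na, nb = rng.integers(3, 12, 2)
            base = np.sort(rng.uniform(50, 400, na))
            a_peaks = list(zip(base, rng.uniform(1, 1000, na)))
            # half of b's peaks shifted onto a's m/z grid to force matches
            k = min(na, nb // 2)
            b_mz = np.sort(
                np.concatenate([
                    base[:k] + rng.uniform(-0.005, 0.005, k),
                    rng.uniform(50, 400, nb - k),
                ])
            )
            b_peaks = list(zip(b_mz, rng.uniform(1, 1000, nb)))
            ours, _ = spectral_similarity(spec(a_peaks), spec(b_peaks), mz_tol=0.01)
            sa = matchms.Spectrum(
                mz=np.array([p[0] for p in a_peaks]),
                intensities=np.sqrt([p[1] for p in a_peaks]),
                metadata={"precursor_mz": PRECURSOR.mz},
            )
            sb = matchms.Spectrum(
                mz=np.array([p[0] for p in b_peaks]),
                intensities=np.sqrt([p[1] for p in b_peaks]),
                metadata={"precursor_mz": PRECURSOR.mz},
            )
            theirs = float(CosineGreedy(tolerance=0.01).pair(sa, sb)["score"])
            assert ours == pytest.approx(theirs, abs=5e-3)


class TestAssignMSILevel:
    @pytest.mark.parametrize(
        "mass_ok,rt_ok,ms2_ok,level",
        [
            (True, True, True, 1),
            (True, False, True, 2),
            (True, True, False, 4),
            (True, False, False, 4),
            (False, True, True, 4),
            (False, False, False, 4),
        ],
    )
    def test_truth_table(self, mass_ok, rt_ok, ms2_ok, level):
        assert assign_msi_level(mass_ok, rt_ok, ms2_ok) == level


def feature_from(record, rt_offset=0.0, mz_ppm=0.0, with_ms2=True):
    return Feature(
        mz=record.precursor.mz * (1 + mz_ppm * 1e-6),
        rt=record.rt + rt_offset,
        intensity=1e6,
        polarity=record.precursor.polarity,
        ms2=record.spectrum if with_ms2 else None,
        id=record.compound.id,
    )


class TestMatchFeatures:
    def test_self_match_gives_level_one(self):
        db = [make_record(i, mass=150.0 + 11 * i, rt=2.0 + i) for i in range(5)]
        features = [feature_from(r) for r in db]
        annotations = match_features(features, db)
        assert all(a.msi_level == 1 for a in annotations)
        assert all(a.record.compound.id == a.feature.id for a in annotations)

    def test_rt_outside_window_demotes_to_level_two(self):
        db = [make_record(1, rt=5.0)]
        ann = match_features([feature_from(db[0], rt_offset=0.6)], db)[0]
        assert ann.msi_level == 2
        assert ann.rt_error_min == pytest.approx(0.6)

    def test_no_candidate_in_mass_window_is_level_four(self):
        db = [make_record(1, mass=200.0)]
        orphan = Feature(mz=350.123, rt=5.0, intensity=1.0, polarity="positive")
        ann = match_features([orphan], db)[0]
        assert ann.msi_level == 4 and ann.record is None

    def test_missing_ms2_is_level_four(self):
        db = [make_record(1)]
        ann = match_features([feature_from(db[0], with_ms2=False)], db)[0]
        assert ann.msi_level == 4

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            match_features([], [])

    def test_every_feature_annotated_once_levels_partition(self):
        db = [make_record(i, mass=150.0 + 13 * i, rt=2.0 + 0.7 * i) for i in range(6)]
        features = (
            [feature_from(r) for r in db[:3]]
            + [feature_from(db[3], rt_offset=1.0)]
            + [Feature(mz=900.0, rt=1.0, intensity=1.0, polarity="positive")]
        )
        annotations = match_features(features, db)
        assert len(annotations) == len(features)
        levels = [a.msi_level for a in annotations]
        assert sorted(levels) == [1, 1, 1, 2, 4]

    def test_jitter_beyond_mass_tolerance_loses_level_one(self):
        db = [make_record(i, mass=150.0 + 11 * i, rt=2.0 + i) for i in range(8)]
        clean = match_features([feature_from(r) for r in db], db)
        jittered = match_features(
            [feature_from(r, mz_ppm=8.0) for r in db], db, MatchParams(mass_ppm=5.0)
        )
        n_clean = sum(a.msi_level == 1 for a in clean)
        n_jittered = sum(a.msi_level == 1 for a in jittered)
        assert n_clean == len(db)
        assert n_jittered < n_clean

    def test_shared_record_flagged(self):
        db = [make_record(1, rt=5.0)]
        features = [feature_from(db[0]), feature_from(db[0], rt_offset=0.1)]
        annotations = match_features(features, db)
        assert all(a.shared_record for a in annotations)


class TestSummarize:
    def test_two_run_set_arithmetic(self):
        db = {cid: make_record(i, mass=150.0 + 11 * i)
              for i, cid in enumerate(["x", "y", "z"])}

        def level1(record):
            from amrtkit.annotate import Annotation

            return Annotation(
                feature=feature_from(record), record=record,
                mass_error_ppm=0.0, rt_error_min=0.0, similarity=1.0,
                matched_fragments=6, msi_level=1,
            )

        runs = {
            ("rp", "pos"): [level1(db["x"]), level1(db["y"])],
            ("hilic", "pos"): [level1(db["y"]), level1(db["z"])],
        }
        summary = summarize_identifications(runs)
        only_a = frozenset([("rp", "pos")])
        only_b = frozenset([("hilic", "pos")])
        both = frozenset([("rp", "pos"), ("hilic", "pos")])
        assert summary.regions[only_a] == 1
        assert summary.regions[only_b] == 1
        assert summary.regions[both] == 1
        assert summary.total == 3

    def test_single_run_single_region(self):
        summary = overlap_summary({("rp",): {"a", "b", "c"}})
        assert summary.regions[frozenset([("rp",)])] == 3
        assert summary.total == 3

    def test_disjoint_runs_no_intersection(self):
        summary = overlap_summary({("a",): {"x"}, ("b",): {"y"}, ("c",): {"z"}})
        for labels, count in summary.regions.items():
            assert count == (1 if len(labels) == 1 else 0)
        assert summary.total == 3
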