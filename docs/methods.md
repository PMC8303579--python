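# Methods

This note documents the models and procedures `amrtkit` implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## The AMRT workflow

An AMRT (Accurate Mass Retention Time) library is built from a commercial
standards plate set in four stages, then applied to sample runs:

1. **Manifest filtering.** A standard is analysable only if at least one of
   its default precursor species — protonated `[M+H]+` in positive mode,
   deprotonated `[M-H]-` in negative mode, proton mass 1.007276 Da — falls
   inside the instrument scan range, 70–1000 *m/z* inclusive. The filter is
   applied to the *species* m/z rather than the neutral mass because the
   scan window constrains what the detector sees, not the neutral molecule.
   Duplicate structures (equal `structure_key`) keep their first manifest
   occurrence; later copies are excluded with reason `duplicate`. The filter
   partitions its input exactly and is idempotent on the retained set.
2. **Best collision energy.** MS2 spectra are acquired per compound and
   polarity over the normalized-collision-energy (NCE) ladder 10–120 in
   steps of 10 (12 energies). An energy is *eligible* when its spectrum
   still contains the molecular ion (a peak within 10 ppm of the precursor
   at ≥ 1% of the base peak) and at least 3 fragments at ≥ 1% of the base
   peak. Among eligible energies the score
   `n_fragments + H/log(n_fragments)` is maximised, where `H` is the Shannon
   entropy of the fragment intensity distribution: the entropy term lies in
   [0, 1] so it only arbitrates between energies with equal fragment counts,
   favouring balanced spectra. Ties break to the **lower** energy (gentler
   fragmentation preserves the precursor). If no energy is eligible the
   argmax-score energy is reported flagged for manual review. All
   thresholds are relative to the base peak, so scoring is invariant to
   uniform intensity scaling.
3. **Chromatographic suitability.** Per compound a mass trace is the
   per-scan summed intensity within ±5 ppm of the precursor. The main peak
   is the most intense peak above a noise floor of 3× the median nonzero
   intensity. Metrics, all at sub-sample precision:
   - *width50* — full width at 50% of apex height, pass iff within
     1.8–3.6 s **inclusive**;
   - *symmetry50* — `100·min(A,B)/max(A,B)` with `A`, `B` the left/right
     half-widths at 50% height (100% = perfectly symmetric), pass iff
     **strictly above** 90%;
   - *tailing factor* — `(A5+B5)/(2·A5)` at 5% height (report-only);
   - *overloaded* — the contiguous region within 1% of the apex spans
     > 0.5 s, a flat top typical of column/detector overload (report-only).
   Conditions (column × mobile phase) are ranked by the **minimum over
   polarities** of the pass-both count — a column must serve both
   polarities, so it is only as good as its weaker mode — with ties broken
   by the sum and then the label.
4. **Mixtures, planning, annotation.** See below.

## Non-isobaric mixture design

For RT assignment the standards are pooled; two compounds may share a
mixture only if their precursor m/z values are ≥ δ apart in every polarity.
The default δ = 1.5 Da exceeds the 1.4 Da DDA isolation window, so mixture
members can never be co-isolated. Conflicts `|m_i − m_j| < δ` on the m/z
line form a unit-interval (indifference) graph, which is perfect: first-fit
assignment over compounds sorted by m/z colours it with exactly as many
mixtures as the largest pairwise-conflicting set, the provable minimum. The
test suite confirms optimality against an exact backtracking
graph-colouring oracle on random instances. A pair conflicting in *either*
polarity conflicts outright, because each mixture is injected once and
acquired in both polarities.

## Inclusion-list planning

Each library record becomes an inclusion entry (precursor m/z, RT window
±0.5 min, per polarity). The instrument services at most the loop count —
default capacity 5 — of co-eluting precursors per duty cycle, so entries
are split across files such that no file ever holds more than 5 temporally
overlapping windows. Entries sorted by window start are assigned first-fit;
because earlier entries start no later, concurrency inside a new entry's
window is maximal at its start, and the resulting file count equals
⌈max instantaneous concurrency / capacity⌉, which is optimal. Windows are
closed intervals: touching endpoints count as overlapping (conservative for
scheduling).

## Annotation and MSI levels

Candidates for a feature are records of the same polarity within 5 ppm.
Spectral evidence is a cosine over square-root-transformed intensities with
greedy fragment pairing at 0.01 Da (pairs taken in order of increasing m/z
difference, each peak used once; unmatched peaks contribute to the norms),
the standard library-search practice. MS2 evidence requires similarity
≥ 0.7 and ≥ 3 matched fragments; RT evidence requires |ΔRT| ≤ 0.5 min (the
same window used for inclusion-list scheduling). Levels: mass + RT + MS2
→ 1; mass + MS2 → 2; otherwise 4. Level 3 (compound-class) is not assigned
— it would require class ontologies out of scope here. The best candidate
is the highest similarity, ties broken by smaller |ΔRT| then record
identity; records annotating several features are flagged. Level-1 overlap
across runs is reported as exclusive intersection-region counts (a
machine-readable Venn diagram).

## Synthetic data: what it emulates

All generators are bitwise-deterministic under their seeds (independent
streams are derived per compound/energy/polarity via CRC-keyed sub-seeds).

**Standards manifest.** 634 entries emulating a 7-plate commercial library:
exactly 5 compounds whose species fall outside 70–1000 m/z in both
polarities, exactly 37 exact-structure duplicates of earlier in-range
entries, so filtering retains 634 − 5 − 37 = 592. Defect classes are
disjoint by construction, making that arithmetic exact. Neutral masses are
placed in clusters whose centres keep ≥ 3 Da spacing and whose members span
≤ 1.2 Da; exactly one cluster has 9 members and no larger cluster can arise,
so the mixture partitioner needs exactly 9 mixtures. The generator
self-validates all planted counts before returning, for every seed.

**Fragmentation model.** Each compound gets a planted optimal energy E* on
the ladder. The precursor survives activation with probability
`1/(1 + exp((E − E½)/s))`, `E½ = E* + 20`, `s = 8` NCE. Fragments (5–9 per
compound) follow Gaussian breakdown curves with centres within ±5 NCE of
E*, widths 5–8 NCE and heights 200–800 against a precursor height of 1000,
so at E* the spectrum is eligible by construction and fragment counts fall
off on both sides. Noise is multiplicative log-normal (σ = 0.05) on every
intensity plus Poisson(1) spurious peaks at 0.1–0.5% of the precursor
height — below the 1% presence floor near E*. The curve steepness matters:
breakdown widths much wider than the ladder step flatten the fragment-count
profile and let spurious peaks (measured against a shrinking base peak)
drag the selector toward higher energies. Under these defaults the selector
recovers E* within ±1 ladder step for ≥ 95% of compounds, as the
parameter-recovery tests verify. The model makes no claim of physical
realism — no isotope envelopes, charge states, or rearrangement chemistry.

**Chromatographic peaks.** The exponentially modified Gaussian (EMG,
Gaussian of width σ convolved with an exponential tail τ) via
`scipy.stats.exponnorm`; τ = 0 degenerates to a pure Gaussian, for which
width50 = 2√(2 ln 2)·σ ≈ 2.3548σ is the closed-form check. Test oracles
evaluate the analytic EMG on a 1 ms grid with root-finding for the
half-height crossings. The simulated LC run plants one EMG peak per
compound at a drawn RT over a 1–14 min gradient window, sampled at 6 Hz by
default.

**DDA runs.** Per surviving record (dropout optional) one MS1 feature at
the record's m/z and RT plus jitter, with MS2 granted cycle-by-cycle to the
top-5 most intense co-eluting untriggered features (dynamic exclusion keeps
triggered precursors off the list). A systematic +0.6 min RT shift pushes
every match just outside the ±0.5 min window and demotes all annotations to
level 2 — the rule-application check.

Passing tests on these generators demonstrate the *logic* of the workflow —
filtering arithmetic, optimality of the partitions and plans, threshold
semantics, recovery under the stated noise — not performance on real
instrument data, which adds matrix effects, ion suppression, RT drift and
chimeric MS2 spectra that the simulators deliberately omit.

## Numerical choices

- **Apex refinement.** The main-peak apex is the discrete argmax refined by
  a parabola through its two neighbours. The raw argmax is off the true
  apex by up to half a sampling interval, which by itself would bias the
  half-width split enough to push genuinely symmetric peaks below the
  strict 90% symmetry threshold at routine MS1 scan rates; the quadratic
  vertex removes that bias for any smooth peak top while staying cheap and
  testable. Half-height and 5%-height crossings use linear interpolation
  between bracketing samples.
- **Degenerate traces.** All-zero or monotone traces yield a "no peak"
  result, never an exception; a screen records such compounds as not found
  and continues.
- **Strict vs inclusive thresholds.** Symmetry is a strict lower bound
  ("above 90%"); width bounds are inclusive ("between 1.8 and 3.6 s").
- **Tie-breaks.** Best energy → lower energy; annotation candidates →
  smaller |ΔRT| then record id; mixture assignment → compounds sorted by
  m/z then id (making the partition independent of input order).
- **MSP dialect.** NIST-style blocks with `Name`, `Formula`, `PrecursorMZ`,
  `Precursor_type`, `Charge`, `Ion_mode`, `Collision_energy`,
  `Comment: RT=<min> column=<mode> id=... well=... structure_key=...
  neutral_mass=...`, `Num Peaks`; unknown header fields round-trip through
  an annotations map. Numeric fields are serialized at six decimals, so
  round trips are identities to 1e-4 relative tolerance.
- **mzML.** Reading and writing are a minimal implementation (centroided
  MS1 spectra, 32/64-bit float arrays, optional zlib, scan start times in
  minutes or seconds) sufficient for exchanging simulated runs.
- **Units.** RT in minutes everywhere; peak widths and trace times in
  seconds; energies are dimensionless NCE values; masses in Da.

## Problem sizes

The shipped tests and the acceptance script run the full 634-compound
manifest, 200-compound energy-recovery batches, 100-record DDA runs, and
100-instance optimality sweeps with brute-force oracles at n ≤ 12 — sizes
chosen so each suite stage completes in seconds while still exercising every
planted structure at full scale.

## Known limitations

- Duplicate detection relies on an exact `structure_key`; near-duplicates
  (salts, stereoisomers with distinct keys) are retained.
- The energy-selection score is one reasonable operationalisation of
  "molecular ion plus sufficient fragments"; vendor library-builder
  algorithms are proprietary and may rank differently near ties.
- The mixture partitioner's optimality argument assumes conflicts along an
  m/z line per polarity (true for single default species per polarity);
  with arbitrary multi-adduct conflict sets first-fit remains valid but is
  not guaranteed minimum.
- Chromatographic screening evaluates one main peak per trace; co-eluting
  isomers sharing a m/z window are not deconvolved.
- MSI level 3 is not assigned; quantification, cross-run alignment and
  isotope-pattern scoring are out of scope.
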