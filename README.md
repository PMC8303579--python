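# amrtkit

Tools for building and applying an **Accurate Mass Retention Time (AMRT)
library** for LC-HRMS untargeted metabolomics.

Untargeted metabolomics can detect thousands of features in plasma or urine,
but confident identification requires matching each feature against authentic
standards measured under identical analytical conditions. An AMRT library
pairs every standard with its precursor *m/z*, its retention time (RT) on a
given column chemistry, and a reference MS2 spectrum acquired at that
compound's optimal collision energy. With all three pieces of orthogonal
evidence a feature reaches **MSI level 1** (Metabolomics Standards Initiative
identification: accurate mass + RT + MS2 against a pure standard); accurate
mass + MS2 without RT agreement is level 2; anything less is unidentified
(level 4).

`amrtkit` implements the whole library-building and application workflow for
laboratories that start from a commercial standards plate set:

- **Manifest filtering** (`amrtkit.library_model`) — screen the standards
  manifest against the instrument scan range (a compound is analysable only
  if its protonated or deprotonated species falls inside 70–1000 *m/z*) and
  remove duplicate structures. Export/import the library as NIST-style
  `.msp` text.
- **Best collision energy** (`amrtkit.nce`) — acquire (or simulate) MS2
  spectra over a normalized-collision-energy ladder (10–120 in steps of 10)
  and select, per compound and polarity, the energy whose spectrum retains
  the molecular ion while giving a rich, balanced fragment set
  (score = fragment count + normalized spectral entropy; ties go to the
  gentler energy).
- **Chromatographic suitability** (`amrtkit.chromatography`) — per-compound
  mass traces, peak width at 50% height (pass: 1.8–3.6 s inclusive),
  half-width symmetry (pass: strictly above 90%), tailing factor, overload
  flag; condition ranking that prefers columns performing well in *both*
  polarities.
- **Non-isobaric mixtures** (`amrtkit.mixtures`) — partition the standards
  into the provably minimum number of mixtures such that no two compounds in
  a mixture are within 1.5 Da in either polarity (so the 1.4 Da DDA isolation
  window never co-selects mixture members during RT assignment).
- **Inclusion-list planning** (`amrtkit.planner`) — split the library into
  data-dependent acquisition (DDA) inclusion files with ±0.5 min RT windows,
  never exceeding the instrument loop count (5) in co-eluting precursors per
  file; the file count is the optimal ⌈max concurrency / capacity⌉.
- **Annotation** (`amrtkit.annotate`) — match sample-run features against the
  AMRT database (5 ppm, ±0.5 min, √-intensity greedy cosine ≥ 0.7 with ≥ 3
  matched fragments), assign MSI levels, and summarize level-1 overlaps
  across column × polarity runs.
- **Synthetic data** (`amrtkit.simulate`) — seeded generators for every
  input: a 634-entry manifest with planted defects, energy-dependent
  fragmentation with a planted optimal energy, exponentially-modified-
  Gaussian (EMG) chromatographic peaks, and full synthetic DDA runs.

## Worked example

The `amrt` command chains the workflow. Starting from the synthetic
standards manifest:

```bash
$ amrt --seed 42 simulate --out manifest.csv
simulate: wrote 634 compounds to manifest.csv (seed 42)

$ amrt filter --manifest manifest.csv
filter: 634 input, 592 retained, 5 out_of_mass_range, 37 duplicate -> filter_report.csv

$ amrt design-mixtures --manifest manifest.csv
design-mixtures: 9 mixtures over 592 compounds (delta 1.5 Da) -> mixtures.csv

$ amrt --seed 1 build-library --manifest manifest.csv --limit 30 --out lib.msp
build-library: 30 records (positive, reversed_phase) -> lib.msp

$ amrt plan-inclusion --library lib.msp --out-dir incl
plan-inclusion: 30 entries -> 2 files (capacity 5, window ±0.5 min) in incl

$ amrt --seed 2 annotate --library lib.msp --out ann_rp.csv
annotate: 30 features, levels {1: 30} -> ann_rp.csv
```

Reading the numbers: of 634 manifest entries, 5 have no ionizable species
inside the 70–1000 *m/z* scan window and 37 duplicate an earlier structure,
leaving 592 compounds to characterize. Those 592 need 9 mixtures for RT
assignment because the most crowded isobaric cluster holds 9 compounds —
no smaller partition exists. A 30-compound positive-mode sub-library needs
2 inclusion files (at most 5 precursors may co-elute per file), and
annotating a simulated DDA run of that library recovers all 30 compounds at
MSI level 1.

The same operations are available as library functions:

```python
from amrtkit import (ManifestProfile, generate_manifest, filter_library,
                     partition_non_isobaric, species_mz_table)

manifest = generate_manifest(ManifestProfile(seed=42))
report = filter_library(manifest, mass_range=(70.0, 1000.0))
plan = partition_non_isobaric(species_mz_table(report.retained), delta=1.5)
print(report.n_retained, plan.n_mixtures)   # 592 9
```

## Layout

```
src/amrtkit/
  library_model.py   compounds, AMRT records, filters, MSP + manifest I/O
  nce.py             energy ladder, spectrum scoring, best-energy selection
  chromatography.py  traces, peak metrics, screening, condition ranking
  mixtures.py        non-isobaric partitioning + validator
  planner.py         inclusion-list interval partitioning
  annotate.py        similarity, MSI levels, matching, overlap summaries
  simulate.py        seeded generators for all pipeline inputs
  mzml_io.py         minimal mzML read/write for MS1 runs
  cli.py             the `amrt` command
docs/methods.md      models, parameters, numerical choices, limitations
```
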