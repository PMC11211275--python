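# fibriltrace

Characterization pipeline for amyloid-beta 1-42 fibrillogenesis, combining
three complementary measurements of the same aggregation process:

- **SERS spectroscopy** — surface-enhanced Raman spectra report backbone
  conformation. The amide I envelope (1640–1690 cm⁻¹) is deconvolved into
  pseudo-Voigt sub-bands (α-helix ≈ 1650, β-sheet ≈ 1670, random coil
  ≈ 1680 cm⁻¹) whose relative areas are the secondary-structure fractions.
- **AFM morphometry** — atomic force topographs of the aggregates on mica.
  Objects are segmented, skeletonized and measured (contour length, crest
  height, width); the lateral tip-dilation artifact is removed with a
  spherical-tip geometric correction so true widths are recovered.
- **ThT kinetics** — thioflavin-T fluorescence over a 48-hour plate read
  follows a Boltzmann sigmoid; the fit yields the lag/exponential/plateau
  phase boundaries of the aggregation run.

A timeline layer integrates the three channels across seven incubation
timepoints (0, 60, 120, 240, 480 min, 24 h, 48 h) and detects the
**β transition**: the earliest timepoint from which the β-sheet fraction
strictly dominates both α-helix and coil and keeps doing so at every later
timepoint.

Because raw instrument data for this system are not publicly deposited, the
package ships a seeded synthetic generator (`fibriltrace.synthgen`) that
emulates all three instruments — noisy replicate spectra with cosmic-ray
spikes and a polynomial baseline, tip-dilated topographs on a rough
substrate, and quintuplicate plate reads — so every analysis routine can be
validated by round-trip parameter recovery. See
[docs/methods.md](docs/methods.md) for models, parameters and limitations.

## Worked example

Simulate the freshly-dissolved (0 min) timepoint, image it through an
8-nm AFM tip, and recover the protofibril morphometry:

```python
from fibriltrace import (
    TipModel, make_timeline_preset, measure_all_objects,
    segment_objects, synthgen,
)

preset = make_timeline_preset("0min")
cfg = synthgen.field_config_for(preset, seed=2, shape=(1024, 1024))
truth, observed = synthgen.generate_topograph(cfg, seed=3)

labels = segment_objects(observed)
measures = measure_all_objects(observed, labels, tip=TipModel(cfg.tip_radius))
protos = [m for m in measures if m.object_class == "protofibril"]
print(len(protos), "protofibrils")
```

Running `python examples/02_afm_morphometry.py` (which does the above plus
width correction and network coverage) prints:

```
field: 1024x1024 px at 2 nm/px, tip radius 8 nm
substrate RMS roughness: 0.206 nm (plane-subtracted, objects included but sparse)
segmented 34 objects
  oligomer     n= 10  length    2.5 nm  width(corr) 13.35 nm  height  1.24 nm
  protofibril  n= 24  length   88.4 nm  width(corr)  7.73 nm  height  0.50 nm
tip broadening removed: 11.7 nm measured -> 7.7 nm corrected
protofibril network coverage: 0.0005 (largest connected protofibril component / field area)
```

The full seven-timepoint integration (`python examples/04_full_timeline.py`)
produces:

```
 timepoint  alpha%   beta%   coil%  protofib  fibrils  coverage
      0min    18.4    31.7    49.9        24        0    0.0005
     60min    24.2    32.1    43.7        28        0    0.0017
    120min    29.8    33.7    36.5        34        0    0.0074
    240min    23.8    37.9    38.3        22        8    0.0016
    480min    17.8    47.8    34.4        14        9    0.0011
       24h    12.9    57.3    29.8         6       10    0.0003
       48h     9.9    64.8    25.3         2       12    0.0002

beta transition detected at: 480min
ThT phase onsets: exponential 8.01 h, plateau 15.00 h
```

The other examples walk through the individual channels:
`examples/01_tht_kinetics.py` (plate read → phase onsets) and
`examples/03_amide_deconvolution.py` (raw replicates → structure fractions).

## Command line

The `fibriltrace` command mirrors the pipeline stages:

```bash
fibriltrace simulate --timepoint 240min --seed 0 --outdir raw/   # write synthetic raw data
fibriltrace sers  --in raw/sers --out avg.csv                    # preprocess + average replicates
fibriltrace amide --in avg.csv --out amide.json                  # amide I deconvolution
fibriltrace afm   --in raw/topo_observed.tif --out objects.csv   # segment + measure
fibriltrace tht   --in raw/tht_plate.csv --out kinetics.json     # sigmoid fit + onsets
fibriltrace run-all --seed 0 --outdir out/                       # full timeline + report
```

## Reproducing results

The headline numbers are recovered from scratch (no stored fixtures) by the
acceptance script:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This regenerates the synthetic inputs with seeds derived from `--seed`,
runs the full measurement pipeline, and writes one JSON entry per target:
ThT exponential/plateau onsets (t1/t2, expected 8 h / 15 h), mean
protofibril skeleton length and tip-corrected width on the 0-min field
(t3/t4, 85 nm / 8 nm), mean fibril crest heights at 240 min and 24 h
(t5/t6, 4.2 nm / 4.7 nm), and empty-substrate RMS roughness (t7, 0.2 nm).

The test suite (≈ 20 s) covers the same recoveries plus unit and property
tests for every module:

```bash
python -m pytest -q tests/
```

## Repository layout

```
src/fibriltrace/     library (sers, amide, afm, tht, timeline, presets, synthgen, io, cli)
tests/               unit, property and acceptance tests
examples/            narrative walk-throughs of each channel
scripts/acceptance.py  seeded end-to-end target recovery
docs/methods.md      models, parameters, numerical choices, limitations
```
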