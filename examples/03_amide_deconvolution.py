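"""SERS amide I deconvolution: from raw replicates to structure fractions.

The amide I envelope (1640-1690 cm^-1) is a sum of heavily overlapping
sub-bands: alpha-helix near 1650, beta-sheet near 1670 and random coil
near 1680 cm^-1. Their relative areas are the secondary-structure
fractions. This script simulates 50 raw replicate acquisitions for a late
(24-h) timepoint, runs the preprocessing chain (despike, smooth, baseline,
normalize, average) and deconvolves the amide I band with pseudo-Voigt
components that share one line shape — the constraint that makes this
10-cm^-1-spaced decomposition identifiable at realistic noise.
"""

from fibriltrace import (
    fit_amide_band,
    make_timeline_preset,
    preprocess_and_average,
    synthgen,
)

# --- simulate raw replicates --------------------------------------------
preset = make_timeline_preset("24h")
cfg = synthgen.spectrum_config_for(preset)
replicates = synthgen.generate_spectrum_set(cfg, seed=5)
print(f"simulated {len(replicates)} replicates, "
      f"{replicates[0].shift.size} points each "
      f"({replicates[0].shift[0]:.0f}-{replicates[0].shift[-1]:.0f} cm^-1)")

# --- preprocess: despike, smooth, subtract baseline, normalize, average --
avg = preprocess_and_average(replicates)
print("preprocessed and averaged to one spectrum")

# --- deconvolve the amide I band ----------------------------------------
fit = fit_amide_band(avg, seed=5)
print(f"fit converged: {fit.converged}, residual rms {fit.residual_rms:.4g}")
for name in ("alpha", "beta", "coil"):
    c = fit.components[name]
    print(f"  {name:6s} center {c.center:7.1f} cm^-1  fwhm {c.fwhm:5.1f}  "
          f"area {c.area:8.1f}")

alpha, beta, coil = fit.fractions
print(f"secondary structure: alpha {alpha:.1f}% / beta {beta:.1f}% / coil {coil:.1f}%")
print("after 24 h of incubation the beta-sheet band dominates, as expected "
      "for mature amyloid fibrils")

truth = preset.structure_fractions
print("generator truth:     alpha {:.1f}% / beta {:.1f}% / coil {:.1f}%".format(
    *(100 * f for f in truth)))
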