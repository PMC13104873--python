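# memquant

Simulation and quantification pipeline for focus-stabilized two-plane
fluorescence imaging of receptor–arrestin recruitment at the plasma membrane.

## The problem

Watching a cytoplasmic adaptor protein (arrestin-2) move to the plasma
membrane after a G-protein-coupled receptor (here, the muscarinic M2 receptor)
is activated requires imaging the *same* two axial planes of a living cell —
the basolateral membrane and a cross-section ~2.3 µm deeper — every few
minutes for an hour. Thermal drift and stage backlash on a conventional
motorized objective make that impossible at the required precision, so the
imaging system tracks a fiducial reference bead on the coverslip: a library
of bead images at known axial positions acts as a lookup table, and a
correction loop keeps each revisited plane within tens of nanometers.

`memquant` implements the complete quantitative machinery around that
experiment as testable, simulation-backed code:

- **Synthetic data generators** for every input, with ground truth: bead
  z-stacks versus reported stage position, stage traces with drift/backlash,
  and two-fluorophore spectral image time series of a recruiting cell.
- **Axial calibration** — the stage under-reports true focal displacement;
  the correction factor (true/reported ≈ 1.17) is measured two ways from
  beads of known radius, using symmetric double-Gaussian width fits and 2D
  Gaussian localization of a glass-surface impurity.
- **Focal tracking** — reference-library lookup (zero-normalized
  cross-correlation, sub-spacing parabolic refinement) plus a deadband
  proportional controller, benchmarked on the five-z-scan protocol.
- **Spectral unmixing** — per-pixel linear decomposition of 16-channel
  emission spectra into mEGFP-like and mCitrine-like abundances.
- **Membrane quantification** — the core analysis: per-row curvature
  correction of a membrane cross-section ROI, column-mean profiles, and
  model fits

  ```
  f(x) = A exp(-(µ-x)²/2σ²)                        (membrane ridge)
  g(x) = L + (U-L)/(1 + (x/C)^B)                   (cytoplasmic pool)
  ```

  with µ fixed by the alignment and C fixed from untreated frames. The
  membrane signal I_Gauss = Aσ√(2π) is converted to an effective
  concentration by dividing by the fluorophore's monomeric brightness
  ε_proto and the squared-PSF area factor ∬PSF²(0,y,z) dy dz.
- **Brightness calibration** — ε_proto = Θ·∭PSF² dV from the slope Θ of a
  dilution series of purified fluorophore.

## Worked example

```python
import numpy as np
from memquant import (CellGroundTruth, generate_cell_timeseries,
                      quantify_recruitment)

truth = CellGroundTruth.default(n_timepoints=14, interval_s=300.0)
pairs, truth = generate_cell_timeseries(truth, seed=5)
scans = [(t, cross) for t, (baso, cross) in zip(truth.times_min, pairs)]
res = quantify_recruitment(scans, truth.spectra, truth.epsilon,
                           truth.area_factor_um2)
arr = [round(p.concentration, 1) for p in res["points"]
       if p.protein_label == "mCitrine"]
print(arr)
```

prints (concentrations in relative units, one per 5-minute scan; agonist
added just before the third scan):

```
[24.4, 24.1, 25.0, 453.7, 777.6, 1023.1, 1210.0, 1350.2, 1457.2,
 1535.5, 1599.8, 1648.8, 1681.7, 1706.9]
```

The first three values are the pre-/at-treatment baseline; the subsequent
rise is membrane-recruited arrestin, saturating as the cytoplasmic pool
empties. The receptor series from the same run stays flat (fitted relative
change < 0.1%), and the sum of membrane and cytoplasm arrestin signal is
constant to within a few percent — recruitment moves protein between
compartments without creating it.

A CLI mirrors the stages (`memquant simulate beads|trace|cells`,
`calibrate`, `track`, `unmix`, `coloc`, `profile`, `brightness`); see
`memquant --help`.

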