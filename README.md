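# mtlmorph

Longitudinal surface diffeomorphometry of medial-temporal-lobe (MTL)
structures, and 3D reconstruction of section-based tau pathology — as one
tested Python package.

Neurodegeneration in early Alzheimer's disease is measured in vivo as
*atrophy rate*: percent loss of amygdala volume or entorhinal/transentorhinal
cortical thickness per year, estimated from each subject's series of
segmented MRI surfaces.  Postmortem, the underlying pathology is measured
directly as the density of neurofibrillary tangles (NFTs, count per mm² of
tissue) on stained serial sections.  `mtlmorph` implements both measurement
chains and the machinery to place them in a common space:

- **Longitudinal arm** — large-deformation diffeomorphic metric mapping
  (LDDMM) by geodesic shooting: each subject's scan series S_{t₁},…,S_{tₖ}
  is fitted by a single geodesic flow φ_t of a common hypertemplate,
  parameterized by one initial momentum ρ at an insertion time t*
  (minimizing ‖ρ‖²_K + Σᵢ‖S_{tᵢ} − φ_{tᵢ}·S^{temp}‖²_W with a varifold
  attachment ‖·‖_W).  The fitted trajectory filters measurement noise out of
  per-scan volumes/thicknesses; per-subject rates are least-squares slopes
  in %/year, and per-triangle markers J_v(s) (log-determinant Jacobian of
  the first-to-last-scan map per year) feed linear fixed-effects models
  H₀: J_v = α + γ·sex + δ·log-ICV + κ·age vs H₁ adding a group term, with
  familywise error controlled by permutation of the max statistic
  S* = max_v (ℓ_v^{H1} − ℓ_v^{H0}).  ROC analysis discriminates groups by
  rate.
- **Histology arm** — serial 2D sections are registered to a 3D volume
  through slice-projection operators and per-slice smooth 2D maps, with a
  scattering-transform contrast predictor and EM-based artifact weighting;
  tangles are detected (pluggable per-pixel classifier, classical blob
  detector by default), counted per mm² of Otsu foreground, carried as
  weighted particle measures {xᵢ, wᵢ, fᵢ} into reference space, and
  smoothed onto subregion surfaces in the Laplace–Beltrami eigenbasis
  (coefficient shrinkage 1/(1+kλᵢ), k = 2).
- **Synthetic module** — seeded generators for longitudinal surface cohorts
  (known per-subject atrophy rates, covariates) and serial-section phantoms
  (known warps, blob positions, densities, artifacts), so every stage is
  testable end-to-end without any data download.

See `docs/methods.md` for the model details, parameter choices, and
limitations.

## Worked example

Fit one synthetic subject's scan series and read off its atrophy rate:

```python
import numpy as np
from mtlmorph import synthetic as syn, longitudinal as lng
from mtlmorph.surface import surface_volume

spec = syn.CohortSpec(
    groups={"progressing": syn.GroupSpec(2, rate_mean=11.6, rate_sd=0.0)},
    scans_range=(4, 4), period_range=(2.0, 2.0), noise_level=0.05, seed=3)
cohort = syn.generate_longitudinal_cohort(spec)
sub = cohort.subjects[0]

series = lng.SeriesInput(sub.subject_id, sub.times_years, sub.surfaces,
                         cohort.hypertemplate)
traj = lng.fit_series(series, syn.cohort_kernel_params(cohort))
rate = lng.subject_rate(traj.fitted_measures, traj.times_years)
print(f"true {sub.true_rate:.2f} %/y  raw "
      f"{lng.subject_rate([surface_volume(s) for s in sub.surfaces], sub.times_years):.2f} %/y"
      f"  fitted {rate:.2f} %/y")
```

Output (seed 3):

```
true 11.60 %/y  raw 11.44 %/y  fitted 12.15 %/y
```

The subject's true volume declines 11.6 %/year; raw per-scan volumes carry
5% vertex noise, and the geodesic fit recovers the rate to ~0.5 percentage
points for a single subject (cohort means recover to ~0.2, see the
validation studies) while producing smooth, vertex-corresponded surfaces at
every scan time — the basis for the per-triangle group statistics.

A config-driven CLI covers both arms at any scale:

```bash
mtlmorph run src/mtlmorph/configs/demo.yaml     # tiny end-to-end demo
mtlmorph simulate-cohort --params '{"seed": 1, "n_per_group": 4}'
mtlmorph detect
```

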