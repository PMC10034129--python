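# Methods

`mtlmorph` implements two computational arms for studying medial-temporal-lobe
(MTL) neurodegeneration: (1) longitudinal surface diffeomorphometry — fitting
smooth geodesic trajectories through each subject's series of segmented
surfaces to estimate atrophy rates and per-triangle deformation markers, with
permutation-based familywise error control and ROC discrimination; and (2) 3D
reconstruction of section-based pathology — registering serial 2D stained
sections to a 3D reference volume, detecting and counting tangle-like
objects, and transporting the resulting density measures onto subregion
surfaces with Laplace–Beltrami smoothing.  A synthetic-data module generates
seeded inputs with known ground truth for every stage, standing in for
clinical MRI cohorts and postmortem section stacks.

## Geodesic shooting (LDDMM)

Deformations are flows of smooth time-varying velocity fields.  With a
Gaussian reproducing kernel K(x, y) = exp(−|x−y|²/2σ_V²) and momenta p_i on
control points x_i (the template vertices), the velocity field is
v_t(·) = Σ_i K(·, x_i(t)) p_i(t), and the geodesic is determined entirely by
the initial momentum via the canonical (EPDiff) equations

    ẋ_i = Σ_j K_ij p_j,      ṗ_i = (1/σ_V²) Σ_j (p_i·p_j) K_ij (x_i − x_j),

which conserve the Hamiltonian H = ½ Σ_ij p_i·p_j K_ij.  The system is
integrated with RK4 (10 steps on [0,1] for pairwise matching; fewer,
per-interval steps in the longitudinal fit).  Conservation is monitored:
relative drift stays below 1e−3 in the tested regimes.

Gradients of endpoint functionals with respect to the initial momentum are
exact reverse-mode derivatives of the *discrete* integrator
(discretize-then-optimize): the vector–Jacobian products of the canonical
right-hand side are hand-derived from the Hamiltonian's second derivatives
and chained backward through each RK4 stage.  They match central finite
differences to ~1e−9 (tested).  All pairwise operations are written as
matrix products (no N²×3 temporaries), and the optimization loops run in
single precision with double-precision accumulation at the optimizer
interface; this is purely a speed choice and changes fitted rates by far
less than the reported tolerances.

**Surface attachment.** Surfaces are compared with an orientation-insensitive
varifold metric built from cell centers and area-weighted normals:
⟨S, S′⟩ = Σ_fg exp(−|c_f−c_g|²/2σ_W²)(N_f·N_g)²/(|N_f||N_g|).  Zero-area
cells are excluded.  Defaults: σ_V = 0.25× and σ_W = 0.1× the structure's
bounding-box diagonal; for laminar two-sheet structures σ_W = 0.05× the
diagonal, because the matching kernel must be narrower than the inter-sheet
separation to resolve thickness change.  The data-attachment weight is
normalized by the template's mean squared cell area so the default transfers
across structure sizes.

**Pairwise matching** minimizes |p₀|²_K + λ·varifold² by L-BFGS with the
exact adjoint gradient; accepted iterates have non-increasing energy.
Recovery tests: a 1 mm translation of an 8 mm sphere is matched to ~0.003 mm
mean vertex error; a 0.9 uniform scale to <0.1% volume error.

## Longitudinal trajectory fitting

Each subject's scans S_{t1},…,S_{tk} (k ≥ 3, raw years affinely mapped to
[0.05, 0.95]) are fitted by one geodesic through a subject-specific template
inserted at a time t*: a single interface momentum ρ shoots the template
backward over scans before t* (momentum −ρ) and forward over scans at or
after t*, and the objective is |ρ|²_K plus the varifold mismatch at every
scan.  Gradients chain through the segment boundaries by reverse
accumulation, injecting each checkpoint's attachment gradient during the
backward sweep.

The common hypertemplate is first registered (pairwise match) onto the scan
at the insertion time, giving the subject template; template registration
and trajectory fit can be alternated (block-coordinate rounds), although one
round suffices on the phantoms used here (monitored by the objective).

**Insertion time.**  The default picks t* as the scan whose surface is
closest in varifold distance to all others (a medoid); a full grid search
over the normalized scan times, refitting ρ for each candidate and keeping
the lowest objective, is available (`tstar="search"`).  On noiseless and
noisy phantoms the two choices produce rate estimates differing by far less
than the reported tolerances, and the medoid costs one fit instead of k+1.

**Measures and rates.**  Smoothed surfaces at scan times are read off the
fitted flow; the per-scan measure is the enclosed volume (closed surfaces)
or the composite laminar thickness (two-sheet structures).  The per-subject
rate is the ordinary least-squares slope of measure versus years, expressed
as percent of the fitted baseline per year, reported positive for loss.
Per-triangle deformation markers are the log-determinant of the 3D Jacobian
of the composed first-to-last-scan map at cell centers (obtained by
integrating dA/dt = Dv·A along the flow), divided by the elapsed years;
percent area change per year is reported alongside.  Markers live on the
hypertemplate's cells and are therefore corresponded across subjects.

**Thickness.**  The inner sheet is advanced along its own recomputed normals
in 0.05 mm steps until it crosses the outer sheet (distance to the outer
surface computed exactly per point against all triangles); the accumulated
path length is the thickness.  A closed-form fallback (ray cast along the
vertex normal) is selectable and agrees within 5% on laminar phantoms.
Parallel flat sheets and concentric hemispheres are recovered to ≤2% / ≤5%.

## Group statistics

Per vertex, nested Gaussian linear models (intercept + sex + log-ICV + age,
with/without a group indicator) are fitted by OLS; the statistic is the
profiled log-likelihood ratio S_v = (n/2)·log(RSS₀/RSS₁), capped at a large
sentinel for numerically perfect fits.  Familywise error is controlled by
permuting H₀ residuals at the subject level (one permutation shared across
vertices per replicate, preserving spatial dependence), reconstructing
responses, refitting, and thresholding observed S_v at the 95th percentile
q* of the permutation distribution of S* = max_v S_v.  β enters two-sided
(unsigned likelihood ratio).  1000 permutations by default, seeded; refits
use precomputed orthonormal design bases, so a 500-permutation test on
34×200 markers takes ~30 ms.  The residual-permutation scheme is approximate
at very small n; at n = 34 the global p-value is uniform to KS tolerance
(tested over 500 replicates).

ROC discrimination of per-subject rates uses the midrank Mann–Whitney AUC
and picks the operating threshold maximizing Youden's J, ties broken toward
higher specificity.

## Synthetic cohorts

The volume structure is a superellipsoid (default semi-axes 9×6×5 mm,
exponent 2.5, icosphere-subdivision mesh, 642 vertices) standing in for an
amygdala; the thickness structure is a pair of gently curved offset sheets
(14×10 mm, 2.5 mm apart) standing in for the entorhinal/transentorhinal
laminae, with vertex labels for sheet membership and subregion.  Per
subject, a true percent rate per year is drawn from the group's Normal
distribution, and the measure declines *linearly in time* — volume via a
(optionally spatially weighted) radial scaling field about the centroid,
thickness via the sheet offset — so the printed percent-change formula and
the OLS rate recover the drawn rate exactly in the noiseless case.  Vertex
correspondence is exact by construction (no re-meshing).  Measurement noise
is i.i.d. Gaussian per vertex coordinate, scaled to a fraction of the
structure scale (mean centroid distance, or sheet thickness).  Covariates:
sex ~ Bernoulli, age ~ Normal, log-ICV ~ Normal, with group demographics
following the three-group design (33/16/18; rates 1.5±2.0, 6.8±4.1,
11.6±5.8 %/y volume; 1.1±1.6, 3.8±1.9, 7.0±3.4 %/y thickness).  All
randomness flows from one integer seed; per-subject substreams are derived
by counter.

For recovery experiments the per-group rates can be drawn *antithetically*
(paired μ±ε draws): each rate is still marginally Normal(μ, σ), but the
cohort's drawn mean equals μ exactly for even group sizes, so the
experiment measures pipeline error rather than finite-sample draw noise.
This is the default in the bundled recovery studies.

What the generator does **not** emulate: MRI contrast, bias fields, scanner
or segmentation-protocol idiosyncrasies, re-meshing variability (real scans
are segmented and meshed independently per timepoint), and anatomically
realistic shape variability.  Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the assumed noise model, not
performance on clinical data.

## Histology phantom and reconstruction arm

The phantom builds a companion volume of elliptical "tissue" cross-sections
partitioned into four compartments (standing in for amygdala, ERC, CA1,
subiculum), with softened edges and a smooth intra-tissue texture field
(σ=5 px, amplitude 0.08) — real tissue is not flat, and the texture is what
registration locks onto.  Sections are the volume's slices at the given
z-positions, warped by known smooth random in-plane displacement fields,
with tangle "blobs" (Gaussian peaks, σ=1.2 px, amplitude 0.45) planted at
Poisson counts from region densities (count/mm², optional rostral-high
axial gradient), optional artifact patches, and additive noise.  Staining
differences are emulated by amplitude scaling or by proportional thinning
of planted blobs (for calibration-ratio studies).  A zero-deformation,
zero-noise phantom reproduces its volume slices exactly.

**Registration** (`register_stack`) alternates per slice: an affine contrast
predictor on wavelet-scattering channels (depth 2, 4 orientations × 2
scales + lowpass, 13 channels; PCA to 7 components computed on
foreground-weighted, per-channel-standardized data — without
standardization the large-magnitude modulus channels squeeze out the
low-contrast intensity direction), then a kernel-parameterized smooth 2D
map (Gaussian kernel σ=0.5 mm, control grid at 0.5 mm, integrated in 5
steps) updated by gradient descent with backtracking.  Pixels are
soft-classified by a three-class 1D Gaussian-mixture EM (background /
foreground tissue / artifact-object); the foreground posterior, minimum-
filtered so object halos are suppressed with their cores, weights both the
contrast fit and the matching term.  Foreground is identified as the
non-background component maximizing mixing/√variance (tissue is populous
*and* tight; a broad component sweeping up edges and objects can carry more
mass), with near-ties resolved toward the lower mean.  Class weights are
computed once from the raw sections, so the tracked objective is fixed and
non-increasing across rounds.  The 3D map is held at identity at this desk
scale (phantoms are generated without one; real use would precede this
with `rigid_align`).  On phantoms with ~1.3 px RMS true warps, slice maps
are recovered to <1 px RMS and mapped region labels overlap ground truth at
Dice ≥ 0.95.

**Detection** is pluggable; the default scores each pixel by a
scale-normalized Laplacian-of-Gaussian blob response divided by the Otsu
tissue/background contrast gap, through a logistic.  The contrast gap is
used because it is stable across sections and stacks, whereas noise- or
spread-based normalizations drift with the number of objects present,
which biases between-stack count ratios.  Instances are watershed-split
from local-maximum seeds above p=0.5; densities are counts per mm² of Otsu
foreground, by centroid-in-region assignment.  On default phantoms, recall
is ~85% with no false positives; merging of nearby objects is the dominant
loss, comparable to the ~19% count discrepancy cited as the realism bar for
watershed counting.  Cross-stack calibration divides densities by the mean
per-section original/replicate count ratio and maps each stack to [0,1] by
its maximum (order-preserving).  Calibration studies use wide sparse stacks
(12 sections, 10.2 mm field, densities 3/2/1/0.5 per mm²) so counting stays
near-linear; the single-pair ratio estimator still carries ~6% standard
error.

**Transport.**  Detections and foreground areas become particles {x_i, w_i,
f_i} on a coarse per-section grid (w = tissue mm², f = counts); pushforward
through the estimated maps conserves feature totals exactly and can rescale
weights by the local area Jacobian (on by default, so physical densities
transform consistently).  Grid resampling splats each particle's weight
over nodes with normalized Gaussian fractions (partition of unity → total
weight conserved to 1e−6); per-node density is the weight-averaged f/w.
Surface resampling assigns each particle wholly to its nearest surface
vertex (ties to the lowest index).

**Laplace–Beltrami smoothing** uses the cotangent stiffness matrix with
lumped barycentric vertex masses; eigenpairs of the generalized problem
S β = λ M β (full dense basis for small meshes, shift-invert Lanczos
otherwise; n_basis default 100).  Minimizing |ĝ−g|² + k|∇ĝ|² in this basis
shrinks each coefficient by 1/(1 + kλ_i); k = 0 is the identity (up to
truncation), the constant mode passes unchanged, and the surface integral
is preserved.  An alternative shrinkage factor of the form 1 − kλw(·)
circulates in the literature for this smoother; it is not the minimizer of
the stated variational objective (and is not even guaranteed positive), so
the objective's minimizer is used.  Smoothed density is the ratio of
smoothed counts to smoothed areas (with a floor on the area to avoid
division blow-up where no tissue projects); a constant density field is a
fixed point of this ratio for any k.  Default k = 2.

## Problem sizes in the bundled studies

The validation studies run at desk scale, chosen so the full battery
completes in minutes while every contract is exercised at the stated study
conditions: FWER calibration uses 200 replicates × 500 permutations of
34-subject, 200-vertex null cohorts; rate-recovery cohorts use 12 subjects ×
4 scans over 2 years on 642-vertex amygdala meshes (5% vertex noise) and
216-vertex sheet meshes (3% noise); the histology study uses five 96×96
sections at 32 µm with ~1.3 px RMS warps; calibration uses a 12-section
320×320 stack pair.  Longitudinal fits in these studies use the medoid
insertion time, one substep per scan interval, and capped L-BFGS iterations;
these choices were validated against longer runs on phantoms and change
cohort-mean rates by ≪ the reported tolerances.

## Known limitations

- The trajectory fit carries a small regularization bias toward less
  deformation (fitted measure curves are slightly flattened); on the bundled
  phantoms this biases cohort-mean rates by ~0.2–0.5 percentage points,
  within the reported tolerances but not zero.
- The residual-permutation test is approximate (exact only asymptotically);
  at n ≲ 16 its p-values are visibly non-uniform.
- The default blob detector is a classical single-scale operator intended
  for phantoms and as a reference implementation of the counting contract; 
  real stained sections need a trained per-pixel classifier plugged in via
  `register_detector`.
- The 3D volume deformation in `register_stack` is not estimated (identity);
  multi-block seam handling and atlas-specific coordinates are out of scope.
- Watershed counting is sublinear in true count at high density (object
  merging); calibration ratios between stacks of very different densities
  inherit a few percent of bias from this.
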