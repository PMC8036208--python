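# Methods

`voxdose` implements whole-body voxel-level internal dosimetry for
F-18 (FDG-like PET) on voxelized density maps: Monte Carlo generation of
voxel S-value kernels, the MIRD-style superposition of kernels with
cumulated activity, a reciprocity correction for heterogeneous media, a
learned kernel predictor, and the statistics used to compare dose maps.
Everything runs on synthetic torso phantoms; no patient data is involved.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Voxel-MIRD formalism

The absorbed dose to voxel *k* is

    D(k) = sum_h  A~(h) * S(k <- h),

where `A~(h)` is the cumulated activity (total disintegrations) in source
voxel *h* and `S(k <- h)` the voxel S-value: mean energy imparted to *k*
per decay in *h*. All kernels live on a 64^3 grid at 3 mm isotropic
spacing (19.2 cm per axis — beyond the ~7 cm half-value layer of 511 keV
photons in tissue) with the source voxel fixed at 0-based index
(32, 32, 32). 64 is even, so this convention is asserted across modules.

Three engines share the formalism and differ only in the kernel:

* **SSV** — one homogeneous soft-tissue kernel for every voxel (FFT
  convolution);
* **MSV** — one homogeneous kernel per medium (soft tissue, lung,
  trabecular ~1.18 g/cm^3 and cortical ~1.92 g/cm^3 bone), each applied
  inside the binary mask of its segmented medium; the 13 tissue classes
  are reduced to these four by nearest nominal density;
* **specific** — a kernel per source voxel computed (or predicted) for
  the actual 64^3 density patch around it, scatter-added.

Direct Monte Carlo on the whole volume is the reference engine.

## Tissue model

CT numbers are mapped to mass density by a piecewise-linear calibration
(breakpoints at HU −1024, −1000, −100, 0, 100, 1600, 3000 mapping to
0.00121, 0.00121, 0.93, 1.00, 1.14, 2.00, 2.80 g/cm^3), then binned into
13 classes: air, lung (0.26, ICRU inflated lung), adipose (0.95), soft
tissue (1.04), a transitional class (1.10), and eight bone bins from 1.18
to 2.10 g/cm^3 whose compositions interpolate between soft tissue and
ICRU cortical bone. Bins are half-open `[low, high)`; the published
sources cite a stoichiometric calibration without printing breakpoints,
so these values are this package's reference mapping, shipped as a
versioned JSON data file and swappable via `load_material_table`.

Photon data are computed from composition: Compton scattering from the
analytic Klein–Nishina total and energy-transfer cross sections
(free-electron approximation), photoelectric absorption from a
`Z^4.5 / E^3.2` per-element parametrization anchored to water's
energy-absorption coefficient at 10 keV. Rayleigh scattering and pair
production are omitted (511 keV photons; pair threshold 1022 keV), as are
binding effects and fluorescence. The packaged table holds 40 log-spaced
nodes over 10–1000 keV per material; lookups use log–log interpolation.
At 511 keV the model reproduces water's mu/rho within ~2% of standard
compilations; below ~50 keV the photoelectric parametrization is cruder,
which matters little because photons arrive there only after many
scatters carrying a small share of the energy budget.

## Positron spectrum

The F-18 beta+ spectrum is the allowed Fermi shape
`p W (W0 − W)^2 F(Z_eff, W)` with endpoint 633.5 keV and the
nonrelativistic Coulomb factor for positrons. The standard daughter
charge (Z = 8) yields a mean of ~250.4 keV, while the tabulated mean this
package adopts is 242.8 keV; since the mean and the endpoint are the two
published constraints, the effective charge is calibrated once,
Z_eff = 1.883, so the quadrature mean equals 242.8 keV. Sampling inverts
a 4096-node CDF.

## Monte Carlo transport

Per decay: a positron energy is sampled; the positron travels in a
straight line over its CSDA range (water range table scaled by local
density) depositing energy uniformly per unit areal density — a
deliberate simplification of condensed-history transport, acceptable
because the positron range (~0.5 mm mean in soft tissue) is below the
3 mm voxel size; annihilation at the track end emits two back-to-back
511 keV photons (branching handled below). Photons are tracked with
Amanatides–Woo voxel traversal using the local linear attenuation
coefficient, Compton scattering sampled by Kahn's rejection method,
photoelectric absorption, and a 10 keV cutoff with local deposition.

Two estimators are tallied at once:

* a **track-length kerma (heating) tally**, `E * mu_en(E) * path` per
  voxel crossed — the reported deposition. A collision estimator cannot
  reach few-percent uncertainty in 3 mm border voxels ~10 cm from the
  source at 3e6 histories (collisions there are too rare), whereas every
  crossing scores under the track-length estimator; this mirrors how mesh
  heating tallies are implemented in production transport codes;
* an **analog collision tally** plus an escape tally, which together
  conserve energy exactly per history and back the conservation tests.

Positron deposition is kept on its own grid so the photon heating field
can be separated; the reported border-to-center ratio (~1e-4 for the
soft-tissue kernel) is a property of the photon field — including the
positron self-dose in the denominator would push it to ~3e-6 and say
nothing about the photon mean free path argument for the kernel size.

Boundary modes: homogeneous SSV/MSV kernels are defined in an *infinite*
medium — photons leaving the 64^3 mesh keep propagating analytically in
the same medium and may scatter back, with a kill radius six mean free
paths beyond the mesh; patch-specific kernels and whole-body dose maps
use *vacuum* boundaries (nothing returns from outside the volume).

Statistical uncertainty comes from grouping histories into batches
(default 10): the per-voxel relative standard error of the batch mean.
The uncertainty contract — mean shell uncertainty at ~10 cm below 4% —
is met at 3e6 histories. Runs are reproducible for fixed (seed,
histories, batch count); execution is single-threaded by design.

The positron branching fraction of F-18 (0.9673) is not applied during
transport (every simulated decay emits the positron and both photons);
it multiplies the final Gy conversion,
`Gy = tally[MeV/cm^3] * decays * 0.9673 * 1.602176634e-10 / rho`.

## Cumulated activity

Dynamic frames (13 mid-times at increasing intervals over 0–90 min by
default) are integrated per voxel with the trapezoidal rule plus the
analytic physical-decay tail `A_f / lambda` after the last frame
(lambda from the 109.77 min half-life). The printed form of the frame
sum in the source formalism lacks the 1/2 factor of the trapezoid; the
standard trapezoid is the default and `printed_sum=True` reproduces the
literal form. Concentrations (Bq/mL) convert to decays via the voxel
volume and 60 s/min. The uptake model behind the synthetic frames is
`A(t) = A0 (1 − e^{−k_u t}) e^{−lambda t}` per tissue class, with
optional Poisson-like Gaussian noise (variance proportional to A).

## Reciprocity correction

Deposited energy per unit mass at a target approximately equals the
source/target-interchanged value times the target-to-source *mass*
energy-absorption coefficient ratio, evaluated at 511 keV (annihilation
photons dominate cross-voxel transport; the energy at which to evaluate
the ratio is otherwise unspecified, and a single-energy ratio is this
package's choice). The approximation is exact for primary fluence
(identical attenuation path both ways) and approximate for scatter; on a
three-media junction with nearby source/target pairs the residual is
2–4%, within the 5% the benchmark asserts. In the dose engines the
correction is applied at inference to learned kernels only — oracle
kernels are simulated in the actual patch and need none.

## Learned kernel predictor

A 20-layer dilated residual network (3^3 windows, dilations 1×7, 2×7,
4×6, LReLU, 9 residual blocks over the 18 interior layers, single
input/output channel) maps the density patch to its kernel. Two
desk-scale realities shaped the regression target:

* "dilation factor of zero" in the source description is read as an
  undilated convolution (dilation 1), since dilation zero is undefined;
* a translation-equivariant CNN fed a near-constant density patch cannot
  represent the kernel's fixed four-decade radial falloff (only boundary
  padding breaks translation symmetry), so the network predicts the
  **log-ratio of the specific kernel to the homogeneous soft-tissue
  reference kernel** — the medium-dependent modulation the density patch
  actually determines. The ratio is passed through a monotone sigmoid of
  its logarithm (center = median, scale set from the IQR but bounded so
  the full dynamic range stays numerically invertible), and predictions
  are clipped to the modulation range seen in training before being
  multiplied back onto the reference.

The second convolution of each residual block and the output layer are
zero-initialized so the deep stack starts as a near-identity map.
Training uses Adam (lr 0.001 by default, weight decay 0.0001, L2 loss),
a 90/10 train/validation split keyed by a content hash of the quantized
material patch, and full 64^3 patches (a model trained on central crops
never sees the far field's statistics and extrapolates badly). The
network is implemented in numpy with numba convolution kernels —
hand-written gradients, float32 compute, float64 parameters — runs
single-threaded and is bit-reproducible for a fixed seed. The reduced
profile (2 channels, 200 pairs at 1e4 histories each, one epoch at
lr 0.01 — a single epoch at the default rate cannot move the outputs
far enough from their zero initialization) trains in minutes on one CPU
core. The training set mixes patches
sampled uniformly from torso-phantom bodies with ~12% fully homogeneous
single-medium patches, so uniform media are in-distribution.

This profile is a proof of behaviour (the provider discriminates media
and plugs into the dose engine unchanged), not a claim of the accuracy a
full-scale trained model reaches on patient anatomy.

## Synthetic phantoms

The torso phantom is a soft-tissue body ellipsoid containing two lung
ellipsoids, a spine cylinder (cortical shell, trabecular core) and an
optional spherical lesion, painted with precedence
lesion > bone > lung > soft tissue; air outside the body. Densities are
nominal class values plus a small seeded jitter (sigma 0.01 g/cm^3)
clipped to stay inside the class's density bin, so the material volume
always equals the classification of the density volume. What the
phantoms do **not** emulate: anthropomorphic anatomy, respiratory or
cardiac motion, scanner PSF/reconstruction effects, or realistic organ
kinetics — tests passing on these phantoms validate the dosimetry chain,
not clinical accuracy on patients.

## Evaluation conventions

MAE/MRAE/RMSE are computed over an explicit mask; relative errors
exclude voxels whose reference magnitude is below 1e-3 of the masked
maximum (the handling of near-zero denominators is otherwise
unspecified), and the voxel count actually used is reported. Bland–
Altman differences are percent of the reference voxel value; limits of
agreement are bias ± 1.96 SD. Lesion segmentation takes the 26-connected
component above 42% of the regional maximum containing the peak voxel.
Dose-map comparisons are made inside the body contour: dividing a tally
by the air density (0.00121 g/cm^3) produces numerically huge, physically
meaningless "doses" outside the body that would otherwise dominate every
relative metric.

## Problem sizes

Defaults chosen for the package's own test/benchmark runs: homogeneous
kernels at 1e5 histories (3e6 for the uncertainty contract),
reciprocity benchmark at 1e6 histories per run, engine comparisons on a
32^3 torso phantom with 80 active source voxels against a 2e6-history
direct reference, and the reduced training profile above. All are
configurable upward; totals and ratios quoted in the README were
produced at these sizes.

## Known limitations

* Simplified physics: free-electron Compton, parametrized photoelectric,
  no Rayleigh scattering, no bremsstrahlung or annihilation-in-flight,
  straight-track positrons. Inter-medium kernel energy ratios are
  sensitive to these choices and to the nominal lung density (0.26
  g/cm^3 here; a denser lung medium would shrink the soft-vs-lung
  kernel-energy gap roughly like the attenuation it adds).
* Single radionuclide (F-18); other emitters would need their spectra
  and a kernel extent matched to their positron range.
* The finite 19.2 cm kernel truncates cross-dose beyond one photon
  half-value layer; whole-body dose maps assembled from kernels inherit
  this approximation.
* No bladder-voiding or biokinetic compartment modelling; the decay tail
  after the last frame assumes physical decay only.
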