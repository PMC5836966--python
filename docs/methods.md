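# Methods

## The model

`ivimdti` fits the combined intravoxel-incoherent-motion / diffusion-tensor
(IVIM-DTI) signal model to diffusion-weighted MRI.  The voxel signal measured
at diffusion weighting b along unit gradient direction ĝ is

    S(b, ĝ) = S0 [ f exp(−b ĝᵀD*ĝ) + (1 − f) exp(−b ĝᵀDĝ) ],

where f is the vascular (perfusion) volume fraction, D* the pseudo-diffusion
tensor describing the fast, flow-driven signal decay of blood water, and D
the tissue diffusion tensor.  Both tensors are kept positive semidefinite by
construction through upper-triangular Cholesky factors, D* = UᵀU and D = VᵀV,
so the 14 unknowns per voxel are X = (S0, f, U1..U6, V1..V6) and no box
constraints are needed during optimization.  The observation model is
Y = S(X) + e with magnitude (Rician) noise e.

Units: b in s/mm², diffusivities in mm²/s, pulse timings in seconds.  The
factor components numerically carry (mm²/s)^½.

## Estimators

Four estimators of X are provided; all iterate at most `max_iterations`
(default 10) with step/gradient/residual tolerances of 1e-6.

* **TSM (two-step).**  Step 1 fits the amplitude S0(1−f) and V to the
  b ≥ b_cutoff subset (default 500 s/mm², where the vascular signal has
  decayed) by Levenberg–Marquardt; f follows from the separately measured S0
  (mean of the b0 repeats), clipped to [0, 1] with a logged warning.  Step 2
  fits U to all measurements with (S0, f, V) frozen.  Requires at least 7
  high-b measurements.
* **OSM (one-step).**  Levenberg–Marquardt on all 14 parameters jointly,
  minimizing ‖Y − S(X)‖².  Damping update: λ ← λ/10 after a residual-lowering
  step, λ ← 10λ otherwise, starting from λ0 = 1e-2.
* **OSM-DGN1.**  Damped Gauss–Newton: the Gauss–Newton direction with a
  backtracking line search (sufficient-decrease constant 0.25, backtrack
  factor 0.5, at most 20 backtracks, initial step 1).
* **OSM-DGN2.**  DGN on the penalized objective
  ‖Y − S(X)‖² + λ (X − X*)ᵀΓ⁻¹(X − X*), the maximum-a-posteriori estimate
  under a diagonal Gaussian prior N(X*, Γ).  The weight
  λ = 10⁻² · tr(JᵀJ)/tr(Γ⁻¹) is recomputed from the current Jacobian at every
  iteration and held fixed during that iteration's line search.

### The Gaussian prior

The prior encodes literature-typical parameter magnitudes: f ~ 0.1 ± 0.1;
pseudo-diffusion magnitude 0.007 ± 0.005 mm²/s; tissue diffusivity
0.0007 ± 0.000025 mm²/s; S0 mean and standard deviation from the measured b0
repeats (a 10%-of-mean floor covers the single-replicate case).  Because the
literature states these on the diffusivity scale while the solver iterates on
factor components (their square roots), the tensor rows are propagated to
component scale by first-order error propagation: diagonal components
centred at √m with standard deviation s/(2√m); off-diagonal components
centred at 0 (the prior tensor is isotropic) with the same spread.  Applying
the diffusivity-scale numbers directly to the components would place the
prior mean hundreds of standard deviations from any physiological tensor and
move the MAP estimate into a spurious basin (f → 1, collapsed D); the
propagated form reproduces the intended gentle shrinkage.

### Numerical safeguards

The voxel-wise problem is ill-conditioned at clinical SNR: when f collapses
the U-block of JᵀJ has near-zero curvature, and unprotected Newton-type steps
along such noise-flat directions grow without bound while reducing the
residual only marginally (overfitting).  Three safeguards address this; all
vanish on noise-free data, so exact recovery is unaffected.

* LM damping is floored at 1e-2 · (R/‖Y‖²) · tr(JᵀJ)/n_free, so the damping
  stays meaningful relative to the curvature scale even after many accepted
  steps have divided λ down.  The ×/÷10 schedule itself is unchanged (and is
  what the logged λ trace records).
* The unregularized Gauss–Newton step is computed through a truncated
  eigendecomposition of JᵀJ with relative cutoff 1e-3 · (R/‖Y‖²) — a
  discrepancy-principle rule: directions whose curvature is below the noise
  level are left untouched.  The prior-regularized normal matrix is positive
  definite by construction and is solved directly.
* The line search requires an actual decrease of at least 0.25 of the
  linearized prediction, which accepts ideal Gauss–Newton steps (ratio → 0.5)
  but rejects long steps with negligible payoff.

Degenerate voxels (non-finite iterates, exhausted line search, singular
normal matrix) return `converged=False` with the best/initial iterate; a
whole-volume fit never aborts.  Voxels are fitted independently and
sequentially; results are bit-reproducible from the seed.

### Initialization

Fits start from isotropic tensors: U, V diagonals set to the square roots of
the requested initial mean diffusivities (so MD of the initial tensors equals
the request exactly), f and S0 as given; S0 defaults to the mean of the
measured b0 repeats.  For whole-volume fits the (f, MD(D*), MD(D)) triple can
be obtained automatically from a scalar bi-exponential fit of the
volume-average signal.  Initialization-sensitivity experiments express the
offset as a single ratio X_init applied jointly to f and both mean
diffusivities.

## Synthetic phantoms

### Single-voxel phantom

Emulates a bundle of identically oriented vessels undergoing plug flow with
Gaussian-distributed velocities v ~ N(0.86, 0.34) mm/s along x, plus an
extravascular compartment of 20% axons (D∥ = 1.7e-3 mm²/s, axis 30° from x in
the xy-plane) in an 80% isotropic matrix (8e-4 mm²/s); f = 0.12, S0 = 1,
blood diffusivity 3e-3 mm²/s.  The flow-induced attenuation has the closed
form exp(−γ²(m·v̂)²σ_v²/2) with first gradient moment m = GδΔĝ and G from the
Stejskal–Tanner relation b = γ²G²δ²(Δ − δ/3) (γ = 2.675e8 rad s⁻¹ T⁻¹); it
is exactly exp(−b ĝᵀWĝ) with W = [σ_v²Δ²/(2(Δ − δ/3))] v̂v̂ᵀ, so the full
ground truth is the tensor pair D*_eff = D_blood·I + W and
D = 0.2 D∥ n̂n̂ᵀ + 0.8 D_iso I.  The mean velocity contributes only a global
phase and drops out of the magnitude.  A quadrature oracle in the test suite
confirms the closed form to 1e-6 relative on every scheme entry.

The acquisition protocol is 11 b-values (0, 50, 150, ..., 850, 1150 s/mm²)
with 12 b0 images and 60 gradient directions per nonzero shell (612
measurements), δ = 1.9 ms, Δ = 2 ms.  Directions come from a seeded
electrostatic-repulsion relaxation on the sphere with antipodal symmetry.
Rician noise is applied per measurement as √((S+n₁)² + n₂²) with
n₁, n₂ ~ N(0, σ²) and σ = S0/SNR (SNR defined on the b0 signal).  The
default SNR of 20 sits mid-range of the 5–50 band the phantom is meant to
cover; the sensitivity experiments use SNR 10.

With f = 0.12, the vascular compartment carries an effective SNR of only
f·SNR ≈ 2.4 at SNR 20, and the anisotropic part of D*_eff is ~5% of its
isotropic part.  The Cramér–Rao bound at the phantom truth therefore allows
no unbiased estimator to determine FA(D*) (bound ≈ 0.23 on a target of
0.032) or the D* principal direction at these conditions; D-side measures
(MD, FA, orientation) are well determined.  Passing recovery tests on this
phantom demonstrate correctness of the fitting machinery, not that D*
micro-architecture is clinically resolvable at SNR 20.

### Spatial phantom

A small volumetric phantom (default 5×1×10 voxels of 0.2×1×0.2 mm,
i.e. a 1×1×2 mm domain): S0 is log-Gaussian from a first-order Gaussian
Markov random field (precision I + 4·Laplacian, dense factorization — meant
for small grids); each voxel holds 50 axons with orientations drawn from a
bipolar Watson distribution whose mean direction rotates smoothly through
60° across the volume and whose concentration is log-interpolated between 8
and 64 across the grid; per-axon D∥ ~ N(1.7e-3, 0.8e-3) mm²/s clipped at
1e-5 (negative diffusivities are unphysical); the voxel diffusion signal is
the mean of the per-axon attenuations and the ground-truth D is the mean
per-axon tensor.  The vascular compartment uses a parametric per-voxel
plug-flow D* (isotropic blood part plus a rank-1 flow part along the local
mean direction, scaled so MD(D*) matches the requested field, default
5e-3 mm²/s) with f = 0.02 and SNR 50.  What this phantom does *not* emulate:
synthesized vascular trees and capillary flow networks, axon packing
geometry, compartment exchange, relaxation effects — so conclusions about
those features cannot be drawn from tests passing here.

## Experiments

* `sensitivity_sweep` — errors of all four estimators against the X_init
  ratio (default grid 0.2–3.5): residual R = ‖Y − S(X̂)‖², percent errors of
  f, MD and FA of both tensors (absolute relative error; percentage error is
  undefined for a zero target), and axial principal-direction errors in
  degrees (0–90°).
* `convergence_trace` — per-iteration mean/std of S0, f, U1, V1; realizations
  that stop early are padded with their final iterate.
* `cutoff_scan` — mean TSM residual against the cut-off b-value.  The
  residual rise at low cutoffs is caused by vascular contamination of the
  high-b subset; because that bias (~0.01 in R) sits far below the Rician
  noise floor at SNR ≤ 20 (~1.5), the scan is run at SNR 100 where the
  phenomenon is resolvable; the curve then decreases and flattens for
  cutoffs ≥ 500 s/mm².

Problem sizes: the shipped experiments and the acceptance script use 100
noisy realizations per condition (60 for the cutoff scan), which puts the
Monte-Carlo standard error of the reported means at a few percent of their
values.

## Known limitations

* The least-squares objective assumes zero-mean Gaussian noise; Rician
  magnitude bias is present in the data (and visible as a residual floor)
  but not modelled in the likelihood.
* The prior-regularized estimator is a MAP estimator and therefore biased;
  on noise-free data the residual bias is ~1% in the tensor components and
  ~19% in f (compensation for the tight diffusion-tensor prior row).  It
  also keeps adjusting until the iteration cap because the prior weight λ is
  recomputed each iteration, so it settles later than the unregularized
  variant by the iterations-to-final-value measure.
* Gradient directions are assumed to be given in the image coordinate frame;
  no scanner-frame reorientation is applied.
* The scalar IVIM auto-initialization assumes the volume-average decay is
  bi-exponential; it is a convenience, not an estimator.
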