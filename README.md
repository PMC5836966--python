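# ivimdti

Simultaneous diffusion and pseudo-diffusion tensor imaging from
diffusion-weighted MRI.

Capillary blood water moving through randomly oriented microvessels produces
a fast, perfusion-driven signal decay in diffusion MRI (intravoxel incoherent
motion), on top of the slower decay from tissue water diffusion.  When both
effects are anisotropic, the voxel signal follows the bi-tensor model

    S(b, ĝ) = S0 [ f exp(−b ĝᵀD*ĝ) + (1 − f) exp(−b ĝᵀDĝ) ],

with perfusion fraction f, pseudo-diffusion tensor **D\*** (vascular) and
diffusion tensor **D** (tissue).  Estimating both tensors at once gives
perfusion-sensitive measures (f, MD(D*), FA(D*), vascular orientation)
alongside the standard DTI measures from a single multi-shell acquisition.
The package is aimed at diffusion-MRI methods researchers who want to fit,
validate, or stress-test this model.

Both tensors are parameterized by Cholesky factors (D* = UᵀU, D = VᵀV), so
every iterate is positive semidefinite without constraints.  Four voxel-wise
estimators are implemented:

| method     | idea                                                            |
|------------|-----------------------------------------------------------------|
| `tsm`      | two-step: D from the high-b subset, then D* with (f, D) frozen  |
| `osm`      | one-step Levenberg–Marquardt on all 14 parameters               |
| `osm-dgn1` | damped Gauss–Newton with a backtracking line search             |
| `osm-dgn2` | DGN on the MAP objective with a Gaussian parameter prior        |

A synthetic-phantom suite provides a single-voxel plug-flow phantom with a
closed-form ground-truth D* (for parameter-recovery studies under Rician
noise) and a small spatial phantom with a random-field S0 map and
Watson-dispersed axons.  See `docs/methods.md` for the model, solver and
phantom details.

## Worked example

Simulate one noisy voxel of the plug-flow phantom (SNR 20) and fit it with
the prior-regularized damped Gauss–Newton method:

```python
import ivimdti as iv

scheme = iv.make_scheme(seed=0)                 # 11 shells, 12 b0, 60 dirs
spec = iv.Config1Spec(snr=20, n_realizations=1, seed=42)
signals, truth = iv.synthesize_voxel(spec, scheme)

model = iv.IVIMDTI(signals[0], scheme)
res = model.fit("osm-dgn2")
print(res.summary())
```

```
IVIM-DTI fit results
==========================================================
method:            osm-dgn2
converged:         False (max iterations reached)
iterations:        10
residual R:        1.3852
----------------------------------------------------------
S0:                0.995281
f (perfusion):     0.0833
MD(D*):            3.2074e-03 mm^2/s
FA(D*):            0.7242
dir(D*):           [ 0.757  0.229 -0.612]
MD(D):             8.0371e-04 mm^2/s
FA(D):             0.2048
dir(D):            [ 0.846  0.529  0.064]
==========================================================
```

The ground truth here is f = 0.12, MD(D*) = 3.06e-3 mm²/s,
MD(D) = 7.53e-4 mm²/s, FA(D) = 0.255 with the tissue axis 30° from x in the
xy-plane.  From a single voxel at SNR 20 the tissue tensor comes back
accurately (MD(D) +7%, FA(D) −20%, orientation within a few degrees — `dir(D)`
vs (0.866, 0.5, 0)), f and MD(D*) land near the truth, while FA(D*) is
noise-dominated: the vascular compartment carries only f·SNR ≈ 2.4 effective
SNR and its true anisotropy is ~3%, below what any estimator can resolve
here.  `residual R` is the squared misfit; its value ≈ 1.4 matches the
Rician noise floor (612 measurements × σ² = 0.0025).  Averaged over 100
realizations the prior-regularized method keeps the mean MD(D) error below
6% and the tissue-orientation error below 10°.

The same interface fits whole volumes (`ivimdti.fit_volume`) and the command
line exposes the pipeline:

```bash
ivimdti simulate --config1 --snr 20 --n 100 --seed 7 --out sim/phantom
ivimdti fit --dwi sim/phantom.nii --bval sim/phantom.bval \
            --bvec sim/phantom.bvec --method osm-dgn2 --out maps/
ivimdti sweep --snr 10 --n 100 --out sweep.tsv
```

`fit` writes float32 NIfTI maps of f, MD/FA of both tensors, the residual,
a convergence flag, and FA-weighted RGB orientation maps.

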