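"""Synthetic diffusion-MRI generation with known ground truth.

Two phantoms are provided:

* A single-voxel phantom ("configuration 1"): a bundle of identically
  oriented vessels undergoing plug flow with Gaussian-distributed velocities,
  plus an extravascular compartment of partially oriented axons in an
  isotropic matrix.  The pseudo-diffusion equivalent of the flow has a closed
  form, so the full 14-parameter ground truth is known and parameter-recovery
  experiments are possible.

* A small spatial phantom ("configuration 2" analogue): a Gaussian
  Markov-random-field S0 map, Watson-dispersed axon orientations with smoothly
  varying mean direction and concentration, per-axon intrinsic diffusivities,
  and a parametric per-voxel plug-flow pseudo-diffusion field.

Magnitude-MRI noise is Rician: sqrt((S + n1)² + n2²) with iid Gaussian n1,
n2 of standard deviation σ = S0 / SNR (SNR defined on the b0 signal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.linalg import cho_factor, solve_triangular

from .params import ParamVector
from .scheme import AcquisitionScheme
from .tensors import tensor_to_cholesky

__all__ = [
    "Config1Spec",
    "SpatialPhantomSpec",
    "make_directions",
    "make_scheme",
    "vascular_signal_plugflow",
    "plugflow_dstar",
    "extravascular_signal",
    "synthesize_voxel",
    "add_rician_noise",
    "spatial_phantom",
    "GAMMA",
]

# gyromagnetic ratio of the proton, rad s^-1 T^-1
GAMMA = 2.675e8

PROTOCOL_BVALUES = (0.0, 50.0, 150.0, 250.0, 350.0, 450.0, 550.0, 650.0, 750.0, 850.0, 1150.0)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class Config1Spec:
    """Single-voxel study conditions.

    Defaults are the study values: perfusion fraction 0.12, unit S0, plug-flow
    velocities N(0.86, 0.34) mm/s along x, blood diffusivity 3e-3 mm²/s, an
    axon compartment (20%, D∥ = 1.7e-3 mm²/s, axis 30° from x in the xy-plane)
    in an isotropic matrix (80%, 8e-4 mm²/s).  The SNR default of 20 sits in
    the middle of the studied 5-50 range.
    """

    f: float = 0.12
    s0: float = 1.0
    mu_v: float = 0.86          # mm/s
    sigma_v: float = 0.34       # mm/s
    flow_dir: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    d_blood: float = 3.0e-3     # mm^2/s
    d_par: float = 1.7e-3       # mm^2/s
    d_iso: float = 8.0e-4       # mm^2/s
    axon_dir: Tuple[float, float, float] = (
        np.cos(np.radians(30.0)),
        np.sin(np.radians(30.0)),
        0.0,
    )
    axon_fraction: float = 0.2
    snr: float = 20.0
    n_realizations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.sigma_v <= 0:
            raise ValueError("sigma_v must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    @property
    def diffusion_tensor(self) -> np.ndarray:
        """Extravascular tensor: axon_fraction·D∥·n̂n̂ᵀ + (1-axon_fraction)·D_iso·I."""
        n = _unit(self.axon_dir)
        return self.axon_fraction * self.d_par * np.outer(n, n) + (
            1.0 - self.axon_fraction
        ) * self.d_iso * np.eye(3)

    def pseudo_diffusion_tensor(self, scheme: AcquisitionScheme) -> np.ndarray:
        """Closed-form effective D* of the plug-flow vascular compartment."""
        return plugflow_dstar(
            scheme.delta, scheme.Delta, self.sigma_v, self.flow_dir, self.d_blood
        )

    def ground_truth(self, scheme: AcquisitionScheme) -> ParamVector:
        return ParamVector(
            s0=self.s0,
            f=self.f,
            u=tensor_to_cholesky(self.pseudo_diffusion_tensor(scheme)),
            v=tensor_to_cholesky(self.diffusion_tensor),
        )


def make_directions(n: int, seed: int = 0, n_iter: int = 400) -> np.ndarray:
    """n approximately uniformly spread unit vectors on the half-sphere.

    Electrostatic repulsion between antipodally symmetrized point charges,
    relaxed with a deterministic, seeded projected-gradient scheme.
    """
    if n < 6:
        raise ValueError("need at least 6 directions for a tensor fit")
    rng = np.random.default_rng(seed)
    p = rng.normal(size=(n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    step = 0.05
    for it in range(n_iter):
        diff = p[:, None, :] - p[None, :, :]
        summ = p[:, None, :] + p[None, :, :]
        d2 = np.sum(diff**2, axis=-1)
        s2 = np.sum(summ**2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        np.fill_diagonal(s2, np.inf)
        # Coulomb forces from both the charge and its antipode
        force = np.sum(diff / d2[..., None] ** 1.5, axis=1) + np.sum(
            summ / s2[..., None] ** 1.5, axis=1
        )
        # tangential component only
        force -= np.sum(force * p, axis=1, keepdims=True) * p
        p = p + step * force / max(np.linalg.norm(force, axis=1).max(), 1e-12)
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        step *= 0.99
    # canonical hemisphere/sign for reproducibility
    flip = p[:, 0] < 0
    p[flip] *= -1.0
    return p


def make_scheme(
    b_values=PROTOCOL_BVALUES,
    n_b0: int = 12,
    n_directions: int = 60,
    delta: float = 1.9e-3,
    Delta: float = 2.0e-3,
    seed: int = 0,
) -> AcquisitionScheme:
    """Multi-shell scheme: n_b0 b0 images plus every b > 0 shell along the
    same n_directions repulsion-optimized directions.

    The defaults reproduce the 11-shell / 12-b0 / 60-direction protocol
    (612 measurements total).
    """
    b_values = np.asarray(sorted(set(float(b) for b in b_values)))
    dirs = make_directions(n_directions, seed=seed)
    bvals = [np.zeros(n_b0)]
    bvecs = [np.zeros((n_b0, 3))]
    for b in b_values[b_values > 0]:
        bvals.append(np.full(n_directions, b))
        bvecs.append(dirs)
    return AcquisitionScheme(
        np.concatenate(bvals), np.vstack(bvecs), delta=delta, Delta=Delta
    )


def plugflow_dstar(
    delta: float,
    Delta: float,
    sigma_v: float,
    flow_dir,
    d_blood: float,
) -> np.ndarray:
    """Effective pseudo-diffusion tensor of Gaussian-velocity plug flow.

    The flow-induced attenuation exp(-γ²(m·v̂)²σ_v²/2), with first gradient
    moment m = GδΔĝ and G from b = γ²G²δ²(Δ - δ/3), equals
    exp(-b ĝᵀ W ĝ) with W = [σ_v²Δ²/(2(Δ - δ/3))] v̂v̂ᵀ; adding the intrinsic
    blood diffusivity gives D*_eff = D_blood·I + W.
    """
    if Delta < delta:
        raise ValueError("pulse separation Delta must be >= duration delta")
    fdir = _unit(flow_dir)
    w = sigma_v**2 * Delta**2 / (2.0 * (Delta - delta / 3.0))
    return d_blood * np.eye(3) + w * np.outer(fdir, fdir)


def vascular_signal_plugflow(
    scheme: AcquisitionScheme,
    mu_v: float = 0.86,
    sigma_v: float = 0.34,
    flow_dir=(1.0, 0.0, 0.0),
    d_blood: float = 3.0e-3,
) -> np.ndarray:
    """Closed-form vascular (plug-flow) signal, normalized to 1 at b = 0.

    Magnitude of the ensemble average of the flow phase factor over
    v ~ N(mu_v, sigma_v) along ``flow_dir``, times the blood-diffusion decay.
    The mean velocity only contributes a global phase and drops out of the
    magnitude.
    """
    dstar = plugflow_dstar(scheme.delta, scheme.Delta, sigma_v, flow_dir, d_blood)
    q = np.einsum("ij,jk,ik->i", scheme.bvecs, dstar, scheme.bvecs)
    return np.exp(-scheme.bvals * q)


def extravascular_signal(scheme: AcquisitionScheme, d: np.ndarray) -> np.ndarray:
    """Monoexponential tensor attenuation exp(-b ĝᵀDĝ), 1 at b = 0."""
    d = np.asarray(d, dtype=float)
    q = np.einsum("ij,jk,ik->i", scheme.bvecs, d, scheme.bvecs)
    return np.exp(-scheme.bvals * q)


def noise_free_signal(spec: Config1Spec, scheme: AcquisitionScheme) -> np.ndarray:
    """S0 (f·Y_vascular + (1-f)·Y_diffusion) without noise."""
    y_vasc = vascular_signal_plugflow(
        scheme, spec.mu_v, spec.sigma_v, spec.flow_dir, spec.d_blood
    )
    y_diff = extravascular_signal(scheme, spec.diffusion_tensor)
    return spec.s0 * (spec.f * y_vasc + (1.0 - spec.f) * y_diff)


def add_rician_noise(
    signal: np.ndarray,
    snr: float,
    rng: np.random.Generator,
    s0: float = 1.0,
) -> np.ndarray:
    """Rician-corrupted magnitude signal with σ = s0 / snr.

    ``snr = inf`` returns the input unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if snr <= 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return signal.copy()
    sigma = s0 / snr
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def synthesize_voxel(
    spec: Config1Spec,
    scheme: AcquisitionScheme,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, ParamVector]:
    """Noisy realizations of the single-voxel phantom plus its ground truth.

    Returns
    -------
    realizations : (n_realizations, n_measurements) array
    truth : ParamVector
        (S0, f, Cholesky factors of the closed-form D*_eff and of D).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    clean = noise_free_signal(spec, scheme)
    reals = np.empty((spec.n_realizations, len(scheme)))
    for i in range(spec.n_realizations):
        reals[i] = add_rician_noise(clean, spec.snr, rng, s0=spec.s0)
    return reals, spec.ground_truth(scheme)


# ---------------------------------------------------------------------------
# Spatial phantom


@dataclass
class SpatialPhantomSpec:
    """Small volumetric phantom with spatially varying tissue properties.

    The default 5 x 1 x 10 grid of 0.2 x 1 x 0.2 mm voxels matches a
    1 x 1 x 2 mm domain.  The S0 map is log-Gaussian from a first-order GMRF;
    per-voxel axon bundles are Watson-dispersed about a mean direction that
    rotates smoothly through the volume, with concentration interpolated
    geometrically between ``kappa_range`` endpoints; each axon's intrinsic
    parallel diffusivity is drawn from N(1.7e-3, 8e-4) mm²/s (clipped to stay
    physical).  The vascular compartment uses the parametric plug-flow
    pseudo-diffusion form per voxel.
    """

    shape: Tuple[int, int, int] = (5, 1, 10)
    voxel_size: Tuple[float, float, float] = (0.2, 1.0, 0.2)  # mm
    s0_mean: float = 1.0
    s0_log_std: float = 0.2
    gmrf_smoothness: float = 4.0  # neighbour coupling relative to the nugget
    f: float = 0.02
    md_star: float = 5.0e-3      # mm^2/s, target MD of the vascular tensor
    d_blood: float = 3.0e-3      # mm^2/s
    kappa_range: Tuple[float, float] = (8.0, 64.0)
    n_axons: int = 50
    d_par_mean: float = 1.7e-3   # mm^2/s
    d_par_std: float = 0.8e-3    # mm^2/s
    d_iso: float = 8.0e-4        # mm^2/s
    axon_fraction: float = 0.2
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.prod(self.shape) < 1:
            raise ValueError("empty grid")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.md_star < self.d_blood:
            raise ValueError("md_star below the isotropic blood diffusivity")


def gmrf_field(shape, smoothness: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-marginal-variance draw from a first-order lattice GMRF.

    Precision Q = I + smoothness * L with L the grid-graph Laplacian (free
    boundary); the draw is rescaled by the exact marginal standard deviations
    from Q⁻¹.  Dense factorization — intended for small grids.
    """
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    lap = np.zeros((n, n))
    for axis in range(len(shape)):
        if shape[axis] < 2:
            continue
        a = np.take(idx, range(shape[axis] - 1), axis=axis).ravel()
        b = np.take(idx, range(1, shape[axis]), axis=axis).ravel()
        lap[a, b] -= 1.0
        lap[b, a] -= 1.0
        np.add.at(lap, (a, a), 1.0)
        np.add.at(lap, (b, b), 1.0)
    q = np.eye(n) + smoothness * lap
    # x = L^-T z has covariance Q^-1 when Q = L L^T
    chol, _ = cho_factor(q, lower=True)
    z = rng.normal(size=n)
    x = solve_triangular(np.tril(chol), z, lower=True, trans="T")
    marg_std = np.sqrt(np.diag(np.linalg.inv(q)))
    return (x / marg_std).reshape(shape)


def sample_watson(
    mu: np.ndarray, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n axes from the bipolar Watson distribution with mode mu.

    Rejection sampling from the uniform sphere with envelope
    exp(kappa (t² - 1)) <= 1 where t = mu·x.
    """
    mu = _unit(mu)
    out = np.empty((n, 3))
    have = 0
    while have < n:
        m = max(4 * (n - have), 64)
        z = rng.normal(size=(m, 3))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        t = z @ mu
        keep = rng.uniform(size=m) < np.exp(kappa * (t**2 - 1.0))
        z = z[keep]
        take = min(z.shape[0], n - have)
        out[have : have + take] = z[:take]
        have += take
    return out


def spatial_phantom(spec: SpatialPhantomSpec, scheme: AcquisitionScheme):
    """4D signal volume plus per-voxel ground-truth maps.

    Returns
    -------
    volume : (nx, ny, nz, n_measurements) array
        Rician-noisy signal (σ = s0_mean / SNR).
    truth : dict of arrays
        's0', 'f' (3D); 'd' and 'd_star' ((...,'6') Cholesky components,
        the diffusion entry being the factor of the axon-averaged tensor);
        'mean_dir' (...,'3') mean axon orientation per voxel.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    s0 = spec.s0_mean * np.exp(
        spec.s0_log_std * gmrf_field(spec.shape, spec.gmrf_smoothness, rng)
    )

    # smoothly rotating mean axon direction (xy-plane) and log-interpolated
    # dispersion along the slowest axis
    zfrac = (np.arange(nz) + 0.5) / nz
    theta_z = np.radians(60.0) * zfrac  # 0° -> 60° sweep
    xfrac = (np.arange(nx) + 0.5) / max(nx, 1)
    kappa_x = np.exp(
        np.log(spec.kappa_range[0])
        + (np.log(spec.kappa_range[1]) - np.log(spec.kappa_range[0])) * xfrac
    )

    w = spec.md_star - spec.d_blood  # MD(D*) = d_blood + w/3 * ... see below
    # per-voxel plug-flow D*: isotropic blood part + rank-1 flow part chosen so
    # MD(D*) = md_star; flow along the local mean axon direction
    flow_scale = 3.0 * w

    volume = np.empty((nx, ny, nz, len(scheme)))
    truth_d = np.empty((nx, ny, nz, 6))
    truth_dstar = np.empty((nx, ny, nz, 6))
    mean_dir = np.empty((nx, ny, nz, 3))
    f_map = np.full(spec.shape, spec.f)
    sigma = spec.s0_mean / spec.snr

    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                mu = np.array([np.cos(theta_z[iz]), np.sin(theta_z[iz]), 0.0])
                axes = sample_watson(mu, kappa_x[ix], spec.n_axons, rng)
                d_par = np.clip(
                    rng.normal(spec.d_par_mean, spec.d_par_std, size=spec.n_axons),
                    1e-5,
                    None,
                )
                # per-axon tensors; voxel signal averages their attenuations
                sig_diff = np.zeros(len(scheme))
                d_mean = np.zeros((3, 3))
                for a in range(spec.n_axons):
                    d_a = spec.axon_fraction * d_par[a] * np.outer(axes[a], axes[a]) + (
                        1.0 - spec.axon_fraction
                    ) * spec.d_iso * np.eye(3)
                    sig_diff += extravascular_signal(scheme, d_a)
                    d_mean += d_a
                sig_diff /= spec.n_axons
                d_mean /= spec.n_axons

                dstar = spec.d_blood * np.eye(3) + flow_scale * np.outer(mu, mu)
                q = np.einsum("ij,jk,ik->i", scheme.bvecs, dstar, scheme.bvecs)
                sig_vasc = np.exp(-scheme.bvals * q)

                clean = s0[ix, iy, iz] * (
                    spec.f * sig_vasc + (1.0 - spec.f) * sig_diff
                )
                if np.isinf(spec.snr):
                    volume[ix, iy, iz] = clean
                else:
                    n1 = rng.normal(0.0, sigma, size=len(scheme))
                    n2 = rng.normal(0.0, sigma, size=len(scheme))
                    volume[ix, iy, iz] = np.sqrt((clean + n1) ** 2 + n2**2)
                truth_d[ix, iy, iz] = tensor_to_cholesky(d_mean)
                truth_dstar[ix, iy, iz] = tensor_to_cholesky(dstar)
                mean_dir[ix, iy, iz] = mu

    return volume, {
        "s0": s0,
        "f": f_map,
        "d": truth_d,
        "d_star": truth_dstar,
        "mean_dir": mean_dir,
    }
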