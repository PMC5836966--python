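"""Voxel-wise fitting of the IVIM-DTI model.

Four estimation strategies are provided:

``tsm_fit``
    Two-step method.  Step 1 fits the amplitude S0(1-f) and the diffusion
    tensor D to the high-b subset (where the vascular signal has decayed),
    derives f from a separately measured S0, then step 2 fits the
    pseudo-diffusion tensor D* to all measurements with (f, D) frozen.
``osm_fit``
    One-step method: Levenberg-Marquardt on all 14 parameters jointly.
``dgn_fit``
    Damped Gauss-Newton with an Armijo backtracking line search; optionally
    regularized by a Gaussian prior on the parameters (maximum a posteriori
    under a diagonal Gaussian), with the regularization weight rescaled every
    iteration as scale * tr(JᵀJ) / tr(Γ⁻¹).

The LM damping schedule follows the classic rule: divide λ by 10 after a step
that lowers the residual, multiply by 10 otherwise.  No box constraints are
applied anywhere — tensor positive-semidefiniteness comes entirely from the
Cholesky parameterization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .forward import jacobian, predict_signal
from .params import IDX_F, IDX_S0, N_PARAMS, SL_U, SL_V, ParamVector
from .scheme import AcquisitionScheme

__all__ = [
    "SolverOptions",
    "GaussianPrior",
    "FitResult",
    "lm_fit",
    "dgn_fit",
    "osm_fit",
    "tsm_fit",
    "build_prior",
    "regularization_weight",
    "initialize_params",
    "f_init_from_ratio",
]

logger = logging.getLogger(__name__)

# Tabulated prior knowledge about the model parameters, stated on the scale
# practitioners report them: the perfusion fraction directly, and typical
# pseudo-diffusion / diffusion magnitudes in mm^2/s (i.e. on the scale of the
# tensors' mean diffusivity).  The S0 row is filled from the measured b0
# replicates at build time.
PRIOR_F_MEAN = 0.1
PRIOR_F_STD = 0.1
PRIOR_MD_STAR_MEAN = 0.007    # mm^2/s
PRIOR_MD_STAR_STD = 0.005     # mm^2/s
PRIOR_MD_MEAN = 0.0007        # mm^2/s
PRIOR_MD_STD = 0.000025       # mm^2/s
S0_STD_FLOOR_FRACTION = 0.1


@dataclass
class SolverOptions:
    """Iteration controls shared by the LM and DGN solvers.

    Defaults follow the study settings: at most 10 iterations, step /
    gradient / residual tolerances of 1e-6.  The line-search constants
    (sufficient-decrease 0.25, backtrack 0.5, 20 backtracks), the initial LM
    damping 1e-2, and the misfit-scaled damping floor / truncation level are
    implementation choices (see the methods note).
    """

    max_iterations: int = 10
    step_tol: float = 1e-6
    grad_tol: float = 1e-6
    resid_tol: float = 1e-6
    lambda0: float = 1e-2
    armijo_c: float = 0.25
    backtrack_factor: float = 0.5
    max_backtracks: int = 20
    lambda_max: float = 1e12
    lambda_floor_scale: float = 1e-2
    gn_rcond: float = 1e-12
    gn_rcond_scale: float = 1e-3

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        for name in ("step_tol", "grad_tol", "resid_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class GaussianPrior:
    """Diagonal Gaussian prior N(X*, Γ_X) with a trace-matched weight.

    The penalty added to the least-squares objective is
    λ ||L (X - X*)||² with LᵀL = Γ_X⁻¹ and
    λ = scale * tr(JᵀJ) / tr(Γ_X⁻¹), recomputed at every iteration.
    """

    mean: np.ndarray
    variances: np.ndarray
    scale: float = 1e-2

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(N_PARAMS)
        self.variances = np.asarray(self.variances, dtype=float).reshape(N_PARAMS)
        if np.any(self.variances <= 0):
            raise ValueError("prior variances must be positive")

    @property
    def precision_diag(self) -> np.ndarray:
        return 1.0 / self.variances

    def with_scale(self, scale: float) -> "GaussianPrior":
        return GaussianPrior(self.mean.copy(), self.variances.copy(), scale)


@dataclass
class FitResult:
    """Outcome of a single-voxel fit."""

    params: ParamVector
    residual: float
    n_iterations: int
    converged: bool
    residual_trace: np.ndarray
    method: str
    x_trace: np.ndarray  # (n_recorded, 14) parameter iterates, row 0 = x0
    lambda_trace: list = field(default_factory=list)  # LM: (lambda, accepted) per trial
    objective_steps: list = field(default_factory=list)  # DGN: (pre, post) per accepted step
    message: str = ""


def _free_indices(fixed_mask: Optional[Sequence[bool]]) -> np.ndarray:
    if fixed_mask is None:
        return np.arange(N_PARAMS)
    fixed = np.asarray(fixed_mask, dtype=bool).reshape(N_PARAMS)
    free = np.flatnonzero(~fixed)
    if free.size == 0:
        raise ValueError("all parameters fixed; nothing to fit")
    return free


def _sumsq(y: np.ndarray, x: np.ndarray, scheme: AcquisitionScheme) -> float:
    r = y - predict_signal(x, scheme)
    return float(r @ r)


def lm_fit(
    y: np.ndarray,
    scheme: AcquisitionScheme,
    x0: ParamVector,
    opts: Optional[SolverOptions] = None,
    fixed_mask: Optional[Sequence[bool]] = None,
    method_tag: str = "lm",
) -> FitResult:
    """Levenberg-Marquardt minimization of ||Y - S(X)||² over the free subset.

    The damping λ is divided by 10 after every accepted (residual-lowering)
    step and multiplied by 10 after a rejected trial; a singular normal matrix
    is likewise handled by raising λ.  Persistent failure returns a
    non-converged result rather than raising.
    """
    opts = opts or SolverOptions()
    y = np.asarray(y, dtype=float).ravel()
    x = x0.to_array()
    free = _free_indices(fixed_mask)

    r = y - predict_signal(x, scheme)
    rss = float(r @ r)
    lam = opts.lambda0
    resid_trace = [rss]
    x_trace = [x.copy()]
    lambda_trace: list = []
    converged = False
    message = "max iterations reached"
    n_done = 0

    for _ in range(opts.max_iterations):
        jac = jacobian(x, scheme)[:, free]
        grad = jac.T @ r
        if np.linalg.norm(grad, np.inf) < opts.grad_tol:
            converged = True
            message = "gradient tolerance reached"
            break
        jtj = jac.T @ jac
        # The identity damping follows the classic update; the floor keeps
        # the effective damping meaningful relative to the problem's
        # curvature even after many accepted steps have divided λ down,
        # which protects near-unidentifiable directions (e.g. the
        # pseudo-diffusion factor when f collapses) from unbounded steps.
        # Scaling the floor with the relative misfit lets it vanish for
        # (near-)exactly fitting data, where the full Gauss-Newton step is
        # safe and fast.
        lam_floor = (
            opts.lambda_floor_scale
            * (rss / max(float(y @ y), 1e-300))
            * np.trace(jtj)
            / free.size
        )
        accepted = False
        while lam <= opts.lambda_max:
            h = jtj + max(lam, lam_floor) * np.eye(free.size)
            try:
                step = np.linalg.solve(h, grad)
            except np.linalg.LinAlgError:
                lambda_trace.append((lam, False))
                lam *= 10.0
                continue
            x_new = x.copy()
            x_new[free] += step
            if np.all(np.isfinite(x_new)):
                rss_new = _sumsq(y, x_new, scheme)
            else:
                rss_new = np.inf
            if rss_new < rss:
                lambda_trace.append((lam, True))
                lam /= 10.0
                accepted = True
                break
            lambda_trace.append((lam, False))
            lam *= 10.0
        if not accepted:
            message = "damping exhausted without residual decrease"
            break
        n_done += 1
        prev_rss = rss
        x, rss, r = x_new, rss_new, y - predict_signal(x_new, scheme)
        resid_trace.append(rss)
        x_trace.append(x.copy())
        if np.linalg.norm(step) < opts.step_tol * (1.0 + np.linalg.norm(x)):
            converged = True
            message = "step tolerance reached"
            break
        if abs(prev_rss - rss) < opts.resid_tol * max(prev_rss, 1.0):
            converged = True
            message = "residual tolerance reached"
            break

    if not np.all(np.isfinite(x)):
        # non-finite iterate: echo the starting point, flag failure
        x = x0.to_array()
        rss = _sumsq(y, x, scheme)
        converged = False
        message = "non-finite iterate; initial parameters returned"

    return FitResult(
        params=ParamVector.from_array(x),
        residual=rss,
        n_iterations=n_done,
        converged=converged,
        residual_trace=np.asarray(resid_trace),
        method=method_tag,
        x_trace=np.asarray(x_trace),
        lambda_trace=lambda_trace,
        message=message,
    )


def regularization_weight(jac: np.ndarray, prior: GaussianPrior) -> float:
    """Trace-matched prior weight: scale * tr(JᵀJ) / tr(Γ_X⁻¹)."""
    jac = np.asarray(jac, dtype=float)
    return prior.scale * float(np.sum(jac * jac)) / float(np.sum(prior.precision_diag))


def dgn_fit(
    y: np.ndarray,
    scheme: AcquisitionScheme,
    x0: ParamVector,
    opts: Optional[SolverOptions] = None,
    prior: Optional[GaussianPrior] = None,
    method_tag: Optional[str] = None,
) -> FitResult:
    """Damped Gauss-Newton with Armijo backtracking line search.

    Without a prior this minimizes the plain least-squares objective; with a
    prior it minimizes ||Y - S(X)||² + λ (X - X*)ᵀ Γ⁻¹ (X - X*) where λ is
    recomputed from the current Jacobian at each iteration and held fixed
    during that iteration's line search.  Accepted steps never increase the
    (current-λ) objective.
    """
    opts = opts or SolverOptions()
    y = np.asarray(y, dtype=float).ravel()
    x = x0.to_array()
    tag = method_tag or ("osm-dgn2" if prior is not None else "osm-dgn1")

    def rss_of(xv: np.ndarray) -> float:
        return _sumsq(y, xv, scheme)

    rss = rss_of(x)
    resid_trace = [rss]
    x_trace = [x.copy()]
    objective_steps: list = []
    converged = False
    message = "max iterations reached"
    n_done = 0

    for _ in range(opts.max_iterations):
        jac = jacobian(x, scheme)
        r = y - predict_signal(x, scheme)
        if prior is not None:
            lam = regularization_weight(jac, prior)
            prec = prior.precision_diag
            dx_prior = x - prior.mean

            def objective(xv: np.ndarray) -> float:
                d = xv - prior.mean
                return rss_of(xv) + lam * float(d * prec @ d)

            h = jac.T @ jac + lam * np.diag(prec)
            rhs = jac.T @ r - lam * prec * dx_prior
        else:

            def objective(xv: np.ndarray) -> float:
                return rss_of(xv)

            h = jac.T @ jac
            rhs = jac.T @ r

        grad_norm = np.linalg.norm(rhs, np.inf)
        if grad_norm < opts.grad_tol:
            converged = True
            message = "gradient tolerance reached"
            break
        if prior is not None:
            # The regularized normal matrix is positive definite by
            # construction; solve it directly (tiny jitter on numerical
            # failure).
            try:
                step = np.linalg.solve(h, rhs)
            except np.linalg.LinAlgError:
                h = h + (1e-12 * np.trace(h) / N_PARAMS) * np.eye(N_PARAMS)
                try:
                    step = np.linalg.solve(h, rhs)
                except np.linalg.LinAlgError:
                    message = "singular normal matrix"
                    break
        else:
            # Unregularized Gauss-Newton: solve through a truncated
            # eigendecomposition.  Directions with negligible curvature are
            # discarded, keeping the step finite when the Jacobian is
            # (numerically) rank-deficient.  The truncation level scales
            # with the relative misfit (discrepancy principle): directions
            # the data cannot resolve above the noise are left untouched,
            # while an (almost) exactly fitting model keeps full rank.
            try:
                evals, evecs = np.linalg.eigh(h)
            except np.linalg.LinAlgError:
                message = "singular normal matrix"
                break
            y_norm2 = max(float(y @ y), 1e-300)
            rcond = max(opts.gn_rcond, opts.gn_rcond_scale * rss / y_norm2)
            cut = rcond * max(evals[-1], 0.0)
            keep = evals > cut
            if not np.any(keep):
                message = "singular normal matrix"
                break
            step = evecs[:, keep] @ ((evecs[:, keep].T @ rhs) / evals[keep])

        phi0 = objective(x)
        # d(objective)/ds at s=0 along the step is -2 rhs.step (< 0 for SPD h)
        slope = -2.0 * float(rhs @ step)
        s = 1.0
        accepted = False
        for _bt in range(opts.max_backtracks + 1):
            x_new = x + s * step
            if np.all(np.isfinite(x_new)):
                phi_new = objective(x_new)
                if phi_new <= phi0 + opts.armijo_c * s * slope:
                    accepted = True
                    break
            s *= opts.backtrack_factor
        if not accepted:
            message = "line search failed"
            break

        n_done += 1
        prev_rss = rss
        x = x_new
        rss = rss_of(x)
        resid_trace.append(rss)
        x_trace.append(x.copy())
        objective_steps.append((phi0, phi_new))
        if np.linalg.norm(s * step) < opts.step_tol * (1.0 + np.linalg.norm(x)):
            converged = True
            message = "step tolerance reached"
            break
        if abs(prev_rss - rss) < opts.resid_tol * max(prev_rss, 1.0):
            converged = True
            message = "residual tolerance reached"
            break

    if not np.all(np.isfinite(x)):
        x = x0.to_array()
        rss = rss_of(x)
        converged = False
        message = "non-finite iterate; initial parameters returned"

    return FitResult(
        params=ParamVector.from_array(x),
        residual=rss,
        n_iterations=n_done,
        converged=converged,
        residual_trace=np.asarray(resid_trace),
        method=tag,
        x_trace=np.asarray(x_trace),
        objective_steps=objective_steps,
        message=message,
    )


def osm_fit(
    y: np.ndarray,
    scheme: AcquisitionScheme,
    x0: ParamVector,
    opts: Optional[SolverOptions] = None,
) -> FitResult:
    """One-step method: LM on all 14 parameters jointly."""
    res = lm_fit(y, scheme, x0, opts, fixed_mask=None, method_tag="osm")
    return res


def tsm_fit(
    y: np.ndarray,
    scheme: AcquisitionScheme,
    s0_measured: float,
    b_cutoff: float = 500.0,
    x0: Optional[ParamVector] = None,
    opts: Optional[SolverOptions] = None,
) -> FitResult:
    """Two-step method.

    Step 1 fits the amplitude S0(1-f) and the diffusion-tensor factor V to the
    b >= b_cutoff subset (monoexponential regime); f follows from the measured
    S0.  Step 2 fits the pseudo-diffusion factor U to all measurements with
    (S0, f, V) frozen.
    """
    y = np.asarray(y, dtype=float).ravel()
    if s0_measured <= 0:
        raise ValueError("s0_measured must be positive")
    high = scheme.bvals >= b_cutoff
    if np.count_nonzero(high) < 7:
        raise ValueError(
            f"only {np.count_nonzero(high)} measurements with b >= {b_cutoff}; "
            "step 1 needs at least 7"
        )
    if x0 is None:
        x0 = initialize_params(s0_measured, 0.1, 3e-3, 7e-4)

    # Step 1: amplitude (stored in the S0 slot) + V on the high-b subset.
    # With f frozen at 0 the model reduces to amp * exp(-b gᵀVᵀVg).
    x1 = x0.to_array().copy()
    x1[IDX_S0] = x0.s0 * (1.0 - np.clip(x0.f, 0.0, 0.99))
    x1[IDX_F] = 0.0
    fixed1 = np.ones(N_PARAMS, dtype=bool)
    fixed1[IDX_S0] = False
    fixed1[SL_V] = False
    step1 = lm_fit(
        y[high],
        scheme.subset(high),
        ParamVector.from_array(x1),
        opts,
        fixed_mask=fixed1,
        method_tag="tsm-step1",
    )
    amplitude = step1.params.s0
    f_hat = 1.0 - amplitude / s0_measured
    if f_hat < 0.0 or f_hat > 1.0:
        logger.warning(
            "TSM: amplitude/S0 ratio gives f=%.3g outside [0, 1]; clipping", f_hat
        )
        f_hat = float(np.clip(f_hat, 0.0, 1.0))

    # Step 2: pseudo-diffusion factor U on all data; (S0, f, V) frozen.
    x2 = x0.to_array().copy()
    x2[IDX_S0] = s0_measured
    x2[IDX_F] = f_hat
    x2[SL_V] = step1.params.v
    fixed2 = np.ones(N_PARAMS, dtype=bool)
    fixed2[SL_U] = False
    step2 = lm_fit(
        y,
        scheme,
        ParamVector.from_array(x2),
        opts,
        fixed_mask=fixed2,
        method_tag="tsm",
    )
    step2.converged = step1.converged and step2.converged
    step2.message = f"step1: {step1.message}; step2: {step2.message}"
    step2.n_iterations = step1.n_iterations + step2.n_iterations
    return step2


def _component_prior(md_mean: float, md_std: float) -> tuple:
    """Map a (mean, std) on the diffusivity scale to the factor components.

    The tabulated priors describe typical tensor magnitudes (mean
    diffusivities, mm^2/s), but the parameter vector carries Cholesky factor
    components whose squares are diffusivities.  First-order (delta-method)
    propagation through c = sqrt(m) gives the component-scale prior: diagonal
    components centred at sqrt(md_mean) with std md_std / (2 sqrt(md_mean));
    off-diagonal components centred at 0 (isotropic prior tensor) with the
    same spread.
    """
    c = np.sqrt(md_mean)
    s = md_std / (2.0 * c)
    mean = np.array([c, c, c, 0.0, 0.0, 0.0])
    std = np.full(6, s)
    return mean, std


def build_prior(
    s0_replicates: Sequence[float], scale: float = 1e-2
) -> GaussianPrior:
    """Gaussian parameter prior; the S0 row comes from the b0 replicates.

    The tensor rows encode typical pseudo-diffusion and diffusion magnitudes
    (0.007 +/- 0.005 and 0.0007 +/- 0.000025 mm^2/s), propagated to the
    Cholesky-component scale the solver iterates on; the perfusion-fraction
    row is 0.1 +/- 0.1.  With a single S0 replicate (or degenerate spread)
    the S0 standard deviation falls back to 10% of the mean.
    """
    reps = np.asarray(s0_replicates, dtype=float).ravel()
    if reps.size == 0:
        raise ValueError("at least one S0 replicate is required")
    s0_mean = float(reps.mean())
    s0_std = float(reps.std(ddof=1)) if reps.size > 1 else 0.0
    floor = S0_STD_FLOOR_FRACTION * abs(s0_mean)
    if s0_std < floor:
        s0_std = floor
    if s0_std <= 0:
        raise ValueError("degenerate S0 replicates (zero mean and spread)")
    mean = np.empty(N_PARAMS)
    std = np.empty(N_PARAMS)
    mean[IDX_S0], std[IDX_S0] = s0_mean, s0_std
    mean[IDX_F], std[IDX_F] = PRIOR_F_MEAN, PRIOR_F_STD
    mean[SL_U], std[SL_U] = _component_prior(PRIOR_MD_STAR_MEAN, PRIOR_MD_STAR_STD)
    mean[SL_V], std[SL_V] = _component_prior(PRIOR_MD_MEAN, PRIOR_MD_STD)
    return GaussianPrior(mean=mean, variances=std**2, scale=scale)


def initialize_params(
    s0_measured: float,
    f_init: float,
    md_star_init: float,
    md_init: float,
) -> ParamVector:
    """Isotropic-tensor initialization.

    The Cholesky diagonals are set to the square roots of the requested mean
    diffusivities so that MD(D*_init) = md_star_init and MD(D_init) = md_init
    exactly; off-diagonals start at zero.
    """
    if md_star_init <= 0 or md_init <= 0:
        raise ValueError("initial mean diffusivities must be positive")
    if not (0.0 < f_init < 1.0):
        raise ValueError("f_init must lie in (0, 1)")
    u = np.zeros(6)
    v = np.zeros(6)
    u[:3] = np.sqrt(md_star_init)
    v[:3] = np.sqrt(md_init)
    return ParamVector(s0=float(s0_measured), f=float(f_init), u=u, v=v)


def f_init_from_ratio(f_target: float, x_init_ratio: float) -> float:
    """Initial f implied by a common initialization ratio X_init."""
    return x_init_ratio * f_target
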