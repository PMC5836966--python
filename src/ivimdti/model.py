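"""Model/Results interface for single-voxel and volume IVIM-DTI fitting.

``IVIMDTI`` holds one voxel's diffusion-weighted signal together with its
acquisition scheme; ``fit`` dispatches to the two-step or one-step estimators
and returns an ``IVIMDTIResults`` carrying the parameter estimates, the
derived tensor measures, the iteration trace and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from . import estimators, tensors
from .estimators import FitResult, GaussianPrior, SolverOptions
from .forward import predict_signal
from .params import ParamVector
from .scheme import AcquisitionScheme

__all__ = ["IVIMDTI", "IVIMDTIResults", "fit_volume", "scalar_ivim_initialization"]

logger = logging.getLogger(__name__)

_METHODS = ("tsm", "osm", "osm-dgn1", "osm-dgn2")


def scalar_ivim_initialization(
    signal: np.ndarray, scheme: AcquisitionScheme
) -> tuple[float, float, float]:
    """(f, MD(D*), MD(D)) from a scalar bi-exponential fit of an average signal.

    Used to auto-initialize whole-volume fits from the volume-average decay
    curve; the scalar model is the isotropic degenerate case of the tensor
    model.
    """
    from scipy.optimize import least_squares

    y = np.asarray(signal, dtype=float).ravel()
    b = scheme.bvals
    s0_guess = float(y[scheme.b0_mask].mean()) if scheme.n_b0 else float(y.max())

    def resid(p):
        s0, f, dstar, d = p
        return s0 * (f * np.exp(-b * dstar) + (1 - f) * np.exp(-b * d)) - y

    sol = least_squares(
        resid,
        x0=[s0_guess, 0.1, 10e-3, 1e-3],
        bounds=([0.0, 0.0, 1e-6, 1e-7], [np.inf, 1.0, 1.0, 0.1]),
    )
    s0, f, dstar, d = sol.x
    if dstar < d:  # label-swap guard: D* is the fast component
        dstar, d = d, dstar
        f = 1.0 - f
    f = float(np.clip(f, 0.01, 0.99))
    return f, float(dstar), float(d)


class IVIMDTI:
    """Bi-tensor intravoxel-incoherent-motion model for one voxel.

    Parameters
    ----------
    signal : (n,) array
        Magnitude DWI signal aligned with the scheme.
    scheme : AcquisitionScheme
    """

    def __init__(self, signal: np.ndarray, scheme: AcquisitionScheme):
        signal = np.asarray(signal, dtype=float).ravel()
        if signal.size != len(scheme):
            raise ValueError(
                f"signal length {signal.size} != scheme length {len(scheme)}"
            )
        if np.any(signal < 0):
            raise ValueError("magnitude signal must be nonnegative")
        self.signal = signal
        self.scheme = scheme

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        delta: float = 1.9e-3,
        Delta: float = 2.0e-3,
        columns=("b", "gx", "gy", "gz", "signal"),
    ) -> "IVIMDTI":
        """Build from a tidy table with b-value, gradient and signal columns."""
        b, gx, gy, gz, sig = (df[c].to_numpy(dtype=float) for c in columns)
        scheme = AcquisitionScheme(b, np.column_stack([gx, gy, gz]), delta, Delta)
        return cls(sig, scheme)

    @property
    def s0_measured(self) -> float:
        """Mean of the b0 repeats (the measured S0)."""
        if self.scheme.n_b0 == 0:
            raise ValueError("scheme has no b0 measurements")
        return float(self.signal[self.scheme.b0_mask].mean())

    def starting_params(
        self,
        f_init: float = 0.1,
        md_star_init: float = 3.0e-3,
        md_init: float = 6.0e-4,
    ) -> ParamVector:
        """Isotropic initialization anchored at the measured S0."""
        return estimators.initialize_params(
            self.s0_measured, f_init, md_star_init, md_init
        )

    def default_prior(self, scale: float = 1e-2) -> GaussianPrior:
        """Gaussian parameter prior with S0 statistics from the b0 repeats."""
        return estimators.build_prior(
            self.signal[self.scheme.b0_mask], scale=scale
        )

    def fit(
        self,
        method: str = "osm-dgn2",
        x0: Optional[ParamVector] = None,
        options: Optional[SolverOptions] = None,
        prior: Optional[GaussianPrior] = None,
        b_cutoff: float = 500.0,
        f_init: float = 0.1,
        md_star_init: float = 3.0e-3,
        md_init: float = 6.0e-4,
    ) -> "IVIMDTIResults":
        if method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
        if x0 is None:
            x0 = self.starting_params(f_init, md_star_init, md_init)
        if method == "tsm":
            res = estimators.tsm_fit(
                self.signal, self.scheme, self.s0_measured, b_cutoff, x0, options
            )
        elif method == "osm":
            res = estimators.osm_fit(self.signal, self.scheme, x0, options)
        elif method == "osm-dgn1":
            res = estimators.dgn_fit(self.signal, self.scheme, x0, options, prior=None)
        else:  # osm-dgn2
            if prior is None:
                prior = self.default_prior()
            res = estimators.dgn_fit(
                self.signal, self.scheme, x0, options, prior=prior, method_tag="osm-dgn2"
            )
        return IVIMDTIResults(self, res)

    def predict(self, params: ParamVector) -> np.ndarray:
        return predict_signal(params, self.scheme)


class IVIMDTIResults:
    """Estimates and diagnostics of a single-voxel IVIM-DTI fit."""

    def __init__(self, model: IVIMDTI, fit: FitResult):
        self.model = model
        self._fit = fit

    # -- raw fit -----------------------------------------------------------
    @property
    def params(self) -> ParamVector:
        return self._fit.params

    @property
    def method(self) -> str:
        return self._fit.method

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def n_iterations(self) -> int:
        return self._fit.n_iterations

    @property
    def residual(self) -> float:
        """Squared-norm data misfit R = ||Y - S(X)||²."""
        return self._fit.residual

    @property
    def residual_trace(self) -> np.ndarray:
        return self._fit.residual_trace

    @property
    def fit_result(self) -> FitResult:
        return self._fit

    # -- derived quantities --------------------------------------------------
    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.signal - self.fittedvalues

    @property
    def f(self) -> float:
        """Perfusion fraction, clipped to [0, 1] for reporting."""
        f = self.params.f
        if not 0.0 <= f <= 1.0:
            logger.warning("estimated f=%.4g outside [0, 1]; clipped for reporting", f)
        return float(np.clip(f, 0.0, 1.0))

    @property
    def s0(self) -> float:
        return self.params.s0

    @property
    def d_star(self) -> np.ndarray:
        return self.params.d_star

    @property
    def d(self) -> np.ndarray:
        return self.params.d

    @property
    def md_d_star(self) -> float:
        return tensors.mean_diffusivity(self.d_star)

    @property
    def fa_d_star(self) -> float:
        return tensors.fractional_anisotropy(self.d_star)

    @property
    def md_d(self) -> float:
        return tensors.mean_diffusivity(self.d)

    @property
    def fa_d(self) -> float:
        return tensors.fractional_anisotropy(self.d)

    def principal_direction(self, tensor: str = "d") -> np.ndarray:
        t = self.d if tensor == "d" else self.d_star
        return tensors.principal_direction(t)

    def summary(self) -> str:
        """Human-readable fit report."""
        pd_star = self.principal_direction("d_star")
        pdir = self.principal_direction("d")
        lines = [
            "IVIM-DTI fit results",
            "=" * 58,
            f"method:            {self.method}",
            f"converged:         {self.converged} ({self._fit.message})",
            f"iterations:        {self.n_iterations}",
            f"residual R:        {self.residual:.6g}",
            "-" * 58,
            f"S0:                {self.s0:.6g}",
            f"f (perfusion):     {self.f:.4f}",
            f"MD(D*):            {self.md_d_star:.4e} mm^2/s",
            f"FA(D*):            {self.fa_d_star:.4f}",
            f"dir(D*):           [{pd_star[0]: .3f} {pd_star[1]: .3f} {pd_star[2]: .3f}]",
            f"MD(D):             {self.md_d:.4e} mm^2/s",
            f"FA(D):             {self.fa_d:.4f}",
            f"dir(D):            [{pdir[0]: .3f} {pdir[1]: .3f} {pdir[2]: .3f}]",
            "=" * 58,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<IVIMDTIResults method={self.method} f={self.f:.3f} "
            f"MD(D*)={self.md_d_star:.3e} MD(D)={self.md_d:.3e}>"
        )


def fit_volume(
    data: np.ndarray,
    scheme: AcquisitionScheme,
    method: str = "osm-dgn2",
    mask: Optional[np.ndarray] = None,
    options: Optional[SolverOptions] = None,
    b_cutoff: float = 500.0,
    init: Optional[tuple] = None,
):
    """Voxel-wise fit of a 4D DWI volume.

    Voxels are fitted independently (sequentially, deterministically).  When
    ``init`` is None the (f, MD(D*), MD(D)) initialization is obtained from a
    scalar bi-exponential fit of the volume-average signal inside the mask.

    Returns a dict of 3D result maps: f, md_d_star, fa_d_star, md_d, fa_d,
    residual, converged, plus 4D principal-direction maps dir_d_star, dir_d.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4 or data.shape[-1] != len(scheme):
        raise ValueError("data must be 4D with last axis matching the scheme")
    spatial = data.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    if init is None:
        avg = data[mask].mean(axis=0)
        init = scalar_ivim_initialization(avg, scheme)
        logger.info(
            "auto-initialization from volume-average signal: f=%.3g, "
            "MD(D*)=%.3g, MD(D)=%.3g",
            *init,
        )
    f0, mds0, md0 = init

    maps = {
        k: np.zeros(spatial, dtype=np.float32)
        for k in ("f", "md_d_star", "fa_d_star", "md_d", "fa_d", "residual")
    }
    maps["converged"] = np.zeros(spatial, dtype=np.float32)
    maps["dir_d_star"] = np.zeros(spatial + (3,), dtype=np.float32)
    maps["dir_d"] = np.zeros(spatial + (3,), dtype=np.float32)

    for idx in np.argwhere(mask):
        ix, iy, iz = idx
        res = IVIMDTI(data[ix, iy, iz], scheme).fit(
            method=method,
            options=options,
            b_cutoff=b_cutoff,
            f_init=f0,
            md_star_init=mds0,
            md_init=md0,
        )
        maps["f"][ix, iy, iz] = res.f
        maps["md_d_star"][ix, iy, iz] = res.md_d_star
        maps["fa_d_star"][ix, iy, iz] = res.fa_d_star
        maps["md_d"][ix, iy, iz] = res.md_d
        maps["fa_d"][ix, iy, iz] = res.fa_d
        maps["residual"][ix, iy, iz] = res.residual
        maps["converged"][ix, iy, iz] = float(res.converged)
        maps["dir_d_star"][ix, iy, iz] = res.principal_direction("d_star")
        maps["dir_d"][ix, iy, iz] = res.principal_direction("d")
    return maps
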