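"""IVIM-DTI signal equation, analytic Jacobian, and residual.

The voxel signal along gradient direction g at weighting b is the bi-tensor
mixture

    S = S0 ( f exp(-b gᵀ D* g) + (1 - f) exp(-b gᵀ D g) ),

with the vascular (pseudo-diffusion) tensor D* = UᵀU and the tissue diffusion
tensor D = VᵀV.  The Jacobian is computed analytically through the Cholesky
parameterization; a finite-difference oracle in the test suite pins it down.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .params import IDX_F, IDX_S0, N_PARAMS, SL_U, SL_V, ParamVector
from .scheme import AcquisitionScheme
from .tensors import _FACTOR_SLOTS, factor_matrix

__all__ = ["predict_signal", "jacobian", "residual"]

ArrayOrParams = Union[np.ndarray, ParamVector]


def _as_array(x: ArrayOrParams) -> np.ndarray:
    if isinstance(x, ParamVector):
        return x.to_array()
    return np.asarray(x, dtype=float).reshape(N_PARAMS)


def _attenuations(x: np.ndarray, scheme: AcquisitionScheme):
    """Per-measurement exponential attenuations of the two compartments."""
    u = factor_matrix(x[SL_U])
    v = factor_matrix(x[SL_V])
    g = scheme.bvecs
    ug = g @ u.T  # row i is U g_i
    vg = g @ v.T
    q_star = np.einsum("ij,ij->i", ug, ug)  # gᵀUᵀUg
    q = np.einsum("ij,ij->i", vg, vg)
    a_star = np.exp(-scheme.bvals * q_star)
    a = np.exp(-scheme.bvals * q)
    return a_star, a, ug, vg


def predict_signal(x: ArrayOrParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Model signal for every measurement of the scheme (equals S0 at b = 0)."""
    x = _as_array(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite parameter vector")
    a_star, a, _, _ = _attenuations(x, scheme)
    s0, f = x[IDX_S0], x[IDX_F]
    return s0 * (f * a_star + (1.0 - f) * a)


def jacobian(x: ArrayOrParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Analytic (n_measurements x 14) Jacobian of ``predict_signal``.

    Chain rule through the quadratic forms: with q* = gᵀUᵀUg,
    ∂q*/∂U_(r,c) = 2 (Ug)_r g_c, and the signal's U-columns are
    -b S0 f exp(-b q*) ∂q*/∂U; symmetrically for V with weight (1 - f).
    """
    x = _as_array(x)
    a_star, a, ug, vg = _attenuations(x, scheme)
    s0, f = x[IDX_S0], x[IDX_F]
    b = scheme.bvals
    g = scheme.bvecs
    n = len(scheme)
    jac = np.empty((n, N_PARAMS))
    jac[:, IDX_S0] = f * a_star + (1.0 - f) * a
    jac[:, IDX_F] = s0 * (a_star - a)
    w_star = -b * s0 * f * a_star
    w = -b * s0 * (1.0 - f) * a
    for k, (r, c) in enumerate(_FACTOR_SLOTS):
        jac[:, SL_U.start + k] = w_star * 2.0 * ug[:, r] * g[:, c]
        jac[:, SL_V.start + k] = w * 2.0 * vg[:, r] * g[:, c]
    return jac


def residual(y: np.ndarray, x: ArrayOrParams, scheme: AcquisitionScheme) -> float:
    """Squared-norm misfit R = ||Y - S(X)||²."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size != len(scheme):
        raise ValueError(
            f"signal length {y.size} does not match scheme length {len(scheme)}"
        )
    misfit = y - predict_signal(x, scheme)
    return float(misfit @ misfit)
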