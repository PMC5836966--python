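"""Symmetric 3x3 tensors via upper-triangular Cholesky factors.

Both the diffusion tensor D and the pseudo-diffusion tensor D* are kept
positive semidefinite by construction: each is represented by six components
``(c1..c6)`` of an upper-triangular factor

    U = [[c1, c4, c6],
         [ 0, c2, c5],
         [ 0,  0, c3]]

and reconstructed as ``T = U.T @ U``.  Any real-valued factor yields a PSD
tensor, so the fitting routines can iterate unconstrained.  Scalar measures
(mean diffusivity, fractional anisotropy) and the principal eigenvector used
for orientation-error maps live here too.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "cholesky_to_tensor",
    "tensor_to_cholesky",
    "factor_matrix",
    "mean_diffusivity",
    "fractional_anisotropy",
    "principal_direction",
    "angle_error",
    "DegenerateEigenvectorWarning",
]

# component index -> (row, col) in the upper-triangular factor
_FACTOR_SLOTS = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]


class DegenerateEigenvectorWarning(UserWarning):
    """Largest eigenvalue is (numerically) repeated; principal direction arbitrary."""


def factor_matrix(components: np.ndarray) -> np.ndarray:
    """Assemble the 3x3 upper-triangular factor from its six components."""
    c = np.asarray(components, dtype=float)
    if c.shape != (6,):
        raise ValueError(f"expected 6 Cholesky components, got shape {c.shape}")
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite Cholesky component")
    u = np.zeros((3, 3))
    for k, (i, j) in enumerate(_FACTOR_SLOTS):
        u[i, j] = c[k]
    return u


def cholesky_to_tensor(components: np.ndarray) -> np.ndarray:
    """Reconstruct the symmetric PSD tensor ``U.T @ U`` from factor components."""
    u = factor_matrix(components)
    return u.T @ u


def tensor_to_cholesky(t: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Upper-triangular factor of a symmetric PSD tensor (``t = U.T @ U``).

    Zero pivots are tolerated (rank-deficient tensors map to factors with zero
    rows), so the zero tensor round-trips.  Indefinite input raises
    ``np.linalg.LinAlgError``.  The returned factor has nonnegative diagonal,
    making it the canonical representative of its sign orbit.
    """
    t = np.asarray(t, dtype=float)
    if t.shape != (3, 3):
        raise ValueError(f"expected a 3x3 tensor, got shape {t.shape}")
    if not np.allclose(t, t.T, atol=1e-10 * max(1.0, np.abs(t).max())):
        raise ValueError("tensor is not symmetric")
    scale = max(np.abs(t).max(), 1.0)
    eps = tol * scale

    def _sqrt_pivot(val: float) -> float:
        if val < -eps:
            raise np.linalg.LinAlgError("tensor is not positive semidefinite")
        return np.sqrt(max(val, 0.0))

    c1 = _sqrt_pivot(t[0, 0])
    if c1 > eps:
        c4 = t[0, 1] / c1
        c6 = t[0, 2] / c1
    else:
        c1, c4, c6 = 0.0, 0.0, 0.0
        if abs(t[0, 1]) > eps or abs(t[0, 2]) > eps:
            raise np.linalg.LinAlgError("tensor is not positive semidefinite")
    c2 = _sqrt_pivot(t[1, 1] - c4 * c4)
    if c2 > eps:
        c5 = (t[1, 2] - c4 * c6) / c2
    else:
        c2, c5 = 0.0, 0.0
        if abs(t[1, 2] - c4 * c6) > eps:
            raise np.linalg.LinAlgError("tensor is not positive semidefinite")
    c3 = _sqrt_pivot(t[2, 2] - c6 * c6 - c5 * c5)
    return np.array([c1, c2, c3, c4, c5, c6])


def mean_diffusivity(t: np.ndarray) -> float:
    """Trace of the tensor divided by three (mm^2/s for diffusion tensors)."""
    t = np.asarray(t, dtype=float)
    return float(np.trace(t)) / 3.0


def fractional_anisotropy(t: np.ndarray) -> float:
    """Standard FA in [0, 1]; the zero tensor is defined to have FA 0."""
    t = np.asarray(t, dtype=float)
    lam = np.linalg.eigvalsh(t)
    denom = np.sqrt(np.sum(lam**2))
    if denom == 0.0:
        return 0.0
    dev = lam - lam.mean()
    fa = np.sqrt(1.5 * np.sum(dev**2)) / denom
    return float(min(max(fa, 0.0), 1.0))


def principal_direction(t: np.ndarray, degeneracy_rtol: float = 1e-8) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue.

    Sign convention: the first nonzero component is made positive so maps are
    reproducible.  If the top eigenvalue is numerically repeated a
    ``DegenerateEigenvectorWarning`` is emitted and any vector of the top
    eigenspace is returned.
    """
    t = np.asarray(t, dtype=float)
    lam, vec = np.linalg.eigh(t)
    v = vec[:, -1]
    gap_scale = max(abs(lam[-1]), abs(lam[0]), 1e-300)
    if (lam[-1] - lam[-2]) <= degeneracy_rtol * gap_scale:
        warnings.warn(
            "largest eigenvalue is degenerate; principal direction is arbitrary "
            "within the top eigenspace",
            DegenerateEigenvectorWarning,
            stacklevel=2,
        )
    for comp in v:
        if comp != 0.0:
            if comp < 0.0:
                v = -v
            break
    return v / np.linalg.norm(v)


def angle_error(v1: np.ndarray, v2: np.ndarray) -> float:
    """Axial angle between two directions, in degrees in [0, 90].

    Sign-invariant: v and -v describe the same fiber/vessel axis.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("angle_error requires nonzero vectors")
    c = abs(float(np.dot(v1, v2)) / (n1 * n2))
    return float(np.degrees(np.arccos(min(c, 1.0))))
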