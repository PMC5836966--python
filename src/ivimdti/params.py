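"""The 14-element IVIM-DTI parameter vector X = (S0, f, U1..U6, V1..V6)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tensors

__all__ = ["ParamVector", "IDX_S0", "IDX_F", "SL_U", "SL_V", "N_PARAMS"]

N_PARAMS = 14
IDX_S0 = 0
IDX_F = 1
SL_U = slice(2, 8)   # Cholesky components of the pseudo-diffusion tensor D*
SL_V = slice(8, 14)  # Cholesky components of the diffusion tensor D


@dataclass
class ParamVector:
    """Unknowns of the bi-tensor signal model for one voxel.

    ``u`` and ``v`` hold the six upper-triangular Cholesky components of the
    pseudo-diffusion tensor D* = UᵀU and the diffusion tensor D = VᵀV.
    """

    s0: float
    f: float
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float).reshape(6)
        self.v = np.asarray(self.v, dtype=float).reshape(6)
        if not np.all(np.isfinite(self.to_array())):
            raise ValueError("non-finite parameter entry")

    def to_array(self) -> np.ndarray:
        x = np.empty(N_PARAMS)
        x[IDX_S0] = self.s0
        x[IDX_F] = self.f
        x[SL_U] = self.u
        x[SL_V] = self.v
        return x

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ParamVector":
        x = np.asarray(x, dtype=float).reshape(N_PARAMS)
        return cls(s0=float(x[IDX_S0]), f=float(x[IDX_F]), u=x[SL_U].copy(), v=x[SL_V].copy())

    @property
    def d_star(self) -> np.ndarray:
        """Pseudo-diffusion tensor D* = UᵀU (mm^2/s)."""
        return tensors.cholesky_to_tensor(self.u)

    @property
    def d(self) -> np.ndarray:
        """Diffusion tensor D = VᵀV (mm^2/s)."""
        return tensors.cholesky_to_tensor(self.v)

    def canonical(self) -> "ParamVector":
        """Equivalent vector with canonical (nonnegative-diagonal) factors.

        The map U -> UᵀU is many-to-one; this resolves the sign ambiguity for
        parameter-level comparisons.
        """
        return ParamVector(
            s0=self.s0,
            f=self.f,
            u=tensors.tensor_to_cholesky(self.d_star),
            v=tensors.tensor_to_cholesky(self.d),
        )
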