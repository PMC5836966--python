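"""Diffusion acquisition scheme: b-values, gradient directions, pulse timing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionScheme"]


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-measurement b-values and unit gradient directions.

    Parameters
    ----------
    bvals : (n,) array, s/mm^2
        Diffusion weighting per measurement; zero entries are b0 images.
    bvecs : (n, 3) array
        Unit gradient directions for b > 0 measurements.  The direction of a
        b0 entry is irrelevant and conventionally stored as (0, 0, 0).
    delta : float, s
        Diffusion gradient pulse duration.
    Delta : float, s
        Separation of the two gradient pulses (``Delta >= delta > 0``).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    delta: float = 1.9e-3
    Delta: float = 2.0e-3

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        if not (self.Delta >= self.delta > 0):
            raise ValueError("pulse timing must satisfy Delta >= delta > 0")
        dwi = bvals > 0
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if dwi.any() and not np.allclose(norms, 1.0, atol=1e-3):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                f"non-unit gradient direction for diffusion-weighted entry {bad}"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(np.count_nonzero(self.b0_mask))

    def subset(self, mask: np.ndarray) -> "AcquisitionScheme":
        """Scheme restricted to the measurements selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return AcquisitionScheme(
            self.bvals[mask], self.bvecs[mask], self.delta, self.Delta
        )

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique b-values."""
        return np.unique(self.bvals)
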