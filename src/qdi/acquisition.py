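"""Acquisition scheme: b-values, gradient directions, shell grouping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionScheme", "SHELL_TOLERANCE"]

#: b-values within this tolerance (s/mm^2) are grouped into one shell.
SHELL_TOLERANCE = 50.0


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values and unit gradient directions.

    Attributes
    ----------
    bvals : ndarray, shape (n,)
        b-values in s/mm^2 (>= 0).
    bvecs : ndarray, shape (n, 3)
        Unit gradient directions; the zero vector for b = 0 volumes.
    delta_small, delta_big : float or None
        Gradient duration and separation in ms (metadata only).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    delta_small: float | None = None
    delta_big: float | None = None

    def __post_init__(self):
        b = np.asarray(self.bvals, dtype=float).ravel()
        v = np.asarray(self.bvecs, dtype=float)
        if v.shape != (b.size, 3):
            raise ValueError(f"bvecs shape {v.shape} != ({b.size}, 3)")
        if np.any(b < 0.0) or not np.all(np.isfinite(b)):
            raise ValueError("bvals must be finite and >= 0")
        norms = np.linalg.norm(v, axis=1)
        nz = b > 0.0
        if np.any(np.abs(norms[nz] - 1.0) > 1e-6):
            raise ValueError("non-zero-b directions must have unit norm (within 1e-6)")
        object.__setattr__(self, "bvals", b)
        object.__setattr__(self, "bvecs", v)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0.0

    def shells(self, tolerance: float = SHELL_TOLERANCE):
        """Group volumes into b-shells.

        Returns a list of ``(b_center, indices)`` sorted by b, where
        ``b_center`` is the mean b of the shell's volumes (handles
        scanner-reported jitter up to ``tolerance``).  The b = 0 shell, if
        present, comes first.
        """
        order = np.argsort(self.bvals, kind="stable")
        groups: list[list[int]] = []
        for idx in order:
            b = self.bvals[idx]
            if groups and b - self.bvals[groups[-1][0]] <= tolerance:
                groups[-1].append(int(idx))
            else:
                groups.append([int(idx)])
        return [(float(np.mean(self.bvals[g])), np.array(g, dtype=int)) for g in groups]

    def subset(self, indices) -> "AcquisitionScheme":
        idx = np.asarray(indices)
        return AcquisitionScheme(bvals=self.bvals[idx], bvecs=self.bvecs[idx],
                                 delta_small=self.delta_small, delta_big=self.delta_big)
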