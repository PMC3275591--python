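"""Diffusion gradient tables (b-values and unit direction vectors).

The acquisition emulated throughout the package is a single-shell
high-angular-resolution scheme: 126 diffusion-weighted measurements at
b = 3000 s/mm^2 plus one unweighted (b = 0) reference.  A reduced
30-direction shell is provided for fast desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GradientScheme",
    "spread_directions",
    "default_scheme",
    "read_bval_bvec",
    "write_bval_bvec",
]

#: Tolerance on the norm of a diffusion-weighted direction vector.
UNIT_NORM_TOL = 1e-3


@dataclass(frozen=True)
class GradientScheme:
    """One b-value and one direction per measurement.

    Directions are interpreted in image (voxel) coordinates, FSL style.
    Measurements with ``b == 0`` may carry a zero direction vector; all
    others must be unit vectors to within ``UNIT_NORM_TOL``.
    """

    b_values: np.ndarray  # (n,) s/mm^2
    directions: np.ndarray  # (n, 3) unit vectors (zero allowed when b == 0)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float).ravel()
        g = np.asarray(self.directions, dtype=float)
        if g.ndim != 2 or g.shape[1] != 3:
            raise ValueError(f"directions must be (n, 3), got {g.shape}")
        if b.shape[0] != g.shape[0]:
            raise ValueError(
                f"{b.shape[0]} b-values but {g.shape[0]} directions"
            )
        if np.any(b < 0):
            raise ValueError("negative b-values")
        if not np.any(b == 0):
            raise ValueError("scheme must contain at least one b = 0 measurement")
        if not np.any(b > 0):
            raise ValueError("no diffusion weighting: all b-values are zero")
        norms = np.linalg.norm(g[b > 0], axis=1)
        if np.any(np.abs(norms - 1.0) > UNIT_NORM_TOL):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                "non-unit gradient direction for a b > 0 measurement "
                f"(norm {norms[bad]:.6f})"
            )
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    def __len__(self) -> int:
        return self.b_values.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.b_values > 0

    @property
    def n_dwi(self) -> int:
        return int(np.count_nonzero(self.dwi_mask))


def spread_directions(n: int) -> np.ndarray:
    """Return ``n`` well-spread unit vectors on the sphere.

    Uses the spherical Fibonacci (golden-angle) point set, which gives a
    near-uniform angular coverage adequate for a well-conditioned tensor
    design matrix at any ``n >= 6``.  Deterministic.
    """
    if n < 1:
        raise ValueError("n must be positive")
    i = np.arange(n, dtype=float)
    # Offset 0.5 avoids placing points exactly at the poles.
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    g = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def default_scheme(n_directions: int = 126, b_value: float = 3000.0) -> GradientScheme:
    """Single-shell scheme: one b = 0 then ``n_directions`` at ``b_value``."""
    g = spread_directions(n_directions)
    b = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    directions = np.vstack([np.zeros(3), g])
    return GradientScheme(b, directions)


def read_bval_bvec(bval_path, bvec_path) -> GradientScheme:
    """Read FSL-dialect gradient tables (.bval one row, .bvec three rows)."""
    b = np.loadtxt(bval_path, dtype=float).ravel()
    g = np.loadtxt(bvec_path, dtype=float)
    if g.ndim != 2 or g.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows, got shape {g.shape}")
    if g.shape[1] != b.shape[0]:
        raise ValueError(
            f"bval has {b.shape[0]} entries but bvec has {g.shape[1]} columns"
        )
    return GradientScheme(b, g.T)


def write_bval_bvec(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")
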