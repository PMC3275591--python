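"""Per-voxel diffusion-tensor estimation and scalar/shape maps.

The single-tensor model is ``S_k = S0 * exp(-b_k * g_k^T D g_k)`` with a
symmetric positive tensor ``D`` (mm^2/s).  Fitting is log-linear least
squares for the six tensor components plus ``log S0``; weighted least
squares (weights ``S_k^2``, the first-order variance propagation of log
noise) is available as an option.  From the sorted eigenvalues
``l1 >= l2 >= l3`` the scalar maps are

    ADC    = (l1 + l2 + l3) / 3
    axial  = l1
    radial = (l2 + l3) / 2
    FA     = sqrt(3/2) * sqrt(sum (li - lbar)^2) / sqrt(sum li^2)

and the Westin shape coefficients, normalized by the trace so that the
three partition the anisotropy budget:

    linearity  = (l1 - l2) / (l1 + l2 + l3)
    planarity  = 2 (l2 - l3) / (l1 + l2 + l3)
    sphericity = 3 l3 / (l1 + l2 + l3)

which sum to 1 wherever the trace is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DWIVolume, check_same_grid
from .mask import BrainMask

__all__ = [
    "TensorField",
    "ScalarMapSet",
    "fit_tensors",
    "scalar_maps",
    "wm_mask_from_fa",
    "eigenvalues_to_fa",
    "design_matrix",
]

METRIC_NAMES = (
    "fa",
    "adc",
    "axial_diffusivity",
    "radial_diffusivity",
    "linearity",
    "planarity",
    "sphericity",
)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors with their eigen-systems.

    ``eigenvalues`` are sorted descending along the last axis; negative
    fitted eigenvalues are clamped to zero and counted in ``n_clamped``.
    ``eigenvectors[..., :, i]`` is the unit eigenvector of eigenvalue ``i``.
    """

    tensors: np.ndarray  # (X, Y, Z, 3, 3)
    eigenvalues: np.ndarray  # (X, Y, Z, 3) descending
    eigenvectors: np.ndarray  # (X, Y, Z, 3, 3)
    s0: np.ndarray  # (X, Y, Z)
    valid_mask: np.ndarray  # bool
    voxel_size: np.ndarray
    n_clamped: int = 0

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    @classmethod
    def from_eigensystem(
        cls, eigenvalues, eigenvectors, s0, valid_mask, voxel_size
    ) -> "TensorField":
        """Assemble D = V diag(l) V^T from an eigen-system (no clamping)."""
        lam = np.asarray(eigenvalues, dtype=float)
        vec = np.asarray(eigenvectors, dtype=float)
        tensors = np.einsum("...ij,...j,...kj->...ik", vec, lam, vec)
        return cls(
            tensors=tensors,
            eigenvalues=lam,
            eigenvectors=vec,
            s0=np.asarray(s0, dtype=float),
            valid_mask=np.asarray(valid_mask, dtype=bool),
            voxel_size=np.asarray(voxel_size, dtype=float),
        )


@dataclass
class ScalarMapSet:
    """The seven diffusion scalar maps on one grid, with a validity mask."""

    fa: np.ndarray
    adc: np.ndarray
    axial_diffusivity: np.ndarray
    radial_diffusivity: np.ndarray
    linearity: np.ndarray
    planarity: np.ndarray
    sphericity: np.ndarray
    valid_mask: np.ndarray
    degenerate_mask: np.ndarray = field(default=None)  # zero-trace voxels
    voxel_size: np.ndarray = field(default=None)

    def __getitem__(self, metric: str) -> np.ndarray:
        if metric not in METRIC_NAMES:
            raise KeyError(metric)
        return getattr(self, metric)

    @property
    def metrics(self) -> tuple[str, ...]:
        return METRIC_NAMES


def design_matrix(scheme) -> np.ndarray:
    """Rows ``[-b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz, 1]``.

    The unknowns are ``(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0)``.
    """
    b = scheme.b_values
    g = scheme.directions
    X = np.empty((len(scheme), 7))
    X[:, 0] = -b * g[:, 0] ** 2
    X[:, 1] = -b * g[:, 1] ** 2
    X[:, 2] = -b * g[:, 2] ** 2
    X[:, 3] = -2 * b * g[:, 0] * g[:, 1]
    X[:, 4] = -2 * b * g[:, 0] * g[:, 2]
    X[:, 5] = -2 * b * g[:, 1] * g[:, 2]
    X[:, 6] = 1.0
    return X


def _components_to_matrices(theta: np.ndarray) -> np.ndarray:
    """(n, 6) tensor components -> (n, 3, 3) symmetric matrices."""
    D = np.empty(theta.shape[:-1] + (3, 3))
    D[..., 0, 0] = theta[..., 0]
    D[..., 1, 1] = theta[..., 1]
    D[..., 2, 2] = theta[..., 2]
    D[..., 0, 1] = D[..., 1, 0] = theta[..., 3]
    D[..., 0, 2] = D[..., 2, 0] = theta[..., 4]
    D[..., 1, 2] = D[..., 2, 1] = theta[..., 5]
    return D


def fit_tensors(
    dwi: DWIVolume,
    mask: BrainMask,
    method: str = "ols",
    clamp_negative: bool = True,
) -> TensorField:
    """Log-linear least-squares tensor fit inside the brain mask.

    Voxels with any non-positive signal are excluded from ``valid_mask``
    (the log-signal is undefined there).  Eigenvalues are sorted descending;
    negatives are clamped to zero (``clamp_negative=False`` instead drops
    the voxel from ``valid_mask``).  Raises on a rank-deficient design
    matrix (collinear gradients).
    """
    check_same_grid(dwi.grid_shape, mask.mask.shape, "brain mask")
    scheme = dwi.scheme
    if scheme.n_dwi < 6:
        raise ValueError("need at least 6 diffusion-weighted measurements")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient design matrix: gradient directions are collinear")

    shape = dwi.grid_shape
    in_mask = mask.mask
    signals = dwi.data[in_mask]  # (n_vox, n_meas)
    positive = np.all(signals > 0, axis=1)
    log_s = np.log(np.where(signals > 0, signals, 1.0))

    if method == "ols":
        theta = log_s @ np.linalg.pinv(X).T
    elif method == "wls":
        # per-voxel weights S_k^2; solve each voxel's weighted normal equations
        theta = np.empty((signals.shape[0], 7))
        w = signals**2
        for i in range(signals.shape[0]):
            theta[i] = np.linalg.solve(X.T @ (w[i][:, None] * X), X.T @ (w[i] * log_s[i]))
    else:
        raise ValueError(f"unknown method {method!r}")

    D = _components_to_matrices(theta[:, :6])
    lam, vec = np.linalg.eigh(D)  # ascending
    lam = lam[:, ::-1]
    vec = vec[:, :, ::-1]

    negative = lam < 0
    n_clamped = int(np.count_nonzero(negative & positive[:, None]))
    if clamp_negative:
        lam = np.where(negative, 0.0, lam)
        valid_vox = positive
    else:
        valid_vox = positive & ~negative.any(axis=1)

    tensors = np.zeros(shape + (3, 3))
    eigenvalues = np.zeros(shape + (3,))
    eigenvectors = np.zeros(shape + (3, 3))
    eigenvectors[..., :, :] = np.eye(3)
    s0 = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)

    tensors[in_mask] = D
    eigenvalues[in_mask] = lam
    eigenvectors[in_mask] = vec
    s0[in_mask] = np.exp(theta[:, 6])
    valid[in_mask] = valid_vox

    return TensorField(
        tensors=tensors,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        s0=s0,
        valid_mask=valid,
        voxel_size=dwi.voxel_size,
        n_clamped=n_clamped,
    )


def eigenvalues_to_fa(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from eigenvalues (any leading shape, last axis length 3)."""
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def scalar_maps(tf: TensorField) -> ScalarMapSet:
    """Derive the seven scalar maps from a tensor field.

    Zero-trace voxels get 0 in all shape maps and are flagged in
    ``degenerate_mask`` (they stay inside ``valid_mask`` if the fit was
    valid; downstream masks should intersect with both as needed).
    """
    lam = tf.eigenvalues
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    trace = l1 + l2 + l3
    degenerate = trace <= 0
    safe = np.where(degenerate, 1.0, trace)
    return ScalarMapSet(
        fa=eigenvalues_to_fa(lam),
        adc=trace / 3.0,
        axial_diffusivity=l1,
        radial_diffusivity=(l2 + l3) / 2.0,
        linearity=np.where(degenerate, 0.0, (l1 - l2) / safe),
        planarity=np.where(degenerate, 0.0, 2.0 * (l2 - l3) / safe),
        sphericity=np.where(degenerate, 0.0, 3.0 * l3 / safe),
        valid_mask=tf.valid_mask.copy(),
        degenerate_mask=degenerate & tf.valid_mask,
        voxel_size=tf.voxel_size,
    )


def wm_mask_from_fa(fa: np.ndarray, brain: BrainMask, threshold: float = 0.20) -> BrainMask:
    """White-matter proxy mask: brain voxels with FA above the threshold.

    No morphology is applied.  An empty result is allowed (warning left to
    the caller's logging); the conventional default threshold is 0.20.
    """
    if not (0 <= threshold < 1):
        raise ValueError("FA threshold must lie in [0, 1)")
    check_same_grid(fa.shape, brain.mask.shape, "FA map")
    return BrainMask(brain.mask & (np.asarray(fa) > threshold), brain.voxel_size)
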