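"""Gaussian scale-space second derivatives and Hessian eigenanalysis.

The local shape of an image around a voxel is summarised by the 3x3
symmetric Hessian of the Gaussian-smoothed intensity.  Derivatives are
taken at a physical scale ``omega`` (the Gaussian standard deviation in
mm, converted per axis to voxel units through the spacing) and
gamma-normalised: each second derivative is multiplied by
``omega**gamma`` so responses are comparable across scales and the
cross-scale maximum of the vesselness score is meaningful.  With the
default ``gamma = 2`` a Gaussian-profile tube of cross-sectional
standard deviation ``s`` attains its strongest normalised axial
response exactly at ``omega = s``.

Eigenvalues are sorted by magnitude, ``|l1| <= |l2| <= |l3|``: for a
bright tube l1 is near zero and its eigenvector points along the vessel,
while l2 and l3 are large and negative across it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import Volume

logger = logging.getLogger(__name__)

# index pairs of the six unique Hessian components, (z, y, x) axis order
_COMPONENT_AXES = {
    "zz": (0, 0), "zy": (0, 1), "zx": (0, 2),
    "yy": (1, 1), "yx": (1, 2),
    "xx": (2, 2),
}


@dataclass
class HessianField:
    """Six unique second-derivative components per voxel, at one scale.

    Components are stored in a dict keyed ``zz, zy, zx, yy, yx, xx``
    (axis order (z, y, x)); units are intensity/mm^2 scaled by
    ``omega**gamma``.  The implied matrix is symmetric by construction.
    """

    components: dict[str, np.ndarray]
    scale: float
    gamma: float = 2.0

    def __post_init__(self) -> None:
        missing = set(_COMPONENT_AXES) - set(self.components)
        if missing:
            raise ValueError(f"missing Hessian components: {sorted(missing)}")
        shapes = {c.shape for c in self.components.values()}
        if len(shapes) != 1:
            raise ValueError(f"component shapes disagree: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.components.values())).shape

    def as_matrix_field(self) -> np.ndarray:
        """Assemble the full symmetric (..., 3, 3) matrix field."""
        H = np.empty(self.shape + (3, 3), dtype=np.float64)
        for name, (i, j) in _COMPONENT_AXES.items():
            H[..., i, j] = self.components[name]
            H[..., j, i] = self.components[name]
        return H


@dataclass
class EigenField:
    """Per-voxel Hessian eigenvalues (magnitude-sorted) and eigenvectors.

    ``lambda1..3`` satisfy ``|l1| <= |l2| <= |l3|`` voxelwise.  The
    eigenvector arrays (shape ``(..., 3)``, (z, y, x) components) are
    ``None`` when the decomposition was run values-only, which is all
    the vesselness score needs.
    """

    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray
    scale: float
    v1: np.ndarray | None = None
    v2: np.ndarray | None = None
    v3: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.lambda1.shape


def _gaussian_kernel1d(sigma: float, order: int, truncate: float = 4.0) -> np.ndarray:
    """Sampled Gaussian-derivative kernel, corrected for polynomial exactness.

    Truncating the analytic kernel leaves residual sums of order
    exp(-truncate^2/2), enough to make a constant image produce a
    non-zero 'second derivative'.  The corrections below are the usual
    discrete-exactness ones: unit mass (order 0), exact unit response
    on a ramp (order 1), zero sum and exact unit response on x^2/2
    (order 2).  Kernels are laid out for ``ndimage.correlate1d``.
    """
    radius = max(int(truncate * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    g /= g.sum()
    if order == 0:
        return g
    if order == 1:
        k = -x / sigma ** 2 * g          # analytic g'
        k -= k.mean()                     # exact zero response on constants
        return k / (k @ x)                # exact unit response on a ramp
    if order == 2:
        k = (x ** 2 - sigma ** 2) / sigma ** 4 * g   # analytic g''
        k -= k.mean()
        k -= x * (k @ x) / (x @ x)        # kill any odd residue
        return k / (k @ (x ** 2 / 2.0))  # exact unit response on x^2/2
    raise ValueError(f"unsupported derivative order {order}")


def gaussian_hessian(volume: Volume, scale: float, normalization_gamma: float = 2.0,
                     mode: str = "nearest") -> HessianField:
    """Scale-normalised Gaussian second derivatives of a volume.

    Each component is the image convolved with the corresponding
    second-derivative-of-Gaussian kernel at standard deviation ``scale``
    (mm; per-axis voxel sigma = scale / spacing), multiplied by
    ``scale**normalization_gamma``.  Boundaries use edge replication by
    default (``mode='nearest'``); ``'reflect'`` is available.

    Raises ``ValueError`` for non-positive scales; logs a warning when
    the scale undercuts the largest voxel spacing (undersmoothing).
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    spacing = np.asarray(volume.spacing, dtype=np.float64)
    if scale < spacing.max():
        logger.warning(
            "scale %.3g mm is below the largest voxel spacing %.3g mm; "
            "derivatives will be undersmoothed", scale, spacing.max())
    sigmas = scale / spacing  # voxel units per axis
    data = np.asarray(volume.data, dtype=np.float64)
    # Derivatives are invariant to intensity offsets; removing one makes a
    # constant volume an exact zero array (so its Hessian is exactly zero
    # rather than kernel-truncation dust) and improves conditioning.
    data = data - data.min()
    norm = float(scale) ** normalization_gamma
    components: dict[str, np.ndarray] = {}
    kernels = {axis: {o: _gaussian_kernel1d(sigmas[axis], o) for o in (0, 1, 2)}
               for axis in range(3)}
    for name, (i, j) in _COMPONENT_AXES.items():
        order = [0, 0, 0]
        order[i] += 1
        order[j] += 1
        deriv = data
        for axis in range(3):
            deriv = ndimage.correlate1d(deriv, kernels[axis][order[axis]],
                                        axis=axis, mode=mode)
        # kernels differentiate w.r.t. voxel index; rescale to per-mm.
        components[name] = deriv * (norm / (spacing[i] * spacing[j]))
    return HessianField(components=components, scale=float(scale),
                        gamma=float(normalization_gamma))


def _sort_by_magnitude(values: np.ndarray) -> np.ndarray:
    """Argsort eigenvalues ascending by |value|, ties by signed value ascending.

    ``values`` has shape (..., 3) and is already ascending by signed
    value (LAPACK order), so a stable sort on magnitude preserves the
    signed ascending order within magnitude ties.
    """
    return np.argsort(np.abs(values), axis=-1, kind="stable")


def eigen_decompose(hessian: HessianField, compute_vectors: bool = True) -> EigenField:
    """Per-voxel eigendecomposition of a symmetric Hessian field.

    Eigenvalues come back magnitude-sorted (``|l1| <= |l2| <= |l3|``);
    eigenvectors are column-matched, unit norm.  Set
    ``compute_vectors=False`` to skip eigenvectors (roughly halves the
    cost; vesselness only needs the values).
    """
    H = hessian.as_matrix_field()
    flat = H.reshape(-1, 3, 3)
    if compute_vectors:
        values, vectors = np.linalg.eigh(flat)
    else:
        values = np.linalg.eigvalsh(flat)
        vectors = None
    order = _sort_by_magnitude(values)
    values = np.take_along_axis(values, order, axis=-1)
    shape = hessian.shape
    out = {}
    if vectors is not None:
        # eigh returns eigenvectors as columns; reorder columns then expose rows
        vectors = np.take_along_axis(vectors, order[:, np.newaxis, :], axis=-1)
        for k in range(3):
            out[f"v{k + 1}"] = vectors[:, :, k].reshape(shape + (3,))
    return EigenField(
        lambda1=values[:, 0].reshape(shape),
        lambda2=values[:, 1].reshape(shape),
        lambda3=values[:, 2].reshape(shape),
        scale=hessian.scale,
        **out,
    )
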