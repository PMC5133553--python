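"""In-memory containers for volumetric data on a regular voxel grid.

All physical quantities are expressed in millimetres.  A :class:`VolumeGrid`
carries the voxel lattice (shape) together with the affine that maps 0-based
voxel indices to physical RAS coordinates; derivatives with respect to the
undeformed configuration are always taken in these physical coordinates.

Symmetric 3x3 tensors are stored as 6 unique components in the fixed order
``(xx, yy, zz, xy, yz, zx)`` (see :data:`TENSOR_COMPONENT_ORDER`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "TENSOR_COMPONENT_ORDER",
    "VolumeGrid",
    "ScalarMap",
    "TensorMap",
    "DisplacementField",
    "DeformationGradientField",
    "LabelAtlas",
    "GridMismatchError",
]

#: storage order of the 6 unique components of a symmetric 3x3 tensor
TENSOR_COMPONENT_ORDER: tuple[str, ...] = ("xx", "yy", "zz", "xy", "yz", "zx")

#: (row, col) index pairs matching TENSOR_COMPONENT_ORDER
_TENSOR_INDEX_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0),
)

#: relative tolerance for declaring two affines equal
AFFINE_RTOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when two volumes disagree in shape or affine."""


@dataclass(frozen=True)
class VolumeGrid:
    """A regular 3-D voxel lattice with a voxel-index -> mm affine.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    affine
        4x4 homogeneous matrix mapping 0-based voxel indices to physical
        coordinates in mm.  Must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be a positive integer triple, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        if np.any(spacing <= 0):
            raise ValueError(f"all spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def from_spacing(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "VolumeGrid":
        """Axis-aligned grid with the given voxel size (mm) and origin."""
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        affine[:3, 3] = origin
        return cls(tuple(shape), affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm along each axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to physical mm coordinates."""
        idx = np.asarray(indices, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, coords: np.ndarray) -> np.ndarray:
        """Map (..., 3) physical mm coordinates to (fractional) voxel indices."""
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(coords, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def coordinates(self) -> np.ndarray:
        """Physical coordinates of every voxel centre, shape ``shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)

    def matches(self, other: "VolumeGrid", rtol: float = AFFINE_RTOL) -> bool:
        if self.shape != other.shape:
            return False
        scale = max(np.abs(self.affine).max(), 1.0)
        return bool(np.allclose(self.affine, other.affine, rtol=0.0, atol=rtol * scale))

    def require_matches(self, other: "VolumeGrid", what: str = "volumes") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what} live on different grids: "
                f"shape {self.shape} vs {other.shape}, affines differ beyond tolerance"
            )


def _default_mask(shape: tuple[int, ...]) -> np.ndarray:
    return np.ones(shape, dtype=bool)


def _check_mask(mask: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid shape {shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


@dataclass
class ScalarMap:
    """One real value per voxel (e.g. a Jacobian-determinant map)."""

    grid: VolumeGrid
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = _default_mask(self.grid.shape)
        self.mask = _check_mask(self.mask, self.grid.shape)

    def masked(self) -> np.ndarray:
        """Values at masked voxels as a 1-D array."""
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, **meta) -> "ScalarMap":
        return ScalarMap(self.grid, values, self.mask.copy(), {**self.meta, **meta})


@dataclass
class TensorMap:
    """A symmetric 3x3 tensor per voxel, stored as 6 unique components.

    Component order is ``(xx, yy, zz, xy, yz, zx)``; the reconstructed
    3x3 matrices are exactly symmetric by construction.
    """

    grid: VolumeGrid
    values: np.ndarray  # shape + (6,)
    mask: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape + (6,):
            raise ValueError(
                f"tensor values must have shape {self.grid.shape + (6,)}, "
                f"got {self.values.shape}"
            )
        if self.mask is None:
            self.mask = _default_mask(self.grid.shape)
        self.mask = _check_mask(self.mask, self.grid.shape)
        self.meta.setdefault("tensor_order", ",".join(TENSOR_COMPONENT_ORDER))

    def as_matrices(self) -> np.ndarray:
        """Full symmetric 3x3 matrices, shape ``shape + (3, 3)``."""
        m = np.zeros(self.grid.shape + (3, 3))
        for comp, (i, j) in zip(range(6), _TENSOR_INDEX_PAIRS):
            m[..., i, j] = self.values[..., comp]
            if i != j:
                m[..., j, i] = self.values[..., comp]
        return m

    @classmethod
    def from_matrices(
        cls,
        grid: VolumeGrid,
        matrices: np.ndarray,
        mask: np.ndarray | None = None,
        meta: dict | None = None,
    ) -> "TensorMap":
        matrices = np.asarray(matrices, dtype=float)
        if matrices.shape != grid.shape + (3, 3):
            raise ValueError(f"matrices must have shape {grid.shape + (3, 3)}")
        # symmetrise to guard against round-off asymmetry
        sym = 0.5 * (matrices + np.swapaxes(matrices, -1, -2))
        vals = np.stack([sym[..., i, j] for i, j in _TENSOR_INDEX_PAIRS], axis=-1)
        return cls(grid, vals, mask, meta or {})

    def component(self, name: str) -> np.ndarray:
        """One component plane by name, e.g. ``'xy'``."""
        return self.values[..., TENSOR_COMPONENT_ORDER.index(name)]


@dataclass
class DisplacementField:
    """Voxel-wise displacement u(X) in mm with semantics x = X + u(X).

    X is the undeformed (earlier-time) configuration; x the deformed one.
    """

    grid: VolumeGrid
    u: np.ndarray  # shape + (3,)
    mask: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != self.grid.shape + (3,):
            raise ValueError(
                f"displacement must have shape {self.grid.shape + (3,)}, got {self.u.shape}"
            )
        if self.mask is None:
            self.mask = _default_mask(self.grid.shape)
        self.mask = _check_mask(self.mask, self.grid.shape)
        bad = ~np.isfinite(self.u[self.mask]).all(axis=-1)
        if bad.any():
            raise ValueError(
                f"displacement is non-finite at {int(bad.sum())} masked voxel(s)"
            )


@dataclass
class DeformationGradientField:
    """Per-voxel deformation gradient F = I + du/dX (dimensionless)."""

    grid: VolumeGrid
    F: np.ndarray  # shape + (3, 3)
    mask: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != self.grid.shape + (3, 3):
            raise ValueError(
                f"F must have shape {self.grid.shape + (3, 3)}, got {self.F.shape}"
            )
        if self.mask is None:
            self.mask = _default_mask(self.grid.shape)
        self.mask = _check_mask(self.mask, self.grid.shape)
        if not np.isfinite(self.F[self.mask]).all():
            raise ValueError("F is non-finite at masked voxels")


@dataclass
class LabelAtlas:
    """Integer-labelled parcellation; 0 is background."""

    grid: VolumeGrid
    labels: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValueError("atlas labels must be integer-valued")
            labels = np.round(labels).astype(np.int32)
        if labels.shape != self.grid.shape:
            raise ValueError(
                f"label shape {labels.shape} does not match grid {self.grid.shape}"
            )
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels
        self.names = {int(k): str(v) for k, v in dict(self.names).items()}
        present = {int(v) for v in np.unique(labels)} - {0}
        unnamed = sorted(present - set(self.names))
        if unnamed:
            raise ValueError(f"labels present in the volume but unnamed: {unnamed}")

    @property
    def roi_labels(self) -> list[int]:
        """Sorted nonzero labels present in the volume."""
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)

    def roi_mask(self, label: int) -> np.ndarray:
        return self.labels == label
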