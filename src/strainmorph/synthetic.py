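"""Synthetic inputs with closed-form ground truth.

Two kinds of test inputs replace longitudinal MRI data:

* **Analytic deformations** — displacement fields u(X) whose deformation
  gradient, Jacobian determinant and Lagrange strain are known in closed
  form at every point, used as oracles for the finite-strain code.  The
  catalogue covers affine fields (for which central differences are exact),
  rigid rotations (E must vanish), simple shear, uniform scaling, and a
  smooth Gaussian radial expansion for discretisation-order studies.

* **Simulated longitudinal cohorts** — per-(subject, interval) parameter
  maps following the random-intercept model
  y_ij(v) = b0 + b1 * age_ij * blob(v) + u_i + e_ij(v),
  with a per-subject intercept u_i ~ N(0, s2_b) shared across voxels, i.i.d.
  Gaussian voxel noise, and the age effect confined to a known "blob"
  region, so that voxel-wise statistics can be checked against ground truth.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    DeformationGradientField,
    DisplacementField,
    LabelAtlas,
    ScalarMap,
    TensorMap,
    VolumeGrid,
)

__all__ = [
    "AnalyticDeformation",
    "sample_field",
    "make_phantom_atlas",
    "SyntheticCohortSpec",
    "simulate_cohort",
    "simulate_scalar_cohort",
    "default_grid",
    "ellipsoid_mask",
]

#: paper-style scan schedule: scans at 14 d and 3/6/9/12 months give these
#: interval midpoints (days) and lengths (days)
DEFAULT_MIDPOINT_AGES = (45.0, 145.0, 234.0, 325.0)
DEFAULT_INTERVAL_DAYS = (77.0, 91.0, 92.0, 91.0)
DEFAULT_INTERVAL_IDS = ("0-3", "3-6", "6-9", "9-12")


def default_grid(n: int = 32, spacing: float = 2.0) -> VolumeGrid:
    """Cubic test grid, centred on the origin."""
    origin = -spacing * (n - 1) / 2.0
    return VolumeGrid.from_spacing((n, n, n), (spacing,) * 3, (origin,) * 3)


# ---------------------------------------------------------------------------
# analytic deformations
# ---------------------------------------------------------------------------


def _rotation_matrix(angle_rad: float, axis: str) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    i = "xyz".index(axis)
    j, k = (i + 1) % 3, (i + 2) % 3
    R = np.eye(3)
    R[j, j], R[j, k] = c, -s
    R[k, j], R[k, k] = s, c
    return R


@dataclass(frozen=True)
class AnalyticDeformation:
    """A deformation x = X + u(X) with closed-form u, F, JD and E.

    Use the constructors (:meth:`affine`, :meth:`rigid_rotation`,
    :meth:`simple_shear`, :meth:`uniform_scale`,
    :meth:`gaussian_expansion`) rather than instantiating directly.
    """

    kind: str
    A: np.ndarray | None = None  # displacement gradient for affine kinds
    b: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    alpha: float = 0.0  # gaussian amplitude
    sigma: float = 1.0  # gaussian width (mm)

    # -- constructors -------------------------------------------------------

    @classmethod
    def affine(cls, A: np.ndarray, b=(0.0, 0.0, 0.0)) -> "AnalyticDeformation":
        """u(X) = A X + b, so F = I + A everywhere."""
        A = np.asarray(A, dtype=float)
        if A.shape != (3, 3):
            raise ValueError("A must be 3x3")
        return cls(kind="affine", A=A, b=np.asarray(b, float))

    @classmethod
    def rigid_rotation(
        cls, angle_deg: float, axis: str = "z", center=(0.0, 0.0, 0.0)
    ) -> "AnalyticDeformation":
        """u(X) = (R - I)(X - c): a proper rotation, JD = 1 and E = 0."""
        R = _rotation_matrix(np.deg2rad(angle_deg), axis)
        return cls(kind="rigid_rotation", A=R - np.eye(3), center=np.asarray(center, float))

    @classmethod
    def simple_shear(cls, gamma: float, plane: str = "xy") -> "AnalyticDeformation":
        """u_i = gamma * X_j for plane 'ij': F_ij = gamma, diag F = 1."""
        i, j = ("xyz".index(plane[0]), "xyz".index(plane[1]))
        if i == j:
            raise ValueError("shear plane needs two distinct axes")
        A = np.zeros((3, 3))
        A[i, j] = gamma
        return cls(kind="simple_shear", A=A)

    @classmethod
    def uniform_scale(cls, s: float, center=(0.0, 0.0, 0.0)) -> "AnalyticDeformation":
        """Isotropic scaling about a centre: F = s I, JD = s^3."""
        if s <= 0:
            raise ValueError("scale must be positive")
        return cls(
            kind="uniform_scale",
            A=(s - 1.0) * np.eye(3),
            center=np.asarray(center, float),
        )

    @classmethod
    def gaussian_expansion(
        cls, alpha: float, sigma: float, center=(0.0, 0.0, 0.0)
    ) -> "AnalyticDeformation":
        """Smooth radial expansion u = alpha * exp(-r^2/(2 sigma^2)) * (X - c).

        F has eigenvalues 1 + alpha*g (twice, tangential) and
        1 + alpha*g*(1 - r^2/sigma^2) (radial); the radial factor attains its
        global minimum 1 - 2 alpha e^{-3/2} at r = sigma*sqrt(3), so the
        field is fold-free iff -1 < alpha < e^{3/2}/2.  Construction fails
        outside that range.
        """
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        alpha_max = 0.5 * np.exp(1.5)
        if not (-1.0 < alpha < alpha_max):
            raise ValueError(
                f"gaussian_expansion folds (JD <= 0 somewhere) for alpha={alpha}; "
                f"need -1 < alpha < {alpha_max:.4f}"
            )
        return cls(
            kind="gaussian_expansion",
            alpha=float(alpha),
            sigma=float(sigma),
            center=np.asarray(center, float),
        )

    # -- closed forms -------------------------------------------------------

    def u(self, X: np.ndarray) -> np.ndarray:
        """Displacement (mm) at physical points X, shape (..., 3)."""
        X = np.asarray(X, dtype=float)
        d = X - self.center
        if self.kind == "gaussian_expansion":
            g = np.exp(-(d**2).sum(axis=-1, keepdims=True) / (2.0 * self.sigma**2))
            return self.alpha * g * d
        return d @ self.A.T + self.b

    def F(self, X: np.ndarray) -> np.ndarray:
        """Deformation gradient at X, shape (..., 3, 3)."""
        X = np.asarray(X, dtype=float)
        if self.kind == "gaussian_expansion":
            d = X - self.center
            g = np.exp(-(d**2).sum(axis=-1) / (2.0 * self.sigma**2))
            eye = np.broadcast_to(np.eye(3), X.shape[:-1] + (3, 3))
            outer = d[..., :, None] * d[..., None, :] / self.sigma**2
            return eye + self.alpha * g[..., None, None] * (eye - outer)
        return np.broadcast_to(np.eye(3) + self.A, X.shape[:-1] + (3, 3)).copy()

    def jd(self, X: np.ndarray) -> np.ndarray:
        return np.linalg.det(self.F(X))

    def E(self, X: np.ndarray) -> np.ndarray:
        """Lagrange strain (F'F - I)/2 at X, shape (..., 3, 3)."""
        F = self.F(X)
        return 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(3))


def sample_field(
    deformation: AnalyticDeformation,
    grid: VolumeGrid,
    mask: np.ndarray | None = None,
) -> tuple[DisplacementField, dict]:
    """Sample a deformation at voxel centres, with oracle strain maps.

    Returns the displacement field plus a dict of closed-form maps
    (``'F'``: :class:`DeformationGradientField`, ``'jd'``: ScalarMap,
    ``'E'``: TensorMap) for checking the finite-difference pipeline.
    """
    X = grid.coordinates()
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    fld = DisplacementField(grid, deformation.u(X), mask)
    F = deformation.F(X)
    jd = np.linalg.det(F)
    if (jd[mask] <= 0).any():
        raise ValueError(
            f"deformation folds on this grid: {int((jd[mask] <= 0).sum())} voxels with JD <= 0"
        )
    oracle = {
        "F": DeformationGradientField(grid, F, mask.copy()),
        "jd": ScalarMap(grid, jd, mask.copy()),
        "E": TensorMap.from_matrices(grid, deformation.E(X), mask.copy()),
    }
    return fld, oracle


# ---------------------------------------------------------------------------
# phantom atlas
# ---------------------------------------------------------------------------


def ellipsoid_mask(grid: VolumeGrid, semi_axes_frac=(0.42, 0.42, 0.42)) -> np.ndarray:
    """Ellipsoidal 'brain' mask centred in the grid's field of view."""
    idx = np.stack(
        np.meshgrid(*(np.arange(s) for s in grid.shape), indexing="ij"), axis=-1
    ).astype(float)
    half = (np.array(grid.shape) - 1) / 2.0
    semi = np.array(semi_axes_frac) * np.array(grid.shape)
    r2 = (((idx - half) / semi) ** 2).sum(axis=-1)
    return r2 <= 1.0


def make_phantom_atlas(
    grid: VolumeGrid, n_rois: int, semi_axes_frac=(0.42, 0.42, 0.42)
) -> tuple[LabelAtlas, np.ndarray]:
    """Deterministic partition of an ellipsoidal mask into contiguous ROIs.

    Masked voxels are sorted along the first axis (ties broken by the other
    indices) and split into ``n_rois`` equal-count slabs, so every ROI is
    non-empty, the ROIs are pairwise disjoint, and their union is the mask.
    """
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    mask = ellipsoid_mask(grid, semi_axes_frac)
    n_vox = int(mask.sum())
    if n_vox < n_rois:
        raise ValueError(f"grid too small: {n_vox} masked voxels for {n_rois} ROIs")
    labels = np.zeros(grid.shape, dtype=np.int32)
    order = np.argsort(
        np.ravel_multi_index(np.nonzero(mask), grid.shape), kind="stable"
    )
    flat_idx = np.flatnonzero(mask.reshape(-1))[order]
    chunks = np.array_split(flat_idx, n_rois)
    lab_flat = labels.reshape(-1)
    for i, chunk in enumerate(chunks, start=1):
        lab_flat[chunk] = i
    names = {i: f"ROI_{i:03d}" for i in range(1, n_rois + 1)}
    return LabelAtlas(grid, labels, names), mask


# ---------------------------------------------------------------------------
# longitudinal cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Design of a simulated longitudinal cohort of growth-parameter maps.

    Defaults mirror a first-year-of-life longitudinal study: 33 subjects
    imaged at 5 time points (2 weeks, 3, 6, 9, 12 months), giving 4 growth
    intervals with midpoint ages of roughly 45, 145, 234 and 325 days; the
    age effect is a linear decline of the growth rate (b1 = -0.002 per day
    of midpoint age), between-subject SD 0.05, voxel noise SD 0.02.
    """

    n_subjects: int = 33
    midpoint_age_days: tuple[float, ...] = DEFAULT_MIDPOINT_AGES
    days_between_scans: tuple[float, ...] = DEFAULT_INTERVAL_DAYS
    interval_ids: tuple[str, ...] = DEFAULT_INTERVAL_IDS
    beta0: float = 1.2
    beta1: float = -0.002  # per day of midpoint age, inside the blob
    sigma_b: float = 0.05  # between-subject (random intercept) SD
    sigma_e: float = 0.02  # residual SD per voxel-observation
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.midpoint_age_days)
        if not (len(self.days_between_scans) == len(self.interval_ids) == k):
            raise ValueError("interval schedule tuples must have equal length")
        if self.n_subjects < 2 or k < 2:
            raise ValueError("need >= 2 subjects and >= 2 intervals")
        if min(self.days_between_scans) <= 0 or min(self.midpoint_age_days) <= 0:
            raise ValueError("ages and interval lengths must be positive")
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def n_intervals(self) -> int:
        return len(self.midpoint_age_days)


def _cohort_frame(spec: SyntheticCohortSpec) -> pd.DataFrame:
    rows = []
    for s in range(spec.n_subjects):
        for k in range(spec.n_intervals):
            rows.append(
                {
                    "subject_id": f"sub-{s + 1:03d}",
                    "interval_id": spec.interval_ids[k],
                    "days_between_scans": spec.days_between_scans[k],
                    "midpoint_age_days": spec.midpoint_age_days[k],
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: SyntheticCohortSpec,
    grid: VolumeGrid,
    blob: np.ndarray,
    brain_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ScalarMap], pd.DataFrame]:
    """Simulate per-(subject, interval) parameter maps with a known age effect.

    y_ij(v) = b0 + b1 * age_ij * blob(v) + u_i + e_ij(v), with the subject
    intercept u_i shared across voxels of all of subject i's maps and e
    i.i.d. per voxel-observation.  Returns the maps (aligned row-for-row
    with the cohort table) and the table itself.
    """
    if brain_mask is None:
        brain_mask = np.ones(grid.shape, dtype=bool)
    if blob.shape != grid.shape:
        raise ValueError("blob mask shape must match grid")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cohort = _cohort_frame(spec)
    b = rng.normal(0.0, spec.sigma_b, size=spec.n_subjects)
    blob_f = blob.astype(float)
    maps: list[ScalarMap] = []
    for row_i, row in enumerate(cohort.itertuples()):
        subj = row_i // spec.n_intervals
        signal = spec.beta0 + spec.beta1 * row.midpoint_age_days * blob_f + b[subj]
        noise = rng.normal(0.0, spec.sigma_e, size=grid.shape)
        maps.append(ScalarMap(grid, signal + noise, brain_mask.copy()))
    return maps, cohort


def simulate_scalar_cohort(
    spec: SyntheticCohortSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One scalar response per (subject, interval): the cohort model at a
    single voxel inside the effect region.

    Used for mixed-model parameter-recovery studies without the voxel loop.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cohort = _cohort_frame(spec)
    b = rng.normal(0.0, spec.sigma_b, size=spec.n_subjects)
    subj_idx = np.repeat(np.arange(spec.n_subjects), spec.n_intervals)
    age = cohort["midpoint_age_days"].to_numpy()
    y = (
        spec.beta0
        + spec.beta1 * age
        + b[subj_idx]
        + rng.normal(0.0, spec.sigma_e, size=len(cohort))
    )
    return cohort.assign(y=y)
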