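"""Finite-strain analysis of voxel-wise displacement fields.

Given a displacement field u(X) with the pull-from-reference convention
x = X + u(X), this module computes, per voxel:

* the deformation gradient  F = I + du/dX  (derivatives in physical mm),
* the Jacobian determinant  JD = det(F), the local volume-change ratio
  (JD > 1 expansion, JD < 1 contraction, JD <= 0 folding),
* the Green-Lagrange strain  E = (F'F - I)/2, whose diagonal components are
  directional normal strains and off-diagonals shear strains,
* principal stretches  lambda_i = sqrt(1 + 2 e_i)  from the eigenvalues e_i
  of E (unit extension along principal direction i is lambda_i - 1),
* the anisotropy of directional growth (ADG), a fractional-anisotropy-style
  normalised dispersion of the three principal stretches, and
* signed shear deformation angles  theta_ij = arcsin(2 E_ij / (lambda_i
  lambda_j)),  the reduction of the angle between originally perpendicular
  axis-aligned line elements.

E is objective: any rigid rotation of the deformed configuration leaves it
unchanged, which is why it is preferred over the raw Jacobian matrix for
directional growth mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import (
    DeformationGradientField,
    DisplacementField,
    ScalarMap,
    TensorMap,
    VolumeGrid,
)

__all__ = [
    "deformation_gradient",
    "jacobian_determinant",
    "lagrange_strain",
    "principal_stretches",
    "adg",
    "deformation_angles",
    "compute_strain_field",
    "StrainField",
    "ADG_NORMALISATION",
]

#: FA-style normalisation constant so that ADG -> 1 in the fully anisotropic limit
ADG_NORMALISATION = np.sqrt(1.5)

# 6-connected structuring element: central differences need the +/-1
# neighbours along each axis
_CROSS = ndimage.generate_binary_structure(3, 1)


def deformation_gradient(
    dispfield: DisplacementField, scheme: str = "central"
) -> DeformationGradientField:
    """Per-voxel deformation gradient F = I + du/dX.

    Derivatives are taken in physical units: voxel-index differences are
    mapped through the inverse of the affine's linear part, so anisotropic
    spacing and oblique grids are handled uniformly.

    Parameters
    ----------
    dispfield
        Displacement field u(X) in mm.
    scheme
        ``"central"`` (second order; output mask eroded by one voxel) or
        ``"forward"`` (first order; a voxel stays masked if its +1
        neighbour along every axis is masked).
    """
    grid = dispfield.grid
    if np.any(grid.spacing <= 0):
        raise ValueError("grid spacing must be positive")
    u = np.where(dispfield.mask[..., None], dispfield.u, 0.0)

    if scheme == "central":
        # du/d(index): np.gradient uses central differences on the interior
        dudi = np.stack(np.gradient(u, axis=(0, 1, 2)), axis=-1)  # (..., 3, 3)
        out_mask = ndimage.binary_erosion(dispfield.mask, structure=_CROSS)
        # border voxels of the array use one-sided stencils; drop them too
        border = np.zeros(grid.shape, dtype=bool)
        border[1:-1, 1:-1, 1:-1] = True
        out_mask &= border
    elif scheme == "forward":
        dudi = np.zeros(grid.shape + (3, 3))
        out_mask = dispfield.mask.copy()
        for ax in range(3):
            sl_hi = [slice(None)] * 3
            sl_lo = [slice(None)] * 3
            sl_hi[ax] = slice(1, None)
            sl_lo[ax] = slice(None, -1)
            dudi[tuple(sl_lo) + (slice(None), ax)] = (
                u[tuple(sl_hi)] - u[tuple(sl_lo)]
            )
            valid = np.zeros(grid.shape, dtype=bool)
            valid[tuple(sl_lo)] = dispfield.mask[tuple(sl_hi)]
            out_mask &= valid
    else:
        raise ValueError(f"unknown derivative scheme {scheme!r}")

    if not out_mask.any():
        raise ValueError(
            f"mask too thin for {scheme} differences: "
            f"{int(dispfield.mask.sum())} input voxels leave 0 valid voxels"
        )

    # d(index)/dX = inv(L) with L the affine's linear part, so
    # du/dX = du/d(index) @ inv(L)
    inv_lin = np.linalg.inv(grid.affine[:3, :3])
    dudX = dudi @ inv_lin
    F = dudX + np.eye(3)
    F[~out_mask] = np.eye(3)  # keep container finite outside the mask
    return DeformationGradientField(grid, F, out_mask, {"scheme": scheme})


def jacobian_determinant(Ffield: DeformationGradientField) -> ScalarMap:
    """JD = det(F): local volume-change ratio.

    Voxels with JD <= 0 (folding) are retained in the map but counted in
    ``meta['n_folding']``.
    """
    jd = np.linalg.det(Ffield.F)
    n_fold = int((jd[Ffield.mask] <= 0).sum())
    return ScalarMap(Ffield.grid, jd, Ffield.mask.copy(), {"n_folding": n_fold})


def lagrange_strain(Ffield: DeformationGradientField) -> TensorMap:
    """Green-Lagrange strain E = (F'F - I)/2, symmetric by construction."""
    FtF = np.swapaxes(Ffield.F, -1, -2) @ Ffield.F
    E = 0.5 * (FtF - np.eye(3))
    return TensorMap.from_matrices(Ffield.grid, E, Ffield.mask.copy())


def principal_stretches(Emap: TensorMap) -> tuple[ScalarMap, ScalarMap, ScalarMap]:
    """Principal stretches lambda_i = sqrt(1 + 2 e_i), sorted descending.

    Eigenvalues e_i <= -1/2 would give imaginary stretches (a line element
    compressed to nothing or through itself); such voxels are masked out and
    counted in ``meta['n_invalid_stretch']``.
    """
    e = np.linalg.eigvalsh(Emap.as_matrices())  # ascending
    valid = Emap.mask & (e[..., 0] > -0.5)
    n_invalid = int((Emap.mask & ~valid).sum())
    lam = np.sqrt(np.clip(1.0 + 2.0 * e, 0.0, None))[..., ::-1]  # descending
    meta = {"n_invalid_stretch": n_invalid}
    return tuple(
        ScalarMap(Emap.grid, lam[..., i], valid.copy(), dict(meta)) for i in range(3)
    )


def adg(lam1: ScalarMap, lam2: ScalarMap, lam3: ScalarMap) -> ScalarMap:
    """Anisotropy of directional growth from the three principal stretches.

    The fractional-anisotropy form

        ADG = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||

    is 0 for isotropic growth (all stretches equal) and approaches 1 when a
    single direction dominates; it is invariant to permutation and positive
    rescaling of the stretches.
    """
    lam = np.stack([lam1.values, lam2.values, lam3.values], axis=-1)
    mask = lam1.mask & lam2.mask & lam3.mask
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ADG_NORMALISATION * num / den
    out = np.where(den > 0, out, 0.0)
    return ScalarMap(
        lam1.grid, out, mask, {"adg_normalisation": float(ADG_NORMALISATION)}
    )


def deformation_angles(
    Emap: TensorMap,
) -> tuple[ScalarMap, ScalarMap, ScalarMap]:
    """Signed shear angles (theta_xy, theta_yz, theta_zx) in radians.

    theta_ij = arcsin(2 E_ij / (lambda_i lambda_j)) with the axis-aligned
    stretches lambda_i = sqrt(1 + 2 E_ii): the reduction of the angle between
    line elements initially along axes i and j.  Voxels where the arcsin
    argument falls outside [-1, 1] (non-physical strain) are masked out and
    counted in ``meta['n_invalid_angle']``.
    """
    Exx = Emap.component("xx")
    Eyy = Emap.component("yy")
    Ezz = Emap.component("zz")
    diag_ok = (Exx > -0.5) & (Eyy > -0.5) & (Ezz > -0.5)
    lam_x = np.sqrt(np.clip(1 + 2 * Exx, 0, None))
    lam_y = np.sqrt(np.clip(1 + 2 * Eyy, 0, None))
    lam_z = np.sqrt(np.clip(1 + 2 * Ezz, 0, None))

    out: list[ScalarMap] = []
    pairs = (("xy", lam_x, lam_y), ("yz", lam_y, lam_z), ("zx", lam_z, lam_x))
    for name, li, lj in pairs:
        with np.errstate(invalid="ignore", divide="ignore"):
            s = 2.0 * Emap.component(name) / (li * lj)
        valid = Emap.mask & diag_ok & (np.abs(s) <= 1.0)
        n_invalid = int((Emap.mask & ~valid).sum())
        theta = np.arcsin(np.clip(s, -1.0, 1.0))
        theta[~valid] = 0.0
        out.append(
            ScalarMap(Emap.grid, theta, valid, {"n_invalid_angle": n_invalid})
        )
    return tuple(out)


@dataclass
class StrainField:
    """All per-voxel finite-strain quantities derived from one displacement field."""

    grid: VolumeGrid
    F: DeformationGradientField
    jd: ScalarMap
    E: TensorMap
    stretches: tuple[ScalarMap, ScalarMap, ScalarMap]  # lambda1 >= lambda2 >= lambda3
    adg: ScalarMap
    angles: tuple[ScalarMap, ScalarMap, ScalarMap]  # theta_xy, theta_yz, theta_zx
    mask: np.ndarray = None  # type: ignore[assignment]
    qc: dict = field(default_factory=dict)

    def scalar_maps(self) -> dict[str, ScalarMap]:
        """Named scalar maps: jd, Exx..Ezx, lambda1-3, adg, theta_*."""
        maps = {"jd": self.jd, "adg": self.adg}
        for comp in ("xx", "yy", "zz", "xy", "yz", "zx"):
            maps[f"E{comp}"] = ScalarMap(
                self.grid, self.E.component(comp), self.E.mask.copy()
            )
        for i, lam in enumerate(self.stretches, start=1):
            maps[f"lambda{i}"] = lam
        for name, th in zip(("theta_xy", "theta_yz", "theta_zx"), self.angles):
            maps[name] = th
        return maps


def compute_strain_field(
    dispfield: DisplacementField, scheme: str = "central"
) -> StrainField:
    """Full per-voxel strain analysis of one displacement field.

    Chains gradient -> JD -> E -> stretches -> ADG -> angles; one common
    mask (the gradient stencil's valid voxels) is propagated, and QC counts
    (folding voxels, invalid stretches/angles) are collected.
    """
    F = deformation_gradient(dispfield, scheme=scheme)
    jd = jacobian_determinant(F)
    E = lagrange_strain(F)
    lam1, lam2, lam3 = principal_stretches(E)
    a = adg(lam1, lam2, lam3)
    angles = deformation_angles(E)
    qc = {
        "n_mask_voxels": int(F.mask.sum()),
        "n_folding": jd.meta["n_folding"],
        "n_invalid_stretch": lam1.meta["n_invalid_stretch"],
        "n_invalid_angle": sum(t.meta["n_invalid_angle"] for t in angles),
        "scheme": scheme,
    }
    return StrainField(
        grid=dispfield.grid,
        F=F,
        jd=jd,
        E=E,
        stretches=(lam1, lam2, lam3),
        adg=a,
        angles=angles,
        mask=F.mask.copy(),
        qc=qc,
    )
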