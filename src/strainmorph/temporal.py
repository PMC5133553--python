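"""Interval normalisation, spatial warping, and edge-preserving smoothing.

Longitudinal scan intervals differ between subjects, so per-interval growth
parameters are normalised to a common 90-day (3-month) scale before group
statistics: values are multiplied by 90/days_between_scans.  For strain
components and angles the null value is 0 and plain scaling applies; for the
Jacobian determinant the null is 1, so by default the *deviation from unity*
is scaled (JD_adj = 1 + (JD - 1) * 90/days), which keeps the one-sample null
JD = 1 meaningful after adjustment.  Direct scaling of JD itself is available
as ``jd_mode="direct"``.

Parameter maps are warped into a common (atlas) space through supplied
displacement fields; tensor maps are resampled componentwise without
reorientation, a deliberate simplification for scalar statistics on the
components.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import (
    DisplacementField,
    GridMismatchError,
    ScalarMap,
    TensorMap,
    VolumeGrid,
)

__all__ = ["interval_adjust", "warp_map", "smooth_map", "REFERENCE_INTERVAL_DAYS"]

#: the common interval length all growth parameters are normalised to (days)
REFERENCE_INTERVAL_DAYS = 90.0


def interval_adjust(
    m: ScalarMap | TensorMap,
    days_between_scans: float,
    null_value: float = 0.0,
    jd_mode: str | None = None,
    **metadata,
) -> ScalarMap | TensorMap:
    """Normalise a per-interval parameter map to the 90-day scale.

    Parameters
    ----------
    m
        Parameter map for one (subject, interval).
    days_between_scans
        Actual interval length in days (> 0).
    null_value
        The no-growth value of this parameter: 0 for strain components and
        angles, 1 for JD.  The deviation (value - null) is scaled by
        90/days and the null added back, so the null is preserved exactly.
    jd_mode
        ``"offset"`` (default behaviour, equivalent to ``null_value=1``) or
        ``"direct"`` to scale JD itself; only meaningful for JD maps.
    metadata
        Extra metadata (subject_id, interval_id, ...) stamped on the result.

    Raises
    ------
    ValueError
        If days <= 0 or the map has already been adjusted.
    """
    if days_between_scans <= 0:
        raise ValueError(f"days_between_scans must be > 0, got {days_between_scans}")
    if m.meta.get("adjustment") == "per-90-day":
        raise ValueError("map is already interval-adjusted (per-90-day)")
    if jd_mode is not None:
        if jd_mode == "direct":
            null_value = 0.0
        elif jd_mode == "offset":
            null_value = 1.0
        else:
            raise ValueError(f"unknown jd_mode {jd_mode!r}")

    factor = REFERENCE_INTERVAL_DAYS / float(days_between_scans)
    values = null_value + (m.values - null_value) * factor
    meta = {
        **m.meta,
        **metadata,
        "adjustment": "per-90-day",
        "days_between_scans": float(days_between_scans),
        "adjust_null_value": float(null_value),
    }
    cls = type(m)
    return cls(m.grid, values, m.mask.copy(), meta)


def warp_map(
    m: ScalarMap | TensorMap,
    deformation: DisplacementField,
    target_grid: VolumeGrid | None = None,
    interpolation: str = "linear",
) -> ScalarMap | TensorMap:
    """Resample a map through a displacement field into a target space.

    The deformation lives on the target grid and maps each target voxel's
    physical position X to the source position X + u(X) at which the map is
    sampled.  An identity (zero) field therefore leaves the map unchanged.

    Scalar and tensor maps use ``"linear"`` interpolation by default
    (``"nearest"`` for label-like data); tensor maps are resampled
    componentwise.  Voxels sampling outside the source field of view or
    outside the source mask are removed from the output mask.
    """
    if target_grid is None:
        target_grid = deformation.grid
    else:
        target_grid.require_matches(deformation.grid, "deformation and target grid")
    orders = {"linear": 1, "nearest": 0}
    if interpolation not in orders:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = orders[interpolation]

    # physical sample positions, then fractional voxel indices in the source
    source_xyz = target_grid.coordinates() + deformation.u
    idx = m.grid.world_to_voxel(source_xyz)  # target_shape + (3,)
    coords = np.moveaxis(idx, -1, 0)

    inside = np.ones(target_grid.shape, dtype=bool)
    for ax, n in enumerate(m.grid.shape):
        inside &= (idx[..., ax] >= -0.5) & (idx[..., ax] <= n - 0.5)

    def _resample(vol: np.ndarray, order_: int) -> np.ndarray:
        return ndimage.map_coordinates(
            vol, coords, order=order_, mode="nearest", output=float
        )

    # a target voxel is kept only where the interpolation footprint is
    # fully inside the source mask
    mask_w = _resample(m.mask.astype(float), order)
    out_mask = deformation.mask & inside & (mask_w >= 1.0 - 1e-9)
    if not out_mask.any():
        raise GridMismatchError("warp produced an empty mask: no overlap with source")

    src = np.where(
        (m.mask if isinstance(m, ScalarMap) else m.mask[..., None]),
        m.values,
        0.0,
    )
    meta = {**m.meta, "warped": True, "interpolation": interpolation}
    if isinstance(m, ScalarMap):
        out = _resample(src, order)
        out[~out_mask] = np.nan
        return ScalarMap(target_grid, out, out_mask, meta)
    out6 = np.stack([_resample(src[..., c], order) for c in range(6)], axis=-1)
    out6[~out_mask] = np.nan
    return TensorMap(target_grid, out6, out_mask, meta)


# 6-neighbour offsets for the diffusion stencil
_NEIGHBOUR_OFFSETS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]


def smooth_map(
    m: ScalarMap,
    iterations: int = 1,
    kappa: float = 0.1,
    step: float = 1.0 / 6.0,
) -> ScalarMap:
    """Edge-preserving smoothing: explicit Perona-Malik diffusion passes.

    Each pass updates v <- v + step * sum_n g(d_n) d_n over the 6-neighbour
    differences d_n = v_n - v, with conductance g(d) = exp(-(d/kappa)^2):
    small differences (noise) diffuse, large differences (edges) are
    preserved.  Fluxes across the mask boundary are zero, so the mean over
    the mask is conserved exactly; constant maps are fixed points.

    Parameters
    ----------
    iterations
        Number of diffusion passes (the pipeline default is one minimal pass).
    kappa
        Edge threshold in the map's units: differences well below kappa are
        smoothed, well above are kept.
    step
        Time step; <= 1/6 is stable for the 6-neighbour stencil.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if not (0 < step <= 1.0 / 6.0):
        raise ValueError("step must be in (0, 1/6] for stability")

    v = np.where(m.mask, m.values, 0.0)
    mask = m.mask
    for _ in range(iterations):
        update = np.zeros_like(v)
        for off in _NEIGHBOUR_OFFSETS:
            shifted = np.roll(v, shift=tuple(-o for o in off), axis=(0, 1, 2))
            shifted_mask = np.roll(mask, shift=tuple(-o for o in off), axis=(0, 1, 2))
            # zero out wrap-around of np.roll
            edge_ok = np.ones(v.shape, dtype=bool)
            for ax, o in enumerate(off):
                if o == 1:
                    sl = [slice(None)] * 3
                    sl[ax] = slice(-1, None)
                    edge_ok[tuple(sl)] = False
                elif o == -1:
                    sl = [slice(None)] * 3
                    sl[ax] = slice(0, 1)
                    edge_ok[tuple(sl)] = False
            d = shifted - v
            g = np.exp(-((d / kappa) ** 2))
            flux = np.where(mask & shifted_mask & edge_ok, g * d, 0.0)
            update += flux
        v = v + step * update
    out = m.values.copy()
    out[mask] = v[mask]
    return ScalarMap(
        m.grid, out, mask.copy(),
        {**m.meta, "smoothing_iterations": int(m.meta.get("smoothing_iterations", 0)) + iterations},
    )
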