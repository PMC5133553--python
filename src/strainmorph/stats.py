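"""Voxel-wise and ROI statistics for longitudinal growth parameters.

Implements the study-style inference chain:

* one-sample t-tests of each voxel's growth parameter against its no-growth
  null (JD = 1, strain/angle = 0),
* Benjamini-Hochberg false-discovery-rate correction across voxels,
* a random-intercept linear mixed-effects model for the age dependence of
  growth rates, y_ij = b0 + b1 * age_ij + u_i + e_ij with u_i ~ N(0, s2_b)
  per subject and e_ij ~ N(0, s2_e), fitted by REML, and
* ROI summaries with percentile-based fast/slow growth classification
  (ROI mean above the whole-brain 75th percentile = fast, below the 25th =
  slow, strict inequalities).

The mixed model is fitted by profiling the REML criterion down to the single
variance ratio rho = s2_b/s2_e: for fixed rho the GLS estimate of the fixed
effects and the residual variance have closed forms through the
Sherman-Morrison identity for the compound-symmetric per-subject covariance,
so only a 1-D bounded search over rho remains.  This keeps the voxel-wise
loop deterministic and fast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .containers import LabelAtlas, ScalarMap

__all__ = [
    "one_sample_t_map",
    "bh_fdr",
    "fit_lme",
    "voxelwise_lme",
    "roi_summarize",
    "classify_growth",
    "VoxelTestResult",
    "LmeFit",
    "VoxelLmeResult",
]

#: percentile definition used throughout (NumPy's default)
PERCENTILE_METHOD = "linear"


# ---------------------------------------------------------------------------
# one-sample t-test
# ---------------------------------------------------------------------------


@dataclass
class VoxelTestResult:
    """Voxel-wise one-sample test results against a growth null."""

    mean: ScalarMap
    t: ScalarMap
    p: ScalarMap
    p_adj: ScalarMap
    significant: np.ndarray  # p_adj < q
    df: int
    null_value: float
    q: float
    n_zero_variance_flagged: int


def one_sample_t_map(
    maps: list[ScalarMap], null_value: float, q: float = 0.05
) -> VoxelTestResult:
    """Two-sided one-sample t-test per voxel across subjects, with BH-FDR.

    Zero-variance voxels get p = 1 when the common value equals the null
    (no evidence against it) and p = 0 with a flag count otherwise.
    """
    n = len(maps)
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    grid = maps[0].grid
    mask = maps[0].mask.copy()
    for m in maps[1:]:
        grid.require_matches(m.grid, "subject maps")
        mask &= m.mask
    data = np.stack([m.values for m in maps], axis=0)

    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean - null_value) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), df)

    zero_var = mask & (sd == 0)
    at_null = zero_var & (mean == null_value)
    off_null = zero_var & ~at_null
    t[at_null], p[at_null] = 0.0, 1.0
    t[off_null] = np.inf * np.sign(mean[off_null] - null_value)
    p[off_null] = 0.0

    p_adj = np.ones_like(p)
    p_adj[mask], reject_mask = bh_fdr(p[mask], q=q)
    sig = np.zeros(grid.shape, dtype=bool)
    sig[mask] = reject_mask

    def smap(v):
        return ScalarMap(grid, v, mask.copy())

    return VoxelTestResult(
        mean=smap(mean),
        t=smap(np.where(mask, t, 0.0)),
        p=smap(np.where(mask, p, 1.0)),
        p_adj=smap(p_adj),
        significant=sig,
        df=df,
        null_value=null_value,
        q=q,
        n_zero_variance_flagged=int(off_null.sum()),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Sort p ascending; reject all hypotheses up to the largest i with
    p_(i) <= i*q/m.  Adjusted p-values are min over j >= i of m*p_(j)/j,
    capped at 1, so they are monotone in rank and rejection at level q is
    exactly ``p_adj <= q``... with step-up semantics enforced via the
    running minimum from the largest rank downwards.

    Returns
    -------
    (p_adjusted, reject) in the input order; empty input gives empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    scaled = ranked * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])

    passing = np.nonzero(ranked <= np.arange(1, m + 1) * q / m)[0]
    k = passing[-1] + 1 if passing.size else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k] = True

    p_adj = np.empty(m)
    reject = np.empty(m, dtype=bool)
    p_adj[order] = adj_sorted
    reject[order] = reject_sorted
    return p_adj, reject


# ---------------------------------------------------------------------------
# random-intercept linear mixed model (profiled REML)
# ---------------------------------------------------------------------------


@dataclass
class LmeFit:
    """REML fit of y = b0 + b1*age + subject intercept + residual.

    Wald tests use a Student-t reference with containment degrees of
    freedom: the age slope is identified by within-subject contrasts
    (df = n_obs - n_subjects - 1, exact for balanced designs), the
    intercept by between-subject information (df = n_subjects - 1).
    """

    beta: np.ndarray  # (intercept, age slope)
    se: np.ndarray
    df: np.ndarray  # t degrees of freedom per coefficient
    p_values: np.ndarray  # Wald t, two-sided
    sigma2_b: float  # random-intercept variance
    sigma2_e: float  # residual variance
    loglik_reml: float
    n_subjects: int
    n_obs: int
    variance_ratio: float  # sigma2_b / sigma2_e

    @property
    def slope(self) -> float:
        return float(self.beta[1])

    @property
    def slope_p(self) -> float:
        return float(self.p_values[1])

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        t = sps.t.ppf(0.5 + level / 2.0, self.df[1])
        return (self.beta[1] - t * self.se[1], self.beta[1] + t * self.se[1])


class _ProfiledREML:
    """Sufficient statistics for the profiled REML criterion.

    The design (subjects, ages) is shared across voxels, so everything that
    depends on X alone is precomputed once; fitting a new response needs
    only its per-subject sums, X'y and y'y.
    """

    RHO_MAX = 1e7

    def __init__(self, subject_codes: np.ndarray, age: np.ndarray):
        age = np.asarray(age, dtype=float)
        if np.ptp(age) == 0:
            raise ValueError("age does not vary: fixed-effect design is singular")
        self.codes = np.asarray(subject_codes)
        self.n_groups = int(self.codes.max()) + 1
        self.n_obs = age.size
        counts = np.bincount(self.codes, minlength=self.n_groups)
        if (counts == 0).any():
            raise ValueError("empty subject group")
        if self.n_groups < 2:
            raise ValueError("need at least 2 subjects")
        self.counts = counts.astype(float)
        self.X = np.column_stack([np.ones(self.n_obs), age])
        self.XtX = self.X.T @ self.X
        # per-group column sums of X: (G, 2)
        self.Sx = np.column_stack(
            [np.bincount(self.codes, weights=self.X[:, j], minlength=self.n_groups)
             for j in range(2)]
        )
        self.p = 2

    def y_stats(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        Sy = np.bincount(self.codes, weights=y, minlength=self.n_groups)
        return self.X.T @ y, float(y @ y), Sy

    def _gls(self, rho: float, Xty, yty, Sy):
        a = rho / (1.0 + rho * self.counts)  # (G,)
        XtWX = self.XtX - (self.Sx * a[:, None]).T @ self.Sx
        XtWy = Xty - self.Sx.T @ (a * Sy)
        beta = np.linalg.solve(XtWX, XtWy)
        # r'Wr via group sums of residuals
        Sr = Sy - self.Sx @ beta
        rtr = yty - 2.0 * beta @ Xty + beta @ self.XtX @ beta
        qform = rtr - float(a @ (Sr**2))
        return beta, XtWX, max(qform, 1e-300)

    def _neg2_reml(self, rho: float, Xty, yty, Sy) -> float:
        beta, XtWX, qform = self._gls(rho, Xty, yty, Sy)
        nmp = self.n_obs - self.p
        logdet_v = float(np.log1p(rho * self.counts).sum())
        sign, logdet_x = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return nmp * np.log(qform) + logdet_v + logdet_x

    def fit(self, y: np.ndarray) -> LmeFit:
        Xty, yty, Sy = self.y_stats(y)
        obj = lambda r: self._neg2_reml(r, Xty, yty, Sy)
        res = optimize.minimize_scalar(
            obj,
            bounds=(0.0, self.RHO_MAX),
            method="bounded",
            options={"xatol": 1e-10},
        )
        rho = float(res.x)
        # the bounded search can park near a flat boundary; compare explicitly
        if obj(0.0) <= res.fun:
            rho = 0.0
        crit = obj(rho)
        if not np.isfinite(crit):
            raise RuntimeError(
                f"REML optimisation failed: criterion {crit} at rho={rho}"
            )
        beta, XtWX, qform = self._gls(rho, Xty, yty, Sy)
        nmp = self.n_obs - self.p
        sigma2_e = qform / nmp
        cov = sigma2_e * np.linalg.inv(XtWX)
        se = np.sqrt(np.diag(cov))
        # containment df: intercept between subjects, slope within
        df = np.array(
            [max(self.n_groups - 1, 1), max(self.n_obs - self.n_groups - 1, 1)],
            dtype=float,
        )
        p = 2.0 * sps.t.sf(np.abs(beta / se), df)
        loglik = -0.5 * (
            crit
            + nmp * (1.0 - np.log(nmp))
            + nmp * np.log(2.0 * np.pi)
        )
        return LmeFit(
            beta=beta,
            se=se,
            df=df,
            p_values=p,
            sigma2_b=rho * sigma2_e,
            sigma2_e=sigma2_e,
            loglik_reml=float(loglik),
            n_subjects=self.n_groups,
            n_obs=self.n_obs,
            variance_ratio=rho,
        )


def _design_from_table(table: pd.DataFrame):
    for col in ("subject_id", "midpoint_age_days"):
        if col not in table.columns:
            raise ValueError(f"long table missing column {col!r}")
    codes, _ = pd.factorize(table["subject_id"])
    return _ProfiledREML(codes, table["midpoint_age_days"].to_numpy(dtype=float))


def fit_lme(table: pd.DataFrame, y: str | np.ndarray = "y") -> LmeFit:
    """Fit the random-intercept age model to long-format data by REML.

    Parameters
    ----------
    table
        One row per observation with columns ``subject_id``,
        ``midpoint_age_days`` and the response.
    y
        Response column name, or an array aligned with the table's rows.
    """
    design = _design_from_table(table)
    yv = table[y].to_numpy(dtype=float) if isinstance(y, str) else np.asarray(y, float)
    if yv.shape != (design.n_obs,):
        raise ValueError("response length does not match table")
    return design.fit(yv)


@dataclass
class VoxelLmeResult:
    """Voxel-wise age-effect maps from the random-intercept model."""

    slope: ScalarMap  # b1 per day of midpoint age
    p: ScalarMap
    p_adj: ScalarMap
    significant: np.ndarray
    q: float
    n_failed_voxels: int


def voxelwise_lme(
    maps: list[ScalarMap], cohort: pd.DataFrame, q: float = 0.05
) -> VoxelLmeResult:
    """Fit the age model independently at every masked voxel, then BH-FDR.

    ``maps`` must align row-for-row with ``cohort``; every (subject,
    interval) row needs a map on the common grid.  Voxels where the fit
    fails are removed from the output mask and counted.
    """
    if len(maps) != len(cohort):
        raise ValueError(
            f"{len(maps)} maps for {len(cohort)} cohort rows: one map per row required"
        )
    grid = maps[0].grid
    mask = maps[0].mask.copy()
    for m in maps[1:]:
        grid.require_matches(m.grid, "cohort maps")
        mask &= m.mask
    design = _design_from_table(cohort)
    data = np.stack([m.values for m in maps], axis=0)  # (n_obs,) + shape
    flat = data[:, mask]  # (n_obs, n_voxels)

    n_vox = flat.shape[1]
    slope = np.zeros(n_vox)
    pvals = np.ones(n_vox)
    ok = np.ones(n_vox, dtype=bool)
    for v in range(n_vox):
        try:
            fit = design.fit(flat[:, v])
        except (RuntimeError, np.linalg.LinAlgError):
            ok[v] = False
            continue
        slope[v] = fit.slope
        pvals[v] = fit.slope_p

    out_mask = mask.copy()
    out_mask[mask] = ok
    p_adj_vals, reject = bh_fdr(pvals[ok], q=q)

    slope_map = np.zeros(grid.shape)
    p_map = np.ones(grid.shape)
    padj_map = np.ones(grid.shape)
    sig = np.zeros(grid.shape, dtype=bool)
    slope_map[out_mask] = slope[ok]
    p_map[out_mask] = pvals[ok]
    padj_map[out_mask] = p_adj_vals
    sig[out_mask] = reject

    def smap(v):
        return ScalarMap(grid, v, out_mask.copy())

    return VoxelLmeResult(
        slope=smap(slope_map),
        p=smap(p_map),
        p_adj=smap(padj_map),
        significant=sig,
        q=q,
        n_failed_voxels=int((~ok).sum()),
    )


# ---------------------------------------------------------------------------
# ROI summaries and fast/slow classification
# ---------------------------------------------------------------------------


def roi_summarize(m: ScalarMap, atlas: LabelAtlas) -> pd.DataFrame:
    """Arithmetic mean of the map over each atlas ROI (masked voxels only).

    Empty ROIs (no masked voxels) are excluded with a warning.
    """
    m.grid.require_matches(atlas.grid, "map and atlas")
    rows = []
    for label in atlas.roi_labels:
        sel = atlas.roi_mask(label) & m.mask
        n = int(sel.sum())
        if n == 0:
            warnings.warn(
                f"ROI {label} ({atlas.names.get(label)}) has no masked voxels; excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "label": label,
                "name": atlas.names[label],
                "n_voxels": n,
                "mean": float(m.values[sel].mean()),
            }
        )
    return pd.DataFrame(rows, columns=["label", "name", "n_voxels", "mean"])


def classify_growth(m: ScalarMap, atlas: LabelAtlas) -> pd.DataFrame:
    """Percentile-based fast/slow growth classification of atlas ROIs.

    Thresholds are the 25th and 75th percentiles of the parameter over ALL
    masked voxels in the brain (not over ROI means), with linear
    interpolation between order statistics.  An ROI is ``fast`` if its mean
    exceeds the 75th percentile, ``slow`` if below the 25th, else
    ``neither``; strict inequalities make fast and slow mutually exclusive.
    """
    table = roi_summarize(m, atlas)
    vox = m.masked()
    p25, p75 = np.percentile(vox, [25, 75], method=PERCENTILE_METHOD)
    # strict inequalities with a round-off guard, so a uniform map (where
    # p25 = p75 = the common value up to summation error) classifies nothing
    tol = 1e-12 * max(1.0, abs(p25), abs(p75))
    cls = np.where(
        table["mean"] > p75 + tol,
        "fast",
        np.where(table["mean"] < p25 - tol, "slow", "neither"),
    )
    table = table.assign(
        whole_brain_p25=p25, whole_brain_p75=p75, classification=cls
    )
    table.attrs["percentile_method"] = PERCENTILE_METHOD
    return table
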