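"""Voxelwise morphometry statistics with permutation cluster-extent correction.

Three voxelwise analyses over the in-mask GMV matrix: an F map for the
three-group comparison (controlling TIV, age, sex), a partial-correlation
map of GMV against epilepsy duration within one patient group, and a t
map for the group-by-duration slope interaction between the two patient
groups.  Family-wise error over voxels is controlled nonparametrically:
maps are thresholded at an uncorrected voxel p, 26-connected clusters are
formed, and cluster extent is referred to the permutation null of the
maximum cluster size, with nuisance covariates handled by
Freedman-Lane-style residual permutation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, stats

from .core import GMVDataset
from .wta import _residual_projector

__all__ = [
    "StatMap",
    "ClusterResult",
    "voxelwise_group_anova",
    "voxelwise_duration_corr",
    "slope_interaction_map",
    "cluster_correct",
]

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclasses.dataclass
class StatMap:
    """A per-voxel statistic over the dataset's in-mask columns."""

    kind: str                 # "F", "t" or "r"
    values: np.ndarray        # one value per dataset column
    df: tuple[int, ...]
    design: dict              # enough to re-run the analysis under permutation

    def __post_init__(self) -> None:
        if self.kind not in ("F", "t", "r"):
            raise ValueError("kind must be F, t or r")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("statistic must be finite within the mask")


def _covariate_matrix(ds: GMVDataset, rows: np.ndarray,
                      covariates: tuple[str, ...]) -> np.ndarray:
    cols = []
    sub = ds.cohort.iloc[rows]
    for c in covariates:
        if c == "sex":
            cols.append((sub["sex"] == "M").to_numpy(float))
        else:
            cols.append(sub[c].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(rows), 0))


def _rss(Y: np.ndarray, q: np.ndarray) -> np.ndarray:
    resid = Y - q @ (q.T @ Y)
    return np.einsum("ij,ij->j", resid, resid)


def _anova_F(Y: np.ndarray, q_full: np.ndarray, q_red: np.ndarray,
             df1: int, df2: int) -> np.ndarray:
    rss_f = _rss(Y, q_full)
    rss_r = _rss(Y, q_red)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_r - rss_f) / df1) / (rss_f / df2)
    return np.where(rss_f > 0, np.maximum(f, 0.0), 0.0)


def voxelwise_group_anova(ds: GMVDataset,
                          groups: tuple[str, str, str] = ("GE_GTCS", "FE_FBTS", "HC"),
                          covariates: tuple[str, ...] = ("tiv", "age", "sex")
                          ) -> StatMap:
    """Per-voxel F for the group factor, adjusting for nuisance covariates.

    The F compares the full OLS model (intercept, two group dummies,
    covariates) against the reduced model without the group dummies.
    """
    rows = np.concatenate([ds.group_rows(g) for g in groups])
    for g in groups:
        if len(ds.group_rows(g)) < 3:
            raise ValueError(f"group {g} has fewer than 3 subjects")
    glab = ds.cohort["group"].to_numpy()[rows]
    dummies = np.column_stack([(glab == g).astype(float) for g in groups[:2]])
    Z = _covariate_matrix(ds, rows, covariates)
    n = len(rows)
    q_full = _residual_projector(np.column_stack([dummies, Z]), n)
    q_red = _residual_projector(Z, n)
    df1, df2 = 2, n - q_full.shape[1]
    F = _anova_F(ds.matrix[rows], q_full, q_red, df1, df2)
    return StatMap(kind="F", values=F, df=(df1, df2),
                   design={"kind": "group_anova", "groups": groups,
                           "covariates": covariates, "rows": rows})


def voxelwise_duration_corr(ds: GMVDataset, group: str,
                            covariates: tuple[str, ...] = ("tiv", "sex", "age")
                            ) -> StatMap:
    """Per-voxel partial correlation of GMV with epilepsy duration in one group."""
    rows = ds.group_rows(group)
    if len(rows) < 10:
        raise ValueError("need at least 10 subjects")
    d = ds.cohort["duration_months"].to_numpy(float)[rows]
    if np.isnan(d).any():
        raise ValueError("duration missing for a subject in the group")
    Z = _covariate_matrix(ds, rows, covariates)
    q = _residual_projector(Z, len(rows))
    rd = d - q @ (q.T @ d)
    RY = ds.matrix[rows] - q @ (q.T @ ds.matrix[rows])
    r = _corr_against(rd, RY)
    df = len(rows) - Z.shape[1] - 2  # subjects minus covariates, intercept, and 2
    return StatMap(kind="r", values=r, df=(df,),
                   design={"kind": "duration_corr", "group": group,
                           "covariates": covariates, "rows": rows})


def _corr_against(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    nx = np.linalg.norm(x)
    denom = np.linalg.norm(Y, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ Y) / (nx * denom)
    return np.clip(np.where(denom > 0, r, 0.0), -1.0, 1.0)


def slope_interaction_map(ds: GMVDataset,
                          groups: tuple[str, str] = ("GE_GTCS", "FE_FBTS"),
                          covariates: tuple[str, ...] = ("tiv", "age", "sex")
                          ) -> StatMap:
    """Per-voxel t for the group-by-duration interaction between patient groups."""
    ra, rb = ds.group_rows(groups[0]), ds.group_rows(groups[1])
    if len(ra) < 10 or len(rb) < 10:
        raise ValueError("both groups need at least 10 subjects")
    rows = np.concatenate([ra, rb])
    g = (ds.cohort["group"].to_numpy()[rows] == groups[0]).astype(float)
    d = ds.cohort["duration_months"].to_numpy(float)[rows]
    Z = _covariate_matrix(ds, rows, covariates)
    X = np.column_stack([np.ones(len(rows)), g, d, g * d, Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design")
    t, df = _interaction_t(X, ds.matrix[rows], idx=3)
    return StatMap(kind="t", values=t, df=(df,),
                   design={"kind": "interaction", "groups": groups,
                           "covariates": covariates, "rows": rows})


def _interaction_t(X: np.ndarray, Y: np.ndarray, idx: int) -> tuple[np.ndarray, int]:
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    c = np.linalg.inv(X.T @ X)[idx, idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[idx] / np.sqrt(sigma2 * c)
    return np.where(sigma2 > 0, t, 0.0), df


@dataclasses.dataclass
class ClusterResult:
    """Suprathreshold clusters with permutation-corrected extent p values."""

    voxel_p_threshold: float
    clusters: list[dict]      # each: size, corrected_p, peak_column, columns
    n_perm: int
    seed: int
    max_null_sizes: np.ndarray


def _stat_threshold(kind: str, df: tuple[int, ...], voxel_p: float) -> float:
    if kind == "F":
        return float(stats.f.isf(voxel_p, *df))
    if kind == "t":
        return float(stats.t.isf(voxel_p / 2, df[0]))
    # r: invert the t transform r = t / sqrt(t^2 + df)
    tcrit = stats.t.isf(voxel_p / 2, df[0])
    return float(tcrit / np.sqrt(tcrit**2 + df[0]))


def _cluster_sizes(supra_cols: np.ndarray, ds: GMVDataset
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Label 26-connected components of suprathreshold columns; return (labels, sizes)."""
    vol = np.zeros(ds.atlas.labels.shape, dtype=bool)
    vol[tuple(ds.voxel_ijk[supra_cols].T)] = True
    lab, n = ndimage.label(vol, structure=_CONN26)
    col_labels = lab[tuple(ds.voxel_ijk.T)]
    sizes = np.bincount(lab.ravel())[1:] if n else np.empty(0, int)
    return col_labels, sizes


def cluster_correct(stat_map: StatMap, voxel_p: float, n_perm: int, seed: int,
                    ds: GMVDataset) -> ClusterResult:
    """Cluster-extent family-wise correction of a voxelwise statistic map.

    The map is thresholded at the uncorrected voxel ``p``; 26-connected
    components are compared with the permutation null of the maximum
    cluster size, rebuilt from the design recorded on the map.  Covariates
    are kept valid under the null by permuting reduced-model residuals
    (Freedman-Lane).  No suprathreshold voxels is an empty, not an error,
    result.
    """
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0, 1)")
    design = stat_map.design
    rows = design["rows"]
    thr = _stat_threshold(stat_map.kind, stat_map.df, voxel_p)
    rng = np.random.default_rng(seed)

    # build the permutation-recompute closure for this design
    if design["kind"] == "group_anova":
        groups = design["groups"]
        glab = ds.cohort["group"].to_numpy()[rows]
        dummies = np.column_stack([(glab == g).astype(float) for g in groups[:2]])
        Z = _covariate_matrix(ds, rows, design["covariates"])
        n = len(rows)
        q_full = _residual_projector(np.column_stack([dummies, Z]), n)
        q_red = _residual_projector(Z, n)
        df1, df2 = stat_map.df
        Y = ds.matrix[rows]
        fitted = q_red @ (q_red.T @ Y)
        resid = Y - fitted

        def null_stat():
            Ystar = fitted + resid[rng.permutation(n)]
            return _anova_F(Ystar, q_full, q_red, df1, df2)

    elif design["kind"] == "duration_corr":
        d = ds.cohort["duration_months"].to_numpy(float)[rows]
        Z = _covariate_matrix(ds, rows, design["covariates"])
        q = _residual_projector(Z, len(rows))
        rd = d - q @ (q.T @ d)
        RY = ds.matrix[rows] - q @ (q.T @ ds.matrix[rows])

        def null_stat():
            return _corr_against(rd[rng.permutation(len(rd))], RY)

    elif design["kind"] == "interaction":
        groups = design["groups"]
        g = (ds.cohort["group"].to_numpy()[rows] == groups[0]).astype(float)
        d = ds.cohort["duration_months"].to_numpy(float)[rows]
        Z = _covariate_matrix(ds, rows, design["covariates"])
        n = len(rows)
        X = np.column_stack([np.ones(n), g, d, g * d, Z])
        Xred = np.column_stack([np.ones(n), g, d, Z])
        q_red = _residual_projector(Xred[:, 1:], n)
        Y = ds.matrix[rows]
        fitted = q_red @ (q_red.T @ Y)
        resid = Y - fitted

        def null_stat():
            Ystar = fitted + resid[rng.permutation(n)]
            return _interaction_t(X, Ystar, idx=3)[0]

    else:
        raise ValueError(f"unknown design kind {design['kind']!r}")

    def supra(values):
        v = np.abs(values) if stat_map.kind in ("t", "r") else values
        return np.flatnonzero(v >= thr)

    obs_cols = supra(stat_map.values)
    col_labels, sizes = _cluster_sizes(obs_cols, ds)

    max_null = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        cols = supra(null_stat())
        if cols.size:
            _, nsz = _cluster_sizes(cols, ds)
            max_null[b] = nsz.max() if nsz.size else 0

    clusters = []
    for ci, size in enumerate(sizes, start=1):
        cols = np.flatnonzero(col_labels == ci)
        stat_vals = np.abs(stat_map.values[cols]) if stat_map.kind in ("t", "r") \
            else stat_map.values[cols]
        p_corr = (1.0 + (max_null >= size).sum()) / (1.0 + n_perm)
        clusters.append({
            "size": int(size),
            "corrected_p": float(p_corr),
            "peak_column": int(cols[np.argmax(stat_vals)]),
            "columns": cols,
        })
    clusters.sort(key=lambda c: c["size"], reverse=True)
    return ClusterResult(voxel_p_threshold=voxel_p, clusters=clusters,
                         n_perm=n_perm, seed=seed, max_null_sizes=max_null)
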