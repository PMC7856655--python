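"""Winner-take-all (WTA) structural covariance mapping.

For each group, every voxel of the striatum, thalamus and cerebellum is
correlated (partial correlation, controlling the other four lobes' mean
GMV and TIV) with the mean GMV of each of the five cortical lobes across
subjects, and labeled by the lobe with the highest coefficient.  Group
maps are compared by counting labeled voxels per lobe and building a
permutation null that rearranges group membership and recomputes both
maps per draw.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import Atlas, GMVDataset, LOBE_NAMES, STRUCTURE_NAMES, roi_mean_signal

__all__ = [
    "SCNMap",
    "MapComparison",
    "partial_correlation",
    "lobe_mean_signals",
    "seed_structure_map",
    "structure_wta_map",
    "wta_label",
    "count_labels",
    "permutation_map_test",
]


def _residual_projector(Z: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis Q of the column space of [1, Z] (for residualizing)."""
    if Z is None or Z.size == 0:
        D = np.ones((n, 1))
    else:
        Z = np.atleast_2d(np.asarray(Z, float))
        if Z.shape[0] != n:
            Z = Z.T
        D = np.column_stack([np.ones(n), Z])
    q, r = np.linalg.qr(D)
    if np.abs(np.diag(r)).min() < 1e-10 * max(np.abs(np.diag(r)).max(), 1.0):
        raise ValueError("rank-deficient covariate design")
    return q


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        Z: np.ndarray | None = None) -> float:
    """Partial Pearson correlation of ``x`` and ``y`` given covariates ``Z``.

    Both variables are residualized on an intercept plus the covariate
    columns by least squares; the result is the Pearson correlation of the
    residuals, identical to the precision-matrix definition of partial
    correlation.  With no covariates this is the plain Pearson r.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    k = 0 if Z is None or np.size(Z) == 0 else np.atleast_2d(np.asarray(Z)).reshape(n, -1).shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate: constant input has zero variance")
    q = _residual_projector(Z, n)
    rx = x - q @ (q.T @ x)
    ry = y - q @ (q.T @ y)
    nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
    # a variable fully absorbed by the covariates has nothing left to
    # correlate: its partial correlation with anything is zero
    if nx < 1e-10 * np.linalg.norm(x - x.mean()) or \
            ny < 1e-10 * np.linalg.norm(y - y.mean()):
        return 0.0
    return float(np.clip(rx @ ry / (nx * ny), -1.0, 1.0))


def lobe_mean_signals(ds: GMVDataset) -> np.ndarray:
    """Subjects x 5 matrix of mean GMV per cortical lobe."""
    return np.column_stack([
        roi_mean_signal(ds, ds.label_columns(l)) for l in range(1, 6)
    ])


def _seed_maps_from_parts(lobes: np.ndarray, tiv: np.ndarray, Y: np.ndarray,
                          rows: np.ndarray) -> np.ndarray:
    """All five seeded partial-correlation maps for one structure (5 x voxels).

    ``lobes`` is subjects x 5 lobe means, ``Y`` subjects x structure-voxels;
    ``rows`` selects the subject subset.  Vectorized across voxels: the seed
    and every voxel column are residualized on [1, other lobes, TIV] at once.
    """
    L = lobes[rows]
    t = tiv[rows]
    Ys = Y[rows]
    n = len(rows)
    out = np.empty((5, Ys.shape[1]))
    for l in range(5):
        others = [j for j in range(5) if j != l]
        q = _residual_projector(np.column_stack([L[:, others], t]), n)
        rx = L[:, l] - q @ (q.T @ L[:, l])
        RY = Ys - q @ (q.T @ Ys)
        nx = np.linalg.norm(rx)
        if nx < 1e-12:
            raise ValueError("degenerate: seed lobe has zero residual variance")
        denom = np.linalg.norm(RY, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[l] = np.clip((rx @ RY) / (nx * denom), -1.0, 1.0)
    return out


def seed_structure_map(ds: GMVDataset, seed_lobe: int, structure: str,
                       rows: np.ndarray | None = None) -> np.ndarray:
    """Partial-correlation map of one structure against one cortical seed lobe.

    Returns one coefficient per structure voxel (column order of the
    dataset restricted to the structure).  Covariates are the other four
    lobes' mean GMV and TIV.
    """
    if seed_lobe not in LOBE_NAMES:
        raise ValueError(f"seed_lobe must be 1..5, got {seed_lobe}")
    rows = np.arange(ds.n_subjects) if rows is None else np.asarray(rows, int)
    if len(rows) <= 8:
        raise ValueError("need more than 8 subjects for the 7-column design")
    sid = ds.atlas.structure_id_by_name(structure)
    cols = ds.label_columns(sid)
    if cols.size == 0:
        raise ValueError(f"structure {structure} is empty")
    lobes = lobe_mean_signals(ds)
    tiv = ds.cohort["tiv"].to_numpy(float)
    maps = _seed_maps_from_parts(lobes, tiv, ds.matrix[:, cols], rows)
    return maps[seed_lobe - 1]


@dataclasses.dataclass
class SCNMap:
    """Winner-take-all map of one subcortical structure for one subject set."""

    group: str
    structure: str
    voxel_columns: np.ndarray   # dataset columns of the structure voxels
    winner_label: np.ndarray    # per voxel, winning lobe id 1-5
    winner_r: np.ndarray        # per voxel, the winning coefficient
    all_r: np.ndarray           # 5 x voxels, all seeded coefficients
    n_ties: int = 0

    def __post_init__(self) -> None:
        if not np.array_equal(self.winner_r,
                              self.all_r[self.winner_label - 1,
                                         np.arange(self.all_r.shape[1])]):
            raise ValueError("winner_r must be the row maximum of all_r")


def wta_label(all_r: np.ndarray, group: str = "", structure: str = "",
              voxel_columns: np.ndarray | None = None,
              use_abs: bool = False) -> SCNMap:
    """Label each voxel by the lobe with the highest (signed) coefficient.

    The winner is the signed maximum by default; ``use_abs`` switches to
    magnitude.  Ties break to the lowest lobe id and are counted.  A voxel
    whose five coefficients are all non-finite is an error.
    """
    all_r = np.asarray(all_r, float)
    if all_r.shape[0] != 5:
        raise ValueError("all_r must be 5 x voxels")
    finite = np.isfinite(all_r)
    if not finite.any(axis=0).all():
        raise ValueError("a voxel has no finite coefficient in any of the 5 maps")
    scores = np.abs(all_r) if use_abs else all_r
    scores = np.where(finite, scores, -np.inf)
    winner = scores.argmax(axis=0)  # argmax takes the first (lowest id) on ties
    top = scores[winner, np.arange(scores.shape[1])]
    n_ties = int(((scores == top).sum(axis=0) > 1).sum())
    cols = (np.arange(all_r.shape[1]) if voxel_columns is None
            else np.asarray(voxel_columns, int))
    return SCNMap(group=group, structure=structure, voxel_columns=cols,
                  winner_label=(winner + 1).astype(np.int32),
                  winner_r=all_r[winner, np.arange(all_r.shape[1])],
                  all_r=all_r, n_ties=n_ties)


def structure_wta_map(ds: GMVDataset, structure: str, rows: np.ndarray,
                      group: str = "", use_abs: bool = False) -> SCNMap:
    """Compute all five seeded maps for one structure and take the winner."""
    sid = ds.atlas.structure_id_by_name(structure)
    cols = ds.label_columns(sid)
    if cols.size == 0:
        raise ValueError(f"structure {structure} is empty")
    lobes = lobe_mean_signals(ds)
    tiv = ds.cohort["tiv"].to_numpy(float)
    all_r = _seed_maps_from_parts(lobes, tiv, ds.matrix[:, cols],
                                  np.asarray(rows, int))
    return wta_label(all_r, group=group, structure=structure,
                     voxel_columns=cols, use_abs=use_abs)


def count_labels(m: SCNMap) -> np.ndarray:
    """Voxel count per winning lobe (length-5 vector summing to the mask size)."""
    return np.bincount(m.winner_label, minlength=6)[1:6]


@dataclasses.dataclass
class MapComparison:
    """Per-lobe voxel-count comparison of two groups' WTA maps."""

    structure: str
    group_a: str
    group_b: str
    table: pd.DataFrame  # columns: lobe, lobe_name, count_a, count_b, diff, p_perm, direction
    n_perm: int
    seed: int


def permutation_map_test(ds: GMVDataset, group_a: str, group_b: str,
                         structure: str, n_perm: int = 5000,
                         seed: int = 0, use_abs: bool = False) -> MapComparison:
    """Compare two groups' WTA voxel counts with a group-label permutation test.

    The observed statistic per lobe is ``count_A - count_B`` from each
    group's own map.  Each permutation rearranges the pooled subjects into
    pseudo-groups of the original sizes and recomputes both WTA maps from
    scratch.  Two-sided p uses the add-one estimator (1 + b) / (1 + n_perm),
    so p is never zero; direction is the sign of the observed difference.
    """
    import warnings
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p", stacklevel=2)
    rows_a = ds.group_rows(group_a)
    rows_b = ds.group_rows(group_b)
    if np.intersect1d(rows_a, rows_b).size:
        raise ValueError("groups overlap")
    if len(rows_a) < 10 or len(rows_b) < 10:
        raise ValueError("both groups need at least 10 subjects")

    sid = ds.atlas.structure_id_by_name(structure)
    cols = ds.label_columns(sid)
    lobes = lobe_mean_signals(ds)
    tiv = ds.cohort["tiv"].to_numpy(float)
    Y = ds.matrix[:, cols]

    def counts(rows):
        all_r = _seed_maps_from_parts(lobes, tiv, Y, rows)
        m = wta_label(all_r, use_abs=use_abs)
        return count_labels(m)

    obs = counts(rows_a).astype(int) - counts(rows_b).astype(int)
    pooled = np.concatenate([rows_a, rows_b])
    na = len(rows_a)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(5, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        null = counts(perm[:na]).astype(int) - counts(perm[na:]).astype(int)
        exceed += np.abs(null) >= np.abs(obs)
    p = (1.0 + exceed) / (1.0 + n_perm)

    ca = counts(rows_a)
    cb = counts(rows_b)
    table = pd.DataFrame({
        "lobe": np.arange(1, 6),
        "lobe_name": [LOBE_NAMES[l] for l in range(1, 6)],
        "count_a": ca,
        "count_b": cb,
        "diff": obs,
        "p_perm": p,
        "direction": np.where(obs > 0, "Increased", np.where(obs < 0, "Decreased", "Equal")),
    })
    return MapComparison(structure=structure, group_a=group_a, group_b=group_b,
                         table=table, n_perm=n_perm, seed=seed)
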