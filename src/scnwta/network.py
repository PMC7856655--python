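"""The 20-node cortico-striato-thalamo-cerebellar covariance network.

Nodes are the five cortical lobes plus, in each of the striatum, thalamus
and cerebellum, the five WTA subregions (one per seeding lobe).  Edges
are pairwise partial correlations of the node mean-GMV signals across
subjects, controlling TIV by default.  Group networks are compared edge
by edge with a Fisher-z difference statistic under group-label
permutation, and the family of 190 edges is screened with the
false-positive-adjustment omnibus check (observed significant edges must
exceed the count expected by chance).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import GMVDataset, LOBE_NAMES, STRUCTURE_NAMES, roi_mean_signal
from .wta import SCNMap, _residual_projector, _seed_maps_from_parts, lobe_mean_signals, wta_label

__all__ = [
    "NODE_STRUCTURES",
    "node_labels",
    "CovNetwork",
    "NetworkComparison",
    "extract_node_signals",
    "build_network",
    "compare_networks",
    "fpa_adjust",
]

NODE_STRUCTURES = ("cortex", "striatum", "thalamus", "cerebellum")


def node_labels() -> list[str]:
    """Canonical node order: cortex(lobe) 1-5, then each structure's subregions."""
    return [f"{s}({LOBE_NAMES[l]})" for s in NODE_STRUCTURES for l in range(1, 6)]


def extract_node_signals(ds: GMVDataset, wta_maps: dict[str, SCNMap],
                         rows: np.ndarray | None = None) -> np.ndarray:
    """Subjects x 20 mean-GMV signals in canonical node order.

    Cortex nodes average over the lobe mask; subcortical nodes average over
    the voxels the WTA map assigned to that lobe.  A lobe that won zero
    voxels in a structure yields a NaN column (node missing, excluded from
    edges downstream).
    """
    rows = np.arange(ds.n_subjects) if rows is None else np.asarray(rows, int)
    cols_list: list[np.ndarray | None] = []
    for l in range(1, 6):
        cols_list.append(ds.label_columns(l))
    for sname in ("striatum", "thalamus", "cerebellum"):
        m = wta_maps[sname]
        for l in range(1, 6):
            sel = m.voxel_columns[m.winner_label == l]
            cols_list.append(sel if sel.size else None)
    out = np.full((len(rows), 20), np.nan)
    for j, cols in enumerate(cols_list):
        if cols is None:
            continue
        out[:, j] = roi_mean_signal(ds, cols)[rows]
    return out


@dataclasses.dataclass
class CovNetwork:
    """Symmetric 20x20 partial-correlation matrix with unit diagonal."""

    group: str
    node_labels: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, float)
        if R.shape != (20, 20):
            raise ValueError("R must be 20x20")
        finite = np.isfinite(R)
        if not np.allclose(np.where(finite, R, 0), np.where(finite.T, R.T, 0)):
            raise ValueError("R must be symmetric")
        self.R = R


def build_network(signals: np.ndarray, covariates: np.ndarray | None = None,
                  group: str = "") -> CovNetwork:
    """Partial-correlation network over the 20 node signals.

    Each edge is the correlation of the two node signals after both are
    residualized on an intercept plus the covariate columns (TIV in the
    default pipeline).  Missing (NaN) nodes give NaN rows/columns.
    """
    signals = np.asarray(signals, float)
    n, p = signals.shape
    if p != 20:
        raise ValueError("signals must be subjects x 20")
    k = 0 if covariates is None or np.size(covariates) == 0 else \
        np.atleast_2d(np.asarray(covariates)).reshape(n, -1).shape[1]
    if n <= 20 + k:
        raise ValueError(f"need more subjects than nodes + covariates (n={n})")
    q = _residual_projector(covariates, n)
    valid = ~np.isnan(signals).any(axis=0)
    R = np.full((20, 20), np.nan)
    res = signals[:, valid] - q @ (q.T @ signals[:, valid])
    norms = np.linalg.norm(res, axis=0)
    if (norms < 1e-12).any():
        raise ValueError("degenerate: a node has zero residual variance")
    C = (res / norms).T @ (res / norms)
    R[np.ix_(valid, valid)] = np.clip(C, -1.0, 1.0)
    R[np.arange(20), np.arange(20)] = np.where(valid, 1.0, np.nan)
    iu = np.triu_indices(20, 1)
    R[(iu[1], iu[0])] = R[iu]  # enforce exact symmetry
    return CovNetwork(group=group, node_labels=node_labels(), R=R)


@dataclasses.dataclass
class NetworkComparison:
    """Edgewise permutation comparison of two group networks with FPA screen."""

    group_a: str
    group_b: str
    R_a: np.ndarray
    R_b: np.ndarray
    p_matrix: np.ndarray
    direction: np.ndarray  # sign of z(R_a) - z(R_b)
    n_perm: int
    seed: int
    fpa: dict

    def to_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Long-format edge table (upper triangle) mirroring a results listing."""
        labels = node_labels()
        iu = np.triu_indices(20, 1)
        df = pd.DataFrame({
            "node_a": [labels[i] for i in iu[0]],
            "node_b": [labels[j] for j in iu[1]],
            "r_a": self.R_a[iu],
            "r_b": self.R_b[iu],
            "p_perm": self.p_matrix[iu],
            "direction": np.where(self.direction[iu] > 0, "Increased",
                                  np.where(self.direction[iu] < 0, "Decreased", "Equal")),
        })
        df["significant"] = (df["p_perm"] < alpha) & self.fpa["omnibus_pass"]
        return df


def _fisher_z(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, float)
    if np.any(np.abs(r[np.isfinite(r)]) >= 1.0 - 1e-12):
        off = r - np.eye(len(r)) if r.ndim == 2 else r
        if np.any(np.abs(off[np.isfinite(off)]) >= 1.0 - 1e-12):
            raise ValueError("degenerate: |r| = 1 gives infinite Fisher z")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))


def _group_network_R(ds: GMVDataset, rows: np.ndarray, lobes: np.ndarray,
                     tiv: np.ndarray, struct_Y: dict[str, np.ndarray],
                     struct_cols: dict[str, np.ndarray]) -> np.ndarray:
    """Recompute WTA subregions and the 20x20 network for one subject subset."""
    maps = {}
    for sname in ("striatum", "thalamus", "cerebellum"):
        all_r = _seed_maps_from_parts(lobes, tiv, struct_Y[sname], rows)
        maps[sname] = wta_label(all_r, structure=sname,
                                voxel_columns=struct_cols[sname])
    sig = extract_node_signals(ds, maps, rows)
    net = build_network(sig, tiv[rows])
    return net.R


def compare_networks(ds: GMVDataset, group_a: str, group_b: str,
                     n_perm: int = 5000, seed: int = 0) -> NetworkComparison:
    """Edgewise two-sided permutation comparison of two group networks.

    The statistic per edge is the Fisher-z difference of the two groups'
    partial correlations.  Each permutation reassigns the pooled subjects
    to pseudo-groups of the original sizes and recomputes everything —
    including each pseudo-group's own WTA subregions — to keep the null
    exchangeable.  The result carries the FPA omnibus record at alpha=.05.
    """
    rows_a = ds.group_rows(group_a)
    rows_b = ds.group_rows(group_b)
    if np.intersect1d(rows_a, rows_b).size:
        raise ValueError("groups overlap")
    if len(rows_a) < 10 or len(rows_b) < 10:
        raise ValueError("both groups need at least 10 subjects")

    lobes = lobe_mean_signals(ds)
    tiv = ds.cohort["tiv"].to_numpy(float)
    struct_Y, struct_cols = {}, {}
    for sname in ("striatum", "thalamus", "cerebellum"):
        cols = ds.label_columns(ds.atlas.structure_id_by_name(sname))
        struct_cols[sname] = cols
        struct_Y[sname] = ds.matrix[:, cols]

    def net_R(rows):
        return _group_network_R(ds, rows, lobes, tiv, struct_Y, struct_cols)

    R_a = net_R(rows_a)
    R_b = net_R(rows_b)
    obs = _fisher_z(R_a) - _fisher_z(R_b)

    pooled = np.concatenate([rows_a, rows_b])
    na = len(rows_a)
    rng = np.random.default_rng(seed)
    exceed = np.zeros((20, 20))
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        null = _fisher_z(net_R(perm[:na])) - _fisher_z(net_R(perm[na:]))
        # a pseudo-group with an empty subregion leaves the edge inestimable
        # in that draw; counting it as extreme keeps the p conservative
        exceed += ~np.isfinite(null) | (np.abs(null) >= np.abs(obs) - 1e-15)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.where(np.isfinite(obs), p, np.nan)  # edges of missing nodes
    np.fill_diagonal(p, 1.0)
    p = np.minimum(p, p.T)

    fpa = fpa_adjust(p, alpha=0.05)
    return NetworkComparison(group_a=group_a, group_b=group_b, R_a=R_a, R_b=R_b,
                             p_matrix=p, direction=np.sign(obs), n_perm=n_perm,
                             seed=seed, fpa=fpa)


def fpa_adjust(p_matrix: np.ndarray, alpha: float = 0.05) -> dict:
    """False-positive-adjustment omnibus screen on the 190 unique edges.

    The count of edges with p < alpha is compared with the count expected
    under the global null (alpha times the number of edges tested); edge
    results are taken seriously only when the observed count exceeds it.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p_matrix = np.asarray(p_matrix, float)
    iu = np.triu_indices(p_matrix.shape[0], 1)
    pvals = p_matrix[iu]
    tested = int(np.isfinite(pvals).sum())
    n_sig = int((pvals < alpha).sum())
    expected = alpha * tested
    return {
        "alpha": float(alpha),
        "n_edges_tested": tested,
        "n_significant": n_sig,
        "expected_false": float(expected),
        "omnibus_pass": bool(n_sig > expected),
    }
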