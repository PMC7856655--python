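"""Duration-modulation analysis of structural covariance.

Within a patient group, the coupling between a seed and a target region
is said to be modulated by disease duration when the seed-by-duration
interaction coefficient in

    GM_target ~ 1 + GM_seed + Duration + GM_seed*Duration + TIV

is non-zero; its t statistic (df = n - 5) carries the effect.  Between
the two patient groups, the triple interaction Group*GM_seed*Duration in
the expanded model

    GM_target ~ 1 + Group + GM_seed + Duration + Group*GM_seed
                + Group*Duration + GM_seed*Duration
                + Group*GM_seed*Duration + TIV

(df = n - 9, Group coded 0/1 with GE_GTCS = 1) tests whether the
modulation differs by syndrome.  p values are one-tailed on the
magnitude, reported with the estimate's sign — the convention under
which reference (t, p) pairs such as (2.284, .012) at df 106 are
internally consistent.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .core import GMVDataset, LOBE_NAMES, roi_mean_signal
from .wta import SCNMap

__all__ = [
    "ModulationFit",
    "one_tailed_p",
    "fit_within_group",
    "fit_between_group",
    "subnetwork_modulation_scan",
]

WITHIN_TERMS = ("intercept", "gm_seed", "duration", "gm_seed:duration", "tiv")
BETWEEN_TERMS = ("intercept", "group", "gm_seed", "duration", "group:gm_seed",
                 "group:duration", "gm_seed:duration", "group:gm_seed:duration", "tiv")


@dataclasses.dataclass
class ModulationFit:
    """OLS fit summary focused on the modulation (interaction) coefficient."""

    terms: tuple[str, ...]
    betas: np.ndarray
    t_interaction: float
    df: int
    p_one_tailed: float
    p_two_tailed: float
    direction: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p_one_tailed < 1.0:
            raise ValueError("p must lie strictly in (0, 1)")


def one_tailed_p(t: float, df: int) -> float:
    """Upper-tail t probability of the magnitude, P(T_df >= |t|)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.sf(abs(t), df))


def _ols_interaction(X: np.ndarray, y: np.ndarray, terms: tuple[str, ...],
                     idx: int) -> ModulationFit:
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("collinear design")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[idx, idx])
    t = float(beta[idx] / se)
    return ModulationFit(
        terms=terms,
        betas=beta,
        t_interaction=t,
        df=df,
        p_one_tailed=one_tailed_p(t, df),
        p_two_tailed=float(2 * stats.t.sf(abs(t), df)),
        direction=int(np.sign(t)),
    )


def fit_within_group(gm_target: np.ndarray, gm_seed: np.ndarray,
                     duration: np.ndarray, tiv: np.ndarray) -> ModulationFit:
    """Fit the within-group modulation model and test the seed-by-duration term."""
    y = np.asarray(gm_target, float).ravel()
    s = np.asarray(gm_seed, float).ravel()
    d = np.asarray(duration, float).ravel()
    v = np.asarray(tiv, float).ravel()
    n = len(y)
    if not (len(s) == len(d) == len(v) == n):
        raise ValueError("all vectors must share length")
    if n <= 6:
        raise ValueError("need n > 6")
    if np.isnan(np.concatenate([y, s, d, v])).any():
        raise ValueError("missing values not allowed")
    X = np.column_stack([np.ones(n), s, d, s * d, v])
    return _ols_interaction(X, y, WITHIN_TERMS, idx=3)


def fit_between_group(gm_target: np.ndarray, gm_seed: np.ndarray,
                      duration: np.ndarray, tiv: np.ndarray,
                      group: np.ndarray) -> ModulationFit:
    """Fit the expanded model over both patient groups; test the triple interaction.

    ``group`` may be 0/1 codes or the group-name strings, in which case
    GE_GTCS is coded 1 and FE_FBTS 0.
    """
    y = np.asarray(gm_target, float).ravel()
    s = np.asarray(gm_seed, float).ravel()
    d = np.asarray(duration, float).ravel()
    v = np.asarray(tiv, float).ravel()
    g = np.asarray(group).ravel()
    if g.dtype.kind in "UOS":
        g = (g == "GE_GTCS").astype(float)
    g = g.astype(float)
    n = len(y)
    if n <= 10:
        raise ValueError("need n > 10")
    if len(np.unique(g)) < 2:
        raise ValueError("both groups must be present")
    X = np.column_stack([np.ones(n), g, s, d, g * s, g * d, s * d, g * s * d, v])
    return _ols_interaction(X, y, BETWEEN_TERMS, idx=7)


def _node_signal(ds: GMVDataset, wta_maps: dict[str, SCNMap], structure: str,
                 lobe: int, rows: np.ndarray) -> np.ndarray | None:
    if structure == "cortex":
        cols = ds.label_columns(lobe)
    else:
        m = wta_maps[structure]
        cols = m.voxel_columns[m.winner_label == lobe]
    if cols.size == 0:
        return None
    return roi_mean_signal(ds, cols)[rows]


def subnetwork_modulation_scan(ds: GMVDataset, wta_maps: dict[str, SCNMap],
                               scope: str, groups: tuple[str, ...] | str
                               ) -> pd.DataFrame:
    """Fit the requested modulation model for every directed pair in each subnetwork.

    Comparisons stay within a lobe's own subnetwork (the lobe node plus the
    three subcortical subregions that lobe won), giving 12 directed
    seed->target pairs per lobe, 60 rows per scope.  ``scope`` is
    ``"within_group"`` (one patient group) or ``"between_group"`` (both).
    Pairs whose seed or target subregion is empty are emitted with NaN
    statistics rather than dropped.
    """
    if scope not in ("within_group", "between_group"):
        raise ValueError("scope must be 'within_group' or 'between_group'")
    if scope == "within_group":
        if isinstance(groups, (tuple, list)):
            (group,) = groups
        else:
            group = groups
        rows = ds.group_rows(group)
        g_codes = None
    else:
        ga, gb = ("GE_GTCS", "FE_FBTS") if isinstance(groups, str) else tuple(groups)
        rows = np.concatenate([ds.group_rows(ga), ds.group_rows(gb)])
        g_codes = ds.cohort["group"].to_numpy()[rows]

    dur = ds.cohort["duration_months"].to_numpy(float)[rows]
    tiv = ds.cohort["tiv"].to_numpy(float)[rows]

    structures = ("cortex", "striatum", "thalamus", "cerebellum")
    recs = []
    for lobe in range(1, 6):
        for seed_s in structures:
            for target_s in structures:
                if seed_s == target_s:
                    continue
                xs = _node_signal(ds, wta_maps, seed_s, lobe, rows)
                yt = _node_signal(ds, wta_maps, target_s, lobe, rows)
                rec = {
                    "subnetwork": LOBE_NAMES[lobe],
                    "seed": seed_s,
                    "target": target_s,
                    "scope": scope,
                    "n": len(rows),
                }
                if xs is None or yt is None:
                    rec.update(t=np.nan, p_one_tailed=np.nan, direction=0)
                else:
                    fit = (fit_within_group(yt, xs, dur, tiv)
                           if scope == "within_group"
                           else fit_between_group(yt, xs, dur, tiv, g_codes))
                    rec.update(t=fit.t_interaction, p_one_tailed=fit.p_one_tailed,
                               direction=fit.direction)
                recs.append(rec)
    return pd.DataFrame.from_records(recs)
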