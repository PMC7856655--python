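"""Core data containers and I/O for gray-matter volume (GMV) analysis.

The analyses in this package operate on subject-level gray-matter
probability maps that have already been segmented and spatially
normalized to a common voxel grid (the usual output of a VBM
preprocessing pipeline).  This module provides the in-memory containers
for single volumes, atlases, and the subjects-by-voxels data matrix, the
NIfTI/TSV plumbing around them, Gaussian smoothing, ROI averaging, and
the demographic balance statistics reported for a three-group cohort.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "GROUPS",
    "LOBE_NAMES",
    "STRUCTURE_NAMES",
    "VolumeImage",
    "Atlas",
    "GMVDataset",
    "read_volume",
    "write_volume",
    "smooth_volume",
    "fwhm_to_sigma",
    "roi_mean_signal",
    "read_cohort_table",
    "write_cohort_table",
    "validate_cohort",
    "demographic_balance",
    "anova_from_summary",
]

#: Canonical group labels: two generalized-seizure patient groups and controls.
GROUPS = ("GE_GTCS", "FE_FBTS", "HC")

#: Atlas integer id -> cortical lobe name (five non-overlapping lobes).
LOBE_NAMES: Mapping[int, str] = {
    1: "frontal",
    2: "motor_premotor",
    3: "somatosensory",
    4: "parietal_occipital",
    5: "temporal",
}

#: Atlas integer id -> subcortical structure name.
STRUCTURE_NAMES: Mapping[int, str] = {
    10: "striatum",
    11: "thalamus",
    12: "cerebellum",
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation."""
    return fwhm * _FWHM_TO_SIGMA


@dataclasses.dataclass
class VolumeImage:
    """A 3D scalar field on a voxel grid with an affine mapping to world mm.

    ``data`` holds either gray-matter probabilities (values in [0, 1]) or
    integer atlas labels.  ``affine`` is the 4x4 voxel -> mm map; voxel
    sizes are the column norms of its 3x3 part.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.data.ndim} dims (shape {self.data.shape})"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dims must be >= 1, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge length in mm along each axis (affine column norms)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def is_axis_aligned(self, tol: float = 1e-6) -> bool:
        """True when each voxel axis maps to a single world axis (no shear/oblique)."""
        m = np.abs(self.affine[:3, :3])
        return bool(np.all((m > tol).sum(axis=0) == 1) and np.all((m > tol).sum(axis=1) == 1))


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1/2 file into a :class:`VolumeImage`.

    Raises ``ValueError`` for non-3D images and ``IOError``/``FileNotFoundError``
    for unreadable files.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim} dims (shape {data.shape})"
        )
    return VolumeImage(data=data, affine=np.asarray(img.affine))


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write a :class:`VolumeImage` as NIfTI-1 (.nii or .nii.gz)."""
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    nib.save(img, str(path))


def smooth_volume(vol: VolumeImage, fwhm_mm: float) -> VolumeImage:
    """Smooth a volume with an isotropic Gaussian kernel of given FWHM in mm.

    The kernel standard deviation is ``fwhm / (2 sqrt(2 ln 2))`` converted to
    voxel units per axis.  Boundaries are zero-padded, matching the convention
    that tissue probability is zero outside the head.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if not vol.is_axis_aligned():
        raise ValueError("smoothing requires an axis-aligned (shear-free) affine")
    sigma_vox = fwhm_to_sigma(fwhm_mm) / vol.voxel_size
    out = ndimage.gaussian_filter(np.asarray(vol.data, dtype=float), sigma=sigma_vox,
                                  mode="constant", cval=0.0)
    return VolumeImage(data=out, affine=vol.affine.copy())


@dataclasses.dataclass
class Atlas:
    """Integer label volume naming five cortical lobes and three subcortical structures.

    Labels 1-5 are the lobes (frontal, motor/premotor, somatosensory,
    parietal/occipital, temporal), 10-12 the striatum, thalamus and
    cerebellum; 0 is background.  Lobe and structure voxel sets are
    pairwise disjoint by construction of the label volume.
    """

    labels: VolumeImage
    lobe_ids: Mapping[int, str] = dataclasses.field(default_factory=lambda: dict(LOBE_NAMES))
    structure_ids: Mapping[int, str] = dataclasses.field(
        default_factory=lambda: dict(STRUCTURE_NAMES)
    )

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels.data)
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("atlas labels must be integer-valued")
        for sid, name in self.structure_ids.items():
            if not np.any(lab == sid):
                raise ValueError(f"structure mask '{name}' (id {sid}) is empty")

    def mask(self, label_id: int) -> np.ndarray:
        """Boolean mask for one label id."""
        return np.asarray(self.labels.data) == label_id

    def brain_mask(self) -> np.ndarray:
        """All labeled (non-background) voxels."""
        return np.asarray(self.labels.data) > 0

    def structure_id_by_name(self, name: str) -> int:
        for sid, n in self.structure_ids.items():
            if n == name:
                return sid
        raise KeyError(name)


REQUIRED_COHORT_COLUMNS = ("subject_id", "group", "duration_months", "tiv", "age", "sex")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table: unique ids, known groups, durations for patients, TIV > 0."""
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if cohort["subject_id"].duplicated().any():
        raise ValueError("subject_id values must be unique")
    bad = set(cohort["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    patients = cohort["group"] != "HC"
    if cohort.loc[patients, "duration_months"].isna().any():
        raise ValueError("duration_months missing for a patient row")
    if (cohort.loc[patients, "duration_months"] < 0).any():
        raise ValueError("duration_months must be non-negative")
    if (cohort["tiv"] <= 0).any():
        raise ValueError("tiv must be positive")
    if not cohort["sex"].isin(["M", "F"]).all():
        raise ValueError("sex must be 'M' or 'F'")
    return cohort


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated cohort table."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return validate_cohort(df)


def write_cohort_table(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


class GMVDataset:
    """Subjects x in-mask-voxels matrix view of aligned GMV volumes.

    Columns are the atlas's labeled voxels in lexicographic (i, j, k)
    order; ``voxel_ijk[c]`` gives the grid coordinate of column ``c``.
    """

    def __init__(self, matrix: np.ndarray, voxel_ijk: np.ndarray,
                 cohort: pd.DataFrame, atlas: Atlas):
        matrix = np.asarray(matrix, dtype=float)
        voxel_ijk = np.asarray(voxel_ijk)
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2D (subjects x voxels)")
        if matrix.shape[0] != len(cohort):
            raise ValueError("matrix row count must equal cohort row count")
        if matrix.shape[1] != voxel_ijk.shape[0]:
            raise ValueError("voxel index length must equal matrix column count")
        order = np.lexsort((voxel_ijk[:, 2], voxel_ijk[:, 1], voxel_ijk[:, 0]))
        self.matrix = matrix[:, order]
        self.voxel_ijk = voxel_ijk[order]
        self.cohort = validate_cohort(cohort.reset_index(drop=True))
        self.atlas = atlas
        # map label id -> column indices, derived once from the atlas
        lab = np.asarray(atlas.labels.data)
        col_labels = lab[tuple(self.voxel_ijk.T)]
        self._label_cols = {
            int(l): np.flatnonzero(col_labels == l) for l in np.unique(col_labels)
        }
        self.column_labels = col_labels

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]

    def label_columns(self, label_id: int) -> np.ndarray:
        """Matrix columns belonging to one atlas label (empty array if none)."""
        return self._label_cols.get(int(label_id), np.empty(0, dtype=int))

    def group_rows(self, group: str) -> np.ndarray:
        """Row indices of the subjects in one group."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return np.flatnonzero((self.cohort["group"] == group).to_numpy())

    @classmethod
    def from_volumes(cls, volumes: Sequence[VolumeImage], cohort: pd.DataFrame,
                     atlas: Atlas) -> "GMVDataset":
        """Stack subject volumes (all on the atlas grid) into the data matrix."""
        mask = atlas.brain_mask()
        ijk = np.argwhere(mask)
        rows = []
        for v in volumes:
            if v.shape != atlas.labels.shape:
                raise ValueError("subject volume grid does not match atlas grid")
            rows.append(np.asarray(v.data, dtype=float)[mask])
        return cls(np.vstack(rows), ijk, cohort, atlas)


def roi_mean_signal(ds: GMVDataset, voxel_columns: np.ndarray) -> np.ndarray:
    """Per-subject mean GMV over a set of matrix columns (an ROI)."""
    voxel_columns = np.asarray(voxel_columns, dtype=int)
    if voxel_columns.size == 0:
        raise ValueError("voxel set is empty")
    if voxel_columns.min() < 0 or voxel_columns.max() >= ds.n_voxels:
        raise ValueError("voxel set outside mask")
    return ds.matrix[:, voxel_columns].mean(axis=1)


def demographic_balance(cohort: pd.DataFrame) -> dict:
    """Between-group balance statistics for a three-group cohort.

    Age is compared with a one-way ANOVA across the three groups, sex with
    a Pearson chi-square (no continuity correction) on the 3x2 group-by-sex
    table, and duration with a pooled-variance two-sample t test between the
    two patient groups.  All p values are two-tailed.
    """
    validate_cohort(cohort)
    present = [g for g in GROUPS if (cohort["group"] == g).any()]
    if len(present) != 3:
        raise ValueError("exactly three groups required")
    for g in GROUPS:
        if (cohort["group"] == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")

    ages = [cohort.loc[cohort["group"] == g, "age"].to_numpy() for g in GROUPS]
    age_f, age_p = stats.f_oneway(*ages)
    if all(np.ptp(a) == 0 for a in ages) and len({a[0] for a in ages}) == 1:
        age_f, age_p = 0.0, 1.0  # identical constant vectors: F is 0/0, define as no effect

    sex_table = pd.crosstab(cohort["group"], cohort["sex"]).reindex(
        index=list(GROUPS), fill_value=0
    )
    chi2, chi2_p, _, _ = stats.chi2_contingency(sex_table.to_numpy(), correction=False)

    d1 = cohort.loc[cohort["group"] == "GE_GTCS", "duration_months"].to_numpy(float)
    d2 = cohort.loc[cohort["group"] == "FE_FBTS", "duration_months"].to_numpy(float)
    t, t_p = stats.ttest_ind(d1, d2, equal_var=True)
    if np.isnan(t):  # zero pooled variance with equal means
        t, t_p = 0.0, 1.0

    return {
        "age_F": float(age_f),
        "age_p": float(age_p),
        "age_df": (2, len(cohort) - 3),
        "sex_chi2": float(chi2),
        "sex_p": float(chi2_p),
        "duration_t": float(t),
        "duration_p": float(t_p),
        "duration_df": len(d1) + len(d2) - 2,
    }


def anova_from_summary(means: Sequence[float], sems: Sequence[float],
                       ns: Sequence[int]) -> tuple[float, float]:
    """One-way ANOVA F and p reconstructed from per-group mean, SEM and n.

    Group SDs are recovered as SEM * sqrt(n); the F statistic uses the
    standard between/within sum-of-squares decomposition and is referred
    to an F(k-1, N-k) distribution.  Identical to an ANOVA on raw data
    whose summaries match.
    """
    m = np.asarray(means, float)
    se = np.asarray(sems, float)
    n = np.asarray(ns, int)
    if len(m) != len(se) or len(m) != len(n):
        raise ValueError("means, sems, ns must have equal length")
    if np.any(n < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(se <= 0):
        raise ValueError("sems must be positive")
    sd = se * np.sqrt(n)
    grand = float((n * m).sum() / n.sum())
    ss_between = float((n * (m - grand) ** 2).sum())
    ss_within = float(((n - 1) * sd**2).sum())
    df1 = len(m) - 1
    df2 = int(n.sum() - len(m))
    if ss_within == 0:
        return (0.0, 1.0) if ss_between == 0 else (np.inf, 0.0)
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), float(stats.f.sf(f, df1, df2))
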