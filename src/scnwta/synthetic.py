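"""Synthetic cohort generator with planted structural-covariance territories.

Real structural-covariance studies of generalized-seizure epilepsy rest on
subject MRI collections that are rarely shareable, so this module builds a
fully synthetic stand-in with known ground truth: a geometric atlas (a
cortical shell split into five lobes plus three interior subcortical
blobs), and per-subject gray-matter volumes in which

* each cortical lobe's mean GMV tracks a latent per-subject "lobe factor"
  drawn from a configurable 5x5 correlation matrix,
* each subcortical voxel belongs to a territory assigned to one lobe and
  covaries with that lobe's factor through a coupling weight that may
  depend linearly on disease duration,
* group-specific atrophy removes GMV in proportion to duration,
* head size (TIV) adds a global confound, and
* spatially smoothed Gaussian noise is layered on top.

Because coupling acts through the latent factor rather than through voxel
means, across-subject covariance is the generative mechanism itself — the
quantity the winner-take-all estimator is supposed to recover.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, stats

from .core import (
    Atlas,
    GMVDataset,
    LOBE_NAMES,
    STRUCTURE_NAMES,
    GROUPS,
    VolumeImage,
    fwhm_to_sigma,
    read_cohort_table,
    read_volume,
    write_cohort_table,
    write_volume,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_atlas",
    "generate_cohort",
    "write_cohort_dir",
    "read_cohort_dir",
]


def _compound_symmetric(rho: float = 0.3, k: int = 5) -> np.ndarray:
    m = np.full((k, k), rho)
    np.fill_diagonal(m, 1.0)
    return m


@dataclasses.dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Coupling maps are dictionaries keyed ``(group, structure_name, lobe_id)``;
    keys that are absent fall back to the ``*_default`` scalar, so a single
    planted effect is one dictionary entry.  Durations are months, TIV is ml,
    GMV is a unitless probability in [0, 1].
    """

    grid: tuple[int, int, int] = (32, 32, 32)
    voxel_mm: float = 1.5
    n_per_group: int = 40
    lobe_factor_corr: np.ndarray = dataclasses.field(default_factory=_compound_symmetric)
    cortical_loading: float = 0.05          # GMV change per unit latent factor, cortex
    coupling_w0: Mapping[tuple, float] = dataclasses.field(default_factory=dict)
    coupling_w0_default: float = 0.03       # baseline subcortical coupling
    coupling_w1: Mapping[tuple, float] = dataclasses.field(default_factory=dict)
    coupling_w1_default: float = 0.0        # coupling change per month of duration
    atrophy_slope: Mapping[tuple, float] = dataclasses.field(default_factory=dict)
    atrophy_slope_default: float = 0.0      # GMV loss per month, keyed (group, region)
    tiv_mean: float = 1500.0
    tiv_sd: float = 120.0
    tiv_slope: float = 5e-5                 # GMV per ml of TIV deviation
    duration_mean: float = 83.0
    duration_sd: float = 94.0               # heavy right tail; truncated at 1 month
    age_mean: float = 26.0
    age_sd: float = 7.8
    p_male: float = 71.0 / 111.0
    mu_cortex: float = 0.5
    mu_subcortex: float = 0.5
    noise_sd: float = 0.03
    smooth_noise_fwhm_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = tuple(int(g) for g in np.broadcast_to(self.grid, (3,))) \
            if np.isscalar(self.grid) else tuple(int(g) for g in self.grid)
        c = np.asarray(self.lobe_factor_corr, float)
        if c.shape != (5, 5) or not np.allclose(c, c.T):
            raise ValueError("lobe_factor_corr must be a symmetric 5x5 matrix")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("lobe_factor_corr must be positive definite")
        self.lobe_factor_corr = c
        if self.n_per_group < 4:
            raise ValueError("n_per_group must be >= 4")

    def w0(self, group: str, structure: str, lobe: int) -> float:
        return float(self.coupling_w0.get((group, structure, lobe), self.coupling_w0_default))

    def w1(self, group: str, structure: str, lobe: int) -> float:
        return float(self.coupling_w1.get((group, structure, lobe), self.coupling_w1_default))

    def atrophy(self, group: str, region: str) -> float:
        return float(self.atrophy_slope.get((group, region), self.atrophy_slope_default))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lobe_factor_corr"] = np.asarray(self.lobe_factor_corr).tolist()
        for k in ("coupling_w0", "coupling_w1", "atrophy_slope"):
            d[k] = {"|".join(str(p) for p in key): v for key, v in d[k].items()}
        d["grid"] = list(self.grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["grid"] = tuple(d["grid"])
        d["lobe_factor_corr"] = np.asarray(d["lobe_factor_corr"], float)
        for k in ("coupling_w0", "coupling_w1", "atrophy_slope"):
            raw = d.get(k, {})
            parsed = {}
            for key, v in raw.items():
                parts = key.split("|")
                parsed[(parts[0], parts[1], int(parts[2])) if len(parts) == 3
                       else (parts[0], parts[1])] = float(v)
            d[k] = parsed
        return cls(**d)


@dataclasses.dataclass
class GroundTruth:
    """What was actually planted: territory labels and the parameters used.

    ``territory_labels`` is a label volume over the atlas grid holding, for
    every subcortical voxel, the lobe id (1-5) whose factor drives it; zero
    elsewhere.  Each structure's mask is partitioned into five non-empty
    territories.
    """

    territory_labels: np.ndarray
    coupling_w0: dict
    coupling_w1: dict
    atrophy_slope: dict

    def territory_mask(self, atlas: Atlas, structure: str, lobe: int) -> np.ndarray:
        sid = atlas.structure_id_by_name(structure)
        return (np.asarray(atlas.labels.data) == sid) & (self.territory_labels == lobe)


def _angular_partition(ijk: np.ndarray, center: np.ndarray, n_parts: int = 5) -> np.ndarray:
    """Split voxels into contiguous azimuthal arcs with near-equal counts.

    Returns a 1..n_parts label per voxel.  Equal-count arcs keep every part
    non-empty whenever there are at least ``n_parts`` voxels.
    """
    rel = ijk - center
    az = np.arctan2(rel[:, 1], rel[:, 0])
    order = np.argsort(az, kind="stable")
    labels = np.empty(len(ijk), dtype=np.int32)
    for part, chunk in enumerate(np.array_split(order, n_parts), start=1):
        labels[chunk] = part
    return labels


def generate_atlas(config: GeneratorConfig) -> tuple[Atlas, GroundTruth]:
    """Build the geometric atlas and its ground-truth territory partition.

    The cortex is a spherical shell split into five azimuthal sectors; the
    striatum, thalamus and cerebellum are three interior spherical blobs
    placed 120 degrees apart, each partitioned into five contiguous
    angular territories.  Construction is purely geometric, hence
    deterministic for a given config.
    """
    grid = np.asarray(config.grid)
    if np.any(grid < 16):
        raise ValueError("grid must be at least 16 voxels per axis")
    center = (grid - 1) / 2.0
    radius = 0.45 * grid.min()

    idx = np.indices(config.grid).reshape(3, -1).T.astype(float)
    rel = idx - center
    rho = np.linalg.norm(rel, axis=1)

    labels = np.zeros(config.grid, dtype=np.int32).reshape(-1)
    territory = np.zeros(config.grid, dtype=np.int32).reshape(-1)

    # cortical shell -> five lobes by fixed 72-degree sectors
    shell = (rho >= 0.75 * radius) & (rho <= radius)
    az = np.arctan2(rel[:, 1], rel[:, 0])
    sector = np.minimum((np.floor((az + np.pi) / (2 * np.pi / 5))).astype(np.int32), 4) + 1
    labels[shell] = sector[shell]

    # three interior blobs, centers 120 degrees apart in the xy-plane
    blob_spec = {
        10: (np.deg2rad(90.0), 0.28),   # striatum
        11: (np.deg2rad(210.0), 0.25),  # thalamus
        12: (np.deg2rad(330.0), 0.30),  # cerebellum
    }
    for sid, (theta, rfrac) in blob_spec.items():
        bc = center + 0.35 * radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        dist = np.linalg.norm(idx - bc, axis=1)
        inside = dist <= rfrac * radius
        if not inside.any():
            raise ValueError("grid too small to host a non-empty structure")
        if (labels[inside] != 0).any():
            raise ValueError("structure blob overlaps another region")
        labels[inside] = sid
        ijk = idx[inside]
        if len(ijk) < 5:
            raise ValueError("grid too small to partition a structure into 5 territories")
        territory[inside] = _angular_partition(ijk, bc)

    for lobe in range(1, 6):
        if not (labels == lobe).any():
            raise ValueError("grid too small to host a non-empty lobe")

    affine = np.diag([config.voxel_mm] * 3 + [1.0])
    atlas = Atlas(labels=VolumeImage(labels.reshape(config.grid), affine))
    truth = GroundTruth(
        territory_labels=territory.reshape(config.grid),
        coupling_w0=dict(config.coupling_w0),
        coupling_w1=dict(config.coupling_w1),
        atrophy_slope=dict(config.atrophy_slope),
    )
    return atlas, truth


def _smoothed_noise_scale(sigma_vox: np.ndarray, probe: int = 65) -> float:
    """Std-reduction factor of white noise under separable Gaussian smoothing."""
    factor = 1.0
    for s in sigma_vox:
        if s <= 0:
            continue
        impulse = np.zeros(probe)
        impulse[probe // 2] = 1.0
        k = ndimage.gaussian_filter1d(impulse, sigma=s, mode="constant")
        factor *= float(np.sqrt((k**2).sum()))
    return factor


def _subject_rng(seed: int, group_index: int, subject_index: int) -> np.random.Generator:
    # per-subject stream: adding subjects never perturbs earlier ones
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(group_index, subject_index)))


def generate_cohort(config: GeneratorConfig, atlas: Atlas,
                    truth: GroundTruth) -> tuple[GMVDataset, pd.DataFrame]:
    """Draw the cohort table and subject volumes, returning the data matrix.

    Patients' durations follow a truncated normal (lower bound one month)
    whose mean and SD mimic a chronic-epilepsy clinic sample; controls have
    no duration.  Values are clipped to [0, 1] last; a config that clips
    more than 5% of in-mask voxels is logged as a warning and more than 50%
    is an error, since heavy clipping would bias the linear recovery models.

    The latent lobe factors actually drawn are exposed on the returned
    dataset as ``latent_factors`` (subjects x 5) for calibration checks.
    """
    lab = np.asarray(atlas.labels.data)
    terr = np.asarray(truth.territory_labels)
    if lab.shape != terr.shape:
        raise ValueError("atlas and ground truth grids differ")
    mask = lab > 0
    ijk = np.argwhere(mask)
    mask_labels = lab[mask]
    mask_terr = terr[mask]

    chol = np.linalg.cholesky(config.lobe_factor_corr)
    sigma_vox = np.full(3, fwhm_to_sigma(config.smooth_noise_fwhm_mm) / config.voxel_mm)
    noise_scale = _smoothed_noise_scale(sigma_vox)

    # per-voxel deterministic templates: loading on each lobe factor and
    # duration-dependent terms, assembled once per group
    rows, records, factors = [], [], []
    n_clipped = 0
    n_total = 0
    for gi, group in enumerate(GROUPS):
        # coupling lookup tables for this group, indexed by (structure, lobe)
        for si in range(config.n_per_group):
            rng = _subject_rng(config.seed, gi, si)
            if group == "HC":
                duration = np.nan
            else:
                a = (1.0 - config.duration_mean) / config.duration_sd
                duration = float(stats.truncnorm.rvs(
                    a, np.inf, loc=config.duration_mean, scale=config.duration_sd,
                    random_state=rng))
            tiv = float(rng.normal(config.tiv_mean, config.tiv_sd))
            age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, None))
            sex = "M" if rng.random() < config.p_male else "F"
            f = chol @ rng.standard_normal(5)
            d = 0.0 if np.isnan(duration) else duration

            vals = np.empty(len(ijk))
            tiv_dev = config.tiv_slope * (tiv - config.tiv_mean)
            for lobe in range(1, 6):
                sel = mask_labels == lobe
                vals[sel] = (config.mu_cortex + config.cortical_loading * f[lobe - 1]
                             + tiv_dev
                             - config.atrophy(group, LOBE_NAMES[lobe]) * d)
            for sid, sname in STRUCTURE_NAMES.items():
                for lobe in range(1, 6):
                    sel = (mask_labels == sid) & (mask_terr == lobe)
                    w = config.w0(group, sname, lobe) + config.w1(group, sname, lobe) * d
                    vals[sel] = (config.mu_subcortex + w * f[lobe - 1]
                                 + tiv_dev
                                 - config.atrophy(group, sname) * d)

            white = rng.standard_normal(config.grid)
            smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="constant")
            vals = vals + (config.noise_sd / noise_scale) * smooth[mask]

            clipped = (vals < 0) | (vals > 1)
            n_clipped += int(clipped.sum())
            n_total += len(vals)
            vals = np.clip(vals, 0.0, 1.0)

            rows.append(vals)
            factors.append(f)
            records.append({
                "subject_id": f"{group}_{si:03d}",
                "group": group,
                "duration_months": duration,
                "tiv": tiv,
                "age": age,
                "sex": sex,
            })

    frac = n_clipped / max(n_total, 1)
    if frac >= 0.5:
        raise ValueError(f"{frac:.0%} of voxel values clipped; config is degenerate")
    if frac >= 0.05:
        logger.warning("%.1f%% of voxel values clipped to [0, 1]", 100 * frac)

    cohort = pd.DataFrame.from_records(records)
    ds = GMVDataset(np.vstack(rows), ijk, cohort, atlas)
    ds.latent_factors = np.vstack(factors)  # type: ignore[attr-defined]
    return ds, cohort


def write_cohort_dir(path: str | Path, config: GeneratorConfig, atlas: Atlas,
                     truth: GroundTruth, ds: GMVDataset) -> None:
    """Write a cohort directory: atlas, territories, cohort TSV, subject volumes."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_volume(atlas.labels, path / "atlas.nii.gz")
    write_volume(VolumeImage(truth.territory_labels, atlas.labels.affine),
                 path / "territories.nii.gz")
    with open(path / "truth.json", "w") as fh:
        json.dump({
            "coupling_w0": {"|".join(map(str, k)): v for k, v in truth.coupling_w0.items()},
            "coupling_w1": {"|".join(map(str, k)): v for k, v in truth.coupling_w1.items()},
            "atrophy_slope": {"|".join(map(str, k)): v
                              for k, v in truth.atrophy_slope.items()},
        }, fh, indent=2)
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    write_cohort_table(ds.cohort, path / "cohort.tsv")
    mask = atlas.brain_mask()
    for row, sid in zip(ds.matrix, ds.cohort["subject_id"]):
        vol = np.zeros(atlas.labels.shape, dtype=np.float32)
        vol[mask] = row
        write_volume(VolumeImage(vol, atlas.labels.affine), path / f"{sid}_gmv.nii.gz")


def read_cohort_dir(path: str | Path, fwhm_mm: float | None = None
                    ) -> tuple[GeneratorConfig, Atlas, GroundTruth, GMVDataset]:
    """Read a cohort directory back, optionally smoothing subject volumes."""
    path = Path(path)
    with open(path / "config.yaml") as fh:
        config = GeneratorConfig.from_dict(yaml.safe_load(fh))
    atlas_vol = read_volume(path / "atlas.nii.gz")
    atlas = Atlas(labels=VolumeImage(np.asarray(atlas_vol.data, dtype=np.int32),
                                     atlas_vol.affine))
    terr = read_volume(path / "territories.nii.gz")
    with open(path / "truth.json") as fh:
        raw = json.load(fh)

    def _parse(d):
        out = {}
        for k, v in d.items():
            parts = k.split("|")
            key = (parts[0], parts[1], int(parts[2])) if len(parts) == 3 else tuple(parts)
            out[key] = float(v)
        return out

    truth = GroundTruth(
        territory_labels=np.asarray(terr.data, dtype=np.int32),
        coupling_w0=_parse(raw["coupling_w0"]),
        coupling_w1=_parse(raw["coupling_w1"]),
        atrophy_slope=_parse(raw["atrophy_slope"]),
    )
    cohort = read_cohort_table(path / "cohort.tsv")
    from .core import smooth_volume
    vols = []
    for sid in cohort["subject_id"]:
        v = read_volume(path / f"{sid}_gmv.nii.gz")
        if fwhm_mm:
            v = smooth_volume(v, fwhm_mm)
        vols.append(v)
    ds = GMVDataset.from_volumes(vols, cohort, atlas)
    return config, atlas, truth, ds
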