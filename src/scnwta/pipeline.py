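"""End-to-end reproducible runs: generate -> smooth -> map -> compare -> model.

A run takes a :class:`RunConfig` and fills an output directory with the
report tables of the full analysis: cohort demographics, WTA voxel
counts with permutation p values, radar-normalized counts, the 20-node
network comparisons with the FPA screen, the duration-modulation scans,
and the voxelwise cluster tables, plus a manifest recording the exact
configuration and seeds.  Identical configs and seeds give byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GROUPS, LOBE_NAMES, STRUCTURE_NAMES, demographic_balance
from .modulation import subnetwork_modulation_scan
from .network import compare_networks, node_labels
from .synthetic import (
    GeneratorConfig,
    generate_atlas,
    generate_cohort,
    read_cohort_dir,
    write_cohort_dir,
)
from .vbm import cluster_correct, slope_interaction_map, voxelwise_duration_corr, \
    voxelwise_group_anova
from .wta import count_labels, permutation_map_test, structure_wta_map

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_FLOAT_FMT = "%.6g"
PAIRS = (("GE_GTCS", "HC"), ("FE_FBTS", "HC"), ("GE_GTCS", "FE_FBTS"))


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    cohort_dir: str | None = None     # read an existing cohort instead of generating
    out_dir: str = "scnwta_run"
    fwhm_mm: float = 8.0              # 0 disables the smoothing stage
    n_perm: int = 5000
    alpha: float = 0.05
    voxel_p: float = 0.01
    seed: int = 0
    use_abs_wta: bool = False
    run_vbm: bool = True
    run_network: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        gen = d.pop("generator", None)
        cfg = cls(**d)
        if gen is not None:
            cfg.generator = GeneratorConfig.from_dict(gen)
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages and return the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage '{name}' failed") from exc
            stage_log.append({"stage": name, "elapsed_s": round(time.time() - t0, 3)})
        return deco

    state: dict = {}

    @stage("cohort")
    def _cohort():
        if cfg.cohort_dir:
            _, atlas, truth, ds = read_cohort_dir(cfg.cohort_dir,
                                                  fwhm_mm=cfg.fwhm_mm or None)
        else:
            atlas, truth = generate_atlas(cfg.generator)
            ds, _ = generate_cohort(cfg.generator, atlas, truth)
            cdir = out / "cohort"
            cached = cdir / "config.yaml"
            stale = True
            if cached.exists():
                with open(cached) as fh:
                    stale = yaml.safe_load(fh) != cfg.generator.to_dict()
            if stale:
                write_cohort_dir(cdir, cfg.generator, atlas, truth, ds)
            if cfg.fwhm_mm:
                _, atlas, truth, ds = read_cohort_dir(cdir, fwhm_mm=cfg.fwhm_mm)
        state.update(atlas=atlas, truth=truth, ds=ds)

    @stage("demographics")
    def _demo():
        rep = demographic_balance(state["ds"].cohort)
        df = pd.DataFrame([
            {"measure": "age", "test": "one_way_anova",
             "stat": rep["age_F"], "p": rep["age_p"]},
            {"measure": "sex", "test": "chi_square",
             "stat": rep["sex_chi2"], "p": rep["sex_p"]},
            {"measure": "duration", "test": "two_sample_t",
             "stat": rep["duration_t"], "p": rep["duration_p"]},
        ])
        _write_tsv(df, out / "demographics.tsv")

    @stage("wta_maps")
    def _maps():
        ds = state["ds"]
        maps = {}
        count_rows = []
        for g in GROUPS:
            rows = ds.group_rows(g)
            maps[g] = {}
            for sname in STRUCTURE_NAMES.values():
                m = structure_wta_map(ds, sname, rows, group=g,
                                      use_abs=cfg.use_abs_wta)
                maps[g][sname] = m
                c = count_labels(m)
                for l in range(1, 6):
                    count_rows.append({"group": g, "structure": sname,
                                       "lobe": LOBE_NAMES[l], "count": int(c[l - 1])})
        state["maps"] = maps
        counts = pd.DataFrame(count_rows)
        _write_tsv(counts, out / "wta_counts.tsv")
        # radar-normalized counts: patient counts divided by the HC count
        hc = counts[counts.group == "HC"].set_index(["structure", "lobe"])["count"]
        radar = counts[counts.group != "HC"].copy()
        radar["normalized"] = [
            r["count"] / hc.loc[(r["structure"], r["lobe"])] if
            hc.loc[(r["structure"], r["lobe"])] else np.nan
            for _, r in radar.iterrows()
        ]
        _write_tsv(radar, out / "wta_counts_normalized.tsv")

    @stage("map_comparisons")
    def _map_cmp():
        ds = state["ds"]
        frames = []
        for i, (ga, gb) in enumerate(PAIRS):
            for j, sname in enumerate(STRUCTURE_NAMES.values()):
                cmp_ = permutation_map_test(
                    ds, ga, gb, sname, n_perm=cfg.n_perm,
                    seed=cfg.seed + 17 * i + 3 * j, use_abs=cfg.use_abs_wta)
                t = cmp_.table.copy()
                t.insert(0, "structure", sname)
                t.insert(0, "group_b", gb)
                t.insert(0, "group_a", ga)
                frames.append(t)
        _write_tsv(pd.concat(frames, ignore_index=True), out / "map_comparisons.tsv")

    if cfg.run_network:
        @stage("network")
        def _network():
            ds = state["ds"]
            frames = []
            fpa_rows = []
            for i, (ga, gb) in enumerate(PAIRS):
                cmp_ = compare_networks(ds, ga, gb, n_perm=cfg.n_perm,
                                        seed=cfg.seed + 101 + i)
                t = cmp_.to_table(alpha=cfg.alpha)
                t.insert(0, "group_b", gb)
                t.insert(0, "group_a", ga)
                frames.append(t)
                fpa_rows.append({"group_a": ga, "group_b": gb, **cmp_.fpa})
                np.savez(out / f"network_{ga}_vs_{gb}.npz", R_a=cmp_.R_a,
                         R_b=cmp_.R_b, p=cmp_.p_matrix,
                         nodes=np.array(node_labels()))
            _write_tsv(pd.concat(frames, ignore_index=True),
                       out / "network_comparisons.tsv")
            _write_tsv(pd.DataFrame(fpa_rows), out / "network_fpa.tsv")

    @stage("modulation")
    def _modulation():
        ds = state["ds"]
        maps = state["maps"]
        frames = []
        for g in ("GE_GTCS", "FE_FBTS"):
            t = subnetwork_modulation_scan(ds, maps[g], "within_group", g)
            t.insert(0, "analysis", g)
            frames.append(t)
        # between-group scope needs one shared territory definition: use the
        # WTA maps of the pooled patient subjects
        pooled = np.concatenate([ds.group_rows("GE_GTCS"), ds.group_rows("FE_FBTS")])
        pooled_maps = {s: structure_wta_map(ds, s, pooled, group="patients",
                                            use_abs=cfg.use_abs_wta)
                       for s in STRUCTURE_NAMES.values()}
        t = subnetwork_modulation_scan(ds, pooled_maps, "between_group",
                                       ("GE_GTCS", "FE_FBTS"))
        t.insert(0, "analysis", "GE_GTCS_vs_FE_FBTS")
        frames.append(t)
        _write_tsv(pd.concat(frames, ignore_index=True), out / "modulation.tsv")

    if cfg.run_vbm:
        @stage("vbm")
        def _vbm():
            ds = state["ds"]
            rows = []
            fmap = voxelwise_group_anova(ds)
            res = cluster_correct(fmap, cfg.voxel_p, cfg.n_perm, cfg.seed + 211, ds)
            rows += _cluster_rows("group_anova", res, ds)
            for g in ("GE_GTCS", "FE_FBTS"):
                rmap = voxelwise_duration_corr(ds, g)
                res = cluster_correct(rmap, cfg.voxel_p, cfg.n_perm,
                                      cfg.seed + 223, ds)
                rows += _cluster_rows(f"duration_corr_{g}", res, ds)
            tmap = slope_interaction_map(ds)
            res = cluster_correct(tmap, cfg.voxel_p, cfg.n_perm, cfg.seed + 227, ds)
            rows += _cluster_rows("slope_interaction", res, ds)
            df = pd.DataFrame(rows, columns=["analysis", "cluster_size",
                                             "corrected_p", "peak_i", "peak_j",
                                             "peak_k"])
            _write_tsv(df, out / "vbm_clusters.tsv")

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "stages": stage_log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def _cluster_rows(analysis: str, res, ds) -> list[dict]:
    rows = []
    for c in res.clusters:
        i, j, k = ds.voxel_ijk[c["peak_column"]]
        rows.append({"analysis": analysis, "cluster_size": c["size"],
                     "corrected_p": c["corrected_p"],
                     "peak_i": int(i), "peak_j": int(j), "peak_k": int(k)})
    if not rows:
        rows.append({"analysis": analysis, "cluster_size": 0, "corrected_p": np.nan,
                     "peak_i": -1, "peak_j": -1, "peak_k": -1})
    return rows
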