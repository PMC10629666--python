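"""Configuration, orchestration and reporting for the four analysis levels.

``run_pipeline`` generates (or loads) a cohort, fits the first-level GLMs it
needs, and executes any subset of the voxel / ROI / cluster / network levels
in dependency order.  ``simulate_and_recover`` repeats the pipeline over
replicate cohorts and tabulates discovery and recovery statistics; it is the
engine behind the calibration and power checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import clusters as cl
from . import network as net
from . import regional as reg
from .glm import ExcessiveMotionError, change_map, fit_first_level
from .stats import pearson
from .synthetic import Cohort, CohortConfig, EFFieldParams, PlantSpec, generate_cohort
from .volume import Mask, write_volume

log = logging.getLogger(__name__)

LEVELS = ("voxel", "roi", "cluster", "network")


class ConfigError(ValueError):
    pass


@dataclass
class Thresholds:
    """Every decision threshold used across the four levels."""

    q: float = 0.05                  # BH FDR level (voxel, ROI, cluster tables)
    cluster_voxel_p: float = 0.005   # cluster-level forming threshold
    cluster_extent_k: int | None = None  # fixed extent (e.g. 41); None -> MC
    cluster_extent_alpha: float = 0.05
    gppi_voxel_p: float = 0.01
    gppi_cluster_q: float = 0.05
    seed_percentile: float = 99.0
    seed_radius_mm: float = 10.0
    censor_threshold: float = 0.3
    connectivity: int = 18
    mc_iterations: int = 1000

    def validate(self) -> None:
        for name in ("q", "cluster_voxel_p", "cluster_extent_alpha",
                     "gppi_voxel_p", "gppi_cluster_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if not 0 <= self.seed_percentile <= 100:
            raise ConfigError("seed_percentile must lie in [0, 100]")
        if self.seed_radius_mm <= 0 or self.censor_threshold <= 0:
            raise ConfigError("seed_radius_mm and censor_threshold must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
        if self.mc_iterations < 100:
            raise ConfigError("mc_iterations must be >= 100")
        if self.cluster_extent_k is not None and self.cluster_extent_k < 1:
            raise ConfigError("cluster_extent_k must be >= 1")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    levels: tuple = LEVELS
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        bad = [lv for lv in self.levels if lv not in LEVELS]
        if bad:
            raise ConfigError(f"unknown levels {bad}; valid: {LEVELS}")
        self.thresholds.validate()
        if self.cohort.n_active < 3 or self.cohort.n_sham < 1:
            raise ConfigError("need >= 3 active and >= 1 sham subjects")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            cohort = dict(cohort)
            ef = cohort.pop("ef", {})
            plant = cohort.pop("plant", {})
            hrf = cohort.pop("hrf", {})
            for tup in ("grid_shape", "amp_seed", "amp_parietal", "amp_amygdala",
                        "amp_background", "vas_means", "parietal_center_mm",
                        "amygdala_center_mm"):
                if tup in cohort and isinstance(cohort[tup], list):
                    cohort[tup] = tuple(cohort[tup])
            from .glm import HRFParams

            if isinstance(ef, dict):
                for tup in ("anode_center_mm", "cathode_center_mm"):
                    if tup in ef and isinstance(ef[tup], list):
                        ef[tup] = tuple(ef[tup])
                ef = EFFieldParams(**ef)
            if isinstance(plant, dict):
                plant = PlantSpec(**plant)
            if isinstance(hrf, dict):
                hrf = HRFParams(**hrf)
            cohort = CohortConfig(**cohort, ef=ef, plant=plant, hrf=hrf)
        thr = d.pop("thresholds", {})
        if isinstance(thr, dict):
            thr = Thresholds(**thr)
        levels = tuple(d.pop("levels", LEVELS))
        return cls(cohort=cohort, thresholds=thr, levels=levels, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def paper2023_thresholds() -> Thresholds:
    """Preset encoding the study's printed thresholds: FDR q = 0.05; cluster
    forming p < 0.005 with size > 40 (extent k = 41, no Monte-Carlo); gPPI
    voxel p < 0.01 with cluster-level FDR < 0.05; 99th-percentile seed with a
    10-mm sphere; motion censoring at 0.3."""
    return Thresholds(cluster_extent_k=41)


@dataclass
class RunReport:
    seed: int
    levels: dict = field(default_factory=dict)
    glm_excluded: list = field(default_factory=list)
    runtime_s: float = 0.0
    config: dict = field(default_factory=dict)

    def checksum(self) -> str:
        """Stable digest of every numeric result in the report."""

        def norm(obj):
            if isinstance(obj, pd.DataFrame):
                return obj.round(12).to_csv()
            if isinstance(obj, dict):
                return {k: norm(v) for k, v in sorted(obj.items(), key=lambda x: str(x[0]))}
            if isinstance(obj, (list, tuple)):
                return [norm(v) for v in obj]
            if isinstance(obj, (np.floating, float)):
                return round(float(obj), 12)
            if isinstance(obj, (np.integer, int, str, bool)) or obj is None:
                return obj
            if isinstance(obj, np.ndarray):
                return np.round(obj, 12).tolist()
            return str(obj)

        payload = json.dumps(norm({"levels": self.levels, "seed": self.seed}),
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _fit_glms(cohort: Cohort, arms: set, censor_threshold: float):
    """First-level GLM per subject-session; returns delta maps + exclusions."""
    pre, post, delta = {}, {}, {}
    excluded = []
    for s in cohort.subjects:
        if s.arm not in arms:
            continue
        try:
            bm_pre = fit_first_level(
                s.series_pre, cohort.design, s.motion_pre,
                censor_threshold=censor_threshold, session="pre", grid=cohort.grid,
            )
            bm_post = fit_first_level(
                s.series_post, cohort.design, s.motion_post,
                censor_threshold=censor_threshold, session="post", grid=cohort.grid,
            )
        except ExcessiveMotionError as err:
            log.warning("subject %s excluded: %s", s.id, err)
            excluded.append(s.id)
            continue
        pre[s.id] = bm_pre.contrast
        post[s.id] = bm_post.contrast
        delta[s.id] = change_map(bm_pre, bm_post)
    return pre, post, delta, excluded


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> RunReport:
    """Execute the requested levels on a (synthetic) cohort.

    Levels needing first-level GLM products trigger the GLM automatically.
    Deterministic given ``config.seed``.
    """
    config.validate()
    t0 = time.time()
    thr = config.thresholds
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if cohort is None:
        cohort = generate_cohort(config.cohort, config.seed)
    report = RunReport(seed=config.seed, config=config.to_dict())

    active_ids = [s.id for s in cohort.arm_subjects("active")]
    arm_of = {s.id: s.arm for s in cohort.subjects}
    ef_maps = {s.id: s.ef for s in cohort.subjects}

    needs_glm_active = any(lv in config.levels for lv in ("voxel", "roi", "cluster"))
    needs_glm_all = "cluster" in config.levels
    pre = post = delta = None
    if needs_glm_active or needs_glm_all:
        arms = {"active", "sham"} if needs_glm_all else {"active"}
        pre, post, delta, excluded = _fit_glms(cohort, arms, thr.censor_threshold)
        report.glm_excluded = excluded
    active_ok = [i for i in active_ids if delta and i in delta]

    if "voxel" in config.levels:
        mats = reg.build_matrices(
            ef_maps, {i: delta[i] for i in active_ok}, cohort.brain_mask, active_ok
        )
        dr = reg.voxelwise_correlation(mats, q=thr.q)
        report.levels["voxel"] = {
            "n_significant": dr.n_significant,
            "bins": dr.bins.as_dict(),
            "n_subjects": dr.n_subjects,
            "maps": dr,
        }

    if "roi" in config.levels:
        tab = reg.roi_association(
            ef_maps, {i: delta[i] for i in active_ok}, cohort.atlas,
            subjects=active_ok, mask=cohort.brain_mask, q=thr.q,
        )
        report.levels["roi"] = {
            "table": tab, "n_significant": int(tab["significant"].sum()),
        }

    if "cluster" in config.levels:
        both = [i for i in pre if i in post]
        tmap, resid, df = cl.lme_tmap(
            {i: pre[i] for i in both}, {i: post[i] for i in both},
            arm_of, cohort.brain_mask,
        )
        if thr.cluster_extent_k is not None:
            extent_k = thr.cluster_extent_k
        else:
            smooth = cl.estimate_smoothness(resid, cohort.brain_mask)
            table = cl.monte_carlo_extent(
                cohort.grid, cohort.brain_mask, smooth.fwhm_mm,
                voxel_p=thr.cluster_voxel_p, alpha=thr.cluster_extent_alpha,
                n_iter=thr.mc_iterations, connectivity=thr.connectivity, rng=rng,
            )
            extent_k = table.k[(thr.cluster_voxel_p, thr.cluster_extent_alpha)]
        cset = cl.extract_clusters(
            tmap, df, voxel_p=thr.cluster_voxel_p, extent_k=extent_k,
            connectivity=thr.connectivity, mask=cohort.brain_mask,
        )
        dr_tab = cl.cluster_dose_response(
            cset, ef_maps, {i: delta[i] for i in active_ok}, active_ok, q=thr.q
        )
        report.levels["cluster"] = {
            "n_clusters": len(cset), "extent_k": extent_k, "df": df,
            "table": dr_tab, "tmap": tmap,
            "n_significant": int(dr_tab["significant"].sum()) if len(dr_tab) else 0,
        }

    if "network" in config.levels:
        report.levels["network"] = _run_network_level(cohort, config, rng)

    report.runtime_s = time.time() - t0
    if config.out_dir:
        _write_report(report, cohort, config.out_dir)
    return report


def _run_network_level(cohort: Cohort, config: PipelineConfig, rng) -> dict:
    thr = config.thresholds
    arm_of = {s.id: s.arm for s in cohort.subjects}
    active_ef = {s.id: s.ef for s in cohort.arm_subjects("active")}
    seed_def = net.define_seed(
        active_ef, cohort.brain_mask,
        percentile=thr.seed_percentile, radius_mm=thr.seed_radius_mm,
    )
    # fold sham subjects' dose into the seed definition for per-arm correlation
    for s in cohort.arm_subjects("sham"):
        seed_def.mean_ef_per_subject[s.id] = float(
            s.ef.values[seed_def.mask.member].mean()
        )

    ppi_maps = {}
    for s in cohort.subjects:
        maps = {}
        for ses, series, motion in (
            ("pre", s.series_pre, s.motion_pre),
            ("post", s.series_post, s.motion_post),
        ):
            seed_ts = np.asarray(series)[seed_def.mask.member].mean(
                axis=0, dtype=np.float64
            )
            gppi = net.build_gppi_design(
                seed_ts, cohort.design, motion, cohort.config.hrf,
                censor_threshold=thr.censor_threshold,
            )
            maps[ses] = net.seed_to_voxel_gppi(series, gppi, cohort.grid)["contrast"]
        ppi_maps[s.id] = maps

    search_mask = Mask(cohort.grid,
                       cohort.brain_mask.member & ~seed_def.mask.member)
    cset = net.second_level_interaction(
        ppi_maps, arm_of, search_mask,
        voxel_p=thr.gppi_voxel_p, cluster_q=thr.gppi_cluster_q,
        connectivity=thr.connectivity, n_null=thr.mc_iterations, rng=rng,
    )

    rows = []
    dose_results = {}
    for ci, cluster in enumerate(cset.clusters):
        target = Mask(cohort.grid, cluster.mask.member & ~seed_def.mask.member)
        if target.n_voxels == 0:
            continue
        results = [
            net.roi_to_roi_gppi(
                {"pre": s.series_pre, "post": s.series_post},
                seed_def.mask, target, cohort.design,
                {"pre": s.motion_pre, "post": s.motion_post},
                cohort.config.hrf, subject=s.id,
                censor_threshold=thr.censor_threshold,
            )
            for s in cohort.subjects
        ]
        dose = net.dose_connectivity_correlation(seed_def, results, arm_of)
        dose_results[ci] = (results, dose)
        for arm, res in dose.per_arm.items():
            rows.append({"cluster": ci + 1, "size": cluster.size_voxels,
                         "arm": arm, "n": dose.n_per_arm[arm],
                         "r": res.r, "p": res.p})
    dose_tab = pd.DataFrame(rows, columns=["cluster", "size", "arm", "n", "r", "p"])
    if len(dose_tab):
        from .stats import fdr_bh

        for arm in dose_tab["arm"].unique():
            sel = dose_tab["arm"] == arm
            qv, rej = fdr_bh(dose_tab.loc[sel, "p"].to_numpy(), q=thr.q)
            dose_tab.loc[sel, "q"] = qv
            dose_tab.loc[sel, "significant"] = rej

    out = {
        "seed_center_mm": seed_def.center_mm.tolist(),
        "seed_n_voxels": seed_def.mask.n_voxels,
        "n_clusters": len(cset),
        "cluster_sizes": [c.size_voxels for c in cset.clusters],
        "dose_connectivity": dose_tab,
        "seed": seed_def,
        "clusters": cset,
    }
    if len(cset.clusters) and 0 in dose_results:
        vas_tab = pd.DataFrame(
            [{"subject": s.id, "arm": s.arm,
              **{f"T{t}": float(v) for t, v in enumerate(s.vas)}}
             for s in cohort.subjects]
        )
        out["behavior"] = net.behavior_association(
            vas_tab, dose_results[0][0], seed_def, arm_of
        )
    return out


def _write_report(report: RunReport, cohort: Cohort, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"seed": report.seed, "runtime_s": report.runtime_s,
               "checksum": report.checksum(), "glm_excluded": report.glm_excluded}
    for lv, res in report.levels.items():
        for key, val in res.items():
            if isinstance(val, pd.DataFrame):
                val.to_csv(out / f"{lv}_{key}.tsv", sep="\t", index=False)
        if lv == "voxel":
            dr = res["maps"]
            write_volume(dr.r_map, out / "voxel_r.nii.gz")
            write_volume(dr.p_map, out / "voxel_p.nii.gz")
            write_volume(dr.q_map, out / "voxel_q.nii.gz")
            summary["voxel"] = {"n_significant": res["n_significant"],
                                "bins": res["bins"]}
        elif lv == "cluster":
            write_volume(res["tmap"], out / "cluster_tmap.nii.gz")
            summary["cluster"] = {"n_clusters": res["n_clusters"],
                                  "extent_k": res["extent_k"]}
        elif lv == "roi":
            summary["roi"] = {"n_significant": res["n_significant"]}
        elif lv == "network":
            summary["network"] = {"n_clusters": res["n_clusters"],
                                  "seed_center_mm": res["seed_center_mm"]}
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def simulate_and_recover(
    config: PipelineConfig,
    n_replicates: int,
    seed: int,
    recovery_target: str = "parietal",
) -> pd.DataFrame:
    """Replicate cohorts -> per-replicate discovery and recovery statistics.

    Each replicate runs the configured levels on a fresh cohort.  For the
    network level two statistics are reported: the discovery path (largest
    surviving second-level cluster, if any) and a recovery path correlating
    dose with connectivity to the generator's planted target node — the
    latter uses only the node's geometry, never the planted response values.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    config.validate()
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for rep, child in enumerate(children):
        cohort = generate_cohort(config.cohort, child)
        rep_cfg = dataclasses.replace(config, seed=int(child.generate_state(1)[0] % (2**31)))
        report = run_pipeline(rep_cfg, cohort=cohort)
        row = {"replicate": rep}
        if "voxel" in report.levels:
            row["voxel_n_sig"] = report.levels["voxel"]["n_significant"]
            row.update({f"bin_{k}": v for k, v in
                        report.levels["voxel"]["bins"].items()})
        if "roi" in report.levels:
            row["roi_n_sig"] = report.levels["roi"]["n_significant"]
        if "cluster" in report.levels:
            row["cluster_n"] = report.levels["cluster"]["n_clusters"]
            row["cluster_n_sig"] = report.levels["cluster"]["n_significant"]
        if "network" in report.levels:
            nw = report.levels["network"]
            row["network_cluster_found"] = nw["n_clusters"] > 0
            tab = nw["dose_connectivity"]
            for arm in ("active", "sham"):
                sel = tab[(tab["arm"] == arm) & (tab["cluster"] == 1)]
                row[f"network_r_{arm}"] = float(sel["r"].iloc[0]) if len(sel) else np.nan
                row[f"network_p_{arm}"] = float(sel["p"].iloc[0]) if len(sel) else np.nan
            row.update(_recovery_stats(cohort, nw["seed"], recovery_target, config))
        rows.append(row)
    return pd.DataFrame(rows)


def _recovery_stats(cohort: Cohort, seed_def, target_node: str,
                    config: PipelineConfig) -> dict:
    """Dose vs. connectivity-to-planted-node correlation, per arm."""
    thr = config.thresholds
    target = Mask(cohort.grid,
                  cohort.node_masks[target_node].member & ~seed_def.mask.member)
    arm_of = {s.id: s.arm for s in cohort.subjects}
    results = [
        net.roi_to_roi_gppi(
            {"pre": s.series_pre, "post": s.series_post},
            seed_def.mask, target, cohort.design,
            {"pre": s.motion_pre, "post": s.motion_post},
            cohort.config.hrf, subject=s.id,
            censor_threshold=thr.censor_threshold,
        )
        for s in cohort.subjects
    ]
    dose = net.dose_connectivity_correlation(seed_def, results, arm_of)
    out = {}
    for arm, res in dose.per_arm.items():
        out[f"recovery_r_{arm}"] = res.r
        out[f"recovery_p_{arm}"] = res.p
    truth_ef = np.array([s.truth["mean_ef_seed_node"]
                         for s in cohort.arm_subjects("active")])
    truth_delta = np.array([s.truth["delta_coupling"]
                            for s in cohort.arm_subjects("active")])
    tr = pearson(truth_ef, truth_delta)
    out["truth_r_active"] = tr.r
    return out
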