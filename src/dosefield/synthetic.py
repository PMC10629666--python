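"""Synthetic two-arm tES-fMRI cohort with plantable dose-response structure.

Stands in for the study's non-public MRI data: per-subject electric-field
(EF) surrogate maps (two-lobe Gaussian field peaked at a right-frontal anode
site and a supraorbital cathode site), a randomized cue-reactivity block
design (4 meth + 4 neutral 31-s blocks), pre/post BOLD series with
condition-dependent seed-parietal coupling, motion tables with occasional
censorable spikes, and VAS craving scores at T0..T5.

The planted effect is configurable at voxel, ROI or network level.  For the
network plant, each active-arm subject's post-stimulation change in
meth-vs-neutral psychophysiological coupling is
``delta = gamma * meanEF(seed node) + eps``; ``gamma`` is calibrated from a
target population dose-response correlation ``rho`` so recovery is a
first-class test.  Ground truth is stored alongside the data and never read
by the analysis pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .glm import HRFParams, TaskDesign, build_condition_regressor
from .volume import (
    AtlasParcellation,
    BrainVolume,
    GridSpec,
    Mask,
    make_sphere_mask,
    write_mask,
    write_volume,
)

CATHODE_LOBE_WEIGHT = 0.8  # relative amplitude of the return-electrode lobe


class SyntheticError(ValueError):
    pass


def default_sim_grid(n: int = 16, voxel_mm: float = 4.0) -> GridSpec:
    """Small centered isotropic grid used for simulation studies."""
    return GridSpec.isotropic((n, n, n), voxel_mm)


@dataclass(frozen=True)
class EFFieldParams:
    """Two-lobe Gaussian EF surrogate field parameters (world mm, V/m)."""

    anode_center_mm: tuple = (14.0, 18.0, 12.0)     # right-frontal (F4-like)
    cathode_center_mm: tuple = (-10.0, 24.0, 2.0)   # left supraorbital (Fp1-like)
    sigma_mm: float = 12.0
    amp_mean: float = 0.25   # V/m; modelling choice, not an observed value
    amp_cv: float = 0.3
    jitter_mm: float = 2.0

    def __post_init__(self):
        if self.sigma_mm <= 0 or self.amp_mean <= 0 or self.amp_cv < 0:
            raise SyntheticError("sigma_mm/amp_mean must be > 0, amp_cv >= 0")


@dataclass
class PlantSpec:
    """Where and how strongly dose drives response in the generated cohort."""

    level: str = "network"           # none | voxel | roi | network
    gamma: float | None = None       # response units per V/m; None -> from rho
    rho: float | None = 0.6          # target population dose-response corr
    noise_sd: float = 0.4            # SD of the planted response residual
    target: object = None            # ROI label (roi) or voxel indices (voxel)
    arm_specific: bool = True

    def __post_init__(self):
        if self.level not in ("none", "voxel", "roi", "network"):
            raise SyntheticError(f"unknown plant level {self.level!r}")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")
        if self.level == "none":
            self.gamma = 0.0
            self.rho = None
        elif self.level in ("voxel", "roi") and self.target is None:
            raise SyntheticError(f"plant level={self.level} requires a target")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort (defaults: 30/30 arms)."""

    n_active: int = 30
    n_sham: int = 30
    grid_shape: tuple = (16, 16, 16)
    voxel_mm: float = 4.0
    brain_radius_mm: float = 28.0
    tr: float = 2.0
    ef: EFFieldParams = field(default_factory=EFFieldParams)
    plant: PlantSpec = field(default_factory=PlantSpec)
    n_parcels: int = 24
    # node geometry (world mm)
    seed_node_radius_mm: float = 8.0
    parietal_center_mm: tuple = (16.0, -16.0, 14.0)
    parietal_radius_mm: float = 8.0
    amygdala_center_mm: tuple = (10.0, -2.0, -14.0)
    amygdala_radius_mm: float = 7.0
    # activation amplitudes (meth, neutral) in BOLD units
    amp_seed: tuple = (1.0, 0.2)
    amp_parietal: tuple = (0.3, 0.1)
    amp_amygdala: tuple = (0.8, 0.1)
    amp_background: tuple = (0.2, 0.1)
    # coupling: physiological baseline and meth-vs-neutral PPI coupling
    coupling_phys: float = 0.6
    coupling_ppi_base: float = 0.3
    # noise
    noise_sd_bold: float = 0.8
    ar_coef: float = 0.3
    # motion
    motion_walk_sd: float = 0.02
    motion_spike_prob: float = 0.02
    motion_spike_size: float = 0.5
    # VAS craving: pooled timepoint means (T0..T5), no group effect
    vas_means: tuple = (55.0, 41.0, 62.0, 22.0, 26.0, 12.0)
    vas_subject_sd: float = 12.0
    vas_noise_sd: float = 6.0
    hrf: HRFParams = field(default_factory=HRFParams)

    def grid(self) -> GridSpec:
        return GridSpec.isotropic(self.grid_shape, self.voxel_mm)


@dataclass
class SubjectRecord:
    id: str
    arm: str
    ef: BrainVolume
    series_pre: np.ndarray
    series_post: np.ndarray
    motion_pre: pd.DataFrame
    motion_post: pd.DataFrame
    vas: np.ndarray
    truth: dict = field(default_factory=dict)


@dataclass
class Cohort:
    subjects: list
    grid: GridSpec
    atlas: AtlasParcellation
    design: TaskDesign
    plant: PlantSpec
    brain_mask: Mask
    node_masks: dict
    config: CohortConfig = None
    rng_seed: int = 0

    def arm_subjects(self, arm: str) -> list:
        return [s for s in self.subjects if s.arm == arm]


# ---------------------------------------------------------------------------
# EF maps


def _lobe_field(points: np.ndarray, center: np.ndarray, sigma: float) -> np.ndarray:
    d2 = ((points - center) ** 2).sum(axis=-1)
    return np.exp(-d2 / (2.0 * sigma**2))


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    s2 = np.log1p(cv**2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def generate_ef_map(params: EFFieldParams, grid: GridSpec, rng: np.random.Generator) -> BrainVolume:
    """Per-subject EF magnitude surrogate: jittered two-lobe Gaussian field."""
    lo, hi = grid.world_bbox()
    for c in (params.anode_center_mm, params.cathode_center_mm):
        c = np.asarray(c, dtype=float)
        if (c < lo).any() or (c > hi).any():
            raise SyntheticError(f"electrode center {tuple(c)} outside grid bbox")
    mu, sig = _lognormal_params(params.amp_mean, max(params.amp_cv, 0.0))
    amp = float(np.exp(mu + sig * rng.standard_normal())) if params.amp_cv > 0 else params.amp_mean
    pa = np.asarray(params.anode_center_mm) + params.jitter_mm * rng.standard_normal(3)
    pc = np.asarray(params.cathode_center_mm) + params.jitter_mm * rng.standard_normal(3)
    pts = grid.voxel_centers()
    vals = amp * (
        _lobe_field(pts, pa, params.sigma_mm)
        + CATHODE_LOBE_WEIGHT * _lobe_field(pts, pc, params.sigma_mm)
    )
    return BrainVolume(grid, vals, "EF_Vm")


def mean_ef_moments(
    params: EFFieldParams,
    node_points: np.ndarray,
    n_mc: int = 500,
    seed: int = 20231026,
) -> tuple[float, float]:
    """(mean, sd) of the node-averaged EF over the subject population.

    The amplitude is lognormal with known moments; the geometric factor
    (jittered lobes averaged over the node voxels) is integrated by a short
    deterministic Monte-Carlo over jitter draws.
    """
    rng = np.random.default_rng(seed)
    g = np.empty(n_mc)
    pa0 = np.asarray(params.anode_center_mm, dtype=float)
    pc0 = np.asarray(params.cathode_center_mm, dtype=float)
    for i in range(n_mc):
        pa = pa0 + params.jitter_mm * rng.standard_normal(3)
        pc = pc0 + params.jitter_mm * rng.standard_normal(3)
        g[i] = (
            _lobe_field(node_points, pa, params.sigma_mm)
            + CATHODE_LOBE_WEIGHT * _lobe_field(node_points, pc, params.sigma_mm)
        ).mean()
    ea = params.amp_mean
    ea2 = params.amp_mean**2 * (1.0 + params.amp_cv**2)
    eg, eg2 = g.mean(), (g**2).mean()
    mean = ea * eg
    var = ea2 * eg2 - mean**2
    return float(mean), float(np.sqrt(max(var, 0.0)))


def calibrate_gamma(plant: PlantSpec, ef_params: EFFieldParams, node_points: np.ndarray) -> float:
    """Dose->response slope giving population corr(meanEF, delta) = plant.rho.

    With delta = gamma*meanEF + eps, rho = gamma*sd(meanEF) /
    sqrt(gamma^2 sd^2 + noise_sd^2), hence
    gamma = rho/sqrt(1-rho^2) * noise_sd / sd(meanEF).
    """
    if plant.rho is None:
        raise SyntheticError("plant.rho required to calibrate gamma")
    if not 0 < plant.rho < 1:
        raise SyntheticError("plant.rho must lie in (0, 1)")
    if plant.noise_sd == 0:
        raise SyntheticError("rho calibration needs noise_sd > 0; set gamma directly")
    _, sd_ef = mean_ef_moments(ef_params, node_points)
    return float(plant.rho / np.sqrt(1 - plant.rho**2) * plant.noise_sd / sd_ef)


# ---------------------------------------------------------------------------
# Task design


def generate_task_design(
    tr: float,
    rng: np.random.Generator,
    n_blocks_per_condition: int = 4,
    block_duration: float = 31.0,
    lead_in: float = 10.0,
    response_period: float = 6.0,
    fixation_range: tuple = (8.0, 12.0),
    tail: float = 12.0,
) -> TaskDesign:
    """Randomized-order block design: 4 meth + 4 neutral 31-s blocks.

    Each block is followed by an unmodelled 6-s response period; fixation of
    8-12 s separates blocks.  Total run length is about 6.5 minutes.
    """
    if tr <= 0:
        raise SyntheticError("tr must be positive")
    conds = ["meth"] * n_blocks_per_condition + ["neutral"] * n_blocks_per_condition
    order = rng.permutation(len(conds))
    blocks = []
    t = lead_in
    for i, k in enumerate(order):
        blocks.append((round(t, 3), block_duration, conds[k]))
        t += block_duration + response_period
        if i < len(conds) - 1:
            t += rng.uniform(*fixation_range)
    t += tail
    n_volumes = int(np.ceil(t / tr))
    return TaskDesign(tr, n_volumes, tuple(blocks))


# ---------------------------------------------------------------------------
# BOLD series

def _ar1_noise(rng, n_series: int, n_t: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.zeros((n_series, n_t), dtype=np.float32)
    e = rng.standard_normal((n_series, n_t), dtype=np.float32)
    e *= sd * np.sqrt(1.0 - phi**2)
    e[:, 0] /= np.sqrt(1.0 - phi**2)  # stationary start
    return lfilter(
        np.array([1.0], dtype=np.float32),
        np.array([1.0, -phi], dtype=np.float32),
        e, axis=1,
    )


def generate_motion_table(rng: np.random.Generator, n_volumes: int, cfg: CohortConfig) -> pd.DataFrame:
    """Small random-walk motion with occasional censorable spikes."""
    inc = rng.standard_normal((n_volumes, 6)) * cfg.motion_walk_sd
    inc[0] = 0.0
    spikes = rng.random(n_volumes) < cfg.motion_spike_prob
    spikes[0] = False
    for t in np.flatnonzero(spikes):
        inc[t, rng.integers(6)] += cfg.motion_spike_size * (1 if rng.random() < 0.5 else -1)
    walk = np.cumsum(inc, axis=0)
    return pd.DataFrame(
        walk, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    )


def generate_subject_series(
    design: TaskDesign,
    ef: BrainVolume,
    node_masks: dict,
    plant: PlantSpec,
    session: str,
    arm: str,
    rng: np.random.Generator,
    cfg: CohortConfig,
    brain_mask: Mask | None = None,
):
    """One session's 4-D BOLD + motion table (+ the planted truth value).

    Neural model: every node's voxels share an HRF-convolved task signal;
    the parietal node additionally couples to the seed node with a
    meth-vs-neutral coupling ``c_ppi`` built exactly as a gPPI interaction
    (centred seed signal x centred meth regressor).  For the post session of
    an active-arm subject under a network plant, ``c_ppi`` gains
    ``gamma * meanEF(seed node) + eps``.  All in-brain voxels get i.i.d.
    AR(1) noise on top.  Returns ``(series float32, motion, truth_delta)``.
    """
    if session not in ("pre", "post"):
        raise SyntheticError("session must be 'pre' or 'post'")
    for a in ("seed", "parietal", "amygdala"):
        if a not in node_masks:
            raise SyntheticError(f"missing node mask {a!r}")
    grid = ef.grid
    members = [node_masks[k].member for k in ("seed", "parietal", "amygdala")]
    if (members[0] & members[1]).any() or (members[0] & members[2]).any() or (
        members[1] & members[2]
    ).any():
        raise SyntheticError("node masks must be disjoint")
    if plant.level in ("voxel", "roi") and "target" not in node_masks:
        raise SyntheticError(f"plant level={plant.level} requires node_masks['target']")
    if plant.level != "none" and plant.gamma is None:
        raise SyntheticError("plant.gamma unresolved; call generate_cohort or set gamma")

    motion = generate_motion_table(rng, design.n_volumes, cfg)
    r_m = build_condition_regressor(design, "meth", cfg.hrf)
    r_n = build_condition_regressor(design, "neutral", cfg.hrf)
    seed_clean = cfg.amp_seed[0] * r_m + cfg.amp_seed[1] * r_n
    # gPPI-style interaction, orthogonalized against the evoked regressors
    # over the motion-censored frames (the frames a censoring GLM fits), so a
    # coupling plant changes connectivity without changing evoked amplitude
    from .glm import DEFAULT_CENSOR_THRESHOLD, censor_trs, legendre_drift

    keep = censor_trs(motion, DEFAULT_CENSOR_THRESHOLD)
    inter = (seed_clean - seed_clean.mean()) * (r_m - r_m.mean())
    evoked = np.column_stack(
        [legendre_drift(design.n_volumes, 2), np.asarray(motion, dtype=float),
         r_m, r_n]
    )
    coef, *_ = np.linalg.lstsq(evoked[keep], inter[keep], rcond=None)
    inter = inter - evoked @ coef

    plants_here = plant.level != "none" and session == "post" and (
        arm == "active" or not plant.arm_specific
    )
    truth_delta = 0.0
    if plants_here:
        dose_mask = node_masks["seed"] if plant.level == "network" else node_masks["target"]
        mean_ef = float(ef.values[dose_mask.member].mean())
        eps = rng.normal(0.0, plant.noise_sd) if plant.noise_sd > 0 else 0.0
        truth_delta = plant.gamma * mean_ef + eps
    elif plant.level != "none" and session == "post":
        rng.normal()  # keep active/sham streams aligned

    c_ppi = cfg.coupling_ppi_base + (truth_delta if plant.level == "network" else 0.0)
    parietal_clean = (
        cfg.amp_parietal[0] * r_m
        + cfg.amp_parietal[1] * r_n
        + cfg.coupling_phys * seed_clean
        + c_ppi * inter
    )
    amygdala_clean = cfg.amp_amygdala[0] * r_m + cfg.amp_amygdala[1] * r_n
    background_clean = cfg.amp_background[0] * r_m + cfg.amp_background[1] * r_n

    if brain_mask is None:
        brain_mask = Mask(grid, np.ones(grid.dims, dtype=bool))
    n_t = design.n_volumes
    series = np.zeros(grid.dims + (n_t,), dtype=np.float32)
    clean = np.tile(background_clean, (brain_mask.n_voxels, 1))
    flat_members = {k: m.member[brain_mask.member] for k, m in node_masks.items()}
    clean[flat_members["seed"]] = seed_clean
    clean[flat_members["parietal"]] = parietal_clean
    clean[flat_members["amygdala"]] = amygdala_clean
    if plant.level in ("voxel", "roi") and plants_here:
        clean[flat_members["target"]] += truth_delta * r_m
    noise = _ar1_noise(rng, brain_mask.n_voxels, n_t, cfg.noise_sd_bold, cfg.ar_coef)
    series[brain_mask.member] = (clean + noise).astype(np.float32)
    return series, motion, truth_delta


# ---------------------------------------------------------------------------
# Atlas


def generate_atlas(
    grid: GridSpec, n_parcels: int, rng: np.random.Generator, mask: Mask
) -> AtlasParcellation:
    """Voronoi parcellation of the brain mask around random in-mask sites.

    Every in-mask voxel gets the label of its nearest site by world
    distance; parcels are not guaranteed to be connected.
    """
    if n_parcels < 1:
        raise SyntheticError("n_parcels must be >= 1")
    if n_parcels > mask.n_voxels:
        raise SyntheticError("n_parcels exceeds in-mask voxel count")
    centers = grid.voxel_centers()
    in_pts = centers[mask.member]
    sites = in_pts[rng.choice(in_pts.shape[0], size=n_parcels, replace=False)]
    d2 = ((in_pts[:, None, :] - sites[None, :, :]) ** 2).sum(axis=-1)
    lab = np.zeros(grid.dims)
    lab[mask.member] = d2.argmin(axis=1) + 1
    table = {i + 1: f"parcel_{i + 1:03d}" for i in range(n_parcels)}
    return AtlasParcellation(BrainVolume(grid, lab, "label"), table)


# ---------------------------------------------------------------------------
# Cohort


def generate_vas(rng: np.random.Generator, cfg: CohortConfig) -> np.ndarray:
    base = rng.normal(0.0, cfg.vas_subject_sd)
    vals = np.asarray(cfg.vas_means) + base + rng.normal(0, cfg.vas_noise_sd, 6)
    return np.clip(vals, 0.0, 100.0)


def build_node_masks(grid: GridSpec, cfg: CohortConfig, brain_mask: Mask) -> dict:
    seed = make_sphere_mask(grid, cfg.ef.anode_center_mm, cfg.seed_node_radius_mm)
    parietal = make_sphere_mask(grid, cfg.parietal_center_mm, cfg.parietal_radius_mm)
    amygdala = make_sphere_mask(grid, cfg.amygdala_center_mm, cfg.amygdala_radius_mm)
    return {
        "seed": seed & brain_mask,
        "parietal": parietal & brain_mask,
        "amygdala": amygdala & brain_mask,
    }


def resolve_plant(plant: PlantSpec, cfg: CohortConfig, grid: GridSpec, node_masks: dict) -> PlantSpec:
    """Return a copy of the plant with gamma resolved from rho if needed."""
    plant = dataclasses.replace(plant)
    if plant.level != "none" and plant.gamma is None:
        dose_mask = node_masks["seed"] if plant.level == "network" else node_masks["target"]
        pts = grid.voxel_centers()[dose_mask.member]
        plant.gamma = calibrate_gamma(plant, cfg.ef, pts)
    return plant


def generate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Fully reproducible synthetic cohort (per-subject spawned streams)."""
    grid = config.grid()
    master = np.random.default_rng(seed)
    n = config.n_active + config.n_sham
    streams = master.spawn(n + 2)
    atlas_rng, design_rng = streams[n], streams[n + 1]

    brain_mask = make_sphere_mask(grid, (0.0, 0.0, 0.0), config.brain_radius_mm)
    atlas = generate_atlas(grid, config.n_parcels, atlas_rng, brain_mask)
    design = generate_task_design(config.tr, design_rng)
    node_masks = build_node_masks(grid, config, brain_mask)
    if config.plant.level == "roi":
        node_masks["target"] = atlas.region_mask(int(config.plant.target)) & brain_mask
    elif config.plant.level == "voxel":
        member = np.zeros(grid.dims, dtype=bool)
        member.ravel()[np.asarray(config.plant.target, dtype=int)] = True
        node_masks["target"] = Mask(grid, member) & brain_mask
    if "target" in node_masks:
        for k in ("seed", "parietal", "amygdala"):
            node_masks[k] = Mask(grid, node_masks[k].member & ~node_masks["target"].member)
    plant = resolve_plant(config.plant, config, grid, node_masks)

    subjects = []
    arms = ["active"] * config.n_active + ["sham"] * config.n_sham
    for i, (arm, rng) in enumerate(zip(arms, streams[:n])):
        ef = generate_ef_map(config.ef, grid, rng)
        s_pre, m_pre, _ = generate_subject_series(
            design, ef, node_masks, plant, "pre", arm, rng, config, brain_mask
        )
        s_post, m_post, delta = generate_subject_series(
            design, ef, node_masks, plant, "post", arm, rng, config, brain_mask
        )
        vas = generate_vas(rng, config)
        dose_mask = node_masks.get("target") if plant.level in ("voxel", "roi") else node_masks["seed"]
        truth = {
            "delta_coupling": float(delta),
            "mean_ef_seed_node": float(ef.values[node_masks["seed"].member].mean()),
            "mean_ef_dose_mask": float(ef.values[dose_mask.member].mean()) if dose_mask else np.nan,
            "gamma": float(plant.gamma or 0.0),
        }
        subjects.append(
            SubjectRecord(
                id=f"sub-{i + 1:03d}", arm=arm, ef=ef,
                series_pre=s_pre, series_post=s_post,
                motion_pre=m_pre, motion_post=m_post, vas=vas, truth=truth,
            )
        )
    return Cohort(subjects, grid, atlas, design, plant, brain_mask, node_masks,
                  config, seed)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write per-subject NIfTI/TSV fixtures plus a YAML truth sidecar."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(cohort.brain_mask, out / "brain_mask.nii.gz")
    write_volume(cohort.atlas.labels, out / "atlas.nii.gz")
    cohort.atlas.to_tsv(out / "atlas.tsv")
    cohort.design.to_tsv(out / "events.tsv")
    truth = {}
    vas_rows = []
    for s in cohort.subjects:
        sd = out / s.id
        sd.mkdir(exist_ok=True)
        write_volume(s.ef, sd / "ef.nii.gz")
        for ses, series, motion in (
            ("pre", s.series_pre, s.motion_pre),
            ("post", s.series_post, s.motion_post),
        ):
            write_volume(BrainVolume(cohort.grid, series, "bold"), sd / f"bold_{ses}.nii.gz")
            motion.to_csv(sd / f"motion_{ses}.tsv", sep="\t", index=False)
        truth[s.id] = {"arm": s.arm, **{k: float(v) for k, v in s.truth.items()}}
        vas_rows.append({"subject": s.id, "arm": s.arm,
                         **{f"T{t}": float(v) for t, v in enumerate(s.vas)}})
    pd.DataFrame(vas_rows).to_csv(out / "vas.tsv", sep="\t", index=False)
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump({"seed": cohort.rng_seed, "subjects": truth}, fh)
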