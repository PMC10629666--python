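"""Level 4: EF-defined seed, generalized PPI, second-level interaction with
Monte-Carlo cluster-level FDR, dose-connectivity and behavioral correlation.

The seed is a 10-mm sphere placed at the centre of mass of voxels above the
99th percentile of the group-mean EF map.  The gPPI design regresses a
target series on drift terms, the HRF-convolved psychological regressors,
the physiological seed series, and one interaction column per condition
(centred seed BOLD x mean-centred condition regressor); the meth - neutral
interaction contrast quantifies context-dependent connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import ClusterSet, extract_clusters, lme_tmap, estimate_smoothness, monte_carlo_extent
from .glm import (
    DEFAULT_CENSOR_THRESHOLD,
    GlmError,
    HRFParams,
    TaskDesign,
    build_condition_regressor,
    censor_trs,
    legendre_drift,
)
from .stats import CorrResult, fdr_bh, pearson
from .volume import BrainVolume, Mask, make_sphere_mask


class NetworkError(ValueError):
    pass


@dataclass
class SeedDefinition:
    """EF-derived seed sphere plus per-subject mean dose inside it."""

    center_mm: np.ndarray
    radius_mm: float
    percentile: float
    mask: Mask
    mean_ef_per_subject: dict  # subject id -> mean EF (V/m) in the sphere


def define_seed(
    ef_maps: dict,
    brain_mask: Mask,
    percentile: float = 99.0,
    radius_mm: float = 10.0,
    center: str = "com",
) -> SeedDefinition:
    """Seed sphere from the group-mean EF map.

    The mean EF over subjects is thresholded at the given percentile of
    in-mask values; the sphere is centred on the centre of mass of the
    suprathreshold voxels (``center='peak'`` uses the peak voxel instead).
    """
    if not ef_maps:
        raise NetworkError("need at least one EF map")
    subjects = sorted(ef_maps)
    grid = ef_maps[subjects[0]].grid
    mean_ef = np.mean([ef_maps[s].values for s in subjects], axis=0)
    vals = mean_ef[brain_mask.member]
    thr = np.percentile(vals, percentile)
    supra = (mean_ef >= thr) & brain_mask.member
    if not supra.any():
        raise NetworkError("no suprathreshold voxels at this percentile")
    centers = grid.voxel_centers()
    if center == "peak":
        masked = np.where(brain_mask.member, mean_ef, -np.inf)
        c = centers[np.unravel_index(np.argmax(masked), grid.dims)]
    else:
        c = centers[supra].mean(axis=0)
    sphere = make_sphere_mask(grid, c, radius_mm) & brain_mask
    mean_per_subject = {
        s: float(ef_maps[s].values[sphere.member].mean()) for s in subjects
    }
    return SeedDefinition(np.asarray(c, dtype=float), radius_mm, percentile,
                          sphere, mean_per_subject)


@dataclass
class GPPIDesign:
    X: np.ndarray
    names: list
    keep: np.ndarray
    interaction_index: dict
    psych_index: dict = field(default_factory=dict)


def build_gppi_design(
    seed_series: np.ndarray,
    design: TaskDesign,
    motion=None,
    hrf_params: HRFParams = HRFParams(),
    poly_order: int = 2,
    censor_threshold: float = DEFAULT_CENSOR_THRESHOLD,
    conditions=("meth", "neutral"),
) -> GPPIDesign:
    """gPPI design: drift + psychological + physiological + interactions.

    Interaction column for condition c = (centred seed series) x
    (mean-centred HRF-convolved regressor of c); centring happens before the
    censor rows are dropped.  ``motion``, when given, supplies both the
    censor vector and nuisance columns (zero-variance columns dropped).
    """
    seed_series = np.asarray(seed_series, dtype=float)
    if seed_series.shape != (design.n_volumes,):
        raise NetworkError("seed series length must equal design.n_volumes")
    if seed_series.std() == 0:
        raise NetworkError("zero-variance seed series")
    cols = [legendre_drift(design.n_volumes, poly_order)]
    names = [f"poly{k}" for k in range(poly_order + 1)]
    if motion is not None:
        marr = np.asarray(motion, dtype=float)
        for j in range(marr.shape[1]):
            if marr[:, j].std() > 1e-12:
                cols.append(marr[:, j:j + 1])
                names.append(f"motion{j}")
    psych_index = {}
    inter_index = {}
    phys = seed_series - seed_series.mean()
    regs = {}
    for cond in conditions:
        if cond not in design.conditions:
            raise GlmError(f"condition {cond!r} not present in design")
        regs[cond] = build_condition_regressor(design, cond, hrf_params)
        psych_index[cond] = len(names)
        names.append(f"psych_{cond}")
        cols.append(regs[cond][:, None])
    names.append("phys")
    cols.append(phys[:, None])
    for cond in conditions:
        inter_index[cond] = len(names)
        names.append(f"ppi_{cond}")
        col = phys * (regs[cond] - regs[cond].mean())
        cols.append((col - col.mean())[:, None])  # absorbed by the intercept
    X = np.column_stack(cols)
    if motion is not None:
        keep = censor_trs(motion, censor_threshold)
    else:
        keep = np.ones(design.n_volumes, dtype=bool)
    return GPPIDesign(X, names, keep, inter_index, psych_index)


def _ols_betas(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NetworkError("rank-deficient gPPI design")
    return np.linalg.pinv(X) @ Y


def seed_to_voxel_gppi(series: np.ndarray, gppi: GPPIDesign, grid) -> dict:
    """Voxelwise OLS of the gPPI design; returns PPI beta and contrast maps."""
    n_t = gppi.X.shape[0]
    Y = np.asarray(series).reshape(-1, n_t).T[gppi.keep]
    beta = _ols_betas(gppi.X[gppi.keep], Y)
    out = {}
    for cond, j in gppi.interaction_index.items():
        out[f"ppi_{cond}"] = BrainVolume(grid, beta[j].reshape(grid.dims), "beta")
    conds = list(gppi.interaction_index)
    contrast = (
        beta[gppi.interaction_index[conds[0]]] - beta[gppi.interaction_index[conds[1]]]
    )
    out["contrast"] = BrainVolume(grid, contrast.reshape(grid.dims), "beta")
    return out


@dataclass
class ConnectivityResult:
    subject: str
    beta_ppi_meth: dict      # session -> beta
    beta_ppi_neutral: dict
    contrast: dict           # session -> meth - neutral interaction beta
    delta: float = np.nan    # post - pre contrast

    @property
    def pre(self):
        return self.contrast.get("pre", np.nan)

    @property
    def post(self):
        return self.contrast.get("post", np.nan)


def roi_to_roi_gppi(
    series_by_session: dict,
    seed_mask: Mask,
    target_mask: Mask,
    design: TaskDesign,
    motion_by_session: dict | None = None,
    hrf_params: HRFParams = HRFParams(),
    subject: str = "",
    censor_threshold: float = DEFAULT_CENSOR_THRESHOLD,
) -> ConnectivityResult:
    """Seed-to-target gPPI per session; delta = post - pre contrast.

    The seed series is the mean BOLD over the seed mask, the target series
    the mean over the target mask; masks must be disjoint.
    """
    if (seed_mask.member & target_mask.member).any():
        raise NetworkError("seed and target masks overlap")
    betas_m, betas_n, contrast = {}, {}, {}
    for ses, series in series_by_session.items():
        series = np.asarray(series)
        seed_ts = series[seed_mask.member].mean(axis=0, dtype=np.float64)
        target_ts = series[target_mask.member].mean(axis=0, dtype=np.float64)
        motion = motion_by_session.get(ses) if motion_by_session else None
        gppi = build_gppi_design(seed_ts, design, motion, hrf_params,
                                 censor_threshold=censor_threshold)
        beta = _ols_betas(gppi.X[gppi.keep], target_ts[gppi.keep, None])[:, 0]
        bm = float(beta[gppi.interaction_index["meth"]])
        bn = float(beta[gppi.interaction_index["neutral"]])
        betas_m[ses], betas_n[ses] = bm, bn
        contrast[ses] = bm - bn
    delta = (
        contrast["post"] - contrast["pre"]
        if "pre" in contrast and "post" in contrast
        else np.nan
    )
    return ConnectivityResult(subject, betas_m, betas_n, contrast, delta)


def second_level_interaction(
    ppi_maps: dict,
    arms: dict,
    mask: Mask,
    voxel_p: float = 0.01,
    cluster_q: float = 0.05,
    connectivity: int = 18,
    n_null: int = 1000,
    rng: np.random.Generator | None = None,
) -> ClusterSet:
    """Time x group interaction on per-subject PPI contrast maps.

    ``ppi_maps`` maps subject id -> {'pre': BrainVolume, 'post': BrainVolume}.
    Suprathreshold clusters at ``voxel_p`` receive an empirical cluster-level
    p = P(max null cluster size >= observed size) from smooth-null-field
    simulation at the residual smoothness, then BH across clusters at
    ``cluster_q``.  Surviving clusters only are returned in ``clusters``.
    """
    rng = rng or np.random.default_rng()
    pre = {s: m["pre"] for s, m in ppi_maps.items()}
    post = {s: m["post"] for s, m in ppi_maps.items()}
    tmap, resid, df = lme_tmap(pre, post, arms, mask)
    candidates = extract_clusters(
        tmap, df, voxel_p=voxel_p, extent_k=1, connectivity=connectivity, mask=mask
    )
    if not candidates.clusters:
        return candidates
    smooth = estimate_smoothness(resid, mask)
    table = monte_carlo_extent(
        tmap.grid, mask, smooth.fwhm_mm, voxel_p=voxel_p, alpha=cluster_q,
        n_iter=n_null, connectivity=connectivity, rng=rng,
    )
    pvals = np.array(
        [table.cluster_p(voxel_p, c.size_voxels) for c in candidates.clusters]
    )
    qvals, reject = fdr_bh(pvals, q=cluster_q)
    kept = [c for c, rej in zip(candidates.clusters, reject) if rej]
    return ClusterSet(
        kept, voxel_p, candidates.extent_k, connectivity, df,
        cluster_p=list(pvals[reject]), cluster_q=list(qvals[reject]),
    )


@dataclass
class DoseConnectivityResult:
    per_arm: dict  # arm -> CorrResult
    n_per_arm: dict


def dose_connectivity_correlation(
    seed: SeedDefinition, results: list, arms: dict
) -> DoseConnectivityResult:
    """Per-arm Pearson correlation of mean seed EF vs. delta connectivity."""
    per_arm, n_per_arm = {}, {}
    for arm in sorted(set(arms.values())):
        subs = [r for r in results if arms[r.subject] == arm]
        if len(subs) < 3:
            raise NetworkError(f"arm {arm!r} has fewer than 3 subjects")
        ef = np.array([seed.mean_ef_per_subject[r.subject] for r in subs])
        delta = np.array([r.delta for r in subs])
        per_arm[arm] = pearson(ef, delta)
        n_per_arm[arm] = len(subs)
    return DoseConnectivityResult(per_arm, n_per_arm)


def behavior_association(
    vas_table: pd.DataFrame,
    results: list,
    seed: SeedDefinition,
    arms: dict,
    timepoint_pair: tuple = ("T3", "T4"),
) -> pd.DataFrame:
    """Correlate craving change (default T3->T4) with network quantities.

    Per arm, Pearson r between delta-VAS and each of: delta connectivity,
    pre-stimulation (baseline) connectivity, and mean seed EF.  Undefined
    correlations (e.g. constant VAS change) are flagged.
    """
    t0, t1 = timepoint_pair
    for col in (t0, t1):
        if col not in vas_table.columns:
            raise NetworkError(f"missing VAS timepoint {col}")
    vas = vas_table.set_index("subject")
    rows = []
    for arm in sorted(set(arms.values())):
        subs = [r for r in results if arms[r.subject] == arm]
        dvas = np.array([vas.loc[r.subject, t1] - vas.loc[r.subject, t0] for r in subs])
        measures = {
            "delta_connectivity": np.array([r.delta for r in subs]),
            "pre_connectivity": np.array([r.pre for r in subs]),
            "mean_seed_ef": np.array(
                [seed.mean_ef_per_subject[r.subject] for r in subs]
            ),
        }
        for name, vec in measures.items():
            res = pearson(vec, dvas)
            rows.append(
                {"arm": arm, "measure": name, "n": res.n, "r": res.r,
                 "p": res.p, "defined": res.defined}
            )
    return pd.DataFrame(rows)
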