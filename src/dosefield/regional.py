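"""Levels 1-2: voxelwise and atlas-ROI dose-response correlation with FDR.

Dose is the per-subject EF magnitude map (resampled to the functional grid),
response the per-subject post-pre change in the meth > neutral contrast.
Association is computed across active-arm subjects, voxel by voxel (one BH
family over defined in-mask voxels) or region by region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import EffectBins, classify_effect_sizes, fdr_bh, pearson_rows
from .volume import AtlasParcellation, BrainVolume, GridSpec, Mask, resample_to_grid


class RegionalError(ValueError):
    pass


@dataclass
class DoseResponseMatrices:
    """Vectorized in-mask EF and delta-BOLD maps, voxels x subjects."""

    ef: np.ndarray
    dbold: np.ndarray
    voxel_index: np.ndarray  # flat C-order grid index per row
    subjects: list
    grid: GridSpec
    mask: Mask


@dataclass
class DoseResponseMap:
    r_map: BrainVolume
    p_map: BrainVolume
    q_map: BrainVolume
    n_subjects: int
    bins: EffectBins
    n_significant: int


def build_matrices(
    ef_maps: dict,
    delta_maps: dict,
    mask: Mask,
    subjects: list | None = None,
) -> DoseResponseMatrices:
    """Stack per-subject EF and delta-beta maps into voxels x subjects matrices.

    ``ef_maps``/``delta_maps`` map subject id -> BrainVolume.  EF maps not on
    the functional grid are resampled (linear) first.  Row order is ascending
    flat voxel index over the mask.
    """
    if subjects is None:
        subjects = sorted(delta_maps)
    missing = [s for s in subjects if s not in ef_maps or s not in delta_maps]
    if missing:
        raise RegionalError(f"subjects missing a map: {missing}")
    grid = delta_maps[subjects[0]].grid
    idx = mask.indices()
    ef = np.empty((idx.size, len(subjects)))
    db = np.empty((idx.size, len(subjects)))
    for j, s in enumerate(subjects):
        dmap = delta_maps[s]
        if not dmap.grid.same_grid(grid):
            raise RegionalError("delta maps must share the functional grid")
        emap = ef_maps[s]
        if not emap.grid.same_grid(grid):
            emap = resample_to_grid(emap, grid, method="linear")
        ef[:, j] = emap.values.ravel(order="C")[idx]
        db[:, j] = dmap.values.ravel(order="C")[idx]
    return DoseResponseMatrices(ef, db, idx, list(subjects), grid, mask)


def voxelwise_correlation(m: DoseResponseMatrices, q: float = 0.05) -> DoseResponseMap:
    """Per-voxel Pearson correlation between dose and response columns.

    p-values form a single BH family across defined voxels; an effect-size
    bin summary of the r-map is attached.
    """
    if len(m.subjects) < 3:
        raise RegionalError("need at least 3 subjects")
    r, p, defined = pearson_rows(m.ef, m.dbold)
    qv, rej = fdr_bh(np.where(defined, p, np.nan), q=q)

    def to_map(vec, payload):
        out = np.full(m.grid.n_voxels, np.nan)
        out[m.voxel_index] = vec
        return BrainVolume(m.grid, out.reshape(m.grid.dims), payload)

    bins = classify_effect_sizes(r[defined])
    return DoseResponseMap(
        r_map=to_map(r, "r"),
        p_map=to_map(p, "p"),
        q_map=to_map(qv, "q"),
        n_subjects=len(m.subjects),
        bins=bins,
        n_significant=int(rej.sum()),
    )


def roi_association(
    ef_maps: dict,
    delta_maps: dict,
    atlas: AtlasParcellation,
    subjects: list | None = None,
    mask: Mask | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-region mean dose vs. mean response correlation across subjects.

    Returns one row per region with >= 1 in-mask voxel: region id, name,
    voxel count, mean EF, r, uncorrected p, BH q and the rejection flag.
    Regions with no in-mask voxels are dropped with a warning.
    """
    import warnings

    if subjects is None:
        subjects = sorted(delta_maps)
    grid = atlas.grid
    labels = atlas.labels.values
    region_ids = sorted(atlas.table)
    in_mask = mask.member if mask is not None else np.ones(grid.dims, dtype=bool)

    ef_means = {}
    db_means = {}
    kept, n_vox = [], {}
    region_sel = {}
    for rid in region_ids:
        sel = (labels == rid) & in_mask
        if not sel.any():
            warnings.warn(f"region {rid} has no in-mask voxels; dropped")
            continue
        kept.append(rid)
        region_sel[rid] = sel
        n_vox[rid] = int(sel.sum())
    for s in subjects:
        emap = ef_maps[s]
        if not emap.grid.same_grid(grid):
            emap = resample_to_grid(emap, grid, method="linear")
        ev, dv = emap.values, delta_maps[s].values
        ef_means[s] = {rid: ev[region_sel[rid]].mean() for rid in kept}
        db_means[s] = {rid: dv[region_sel[rid]].mean() for rid in kept}

    E = np.array([[ef_means[s][rid] for s in subjects] for rid in kept])
    D = np.array([[db_means[s][rid] for s in subjects] for rid in kept])
    r, p, defined = pearson_rows(E, D)
    qv, rej = fdr_bh(np.where(defined, p, np.nan), q=q)
    return pd.DataFrame(
        {
            "region": kept,
            "name": [atlas.table[rid] for rid in kept],
            "n_vox": [n_vox[rid] for rid in kept],
            "mean_ef": E.mean(axis=1),
            "r": r,
            "p": p,
            "q": qv,
            "significant": rej,
        }
    )
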