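"""First-level block-design GLM: regressors, motion censoring, betas.

The task is a cue-reactivity block design (meth vs. neutral picture blocks).
Each condition is modelled by convolving its 31-s block timing with a
canonical double-gamma HRF on a 10x-upsampled time grid, fitting ordinary
least squares per voxel with Legendre drift terms (orders 0..2, i.e. the
conventional "three polynomial terms") and the six motion parameters as
nuisance columns.  High-motion TRs (Euclidean norm of the motion derivative
above 0.3) are censored by row deletion before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy.special import gammaln

from .volume import BrainVolume, GridSpec

log = logging.getLogger(__name__)

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
DEFAULT_CENSOR_THRESHOLD = 0.3
DEFAULT_BLOCK_DURATION_S = 31.0  # 6 pictures x 5 s + 5 gaps x 0.2 s


class GlmError(ValueError):
    pass


class ExcessiveMotionError(GlmError):
    """More than half the TRs censored: the subject-session is excluded."""


@dataclass(frozen=True)
class TaskDesign:
    """Block timing for one run: (onset s, duration s, condition) triples."""

    tr: float
    n_volumes: int
    blocks: tuple = ()

    def __post_init__(self):
        if self.tr <= 0:
            raise GlmError("tr must be positive")
        scan_end = self.tr * self.n_volumes
        for onset, dur, cond in self.blocks:
            if onset < 0 or onset + dur > scan_end + 1e-9:
                raise GlmError(f"block ({onset}, {dur}, {cond}) outside the scan")

    @property
    def conditions(self) -> tuple:
        seen = []
        for _, _, c in self.blocks:
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.blocks, columns=["onset", "duration", "condition"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, tr: float, n_volumes: int) -> "TaskDesign":
        tab = pd.read_csv(path, sep="\t")
        blocks = tuple(
            (float(r.onset), float(r.duration), str(r.condition))
            for r in tab.itertuples()
        )
        return cls(tr, n_volumes, blocks)


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF (SPM-like parameterisation, seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0
    length: float = 32.0

    def __post_init__(self):
        vals = (self.peak_delay, self.undershoot_delay, self.peak_disp,
                self.undershoot_disp, self.ratio, self.length)
        if any(v <= 0 for v in vals):
            raise GlmError("HRF parameters must all be positive")


def _gamma_pdf(t, shape, scale):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


def hrf(t_grid, params: HRFParams = HRFParams()) -> np.ndarray:
    """Double-gamma HRF sampled at ``t_grid``, peak-normalized to 1."""
    t = np.asarray(t_grid, dtype=float)
    peak = _gamma_pdf(t, params.peak_delay / params.peak_disp, params.peak_disp)
    under = _gamma_pdf(
        t, params.undershoot_delay / params.undershoot_disp, params.undershoot_disp
    )
    kern = peak - under / params.ratio
    dense = np.arange(0, params.length, 0.01)
    ref = _gamma_pdf(dense, params.peak_delay / params.peak_disp, params.peak_disp)
    ref = ref - _gamma_pdf(
        dense, params.undershoot_delay / params.undershoot_disp,
        params.undershoot_disp) / params.ratio
    return kern / ref.max()


def build_condition_regressor(
    design: TaskDesign,
    condition: str,
    hrf_params: HRFParams = HRFParams(),
    oversample: int = 10,
) -> np.ndarray:
    """HRF-convolved boxcar for one condition, sampled at the TR grid.

    The boxcar is built on an ``oversample``-times finer grid (0.2-s picture
    gaps are sub-TR), convolved, then sampled at frame times.
    """
    if condition not in design.conditions:
        raise GlmError(f"condition {condition!r} not present in design")
    blocks = [(o, d) for o, d, c in design.blocks if c == condition]
    return _convolved_boxcar(
        tuple(blocks), design.tr, design.n_volumes, hrf_params, oversample
    ).copy()


@lru_cache(maxsize=128)
def _convolved_boxcar(blocks, tr, n_volumes, hrf_params, oversample):
    dt = tr / oversample
    n_hi = n_volumes * oversample
    t_hi = np.arange(n_hi) * dt
    box = np.zeros(n_hi)
    for onset, dur in blocks:
        box[(t_hi >= onset) & (t_hi < onset + dur)] = 1.0
    kern = hrf(np.arange(0, hrf_params.length, dt), hrf_params)
    conv = np.convolve(box, kern)[:n_hi] * dt
    return conv[::oversample]


def zero_regressor(design: TaskDesign) -> np.ndarray:
    return np.zeros(design.n_volumes)


def censor_trs(motion: pd.DataFrame | np.ndarray,
               threshold: float = DEFAULT_CENSOR_THRESHOLD) -> np.ndarray:
    """Keep-vector: TR t kept unless ||motion[t]-motion[t-1]||_2 > threshold.

    The first TR is never censored by this rule.
    """
    arr = np.asarray(motion, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise GlmError(f"motion table must have 6 columns, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise GlmError("motion table needs at least 2 TRs")
    enorm = np.linalg.norm(np.diff(arr, axis=0), axis=1)
    keep = np.ones(arr.shape[0], dtype=bool)
    keep[1:] = enorm <= threshold
    return keep


def legendre_drift(n_volumes: int, order: int = 2) -> np.ndarray:
    """Legendre polynomial drift columns of order 0..order on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    return np.column_stack(
        [legendre.Legendre.basis(k)(x) for k in range(order + 1)]
    )


@dataclass
class BetaMaps:
    """Per-session condition betas and their meth - neutral contrast."""

    beta_meth: BrainVolume
    beta_neutral: BrainVolume
    contrast: BrainVolume
    session: str = ""
    censored_fraction: float = 0.0


@dataclass
class GlmDesign:
    X: np.ndarray
    names: list
    keep: np.ndarray
    condition_index: dict = field(default_factory=dict)


def build_design_matrix(
    design: TaskDesign,
    motion,
    hrf_params: HRFParams = HRFParams(),
    poly_order: int = 2,
    censor_threshold: float = DEFAULT_CENSOR_THRESHOLD,
    conditions=("meth", "neutral"),
) -> GlmDesign:
    drift = legendre_drift(design.n_volumes, poly_order)
    names = [f"poly{k}" for k in range(poly_order + 1)]
    cols = [drift]
    motion_arr = np.asarray(motion, dtype=float)
    if motion_arr.shape[0] != design.n_volumes:
        raise GlmError("motion table length does not match scan length")
    cols.append(motion_arr)
    names += MOTION_COLUMNS
    cond_index = {}
    for cond in conditions:
        reg = (build_condition_regressor(design, cond, hrf_params)
               if cond in design.conditions else zero_regressor(design))
        cond_index[cond] = len(names)
        names.append(cond)
        cols.append(reg[:, None])
    keep = censor_trs(motion_arr, censor_threshold)
    return GlmDesign(np.column_stack(cols), names, keep, cond_index)


def fit_first_level(
    series: BrainVolume | np.ndarray,
    design: TaskDesign,
    motion,
    poly_order: int = 2,
    hrf_params: HRFParams = HRFParams(),
    censor_threshold: float = DEFAULT_CENSOR_THRESHOLD,
    session: str = "",
    grid: GridSpec | None = None,
) -> BetaMaps:
    """Voxelwise OLS on the censored design; returns condition betas.

    Raises :class:`ExcessiveMotionError` when more than 50% of TRs are
    censored.  If the censored design is rank deficient all condition betas
    are flagged undefined (NaN).
    """
    if isinstance(series, BrainVolume):
        grid = series.grid
        data = series.values
    else:
        data = np.asarray(series, dtype=float)
        if grid is None:
            raise GlmError("grid required when series is a bare array")
    if data.shape[3] != design.n_volumes:
        raise GlmError("series length does not match design.n_volumes")
    gd = build_design_matrix(design, motion, hrf_params, poly_order, censor_threshold)
    censored_fraction = 1.0 - gd.keep.mean()
    if censored_fraction > 0.5:
        raise ExcessiveMotionError(
            f"{censored_fraction:.0%} of TRs censored (> 50%); session excluded"
        )
    X = gd.X[gd.keep]
    Y = data.reshape(-1, design.n_volumes).T[gd.keep]
    # conditions are identifiable iff adding their columns raises the rank by 2
    cond_cols = [gd.condition_index["meth"], gd.condition_index["neutral"]]
    nuis = np.delete(X, cond_cols, axis=1)
    if np.linalg.matrix_rank(X) - np.linalg.matrix_rank(nuis) < len(cond_cols):
        log.warning("condition columns unidentifiable after censoring; betas undefined")
        bm = np.full(grid.dims, np.nan)
        bn = np.full(grid.dims, np.nan)
    else:
        beta = np.linalg.pinv(X) @ Y
        bm = beta[gd.condition_index["meth"]].reshape(grid.dims)
        bn = beta[gd.condition_index["neutral"]].reshape(grid.dims)
    return BetaMaps(
        beta_meth=BrainVolume(grid, bm, "beta"),
        beta_neutral=BrainVolume(grid, bn, "beta"),
        contrast=BrainVolume(grid, bm - bn, "beta"),
        session=session,
        censored_fraction=float(censored_fraction),
    )


def change_map(pre: BetaMaps, post: BetaMaps) -> BrainVolume:
    """Post minus pre contrast map (meth > neutral), voxelwise."""
    if not pre.contrast.grid.same_grid(post.contrast.grid):
        raise GlmError("pre/post grids differ")
    vals = post.contrast.values - pre.contrast.values
    return BrainVolume(pre.contrast.grid, vals, "delta_beta")
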