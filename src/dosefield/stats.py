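"""Shared statistics: Pearson r with exact p, BH FDR, effect-size bins,
two-sample power, and the linear mixed-effects cell used at every level.

The LME tests the time (pre/post) x group (sham/active) interaction with a
subject random intercept.  On balanced complete data this is algebraically
identical to a two-sample t-test comparing arms on within-subject post-pre
difference scores, and that closed form is the canonical fast path; the
general (unbalanced) case is delegated to statsmodels MixedLM under REML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .volume import BrainVolume, Mask


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class CorrResult:
    r: float
    p: float
    n: int
    defined: bool = True

    @classmethod
    def undefined(cls, n: int = 0) -> "CorrResult":
        return cls(np.nan, np.nan, n, False)


def pearson(x, y) -> CorrResult:
    """Sample Pearson correlation with two-sided p from the t-transform.

    Inputs of length < 3 or with zero variance give an undefined result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-D and the same length")
    n = x.size
    if n < 3:
        return CorrResult.undefined(n)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return CorrResult.undefined(n)
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return CorrResult(r, 0.0, n)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return CorrResult(r, float(p), n)


def pearson_rows(X: np.ndarray, Y: np.ndarray):
    """Row-wise Pearson r and two-sided p for paired matrices (rows x subjects).

    Returns ``(r, p, defined)`` arrays; rows where either input is constant
    (or contains non-finite values) are undefined (NaN, defined=False).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise StatsError("matrices must share shape")
    n = X.shape[1]
    finite = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
    Xc = X - np.nanmean(X, axis=1, keepdims=True)
    Yc = Y - np.nanmean(Y, axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((Yc**2).sum(axis=1))
    defined = finite & (sx > 0) & (sy > 0) & (n >= 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * Yc).sum(axis=1) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    r[~defined] = np.nan
    p = np.full_like(r, np.nan)
    if n >= 3:
        ok = defined & (np.abs(r) < 1.0)
        t = r[ok] * np.sqrt((n - 2) / (1 - r[ok] ** 2))
        p[ok] = 2.0 * sps.t.sf(np.abs(t), n - 2)
        p[defined & (np.abs(r) >= 1.0)] = 0.0
    return r, p, defined


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up over the defined (finite) p-values.

    Returns ``(qvals, reject)``; undefined entries get NaN q and are never
    rejected (they are excluded from the family, not set to p = 1).
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise StatsError("empty p-value vector")
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise StatsError("p-values must lie in [0, 1]")
    qvals = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    if finite.any():
        rej, qv, _, _ = multipletests(p[finite], alpha=q, method="fdr_bh")
        qvals[finite] = qv
        reject[finite] = rej
    return qvals, reject


#: effect-size bin edges on |r| (boundaries assigned to the lower bin)
EFFECT_BIN_EDGES = (0.1, 0.3, 0.5)


@dataclass(frozen=True)
class EffectBins:
    """Proportions of defined voxels per |r| effect-size bin.

    negligible: 0 <= |r| <= 0.1; small: 0.1 < |r| < 0.3 (0.3 to lower bin);
    medium: 0.3 < |r| < 0.5; large: 0.5 < |r| < 1.
    """

    prop_negligible: float
    prop_small: float
    prop_medium: float
    prop_large: float
    n_defined: int = 0

    def as_dict(self) -> dict:
        return {
            "negligible": self.prop_negligible,
            "small": self.prop_small,
            "medium": self.prop_medium,
            "large": self.prop_large,
        }


def classify_effect_sizes(rmap: BrainVolume | np.ndarray, mask: Mask | None = None) -> EffectBins:
    """Bin |r| values of defined in-mask voxels into effect-size classes."""
    vals = rmap.values if isinstance(rmap, BrainVolume) else np.asarray(rmap, dtype=float)
    if mask is not None:
        vals = vals[mask.member]
    vals = np.abs(vals[np.isfinite(vals)])
    if vals.size == 0:
        raise StatsError("no defined voxels to classify")
    lo, mid, hi = EFFECT_BIN_EDGES
    n = vals.size
    neg = (vals <= lo).sum()
    small = ((vals > lo) & (vals <= mid)).sum()
    medium = ((vals > mid) & (vals <= hi)).sum()
    large = (vals > hi).sum()
    return EffectBins(neg / n, small / n, medium / n, large / n, n)


def two_sample_power(n_per_arm: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test via the noncentral t.

    df = 2n - 2, noncentrality d * sqrt(n/2).
    """
    if n_per_arm < 2:
        raise StatsError("need n >= 2 per arm")
    if d < 0 or not (0 < alpha < 1):
        raise StatsError("require d >= 0 and alpha in (0, 1)")
    df = 2 * n_per_arm - 2
    nc = d * np.sqrt(n_per_arm / 2.0)
    tcrit = sps.t.isf(alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


@dataclass
class LmeFit:
    """Random-intercept LME fit of y ~ time * group + (1 | subject)."""

    coefficients: dict
    tstats: dict
    subject_var: float
    resid_var: float
    df_interaction: float
    method: str = "closed_form"


def _closed_form_lme(y, time, group, subject) -> LmeFit:
    subjects = np.unique(subject)
    d = np.empty(subjects.size)
    s_mean = np.empty(subjects.size)
    g = np.empty(subjects.size)
    pre_mean = np.empty(subjects.size)
    for i, s in enumerate(subjects):
        sel = subject == s
        d[i] = y[sel & (time == 1)].item() - y[sel & (time == 0)].item()
        s_mean[i] = y[sel].mean()
        pre_mean[i] = y[sel & (time == 0)].item()
        g[i] = group[sel][0]
    act, sham = g == 1, g == 0
    n_a, n_s = int(act.sum()), int(sham.sum())
    inter = d[act].mean() - d[sham].mean()
    sd2 = (
        ((d[act] - d[act].mean()) ** 2).sum() + ((d[sham] - d[sham].mean()) ** 2).sum()
    ) / (n_a + n_s - 2)
    resid_var = sd2 / 2.0
    se_inter = np.sqrt(sd2 * (1.0 / n_a + 1.0 / n_s))
    t_inter = inter / se_inter if se_inter > 0 else np.sign(inter) * np.inf
    # remaining fixed effects under pre=0/post=1, sham=0/active=1 coding
    intercept = pre_mean[sham].mean()
    time_coef = d[sham].mean()
    group_coef = pre_mean[act].mean() - pre_mean[sham].mean()
    sm2 = (
        ((s_mean[act] - s_mean[act].mean()) ** 2).sum()
        + ((s_mean[sham] - s_mean[sham].mean()) ** 2).sum()
    ) / max(n_a + n_s - 2, 1)
    subject_var = max(sm2 - resid_var / 2.0, 0.0)
    se_time = np.sqrt(sd2 / n_s)
    se_group = np.sqrt((subject_var + resid_var) * (1.0 / n_a + 1.0 / n_s))
    tstats = {
        "intercept": np.nan,
        "time": time_coef / se_time if se_time > 0 else np.nan,
        "group": group_coef / se_group if se_group > 0 else np.nan,
        "time:group": float(t_inter),
    }
    coefs = {
        "intercept": float(intercept),
        "time": float(time_coef),
        "group": float(group_coef),
        "time:group": float(inter),
    }
    return LmeFit(coefs, tstats, float(subject_var), float(resid_var),
                  float(n_a + n_s - 2), "closed_form")


def _is_balanced(time, subject) -> bool:
    subjects, counts = np.unique(subject, return_counts=True)
    if not (counts == 2).all():
        return False
    for s in subjects:
        tt = np.sort(time[subject == s])
        if not np.array_equal(tt, [0, 1]):
            return False
    return True


def fit_lme_cell(y, time, group, subject) -> LmeFit:
    """Fit the time x group random-intercept model for one voxel/ROI cell.

    ``time`` coded pre=0/post=1 and ``group`` sham=0/active=1.  Balanced
    complete data take the closed form (interaction t equals the two-sample
    t on difference scores); anything else goes through MixedLM (REML).
    """
    y = np.asarray(y, dtype=float)
    time = np.asarray(time, dtype=int)
    group = np.asarray(group, dtype=int)
    subject = np.asarray(subject)
    if not (len(y) == len(time) == len(group) == len(subject)):
        raise StatsError("inputs must share length")
    if np.unique(group).size < 2 or np.unique(time).size < 2:
        raise StatsError("interaction undefined: need both arms and both timepoints")
    if _is_balanced(time, subject):
        return _closed_form_lme(y, time, group, subject)
    import pandas as pd
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "time": time, "group": group, "subject": subject})
    fit = smf.mixedlm("y ~ time * group", df, groups=df["subject"]).fit(reml=True)
    names = {"Intercept": "intercept", "time": "time", "group": "group",
             "time:group": "time:group"}
    coefs = {v: float(fit.params[k]) for k, v in names.items()}
    tstats = {v: float(fit.params[k] / fit.bse[k]) for k, v in names.items()}
    nsub = np.unique(subject).size
    return LmeFit(coefs, tstats, float(fit.cov_re.iloc[0, 0]), float(fit.scale),
                  float(nsub - 2), "reml")


def difference_score_tmap(pre: np.ndarray, post: np.ndarray, arm_active: np.ndarray,
                          t_cap: float = 1e6):
    """Vectorized balanced LME interaction t over the last axis = subjects.

    ``pre``/``post`` are (..., n_subjects) stacks of per-subject maps and
    ``arm_active`` a boolean subject vector.  Returns (tmap, df, resid)
    where ``resid`` are the group-mean-centred difference scores divided by
    their pooled SD (inputs to smoothness estimation).  Voxels with zero
    residual variance but nonzero effect get the capped sentinel ``t_cap``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    arm_active = np.asarray(arm_active, dtype=bool)
    d = post - pre
    n_a = int(arm_active.sum())
    n_s = int((~arm_active).sum())
    if n_a < 2 or n_s < 2:
        raise StatsError("need >= 2 subjects per arm")
    da = d[..., arm_active]
    ds = d[..., ~arm_active]
    ma, ms = da.mean(axis=-1), ds.mean(axis=-1)
    ss = ((da - ma[..., None]) ** 2).sum(axis=-1) + (
        (ds - ms[..., None]) ** 2
    ).sum(axis=-1)
    df = n_a + n_s - 2
    sd2 = ss / df
    se = np.sqrt(sd2 * (1.0 / n_a + 1.0 / n_s))
    eff = ma - ms
    with np.errstate(invalid="ignore", divide="ignore"):
        t = eff / se
    t[(se == 0) & (eff != 0)] = np.sign(eff[(se == 0) & (eff != 0)]) * t_cap
    t[(se == 0) & (eff == 0)] = 0.0
    t = np.clip(t, -t_cap, t_cap)
    resid = np.empty_like(d)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(sd2)
        resid[..., arm_active] = (da - ma[..., None]) / sd[..., None]
        resid[..., ~arm_active] = (ds - ms[..., None]) / sd[..., None]
    return t, df, resid
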