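"""Self-contained validation studies: power, null calibration, recovery.

These functions run the package end to end under fixed study conditions and
summarize the outcome:

* the design's power statement (two-sample t at n = 30/arm, d = 0.74),
  analytically and by Monte-Carlo;
* false-positive calibration of the voxel-level FDR analysis and of the
  Monte-Carlo cluster-extent threshold on global-null cohorts/fields;
* recovery of a planted network-level dose-response correlation, including
  the per-arm specificity (sham shows nothing);
* the level-contrast pattern: a network-level plant is detected by the gPPI
  path while voxel- and ROI-level FDR maps stay empty.

Every study takes a single integer seed and is deterministic given it.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .clusters import monte_carlo_extent, simulate_null_max_sizes
from .pipeline import PipelineConfig, simulate_and_recover
from .stats import two_sample_power
from .synthetic import CohortConfig, PlantSpec
from .volume import GridSpec, make_sphere_mask

#: smoothness used for null-field cluster-extent studies on the 4-mm test
#: grid; 2.25x voxel size, matching the effective smoothness of kernel-
#: smoothed fMRI relative to its voxel size
NULL_FIELD_FWHM_MM = 9.0


def _child_seed(seed: int, key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) % (2**31), key])


def power_study(seed: int, n_per_arm: int = 30, d: float = 0.74,
                alpha: float = 0.05, mc_tests: int = 200_000) -> dict:
    """Analytic noncentral-t power plus a Monte-Carlo cross-check."""
    analytic = two_sample_power(n_per_arm, d, alpha)
    rng = np.random.default_rng(_child_seed(seed, 1))
    hits = 0
    block = 20_000
    done = 0
    while done < mc_tests:
        b = min(block, mc_tests - done)
        a = rng.standard_normal((b, n_per_arm)) + d
        c = rng.standard_normal((b, n_per_arm))
        _, p = sps.ttest_ind(a, c, axis=1)
        hits += (p < alpha).sum()
        done += b
    return {"power_analytic": float(analytic),
            "power_monte_carlo": float(hits / mc_tests),
            "n_tests": mc_tests}


def _default_grid_cohort(**kw) -> CohortConfig:
    return CohortConfig(**kw)


def voxel_null_calibration(seed: int, n_replicates: int = 200,
                           n_active: int = 30, n_sham: int = 30) -> dict:
    """Family-wise rate of >= 1 BH-FDR voxel discovery on null cohorts."""
    cfg = PipelineConfig(
        cohort=_default_grid_cohort(n_active=n_active, n_sham=n_sham,
                                    plant=PlantSpec(level="none")),
        levels=("voxel",),
    )
    tab = simulate_and_recover(cfg, n_replicates,
                               int(_child_seed(seed, 2).generate_state(1)[0] % 2**31))
    rate = float((tab["voxel_n_sig"] > 0).mean())
    return {"voxel_family_rate": rate, "n_replicates": n_replicates,
            "mc_se": float(np.sqrt(0.05 * 0.95 / n_replicates))}


def cluster_fwe_validation(seed: int, n_calibration: int = 2000,
                           n_validation: int = 500,
                           voxel_p: float = 0.005, alpha: float = 0.05) -> dict:
    """Calibrate the extent threshold, then validate FWE on fresh null fields."""
    grid = GridSpec.isotropic((16, 16, 16), 4.0)
    mask = make_sphere_mask(grid, (0.0, 0.0, 0.0), 28.0)
    fwhm = [NULL_FIELD_FWHM_MM] * 3
    rng = np.random.default_rng(_child_seed(seed, 3))
    table = monte_carlo_extent(grid, mask, fwhm, voxel_p=voxel_p, alpha=alpha,
                               n_iter=n_calibration, rng=rng)
    k = table.k[(voxel_p, alpha)]
    fresh = simulate_null_max_sizes(grid, mask, fwhm, voxel_p, n_validation,
                                    18, np.random.default_rng(_child_seed(seed, 4)))
    return {"extent_k": int(k),
            "empirical_fwe": float((fresh >= k).mean()),
            "alpha": alpha, "n_validation": n_validation}


def recovery_study(seed: int, n_replicates: int = 100, rho: float = 0.45,
                   n_active: int = 30, n_sham: int = 30) -> dict:
    """Planted network dose-response correlation: recovery and specificity.

    The plant targets corr(seed-node dose, delta coupling) = ``rho``; each
    replicate runs the full network pipeline (seed definition, gPPI,
    second-level discovery) plus the recovery correlation against the
    planted parietal node.  Detection = two-sided p < 0.05 on the active-arm
    recovery correlation.
    """
    cfg = PipelineConfig(
        cohort=_default_grid_cohort(
            n_active=n_active, n_sham=n_sham,
            plant=PlantSpec(level="network", rho=rho)),
        levels=("network",),
    )
    cfg.thresholds.mc_iterations = 500
    tab = simulate_and_recover(cfg, n_replicates,
                               int(_child_seed(seed, 5).generate_state(1)[0] % 2**31))
    n = n_active
    expected = rho - rho * (1 - rho**2) / (2 * (n - 1))
    return {
        "mean_r_active": float(tab["recovery_r_active"].mean()),
        "abs_mean_r_sham": float(abs(tab["recovery_r_sham"].mean())),
        "detection_rate": float((tab["recovery_p_active"] < 0.05).mean()),
        "cluster_found_rate": float(tab["network_cluster_found"].mean()),
        "truth_mean_r": float(tab["truth_r_active"].mean()),
        "expected_mean_r": float(expected),
        "mc_se_mean_r": float((1 - rho**2) / np.sqrt(n - 1) / np.sqrt(n_replicates)),
        "n_replicates": n_replicates,
        "rho": rho,
    }


def level_contrast_study(seed: int, n_replicates: int = 40) -> dict:
    """Default network plant: regional levels stay silent, network detects.

    Voxel-/ROI-level rates are the replicate frequencies of any FDR-corrected
    finding; the network rate is the frequency of a surviving second-level
    cluster whose active-arm dose-connectivity correlation has p < 0.05.
    """
    cfg = PipelineConfig(
        cohort=_default_grid_cohort(),  # default plant: network, rho = 0.6
        levels=("voxel", "roi", "network"),
    )
    cfg.thresholds.mc_iterations = 500
    tab = simulate_and_recover(cfg, n_replicates,
                               int(_child_seed(seed, 6).generate_state(1)[0] % 2**31))
    detected = tab["network_cluster_found"] & (tab["network_p_active"] < 0.05)
    bins = {f"mean_prop_{k}_pct": float(100 * tab[f"bin_{k}"].mean())
            for k in ("small", "medium", "large")}
    return {
        "voxel_rate": float((tab["voxel_n_sig"] > 0).mean()),
        "roi_rate": float((tab["roi_n_sig"] > 0).mean()),
        "network_rate": float(detected.mean()),
        "n_replicates": n_replicates,
        **bins,
    }
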