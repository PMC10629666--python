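"""Seed definition, gPPI designs and estimators, dose-connectivity, behavior."""

import numpy as np
import pandas as pd
import pytest

import dosefield as dfd
from dosefield.network import (
    NetworkError,
    SeedDefinition,
    behavior_association,
    build_gppi_design,
    define_seed,
    dose_connectivity_correlation,
    roi_to_roi_gppi,
    second_level_interaction,
    seed_to_voxel_gppi,
)
from dosefield.synthetic import generate_subject_series
from dosefield.volume import BrainVolume, Mask, make_sphere_mask


@pytest.fixture(scope="module")
def noiseless_cohort():
    cfg = dfd.CohortConfig(
        n_active=2, n_sham=1,
        noise_sd_bold=0.0, motion_walk_sd=0.0, motion_spike_prob=0.0,
        plant=dfd.PlantSpec(level="none"),
    )
    return dfd.generate_cohort(cfg, 21)


class TestDefineSeed:
    def test_center_near_dominant_lobe_peak(self, sim_grid, sim_mask):
        params = dfd.EFFieldParams(amp_cv=0.0, jitter_mm=0.0)
        ef = {"s0": dfd.generate_ef_map(params, sim_grid, np.random.default_rng(0))}
        seed = define_seed(ef, sim_mask)
        # analytic peak of the combined field sits by the anode center
        peak_idx = np.unravel_index(
            np.where(sim_mask.member, ef["s0"].values, -1).argmax(), sim_grid.dims
        )
        peak_mm = sim_grid.index_to_world([peak_idx])[0]
        assert np.linalg.norm(seed.center_mm - peak_mm) <= np.max(sim_grid.voxel_size)

    def test_mean_idempotent_for_identical_maps(self, sim_grid, sim_mask):
        params = dfd.EFFieldParams()
        one = dfd.generate_ef_map(params, sim_grid, np.random.default_rng(1))
        a = define_seed({"s0": one}, sim_mask)
        b = define_seed({"s0": one, "s1": one}, sim_mask)
        assert np.array_equal(a.mask.member, b.mask.member)
        assert np.allclose(a.center_mm, b.center_mm)

    def test_percentile_zero_is_mask_com(self, sim_grid, sim_mask):
        params = dfd.EFFieldParams()
        ef = {"s0": dfd.generate_ef_map(params, sim_grid, np.random.default_rng(2))}
        seed = define_seed(ef, sim_mask, percentile=0.0)
        com = sim_grid.voxel_centers()[sim_mask.member].mean(axis=0)
        assert np.allclose(seed.center_mm, com, atol=1e-9)


class TestGppiDesign:
    def test_interaction_columns_centred_and_guarded(self, noiseless_cohort):
        cohort = noiseless_cohort
        s = cohort.subjects[0]
        seed_ts = s.series_pre[cohort.node_masks["seed"].member].mean(axis=0)
        g = build_gppi_design(seed_ts.astype(float), cohort.design)
        for cond, j in g.interaction_index.items():
            assert abs(g.X[:, j].mean()) < 1e-12
        with pytest.raises(NetworkError):
            build_gppi_design(np.zeros(cohort.design.n_volumes), cohort.design)

    def test_column_layout(self, noiseless_cohort):
        cohort = noiseless_cohort
        s = cohort.subjects[0]
        seed_ts = s.series_pre[cohort.node_masks["seed"].member].mean(axis=0)
        g = build_gppi_design(seed_ts.astype(float), cohort.design, poly_order=2)
        # drift(3) + psych(2) + phys(1) + interactions(2)
        assert g.X.shape[1] == 8
        assert g.names[:3] == ["poly0", "poly1", "poly2"]
        assert "phys" in g.names and "ppi_meth" in g.names


class TestSeedToVoxel:
    def test_exact_recovery_of_constructed_betas(self, rng, noiseless_cohort):
        cohort = noiseless_cohort
        s = cohort.subjects[0]
        seed_ts = s.series_pre[cohort.node_masks["seed"].member].mean(axis=0).astype(float)
        g = build_gppi_design(seed_ts, cohort.design)
        w = rng.standard_normal(g.X.shape[1])
        n_t = cohort.design.n_volumes
        series = np.broadcast_to(g.X @ w, cohort.grid.dims + (n_t,)).copy()
        out = seed_to_voxel_gppi(series, g, cohort.grid)
        expected = w[g.interaction_index["meth"]] - w[g.interaction_index["neutral"]]
        assert np.allclose(out["contrast"].values, expected, atol=1e-10)

    def test_betas_match_generic_ols_oracle(self, rng, noiseless_cohort):
        import statsmodels.api as sm

        cohort = noiseless_cohort
        s = cohort.subjects[0]
        seed_ts = s.series_pre[cohort.node_masks["seed"].member].mean(axis=0).astype(float)
        g = build_gppi_design(seed_ts, cohort.design, motion=s.motion_pre)
        target = s.series_post[cohort.node_masks["parietal"].member].mean(axis=0)
        from dosefield.network import _ols_betas

        ours = _ols_betas(g.X[g.keep], target[g.keep, None].astype(float))[:, 0]
        ref = sm.OLS(target[g.keep].astype(float), g.X[g.keep]).fit().params
        assert np.allclose(ours, ref, atol=1e-10)

    def test_nontarget_voxels_zero_noiseless(self, noiseless_cohort):
        cohort = noiseless_cohort
        s = cohort.subjects[0]
        seed_ts = s.series_pre[cohort.node_masks["seed"].member].mean(axis=0).astype(float)
        g = build_gppi_design(seed_ts, cohort.design)
        out = seed_to_voxel_gppi(s.series_pre, g, cohort.grid)
        bg = cohort.brain_mask.member & ~cohort.node_masks["parietal"].member
        assert np.abs(out["contrast"].values[bg]).max() < 1e-4


class TestRoiToRoi:
    def test_overlapping_masks_error(self, noiseless_cohort):
        cohort = noiseless_cohort
        s = cohort.subjects[0]
        with pytest.raises(NetworkError):
            roi_to_roi_gppi({"pre": s.series_pre}, cohort.node_masks["seed"],
                            cohort.node_masks["seed"], cohort.design)

    def test_noiseless_planted_coupling_recovered_exactly(self, noiseless_cohort):
        """Post-only planted delta-coupling 0.5 -> delta = 0.5 (< 1e-6)."""
        cohort = noiseless_cohort
        cfg = cohort.config
        s = cohort.subjects[0]
        mean_ef = s.truth["mean_ef_seed_node"]
        plant = dfd.PlantSpec(level="network", gamma=0.5 / mean_ef, rho=None,
                              noise_sd=0.0)
        rng = np.random.default_rng(0)
        s_post, m_post, delta = generate_subject_series(
            cohort.design, s.ef, cohort.node_masks, plant, "post", "active",
            rng, cfg, cohort.brain_mask)
        assert delta == pytest.approx(0.5, abs=1e-9)
        res = roi_to_roi_gppi(
            {"pre": s.series_pre, "post": s_post},
            cohort.node_masks["seed"], cohort.node_masks["parietal"],
            cohort.design, {"pre": s.motion_pre, "post": m_post},
            cfg.hrf, subject=s.id)
        assert res.delta == pytest.approx(0.5, abs=1e-6)
        assert res.contrast["pre"] == pytest.approx(cfg.coupling_ppi_base, abs=1e-6)

    def test_sham_noiseless_delta_zero(self, noiseless_cohort):
        cohort = noiseless_cohort
        s = cohort.arm_subjects("sham")[0]
        res = roi_to_roi_gppi(
            {"pre": s.series_pre, "post": s.series_post},
            cohort.node_masks["seed"], cohort.node_masks["parietal"],
            cohort.design, {"pre": s.motion_pre, "post": s.motion_post},
            cohort.config.hrf, subject=s.id)
        assert res.delta == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_conditions_zero_contrast(self, noiseless_cohort):
        """Equal meth and neutral coupling -> interaction contrast 0 exactly."""
        cohort = noiseless_cohort
        s = cohort.subjects[0]
        seed_ts = s.series_pre[cohort.node_masks["seed"].member].mean(axis=0).astype(float)
        g = build_gppi_design(seed_ts, cohort.design)
        c = 0.7
        jm, jn = g.interaction_index["meth"], g.interaction_index["neutral"]
        target = 0.4 * seed_ts + c * g.X[:, jm] + c * g.X[:, jn]
        from dosefield.network import _ols_betas

        beta = _ols_betas(g.X, target[:, None])[:, 0]
        assert beta[jm] - beta[jn] == pytest.approx(0.0, abs=1e-9)


class TestSecondLevel:
    def test_identical_inputs_give_empty_set(self, sim_grid, sim_mask, rng):
        vol = BrainVolume(sim_grid, rng.standard_normal(sim_grid.dims), "beta")
        maps = {f"s{j}": {"pre": vol, "post": vol} for j in range(8)}
        arms = {f"s{j}": ("active" if j < 4 else "sham") for j in range(8)}
        cs = second_level_interaction(maps, arms, sim_mask, n_null=150,
                                      rng=np.random.default_rng(0))
        assert len(cs) == 0

    def test_planted_group_shift_found_in_parietal(self):
        cfg = dfd.CohortConfig(n_active=12, n_sham=12)
        cohort = dfd.generate_cohort(cfg, 77)
        cfgp = dfd.PipelineConfig(levels=("network",), seed=5)
        cfgp.thresholds.mc_iterations = 400
        report = dfd.run_pipeline(cfgp, cohort=cohort)
        nw = report.levels["network"]
        assert nw["n_clusters"] >= 1
        # the largest surviving cluster overlaps the planted parietal node
        largest = nw["clusters"].clusters[0]
        overlap = largest.mask.member & cohort.node_masks["parietal"].member
        assert overlap.sum() > 0


class TestDoseConnectivity:
    def _results(self, ef, deltas):
        from dosefield.network import ConnectivityResult

        return [ConnectivityResult(f"s{j}", {}, {}, {"pre": 0.0, "post": d},
                                   delta=d)
                for j, d in enumerate(deltas)]

    def _seed(self, sim_grid, sim_mask, ef_values):
        sphere = make_sphere_mask(sim_grid, (14.0, 18.0, 12.0), 10.0)
        return SeedDefinition(np.array([14.0, 18.0, 12.0]), 10.0, 99.0,
                              Mask(sim_grid, sphere.member & sim_mask.member),
                              {f"s{j}": v for j, v in enumerate(ef_values)})

    def test_exact_linear_gives_unit_r(self, sim_grid, sim_mask, rng):
        ef = rng.uniform(0.1, 0.4, 10)
        seed = self._seed(sim_grid, sim_mask, ef)
        res = self._results(ef, 2.0 * ef)
        arms = {f"s{j}": "active" for j in range(10)}
        out = dose_connectivity_correlation(seed, res, arms)
        assert out.per_arm["active"].r == pytest.approx(1.0)

    def test_small_arm_errors(self, sim_grid, sim_mask, rng):
        ef = rng.uniform(0.1, 0.4, 4)
        seed = self._seed(sim_grid, sim_mask, ef)
        res = self._results(ef, ef)
        arms = {"s0": "active", "s1": "active", "s2": "active", "s3": "sham"}
        with pytest.raises(NetworkError):
            dose_connectivity_correlation(seed, res, arms)

    def test_shuffled_deltas_center_on_zero(self, sim_grid, sim_mask, rng):
        ef = rng.uniform(0.1, 0.4, 30)
        seed = self._seed(sim_grid, sim_mask, ef)
        arms = {f"s{j}": "active" for j in range(30)}
        rs = []
        deltas = 2.0 * ef
        for _ in range(200):
            rs.append(dose_connectivity_correlation(
                seed, self._results(ef, rng.permutation(deltas)), arms
            ).per_arm["active"].r)
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs)) + 0.02


class TestBehavior:
    def _vas(self, subjects, rng, constant=False):
        rows = []
        for s in subjects:
            base = 50.0 if constant else rng.uniform(20, 80)
            rows.append({"subject": s, "T0": base, "T1": base, "T2": base,
                         "T3": base, "T4": base if constant else rng.uniform(10, 90),
                         "T5": base})
        return pd.DataFrame(rows)

    def test_constant_delta_vas_flagged_undefined(self, sim_grid, sim_mask, rng):
        ef = rng.uniform(0.1, 0.4, 6)
        seed = TestDoseConnectivity()._seed(sim_grid, sim_mask, ef)
        res = TestDoseConnectivity()._results(ef, 2 * ef)
        arms = {f"s{j}": "active" for j in range(6)}
        vas = self._vas([r.subject for r in res], rng, constant=True)
        tab = behavior_association(vas, res, seed, arms)
        assert not tab["defined"].any()

    def test_planted_linear_relation_recovered(self, sim_grid, sim_mask, rng):
        ef = rng.uniform(0.1, 0.4, 8)
        seed = TestDoseConnectivity()._seed(sim_grid, sim_mask, ef)
        res = TestDoseConnectivity()._results(ef, rng.standard_normal(8))
        arms = {f"s{j}": "active" for j in range(8)}
        vas = self._vas([r.subject for r in res], rng)
        # construct delta-VAS exactly linear in baseline (pre) connectivity
        for r in res:
            r.contrast["pre"] = rng.standard_normal()
        vas["T4"] = vas["T3"] + 3.0 * np.array([r.pre for r in res])
        tab = behavior_association(vas, res, seed, arms).set_index("measure")
        assert tab.loc["pre_connectivity", "r"] == pytest.approx(1.0, abs=1e-9)

    def test_missing_timepoint_errors(self, sim_grid, sim_mask, rng):
        ef = rng.uniform(0.1, 0.4, 6)
        seed = TestDoseConnectivity()._seed(sim_grid, sim_mask, ef)
        res = TestDoseConnectivity()._results(ef, ef)
        arms = {f"s{j}": "active" for j in range(6)}
        vas = self._vas([r.subject for r in res], rng).drop(columns=["T4"])
        with pytest.raises(NetworkError):
            behavior_association(vas, res, seed, arms)
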