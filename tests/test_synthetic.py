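"""Synthetic cohort generator: EF fields, task design, BOLD, atlas, truth."""

import dataclasses

import numpy as np
import pytest

import dosefield as dfd
from dosefield.synthetic import (
    CATHODE_LOBE_WEIGHT,
    SyntheticError,
    calibrate_gamma,
    generate_motion_table,
    generate_task_design,
    generate_vas,
    mean_ef_moments,
)
from dosefield.volume import GridSpec, make_sphere_mask


class TestEfMaps:
    def test_no_jitter_no_cv_identical_across_subjects(self, sim_grid):
        params = dfd.EFFieldParams(amp_cv=0.0, jitter_mm=0.0)
        a = dfd.generate_ef_map(params, sim_grid, np.random.default_rng(1))
        b = dfd.generate_ef_map(params, sim_grid, np.random.default_rng(99))
        assert np.array_equal(a.values, b.values)

    def test_peak_value_matches_closed_form(self):
        """Grid containing the anode center: max = A(1 + w exp(-D^2/2s^2))."""
        params = dfd.EFFieldParams(
            anode_center_mm=(8.0, 8.0, 8.0), cathode_center_mm=(-8.0, -8.0, 0.0),
            amp_cv=0.0, jitter_mm=0.0, sigma_mm=10.0,
        )
        grid = GridSpec.isotropic((17, 17, 17), 2.0)  # odd dims: centers on lattice
        vol = dfd.generate_ef_map(params, grid, np.random.default_rng(0))
        d2 = ((np.array(params.anode_center_mm) - np.array(params.cathode_center_mm)) ** 2).sum()
        expected = params.amp_mean * (
            1 + CATHODE_LOBE_WEIGHT * np.exp(-d2 / (2 * params.sigma_mm**2))
        )
        assert vol.values.max() == pytest.approx(expected, rel=1e-9)
        peak = np.unravel_index(vol.values.argmax(), grid.dims)
        assert np.allclose(grid.index_to_world([peak])[0], params.anode_center_mm)

    def test_amplitude_lognormal_moments(self, sim_grid):
        params = dfd.EFFieldParams(jitter_mm=0.0, amp_cv=0.3)
        rng = np.random.default_rng(5)
        anode_idx = sim_grid.world_to_index([params.anode_center_mm])[0].round().astype(int)
        ref = dfd.generate_ef_map(
            dfd.EFFieldParams(jitter_mm=0.0, amp_cv=0.0), sim_grid, rng
        ).values[tuple(anode_idx)]
        draws = np.array([
            dfd.generate_ef_map(params, sim_grid, rng).values[tuple(anode_idx)]
            for _ in range(1000)
        ]) / (ref / params.amp_mean)
        se = params.amp_mean * params.amp_cv / np.sqrt(1000)
        assert abs(draws.mean() - params.amp_mean) < 3 * se

    def test_nonnegative_and_deterministic(self, sim_grid):
        params = dfd.EFFieldParams()
        a = dfd.generate_ef_map(params, sim_grid, np.random.default_rng(3))
        b = dfd.generate_ef_map(params, sim_grid, np.random.default_rng(3))
        assert (a.values >= 0).all()
        assert np.array_equal(a.values, b.values)

    def test_center_outside_grid_errors(self, sim_grid):
        params = dfd.EFFieldParams(anode_center_mm=(500.0, 0.0, 0.0))
        with pytest.raises(SyntheticError):
            dfd.generate_ef_map(params, sim_grid, np.random.default_rng(0))


class TestTaskDesign:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_block_structure(self, seed):
        d = generate_task_design(2.0, np.random.default_rng(seed))
        conds = [c for _, _, c in d.blocks]
        assert conds.count("meth") == 4 and conds.count("neutral") == 4
        assert all(dur == 31.0 for _, dur, _ in d.blocks)
        onsets = [o for o, _, _ in d.blocks]
        assert onsets == sorted(onsets)
        for (o1, dur1, _), (o2, _, _) in zip(d.blocks, d.blocks[1:]):
            assert o2 >= o1 + dur1  # non-overlapping
        assert 5.5 * 60 <= d.tr * d.n_volumes <= 7.5 * 60  # about 6.5 minutes

    def test_deterministic_given_seed(self):
        a = generate_task_design(2.0, np.random.default_rng(4))
        b = generate_task_design(2.0, np.random.default_rng(4))
        assert a == b

    def test_order_varies_across_seeds(self):
        orders = {
            tuple(c for _, _, c in generate_task_design(2.0, np.random.default_rng(s)).blocks)
            for s in range(8)
        }
        assert len(orders) > 1


class TestSubjectSeries:
    def test_noiseless_zero_coupling_parietal_is_scalar_multiple(self, sim_grid):
        cfg = dfd.CohortConfig(
            noise_sd_bold=0.0, motion_walk_sd=0.0, motion_spike_prob=0.0,
            amp_parietal=(0.0, 0.0), coupling_ppi_base=0.0,
            plant=dfd.PlantSpec(level="none"),
        )
        cohort = dfd.generate_cohort(dataclasses.replace(cfg, n_active=1, n_sham=0), 3)
        s = cohort.subjects[0]
        seed_ts = s.series_pre[cohort.node_masks["seed"].member][0]
        par_ts = s.series_pre[cohort.node_masks["parietal"].member][0]
        ratio = par_ts[np.abs(seed_ts) > 1e-6] / seed_ts[np.abs(seed_ts) > 1e-6]
        assert np.allclose(ratio, cfg.coupling_phys, atol=1e-4)

    def test_sham_truth_delta_is_zero(self):
        cfg = dfd.CohortConfig(n_active=2, n_sham=3)
        cohort = dfd.generate_cohort(cfg, 9)
        for s in cohort.arm_subjects("sham"):
            assert s.truth["delta_coupling"] == 0.0

    def test_plant_without_target_errors(self):
        with pytest.raises(SyntheticError):
            dfd.PlantSpec(level="roi", target=None)

    def test_motion_spikes_exceed_threshold(self):
        cfg = dfd.CohortConfig(motion_spike_prob=0.2)
        mot = generate_motion_table(np.random.default_rng(2), 200, cfg)
        from dosefield.glm import censor_trs

        keep = censor_trs(mot, 0.3)
        assert 0 < (~keep).sum() < 100


class TestCohort:
    def test_smoke_tiny_cohort_fast(self):
        import time

        t0 = time.time()
        cohort = dfd.generate_cohort(dfd.CohortConfig(n_active=2, n_sham=2), 1)
        assert time.time() - t0 < 5.0
        assert len(cohort.subjects) == 4
        assert cohort.subjects[0].series_pre.shape[3] == cohort.design.n_volumes

    def test_same_seed_bitwise_identical(self):
        a = dfd.generate_cohort(dfd.CohortConfig(n_active=2, n_sham=2), 17)
        b = dfd.generate_cohort(dfd.CohortConfig(n_active=2, n_sham=2), 17)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.ef.values, sb.ef.values)
            assert np.array_equal(sa.series_pre, sb.series_pre)
            assert np.array_equal(sa.series_post, sb.series_post)
            assert sa.motion_pre.equals(sb.motion_pre)
            assert np.array_equal(sa.vas, sb.vas)
            assert sa.truth == sb.truth
        assert a.design == b.design
        assert np.array_equal(a.atlas.labels.values, b.atlas.labels.values)

    def test_gamma_recovery_from_truth(self):
        """Regressing planted delta on seed-node dose returns gamma (3 SE)."""
        cfg = dfd.CohortConfig(n_active=30, n_sham=5)
        cohort = dfd.generate_cohort(cfg, 23)
        act = cohort.arm_subjects("active")
        x = np.array([s.truth["mean_ef_seed_node"] for s in act])
        y = np.array([s.truth["delta_coupling"] for s in act])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        se = np.sqrt(resid.var(ddof=2) / ((x - x.mean()) ** 2).sum())
        assert abs(slope - cohort.plant.gamma) < 3 * se

    def test_vas_range_and_time_effect_without_group_effect(self):
        cfg = dfd.CohortConfig(n_active=20, n_sham=20)
        cohort = dfd.generate_cohort(cfg, 31)
        vas = np.stack([s.vas for s in cohort.subjects])
        assert (vas >= 0).all() and (vas <= 100).all()
        # time effect present by construction (T2 peak, T5 trough)
        assert vas[:, 2].mean() > vas[:, 5].mean() + 20
        # no group effect: same generative means for both arms
        act = np.stack([s.vas for s in cohort.arm_subjects("active")])
        sham = np.stack([s.vas for s in cohort.arm_subjects("sham")])
        pooled_se = np.sqrt(act.mean(1).var() / len(act) + sham.mean(1).var() / len(sham))
        assert abs(act.mean() - sham.mean()) < 4 * pooled_se

    def test_write_cohort_fixtures(self, tmp_path, tiny_cohort):
        dfd.write_cohort(tiny_cohort, tmp_path)
        first = tiny_cohort.subjects[0].id
        for f in ("brain_mask.nii.gz", "atlas.nii.gz", "atlas.tsv", "events.tsv",
                  "vas.tsv", "truth.yaml", f"{first}/ef.nii.gz",
                  f"{first}/bold_pre.nii.gz", f"{first}/motion_post.tsv"):
            assert (tmp_path / f).exists()
        from dosefield.volume import read_volume

        back = read_volume(tmp_path / first / "ef.nii.gz", payload="EF_Vm")
        assert np.allclose(back.values, tiny_cohort.subjects[0].ef.values, atol=1e-6)


class TestAtlas:
    def test_single_parcel_covers_mask(self, sim_grid, sim_mask):
        atlas = dfd.generate_atlas(sim_grid, 1, np.random.default_rng(0), sim_mask)
        assert (atlas.labels.values[sim_mask.member] == 1).all()

    def test_partition_sizes_sum_to_mask(self, sim_grid, sim_mask):
        atlas = dfd.generate_atlas(sim_grid, 10, np.random.default_rng(1), sim_mask)
        lab = atlas.labels.values
        assert (lab[~sim_mask.member] == 0).all()
        sizes = [(lab == i).sum() for i in atlas.table]
        assert sum(sizes) == sim_mask.n_voxels
        assert all(s > 0 for s in sizes)

    def test_nearest_site_oracle(self, sim_grid, sim_mask):
        rng = np.random.default_rng(2)
        atlas = dfd.generate_atlas(sim_grid, 6, rng, sim_mask)
        lab = atlas.labels.values
        centers = sim_grid.voxel_centers()
        # site location = mean position is not a site; recover sites as the
        # voxel of each label nearest to which all its members map.  Instead
        # check the defining property directly: for every voxel, its assigned
        # label's site is at least as close as any other label's site.
        sites = {}
        for i in atlas.table:
            members = centers[(lab == i) & sim_mask.member]
            sites[i] = members  # candidate cloud
        # reconstruct exact sites by regenerating with the same stream
        rng2 = np.random.default_rng(2)
        in_pts = centers[sim_mask.member]
        site_pts = in_pts[rng2.choice(in_pts.shape[0], size=6, replace=False)]
        for v, label in zip(centers[sim_mask.member], lab[sim_mask.member]):
            d = ((site_pts - v) ** 2).sum(axis=1)
            assert d[int(label) - 1] == d.min()

    def test_too_many_parcels_errors(self, sim_grid, sim_mask):
        with pytest.raises(SyntheticError):
            dfd.generate_atlas(sim_grid, sim_mask.n_voxels + 1,
                               np.random.default_rng(0), sim_mask)


class TestCalibration:
    def test_gamma_formula_against_moments(self, sim_grid):
        params = dfd.EFFieldParams()
        node = make_sphere_mask(sim_grid, params.anode_center_mm, 8.0)
        pts = sim_grid.voxel_centers()[node.member]
        mean, sd = mean_ef_moments(params, pts)
        plant = dfd.PlantSpec(level="network", rho=0.5, noise_sd=0.2)
        gamma = calibrate_gamma(plant, params, pts)
        rho_implied = gamma * sd / np.sqrt(gamma**2 * sd**2 + plant.noise_sd**2)
        assert rho_implied == pytest.approx(0.5, abs=1e-12)

    def test_moments_match_direct_simulation(self, sim_grid):
        """MC moments of node-mean EF agree with full-map simulation."""
        params = dfd.EFFieldParams()
        node = make_sphere_mask(sim_grid, params.anode_center_mm, 8.0)
        pts = sim_grid.voxel_centers()[node.member]
        mean, sd = mean_ef_moments(params, pts, n_mc=2000)
        rng = np.random.default_rng(8)
        draws = np.array([
            dfd.generate_ef_map(params, sim_grid, rng).values[node.member].mean()
            for _ in range(800)
        ])
        assert draws.mean() == pytest.approx(mean, rel=0.05)
        assert draws.std() == pytest.approx(sd, rel=0.15)


def test_generate_vas_clipped():
    cfg = dfd.CohortConfig(vas_subject_sd=60.0)
    vals = np.concatenate([
        generate_vas(np.random.default_rng(s), cfg) for s in range(50)
    ])
    assert (vals >= 0).all() and (vals <= 100).all()
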