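"""Seed filtering, MA/ALE maps, Monte-Carlo significance and contrasts."""

import numpy as np
import pytest

from nucleimap import synthdata as sd
from nucleimap.grids import Grid
from nucleimap.macm import (
    Experiment,
    NoExperimentsError,
    ale_map,
    compute_ale,
    contrast,
    default_fwhm,
    filter_by_seed,
    ma_map,
    read_experiments,
    significance,
    write_experiments,
)


@pytest.fixture(scope="module")
def grid():
    return Grid.isotropic((24, 24, 24), origin_mm=(-24.0, -24.0, -24.0), voxel_size_mm=2.0)


def exp(eid, foci, n=20):
    return Experiment(eid, np.asarray(foci, float), n)


class TestFwhm:
    def test_monotone_non_increasing_in_sample_size(self):
        widths = [default_fwhm(n) for n in range(1, 200)]
        assert all(a >= b for a, b in zip(widths, widths[1:]))

    def test_plausible_width_range(self):
        assert 8.0 < default_fwhm(50) < default_fwhm(10) < 12.0


class TestFilterBySeed:
    def test_focus_at_seed_voxel_retained(self, grid):
        seed = np.zeros(grid.shape, bool)
        seed[12, 12, 12] = True
        center = grid.voxel_to_mm([12, 12, 12])[0]
        assert filter_by_seed([exp("a", [center])], seed, grid) != []

    def test_far_focus_excluded(self, grid):
        seed = np.zeros(grid.shape, bool)
        seed[12, 12, 12] = True
        far = grid.voxel_to_mm([12, 12, 12])[0] + 50.0
        assert filter_by_seed([exp("a", [far])], seed, grid) == []

    def test_empty_seed_rejected(self, grid):
        with pytest.raises(ValueError, match="empty"):
            filter_by_seed([exp("a", [[0, 0, 0]])], np.zeros(grid.shape, bool), grid)

    def test_planted_hit_rate_recovered(self):
        link = sd.PlantedLink("s", (-16.0, 0.0, 0.0), 7.0, (20.0, 26.0, 16.0), 0.0, 0.2)
        spec = sd.default_database_spec(seed=31, n_experiments=1000, planted_links=(link,))
        db = sd.gen_experiment_db(spec)
        retained = filter_by_seed(db.experiments, spec.seed_mask("s"), spec.grid)
        # 99% binomial interval around 1000 x 0.2, widened by the chance-hit
        # rate of ~3 background foci against the seed/mask volume ratio
        p_chance = 1 - (1 - spec.seed_mask("s").sum() / spec.background_mask().sum()) ** 3
        lo = 200 - 2.576 * np.sqrt(1000 * 0.2 * 0.8)
        hi = 200 + 2.576 * np.sqrt(1000 * 0.2 * 0.8) + 1000 * p_chance
        assert lo <= len(retained) <= hi


class TestMaMap:
    def test_peak_one_at_focus_and_half_at_half_fwhm(self):
        grid = Grid.isotropic((41, 41, 41), origin_mm=(-20.0, -20.0, -20.0))
        fwhm_fn = lambda n: 10.0
        m = ma_map(exp("a", [[0.0, 0.0, 0.0]]), grid, fwhm_fn)
        assert m.values[20, 20, 20] == pytest.approx(1.0)
        assert m.values[25, 20, 20] == pytest.approx(0.5, abs=1e-9)  # 5 mm = FWHM/2

    def test_coincident_foci_idempotent(self, grid):
        single = ma_map(exp("a", [[0.0, 0.0, 0.0]]), grid)
        double = ma_map(exp("b", [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]), grid)
        assert np.array_equal(single.values, double.values)

    def test_separated_foci_equal_voxelwise_max_of_singles(self, grid):
        f1, f2 = [0.0, 0.0, 0.0], [10.0, -6.0, 4.0]
        both = ma_map(exp("a", [f1, f2]), grid)
        m1 = ma_map(exp("a1", [f1]), grid)
        m2 = ma_map(exp("a2", [f2]), grid)
        assert np.allclose(both.values, np.maximum(m1.values, m2.values))

    def test_monotone_decay_from_single_focus(self, grid):
        m = ma_map(exp("a", [[0.0, 0.0, 0.0]]), grid)
        line = m.values[12:, 12, 12]
        assert np.all(np.diff(line) <= 1e-15)

    def test_kernel_mass_translation_invariant(self, grid):
        a = ma_map(exp("a", [[0.0, 0.0, 0.0]]), grid).values.sum()
        b = ma_map(exp("b", [[3.0, -2.0, 5.0]]), grid).values.sum()
        assert abs(a - b) / a < 0.01

    def test_focus_outside_grid_contributes_nothing(self, grid):
        m = ma_map(exp("a", [[500.0, 500.0, 500.0]]), grid)
        assert m.values.sum() == 0.0


class TestAleMap:
    def test_single_experiment_identity(self, grid):
        m = ma_map(exp("a", [[0.0, 0.0, 0.0]]), grid)
        assert np.allclose(ale_map([m]), m.values)

    def test_closed_form_union(self, grid):
        m1 = ma_map(exp("a", [[0.0, 0.0, 0.0]]), grid)
        m2 = ma_map(exp("b", [[0.0, 0.0, 0.0]]), grid)
        combined = ale_map([m1, m2])
        v = m1.values[12, 12, 12]
        assert combined[12, 12, 12] == pytest.approx(1 - (1 - v) ** 2)

    def test_matches_per_voxel_product_oracle(self, grid):
        rng = np.random.default_rng(5)
        mas = []
        for i in range(5):
            m = ma_map(exp(f"e{i}", rng.uniform(-15, 15, (3, 3))), grid)
            mas.append(m)
        combined = ale_map(mas)
        oracle = 1.0 - np.prod([1.0 - m.values for m in mas], axis=0)
        assert np.allclose(combined, oracle, atol=1e-12)

    def test_compute_ale_equals_explicit_ma_route(self, grid):
        rng = np.random.default_rng(11)
        exps = [
            exp(f"e{i}", rng.uniform(-18, 18, (rng.integers(1, 5), 3)),
                n=int(rng.integers(8, 30)))
            for i in range(12)
        ]
        direct = compute_ale(exps, grid)
        via_ma = ale_map([ma_map(e, grid) for e in exps])
        assert np.allclose(direct, via_ma, atol=1e-12)

    def test_ale_dominates_each_ma_and_is_monotone(self, grid):
        rng = np.random.default_rng(7)
        exps = [exp(f"e{i}", rng.uniform(-15, 15, (2, 3))) for i in range(4)]
        ale4 = compute_ale(exps, grid)
        for e in exps:
            assert np.all(ale4 >= ma_map(e, grid).values - 1e-12)
        ale5 = compute_ale(exps + [exp("x", rng.uniform(-15, 15, (2, 3)))], grid)
        assert np.all(ale5 >= ale4 - 1e-12)


@pytest.fixture(scope="module")
def setup():
    spec = sd.default_database_spec(seed=19, n_experiments=300)
    db = sd.gen_experiment_db(spec)
    subset = filter_by_seed(db.experiments, spec.seed_mask("dentate"), spec.grid)
    return spec, subset


class TestSignificance:
    def test_seeded_run_is_deterministic(self, setup):
        spec, subset = setup
        kw = dict(n_null=100, seed=5)
        r1 = significance(subset, spec.grid, spec.background_mask(), **kw)
        r2 = significance(subset, spec.grid, spec.background_mask(), **kw)
        assert r1.clusters.equals(r2.clusters)
        assert np.array_equal(r1.voxel_p, r2.voxel_p)

    def test_recovers_planted_target(self, setup):
        spec, subset = setup
        res = significance(subset, spec.grid, spec.background_mask(), n_null=100, seed=5)
        sig = res.clusters[res.clusters.significant]
        peaks = sig[["peak_x", "peak_y", "peak_z"]].to_numpy()
        target = np.array([20.0, 26.0, 16.0])
        assert (np.linalg.norm(peaks - target, axis=1) <= 6.0).any()

    def test_refuses_empty_input_and_small_null(self, setup):
        spec, subset = setup
        with pytest.raises(NoExperimentsError):
            significance([], spec.grid, spec.background_mask(), n_null=100, seed=1)
        with pytest.raises(ValueError, match="n_null"):
            significance(subset, spec.grid, spec.background_mask(), n_null=10, seed=1)

    def test_mask_smaller_than_kernel_rejected(self, setup):
        spec, subset = setup
        tiny = np.zeros(spec.grid.shape, bool)
        tiny[20, 24, 18] = True
        with pytest.raises(ValueError, match="kernel support"):
            significance(subset, spec.grid, tiny, n_null=100, seed=1)


class TestContrast:
    def test_identical_sets_yield_no_significant_voxels(self, grid):
        rng = np.random.default_rng(3)
        exps = [exp(f"e{i}", rng.uniform(-15, 15, (2, 3))) for i in range(6)]
        res = contrast(exps, list(exps), grid, n_perm=100, seed=2)
        assert np.all(res.diff == 0)
        assert len(res.clusters_a_gt_b) == 0
        assert len(res.clusters_b_gt_a) == 0

    def test_swapping_inputs_swaps_maps_exactly(self, grid):
        rng = np.random.default_rng(9)
        a = [exp(f"a{i}", rng.uniform(-15, 15, (2, 3))) for i in range(5)]
        b = [exp(f"b{i}", rng.uniform(-15, 15, (2, 3))) for i in range(5)]
        r1 = contrast(a, b, grid, n_perm=60, seed=4)
        r2 = contrast(b, a, grid, n_perm=60, seed=4)
        assert np.allclose(r1.diff, -r2.diff)
        assert np.array_equal(r1.p_a_gt_b, r2.p_b_gt_a)
        assert np.array_equal(r1.p_b_gt_a, r2.p_a_gt_b)
        assert r1.clusters_a_gt_b.equals(r2.clusters_b_gt_a)


class TestDatabaseIo:
    def test_tsv_round_trip(self, tmp_path):
        db = sd.gen_experiment_db(sd.default_database_spec(seed=2, n_experiments=25))
        path = tmp_path / "db.tsv"
        write_experiments(path, db.experiments)
        back = read_experiments(path)
        assert len(back) == 25
        for orig, re_read in zip(db.experiments, back):
            assert orig.experiment_id == re_read.experiment_id
            assert np.allclose(orig.foci, re_read.foci)
            assert orig.domains == re_read.domains
            assert orig.n_subjects == re_read.n_subjects
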