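"""Agreement metrics: DSC, surface Dice, percentile Hausdorff, MDA."""

import numpy as np
import pytest

from contour_iov import (
    BinaryMask,
    EmptyMaskError,
    ObserverSet,
    ToleranceConfig,
    VoxelGrid,
    CaseStudy,
    compute_case_metrics,
    dice,
    directed_percentile_hd,
    extract_surface,
    mean_distance_to_agreement,
    nearest_surface_distances,
    surface_dice,
)
from contour_iov.synthetic import ObserverModel, simulate_observer

from conftest import brute_force_nearest, random_mask, sphere_mask

G48 = VoxelGrid((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (48, 48, 48))
G64 = VoxelGrid((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (64, 64, 64))
VOXEL_DIAG = np.sqrt(3.0)


def single_voxel(grid, idx):
    occ = np.zeros(grid.shape, dtype=bool)
    occ[idx] = True
    return BinaryMask(grid=grid, occupancy=occ)


class TestNearestSurfaceDistances:
    def test_set_vs_itself_is_zero(self, iso_grid):
        s = extract_surface(random_mask(iso_grid, 0))
        np.testing.assert_allclose(nearest_surface_distances(s, s), 0.0)

    def test_two_voxels_ten_mm_apart(self):
        g = VoxelGrid((0, 0, 0), (1, 1, 1), (15, 5, 5))
        a, b = single_voxel(g, (1, 2, 2)), single_voxel(g, (11, 2, 2))
        d = nearest_surface_distances(extract_surface(a), extract_surface(b))
        # facing faces are 10 - 2*(0.5) = 9 mm apart
        assert d.min() == pytest.approx(9.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        g = VoxelGrid((1.0, 0.0, -2.0), (1.0, 1.25, 3.0), (9, 8, 7))
        a, b = random_mask(g, seed, p=0.3), random_mask(g, 1000 + seed, p=0.3)
        sa, sb = extract_surface(a), extract_surface(b)
        fast = nearest_surface_distances(sa, sb)
        np.testing.assert_allclose(fast, brute_force_nearest(sa.centers, sb.centers), atol=1e-6)


class TestDice:
    def test_identity_disjoint_and_undefined(self, iso_grid):
        m = random_mask(iso_grid, 1)
        assert dice(m, m) == 1.0
        a, b = single_voxel(iso_grid, (0, 0, 0)), single_voxel(iso_grid, (5, 5, 5))
        assert dice(a, b) == 0.0
        empty = BinaryMask(grid=iso_grid, occupancy=np.zeros(iso_grid.shape, bool))
        with pytest.raises(EmptyMaskError):
            dice(empty, empty)

    def test_nested_spheres_match_analytic_ratio(self):
        g = VoxelGrid((0, 0, 0), (1, 1, 1), (56, 56, 56))
        a, b = sphere_mask(g, 20.0), sphere_mask(g, 25.0)
        analytic = 2 * 20.0**3 / (20.0**3 + 25.0**3)
        assert dice(a, b) == pytest.approx(analytic, abs=0.01)

    def test_nested_masks_exact_formula_and_symmetry(self, iso_grid):
        small = random_mask(iso_grid, 5, p=0.2)
        big = BinaryMask(grid=iso_grid, occupancy=small.occupancy | random_mask(iso_grid, 6, p=0.3).occupancy)
        expected = 2 * small.voxel_count / (small.voxel_count + big.voxel_count)
        assert dice(small, big) == pytest.approx(expected)
        assert dice(small, big) == dice(big, small)


class TestSurfaceDice:
    def test_identity_is_one(self, iso_grid):
        m = random_mask(iso_grid, 2)
        assert surface_dice(m, m) == 1.0

    def test_two_mm_offset_within_three_mm_tolerance(self):
        a = sphere_mask(G48, 15.0)
        b = simulate_observer(a, ObserverModel(offset=(2.0, 0.0, 0.0)), draw_seed=0)
        assert surface_dice(a, b, ToleranceConfig(sdsc_tolerance=3.0)) == pytest.approx(1.0, abs=0.02)

    def test_large_offset_is_strictly_below_one_and_matches_oracle(self):
        a = sphere_mask(G64, 15.0)
        b = simulate_observer(a, ObserverModel(offset=(10.0, 0.0, 0.0)), draw_seed=0)
        cfg = ToleranceConfig(sdsc_tolerance=3.0)
        val = surface_dice(a, b, cfg)
        assert val < 1.0
        sa, sb = extract_surface(a), extract_surface(b)
        d_ab = brute_force_nearest(sa.centers, sb.centers)
        d_ba = brute_force_nearest(sb.centers, sa.centers)
        oracle = (sa.areas[d_ab <= 3.0].sum() + sb.areas[d_ba <= 3.0].sum()) / (
            sa.total_area + sb.total_area
        )
        assert val == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_and_monotone_in_tolerance(self, iso_grid):
        a, b = random_mask(iso_grid, 7, p=0.3), random_mask(iso_grid, 8, p=0.3)
        assert surface_dice(a, b) == pytest.approx(surface_dice(b, a))
        values = [
            surface_dice(a, b, ToleranceConfig(sdsc_tolerance=t)) for t in (0.0, 1.0, 3.0, 5.0, 10.0)
        ]
        assert all(v1 <= v2 + 1e-12 for v1, v2 in zip(values, values[1:]))
        assert values[-1] == pytest.approx(1.0)  # tolerance beyond grid extent


class TestPercentileHausdorff:
    def test_identity_is_zero_at_any_percentile(self, iso_grid):
        m = random_mask(iso_grid, 3)
        for pct in (50.0, 98.0, 100.0):
            assert directed_percentile_hd(m, m, ToleranceConfig(hd_percentile=pct)) == 0.0

    @pytest.mark.parametrize("t", [2.0, 5.0, 10.0])
    def test_translated_spheres_hd100_equals_offset(self, t):
        a = sphere_mask(G64, 15.0)
        b = simulate_observer(a, ObserverModel(offset=(t, 0.0, 0.0)), draw_seed=0)
        hd100 = directed_percentile_hd(b, a, ToleranceConfig(hd_percentile=100.0))
        assert hd100 == pytest.approx(t, abs=VOXEL_DIAG)
        hd98 = directed_percentile_hd(b, a, ToleranceConfig(hd_percentile=98.0))
        assert hd98 <= hd100 + 1e-12

    def test_directed_hd_is_asymmetric_for_nested_masks(self):
        g = VoxelGrid((0, 0, 0), (1, 1, 1), (40, 40, 40))
        small, big = sphere_mask(g, 5.0), sphere_mask(g, 15.0)
        cfg = ToleranceConfig(hd_percentile=100.0)
        assert directed_percentile_hd(small, big, cfg) > 5.0
        assert directed_percentile_hd(small, big, cfg) != pytest.approx(
            directed_percentile_hd(big, small, cfg)
        )
        symmetric = directed_percentile_hd(small, big, cfg, symmetric=True)
        assert symmetric == max(
            directed_percentile_hd(small, big, cfg), directed_percentile_hd(big, small, cfg)
        )


class TestMeanDistanceToAgreement:
    def test_identity_is_zero(self, iso_grid):
        m = random_mask(iso_grid, 4)
        assert mean_distance_to_agreement(m, m) == (0.0, 0.0)

    def test_one_voxel_dilation_gives_about_one_mm(self):
        g = VoxelGrid((0, 0, 0), (1, 1, 1), (40, 40, 40))
        a = sphere_mask(g, 10.0)
        b = simulate_observer(a, ObserverModel(systematic_margin=1.0), draw_seed=0)
        mean, _sd = mean_distance_to_agreement(b, a)
        assert mean == pytest.approx(1.0, abs=0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_mean_and_population_sd(self, iso_grid, seed):
        a, b = random_mask(iso_grid, 20 + seed, p=0.3), random_mask(iso_grid, 40 + seed, p=0.3)
        mean, sd = mean_distance_to_agreement(a, b)
        d = brute_force_nearest(extract_surface(a).centers, extract_surface(b).centers)
        assert mean == pytest.approx(d.mean(), abs=1e-6)
        assert sd == pytest.approx(d.std(), abs=1e-6)  # divisor n


class TestTranslationInvariance:
    def test_metrics_invariant_under_joint_voxel_shift(self):
        g = VoxelGrid((0, 0, 0), (1, 1, 1), (20, 20, 20))
        a, b = random_mask(g, 9, p=0.3), random_mask(g, 10, p=0.3)
        shift = (2, 1, 3)
        # masks are kept away from the border so the roll is a true translation
        for m in (a, b):
            m.occupancy[:4] = m.occupancy[-4:] = False
            m.occupancy[:, :4] = m.occupancy[:, -4:] = False
            m.occupancy[:, :, :4] = m.occupancy[:, :, -4:] = False
        a2 = BinaryMask(grid=g, occupancy=np.roll(a.occupancy, shift, axis=(0, 1, 2)))
        b2 = BinaryMask(grid=g, occupancy=np.roll(b.occupancy, shift, axis=(0, 1, 2)))
        assert dice(a, b) == pytest.approx(dice(a2, b2))
        assert surface_dice(a, b) == pytest.approx(surface_dice(a2, b2))
        assert directed_percentile_hd(a, b) == pytest.approx(directed_percentile_hd(a2, b2))
        assert mean_distance_to_agreement(a, b)[0] == pytest.approx(
            mean_distance_to_agreement(a2, b2)[0]
        )


class TestComputeCaseMetrics:
    @staticmethod
    def _case(groups):
        return CaseStudy(case_id="c", groups=groups)

    def test_identical_observers_are_perfect(self, iso_grid):
        m = random_mask(iso_grid, 11)
        s = ObserverSet(masks=[m, m, m], observer_ids=["a", "b", "c"], group="RAD")
        records = compute_case_metrics(self._case({"RAD": s}))
        assert len(records) == 3
        for r in records:
            assert r.dsc == 1.0 and r.sdsc == 1.0
            assert r.hd98 == 0.0 and r.mda_mean == 0.0

    def test_single_observer_group_scores_one_against_itself(self, iso_grid):
        m = random_mask(iso_grid, 12)
        s = ObserverSet(masks=[m], observer_ids=["solo"], group="GTV-")
        (rec,) = compute_case_metrics(self._case({"GTV-": s}))
        assert rec.dsc == 1.0

    def test_low_noise_group_beats_high_noise_group(self):
        truth = sphere_mask(G48, 14.0)
        groups = {}
        for label, sd_mm, seed0 in (("GTV+", 1.0, 0), ("GTV-", 4.0, 50)):
            model = ObserverModel(boundary_noise_sd=sd_mm, seed=7)
            masks = [simulate_observer(truth, model, draw_seed=seed0 + i) for i in range(5)]
            groups[label] = ObserverSet(
                masks=masks, observer_ids=[f"{label}{i}" for i in range(5)], group=label
            )
        records = compute_case_metrics(self._case(groups))
        med = lambda lab, attr: np.median([getattr(r, attr) for r in records if r.group == lab])
        assert med("GTV+", "dsc") > med("GTV-", "dsc")
        assert med("GTV+", "sdsc") > med("GTV-", "sdsc")
        assert med("GTV+", "hd98") < med("GTV-", "hd98")
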