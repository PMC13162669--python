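"""Spatial metrics: oracle equivalence, worked geometries, and invariances."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from immunoprox import (
    Phenotype,
    ProximityConfig,
    aggregate_patient_iv,
    count_cd8_within,
    distance_profile,
    interaction_variable,
    median_nn_distance,
    nearest_neighbor_distances,
    radius_sensitivity,
)
from immunoprox.spatial import InsufficientDataError

from conftest import (
    brute_force_count_within,
    brute_force_nn,
    make_region,
    random_region,
)


class TestNearestNeighborDistances:
    def test_three_four_five_triangle(self):
        region = make_region(tam_xy=[(0, 0)], cd8_xy=[(3, 4), (10, 0)])
        d = nearest_neighbor_distances(region, Phenotype.PDL1_TAM, Phenotype.CD8_T)
        assert d.tolist() == [5.0]

    def test_no_targets_gives_undefined(self):
        region = make_region(tam_xy=[(1, 1), (2, 2)])
        d = nearest_neighbor_distances(region, Phenotype.PDL1_TAM, Phenotype.CD8_T)
        assert np.isnan(d).all() and d.size == 2

    def test_directionality(self):
        region = make_region(tam_xy=[(0, 0), (100, 0)], cd8_xy=[(10, 0)])
        d_tam = nearest_neighbor_distances(region, Phenotype.PDL1_TAM, Phenotype.CD8_T)
        d_cd8 = nearest_neighbor_distances(region, Phenotype.CD8_T, Phenotype.PDL1_TAM)
        assert d_tam.tolist() == [10.0, 90.0]
        assert d_cd8.tolist() == [10.0]

    def test_matches_brute_force_exactly(self, rng):
        for _ in range(20):
            region = random_region(rng, int(rng.integers(1, 60)),
                                   int(rng.integers(1, 140)), 30)
            fast = nearest_neighbor_distances(region, Phenotype.CD8_T,
                                              Phenotype.PDL1_TAM)
            brute = brute_force_nn(region.coordinates(Phenotype.CD8_T),
                                   region.coordinates(Phenotype.PDL1_TAM))
            np.testing.assert_array_equal(fast, brute)

    def test_unknown_phenotype_rejected(self):
        region = make_region(tam_xy=[(0, 0)])
        with pytest.raises(ValueError):
            nearest_neighbor_distances(region, "TAM", Phenotype.CD8_T)


class TestMedianNNDistance:
    @pytest.mark.parametrize("values, expected", [
        ([5, 13, 40], 13.0),
        ([10, 20], 15.0),
        ([7, float("nan"), 9, float("nan")], 8.0),
    ])
    def test_median_conventions(self, values, expected):
        assert median_nn_distance(values) == expected

    def test_all_undefined(self):
        assert math.isnan(median_nn_distance([float("nan")]))
        assert math.isnan(median_nn_distance([]))


class TestCountWithin:
    def test_worked_geometry(self):
        # (60,0) is 40 from its nearest TAM, (100,30) is 30: both outside 25
        region = make_region(
            tam_xy=[(0, 0), (100, 0)],
            cd8_xy=[(0, 20), (0, 24), (60, 0), (100, 30)],
        )
        assert count_cd8_within(region, 25.0) == 2

    def test_boundary_inclusive_convention(self):
        region = make_region(tam_xy=[(0, 0)], cd8_xy=[(0, 25)], width=50, height=50)
        assert count_cd8_within(region, 25.0, boundary_inclusive=True) == 1
        assert count_cd8_within(region, 25.0, boundary_inclusive=False) == 0

    def test_cd8_near_several_tams_counts_once(self):
        region = make_region(tam_xy=[(0, 0), (5, 0), (0, 5)], cd8_xy=[(2, 2)])
        assert count_cd8_within(region, 25.0) == 1

    def test_matches_brute_force_exactly(self, rng):
        for _ in range(20):
            region = random_region(rng, int(rng.integers(1, 50)),
                                   int(rng.integers(1, 120)))
            r = float(rng.uniform(5, 60))
            assert count_cd8_within(region, r) == brute_force_count_within(
                region.coordinates(Phenotype.CD8_T),
                region.coordinates(Phenotype.PDL1_TAM), r)


class TestInteractionVariable:
    def test_all_within(self, rng):
        pts = rng.uniform(0, 10, size=(10, 2))
        region = make_region(tam_xy=pts, cd8_xy=pts + 0.1, width=20, height=20)
        res = interaction_variable(region)
        assert res.iv == pytest.approx(50.0)

    def test_worked_geometry_value(self):
        region = make_region(
            tam_xy=[(0, 0), (100, 0)],
            cd8_xy=[(0, 20), (0, 24), (60, 0), (100, 30)],
        )
        res = interaction_variable(region)
        assert res.n_cd8_within == 2
        assert res.iv == pytest.approx(100 * 2 / 6)

    def test_no_cd8_gives_defined_zero(self):
        region = make_region(tam_xy=[(i * 10.0, 0) for i in range(5)])
        res = interaction_variable(region)
        assert res.iv == 0.0 and res.defined

    def test_no_tam_with_cd8_gives_zero(self):
        region = make_region(cd8_xy=[(1, 1), (2, 2)])
        res = interaction_variable(region)
        assert res.iv == 0.0 and res.defined

    def test_empty_phenotypes_undefined_not_zero(self):
        region = make_region(other_xy=[(1, 1)])
        res = interaction_variable(region)
        assert not res.defined and math.isnan(res.iv)

    def test_rigid_motion_invariance(self, rng):
        region = random_region(rng, 20, 40, width=100, height=100)
        theta, tx, ty = 0.7, 40.0, 25.0
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        tam = region.coordinates(Phenotype.PDL1_TAM) @ R.T + (tx, ty)
        cd8 = region.coordinates(Phenotype.CD8_T) @ R.T + (tx, ty)
        moved = make_region(tam_xy=tam, cd8_xy=cd8, width=400, height=400)
        a = interaction_variable(region)
        b = interaction_variable(moved)
        assert a.n_cd8_within == b.n_cd8_within
        da = nearest_neighbor_distances(region, Phenotype.CD8_T, Phenotype.PDL1_TAM)
        db = nearest_neighbor_distances(moved, Phenotype.CD8_T, Phenotype.PDL1_TAM)
        np.testing.assert_allclose(da, db, atol=1e-9)

    def test_density_decoupling(self, rng):
        """Extra bystander cells and duplicated phenotype cells leave iv fixed."""
        region = random_region(rng, 15, 30, n_other=0)
        diluted = make_region(
            tam_xy=region.coordinates(Phenotype.PDL1_TAM),
            cd8_xy=region.coordinates(Phenotype.CD8_T),
            other_xy=rng.uniform(0, 200, size=(200, 2)),
        )
        assert interaction_variable(diluted).iv == interaction_variable(region).iv
        tam = region.coordinates(Phenotype.PDL1_TAM)
        cd8 = region.coordinates(Phenotype.CD8_T)
        doubled = make_region(tam_xy=np.vstack([tam, tam]),
                              cd8_xy=np.vstack([cd8, cd8]))
        assert interaction_variable(doubled).iv == \
            pytest.approx(interaction_variable(region).iv)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds_and_radius_monotonicity(self, seed):
        """iv lies in [0,100] and is nondecreasing in the radius."""
        r = np.random.default_rng(seed)
        region = random_region(r, int(r.integers(0, 25)), int(r.integers(0, 50)))
        ivs = []
        for radius in (5.0, 15.0, 25.0, 50.0, 1e6):
            res = interaction_variable(region, radius=radius)
            if res.defined:
                assert 0.0 <= res.iv <= 100.0
            ivs.append(res.iv)
        defined = [v for v in ivs if not math.isnan(v)]
        assert all(a <= b + 1e-12 for a, b in zip(defined, defined[1:]))
        n_cd8 = region.count(Phenotype.CD8_T)
        n_tam = region.count(Phenotype.PDL1_TAM)
        if n_tam > 0:
            assert ivs[-1] == pytest.approx(100 * n_cd8 / (n_cd8 + n_tam))


class TestDistanceProfile:
    def test_direct_binning(self):
        region = make_region(tam_xy=[(0, 0)], cd8_xy=[(0, 3), (0, 7), (0, 12)],
                             width=50, height=50)
        prof = distance_profile(region)
        assert prof.per_bin_counts[:3].tolist() == [1, 1, 1]
        assert prof.per_bin_counts[3:].sum() == 0
        np.testing.assert_allclose(prof.cumulative_proportions[:3],
                                   [1 / 3, 2 / 3, 1.0])

    def test_half_open_bins(self):
        region = make_region(tam_xy=[(0, 0)], cd8_xy=[(0, 5)], width=50, height=50)
        prof = distance_profile(region)
        assert prof.per_bin_counts[0] == 0 and prof.per_bin_counts[1] == 1

    def test_zero_tams(self):
        region = make_region(cd8_xy=[(1, 1)])
        prof = distance_profile(region)
        assert prof.per_bin_counts.sum() == 0
        assert math.isnan(prof.median_nn_distance)

    def test_counts_sum_to_cd8_within_max_distance(self, rng):
        region = random_region(rng, 10, 80, width=400, height=400)
        prof = distance_profile(region)
        d = nearest_neighbor_distances(region, Phenotype.CD8_T, Phenotype.PDL1_TAM)
        assert prof.per_bin_counts.sum() == int((d < 100.0).sum())
        assert np.all(np.diff(prof.cumulative_proportions) >= 0)
        assert prof.cumulative_proportions[-1] <= 1.0


class TestPatientAggregation:
    def _two_region_patient(self):
        # region A: 2 of (2 cd8-within / denom 6); region B: 4 within, denom 14
        ra = make_region(tam_xy=[(0, 0), (100, 0)],
                         cd8_xy=[(0, 20), (0, 24), (60, 0), (100, 30)],
                         region_id="RA")
        rb = make_region(
            tam_xy=[(0, 0), (50, 50), (100, 100), (150, 150)],
            cd8_xy=[(0, 5), (0, 10), (50, 55), (100, 95),
                    (0, 90), (60, 120), (190, 20), (190, 40), (190, 60), (190, 80)],
            region_id="RB")
        assert interaction_variable(rb).n_cd8_within == 4
        return ra, rb

    def test_pooled_arithmetic(self):
        ra, rb = self._two_region_patient()
        res = aggregate_patient_iv([ra, rb])
        assert res.iv == pytest.approx(100 * 6 / 20)

    def test_mean_of_region_scores(self):
        ra, rb = self._two_region_patient()
        res = aggregate_patient_iv([ra, rb], method="mean")
        assert res.iv == pytest.approx((100 * 2 / 6 + 100 * 4 / 14) / 2)

    def test_single_region_identity(self):
        ra, _ = self._two_region_patient()
        iv = interaction_variable(ra).iv
        assert aggregate_patient_iv([ra]).iv == pytest.approx(iv)
        assert aggregate_patient_iv([ra], method="mean").iv == pytest.approx(iv)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient_iv([])

    def test_mixed_patients_rejected(self):
        ra, _ = self._two_region_patient()
        rb = make_region(tam_xy=[(0, 0)], patient_id="P2", region_id="RX")
        with pytest.raises(ValueError):
            aggregate_patient_iv([ra, rb])


class TestRadiusSensitivity:
    def test_coincident_points_give_rho_one(self):
        regions = []
        for i in range(6):
            pts = [(float(10 * i + 1), 1.0)] * (i + 1)
            regions.append(make_region(tam_xy=[(float(10 * i + 1), 1.0)],
                                       cd8_xy=pts, region_id=f"R{i}"))
        res = radius_sensitivity(regions)
        for r in (15.0, 30.0, 50.0):
            assert res.rho[r] == pytest.approx(1.0)

    def test_constant_column_flagged_nan(self):
        # all regions identical -> zero variance at every radius
        regions = [
            make_region(tam_xy=[(0, 0)], cd8_xy=[(0, 10)], region_id=f"R{i}")
            for i in range(4)
        ]
        res = radius_sensitivity(regions)
        assert math.isnan(res.rho[15.0])

    def test_insufficient_units_rejected(self):
        regions = [make_region(tam_xy=[(0, 0)], cd8_xy=[(0, 10)], region_id="R0"),
                   make_region(other_xy=[(1, 1)], region_id="R1")]
        with pytest.raises(InsufficientDataError):
            radius_sensitivity(regions)
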