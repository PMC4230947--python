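"""Voxel-wise GLM, thresholding, permutation FWE and map regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qmrivox.geometry import Grid
from qmrivox.voxelstats import (DesignInfo, StatMap, edss_slope_map,
                                glm_group_contrast, map_regression,
                                permutation_fwe_svc, threshold_map)

GRID = Grid.isotropic((5, 5, 4), 2.0)
MASK = np.ones(GRID.shape, dtype=bool)


def _design(n_ref=4, n_pat=4, seed=0, edss=False):
    rng = np.random.default_rng(seed)
    n = n_ref + n_pat
    ids = [f"s{i}" for i in range(n)]
    group = np.array([0.0] * n_ref + [1.0] * n_pat)
    age = rng.uniform(30.0, 60.0, n)
    e = None
    if edss:
        e = rng.uniform(1.0, 8.0, n)
    return DesignInfo(ids, group, age, e)


def _cohort_maps(design, rng, shift_patients=0.0):
    maps = []
    for g in design.group:
        vol = rng.normal(size=GRID.shape)
        if g == 1.0:
            vol = vol - shift_patients  # patients lower
        maps.append(vol)
    return maps


class TestDesign:
    def test_from_frame_requires_columns(self):
        frame = pd.DataFrame({"id": ["a"], "group": ["patient"]})
        with pytest.raises(ValueError, match="age"):
            DesignInfo.from_frame(frame)

    def test_from_frame_codes_patients_as_one(self):
        frame = pd.DataFrame({"id": ["a", "b"], "group": ["patient", "reference"],
                              "age": [50.0, 52.0]})
        d = DesignInfo.from_frame(frame)
        assert list(d.group) == [1.0, 0.0]

    def test_collinear_design_rejected(self):
        d = _design()
        d.age = d.group * 10.0 + 30.0  # age duplicates group
        maps = [np.zeros(GRID.shape)] * d.n
        with pytest.raises(ValueError, match="collinear"):
            glm_group_contrast(maps, d, GRID, MASK)


class TestGroupContrast:
    def test_identical_groups_give_zero_t(self):
        d = _design()
        vol = np.random.default_rng(1).normal(size=GRID.shape)
        tmap = glm_group_contrast([vol.copy() for _ in range(d.n)], d, GRID, MASK)
        assert np.allclose(tmap.data, 0.0)
        assert tmap.df == d.n - 3

    def test_single_voxel_matches_normal_equation_oracle(self):
        d = _design(5, 5, seed=3)
        rng = np.random.default_rng(4)
        maps = _cohort_maps(d, rng, shift_patients=0.7)
        tmap = glm_group_contrast(maps, d, GRID, MASK)

        # independent oracle: explicit OLS at one voxel
        y = np.array([m[2, 3, 1] for m in maps])
        x = np.column_stack([np.ones(d.n), d.group, d.age - d.age.mean()])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        sigma2 = resid @ resid / (d.n - 3)
        c = np.array([0.0, -1.0, 0.0])  # positive = reference > patient
        se = np.sqrt(sigma2 * c @ np.linalg.inv(x.T @ x) @ c)
        assert tmap.data[2, 3, 1] == pytest.approx((c @ beta) / se, abs=1e-10)

    def test_positive_t_means_reference_above_patient(self):
        d = _design(6, 6, seed=5)
        maps = _cohort_maps(d, np.random.default_rng(6), shift_patients=3.0)
        tmap = glm_group_contrast(maps, d, GRID, MASK)
        assert tmap.data[MASK].mean() > 2.0

    def test_requires_two_subjects_per_group(self):
        d = _design(1, 4)
        with pytest.raises(ValueError):
            glm_group_contrast([np.zeros(GRID.shape)] * 5, d, GRID, MASK)

    def test_null_t_tail_matches_student_distribution(self):
        # calibration: iid normal data, 6+6 subjects -> df 9
        d = _design(6, 6, seed=7)
        big_grid = Grid.isotropic((30, 30, 22), 2.0)
        big_mask = np.ones(big_grid.shape, dtype=bool)
        rng = np.random.default_rng(8)
        maps = [rng.normal(size=big_grid.shape) for _ in range(d.n)]
        tmap = glm_group_contrast(maps, d, big_grid, big_mask)
        v = big_mask.sum()
        p_expected = stats.t.sf(2.0, d.n - 3)
        freq = float((tmap.data[big_mask] > 2.0).mean())
        tol = 3.0 * np.sqrt(p_expected * (1 - p_expected) / v)
        assert abs(freq - p_expected) < tol


class TestEdssSlope:
    def test_known_slope_recovered(self):
        d = _design(0, 8, seed=9, edss=True)
        rng = np.random.default_rng(10)
        maps = [rng.normal(scale=0.01, size=GRID.shape) + 0.5 * e
                for e in d.edss]
        slope_map, t_map = edss_slope_map(maps, d, GRID, MASK, return_t=True)
        assert np.allclose(slope_map.data[MASK], 0.5, atol=0.02)
        assert slope_map.kind == "slope"
        assert np.all(t_map.data[MASK] > 10.0)

    def test_missing_edss_rejected(self):
        d = _design(0, 6, edss=False)
        with pytest.raises(ValueError, match="EDSS"):
            edss_slope_map([np.zeros(GRID.shape)] * 6, d, GRID, MASK)

    def test_constant_edss_rejected(self):
        d = _design(0, 6, edss=True)
        d.edss = np.full(6, 4.0)
        with pytest.raises(ValueError, match="constant"):
            edss_slope_map([np.zeros(GRID.shape)] * 6, d, GRID, MASK)


class TestThreshold:
    def test_threshold_is_strict(self):
        data = np.zeros(GRID.shape)
        data[0, 0, 0] = 1.9
        data[0, 0, 1] = 2.0
        data[0, 0, 2] = 2.1
        sm = StatMap(data, "t", 9, "c", GRID, MASK)
        overlay = threshold_map(sm, 2.0)
        assert not overlay[0, 0, 0]
        assert not overlay[0, 0, 1]  # strictly greater than
        assert overlay[0, 0, 2]
        assert sm.threshold == 2.0

    def test_two_sided_uses_absolute_value(self):
        data = np.zeros(GRID.shape)
        data[0, 0, 0] = -3.0
        sm = StatMap(data, "t", 9, "c", GRID, MASK)
        assert not threshold_map(sm, 2.0)[0, 0, 0]
        assert threshold_map(sm, 2.0, two_sided=True)[0, 0, 0]

    def test_slope_map_rejected(self):
        sm = StatMap(np.zeros(GRID.shape), "slope", 9, "c", GRID, MASK)
        with pytest.raises(ValueError):
            threshold_map(sm, 2.0)


class TestPermutation:
    def _rois(self):
        roi_a = np.zeros(GRID.shape, dtype=bool)
        roi_a[:2] = True
        roi_b = np.zeros(GRID.shape, dtype=bool)
        roi_b[3:] = True
        return {"a": roi_a, "b": roi_b}

    def test_small_cohorts_enumerate_exhaustively(self):
        # 4+4 subjects: C(8,4) = 70 distinct assignments; the exact test
        # must not depend on the Monte-Carlo seed
        d = _design(4, 4, seed=11)
        maps = _cohort_maps(d, np.random.default_rng(12), shift_patients=1.0)
        r1 = permutation_fwe_svc(maps, d, GRID, MASK, self._rois(),
                                 n_perm=200, seed=1)
        r2 = permutation_fwe_svc(maps, d, GRID, MASK, self._rois(),
                                 n_perm=200, seed=999)
        assert np.array_equal(r1["p_uncorrected"], r2["p_uncorrected"])
        assert (r1["n_perm"] == 70).all()
        assert (r1["p_uncorrected"] >= 1.0 / 70).all()

    def test_bonferroni_over_rois(self):
        d = _design(4, 4, seed=11)
        maps = _cohort_maps(d, np.random.default_rng(12), shift_patients=1.0)
        res = permutation_fwe_svc(maps, d, GRID, MASK, self._rois(),
                                  n_perm=200, seed=1)
        expected = np.minimum(res["p_uncorrected"] * 2, 1.0)
        assert np.allclose(res["p_fwe"], expected)

    def test_monte_carlo_path_is_seed_deterministic(self):
        d = _design(10, 10, seed=13)
        maps = _cohort_maps(d, np.random.default_rng(14), shift_patients=0.5)
        r1 = permutation_fwe_svc(maps, d, GRID, MASK, self._rois(),
                                 n_perm=150, seed=3)
        r2 = permutation_fwe_svc(maps, d, GRID, MASK, self._rois(),
                                 n_perm=150, seed=3)
        assert np.array_equal(r1["p_uncorrected"], r2["p_uncorrected"])
        assert (r1["p_uncorrected"] > 0).all()

    def test_strong_effect_reaches_minimal_p(self):
        d = _design(6, 6, seed=15)
        maps = _cohort_maps(d, np.random.default_rng(16), shift_patients=5.0)
        res = permutation_fwe_svc(maps, d, GRID, MASK, self._rois(),
                                  n_perm=400, seed=2)
        assert (res["p_uncorrected"] <= 0.01).all()

    def test_roi_outside_mask_rejected(self):
        d = _design(4, 4)
        mask = MASK.copy()
        mask[0] = False
        roi = np.zeros(GRID.shape, dtype=bool)
        roi[0] = True
        with pytest.raises(ValueError, match="outside"):
            permutation_fwe_svc([np.zeros(GRID.shape)] * 8, d, GRID, mask,
                                {"bad": roi}, n_perm=100)

    def test_too_few_permutations_rejected(self):
        d = _design(4, 4)
        with pytest.raises(ValueError):
            permutation_fwe_svc([np.zeros(GRID.shape)] * 8, d, GRID, MASK,
                                self._rois(), n_perm=10)


class TestMapRegression:
    def test_proportional_maps_give_exact_slope_and_r2(self, rng):
        t = rng.normal(size=GRID.shape)
        tm = StatMap(t, "t", 9, "c", GRID, MASK)
        sm = StatMap(2.5 * t, "slope", 9, "c", GRID, MASK)
        slope, r2 = map_regression(tm, sm)
        assert slope == pytest.approx(2.5, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_independent_maps_give_low_r2(self, rng):
        tm = StatMap(rng.normal(size=GRID.shape), "t", 9, "c", GRID, MASK)
        sm = StatMap(rng.normal(size=GRID.shape), "slope", 9, "c", GRID, MASK)
        _, r2 = map_regression(tm, sm)
        assert r2 < 0.2

    def test_empty_mask_rejected(self, rng):
        tm = StatMap(rng.normal(size=GRID.shape), "t", 9, "c", GRID, MASK)
        sm = StatMap(rng.normal(size=GRID.shape), "slope", 9, "c", GRID, MASK)
        with pytest.raises(ValueError):
            map_regression(tm, sm, np.zeros(GRID.shape, dtype=bool))
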