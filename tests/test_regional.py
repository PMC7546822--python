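"""Regional statistics: normalization, residualization, permutation tests."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoperf import (
    ComparisonSpec,
    SimulationConfig,
    build_regional_table,
    compare_groups,
    normalize_to_whole_brain,
    permutation_test,
    quantify_subject,
    regionalize,
    residualize,
    simulate_cohort,
)
from neoperf.quantify import CBFMap


def brute_force_two_sided_p(values_a, values_b):
    """Independent enumeration oracle for the exhaustive permutation p.

    Uses plain python sums over itertools combinations and the same
    published tie rule (1e-12 relative tolerance on |T|).
    """
    pooled = list(values_a) + list(values_b)
    n, n_a = len(pooled), len(values_a)
    obs = sum(values_b) / len(values_b) - sum(values_a) / n_a
    threshold = abs(obs) - 1e-12 * (1.0 + abs(obs))
    count, total = 0, 0
    for combo in combinations(range(n), n_a):
        in_a = set(combo)
        a = [pooled[i] for i in range(n) if i in in_a]
        b = [pooled[i] for i in range(n) if i not in in_a]
        t = sum(b) / len(b) - sum(a) / len(a)
        if abs(t) >= threshold:
            count += 1
        total += 1
    return Fraction(count, total)


def _cbf_from_volume(volume, mask):
    return CBFMap(volume=np.where(mask, volume, np.nan), mask=mask)


class TestRegionalize:
    def test_constant_map_gives_constant_means(self, default_atlas):
        mask = default_atlas.brain_mask
        cbf = _cbf_from_volume(np.full(mask.shape, 3.0), mask)
        means = regionalize(cbf, default_atlas)
        assert all(v == pytest.approx(3.0) for v in means.values())

    def test_mean_of_region_voxels(self, default_atlas):
        mask = default_atlas.brain_mask
        volume = np.zeros(mask.shape)
        sel = default_atlas.region_mask(3)
        flat = np.flatnonzero(sel.ravel())
        values = np.zeros(sel.sum())
        values[0], values[1] = 1.0, 3.0
        volume.ravel()[flat] = values
        means = regionalize(_cbf_from_volume(volume, mask), default_atlas)
        assert means[3] == pytest.approx(values.mean())

    def test_fully_undefined_region_warns_nan(self, default_atlas):
        mask = default_atlas.brain_mask
        volume = np.ones(mask.shape)
        volume[default_atlas.region_mask(5)] = np.nan
        with pytest.warns(RuntimeWarning, match="region 5"):
            means = regionalize(_cbf_from_volume(volume, mask), default_atlas)
        assert np.isnan(means[5])


class TestNormalize:
    def test_uniform_map_normalizes_to_one(self, default_atlas):
        mask = default_atlas.brain_mask
        cbf = _cbf_from_volume(np.full(mask.shape, 17.0), mask)
        norm = normalize_to_whole_brain(regionalize(cbf, default_atlas), cbf)
        assert all(v == pytest.approx(1.0) for v in norm.values())

    def test_scale_invariance(self, default_atlas, rng):
        mask = default_atlas.brain_mask
        volume = rng.uniform(5, 40, size=mask.shape)
        cbf = _cbf_from_volume(volume, mask)
        scaled = _cbf_from_volume(7.3 * volume, mask)
        a = normalize_to_whole_brain(regionalize(cbf, default_atlas), cbf)
        b = normalize_to_whole_brain(regionalize(scaled, default_atlas), scaled)
        for rid in a:
            assert a[rid] == pytest.approx(b[rid], rel=1e-12)

    def test_nonpositive_whole_brain_mean_rejected(self, default_atlas):
        mask = default_atlas.brain_mask
        cbf = _cbf_from_volume(np.full(mask.shape, -1.0), mask)
        with pytest.raises(ValueError, match="positive"):
            normalize_to_whole_brain(regionalize(cbf, default_atlas), cbf)

    def test_voxel_weighted_mean_is_one(self, zero_noise_cohort):
        subjects, atlas = zero_noise_cohort
        counts = atlas.voxel_counts()
        total = sum(counts.values())
        for s in subjects:
            cbf = quantify_subject(s.asl, s.m0_image, s.t2_image)
            norm = normalize_to_whole_brain(regionalize(cbf, atlas), cbf)
            weighted = sum(counts[r] * norm[r] for r in norm) / total
            assert weighted == pytest.approx(1.0, abs=1e-9)


class TestResidualize:
    @staticmethod
    def _table(noise_sd=0.0, subject_cv=0.0, age_slope=0.02, sex_offset=0.1, n=16, seed=3):
        config = SimulationConfig(
            groups=(("control", n), ("hie_neg", 1), ("hie_pos", 1)),
            n_pairs=3,
            noise_sd=noise_sd,
            subject_cv=subject_cv,
            age_slope=age_slope,
            sex_offset=sex_offset,
            seed=seed,
        )
        subjects, atlas = simulate_cohort(config)
        cbf_maps = {
            s.subject_id: quantify_subject(s.asl, s.m0_image, s.t2_image)
            for s in subjects
        }
        demo = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "age_days": [s.age_days for s in subjects],
                "sex": [s.sex for s in subjects],
                "group": [s.group for s in subjects],
            }
        )
        return build_regional_table(cbf_maps, atlas, demo)

    def test_planted_age_effect_removed(self):
        # normalization makes the age effect mildly nonlinear, so a linear
        # fit removes most (not all) of the variance at a modest slope
        table = self._table(age_slope=0.01).query("group == 'control'").reset_index(drop=True)
        adjusted = residualize(table)
        region_cols = [c for c in table.columns
                       if c not in ("subject_id", "age_days", "sex", "group", "whole_brain_mean")]
        for col in region_cols:
            before = table[col].std(ddof=1)
            after = adjusted[col].std(ddof=1)
            if before > 1e-12:
                assert after < 0.10 * before, (col, before, after)
            # re-centering preserves the mean
            assert adjusted[col].mean() == pytest.approx(table[col].mean())

    def test_zero_effect_leaves_values_nearly_unchanged(self):
        table = self._table(age_slope=0.0, sex_offset=0.0).query("group == 'control'")
        adjusted = residualize(table.reset_index(drop=True))
        region_cols = [c for c in table.columns
                       if c not in ("subject_id", "age_days", "sex", "group", "whole_brain_mean")]
        for col in region_cols:
            np.testing.assert_allclose(adjusted[col], table[col], atol=1e-9)

    def test_adjust_disabled_is_identity(self):
        table = self._table(subject_cv=0.2)
        out = residualize(table, adjust_covariates=False)
        pd.testing.assert_frame_equal(out, table)

    def test_rank_deficient_design_warns(self):
        table = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "age_days": [5.0, 5.0, 5.0],
                "sex": ["M", "M", "M"],
                "group": ["g", "g", "g"],
                "whole_brain_mean": [1.0, 1.0, 1.0],
                "r": [1.0, 2.0, 3.0],
            }
        )
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            out = residualize(table)
        pd.testing.assert_frame_equal(out, table)


class TestPermutationTest:
    def test_separated_groups_exhaustive_p(self):
        result = permutation_test([1, 2, 3], [4, 5, 6])
        assert result.mode == "exhaustive"
        # only the identity and the fully swapped relabeling reach |T_obs|
        assert result.p_value == 2 / 20

    def test_identical_multisets_give_p_one(self):
        result = permutation_test([1, 2, 3, 4], [4, 3, 2, 1])
        assert result.p_value == 1.0

    def test_degenerate_constant_data(self):
        result = permutation_test([2.0] * 4, [2.0] * 5)
        assert result.p_value == 1.0

    def test_exhaustive_matches_brute_force(self, rng):
        for _ in range(25):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b) + rng.normal() * 0.5
            got = permutation_test(a, b)
            want = brute_force_two_sided_p(list(a), list(b))
            assert got.mode == "exhaustive"
            assert got.p_value == float(want)

    def test_monte_carlo_converges_to_exhaustive(self, rng):
        a = list(rng.normal(size=6))
        b = list(rng.normal(loc=1.0, size=6))
        exact = float(brute_force_two_sided_p(a, b))
        spec = ComparisonSpec(group_a="a", group_b="b", n_permutations=40000,
                              exhaustive_limit=10)  # force MC
        got = permutation_test(a, b, spec, rng=np.random.default_rng(17))
        se = np.sqrt(exact * (1 - exact) / 40000)
        assert abs(got.p_value - exact) <= 3 * se + 1 / 40000

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            permutation_test([1.0], [2.0, 3.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.01, 50.0),
        shift=st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, scale, shift):
        """p is unchanged by a common positive-scale affine transform."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=5)
        b = rng.normal(size=7) + 0.8
        base = permutation_test(a, b).p_value
        moved = permutation_test(scale * a + shift, scale * b + shift).p_value
        assert moved == pytest.approx(base, abs=1e-12)


class TestCompareGroups:
    @staticmethod
    def _toy_table(rng, n_a=8, n_b=8, shift_region=None, shift=0.0):
        rows = []
        for i in range(n_a + n_b):
            group = "control" if i < n_a else "hie_neg"
            row = {
                "subject_id": f"s{i}",
                "age_days": float(rng.uniform(1, 30)),
                "sex": "F" if rng.random() < 0.5 else "M",
                "group": group,
                "whole_brain_mean": 15.0,
            }
            for r in ("ra", "rb", "rc"):
                value = rng.normal(1.0, 0.1)
                if r == shift_region and group == "hie_neg":
                    value += shift
                row[r] = value
            rows.append(row)
        table = pd.DataFrame(rows)
        table.attrs["region_ids"] = {"ra": 1, "rb": 2, "rc": 3}
        return table

    def test_planted_shift_is_top_ranked(self, rng):
        table = self._toy_table(rng, shift_region="rb", shift=-0.5)
        spec = ComparisonSpec(group_a="control", group_b="hie_neg",
                              n_permutations=2000, seed=5)
        result = compare_groups(table, spec)
        assert result.iloc[0]["name"] == "rb"
        assert result.iloc[0]["significant"]
        assert result.iloc[0]["direction"] == "decreased"

    def test_single_subject_group_rejected(self, rng):
        table = self._toy_table(rng, n_a=1, n_b=8)
        spec = ComparisonSpec(group_a="control", group_b="hie_neg")
        with pytest.raises(ValueError, match=">= 2"):
            compare_groups(table, spec)

    def test_missing_group_rejected(self, rng):
        table = self._toy_table(rng)
        spec = ComparisonSpec(group_a="control", group_b="hie_pos")
        with pytest.raises(ValueError, match="not present"):
            compare_groups(table, spec)

    def test_pooled_group_b(self, rng):
        table = self._toy_table(rng)
        table.loc[table.index[-4:], "group"] = "hie_pos"
        spec = ComparisonSpec(group_a="control", group_b=("hie_neg", "hie_pos"),
                              n_permutations=500, seed=1)
        result = compare_groups(table, spec)
        assert len(result) == 3

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ComparisonSpec(group_a="control", group_b=("control", "hie_neg"))
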