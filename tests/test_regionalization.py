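"""PCA, varimax rotation, region assignment and factor scores."""

import numpy as np
import pytest

from cc_centile import (
    CCError, CCWarning, CohortWidths, GeneratorConfig, assign_regions,
    factor_scores, generate_cohort, pca, regionalize, retain_components,
    varimax,
)
from cc_centile.regionalization import contiguous_runs
from cc_centile.synthetic import designed_partition


def _cohort(matrix):
    n = len(matrix)
    return CohortWidths(matrix=matrix,
                        group=np.array(["case"] * (n // 2)
                                       + ["control"] * (n - n // 2)),
                        age=np.full(n, 5.0))


class TestPca:
    def test_rank_one_structure(self):
        rng = np.random.default_rng(0)
        subject = rng.normal(10, 2, size=(40, 1))
        X = subject + rng.normal(0, 1e-3, size=(40, 99))
        _, _, frac = pca(_cohort(X))
        assert frac[0] > 0.99

    def test_two_block_latents(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((2000, 1))
        b = rng.standard_normal((2000, 1))
        X = np.hstack([a.repeat(50, 1), b.repeat(49, 1)])
        X += 0.1 * rng.standard_normal(X.shape)
        _, _, frac = pca(_cohort(X))
        # block sizes 50/49 of 99 columns; finite-sample coupling between
        # the two latents shifts the split by a couple of percent
        assert 0.44 <= frac[0] <= 0.53 and 0.44 <= frac[1] <= 0.53
        assert np.all(frac[2:] < 0.02)

    def test_explained_fraction_sums_to_one(self):
        coh = generate_cohort(GeneratorConfig(seed=3))
        _, _, frac = pca(coh)
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_centile_errors(self):
        X = np.random.default_rng(0).normal(5, 1, (20, 99))
        X[:, 10] = 7.0
        with pytest.raises(CCError) as exc:
            pca(_cohort(X))
        assert exc.value.code == "constant-centile"


class TestRetainComponents:
    @pytest.mark.parametrize("fracs, expected", [
        ((0.60, 0.20, 0.011, 0.009, 0.002), 3),
        ((0.5, 0.5), 2),
        ((0.99, 0.01), 1),          # strict: exactly 1% not retained
    ])
    def test_threshold_rule(self, fracs, expected):
        assert retain_components(np.array(fracs)) == expected

    def test_nothing_retained_errors(self):
        with pytest.raises(CCError) as exc:
            retain_components(np.array([0.009, 0.005]))
        assert exc.value.code == "nothing-retained"


class TestVarimax:
    def test_single_factor_unchanged(self):
        L = np.random.default_rng(0).standard_normal((99, 1))
        assert np.allclose(varimax(L), L)

    def test_simple_structure_is_fixed_point(self):
        L = np.zeros((99, 3))
        L[:33, 0] = 0.9
        L[33:66, 1] = 0.9
        L[66:, 2] = 0.9
        R = varimax(L)
        # unchanged up to column order and sign
        match = np.abs(R.T @ L) / 0.81
        assert np.allclose(np.sort(match.max(axis=1)), [33, 33, 33])

    def test_recovers_45_degree_mixed_structure(self):
        L = np.zeros((99, 2))
        L[:50, 0] = 0.8
        L[50:, 1] = 0.8
        theta = np.pi / 4
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        mixed = L @ rot
        recovered = varimax(mixed)
        # each recovered column matches one original column up to sign
        sim = np.abs(recovered.T @ L)
        sim /= np.linalg.norm(recovered, axis=0)[:, None]
        sim /= np.linalg.norm(L, axis=0)[None, :]
        assert np.allclose(np.sort(sim.max(axis=0)), [1, 1], atol=1e-6)

    def test_communalities_preserved(self):
        coh = generate_cohort(GeneratorConfig(seed=2))
        vec, val, frac = pca(coh)
        k = retain_components(frac)
        L = vec[:, :k] * np.sqrt(val[:k])
        R = varimax(L)
        assert np.allclose((R ** 2).sum(axis=1), (L ** 2).sum(axis=1),
                           rtol=1e-10, atol=1e-12)


class TestAssignRegions:
    def test_block_structure_reproduced(self):
        L = np.zeros((99, 2))
        L[:40, 0] = 0.9
        L[40:, 1] = -0.9          # sign must not matter
        region = assign_regions(L)
        assert np.all(region[:40] == 1) and np.all(region[40:] == 2)

    def test_tie_goes_to_lower_index_with_warning(self):
        L = np.full((99, 3), 0.5)
        with pytest.warns(CCWarning, match="tie"):
            region = assign_regions(L)
        assert np.all(region == 1)

    def test_permutation_and_sign_invariance(self):
        rng = np.random.default_rng(4)
        L = rng.standard_normal((99, 4))
        base = assign_regions(L)
        perm = [2, 0, 3, 1]
        flipped = L[:, perm] * np.array([1, -1, 1, -1])
        remapped = np.array(perm)[assign_regions(flipped) - 1] + 1
        assert np.array_equal(remapped, base)

    def test_contiguous_runs_reporting(self):
        region = np.array([1] * 10 + [2] * 5 + [1] * 3)
        runs = contiguous_runs(region)
        assert runs[1] == [(1, 10), (16, 18)]
        assert runs[2] == [(11, 15)]


class TestFactorScores:
    def test_score_columns_have_mean_zero(self):
        coh = generate_cohort(GeneratorConfig(seed=5))
        rf = regionalize(coh)
        assert np.abs(rf.scores.mean(axis=0)).max() < 1e-10

    def test_thickened_subject_gets_top_regional_score(self):
        cfg = GeneratorConfig(seed=6, effects=())
        coh = generate_cohort(cfg)
        target = cfg.regions[3]                      # mid-posterior body
        coh.matrix[0, target.lo - 1:target.hi] += 4.0
        rf = regionalize(coh)
        des = designed_partition(cfg)
        overlap = [np.sum((rf.region_of_centile == j + 1) & (des == 3))
                   for j in range(rf.retained_k)]
        j4 = int(np.argmax(overlap))
        assert np.argmax(rf.scores[:, j4]) == 0

    def test_duplicated_subjects_get_identical_scores(self):
        coh = generate_cohort(GeneratorConfig(seed=7))
        dup = CohortWidths(matrix=np.vstack([coh.matrix, coh.matrix]),
                           group=np.concatenate([coh.group, coh.group]),
                           age=np.concatenate([coh.age, coh.age]))
        rf = regionalize(dup)
        n = len(coh.matrix)
        assert np.allclose(rf.scores[:n], rf.scores[n:], atol=1e-8)


class TestDefaultRecovery:
    def test_region_recovery_across_twenty_seeds(self):
        """Varimax regions recover >= 80% of the designed partition."""
        des = designed_partition(GeneratorConfig())
        for seed in range(1, 21):
            rf = regionalize(generate_cohort(GeneratorConfig(seed=seed)))
            agree = sum(
                np.unique(rf.region_of_centile[des == f],
                          return_counts=True)[1].max()
                for f in np.unique(des))
            assert agree / 99 >= 0.8

    def test_default_big_cohort_retains_seven_with_end_taper_flag(self):
        coh = generate_cohort(
            GeneratorConfig(n_case=100, n_control=100, seed=42))
        rf = regionalize(coh)
        assert rf.retained_k == 7
        assert len(rf.end_taper_factors) == 1
        assert len(rf.anatomical_factors) == 6
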