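"""Procrustes superimposition, shape PCA and permutation testing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cranioform import (
    CohortSpec,
    EffectSpec,
    LandmarkConfiguration,
    align_pair,
    centroid_size,
    desk_template,
    gpa,
    group_permutation_test,
    integrative_distance_pca,
    procrustes_distance,
    sample_cohort,
    shape_pca,
)
from cranioform.procrustes import ProcrustesError, _center_and_scale


def make_config(coords, specimen_id="s", group="g"):
    coords = np.asarray(coords, dtype=float)
    k = coords.shape[0]
    return LandmarkConfiguration(
        specimen_id=specimen_id, group=group, unit="cranium",
        landmark_names=tuple(f"L{i}" for i in range(k)),
        regions=tuple("r" for _ in range(k)), coords=coords,
    )


def oracle_min_distance(a, b, n_starts=60, seed=0):
    """Independent numeric minimization over rotations (rotvec parametrized)."""
    xa, _ = _center_and_scale(np.asarray(a, float))
    xb, _ = _center_and_scale(np.asarray(b, float))

    def cost(rotvec):
        return np.sum((xa - xb @ Rotation.from_rotvec(rotvec).as_matrix().T) ** 2)

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        start = rng.normal(size=3) * np.pi
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return np.sqrt(best)


class TestAlignPair:
    def test_identity_gives_zero_distance(self, template):
        c = make_config(template.coords)
        _, d = align_pair(c, c)
        assert d == 0.0

    def test_rigid_scaled_copy_gives_zero_distance(self, template, rng):
        rot = Rotation.random(rng=rng).as_matrix()
        moved = 3.7 * template.coords @ rot.T + np.array([5.0, -2.0, 1.0])
        _, d = align_pair(make_config(template.coords), make_config(moved))
        assert d < 1e-9

    def test_matches_brute_force_rotation_search(self, rng):
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        _, d = align_pair(make_config(a), make_config(b))
        assert d == pytest.approx(oracle_min_distance(a, b), abs=1e-6)

    def test_reflection_is_not_used(self, rng):
        """A mirrored configuration keeps a nonzero residual: chirality preserved."""
        a = rng.normal(size=(8, 3))
        mirrored = a * np.array([1.0, 1.0, -1.0])
        _, d = align_pair(make_config(a), make_config(mirrored))
        assert d > 1e-3

    def test_collinear_landmarks_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ProcrustesError, match="collinear"):
            align_pair(make_config(line), make_config(line))

    def test_landmark_order_mismatch_rejected(self, template):
        a = make_config(template.coords)
        b = LandmarkConfiguration(
            specimen_id="x", group="g", unit="cranium",
            landmark_names=tuple(reversed(a.landmark_names)),
            regions=a.regions, coords=a.coords,
        )
        with pytest.raises(ProcrustesError):
            align_pair(a, b)


class TestProcrustesDistanceMetric:
    @given(st.integers(0, 10_000))
    def test_metric_properties_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (rng.normal(size=(6, 3)) for _ in range(3))
        dab = procrustes_distance(a, b)
        dba = procrustes_distance(b, a)
        assert dab == pytest.approx(dba, abs=1e-9)  # symmetry
        assert procrustes_distance(a, a) == 0.0  # identity
        # triangle inequality
        assert dab <= procrustes_distance(a, c) + procrustes_distance(c, b) + 1e-9


class TestGpa:
    def test_rigid_copies_align_identically(self, template, rng):
        configs = []
        for i in range(6):
            rot = Rotation.random(rng=rng).as_matrix()
            moved = rng.uniform(0.5, 2.0) * template.coords @ rot.T + rng.normal(size=3)
            configs.append(make_config(moved, specimen_id=f"s{i}"))
        result = gpa(configs)
        for i in range(1, 6):
            np.testing.assert_allclose(result.aligned[i], result.aligned[0], atol=1e-8)

    def test_aligned_invariants(self, null_cohort):
        result = gpa(null_cohort)
        for i in range(result.n_specimens):
            assert np.abs(result.aligned[i].mean(axis=0)).max() < 1e-9
            assert centroid_size(result.aligned[i]) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            result.consensus, result.aligned.mean(axis=0), atol=1e-12
        )
        assert result.final_change < 1e-8

    def test_two_specimens_consensus_is_equidistant(self, template, rng):
        a = template.coords + rng.normal(size=template.coords.shape) * 0.3
        b = template.coords + rng.normal(size=template.coords.shape) * 0.3
        result = gpa([make_config(a, "a"), make_config(b, "b")])
        da = np.linalg.norm(result.aligned[0] - result.consensus)
        db = np.linalg.norm(result.aligned[1] - result.consensus)
        assert da == pytest.approx(db, abs=1e-9)

    def test_local_optimality_of_rotations(self, null_cohort, rng):
        """Perturbing any specimen's rotation cannot reduce total misfit."""
        result = gpa(null_cohort)
        base = np.sum((result.aligned - result.consensus) ** 2)
        for _ in range(100):
            i = int(rng.integers(result.n_specimens))
            perturb = Rotation.from_rotvec(rng.normal(size=3) * 0.05).as_matrix()
            perturbed = result.aligned.copy()
            perturbed[i] = perturbed[i] @ perturb
            assert np.sum((perturbed - result.consensus) ** 2) >= base - 1e-12

    def test_invariant_to_per_specimen_rigid_motion_and_scale(self, null_cohort, rng):
        moved = []
        for c in null_cohort.configurations:
            rot = Rotation.random(rng=rng).as_matrix()
            coords = rng.uniform(0.2, 5.0) * c.coords @ rot.T + rng.normal(size=3) * 10
            moved.append(make_config(coords, c.specimen_id, c.group))
        a = gpa(null_cohort)
        b = gpa(moved)
        assert procrustes_distance(a.consensus, b.consensus) < 1e-6
        # inter-specimen residual geometry is unchanged
        for i in (0, 5, 12):
            for j in (3, 9):
                da = np.linalg.norm(a.aligned[i] - a.aligned[j])
                db = np.linalg.norm(b.aligned[i] - b.aligned[j])
                assert da == pytest.approx(db, abs=1e-6)


class TestShapePca:
    def test_rank_one_variation_loads_on_pc1(self, template):
        direction = np.zeros_like(template.coords)
        direction[0] = [1.0, 0.5, -0.2]
        configs = [
            make_config(template.coords + t * direction, specimen_id=f"s{i}")
            for i, t in enumerate(np.linspace(-1, 1, 8))
        ]
        pca = shape_pca(gpa(configs))
        assert pca.variance_fraction[0] >= 0.999

    def test_variance_fractions_sum_to_one(self, null_cohort):
        pca = shape_pca(gpa(null_cohort))
        assert np.sum(pca.variance_fraction) == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(pca.variance_fraction) <= 1e-12)

    def test_eigenvalues_match_covariance_oracle(self, null_cohort):
        result = gpa(null_cohort)
        pca = shape_pca(result)
        flat = result.aligned.reshape(result.n_specimens, -1)
        cov = np.cov(flat, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        fractions = eigvals[: pca.n_components] / eigvals.sum()
        np.testing.assert_allclose(pca.variance_fraction, fractions, atol=1e-8)

    def test_consensus_projects_to_origin(self, null_cohort):
        result = gpa(null_cohort)
        pca = shape_pca(result)
        # specimen scores are centered on the consensus
        np.testing.assert_allclose(pca.scores.mean(axis=0), 0.0, atol=1e-9)
        projected = (result.consensus.reshape(-1) - result.consensus.reshape(-1)) @ pca.loadings.T
        np.testing.assert_allclose(projected, 0.0, atol=1e-12)

    def test_deterministic_sign_convention(self, null_cohort):
        a = shape_pca(gpa(null_cohort))
        b = shape_pca(gpa(null_cohort))
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for row in a.loadings:
            assert row[np.argmax(np.abs(row))] > 0


class TestGroupPermutationTest:
    def test_seed_reproducible_bit_for_bit(self, contraction_cohort):
        result_gpa = gpa(contraction_cohort)
        a = group_permutation_test(result_gpa, n_perm=100, seed=5)
        b = group_permutation_test(result_gpa, n_perm=100, seed=5)
        assert a.p_values.equals(b.p_values)
        assert a.observed_distance.equals(b.observed_distance)

    def test_matrix_structure(self, contraction_cohort):
        result = group_permutation_test(gpa(contraction_cohort), n_perm=100, seed=1)
        assert result.observed_distance.loc["WT", "WT"] == 0.0
        assert (
            result.observed_distance.loc["WT", "MUT"]
            == result.observed_distance.loc["MUT", "WT"]
        )
        p = result.p_values.loc["WT", "MUT"]
        assert 0 < p <= 1

    def test_strong_effect_reaches_minimum_p(self, template):
        cohort = sample_cohort(
            CohortSpec(template=template,
                       effect=EffectSpec(region_scale={"midface": 0.8}, label="MUT"),
                       noise_sd=0.02, seed=3)
        )
        result = group_permutation_test(gpa(cohort), n_perm=200, seed=9)
        assert result.p_values.loc["WT", "MUT"] == pytest.approx(1 / 201)

    def test_relabeling_symmetry(self, contraction_cohort):
        """Swapping group names permutes the matrix but not the p-value."""
        result_gpa = gpa(contraction_cohort)
        swapped = ["A" if g == "MUT" else "B" for g in result_gpa.groups]
        a = group_permutation_test(result_gpa, n_perm=100, seed=2)
        b = group_permutation_test(result_gpa, labels=swapped, n_perm=100, seed=2)
        assert set(b.groups) == {"A", "B"}
        assert a.observed_distance.loc["WT", "MUT"] == pytest.approx(
            b.observed_distance.iloc[0, 1], abs=1e-12
        )

    def test_small_group_rejected(self, contraction_cohort):
        result_gpa = gpa(contraction_cohort)
        labels = list(result_gpa.groups)
        labels[0] = "lonely"
        with pytest.raises(ProcrustesError):
            group_permutation_test(result_gpa, labels=labels, n_perm=50, seed=0)


class TestIntegrativeDistancePca:
    def test_duplicated_cohort_overlaps_in_score_space(self, null_cohort):
        pca = integrative_distance_pca([("m1", null_cohort), ("m2", null_cohort)])
        info = pca.sample_info
        c1 = pca.scores[info["model"] == "m1"].mean(axis=0)
        c2 = pca.scores[info["model"] == "m2"].mean(axis=0)
        assert np.linalg.norm(c1 - c2) < 1e-9
        assert np.sum(pca.variance_fraction) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_effects_separate_affected_groups(self):
        from sklearn.metrics import silhouette_score

        template = desk_template(seed=0)
        cohorts = []
        for label, seed, effect in (
            ("modelA", 101, EffectSpec(region_scale={"midface": 0.85}, label="mutA")),
            ("modelB", 202, EffectSpec(region_scale={"neurocranium": 1.15}, label="mutB")),
        ):
            cohorts.append(
                (label,
                 sample_cohort(CohortSpec(template=template, effect=effect,
                                          noise_sd=0.05, seed=seed)))
            )
        pca = integrative_distance_pca(cohorts)
        info = pca.sample_info
        affected = info["group"].isin(["mutA", "mutB"]).to_numpy()
        score = silhouette_score(
            pca.scores[affected][:, :3], info.loc[affected, "model"]
        )
        assert score > 0

    def test_inventory_mismatch_rejected(self, null_cohort):
        other = sample_cohort(CohortSpec(template=desk_template(seed=4), noise_sd=0.02, seed=0))
        renamed = other  # same K but different template seed -> same names; force mismatch
        from cranioform import SpecimenSet

        configs = [
            LandmarkConfiguration(
                specimen_id=c.specimen_id, group=c.group, unit=c.unit,
                landmark_names=tuple(n + "_x" for n in c.landmark_names),
                regions=c.regions, coords=c.coords,
            )
            for c in renamed.configurations
        ]
        with pytest.raises(ProcrustesError):
            integrative_distance_pca(
                [("a", null_cohort), ("b", SpecimenSet.from_configurations(configs))]
            )
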