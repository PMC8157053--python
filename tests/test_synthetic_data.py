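"""Generator fidelity: pedigree structure, breeding-value covariance,
residual covariance, missingness rules and determinism."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from mtgibbs.pedigree import build_A_dense, load_pedigree
from mtgibbs.phenotypes import derive_yearling_weight, load_phenotypes
from mtgibbs.synthetic_data import (
    HANWOO_CLASSES,
    SimulationDesign,
    hanwoo_design,
    recovery_design,
    reference_G,
    reference_R,
    simulate_breeding_values,
    simulate_dataset,
    simulate_pedigree,
    simulate_phenotypes,
    write_dataset,
)


class TestDesigns:
    def test_reference_covariances_are_pd(self):
        for M in (reference_G(), reference_R(),
                  recovery_design().true_G, recovery_design().true_R):
            assert np.linalg.eigvalsh(M).min() > 0

    def test_reference_diagonals_match_published_variances(self):
        G = reference_G(("CW", "EMA", "MS"))
        np.testing.assert_allclose(np.diag(G), [596.32, 34.60, 1.43], rtol=1e-6)
        R = reference_R(("CW", "EMA", "MS"))
        np.testing.assert_allclose(np.diag(R), [828.31, 34.40, 0.97], rtol=5e-3)

    def test_class_proportions_validated(self):
        d = recovery_design()
        with pytest.raises(ValueError, match="sum"):
            replace(d, classes=(("a", 0.5, ("CW",)),))

    def test_non_pd_truth_rejected(self):
        d = recovery_design()
        bad = d.true_G.copy()
        bad[0, 1] = bad[1, 0] = 1e6
        with pytest.raises(ValueError, match="positive definite"):
            replace(d, true_G=bad)

    def test_hanwoo_class_proportions_sum_to_one(self):
        assert sum(p for _, p, _ in HANWOO_CLASSES) == pytest.approx(1.0)


class TestPedigreeSimulation:
    def test_zero_generations_founders_only(self, rng):
        d = replace(recovery_design(), n_generations=0, n_founders=7)
        ped = simulate_pedigree(d, rng)
        assert len(ped) == 7
        assert ped.founder_mask.all()

    def test_fullsib_family_structure(self, rng):
        d = replace(recovery_design(), n_founders=2, n_generations=1,
                    matings_per_generation=1, offspring_per_mating=3)
        ped = simulate_pedigree(d, rng)
        assert len(ped) == 5
        A = build_A_dense(ped)
        sibs = [i for i in range(5) if not ped.is_founder(i)]
        assert len(sibs) == 3
        for i in sibs:
            for j in sibs:
                if i != j:
                    assert A[i, j] == pytest.approx(0.5)

    def test_output_passes_loader_validation(self, rng, tmp_path):
        d = replace(recovery_design(), n_founders=12, n_generations=2,
                    matings_per_generation=4, offspring_per_mating=3)
        info = write_dataset(d, seed=9, out_dir=tmp_path)
        ped = load_pedigree(info["pedigree"])  # validates topology on load
        assert len(ped) == d.n_animals
        table = load_phenotypes(info["phenotypes"], d.trait_definitions(),
                                pedigree=ped)
        assert table.n_records == d.n_animals


class TestBreedingValues:
    def test_founder_covariance_matches_G(self, rng):
        d = replace(recovery_design(), n_founders=10_000, n_generations=0)
        ped = simulate_pedigree(d, rng)
        u = simulate_breeding_values(ped, d.true_G, rng)
        emp = np.cov(u.T)
        n = len(ped)
        for i in range(3):
            for j in range(3):
                # SE of a covariance estimate ~ sqrt((g_ii g_jj + g_ij^2)/n)
                se = np.sqrt(
                    (d.true_G[i, i] * d.true_G[j, j] + d.true_G[i, j] ** 2) / n
                )
                assert abs(emp[i, j] - d.true_G[i, j]) < 3 * se

    def test_fullsib_difference_variance_is_twice_mendelian(self, rng):
        # u_s1 - u_s2 = m1 - m2 with Var(m) = 0.5 G for non-inbred parents
        G = reference_G(("CW",))
        d = replace(recovery_design(), traits=("CW",), true_G=G,
                    true_R=reference_R(("CW",)), n_founders=4000,
                    n_generations=1, matings_per_generation=2000,
                    offspring_per_mating=2,
                    classes=(("all", 1.0, ("CW",)),),
                    trait_factors={"CW": ()}, trait_covariates={"CW": ()})
        ped = simulate_pedigree(d, rng)
        u = simulate_breeding_values(ped, G, rng)
        kids = np.flatnonzero(~ped.founder_mask).reshape(-1, 2)
        diff = u[kids[:, 0], 0] - u[kids[:, 1], 0]
        expect = float(G[0, 0])  # 2 * 0.5 G
        se = expect * np.sqrt(2.0 / len(diff))
        assert abs(diff.var(ddof=1) - expect) < 3 * se

    def test_pairwise_covariance_tracks_relationship(self, rng):
        """Across replicates, Cov(u_i, u_j) = a(i,j) * G elementwise."""
        from mtgibbs.pedigree import from_records

        ped = from_records(
            [("f1", None, None), ("f2", None, None), ("f3", None, None),
             ("c1", "f1", "f2"), ("c2", "f1", "f2"), ("g1", "c1", "f3"),
             ("g2", "c2", "f3")]
        )
        A = build_A_dense(ped)
        G = reference_G(("CW", "MS"))
        reps = 6000
        us = np.stack([simulate_breeding_values(ped, G, rng) for _ in range(reps)])
        # check a strongly related and a weakly related pair, CW component
        for (i, j) in ((3, 4), (5, 6), (0, 6)):
            prod = us[:, i, 0] * us[:, j, 0]
            emp = prod.mean()
            se = prod.std(ddof=1) / np.sqrt(reps)
            assert abs(emp - A[i, j] * G[0, 0]) < 3.5 * se


class TestPhenotypes:
    def test_residual_covariance_recovered(self, rng):
        d = replace(recovery_design(), n_founders=100, n_generations=1,
                    matings_per_generation=5000, offspring_per_mating=2,
                    classes=(), fixed_fraction=0.0,
                    trait_factors={}, trait_covariates={},
                    emit_weights_for_yw=False)
        ped = simulate_pedigree(d, rng)
        u = simulate_breeding_values(ped, d.true_G, rng)
        table, _ = simulate_phenotypes(ped, u, d, rng)
        resid = table.values - u
        emp = np.cov(resid.T)
        n = len(ped)
        for i in range(3):
            for j in range(3):
                se = np.sqrt(
                    (d.true_R[i, i] * d.true_R[j, j] + d.true_R[i, j] ** 2) / n
                )
                assert abs(emp[i, j] - d.true_R[i, j]) < 3 * se

    def test_steer_only_masking(self, rng):
        d = hanwoo_design(0.25)
        ped, table, u, truth = simulate_dataset(d, seed=2)
        class_names = truth["class_names"]
        class_of = np.array(truth["class_of"])
        carcass = [table.trait_index(t) for t in ("BFT", "CW", "EMA", "MS")]
        bull_classes = [i for i, nm in enumerate(class_names) if nm.startswith("bull")]
        bull_rows = np.isin(class_of, bull_classes)
        assert bull_rows.any()
        assert not table.observed[np.ix_(bull_rows, carcass)].any()

    def test_founders_unrecorded(self, rng):
        d = recovery_design(500)
        ped, table, u, truth = simulate_dataset(d, seed=3)
        founders = ped.founder_mask
        assert not table.observed[founders].any()

    def test_yw_weights_reproduce_trait(self, rng):
        d = hanwoo_design(0.25)
        ped, table, u, truth = simulate_dataset(d, seed=4)
        jw = table.trait_index("YW")
        w_t = table.covariates["weight_term"]
        w_p = table.covariates["weight_prev"]
        t_t = table.covariates["day_term"]
        t_p = table.covariates["day_prev"]
        for i in (0, 11, 57):
            yw = derive_yearling_weight(w_t[i], w_p[i], t_t[i], t_p[i])
            assert yw == pytest.approx(table.values[i, jw], rel=1e-9)

    def test_midparent_regression_recovers_heritability(self, rng):
        """Offspring-on-midparent regression slope estimates h2 (single
        trait, no fixed effects, large family count)."""
        G = reference_G(("CW",))
        R = reference_R(("CW",))
        h2_true = float(G[0, 0] / (G[0, 0] + R[0, 0]))
        n_mat = 2700
        d = SimulationDesign(
            traits=("CW",), true_G=G, true_R=R,
            n_founders=2 * n_mat, n_generations=1,
            matings_per_generation=n_mat, offspring_per_mating=2,
            classes=(("all", 1.0, ("CW",)),),
            trait_factors={"CW": ()}, trait_covariates={"CW": ()},
            fixed_fraction=0.0, emit_weights_for_yw=False,
        )
        ped, table, u, truth = simulate_dataset(d, seed=6)
        y = table.values[:, 0]
        kids = np.flatnonzero(~ped.founder_mask)
        mid = 0.5 * (y[ped.sire[kids]] + y[ped.dam[kids]])
        off_mean = y[kids].reshape(-1, 2).mean(axis=1)
        mid = mid.reshape(-1, 2)[:, 0]
        fit = stats.linregress(mid, off_mean)
        assert abs(fit.slope - h2_true) < 3 * fit.stderr


class TestDeterminism:
    def test_identical_seed_identical_files(self, tmp_path):
        d = replace(recovery_design(), n_founders=10, n_generations=2,
                    matings_per_generation=3, offspring_per_mating=3)
        write_dataset(d, seed=5, out_dir=tmp_path / "a")
        write_dataset(d, seed=5, out_dir=tmp_path / "b")
        for name in ("pedigree.csv", "phenotypes.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
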