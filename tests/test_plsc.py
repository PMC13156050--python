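import numpy as np
import pandas as pd
import pytest
from scipy import stats

from callothick.moderation import aggregate_regions
from callothick.plsc import (
    behavior_scores,
    bootstrap_ratios,
    build_inputs,
    fdr_across_regions,
    fit,
    permutation_test,
    symptom_jn,
)
from callothick.simulate import SyntheticCohortConfig, simulate_cohort


def _patient_inputs(cohort, profiles, symptoms, region="IV"):
    pat = (cohort["group"] == "patient").to_numpy()
    means = aggregate_regions(profiles)[pat][region].reset_index(drop=True)
    ages = cohort.loc[pat, "age"].reset_index(drop=True)
    return build_inputs(means, ages, symptoms.drop(columns="subject_id"))


class TestBuildInputs:
    def test_columns_are_standardised(self, plsc_cohort):
        _, cohort, profiles, symptoms, _ = plsc_cohort
        inputs = _patient_inputs(cohort, profiles, symptoms)
        for df in (inputs.X, inputs.Y):
            np.testing.assert_allclose(df.mean(), 0, atol=1e-10)
            np.testing.assert_allclose(df.std(ddof=1), 1, atol=1e-10)

    def test_constant_symptom_column_excluded(self, plsc_cohort):
        _, cohort, profiles, symptoms, _ = plsc_cohort
        sym = symptoms.copy()
        sym["flat"] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            inputs = _patient_inputs(cohort, profiles, sym)
        assert "flat" not in inputs.Y.columns

    def test_joint_row_shuffle_leaves_R_unchanged(self, plsc_cohort, rng):
        _, cohort, profiles, symptoms, _ = plsc_cohort
        inputs = _patient_inputs(cohort, profiles, symptoms)
        perm = rng.permutation(inputs.n)
        shuffled = type(inputs)(
            X=inputs.X.iloc[perm].reset_index(drop=True),
            Y=inputs.Y.iloc[perm].reset_index(drop=True),
            n=inputs.n,
            kept=inputs.kept,
        )
        np.testing.assert_allclose(fit(inputs).R, fit(shuffled).R, atol=1e-12)

    def test_incomplete_rows_dropped(self, plsc_cohort):
        _, cohort, profiles, symptoms, _ = plsc_cohort
        sym = symptoms.copy()
        sym.loc[sym.index[:14], "P1"] = np.nan  # mirrors unavailable PANSS rows
        with pytest.warns(UserWarning, match="dropping 14"):
            inputs = _patient_inputs(cohort, profiles, sym)
        assert inputs.n == 137 - 14

    def test_too_few_rows_error(self):
        sym = pd.DataFrame({"subject_id": list("abcde"), "P1": np.arange(5.0)})
        with pytest.raises(ValueError, match="at least 10"):
            build_inputs(np.arange(5.0), np.arange(5.0), sym.drop(columns="subject_id"))


class TestFit:
    def test_self_covariance_singular_values(self, rng):
        """Y = X: singular values of R equal the eigenvalues of the column
        correlation matrix."""
        X = rng.normal(size=(60, 3))
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        df = pd.DataFrame(Xz, columns=list("abc"))
        from callothick.plsc import PLSCInputs

        inputs = PLSCInputs(X=df, Y=df.copy(), n=60, kept=np.arange(60))
        model = fit(inputs)
        corr = np.corrcoef(Xz, rowvar=False)
        np.testing.assert_allclose(
            np.sort(model.S), np.sort(np.linalg.eigvalsh(corr)), rtol=1e-8
        )

    def test_toy_matrix_matches_characteristic_polynomial(self):
        """Dense oracle: singular values from the roots of det(R R' - x I)."""
        X = pd.DataFrame(
            [[1.0, 2, 0], [0, 1, 1], [2, 0, 1], [1, 1, 3]], columns=list("abc")
        )
        Y = pd.DataFrame(
            [[2.0, 1, 1], [1, 0, 2], [0, 2, 1], [3, 1, 0]], columns=list("xyz")
        )
        from callothick.plsc import PLSCInputs

        inputs = PLSCInputs(X=X, Y=Y, n=4, kept=np.arange(4))
        model = fit(inputs)
        R = X.to_numpy().T @ Y.to_numpy() / 3
        coeffs = np.poly(R @ R.T)  # characteristic polynomial of R R'
        eig = np.sort(np.roots(coeffs).real)
        np.testing.assert_allclose(np.sort(model.S**2), eig, rtol=1e-8)

    def test_energy_conservation(self, rng):
        from callothick.plsc import PLSCInputs

        for _ in range(10):
            X = pd.DataFrame(rng.normal(size=(30, 3)))
            Y = pd.DataFrame(rng.normal(size=(30, 12)))
            model = fit(PLSCInputs(X=X, Y=Y, n=30, kept=np.arange(30)))
            assert np.sum(model.S**2) == pytest.approx(
                np.linalg.norm(np.asarray(model.R)) ** 2, rel=1e-10
            )

    def test_rank1_recovery_of_planted_salience(self, plsc_cohort):
        _, cohort, profiles, symptoms, truth = plsc_cohort
        model = fit(_patient_inputs(cohort, profiles, symptoms))
        assert abs(np.dot(model.U[:, 0], truth.design_salience)) > 0.9

    def test_sign_convention_deterministic(self, plsc_cohort):
        _, cohort, profiles, symptoms, _ = plsc_cohort
        inputs = _patient_inputs(cohort, profiles, symptoms)
        model = fit(inputs)
        for k in range(model.n_lv):
            assert model.U[np.argmax(np.abs(model.U[:, k])), k] > 0

    def test_score_cross_products_recover_singular_values(self, rng):
        """SVD identity: (X U)' (Y V) is diagonal with entries (n-1) S."""
        from callothick.plsc import PLSCInputs

        X = pd.DataFrame(rng.normal(size=(40, 3)))
        Y = pd.DataFrame(rng.normal(size=(40, 8)))
        inputs = PLSCInputs(X=X, Y=Y, n=40, kept=np.arange(40))
        model = fit(inputs)
        G = (X.to_numpy() @ model.U).T @ (Y.to_numpy() @ model.V)
        np.testing.assert_allclose(np.diag(G), (40 - 1) * model.S, rtol=1e-8)
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6 * max(1.0, np.abs(G).max())


class TestPermutation:
    def test_seeded_determinism(self, plsc_cohort):
        _, cohort, profiles, symptoms, _ = plsc_cohort
        inputs = _patient_inputs(cohort, profiles, symptoms)
        p1 = permutation_test(inputs, n_perm=200, seed=9)
        p2 = permutation_test(inputs, n_perm=200, seed=9)
        np.testing.assert_array_equal(p1, p2)

    def test_p_never_zero(self, plsc_cohort):
        _, cohort, profiles, symptoms, _ = plsc_cohort
        inputs = _patient_inputs(cohort, profiles, symptoms)
        p = permutation_test(inputs, n_perm=200, seed=0)
        assert p.min() >= 1.0 / 201

    def test_planted_covariance_detected(self, plsc_cohort):
        _, cohort, profiles, symptoms, _ = plsc_cohort
        inputs = _patient_inputs(cohort, profiles, symptoms)
        p = permutation_test(inputs, n_perm=500, seed=1)
        assert p[0] <= 0.05

    def test_null_p_uniform_across_replicates(self):
        ps = []
        for r in range(60):
            cfg = SyntheticCohortConfig(
                n_patients=80, n_controls=10, symptom_latent_strength=0.0,
                seed=7000 + r,
            )
            cohort, profiles, symptoms, _ = simulate_cohort(cfg)
            inputs = _patient_inputs(cohort, profiles, symptoms)
            ps.append(permutation_test(inputs, n_perm=300, seed=r)[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_requires_min_permutations(self, plsc_cohort):
        _, cohort, profiles, symptoms, _ = plsc_cohort
        inputs = _patient_inputs(cohort, profiles, symptoms)
        with pytest.raises(ValueError):
            permutation_test(inputs, n_perm=10)


class TestBootstrap:
    def test_seeded_determinism(self, plsc_cohort):
        _, cohort, profiles, symptoms, _ = plsc_cohort
        inputs = _patient_inputs(cohort, profiles, symptoms)
        b1 = bootstrap_ratios(inputs, n_boot=150, seed=4)
        b2 = bootstrap_ratios(inputs, n_boot=150, seed=4)
        np.testing.assert_array_equal(b1["bsr_v"], b2["bsr_v"])

    def test_heavily_loaded_item_significant_across_replicates(self):
        """An item with a large planted salience shows |BSR| > 2 in nearly
        every replicate cohort."""
        from callothick.simulate import PANSS_ITEMS

        hits = []
        for r in range(10):
            cfg = SyntheticCohortConfig(
                n_patients=137, n_controls=10, symptom_latent_strength=0.8,
                seed=4000 + r,
            )
            cohort, profiles, symptoms, truth = simulate_cohort(cfg)
            inputs = _patient_inputs(cohort, profiles, symptoms)
            bsr = bootstrap_ratios(inputs, n_boot=300, seed=r)
            top = PANSS_ITEMS[int(np.argmax(truth.item_salience))]
            j = inputs.Y.columns.get_loc(top)
            hits.append(abs(bsr["bsr_v"][j, 0]) > 2)
        assert np.mean(hits) >= 0.9

    def test_null_column_false_positive_rate(self, rng):
        """|BSR| > 2 on pure-noise symptom columns fires at roughly the
        two-sided normal rate P(|Z| > 2) ~ 4.6%."""
        from callothick.plsc import PLSCInputs

        hits, total = 0, 0
        for r in range(15):
            g = np.random.default_rng(r)
            X = pd.DataFrame(g.normal(size=(80, 3)))
            Y = pd.DataFrame(g.normal(size=(80, 20)))
            inputs = PLSCInputs(X=X, Y=Y, n=80, kept=np.arange(80))
            bsr = bootstrap_ratios(inputs, n_boot=200, seed=r)
            hits += bsr["significant_v"].sum()
            total += bsr["significant_v"].size
        rate = hits / total
        assert 0.005 < rate < 0.12


class TestBehaviorScores:
    def test_identity_salience_returns_Y(self, rng):
        Y = rng.normal(size=(10, 4))
        np.testing.assert_array_equal(behavior_scores(Y, np.eye(4)), Y)

    def test_rank1_rows_give_constant_norm(self):
        u = np.array([0.6, 0.8])
        Y = np.tile(u, (5, 1))
        scores = behavior_scores(Y, u[:, None])
        np.testing.assert_allclose(scores[:, 0], np.linalg.norm(u) ** 2)

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="shape"):
            behavior_scores(rng.normal(size=(5, 3)), rng.normal(size=(4, 2)))


class TestSymptomJN:
    def test_planted_coupling_recovered(self, plsc_cohort):
        cfg, cohort, profiles, symptoms, _ = plsc_cohort
        inputs = _patient_inputs(cohort, profiles, symptoms)
        model = fit(inputs)
        scores = behavior_scores(inputs.Y, model.V)
        pat_age = cohort.loc[(cohort["group"] == "patient").to_numpy(), "age"]
        mfit, sol = symptom_jn(
            scores[:, 0], inputs.X["thickness"], pat_age.to_numpy()[inputs.kept]
        )
        # the latent couples thickness and symptoms through the interaction,
        # so the age-moderated thickness effect must be significant somewhere
        assert sol.significant_anywhere()

    def test_constant_thickness_propagates_rank_error(self, plsc_cohort):
        _, cohort, profiles, symptoms, _ = plsc_cohort
        n = 40
        with pytest.raises(ValueError, match="collinear"):
            symptom_jn(
                np.random.default_rng(0).normal(size=n),
                np.full(n, 2.0),
                np.linspace(11, 42, n),
            )


class TestFDRAcrossRegions:
    def test_worked_example(self):
        np.testing.assert_allclose(
            fdr_across_regions([0.01, 0.02, 0.03, 0.04]), 0.04
        )

    def test_identical_p_unchanged(self):
        np.testing.assert_allclose(fdr_across_regions([0.2] * 4), 0.2)

    def test_requires_exactly_four(self):
        with pytest.raises(ValueError):
            fdr_across_regions([0.1, 0.2])
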