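"""Subspace-mixture clustering: embedding metric, EM properties, BIC selection."""

import numpy as np
import pytest
from scipy.integrate import simpson
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from chronoprof import FourierBasis, FunHDDC, embed_curves, select_k_by_bic
from chronoprof.cluster import FunHDDCResults, _Component, profile_contact_table
from chronoprof.schema import SLOT_NAMES


@pytest.fixture(scope="module")
def basis():
    return FourierBasis()


class TestEmbedding:
    def test_identical_curves_identical_embeddings(self, basis, rng):
        g = rng.normal(size=5)
        Z = embed_curves(np.stack([g, g]), basis)
        assert np.allclose(Z[0], Z[1])

    def test_embedding_distance_equals_l2_curve_distance(self, basis, rng):
        t = np.linspace(0, 24, 9601)
        Phi = basis.evaluate(t)
        for _ in range(10):
            g1, g2 = rng.normal(size=(2, 5))
            quad = simpson((Phi @ (g1 - g2)) ** 2, x=t)   # quadrature oracle
            z = embed_curves(np.stack([g1, g2]), basis)
            assert np.sum((z[0] - z[1]) ** 2) == pytest.approx(quad, abs=1e-8)

    def test_constant_curves_scale_by_sqrt_period(self, basis):
        z = embed_curves(np.array([[1.0, 0, 0, 0, 0], [3.0, 0, 0, 0, 0]]), basis)
        assert np.linalg.norm(z[1] - z[0]) == pytest.approx(np.sqrt(24) * 2)


class TestEM:
    def test_two_distant_clouds_recovered_exactly(self, rng):
        Z = np.vstack([rng.normal(0, 1, (40, 5)), rng.normal(40, 1, (40, 5))])
        res = FunHDDC(2, n_init=5).fit(Z, random_state=0)
        truth = np.repeat([1, 2], 40)
        assert adjusted_rand_score(truth, res.assignments) == 1.0

    def test_single_component_closed_form(self, rng):
        Z = rng.normal(2.0, 1.0, (50, 5))
        res = FunHDDC(1, n_init=1).fit(Z, random_state=0)
        assert np.allclose(res.means[0], Z.mean(axis=0), atol=1e-8)
        assert res.pi[0] == pytest.approx(1.0)

    def test_loglik_monotone_over_seeded_runs(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            Z = np.vstack([r.normal(0, 1, (30, 5)), r.normal(4, 2, (30, 5))])
            res = FunHDDC(2, n_init=3).fit(Z, random_state=seed)
            assert all(np.diff(res.loglik_path) >= -1e-8)

    def test_responsibilities_are_a_stochastic_matrix(self, rng):
        Z = rng.normal(0, 1, (60, 5))
        res = FunHDDC(3, n_init=3).fit(Z, random_state=1)
        assert np.allclose(res.responsibilities.sum(axis=1), 1.0)
        assert res.pi.sum() == pytest.approx(1.0)

    def test_row_permutation_permutes_assignments(self, rng):
        Z = np.vstack([rng.normal(0, 1, (30, 5)), rng.normal(10, 1, (30, 5))])
        perm = rng.permutation(len(Z))
        res1 = FunHDDC(2, n_init=3).fit(Z, random_state=5)
        res2 = FunHDDC(2, n_init=3).fit(Z[perm], random_state=5)
        # same partition up to label names
        assert adjusted_rand_score(res1.assignments[perm], res2.assignments) == 1.0

    def test_full_subspace_density_matches_gaussian_mixture_oracle(self, rng):
        """With d = p−1 the member is a full-covariance Gaussian: plugging
        sklearn's fitted parameters into our density must reproduce its
        log-likelihood."""
        Z = np.vstack([rng.normal(0, 1, (25, 5)), rng.normal(5, 2, (25, 5))])
        gm = GaussianMixture(2, covariance_type="full", random_state=0,
                             reg_covar=1e-10).fit(Z)
        comps = []
        for k in range(2):
            evals, evecs = np.linalg.eigh(gm.covariances_[k])
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            comps.append(_Component(pi=gm.weights_[k], mu=gm.means_[k],
                                    Q=evecs[:, :4], d=4, a=evals[:4],
                                    b=float(evals[4])))
        model = FunHDDC(2)
        from scipy.special import logsumexp
        ll = float(logsumexp(model._log_density(Z, comps), axis=1).sum())
        assert ll == pytest.approx(gm.score(Z) * len(Z), abs=1e-6)


class TestSelection:
    def test_three_separated_clusters_selected(self, rng):
        centers = np.array([[0] * 5, [25, 0, 0, 0, 0], [0, 25, 0, 0, 0]], float)
        Z = np.vstack([rng.normal(c, 1.0, (50, 5)) for c in centers])
        best, tab = select_k_by_bic(Z, range(2, 7), random_state=0, n_init=5)
        assert best.n_clusters == 3
        assert adjusted_rand_score(np.repeat([1, 2, 3], 50), best.assignments) == 1.0

    def test_single_blob_selects_near_range_minimum(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            Z = r.normal(0, 1, (120, 5))
            best, _ = select_k_by_bic(Z, range(2, 7), random_state=seed, n_init=3)
            hits += best.n_clusters <= 3
        assert hits >= 8

    def test_empty_k_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k_by_bic(rng.normal(size=(20, 5)), [])

    def test_family_members_have_decreasing_parameter_counts(self, rng):
        Z = rng.normal(0, 1, (80, 5))
        m_general = FunHDDC(2, model="AkjBkQkDk", n_init=2).fit(Z, 0)
        m_tight = FunHDDC(2, model="ABQkDk", n_init=2).fit(Z, 0)
        p = 5
        assert (m_general.model.bic_params(m_general.components, p)
                > m_tight.model.bic_params(m_tight.components, p))


class TestProfileTable:
    def test_single_cluster_column_equals_overall(self, small_cohort, rng):
        cohort, _ = small_cohort
        flags = cohort[list(SLOT_NAMES)]
        tab = profile_contact_table(flags, np.ones(len(cohort), dtype=int),
                                    rng=rng)
        assert (tab["overall"] == tab["profile_1"]).all()

    def test_large_n_cells_approach_generator_probabilities(self):
        from chronoprof import GeneratorConfig, generate_cohort
        from chronoprof.generate import CONTACT_PROB
        cohort, truth = generate_cohort(GeneratorConfig(n=40_000, seed=21))
        flags = cohort[list(SLOT_NAMES)]
        lab = truth["true_profile"].to_numpy()
        tab = profile_contact_table(flags, lab, rng=np.random.default_rng(0))
        # profile 1 is the largest cluster -> first profile column
        row = tab[tab["slot"] == "morning_snack"].iloc[0]
        pct = float(row["profile_1"].split("(")[1].rstrip("%)"))
        assert pct == pytest.approx(100 * 34 / 80, abs=1.5)

    def test_uninformative_slot_has_well_calibrated_test(self, rng):
        # same distribution in both clusters -> p roughly uniform
        n = 400
        flags = {s: np.zeros(n, dtype=int) for s in SLOT_NAMES}
        flags["breakfast"] = (rng.random(n) < 0.5).astype(int)
        import pandas as pd
        ps = []
        for rep in range(40):
            lab = rng.integers(1, 3, n)
            tab = profile_contact_table(pd.DataFrame(flags), lab, rng=rng,
                                        mc_reps=2000)
            ps.append(tab.loc[tab["slot"] == "breakfast", "p_value"].iloc[0])
        assert 0.02 < np.mean(ps) < 0.8     # no systematic anti-conservatism
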