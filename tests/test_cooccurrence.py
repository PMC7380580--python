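"""Conditional-probability factorization, biplot, and ranked cooccurrence."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from fermomics import (CooccurrenceFactorizer, SimulationConfig,
                       axis_vs_differentials, biplot,
                       rank_cooccurring_microbes, simulate_cohort,
                       simulate_metabolites)


@pytest.fixture(scope="module")
def fitted_pair():
    cfg = SimulationConfig(n_subjects_per_group=40, n_timepoints=1,
                           n_microbes=25, n_metabolites=30, n_latent=2,
                           subject_sd=2.0, base_logit_sd=0.5, seed=31)
    table, meta, truth = simulate_cohort(cfg)
    mets = simulate_metabolites(table, truth, cfg)
    model = CooccurrenceFactorizer(n_components=2, epochs=1200,
                                   seed=0).fit(table, mets)
    return table, mets, truth, model


class TestFit:
    def test_conditional_rows_are_distributions(self, fitted_pair):
        _, _, _, model = fitted_pair
        cond = model.conditional_.to_numpy()
        assert (cond >= 0).all()
        assert np.allclose(cond.sum(axis=1), 1.0, atol=1e-6)

    def test_loss_decreases_on_epoch_average(self, fitted_pair):
        _, _, _, model = fitted_pair
        curve = model.loss_curve_
        thirds = np.array_split(curve, 3)
        assert thirds[0].mean() > thirds[1].mean() > thirds[2].mean()

    def test_identical_metabolite_profiles_give_uniform_rows(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.integers(1, 100, size=(20, 8)),
                         index=[f"s{i}" for i in range(20)],
                         columns=[f"m{i}" for i in range(8)])
        profile = np.array([5, 10, 20, 40, 25])
        Y = pd.DataFrame(np.tile(profile, (20, 1)), index=X.index,
                         columns=[f"met{i}" for i in range(5)])
        model = CooccurrenceFactorizer(n_components=1, epochs=1500,
                                       seed=0).fit(X, Y)
        expected = profile / profile.sum()
        assert np.abs(model.conditional_.to_numpy()
                      - expected[None, :]).max() < 0.02

    def test_sample_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(15)]
        X = pd.DataFrame(rng.integers(1, 50, (15, 6)), index=idx,
                         columns=[f"m{i}" for i in range(6)])
        Y = pd.DataFrame(rng.integers(1, 50, (15, 7)), index=idx,
                         columns=[f"t{i}" for i in range(7)])
        perm = rng.permutation(15)
        m1 = CooccurrenceFactorizer(n_components=1, epochs=300,
                                    seed=0).fit(X, Y)
        m2 = CooccurrenceFactorizer(n_components=1, epochs=300, seed=0).fit(
            X.iloc[perm], Y.iloc[perm])
        assert np.allclose(m1.conditional_.to_numpy(),
                           m2.conditional_.to_numpy(), atol=1e-8)

    def test_alignment_on_shared_samples(self, fitted_pair):
        table, mets, _, _ = fitted_pair
        model = CooccurrenceFactorizer(n_components=1, epochs=50, seed=0)
        model.fit(table, mets.iloc[:-3])
        assert model.n_dropped_samples_ == 3

    def test_dimension_errors(self, fitted_pair):
        table, mets, _, _ = fitted_pair
        with pytest.raises(ValueError, match="n_components"):
            CooccurrenceFactorizer(n_components=25).fit(table, mets)
        with pytest.raises(ValueError, match="shared samples"):
            CooccurrenceFactorizer(n_components=1).fit(
                table.iloc[:1], mets.iloc[-1:])


class TestBiplot:
    def test_axes_orthogonal_with_ordered_variance(self, fitted_pair):
        _, _, _, model = fitted_pair
        coords = biplot(model)
        loadings = coords.metabolite_loadings.to_numpy()
        gram = loadings.T @ loadings
        assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-8)
        prop = coords.proportion_explained
        assert (np.diff(prop) <= 1e-12).all()
        assert 0 < prop.sum() <= 1.0 + 1e-9

    def test_sign_convention(self, fitted_pair):
        _, _, _, model = fitted_pair
        coords = biplot(model)
        for axis in coords.metabolite_loadings.columns:
            col = coords.metabolite_loadings[axis].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_rank1_structure_concentrates_on_axis1(self):
        cfg = SimulationConfig(n_subjects_per_group=60, n_timepoints=1,
                               n_microbes=25, n_metabolites=30, n_latent=1,
                               subject_sd=2.5, base_logit_sd=0.5,
                               metabolite_noise_sd=0.2, seed=41)
        table, _, truth = simulate_cohort(cfg)
        mets = simulate_metabolites(table, truth, cfg)
        model = CooccurrenceFactorizer(n_components=1, epochs=1500,
                                       seed=0).fit(table, mets)
        coords = biplot(model)
        assert coords.proportion_explained[0] > 0.8

    def test_reconstruction_error_decreases_with_rank(self, fitted_pair):
        from fermomics import centered_log_conditional
        _, _, _, model = fitted_pair
        logc = centered_log_conditional(model).to_numpy()
        u, s, vt = np.linalg.svd(logc, full_matrices=False)
        errors = []
        for d in (1, 2, 3):
            approx = (u[:, :d] * s[:d]) @ vt[:d]
            errors.append(np.linalg.norm(logc - approx))
        assert errors[0] > errors[1] > errors[2]


class TestRankedCooccurrence:
    def test_full_ranking_is_permutation(self, fitted_pair):
        _, _, truth, model = fitted_pair
        ranked = rank_cooccurring_microbes(
            model, truth.enriched_metabolite_id,
            top_n=model.conditional_.shape[0])
        assert sorted(ranked) == sorted(model.conditional_.index)

    def test_top_n_length(self, fitted_pair):
        _, _, truth, model = fitted_pair
        assert len(rank_cooccurring_microbes(
            model, truth.enriched_metabolite_id, 10)) == 10

    def test_strongest_affinity_microbe_ranks_high(self):
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(n_subjects_per_group=60, n_timepoints=2,
                                   n_microbes=25, n_metabolites=30,
                                   n_latent=1, latent_group_coupling=0.0,
                                   subject_sd=2.5, base_logit_sd=0.5,
                                   metabolite_noise_sd=0.3, seed=60 + seed)
            table, _, truth = simulate_cohort(cfg)
            mets = simulate_metabolites(table, truth, cfg)
            model = CooccurrenceFactorizer(n_components=1, epochs=1200,
                                           seed=0).fit(table, mets)
            target = truth.cooccurrence_true.columns[5]
            best = truth.cooccurrence_true[target].idxmax()
            top5 = rank_cooccurring_microbes(model, target, 5)
            hits += best in top5
        assert hits >= 4

    def test_unknown_metabolite_errors(self, fitted_pair):
        _, _, _, model = fitted_pair
        with pytest.raises(KeyError, match="unknown"):
            model.rank_microbes("not-a-metabolite")


class TestAxisVsDifferentials:
    def test_self_correlation_is_one(self, fitted_pair):
        _, _, truth, model = fitted_pair
        coords = biplot(model)
        fake = coords.microbe_scores["PC1"]
        r, p, n = axis_vs_differentials(coords, fake)
        assert r == pytest.approx(1.0)
        assert n == len(fake)

    def test_constant_vector_errors(self, fitted_pair):
        _, _, truth, model = fitted_pair
        coords = biplot(model)
        const = pd.Series(1.0, index=coords.microbe_scores.index)
        with pytest.raises(ValueError, match="constant"):
            axis_vs_differentials(coords, const)

    def test_uncoupled_structures_give_null_correlation(self):
        """With no planted coupling between the latent factor and the
        group differentials, axis 1 carries no differential signal."""
        rs = []
        for seed in range(5):
            cfg = SimulationConfig(n_subjects_per_group=60, n_timepoints=2,
                                   n_microbes=40, n_metabolites=50,
                                   n_latent=1, latent_group_coupling=0.0,
                                   subject_sd=2.5, base_logit_sd=0.5,
                                   seed=100 + seed)
            table, _, truth = simulate_cohort(cfg)
            mets = simulate_metabolites(table, truth, cfg)
            model = CooccurrenceFactorizer(n_components=1, epochs=1200,
                                           seed=0).fit(table, mets)
            r, _, _ = axis_vs_differentials(biplot(model), truth.beta_true)
            rs.append(abs(r))
        assert np.median(rs) < 0.45
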