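"""Engine tests: correlations, projection, training, fitting, inference."""

import numpy as np
import pandas as pd
import pytest

from rankdecon import RunConfig
from rankdecon.core import (TrainingSet, build_training_set, expand, fit_map,
                            infer_abundance, load_model, normalize_probabilities,
                            project, proximity_of_coords, proximity_score,
                            rank_correlation_matrix, rank_correlation_vector,
                            sample_abundance_mixture, save_model, train_model)
from rankdecon.downstream import aggregate_cell_types, pearson
from rankdecon.errors import ValidationError
from rankdecon.latent import latent_from_matrix
from rankdecon.simdata import make_bulk_discrete, sample_type_fractions


class TestRankCorrelation:
    def test_self_and_reversed(self, rng):
        col = rng.permutation(20).astype(float)  # no ties
        agg = np.column_stack([col, col.max() - col])  # identical / antitone
        c = rank_correlation_matrix(col[:, None], agg)[0]
        np.testing.assert_allclose(c, [1.0, -1.0], atol=1e-12)

    def test_closed_form_three_genes(self):
        # ranks (1,2,3) vs (1,3,2): rho = 1 - 6*2/(3*8) = 0.5
        c = rank_correlation_vector(np.array([10.0, 20.0, 30.0]),
                                    np.array([[1.0], [5.0], [3.0]]),
                                    pd.Index(["a", "b", "c"]))
        np.testing.assert_allclose(c.c, [0.5], atol=1e-12)

    def test_constant_profile_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            c = rank_correlation_matrix(np.array([[1.0], [1.0], [1.0]]),
                                        np.array([[1.0], [2.0], [3.0]]))
        assert c[0, 0] == 0.0

    def test_matches_scipy_spearman(self, rng):
        from scipy.stats import spearmanr
        bulk = rng.poisson(5, 40).astype(float)
        agg = rng.poisson(5, (40, 6)).astype(float)
        ours = rank_correlation_matrix(bulk[:, None], agg)[0]
        ref = [spearmanr(bulk, agg[:, j]).statistic for j in range(6)]
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestProjection:
    toy = latent_from_matrix(np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]),
                             ["c1", "c2", "c3"])

    def test_explicit_pseudoinverse(self):
        np.testing.assert_allclose(project(self.toy, np.array([2.0, 3.0, 5.0])),
                                   [2.0, 3.0], atol=1e-12)

    def test_expand_explicit(self):
        np.testing.assert_allclose(expand(self.toy, np.array([1.0, 1.0])),
                                   [1.0, 1.0, 0.0], atol=1e-12)

    def test_nullspace_annihilation(self):
        np.testing.assert_allclose(project(self.toy, np.array([0.0, 0.0, 9.0])),
                                   [0.0, 0.0], atol=1e-12)

    def test_roundtrip(self, rng):
        Z = rng.normal(size=(12, 4))
        lat = latent_from_matrix(Z, [f"c{i}" for i in range(12)])
        y = rng.normal(size=4)
        np.testing.assert_allclose(project(lat, expand(lat, y)), y, atol=1e-8)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            project(self.toy, np.zeros(5))
        with pytest.raises(ValidationError):
            expand(self.toy, np.zeros(3))


class TestMixtureSampling:
    def test_simplex_output(self, small_model):
        dist, spec = sample_abundance_mixture(small_model.latent, seed=5)
        p = dist.p.to_numpy()
        assert abs(p.sum() - 1.0) < 1e-9
        assert (p >= 0).all()
        assert 1 <= spec.n_components <= 5

    def test_two_sigma_capture_target(self, small_model):
        lat = small_model.latent
        dist, spec = sample_abundance_mixture(lat, m_range=(1, 1),
                                              sigma_percentile_range=(5.0, 5.0),
                                              seed=2)
        center = lat.Z[spec.centers[0]]
        d = np.linalg.norm(lat.Z - center, axis=1)
        captured = (d <= 2 * spec.sigmas[0]).sum()
        target = round(0.05 * lat.n_cells)
        assert abs(captured - target) <= 1  # discretization tolerance

    def test_seeded_determinism(self, small_model):
        a, sa = sample_abundance_mixture(small_model.latent, seed=9)
        b, sb = sample_abundance_mixture(small_model.latent, seed=9)
        np.testing.assert_array_equal(a.p.to_numpy(), b.p.to_numpy())
        np.testing.assert_array_equal(sa.sigmas, sb.sigmas)


class TestTraining:
    def test_shapes(self, small_model):
        tr = small_model.training
        assert tr.X.shape == (400, 5)
        assert tr.Y.shape == (400, 5)
        assert tr.n_sampled == 150  # J/2 default

    def test_tight_cluster_concentrates_correlation(self, small_discrete, small_model):
        # synthetic bulk drawn from group0 only correlates highest with group0
        rng = np.random.default_rng(0)
        members = small_discrete.labels == "group0"
        p = members.to_numpy(dtype=float)
        p /= p.sum()
        draws = rng.multinomial(200, p)
        bulk = small_model.aggregated.index  # var genes
        counts_var = small_discrete.counts.loc[bulk]
        synth = counts_var.to_numpy() @ draws
        c = rank_correlation_matrix(synth[:, None].astype(float),
                                    small_model.aggregated.to_numpy(float))[0]
        assert c[members.to_numpy()].mean() > c[~members.to_numpy()].mean()

    def test_synthetic_bulk_depth(self, small_discrete, small_model):
        # mean synthetic-bulk depth ~ n_sampled x mean per-cell depth (var genes)
        tr = small_model.training
        var_genes = small_model.aggregated.index
        per_cell = small_discrete.counts.loc[var_genes].sum(axis=0).mean()
        rng = np.random.default_rng(1)
        p = np.full(small_discrete.n_cells, 1.0 / small_discrete.n_cells)
        draws = rng.multinomial(tr.n_sampled, np.tile(p, (50, 1)))
        depths = (small_discrete.counts.loc[var_genes].to_numpy() @ draws.T).sum(axis=0)
        expected = tr.n_sampled * per_cell
        assert abs(depths.mean() - expected) / expected < 0.05


class TestFitMap:
    def test_exact_linear_recovery(self, rng):
        B = rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        X = rng.normal(size=(200, 3))
        Y = X @ B.T + b
        tr = TrainingSet(X=X, Y=Y, specs=[], n_sampled=1)
        model = fit_map(tr, degree=1)
        np.testing.assert_allclose(model.beta[0], b, atol=1e-6)
        np.testing.assert_allclose(model.beta[1:], B.T, atol=1e-6)

    def test_least_squares_optimality(self, rng):
        X = rng.normal(size=(80, 2))
        Y = X @ rng.normal(size=(2, 2)) + rng.normal(size=(80, 2)) * 0.3
        tr = TrainingSet(X=X, Y=Y, specs=[], n_sampled=1)
        model = fit_map(tr, degree=1)
        from rankdecon.core import _monomial_design
        design = _monomial_design(X, 1)
        best = np.linalg.norm(design @ model.beta - Y)
        for _ in range(20):
            perturbed = model.beta + rng.normal(size=model.beta.shape) * 0.01
            assert np.linalg.norm(design @ perturbed - Y) >= best

    def test_quadratic_terms_vanish_on_linear_data(self, rng):
        X = rng.normal(size=(5000, 2))
        B = rng.normal(size=(2, 2))
        tr = TrainingSet(X=X, Y=X @ B.T, specs=[], n_sampled=1)
        model = fit_map(tr, degree=2)
        quad = model.beta[3:]  # rows past intercept + linear terms
        assert np.abs(quad).max() < 1e-4

    def test_underdetermined_raises(self, rng):
        tr = TrainingSet(X=rng.normal(size=(3, 3)), Y=rng.normal(size=(3, 3)),
                         specs=[], n_sampled=1)
        with pytest.raises(ValidationError):
            fit_map(tr, degree=1)


class TestNormalization:
    def test_hand_example(self):
        np.testing.assert_allclose(
            normalize_probabilities(np.array([0.6, 0.6, -0.2])),
            [0.5, 0.5, 0.0], atol=1e-12)

    def test_all_nonnegative_passthrough_scaling(self):
        out = normalize_probabilities(np.array([1.0, 3.0]))
        np.testing.assert_allclose(out, [0.25, 0.75])

    def test_degenerate_error(self):
        with pytest.raises(ValidationError):
            normalize_probabilities(np.array([-0.3, -0.3]))


@pytest.fixture(scope="module")
def bulk(small_discrete):
    return make_bulk_discrete(small_discrete, (0.6, 0.3, 0.1), seed=3).bulk_counts


class TestInference:
    def test_simplex_output(self, small_model, bulk):
        dist = infer_abundance(small_model, bulk)
        p = dist.p.to_numpy()
        assert abs(p.sum() - 1.0) < 1e-9
        assert (p >= 0).all() and (p <= 1).all()

    def test_scale_invariance(self, small_model, bulk):
        a = infer_abundance(small_model, bulk)
        b = infer_abundance(small_model, bulk * 10)
        np.testing.assert_array_equal(a.p.to_numpy(), b.p.to_numpy())

    def test_monotone_transform_invariance(self, small_model, bulk):
        a = infer_abundance(small_model, bulk)
        b = infer_abundance(small_model, bulk.astype(float) ** 1.3)
        np.testing.assert_array_equal(a.p.to_numpy(), b.p.to_numpy())

    def test_gene_permutation_invariance(self, small_discrete, bulk):
        from tests.conftest import SMALL_RUN
        perm = np.random.default_rng(5).permutation(small_discrete.n_genes)
        shuffled = small_discrete.counts.iloc[perm]
        m1 = train_model(small_discrete.counts, config=SMALL_RUN)
        m2 = train_model(shuffled, config=SMALL_RUN)
        a = infer_abundance(m1, bulk)
        b = infer_abundance(m2, bulk.iloc[perm])
        np.testing.assert_array_equal(a.p.to_numpy(), b.p.to_numpy())

    def test_too_few_shared_genes(self, small_model):
        stranger = pd.Series([1.0, 2.0], index=["x1", "x2"])
        with pytest.raises(ValidationError):
            infer_abundance(small_model, stranger)

    def test_in_sample_self_consistency(self, small_model):
        """The fitted map explains most training variance (R^2 >= 0.8)."""
        from rankdecon.core import _monomial_design
        tr = small_model.training
        pred = _monomial_design(tr.X, small_model.degree) @ small_model.beta
        ss_res = ((pred - tr.Y) ** 2).sum()
        ss_tot = ((tr.Y - tr.Y.mean(axis=0)) ** 2).sum()
        assert 1 - ss_res / ss_tot >= 0.8

    def test_fraction_recovery(self, small_discrete, small_model):
        """Aggregated estimates track true fractions across 25 random bulks."""
        rng = np.random.default_rng(17)
        rs = []
        for _ in range(25):
            f = sample_type_fractions(3, rng)
            bulk = make_bulk_discrete(small_discrete, f,
                                      seed=int(rng.integers(2 ** 31)))
            dist = infer_abundance(small_model, bulk.bulk_counts)
            est = aggregate_cell_types(dist.p, small_discrete.labels)
            rs.append(pearson(est.to_numpy(),
                              bulk.truth_type_fractions.reindex(est.index).to_numpy()))
        assert np.mean(rs) >= 0.8

    def test_seed_stability_smaller_than_bulk_spread(self, small_discrete):
        """Across-seed spread of estimates < across-bulk spread."""
        from tests.conftest import SMALL_RUN
        import dataclasses
        rng = np.random.default_rng(23)
        bulks = []
        for _ in range(8):
            f = sample_type_fractions(3, rng)
            bulks.append(make_bulk_discrete(small_discrete, f,
                                            seed=int(rng.integers(2 ** 31))))
        models = [train_model(small_discrete.counts,
                              config=dataclasses.replace(SMALL_RUN, seed=s))
                  for s in range(6)]
        est = np.array([[aggregate_cell_types(
            infer_abundance(m, b.bulk_counts).p, small_discrete.labels).to_numpy()
            for b in bulks] for m in models])  # seeds x bulks x types
        seed_spread = est.std(axis=0).mean()
        bulk_spread = est.std(axis=1).mean()
        assert seed_spread < bulk_spread


class TestProximity:
    def test_bruteforce_2d(self, rng):
        Y = rng.normal(size=(12, 2))
        y = rng.normal(size=2)
        d = np.sort(np.linalg.norm(Y - y, axis=1))[:10]
        idx = np.argsort(np.linalg.norm(Y - y, axis=1))[:10]
        pair = [np.linalg.norm(Y[i] - Y[j]) for i in idx for j in idx if i < j]
        expected = d.mean() / np.mean(pair)
        np.testing.assert_allclose(proximity_of_coords(Y, y), expected, rtol=1e-12)

    def test_zero_at_duplicated_training_point(self):
        Y = np.tile([[1.0, 2.0]], (12, 1))
        assert proximity_of_coords(Y, np.array([1.0, 2.0])) == 0.0

    def test_translation_increases_score(self, rng):
        Y = rng.normal(size=(30, 3))
        y = Y.mean(axis=0)
        near = proximity_of_coords(Y, y)
        far = proximity_of_coords(Y, y + 50.0)
        assert far > near

    def test_too_few_points(self, rng):
        with pytest.raises(ValidationError):
            proximity_of_coords(rng.normal(size=(5, 2)), np.zeros(2))

    def test_model_path(self, small_model, small_discrete):
        bulk = make_bulk_discrete(small_discrete, (0.4, 0.4, 0.2), seed=2)
        score = proximity_score(small_model, bulk.bulk_counts)
        assert score >= 0


class TestModelArchive:
    def test_roundtrip_predictions(self, tmp_path, small_model, small_discrete):
        bulk = make_bulk_discrete(small_discrete, (0.2, 0.5, 0.3), seed=6).bulk_counts
        before = infer_abundance(small_model, bulk)
        path = tmp_path / "model.zip"
        save_model(small_model, path)
        loaded = load_model(path)
        after = infer_abundance(loaded, bulk)
        np.testing.assert_allclose(after.p.to_numpy(), before.p.to_numpy(),
                                   atol=1e-12)
        assert proximity_score(loaded, bulk) == pytest.approx(
            proximity_score(small_model, bulk))

    def test_version_check(self, tmp_path, small_model):
        import json, zipfile
        path = tmp_path / "model.zip"
        save_model(small_model, path)
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
        assert meta["format_version"].startswith("rankdecon-model")
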