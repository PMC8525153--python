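"""t-SNE contract, structured-GMM EM, BIC selection and compositions."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from cytoilc import ClusterAssignment, EmbeddingConfig, bic_select, \
    cluster_composition, cluster_stage_association, gmm_fit, tsne_embed
from cytoilc.embed_cluster import FAMILIES, n_free_params, \
    per_sample_cluster_fractions
from conftest import make_events


def _embed_matrix(mini_panel, x, labels=None):
    vals = np.zeros((len(x), mini_panel.n_markers))
    vals[:, :x.shape[1]] = x
    em = make_events(np.abs(vals), mini_panel, scale_state="transformed")
    if labels is not None:
        em.annotations["blob"] = labels
    return em


def _blobs(rng, centers, n_each, sigma, d):
    xs, labels = [], []
    for i, c in enumerate(centers):
        mu = np.full(d, c, dtype=float)
        xs.append(rng.normal(mu, sigma, size=(n_each, d)))
        labels += [i] * n_each
    return np.vstack(xs), np.array(labels)


class TestTsne:
    def test_too_few_events_for_perplexity(self, mini_panel):
        rng = np.random.default_rng(0)
        em = _embed_matrix(mini_panel, rng.uniform(0, 1, (50, 5)))
        cfg = EmbeddingConfig(markers_used=tuple(
            mini_panel.marker_names[:5]), perplexity=30)
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(em, cfg)

    def test_separated_blobs_stay_separated(self, mini_panel):
        rng = np.random.default_rng(1)
        x, labels = _blobs(rng, centers=[0, 10, 20], n_each=100,
                           sigma=0.1, d=10)
        em = _embed_matrix(mini_panel, x)
        cfg = EmbeddingConfig(
            markers_used=tuple(mini_panel.marker_names), perplexity=30,
            seed=0)
        coords = tsne_embed(em, cfg)
        assert coords.shape == (300, 2)
        assert silhouette_score(coords, labels) > 0.5

    def test_same_seed_identical_coordinates(self, mini_panel):
        rng = np.random.default_rng(2)
        em = _embed_matrix(mini_panel, rng.uniform(0, 3, (120, 10)))
        cfg = EmbeddingConfig(markers_used=tuple(mini_panel.marker_names),
                              perplexity=10, seed=7, n_iterations=300)
        np.testing.assert_array_equal(tsne_embed(em, cfg),
                                      tsne_embed(em, cfg))


class TestGmmFit:
    def test_single_component_matches_closed_form_mle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(800, 2))
        m = gmm_fit(x, G=1, family="EII", seed=0)
        np.testing.assert_allclose(m.means[0], x.mean(axis=0), atol=1e-8)
        sigma2 = ((x - x.mean(axis=0)) ** 2).mean()  # pooled over both dims
        assert m.covariances[0][0, 0] == pytest.approx(sigma2, rel=1e-6)
        assert m.weights[0] == 1.0

    def test_loglik_monotone_in_G(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(400, 2))
        l1 = gmm_fit(x, 1, "VVV", seed=0).loglik
        l2 = gmm_fit(x, 2, "VVV", seed=0).loglik
        assert l2 >= l1 - 1e-6

    def test_two_blob_mean_recovery(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal((0, 0), 1, (500, 2)),
                       rng.normal((10, 10), 1, (500, 2))])
        m = gmm_fit(x, 2, "VVV", seed=0)
        found = m.means[np.argsort(m.means[:, 0])]
        np.testing.assert_allclose(found, [[0, 0], [10, 10]], atol=0.2)

    def test_em_never_decreases_loglik(self):
        rng = np.random.default_rng(6)
        x = np.vstack([rng.normal((0, 0), 1, (200, 2)),
                       rng.normal((4, 1), 0.5, (200, 2))])
        for fam in FAMILIES:
            m = gmm_fit(x, 3, fam, seed=1)
            assert np.all(np.diff(m.loglik_path) >= -1e-6)

    def test_free_parameter_counts(self):
        # hand-enumerated: means 2G + weights (G-1) + covariance params
        expected = {
            ("EII", 1): 3, ("EII", 3): 9,
            ("VII", 2): 7, ("VII", 3): 11,
            ("EEI", 2): 7, ("VVI", 2): 9,
            ("EEE", 2): 8, ("EEE", 3): 11,
            ("VVV", 2): 11, ("VVV", 3): 17,
        }
        for (fam, G), k in expected.items():
            assert n_free_params(fam, G) == k, (fam, G)

    def test_bic_definition(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(300, 2))
        m = gmm_fit(x, 2, "VII", seed=0)
        assert m.bic == pytest.approx(
            2 * m.loglik - m.k_params * np.log(300))

    def test_weights_sum_to_one_and_spd_covariances(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(500, 2)) * [1, 3]
        for fam in FAMILIES:
            m = gmm_fit(x, 2, fam, seed=0)
            assert m.weights.sum() == pytest.approx(1.0, abs=1e-9)
            for cov in m.covariances:
                assert np.all(np.linalg.eigvalsh(cov) > 0)
                np.testing.assert_allclose(cov, cov.T)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            gmm_fit(np.zeros((5, 2)), G=2, family="VVV", seed=0)

    def test_matches_sklearn_on_separated_blobs(self):
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal((0, 0), 1, (400, 2)),
                       rng.normal((8, 8), 1, (400, 2))])
        ours = gmm_fit(x, 2, "VVV", seed=0)
        ref = GaussianMixture(2, covariance_type="full", random_state=0,
                              n_init=3).fit(x)
        # both should reach the same (global) optimum on separated blobs
        assert ours.loglik / len(x) == pytest.approx(
            ref.score(x), abs=0.01)


class TestBicSelect:
    def test_single_gaussian_selects_G1(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            x = rng.normal(size=(300, 2))
            best, _ = bic_select(x, range(1, 6), seed=rep)
            hits += best.G == 1
        assert hits >= 18

    def test_two_blobs_select_G2(self):
        rng = np.random.default_rng(10)
        x = np.vstack([rng.normal((0, 0), 1, (300, 2)),
                       rng.normal((12, 0), 1, (300, 2))])
        best, table = bic_select(x, range(1, 5), seed=0)
        assert best.G == 2

    def test_table_covers_full_grid(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(200, 2))
        best, table = bic_select(x, range(1, 4), seed=0)
        assert len(table) == 3 * len(FAMILIES)
        ok = table[~table.failed]
        assert np.isfinite(ok.bic).all()


class TestComposition:
    def _assign(self, ids, G=3):
        class _Stub:
            pass
        m = _Stub()
        m.G = G
        return ClusterAssignment(np.asarray(ids), m)

    def test_single_label_single_column(self):
        a = self._assign([1, 1, 2, 3, 3], G=3)
        comp = cluster_composition(a, np.array(["ILC1"] * 5))
        assert comp["ILC1"].sum() == 5
        count_cols = [c for c in comp.columns if not str(c).startswith("frac")]
        assert count_cols == ["ILC1"]

    def test_crafted_counts(self):
        a = self._assign([1, 1, 2, 2, 2, 3], G=3)
        labels = np.array(["ILC1", "ILC2", "ILC1", "ILC1", "ILC2", "ILC1"])
        comp = cluster_composition(a, labels)
        assert comp.loc[1, "ILC1"] == 1 and comp.loc[1, "ILC2"] == 1
        assert comp.loc[2, "ILC1"] == 2 and comp.loc[2, "ILC2"] == 1
        assert comp.loc[3, "ILC1"] == 1
        assert comp.loc[2, "frac_ILC1"] == pytest.approx(2 / 3)

    def test_total_conserved(self):
        rng = np.random.default_rng(12)
        ids = rng.integers(1, 5, 200)
        labels = rng.choice(["ILC1", "ILC2", "nonILC"], 200)
        comp = cluster_composition(self._assign(ids, G=4), labels)
        counts = comp[[c for c in comp.columns
                       if not str(c).startswith("frac")]]
        assert counts.to_numpy().sum() == 200

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            cluster_composition(self._assign([1, 2]), np.array(["ILC1"]))


class TestStageAssociation:
    def test_identical_fractions_give_p_one(self):
        frac = pd.DataFrame({1: [0.5] * 6, 2: [0.5] * 6},
                            index=[f"s{i}" for i in range(6)])
        stages = pd.Series(["T2"] * 3 + ["T3"] * 3, index=frac.index)
        out = cluster_stage_association(frac, stages)
        assert (out.p_value == 1.0).all()

    def test_enriched_cluster_has_smallest_p(self):
        rng = np.random.default_rng(13)
        base = rng.uniform(0.2, 0.3, (10, 3))
        base[5:, 0] += 0.5  # cluster 1 enriched in the T3+ half
        frac = pd.DataFrame(base, columns=[1, 2, 3],
                            index=[f"s{i}" for i in range(10)])
        stages = pd.Series(["T2"] * 5 + ["T3"] * 5, index=frac.index)
        out = cluster_stage_association(frac, stages).set_index("cluster")
        assert out.p_value.idxmin() == 1

    def test_too_few_samples_errors(self):
        frac = pd.DataFrame({1: [0.5, 0.5]}, index=["a", "b"])
        stages = pd.Series(["T2", "T3"], index=frac.index)
        with pytest.raises(ValueError):
            cluster_stage_association(frac, stages)

    def test_per_sample_fractions_sum_to_one(self):
        rng = np.random.default_rng(14)
        ids = rng.integers(1, 4, 120)
        samples = rng.choice(["s1", "s2", "s3"], 120)
        fr = per_sample_cluster_fractions(
            ClusterAssignment(ids, type("M", (), {"G": 3})()), samples)
        np.testing.assert_allclose(fr.sum(axis=1), 1.0)
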