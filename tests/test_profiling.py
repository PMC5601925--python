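import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score, silhouette_score

from tetrascreen.errors import ConfigurationError, ValidationError
from tetrascreen.events import EventTable
from tetrascreen.profiling import (CLUSTER_IDS, ClusterRuleSet, LogicleParams,
                                   ProfileParams, RuleThresholds, assign_rule_clusters,
                                   cluster_embedding, cluster_profile,
                                   compare_clusterings, downsample, inverse_logicle,
                                   logicle_transform, run_tsne)
from tetrascreen.synthetic import (DEFAULT_ARCHETYPES, PHENOTYPE_MARKERS, NoiseModel,
                                   archetype_thresholds)


def oracle_logicle(x, w=0.25, t=16409.0, m=4.5, a=0.0):
    """Independent oracle: per-value Brent root-finding on the biexponential."""
    span = m + a
    wn = w / span
    x2 = a / span
    x1 = x2 + wn
    x0 = x2 + 2 * wn
    b = span * np.log(10.0)
    d = brentq(lambda dd: 2 * (np.log(dd) - np.log(b)) + wn * (b + dd), 1e-12, b,
               xtol=1e-15)
    c_a = np.exp(x0 * (b + d))
    mf_a = np.exp(b * x1) - c_a * np.exp(-d * x1)
    aa = t / ((np.exp(b) - mf_a) - c_a * np.exp(-d))
    cc = c_a * aa
    ff = mf_a * aa

    def biexp(y):
        return aa * np.exp(b * y) - cc * np.exp(-d * y) - ff

    return np.array([brentq(lambda y: biexp(y) - xi, -5, 5, xtol=1e-13) * span
                     for xi in np.atleast_1d(x)])


class TestLogicle:
    def test_monotone_on_grid(self, logicle):
        grid = np.linspace(-100, 16409, 1000)
        vals = logicle_transform(grid, logicle)
        assert np.all(np.diff(vals) > 0)

    def test_round_trip(self, logicle):
        grid = np.linspace(-100, 16409, 513)
        back = inverse_logicle(logicle_transform(grid, logicle), logicle)
        assert np.max(np.abs(back - grid) / np.maximum(np.abs(grid), 1.0)) < 1e-6

    def test_top_of_scale_maps_to_m(self, logicle):
        assert logicle_transform(np.array([16409.0]), logicle)[0] == pytest.approx(4.5, abs=1e-8)
        assert oracle_logicle(16409.0)[0] == pytest.approx(4.5, abs=1e-8)

    def test_agrees_with_independent_oracle(self, logicle):
        xs = np.array([-100.0, -1.0, 0.0, 0.5, 5.0, 100.0, 2500.0, 16409.0])
        np.testing.assert_allclose(logicle_transform(xs, logicle),
                                   oracle_logicle(xs), atol=1e-8)

    def test_nonzero_a_parameter(self):
        p = LogicleParams(w=0.5, t=262144.0, m=4.5, a=0.5)
        xs = np.array([-50.0, 0.0, 10.0, 262144.0])
        np.testing.assert_allclose(logicle_transform(xs, p),
                                   oracle_logicle(xs, 0.5, 262144.0, 4.5, 0.5),
                                   atol=1e-8)

    @settings(max_examples=100, deadline=None)
    @given(x=st.floats(min_value=-100.0, max_value=16409.0),
           y=st.floats(min_value=-100.0, max_value=16409.0))
    def test_property_monotone_and_invertible(self, x, y):
        p = LogicleParams()
        fx, fy = logicle_transform(np.array([x, y]), p)
        if x + 1e-6 < y:  # strict order only at representable separations
            assert fx < fy
        back = inverse_logicle(np.array([fx]), p)[0]
        assert abs(back - x) <= 1e-6 * max(abs(x), 1.0)

    @pytest.mark.parametrize("kw", [{"t": -1.0}, {"m": 0.0}, {"w": 3.0}, {"a": -0.1}])
    def test_invalid_params(self, kw):
        with pytest.raises(ValidationError):
            LogicleParams(**kw)

    def test_dataframe_round_trip(self, logicle):
        df = pd.DataFrame({"a": [0.0, 10.0], "b": [100.0, 1000.0]})
        out = logicle_transform(df, logicle)
        assert list(out.columns) == ["a", "b"]
        np.testing.assert_allclose(inverse_logicle(out, logicle).to_numpy(),
                                   df.to_numpy(), atol=1e-8)


class TestDownsample:
    def test_cap_applied_exactly(self):
        df = pd.DataFrame({"x": np.arange(25_000.0)})
        out = downsample(df, 10_000, seed=1)
        assert len(out) == 10_000

    def test_small_input_kept(self):
        df = pd.DataFrame({"x": np.arange(500.0)})
        assert len(downsample(df, 10_000, seed=1)) == 500

    def test_no_duplicates(self):
        df = pd.DataFrame({"x": np.arange(25_000.0)})
        out = downsample(df, 10_000, seed=2)
        assert out["x"].is_unique

    def test_deterministic(self):
        df = pd.DataFrame({"x": np.arange(25_000.0)})
        pd.testing.assert_frame_equal(downsample(df, 100, seed=3),
                                      downsample(df, 100, seed=3))

    def test_event_table_supported(self, tumour_events):
        out = downsample(tumour_events, 1000, seed=4)
        assert isinstance(out, EventTable)
        assert out.n_events == 1000
        assert out.truth is not None

    def test_unbiased_frequencies(self, tumour_events):
        truth = tumour_events.truth["antigen"].to_numpy()
        p = (truth == "mLama4").mean()
        out = downsample(tumour_events, 10_000, seed=5)
        q = (out.truth["antigen"] == "mLama4").mean()
        sd = np.sqrt(p * (1 - p) / 10_000)
        assert abs(q - p) < 3 * sd


@pytest.fixture(scope="module")
def blobs():
    X, y = make_blobs(n_samples=2000, n_features=20, centers=2,
                      cluster_std=1.0, center_box=(-8, 8), random_state=0)
    return X, y


class TestTsne:

    def test_separates_blobs(self, blobs):
        X, y = blobs
        emb = run_tsne(X, ProfileParams(seed=0, n_iter=500))
        assert silhouette_score(emb.embedding, y) > 0.5

    def test_deterministic(self, blobs):
        X, _ = blobs
        p = ProfileParams(seed=1, n_iter=260)
        e1 = run_tsne(X[:400], p).embedding
        e2 = run_tsne(X[:400], p).embedding
        np.testing.assert_array_equal(e1, e2)

    def test_duplicates_embed_nearby(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (300, 10))
        X[150:] = X[:150]  # exact duplicates
        emb = run_tsne(X, ProfileParams(seed=0, perplexity=20, n_iter=400)).embedding
        d_dup = np.linalg.norm(emb[:150] - emb[150:], axis=1)
        spread = np.linalg.norm(emb - emb.mean(0), axis=1).mean()
        assert np.median(d_dup) < 0.25 * spread

    def test_too_few_rows(self):
        with pytest.raises(ValidationError, match="91"):
            run_tsne(np.zeros((50, 5)), ProfileParams(perplexity=30))

    def test_kl_reported(self, blobs):
        X, _ = blobs
        emb = run_tsne(X[:300], ProfileParams(seed=0, n_iter=260))
        assert len(emb.kl_checkpoints) >= 1
        assert np.isfinite(emb.kl_checkpoints[0])


class TestKMeans:
    def test_recovers_separated_blobs(self):
        X, y = make_blobs(n_samples=1500, n_features=2, centers=10,
                          cluster_std=0.3, center_box=(-30, 30), random_state=2)
        model = cluster_embedding(X, k=10, restarts=50, seed=0)
        assert adjusted_rand_score(y, model.labels) == 1.0
        assert set(model.labels) == set(range(1, 11))

    def test_k1_single_cluster_total_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (500, 2))
        model = cluster_embedding(X, k=1, restarts=1, seed=0)
        assert len(set(model.labels)) == 1
        total_ss = float(((X - X.mean(0)) ** 2).sum())
        assert model.wcss == pytest.approx(total_ss, rel=1e-9)

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(i, 0.8, (40, 2)) for i in range(8)])
        w1 = cluster_embedding(X, k=8, restarts=1, seed=0).wcss
        w1000 = cluster_embedding(X, k=8, restarts=1000, seed=0).wcss
        assert w1000 <= w1 + 1e-9

    def test_too_few_rows(self):
        with pytest.raises(ValidationError):
            cluster_embedding(np.zeros((5, 2)), k=10)

    def test_deterministic(self):
        X, _ = make_blobs(n_samples=300, centers=4, n_features=2, random_state=4)
        m1 = cluster_embedding(X, k=4, restarts=20, seed=9)
        m2 = cluster_embedding(X, k=4, restarts=20, seed=9)
        np.testing.assert_array_equal(m1.labels, m2.labels)


def _archetype_cells(cid, n, noise, rng, logicle_params):
    arch = DEFAULT_ARCHETYPES[cid]
    X = np.column_stack([noise.draw_level(rng, arch.levels[m], n)
                         for m in PHENOTYPE_MARKERS])
    return pd.DataFrame(logicle_transform(X, logicle_params),
                        columns=PHENOTYPE_MARKERS)


class TestRuleClusters:
    def test_c3_cells_labeled_c3(self, noise, logicle):
        rng = np.random.default_rng(0)
        df = _archetype_cells("C3", 3000, noise, rng, logicle)
        labels = assign_rule_clusters(df, archetype_thresholds(noise, logicle))
        assert (labels == "C3").mean() >= 0.95

    @pytest.mark.parametrize("cid", CLUSTER_IDS)
    def test_every_archetype_recovered(self, cid, noise, logicle):
        rng = np.random.default_rng(10)
        df = _archetype_cells(cid, 1000, noise, rng, logicle)
        labels = assign_rule_clusters(df, archetype_thresholds(noise, logicle))
        assert (labels == cid).mean() >= 0.95

    def test_background_goes_to_c1_or_c2(self, noise, noise_free, logicle):
        # exact at zero noise; a tiny background tail is tolerated at default noise
        X0 = np.zeros((500, len(PHENOTYPE_MARKERS)))
        df0 = pd.DataFrame(logicle_transform(X0, logicle), columns=PHENOTYPE_MARKERS)
        labels0 = assign_rule_clusters(df0, archetype_thresholds(noise, logicle))
        assert set(np.unique(labels0)) <= {"C1", "C2"}

        rng = np.random.default_rng(1)
        X = np.column_stack([noise.draw_level(rng, "negative", 2000)
                             for _ in PHENOTYPE_MARKERS])
        df = pd.DataFrame(logicle_transform(X, logicle), columns=PHENOTYPE_MARKERS)
        labels = assign_rule_clusters(df, archetype_thresholds(noise, logicle))
        assert np.isin(labels, ["C1", "C2"]).mean() >= 0.99

    def test_missing_marker_rejected(self, noise, logicle):
        df = pd.DataFrame({"PD-1": [1.0]})
        with pytest.raises(ConfigurationError):
            assign_rule_clusters(df, archetype_thresholds(noise, logicle))

    def test_invariant_to_monotone_rescaling(self, noise, logicle):
        rng = np.random.default_rng(2)
        df = pd.concat([_archetype_cells(c, 200, noise, rng, logicle)
                        for c in CLUSTER_IDS], ignore_index=True)
        thr = archetype_thresholds(noise, logicle)
        labels = assign_rule_clusters(df, thr)
        scaled = df * 2.0 + 1.0
        thr2 = RuleThresholds(positive={m: 2 * v + 1 for m, v in thr.positive.items()},
                              split={m: 2 * v + 1 for m, v in thr.split.items()})
        np.testing.assert_array_equal(labels, assign_rule_clusters(scaled, thr2))


class TestCompareClusterings:
    def test_identical_balanced_labelings_closed_form(self):
        # oracle: diagonal 3x3 table with 100 per class gives chi2 = n(k-1) = 600
        labels = np.repeat(["a", "b", "c"], 100)
        stat, dof, p = compare_clusterings(labels, labels)
        assert stat == pytest.approx(600.0)
        assert dof == 4
        assert p < 1e-10

    def test_independent_labels_p_distribution(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(500):
            a = rng.integers(0, 3, 900)
            b = rng.integers(0, 3, 900)
            pvals.append(compare_clusterings(a, b)[2])
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.02 <= frac <= 0.09
        assert 0.4 < np.mean(pvals) < 0.6

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            compare_clusterings([1, 2], [1, 2, 3])

    def test_single_category_undefined(self):
        with pytest.raises(ValidationError):
            compare_clusterings(np.zeros(50), np.r_[np.zeros(25), np.ones(25)])


class TestClusterProfile:
    def test_identical_cells(self):
        df = pd.DataFrame({"m": np.full(10, 2.5)})
        prof = cluster_profile(df, ["C1"] * 10, positive_thresholds={"m": 1.0})
        assert prof.medians.loc["C1", "m"] == 2.5
        assert prof.percent_positive.loc["C1", "m"] == 100.0
        prof2 = cluster_profile(df, ["C1"] * 10, positive_thresholds={"m": 3.0})
        assert prof2.percent_positive.loc["C1", "m"] == 0.0

    def test_archetype_ordering_recovered(self, noise, logicle):
        rng = np.random.default_rng(3)
        df = pd.concat([_archetype_cells("C2", 500, noise, rng, logicle),
                        _archetype_cells("C5", 500, noise, rng, logicle)],
                       ignore_index=True)
        labels = ["C2"] * 500 + ["C5"] * 500
        prof = cluster_profile(df, labels)
        # C5 is PD-1/Tim-3/CD39 high; C2 is negative for all three
        for m in ("PD-1", "Tim-3", "CD39"):
            assert prof.medians.loc["C5", m] > prof.medians.loc["C2", m] + 1.0

    def test_sizes_sum_to_total(self, noise, logicle):
        rng = np.random.default_rng(4)
        df = _archetype_cells("C1", 700, noise, rng, logicle)
        labels = rng.choice(["C1", "C2", "C3"], 700)
        prof = cluster_profile(df, labels)
        assert int(prof.n.sum()) == 700

    def test_empty_cluster_flagged(self):
        df = pd.DataFrame({"m": [1.0, 2.0]})
        prof = cluster_profile(df, ["C1", "C1"], cluster_order=["C1", "C2"])
        assert prof.n.loc["C2"] == 0
        assert np.isnan(prof.medians.loc["C2", "m"])

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValidationError):
            cluster_profile(pd.DataFrame({"m": [1.0]}), ["C1", "C2"])
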