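import numpy as np
import pytest

from fivep_cre import (
    ClusterFeatures,
    CtssIndex,
    CtssRecord,
    LogisticModel,
    apply_cutoff,
    compute_features,
    fit_logistic,
    label_by_atac,
    roc_auc,
)
from fivep_cre.classify import FitError, TrainingDataError, PREDICTORS
from fivep_cre.cluster import TssCluster
from fivep_cre.io import SignalTrack


def cluster_at(positions, counts, chrom="chr1", strand="+"):
    pos = np.asarray(positions)
    return TssCluster(
        chrom, strand, int(pos[0]), int(pos[-1]) + 1,
        pos, np.asarray(counts, float), 0.0, float("inf"),
    )


def index_from(sites):
    """sites: (pos, umi, g_umi) on chr1 + strand."""
    return CtssIndex(
        CtssRecord("chr1", p, "+", {"B": (u, g)}) for p, u, g in sites
    )


class TestComputeFeatures:
    def test_point_source_with_empty_background(self):
        idx = index_from([(5000, 40, 10)])
        c = cluster_at([5000], [40])
        f = compute_features(c, idx)
        assert f.cluster_count == f.summit_count == f.flanking_count == 40
        assert f.corrected_expression == pytest.approx(40.0)
        assert f.unencoded_g_pct == pytest.approx(0.25)

    def test_uniform_background_cancels_flanking_count(self):
        # 1 UMI/bp across the whole +/-2000 window: observed flank equals
        # expectation, so the corrected count clips to ~0
        sites = [(p, 1, 0) for p in range(3000, 7001)]
        idx = index_from(sites)
        c = cluster_at([5000], [1])
        f = compute_features(c, idx)
        assert f.corrected_expression == pytest.approx(0.0, abs=1e-9)

    def test_planted_excess_over_background(self):
        # flanking: 120 UMIs at the summit; background B UMIs uniform outside
        bg = [(p, 1, 0) for p in range(3200, 3585)]  # 385 background UMIs
        idx = index_from(bg + [(5000, 120, 0)])
        c = cluster_at([5000], [120])
        f = compute_features(c, idx)
        lam = 385 / (2 * 2000 - 151)
        assert f.flanking_count == 120
        assert f.corrected_expression == pytest.approx(120 - lam * 151)

    def test_background_window_must_exceed_flank(self):
        idx = index_from([(5000, 10, 0)])
        with pytest.raises(ValueError):
            compute_features(cluster_at([5000], [10]), idx, background_half_width=75)

    def test_unknown_strand_data_raises(self):
        idx = index_from([(5000, 10, 0)])
        c = cluster_at([5000], [10], strand="-")
        with pytest.raises(KeyError):
            compute_features(c, idx)

    def test_feature_invariants_rejected(self):
        with pytest.raises(ValueError):
            ClusterFeatures(5, 6, 6, 0.1, 0.0)  # summit > cluster
        with pytest.raises(ValueError):
            ClusterFeatures(5, 3, 2, 0.1, 0.0)  # flanking < summit
        with pytest.raises(ValueError):
            ClusterFeatures(5, 3, 3, 1.5, 0.0)  # pct out of range


class TestLabelByAtac:
    def _clusters(self, n=125):
        return [cluster_at([p], [10]) for p in range(1000, 1000 + 200 * n, 200)]

    def test_zero_signal_is_negative_peak_signal_is_positive(self):
        clusters = self._clusters()
        track = SignalTrack.from_intervals(
            [("chr1", c.summit - 80, c.summit + 80, 10.0) for c in clusters[:60]]
        )
        labels = label_by_atac(clusters, track, min_per_class=50)
        assert {l.label for l in labels[:60]} == {"positive"}
        assert {l.label for l in labels[60:]} == {"negative"}

    def test_mid_signal_excluded(self):
        clusters = self._clusters()
        ivs = [("chr1", c.summit - 80, c.summit + 80, 10.0) for c in clusters[:60]]
        ivs.append(("chr1", clusters[60].summit - 80, clusters[60].summit + 80, 1.0))
        labels = label_by_atac(clusters, SignalTrack.from_intervals(ivs), min_per_class=50)
        assert labels[60].label == "excluded"
        assert sum(l.label == "negative" for l in labels) == 64

    def test_too_few_examples_raises(self):
        clusters = self._clusters()[:20]
        track = SignalTrack.from_intervals(
            [("chr1", c.summit - 80, c.summit + 80, 10.0) for c in clusters[:10]]
        )
        with pytest.raises(TrainingDataError):
            label_by_atac(clusters, track, min_per_class=50)


def simulate_features(rng, n, beta):
    """Bernoulli draws from a logistic model on the transformed predictors.

    Counts are low-mean so that both classes stay well represented under the
    given coefficients.
    """
    flank = rng.poisson(1.5, size=n)
    gpct = rng.random(size=n)
    corr = rng.poisson(1.5, size=n)
    x = np.column_stack([np.log2(flank + 1.0), gpct, np.log2(corr + 1.0)])
    p = 1 / (1 + np.exp(-(beta[0] + x @ np.asarray(beta[1:]))))
    y = (rng.random(n) < p).astype(int)
    feats = [
        ClusterFeatures(int(f), 0, int(f), float(g), float(c))
        for f, g, c in zip(flank, gpct, corr)
    ]
    return feats, y


class TestFitLogistic:
    def test_recovers_known_coefficients_within_3_se(self):
        beta = (-2.0, 1.0, 6.0, 0.8)
        rng = np.random.default_rng(71)
        feats, y = simulate_features(rng, 5000, beta)
        model = fit_logistic(feats, y)
        est = [model.intercept, *model.coef.values()]
        ses = [model.standard_errors[k] for k in ("intercept", *PREDICTORS)]
        for b, e, se in zip(beta, est, ses):
            assert abs(e - b) <= 3 * se

    def test_permuted_labels_give_null_slopes(self):
        rng = np.random.default_rng(72)
        feats, y = simulate_features(rng, 5000, (-2.0, 1.0, 6.0, 0.8))
        rng.shuffle(y)
        model = fit_logistic(feats, y)
        for name in PREDICTORS:
            assert abs(model.coef[name]) <= 3 * model.standard_errors[name]

    def test_collinear_predictors_raise_without_l2(self):
        rng = np.random.default_rng(73)
        flank = rng.integers(0, 300, size=500)
        y = (flank > 150).astype(int)
        # corrected_expression duplicates flanking_count exactly (both use
        # the log2(x+1) transform), a singular design
        feats = [ClusterFeatures(int(f), 0, int(f), 0.0, float(f)) for f in flank]
        with pytest.raises(FitError):
            fit_logistic(feats, y, allow_l2=False)
        model = fit_logistic(feats, y, allow_l2=True)
        assert model.metadata["method"] == "l2"

    def test_perfect_separation_flagged_under_l2(self):
        rng = np.random.default_rng(74)
        flank = rng.integers(0, 300, size=500)
        y = (flank > 150).astype(int)
        feats = [ClusterFeatures(int(f), 0, int(f), 0.0, 0.0) for f in flank]
        model = fit_logistic(feats, y, allow_l2=True)
        assert model.metadata["method"] == "l2"


class TestPredict:
    def test_zero_model_gives_half(self):
        m = LogisticModel(0.0, {n: 0.0 for n in PREDICTORS})
        assert m.predict_probability(ClusterFeatures(5, 1, 3, 0.5, 2.0)) == 0.5

    def test_intercept_only_closed_form(self):
        m = LogisticModel(1.0, {n: 0.0 for n in PREDICTORS})
        p = m.predict_probability(ClusterFeatures(5, 1, 3, 0.5, 2.0))
        assert p == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)

    def test_saturates_at_one(self):
        m = LogisticModel(1000.0, {n: 0.0 for n in PREDICTORS})
        assert m.predict_probability(ClusterFeatures(5, 1, 3, 0.5, 2.0)) == 1.0

    def test_monotone_in_positive_coefficient_feature(self):
        m = LogisticModel(-1.0, {"flanking_count": 1.0, "unencoded_g_pct": 2.0,
                                 "corrected_expression": 0.5})
        probs = [
            m.predict_probability(ClusterFeatures(100, 0, f, 0.3, 10.0))
            for f in (1, 10, 100)
        ]
        assert probs == sorted(probs)

    def test_round_trip_probabilities_identical(self, tmp_path):
        rng = np.random.default_rng(75)
        feats, y = simulate_features(rng, 500, (-1.0, 0.5, 3.0, 0.4))
        model = fit_logistic(feats, y, min_per_class=10)
        path = tmp_path / "model.txt"
        model.save(str(path))
        loaded = LogisticModel.load(str(path))
        p0 = model.predict_probability(feats)
        p1 = loaded.predict_probability(feats)
        assert np.max(np.abs(p0 - p1)) <= 1e-12


class TestCutoff:
    def test_boundary_is_kept(self):
        mask = apply_cutoff([0.5, 0.49, 0.51], 0.5)
        assert mask.tolist() == [True, False, True]

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_invalid_cutoff_rejected(self, bad):
        with pytest.raises(ValueError):
            apply_cutoff([0.5], bad)


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(76)
        s = rng.random(200)
        y = rng.integers(0, 2, size=200)
        assert roc_auc(s, y) == pytest.approx(roc_auc(np.exp(5 * s), y), abs=1e-12)
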