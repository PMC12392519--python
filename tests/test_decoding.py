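import numpy as np
import pandas as pd
import pytest

from thetadefeat.decoding import (DecoderResult, METRICS, build_features,
                                  compare_featuresets, shuffle_control,
                                  train_eval)
from thetadefeat.spectral import BAND_ORDER


def tidy_table(n_subjects=8, epochs_per_subject=6, separation=0.0, seed=0,
               regions=("BLA", "vHPC"), region_signal=("BLA", "vHPC")):
    """Tidy band-power rows for a two-class cohort; ``separation`` shifts the
    class means of the theta column in ``region_signal`` regions."""
    rng = np.random.default_rng(seed)
    rows = []
    for label in ("CON", "RSDS"):
        for s in range(n_subjects):
            subject = f"{label}{s}"
            for e in range(epochs_per_subject):
                sid = f"{subject}:ev{e}"
                for region in regions:
                    for band in BAND_ORDER:
                        v = rng.normal(1.0, 0.3)
                        if (band == "theta" and label == "RSDS"
                                and region in region_signal):
                            v += separation
                        rows.append({"sample_id": sid, "subject": subject,
                                     "label": label, "region": region,
                                     "band": band, "value": v})
    return pd.DataFrame(rows)


class TestBuildFeatures:
    def test_column_count_and_order(self):
        t = tidy_table()
        single = build_features(t, ["BLA"])
        fused = build_features(t, ["BLA", "vHPC"])
        assert list(single.X.columns) == [f"BLA:{b}" for b in BAND_ORDER]
        assert list(fused.X.columns) == ([f"BLA:{b}" for b in BAND_ORDER]
                                         + [f"vHPC:{b}" for b in BAND_ORDER])

    def test_order_invariant_under_row_shuffle(self):
        t = tidy_table()
        shuffled = t.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = build_features(t, ["BLA", "vHPC"])
        b = build_features(shuffled, ["BLA", "vHPC"])
        assert list(a.X.columns) == list(b.X.columns)
        pd.testing.assert_frame_equal(a.X.sort_index(), b.X.sort_index())

    def test_missing_band_raises(self):
        t = tidy_table()
        t = t[~((t["band"] == "beta") & (t["sample_id"] == "CON0:ev0"))]
        with pytest.raises(ValueError, match="beta|CON0"):
            build_features(t, ["BLA"])


class TestTrainEval:
    def test_separable_clusters_perfect_accuracy(self):
        t = tidy_table(separation=50.0, seed=1)
        metrics = train_eval(build_features(t, ["BLA", "vHPC"]), seed=0)
        assert metrics["accuracy"] == 100.0
        assert metrics["auc"] == 100.0

    def test_chance_level_when_labels_independent(self):
        accs = []
        for seed in range(40):
            t = tidy_table(separation=0.0, seed=seed)
            accs.append(train_eval(build_features(t, ["BLA"]), seed=seed)
                        ["accuracy"])
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 50.0) <= 3 * max(se, 1.0)


class TestShuffleControl:
    def test_repetition_count_and_determinism(self):
        t = tidy_table(separation=1.0)
        f = build_features(t, ["BLA"])
        a = shuffle_control(f, n=5, seed=42)
        b = shuffle_control(f, n=5, seed=42)
        assert a.n_repetitions == 5
        for m in METRICS:
            assert np.array_equal(a.real[m], b.real[m])
            assert np.array_equal(a.shuffled[m], b.shuffled[m])

    def test_real_beats_shuffled_with_signal_and_fused_wins(self):
        t = tidy_table(n_subjects=12, separation=2.0, seed=3)
        results = {}
        for name, regions in (("BLA", ["BLA"]), ("vHPC", ["vHPC"]),
                              ("FUSED", ["BLA", "vHPC"])):
            res = shuffle_control(build_features(t, regions), n=30, seed=7,
                                  featureset=name)
            assert (res.mean("real")["accuracy"]
                    > np.quantile(res.shuffled["accuracy"], 0.975))
            results[name] = res
        fused = results["FUSED"].mean("real")["accuracy"]
        assert fused >= results["BLA"].mean("real")["accuracy"] - 1e-9
        assert fused >= results["vHPC"].mean("real")["accuracy"] - 1e-9

    def test_shuffled_accuracy_at_majority_rate(self):
        t = tidy_table(separation=2.0, seed=9)
        res = shuffle_control(build_features(t, ["BLA"]), n=60, seed=1)
        accs = res.shuffled["accuracy"]
        se = np.std(accs, ddof=1) / np.sqrt(accs.size)
        # balanced classes: majority rate 50%
        assert abs(np.mean(accs) - 50.0) <= 3 * max(se, 1.5)

    def test_zero_repetitions_raises(self):
        t = tidy_table()
        with pytest.raises(ValueError):
            shuffle_control(build_features(t, ["BLA"]), n=0)


def _result(featureset, real_acc, shuf_acc):
    n = len(real_acc)
    fill = {m: np.asarray(real_acc, dtype=float) for m in METRICS}
    fills = {m: np.asarray(shuf_acc, dtype=float) for m in METRICS}
    return DecoderResult(featureset=featureset, real=fill, shuffled=fills,
                         n_repetitions=n)


class TestCompareFeaturesets:
    def test_identical_distributions_p_near_one(self, rng):
        vals = rng.normal(50, 5, size=400)
        results = {f: _result(f, vals, vals) for f in ("BLA", "vHPC", "FUSED")}
        report = compare_featuresets(results)
        assert (report["p_two_sided"] > 0.5).all()

    def test_disjoint_distributions_smallest_p(self, rng):
        real = rng.normal(90, 1, size=200)
        shuf = rng.normal(50, 1, size=200)
        results = {f: _result(f, real, shuf) for f in ("BLA", "vHPC", "FUSED")}
        report = compare_featuresets(results)
        assert np.allclose(report["p_two_sided"], 2 / 201)

    def test_ranking_prefers_stronger_featureset(self, rng):
        results = {
            "BLA": _result("BLA", rng.normal(70, 1, 100), rng.normal(50, 1, 100)),
            "vHPC": _result("vHPC", rng.normal(65, 1, 100), rng.normal(50, 1, 100)),
            "FUSED": _result("FUSED", rng.normal(85, 1, 100), rng.normal(50, 1, 100)),
        }
        report = compare_featuresets(results)
        ranks = report.set_index("featureset")["rank_by_accuracy"]
        assert (ranks["FUSED"] == 1).all()

    def test_missing_featureset_raises(self, rng):
        results = {"BLA": _result("BLA", rng.normal(70, 1, 50),
                                  rng.normal(50, 1, 50))}
        with pytest.raises(ValueError, match="missing"):
            compare_featuresets(results)


class TestLeakageGuard:
    def test_label_using_selection_inflates_chance_accuracy(self):
        """Negative control: selecting features by their full-dataset label
        correlation (a leak across the train/test boundary) inflates accuracy
        on pure-noise features well above the chance level the proper
        train-fold-only route stays at."""
        rng = np.random.default_rng(0)
        proper, leaky = [], []
        for rep in range(15):
            X = rng.standard_normal((40, 200))
            y = np.array(["CON", "RSDS"] * 20)
            subjects = np.array([f"s{i}" for i in range(40)])
            # leaky route: pick the 5 columns most label-correlated overall
            ybin = (y == "RSDS").astype(float)
            corr = np.abs((X - X.mean(0)).T @ (ybin - ybin.mean())) / X.shape[0]
            cols = np.argsort(corr)[-5:]
            from thetadefeat.decoding import FeatureTable
            make = lambda M: FeatureTable(
                X=pd.DataFrame(M, index=[f"r{i}" for i in range(40)]),
                y=y, subjects=subjects)
            leaky.append(train_eval(make(X[:, cols]), seed=rep,
                                    unit="subject")["accuracy"])
            proper.append(train_eval(make(X[:, :5]), seed=rep,
                                     unit="subject")["accuracy"])
        assert np.mean(leaky) > np.mean(proper) + 10.0
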