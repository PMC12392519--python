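"""SVM decoding of stress group from band-power features, with a
shuffle-null control.

The decoder distinguishes control from stressed (susceptible) animals from
the mean PSD in five frequency bands per region — 5 features for a single
region, 10 for the fused BLA+vHPC set. Each repetition draws a fresh
stratified 80/20 split, fits a maximum-margin (RBF-kernel SVM) classifier on
the training portion (standardization fitted on the training fold only,
inside an sklearn Pipeline), and evaluates accuracy, precision, F1 (positive
class = stressed) and ROC AUC on the held-out portion. A matched shuffled
run re-scores the identical split and hyperparameters under null labels:
by default the subject->label assignment is permuted within each side of
the split (labels stay constant within a subject and both partitions keep
their class balance, so the null is centred on the majority-class rate); a
circular offset of the label vector along the subject-ordered sample
sequence is available as an alternative scheme, but with block-contiguous
labels small offsets retain most of the true alignment, making that null
very wide.

Because the study has few subjects, the default sample unit is the epoch
with subject-grouped splitting (all epochs of a subject land on one side of
the split, preventing subject leakage); ``unit="subject"`` collapses to one
sample per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             roc_auc_score)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .spectral import BAND_ORDER

POSITIVE_CLASS = "RSDS"
NEGATIVE_CLASS = "CON"
METRICS = ("accuracy", "precision", "f1", "auc")
FEATURESETS = ("BLA", "vHPC", "FUSED")


@dataclass
class FeatureTable:
    """Samples x band-power features with labels and subject ids.

    Columns are ordered (region, band ascending-frequency); labels are the
    two class names; ``subjects`` drives grouped splitting.
    """

    X: pd.DataFrame
    y: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        classes, counts = np.unique(self.y, return_counts=True)
        if len(classes) != 2 or counts.min() < 2:
            raise ValueError("need two classes with >= 2 samples each")
        if self.X.index.duplicated().any():
            dup = self.X.index[self.X.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")

    @property
    def n_samples(self) -> int:
        return len(self.X)


def build_features(band_powers: pd.DataFrame, regions: list[str]) -> FeatureTable:
    """Pivot a tidy band-power table into a FeatureTable.

    ``band_powers`` needs columns sample_id, subject, label, region, band,
    value (one row per sample x region x band, full-epoch stage). Column
    order of the result is deterministic: regions in the given order, bands
    ascending in frequency.
    """
    required = {"sample_id", "subject", "label", "region", "band", "value"}
    missing = required - set(band_powers.columns)
    if missing:
        raise ValueError(f"band_powers missing columns {sorted(missing)}")
    sub = band_powers[band_powers["region"].isin(regions)]
    wide = sub.pivot_table(index="sample_id", columns=["region", "band"],
                           values="value", aggfunc="first")
    columns = []
    for region in regions:
        for band in BAND_ORDER:
            col = (region, band)
            if col not in wide.columns:
                bad = wide.index[wide.index.notna()][:1]
                raise ValueError(
                    f"missing band {band!r} for region {region!r} "
                    f"(e.g. sample {bad.tolist()})"
                )
            columns.append(col)
    wide = wide[columns]
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"sample {bad!r} lacks a band/region value")
    wide.columns = [f"{r}:{b}" for r, b in wide.columns]
    meta = sub.drop_duplicates("sample_id").set_index("sample_id")
    meta = meta.loc[wide.index]
    return FeatureTable(X=wide, y=meta["label"].to_numpy(),
                        subjects=meta["subject"].to_numpy())


def _make_classifier(kernel: str, seed: int | None) -> Pipeline:
    # scaler inside the pipeline => standardization parameters come from the
    # training folds only (leakage guard)
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(C=1.0, kernel=kernel, gamma="scale",
                    random_state=seed)),
    ])


def _subject_labels(features: FeatureTable) -> dict:
    out: dict = {}
    for subj, label in zip(features.subjects, features.y):
        out[subj] = label
    return out


def _split(features: FeatureTable, split: float, rng: np.random.Generator,
           unit: str) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified 80/20 split at the subject level.

    All epochs of a subject land on one side (no subject leakage), and the
    held-out subjects are drawn per class so both partitions stay balanced —
    with few subjects an unstratified grouped draw leaves the test set
    dominated by one class and biases test accuracy below chance.
    Redraws up to 10 times if a class still ends up missing from a side.
    """
    subj_label = _subject_labels(features)
    for _ in range(10):
        test_subjects: list = []
        for cls in np.unique(features.y):
            members = [s for s, lab in subj_label.items() if lab == cls]
            n_test = max(1, int(round((1 - split) * len(members))))
            if n_test >= len(members):
                n_test = len(members) - 1
            picked = rng.choice(len(members), size=n_test, replace=False)
            test_subjects += [members[i] for i in picked]
        in_test = np.isin(features.subjects, test_subjects)
        train = np.flatnonzero(~in_test)
        test = np.flatnonzero(in_test)
        if (len(set(features.y[train])) == 2 and
                len(set(features.y[test])) == 2):
            return train, test
    raise RuntimeError(
        "could not draw a split with both classes on both sides; "
        "need at least 2 subjects per class"
    )


def _evaluate(clf: Pipeline, X: pd.DataFrame, y: np.ndarray,
              train: np.ndarray, test: np.ndarray) -> dict[str, float]:
    ybin = (y == POSITIVE_CLASS).astype(int)
    clf.fit(X.iloc[train], ybin[train])
    pred = clf.predict(X.iloc[test])
    scores = clf.decision_function(X.iloc[test])
    true = ybin[test]
    return {
        "accuracy": 100.0 * accuracy_score(true, pred),
        "precision": 100.0 * precision_score(true, pred, zero_division=0),
        "f1": 100.0 * f1_score(true, pred, zero_division=0),
        "auc": 100.0 * (roc_auc_score(true, scores)
                        if len(set(true)) == 2 else 0.5),
    }


def train_eval(features: FeatureTable, split: float = 0.8,
               seed: int | None = None, kernel: str = "rbf",
               unit: str = "epoch") -> dict[str, float]:
    """One 80/20 train/test round; returns the four metrics in percent."""
    rng = np.random.default_rng(seed)
    train, test = _split(features, split, rng, unit)
    clf = _make_classifier(kernel, int(rng.integers(2**31 - 1)))
    return _evaluate(clf, features.X, features.y, train, test)


def _shuffle_labels(features: FeatureTable, train: np.ndarray,
                    test: np.ndarray, rng: np.random.Generator,
                    scheme: str = "within_split") -> np.ndarray:
    """Null labels for the shuffled run.

    ``within_split`` (default): permute the subject->label assignment
    separately among training subjects and among held-out subjects. This
    destroys the feature-label association completely while keeping labels
    constant within a subject and both partitions at their real class
    balance, so the null accuracy is centred on the majority-class rate.

    ``circular``: circularly offset the label vector along the
    subject-ordered sample sequence by a random nonzero offset. With labels
    contiguous in blocks this retains most of the true alignment for small
    offsets, so its null is much wider; kept for comparison.
    """
    y = features.y
    if scheme == "circular":
        order = np.argsort(features.subjects, kind="stable")
        offset = int(rng.integers(1, y.size))
        shuffled = np.empty_like(y)
        shuffled[order] = np.roll(y[order], offset)
        return shuffled
    if scheme != "within_split":
        raise ValueError(f"unknown shuffle scheme {scheme!r}")
    subj_label = _subject_labels(features)
    shuffled_map = dict(subj_label)
    for side in (train, test):
        side_subjects = list(dict.fromkeys(features.subjects[side]))
        labels = [subj_label[s] for s in side_subjects]
        perm = rng.permutation(len(labels))
        for s, j in zip(side_subjects, perm):
            shuffled_map[s] = labels[j]
    return np.array([shuffled_map[s] for s in features.subjects])


@dataclass
class DecoderResult:
    """Real and shuffle-null metric distributions over split repetitions for
    one featureset. Metrics are percentages."""

    featureset: str
    real: dict[str, np.ndarray]
    shuffled: dict[str, np.ndarray]
    n_repetitions: int
    seed: int | None = None

    def mean(self, which: str = "real") -> dict[str, float]:
        d = getattr(self, which)
        return {m: float(np.mean(d[m])) for m in METRICS}

    def sem(self, which: str = "real") -> dict[str, float]:
        d = getattr(self, which)
        return {m: float(np.std(d[m], ddof=1) / np.sqrt(self.n_repetitions))
                for m in METRICS}

    def summary(self) -> pd.DataFrame:
        """Mean +/- SEM table of real vs shuffled metrics, statsmodels-style."""
        rows = []
        for m in METRICS:
            rows.append({
                "metric": m,
                "real_mean_pct": self.mean("real")[m],
                "real_sem_pct": self.sem("real")[m],
                "shuffled_mean_pct": self.mean("shuffled")[m],
                "shuffled_sem_pct": self.sem("shuffled")[m],
            })
        return pd.DataFrame(rows).set_index("metric")

    def to_dict(self) -> dict:
        return {
            "featureset": self.featureset,
            "n_repetitions": self.n_repetitions,
            "real_mean": self.mean("real"),
            "real_sem": self.sem("real"),
            "shuffled_mean": self.mean("shuffled"),
            "shuffled_sem": self.sem("shuffled"),
        }


def shuffle_control(features: FeatureTable, n: int = 1000,
                    seed: int | None = None, split: float = 0.8,
                    kernel: str = "rbf", unit: str = "epoch",
                    featureset: str = "FUSED",
                    shuffle_scheme: str = "within_split") -> DecoderResult:
    """Repeated real vs shuffled-label decoding with matched splits.

    For each of ``n`` repetitions: (a) a fresh stratified subject-level
    split and a real fit/evaluation; (b) a shuffled run with null labels
    (see :func:`_shuffle_labels`) using the *same* split and
    hyperparameters.
    """
    if n < 1:
        raise ValueError("need at least one repetition")
    rng = np.random.default_rng(seed)
    real = {m: np.empty(n) for m in METRICS}
    shuf = {m: np.empty(n) for m in METRICS}
    for i in range(n):
        train, test = _split(features, split, rng, unit)
        state = int(rng.integers(2**31 - 1))
        r = _evaluate(_make_classifier(kernel, state), features.X,
                      features.y, train, test)
        y_off = _shuffle_labels(features, train, test, rng, shuffle_scheme)
        s = _evaluate(_make_classifier(kernel, state), features.X,
                      y_off, train, test)
        for m in METRICS:
            real[m][i] = r[m]
            shuf[m][i] = s[m]
    return DecoderResult(featureset=featureset, real=real, shuffled=shuf,
                         n_repetitions=n, seed=seed)


class StressDecoder:
    """Model-style front end: build from a tidy band-power table, ``fit``
    runs the repeated shuffle-controlled decoding for each featureset and
    returns the per-featureset :class:`DecoderResult` objects."""

    def __init__(self, band_powers: pd.DataFrame, unit: str = "epoch",
                 kernel: str = "rbf"):
        self.tables = {
            "BLA": build_features(band_powers, ["BLA"]),
            "vHPC": build_features(band_powers, ["vHPC"]),
            "FUSED": build_features(band_powers, ["BLA", "vHPC"]),
        }
        self.unit = unit
        self.kernel = kernel

    @classmethod
    def from_dataframe(cls, band_powers: pd.DataFrame, **kwargs) -> "StressDecoder":
        return cls(band_powers, **kwargs)

    def fit(self, n_repetitions: int = 1000,
            seed: int | None = None) -> dict[str, DecoderResult]:
        results = {}
        for i, (name, table) in enumerate(self.tables.items()):
            sub_seed = None if seed is None else seed + 1000003 * i
            results[name] = shuffle_control(
                table, n=n_repetitions, seed=sub_seed, unit=self.unit,
                kernel=self.kernel, featureset=name,
            )
        return results


def compare_featuresets(results: dict[str, DecoderResult]) -> pd.DataFrame:
    """Real-vs-shuffled comparison per featureset and metric with a
    two-sided permutation p-value from the repetition distributions, plus a
    ranking of featuresets by mean real accuracy.

    The p-value is the tail rank of the mean real metric in the shuffled
    distribution, doubled and capped at 1; its smallest attainable value is
    2/(n+1).
    """
    missing = [f for f in FEATURESETS if f not in results]
    if missing:
        raise ValueError(f"missing featureset(s) {missing}")
    rank = sorted(FEATURESETS,
                  key=lambda f: -np.mean(results[f].real["accuracy"]))
    rows = []
    for name in FEATURESETS:
        res = results[name]
        for m in METRICS:
            obs = float(np.mean(res.real[m]))
            null = res.shuffled[m]
            n = null.size
            p_hi = (1 + np.sum(null >= obs)) / (n + 1)
            p_lo = (1 + np.sum(null <= obs)) / (n + 1)
            rows.append({
                "featureset": name,
                "metric": m,
                "real_mean_pct": obs,
                "shuffled_mean_pct": float(np.mean(null)),
                "p_two_sided": min(1.0, 2 * min(p_hi, p_lo)),
                "rank_by_accuracy": rank.index(name) + 1,
            })
    return pd.DataFrame(rows)
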