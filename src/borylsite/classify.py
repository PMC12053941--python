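"""Substrate-grouped training protocol for site-selectivity classification.

A model run is one end-to-end cycle: split the dataset 80:20 *by substrate*
(no substrate contributes rows to both sides), randomly oversample the
minority class of the training rows to parity, fit the reduction cascade on
the training rows, train a classifier, and score the held-out rows.  The
production protocol repeats this ten times with fresh splits and reports
each metric as mean +/- SD; per-site predictions are aggregated across runs
as vote fractions (fraction of runs calling the site borylating).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import normalize
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import schema
from .engineering import CascadeConfig, FittedCascade, fit_cascade
from .errors import ConfigError, SchemaError

ALGORITHMS = (
    "decision_tree",
    "svm",
    "random_forest",
    "mlp",
    "gaussian_process",
    "naive_bayes",
    "logistic_regression",
)

#: algorithms whose sample vectors are scaled to unit norm before use
NORMALIZED_ALGORITHMS = frozenset(
    {"svm", "mlp", "gaussian_process", "logistic_regression"}
)


def child_seed(master_seed: int, tag: str) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a master seed and tag."""
    return zlib.crc32(f"{master_seed}:{tag}".encode()) % (2**31 - 1)


@dataclass
class ModelConfig:
    """Learner + protocol settings.

    The forest defaults (500 trees, unlimited depth) are pinned here for
    determinism.  ``normalize_rows`` is forced on for SVM, MLP, Gaussian
    process and logistic regression.
    """

    algorithm: str = "random_forest"
    n_runs: int = 10
    fraction: float = 0.8
    decision_threshold: float = 0.5
    n_estimators: int = 500
    oversample: bool = True
    cascade: CascadeConfig | None = field(default_factory=CascadeConfig)
    seeds: list[int] | None = None

    @property
    def normalize_rows(self) -> bool:
        return self.algorithm in NORMALIZED_ALGORITHMS

    def run_seeds(self, master_seed: int) -> list[int]:
        if self.seeds is not None:
            if len(self.seeds) < self.n_runs:
                raise ConfigError(
                    f"{len(self.seeds)} seeds supplied for {self.n_runs} runs"
                )
            return list(self.seeds[: self.n_runs])
        return [child_seed(master_seed, f"run{i}") for i in range(self.n_runs)]


@dataclass(frozen=True)
class SplitSpec:
    """Substrate-level 80:20 split."""

    train_substrates: frozenset
    test_substrates: frozenset
    seed: int
    fraction: float = 0.8


def grouped_split(groups: Sequence, fraction: float = 0.8, seed: int = 0) -> SplitSpec:
    """Split substrates (not rows) into train/test sets.

    ``groups`` is the per-row substrate id vector or any iterable of ids;
    |train| = round(fraction x n_substrates).
    """
    if not (0.0 < fraction < 1.0):
        raise ConfigError(f"split fraction must be in (0,1), got {fraction}")
    unique = sorted(pd.unique(pd.Series(list(groups))))
    if len(unique) < 2:
        raise ConfigError("grouped split needs at least 2 substrates")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    n_train = round(fraction * len(unique))
    train = frozenset(unique[i] for i in order[:n_train])
    test = frozenset(unique[i] for i in order[n_train:])
    return SplitSpec(train_substrates=train, test_substrates=test,
                     seed=seed, fraction=fraction)


def oversample_minority(
    X: pd.DataFrame, y: pd.Series, groups: pd.Series | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series, pd.Series | None]:
    """Random oversampling of the minority class to exact parity.

    Appends with-replacement duplicates of minority rows; majority rows are
    untouched; already balanced input is returned unchanged.
    """
    y = pd.Series(np.asarray(y)).reset_index(drop=True)
    X = X.reset_index(drop=True)
    counts = y.value_counts()
    if len(counts) < 2:
        raise ConfigError("oversampling needs both classes present")
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X, y, groups.reset_index(drop=True) if groups is not None else None
    rng = np.random.default_rng(seed)
    minority_idx = np.flatnonzero(y.to_numpy() == minority)
    extra = rng.choice(minority_idx, size=deficit, replace=True)
    take = np.concatenate([np.arange(len(y)), extra])
    X2 = X.iloc[take].reset_index(drop=True)
    y2 = y.iloc[take].reset_index(drop=True)
    g2 = None
    if groups is not None:
        g2 = groups.reset_index(drop=True).iloc[take].reset_index(drop=True)
    return X2, y2, g2


def _make_estimator(algorithm: str, seed: int, config: ModelConfig):
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if algorithm == "svm":
        return SVC(probability=True, random_state=seed)
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=config.n_estimators, random_state=seed)
    if algorithm == "mlp":
        return MLPClassifier(random_state=seed, max_iter=500)
    if algorithm == "gaussian_process":
        return GaussianProcessClassifier(random_state=seed)
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    raise ConfigError(f"unknown algorithm {algorithm!r}; known: {ALGORITHMS}")


@dataclass
class FittedModel:
    """A trained classifier bound to its feature columns."""

    estimator: object
    columns: list[str]
    normalize_rows: bool
    decision_threshold: float = 0.5
    cascade: FittedCascade | None = None

    def _prepare(self, X: pd.DataFrame) -> np.ndarray:
        if self.cascade is not None:
            X = self.cascade.apply(X)
        if list(X.columns) != self.columns:
            if set(X.columns) >= set(self.columns):
                X = X.loc[:, self.columns]
            else:
                missing = sorted(set(self.columns) - set(X.columns))
                raise SchemaError(f"prediction table missing columns: {missing}")
        values = X.to_numpy(dtype=float)
        if self.normalize_rows:
            values = normalize(values)
        return values

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Per-row probability of label 1."""
        return self.estimator.predict_proba(self._prepare(X))[:, 1]


def train_classifier(
    X: pd.DataFrame,
    y: Sequence[int],
    config: ModelConfig | None = None,
    seed: int = 0,
) -> FittedModel:
    """Fit one classifier on an engineered matrix (no cascade, no split)."""
    config = config or ModelConfig()
    y = np.asarray(y)
    values = X.to_numpy(dtype=float)
    if config.normalize_rows:
        values = normalize(values)
    est = _make_estimator(config.algorithm, seed, config)
    est.fit(values, y)
    return FittedModel(
        estimator=est,
        columns=list(X.columns),
        normalize_rows=config.normalize_rows,
        decision_threshold=config.decision_threshold,
    )


def predict_sites(model: FittedModel, X: pd.DataFrame, threshold: float | None = None) -> pd.DataFrame:
    """Per-site probability and binary call (strict ``probability > threshold``).

    A probability of exactly 0.5 is a negative call, matching the
    convention that a decision value must exceed the 0.5 base value.
    """
    thr = model.decision_threshold if threshold is None else threshold
    proba = model.predict_proba(X)
    return pd.DataFrame({"probability": proba, "call": (proba > thr).astype(int)})


def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int]) -> dict[str, float]:
    """Accuracy plus per-class precision/recall/F1 (classes 0 and 1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ConfigError("metric vectors must be equal-length and non-empty")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0
    )
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision_0": float(prec[0]),
        "precision_1": float(prec[1]),
        "recall_0": float(rec[0]),
        "recall_1": float(rec[1]),
        "f1_0": float(f1[0]),
        "f1_1": float(f1[1]),
    }


METRIC_NAMES = ("accuracy", "precision_0", "precision_1", "recall_0",
                "recall_1", "f1_0", "f1_1")


@dataclass
class RunSummary:
    """Aggregated outcome of a multi-run protocol."""

    per_run: list[dict]
    mean: dict[str, float]
    sd: dict[str, float]
    vote_fractions: pd.DataFrame | None = None
    votes: pd.DataFrame | None = None
    models: list[FittedModel] | None = None

    @property
    def n_runs(self) -> int:
        return len(self.per_run)


def _feature_columns(table: pd.DataFrame, feature_names: Sequence[str] | None) -> list[str]:
    if feature_names is not None:
        return list(feature_names)
    cols = schema.feature_columns(table.columns)
    return [c for c in cols if pd.api.types.is_numeric_dtype(table[c])]


def run_protocol(
    table: pd.DataFrame,
    config: ModelConfig | None = None,
    master_seed: int = 0,
    feature_names: Sequence[str] | None = None,
    predict_table: pd.DataFrame | None = None,
    keep_models: bool = False,
    permute_feature_order_seed: int | None = None,
) -> RunSummary:
    """The multi-run protocol: fresh grouped split, oversample, cascade,
    train and evaluate per run; metrics as mean +/- SD over runs.

    ``predict_table`` rows (labeled or not) are scored by every run's model;
    their across-run vote fractions are returned (a site voted borylating in
    6 of 10 runs has vote fraction 0.6).

    ``permute_feature_order_seed`` enables the feature-order control: the
    columns of each run's *selected* feature set are presented to the
    learner in a random order (selection itself is untouched).
    """
    config = config or ModelConfig()
    feats = _feature_columns(table, feature_names)
    seeds = config.run_seeds(master_seed)
    per_run: list[dict] = []
    vote_calls = []
    models: list[FittedModel] = []
    for i, seed in enumerate(seeds):
        split = grouped_split(table["substrate_id"], fraction=config.fraction, seed=seed)
        train_mask = table["substrate_id"].isin(split.train_substrates)
        train = table[train_mask]
        test = table[~train_mask]
        X_tr = train.loc[:, feats]
        y_tr = train[schema.LABEL_COLUMN].astype(int)
        if config.oversample:
            X_tr, y_tr, _ = oversample_minority(
                X_tr, y_tr, seed=child_seed(seed, "oversample")
            )
        cascade = None
        if config.cascade is not None:
            cascade = fit_cascade(X_tr, y_tr, config.cascade,
                                  seed=child_seed(seed, "cascade"))
            X_tr = cascade.apply(X_tr)
        if permute_feature_order_seed is not None:
            prng = np.random.default_rng(
                child_seed(permute_feature_order_seed, f"perm{i}")
            )
            X_tr = X_tr.iloc[:, prng.permutation(X_tr.shape[1])]
        model = train_classifier(X_tr, y_tr, config, seed=seed)
        model.cascade = cascade
        y_te = test[schema.LABEL_COLUMN].astype(int).to_numpy()
        pred = predict_sites(model, test.loc[:, feats])
        per_run.append(compute_metrics(y_te, pred["call"].to_numpy()))
        if predict_table is not None:
            p = predict_sites(model, predict_table.loc[:, feats])
            vote_calls.append(p["call"].to_numpy())
        if keep_models:
            models.append(model)
    mean = {m: float(np.mean([r[m] for r in per_run])) for m in METRIC_NAMES}
    sd = {m: float(np.std([r[m] for r in per_run])) for m in METRIC_NAMES}
    vote_fractions = None
    votes = None
    if predict_table is not None:
        votes = pd.DataFrame(
            {f"run_{i + 1}": calls for i, calls in enumerate(vote_calls)}
        )
        votes.insert(0, "substrate_id", predict_table["substrate_id"].to_numpy())
        votes.insert(1, "atom_index", predict_table["atom_index"].to_numpy())
        frac = votes.loc[:, [c for c in votes.columns if c.startswith("run_")]].mean(axis=1)
        vote_fractions = votes[["substrate_id", "atom_index"]].copy()
        vote_fractions["vote_fraction"] = frac
    return RunSummary(
        per_run=per_run,
        mean=mean,
        sd=sd,
        vote_fractions=vote_fractions,
        votes=votes,
        models=models if keep_models else None,
    )


def format_mean_sd(mean: float, sd: float, percent: bool = True) -> str:
    """Render a metric the way benchmark tables print it, e.g. ``88.9 +/- 2.5%``."""
    if percent:
        return f"{100 * mean:.1f} ± {100 * sd:.1f}%"
    return f"{mean:.3f} ± {sd:.3f}"
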