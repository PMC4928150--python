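"""Protein-grouped fold assignment, random-forest training and prediction.

Variants of the same protein are never split across folds: all variants of
a protein share its fold, which prevents the performance inflation that
arises when a classifier is evaluated on new variants of proteins it has
already seen (protein-level circularity).  Inside cross-validation the
log-odds tables and the SIFT imputation value are, by default, rebuilt from
the nine training bins only (``lor_scope="train_fold"``), so no held-out
label can leak into any feature; ``lor_scope="full_dataset"`` computes the
tables once on all labelled variants, emulating formulas defined over the
whole variant compendium.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from ._exceptions import ConfigurationError, ContractError, ValidationError
from .evaluate import MetricsReport, compute_metrics
from .features import (
    CATEGORICAL_FEATURES,
    DEFAULT_XI,
    FEATURE_ORDER,
    FEATURE_ORDER_VERSION,
    VariantFeaturizer,
)
from .io import AnnotationBundle, Dataset
from .ontology import OntologyGraph
from .scales import DEFAULT_SCALES, AminoAcidScales

AA_ALPHABET = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_N_TREES = 26
#: Features considered per split: floor(log2(25) + 1), the classic
#: forest default for this feature count.
DEFAULT_MAX_FEATURES = 5
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class FoldAssignment:
    """A protein -> fold map for grouped k-fold cross-validation."""

    k: int
    protein_to_fold: dict[str, int]
    seed: int

    def proteins_in(self, fold: int) -> set[str]:
        return {p for p, f in self.protein_to_fold.items() if f == fold}


def assign_folds(proteins: set[str] | list[str], k: int, seed: int) -> FoldAssignment:
    """Distribute proteins uniformly at random into ``k`` near-equal bins.

    Deterministic given ``seed``; bin sizes differ by at most one.
    """
    unique = sorted(set(proteins))
    if k < 2:
        raise ConfigurationError(f"need k >= 2 folds, got {k}")
    if k > len(unique):
        raise ConfigurationError(f"k={k} exceeds number of proteins ({len(unique)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    mapping: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            mapping[unique[idx]] = fold
    return FoldAssignment(k=k, protein_to_fold=mapping, seed=seed)


def _one_hot_columns() -> list[str]:
    cols = [c for c in FEATURE_ORDER if c not in CATEGORICAL_FEATURES]
    cols += [f"wt_aa={aa}" for aa in AA_ALPHABET]
    cols += [f"mut_aa={aa}" for aa in AA_ALPHABET]
    return cols


def _encode(features: pd.DataFrame, fill_values: dict[str, float]) -> pd.DataFrame:
    """Expand the semantic frame to the numeric matrix the forest consumes."""
    numeric = features.drop(columns=list(CATEGORICAL_FEATURES)).astype(float)
    for col, fill in fill_values.items():
        numeric[col] = numeric[col].fillna(fill)
    blocks = [numeric]
    for col in CATEGORICAL_FEATURES:
        onehot = pd.DataFrame(
            {f"{col}={aa}": (features[col] == aa).astype(int) for aa in AA_ALPHABET},
            index=features.index,
        )
        blocks.append(onehot)
    out = pd.concat(blocks, axis=1)
    return out[_one_hot_columns()]


class KinaseForestClassifier(BaseEstimator, ClassifierMixin):
    """Random forest over the 25 semantic variant features.

    ``fit`` consumes the semantic feature frame produced by
    :class:`~kinvar.features.VariantFeaturizer` (wild-type/mutant residues
    still categorical) and labels in {"disease", "neutral"}.  The residues
    are one-hot encoded over the fixed 20-letter alphabet and missing SIFT
    scores are imputed with the training median; both the encoding and the
    fill value are stored on the fitted model.  ``p_disease`` is the mean
    leaf class probability across trees; the decision threshold is 0.5 with
    ties resolved to "disease".

    Parameters
    ----------
    n_trees : size of the forest (default 26).
    max_features : features considered per split (default 5).
    threshold : posterior cut-off for calling a variant pathogenic.
    random_state : seed for bootstrap and split randomness.
    """

    POSITIVE = "disease"
    NEGATIVE = "neutral"

    def __init__(
        self,
        n_trees: int = DEFAULT_N_TREES,
        max_features: int = DEFAULT_MAX_FEATURES,
        threshold: float = DEFAULT_THRESHOLD,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.threshold = threshold
        self.random_state = random_state

    def _validate_columns(self, features: pd.DataFrame) -> None:
        got = list(features.columns)
        if got != list(FEATURE_ORDER):
            missing = [c for c in FEATURE_ORDER if c not in got]
            extra = [c for c in got if c not in FEATURE_ORDER]
            raise ContractError(
                f"feature columns do not match the fixed order; missing={missing}, "
                f"unexpected={extra}"
            )

    def fit(self, X: pd.DataFrame, y):
        if self.n_trees < 1:
            raise ConfigurationError(f"n_trees must be >= 1, got {self.n_trees}")
        self._validate_columns(X)
        y = np.asarray([str(v) for v in y])
        classes = set(y)
        if classes - {self.POSITIVE, self.NEGATIVE}:
            raise ValidationError(f"labels must be disease/neutral, got {sorted(classes)}")
        counts = pd.Series(y).value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValidationError(
                f"need >= 2 variants of each class to train, got {counts.to_dict()}"
            )

        sift = X["sift_score"].astype(float)
        median = float(sift.median()) if sift.notna().any() else 0.5
        self.imputation_ = {"sift_score": median}
        matrix = _encode(X, self.imputation_)

        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=min(self.max_features, matrix.shape[1]),
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(matrix.to_numpy(), y)
        self.classes_ = self.forest_.classes_
        self.feature_order_ = list(FEATURE_ORDER)
        self.feature_order_version_ = FEATURE_ORDER_VERSION
        self.matrix_columns_ = list(matrix.columns)
        self.encoder_spec_ = {
            "categorical": {c: list(AA_ALPHABET) for c in CATEGORICAL_FEATURES},
            "probability": "mean_leaf_class_probability",
        }
        self.train_digest_ = hashlib.sha256(
            pd.util.hash_pandas_object(matrix, index=False).to_numpy().tobytes()
            + y.tobytes()
        ).hexdigest()
        return self

    def predict_proba_disease(self, X: pd.DataFrame) -> np.ndarray:
        """P(disease) per row: mean leaf class probability over the trees."""
        check_is_fitted(self, "forest_")
        self._validate_columns(X)
        if len(X) == 0:
            return np.zeros(0)
        matrix = _encode(X, self.imputation_)
        proba = self.forest_.predict_proba(matrix.to_numpy())
        col = list(self.forest_.classes_).index(self.POSITIVE)
        return proba[:, col]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_proba_disease(X)
        order = [self.NEGATIVE, self.POSITIVE]
        out = np.column_stack([1 - p, p])
        # keep sklearn's classes_ ordering contract
        if list(self.classes_) != order:
            out = out[:, [order.index(c) for c in self.classes_]]
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_proba_disease(X)
        return np.where(p >= self.threshold, self.POSITIVE, self.NEGATIVE)


@dataclass
class Prediction:
    """Posterior and call for one variant."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    p_disease: float
    label: str


def train(
    data: Dataset,
    features: pd.DataFrame,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    **kwargs,
) -> KinaseForestClassifier:
    """Fit a forest on a labelled dataset and its semantic feature matrix."""
    labels = [v.label for v in data]
    clf = KinaseForestClassifier(n_trees=n_trees, random_state=seed, **kwargs)
    return clf.fit(features, labels)


def predict(
    model: KinaseForestClassifier, data: Dataset, features: pd.DataFrame
) -> list[Prediction]:
    p = model.predict_proba_disease(features)
    labels = np.where(p >= model.threshold, model.POSITIVE, model.NEGATIVE)
    return [
        Prediction(v.protein_id, v.position, v.wt_aa, v.mut_aa, float(pi), str(li))
        for v, pi, li in zip(data, p, labels, strict=True)
    ]


def predictions_frame(predictions: list[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.protein_id, p.position, p.wt_aa, p.mut_aa, p.p_disease, p.label) for p in predictions],
        columns=["protein_id", "position", "wt_aa", "mut_aa", "p_disease", "label"],
    )


@dataclass
class CVResult:
    """Pooled and per-fold outcomes of a grouped cross-validation run."""

    report: MetricsReport
    fold_reports: list[MetricsReport]
    predictions: pd.DataFrame
    folds: FoldAssignment
    # per fold: variant keys that contributed to that fold's lor tables
    train_contributors: list[set] = field(default_factory=list)

    def fold_mean_sd(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            [
                {
                    "accuracy": r.accuracy,
                    "precision": r.precision,
                    "recall": r.recall,
                    "f_score": r.f_score,
                    "mcc": r.mcc,
                }
                for r in self.fold_reports
            ]
        )
        return rows.agg(["mean", "std"])


def cross_validate(
    data: Dataset,
    ann: AnnotationBundle,
    graph: OntologyGraph,
    scales: AminoAcidScales = DEFAULT_SCALES,
    k: int = 10,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    lor_scope: str = "train_fold",
    xi: float = DEFAULT_XI,
    threshold: float = DEFAULT_THRESHOLD,
    max_features: int = DEFAULT_MAX_FEATURES,
) -> CVResult:
    """Protein-grouped k-fold cross-validation with pooled metrics.

    Each bin serves once as the evaluation set while the other bins train
    the classifier; per-variant predictions are accumulated over all folds
    and a single pooled confusion matrix summarises the run.  Per-fold
    metrics are also returned (mean +/- sd via :meth:`CVResult.fold_mean_sd`).
    """
    if lor_scope not in ("train_fold", "full_dataset"):
        raise ConfigurationError(f"unknown lor_scope {lor_scope!r}")
    labelled = data.labelled()
    if len(labelled) == 0:
        raise ValidationError("no labelled variants to cross-validate")
    folds = assign_folds(labelled.proteins, k, seed)

    full_featurizer = None
    if lor_scope == "full_dataset":
        full_featurizer = VariantFeaturizer(ann, graph, scales, xi).fit(labelled)

    all_preds: list[Prediction] = []
    truth: list[str] = []
    fold_reports: list[MetricsReport] = []
    contributors: list[set] = []

    for fold in range(k):
        eval_proteins = folds.proteins_in(fold)
        train_set = Dataset([v for v in labelled if v.protein_id not in eval_proteins])
        eval_set = Dataset([v for v in labelled if v.protein_id in eval_proteins])

        if full_featurizer is not None:
            featurizer = full_featurizer
        else:
            featurizer = VariantFeaturizer(ann, graph, scales, xi).fit(train_set)
        contributors.append(
            set().union(*(t.contributors for t in featurizer.tables_.values()))
        )

        train_features = featurizer.transform(train_set)
        clf = KinaseForestClassifier(
            n_trees=n_trees,
            max_features=max_features,
            threshold=threshold,
            random_state=seed + fold,
        )
        clf.fit(train_features, [v.label for v in train_set])

        eval_features = featurizer.transform(eval_set)
        preds = predict(clf, eval_set, eval_features)
        all_preds.extend(preds)
        truth.extend(v.label for v in eval_set)

        tp, fp, tn, fn = _confusion(
            [v.label for v in eval_set], [p.label for p in preds]
        )
        fold_reports.append(compute_metrics(tp, fp, tn, fn))

    pred_labels = [p.label for p in all_preds]
    tp, fp, tn, fn = _confusion(truth, pred_labels)
    report = compute_metrics(tp, fp, tn, fn)
    frame = predictions_frame(all_preds)
    frame["true_label"] = truth
    return CVResult(
        report=report,
        fold_reports=fold_reports,
        predictions=frame,
        folds=folds,
        train_contributors=contributors,
    )


def _confusion(truth: list[str], predicted: list[str]) -> tuple[int, int, int, int]:
    tp = sum(1 for t, p in zip(truth, predicted) if t == "disease" and p == "disease")
    fp = sum(1 for t, p in zip(truth, predicted) if t == "neutral" and p == "disease")
    tn = sum(1 for t, p in zip(truth, predicted) if t == "neutral" and p == "neutral")
    fn = sum(1 for t, p in zip(truth, predicted) if t == "disease" and p == "neutral")
    return tp, fp, tn, fn


def save_model(
    path,
    classifier: KinaseForestClassifier,
    featurizer: VariantFeaturizer,
    config: dict | None = None,
) -> None:
    """Persist classifier + featurizer + config as one archive."""
    check_is_fitted(classifier, "forest_")
    payload = {
        "feature_order_version": FEATURE_ORDER_VERSION,
        "classifier": classifier,
        "featurizer": featurizer,
        "config": config or {},
    }
    joblib.dump(payload, path)


def load_model(path) -> tuple[KinaseForestClassifier, VariantFeaturizer, dict]:
    payload = joblib.load(path)
    if payload.get("feature_order_version") != FEATURE_ORDER_VERSION:
        raise ContractError(
            f"model archive feature-order version {payload.get('feature_order_version')!r} "
            f"does not match {FEATURE_ORDER_VERSION!r}"
        )
    return payload["classifier"], payload["featurizer"], payload["config"]
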