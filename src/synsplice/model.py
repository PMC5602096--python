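"""Random-forest disease-causing-probability model and evaluation.

:class:`DiseaseProbabilityClassifier` is a scikit-learn-compatible
estimator wrapping a random forest with the method's fixed hyperparameters
(51 trees, 35 candidate features per node, capped at the schema width when
the matrix is narrower). Its probability output for the disease class is
the disease-causing probability (DCP). Separate models are trained for
splice-site-consensus (VSS) and internal-exon (VIE) variants; the feature
schema is hashed at fit time and checked at predict time.

Evaluation reports the Matthews correlation coefficient at a 0.5 vote
threshold, the ROC AUC, and the two-sample Kolmogorov-Smirnov statistic
between the class-conditional score distributions. The allele-frequency
analysis bins MAF into 20 equal bins of width 0.05 and fits a least-squares
line to the per-bin (mean MAF, mean DCP) points.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import matthews_corrcoef, roc_auc_score, roc_curve
from sklearn.utils.validation import check_is_fitted
from scipy import stats

from .errors import (
    AllBinsEmpty,
    DegenerateLabels,
    SchemaMismatch,
    SingleClass,
)

logger = logging.getLogger(__name__)

N_TREES = 51
FEATURES_PER_NODE = 35
DISEASE_LABEL = 1  # positive class encoding


def schema_hash(feature_names: Sequence[str]) -> str:
    return hashlib.sha256("\x1f".join(feature_names).encode()).hexdigest()[:16]


class DiseaseProbabilityClassifier(ClassifierMixin, BaseEstimator):
    """Random forest scoring variants with a disease-causing probability.

    Parameters
    ----------
    n_trees : int
        Number of trees in the forest (default 51).
    features_per_node : int
        Candidate features considered at each split (default 35); capped at
        the number of columns with a logged warning when the schema is
        narrower.
    criterion : str
        Split criterion, ``'gini'`` (default) or ``'entropy'``.
    random_state : int or None
        Seed; a fixed seed makes predictions byte-reproducible.
    site_class : str or None
        Optional tag ('VSS'/'VIE') recorded for bookkeeping.
    """

    def __init__(
        self,
        n_trees: int = N_TREES,
        features_per_node: int = FEATURES_PER_NODE,
        criterion: str = "gini",
        random_state: Optional[int] = None,
        site_class: Optional[str] = None,
    ):
        self.n_trees = n_trees
        self.features_per_node = features_per_node
        self.criterion = criterion
        self.random_state = random_state
        self.site_class = site_class

    def _coerce(self, X, fit: bool):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            names = [f"f{i}" for i in range(values.shape[1])]
        if fit:
            self.feature_names_in_ = np.asarray(names, dtype=object)
            self.schema_hash_ = schema_hash(names)
        else:
            check_is_fitted(self, "forest_")
            if schema_hash(names) != self.schema_hash_ and isinstance(X, pd.DataFrame):
                raise SchemaMismatch(
                    "feature schema does not match the trained model "
                    f"(expected hash {self.schema_hash_}, got {schema_hash(names)})"
                )
            if values.shape[1] != self.n_features_in_:
                raise SchemaMismatch(
                    f"matrix has {values.shape[1]} columns, model expects "
                    f"{self.n_features_in_}"
                )
        if np.isnan(values).any():
            raise ValueError("feature matrix contains NaN; impute before fitting")
        return values

    def fit(self, X, y):
        values = self._coerce(X, fit=True)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise SingleClass(f"need >= 2 classes, got {classes.tolist()}")
        max_features = self.features_per_node
        if max_features > values.shape[1]:
            logger.warning(
                "features_per_node=%d exceeds %d columns; capping",
                max_features,
                values.shape[1],
            )
            max_features = values.shape[1]
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=max_features,
            criterion=self.criterion,
            random_state=self.random_state,
        )
        self.forest_.fit(values, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = values.shape[1]
        return self

    def predict_proba(self, X):
        values = self._coerce(X, fit=False)
        return self.forest_.predict_proba(values)

    def predict(self, X):
        values = self._coerce(X, fit=False)
        return self.forest_.predict(values)

    def predict_dcp(self, X) -> np.ndarray:
        """Disease-causing probability: forest vote fraction for class 1."""
        proba = self.predict_proba(X)
        col = int(np.nonzero(self.classes_ == DISEASE_LABEL)[0][0])
        return proba[:, col]

    def feature_importances(self) -> pd.Series:
        check_is_fitted(self, "forest_")
        return pd.Series(
            self.forest_.feature_importances_, index=self.feature_names_in_
        ).sort_values(ascending=False)


def train(
    matrix: pd.DataFrame,
    labels,
    n_trees: int = N_TREES,
    features_per_node: int = FEATURES_PER_NODE,
    seed: Optional[int] = None,
    site_class: Optional[str] = None,
) -> DiseaseProbabilityClassifier:
    """Fit a forest on a feature matrix; thin wrapper over the estimator."""
    clf = DiseaseProbabilityClassifier(
        n_trees=n_trees,
        features_per_node=features_per_node,
        random_state=seed,
        site_class=site_class,
    )
    return clf.fit(matrix, np.asarray(labels))


def predict_dcp(model: DiseaseProbabilityClassifier, matrix) -> np.ndarray:
    return model.predict_dcp(matrix)


def evaluate(scores, labels, threshold: float = 0.5) -> dict:
    """MCC at ``threshold``, ROC AUC, K-S D, and the ROC points.

    ``labels`` are 0/1 with 1 = disease. AUC uses the rank statistic with
    midrank tie handling; K-S D compares the score distributions of the two
    classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise DegenerateLabels("need at least one observation of each label")
    pred = (scores >= threshold).astype(int)
    mcc = float(matthews_corrcoef(labels, pred))
    auc = float(roc_auc_score(labels, scores))
    ks = stats.ks_2samp(scores[labels == 1], scores[labels == 0])
    fpr, tpr, thr = roc_curve(labels, scores)
    return {
        "mcc": mcc,
        "auc": auc,
        "ks_d": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_pos": int(labels.sum()),
        "n_neg": int((1 - labels).sum()),
        "roc": {
            "fpr": [float(v) for v in fpr],
            "tpr": [float(v) for v in tpr],
            "threshold": [float(v) for v in thr],
        },
    }


@dataclass(frozen=True)
class MafDcpResult:
    """Binned allele-frequency vs disease-probability relationship."""

    bin_table: pd.DataFrame  # columns: bin, mean_maf, mean_dcp, n
    slope: float
    intercept: float
    r_squared: float


def analyze_maf_dcp(maf, dcp, n_bins: int = 20) -> MafDcpResult:
    """Bin MAF into ``n_bins`` equal right-closed bins and fit a line.

    Bin i covers (i/n_bins, (i+1)/n_bins]; the first bin additionally
    includes 0. Empty bins are dropped. A least-squares line is fitted to
    the occupied bins' (mean MAF, mean DCP) points; its slope and R^2 are
    returned.
    """
    maf = np.asarray(maf, dtype=float)
    dcp = np.asarray(dcp, dtype=float)
    ok = ~np.isnan(maf)
    maf, dcp = maf[ok], dcp[ok]
    if maf.size == 0:
        raise AllBinsEmpty("no variants with a defined MAF")
    if np.any((maf < 0) | (maf > 1)):
        raise ValueError("MAF values must lie in [0, 1]")
    width = 1.0 / n_bins
    idx = np.ceil(maf / width).astype(int) - 1
    idx[idx < 0] = 0  # maf == 0 -> first bin

    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin": b,
                "mean_maf": float(maf[mask].mean()),
                "mean_dcp": float(dcp[mask].mean()),
                "n": int(mask.sum()),
            }
        )
    table = pd.DataFrame(rows)
    x = table["mean_maf"].to_numpy()
    y = table["mean_dcp"].to_numpy()
    if len(table) < 2 or np.allclose(x, x[0]):
        slope, intercept, r2 = 0.0, float(y.mean()), 0.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2) if np.std(y) > 0 else 0.0
    return MafDcpResult(bin_table=table, slope=slope, intercept=intercept, r_squared=r2)


def save_model(model: DiseaseProbabilityClassifier, path) -> None:
    """Persist a fitted model with its schema hash and seed."""
    check_is_fitted(model, "forest_")
    joblib.dump(
        {
            "format_version": 1,
            "schema_hash": model.schema_hash_,
            "feature_names": list(model.feature_names_in_),
            "seed": model.random_state,
            "site_class": model.site_class,
            "model": model,
        },
        path,
    )


def load_model(path) -> DiseaseProbabilityClassifier:
    payload = joblib.load(path)
    model = payload["model"]
    if payload["schema_hash"] != model.schema_hash_:
        raise SchemaMismatch("archive schema hash does not match embedded model")
    return model
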