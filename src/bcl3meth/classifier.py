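"""Binary methylation classifier for the translocation-positive subtype.

The pipeline mirrors how methylation-based subtype classifiers are built in
practice: rank CpGs by variance and keep the top 10,000, collapse redundancy
by k-means clustering of CpG profiles (one medoid representative per
cluster), rebalance the training fold by minority oversampling with
interpolation, fit a random-forest ensemble, evaluate on an untouched
stratified held-out split, and distill a reduced signature (default 20
CpGs) from exact additive per-feature attributions.

Attribution is decision-path based: walking each tree from root to leaf,
every split credits its feature with the change in the node's case
probability, so base value + sum(attributions) equals the forest's
predicted case probability exactly (local accuracy).

The module exposes both the individual pipeline operations and a
statsmodels-style model object: ``TranslocationClassifier(beta, labels).fit()``
returns a :class:`ClassifierResults` with metrics, attributions, the reduced
signature and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split

__all__ = [
    "ClassifierConfig",
    "Metrics",
    "SignatureModel",
    "TranslocationClassifier",
    "ClassifierResults",
    "select_variable_cpgs",
    "cluster_representatives",
    "train_classifier",
    "attribute",
    "extract_signature",
    "classify",
    "labels_from_sheet",
]

CASE = "case"
OTHER = "other"


@dataclass
class ClassifierConfig:
    n_variable: int = 10000
    k_clusters: int = 100
    sampler: str = "oversample"  # oversample | undersample | none
    n_trees: int = 500
    max_depth: Optional[int] = None
    test_fraction: float = 0.25
    n_signature: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_signature <= self.k_clusters <= self.n_variable):
            raise ValueError("require n_signature <= k_clusters <= n_variable")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.sampler not in ("oversample", "undersample", "none"):
            raise ValueError(f"unknown sampler: {self.sampler}")


@dataclass
class Metrics:
    """Held-out performance of a binary classifier (case = positive class)."""

    auroc: float
    auprc: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    confusion: dict[str, int]
    n_test: int

    @property
    def macro_precision(self) -> float:
        return float(np.mean([self.precision[CASE], self.precision[OTHER]]))

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion,
            "n_test": self.n_test,
        }


def labels_from_sheet(
    sheet: pd.DataFrame,
    case_group: str = "BCL3",
    exclude_groups: Sequence[str] = ("PC_LIKE",),
) -> pd.Series:
    """Binary case/other labels from a sample sheet, excluding listed groups."""
    keep = ~sheet["group"].isin(exclude_groups)
    sub = sheet.loc[keep]
    return pd.Series(
        np.where(sub["group"] == case_group, CASE, OTHER),
        index=sub["sample_id"],
        name="label",
    )


# ---------------------------------------------------------------------------
# pipeline operations
# ---------------------------------------------------------------------------


def select_variable_cpgs(beta: pd.DataFrame, n: int) -> list[str]:
    """Top-n CpGs by variance across all samples; ties break lexicographically."""
    if n > len(beta):
        raise ValueError("n exceeds the number of CpGs")
    var = beta.var(axis=1, ddof=1)
    order = sorted(zip(-var.to_numpy(), beta.index.astype(str)))
    return [cpg for _, cpg in order[:n]]


def cluster_representatives(
    beta: pd.DataFrame, cpgs: Sequence[str], k: int, seed: int
) -> list[str]:
    """One medoid CpG per k-means cluster of CpG profile vectors.

    CpGs are the points and samples the dimensions; the representative of a
    cluster is the member closest to its centroid (lexicographic
    tie-break).  A single seeded k-means++ initialization keeps the step
    deterministic and fast at desk scale.
    """
    cpgs = list(cpgs)
    if k > len(cpgs):
        raise ValueError("k exceeds the number of CpGs")
    X = beta.loc[cpgs].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=1, random_state=seed)
    assign = km.fit_predict(X)
    reps: list[str] = []
    ids = np.array(cpgs, dtype=object)
    for c in range(k):
        members = np.flatnonzero(assign == c)
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        best = d.min()
        cands = sorted(ids[members[np.isclose(d, best)]])
        reps.append(str(cands[0]))
    return reps


def _oversample_interpolate(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Grow the minority class to parity by interpolating random member pairs."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() == counts.max():
        return X, y
    minority = classes[np.argmin(counts)]
    need = int(counts.max() - counts.min())
    pool = np.flatnonzero(y == minority)
    i = rng.choice(pool, size=need)
    j = rng.choice(pool, size=need)
    lam = rng.uniform(0.0, 1.0, size=(need, 1))
    synth = X[i] + lam * (X[j] - X[i])
    return np.vstack([X, synth]), np.concatenate([y, np.full(need, minority, dtype=y.dtype)])


def _undersample(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for c in classes:
        pool = np.flatnonzero(y == c)
        keep.append(rng.choice(pool, size=n_min, replace=False))
    idx = np.sort(np.concatenate(keep))
    return X[idx], y[idx]


@dataclass
class FittedClassifier:
    """A trained ensemble plus the bookkeeping needed to reuse its split."""

    model: RandomForestClassifier
    feature_ids: list[str]
    train_ids: list[str]
    test_ids: list[str]
    config: ClassifierConfig
    variable_cpgs: list[str] = field(default_factory=list)

    def case_proba(self, X: np.ndarray) -> np.ndarray:
        case_col = int(np.flatnonzero(self.model.classes_ == CASE)[0])
        return self.model.predict_proba(X)[:, case_col]


def _evaluate(model: RandomForestClassifier, X: np.ndarray, y: np.ndarray) -> Metrics:
    case_col = int(np.flatnonzero(model.classes_ == CASE)[0])
    proba = model.predict_proba(X)[:, case_col]
    pred = np.where(proba >= 0.5, CASE, OTHER)
    y_bin = (y == CASE).astype(int)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, pred, labels=[CASE, OTHER], zero_division=0
    )
    cm = confusion_matrix(y, pred, labels=[CASE, OTHER])
    return Metrics(
        auroc=float(roc_auc_score(y_bin, proba)),
        auprc=float(average_precision_score(y_bin, proba)),
        precision={CASE: float(prec[0]), OTHER: float(prec[1])},
        recall={CASE: float(rec[0]), OTHER: float(rec[1])},
        f1={CASE: float(f1[0]), OTHER: float(f1[1])},
        confusion={"tp": int(cm[0, 0]), "fn": int(cm[0, 1]), "fp": int(cm[1, 0]), "tn": int(cm[1, 1])},
        n_test=len(y),
    )


def _fit_forest(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: ClassifierConfig,
    rng: np.random.Generator,
) -> RandomForestClassifier:
    if config.sampler == "oversample":
        X_train, y_train = _oversample_interpolate(X_train, y_train, rng)
    elif config.sampler == "undersample":
        X_train, y_train = _undersample(X_train, y_train, rng)
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X_train, y_train)
    return model


def train_classifier(
    beta: pd.DataFrame, labels: pd.Series, config: Optional[ClassifierConfig] = None
) -> tuple[FittedClassifier, Metrics]:
    """Run the full pipeline and evaluate on a stratified held-out split.

    Resampling is applied to the training fold only; the test fold stays
    untouched.  Deterministic for a fixed ``config.seed``.
    """
    config = config or ClassifierConfig()
    labels = labels.astype(str)
    counts = labels.value_counts()
    if counts.min() < 5 or len(counts) != 2:
        raise ValueError("need two classes with at least 5 samples each")
    missing = set(labels.index) - set(beta.columns)
    if missing:
        raise ValueError(f"labelled samples missing from beta: {sorted(missing)[:5]}")

    sub = beta[labels.index]
    variable = select_variable_cpgs(sub, min(config.n_variable, len(sub)))
    reps = cluster_representatives(sub, variable, config.k_clusters, config.seed)
    X = sub.loc[reps].T  # samples x features
    y = labels.loc[X.index].to_numpy()

    train_ids, test_ids = train_test_split(
        list(X.index),
        test_size=config.test_fraction,
        stratify=y,
        random_state=config.seed,
    )
    rng = np.random.default_rng(config.seed)
    model = _fit_forest(
        X.loc[train_ids].to_numpy(), labels.loc[train_ids].to_numpy(), config, rng
    )
    metrics = _evaluate(model, X.loc[test_ids].to_numpy(), labels.loc[test_ids].to_numpy())
    fitted = FittedClassifier(
        model=model,
        feature_ids=reps,
        train_ids=list(train_ids),
        test_ids=list(test_ids),
        config=config,
        variable_cpgs=variable,
    )
    return fitted, metrics


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------


def attribute(fitted: FittedClassifier, X: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Exact decision-path attributions for the case probability.

    Returns ``(base_value, contributions)`` where contributions is a
    samples x features frame and, for every sample,
    ``base_value + contributions.sum() == P(case)`` exactly.
    """
    if list(X.columns) != list(fitted.feature_ids):
        if set(X.columns) != set(fitted.feature_ids):
            raise ValueError("feature mismatch between model and data")
        X = X[fitted.feature_ids]
    model = fitted.model
    case_col = int(np.flatnonzero(model.classes_ == CASE)[0])
    Xv = X.to_numpy(dtype=np.float32)
    n, d = Xv.shape
    contrib = np.zeros((n, d))
    base = 0.0
    for est in model.estimators_:
        tree = est.tree_
        value = tree.value[:, 0, :]
        probs = value[:, case_col] / value.sum(axis=1)
        base += probs[0]
        path = tree.decision_path(Xv)  # csr, node ids ascending along the path
        indptr, indices = path.indptr, path.indices
        feat = tree.feature
        for s in range(n):
            nodes = indices[indptr[s] : indptr[s + 1]]
            for parent, child in zip(nodes[:-1], nodes[1:]):
                contrib[s, feat[parent]] += probs[child] - probs[parent]
    n_trees = len(model.estimators_)
    return base / n_trees, pd.DataFrame(contrib / n_trees, index=X.index, columns=X.columns)


# ---------------------------------------------------------------------------
# reduced signature
# ---------------------------------------------------------------------------

HIGH = "high_indicates_case"
LOW = "low_indicates_case"


@dataclass
class SignatureModel:
    """The reduced CpG signature: ids, per-CpG direction and a refit model."""

    cpg_ids: list[str]
    directions: dict[str, str]
    model: object  # RandomForestClassifier or _JSONForest
    metrics: Optional[Metrics] = None

    def case_proba(self, X: np.ndarray) -> np.ndarray:
        if isinstance(self.model, _JSONForest):
            return self.model.case_proba(X)
        case_col = int(np.flatnonzero(self.model.classes_ == CASE)[0])
        return self.model.predict_proba(X)[:, case_col]

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        if isinstance(self.model, _JSONForest):
            trees = self.model.trees
        else:
            case_col = int(np.flatnonzero(self.model.classes_ == CASE)[0])
            trees = []
            for est in self.model.estimators_:
                t = est.tree_
                value = t.value[:, 0, :]
                trees.append(
                    {
                        "children_left": t.children_left.tolist(),
                        "children_right": t.children_right.tolist(),
                        "feature": t.feature.tolist(),
                        "threshold": t.threshold.tolist(),
                        "case_prob": (value[:, case_col] / value.sum(axis=1)).tolist(),
                    }
                )
        payload = {
            "cpg_ids": self.cpg_ids,
            "directions": self.directions,
            "trees": trees,
            "metrics": self.metrics.to_dict() if self.metrics else None,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        payload = json.loads(text)
        metrics = None
        if payload.get("metrics"):
            metrics = Metrics(**payload["metrics"])
        return cls(
            cpg_ids=list(payload["cpg_ids"]),
            directions=dict(payload["directions"]),
            model=_JSONForest(payload["trees"]),
            metrics=metrics,
        )


class _JSONForest:
    """Evaluates a JSON-serialized tree ensemble (mean leaf case probability)."""

    def __init__(self, trees: list[dict]):
        self.trees = trees

    def case_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = np.zeros(len(X))
        for t in self.trees:
            left = t["children_left"]
            right = t["children_right"]
            feat = t["feature"]
            thr = t["threshold"]
            prob = t["case_prob"]
            for s in range(len(X)):
                node = 0
                while left[node] != -1:
                    node = left[node] if X[s, feat[node]] <= thr[node] else right[node]
                out[s] += prob[node]
        return out / len(self.trees)


def extract_signature(
    fitted: FittedClassifier,
    beta: pd.DataFrame,
    labels: pd.Series,
    n: Optional[int] = None,
) -> tuple[SignatureModel, pd.DataFrame]:
    """Distill the reduced signature from attribution magnitudes.

    Features are ranked by mean absolute attribution over all labelled
    samples; the top n become the signature.  Each signature CpG's
    direction is the sign of the correlation between its beta values and
    its attributions (positive: high methylation indicates the case class).
    A reduced model is refit on the same training fold restricted to the
    signature CpGs and evaluated on the same held-out fold.

    Returns the signature model and the attribution matrix used.
    """
    n = n or fitted.config.n_signature
    if n > len(fitted.feature_ids):
        raise ValueError("n exceeds the model's feature count")
    X = beta.loc[fitted.feature_ids, list(labels.index)].T
    base, contrib = attribute(fitted, X)
    strength = contrib.abs().mean(axis=0)
    order = sorted(zip(-strength.to_numpy(), strength.index.astype(str)))
    chosen = [cpg for _, cpg in order[:n]]

    directions: dict[str, str] = {}
    for cpg in chosen:
        v = X[cpg].to_numpy()
        a = contrib[cpg].to_numpy()
        if v.std() == 0 or a.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(v, a)[0, 1])
        directions[cpg] = HIGH if r >= 0 else LOW

    config = fitted.config
    rng = np.random.default_rng(config.seed)
    X_red = beta.loc[chosen].T
    model = _fit_forest(
        X_red.loc[fitted.train_ids].to_numpy(),
        labels.loc[fitted.train_ids].to_numpy(),
        config,
        rng,
    )
    metrics = _evaluate(
        model,
        X_red.loc[fitted.test_ids].to_numpy(),
        labels.loc[fitted.test_ids].to_numpy(),
    )
    return SignatureModel(cpg_ids=chosen, directions=directions, model=model, metrics=metrics), contrib


def classify(signature: SignatureModel, beta: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Classify samples from their signature-CpG beta values.

    ``beta`` is CpGs x samples (or a single sample Series indexed by CpG).
    Returns a frame with columns ``probability`` (of the case class) and
    ``label``; probability exactly 0.5 classifies as case.
    """
    if isinstance(beta, pd.Series):
        beta = beta.to_frame(name=beta.name or "sample")
    missing = [c for c in signature.cpg_ids if c not in beta.index]
    if missing:
        raise ValueError(f"signature CpGs missing: {missing}")
    X = beta.loc[signature.cpg_ids].T.to_numpy(dtype=float)
    proba = signature.case_proba(X)
    return pd.DataFrame(
        {"probability": proba, "label": np.where(proba >= 0.5, CASE, OTHER)},
        index=beta.columns,
    )


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class TranslocationClassifier:
    """Binary subtype classifier as a fit-once model object.

    Parameters
    ----------
    beta : DataFrame
        CpGs x samples beta-value matrix.
    labels : Series
        case/other label per sample id (see :func:`labels_from_sheet`).
    config : ClassifierConfig, optional
    """

    def __init__(self, beta: pd.DataFrame, labels: pd.Series, config: Optional[ClassifierConfig] = None):
        self.beta = beta
        self.labels = labels.astype(str)
        self.config = config or ClassifierConfig()

    @classmethod
    def from_dataset(cls, bundle, case_group: str = "BCL3", exclude_groups=("PC_LIKE",), config=None):
        labels = labels_from_sheet(bundle.sheet, case_group, exclude_groups)
        return cls(bundle.beta, labels, config)

    def fit(self) -> "ClassifierResults":
        fitted, metrics = train_classifier(self.beta, self.labels, self.config)
        signature, contrib = extract_signature(fitted, self.beta, self.labels)
        return ClassifierResults(
            model=fitted,
            metrics=metrics,
            signature=signature,
            attributions=contrib,
            config=self.config,
        )


@dataclass
class ClassifierResults:
    """Fit results: held-out metrics, attributions and the reduced signature."""

    model: FittedClassifier
    metrics: Metrics
    signature: SignatureModel
    attributions: pd.DataFrame
    config: ClassifierConfig

    def predict(self, beta: pd.DataFrame | pd.Series) -> pd.DataFrame:
        return classify(self.signature, beta)

    def summary(self) -> str:
        m, r = self.metrics, self.signature.metrics
        n_low = sum(1 for d in self.signature.directions.values() if d == LOW)
        lines = [
            "Translocation methylation classifier",
            "=" * 52,
            f"features (cluster representatives): {len(self.model.feature_ids)}",
            f"train / test samples: {len(self.model.train_ids)} / {len(self.model.test_ids)}",
            "",
            f"{'':24s}{'full':>10s}{'reduced':>10s}",
            f"{'AUROC':24s}{m.auroc:>10.3f}{r.auroc:>10.3f}",
            f"{'AUPRC':24s}{m.auprc:>10.3f}{r.auprc:>10.3f}",
            f"{'precision (case)':24s}{m.precision[CASE]:>10.3f}{r.precision[CASE]:>10.3f}",
            f"{'recall (case)':24s}{m.recall[CASE]:>10.3f}{r.recall[CASE]:>10.3f}",
            f"{'F1 (case)':24s}{m.f1[CASE]:>10.3f}{r.f1[CASE]:>10.3f}",
            f"{'F1 (other)':24s}{m.f1[OTHER]:>10.3f}{r.f1[OTHER]:>10.3f}",
            "",
            f"signature: {len(self.signature.cpg_ids)} CpGs "
            f"({n_low} low-methylation-indicates-case, "
            f"{len(self.signature.cpg_ids) - n_low} high)",
        ]
        return "\n".join(lines)
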