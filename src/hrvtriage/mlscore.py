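"""Machine-learning triage risk score.

The score combines age, vital signs and the HRV parameter vector into a
continuous 0–100 risk of the adverse outcome (cardiac arrest within 72 h,
or in-hospital death), in three steps:

1. **Cluster-distance base score.** Features are z-scored; the centroids of
   the positive (event) and negative (no-event) classes are computed in the
   standardized space, and a patient's base score is
   ``100 * d_neg / (d_pos + d_neg)`` where ``d_c`` is the Euclidean
   distance to centroid ``c``. The score is 0 at the negative centroid,
   100 at the positive centroid, and 50 on the midplane.
2. **Imbalanced-ensemble adjustment.** Events are rare, so a single
   classifier trained on the raw cohort would be dominated by the majority
   class. The majority rows are shuffled and partitioned into N disjoint
   groups; each group is joined with *all* minority rows to form a balanced
   set, on which one linear support-vector machine is trained. The
   ensemble's majority vote moves the base score up (positive vote) or down
   by a fixed increment, clamped to [0, 100].
3. **Risk strata.** 0–40 low, >40–60 intermediate, >60–100 high.

Validation uses a leave-one-out strategy: the scaler, centroids and
ensemble are refit on the n−1 remaining patients for each held-out patient.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .hrv import HrvFeatures
from .mews import Vitals

#: Order of the feature vector: age, vitals, then the HRV block.
VITALS_FEATURES = ["age", "heart_rate", "resp_rate", "sbp", "dbp", "spo2",
                   "temperature", "gcs"]
FEATURE_NAMES: list[str] = VITALS_FEATURES + HrvFeatures.feature_names()

#: Risk-stratum boundaries on the 0-100 scale: low <= 40 < intermediate <= 60 < high.
STRATA_BOUNDS = (40.0, 60.0)

#: Default score adjustment applied by the ensemble vote.
DEFAULT_DELTA = 15.0

#: Default screening cutoff for a positive ML score.
DEFAULT_ML_CUTOFF = 60.0


class FitError(ValueError):
    """Raised when the model cannot be fit (e.g. an empty class)."""


def risk_category(value: float) -> str:
    low, high = STRATA_BOUNDS
    if value <= low:
        return "low"
    if value <= high:
        return "intermediate"
    return "high"


@dataclass
class RiskScore:
    value: float
    category: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ValueError(f"risk score must be in [0, 100], got {self.value}")
        if not self.category:
            self.category = risk_category(self.value)


def assemble_features(vitals: Vitals, hrv: HrvFeatures,
                      medians: dict[str, float] | None = None,
                      max_missing_fraction: float = 0.5) -> tuple[np.ndarray, list[str]]:
    """Concatenate age + vitals + HRV into the fixed-order feature vector.

    Missing entries (``None`` vitals or ``nan`` HRV fields) are imputed
    with the supplied per-feature medians (typically from the training
    cohort). Returns ``(vector, imputed_names)``.

    Raises
    ------
    ValueError
        If more than ``max_missing_fraction`` of the features are missing:
        the record is rejected rather than scored from mostly-imputed data.
    """
    raw: list[float] = []
    for name in VITALS_FEATURES:
        v = getattr(vitals, name)
        raw.append(math.nan if v is None else float(v))
    hd = hrv.as_dict()
    raw.extend(float(hd[name]) for name in HrvFeatures.feature_names())
    vec = np.asarray(raw, dtype=float)

    missing = ~np.isfinite(vec)
    if missing.mean() > max_missing_fraction:
        raise ValueError(
            f"{int(missing.sum())}/{vec.size} features missing exceeds the "
            f"{max_missing_fraction:.0%} imputation limit; record rejected")
    imputed = [FEATURE_NAMES[i] for i in np.flatnonzero(missing)]
    if medians is None:
        medians = {}
    for i in np.flatnonzero(missing):
        vec[i] = medians.get(FEATURE_NAMES[i], 0.0)
    return vec, imputed


@dataclass
class ScoreModel:
    """Fitted scoring model: scaler, class centroids and SVM ensemble."""

    center: np.ndarray = field(default_factory=lambda: np.empty(0))
    spread: np.ndarray = field(default_factory=lambda: np.empty(0))
    mu_pos: np.ndarray = field(default_factory=lambda: np.empty(0))
    mu_neg: np.ndarray = field(default_factory=lambda: np.empty(0))
    ensemble: list[SVC] = field(default_factory=list)
    partitions: list[np.ndarray] = field(default_factory=list)
    n_partitions: int = 0
    delta: float = DEFAULT_DELTA
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    seed: int = 0

    # ---- fitting -----------------------------------------------------

    def fit_scaler(self, X: np.ndarray) -> None:
        self.center = X.mean(axis=0)
        spread = X.std(axis=0, ddof=0)
        spread[spread == 0] = 1.0  # constant features carry no distance
        self.spread = spread

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.center.size == 0:
            raise FitError("scaler not fitted")
        return (np.atleast_2d(X) - self.center) / self.spread

    def fit_cluster_centers(self, X: np.ndarray, y: np.ndarray) -> None:
        """Class centroids in standardized feature space."""
        y = np.asarray(y).astype(int)
        if not (np.any(y == 1) and np.any(y == 0)):
            raise FitError("both outcome classes must be present")
        Z = self.standardize(X)
        self.mu_pos = Z[y == 1].mean(axis=0)
        self.mu_neg = Z[y == 0].mean(axis=0)

    def fit_imbalanced_ensemble(self, X: np.ndarray, y: np.ndarray,
                                n_partitions: int | None = None,
                                rng: np.random.Generator | None = None,
                                svm_c: float = 1.0) -> None:
        """Train the N-partition balanced ensemble of linear SVMs.

        The majority class is shuffled (seeded) and split into N disjoint
        groups covering it; each group plus all minority rows trains one
        ``SVC(kernel="linear")``. Defaults: N = floor(majority/minority).
        """
        y = np.asarray(y).astype(int)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        minority, majority = (pos_idx, neg_idx) if pos_idx.size <= neg_idx.size else (neg_idx, pos_idx)
        if minority.size < 2:
            raise FitError("minority class needs at least 2 samples")
        if n_partitions is None:
            n_partitions = max(1, majority.size // minority.size)
        if n_partitions < 1:
            raise FitError("n_partitions must be >= 1")
        if rng is None:
            rng = np.random.default_rng(self.seed)
        shuffled = rng.permutation(majority)
        groups = np.array_split(shuffled, n_partitions)

        Z = self.standardize(X)
        self.ensemble = []
        self.partitions = [np.sort(g) for g in groups]
        self.n_partitions = n_partitions
        for g in groups:
            rows = np.concatenate([g, minority])
            clf = SVC(kernel="linear", C=svm_c)
            clf.fit(Z[rows], y[rows])
            self.ensemble.append(clf)

    def fit(self, X: np.ndarray, y: np.ndarray,
            n_partitions: int | None = None, seed: int | None = None) -> "ScoreModel":
        if seed is not None:
            self.seed = seed
        X = np.asarray(X, dtype=float)
        self.fit_scaler(X)
        self.fit_cluster_centers(X, y)
        self.fit_imbalanced_ensemble(X, y, n_partitions=n_partitions)
        return self

    # ---- scoring -----------------------------------------------------

    def distance_score(self, x: np.ndarray) -> RiskScore:
        """Base score from Euclidean distances to the two centroids.

        ``100 * d_neg / (d_pos + d_neg)``: 0 at the negative centroid, 100
        at the positive one, 50 on the midplane. Degenerate identical
        centroids score 50 with a warning.
        """
        if self.mu_pos.size == 0:
            raise FitError("cluster centers not fitted")
        z = self.standardize(x)[0]
        d_pos = float(np.linalg.norm(z - self.mu_pos))
        d_neg = float(np.linalg.norm(z - self.mu_neg))
        if d_pos + d_neg == 0:
            warnings.warn("identical cluster centers; returning midpoint score 50")
            return RiskScore(50.0)
        return RiskScore(100.0 * d_neg / (d_pos + d_neg))

    def ensemble_vote(self, x: np.ndarray) -> int:
        """Majority vote of the ensemble: 1 = predicted event, 0 otherwise."""
        if not self.ensemble:
            raise FitError("ensemble not fitted")
        z = self.standardize(x)
        votes = sum(int(clf.predict(z)[0]) for clf in self.ensemble)
        return int(votes * 2 > len(self.ensemble))

    def score(self, x: np.ndarray) -> RiskScore:
        raw = self.distance_score(x)
        return adjust_score(raw, self.ensemble_vote(x), self.delta)

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.score(row).value for row in np.atleast_2d(X)])

    # ---- serialization -----------------------------------------------

    def to_json(self) -> str:
        """Serialize scaler, centroids and the linear ensemble weights."""
        ens = [{
            "coef": clf.coef_.ravel().tolist(),
            "intercept": float(clf.intercept_[0]),
            "classes": clf.classes_.tolist(),
        } for clf in self.ensemble]
        return json.dumps({
            "feature_names": self.feature_names,
            "center": self.center.tolist(),
            "spread": self.spread.tolist(),
            "mu_pos": self.mu_pos.tolist(),
            "mu_neg": self.mu_neg.tolist(),
            "ensemble_linear": ens,
            "n_partitions": self.n_partitions,
            "delta": self.delta,
            "seed": self.seed,
        }, indent=2)


def fit_cluster_centers(X: np.ndarray, y: np.ndarray) -> ScoreModel:
    """Convenience: fit scaler + class centroids only (no ensemble)."""
    m = ScoreModel()
    X = np.asarray(X, dtype=float)
    m.fit_scaler(X)
    m.fit_cluster_centers(X, y)
    return m


def fit_imbalanced_ensemble(X: np.ndarray, y: np.ndarray,
                            n_partitions: int | None = None,
                            seed: int = 0, delta: float = DEFAULT_DELTA) -> ScoreModel:
    """Fit the complete model: scaler, centroids and balanced SVM ensemble."""
    m = ScoreModel(delta=delta, seed=seed)
    return m.fit(np.asarray(X, dtype=float), y, n_partitions=n_partitions)


def adjust_score(raw: RiskScore, ensemble_vote: int, delta: float = DEFAULT_DELTA) -> RiskScore:
    """Move the base score by ``delta`` in the direction of the vote,
    clamped to [0, 100]; the risk category is recomputed."""
    if ensemble_vote:
        value = min(100.0, raw.value + delta)
    else:
        value = max(0.0, raw.value - delta)
    return RiskScore(value)


def loo_validate(X: np.ndarray, y: np.ndarray, n_partitions: int | None = None,
                 delta: float = DEFAULT_DELTA, seed: int = 0) -> np.ndarray:
    """Leave-one-out risk scores for every row of ``X``.

    For each held-out patient the scaler, centroids and ensemble are refit
    on the remaining n−1 rows. If a fold loses an entire outcome class
    (impossible here for n >= 10 with >= 2 per class, but guarded), the
    held-out score falls back to the centroid-distance score alone.

    Returns the per-patient score vector (0–100) for downstream ROC and
    threshold analysis.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = X.shape[0]
    if n < 10:
        raise FitError("leave-one-out validation needs n >= 10")
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise FitError("both classes need >= 2 samples")
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        model = ScoreModel(delta=delta, seed=seed)
        model.fit_scaler(Xtr)
        model.fit_cluster_centers(Xtr, ytr)
        try:
            model.fit_imbalanced_ensemble(Xtr, ytr, n_partitions=n_partitions)
            scores[i] = model.score(X[i]).value
        except FitError:
            scores[i] = model.distance_score(X[i]).value
        mask[i] = True
    return scores


def ml_positive(score: RiskScore | float, cutoff: float = DEFAULT_ML_CUTOFF) -> bool:
    """Screen-positive flag: score at or above the cutoff (default >= 60)."""
    value = score.value if isinstance(score, RiskScore) else float(score)
    return value >= cutoff
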