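"""Class-imbalance handling by under-sampled classifier pool + AdaBoost.

EIOD-positive points are a small minority of a 6MWT record, so a single
classifier trained on the raw point table is dominated by negatives.  The
strategy implemented here:

1. draw ``L`` balanced training subsets, each = *all* minority rows plus an
   equally sized uniform without-replacement draw of majority rows
   (:func:`undersample_subsets`);
2. fit one base classifier per subset (:func:`train_pool`);
3. run discrete AdaBoost *over the fixed pool*: each round pick the member
   with the smallest weighted 0/1 error on the full (imbalanced) training
   set, weight it by :math:`\\alpha_k = \\tfrac12 \\ln((1-\\epsilon_k)/\\epsilon_k)`,
   reweight the samples, and remove it from the candidate set
   (:func:`adaboost_select`);
4. score new points with the :math:`\\alpha`-weighted mean of the selected
   team's probabilities (:meth:`EnsembleModel.score`).

Boosting runs on the full imbalanced set because the members already saw
balanced data; the reweighting then measures complementarity where the
final classifier will actually operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, TrainingError, ValidationError
from .features import FeatureConfig, LabeledDataset

logger = logging.getLogger(__name__)

EPS_CLIP = 1e-10

SERIAL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# base classifier adapters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseClassifierSpec:
    """Which base learner to use and with what hyperparameters.

    Kinds: ``logistic`` (fast, deterministic — the default for tests and
    desk-scale experiments), ``mlp``, ``svm``.  An ``lstm`` kind is part of
    the method's design space but requires a deep-learning backend that this
    distribution does not bundle; requesting it raises :class:`ConfigError`.
    """

    kind: str = "logistic"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("logistic", "mlp", "svm", "lstm"):
            raise ConfigError(f"unknown base classifier kind {self.kind!r}")


class SklearnAdapter:
    """Uniform fit/score facade over a scikit-learn probabilistic classifier."""

    def __init__(self, estimator) -> None:
        self._est = estimator
        self._single_class: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnAdapter":
        classes = np.unique(y)
        if len(classes) < 2:
            # degenerate balanced subset (can only happen on pathological
            # input); emit the constant class probability
            self._single_class = int(classes[0])
            return self
        self._est.fit(X, y)
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive (EIOD) class, in [0, 1]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._single_class is not None:
            return np.full(len(X), float(self._single_class))
        proba = self._est.predict_proba(X)
        pos = list(self._est.classes_).index(1)
        return proba[:, pos]


def make_classifier(spec: BaseClassifierSpec, seed: int | None = None) -> SklearnAdapter:
    """Instantiate an untrained adapter for the given spec.

    ``seed`` overrides ``spec.seed`` (used by :func:`train_pool` to give
    each pool member its own derived seed).  Every adapter wraps its
    estimator with a StandardScaler fitted on its own training subset only
    (disable with the ``standardize: false`` hyperparameter).
    """
    seed = spec.seed if seed is None else int(seed)
    hp = dict(spec.hyperparameters)
    # z-scaling is fitted on the member's own training subset only (no
    # leakage); besides benefiting scale-sensitive learners it conditions
    # the lbfgs solve (theta features span ~0-100, gradients ~0.01)
    standardize = hp.pop("standardize", True)
    if spec.kind == "logistic":
        est = LogisticRegression(max_iter=hp.pop("max_iter", 1000), **hp)
    elif spec.kind == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (16,)),
            max_iter=hp.pop("max_iter", 300),
            random_state=seed,
            **hp,
        )
    elif spec.kind == "svm":
        est = SVC(
            probability=True,
            random_state=seed,
            gamma=hp.pop("gamma", "scale"),
            **hp,
        )
    else:  # lstm
        raise ConfigError(
            "the 'lstm' base classifier requires a deep-learning backend that "
            "is not bundled with this package; use 'mlp', 'svm' or 'logistic'"
        )
    if standardize:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return SklearnAdapter(est)


# ---------------------------------------------------------------------------
# pool construction
# ---------------------------------------------------------------------------

@dataclass
class ClassifierPool:
    """L base classifiers, each trained on one balanced subset."""

    members: list[SklearnAdapter]
    subset_indices: list[np.ndarray]
    L: int

    def __post_init__(self) -> None:
        if not (len(self.members) == len(self.subset_indices) == self.L):
            raise ValidationError("pool bookkeeping mismatch")


def undersample_subsets(
    dataset: LabeledDataset, L: int, seed: int
) -> list[np.ndarray]:
    """Draw L balanced row-index sets: all minority rows + m random majority rows.

    Majority draws are uniform without replacement and independent across
    subsets; the whole draw is reproducible under ``seed``.
    """
    dataset.require_trainable()
    if L < 1:
        raise ConfigError("L must be >= 1")
    y = dataset.labels
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) <= len(neg):
        minority, majority = pos, neg
    else:
        minority, majority = neg, pos
    m = len(minority)
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(L):
        drawn = rng.choice(majority, size=m, replace=False)
        subsets.append(np.sort(np.concatenate([minority, drawn])))
    return subsets


def _member_seeds(seed: int, L: int) -> np.ndarray:
    """Deterministic per-member seeds derived from the master seed."""
    return np.random.SeedSequence(seed).generate_state(L) % (2**31)


def train_pool(
    dataset: LabeledDataset,
    spec: BaseClassifierSpec,
    L: int = 11,
    seed: int = 0,
) -> ClassifierPool:
    """Fit L base classifiers, one per balanced under-sampled subset."""
    subsets = undersample_subsets(dataset, L, seed)
    seeds = _member_seeds(seed, L)
    members: list[SklearnAdapter] = []
    for k, idx in enumerate(subsets):
        try:
            adapter = make_classifier(spec, seed=int(seeds[k]))
            adapter.fit(dataset.X[idx], dataset.labels[idx])
        except ConfigError:
            raise
        except Exception as exc:  # pragma: no cover - adapter failure path
            raise TrainingError(f"pool member {k} failed to train: {exc}") from exc
        members.append(adapter)
    logger.info("trained pool of %d %s members", L, spec.kind)
    return ClassifierPool(members=members, subset_indices=subsets, L=L)


# ---------------------------------------------------------------------------
# AdaBoost team selection
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """The AdaBoost-selected team with weights, plus the final scorer."""

    team: list[SklearnAdapter]
    alphas: np.ndarray
    feature_config: FeatureConfig | None = None
    member_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if len(self.team) != len(self.alphas):
            raise ValidationError("team and alphas length mismatch")
        if np.any(self.alphas <= 0):
            raise ValidationError("alphas must be positive")

    @property
    def K(self) -> int:
        return len(self.team)

    def score(self, X: np.ndarray) -> np.ndarray:
        """alpha-weighted mean of member probabilities — in [0, 1]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.feature_config is not None and X.shape[1] != self.feature_config.dimension:
            raise ValidationError(
                f"feature dimension {X.shape[1]} does not match model's "
                f"{self.feature_config.dimension}"
            )
        member_scores = np.stack([m.score(X) for m in self.team])
        return np.average(member_scores, axis=0, weights=self.alphas)

    def classify(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Hard labels: 1 iff score strictly exceeds the threshold."""
        if not 0.0 <= threshold <= 1.0:
            raise ConfigError("threshold must be in [0, 1]")
        return (self.score(X) > threshold).astype(np.int64)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "schema_version": SERIAL_SCHEMA_VERSION,
            "team": self.team,
            "alphas": self.alphas,
            "feature_config": self.feature_config,
            "member_indices": self.member_indices,
        }
        joblib.dump(payload, path)
        return path

    @staticmethod
    def load(path: str | Path) -> "EnsembleModel":
        payload = joblib.load(path)
        if payload.get("schema_version") != SERIAL_SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported model archive version {payload.get('schema_version')!r}"
            )
        return EnsembleModel(
            team=payload["team"],
            alphas=payload["alphas"],
            feature_config=payload["feature_config"],
            member_indices=payload["member_indices"],
        )


def ensemble_score(model: EnsembleModel, x: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`EnsembleModel.score`."""
    return model.score(x)


def classify(model: EnsembleModel, x: np.ndarray, threshold: float) -> np.ndarray:
    """Functional alias for :meth:`EnsembleModel.classify`."""
    return model.classify(x, threshold)


def adaboost_select(
    pool: ClassifierPool,
    dataset: LabeledDataset,
    max_rounds: int | None = None,
    feature_config: FeatureConfig | None = None,
) -> EnsembleModel:
    """Select a weighted team of K <= L pool members by discrete AdaBoost.

    Classic AdaBoost over a *fixed* hypothesis pool, on the full
    (imbalanced) training set:

    * start from uniform sample weights;
    * each round evaluate every remaining member's weighted 0/1 error
      ``eps`` (hard label = probability >= 0.5), select the minimiser
      (ties broken by lowest pool index);
    * stop *before* adding it if ``eps >= 0.5``;
    * ``alpha = 0.5 * ln((1 - eps) / eps)`` with ``eps`` clipped to
      ``[1e-10, 1 - 1e-10]``;
    * reweight ``w_i <- w_i * exp(-alpha * y_i * h_i)`` with y, h in {-1,+1},
      renormalise, and remove the member from the candidate set;
    * K = rounds completed: stops at ``max_rounds`` (default L), pool
      exhaustion, ``eps >= 0.5``, or ``eps == 0`` after adding.

    Raises :class:`TrainingError` if no member beats chance in round 1.
    """
    if not pool.members:
        raise ValidationError("empty classifier pool")
    dataset.require_trainable()
    if max_rounds is None:
        max_rounds = pool.L
    n = len(dataset)
    y = np.where(dataset.labels == 1, 1.0, -1.0)
    # hard votes of every member on the full training set, in {-1, +1}
    votes = np.stack(
        [np.where(m.score(dataset.X) >= 0.5, 1.0, -1.0) for m in pool.members]
    )
    miss = votes != y  # (L, n) boolean

    w = np.full(n, 1.0 / n)
    remaining = list(range(pool.L))
    team: list[SklearnAdapter] = []
    alphas: list[float] = []
    chosen: list[int] = []

    for _ in range(max_rounds):
        if not remaining:
            break
        errors = np.array([float(miss[j] @ w) for j in remaining])
        best = int(np.argmin(errors))  # ties -> lowest pool index (stable order)
        eps_raw = float(errors[best])
        j = remaining[best]
        if eps_raw >= 0.5:
            if not team:
                raise TrainingError(
                    "no weak learner beats chance: every pool member has "
                    "weighted error >= 0.5 on round 1"
                )
            break
        eps = min(max(eps_raw, EPS_CLIP), 1.0 - EPS_CLIP)
        alpha = 0.5 * np.log((1.0 - eps) / eps)
        team.append(pool.members[j])
        alphas.append(alpha)
        chosen.append(j)
        remaining.remove(j)
        w = w * np.exp(-alpha * y * votes[j])
        w = w / w.sum()
        if eps_raw == 0.0:
            break

    logger.info("adaboost selected K=%d members (pool L=%d)", len(team), pool.L)
    return EnsembleModel(
        team=team,
        alphas=np.asarray(alphas),
        feature_config=feature_config,
        member_indices=chosen,
    )


def fit_ensemble(
    dataset: LabeledDataset,
    spec: BaseClassifierSpec,
    L: int = 11,
    seed: int = 0,
    max_rounds: int | None = None,
    feature_config: FeatureConfig | None = None,
) -> EnsembleModel:
    """Convenience: undersample -> pool -> AdaBoost in one call."""
    pool = train_pool(dataset, spec, L=L, seed=seed)
    return adaboost_select(pool, dataset, max_rounds=max_rounds, feature_config=feature_config)


def fit_single(
    dataset: LabeledDataset,
    spec: BaseClassifierSpec,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
) -> EnsembleModel:
    """Baseline comparator: one classifier on one balanced subset (K=1)."""
    pool = train_pool(dataset, spec, L=1, seed=seed)
    return EnsembleModel(
        team=[pool.members[0]],
        alphas=np.asarray([1.0]),
        feature_config=feature_config,
        member_indices=[0],
    )
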