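"""Threshold-sweep ROC/AUC, subject-wise LOOCV, and the (w_size, G) grid search.

The global performance index is the area under the ROC curve obtained by
sweeping the decision threshold T over the distinct ensemble scores.  The
trapezoidal AUC of that curve equals the Mann–Whitney statistic with ties
counted one half, which the test suite verifies against a brute-force
pairwise oracle.

Cross-validation is leave-one-*subject*-out: one fold per subject, training
on every other subject's points, so no subject's samples ever inform the
scores of its own points.  The reported AUC pools all out-of-fold point
scores (micro pooling); per-fold score lists are also returned for
inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ensemble import BaseClassifierSpec, fit_ensemble, fit_single
from .errors import ConfigError, ValidationError
from .features import FeatureConfig, LabeledDataset, encode_record
from .signal_io import Cohort, calibrate

logger = logging.getLogger(__name__)

DEFAULT_W_GRID = (5, 7, 9, 11, 13, 15)
DEFAULT_G_GRID = (1, 3, 5, 7, 9)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Threshold sweep output: descending thresholds, FPR/TPR arrays, AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve and trapezoidal AUC from sweeping the threshold T.

    The sweep visits every distinct score (descending) plus the sentinels
    1 and 0, so the curve starts at (0, 0) and ends at (1, 1).  Tied scores
    enter the curve together, which makes the trapezoidal area equal to the
    Mann–Whitney statistic with ties counted 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if len(s) != len(y):
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: both classes must be present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # last index of each distinct score value
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    cut = np.concatenate([distinct, [len(s) - 1]])
    tps = np.cumsum(y_sorted == 1)[cut]
    fps = np.cumsum(y_sorted == 0)[cut]

    thresholds = np.concatenate([[1.0], s_sorted[cut], [0.0]])
    tpr = np.concatenate([[0.0], tps / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], fps / n_neg, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def plot_roc(result: RocResult, path: str | None = None, label: str | None = None):
    """Optional ROC figure (matplotlib imported lazily)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(result.fpr, result.tpr, label=f"{label or 'ROC'} (AUC={result.auc:.4f})")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Out-of-fold scores per subject plus the pooled AUC."""

    per_fold: dict[str, tuple[np.ndarray, np.ndarray]]  # id -> (scores, labels)
    pooled_auc: float
    config: dict = field(default_factory=dict)

    @property
    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        scores = np.concatenate([s for s, _ in self.per_fold.values()])
        labels = np.concatenate([l for _, l in self.per_fold.values()])
        return scores, labels

    def per_fold_auc(self) -> dict[str, float]:
        """Per-subject AUC where defined (subject has both classes)."""
        out = {}
        for sid, (s, l) in self.per_fold.items():
            if np.any(l == 0) and np.any(l == 1):
                out[sid] = roc_auc(s, l).auc
        return out


def _fold_seed(master: int, fold: int) -> int:
    """Stable per-fold seed derived from the master seed."""
    return int(np.random.SeedSequence((master, fold)).generate_state(1)[0] % (2**31))


def loocv(
    cohort: Cohort,
    feature_cfg: FeatureConfig,
    spec: BaseClassifierSpec,
    ens_cfg: Mapping | None = None,
    seed: int = 0,
) -> CvReport:
    """Subject-wise leave-one-out evaluation of the full pipeline.

    For each subject, an ensemble (undersample -> pool -> AdaBoost) is
    trained on all *other* subjects' calibrated, encoded points, and the
    held-out subject's points are scored.  ``ens_cfg`` keys: ``L`` (pool
    size, default 11), ``max_rounds`` (default L), ``method`` ("adaboost",
    the default, or "single" — one classifier on one balanced subset, the
    non-ensembled comparator).

    The pooled AUC over all out-of-fold scores is the headline number.
    """
    cfg = dict(ens_cfg or {})
    L = int(cfg.get("L", 11))
    max_rounds = cfg.get("max_rounds")
    method = cfg.get("method", "adaboost")
    if method not in ("adaboost", "single"):
        raise ConfigError(f"unknown ensemble method {method!r}")
    if len(cohort) < 2:
        raise ValidationError("LOOCV needs at least 2 subjects")

    encoded = [encode_record(calibrate(r), feature_cfg) for r in cohort]
    per_fold: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for fold, held_out in enumerate(cohort):
        train_parts = [encoded[j] for j in range(len(cohort)) if j != fold]
        train = LabeledDataset.concatenate(train_parts)
        if not train.has_both_classes:
            raise ValidationError(
                f"training fold for subject {held_out.subject_id!r} lacks a class"
            )
        fseed = _fold_seed(seed, fold)
        if method == "adaboost":
            model = fit_ensemble(
                train, spec, L=L, seed=fseed, max_rounds=max_rounds,
                feature_config=feature_cfg,
            )
        else:
            model = fit_single(train, spec, seed=fseed, feature_config=feature_cfg)
        test = encoded[fold]
        per_fold[held_out.subject_id] = (model.score(test.X), test.labels.copy())

    scores = np.concatenate([s for s, _ in per_fold.values()])
    labels = np.concatenate([l for _, l in per_fold.values()])
    pooled = roc_auc(scores, labels).auc
    logger.info("loocv: %d folds, pooled AUC %.4f", len(per_fold), pooled)
    return CvReport(
        per_fold=per_fold,
        pooled_auc=pooled,
        config={
            "feature_cfg": feature_cfg,
            "spec": spec,
            "L": L,
            "max_rounds": max_rounds,
            "method": method,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# (w_size, G) grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    """Pooled AUC per (w_size, G) pair and the argmax pair."""

    grid: dict[tuple[int, int], float]
    best: tuple[int, int]

    @property
    def best_auc(self) -> float:
        return self.grid[self.best]


def grid_search(
    cohort: Cohort,
    spec: BaseClassifierSpec,
    w_sizes: Sequence[int] = DEFAULT_W_GRID,
    g_values: Sequence[int] = DEFAULT_G_GRID,
    ens_cfg: Mapping | None = None,
    seed: int = 0,
    variant: str = "extended",
    edge_policy: str = "clamp",
) -> GridSearchResult:
    """LOOCV pooled AUC over the (w_size, G) grid; ties prefer smaller pair.

    The default grid spans w_size 5..15 and G 1..9, both in steps of 2;
    pairs with G >= w_size are skipped as invalid.
    """
    grid: dict[tuple[int, int], float] = {}
    for w in w_sizes:
        for g in g_values:
            if g >= w:
                continue
            cfg = FeatureConfig(w_size=w, g_max=g, variant=variant, edge_policy=edge_policy)
            grid[(w, g)] = loocv(cohort, cfg, spec, ens_cfg=ens_cfg, seed=seed).pooled_auc
            logger.info("grid (w=%d, G=%d): AUC %.4f", w, g, grid[(w, g)])
    if not grid:
        raise ConfigError("empty parameter grid")
    best = min(grid, key=lambda k: (-grid[k], k[0], k[1]))
    return GridSearchResult(grid=grid, best=best)
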