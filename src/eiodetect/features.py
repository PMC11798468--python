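"""Per-point feature encoding of calibrated SpO2/PR series.

Each data point *i* of a record is encoded into a feature vector built from
up to five components:

* ``s``          — the SpO2 value :math:`s_i` itself (percent);
* ``s_window``   — the mean SpO2 over a ``w_size``-sample window centred at
  *i* (percent);
* ``s_gradient`` — the relative one-step change
  :math:`(s_i - s_{i-1}) / s_{i-1}` (dimensionless; defined as 0 at *i* = 0);
* ``p``          — the pulse rate :math:`p_i` (beats/min);
* ``s_correlation`` — the lag-structure statistic
  :math:`\\theta_{ig} = \\frac{1}{w_{size}-g}
  \\sum_{t=i-h}^{i+h-g} (s_t - s_{t+g})^2`, for lags
  :math:`g = 1..G` with :math:`h = (w_{size}-1)/2` — a variogram-style mean
  squared lag difference inside the centred window, sensitive to ramps and
  oscillations that accompany desaturation episodes.

Out-of-range window indices are handled by an edge policy: ``clamp``
(replicate the boundary value, the default, so every point gets a
full-dimension vector) or ``drop`` (average only in-range values/pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .signal_io import Cohort, WalkRecord

#: feature components per variant, in row order
VARIANT_COMPONENTS: dict[str, tuple[str, ...]] = {
    "simple": ("s", "p"),
    "window": ("s", "s_window", "p"),
    "gradient": ("s", "s_gradient", "p"),
    "baseline4": ("s", "s_window", "s_gradient", "p"),
    "extended": ("s", "s_window", "s_gradient", "p", "s_correlation"),
}


@dataclass(frozen=True)
class FeatureConfig:
    """Encoding parameters.

    Defaults (``w_size=11``, ``g_max=5``) are the grid-search optimum pair
    for the method's reference configuration; both are tunable and subject
    to :func:`eiodetect.evaluation.grid_search`.
    """

    w_size: int = 11
    g_max: int = 5
    variant: str = "extended"
    edge_policy: str = "clamp"

    def __post_init__(self) -> None:
        if self.w_size < 3 or self.w_size % 2 == 0:
            raise ConfigError(f"w_size must be odd and >= 3, got {self.w_size}")
        if not 1 <= self.g_max < self.w_size:
            raise ConfigError(
                f"g_max must satisfy 1 <= g_max < w_size, got g_max={self.g_max}, "
                f"w_size={self.w_size}"
            )
        if self.variant not in VARIANT_COMPONENTS:
            raise ConfigError(
                f"unknown variant {self.variant!r}; one of {sorted(VARIANT_COMPONENTS)}"
            )
        if self.edge_policy not in ("clamp", "drop"):
            raise ConfigError(f"unknown edge_policy {self.edge_policy!r}")

    @property
    def dimension(self) -> int:
        dim = 0
        for comp in VARIANT_COMPONENTS[self.variant]:
            dim += self.g_max if comp == "s_correlation" else 1
        return dim

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for comp in VARIANT_COMPONENTS[self.variant]:
            if comp == "s_correlation":
                names.extend(f"theta_{g}" for g in range(1, self.g_max + 1))
            else:
                names.append(comp)
        return names


@dataclass
class LabeledDataset:
    """Per-point feature rows with labels and subject provenance.

    The unit consumed by training and cross-validation.  ``labels`` uses
    -1 for unlabelled rows; training operations require {0, 1} only and
    both classes present.
    """

    X: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D (rows x features)")
        if not (len(self.X) == len(self.labels) == len(self.subject_ids)):
            raise ValidationError("X, labels and subject_ids must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def has_both_classes(self) -> bool:
        return bool(np.any(self.labels == 0) and np.any(self.labels == 1))

    def require_trainable(self) -> None:
        if np.any((self.labels != 0) & (self.labels != 1)):
            raise ValidationError("dataset contains unlabelled rows (label -1)")
        if not self.has_both_classes:
            raise ValidationError("dataset must contain both classes")

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.X[idx],
            self.labels[idx],
            self.subject_ids[idx],
            self.feature_names,
            None if self.timestamps is None else self.timestamps[idx],
        )

    @staticmethod
    def concatenate(parts: Sequence["LabeledDataset"]) -> "LabeledDataset":
        if not parts:
            raise ValidationError("nothing to concatenate")
        names = parts[0].feature_names
        ts = None
        if all(p.timestamps is not None for p in parts):
            ts = np.concatenate([p.timestamps for p in parts])
        return LabeledDataset(
            np.vstack([p.X for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
            names,
            ts,
        )


# ---------------------------------------------------------------------------
# point-wise features
# ---------------------------------------------------------------------------

def _half(cfg: FeatureConfig) -> int:
    return (cfg.w_size - 1) // 2


def window_feature(series: Sequence[float], i: int, cfg: FeatureConfig) -> float:
    """Mean SpO2 over the ``w_size`` window centred at *i*."""
    s = np.asarray(series, dtype=float)
    n = len(s)
    if n == 0 or not 0 <= i < n:
        raise ValidationError(f"index {i} out of bounds for series of length {n}")
    h = _half(cfg)
    idx = np.arange(i - h, i + h + 1)
    if cfg.edge_policy == "clamp":
        return float(np.mean(s[np.clip(idx, 0, n - 1)]))
    idx = idx[(idx >= 0) & (idx < n)]
    return float(np.mean(s[idx]))


def gradient_feature(series: Sequence[float], i: int) -> float:
    """Relative one-step SpO2 change ``(s_i - s_{i-1}) / s_{i-1}``.

    At the series start there is no previous sample; 0 ("no change") is the
    neutral convention used there.
    """
    s = np.asarray(series, dtype=float)
    if not 0 <= i < len(s):
        raise ValidationError(f"index {i} out of bounds")
    if i == 0:
        return 0.0
    if s[i - 1] == 0:
        raise ValidationError(f"zero SpO2 at index {i - 1}: gradient undefined")
    return float((s[i] - s[i - 1]) / s[i - 1])


def correlation_feature(
    series: Sequence[float], i: int, cfg: FeatureConfig
) -> np.ndarray:
    """Lag statistic vector ``(theta_1, ..., theta_G)`` at point *i*.

    ``theta_g`` averages the ``w_size - g`` squared lag-``g`` differences of
    SpO2 inside the centred window; under the ``drop`` edge policy only
    in-range pairs are averaged (an empty pair set yields 0).
    """
    s = np.asarray(series, dtype=float)
    n = len(s)
    if not 0 <= i < n:
        raise ValidationError(f"index {i} out of bounds")
    h = _half(cfg)
    thetas = np.empty(cfg.g_max, dtype=float)
    for g in range(1, cfg.g_max + 1):
        t = np.arange(i - h, i + h - g + 1)
        if cfg.edge_policy == "clamp":
            lo = np.clip(t, 0, n - 1)
            hi = np.clip(t + g, 0, n - 1)
            thetas[g - 1] = np.sum((s[lo] - s[hi]) ** 2) / (cfg.w_size - g)
        else:
            keep = (t >= 0) & (t + g < n)
            t = t[keep]
            thetas[g - 1] = (
                float(np.mean((s[t] - s[t + g]) ** 2)) if len(t) else 0.0
            )
    return thetas


# ---------------------------------------------------------------------------
# vectorised record encoding
# ---------------------------------------------------------------------------

def _window_means(s: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    h = _half(cfg)
    if cfg.edge_policy == "clamp":
        padded = np.pad(s, h, mode="edge")
        view = np.lib.stride_tricks.sliding_window_view(padded, cfg.w_size)
        return view.mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(s)])
    n = len(s)
    lo = np.clip(np.arange(n) - h, 0, n)
    hi = np.clip(np.arange(n) + h + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _gradients(s: np.ndarray) -> np.ndarray:
    g = np.zeros_like(s, dtype=float)
    prev = s[:-1]
    if np.any(prev == 0):
        raise ValidationError("zero SpO2 value: gradient undefined")
    g[1:] = (s[1:] - prev) / prev
    return g


def _thetas(s: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    n = len(s)
    h = _half(cfg)
    out = np.empty((n, cfg.g_max), dtype=float)
    if cfg.edge_policy == "clamp":
        padded = np.pad(s, h, mode="edge")
        for g in range(1, cfg.g_max + 1):
            d2 = (padded[:-g] - padded[g:]) ** 2
            # theta_ig sums d2 over window offsets 0 .. w_size-1-g at origin i
            view = np.lib.stride_tricks.sliding_window_view(d2, cfg.w_size - g)
            out[:, g - 1] = view[:n].sum(axis=1) / (cfg.w_size - g)
    else:
        for i in range(n):
            out[i] = correlation_feature(s, i, cfg)
    return out


def encode_record(record: WalkRecord, cfg: FeatureConfig) -> LabeledDataset:
    """Encode every point of a calibrated record into feature rows.

    Labels are copied from ``is_eiod`` (-1 where unlabelled); row order is
    time order and the subject id is propagated to every row.
    """
    if len(record) == 0:
        raise ValidationError("cannot encode an empty record")
    s = record.spo2
    columns: list[np.ndarray] = []
    for comp in VARIANT_COMPONENTS[cfg.variant]:
        if comp == "s":
            columns.append(s)
        elif comp == "p":
            columns.append(record.pr)
        elif comp == "s_window":
            columns.append(_window_means(s, cfg))
        elif comp == "s_gradient":
            columns.append(_gradients(s))
        elif comp == "s_correlation":
            columns.append(_thetas(s, cfg))
    X = np.column_stack(columns)
    return LabeledDataset(
        X=X,
        labels=record.labels,
        subject_ids=np.full(len(record), record.subject_id, dtype=object),
        feature_names=cfg.feature_names,
        timestamps=record.timestamps,
    )


def encode_cohort(cohort: Cohort, cfg: FeatureConfig) -> LabeledDataset:
    """Encode every record of a cohort and stack the rows."""
    return LabeledDataset.concatenate([encode_record(r, cfg) for r in cohort])
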