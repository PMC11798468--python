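"""The clinical exercise-induced oxygen desaturation (EIOD) rule.

A point during the six-minute walk test is in EIOD status when its SpO2 has
dropped more than ``drop_threshold`` percentage points below the subject's
baseline, and/or is below the ``floor_threshold`` (defaults: > 4-point drop,
floor 90%).  Both inequalities are strict.

The rule is used to assign ground-truth labels to synthetic cohorts and for
sanity checks; it makes no claim of replicating clinicians' manual labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ValidationError
from .signal_io import WalkRecord


@dataclass(frozen=True)
class EiodRuleConfig:
    """Parameters of the desaturation rule.

    ``drop_threshold`` is in SpO2 percentage points (absolute units, the
    standard clinical reading of "drop > 4%"); set ``relative=True`` to read
    it as a relative fraction of baseline instead.  ``baseline_policy`` is
    ``"mean_first_k"`` (mean of the first ``baseline_k`` samples, default)
    or ``"first_sample"``.
    """

    drop_threshold: float = 4.0
    floor_threshold: float = 90.0
    baseline_policy: str = "mean_first_k"
    baseline_k: int = 5
    relative: bool = False

    def __post_init__(self) -> None:
        if self.drop_threshold <= 0:
            raise ConfigError("drop_threshold must be positive")
        if not 0.0 < self.floor_threshold < 100.0:
            raise ConfigError("floor_threshold must be in (0, 100)")
        if self.baseline_policy not in ("first_sample", "mean_first_k"):
            raise ConfigError(f"unknown baseline_policy {self.baseline_policy!r}")
        if self.baseline_k < 1:
            raise ConfigError("baseline_k must be a positive integer")


def compute_baseline(
    record: WalkRecord | np.ndarray, cfg: EiodRuleConfig = EiodRuleConfig()
) -> float:
    """Baseline SpO2 against which drops are measured.

    Accepts a record or a bare SpO2 array (used when labelling latent,
    noise-free trajectories).
    """
    spo2 = record.spo2 if isinstance(record, WalkRecord) else np.asarray(record, float)
    if cfg.baseline_policy == "first_sample":
        return float(spo2[0])
    if len(spo2) < cfg.baseline_k:
        raise ValidationError(
            f"record too short for mean_first_k baseline: {len(spo2)} < {cfg.baseline_k}"
        )
    return float(np.mean(spo2[: cfg.baseline_k]))


def label_points(
    record: WalkRecord | np.ndarray, cfg: EiodRuleConfig = EiodRuleConfig()
) -> np.ndarray:
    """Binary EIOD label per point.

    Point *i* is labelled 1 iff ``baseline - spo2_i > drop_threshold`` or
    ``spo2_i < floor_threshold`` (both strict, as the clinical definition
    is phrased).
    """
    spo2 = record.spo2 if isinstance(record, WalkRecord) else np.asarray(record, float)
    baseline = compute_baseline(spo2, cfg)
    drop = baseline * cfg.drop_threshold if cfg.relative else cfg.drop_threshold
    labels = (baseline - spo2 > drop) | (spo2 < cfg.floor_threshold)
    return labels.astype(np.int64)
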