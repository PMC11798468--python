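"""Seeded synthetic 6MWT cohort generator.

Emulates the statistical structure the identification method assumes: a
stable per-subject SpO2 baseline with episodic desaturations (linear
down-ramp, plateau at baseline minus the episode depth, linear recovery),
a pulse rate that rises during episodes (loose anti-correlation with SpO2),
integer-rounded noisy observations at ~1 Hz over ~360 s, per-point
validity/quality flag dropout, and the resulting severe point-level class
imbalance (EIOD-positive points are a small minority of the cohort).

Ground-truth labels come from the clinical desaturation rule applied to the
*latent, noise-free* SpO2 trajectory, so classifier performance measures
signal recovery rather than label noise; set ``label_observed=True`` for the
harder benchmark where the rule is applied to the noisy observed series.

Seeding is two-level (master seed -> per-subject seed), so growing a cohort
never changes the subjects already generated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .eiod_rules import EiodRuleConfig, label_points
from .errors import ConfigError
from .signal_io import Cohort, SampledPoint, WalkRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Cohort generation parameters.

    The cohort composition default (81% of subjects with at least one
    desaturation episode) mirrors a typical referred-COPD clinic mix of 69
    desaturating patients per 85 walk tests.
    """

    n_subjects: int = 20
    frac_desaturating: float = 69 / 85
    duration_s: float = 360.0
    hz: float = 1.0
    spo2_baseline_mean: float = 97.0
    spo2_baseline_sd: float = 1.0
    episode_rate: float = 1.5
    episode_depth: tuple[float, float] = (5.0, 12.0)
    episode_len_s: tuple[float, float] = (20.0, 80.0)
    ramp_s: tuple[float, float] = (5.0, 20.0)
    pr_baseline_mean: float = 90.0
    pr_baseline_sd: float = 10.0
    pr_episode_rise: tuple[float, float] = (5.0, 20.0)
    pr_noise_sd: float = 2.0
    noise_sd: float = 0.5
    flag_dropout: float = 0.02
    label_observed: bool = False
    rule: EiodRuleConfig = EiodRuleConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hz <= 0:
            raise ConfigError("hz must be positive")
        for name in ("episode_depth", "episode_len_s", "ramp_s", "pr_episode_rise"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} range must be ordered, got ({lo}, {hi})")
        for name in ("frac_desaturating", "flag_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


def _subject_rng(cfg: SimConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, index)))


def _episode_profile(
    n: int, hz: float, rng: np.random.Generator, cfg: SimConfig
) -> np.ndarray:
    """Deficit trajectory (>= 0) of one episode: ramp down, plateau, ramp up.

    The drawn episode length covers the full span including both ramps;
    episodes that would overrun the session are truncated at its end.
    """
    depth = rng.uniform(*cfg.episode_depth)
    total = rng.uniform(*cfg.episode_len_s)
    ramp_down = rng.uniform(*cfg.ramp_s)
    ramp_up = rng.uniform(*cfg.ramp_s)
    if ramp_down + ramp_up > total:  # keep at least a one-sample plateau
        scale = total / (ramp_down + ramp_up + 1.0 / hz)
        ramp_down *= scale
        ramp_up *= scale
    plateau = total - ramp_down - ramp_up
    start = rng.uniform(0.0, cfg.duration_s)

    t = np.arange(n) / hz
    deficit = np.zeros(n)
    t0, t1 = start, start + ramp_down
    t2, t3 = t1 + plateau, t1 + plateau + ramp_up
    if t3 > cfg.duration_s:
        logger.debug("episode truncated at session end (%.1fs > %.1fs)", t3, cfg.duration_s)
    down = (t >= t0) & (t < t1)
    deficit[down] = depth * (t[down] - t0) / max(ramp_down, 1e-9)
    deficit[(t >= t1) & (t < t2)] = depth
    up = (t >= t2) & (t < t3)
    deficit[up] = depth * (1.0 - (t[up] - t2) / max(ramp_up, 1e-9))
    return deficit


def simulate_subject(
    cfg: SimConfig, subject_index: int, desaturating: bool | None = None
) -> WalkRecord:
    """Generate one subject's raw-schema record.

    ``desaturating`` is normally decided by :func:`simulate_cohort`; when
    ``None`` it is drawn here from ``frac_desaturating`` using the subject's
    own generator (so the draw is stable across cohort sizes).
    """
    rng = _subject_rng(cfg, subject_index)
    desat_draw = rng.uniform() < cfg.frac_desaturating
    if desaturating is None:
        desaturating = desat_draw

    n = int(round(cfg.duration_s * cfg.hz))
    baseline = rng.normal(cfg.spo2_baseline_mean, cfg.spo2_baseline_sd)
    latent = np.full(n, baseline)
    max_deficit = np.zeros(n)
    if desaturating:
        n_episodes = max(1, rng.poisson(cfg.episode_rate))
        for _ in range(n_episodes):
            deficit = _episode_profile(n, cfg.hz, rng, cfg)
            max_deficit = np.maximum(max_deficit, deficit)
        latent = latent - max_deficit

    pr_baseline = rng.normal(cfg.pr_baseline_mean, cfg.pr_baseline_sd)
    rise = rng.uniform(*cfg.pr_episode_rise)
    depth_now = np.max(max_deficit) if np.max(max_deficit) > 0 else 1.0
    latent_pr = pr_baseline + rise * (max_deficit / depth_now)

    spo2_obs = np.clip(np.rint(latent + rng.normal(0.0, cfg.noise_sd, n)), 0, 100)
    pr_obs = np.clip(np.rint(latent_pr + rng.normal(0.0, cfg.pr_noise_sd, n)), 30, 250)

    label_source = spo2_obs if cfg.label_observed else latent
    labels = label_points(label_source, cfg.rule)

    dropped = rng.uniform(size=n) < cfg.flag_dropout
    which_flag = rng.integers(0, 2, size=n)  # 0 -> is_valid, 1 -> quality

    points = []
    for i in range(n):
        is_valid = not (dropped[i] and which_flag[i] == 0)
        quality = not (dropped[i] and which_flag[i] == 1)
        # a positive label is only meaningful on a fully valid point
        label = int(labels[i]) if (is_valid and quality) else 0
        points.append(
            SampledPoint(
                timestamp=i / cfg.hz,
                spo2=float(spo2_obs[i]),
                pr=float(pr_obs[i]),
                is_valid=is_valid,
                quality=quality,
                is_event=bool(labels[i]),
                is_eiod=label,
            )
        )
    return WalkRecord(
        subject_id=f"synthetic-{subject_index:03d}",
        points=points,
        sample_interval=1.0 / cfg.hz,
        cohort_group="copd" if desaturating else "normal",
    )


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate a full cohort; desaturating status per subject is Bernoulli
    with probability ``frac_desaturating`` drawn from each subject's own
    generator."""
    if cfg.n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    records = [simulate_subject(cfg, i, desaturating=None) for i in range(cfg.n_subjects)]
    n_desat = sum(r.cohort_group == "copd" for r in records)
    logger.info(
        "simulated cohort: %d subjects (%d desaturating), seed=%d",
        cfg.n_subjects, n_desat, cfg.seed,
    )
    return Cohort(records)


def minority_fraction(cohort: Cohort) -> float:
    """Fraction of EIOD-positive points across the cohort (class imbalance)."""
    labels = np.concatenate([r.labels for r in cohort])
    return float(np.mean(labels == 1))
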