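"""Synthetic per-second locomotion tables with the structure the analysis assumes.

The generator is a hurdle (zero-inflated) lognormal process: each second a
fish is still with probability ``zero_prob``, otherwise its displacement is
lognormal around a deterministic activity template.  The template is
piecewise by illumination segment: a dark baseline, an exponential approach
to a higher light level, and an exponentially decaying surge in any dark
segment that follows light, whose size depends on the preceding light
duration and the genotype.  Assay- and fish-level random effects act
multiplicatively (additively on the log scale).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ScheduleError
from .schedule import DARK, LIGHT, PhotoSchedule

__all__ = [
    "GenotypeEffect",
    "SynthConfig",
    "activity_template",
    "template_series",
    "simulate_fish",
    "simulate_experiment",
]


@dataclass(frozen=True)
class GenotypeEffect:
    """Multiplicative genotype modifiers on the activity template.

    ``surge_scale_by_light_duration`` maps preceding-light duration (s) to a
    multiplier on the post-light dark surge; durations between keys are
    linearly interpolated, outside the key range the nearest key applies, and
    an empty map means multiplier 1 everywhere.
    """

    label: str
    baseline_scale: float = 1.0
    light_scale: float = 1.0
    surge_scale_by_light_duration: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_scale <= 0 or self.light_scale <= 0:
            raise ConfigError("genotype scale multipliers must be > 0")
        for mult in self.surge_scale_by_light_duration.values():
            if mult <= 0:
                raise ConfigError("surge multipliers must be > 0")

    def surge_scale(self, light_duration_s: float) -> float:
        table = self.surge_scale_by_light_duration
        if not table:
            return 1.0
        keys = np.array(sorted(table), dtype=float)
        vals = np.array([table[k] for k in sorted(table)], dtype=float)
        return float(np.interp(light_duration_s, keys, vals))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic experiment."""

    schedule: PhotoSchedule
    n_assays: int = 2
    fish_per_group_per_assay: int = 12
    genotype_effects: tuple[GenotypeEffect, ...] = (GenotypeEffect("WT"),)
    dark_mean_mm_per_min: float = 3.0
    light_mean_mm_per_min: float = 12.0
    surge_peak_mm_per_min: float = 15.0
    surge_rise_tau_s: float = 30.0
    surge_decay_tau_s: float = 240.0
    zero_prob: float = 0.35
    lognormal_sigma: float = 1.0
    assay_sd: float = 0.1
    fish_sd: float = 0.2
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.zero_prob < 1:
            raise ConfigError("zero_prob must lie in [0, 1)")
        for name in (
            "dark_mean_mm_per_min",
            "light_mean_mm_per_min",
            "surge_peak_mm_per_min",
            "surge_rise_tau_s",
            "surge_decay_tau_s",
            "lognormal_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.assay_sd < 0 or self.fish_sd < 0:
            raise ConfigError("random-effect SDs must be >= 0")
        if self.n_assays < 1 or self.fish_per_group_per_assay < 1:
            raise ConfigError("need at least one assay and one fish per group")
        labels = [g.label for g in self.genotype_effects]
        if len(set(labels)) != len(labels):
            raise ConfigError("genotype labels must be unique")


def _child_rng(base_seed: int, *tokens) -> np.random.Generator:
    """Deterministic child generator keyed by (base_seed, tokens).

    Uses a cryptographic hash of the token string so that adding assays or
    fish never perturbs existing streams, independent of iteration order.
    """
    digest = hashlib.sha256("|".join(str(t) for t in tokens).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(base_seed) & 0xFFFFFFFF, *words]))


def template_series(
    schedule: PhotoSchedule, genotype: GenotypeEffect, config: SynthConfig
) -> np.ndarray:
    """Expected displacement rate (mm/min) at every absolute second of the schedule."""
    total = schedule.total_duration_s
    out = np.empty(total, dtype=float)
    dark_base = config.dark_mean_mm_per_min * genotype.baseline_scale
    light_level = config.light_mean_mm_per_min * genotype.light_scale
    pos = 0
    prev = None
    for seg in schedule.segments:
        dt = np.arange(seg.duration_s, dtype=float)
        if seg.phase == LIGHT:
            # exponential approach from the dark baseline to the light level
            out[pos : pos + seg.duration_s] = light_level - (light_level - dark_base) * np.exp(
                -dt / config.surge_rise_tau_s
            )
        else:
            level = np.full(seg.duration_s, dark_base)
            if prev is not None and prev.phase == LIGHT:
                surge = (
                    config.surge_peak_mm_per_min
                    * genotype.surge_scale(prev.duration_s)
                    * np.exp(-dt / config.surge_decay_tau_s)
                )
                level = level + surge
            out[pos : pos + seg.duration_s] = level
        pos += seg.duration_s
        prev = seg
    return out


def activity_template(
    t: int, schedule: PhotoSchedule, genotype: GenotypeEffect, config: SynthConfig
) -> float:
    """Template value at one absolute second offset ``t`` (0-based)."""
    if not 0 <= t < schedule.total_duration_s:
        raise ScheduleError(f"t={t} outside schedule [0, {schedule.total_duration_s})")
    return float(template_series(schedule, genotype, config)[t])


def _assay_effect(config: SynthConfig, assay_id: str) -> float:
    if config.assay_sd == 0:
        return 0.0
    return float(_child_rng(config.base_seed, "assay", assay_id).normal(0.0, config.assay_sd))


def simulate_fish(
    fish_id: str,
    assay_id: str,
    genotype: GenotypeEffect,
    schedule: PhotoSchedule,
    config: SynthConfig,
    template: np.ndarray | None = None,
) -> np.ndarray:
    """Per-second displacement series (mm) for one fish, length = schedule duration.

    Each second is zero with probability ``zero_prob``; otherwise lognormal
    with log-mean ``log(template/60) + assay + fish - sigma^2/2`` so that the
    expected displacement is ``(1 - zero_prob) * template / 60`` times the
    multiplicative random effects.  Deterministic under
    (base_seed, assay_id, fish_id).
    """
    if template is None:
        template = template_series(schedule, genotype, config)
    a_eff = _assay_effect(config, assay_id)
    rng = _child_rng(config.base_seed, "fish", assay_id, fish_id)
    f_eff = rng.normal(0.0, config.fish_sd) if config.fish_sd > 0 else 0.0
    n = template.size
    sigma = config.lognormal_sigma
    meanlog = np.log(template / 60.0) + a_eff + f_eff - 0.5 * sigma**2
    moving = rng.random(n) >= config.zero_prob
    disp = np.exp(rng.normal(meanlog, sigma))
    return np.where(moving, disp, 0.0)


def simulate_experiment(config: SynthConfig) -> pd.DataFrame:
    """Full balanced experiment as a long-format activity table.

    One row per fish per second, columns ``assay_id, fish_id, genotype,
    time_s, dist_mm``.  ``time_s`` is the 1-based absolute second (the second
    ending at ``time_s``); the analyzed axis starts at
    ``schedule.analysis_origin_s``.
    """
    schedule = config.schedule
    total = schedule.total_duration_s
    times = np.arange(1, total + 1, dtype=np.int64)
    frames = []
    for a in range(1, config.n_assays + 1):
        assay_id = f"a{a:02d}"
        fish_counter = 0
        for geno in config.genotype_effects:
            template = template_series(schedule, geno, config)
            for _ in range(config.fish_per_group_per_assay):
                fish_counter += 1
                fish_id = f"{assay_id}_f{fish_counter:03d}"
                disp = simulate_fish(fish_id, assay_id, geno, schedule, config, template)
                frames.append(
                    pd.DataFrame(
                        {
                            "assay_id": assay_id,
                            "fish_id": fish_id,
                            "genotype": geno.label,
                            "time_s": times,
                            "dist_mm": disp,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)
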