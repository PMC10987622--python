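"""Illumination regimens: ordered dark/light segments and indexed photo periods.

A schedule is a contiguous sequence of dark/light segments.  The *analyzed*
time axis starts at ``analysis_origin_s`` (normally the end of the dark
acclimation): analyzed second ``Time = 1`` is the first second after the
origin.  Internally all windows are half-open ``[start, end)`` intervals of
0-based analyzed seconds, so ``Time = start + 1 .. end`` in 1-based reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ScheduleError

__all__ = [
    "Segment",
    "PhotoSchedule",
    "PeriodWindow",
    "build_schedule",
    "period_windows",
    "effective_n",
    "schedule_from_config",
    "get_preset",
    "SCHEDULE_PRESETS",
]

DARK = "dark"
LIGHT = "light"

# high-intensity box settings: white 469.4 uW/cm2 (8000 lx), IR 116.0 uW/cm2 (0 lx)
WHITE_HIGH = (469.4, 8000.0)
WHITE_LOW = (20.5, 300.0)
IR_HIGH = (116.0, 0.0)


@dataclass(frozen=True)
class Segment:
    """One contiguous illumination segment."""

    phase: str
    duration_s: int
    irradiance_uW_cm2: float = 0.0
    illuminance_lx: float = 0.0

    def __post_init__(self) -> None:
        if self.phase not in (DARK, LIGHT):
            raise ScheduleError(f"phase must be 'dark' or 'light', got {self.phase!r}")
        if not isinstance(self.duration_s, (int, np.integer)) or self.duration_s < 1:
            raise ScheduleError(f"duration_s must be a positive integer, got {self.duration_s!r}")
        if self.irradiance_uW_cm2 < 0 or self.illuminance_lx < 0:
            raise ScheduleError("light intensities must be nonnegative")
        if self.phase == DARK and self.illuminance_lx != 0:
            raise ScheduleError("dark segments must have illuminance_lx = 0")


@dataclass(frozen=True)
class PhotoSchedule:
    """Ordered illumination segments plus the analyzed-time origin."""

    segments: tuple[Segment, ...]
    includes_acclimation: bool = False
    includes_final_dark: bool = False
    analysis_origin_s: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ScheduleError("schedule needs at least one segment")
        if not 0 <= self.analysis_origin_s < self.total_duration_s:
            raise ScheduleError(
                f"analysis_origin_s={self.analysis_origin_s} outside [0, {self.total_duration_s})"
            )

    @property
    def total_duration_s(self) -> int:
        return sum(s.duration_s for s in self.segments)

    @property
    def analyzed_span_s(self) -> int:
        """Number of analyzed seconds (Time runs 1..analyzed_span_s)."""
        return self.total_duration_s - self.analysis_origin_s

    def boundaries(self) -> list[int]:
        """Absolute segment start offsets plus the final end, length len(segments)+1."""
        out = [0]
        for s in self.segments:
            out.append(out[-1] + s.duration_s)
        return out

    def segment_at(self, t_abs: int) -> tuple[int, Segment]:
        """Segment index and segment containing absolute second offset ``t_abs``."""
        if not 0 <= t_abs < self.total_duration_s:
            raise ScheduleError(f"t={t_abs} outside schedule [0, {self.total_duration_s})")
        bounds = self.boundaries()
        idx = int(np.searchsorted(bounds, t_abs, side="right") - 1)
        return idx, self.segments[idx]

    def phase_series(self) -> np.ndarray:
        """Per-absolute-second phase labels (array of 'dark'/'light', length total)."""
        out = np.empty(self.total_duration_s, dtype=object)
        pos = 0
        for s in self.segments:
            out[pos : pos + s.duration_s] = s.phase
            pos += s.duration_s
        return out

    def to_config(self) -> list[dict]:
        return [
            {
                "phase": s.phase,
                "minutes": s.duration_s / 60.0,
                "irradiance": s.irradiance_uW_cm2,
                "lux": s.illuminance_lx,
            }
            for s in self.segments
        ]


@dataclass(frozen=True)
class PeriodWindow:
    """One photo period on the analyzed axis, half-open ``[start_s, end_s)``."""

    phase: str
    ordinal: int
    start_s: int
    end_s: int

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ScheduleError("PeriodWindow must have end_s > start_s")
        if self.ordinal < 1:
            raise ScheduleError("ordinal is 1-based")

    @property
    def n_seconds(self) -> int:
        return self.end_s - self.start_s

    @property
    def label(self) -> str:
        return f"{_ordinal_name(self.ordinal)} {self.phase.capitalize()}"


def _ordinal_name(n: int) -> str:
    suffix = {1: "st", 2: "nd", 3: "rd"}.get(n if n < 20 else n % 10, "th")
    return f"{n}{suffix}"


def _to_seconds(minutes: float, what: str) -> int:
    secs = minutes * 60.0
    if abs(secs - round(secs)) > 1e-9:
        raise ScheduleError(f"{what} of {minutes} min is not a whole number of seconds")
    return int(round(secs))


def build_schedule(
    acclimation_min: float,
    n_repeats: int,
    dark_min: float,
    light_min: float,
    final_dark_min: float | None = None,
    *,
    light_intensity: tuple[float, float] = WHITE_HIGH,
    dark_intensity: tuple[float, float] = IR_HIGH,
) -> PhotoSchedule:
    """Build an acclimation + ``n_repeats`` x [dark + light] (+ final dark) regimen.

    Durations are minutes and must map to whole seconds.  The analyzed time
    axis begins at the end of acclimation.  ``light_intensity`` and
    ``dark_intensity`` are (irradiance uW/cm2, illuminance lx) pairs.
    """
    if n_repeats < 1:
        raise ScheduleError("n_repeats must be >= 1")
    for val, name in [(acclimation_min, "acclimation"), (dark_min, "dark"), (light_min, "light")]:
        if val < 0:
            raise ScheduleError(f"{name} duration must be nonnegative")
    if final_dark_min is not None and final_dark_min < 0:
        raise ScheduleError("final dark duration must be nonnegative")
    if dark_min + light_min <= 0:
        raise ScheduleError("repeat block [dark + light] must have positive duration")

    dark_irr, dark_lx = dark_intensity
    light_irr, light_lx = light_intensity

    segs: list[Segment] = []
    acc_s = _to_seconds(acclimation_min, "acclimation")
    if acc_s > 0:
        segs.append(Segment(DARK, acc_s, dark_irr, dark_lx))
    dark_s = _to_seconds(dark_min, "dark period") if dark_min > 0 else 0
    light_s = _to_seconds(light_min, "light period") if light_min > 0 else 0
    for _ in range(n_repeats):
        if dark_s:
            segs.append(Segment(DARK, dark_s, dark_irr, dark_lx))
        if light_s:
            segs.append(Segment(LIGHT, light_s, light_irr, light_lx))
    final_s = 0
    if final_dark_min is not None and final_dark_min > 0:
        final_s = _to_seconds(final_dark_min, "final dark period")
        segs.append(Segment(DARK, final_s, dark_irr, dark_lx))

    return PhotoSchedule(
        segments=tuple(segs),
        includes_acclimation=acc_s > 0,
        includes_final_dark=final_s > 0,
        analysis_origin_s=acc_s,
    )


def period_windows(
    schedule: PhotoSchedule,
    phase: str,
    numbering: str = "exclude_acclimation",
) -> list[PeriodWindow]:
    """Photo-period windows of one phase on the analyzed time axis.

    With the default numbering the acclimation segment is skipped, so in a
    4-repeat regimen the repeat darks are ordinals 1-4 and the final dark is
    ordinal 5.  With ``include_acclimation`` the acclimation dark becomes
    ordinal 1 (its window has a negative start: it precedes the origin).
    """
    if phase not in (DARK, LIGHT):
        raise ScheduleError(f"phase must be 'dark' or 'light', got {phase!r}")
    if numbering not in ("exclude_acclimation", "include_acclimation"):
        raise ScheduleError(f"unknown numbering {numbering!r}")

    bounds = schedule.boundaries()
    windows: list[PeriodWindow] = []
    ordinal = 0
    for i, seg in enumerate(schedule.segments):
        is_acclimation = i == 0 and schedule.includes_acclimation
        if is_acclimation and numbering == "exclude_acclimation":
            continue
        if seg.phase != phase:
            continue
        ordinal += 1
        start = bounds[i] - schedule.analysis_origin_s
        windows.append(PeriodWindow(phase, ordinal, start, start + seg.duration_s))
    return windows


def effective_n(window: PeriodWindow, valid_mask: Sequence[bool] | np.ndarray) -> int:
    """Count of seconds in ``window`` at which the response is defined.

    ``valid_mask[i]`` flags analyzed second ``i`` (0-based); the mask must
    cover the window.
    """
    mask = np.asarray(valid_mask, dtype=bool)
    if window.start_s < 0 or window.end_s > mask.size:
        raise ScheduleError(
            f"valid_mask of length {mask.size} does not cover window "
            f"[{window.start_s}, {window.end_s})"
        )
    return int(mask[window.start_s : window.end_s].sum())


def schedule_from_config(spec: Iterable[dict] | dict | str) -> PhotoSchedule:
    """Build a schedule from a preset name, a preset/inline dict, or a segment list."""
    if isinstance(spec, str):
        return get_preset(spec)
    if isinstance(spec, dict):
        if "preset" in spec:
            return get_preset(spec["preset"])
        if "segments" in spec:
            return schedule_from_config(spec["segments"])
        kwargs = {}
        if "light_lux" in spec or "light_irradiance" in spec:
            kwargs["light_intensity"] = (
                float(spec.get("light_irradiance", WHITE_HIGH[0])),
                float(spec.get("light_lux", WHITE_HIGH[1])),
            )
        return build_schedule(
            spec.get("acclimation_min", 0.0),
            spec.get("n_repeats", 1),
            spec.get("dark_min", 0.0),
            spec.get("light_min", 0.0),
            spec.get("final_dark_min"),
            **kwargs,
        )
    segs = []
    for item in spec:
        segs.append(
            Segment(
                item["phase"],
                _to_seconds(item["minutes"], "segment"),
                float(item.get("irradiance", 0.0)),
                float(item.get("lux", 0.0)),
            )
        )
    first_dark_acc = segs[0].phase == DARK and len(segs) > 1
    return PhotoSchedule(
        segments=tuple(segs),
        includes_acclimation=first_dark_acc,
        includes_final_dark=segs[-1].phase == DARK and len(segs) > 1,
        analysis_origin_s=segs[0].duration_s if first_dark_acc else 0,
    )


def _repeat_preset(light_min: float, intensity=WHITE_HIGH) -> PhotoSchedule:
    return build_schedule(30, 4, 7.5, light_min, 25, light_intensity=intensity)


def _baseline(phase: str) -> PhotoSchedule:
    if phase == LIGHT:
        seg = Segment(LIGHT, 43_200, *WHITE_HIGH)
    else:
        seg = Segment(DARK, 43_200, *IR_HIGH)
    return PhotoSchedule(segments=(seg,), analysis_origin_s=0)


SCHEDULE_PRESETS = {
    "rep7.5": lambda: _repeat_preset(7.5),
    "rep6": lambda: _repeat_preset(6),
    "rep4": lambda: _repeat_preset(4),
    "rep2": lambda: _repeat_preset(2),
    "rep1": lambda: _repeat_preset(1),
    "rep7.5_nofinal": lambda: build_schedule(30, 4, 7.5, 7.5, None),
    "dim_rep7.5": lambda: _repeat_preset(7.5, WHITE_LOW),
    "dim_rep2": lambda: _repeat_preset(2, WHITE_LOW),
    "baseline12h_dark": lambda: _baseline(DARK),
    "baseline12h_light": lambda: _baseline(LIGHT),
}


def get_preset(name: str) -> PhotoSchedule:
    try:
        factory = SCHEDULE_PRESETS[name]
    except KeyError:
        raise ScheduleError(
            f"unknown schedule preset {name!r}; available: {sorted(SCHEDULE_PRESETS)}"
        ) from None
    return factory()


def shifted_numbering(schedule: PhotoSchedule) -> PhotoSchedule:
    """Convenience: same schedule, kept for API symmetry (numbering is a query arg)."""
    return replace(schedule)
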