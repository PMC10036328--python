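"""Wound-repair kinetics: fold expansion, closure rate, recruitment onset.

All three estimators work on measured trajectories / intensity series:

* fold expansion E = max wound area / initial wound area;
* contraction (closure) rate R = (A(t_max) − A(t_half)) / (t_half − t_max),
  where t_max is the time of maximum area and t_half the first time the
  area falls to ≤ 50% of the maximum (the curve's slope changes in the
  50–35% band, so falling below 35% at t_half only attaches a warning);
* recruitment onset = first of ≥ 2 consecutive frames in which the mean
  intensity in a 5-μm annulus outside the wound edge exceeds the far-field
  background mean by 2 SD.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import WoundTrajectory
from .io import TimeLapseStack

__all__ = [
    "ClosureRate",
    "DynamicsSummary",
    "DidNotCloseError",
    "fold_expansion",
    "contraction_rate",
    "detect_onset",
    "summarize_dynamics",
]


class DidNotCloseError(ValueError):
    """The wound never contracted to half of its maximum area."""


@dataclasses.dataclass
class ClosureRate:
    """Two-point closure-rate estimate with its anchor frames."""

    rate: float  # μm²/s, positive
    t_max: float  # s, time of maximum area (ties → earliest)
    t_half: float  # s, first frame at ≤ 50% of maximum area
    a_max: float  # μm²
    a_half: float  # μm²
    band_undershoot: bool  # True if A(t_half) < 35% of maximum

    def __float__(self) -> float:
        return self.rate


def fold_expansion(trajectory: WoundTrajectory) -> float:
    """Maximum wound area divided by the first post-wound frame's area."""
    if len(trajectory.areas) < 2:
        raise ValueError("need at least 2 frames to measure expansion")
    a0 = trajectory.initial_area
    if a0 <= 0:
        raise ValueError("initial wound area is zero; cannot compute expansion")
    return trajectory.max_area / a0


def contraction_rate(trajectory: WoundTrajectory) -> ClosureRate:
    """Closure rate between the maximum-area frame and the half-area frame.

    Raises :class:`DidNotCloseError` if no later frame reaches 50% of the
    maximum area.
    """
    t = trajectory.frame_times
    a = trajectory.areas
    i_max = int(np.argmax(a))  # earliest maximum
    a_max = float(a[i_max])
    after = np.where((np.arange(len(a)) > i_max) & (a <= 0.5 * a_max))[0]
    if len(after) == 0:
        raise DidNotCloseError("wound did not close to half of its maximum area")
    i_half = int(after[0])
    a_half = float(a[i_half])
    rate = (a_max - a_half) / (t[i_half] - t[i_max])
    return ClosureRate(
        rate=float(rate),
        t_max=float(t[i_max]),
        t_half=float(t[i_half]),
        a_max=a_max,
        a_half=a_half,
        band_undershoot=bool(a_half < 0.35 * a_max),
    )


def detect_onset(
    stack: TimeLapseStack,
    trajectory: WoundTrajectory,
    channel: str | None = None,
    annulus_um: float = 5.0,
    n_sd: float = 2.0,
    n_consecutive: int = 2,
) -> float | None:
    """Recruitment-onset time of a reporter at the wound periphery.

    Per frame, the mean intensity in the annulus between the wound edge
    and edge + ``annulus_um`` is compared with the far-field background
    (pixels farther than twice the annulus outer radius from the wound
    center, relaxed to the outermost 3% of pixels when the field of view
    is too small).  The onset is the timestamp of the first of
    ``n_consecutive`` consecutive frames whose annulus mean exceeds
    background mean + ``n_sd``·SD.  Returns None if the reporter is never
    recruited.
    """
    frames = stack.channel(channel) if channel else stack.frames[0]
    if len(frames) != len(trajectory.areas):
        raise ValueError("trajectory and stack have different frame counts")
    px = stack.pixel_size
    h, w = stack.shape

    enriched = np.zeros(len(frames), dtype=bool)
    for i, frame in enumerate(frames):
        if trajectory.areas[i] <= 0:
            continue
        cr, cc = trajectory.center_at(i)
        rr = np.hypot(
            (np.arange(h)[:, None] - cr), (np.arange(w)[None, :] - cc)
        ) * px
        r_w = np.sqrt(trajectory.areas[i] / np.pi)
        annulus = (rr >= r_w) & (rr < r_w + annulus_um)
        r_bg = 2.0 * (r_w + annulus_um)
        bg_mask = rr >= r_bg
        if bg_mask.sum() < 500:  # small field: fall back to outermost pixels
            bg_mask = rr >= np.quantile(rr, 0.97)
        if not annulus.any():
            continue
        bg_vals = frame[bg_mask]
        enriched[i] = frame[annulus].mean() > bg_vals.mean() + n_sd * bg_vals.std()

    run = 0
    for i, flag in enumerate(enriched):
        run = run + 1 if flag else 0
        if run >= n_consecutive:
            return float(stack.frame_times[i - n_consecutive + 1])
    return None


@dataclasses.dataclass
class DynamicsSummary:
    """Per-wound kinetic summary: areas, timings, fold expansion, rate, onsets."""

    a0: float  # μm²
    a_max: float  # μm²
    t_max: float  # s
    t_half: float  # s
    fold_expansion: float
    contraction_rate: float  # μm²/s
    band_undershoot: bool
    onsets: dict[str, float | None] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        onsets = d.pop("onsets")
        for k, v in onsets.items():
            d[f"onset_{k}"] = v
        return d


def summarize_dynamics(
    trajectory: WoundTrajectory,
    stack: TimeLapseStack | None = None,
    channels: list[str] | None = None,
) -> DynamicsSummary:
    """Full kinetic summary; onsets are detected for ``channels`` if a stack is given."""
    closure = contraction_rate(trajectory)
    onsets: dict[str, float | None] = {}
    if stack is not None:
        for label in channels if channels is not None else stack.channel_labels:
            onsets[label] = detect_onset(stack, trajectory, label)
    return DynamicsSummary(
        a0=trajectory.initial_area,
        a_max=closure.a_max,
        t_max=closure.t_max,
        t_half=closure.t_half,
        fold_expansion=fold_expansion(trajectory),
        contraction_rate=closure.rate,
        band_undershoot=closure.band_undershoot,
        onsets=onsets,
    )
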