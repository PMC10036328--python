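"""Radial fluorescence lineplots across the wound.

A lineplot is the mean ± 95% CI intensity over ``n_profiles`` (default 51)
diameter lines anchored at the wound center, with angles equally spaced
over [0°, 180°] inclusive, each sampled at 1-px spacing over a fixed
diameter (default 301 px) by bilinear interpolation.  A dynamic lineplot
is the per-frame sequence of these, anchored at each frame's centroid.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage, stats

from .geometry import WoundTrajectory
from .io import TimeLapseStack

__all__ = ["RadialProfileSet", "radial_lineplot", "dynamic_lineplot", "fold_profile"]


@dataclasses.dataclass
class RadialProfileSet:
    """Mean radial intensity profile with per-position 95% confidence band.

    ``positions`` run symmetrically about the center sample in px
    (``positions_um`` in μm); ``profiles`` holds the raw per-angle samples
    (n_profiles × diameter, NaN outside the image); ``mean`` and
    ``ci_half_width`` are per-position across angles.
    """

    positions: np.ndarray  # px, signed distance from center
    mean: np.ndarray
    ci_half_width: np.ndarray
    profiles: np.ndarray  # (n_profiles, diameter)
    angles: np.ndarray  # degrees
    pixel_size: float
    time: float | None = None

    @property
    def positions_um(self) -> np.ndarray:
        return self.positions * self.pixel_size

    @property
    def n_profiles(self) -> int:
        return len(self.angles)


def radial_lineplot(
    frame: np.ndarray,
    center: tuple[float, float],
    n_profiles: int = 51,
    profile_diameter: int = 301,
    pixel_size: float = 1.0,
    time: float | None = None,
) -> RadialProfileSet:
    """Mean ± 95% CI over equally spaced diameter lines through ``center``.

    Angles span [0°, 180°] inclusive (so first and last sample the same
    line, reversed).  Samples falling outside the image are dropped from
    that position's statistics.  The CI is a t-interval across profiles:
    mean ± t₀.₉₇₅,(n−1) · SD/√n.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if profile_diameter % 2 == 0:
        raise ValueError(f"profile_diameter must be odd, got {profile_diameter}")
    if n_profiles < 2:
        raise ValueError(f"n_profiles must be >= 2, got {n_profiles}")
    r0, c0 = center
    if not (0 <= r0 < frame.shape[0] and 0 <= c0 < frame.shape[1]):
        raise ValueError(f"center {center} outside frame {frame.shape}")

    half = profile_diameter // 2
    positions = np.arange(-half, half + 1, dtype=float)
    angles = np.linspace(0.0, 180.0, n_profiles)
    theta = np.deg2rad(angles)

    rows = r0 + positions[None, :] * np.sin(theta)[:, None]
    cols = c0 + positions[None, :] * np.cos(theta)[:, None]
    inside = (
        (rows >= 0)
        & (rows <= frame.shape[0] - 1)
        & (cols >= 0)
        & (cols <= frame.shape[1] - 1)
    )
    samples = ndimage.map_coordinates(
        frame, np.stack([rows, cols]), order=1, mode="constant", cval=np.nan
    )
    samples[~inside] = np.nan

    n = np.sum(inside, axis=0).astype(float)
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN / ddof slices
        mean = np.nanmean(np.where(inside, samples, np.nan), axis=0)
        sd = np.nanstd(np.where(inside, samples, np.nan), axis=0, ddof=1)
    tcrit = stats.t.ppf(0.975, df=np.maximum(n - 1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(n >= 2, tcrit * sd / np.sqrt(n), np.nan)
    return RadialProfileSet(
        positions=positions,
        mean=mean,
        ci_half_width=ci,
        profiles=samples,
        angles=angles,
        pixel_size=pixel_size,
        time=time,
    )


def dynamic_lineplot(
    stack: TimeLapseStack,
    trajectory: WoundTrajectory,
    channel: str | None = None,
    n_profiles: int = 51,
    profile_diameter: int = 301,
) -> list[RadialProfileSet]:
    """Per-frame lineplots anchored at each frame's wound centroid.

    The sets are ordered by time; rendering concatenates them along the
    time axis to show ring formation and inward translocation.
    """
    frames = stack.channel(channel) if channel else stack.frames[0]
    out = []
    for i, frame in enumerate(frames):
        center = trajectory.center_at(i)
        out.append(
            radial_lineplot(
                frame,
                center,
                n_profiles=n_profiles,
                profile_diameter=profile_diameter,
                pixel_size=stack.pixel_size,
                time=float(stack.frame_times[i]),
            )
        )
    return out


def fold_profile(profile: RadialProfileSet) -> tuple[np.ndarray, np.ndarray]:
    """Fold a diameter profile into a radial curve.

    Returns ``(radii_px, values)`` where values average the two sides of
    the mean profile (NaN-aware), radius 0 = center sample.
    """
    half = len(profile.positions) // 2
    center = profile.mean[half]
    left = profile.mean[:half][::-1]
    right = profile.mean[half + 1 :]
    with np.errstate(invalid="ignore"):
        folded = np.nanmean(np.stack([left, right]), axis=0)
    radii = np.arange(half + 1, dtype=float)
    return radii, np.concatenate([[center], folded])
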