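"""Actomyosin ring morphometry: width and (relative) mean intensity.

The ring is measured at the frame nearest 90 s post-wounding.  Its edges
are delineated on the 51-profile mean radial curve by an FWHM rule: the
innermost and outermost radii where the curve crosses
background + (peak − background)/2.  Width and intensity then follow the
two defining formulas:

    width           = (outer Feret diameter − inner Feret diameter) / 2
    mean intensity  = (I_out − I_in) / (S_out − S_in)

where I/S are the integrated intensity and area of the filled regions
enclosed by the outer and inner edges.  Relative intensity divides the
ring mean by the mean of a 50 × 50-px box at the center of an unwounded
reference frame.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import WoundTrajectory, feret_diameter
from .io import TimeLapseStack
from .profiles import fold_profile, radial_lineplot

__all__ = [
    "RingAnnulus",
    "RingMeasurement",
    "RingNotDetectedError",
    "detect_ring_annulus",
    "ring_width",
    "ring_intensity",
    "unwounded_reference_mean",
    "measure_ring",
]


class RingNotDetectedError(ValueError):
    """The radial profile shows no ring peak above background."""


@dataclasses.dataclass
class RingAnnulus:
    """FWHM-delineated ring edges around the wound center."""

    inner_radius_px: float
    outer_radius_px: float
    inner_mask: np.ndarray  # filled region enclosed by the inner edge
    outer_mask: np.ndarray  # filled region enclosed by the outer edge
    background: float
    peak_value: float
    peak_radius_px: float


@dataclasses.dataclass
class RingMeasurement:
    """Ring morphometry at one timepoint (distances μm, areas μm²).

    Integrated intensities are in intensity·μm² so that
    ``mean_intensity = (i_out − i_in)/(s_out − s_in)`` is the per-pixel
    mean ring intensity, directly comparable to the unwounded reference.
    """

    d_out: float  # outer-edge Feret diameter, μm
    d_in: float  # inner-edge Feret diameter, μm
    s_out: float  # area enclosed by outer edge, μm²
    s_in: float  # area enclosed by inner edge, μm²
    i_out: float  # integrated intensity within outer region, intensity·μm²
    i_in: float  # integrated intensity within inner region, intensity·μm²
    width: float  # (d_out − d_in)/2, μm
    mean_intensity: float
    i_uw: float | None  # unwounded reference mean, intensity units
    relative_intensity: float | None
    time: float | None


def detect_ring_annulus(
    frame: np.ndarray,
    center: tuple[float, float],
    pixel_size: float = 1.0,
    n_profiles: int = 51,
    profile_diameter: int = 301,
    noise_k: float = 3.0,
    min_contrast: float = 0.1,
) -> RingAnnulus:
    """Locate the ring's inner and outer edges by the FWHM rule.

    The mean radial curve (diameter lineplot folded about the center) is
    scanned for its peak; background is the median of the outer 20% of
    valid radii, and the noise scale is their robust SD.  A peak below
    background + ``noise_k``·SD — or below ``(1 + min_contrast)``× the
    background, the detection floor that keeps the maximum over all radii
    from being mistaken for a ring — raises :class:`RingNotDetectedError`.
    Edge radii are linearly interpolated at the half-maximum crossings on
    either side of the peak; the returned masks are the filled discs they
    enclose.
    """
    profile = radial_lineplot(
        frame, center, n_profiles=n_profiles, profile_diameter=profile_diameter,
        pixel_size=pixel_size,
    )
    radii, curve = fold_profile(profile)
    valid = np.isfinite(curve)
    radii, curve = radii[valid], curve[valid]
    if len(curve) < 10:
        raise RingNotDetectedError("radial curve too short to measure a ring")

    n_outer = max(5, int(0.2 * len(curve)))
    outer = curve[-n_outer:]
    background = float(np.median(outer))
    noise_sd = float(1.4826 * np.median(np.abs(outer - background)))

    peak_idx = int(np.argmax(curve))
    peak = float(curve[peak_idx])
    if peak <= background + noise_k * noise_sd or peak <= background * (
        1.0 + min_contrast
    ):
        raise RingNotDetectedError(
            f"no ring detected: peak {peak:.3g} not above background "
            f"{background:.3g} + {noise_k}×SD ({noise_sd:.3g}) "
            f"and {min_contrast:.0%} contrast"
        )
    half_level = background + (peak - background) / 2.0

    def crossing(direction: int) -> float:
        # walk from the peak until the curve drops through half_level
        i = peak_idx
        while 0 <= i + direction < len(curve) and curve[i + direction] >= half_level:
            i += direction
        j = i + direction
        if not (0 <= j < len(curve)):
            raise RingNotDetectedError(
                "ring edge not found: curve never drops to half maximum "
                f"{'inside' if direction < 0 else 'outside'} the peak"
            )
        # linear interpolation between radii[i] (>= half) and radii[j] (< half)
        frac = (curve[i] - half_level) / (curve[i] - curve[j])
        return float(radii[i] + frac * (radii[j] - radii[i]))

    r_in = crossing(-1)
    r_out = crossing(+1)

    h, w = np.asarray(frame).shape
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    rr = np.hypot(rows, cols)
    return RingAnnulus(
        inner_radius_px=r_in,
        outer_radius_px=r_out,
        inner_mask=rr <= r_in,
        outer_mask=rr <= r_out,
        background=background,
        peak_value=peak,
        peak_radius_px=float(radii[peak_idx]),
    )


def ring_width(d_out: float, d_in: float) -> float:
    """Ring width = (outer Feret diameter − inner Feret diameter)/2."""
    if d_out < d_in:
        raise ValueError(f"outer diameter {d_out} smaller than inner {d_in}")
    return (d_out - d_in) / 2.0


def ring_intensity(
    i_out: float,
    i_in: float,
    s_out: float,
    s_in: float,
    i_uw: float | None = None,
) -> tuple[float, float | None]:
    """Ring mean intensity and, optionally, intensity relative to unwounded.

    mean = (i_out − i_in)/(s_out − s_in); relative = mean / i_uw.
    """
    if s_out <= s_in:
        raise ValueError(
            f"outer area ({s_out}) must exceed inner area ({s_in})"
        )
    mean = (i_out - i_in) / (s_out - s_in)
    if i_uw is None:
        return mean, None
    if not i_uw > 0:
        raise ValueError(f"unwounded reference mean must be > 0, got {i_uw}")
    return mean, mean / i_uw


def unwounded_reference_mean(frame: np.ndarray, box: int = 50) -> float:
    """Mean intensity of a ``box``×``box`` px region at the frame center."""
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    r0 = (h - box) // 2
    c0 = (w - box) // 2
    return float(frame[r0 : r0 + box, c0 : c0 + box].mean())


def measure_ring(
    stack: TimeLapseStack,
    trajectory: WoundTrajectory,
    channel: str | None = None,
    at_time: float = 90.0,
    unwounded_frame: np.ndarray | None = None,
    i_uw: float | None = None,
    n_profiles: int = 51,
    profile_diameter: int = 301,
    noise_k: float = 3.0,
) -> RingMeasurement:
    """Full ring measurement at the frame nearest ``at_time`` (ties → earlier).

    The unwounded reference for relative intensity is either an explicit
    frame (``unwounded_frame``, reduced to its central 50 × 50-px mean) or
    a precomputed mean (``i_uw``); with neither, relative intensity is
    omitted.
    """
    frames = stack.channel(channel) if channel else stack.frames[0]
    idx = stack.frame_index_at(at_time)
    frame = frames[idx]
    center = trajectory.center_at(idx)
    annulus = detect_ring_annulus(
        frame, center, pixel_size=stack.pixel_size,
        n_profiles=n_profiles, profile_diameter=profile_diameter, noise_k=noise_k,
    )
    px_area = stack.pixel_size**2
    d_out = feret_diameter(annulus.outer_mask, stack.pixel_size)
    d_in = feret_diameter(annulus.inner_mask, stack.pixel_size)
    s_out = float(annulus.outer_mask.sum()) * px_area
    s_in = float(annulus.inner_mask.sum()) * px_area
    i_out = float(frame[annulus.outer_mask].sum()) * px_area
    i_in = float(frame[annulus.inner_mask].sum()) * px_area

    if i_uw is None and unwounded_frame is not None:
        i_uw = unwounded_reference_mean(unwounded_frame)
    mean, rel = ring_intensity(i_out, i_in, s_out, s_in, i_uw)
    return RingMeasurement(
        d_out=d_out,
        d_in=d_in,
        s_out=s_out,
        s_in=s_in,
        i_out=i_out,
        i_in=i_in,
        width=ring_width(d_out, d_in),
        mean_intensity=mean,
        i_uw=i_uw,
        relative_intensity=rel,
        time=float(stack.frame_times[idx]),
    )
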