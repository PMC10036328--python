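"""Wound segmentation and mask morphometry.

The wound appears as a connected region darker than the cortical
background.  ``segment_wound`` automates the area measurement that was
originally done by hand: per frame, a smoothed copy is thresholded at a
bimodal histogram split, and the wound is the largest below-threshold
component that overlaps the previous frame's wound (temporal continuity).
``accept_masks`` bypasses the segmenter entirely for user-supplied masks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.filters import threshold_otsu

from .io import TimeLapseStack

__all__ = [
    "WoundTrajectory",
    "WoundNotFoundError",
    "segment_wound",
    "accept_masks",
    "feret_diameter",
]


class WoundNotFoundError(ValueError):
    """No wound-like sub-background region was found."""


@dataclasses.dataclass
class WoundTrajectory:
    """Per-frame wound area, centroid and mask.

    ``areas`` are μm² and satisfy ``area == mask.sum() * pixel_size**2``
    exactly.  ``centroids`` are (row, col) pixel coordinates (NaN once the
    wound has closed).
    """

    frame_times: np.ndarray
    areas: np.ndarray
    centroids: np.ndarray  # (T, 2) px
    masks: np.ndarray  # (T, H, W) bool
    pixel_size: float

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.masks = np.asarray(self.masks, dtype=bool)
        if not (
            len(self.frame_times)
            == len(self.areas)
            == len(self.centroids)
            == len(self.masks)
        ):
            raise ValueError("trajectory fields must have one entry per frame")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")

    @property
    def initial_area(self) -> float:
        return float(self.areas[0])

    @property
    def max_area(self) -> float:
        return float(self.areas.max())

    def center_at(self, index: int) -> tuple[float, float]:
        """Centroid at ``index``, falling back to the last known centroid."""
        c = self.centroids[index]
        if np.any(np.isnan(c)):
            known = np.where(~np.isnan(self.centroids[:, 0]))[0]
            if len(known) == 0:
                raise WoundNotFoundError("trajectory has no wound centroid")
            c = self.centroids[known[known <= index][-1] if np.any(known <= index) else known[0]]
        return float(c[0]), float(c[1])


def _measure(masks: np.ndarray, frame_times, pixel_size: float) -> WoundTrajectory:
    areas = masks.reshape(len(masks), -1).sum(axis=1) * pixel_size**2
    centroids = np.full((len(masks), 2), np.nan)
    for i, m in enumerate(masks):
        if m.any():
            centroids[i] = ndimage.center_of_mass(m)
    return WoundTrajectory(frame_times, areas, centroids, masks, pixel_size)


def _wound_candidate(
    smoothed: np.ndarray, reference: np.ndarray
) -> np.ndarray | None:
    """Largest dark connected component overlapping ``reference``, or None.

    The threshold is an Otsu split of the smoothed frame restricted to
    pixels at or below the median, i.e. the wound mode versus the lower
    half of the background mode; this keeps the split between wound
    interior and background even when the bright ring/halo occupy a large
    image fraction.  A candidate must also be genuinely dark — mean below
    60% of the above-threshold background median — which rejects the
    spurious noise split of an unwounded or fully closed frame
    (scale-invariant, so intensity units never matter).
    """
    clipped = smoothed[smoothed <= np.median(smoothed)]
    if clipped.min() == clipped.max():
        return None
    thr = threshold_otsu(clipped)
    below = smoothed < thr
    labels, n = ndimage.label(below)
    if n == 0:
        return None
    overlap_labels = np.unique(labels[(labels > 0) & reference])
    if len(overlap_labels) == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, overlap_labels)
    cand = labels == overlap_labels[np.argmax(sizes)]

    bg = np.median(smoothed[~below])
    if smoothed[cand].mean() >= 0.6 * bg:
        return None
    return cand


def segment_wound(
    stack: TimeLapseStack,
    channel: str | None = None,
    seed_region: tuple[int, int, int, int] | None = None,
    smooth_sigma: float = 1.0,
) -> WoundTrajectory:
    """Segment the wound in every frame and return its trajectory.

    Parameters
    ----------
    stack
        Calibrated time-lapse; the wound must be a connected
        sub-background region in the chosen channel.
    channel
        Channel label; defaults to the first channel.
    seed_region
        ``(row0, row1, col0, col1)`` box the first-frame wound must
        intersect; defaults to the central 20% of the image.
    smooth_sigma
        Gaussian smoothing (px) applied before thresholding.

    Raises
    ------
    WoundNotFoundError
        If no sub-background component is found in the first frame.

    Notes
    -----
    Per frame the wound is the largest below-threshold component that
    overlaps the previous frame's mask (first frame: the seed region);
    ties in overlap go to the larger component.  Frames after full closure
    report area 0.
    """
    frames = stack.channel(channel) if channel else stack.frames[0]
    h, w = frames.shape[1:]
    if seed_region is None:
        seed_region = (int(h * 0.4), int(h * 0.6), int(w * 0.4), int(w * 0.6))
    r0, r1, c0, c1 = seed_region
    reference = np.zeros((h, w), dtype=bool)
    reference[r0:r1, c0:c1] = True

    masks = np.zeros((len(frames), h, w), dtype=bool)
    closed = False
    for i, frame in enumerate(frames):
        if closed:
            continue
        smoothed = ndimage.gaussian_filter(frame, smooth_sigma)
        cand = _wound_candidate(smoothed, reference)
        if cand is None:
            if i == 0:
                raise WoundNotFoundError(
                    "no wound detected: first frame has no sub-background "
                    "component overlapping the seed region"
                )
            closed = True  # wound fully closed; remaining areas stay 0
            continue
        masks[i] = cand
        reference = cand
    return _measure(masks, stack.frame_times, stack.pixel_size)


def accept_masks(stack: TimeLapseStack, masks: np.ndarray) -> WoundTrajectory:
    """Build a trajectory from user-supplied per-frame wound masks verbatim."""
    masks = np.asarray(masks).astype(bool)
    if masks.shape != (stack.n_frames, *stack.shape):
        raise ValueError(
            f"masks shape {masks.shape} does not match stack "
            f"{(stack.n_frames, *stack.shape)}"
        )
    return _measure(masks, stack.frame_times, stack.pixel_size)


def feret_diameter(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Maximum Feret (caliper) diameter of a binary region, in μm.

    Computed as the maximum pairwise distance between boundary pixel
    centers, via the convex hull for efficiency; equals the brute-force
    O(n²) pairwise maximum exactly.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask has no Feret diameter")
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) point sets
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max())) * pixel_size
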