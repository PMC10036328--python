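"""Kymographs: space–time images of a fixed ROI across the wound.

The ROI is a rotated rectangle (default 5.3 × 94.9 μm) centered on the
wound; each frame contributes one row, the per-position intensity averaged
across the ROI width.  The axis is fixed over time, so ring formation,
inward translocation and disassembly appear as converging bright bands.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import TimeLapseStack

__all__ = ["Kymograph", "make_kymograph"]


@dataclasses.dataclass
class Kymograph:
    """T × L space–time matrix with its ROI geometry."""

    image: np.ndarray  # (T, L)
    frame_times: np.ndarray  # s, one per row
    positions: np.ndarray  # px, signed distance along the ROI axis
    center: tuple[float, float]  # (row, col) px
    angle_deg: float
    width_um: float
    length_um: float
    pixel_size: float

    @property
    def positions_um(self) -> np.ndarray:
        return self.positions * self.pixel_size


def make_kymograph(
    stack: TimeLapseStack,
    channel: str | None = None,
    center: tuple[float, float] | None = None,
    angle_deg: float = 0.0,
    length_um: float = 94.9,
    width_um: float = 5.3,
) -> Kymograph:
    """Build a kymograph along a fixed axis through ``center``.

    ``angle_deg`` = 0 is horizontal.  Samples are taken at 1-px spacing
    along the axis (L = round(length/pixel_size) positions) and averaged
    over the rectangle width (bilinear interpolation).  The whole ROI must
    lie inside the frame.
    """
    frames = stack.channel(channel) if channel else stack.frames[0]
    h, w = stack.shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    px = stack.pixel_size
    n_len = int(round(length_um / px))
    n_wid = max(1, int(round(width_um / px)))

    theta = np.deg2rad(angle_deg)
    axis = np.array([np.sin(theta), np.cos(theta)])  # (row, col) unit vector
    normal = np.array([-axis[1], axis[0]])
    s = np.arange(n_len, dtype=float) - (n_len - 1) / 2.0
    q = np.arange(n_wid, dtype=float) - (n_wid - 1) / 2.0

    rows = center[0] + s[None, :] * axis[0] + q[:, None] * normal[0]
    cols = center[1] + s[None, :] * axis[1] + q[:, None] * normal[1]
    if rows.min() < 0 or rows.max() > h - 1 or cols.min() < 0 or cols.max() > w - 1:
        raise ValueError(
            f"ROI ({length_um} × {width_um} μm at {angle_deg}°) exceeds the "
            f"{h}×{w}-px frame; reduce length_um or width_um"
        )
    coords = np.stack([rows, cols])

    image = np.empty((len(frames), n_len))
    for i, frame in enumerate(frames):
        samples = ndimage.map_coordinates(frame, coords, order=1)
        image[i] = samples.mean(axis=0)
    return Kymograph(
        image=image,
        frame_times=np.asarray(stack.frame_times, dtype=float),
        positions=s,
        center=center,
        angle_deg=angle_deg,
        width_um=width_um,
        length_um=length_um,
        pixel_size=px,
    )
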