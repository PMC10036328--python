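"""Calibrated time-lapse stack container and TIFF/CSV/JSON input-output.

A stack is a set of 2-D fluorescence frames (one or more channels) with a
shared physical pixel size (μm/px) and per-frame timestamps in seconds
post-wounding.  Frames are stored as-read: intensities are arbitrary units
and are never rescaled, so every ratio metric downstream is unit-free.

Conventions: pixel indices are 0-based ``(row, col)``; physical lengths are
always derived via ``pixel_size``; time 0 is the first post-wound frame.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = ["TimeLapseStack", "read_stack", "write_stack", "write_results"]

SIDECAR_SUFFIX = ".json"


@dataclasses.dataclass
class TimeLapseStack:
    """A timestamped, pixel-calibrated fluorescence time-lapse.

    Parameters
    ----------
    frames
        Array of shape ``(C, T, H, W)`` — channels × frames × rows × cols.
    channel_labels
        One label per channel, e.g. ``["actin", "scar"]``.
    frame_times
        Strictly increasing timestamps in seconds; first frame is the first
        post-wound frame (t = 0 by convention).
    pixel_size
        Physical size of one pixel in μm.
    """

    frames: np.ndarray
    channel_labels: list[str]
    frame_times: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 3:  # single channel convenience
            self.frames = self.frames[None]
        if self.frames.ndim != 4:
            raise ValueError(
                f"frames must have shape (C, T, H, W); got ndim={self.frames.ndim}"
            )
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.frames.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.frames.shape[0]} channels"
            )
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.ndim != 1 or len(self.frame_times) != self.frames.shape[1]:
            raise ValueError(
                f"{len(self.frame_times)} timestamps for {self.frames.shape[1]} frames"
            )
        if len(self.frame_times) >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    # -- accessors ---------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (H, W)."""
        return self.frames.shape[2], self.frames.shape[3]

    def channel(self, label: str) -> np.ndarray:
        """Return the ``(T, H, W)`` frame array for one channel."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"no channel {label!r}; available: {self.channel_labels}"
            ) from None
        return self.frames[idx]

    def frame_index_at(self, time_s: float) -> int:
        """Index of the frame whose timestamp is nearest ``time_s`` (ties → earlier)."""
        d = np.abs(self.frame_times - time_s)
        return int(np.argmin(d))  # argmin takes the first minimum → earlier frame


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_times: Sequence[float] | None = None,
    channel_labels: Sequence[str] | None = None,
) -> TimeLapseStack:
    """Read a multi-page TIFF stack with calibration.

    Pages are ordered frame-major, channels interleaved within a frame
    (t0c0, t0c1, t1c0, ...).  Calibration (pixel size, timestamps, channel
    labels) is taken from the arguments, or from a JSON sidecar written by
    :func:`write_stack` next to the TIFF.  Missing calibration is an error,
    never a silent default.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    pages = np.atleast_3d(np.asarray(pages, dtype=float))
    if pages.ndim == 2:
        pages = pages[None]

    sidecar = path.with_suffix(SIDECAR_SUFFIX)
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if pixel_size is None:
        pixel_size = meta.get("pixel_size")
    if frame_times is None:
        frame_times = meta.get("frame_times")
    if channel_labels is None:
        channel_labels = meta.get("channel_labels")
    if pixel_size is None:
        raise ValueError(f"pixel_size not supplied and no sidecar at {sidecar}")
    if frame_times is None:
        raise ValueError(f"frame_times not supplied and no sidecar at {sidecar}")
    if channel_labels is None:
        channel_labels = ["ch0"]

    n_channels = len(channel_labels)
    n_pages = pages.shape[0]
    if n_pages % n_channels:
        raise ValueError(
            f"{n_pages} TIFF pages not divisible by {n_channels} channels"
        )
    n_frames = n_pages // n_channels
    if len(frame_times) != n_frames:
        raise ValueError(
            f"{len(frame_times)} timestamps for {n_frames} frames "
            f"({n_pages} pages / {n_channels} channels)"
        )
    frames = pages.reshape(n_frames, n_channels, *pages.shape[1:]).transpose(1, 0, 2, 3)
    return TimeLapseStack(frames, list(channel_labels), frame_times, float(pixel_size))


def write_stack(stack: TimeLapseStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = stack.frames.transpose(1, 0, 2, 3).reshape(-1, *stack.shape)
    # dtype preserved for exact round-trips; minisblack keeps 3-page stacks
    # from being stored as RGB planes
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = path.with_suffix(SIDECAR_SUFFIX)
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size": stack.pixel_size,
                "frame_times": list(map(float, stack.frame_times)),
                "channel_labels": stack.channel_labels,
            },
            indent=2,
        )
    )
    return path


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    metadata: Mapping | None = None,
) -> list[Path]:
    """Write result tables as CSV plus a JSON run-metadata file.

    ``tables`` maps a short name to a DataFrame; each becomes ``<name>.csv``
    with a stable column order.  ``metadata`` (config, seeds, versions) goes
    to ``run_metadata.json``.  Re-running identical inputs yields identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
    if metadata is not None:
        p = out_dir / "run_metadata.json"
        p.write_text(json.dumps(metadata, indent=2, sort_keys=True, default=str))
        written.append(p)
    return written
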