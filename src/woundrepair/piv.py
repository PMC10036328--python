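"""Particle image velocimetry for cortical actin flow.

Windowed normalized cross-correlation between consecutive frames: per
interrogation window, the displacement is the argmax of the NCC map with
3-point Gaussian sub-pixel refinement.  Windows whose correlation peak is
not clearly dominant (peak-to-second-peak ratio < 1.2) or whose texture
variance vanishes are flagged invalid.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import TimeLapseStack

__all__ = ["FlowField", "piv_pair", "piv_interval", "radial_inward_speed"]


@dataclasses.dataclass
class FlowField:
    """Regular grid of displacement/velocity vectors.

    ``u``/``v`` are the x (col) and y (row) displacement components in px
    per frame interval; ``vx``/``vy`` are the same in μm/s.  Invalid
    windows hold NaN.
    """

    grid_rows: np.ndarray  # window-center row coordinates, px
    grid_cols: np.ndarray  # window-center col coordinates, px
    u: np.ndarray  # (ny, nx) px per interval, x = col direction
    v: np.ndarray  # (ny, nx) px per interval, y = row direction
    valid: np.ndarray  # (ny, nx) bool
    window: int
    pixel_size: float
    dt: float  # s per interval

    @property
    def vx(self) -> np.ndarray:
        return self.u * self.pixel_size / self.dt

    @property
    def vy(self) -> np.ndarray:
        return self.v * self.pixel_size / self.dt


def _gauss_subpixel(cm: float, c0: float, cp: float) -> float:
    """3-point Gaussian peak interpolation; 0 if not applicable."""
    if cm <= 0 or c0 <= 0 or cp <= 0:
        return 0.0
    denom = 2.0 * (np.log(cm) + np.log(cp) - 2.0 * np.log(c0))
    if denom >= 0:
        return 0.0
    return float((np.log(cm) - np.log(cp)) / denom)


def piv_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int = 32,
    overlap: float = 0.5,
    pixel_size: float = 1.0,
    dt: float = 1.0,
    min_peak_ratio: float = 1.2,
) -> FlowField:
    """Displacement field from ``frame_a`` to ``frame_b``.

    A feature at position x in ``frame_a`` found at x + (u, v) in
    ``frame_b`` yields u, v at that window.  Displacements are searched up
    to ± window/2.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    h, w = a.shape
    if window > min(h, w) // 2:
        raise ValueError(f"window {window} too large for {h}×{w} frames")
    step = max(1, int(round(window * (1.0 - overlap))))
    max_d = window // 2

    row_starts = np.arange(0, h - window + 1, step)
    col_starts = np.arange(0, w - window + 1, step)
    ny, nx = len(row_starts), len(col_starts)
    u = np.full((ny, nx), np.nan)
    v = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)

    size = 2 * window  # zero-padded FFT correlation
    lags = np.arange(-max_d, max_d + 1)
    # per-lag overlap counts: normalizing by these removes the loss-of-pairs
    # bias that otherwise pulls peaks toward zero displacement
    overlap_n = (window - np.abs(lags))[:, None] * (window - np.abs(lags))[None, :]
    for i, r0 in enumerate(row_starts):
        for j, c0 in enumerate(col_starts):
            wa = a[r0 : r0 + window, c0 : c0 + window]
            wb = b[r0 : r0 + window, c0 : c0 + window]
            sa, sb = wa.std(), wb.std()
            if sa == 0 or sb == 0:
                continue
            fa = np.fft.rfft2(wa - wa.mean(), (size, size))
            fb = np.fft.rfft2(wb - wb.mean(), (size, size))
            corr = np.fft.irfft2(np.conj(fa) * fb, (size, size))
            corr = np.fft.fftshift(corr) / (sa * sb)
            c = size // 2  # zero-displacement position after fftshift
            search = (
                corr[c - max_d : c + max_d + 1, c - max_d : c + max_d + 1] / overlap_n
            )

            pk = np.unravel_index(np.argmax(search), search.shape)
            peak = search[pk]
            if peak <= 0:
                continue
            masked = search.copy()
            masked[
                max(0, pk[0] - 1) : pk[0] + 2, max(0, pk[1] - 1) : pk[1] + 2
            ] = -np.inf
            second = masked.max()
            if second > 0 and peak / second < min_peak_ratio:
                continue

            dy = pk[0] - max_d
            dx = pk[1] - max_d
            if 0 < pk[0] < search.shape[0] - 1:
                dy += _gauss_subpixel(
                    search[pk[0] - 1, pk[1]], peak, search[pk[0] + 1, pk[1]]
                )
            if 0 < pk[1] < search.shape[1] - 1:
                dx += _gauss_subpixel(
                    search[pk[0], pk[1] - 1], peak, search[pk[0], pk[1] + 1]
                )
            u[i, j], v[i, j] = dx, dy
            valid[i, j] = True

    return FlowField(
        grid_rows=row_starts + (window - 1) / 2.0,
        grid_cols=col_starts + (window - 1) / 2.0,
        u=u,
        v=v,
        valid=valid,
        window=window,
        pixel_size=pixel_size,
        dt=dt,
    )


def piv_interval(
    stack: TimeLapseStack,
    channel: str | None = None,
    t_start: float = 60.0,
    t_end: float = 90.0,
    window: int = 32,
    overlap: float = 0.5,
) -> FlowField:
    """Average flow field over consecutive frame pairs within [t_start, t_end].

    Per-pair velocities (μm/s) are averaged over the pairs in which each
    window is valid; a window is valid overall if valid in ≥ 1 pair.
    """
    frames = stack.channel(channel) if channel else stack.frames[0]
    times = stack.frame_times
    idx = np.where((times >= t_start) & (times <= t_end))[0]
    if len(idx) < 2:
        raise ValueError(
            f"need >= 2 frames in [{t_start}, {t_end}] s; found {len(idx)}"
        )
    fields = []
    for k in range(len(idx) - 1):
        i0, i1 = idx[k], idx[k + 1]
        fields.append(
            piv_pair(
                frames[i0],
                frames[i1],
                window=window,
                overlap=overlap,
                pixel_size=stack.pixel_size,
                dt=float(times[i1] - times[i0]),
            )
        )
    vx_stack = np.stack([f.vx for f in fields])
    vy_stack = np.stack([f.vy for f in fields])
    n_ok = np.isfinite(vx_stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        vx = np.where(n_ok > 0, np.nansum(vx_stack, axis=0) / np.maximum(n_ok, 1), np.nan)
        vy = np.where(n_ok > 0, np.nansum(vy_stack, axis=0) / np.maximum(n_ok, 1), np.nan)
    valid = n_ok > 0
    dt_mean = float(np.mean([f.dt for f in fields]))
    ref = fields[0]
    return FlowField(
        grid_rows=ref.grid_rows,
        grid_cols=ref.grid_cols,
        u=vx * dt_mean / stack.pixel_size,
        v=vy * dt_mean / stack.pixel_size,
        valid=valid,
        window=window,
        pixel_size=stack.pixel_size,
        dt=dt_mean,
    )


def radial_inward_speed(
    field: FlowField, center: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Inward radial velocity component (μm/s) and angle to center (deg).

    Returns per-window arrays (NaN where invalid): the projection of each
    velocity vector onto the unit vector pointing at ``center``, and the
    angle between the vector and that direction.
    """
    gy = field.grid_rows[:, None] - center[0]
    gx = field.grid_cols[None, :] - center[1]
    r = np.hypot(gy, gx)
    with np.errstate(invalid="ignore", divide="ignore"):
        in_y = np.where(r > 0, -gy / r, 0.0)
        in_x = np.where(r > 0, -gx / r, 0.0)
        inward = field.vy * in_y + field.vx * in_x
        speed = np.hypot(field.vx, field.vy)
        cosang = np.clip(inward / np.where(speed > 0, speed, np.nan), -1, 1)
    angle = np.degrees(np.arccos(cosang))
    inward = np.where(field.valid, inward, np.nan)
    angle = np.where(field.valid, angle, np.nan)
    return inward, angle
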