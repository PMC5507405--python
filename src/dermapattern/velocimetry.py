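"""Particle image velocimetry over image stacks.

Patchwise displacement fields between successive frames by normalized
cross-correlation of interrogation windows, with 3-point Gaussian subpixel
refinement of the correlation peak; vectors from low-contrast or
low-correlation windows are flagged.  Displacement fields can be integrated
in time to recover average cell paths and per-path accumulated track
lengths, the readout used to compare the local recruitment of normal
patterning with the broad recruitment fields of mesenchyme-only patterning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import median_filter
from skimage.feature import match_template


@dataclass
class FlowField:
    x: np.ndarray        # interrogation-window centre columns (px)
    y: np.ndarray        # centre rows (px)
    dx: np.ndarray       # displacement (px/frame), shape (len(y), len(x))
    dy: np.ndarray
    quality: np.ndarray  # correlation peak in [0, 1]
    valid: np.ndarray    # boolean

    def to_frame(self) -> pd.DataFrame:
        Y, X = np.meshgrid(self.y, self.x, indexing="ij")
        return pd.DataFrame(
            {
                "x": X.ravel(),
                "y": Y.ravel(),
                "dx": self.dx.ravel(),
                "dy": self.dy.ravel(),
                "quality": self.quality.ravel(),
                "valid": self.valid.ravel(),
            }
        )


def _subpixel_offset(cc: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """3-point Gaussian peak interpolation along each axis."""

    def refine(m1, c0, p1):
        # shift = (ln m1 - ln p1) / (2 ln m1 - 4 ln c0 + 2 ln p1)
        m1, c0, p1 = (max(v, 1e-12) for v in (m1, c0, p1))
        denom = 2.0 * np.log(m1) - 4.0 * np.log(c0) + 2.0 * np.log(p1)
        # a near-flat correlation surface makes the 3-point fit ill-conditioned;
        # keep the integer-pixel estimate there
        if abs(denom) < 0.05:
            return 0.0
        return float(np.clip((np.log(m1) - np.log(p1)) / denom, -1.0, 1.0))

    di = dj = 0.0
    if 0 < i < cc.shape[0] - 1:
        di = refine(cc[i - 1, j], cc[i, j], cc[i + 1, j])
    if 0 < j < cc.shape[1] - 1:
        dj = refine(cc[i, j - 1], cc[i, j], cc[i, j + 1])
    return di, dj


def piv_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int = 32,
    overlap: float = 0.5,
    search: int = 8,
    quality_min: float = 0.3,
    contrast_min: float = 0.2,
    validate: bool = True,
) -> FlowField:
    """Displacement field from frame_a to frame_b.

    Each ``window``-pixel interrogation window of frame_a is located in the
    ``search``-pixel-padded corresponding region of frame_b by normalized
    cross-correlation; the peak is refined to subpixel precision.  Windows
    with low contrast (std below ``contrast_min`` times the frame std, where
    the correlation surface is flat and uninformative) or a weak correlation
    peak are flagged invalid; optionally a 3x3 median-consistency validation removes
    outlier vectors.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    if window < 8:
        raise ValueError("window must be >= 8 px")
    contrast_floor = max(1e-12, contrast_min * float(a.std()))
    step = max(1, int(round(window * (1.0 - overlap))))
    rows = np.arange(0, a.shape[0] - window + 1, step)
    cols = np.arange(0, a.shape[1] - window + 1, step)
    dx = np.zeros((len(rows), len(cols)))
    dy = np.zeros_like(dx)
    quality = np.zeros_like(dx)
    valid = np.zeros(dx.shape, dtype=bool)
    for ri, r in enumerate(rows):
        for ci, c in enumerate(cols):
            tpl = a[r : r + window, c : c + window]
            if tpl.std() < contrast_floor:
                continue
            r0, r1 = max(0, r - search), min(b.shape[0], r + window + search)
            c0, c1 = max(0, c - search), min(b.shape[1], c + window + search)
            region = b[r0:r1, c0:c1]
            if region.std() < contrast_floor:
                continue
            cc = match_template(region, tpl)
            i, j = np.unravel_index(np.argmax(cc), cc.shape)
            peak = float(cc[i, j])
            di, dj = _subpixel_offset(cc, int(i), int(j))
            dy[ri, ci] = (r0 + i + di) - r
            dx[ri, ci] = (c0 + j + dj) - c
            quality[ri, ci] = max(0.0, min(1.0, peak))
            valid[ri, ci] = peak >= quality_min
    if validate and valid.any():
        med_dx = median_filter(dx, size=3, mode="nearest")
        med_dy = median_filter(dy, size=3, mode="nearest")
        resid = np.hypot(dx - med_dx, dy - med_dy)
        tol = 2.0 + 2.0 * np.median(resid[valid])
        valid &= resid <= tol
    return FlowField(
        x=cols + window / 2.0,
        y=rows + window / 2.0,
        dx=dx,
        dy=dy,
        quality=quality,
        valid=valid,
    )


def piv_stack(stack: np.ndarray, **kwargs) -> list[FlowField]:
    """PIV between each consecutive frame pair of a (t, y, x) stack."""
    return [piv_pair(stack[i], stack[i + 1], **kwargs) for i in range(len(stack) - 1)]


@dataclass
class Path:
    seed: tuple[float, float]
    points: np.ndarray       # (n+1, 2) of (x, y)
    length: float            # accumulated path length, px
    truncated: bool = False  # left the frame


def integrate_paths(
    fields: list[FlowField],
    seed_points: np.ndarray,
    frame_shape: tuple[int, int] | None = None,
) -> list[Path]:
    """Advect seed points through the time-ordered displacement fields.

    Vectors are bilinearly interpolated between window centres (invalid
    vectors contribute zero displacement; outside the vector grid the field
    extrapolates linearly, so a seed carried past the last window row keeps
    moving and is truncated at the frame border).  The per-path
    accumulated length is the 'track length' readout.
    """
    if len(fields) < 2:
        raise ValueError("need at least 2 displacement fields")
    interps = []
    for f in fields:
        dx = np.where(f.valid, f.dx, 0.0)
        dy = np.where(f.valid, f.dy, 0.0)
        interps.append(
            (
                RegularGridInterpolator((f.y, f.x), dx, bounds_error=False, fill_value=None),
                RegularGridInterpolator((f.y, f.x), dy, bounds_error=False, fill_value=None),
            )
        )
    if frame_shape is None:
        f0 = fields[0]
        frame_shape = (int(f0.y[-1] + f0.y[0]), int(f0.x[-1] + f0.x[0]))
    paths = []
    for sx, sy in np.asarray(seed_points, dtype=float):
        pts = [(sx, sy)]
        length = 0.0
        truncated = False
        x, y = sx, sy
        for fx, fy in interps:
            ddx = float(fx((y, x)))
            ddy = float(fy((y, x)))
            x, y = x + ddx, y + ddy
            length += float(np.hypot(ddx, ddy))
            pts.append((x, y))
            if not (0 <= x < frame_shape[1] and 0 <= y < frame_shape[0]):
                truncated = True
                break
        paths.append(Path((sx, sy), np.asarray(pts), length, truncated))
    return paths


def radial_inflow(field: FlowField, center: tuple[float, float]) -> float:
    """Mean inward radial component of valid vectors around a centre (px/frame)."""
    Y, X = np.meshgrid(field.y, field.x, indexing="ij")
    rx, ry = X - center[0], Y - center[1]
    norm = np.hypot(rx, ry)
    ok = field.valid & (norm > 1e-9)
    if not ok.any():
        return float("nan")
    inward = -(field.dx * rx + field.dy * ry) / np.where(norm > 1e-9, norm, 1.0)
    return float(inward[ok].mean())
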