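"""Membrane arc extraction and circle fitting for fluorescence patch images.

Excised membrane patches expressing a membrane-targeted fluorophore appear as a
bright circular arc spanning the pipette aperture. The radius of curvature of
that arc, together with the applied pressure, gives membrane tension through
the Young-Laplace relation (see :mod:`patchtension.tension_calc`).

Coordinate convention (used at every interface in this package): row-major
pixel grid, origin at the top-left corner, ``x`` is the column index, ``y`` is
the row index, both 0-based. Detected points are reported as ``(row, col)``
pairs; circle fits work in ``(x, y) = (col, row)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import (
    DegenerateGeometryError,
    InsufficientPointsError,
    InvalidArgumentError,
    InvalidGeometryError,
    OutOfRangeError,
)

__all__ = [
    "ImageStack",
    "MembranePointSet",
    "CircleFit",
    "frame_index_for_time",
    "detect_membrane_points",
    "enforce_continuity",
    "fit_circle_three_point",
    "fit_circle_algebraic",
    "radius_physical",
]


@dataclass(frozen=True)
class ImageStack:
    """A time-resolved fluorescence movie with acquisition metadata.

    Parameters
    ----------
    frames:
        Array of shape ``(n_frames, height, width)``.
    frame_rate:
        Acquisition rate in Hz (default cameras in this application record at
        120 Hz).
    pixel_scale:
        Physical size of one pixel in µm/px. Must be supplied by the
        acquisition configuration for recorded data; synthetic stacks carry
        their own.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_scale: float

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise InvalidArgumentError("frames must have shape (n, h, w)")
        if self.frame_rate <= 0:
            raise InvalidArgumentError("frame_rate must be positive")
        if self.pixel_scale <= 0:
            raise InvalidArgumentError("pixel_scale must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @classmethod
    def from_tiff(cls, path, frame_rate: float, pixel_scale: float) -> "ImageStack":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames=frames, frame_rate=frame_rate, pixel_scale=pixel_scale)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, np.asarray(self.frames, dtype=np.float32))


def frame_index_for_time(stack: ImageStack, t: float) -> int:
    """Frame index matched to stimulus time ``t`` (s).

    The index is ``floor(t * frame_rate)`` clamped to the valid range; a time
    equal to the stack duration maps to the last frame.
    """
    if not np.isfinite(t) or t < 0:
        raise OutOfRangeError(f"time {t} is negative or not finite")
    if t > self_duration(stack):
        raise OutOfRangeError(
            f"time {t} s exceeds stack duration {self_duration(stack)} s"
        )
    idx = int(math.floor(t * stack.frame_rate))
    return min(idx, stack.n_frames - 1)


def self_duration(stack: ImageStack) -> float:
    return stack.n_frames / stack.frame_rate


@dataclass(frozen=True)
class MembranePointSet:
    """Per-row membrane coordinates detected in one frame.

    At most one point per image row (the detection contract). ``cols`` may be
    fractional when sub-pixel refinement is enabled.
    """

    rows: np.ndarray
    cols: np.ndarray
    intensities: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype=float)
        cols = np.asarray(self.cols, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if not (rows.shape == cols.shape == inten.shape):
            raise InvalidArgumentError("rows/cols/intensities must align")
        if len(np.unique(rows)) != rows.size:
            raise InvalidArgumentError("at most one point per row")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "cols", cols)
        object.__setattr__(self, "intensities", inten)

    @property
    def n_points(self) -> int:
        return int(self.rows.size)

    @property
    def xy(self) -> np.ndarray:
        """Points as ``(n, 2)`` array of ``(x, y) = (col, row)``."""
        return np.column_stack([self.cols, self.rows])

    def subset(self, mask: np.ndarray) -> "MembranePointSet":
        return MembranePointSet(
            rows=self.rows[mask],
            cols=self.cols[mask],
            intensities=self.intensities[mask],
            frame_index=self.frame_index,
        )

    def to_json(self, path) -> None:
        payload = {
            "frame_index": self.frame_index,
            "rows": self.rows.tolist(),
            "cols": self.cols.tolist(),
            "intensities": self.intensities.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class CircleFit:
    """A circle fitted to membrane coordinates.

    ``center`` is in ``(x, y)`` pixel coordinates; ``radius_um`` is populated
    once a pixel scale is applied (see :func:`radius_physical`).
    """

    center: tuple[float, float]
    radius_px: float
    rms_residual_px: float
    n_points: int
    method: str
    radius_um: float | None = None

    def residuals(self, xy: np.ndarray) -> np.ndarray:
        d = np.hypot(xy[:, 0] - self.center[0], xy[:, 1] - self.center[1])
        return d - self.radius_px


def detect_membrane_points(
    frame: np.ndarray,
    roi: tuple[int, int, int, int],
    frame_index: int = 0,
    subpixel: bool = True,
    enhance: bool = False,
) -> MembranePointSet:
    """Select the brightest pixel in each row of the region of interest.

    Parameters
    ----------
    frame:
        2-D intensity array.
    roi:
        ``(row_start, row_stop, col_start, col_stop)``, half-open bounds.
    subpixel:
        Refine each per-row maximum by a parabolic interpolation of
        log-intensity across the maximum and its two column neighbours (exact
        for a Gaussian cross-section). The integer maximum with a
        smallest-column tie-break remains the base contract.
    enhance:
        Optional percentile (1st-99th) contrast normalization applied to the
        working copy only, never to stored data.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InvalidArgumentError("frame must be 2-D")
    r0, r1, c0, c1 = (int(v) for v in roi)
    h, w = frame.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise InvalidArgumentError(f"roi {roi} empty or outside frame {frame.shape}")
    sub = frame[r0:r1, c0:c1]
    if enhance:
        lo, hi = np.percentile(sub, [1.0, 99.0])
        if hi > lo:
            sub = np.clip((sub - lo) / (hi - lo), 0.0, 1.0)
    idx = np.argmax(sub, axis=1)  # first (leftmost) maximum per row
    rows = np.arange(r0, r1, dtype=float)
    inten = sub[np.arange(sub.shape[0]), idx]
    cols = idx.astype(float)
    if subpixel:
        interior = (idx > 0) & (idx < sub.shape[1] - 1)
        ii = np.nonzero(interior)[0]
        if ii.size:
            a = sub[ii, idx[ii] - 1]
            b = sub[ii, idx[ii]]
            c = sub[ii, idx[ii] + 1]
            use_log = (a > 0) & (b > 0) & (c > 0)
            la = np.where(use_log, np.log(np.where(a > 0, a, 1.0)), a)
            lb = np.where(use_log, np.log(np.where(b > 0, b, 1.0)), b)
            lc = np.where(use_log, np.log(np.where(c > 0, c, 1.0)), c)
            denom = la - 2.0 * lb + lc
            with np.errstate(divide="ignore", invalid="ignore"):
                delta = 0.5 * (la - lc) / denom
            delta = np.where(np.isfinite(delta), delta, 0.0)
            delta = np.clip(delta, -0.5, 0.5)
            cols[ii] = idx[ii] + delta
    return MembranePointSet(
        rows=rows, cols=cols + c0, intensities=inten, frame_index=frame_index
    )


# ---------------------------------------------------------------------------
# Circle fitting


def _check_distinct(p1, p2, p3) -> None:
    pts = [(float(p[0]), float(p[1])) for p in (p1, p2, p3)]
    for i in range(3):
        for j in range(i + 1, 3):
            if (
                math.isclose(pts[i][0], pts[j][0], rel_tol=1e-9, abs_tol=1e-12)
                and math.isclose(pts[i][1], pts[j][1], rel_tol=1e-9, abs_tol=1e-12)
            ):
                raise InvalidArgumentError("the three points must be distinct")


def fit_circle_three_point(p1, p2, p3) -> CircleFit:
    """Exact circle through three points via the determinant intermediates.

    Uses the classic expansion ``A = x1(y2-y3) - y1(x2-x3) + x2*y3 - x3*y2``
    with companion terms B, C, D;
    ``radius = sqrt((B^2 + C^2 - 4AD) / (4A^2))`` and
    ``center = (-B/(2A), -C/(2A))``. Collinear points (A = 0) raise
    :class:`DegenerateGeometryError`.
    """
    _check_distinct(p1, p2, p3)
    (x1, y1), (x2, y2), (x3, y3) = (tuple(map(float, p)) for p in (p1, p2, p3))
    A = x1 * (y2 - y3) - y1 * (x2 - x3) + x2 * y3 - x3 * y2
    s1, s2, s3 = x1 * x1 + y1 * y1, x2 * x2 + y2 * y2, x3 * x3 + y3 * y3
    B = s1 * (y3 - y2) + s2 * (y1 - y3) + s3 * (y2 - y1)
    C = s1 * (x2 - x3) + s2 * (x3 - x1) + s3 * (x1 - x2)
    D = s1 * (x3 * y2 - x2 * y3) + s2 * (x1 * y3 - x3 * y1) + s3 * (x2 * y1 - x1 * y2)
    scale = max(abs(x1), abs(y1), abs(x2), abs(y2), abs(x3), abs(y3), 1.0)
    if abs(A) <= 1e-12 * scale * scale:
        raise DegenerateGeometryError("collinear points define no circle")
    radius = math.sqrt(max(B * B + C * C - 4.0 * A * D, 0.0) / (4.0 * A * A))
    center = (-B / (2.0 * A), -C / (2.0 * A))
    return CircleFit(
        center=center,
        radius_px=radius,
        rms_residual_px=0.0,
        n_points=3,
        method="three_point",
    )


def _as_xy(points) -> np.ndarray:
    if isinstance(points, MembranePointSet):
        return points.xy
    xy = np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise InvalidArgumentError("points must be (n, 2) of (x, y)")
    return xy


def fit_circle_algebraic(points, refine: bool = False) -> CircleFit:
    """Least-squares circle through >= 3 points.

    Minimizes the algebraic (Kåsa) objective
    ``sum((x_i^2 + y_i^2 + a x_i + b y_i + c)^2)`` in closed form; with
    ``refine=True`` the result seeds a geometric refinement minimizing
    ``sum((d_i - r)^2)`` (Gauss-Newton via :func:`scipy.optimize.least_squares`).
    """
    xy = _as_xy(points)
    n = xy.shape[0]
    if n < 3:
        raise InsufficientPointsError("circle fit needs at least 3 points")
    x, y = xy[:, 0], xy[:, 1]
    # center data for conditioning
    mx, my = x.mean(), y.mean()
    u, v = x - mx, y - my
    M = np.column_stack([u, v, np.ones(n)])
    rhs = -(u * u + v * v)
    sol, _, rank, _ = np.linalg.lstsq(M, rhs, rcond=None)
    if rank < 3:
        raise DegenerateGeometryError("points are collinear (rank-deficient)")
    a, b, c = sol
    cx, cy = -a / 2.0, -b / 2.0
    rr = cx * cx + cy * cy - c
    if rr <= 0:
        raise DegenerateGeometryError("algebraic solution has no real radius")
    r = math.sqrt(rr)
    cx, cy = cx + mx, cy + my

    if refine:
        from scipy.optimize import least_squares

        def resid(p):
            return np.hypot(x - p[0], y - p[1]) - p[2]

        out = least_squares(resid, x0=[cx, cy, r], method="lm")
        cx, cy, r = out.x
        if r <= 0:
            raise DegenerateGeometryError("geometric refinement collapsed")
    d = np.hypot(x - cx, y - cy)
    rms = float(np.sqrt(np.mean((d - r) ** 2)))
    return CircleFit(
        center=(float(cx), float(cy)),
        radius_px=float(r),
        rms_residual_px=rms,
        n_points=n,
        method="geometric" if refine else "algebraic",
    )


def radius_physical(fit: CircleFit, pixel_scale: float) -> float:
    """Convert a fitted pixel radius to µm (``radius_px * pixel_scale``)."""
    if pixel_scale <= 0:
        raise InvalidArgumentError("pixel_scale must be positive")
    return fit.radius_px * pixel_scale


def with_physical_radius(fit: CircleFit, pixel_scale: float) -> CircleFit:
    return dataclasses.replace(fit, radius_um=radius_physical(fit, pixel_scale))


# ---------------------------------------------------------------------------
# Continuity filtering

CONTINUITY_METHODS = ("max_jump", "median_residual", "ransac_circle")


def enforce_continuity(
    pts: MembranePointSet,
    method: str = "ransac_circle",
    max_jump_px: float = 5.0,
    residual_c: float = 3.0,
    ransac_tol_px: float = 2.0,
    ransac_iters: int = 500,
    seed: int = 0,
) -> MembranePointSet:
    """Remove outlier coordinates so the retained points trace one membrane.

    Three filters are provided:

    ``max_jump``
        Walk rows in order; drop a point whose column differs from the last
        retained point's column by more than ``max_jump_px``.
    ``median_residual``
        Fit a provisional algebraic circle to all points and drop points whose
        absolute radial residual exceeds ``residual_c`` times the median
        absolute residual.
    ``ransac_circle``
        Sample three-point circles (seeded RNG, ``ransac_iters`` draws) and
        keep the largest consensus set within ``ransac_tol_px`` of a sampled
        circle.

    Raises :class:`InsufficientPointsError` when fewer than three points
    survive (or, for RANSAC, when no non-degenerate circle exists).
    """
    if method not in CONTINUITY_METHODS:
        raise InvalidArgumentError(f"unknown continuity method {method!r}")
    n = pts.n_points
    if n < 3:
        raise InsufficientPointsError("continuity filtering needs >= 3 points")
    order = np.argsort(pts.rows)
    pts = pts.subset(order)

    if method == "max_jump":
        keep = np.zeros(n, dtype=bool)
        keep[0] = True
        last = pts.cols[0]
        for i in range(1, n):
            if abs(pts.cols[i] - last) <= max_jump_px:
                keep[i] = True
                last = pts.cols[i]
        out = pts.subset(keep)
    elif method == "median_residual":
        # provisional circle must itself resist outliers: refine the closed-form
        # seed with a Huber-loss geometric fit before thresholding residuals
        fit = fit_circle_algebraic(pts)
        from scipy.optimize import least_squares as _lsq

        xy = pts.xy

        def _rad_resid(p):
            return np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1]) - p[2]

        robust = _lsq(
            _rad_resid,
            x0=[fit.center[0], fit.center[1], fit.radius_px],
            loss="huber",
            f_scale=1.0,
        )
        res = np.abs(_rad_resid(robust.x))
        med = float(np.median(res))
        thresh = max(residual_c * med, 1e-9)
        out = pts.subset(res <= thresh)
    else:  # ransac_circle
        rng = np.random.default_rng(seed)
        xy = pts.xy
        # sample all candidate triples up front and solve them vectorized
        trips = rng.integers(0, n, size=(int(ransac_iters), 3))
        distinct = (
            (trips[:, 0] != trips[:, 1])
            & (trips[:, 0] != trips[:, 2])
            & (trips[:, 1] != trips[:, 2])
        )
        trips = trips[distinct]
        x1, y1 = xy[trips[:, 0], 0], xy[trips[:, 0], 1]
        x2, y2 = xy[trips[:, 1], 0], xy[trips[:, 1], 1]
        x3, y3 = xy[trips[:, 2], 0], xy[trips[:, 2], 1]
        A = x1 * (y2 - y3) - y1 * (x2 - x3) + x2 * y3 - x3 * y2
        s1, s2, s3 = x1 * x1 + y1 * y1, x2 * x2 + y2 * y2, x3 * x3 + y3 * y3
        B = s1 * (y3 - y2) + s2 * (y1 - y3) + s3 * (y2 - y1)
        C = s1 * (x2 - x3) + s2 * (x3 - x1) + s3 * (x1 - x2)
        scale = max(float(np.max(np.abs(xy))), 1.0)
        ok = np.abs(A) > 1e-12 * scale * scale
        if not ok.any():
            raise InsufficientPointsError("no circle consensus found (RANSAC)")
        with np.errstate(divide="ignore", invalid="ignore"):
            cx = -B / (2.0 * A)
            cy = -C / (2.0 * A)
        cx, cy = cx[ok], cy[ok]
        r = np.hypot(cx - x1[ok], cy - y1[ok])
        d = np.hypot(xy[None, :, 0] - cx[:, None], xy[None, :, 1] - cy[:, None])
        inliers = np.abs(d - r[:, None]) <= ransac_tol_px
        counts = inliers.sum(axis=1)
        best = int(np.argmax(counts))
        if counts[best] < 3:
            raise InsufficientPointsError("no circle consensus found (RANSAC)")
        out = pts.subset(inliers[best])

    if out.n_points < 3:
        raise InsufficientPointsError(
            f"only {out.n_points} points survive continuity filtering"
        )
    return out
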