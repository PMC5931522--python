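"""Subset-based 2D digital image correlation (DIC).

A regular grid of square intensity subsets is matched between frames with
an affine (first-order) shape function, optimized by inverse-compositional
Gauss-Newton (IC-GN) on a zero-normalized sum-of-squared-differences
(ZNSSD) criterion.  ZNSSD is invariant to affine lighting changes (gain and
offset), which matters under surgical-light intensity drift.

Displacements over a sequence are obtained with the "sum of differentials"
scheme: every consecutive frame pair is correlated directly (the reference
subset is re-extracted from the newer frame each step, centred at the
tracked, generally non-integer position) and the per-pair increments are
summed.  A cross-check mode correlates every frame against frame 0, seeded
by the incremental estimate.

Coordinate convention: pixel centres at integer coordinates, origin at the
top-left pixel, x rightward, y downward.  All field exports state this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

logger = logging.getLogger(__name__)

DEFAULT_SUBSET_SIZE = 79
DEFAULT_STEP = 10
DEFAULT_MAX_ITER = 50
DEFAULT_CONV_TOL = 1e-4      # px, norm of the IC-GN parameter update
DEFAULT_SEARCH_RADIUS = 10   # px, integer ZNCC search when no seed exists
NEIGHBOR_RESEED_STEPS = 3    # failed points re-seeded from neighbors within this many steps


class DicError(Exception):
    """Base class for correlation errors."""


class OutOfBoundsError(DicError):
    """Requested interpolation point lies outside the valid image domain."""


class TrackingCollapseError(DicError):
    """More than half of the grid points failed to converge for a frame pair."""


class EmptyFieldError(DicError):
    """A quality filter invalidated every point of a displacement field."""


# ---------------------------------------------------------------------------
# Image containers and interpolation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSequence:
    """Time-stamped grayscale frames from one camera.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Intensity values; integer or float.
    frame_rate : float
        Acquisition rate in Hz; timestamps are ``k / frame_rate``.
    bit_depth : int
        Nominal bit depth of the sensor (8 or 16).
    camera_id : str
    """

    frames: np.ndarray
    frame_rate: float
    bit_depth: int = 8
    camera_id: str = "cam0"
    timestamps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) stack")
        object.__setattr__(self, "frames", frames)
        if self.timestamps is None:
            ts = np.arange(frames.shape[0], dtype=float) / float(self.frame_rate)
            object.__setattr__(self, "timestamps", ts)
        else:
            ts = np.asarray(self.timestamps, dtype=float)
            if ts.shape != (frames.shape[0],):
                raise ValueError("timestamps must match the number of frames")
            dt = np.diff(ts)
            if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
                raise ValueError("timestamps must be strictly increasing and uniform")
            object.__setattr__(self, "timestamps", ts)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames


class BicubicImage:
    """Cubic B-spline interpolator for one image, exact at integer pixels.

    Spline coefficients (image and both first-difference gradients) are
    prefiltered once so repeated subset sampling is cheap.
    """

    def __init__(self, image: np.ndarray):
        img = np.ascontiguousarray(np.asarray(image, dtype=float))
        if img.ndim != 2:
            raise ValueError("expected a 2D grayscale image")
        self.image = img
        self.shape = img.shape
        self._coef = ndimage.spline_filter(img, order=3, mode="mirror")
        gy, gx = np.gradient(img)
        self._coef_gx = ndimage.spline_filter(gx, order=3, mode="mirror")
        self._coef_gy = ndimage.spline_filter(gy, order=3, mode="mirror")

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            self._coef, [y, x], order=3, prefilter=False, mode="mirror"
        )

    def sample_gradient(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gx = ndimage.map_coordinates(self._coef_gx, [y, x], order=3, prefilter=False, mode="mirror")
        gy = ndimage.map_coordinates(self._coef_gy, [y, x], order=3, prefilter=False, mode="mirror")
        return gx, gy


def _as_bicubic(image) -> BicubicImage:
    return image if isinstance(image, BicubicImage) else BicubicImage(np.asarray(image))


def sample_intensity(image, x, y):
    """Bicubic-interpolated intensity at real-valued pixel coordinates.

    Exact at integer coordinates.  Raises :class:`OutOfBoundsError` outside
    the image domain ``[0, W-1] x [0, H-1]``.
    """
    bic = _as_bicubic(image)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    h, w = bic.shape
    if np.any(x < 0) or np.any(x > w - 1) or np.any(y < 0) or np.any(y > h - 1):
        raise OutOfBoundsError(
            f"interpolation point outside image domain [0,{w - 1}]x[0,{h - 1}]"
        )
    scalar = x.ndim == 0 and y.ndim == 0
    out = bic.sample(np.atleast_1d(x), np.atleast_1d(y))
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Grids and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubsetGrid:
    """Regular lattice of subset centres inside a rectangular ROI."""

    centers: np.ndarray              # (N, 2) float, (x, y) px in the reference frame
    subset_size: int = DEFAULT_SUBSET_SIZE
    step: int = DEFAULT_STEP
    roi: tuple[int, int, int, int] | None = None   # (x0, y0, width, height)
    shape: tuple[int, int] | None = None           # (n_rows, n_cols) if lattice

    def __post_init__(self):
        if self.subset_size % 2 == 0 or self.subset_size < 11:
            raise ValueError("subset_size must be odd and >= 11")
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "centers", centers)

    @property
    def half(self) -> int:
        return self.subset_size // 2

    @property
    def n_points(self) -> int:
        return self.centers.shape[0]

    @classmethod
    def from_roi(cls, roi, image_shape, subset_size=DEFAULT_SUBSET_SIZE, step=DEFAULT_STEP):
        """Lattice with spacing ``step`` whose subsets fit fully inside the image."""
        x0, y0, w, h = roi
        half = subset_size // 2
        xs = np.arange(x0, x0 + w + 1e-9, step, dtype=float)
        ys = np.arange(y0, y0 + h + 1e-9, step, dtype=float)
        ih, iw = image_shape
        xs = xs[(xs - half >= 0) & (xs + half <= iw - 1)]
        ys = ys[(ys - half >= 0) & (ys + half <= ih - 1)]
        if len(xs) == 0 or len(ys) == 0:
            raise ValueError("ROI leaves no room for a single subset")
        gx, gy = np.meshgrid(xs, ys)
        centers = np.column_stack([gx.ravel(), gy.ravel()])
        return cls(centers=centers, subset_size=subset_size, step=step,
                   roi=tuple(roi), shape=(len(ys), len(xs)))


@dataclass(frozen=True)
class SubsetMatch:
    """Result of correlating a single subset between two images."""

    u: float
    v: float
    affine: tuple[float, float, float, float]   # (du/dx, du/dy, dv/dx, dv/dy)
    zncc: float
    converged: bool
    iterations: int
    code: str = "ok"


@dataclass
class DisplacementField:
    """Per-grid-point, per-frame displacement with correlation quality.

    ``u`` holds (n_frames, n_points, C) displacement components: C = 2 in
    pixels for single-camera tracking, C = 3 in millimetres after stereo
    triangulation.  Invalid points are masked, never sentinel-valued;
    consumers must honor ``valid``.
    """

    grid: SubsetGrid
    u: np.ndarray                      # (F, N, 2|3)
    valid: np.ndarray                  # (F, N) bool
    zncc: np.ndarray                   # (F, N) cumulative quality (min along chain)
    timestamps: np.ndarray             # (F,) s
    units: str = "px"                  # units of ``u``: "px" or "mm"
    mm_per_px: float | None = None
    reference_frame: int = 0
    accumulation_mode: str = "incremental"
    ref_mm: np.ndarray | None = None   # (N, 2|3) reference positions in mm

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.zncc = np.asarray(self.zncc, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.units == "px" and self.mm_per_px is not None and self.ref_mm is None:
            self.ref_mm = self.grid.centers * self.mm_per_px

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]

    @property
    def n_points(self) -> int:
        return self.u.shape[1]

    @property
    def n_components(self) -> int:
        return self.u.shape[2]

    def displacements_mm(self) -> np.ndarray:
        """Displacement in mm, (F, N, C)."""
        if self.units == "mm":
            return self.u
        if self.mm_per_px is None:
            raise ValueError("no mm_per_px scale available for px -> mm conversion")
        return self.u * self.mm_per_px

    def positions_mm(self) -> np.ndarray:
        """Current positions in mm, (F, N, C)."""
        if self.ref_mm is None:
            raise ValueError("field carries no reference positions in mm")
        return self.ref_mm[None, :, :] + self.displacements_mm()


# ---------------------------------------------------------------------------
# IC-GN core
# ---------------------------------------------------------------------------


def _subset_offsets(half: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(-half, half + 1, dtype=float)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    return dx.ravel(), dy.ravel()


def _warp_matrices(p: np.ndarray) -> np.ndarray:
    """(N, 6) params (u, ux, uy, v, vx, vy) -> (N, 3, 3) local affine warps."""
    n = p.shape[0]
    w = np.tile(np.eye(3), (n, 1, 1))
    w[:, 0, 0] += p[:, 1]
    w[:, 0, 1] = p[:, 2]
    w[:, 0, 2] = p[:, 0]
    w[:, 1, 0] = p[:, 4]
    w[:, 1, 1] += p[:, 5]
    w[:, 1, 2] = p[:, 3]
    return w


def _icgn_batch(ref: BicubicImage, cur: BicubicImage, centers: np.ndarray,
                half: int, init: np.ndarray,
                max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_CONV_TOL):
    """Run IC-GN for many subsets of one frame pair simultaneously.

    Returns dict with u, v, affine, zncc, converged, iterations, code.
    """
    n = centers.shape[0]
    dx, dy = _subset_offsets(half)
    s2 = dx.size
    cx = centers[:, 0][:, None]
    cy = centers[:, 1][:, None]

    xs = cx + dx[None, :]
    ys = cy + dy[None, :]
    f = ref.sample(xs.ravel(), ys.ravel()).reshape(n, s2)
    gx, gy = ref.sample_gradient(xs.ravel(), ys.ravel())
    gx = gx.reshape(n, s2)
    gy = gy.reshape(n, s2)

    fbar = f.mean(axis=1, keepdims=True)
    fc = f - fbar
    df = np.sqrt((fc * fc).sum(axis=1))            # (N,)

    sd = np.empty((n, s2, 6))
    sd[:, :, 0] = gx
    sd[:, :, 1] = gx * dx
    sd[:, :, 2] = gx * dy
    sd[:, :, 3] = gy
    sd[:, :, 4] = gy * dx
    sd[:, :, 5] = gy * dy
    hess = np.einsum("nsi,nsj->nij", sd, sd)

    warp = _warp_matrices(init)
    code = np.full(n, "ok", dtype=object)
    converged = np.zeros(n, dtype=bool)
    iterations = np.zeros(n, dtype=int)
    scale = np.array([1.0, half, half, 1.0, half, half])

    flat = df < 1e-12
    code[flat] = "flat-subset"
    active = ~flat
    # regularize Hessians of flat subsets so the batched solve stays defined
    hess[flat] = np.eye(3 * 2)

    ih, iw = cur.shape
    g_last = np.zeros_like(f)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        w = warp[idx]
        xw = (cx[idx] + w[:, 0, 0, None] * dx[None, :]
              + w[:, 0, 1, None] * dy[None, :] + w[:, 0, 2, None])
        yw = (cy[idx] + w[:, 1, 0, None] * dx[None, :]
              + w[:, 1, 1, None] * dy[None, :] + w[:, 1, 2, None])

        oob = ((xw.min(axis=1) < 0) | (xw.max(axis=1) > iw - 1)
               | (yw.min(axis=1) < 0) | (yw.max(axis=1) > ih - 1))
        if oob.any():
            bad = idx[oob]
            code[bad] = "out-of-bounds"
            active[bad] = False
            idx = idx[~oob]
            if idx.size == 0:
                continue
            xw, yw = xw[~oob], yw[~oob]

        g = cur.sample(xw.ravel(), yw.ravel()).reshape(idx.size, s2)
        g_last[idx] = g
        gbar = g.mean(axis=1, keepdims=True)
        gc = g - gbar
        dg = np.sqrt((gc * gc).sum(axis=1))
        small = dg < 1e-12
        if small.any():
            bad = idx[small]
            code[bad] = "flat-target"
            active[bad] = False
            idx = idx[~small]
            if idx.size == 0:
                continue
            gc, dg = gc[~small], dg[~small]

        e = fc[idx] - (df[idx] / dg)[:, None] * gc
        b = np.einsum("ns,nsk->nk", e, sd[idx])
        dp = -np.linalg.solve(hess[idx], b[..., None])[..., 0]

        dwarp = _warp_matrices(dp)
        warp[idx] = warp[idx] @ np.linalg.inv(dwarp)
        iterations[idx] += 1

        upd = np.sqrt(((dp * scale) ** 2).sum(axis=1))
        bad = ~np.isfinite(upd) | (np.abs(warp[idx, 0, 2]) > iw) | (np.abs(warp[idx, 1, 2]) > ih)
        if bad.any():
            code[idx[bad]] = "diverged"
            active[idx[bad]] = False
        done = (upd < tol) & ~bad
        converged[idx[done]] = True
        active[idx[done]] = False

    code[active] = "max-iterations"

    # final ZNCC at the converged warp (resample once for converged points)
    zncc = np.full(n, -1.0)
    good = converged & (df > 1e-12)
    if good.any():
        idx = np.flatnonzero(good)
        w = warp[idx]
        xw = (cx[idx] + w[:, 0, 0, None] * dx[None, :]
              + w[:, 0, 1, None] * dy[None, :] + w[:, 0, 2, None])
        yw = (cy[idx] + w[:, 1, 0, None] * dx[None, :]
              + w[:, 1, 1, None] * dy[None, :] + w[:, 1, 2, None])
        np.clip(xw, 0, iw - 1, out=xw)
        np.clip(yw, 0, ih - 1, out=yw)
        g = cur.sample(xw.ravel(), yw.ravel()).reshape(idx.size, s2)
        gc = g - g.mean(axis=1, keepdims=True)
        dg = np.sqrt((gc * gc).sum(axis=1))
        dg[dg < 1e-12] = np.inf
        zncc[idx] = (fc[idx] * gc).sum(axis=1) / (df[idx] * dg)

    return {
        "u": warp[:, 0, 2],
        "v": warp[:, 1, 2],
        "affine": np.column_stack([warp[:, 0, 0] - 1, warp[:, 0, 1],
                                   warp[:, 1, 0], warp[:, 1, 1] - 1]),
        "zncc": np.clip(zncc, -1.0, 1.0),
        "converged": converged,
        "iterations": iterations,
        "code": code,
    }


def _integer_search(ref_image: np.ndarray, cur_image: np.ndarray, center,
                    half: int, radius: int = DEFAULT_SEARCH_RADIUS,
                    search_center=None):
    """Integer-pixel ZNCC search of one subset in a +/- radius window.

    The template is extracted from ``ref_image`` around ``center``; the
    search window in ``cur_image`` is centred at ``search_center`` (defaults
    to ``center``).  Returns the (u, v) offset relative to ``center``.
    """
    cx, cy = int(round(center[0])), int(round(center[1]))
    if search_center is None:
        sx, sy = cx, cy
    else:
        sx, sy = int(round(search_center[0])), int(round(search_center[1]))
    h, w = ref_image.shape
    if cx - half < 0 or cx + half > w - 1 or cy - half < 0 or cy + half > h - 1:
        return 0.0, 0.0
    tmpl = np.asarray(ref_image, dtype=float)[cy - half:cy + half + 1, cx - half:cx + half + 1]
    ch, cw = cur_image.shape
    y0 = max(sy - half - radius, 0)
    y1 = min(sy + half + radius + 1, ch)
    x0 = max(sx - half - radius, 0)
    x1 = min(sx + half + radius + 1, cw)
    region = np.asarray(cur_image, dtype=float)[y0:y1, x0:x1]
    if region.shape[0] < tmpl.shape[0] or region.shape[1] < tmpl.shape[1]:
        return 0.0, 0.0
    resp = match_template(region, tmpl, pad_input=False)
    iy, ix = np.unravel_index(np.argmax(resp), resp.shape)
    return float(x0 + ix + half - cx), float(y0 + iy + half - cy)


def correlate_subset(ref_image, cur_image, center, init=None,
                     subset_size: int = DEFAULT_SUBSET_SIZE,
                     max_iter: int = DEFAULT_MAX_ITER,
                     tol: float = DEFAULT_CONV_TOL) -> SubsetMatch:
    """Match one subset between two images with subpixel precision.

    ``init`` is (u, v) or a full 6-vector (u, ux, uy, v, vx, vy); when
    absent, an integer-pixel ZNCC search seeds the optimization.
    Divergence never raises: the returned match carries ``converged=False``
    and a diagnostic code.
    """
    ref_arr = np.asarray(ref_image) if not isinstance(ref_image, BicubicImage) else None
    cur_arr = np.asarray(cur_image) if not isinstance(cur_image, BicubicImage) else None
    ref = _as_bicubic(ref_image)
    cur = _as_bicubic(cur_image)
    half = subset_size // 2

    p0 = np.zeros(6)
    if init is None:
        if ref_arr is None or cur_arr is None:
            raise ValueError("integer search needs raw arrays; pass init explicitly")
        p0[0], p0[3] = _integer_search(ref_arr, cur_arr, center, half)
    else:
        init = np.asarray(init, dtype=float).ravel()
        if init.size == 2:
            p0[0], p0[3] = init
        elif init.size == 6:
            p0 = init.copy()
        else:
            raise ValueError("init must have 2 or 6 entries")

    res = _icgn_batch(ref, cur, np.atleast_2d(np.asarray(center, dtype=float)),
                      half, p0[None, :], max_iter=max_iter, tol=tol)
    return SubsetMatch(
        u=float(res["u"][0]), v=float(res["v"][0]),
        affine=tuple(res["affine"][0]),
        zncc=float(res["zncc"][0]),
        converged=bool(res["converged"][0]),
        iterations=int(res["iterations"][0]),
        code=str(res["code"][0]),
    )


def track_frame_pair(prev_frame, next_frame, grid: SubsetGrid, init_field=None,
                     centers=None, max_iter: int = DEFAULT_MAX_ITER,
                     tol: float = DEFAULT_CONV_TOL,
                     accept_zncc: float = 0.7):
    """Correlate every grid subset between two consecutive frames.

    Each point is seeded from its own previous solution (``init_field``,
    (N,2) or (N,6); zeros allowed).  Points that fail — including matches
    that converged onto a false optimum, recognized by ZNCC below
    ``accept_zncc`` — are re-seeded from the median increment of converged
    neighbors within ``NEIGHBOR_RESEED_STEPS * grid.step`` px and retried,
    then rescued by an integer ZNCC search if the motion outran the
    optimizer's convergence radius.

    Returns ``(increments (N,2), affine (N,4), zncc (N,), valid (N,))``.
    Raises :class:`TrackingCollapseError` if more than half the points fail.
    """
    ref = _as_bicubic(prev_frame)
    cur = _as_bicubic(next_frame)
    half = grid.half
    pts = grid.centers if centers is None else np.asarray(centers, dtype=float)
    n = pts.shape[0]

    if init_field is None:
        # no seed: integer-pixel ZNCC search initializes every point
        init = np.zeros((n, 6))
        for i in range(n):
            init[i, 0], init[i, 3] = _integer_search(ref.image, cur.image,
                                                     pts[i], half)
    else:
        init_field = np.asarray(init_field, dtype=float)
        init = np.zeros((n, 6))
        if init_field.shape == (n, 2):
            init[:, 0] = init_field[:, 0]
            init[:, 3] = init_field[:, 1]
        elif init_field.shape == (n, 6):
            init = init_field.copy()
        else:
            raise ValueError("init_field must be (N,2) or (N,6)")

    res = _icgn_batch(ref, cur, pts, half, init, max_iter=max_iter, tol=tol)
    conv = res["converged"] & (res["zncc"] >= accept_zncc)
    u = np.column_stack([res["u"], res["v"]])
    affine = res["affine"].copy()
    zncc = res["zncc"].copy()

    failed = np.flatnonzero(~conv)
    if failed.size and conv.any():
        radius = NEIGHBOR_RESEED_STEPS * grid.step
        reseed_init = np.zeros((failed.size, 6))
        can_retry = np.zeros(failed.size, dtype=bool)
        ref_centers = grid.centers
        for i, p in enumerate(failed):
            d = np.hypot(ref_centers[:, 0] - ref_centers[p, 0],
                         ref_centers[:, 1] - ref_centers[p, 1])
            nb = conv & (d <= radius)
            if nb.any():
                reseed_init[i, 0] = np.median(u[nb, 0])
                reseed_init[i, 3] = np.median(u[nb, 1])
                can_retry[i] = True
        retry = failed[can_retry]
        if retry.size:
            res2 = _icgn_batch(ref, cur, pts[retry], half, reseed_init[can_retry],
                               max_iter=max_iter, tol=tol)
            ok = res2["converged"] & (res2["zncc"] >= accept_zncc)
            conv[retry] = ok
            u[retry[ok], 0] = res2["u"][ok]
            u[retry[ok], 1] = res2["v"][ok]
            affine[retry[ok]] = res2["affine"][ok]
            zncc[retry[ok]] = res2["zncc"][ok]

    # last resort: integer ZNCC search around the best seed, then refine.
    # Rescues points whose motion outran the optimizer's convergence radius.
    failed = np.flatnonzero(~conv)
    if failed.size:
        search_init = np.zeros((failed.size, 6))
        for i, p in enumerate(failed):
            seed = init[p, [0, 3]]
            if conv.any():
                d = np.hypot(grid.centers[:, 0] - grid.centers[p, 0],
                             grid.centers[:, 1] - grid.centers[p, 1])
                nb = conv & (d <= NEIGHBOR_RESEED_STEPS * grid.step)
                if nb.any():
                    seed = np.median(u[nb], axis=0)
            radius = int(DEFAULT_SEARCH_RADIUS + 0.5 * np.hypot(*seed))
            du, dv = _integer_search(ref.image, cur.image, pts[p], half,
                                     radius=radius,
                                     search_center=(pts[p, 0] + seed[0],
                                                    pts[p, 1] + seed[1]))
            search_init[i, 0], search_init[i, 3] = du, dv
        res3 = _icgn_batch(ref, cur, pts[failed], half, search_init,
                           max_iter=max_iter, tol=tol)
        ok = res3["converged"] & (res3["zncc"] >= accept_zncc)
        conv[failed] = ok
        u[failed[ok], 0] = res3["u"][ok]
        u[failed[ok], 1] = res3["v"][ok]
        affine[failed[ok]] = res3["affine"][ok]
        zncc[failed[ok]] = res3["zncc"][ok]

    if (~conv).sum() > 0.5 * n:
        raise TrackingCollapseError(
            f"{(~conv).sum()}/{n} subsets failed to converge for this frame pair"
        )
    return u, affine, zncc, conv


def _frames_and_times(frames, frame_rate=None):
    if isinstance(frames, ImageSequence):
        return frames.frames, frames.timestamps
    arr = np.asarray(frames)
    rate = 1.0 if frame_rate is None else float(frame_rate)
    return arr, np.arange(arr.shape[0], dtype=float) / rate


def accumulate_sequence(frames, grid: SubsetGrid, mode: str = "incremental",
                        frame_rate: float | None = None,
                        mm_per_px: float | None = None,
                        max_iter: int = DEFAULT_MAX_ITER,
                        tol: float = DEFAULT_CONV_TOL) -> DisplacementField:
    """Track a grid through a whole sequence.

    mode="incremental" sums frame-to-frame increments (sum of differentials);
    the reference subset is re-centred at the tracked position each step, so
    shape change accumulates naturally.  mode="to_reference" additionally
    correlates every frame directly against frame 0, seeded by the
    incremental estimate, which avoids random-walk error growth at the cost
    of requiring the full deformation to stay within the affine shape
    function.  Both report cumulative quality = min ZNCC along the chain.
    """
    if mode not in ("incremental", "to_reference"):
        raise ValueError("mode must be 'incremental' or 'to_reference'")
    stack, timestamps = _frames_and_times(frames, frame_rate)
    nf = stack.shape[0]
    if nf < 2:
        raise ValueError("need at least 2 frames")
    n = grid.n_points

    disp = np.zeros((nf, n, 2))
    valid = np.ones((nf, n), dtype=bool)
    zncc = np.ones((nf, n))

    prev = BicubicImage(stack[0])
    ref0 = prev
    inc_prev = np.zeros((n, 2))
    cum = np.zeros((n, 2))
    for k in range(1, nf):
        cur = BicubicImage(stack[k])
        centers_k = grid.centers + cum
        inc, _aff, q, ok = track_frame_pair(prev, cur, grid, init_field=inc_prev,
                                            centers=centers_k, max_iter=max_iter, tol=tol)
        if (~ok).any():
            # carry failed points along the median neighbor increment so the
            # chain can resume if they re-converge later
            med = np.median(inc[ok], axis=0) if ok.any() else np.zeros(2)
            inc[~ok] = med
        cum = cum + inc
        disp[k] = cum
        valid[k] = valid[k - 1] & ok
        zncc[k] = np.minimum(zncc[k - 1], q)
        inc_prev = inc
        prev = cur

    if mode == "to_reference":
        aff_prev = np.zeros((n, 6))
        for k in range(1, nf):
            cur = BicubicImage(stack[k])
            init = aff_prev.copy()
            init[:, 0] = disp[k, :, 0]
            init[:, 3] = disp[k, :, 1]
            res = _icgn_batch(ref0, cur, grid.centers, grid.half, init,
                              max_iter=max_iter, tol=tol)
            ok = res["converged"] & (res["zncc"] >= 0.7)
            disp[k, ok, 0] = res["u"][ok]
            disp[k, ok, 1] = res["v"][ok]
            valid[k] = valid[k] & ok
            zncc[k] = np.minimum(zncc[k], res["zncc"])
            aff_prev[:, 0] = res["u"]
            aff_prev[:, 3] = res["v"]
            aff_prev[:, 1] = res["affine"][:, 0]
            aff_prev[:, 2] = res["affine"][:, 1]
            aff_prev[:, 4] = res["affine"][:, 2]
            aff_prev[:, 5] = res["affine"][:, 3]

    return DisplacementField(
        grid=grid, u=disp, valid=valid, zncc=zncc, timestamps=timestamps,
        units="px", mm_per_px=mm_per_px, accumulation_mode=mode,
    )


def quality_filter(field: DisplacementField, zncc_min: float) -> DisplacementField:
    """Invalidate points whose quality drops below ``zncc_min`` at any frame."""
    zncc_min = max(float(zncc_min), 1e-9)
    if zncc_min > 1.0:
        raise ValueError("zncc_min must be in (0, 1]")
    bad_points = (field.zncc < zncc_min).any(axis=0) | (~field.valid).any(axis=0)
    new_valid = field.valid.copy()
    new_valid[:, bad_points] = False
    n_removed = int(bad_points.sum())
    if n_removed:
        logger.info("quality_filter: invalidated %d/%d points at zncc_min=%.3f",
                    n_removed, field.n_points, zncc_min)
    if bad_points.all():
        raise EmptyFieldError("quality filter removed every grid point")
    return replace(field, valid=new_valid)
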