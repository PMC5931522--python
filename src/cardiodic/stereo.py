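"""Stereo camera calibration, triangulation, and 3D field lifting.

Cameras are plain pinholes: a 3x4 homogeneous projection matrix mapping
world millimetres to image pixels (no lens distortion — a radial-distortion
hook can be layered on the pixel coordinates before calibration if ever
needed).  Calibration is a normalized direct linear transform (DLT) from a
3D target, refined by Gauss-Newton on the reprojection error; the reported
calibration error is the root-mean-square reprojection residual over the
target points.  The world frame is the calibration-target frame and all
millimetre outputs live in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .dic import (
    BicubicImage,
    DisplacementField,
    SubsetGrid,
    _as_bicubic,
    _icgn_batch,
    _integer_search,
)


class StereoError(Exception):
    pass


class DegenerateTargetError(StereoError):
    """Calibration points are coplanar (or otherwise rank-deficient)."""


class InsufficientPointsError(StereoError):
    pass


class ProjectionSingularityError(StereoError):
    """World point lies on the camera's principal plane (zero depth)."""


class IllConditionedError(StereoError):
    """Triangulation rays are (near-)parallel."""


class CorrespondenceCollapseError(StereoError):
    pass


class IncompatibleFieldsError(StereoError):
    pass


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: ``projection`` maps world mm to image px (homogeneous)."""

    projection: np.ndarray                 # 3x4
    image_size: tuple[int, int] | None = None   # (width, height) px

    def __post_init__(self):
        p = np.asarray(self.projection, dtype=float)
        if p.shape != (3, 4):
            raise ValueError("projection must be 3x4")
        if np.linalg.matrix_rank(p) < 3:
            raise ValueError("projection matrix must have rank 3")
        object.__setattr__(self, "projection", p)


@dataclass(frozen=True)
class CalibrationResult:
    camera: CameraModel
    rms_error: float                 # px, sqrt(mean ||residual||^2) over points
    n_points: int
    per_point_residuals: np.ndarray  # (N,) px residual norms

    def __post_init__(self):
        r = np.asarray(self.per_point_residuals, dtype=float)
        object.__setattr__(self, "per_point_residuals", r)
        rms = float(np.sqrt(np.mean(r ** 2))) if r.size else 0.0
        if abs(rms - self.rms_error) > 1e-12 * max(1.0, rms):
            raise ValueError("rms_error inconsistent with per_point_residuals")


# ---------------------------------------------------------------------------
# Construction helpers for synthetic rigs
# ---------------------------------------------------------------------------


def look_at_camera(position, target, focal_px: float, image_size,
                   up=(0.0, 1.0, 0.0)) -> CameraModel:
    """Pinhole at ``position`` (mm) looking at ``target``, principal point centred."""
    position = np.asarray(position, dtype=float)
    target = np.asarray(target, dtype=float)
    forward = target - position
    forward = forward / np.linalg.norm(forward)
    up = np.asarray(up, dtype=float)
    right = np.cross(up, forward)
    nr = np.linalg.norm(right)
    if nr < 1e-12:
        raise ValueError("up vector parallel to viewing direction")
    right /= nr
    down = np.cross(forward, right)
    rot = np.vstack([right, down, forward])          # world -> camera
    t = -rot @ position
    w, h = image_size
    intr = np.array([[focal_px, 0.0, (w - 1) / 2.0],
                     [0.0, focal_px, (h - 1) / 2.0],
                     [0.0, 0.0, 1.0]])
    proj = intr @ np.hstack([rot, t[:, None]])
    return CameraModel(projection=proj, image_size=(int(w), int(h)))


def make_stereo_rig(target=(0.0, 0.0, 0.0), distance_mm: float = 500.0,
                    half_angle_deg: float = 12.0, mm_per_px: float = 0.1,
                    image_size=(512, 512)) -> tuple[CameraModel, CameraModel]:
    """Symmetric two-camera rig with a slanted view of the world X-Y plane.

    The focal length is chosen so the pixel footprint on the target plane is
    about ``mm_per_px``.
    """
    target = np.asarray(target, dtype=float)
    ang = np.deg2rad(half_angle_deg)
    focal_px = distance_mm / mm_per_px
    cams = []
    for sign in (-1.0, +1.0):
        pos = target + distance_mm * np.array([sign * np.sin(ang), 0.0, np.cos(ang)])
        cams.append(look_at_camera(pos, target, focal_px, image_size))
    return cams[0], cams[1]


# ---------------------------------------------------------------------------
# Projection / calibration / triangulation
# ---------------------------------------------------------------------------


def reproject(camera: CameraModel, world_point):
    """Project world mm point(s) to pixel coordinates."""
    pts = np.atleast_2d(np.asarray(world_point, dtype=float))
    ph = np.hstack([pts, np.ones((pts.shape[0], 1))])
    q = ph @ camera.projection.T
    wcomp = q[:, 2]
    if np.any(np.abs(wcomp) < 1e-12):
        raise ProjectionSingularityError("point on the camera's principal plane")
    px = q[:, :2] / wcomp[:, None]
    if np.asarray(world_point).ndim == 1:
        return px[0]
    return px


def _check_target_geometry(world_points: np.ndarray):
    if world_points.shape[0] < 6:
        raise InsufficientPointsError(
            f"need >= 6 calibration points, got {world_points.shape[0]}"
        )
    centered = world_points - world_points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= 1e-6 * s[0]:
        raise DegenerateTargetError("calibration target points are coplanar")


def _normalization(points: np.ndarray) -> np.ndarray:
    """Similarity transform mapping points to zero mean, sqrt(dim) RMS radius."""
    d = points.shape[1]
    mean = points.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((points - mean) ** 2, axis=1)))
    scale = np.sqrt(d) / max(rms, 1e-12)
    t = np.eye(d + 1)
    t[:d, :d] *= scale
    t[:d, d] = -scale * mean
    return t


def calibrate_dlt(world_points, image_points, image_size=None) -> CalibrationResult:
    """Calibrate one camera from >= 6 non-coplanar world<->image correspondences.

    Normalized DLT followed by Gauss-Newton refinement of the 12 projection
    entries (gauge-fixed by unit norm) on the reprojection residuals.
    """
    world = np.asarray(world_points, dtype=float)
    img = np.asarray(image_points, dtype=float)
    if world.shape[0] != img.shape[0]:
        raise ValueError("world and image point counts differ")
    _check_target_geometry(world)

    tw = _normalization(world)
    ti = _normalization(img)
    wh = np.hstack([world, np.ones((world.shape[0], 1))]) @ tw.T
    ih = np.hstack([img, np.ones((img.shape[0], 1))]) @ ti.T

    n = world.shape[0]
    a = np.zeros((2 * n, 12))
    a[0::2, 0:4] = wh
    a[0::2, 8:12] = -ih[:, [0]] * wh
    a[1::2, 4:8] = wh
    a[1::2, 8:12] = -ih[:, [1]] * wh
    _, _, vt = np.linalg.svd(a)
    pnorm = vt[-1].reshape(3, 4)
    proj = np.linalg.inv(ti) @ pnorm @ tw
    proj = proj / np.linalg.norm(proj)

    wh_full = np.hstack([world, np.ones((n, 1))])

    def residuals(p):
        pm = p.reshape(3, 4)
        q = wh_full @ pm.T
        return ((q[:, :2] / q[:, [2]]) - img).ravel()

    sol = least_squares(residuals, proj.ravel(), method="lm", xtol=1e-15, ftol=1e-15)
    proj = sol.x.reshape(3, 4)
    proj = proj / np.linalg.norm(proj)

    res = residuals(proj.ravel()).reshape(n, 2)
    per_point = np.linalg.norm(res, axis=1)
    rms = float(np.sqrt(np.mean(per_point ** 2)))
    cam = CameraModel(projection=proj, image_size=image_size)
    return CalibrationResult(camera=cam, rms_error=rms, n_points=n,
                             per_point_residuals=per_point)


def _triangulate_linear(p1: np.ndarray, p2: np.ndarray,
                        px1: np.ndarray, px2: np.ndarray):
    """Batched homogeneous DLT triangulation.  px arrays are (N, 2)."""
    n = px1.shape[0]
    a = np.empty((n, 4, 4))
    a[:, 0] = px1[:, [0]] * p1[2] - p1[0]
    a[:, 1] = px1[:, [1]] * p1[2] - p1[1]
    a[:, 2] = px2[:, [0]] * p2[2] - p2[0]
    a[:, 3] = px2[:, [1]] * p2[2] - p2[1]
    _, _, vt = np.linalg.svd(a)
    xh = vt[:, -1, :]
    w = xh[:, 3]
    bad = np.abs(w) < 1e-10 * np.linalg.norm(xh[:, :3], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pts = xh[:, :3] / w[:, None]
    return pts, bad


def _reprojection_residual(cam1, cam2, pts, px1, px2):
    r1 = np.linalg.norm(reproject(cam1, pts) - px1, axis=-1)
    r2 = np.linalg.norm(reproject(cam2, pts) - px2, axis=-1)
    return 0.5 * (r1 + r2)


def triangulate_pair(cam1: CameraModel, cam2: CameraModel, px1, px2):
    """Triangulate one correspondence; returns (world_point mm, residual px).

    The residual is the mean reprojection error over both views; a large
    value flags a mismatched correspondence.  Near-parallel rays raise
    :class:`IllConditionedError`.
    """
    if np.allclose(cam1.projection, cam2.projection):
        raise IllConditionedError("identical cameras cannot triangulate")
    px1 = np.asarray(px1, dtype=float)[None, :]
    px2 = np.asarray(px2, dtype=float)[None, :]
    pts, bad = _triangulate_linear(cam1.projection, cam2.projection, px1, px2)
    if bad[0] or not np.all(np.isfinite(pts[0])):
        raise IllConditionedError("triangulation rays are near-parallel")
    resid = float(_reprojection_residual(cam1, cam2, pts, px1, px2)[0])
    return pts[0], resid


def triangulate_batch(cam1: CameraModel, cam2: CameraModel, px1, px2):
    """Vectorized triangulation of (N, 2) pixel arrays -> ((N, 3) mm, (N,) px)."""
    px1 = np.asarray(px1, dtype=float)
    px2 = np.asarray(px2, dtype=float)
    pts, bad = _triangulate_linear(cam1.projection, cam2.projection, px1, px2)
    resid = np.full(px1.shape[0], np.nan)
    ok = ~bad & np.all(np.isfinite(pts), axis=1)
    if ok.any():
        resid[ok] = _reprojection_residual(cam1, cam2, pts[ok], px1[ok], px2[ok])
    return pts, resid, ok


# ---------------------------------------------------------------------------
# Cross-camera correspondence and 3D lifting
# ---------------------------------------------------------------------------


def stereo_correspond(left_ref, right_ref, grid: SubsetGrid,
                      search_radius: int = 40, seed_disparity=None,
                      zncc_min: float = 0.5):
    """Locate every left-grid subset in the right reference image.

    Integer ZNCC search (optionally seeded by a projected-geometry disparity
    guess) followed by subpixel IC-GN refinement.  Returns
    ``(disparity (N,2) px, zncc (N,), valid (N,))``.  Raises
    :class:`CorrespondenceCollapseError` when fewer than half the points
    correspond.
    """
    left_arr = np.asarray(left_ref, dtype=float) if not isinstance(left_ref, BicubicImage) else None
    right_arr = np.asarray(right_ref, dtype=float) if not isinstance(right_ref, BicubicImage) else None
    if left_arr is None or right_arr is None:
        raise ValueError("stereo_correspond needs raw image arrays")
    left = _as_bicubic(left_arr)
    right = _as_bicubic(right_arr)
    half = grid.half
    n = grid.n_points

    if seed_disparity is None:
        sd = np.zeros((n, 2))
    else:
        sd = np.asarray(seed_disparity, dtype=float)
        if sd.shape == (2,):
            sd = np.tile(sd, (n, 1))
    init = np.zeros((n, 6))
    for i, c in enumerate(grid.centers):
        du, dv = _integer_search(left_arr, right_arr, c, half,
                                 radius=search_radius,
                                 search_center=(c[0] + sd[i, 0], c[1] + sd[i, 1]))
        init[i, 0], init[i, 3] = du, dv

    res = _icgn_batch(left, right, grid.centers, half, init)
    valid = res["converged"] & (res["zncc"] >= zncc_min)
    if valid.sum() < 0.5 * n:
        raise CorrespondenceCollapseError(
            f"only {int(valid.sum())}/{n} cross-camera correspondences found"
        )
    disparity = np.column_stack([res["u"], res["v"]])
    return disparity, res["zncc"], valid


def lift_fields_to_3d(field_left: DisplacementField, field_right: DisplacementField,
                      disparity, cam_left: CameraModel, cam_right: CameraModel,
                      disparity_valid=None) -> DisplacementField:
    """Triangulate per-camera 2D pixel fields into one 3D mm field.

    Per frame, each point's current left/right pixel positions are
    triangulated; the 3D displacement is the triangulated position minus the
    reference-frame triangulated position.  A point is invalid wherever any
    of its inputs is.
    """
    if field_left.n_points != field_right.n_points or field_left.n_frames != field_right.n_frames:
        raise IncompatibleFieldsError("left/right fields differ in grid or frame count")
    disparity = np.asarray(disparity, dtype=float)
    if disparity.shape != (field_left.n_points, 2):
        raise IncompatibleFieldsError("disparity shape does not match the grid")
    if disparity_valid is None:
        disparity_valid = np.ones(field_left.n_points, dtype=bool)

    nf, n = field_left.n_frames, field_left.n_points
    left0 = field_left.grid.centers
    right0 = field_right.grid.centers

    ref3d, _, ref_ok = triangulate_batch(cam_left, cam_right, left0, right0)

    u3 = np.zeros((nf, n, 3))
    valid = np.zeros((nf, n), dtype=bool)
    for k in range(nf):
        pl = left0 + field_left.u[k]
        pr = right0 + field_right.u[k]
        pts, _, ok = triangulate_batch(cam_left, cam_right, pl, pr)
        good = (ok & ref_ok & disparity_valid
                & field_left.valid[k] & field_right.valid[k])
        u3[k, good] = pts[good] - ref3d[good]
        valid[k] = good

    zncc = np.minimum(field_left.zncc, field_right.zncc)
    return DisplacementField(
        grid=field_left.grid, u=u3, valid=valid, zncc=zncc,
        timestamps=field_left.timestamps, units="mm",
        mm_per_px=field_left.mm_per_px,
        reference_frame=field_left.reference_frame,
        accumulation_mode=field_left.accumulation_mode,
        ref_mm=ref3d,
    )
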