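"""Synthetic beating-heart benchmark with exact analytic ground truth.

Emulates intraoperative speckle imaging of the right-ventricle surface: a
random dark-dot pattern (surgical marker on light epicardium) on a plane
patch that contracts about a centre, translates, moves out of plane, and is
amplitude-modulated by respiration.  Because the imposed motion is affine
in-plane and uniform out-of-plane, the true displacement, surface strain
tensor, and virtual-extensometer length are available in closed form at
every frame, so every downstream stage (tracking, triangulation, cardiac
metrics) can be validated without patient data.

The cardiac waveform is a piecewise-cosine scale factor c(t) with four
clinically named phases per beat of period T = 60/heart_rate:

* systole: cosine ramp 1 -> 1-a over ``systole_fraction * T``;
* early diastole: cosine ramp 1-a -> 1-a+r_e*a over
  ``early_diastole_fraction * T`` (the E-wave recovery);
* diastasis: plateau;
* atrial kick: cosine ramp back to 1 over ``atrial_fraction * T``.

This reproduces the characteristic rise-plateau-fall fractional-shortening
shape and gives distinct E and A diastolic phases, so the detection of
TVe/TVa and SRe/SRa characteristic points is exercised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .dic import BicubicImage, ImageSequence, SubsetGrid
from .stereo import CameraModel, _check_target_geometry, reproject

logger = logging.getLogger(__name__)


class SynthError(Exception):
    pass


class InvalidParameterError(SynthError):
    pass


class OutOfViewError(SynthError):
    """The tracked surface patch leaves a camera's field of view."""

    def __init__(self, frame: int, camera: str = ""):
        self.frame = frame
        self.camera = camera
        where = f" for camera {camera}" if camera else ""
        super().__init__(f"surface patch leaves the field of view at frame {frame}{where}")


# ---------------------------------------------------------------------------
# Speckle pattern
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecklePatternParams:
    """Random dark-dot pattern parameters (dots per mm^2, radii in mm).

    Dark dots on a light background mimic the marker-on-epicardium
    ("inverse speckle") contrast of the surgical pattern.
    """

    dot_density: float = 2.0        # dots / mm^2
    dot_radius_mean: float = 0.3    # mm
    dot_radius_std: float = 0.1     # mm
    dot_intensity: float = 40.0     # grayscale level
    background_intensity: float = 200.0
    blur_sigma: float = 0.8         # px
    noise_sigma: float = 2.0        # grayscale level, additive Gaussian
    seed: int = 0

    def __post_init__(self):
        if self.dot_density < 0:
            raise InvalidParameterError("dot_density must be >= 0")
        if self.dot_radius_mean <= 0:
            raise InvalidParameterError("dot_radius_mean must be > 0")
        if self.dot_radius_std < 0 or self.noise_sigma < 0 or self.blur_sigma < 0:
            raise InvalidParameterError("sigmas must be >= 0")


class SpeckleField:
    """A seeded set of dots over a rectangular mm domain, rasterizable anywhere.

    Dot placement is a homogeneous Poisson process over the domain; radii
    are Gaussian, clipped away from zero.  The same (params, domain) always
    yields the same dots, so differently cropped or differently sampled
    renders of one field are mutually consistent.
    """

    def __init__(self, params: SpecklePatternParams, domain_mm):
        self.params = params
        x0, y0, x1, y1 = (float(v) for v in domain_mm)
        if x1 <= x0 or y1 <= y0:
            raise InvalidParameterError("empty speckle domain")
        self.domain = (x0, y0, x1, y1)
        rng = np.random.default_rng([int(params.seed), 0x5BEC])
        area = (x1 - x0) * (y1 - y0)
        n = int(rng.poisson(params.dot_density * area))
        self.centers_mm = rng.uniform((x0, y0), (x1, y1), size=(n, 2))
        radii = rng.normal(params.dot_radius_mean, params.dot_radius_std, size=n)
        self.radii_mm = np.clip(radii, 0.05 * params.dot_radius_mean, None)

    @property
    def n_dots(self) -> int:
        return self.centers_mm.shape[0]

    def rasterize(self, origin_mm, shape_px, mm_per_px: float,
                  blur: bool = True) -> np.ndarray:
        """Render the field to float intensities; pixel (row i, col j) is
        centred at mm ``(origin_x + j*mm_per_px, origin_y + i*mm_per_px)``."""
        p = self.params
        h, w = int(shape_px[0]), int(shape_px[1])
        ox, oy = float(origin_mm[0]), float(origin_mm[1])
        coverage = np.zeros((h, w))
        aa = mm_per_px  # one-pixel anti-aliasing edge
        for (cx, cy), r in zip(self.centers_mm, self.radii_mm):
            jx = (cx - ox) / mm_per_px
            iy = (cy - oy) / mm_per_px
            rr = (r + aa) / mm_per_px
            j0, j1 = max(int(np.floor(jx - rr)), 0), min(int(np.ceil(jx + rr)) + 1, w)
            i0, i1 = max(int(np.floor(iy - rr)), 0), min(int(np.ceil(iy + rr)) + 1, h)
            if j0 >= j1 or i0 >= i1:
                continue
            jj = ox + np.arange(j0, j1) * mm_per_px
            ii = oy + np.arange(i0, i1) * mm_per_px
            d = np.hypot(jj[None, :] - cx, ii[:, None] - cy)
            cov = np.clip((r - d) / aa + 0.5, 0.0, 1.0)
            np.maximum(coverage[i0:i1, j0:j1], cov, out=coverage[i0:i1, j0:j1])
        img = p.background_intensity + (p.dot_intensity - p.background_intensity) * coverage
        if blur and p.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, p.blur_sigma)
        return img


def render_speckle_pattern(params: SpecklePatternParams, width_px: int,
                           height_px: int, mm_per_px: float,
                           bit_depth: int = 8) -> np.ndarray:
    """Seeded speckle image: anti-aliased dark dots, Gaussian blur, noise."""
    if width_px <= 0 or height_px <= 0:
        raise InvalidParameterError("image dimensions must be positive")
    if mm_per_px <= 0:
        raise InvalidParameterError("mm_per_px must be > 0")
    fieldw = width_px * mm_per_px
    fieldh = height_px * mm_per_px
    sf = SpeckleField(params, (0.0, 0.0, fieldw, fieldh))
    logger.debug("render_speckle_pattern: %d dots over %.1f mm^2",
                 sf.n_dots, fieldw * fieldh)
    img = sf.rasterize((0.0, 0.0), (height_px, width_px), mm_per_px)
    if params.noise_sigma > 0:
        rng = np.random.default_rng([int(params.seed), 0x401E])
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    return _quantize(img, bit_depth)


def _quantize(img: np.ndarray, bit_depth: int) -> np.ndarray:
    if bit_depth not in (8, 16):
        raise InvalidParameterError("bit_depth must be 8 or 16")
    vmax = 2 ** bit_depth - 1
    out = np.clip(np.rint(img), 0, vmax)
    return out.astype(np.uint8 if bit_depth == 8 else np.uint16)


# ---------------------------------------------------------------------------
# Motion model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotionModelParams:
    """Analytic motion of the synthetic heart surface.

    Contraction is an affine scaling about ``center`` with per-axis
    multipliers ``anisotropy`` on the peak relative shortening
    ``contraction_amplitude``; rigid translation follows the beat waveform
    w(t) = (1 - c(t)) / a in [0, 1]; everything is amplitude-modulated by
    ``1 + respiration_mod_depth * sin(2 pi f_resp t)``.  Defaults are sized
    to the intraoperative regime: a ~200-mm-wide view, peak ROI-mean
    displacement around 25 mm, 20% peak shortening along x, ~10 mm
    out-of-plane excursion, ~5 beats at 60 bpm with shallow 12/min
    respiratory modulation.
    """

    heart_rate: float = 60.0                 # beats / min
    systole_fraction: float = 0.35           # of the beat period
    early_diastole_fraction: float = 0.20
    early_recovery_ratio: float = 0.70       # fraction of a recovered in the E-wave
    atrial_fraction: float = 0.15            # duration of the atrial kick
    contraction_amplitude: float = 0.20      # a, peak relative shortening
    anisotropy: tuple[float, float] = (1.0, 0.8)
    translation_amplitude: tuple[float, float, float] = (16.0, -10.0, 10.0)  # mm
    rotation_amplitude_deg: float = 0.0      # optional stressor on the translation term
    respiration_rate: float = 12.0           # breaths / min
    respiration_mod_depth: float = 0.05
    center: tuple[float, float] | None = None   # mm; None -> scene centre
    n_beats: int = 5
    seed: int = 0

    def __post_init__(self):
        a = self.contraction_amplitude
        if not (0.0 <= a < 1.0):
            raise InvalidParameterError("contraction_amplitude must be in [0, 1)")
        for name in ("systole_fraction", "early_diastole_fraction", "atrial_fraction"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise InvalidParameterError(f"{name} must be in (0, 1)")
        if self.systole_fraction + self.early_diastole_fraction + self.atrial_fraction >= 1.0:
            raise InvalidParameterError("beat phase fractions must sum to < 1")
        if not (0.0 < self.early_recovery_ratio <= 1.0):
            raise InvalidParameterError("early_recovery_ratio must be in (0, 1]")
        if self.heart_rate <= 0:
            raise InvalidParameterError("heart_rate must be > 0")
        amps = (a, *self.anisotropy, *self.translation_amplitude)
        if not np.all(np.isfinite(amps)):
            raise InvalidParameterError("all amplitudes must be finite")

    @property
    def period_s(self) -> float:
        return 60.0 / self.heart_rate


def _cosine_ramp(x):
    """0 -> 1 smoothly as x goes 0 -> 1."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(x, 0.0, 1.0)))


class MotionModel:
    """Vectorized evaluation of the analytic motion; see MotionModelParams."""

    def __init__(self, params: MotionModelParams, center=None):
        self.p = params
        if params.center is not None:
            self.center = np.asarray(params.center, dtype=float)
        elif center is not None:
            self.center = np.asarray(center, dtype=float)
        else:
            self.center = np.zeros(2)

    def _unit_ramp(self, t):
        """Unit beat waveform in [0, 1]: the scale is c(t) = 1 - a * ramp(t)."""
        p = self.p
        t = np.asarray(t, dtype=float)
        tau = np.mod(t, p.period_s) / p.period_s
        fs, fe, fa = p.systole_fraction, p.early_diastole_fraction, p.atrial_fraction
        re = p.early_recovery_ratio
        plateau = 1.0 - re

        r = np.zeros_like(tau)
        m = tau < fs
        r = np.where(m, _cosine_ramp(tau / fs), r)
        m = (tau >= fs) & (tau < fs + fe)
        r = np.where(m, 1.0 - re * _cosine_ramp((tau - fs) / fe), r)
        m = (tau >= fs + fe) & (tau < 1.0 - fa)
        r = np.where(m, plateau, r)
        m = tau >= 1.0 - fa
        r = np.where(m, plateau * (1.0 - _cosine_ramp((tau - (1.0 - fa)) / fa)), r)
        return r

    def scale(self, t):
        """Cardiac scale factor c(t), periodic with the beat period, range [1-a, 1]."""
        c = 1.0 - self.p.contraction_amplitude * self._unit_ramp(t)
        return c if c.ndim else float(c)

    def waveform(self, t):
        """Beat waveform w(t) = (1 - c) / a rescaled to [0, 1]; equal to the
        unit ramp, hence well-defined also for a = 0 (pure rigid motion)."""
        w = self._unit_ramp(t)
        return w if w.ndim else float(w)

    def respiration(self, t):
        p = self.p
        t = np.asarray(t, dtype=float)
        m = 1.0 + p.respiration_mod_depth * np.sin(2.0 * np.pi * p.respiration_rate / 60.0 * t)
        return m if m.ndim else float(m)

    def stretches(self, t):
        """Effective per-axis in-plane stretch (s_x, s_y) at time(s) t."""
        p = self.p
        cm1 = (self.scale(t) - 1.0) * self.respiration(t)
        sx = 1.0 + p.anisotropy[0] * cm1
        sy = 1.0 + p.anisotropy[1] * cm1
        return np.stack([np.broadcast_to(sx, np.shape(cm1)) if np.ndim(cm1) else sx,
                         np.broadcast_to(sy, np.shape(cm1)) if np.ndim(cm1) else sy], axis=-1)

    def _rotation(self, t):
        theta = np.deg2rad(self.p.rotation_amplitude_deg) * self.waveform(t) * self.respiration(t)
        return theta

    def translation(self, t):
        """Rigid-body offset (mm): R(t) applied to the in-plane translation,
        plus the out-of-plane component; all waveform- and respiration-scaled."""
        p = self.p
        t = np.asarray(t, dtype=float)
        wm = self.waveform(t) * self.respiration(t)
        tx, ty, tz = p.translation_amplitude
        theta = self._rotation(t)
        bx = wm * (np.cos(theta) * tx - np.sin(theta) * ty)
        by = wm * (np.sin(theta) * tx + np.cos(theta) * ty)
        bz = wm * tz
        return np.stack([bx, by, bz], axis=-1)

    def displacement(self, points_mm, t: float):
        """True displacement u(X, t) in mm for material points (N, 2|3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        s = self.stretches(float(t))
        b = self.translation(float(t))
        u = np.zeros((pts.shape[0], 3))
        rel = pts[:, :2] - self.center
        u[:, 0] = (s[0] - 1.0) * rel[:, 0] + b[0]
        u[:, 1] = (s[1] - 1.0) * rel[:, 1] + b[1]
        u[:, 2] = b[2]
        if np.asarray(points_mm).ndim == 1:
            return u[0]
        return u

    def map_inplane(self, pts_mm, t: float):
        """Deformed in-plane positions of material points (N, 2)."""
        pts = np.asarray(pts_mm, dtype=float)
        s = self.stretches(float(t))
        b = self.translation(float(t))
        return (pts - self.center) * s[None, :] + self.center + b[None, :2]

    def invert_inplane(self, x_mm, t: float):
        """Material coordinates of deformed in-plane positions (N, 2)."""
        x = np.asarray(x_mm, dtype=float)
        s = self.stretches(float(t))
        b = self.translation(float(t))
        return (x - self.center - b[None, :2]) / s[None, :] + self.center

    def out_of_plane(self, t):
        return self.translation(t)[..., 2]

    def strain_tensor(self, t: float):
        """Green-Lagrange (Exx, Eyy, Exy) of the homogeneous in-plane map."""
        s = self.stretches(float(t))
        return np.array([0.5 * (s[0] ** 2 - 1.0), 0.5 * (s[1] ** 2 - 1.0), 0.0])

    def is_static(self) -> bool:
        p = self.p
        return (p.contraction_amplitude == 0.0
                and all(v == 0.0 for v in p.translation_amplitude)
                and p.rotation_amplitude_deg == 0.0)


def cardiac_scale(params: MotionModelParams, t):
    """Piecewise-cosine cardiac scale factor c(t); c(0) = 1, range [1-a, 1]."""
    if np.any(np.asarray(t) < 0):
        raise InvalidParameterError("t must be >= 0")
    return MotionModel(params).scale(t)


def true_displacement(params: MotionModelParams, point_mm, t):
    """Closed-form ground-truth displacement (ux, uy, uz) in mm."""
    model = MotionModel(params)
    return model.displacement(point_mm, float(t))


# ---------------------------------------------------------------------------
# Ground truth record
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthRecord:
    """Analytic ground truth on the tracked grid.

    ``displacements`` is (n_frames, n_points, 3) mm with u(X, 0) = 0;
    ``strain`` is the spatially constant Green-Lagrange (Exx, Eyy, Exy) per
    frame; ``extensometer_length`` is the true distance between the
    extensometer's material endpoints after deformation.
    """

    timestamps: np.ndarray            # (F,) s
    points_mm: np.ndarray             # (N, 3) material coordinates, z = 0
    displacements: np.ndarray         # (F, N, 3) mm
    strain: np.ndarray                # (F, 3): Exx, Eyy, Exy
    scale: np.ndarray                 # (F,) c(t)
    stretches: np.ndarray             # (F, 2) effective (s_x, s_y)
    extensometer_points: np.ndarray | None = None   # (2, 2) material mm
    extensometer_length: np.ndarray | None = None   # (F,) mm
    grid_px: np.ndarray | None = None               # (N, 2) reference-image px
    mm_per_px: float | None = None

    def roi_mean_length(self) -> np.ndarray:
        """Per-frame mean |u| over all ground-truth points (mm)."""
        return np.linalg.norm(self.displacements, axis=2).mean(axis=1)


def _ground_truth(model: MotionModel, timestamps, points_mm, ext_mm,
                  grid_px=None, mm_per_px=None) -> GroundTruthRecord:
    nf = len(timestamps)
    pts3 = np.zeros((points_mm.shape[0], 3))
    pts3[:, :2] = points_mm
    disp = np.zeros((nf, points_mm.shape[0], 3))
    strain = np.zeros((nf, 3))
    stretches = np.zeros((nf, 2))
    lext = None if ext_mm is None else np.zeros(nf)
    for k, t in enumerate(timestamps):
        disp[k] = model.displacement(points_mm, t)
        strain[k] = model.strain_tensor(t)
        stretches[k] = model.stretches(float(t))
        if ext_mm is not None:
            a, b = model.map_inplane(ext_mm, t)
            lext[k] = float(np.linalg.norm(a - b))
    return GroundTruthRecord(
        timestamps=np.asarray(timestamps, dtype=float),
        points_mm=pts3, displacements=disp, strain=strain,
        scale=np.asarray(model.scale(np.asarray(timestamps, dtype=float))),
        stretches=stretches,
        extensometer_points=None if ext_mm is None else np.asarray(ext_mm, dtype=float),
        extensometer_length=lext, grid_px=grid_px, mm_per_px=mm_per_px,
    )


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------


def _default_n_frames(motion: MotionModelParams, frame_rate: float) -> int:
    return int(np.ceil(motion.n_beats * motion.period_s * frame_rate)) + 1


def generate_sequence(pattern: SpecklePatternParams, motion: MotionModelParams,
                      image_size=(512, 512), mm_per_px: float = 0.1,
                      frame_rate: float = 17.0, n_frames: int | None = None,
                      bit_depth: int = 8, grid: SubsetGrid | None = None,
                      extensometer_px=None, camera_id: str = "cam0"):
    """Single-camera (fronto-parallel) sequence plus analytic ground truth.

    Pixels map to material millimetres by ``X = x_px * mm_per_px``; frames
    are rendered by inverse-mapping each pixel through the motion model at
    its timestamp and bicubically sampling a single reference speckle
    raster, so the imposed displacement is exact at every pixel centre.
    """
    w, h = int(image_size[0]), int(image_size[1])
    if w <= 0 or h <= 0 or mm_per_px <= 0 or frame_rate <= 0:
        raise InvalidParameterError("image size, mm_per_px and frame_rate must be positive")
    if n_frames is None:
        n_frames = _default_n_frames(motion, frame_rate)
    timestamps = np.arange(n_frames, dtype=float) / frame_rate

    model = MotionModel(motion, center=((w - 1) * mm_per_px / 2.0,
                                        (h - 1) * mm_per_px / 2.0))

    if grid is None:
        roi = (w // 4, h // 4, w // 2, h // 2)
        grid = SubsetGrid.from_roi(roi, (h, w), subset_size=31, step=10)
    grid_mm = grid.centers * mm_per_px
    ext_mm = None
    if extensometer_px is not None:
        ext_mm = np.asarray(extensometer_px, dtype=float) * mm_per_px

    gt = _ground_truth(model, timestamps, grid_mm, ext_mm,
                       grid_px=grid.centers, mm_per_px=mm_per_px)

    # field-of-view check on the tracked patch (grid bbox + subset margin)
    margin = grid.half * mm_per_px
    bx0, by0 = grid_mm.min(axis=0) - margin
    bx1, by1 = grid_mm.max(axis=0) + margin
    corners = np.array([[bx0, by0], [bx1, by0], [bx0, by1], [bx1, by1]])
    for k, t in enumerate(timestamps):
        mapped = model.map_inplane(corners, t) / mm_per_px
        if (mapped[:, 0].min() < 0 or mapped[:, 0].max() > w - 1
                or mapped[:, 1].min() < 0 or mapped[:, 1].max() > h - 1):
            raise OutOfViewError(k, camera_id)

    # reference raster padded to cover every inverse-mapped pixel
    img_corners = np.array([[0.0, 0.0], [(w - 1) * mm_per_px, 0.0],
                            [0.0, (h - 1) * mm_per_px],
                            [(w - 1) * mm_per_px, (h - 1) * mm_per_px]])
    lo = img_corners.min(axis=0).copy()
    hi = img_corners.max(axis=0).copy()
    for t in timestamps:
        back = model.invert_inplane(img_corners, t)
        lo = np.minimum(lo, back.min(axis=0))
        hi = np.maximum(hi, back.max(axis=0))
    pad_mm = (3.0 * pattern.blur_sigma + 4.0) * mm_per_px
    pad_px = int(np.ceil(max(np.max(img_corners.min(axis=0) - lo + pad_mm),
                             np.max(hi - img_corners.max(axis=0) + pad_mm)) / mm_per_px))
    origin = np.array([-pad_px * mm_per_px, -pad_px * mm_per_px])
    raster_shape = (h + 2 * pad_px, w + 2 * pad_px)
    sf = SpeckleField(pattern, (origin[0], origin[1],
                                origin[0] + raster_shape[1] * mm_per_px,
                                origin[1] + raster_shape[0] * mm_per_px))
    raster = sf.rasterize(origin, raster_shape, mm_per_px)

    rng_noise = np.random.default_rng([int(pattern.seed), int(motion.seed), 0xA03])
    frames = np.empty((n_frames, h, w), dtype=np.uint8 if bit_depth == 8 else np.uint16)

    if model.is_static():
        base = raster[pad_px:pad_px + h, pad_px:pad_px + w]
        for k in range(n_frames):
            img = base
            if pattern.noise_sigma > 0:
                img = img + rng_noise.normal(0.0, pattern.noise_sigma, img.shape)
            frames[k] = _quantize(img, bit_depth)
    else:
        interp = BicubicImage(raster)
        jj, ii = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        pix_mm = np.column_stack([jj.ravel() * mm_per_px, ii.ravel() * mm_per_px])
        for k, t in enumerate(timestamps):
            mat = model.invert_inplane(pix_mm, t)
            xs = (mat[:, 0] - origin[0]) / mm_per_px
            ys = (mat[:, 1] - origin[1]) / mm_per_px
            img = interp.sample(xs, ys).reshape(h, w)
            if pattern.noise_sigma > 0:
                img = img + rng_noise.normal(0.0, pattern.noise_sigma, img.shape)
            frames[k] = _quantize(img, bit_depth)

    seq = ImageSequence(frames=frames, frame_rate=frame_rate,
                        bit_depth=bit_depth, camera_id=camera_id)
    return seq, gt


def _plane_homography(cam: CameraModel, z_mm: float) -> np.ndarray:
    """World plane (X, Y, z_mm) -> pixel homography."""
    p = cam.projection
    return np.column_stack([p[:, 0], p[:, 1], z_mm * p[:, 2] + p[:, 3]])


def _apply_h(hmat: np.ndarray, pts: np.ndarray) -> np.ndarray:
    q = np.column_stack([pts, np.ones(pts.shape[0])]) @ hmat.T
    return q[:, :2] / q[:, [2]]


def generate_stereo_sequences(pattern: SpecklePatternParams, motion: MotionModelParams,
                              cams: tuple[CameraModel, CameraModel],
                              n_frames: int, frame_rate: float,
                              mm_per_px: float = 0.1, bit_depth: int = 8,
                              grid: SubsetGrid | None = None,
                              extensometer_px=None):
    """Render the deforming surface through two calibrated pinhole cameras.

    The material surface is the world X-Y plane; out-of-plane motion moves
    it rigidly along world Z.  Each frame of each camera is rendered by
    back-projecting every pixel onto the instantaneous plane, inverting the
    in-plane motion, and bicubically sampling one shared reference speckle
    raster.  The ground truth (and optional extensometer) lives on the grid
    defined in camera 1's reference image, so the tracker and the truth use
    the same material points.

    Returns ``(sequence_cam1, sequence_cam2, GroundTruthRecord)``.
    """
    cam1, cam2 = cams
    if cam1.image_size is None or cam2.image_size is None:
        raise InvalidParameterError("cameras must carry image_size")
    if n_frames < 1 or frame_rate <= 0:
        raise InvalidParameterError("n_frames and frame_rate must be positive")
    timestamps = np.arange(n_frames, dtype=float) / frame_rate

    w1, h1 = cam1.image_size
    h0 = _plane_homography(cam1, 0.0)
    h0_inv = np.linalg.inv(h0)

    # scene centre: back-projection of camera 1's image centre at rest
    centre = _apply_h(h0_inv, np.array([[(w1 - 1) / 2.0, (h1 - 1) / 2.0]]))[0]
    model = MotionModel(motion, center=centre)

    if grid is None:
        roi = (w1 // 4, h1 // 4, w1 // 2, h1 // 2)
        grid = SubsetGrid.from_roi(roi, (h1, w1), subset_size=31, step=10)
    grid_mm = _apply_h(h0_inv, grid.centers)
    ext_mm = None
    if extensometer_px is not None:
        ext_mm = _apply_h(h0_inv, np.asarray(extensometer_px, dtype=float))

    gt = _ground_truth(model, timestamps, grid_mm, ext_mm,
                       grid_px=grid.centers, mm_per_px=mm_per_px)

    # patch corners (material mm) for the field-of-view check
    margin = grid.half * mm_per_px
    bx0, by0 = grid_mm.min(axis=0) - margin
    bx1, by1 = grid_mm.max(axis=0) + margin
    patch = np.array([[bx0, by0], [bx1, by0], [bx0, by1], [bx1, by1]])

    # pattern raster domain: union of back-projected image corners over frames
    lo = np.full(2, np.inf)
    hi = np.full(2, -np.inf)
    for ci, cam in enumerate((cam1, cam2)):
        w, h = cam.image_size
        corners_px = np.array([[0.0, 0.0], [w - 1.0, 0.0], [0.0, h - 1.0], [w - 1.0, h - 1.0]])
        for k, t in enumerate(timestamps):
            z = float(model.out_of_plane(t))
            hinv = np.linalg.inv(_plane_homography(cam, z))
            world = _apply_h(hinv, corners_px)
            mat = model.invert_inplane(world, t)
            lo = np.minimum(lo, mat.min(axis=0))
            hi = np.maximum(hi, mat.max(axis=0))
            # out-of-view check: deformed patch must project inside the image
            mapped = model.map_inplane(patch, t)
            world3 = np.column_stack([mapped, np.full(4, z)])
            px = reproject(cam, world3)
            if (px[:, 0].min() < 0 or px[:, 0].max() > w - 1
                    or px[:, 1].min() < 0 or px[:, 1].max() > h - 1):
                raise OutOfViewError(k, f"cam{ci + 1}")

    pad_mm = (3.0 * pattern.blur_sigma + 4.0) * mm_per_px
    x0, y0 = lo - pad_mm
    x1, y1 = hi + pad_mm
    rw = int(np.ceil((x1 - x0) / mm_per_px)) + 1
    rh = int(np.ceil((y1 - y0) / mm_per_px)) + 1
    sf = SpeckleField(pattern, (x0, y0, x0 + rw * mm_per_px, y0 + rh * mm_per_px))
    raster = sf.rasterize((x0, y0), (rh, rw), mm_per_px)
    interp = BicubicImage(raster)

    seqs = []
    for ci, cam in enumerate((cam1, cam2)):
        w, h = cam.image_size
        rng_noise = np.random.default_rng([int(pattern.seed), int(motion.seed), 0xB0, ci])
        frames = np.empty((n_frames, h, w), dtype=np.uint8 if bit_depth == 8 else np.uint16)
        jj, ii = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        px_flat = np.column_stack([jj.ravel(), ii.ravel()])
        for k, t in enumerate(timestamps):
            z = float(model.out_of_plane(t))
            hinv = np.linalg.inv(_plane_homography(cam, z))
            world = _apply_h(hinv, px_flat)
            mat = model.invert_inplane(world, t)
            xs = (mat[:, 0] - x0) / mm_per_px
            ys = (mat[:, 1] - y0) / mm_per_px
            img = interp.sample(xs, ys).reshape(h, w)
            if pattern.noise_sigma > 0:
                img = img + rng_noise.normal(0.0, pattern.noise_sigma, img.shape)
            frames[k] = _quantize(img, bit_depth)
        seqs.append(ImageSequence(frames=frames, frame_rate=frame_rate,
                                  bit_depth=bit_depth, camera_id=f"cam{ci + 1}"))

    return seqs[0], seqs[1], gt


# ---------------------------------------------------------------------------
# Calibration views
# ---------------------------------------------------------------------------


def default_calibration_target(n_points: int = 20, extent_mm=(60.0, 60.0, 30.0),
                               center=(0.0, 0.0, 200.0), seed: int = 0) -> np.ndarray:
    """Random non-coplanar 3D point cloud standing in for a machined target."""
    rng = np.random.default_rng([int(seed), 0xCA11])
    ext = np.asarray(extent_mm, dtype=float)
    pts = rng.uniform(-0.5, 0.5, size=(int(n_points), 3)) * ext + np.asarray(center, dtype=float)
    return pts


def render_calibration_views(world_points, cams, pixel_noise_sigma: float = 0.0,
                             seed: int = 0) -> pd.DataFrame:
    """Project a 3D target through each camera, optionally with pixel noise.

    Returns a correspondence table with one row per world point and columns
    ``point_id, X_mm, Y_mm, Z_mm, cam<i>_x_px, cam<i>_y_px``.  Noise-free
    rows satisfy each camera's projection exactly.
    """
    world = np.asarray(world_points, dtype=float)
    _check_target_geometry(world)
    rng = np.random.default_rng([int(seed), 0xCA1B])
    data = {
        "point_id": np.arange(world.shape[0]),
        "X_mm": world[:, 0], "Y_mm": world[:, 1], "Z_mm": world[:, 2],
    }
    for i, cam in enumerate(cams):
        px = reproject(cam, world)
        if pixel_noise_sigma > 0:
            px = px + rng.normal(0.0, pixel_noise_sigma, px.shape)
        data[f"cam{i + 1}_x_px"] = px[:, 0]
        data[f"cam{i + 1}_y_px"] = px[:, 1]
    return pd.DataFrame(data)
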