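"""Cardiac kinematics from tracked displacement fields.

Converts a per-frame displacement field into the clinical descriptors used
for ventricular monitoring: ROI-averaged displacement components and vector
length, principal surface strains, tissue velocity with its TVs/TVe/TVa
characteristic points, per-beat segmentation and stitching, virtual
extensometer length, fractional shortening, and strain / strain rate with
SRs/SRe/SRa and the per-beat peak strain Ss.

Sign conventions follow the imaging frame: x rightward, y downward, so
leftward systolic motion appears as negative V_x-type values; tissue
velocity is the signed rate of change of the displacement-vector length
(positive while |u| grows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .dic import DisplacementField

logger = logging.getLogger(__name__)

MIN_VALID_ROI_FRACTION = 0.25   # below this, a frame's ROI statistic is missing
DEFAULT_SMOOTHING_WINDOW = 5    # samples, local quadratic smoothing
DEFAULT_MIN_BEAT_S = 0.4
DEFAULT_PROMINENCE_FRAC = 0.3


class MetricsError(Exception):
    pass


class SegmentationError(MetricsError):
    pass


class StitchingGapError(MetricsError):
    pass


class InvalidWindowError(MetricsError):
    pass


class InvalidDimensionError(MetricsError):
    pass


class InvalidLengthError(MetricsError):
    pass


class ExtensometerError(MetricsError):
    pass


# ---------------------------------------------------------------------------
# Definitions and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROIDef:
    """Rectangle in reference-image pixels: (x0, y0, width, height)."""

    x0: float
    y0: float
    width: float
    height: float

    def contains(self, points_px: np.ndarray) -> np.ndarray:
        x, y = points_px[:, 0], points_px[:, 1]
        return ((x >= self.x0) & (x <= self.x0 + self.width)
                & (y >= self.y0) & (y <= self.y0 + self.height))


@dataclass(frozen=True)
class ExtensometerDef:
    """Virtual extensometer endpoints in reference-image pixels."""

    p1: tuple[float, float]
    p2: tuple[float, float]

    def __post_init__(self):
        if np.allclose(self.p1, self.p2):
            raise InvalidDimensionError("extensometer endpoints must be distinct")

    @property
    def endpoints(self) -> np.ndarray:
        return np.array([self.p1, self.p2], dtype=float)


@dataclass
class Trace:
    """Uniformly sampled scalar time series with per-sample dispersion.

    Missing samples are NaN (e.g. frames where too few ROI points were
    valid); they are carried, never interpolated silently.
    """

    values: np.ndarray
    timestamps: np.ndarray
    dispersion: np.ndarray | None = None
    label: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.dispersion is None:
            self.dispersion = np.zeros_like(self.values)
        else:
            self.dispersion = np.asarray(self.dispersion, dtype=float)
        if not (len(self.values) == len(self.timestamps) == len(self.dispersion)):
            raise ValueError("values/timestamps/dispersion lengths differ")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.timestamps)))

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BeatSegmentation:
    """Half-open frame intervals, one per complete heartbeat."""

    intervals: list[tuple[int, int]]
    prominences: np.ndarray | None = None

    def __post_init__(self):
        for (s0, e0), (s1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValueError("beat intervals must be ordered and non-overlapping")

    @property
    def n_beats(self) -> int:
        return len(self.intervals)


@dataclass
class CharPoint:
    value: float
    frame: int


@dataclass
class CharacteristicPoints:
    """Per-beat clinical characteristic points.

    Tissue-velocity entries are in cm/s, strain-rate entries in 1/s, and
    ``s_s`` (per-beat peak-to-peak strain) in percent.  A missing point
    (e.g. no atrial kick) is None, never an invented number.
    """

    tv_s: list = dc_field(default_factory=list)
    tv_e: list = dc_field(default_factory=list)
    tv_a: list = dc_field(default_factory=list)
    sr_s: list = dc_field(default_factory=list)
    sr_e: list = dc_field(default_factory=list)
    sr_a: list = dc_field(default_factory=list)
    s_s: list = dc_field(default_factory=list)
    flags: list = dc_field(default_factory=list)


@dataclass
class StrainSummary:
    """Per-frame principal-strain statistics over the grid.

    ``e_max``/``e_min`` are engineering principal strains in percent,
    derived from the principal stretches of the Green-Lagrange tensor of a
    windowed least-squares displacement gradient; e_max >= e_min everywhere
    and both vanish at the reference frame.
    """

    timestamps: np.ndarray
    e_max_mean: np.ndarray
    e_min_mean: np.ndarray
    e_max_std: np.ndarray
    e_min_std: np.ndarray
    tensor_mean: np.ndarray          # (F, 3): Exx, Eyy, Exy (dimensionless)
    point_e_max: np.ndarray          # (F, N) %
    point_e_min: np.ndarray          # (F, N) %
    valid: np.ndarray                # (F, N)


# ---------------------------------------------------------------------------
# ROI traces
# ---------------------------------------------------------------------------


def roi_traces(field: DisplacementField, roi: ROIDef) -> dict[str, Trace]:
    """ROI-mean displacement components and vector length, with spatial std.

    The vector length V_l is computed per point and then averaged (it is not
    the length of the mean vector).  Frames where fewer than 25% of the
    ROI's points are valid are reported missing (NaN).
    """
    inside = roi.contains(field.grid.centers)
    if inside.sum() < 4:
        raise ValueError("ROI must contain at least 4 grid points")
    u = field.displacements_mm()[:, inside, :]
    valid = field.valid[:, inside]
    nf, n, ncomp = u.shape

    comp_labels = ["V_x", "V_y", "V_z"][:ncomp]
    means = np.full((nf, ncomp + 1), np.nan)
    stds = np.full((nf, ncomp + 1), np.nan)
    for k in range(nf):
        m = valid[k]
        if m.sum() < max(1, MIN_VALID_ROI_FRACTION * n):
            logger.warning("roi_traces: frame %d has too few valid ROI points", k)
            continue
        uk = u[k, m, :]
        vl = np.linalg.norm(uk, axis=1)
        means[k, :ncomp] = uk.mean(axis=0)
        stds[k, :ncomp] = uk.std(axis=0)
        means[k, ncomp] = vl.mean()
        stds[k, ncomp] = vl.std()

    out = {}
    for i, lab in enumerate(comp_labels):
        out[lab] = Trace(means[:, i], field.timestamps, stds[:, i], label=lab, units="mm")
    out["V_l"] = Trace(means[:, ncomp], field.timestamps, stds[:, ncomp],
                       label="V_l", units="mm")
    return out


# ---------------------------------------------------------------------------
# Beat segmentation and stitching
# ---------------------------------------------------------------------------


def segment_beats(v_l: Trace, min_beat_s: float = DEFAULT_MIN_BEAT_S,
                  prominence_frac: float = DEFAULT_PROMINENCE_FRAC) -> BeatSegmentation:
    """Delimit heartbeats at prominent local minima of the V_l trace.

    Beat boundaries sit at local minima of V_l (the maximally dilated
    state, where the surface is closest to its reference configuration)
    whose prominence exceeds ``prominence_frac`` of the trace's range.
    Partial head/tail beats are excluded by construction: only intervals
    between two detected minima are returned.
    """
    vals = v_l.values
    finite = np.isfinite(vals)
    if finite.sum() < 4:
        raise SegmentationError("trace too short or too sparse to segment")
    work = vals.copy()
    if not finite.all():
        work[~finite] = np.interp(np.flatnonzero(~finite),
                                  np.flatnonzero(finite), vals[finite])
    rng = float(np.max(work) - np.min(work))
    if rng <= 0:
        raise SegmentationError("constant trace: no beat structure to segment")
    distance = max(1, int(round(min_beat_s / v_l.dt)))
    minima, props = find_peaks(-work, prominence=prominence_frac * rng, distance=distance)
    if len(minima) < 2:
        raise SegmentationError(
            f"no qualifying beat boundaries (found {len(minima)} minima; "
            f"prominence threshold {prominence_frac * rng:.3g}, "
            f"min separation {distance} frames)"
        )
    intervals = [(int(s), int(e)) for s, e in zip(minima[:-1], minima[1:])]
    return BeatSegmentation(intervals=intervals, prominences=props.get("prominences"))


def stitch_beats(per_beat_fields: list[DisplacementField]) -> DisplacementField:
    """Join per-beat fields into one series referenced to the global start.

    Each beat's field is referenced to its own first frame; beat k is offset
    by the accumulated end displacement of the beats before it.  Beats must
    be temporally contiguous (adjacent frames, or sharing the boundary
    frame, in which case the duplicate is dropped).
    """
    if not per_beat_fields:
        raise ValueError("no beats to stitch")
    if len(per_beat_fields) == 1:
        return per_beat_fields[0]
    first = per_beat_fields[0]
    n = first.n_points
    dt = float(np.mean(np.diff(first.timestamps)))

    us = [first.u.copy()]
    ts = [first.timestamps.copy()]
    vs = [first.valid.copy()]
    qs = [first.zncc.copy()]
    offset = np.zeros((n, first.n_components))
    carry_valid = np.ones(n, dtype=bool)
    for prev, cur in zip(per_beat_fields, per_beat_fields[1:]):
        if cur.n_points != n:
            raise StitchingGapError("beats do not share a grid")
        gap = cur.timestamps[0] - prev.timestamps[-1]
        if abs(gap) < 1e-9 * max(1.0, dt):
            skip = 1          # shared boundary frame
        elif abs(gap - dt) < 1e-9 + 1e-6 * dt:
            skip = 0
        else:
            raise StitchingGapError(
                f"beats are not contiguous: gap of {gap:.6g} s at t={cur.timestamps[0]:.6g}"
            )
        offset = offset + prev.u[-1]
        carry_valid = carry_valid & prev.valid[-1]
        us.append(cur.u[skip:] + offset[None, :, :])
        ts.append(cur.timestamps[skip:])
        vs.append(cur.valid[skip:] & carry_valid[None, :])
        qs.append(cur.zncc[skip:])

    return DisplacementField(
        grid=first.grid, u=np.concatenate(us), valid=np.concatenate(vs),
        zncc=np.concatenate(qs), timestamps=np.concatenate(ts),
        units=first.units, mm_per_px=first.mm_per_px,
        reference_frame=first.reference_frame,
        accumulation_mode=first.accumulation_mode, ref_mm=first.ref_mm,
    )


# ---------------------------------------------------------------------------
# Tissue velocity
# ---------------------------------------------------------------------------


def _smooth_derivative(values: np.ndarray, dt: float, window: int) -> np.ndarray:
    """Local-quadratic (Savitzky-Golay) smoothing, then central differences
    with one-sided endpoints."""
    if window % 2 == 0:
        raise InvalidWindowError("smoothing window must be odd")
    if window >= len(values):
        raise InvalidWindowError(
            f"smoothing window ({window}) must be shorter than the trace ({len(values)})"
        )
    if window >= 3:
        sm = savgol_filter(values, window, polyorder=2, mode="interp")
    else:
        sm = values
    return np.gradient(sm, dt)


def tissue_velocity(v_l: Trace, smoothing_window: int = DEFAULT_SMOOTHING_WINDOW) -> Trace:
    """Signed rate of change of the displacement-vector length, in cm/s."""
    vals = v_l.values
    finite = np.isfinite(vals)
    work = vals.copy()
    if not finite.all():
        work[~finite] = np.interp(np.flatnonzero(~finite),
                                  np.flatnonzero(finite), vals[finite])
    deriv_mm_s = _smooth_derivative(work, v_l.dt, smoothing_window)
    deriv_mm_s[~finite] = np.nan
    disp = None
    if v_l.dispersion is not None:
        # central-difference noise propagation of the spatial scatter
        disp = v_l.dispersion * np.sqrt(2.0) / (2.0 * v_l.dt) / 10.0
    return Trace(deriv_mm_s / 10.0, v_l.timestamps, disp,
                 label="tissue_velocity", units="cm/s")


def detect_tv_points(tv: Trace, beats: BeatSegmentation) -> CharacteristicPoints:
    """Per-beat TVs/TVe/TVa detection.

    TVe is the most negative velocity in the beat, TVs the most positive;
    TVa is the most negative interior local minimum strictly between TVe
    and TVs (in the detected ordering).  A beat with no atrial kick gets
    ``tv_a = None``; a monotone beat is flagged as a detection failure.
    """
    cp = CharacteristicPoints()
    finite = np.isfinite(tv.values)
    work = tv.values.copy()
    if finite.any() and not finite.all():
        work[~finite] = np.interp(np.flatnonzero(~finite),
                                  np.flatnonzero(finite), tv.values[finite])
    all_minima, _ = find_peaks(-work)   # full-trace minima so beat edges count
    for s, e in beats.intervals:
        seg = tv.values[s:e]
        if len(seg) < 5 or not np.isfinite(seg).all():
            cp.tv_s.append(None); cp.tv_e.append(None); cp.tv_a.append(None)
            cp.flags.append("insufficient-samples")
            continue
        d = np.diff(seg)
        if np.all(d >= 0) or np.all(d <= 0):
            cp.tv_s.append(None); cp.tv_e.append(None); cp.tv_a.append(None)
            cp.flags.append("monotone")
            continue
        i_s = int(np.argmax(seg))
        i_e = int(np.argmin(seg))
        cp.tv_s.append(CharPoint(float(seg[i_s]), s + i_s))
        cp.tv_e.append(CharPoint(float(seg[i_e]), s + i_e))
        # TV_a: most negative local minimum strictly between TV_e and TV_s
        # in the detected ordering (wrapping to the beat's end when TV_s
        # precedes TV_e in time)
        lo = s + i_e + 1
        hi = s + i_s if i_s > i_e else e
        cand = all_minima[(all_minima >= lo) & (all_minima < hi)]
        tva = None
        if len(cand):
            j = cand[np.argmin(work[cand])]
            tva = CharPoint(float(work[j]), int(j))
        cp.tv_a.append(tva)
        cp.flags.append("ok" if tva is not None else "no-atrial-kick")
    return cp


# ---------------------------------------------------------------------------
# Strain field
# ---------------------------------------------------------------------------


def _principal_from_tensor(exx, eyy, exy):
    """Principal Green-Lagrange values -> engineering principal strains (%)."""
    mid = 0.5 * (exx + eyy)
    rad = np.sqrt((0.5 * (exx - eyy)) ** 2 + exy ** 2)
    e1 = mid + rad
    e2 = mid - rad
    lam1 = np.sqrt(np.clip(1.0 + 2.0 * e1, 0.0, None))
    lam2 = np.sqrt(np.clip(1.0 + 2.0 * e2, 0.0, None))
    return (lam1 - 1.0) * 100.0, (lam2 - 1.0) * 100.0


def local_strain_field(field: DisplacementField, window_points: int = 5,
                       ref_frame: int | None = None) -> StrainSummary:
    """Green-Lagrange surface strain from a windowed least-squares gradient.

    For every grid point, the in-plane deformation gradient F is fitted over
    a ``window_points``-wide lattice neighborhood by least squares on the
    positions relative to ``ref_frame`` (default: the field's reference);
    E = (F^T F - I) / 2, and the reported principal strains are the
    principal stretches minus one, in percent — finite-strain correct and
    exactly zero under rigid motion.
    """
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    if field.grid.shape is None:
        raise ValueError("strain needs a lattice grid (SubsetGrid.from_roi)")
    rows, cols = field.grid.shape
    if rows < 3 or cols < 3:
        raise ValueError("strain needs at least a 3x3 grid")
    r = ref_frame if ref_frame is not None else field.reference_frame

    pos = field.positions_mm()[:, :, :2]
    ref = pos[r]
    nf, n, _ = pos.shape
    halfw = window_points // 2

    idx = np.arange(n).reshape(rows, cols)
    neighbors = []
    for i in range(rows):
        for j in range(cols):
            i0, i1 = max(i - halfw, 0), min(i + halfw + 1, rows)
            j0, j1 = max(j - halfw, 0), min(j + halfw + 1, cols)
            neighbors.append(idx[i0:i1, j0:j1].ravel())

    point_e_max = np.full((nf, n), np.nan)
    point_e_min = np.full((nf, n), np.nan)
    tensors = np.full((nf, n, 3), np.nan)
    valid = np.zeros((nf, n), dtype=bool)

    pinvs = []
    for nb in neighbors:
        a = np.column_stack([np.ones(len(nb)), ref[nb, 0], ref[nb, 1]])
        if len(nb) < 3 or np.linalg.matrix_rank(a) < 3:
            pinvs.append(None)
        else:
            pinvs.append(np.linalg.pinv(a))

    base_ok = field.valid[r]
    for k in range(nf):
        okk = field.valid[k] & base_ok
        for p, (nb, pinv) in enumerate(zip(neighbors, pinvs)):
            if pinv is None or not okk[nb].all():
                continue
            coef = pinv @ pos[k, nb, :]          # (3, 2): [const; d/dX; d/dY]
            f_t = coef[1:, :].T                  # rows: (dx/dX, dx/dY), (dy/dX, dy/dY)
            e = 0.5 * (f_t.T @ f_t - np.eye(2))
            tensors[k, p] = (e[0, 0], e[1, 1], e[0, 1])
            emax, emin = _principal_from_tensor(e[0, 0], e[1, 1], e[0, 1])
            point_e_max[k, p] = emax
            point_e_min[k, p] = emin
            valid[k, p] = True

    with np.errstate(invalid="ignore"):
        e_max_mean = np.nanmean(point_e_max, axis=1)
        e_min_mean = np.nanmean(point_e_min, axis=1)
        e_max_std = np.nanstd(point_e_max, axis=1)
        e_min_std = np.nanstd(point_e_min, axis=1)
        tensor_mean = np.nanmean(tensors, axis=1)
    return StrainSummary(
        timestamps=field.timestamps, e_max_mean=e_max_mean, e_min_mean=e_min_mean,
        e_max_std=e_max_std, e_min_std=e_min_std, tensor_mean=tensor_mean,
        point_e_max=point_e_max, point_e_min=point_e_min, valid=valid,
    )


# ---------------------------------------------------------------------------
# Virtual extensometer
# ---------------------------------------------------------------------------


def _idw_endpoint(field: DisplacementField, endpoint_px, radius_px: float):
    """Inverse-distance-weighted interpolation of reference position and
    displacement at one endpoint; returns (ref_mm, u_mm (F, C), ok (F,))."""
    centers = field.grid.centers
    d = np.hypot(centers[:, 0] - endpoint_px[0], centers[:, 1] - endpoint_px[1])
    sel = np.flatnonzero(d <= radius_px)
    if sel.size < 3:
        raise ExtensometerError(
            f"extensometer endpoint {tuple(endpoint_px)} has only {sel.size} "
            f"grid points within {radius_px:.1f} px (need >= 3)"
        )
    w = 1.0 / (d[sel] ** 2 + 1e-12)
    u = field.displacements_mm()[:, sel, :]
    ok_pts = field.valid[:, sel]
    nf = field.n_frames
    out = np.full((nf, u.shape[2]), np.nan)
    ok = np.zeros(nf, dtype=bool)
    ref_all = field.ref_mm[sel]
    ref = (ref_all * w[:, None]).sum(axis=0) / w.sum()
    for k in range(nf):
        m = ok_pts[k]
        if m.sum() < 3:
            continue
        wk = w[m]
        out[k] = (u[k, m, :] * wk[:, None]).sum(axis=0) / wk.sum()
        ok[k] = True
    return ref, out, ok


def extensometer_length(field: DisplacementField, ext: ExtensometerDef,
                        radius_steps: float = 2.5) -> Trace:
    """Tracked distance between the extensometer's material endpoints (mm).

    Endpoint displacements are inverse-distance-weighted interpolations of
    the surrounding grid points (3D when the field is triangulated); frames
    where an endpoint has fewer than 3 valid supporting points are gaps.
    """
    radius = radius_steps * field.grid.step
    r1, u1, ok1 = _idw_endpoint(field, ext.endpoints[0], radius)
    r2, u2, ok2 = _idw_endpoint(field, ext.endpoints[1], radius)
    p1 = r1[None, :] + u1
    p2 = r2[None, :] + u2
    length = np.linalg.norm(p2 - p1, axis=1)
    length[~(ok1 & ok2)] = np.nan
    if np.isnan(length).any():
        logger.warning("extensometer_length: %d gap frames", int(np.isnan(length).sum()))
    return Trace(length, field.timestamps, label="extensometer_length", units="mm")


def fractional_shortening(l: Trace, beats: BeatSegmentation) -> Trace:
    """FS(t) = (1 - L(t)/L_max) x 100, normalized per heartbeat.

    L_max is the maximum extensometer length within each beat (the maximally
    dilated state), so FS is in [0, 100) and attains 0 inside every beat.
    Frames outside the segmented beats are NaN.
    """
    fs = np.full(len(l), np.nan)
    disp = np.full(len(l), np.nan)
    for s, e in beats.intervals:
        seg = l.values[s:e]
        if not np.isfinite(seg).any():
            continue
        lmax = np.nanmax(seg)
        if not (lmax > 0):
            raise InvalidLengthError(f"non-positive L_max in beat [{s},{e})")
        fs[s:e] = (1.0 - seg / lmax) * 100.0
        if l.dispersion is not None:
            disp[s:e] = l.dispersion[s:e] / lmax * 100.0
    return Trace(fs, l.timestamps, disp, label="FS", units="%")


def fs_conventional(lvedd: float, lvesd: float) -> float:
    """Conventional fractional shortening (LVEDD - LVESD) / LVEDD x 100 (%)."""
    if not (lvedd > 0):
        raise InvalidDimensionError("LVEDD must be positive")
    if not (0 <= lvesd <= lvedd):
        raise InvalidDimensionError("LVESD must satisfy 0 <= LVESD <= LVEDD")
    return (lvedd - lvesd) / lvedd * 100.0


# ---------------------------------------------------------------------------
# Strain and strain rate
# ---------------------------------------------------------------------------


def strain_and_rate(l: Trace, beats: BeatSegmentation,
                    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW):
    """Extensometer engineering strain, its rate, and SR characteristic points.

    Strain is (L - L_ref)/L_ref x 100 with L_ref the per-beat maximum length
    (so strain <= 0, dipping through systole); strain rate is the smoothed
    derivative of strain/100 in 1/s, computed per beat.  Per beat, SRs is
    the negative extremum, SRe the first positive local maximum (early
    relaxation), SRa the second (atrial kick), and Ss the peak-to-peak
    strain.

    Returns ``(strain Trace %, strain-rate Trace 1/s, CharacteristicPoints)``.
    """
    strain = np.full(len(l), np.nan)
    rate = np.full(len(l), np.nan)
    cp = CharacteristicPoints()
    for s, e in beats.intervals:
        seg = l.values[s:e]
        if not np.isfinite(seg).all():
            cp.sr_s.append(None); cp.sr_e.append(None); cp.sr_a.append(None)
            cp.s_s.append(None); cp.flags.append("gap")
            continue
        lref = np.max(seg)
        if not (lref > 0):
            raise InvalidLengthError(f"non-positive reference length in beat [{s},{e})")
        st = (seg - lref) / lref * 100.0
        strain[s:e] = st
        rt = _smooth_derivative(st / 100.0, l.dt, smoothing_window)
        rate[s:e] = rt

        i_srs = int(np.argmin(rt))
        cp.sr_s.append(CharPoint(float(rt[i_srs]), s + i_srs))
        peaks, _ = find_peaks(rt)
        peaks = [int(p) for p in peaks if rt[p] > 0]
        # the atrial ramp ends at the beat boundary, so its rate peak may
        # land on the last sample of the beat; accept a rising positive
        # endpoint as a candidate
        last = len(rt) - 1
        if rt[last] > 0 and rt[last] > rt[last - 1] and last not in peaks:
            peaks.append(last)
        cp.sr_e.append(CharPoint(float(rt[peaks[0]]), s + int(peaks[0])) if len(peaks) >= 1 else None)
        cp.sr_a.append(CharPoint(float(rt[peaks[1]]), s + int(peaks[1])) if len(peaks) >= 2 else None)
        cp.s_s.append(float(np.max(st) - np.min(st)))
        cp.flags.append("ok" if len(peaks) >= 2 else "missing-sr-peak")

    strain_tr = Trace(strain, l.timestamps, label="strain", units="%")
    rate_tr = Trace(rate, l.timestamps, label="strain_rate", units="1/s")
    return strain_tr, rate_tr, cp


def directional_strains(field: DisplacementField, ext: ExtensometerDef,
                        radius_steps: float = 2.5):
    """Engineering strains along and perpendicular to the extensometer (%).

    The longitudinal strain tracks the extensometer itself; the horizontal
    strain tracks a virtual extensometer of equal initial length through the
    midpoint, perpendicular in the image plane.  If the perpendicular line
    exits the tracked grid it is shortened symmetrically (with a logged
    warning) until both endpoints are supported.
    """
    def line_strain(e: ExtensometerDef) -> Trace:
        length = extensometer_length(field, e, radius_steps)
        l0 = length.values[field.reference_frame]
        vals = (length.values - l0) / l0 * 100.0
        return Trace(vals, length.timestamps, label="strain", units="%")

    pts = ext.endpoints
    longitudinal = line_strain(ext)
    longitudinal.label = "longitudinal_strain"

    mid = pts.mean(axis=0)
    direction = pts[1] - pts[0]
    half_len = 0.5 * np.linalg.norm(direction)
    perp = np.array([-direction[1], direction[0]]) / (2.0 * half_len)

    centers = field.grid.centers
    xmin, ymin = centers.min(axis=0)
    xmax, ymax = centers.max(axis=0)

    def supported(h):
        for sgn in (-1.0, 1.0):
            p = mid + sgn * h * perp
            if not (xmin <= p[0] <= xmax and ymin <= p[1] <= ymax):
                return False
        return True

    h = half_len
    while h > 0.2 * half_len and not supported(h):
        h *= 0.9
    if h < half_len:
        logger.warning(
            "directional_strains: perpendicular line shortened from %.1f to %.1f px",
            2 * half_len, 2 * h,
        )
    horiz_ext = ExtensometerDef(tuple(mid - h * perp), tuple(mid + h * perp))
    horizontal = line_strain(horiz_ext)
    horizontal.label = "horizontal_strain"
    return longitudinal, horizontal
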