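"""Dual-view 3D reconstruction with flat-interface refraction correction.

The rig is one pinhole camera in front of the tank plus a planar overhead
mirror, so a single image holds two views: the *front* view (direct) and
the *top* view (via the mirror).  The mirror is handled by reflecting the
camera across the mirror plane, which turns the top view into a second
(virtual) pinhole camera above the tank.  Each view sees the fish through
exactly one flat air/water interface — the transparent front wall (plane
y = 0) for the front view, the water surface (plane z = water level) for
the top view — and light bends there per Snell's law.  Glass thickness is
ignored (a single air→water interface per view).

Forward projection solves the planar-refraction (Fermat) problem for the
interface crossing point by bisection; reconstruction back-projects each
pixel into an in-water ray and triangulates by the midpoint of the common
perpendicular.  Both directions share the same optical model, so a
noise-free project→reconstruct round trip recovers positions to well below
0.1 mm.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .core import ContainerGeometry, Trajectory3D, ValidationError

__all__ = [
    "OpticalModel",
    "DualViewDetections",
    "TotalInternalReflectionError",
    "refract_direction",
    "project_to_views",
    "reconstruct_trajectory",
    "despike_filter",
]

logger = logging.getLogger(__name__)


class TotalInternalReflectionError(ValueError):
    """The ray cannot cross the interface; the geometry is invalid for tracking."""


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValidationError("zero-length direction vector")
    return v / n


def refract_direction(
    incident: np.ndarray,
    surface_normal: np.ndarray,
    n_from: float,
    n_to: float,
) -> np.ndarray:
    """Bend unit direction(s) across a flat interface by the vector Snell law.

    ``incident`` points *toward* the interface.  The normal's orientation is
    irrelevant (it is flipped internally to oppose the incident ray).  Works
    on a single vector or an (n, 3) stack.

    Raises
    ------
    TotalInternalReflectionError
        If any ray is beyond the critical angle.
    """
    d = np.asarray(incident, dtype=float)
    single = d.ndim == 1
    d = np.atleast_2d(d)
    n = np.atleast_2d(np.asarray(surface_normal, dtype=float))
    n = np.broadcast_to(n, d.shape).copy()

    # orient the normal against the incident ray
    cos_i = -np.sum(d * n, axis=1)
    flip = cos_i < 0
    n[flip] *= -1.0
    cos_i = np.abs(cos_i)

    eta = n_from / n_to
    sin2_t = eta * eta * (1.0 - cos_i * cos_i)
    if np.any(sin2_t > 1.0):
        raise TotalInternalReflectionError(
            f"total internal reflection (n {n_from}->{n_to}); "
            "the optical geometry is invalid for tracking"
        )
    cos_t = np.sqrt(1.0 - sin2_t)
    out = eta * d + (eta * cos_i - cos_t)[:, None] * n
    out = _unit(out)
    return out[0] if single else out


def _reflect_point(p: np.ndarray, plane_point: np.ndarray,
                   plane_normal: np.ndarray) -> np.ndarray:
    n = _unit(plane_normal)
    return p - 2.0 * np.dot(p - plane_point, n) * n


def _reflect_dir(d: np.ndarray, plane_normal: np.ndarray) -> np.ndarray:
    n = _unit(plane_normal)
    return d - 2.0 * np.dot(d, n) * n


@dataclass
class _Plane:
    point: np.ndarray
    normal: np.ndarray  # unit


@dataclass
class _Camera:
    """Pinhole camera basis: image u along `right`, v along `down`."""

    position: np.ndarray
    right: np.ndarray
    down: np.ndarray
    forward: np.ndarray


@dataclass
class OpticalModel:
    """Pinhole camera + planar mirror + one flat refracting interface per view.

    The default rig (``OpticalModel.default(geometry)``) places the camera
    600 mm in front of the tank at mid-water height looking along +y, and a
    45° mirror above the tank center, matching the physical arrangement of
    a front camera that records the top view on an overhead mirror.
    """

    camera_position_mm: np.ndarray
    camera_axis: np.ndarray
    focal_px: float
    principal_point_px: np.ndarray
    mirror_point_mm: np.ndarray
    mirror_normal: np.ndarray
    front_interface_point_mm: np.ndarray
    front_interface_normal: np.ndarray
    top_interface_point_mm: np.ndarray
    top_interface_normal: np.ndarray
    n_air: float = 1.0
    n_water: float = 1.333
    image_size_px: tuple[float, float] = (2048.0, 2048.0)

    def __post_init__(self) -> None:
        for name in (
            "camera_position_mm", "camera_axis", "principal_point_px",
            "mirror_point_mm", "mirror_normal", "front_interface_point_mm",
            "front_interface_normal", "top_interface_point_mm",
            "top_interface_normal",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.n_air < 1.0 or self.n_water < 1.0:
            raise ValidationError("refractive indices must be >= 1")
        if self.focal_px <= 0:
            raise ValidationError("focal_px must be > 0")
        for name in ("camera_axis", "mirror_normal",
                     "front_interface_normal", "top_interface_normal"):
            v = getattr(self, name)
            # normalize only when needed so reloading a serialized model is
            # bit-stable (renormalizing a unit vector can drift one ulp)
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                setattr(self, name, _unit(v))
        if self.top_interface_normal[2] <= 0:
            raise ValidationError("top interface normal must point up")
        to_cam = self.camera_position_mm - self.front_interface_point_mm
        if np.dot(to_cam, self.front_interface_normal) <= 0:
            raise ValidationError("front interface normal must face the camera")

    @classmethod
    def default(cls, geometry: ContainerGeometry,
                camera_distance_mm: float = 600.0,
                focal_px: float = 1500.0,
                mirror_height_mm: float = 500.0) -> "OpticalModel":
        w, d = geometry.width_mm, geometry.depth_mm
        return cls(
            camera_position_mm=[w / 2.0, -camera_distance_mm,
                                geometry.water_level_mm / 2.0],
            camera_axis=[0.0, 1.0, 0.0],
            focal_px=focal_px,
            principal_point_px=[1024.0, 1024.0],
            mirror_point_mm=[w / 2.0, d / 2.0, mirror_height_mm],
            mirror_normal=[0.0, 1.0, 1.0],
            front_interface_point_mm=[0.0, 0.0, 0.0],
            front_interface_normal=[0.0, -1.0, 0.0],
            top_interface_point_mm=[0.0, 0.0, geometry.water_level_mm],
            top_interface_normal=[0.0, 0.0, 1.0],
        )

    # -- derived cameras ---------------------------------------------------

    def _front_camera(self) -> _Camera:
        fwd = self.camera_axis
        up_world = np.array([0.0, 0.0, 1.0])
        right = _unit(np.cross(fwd, up_world))
        down = _unit(np.cross(fwd, right))
        return _Camera(self.camera_position_mm, right, down, fwd)

    def _top_camera(self) -> _Camera:
        """The real camera reflected across the mirror plane."""
        real = self._front_camera()
        pos = _reflect_point(real.position, self.mirror_point_mm,
                             self.mirror_normal)
        return _Camera(
            pos,
            _reflect_dir(real.right, self.mirror_normal),
            _reflect_dir(real.down, self.mirror_normal),
            _reflect_dir(real.forward, self.mirror_normal),
        )

    def _view(self, which: str) -> tuple[_Camera, _Plane]:
        if which == "front":
            return self._front_camera(), _Plane(
                self.front_interface_point_mm, self.front_interface_normal)
        if which == "top":
            return self._top_camera(), _Plane(
                self.top_interface_point_mm, self.top_interface_normal)
        raise ValidationError(f"unknown view {which!r}")


@dataclass
class DualViewDetections:
    """Per-frame 2D centroids of one fish in the front and top views.

    Missing detections are NaN rows; timestamps are strictly increasing.
    """

    fish_id: str
    times_s: np.ndarray
    front_uv_px: np.ndarray
    top_uv_px: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.front_uv_px = np.asarray(self.front_uv_px, dtype=float)
        self.top_uv_px = np.asarray(self.top_uv_px, dtype=float)
        n = self.times_s.size
        if self.front_uv_px.shape != (n, 2) or self.top_uv_px.shape != (n, 2):
            raise ValidationError("detection arrays must be (n, 2)")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValidationError("detection timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.times_s.size


# ---------------------------------------------------------------------------
# forward model


def _solve_interface_crossing(a: np.ndarray, b: np.ndarray, d: np.ndarray,
                              n_air: float, n_water: float,
                              iters: int = 90) -> np.ndarray:
    """Planar-refraction crossing offset r for camera height a (air side),
    point depth b (water side) and in-plane separation d, by bisection on

        f(r) = n_air * r / sqrt(r^2 + a^2) - n_water * (d - r) / sqrt((d-r)^2 + b^2)

    which is strictly increasing on [0, d] with f(0) <= 0 <= f(d)."""
    lo = np.zeros_like(d)
    hi = d.copy()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        rem = d - mid
        f = (n_air * mid / np.sqrt(mid * mid + a * a)
             - n_water * rem / np.sqrt(rem * rem + b * b))
        neg = f < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return 0.5 * (lo + hi)


def _project_view(points: np.ndarray, model: OpticalModel,
                  which: str) -> np.ndarray:
    """Refracted pinhole projection of (n, 3) water points → (n, 2) pixels.

    Points behind the interface or outside the frustum come back NaN.
    """
    cam, plane = model._view(which)
    p0, nrm = plane.point, plane.normal
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    uv = np.full((n, 2), np.nan)

    a = float(np.dot(cam.position - p0, nrm))  # camera height above interface
    if a <= 0:
        raise ValidationError(f"{which} camera is not on the air side")
    depth = -((pts - p0) @ nrm)  # water depth of each point behind interface
    ok = np.isfinite(depth) & (depth >= 0) & np.all(np.isfinite(pts), axis=1)
    if not ok.any():
        return uv

    cam_foot = cam.position - a * nrm
    pts_foot = pts + depth[:, None] * nrm[None, :]
    sep = pts_foot - cam_foot
    d = np.linalg.norm(sep, axis=1)

    r = _solve_interface_crossing(a, np.maximum(depth, 0.0), d,
                                  model.n_air, model.n_water)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(d > 0, r / np.where(d > 0, d, 1.0), 0.0)
    crossing = cam_foot + frac[:, None] * sep

    ray = crossing - cam.position
    fwd = ray @ cam.forward
    good = ok & (fwd > 1e-9)
    u = model.focal_px * (ray @ cam.right) / fwd + model.principal_point_px[0]
    v = model.focal_px * (ray @ cam.down) / fwd + model.principal_point_px[1]
    wpx, hpx = model.image_size_px
    good &= (u >= 0) & (u <= wpx) & (v >= 0) & (v <= hpx)
    uv[good, 0] = u[good]
    uv[good, 1] = v[good]
    return uv


def project_to_views(
    trajectory: Trajectory3D,
    model: OpticalModel,
    noise_sd_px: float = 0.0,
    seed: int | None = None,
) -> DualViewDetections:
    """Forward model: trace each 3D sample to front- and top-view pixels.

    Optional isotropic Gaussian pixel noise with the stated SD is added to
    every detected centroid; ``seed`` makes it reproducible.
    """
    front = _project_view(trajectory.positions_mm, model, "front")
    top = _project_view(trajectory.positions_mm, model, "top")
    if noise_sd_px > 0:
        rng = np.random.default_rng(seed)
        front = front + rng.normal(0.0, noise_sd_px, front.shape)
        top = top + rng.normal(0.0, noise_sd_px, top.shape)
    return DualViewDetections(
        fish_id=trajectory.fish_id,
        times_s=trajectory.times_s.copy(),
        front_uv_px=front,
        top_uv_px=top,
    )


# ---------------------------------------------------------------------------
# reconstruction


def _backproject_view(uv: np.ndarray, model: OpticalModel,
                      which: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixels → in-water rays (origins on the interface, unit directions).

    Returns (origins, directions, valid mask)."""
    cam, plane = model._view(which)
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    n = uv.shape[0]
    valid = np.all(np.isfinite(uv), axis=1)

    du = (uv[:, 0] - model.principal_point_px[0]) / model.focal_px
    dv = (uv[:, 1] - model.principal_point_px[1]) / model.focal_px
    d_air = (cam.forward[None, :]
             + du[:, None] * cam.right[None, :]
             + dv[:, None] * cam.down[None, :])
    norms = np.linalg.norm(d_air, axis=1, keepdims=True)
    d_air = d_air / np.where(norms > 0, norms, 1.0)

    denom = d_air @ plane.normal
    num = (plane.point - cam.position) @ plane.normal
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(np.abs(denom) > 1e-12, num / denom, np.nan)
    valid &= np.isfinite(t) & (t > 0)

    origins = cam.position[None, :] + t[:, None] * d_air
    dirs = np.full_like(origins, np.nan)
    if valid.any():
        dirs[valid] = refract_direction(
            d_air[valid], plane.normal, model.n_air, model.n_water)
    return origins, dirs, valid


def _closest_approach_midpoint(o1, d1, o2, d2, min_angle_deg: float = 1.0):
    """Midpoint of the common perpendicular of two ray bundles.

    Frames where the rays are within ``min_angle_deg`` of parallel are
    ill-conditioned and come back NaN."""
    b = np.sum(d1 * d2, axis=1)
    denom = 1.0 - b * b  # = sin^2(angle)
    w = o1 - o2
    d_ = np.sum(d1 * w, axis=1)
    e = np.sum(d2 * w, axis=1)
    min_denom = math.sin(math.radians(min_angle_deg)) ** 2
    ok = denom >= min_denom
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(ok, (b * e - d_) / np.where(ok, denom, 1.0), np.nan)
        t = np.where(ok, (e - b * d_) / np.where(ok, denom, 1.0), np.nan)
    p1 = o1 + s[:, None] * d1
    p2 = o2 + t[:, None] * d2
    mid = 0.5 * (p1 + p2)
    mid[~ok] = np.nan
    return mid


def _fill_gaps(times: np.ndarray, pos: np.ndarray, max_gap: int) -> np.ndarray:
    """Linear interpolation over runs of <= max_gap missing frames."""
    out = pos.copy()
    good = np.all(np.isfinite(pos), axis=1)
    if good.sum() < 2:
        return out
    idx = np.flatnonzero(~good)
    if idx.size == 0:
        return out
    # group consecutive missing indices
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        left, right = run[0] - 1, run[-1] + 1
        if left < 0 or right >= pos.shape[0]:
            continue  # edge gap: leave missing
        if not (good[left] and good[right]) or run.size > max_gap:
            continue
        frac = ((times[run] - times[left])
                / (times[right] - times[left]))[:, None]
        out[run] = (1.0 - frac) * pos[left] + frac * pos[right]
    return out


def reconstruct_trajectory(
    detections: DualViewDetections,
    model: OpticalModel,
    geometry: ContainerGeometry,
    max_gap_frames: int = 5,
    min_ray_angle_deg: float = 1.0,
    clamp_warn_mm: float = 2.0,
) -> Trajectory3D:
    """Triangulate a 3D trajectory from refraction-corrected dual-view rays.

    For every frame with both detections, each pixel is back-projected to an
    air ray, refracted into the water at its interface (the mirror
    reflection is folded into the virtual top camera), and the two in-water
    rays are intersected at the midpoint of their common perpendicular.
    Gaps of up to ``max_gap_frames`` missing frames are filled by linear
    interpolation; the result is clamped to the water volume, with a logged
    warning for any frame landing more than ``clamp_warn_mm`` outside.
    """
    o1, d1, v1 = _backproject_view(detections.front_uv_px, model, "front")
    o2, d2, v2 = _backproject_view(detections.top_uv_px, model, "top")
    both = v1 & v2
    if both.sum() < 2:
        raise ValidationError(
            f"fish {detections.fish_id!r}: fewer than 2 frames with both views"
        )
    pos = np.full((len(detections), 3), np.nan)
    pos[both] = _closest_approach_midpoint(
        o1[both], d1[both], o2[both], d2[both], min_ray_angle_deg)

    pos = _fill_gaps(detections.times_s, pos, max_gap_frames)

    lo, hi = geometry.water_volume_bounds
    finite = np.all(np.isfinite(pos), axis=1)
    excess = np.maximum(np.maximum(lo - pos[finite], pos[finite] - hi), 0.0)
    worst = excess.max(initial=0.0)
    if worst > clamp_warn_mm:
        logger.warning(
            "fish %s: %d reconstructed frames clamped to the water volume "
            "(worst excursion %.2f mm)",
            detections.fish_id,
            int(np.sum(excess.max(axis=1) > clamp_warn_mm)),
            worst,
        )
    pos[finite] = np.clip(pos[finite], lo, hi)

    if np.all(~np.isfinite(pos)):
        raise ValidationError("all frames missing after reconstruction")
    return Trajectory3D(
        fish_id=detections.fish_id,
        times_s=detections.times_s.copy(),
        positions_mm=pos,
    )


# ---------------------------------------------------------------------------
# despiking


def despike_filter(
    trajectory: Trajectory3D,
    window_frames: int = 5,
    max_speed_mm_s: float = 1000.0,
) -> Trajectory3D:
    """Suppress jigging noise: running median + speed-limit interpolation.

    A running median with the given (odd) window is applied per coordinate,
    then any sample whose incoming *and* outgoing implied speeds exceed
    ``max_speed_mm_s`` is replaced by linear interpolation of its
    neighbours.  Timestamps are never altered, and — both steps being convex
    combinations of existing samples — no point can leave the water volume.
    """
    if window_frames < 3 or window_frames % 2 == 0:
        raise ValidationError("window_frames must be odd and >= 3")
    n = len(trajectory)
    if n < window_frames:
        warnings.warn(
            f"trajectory shorter than window ({n} < {window_frames}); "
            "returned unchanged",
            stacklevel=2,
        )
        return trajectory

    pos = trajectory.positions_mm.copy()
    finite = np.all(np.isfinite(pos), axis=1)
    filt = pos.copy()
    if finite.all():
        for k in range(3):
            filt[:, k] = median_filter(pos[:, k], size=window_frames,
                                       mode="nearest")
    else:
        # median-filter only contiguous finite stretches
        idx = np.flatnonzero(finite)
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            if run.size >= window_frames:
                for k in range(3):
                    filt[run, k] = median_filter(
                        pos[run, k], size=window_frames, mode="nearest")

    # speed-limit pass on the finite samples
    t = trajectory.times_s
    fi = np.flatnonzero(np.all(np.isfinite(filt), axis=1))
    if fi.size >= 3:
        step = np.linalg.norm(np.diff(filt[fi], axis=0), axis=1)
        speed = step / np.diff(t[fi])
        too_fast = speed > max_speed_mm_s
        bad_inner = too_fast[:-1] & too_fast[1:]  # spike: fast in AND out
        for j in np.flatnonzero(bad_inner):
            i_prev, i_bad, i_next = fi[j], fi[j + 1], fi[j + 2]
            frac = (t[i_bad] - t[i_prev]) / (t[i_next] - t[i_prev])
            filt[i_bad] = (1.0 - frac) * filt[i_prev] + frac * filt[i_next]

    return Trajectory3D(
        fish_id=trajectory.fish_id,
        times_s=t.copy(),
        positions_mm=filt,
        states=trajectory.states,
    )
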