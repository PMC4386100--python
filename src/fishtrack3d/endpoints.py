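"""Behavioral endpoints extracted from 3D trajectories.

Endpoints fall into four families, analysed separately downstream:

* kinematic — 3D, horizontal and vertical travel distance;
* dynamic — freezing (3D speed < 2 mm/s sustained >= 1 s) and bursts
  (acceleration magnitude crossing 2 m/s², refractory-merged);
* vertical distribution — mean height over the bottom and time fractions
  in the bottom/middle/top thirds of the water column;
* horizontal distribution — mean distance from the footprint center, time
  fractions in four concentric radial zones (outer diameters 1/3, 2/3 and
  3/3 of the container width, plus the corner zone outside the largest
  circle) and in the four quadrants.

Because single juvenile goldfish freeze in a novel tank, fish are tested
in pairs and the pair mean is the experimental unit
(:func:`summarize_pair`).

Speed uses forward first differences and acceleration central second
differences on the (possibly irregular) timestamp grid; no smoothing is
applied here beyond whatever despiking ran upstream.  Occupancy fractions
are time-weighted: each sample carries the interval to the next sample and
the last sample carries the mean interval.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .core import ContainerGeometry, Trajectory3D, ValidationError

__all__ = [
    "DetectorThresholds",
    "BehavioralEndpoints",
    "travel_distances",
    "detect_freezes",
    "detect_bursts",
    "classify_spatial",
    "summarize_pair",
    "compute_endpoints",
    "ENDPOINT_FAMILIES",
]


@dataclass(frozen=True)
class DetectorThresholds:
    """Event-detection thresholds.

    Defaults: freezing is 3D speed below 2 mm/s sustained for at least 1 s;
    a burst is an upward crossing of 2 m/s² acceleration magnitude, with
    crossings closer than 0.5 s merged into one event.
    """

    freeze_speed_mm_s: float = 2.0
    freeze_min_duration_s: float = 1.0
    burst_accel_m_s2: float = 2.0
    burst_refractory_s: float = 0.5

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{f.name} must be finite and > 0")


@dataclass
class BehavioralEndpoints:
    """The per-fish (or per-pair, after averaging) endpoint vector."""

    dist3d_mm: float
    dist_h_mm: float
    dist_v_mm: float
    freeze_duration_s: float
    freeze_count: float
    burst_count: float
    mean_height_mm: float
    depth_fracs: tuple[float, float, float]          # bottom, middle, top
    mean_center_dist_mm: float
    radial_fracs: tuple[float, float, float, float]  # center, middle, outer, corner
    quadrant_fracs: tuple[float, float, float, float]
    duration_s: float

    def check_invariants(self, atol: float = 1e-9) -> None:
        if not (
            self.dist3d_mm >= max(self.dist_h_mm, self.dist_v_mm) - atol
            and self.dist3d_mm <= self.dist_h_mm + self.dist_v_mm + atol
        ):
            raise ValidationError("distance triangle inequality violated")
        for name in ("depth_fracs", "radial_fracs", "quadrant_fracs"):
            v = np.asarray(getattr(self, name))
            if np.any(v < -atol) or np.any(v > 1 + atol):
                raise ValidationError(f"{name} outside [0, 1]")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValidationError(f"{name} does not sum to 1")
        if self.freeze_duration_s > self.duration_s + atol:
            raise ValidationError("freeze duration exceeds recording duration")
        if self.freeze_count < 0 or self.burst_count < 0:
            raise ValidationError("event counts must be >= 0")

    def as_dict(self) -> dict[str, float]:
        """Flat column mapping used by the endpoint table."""
        d = {
            "dist3d_mm": self.dist3d_mm,
            "dist_h_mm": self.dist_h_mm,
            "dist_v_mm": self.dist_v_mm,
            "freeze_duration_s": self.freeze_duration_s,
            "freeze_count": self.freeze_count,
            "burst_count": self.burst_count,
            "mean_height_mm": self.mean_height_mm,
            "mean_center_dist_mm": self.mean_center_dist_mm,
            "duration_s": self.duration_s,
        }
        for k, v in zip(("bottom", "middle", "top"), self.depth_fracs):
            d[f"depth_frac_{k}"] = v
        for k, v in zip(("center", "middle", "outer", "corner"),
                        self.radial_fracs):
            d[f"radial_frac_{k}"] = v
        for i, v in enumerate(self.quadrant_fracs, start=1):
            d[f"quadrant_frac_q{i}"] = v
        return d


#: endpoint column -> family, for the four-family alpha correction
ENDPOINT_FAMILIES: dict[str, str] = {
    "dist3d_mm": "kinematic",
    "dist_h_mm": "kinematic",
    "dist_v_mm": "kinematic",
    "freeze_duration_s": "dynamic",
    "freeze_count": "dynamic",
    "burst_count": "dynamic",
    "mean_height_mm": "vertical",
    "depth_frac_bottom": "vertical",
    "depth_frac_middle": "vertical",
    "depth_frac_top": "vertical",
    "mean_center_dist_mm": "horizontal",
    "radial_frac_center": "horizontal",
    "radial_frac_middle": "horizontal",
    "radial_frac_outer": "horizontal",
    "radial_frac_corner": "horizontal",
    "quadrant_frac_q1": "horizontal",
    "quadrant_frac_q2": "horizontal",
    "quadrant_frac_q3": "horizontal",
    "quadrant_frac_q4": "horizontal",
}


def _valid_xyz(trajectory: Trajectory3D) -> tuple[np.ndarray, np.ndarray]:
    m = trajectory.valid_mask
    if m.sum() < 2:
        raise ValidationError("fewer than 2 valid samples")
    return trajectory.times_s[m], trajectory.positions_mm[m]


def travel_distances(trajectory: Trajectory3D) -> tuple[float, float, float]:
    """Total 3D, horizontal (x, y) and vertical (|dz|) path lengths in mm.

    Missing samples are skipped by joining the step across the gap.
    """
    _, p = _valid_xyz(trajectory)
    step = np.diff(p, axis=0)
    dist3d = float(np.sum(np.linalg.norm(step, axis=1)))
    dist_h = float(np.sum(np.hypot(step[:, 0], step[:, 1])))
    dist_v = float(np.sum(np.abs(step[:, 2])))
    return dist3d, dist_h, dist_v


def _forward_speeds(t: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval 3D speed (speed[i] covers [t[i], t[i+1]])."""
    dt = np.diff(t)
    step = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return step / dt, dt


def detect_freezes(
    trajectory: Trajectory3D,
    thresholds: DetectorThresholds = DetectorThresholds(),
) -> list[tuple[float, float]]:
    """Freeze episodes: maximal runs of sub-threshold 3D speed >= min duration.

    Returns ``(start_s, end_s)`` per episode.  Speed is the forward
    difference over each inter-sample interval; an interval belongs to a
    run when its speed is strictly below ``freeze_speed_mm_s``.
    """
    t, p = _valid_xyz(trajectory)
    speed, _ = _forward_speeds(t, p)
    slow = speed < thresholds.freeze_speed_mm_s
    episodes: list[tuple[float, float]] = []
    if not slow.any():
        return episodes
    padded = np.concatenate(([0], slow.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    for start, stop in zip(edges[::2], edges[1::2]):
        t0, t1 = t[start], t[stop]  # run covers intervals start..stop-1
        if t1 - t0 >= thresholds.freeze_min_duration_s:
            episodes.append((float(t0), float(t1)))
    return episodes


def _central_accel(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Acceleration magnitude (mm/s²) by central second differences on an
    irregular grid; defined at interior samples 1..n-2."""
    dt0 = (t[1:-1] - t[:-2])[:, None]
    dt1 = (t[2:] - t[1:-1])[:, None]
    acc = 2.0 * (
        dt0 * (p[2:] - p[1:-1]) - dt1 * (p[1:-1] - p[:-2])
    ) / (dt0 * dt1 * (dt0 + dt1))
    return np.linalg.norm(acc, axis=1)


def detect_bursts(
    trajectory: Trajectory3D,
    thresholds: DetectorThresholds = DetectorThresholds(),
) -> int:
    """Count burst events: upward threshold crossings of acceleration.

    Crossings separated by less than ``burst_refractory_s`` are merged into
    the same event.
    """
    t, p = _valid_xyz(trajectory)
    if t.size < 3:
        raise ValidationError("burst detection needs >= 3 valid samples")
    accel_mm = _central_accel(t, p)
    above = accel_mm > thresholds.burst_accel_m_s2 * 1000.0
    rising = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    if rising.size == 0:
        return 0
    cross_t = t[1:-1][rising]
    count = 1
    last = cross_t[0]
    for ct in cross_t[1:]:
        if ct - last >= thresholds.burst_refractory_s:
            count += 1
            last = ct
    return count


def classify_spatial(
    trajectory: Trajectory3D,
    geometry: ContainerGeometry,
) -> tuple[float, tuple, float, tuple, tuple]:
    """Time-weighted spatial occupancy statistics.

    Returns ``(mean_height_mm, depth_fracs, mean_center_dist_mm,
    radial_fracs, quadrant_fracs)``.

    Depth layers are thirds of the water level.  Radial zones are concentric
    circles about the footprint center with radii W/6, W/3 and W/2 where W
    is the footprint width (min(width, depth) for non-square tanks); the
    corner zone is everything beyond W/2.  Zone boundaries are half-open
    with the inner zone winning (r < bound).  Quadrants: 1 = front-left,
    2 = front-right, 3 = back-right, 4 = back-left as seen from the camera
    (front = nearer the camera, left = smaller x).
    """
    t, p = _valid_xyz(trajectory)
    dt = np.diff(t)
    w = np.concatenate((dt, [dt.mean()]))  # last sample: mean interval
    w_total = w.sum()

    z = p[:, 2]
    wl = geometry.water_level_mm
    mean_height = float(np.sum(w * z) / w_total)
    layer = np.minimum((z / (wl / 3.0)).astype(int), 2)  # 0 bottom, 1 mid, 2 top
    depth_fracs = tuple(
        float(np.sum(w[layer == k]) / w_total) for k in range(3))

    cx, cy = geometry.footprint_center_mm
    r = np.hypot(p[:, 0] - cx, p[:, 1] - cy)
    mean_center_dist = float(np.sum(w * r) / w_total)

    half_w = min(geometry.width_mm, geometry.depth_mm) / 2.0
    zone = np.digitize(r, [half_w / 3.0, 2.0 * half_w / 3.0, half_w])
    radial_fracs = tuple(
        float(np.sum(w[zone == k]) / w_total) for k in range(4))

    right = p[:, 0] >= geometry.width_mm / 2.0
    back = p[:, 1] >= geometry.depth_mm / 2.0
    quad = np.where(~back, np.where(~right, 0, 1), np.where(right, 2, 3))
    quadrant_fracs = tuple(
        float(np.sum(w[quad == k]) / w_total) for k in range(4))

    return mean_height, depth_fracs, mean_center_dist, radial_fracs, quadrant_fracs


def compute_endpoints(
    trajectory: Trajectory3D,
    geometry: ContainerGeometry,
    thresholds: DetectorThresholds = DetectorThresholds(),
) -> BehavioralEndpoints:
    """Full endpoint vector for one fish."""
    d3, dh, dv = travel_distances(trajectory)
    episodes = detect_freezes(trajectory, thresholds)
    bursts = detect_bursts(trajectory, thresholds)
    mh, depth_fracs, mcd, radial_fracs, quadrant_fracs = classify_spatial(
        trajectory, geometry)
    t, _ = _valid_xyz(trajectory)
    ep = BehavioralEndpoints(
        dist3d_mm=d3,
        dist_h_mm=dh,
        dist_v_mm=dv,
        freeze_duration_s=float(sum(e - s for s, e in episodes)),
        freeze_count=float(len(episodes)),
        burst_count=float(bursts),
        mean_height_mm=mh,
        depth_fracs=depth_fracs,
        mean_center_dist_mm=mcd,
        radial_fracs=radial_fracs,
        quadrant_fracs=quadrant_fracs,
        duration_s=float(t[-1] - t[0]),
    )
    ep.check_invariants()
    return ep


def summarize_pair(
    fish_a: BehavioralEndpoints,
    fish_b: BehavioralEndpoints,
    duration_rtol: float = 0.01,
) -> BehavioralEndpoints:
    """Pair mean — the experimental unit of the screening design.

    Element-wise arithmetic mean of every endpoint; fraction vectors stay
    normalised because the mean is a convex combination.
    """
    da, db = fish_a.duration_s, fish_b.duration_s
    if abs(da - db) > duration_rtol * max(da, db):
        raise ValidationError(
            f"pair recording durations differ by more than "
            f"{duration_rtol:.0%}: {da:.3f} s vs {db:.3f} s"
        )

    def m(x, y):
        return (x + y) / 2.0

    out = BehavioralEndpoints(
        dist3d_mm=m(fish_a.dist3d_mm, fish_b.dist3d_mm),
        dist_h_mm=m(fish_a.dist_h_mm, fish_b.dist_h_mm),
        dist_v_mm=m(fish_a.dist_v_mm, fish_b.dist_v_mm),
        freeze_duration_s=m(fish_a.freeze_duration_s, fish_b.freeze_duration_s),
        freeze_count=m(fish_a.freeze_count, fish_b.freeze_count),
        burst_count=m(fish_a.burst_count, fish_b.burst_count),
        mean_height_mm=m(fish_a.mean_height_mm, fish_b.mean_height_mm),
        depth_fracs=tuple(
            m(x, y) for x, y in zip(fish_a.depth_fracs, fish_b.depth_fracs)),
        mean_center_dist_mm=m(fish_a.mean_center_dist_mm,
                              fish_b.mean_center_dist_mm),
        radial_fracs=tuple(
            m(x, y) for x, y in zip(fish_a.radial_fracs, fish_b.radial_fracs)),
        quadrant_fracs=tuple(
            m(x, y) for x, y in zip(fish_a.quadrant_fracs,
                                    fish_b.quadrant_fracs)),
        duration_s=m(da, db),
    )
    out.check_invariants()
    return out
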