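"""Synthetic paired-fish recordings with switching swim/freeze/burst dynamics.

The generator emulates pairs of juvenile goldfish swimming in a 25 x 25 cm
observation container (water level 13.5 cm) sampled at ~40 frames/s.  Each
fish follows a three-state continuous-time Markov switching process:

* **cruise** — speed follows a mean-reverting (AR(1)/Ornstein-Uhlenbeck)
  process around ``cruise_speed_mm_s * locomotion_scale`` while the heading
  performs a persistent random walk;
* **freeze** — near-immobility, residual jitter speed drawn uniformly below
  1 mm/s (scaled down with the locomotion multiplier, so a fully sedated
  configuration is exactly stationary);
* **burst** — a brief triangular speed pulse whose peak acceleration equals
  ``burst_peak_accel_m_s2``.

Group-level drug effects are expressed as three dials: ``locomotion_scale``
(multiplies the whole speed process), ``freeze_rate_scale`` (multiplies the
freeze-entry hazard) and ``quadrant_bias`` (a drift toward a designated
quadrant's center).  The control condition is all three at their neutral
values (1, 1, 0).

Walls reflect specularly: unbounded displacement is folded into the water
volume with a triangle wave, which preserves per-step path length except at
the (measure-zero) crossing frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .core import ContainerGeometry, Trajectory3D, ValidationError

__all__ = [
    "SimulationConfig",
    "SurvivalRecord",
    "PairRecording",
    "simulate_pair_recording",
    "simulate_experiment",
    "simulate_survival_counts",
    "CRUISE",
    "FREEZE",
    "BURST",
]

# state codes carried on Trajectory3D.states when requested
CRUISE, FREEZE, BURST = 0, 1, 2

# quadrant centers as fractions of (width, depth); numbering convention:
# 1 = front-left, 2 = front-right, 3 = back-right, 4 = back-left
# ("front" = small y, nearest the camera)
_QUADRANT_CENTERS = {
    1: (0.25, 0.25),
    2: (0.75, 0.25),
    3: (0.75, 0.75),
    4: (0.25, 0.75),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters for one experimental group.

    Defaults describe an untreated control group: 40 fish pairs recorded
    for 10 min at 40 Hz, cruising around 40 mm/s (~0.7 body lengths/s for a
    60 mm juvenile goldfish), entering freezes at 0.02/s and leaving them
    at 0.2/s (equilibrium ~9% time frozen), and bursting at 0.05/s with a
    3 m/s² peak acceleration — comfortably above the 2 m/s² detection
    threshold.
    """

    n_pairs: int = 40
    duration_s: float = 600.0
    frame_rate_hz: float = 40.0
    seed: int = 0
    cruise_speed_mm_s: float = 40.0
    speed_sd_mm_s: float = 15.0
    rate_enter_freeze_per_s: float = 0.02
    rate_exit_freeze_per_s: float = 0.2
    rate_burst_per_s: float = 0.05
    burst_peak_accel_m_s2: float = 3.0
    burst_duration_s: float = 0.15
    locomotion_scale: float = 1.0
    freeze_rate_scale: float = 1.0
    quadrant_bias: float = 0.0
    bias_quadrant: int = 2
    pixel_noise_sd: float = 0.5
    # heading persistence / vertical excursion of the cruise model
    heading_diffusion_rad2_per_s: float = 2.0
    pitch_sd_rad: float = 0.2
    speed_relaxation_s: float = 1.0

    def __post_init__(self) -> None:
        nonneg = (
            "cruise_speed_mm_s",
            "speed_sd_mm_s",
            "rate_enter_freeze_per_s",
            "rate_exit_freeze_per_s",
            "rate_burst_per_s",
            "locomotion_scale",
            "freeze_rate_scale",
            "pixel_noise_sd",
            "heading_diffusion_rad2_per_s",
            "pitch_sd_rad",
        )
        for name in nonneg:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
        positive = (
            "duration_s",
            "frame_rate_hz",
            "burst_peak_accel_m_s2",
            "burst_duration_s",
            "speed_relaxation_s",
        )
        for name in positive:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")
        if not (0.0 <= self.quadrant_bias < 1.0):
            raise ValidationError(
                f"quadrant_bias must be in [0, 1), got {self.quadrant_bias!r}"
            )
        if self.n_pairs < 0:
            raise ValidationError("n_pairs must be >= 0")
        if self.bias_quadrant not in _QUADRANT_CENTERS:
            raise ValidationError("bias_quadrant must be one of 1, 2, 3, 4")


@dataclass(frozen=True)
class SurvivalRecord:
    """Outcome of one acute-exposure group: fish dead or euthanized moribund."""

    compound: str
    dose_mg_per_l: float
    exposure_h: float
    n_total: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValidationError("n_total must be > 0")
        if not (0 <= self.n_dead <= self.n_total):
            raise ValidationError(
                f"n_dead must be in [0, n_total], got {self.n_dead}/{self.n_total}"
            )


@dataclass
class PairRecording:
    """Two co-housed fish recorded simultaneously on one timestamp grid."""

    pair_id: str
    group: str
    fish_a: Trajectory3D
    fish_b: Trajectory3D
    pair_seed: int


# ---------------------------------------------------------------------------
# state sequence


def _simulate_states(config: SimulationConfig, rng: np.random.Generator,
                     n_frames: int, dt: float) -> np.ndarray:
    """Sample the cruise/freeze/burst semi-Markov chain on the frame grid.

    Dwell times are exponential for cruise and freeze; a burst lasts a fixed
    ``burst_duration_s``.  Returns one state code per frame.
    """
    lam_f = config.rate_enter_freeze_per_s * config.freeze_rate_scale
    lam_b = config.rate_burst_per_s
    mu = config.rate_exit_freeze_per_s
    total = n_frames * dt

    # event-driven: segment boundaries then lookup per frame
    bounds = [0.0]
    seg_states = []
    t = 0.0
    state = CRUISE
    while t < total:
        if state == CRUISE:
            rate = lam_f + lam_b
            dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            nxt = FREEZE if (rate > 0 and rng.random() < lam_f / rate) else BURST
        elif state == FREEZE:
            dwell = rng.exponential(1.0 / mu) if mu > 0 else np.inf
            nxt = CRUISE
        else:  # BURST
            dwell = config.burst_duration_s
            nxt = CRUISE
        seg_states.append(state)
        t = min(t + dwell, total) if np.isfinite(dwell) else total
        bounds.append(t)
        state = nxt

    frame_t = np.arange(n_frames) * dt
    idx = np.searchsorted(np.asarray(bounds[1:]), frame_t, side="right")
    return np.asarray(seg_states)[np.minimum(idx, len(seg_states) - 1)]


def _burst_speed_profile(states: np.ndarray, config: SimulationConfig,
                         dt: float) -> np.ndarray:
    """Additive triangular speed pulse over each burst segment (mm/s)."""
    add = np.zeros(states.size)
    accel = config.burst_peak_accel_m_s2 * 1000.0  # mm/s^2
    in_burst = states == BURST
    if not in_burst.any():
        return add
    edges = np.flatnonzero(np.diff(np.concatenate(([0], in_burst.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        tau = (np.arange(start, stop) - start) * dt
        length = (stop - start) * dt
        add[start:stop] = accel * np.minimum(tau, np.maximum(length - tau, 0.0))
    return add


# ---------------------------------------------------------------------------
# one fish


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Triangle-wave fold of an unbounded path into [lo, hi] (specular walls)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + span - np.abs(y - span)


def _simulate_fish(config: SimulationConfig, geometry: ContainerGeometry,
                   rng: np.random.Generator, fish_id: str) -> Trajectory3D:
    dt = 1.0 / config.frame_rate_hz
    n = max(2, int(round(config.duration_s * config.frame_rate_hz)))
    times = np.arange(n) * dt

    states = _simulate_states(config, rng, n, dt)

    scale = config.locomotion_scale
    mean_speed = config.cruise_speed_mm_s * scale
    sd_speed = config.speed_sd_mm_s * scale

    # cruise speed: stationary AR(1) around the scaled mean
    a = math.exp(-dt / config.speed_relaxation_s)
    innov = rng.standard_normal(n)
    innov[0] *= 1.0  # stationary start
    innov[1:] *= math.sqrt(1.0 - a * a)
    dev = lfilter([1.0], [1.0, -a], sd_speed * innov)
    speed = np.clip(mean_speed + dev, 0.0, None)

    # freeze: residual jitter below 1 mm/s, scaled with locomotion
    jitter_cap = min(1.0, mean_speed) if mean_speed > 0 else 0.0
    freeze_speed = rng.uniform(0.0, 1.0, n) * jitter_cap
    speed = np.where(states == FREEZE, freeze_speed, speed)

    # burst: additive triangular pulse, peak acceleration as configured
    speed = speed + _burst_speed_profile(states, config, dt)

    # heading: persistent random walk in azimuth, OU pitch near horizontal
    phi = np.cumsum(
        math.sqrt(config.heading_diffusion_rad2_per_s * dt)
        * rng.standard_normal(n)
    ) + rng.uniform(0.0, 2.0 * math.pi)
    pitch_innov = rng.standard_normal(n)
    pitch_innov[1:] *= math.sqrt(1.0 - a * a)
    pitch = lfilter([1.0], [1.0, -a], config.pitch_sd_rad * pitch_innov)

    direction = np.column_stack(
        (
            np.cos(phi) * np.cos(pitch),
            np.sin(phi) * np.cos(pitch),
            np.sin(pitch),
        )
    )
    velocity = speed[:, None] * direction

    lo = np.zeros(3)
    hi = np.array([geometry.width_mm, geometry.depth_mm, geometry.water_level_mm])
    p0 = rng.uniform(lo, hi)

    if config.quadrant_bias == 0.0:
        raw = p0 + np.cumsum(velocity * dt, axis=0)
        pos = np.column_stack(
            [_fold(raw[:, k], lo[k], hi[k]) for k in range(3)]
        )
    else:
        # drift direction depends on the current position: integrate in
        # short blocks, recomputing the drift from each block's start
        qx, qy = _QUADRANT_CENTERS[config.bias_quadrant]
        target = np.array([qx * geometry.width_mm, qy * geometry.depth_mm])
        drift_speed = config.quadrant_bias * mean_speed
        block = 8
        pos = np.empty((n, 3))
        cur = p0
        for s0 in range(0, n, block):
            s1 = min(s0 + block, n)
            delta = target - cur[:2]
            dist = np.hypot(*delta)
            v_bias = np.zeros(3)
            if dist > 1.0:
                v_bias[:2] = drift_speed * delta / dist
            raw = cur + np.cumsum((velocity[s0:s1] + v_bias) * dt, axis=0)
            for k in range(3):
                pos[s0:s1, k] = _fold(raw[:, k], lo[k], hi[k])
            cur = pos[s1 - 1]

    traj = Trajectory3D(fish_id=fish_id, times_s=times, positions_mm=pos,
                        states=states)
    traj.validate(geometry)
    return traj


# ---------------------------------------------------------------------------
# public operations


def simulate_pair_recording(
    config: SimulationConfig,
    geometry: ContainerGeometry,
    pair_seed: int,
    pair_id: str = "pair0",
    group: str = "control",
) -> PairRecording:
    """Simulate one pair of independently swimming fish on a shared grid.

    The two fish draw from sub-streams 0 and 1 of
    ``np.random.SeedSequence(pair_seed)``; identical ``(config, geometry,
    pair_seed)`` give bit-identical output.
    """
    ss = np.random.SeedSequence(int(pair_seed))
    rng_a, rng_b = (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(2))
    fish_a = _simulate_fish(config, geometry, rng_a, f"{pair_id}_a")
    fish_b = _simulate_fish(config, geometry, rng_b, f"{pair_id}_b")
    return PairRecording(pair_id=pair_id, group=group, fish_a=fish_a,
                         fish_b=fish_b, pair_seed=int(pair_seed))


def simulate_experiment(
    control: SimulationConfig,
    treated: Sequence[SimulationConfig],
    geometry: ContainerGeometry,
    group_names: Sequence[str] | None = None,
) -> list[PairRecording]:
    """Simulate a multi-group experiment, one recording per fish pair.

    Group 0 is the control; the master seed is ``control.seed``.  Pair seeds
    are the first ``sum(n_pairs)`` words of
    ``SeedSequence(master).generate_state``, masked to 31 bits, assigned in
    group order — so the whole experiment is reproducible from the master
    seed, and any single pair can be regenerated from its recorded seed.
    """
    configs = [control, *treated]
    if len(treated) == 0:
        raise ValidationError("at least one treated group is required")
    for i, cfg in enumerate(configs):
        if cfg.n_pairs < 1:
            raise ValidationError(f"group {i} has n_pairs < 1")
    if group_names is None:
        group_names = ["control"] + [f"treated{i + 1}" for i in range(len(treated))]
    if len(group_names) != len(configs):
        raise ValidationError("group_names must match the number of groups")

    total = sum(cfg.n_pairs for cfg in configs)
    words = np.random.SeedSequence(int(control.seed)).generate_state(total)
    pair_seeds = (words & np.uint32(0x7FFFFFFF)).tolist()

    recordings: list[PairRecording] = []
    k = 0
    for name, cfg in zip(group_names, configs):
        for p in range(cfg.n_pairs):
            recordings.append(
                simulate_pair_recording(
                    cfg, geometry, pair_seeds[k],
                    pair_id=f"{name}_p{p:03d}", group=name,
                )
            )
            k += 1
    return recordings


def simulate_survival_counts(
    p_death_by_group: Sequence[float],
    n_by_group: Sequence[int],
    seed: int,
    compounds: Sequence[str] | None = None,
    doses_mg_per_l: Sequence[float] | None = None,
    exposure_h: float = 3.0,
) -> list[SurvivalRecord]:
    """Draw binomial death counts per exposure group."""
    p_death_by_group = list(p_death_by_group)
    n_by_group = list(n_by_group)
    if len(p_death_by_group) != len(n_by_group):
        raise ValidationError("probability and count lists differ in length")
    for p in p_death_by_group:
        if not (np.isfinite(p) and 0.0 <= p <= 1.0):
            raise ValidationError(f"death probability outside [0, 1]: {p!r}")
    for n in n_by_group:
        if n <= 0:
            raise ValidationError(f"group size must be > 0, got {n!r}")
    if compounds is None:
        compounds = [f"group{i + 1}" for i in range(len(n_by_group))]
    if doses_mg_per_l is None:
        doses_mg_per_l = [0.0] * len(n_by_group)

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))
    return [
        SurvivalRecord(
            compound=c,
            dose_mg_per_l=float(d),
            exposure_h=float(exposure_h),
            n_total=int(n),
            n_dead=int(rng.binomial(n, p)),
        )
        for c, d, p, n in zip(compounds, doses_mg_per_l, p_death_by_group, n_by_group)
    ]
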