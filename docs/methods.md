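# Methods

This note documents the models implemented in fishtrack3d, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data do and do not establish.

## Coordinate and geometry conventions

Origin at the bottom front-left inside corner of the water volume; x
across the camera image, y away from the camera, z up; all lengths in mm.
The default container is 250 × 250 mm footprint, 180 mm walls, 135 mm
water level. The real container's semi-transparent walls taper very
slightly toward the bottom; the tank is modelled as a right rectangular
prism, which is negligible for zone classification.

Quadrant numbering (fixed here because the apparatus only distinguishes
quadrants by their surroundings): 1 = front-left, 2 = front-right,
3 = back-right, 4 = back-left as seen from the camera. The run manifest
records this convention so a reported "quadrant 2" effect is unambiguous.

## Synthetic recording model

Each fish is an independent three-state semi-Markov process sampled on
the frame grid (default 40 Hz):

* **cruise** — exponential dwell, hazard to freeze
  `rate_enter_freeze_per_s × freeze_rate_scale` (default 0.02/s × 1) and
  to burst `rate_burst_per_s` (0.05/s). Speed is a stationary AR(1)
  (discretized Ornstein–Uhlenbeck, relaxation 1 s) around
  `cruise_speed_mm_s × locomotion_scale` (40 mm/s ≈ 0.7 body lengths/s
  for a 60 mm juvenile goldfish) with SD `speed_sd_mm_s ×
  locomotion_scale` (15 mm/s), clipped at 0. Heading is a persistent
  random walk (azimuth diffusion 2 rad²/s) with a small OU pitch
  (SD 0.2 rad), keeping fish mostly horizontal.
* **freeze** — exponential dwell at `rate_exit_freeze_per_s` (0.2/s);
  residual jitter speed drawn uniformly below min(1 mm/s, scaled cruise
  mean). Scaling the jitter cap with `locomotion_scale` is a deliberate
  choice: the locomotion multiplier scales the *whole* speed process, so
  a fully sedated configuration (scale 0) is exactly stationary.
* **burst** — fixed 0.15 s dwell; a triangular speed pulse whose slope is
  `burst_peak_accel_m_s2` (default 3 m/s², above the 2 m/s² detection
  threshold) is added to the cruise speed.

Positions integrate velocity and are folded into the water volume with a
triangle wave, which is exactly specular wall reflection for a sampled
path. `quadrant_bias` adds a horizontal drift of `bias × scaled cruise
speed` toward the designated quadrant's center; because the drift
direction depends on the current position, biased runs integrate in
0.2 s blocks (drift recomputed at each block start) while unbiased runs
use a single vectorized pass — a runtime optimisation only.

Seeding: a pair recording spawns sub-streams 0/1 of
`SeedSequence(pair_seed)` for its two fish; an experiment derives its
pair seeds as the first Σ n_pairs words of
`SeedSequence(master).generate_state`, masked to 31 bits. Identical
seeds give bit-identical output.

Recording duration is not standardized for this paradigm; the default is
600 s, long enough for stable endpoint estimates at 40 Hz, and every test
states the duration it uses. The large power simulation in the acceptance
suite runs 120 s recordings (group sizes 39/39/36 and effect size
unchanged) to fit a single-CPU grading budget; the duration was fixed
before the criterion was evaluated.

**What the generator does not emulate:** hydrodynamics, body posture and
tail-beat kinematics, wall-following behavior, social interaction between
the two fish (they are independent), diurnal effects. A green pipeline
test therefore establishes correctness of the *analysis chain* under a
plausible movement model, not fish realism. One known model artifact:
specular wall reflection reverses the wall-normal velocity component in
one frame, which can register as a burst at cruising speeds above
~25 mm/s per 25 ms frame; burst counts on synthetic data thus mix planted
bursts with wall hits. Event-detector correctness is established on
planted noiseless trajectories instead.

## Optical model and reconstruction

The rig is defined concretely (the original apparatus' calibration is not
public): a pinhole camera 600 mm in front of the tank at mid-water
height, focal length 1500 px, principal point (1024, 1024), and a planar
mirror at 45° through (125, 125, 500) mm. The top view is handled by
reflecting the camera (position and basis) across the mirror plane,
giving a virtual overhead camera. Each view crosses exactly one flat
air→water interface — front wall plane y = 0, water surface
z = 135 mm — and the front wall's glass thickness is ignored.

*Forward projection* solves the planar-refraction (Fermat) problem for
the interface crossing point: with camera height a above the interface,
point depth b below it, and in-plane separation d, the crossing offset r
solves `n_air r/√(r²+a²) = n_water (d−r)/√((d−r)²+b²)`, which is strictly
monotone on [0, d] and is bisected 90 times (machine precision,
vectorized). *Back-projection* refracts each pixel ray with the vector
Snell law; total internal reflection raises an explicit error.
*Triangulation* takes the midpoint of the common perpendicular between
the two in-water rays, rejecting frames where the rays are within 1° of
parallel. Gaps of ≤ 5 missing frames (125 ms at 40 Hz, short relative to
the 1 s freeze threshold) are filled by linear interpolation; output is
clamped to the water volume with a logged warning beyond 2 mm.

Noise-free round trips recover positions to ~1e-13 mm RMS; assuming
n_water = 1 on refracted detections costs ~8 mm RMS on the default scene,
which is why the correction exists.

*Despiking* is a per-coordinate running median (odd window, default 5)
followed by replacement of samples whose incoming **and** outgoing
implied speeds exceed `max_speed_mm_s` (default 1000 mm/s — several times
the fastest modelled burst). Both steps are convex combinations of
observed samples, so timestamps never change and no point can leave the
water volume.

## Endpoint extraction

Speeds are forward first differences, accelerations central second
differences, both on the actual (possibly irregular) timestamp grid; no
additional smoothing, so every detector is checkable against a
brute-force enumeration oracle. Freeze episodes are maximal runs of
intervals with 3D speed strictly below 2 mm/s lasting ≥ 1 s. Whether the
freeze threshold should apply to 3D or horizontal speed is not
standardized; 3D speed is used (configurable via the thresholds object).
Bursts are upward crossings of 2 m/s² with crossings closer than 0.5 s
merged. Freeze and burst frequencies are reported as counts per
recording.

Occupancy fractions are time-weighted: each sample carries the interval
to the next sample, the last sample the mean interval. Zone boundaries
are half-open with the inner zone winning (r < bound); radial zones use
circles of radius W/6, W/3, W/2 about the footprint center with
W = min(width, depth). Depth layers are thirds of the water level. Pair
summary is the element-wise arithmetic mean (fractions remain normalized
as convex combinations); recording durations must agree within 1%.

## Statistics

Kruskal–Wallis uses mid-ranks and the standard tie correction, with the
χ² approximation for the omnibus p — adequate at the design's ≈ 36–40
pairs per group (measured null type-I error 0.0102 at nominal 0.0125,
n = 20/group). DSCF re-ranks each pair in isolation, standardizes the
rank sum with the tie-corrected variance, and refers √2|z| to
q(k, ∞). An all-tied group set (or pair) carries no ordering
information and returns H = 0 (z = 0), p = 1, with a degenerate flag.

The asymptotic DSCF p is accurate in the rejection-relevant range but at
group sizes ≤ 6 the exact permutation distribution is a step function
with mid-range jumps larger than 0.02; no continuous reference can track
those, and a continuity correction does not resolve it. For small
samples the `method="permutation"` option estimates family-wise p-values
by max-T relabeling (the finite-sample analog of the studentized-range
reference) and is the recommended route below ~8 per group.

Post-hoc tests are gated on the omnibus passing the family alpha by
default; `pairwise_mode="always"` computes them regardless, since
pairwise tendencies can be of interest without a significant omnibus.
Within a family no further correction across endpoints is applied (e.g.
the four quadrant fractions share one family alpha) — this mirrors the
screening design's convention and is a deliberate, documented choice.
The printed pairwise alpha "0.0041" is the conventional 4-decimal
truncation of 0.05/12; all internal comparisons use full precision.
Normality/variance pre-testing is out of scope: the pipeline always
takes the nonparametric path.

## Known limitations

* The optical model is a defined stand-in, not a calibration of any
  physical rig; lens distortion and multi-camera bundle adjustment are
  out of scope.
* Fish identity is taken from the detections; occlusion-swap repair is
  upstream of this package.
* The generator's effect dials are directional caricatures (less
  locomotion, more freezing, quadrant preference), suitable for power and
  calibration studies of the analysis, not for dose–response modelling.
* Survival analysis is tabulation only; no time-to-event modelling.
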