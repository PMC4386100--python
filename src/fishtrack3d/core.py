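"""Core domain types shared by every pipeline stage.

Coordinate convention (all millimetres): origin at the bottom front-left
inside corner of the water volume; x runs across the camera image, y runs
away from the camera, z runs up from the tank bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ContainerGeometry", "Trajectory3D", "ValidationError"]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class ContainerGeometry:
    """Physical tank and water-volume dimensions.

    The default instance is a 25 x 25 cm observation container with 18 cm
    walls filled to a 13.5 cm water level.  The real container's
    semi-transparent walls taper very slightly toward the bottom; the taper
    is negligible for zone classification and the tank is modelled as a
    right rectangular prism.

    Parameters
    ----------
    width_mm
        Length along the camera-facing axis (x), mm.
    depth_mm
        Length along the viewing axis (y), mm.
    wall_height_mm
        Wall height, mm.
    water_level_mm
        Water depth, mm; must not exceed the wall height.
    """

    width_mm: float = 250.0
    depth_mm: float = 250.0
    wall_height_mm: float = 180.0
    water_level_mm: float = 135.0

    def __post_init__(self) -> None:
        for name in ("width_mm", "depth_mm", "wall_height_mm", "water_level_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")
        if self.water_level_mm > self.wall_height_mm:
            raise ValidationError(
                f"water_level_mm ({self.water_level_mm}) exceeds "
                f"wall_height_mm ({self.wall_height_mm})"
            )

    @property
    def footprint_center_mm(self) -> np.ndarray:
        """Horizontal (x, y) center of the tank footprint."""
        return np.array([self.width_mm / 2.0, self.depth_mm / 2.0])

    @property
    def water_volume_bounds(self) -> np.ndarray:
        """(2, 3) array of lower/upper corners of the water volume."""
        return np.array(
            [[0.0, 0.0, 0.0], [self.width_mm, self.depth_mm, self.water_level_mm]]
        )

    def contains(self, positions_mm: np.ndarray, atol: float = 0.0) -> np.ndarray:
        """Boolean mask: which (n, 3) positions lie inside the water volume."""
        p = np.asarray(positions_mm, dtype=float)
        lo, hi = self.water_volume_bounds
        return np.all((p >= lo - atol) & (p <= hi + atol), axis=-1)


@dataclass
class Trajectory3D:
    """Time-stamped 3D positions of one fish — the pipeline's central record.

    Positions may contain NaN rows for frames where the fish could not be
    localised; timestamps must be strictly increasing and at least two
    samples must be present.  Finite positions must lie inside the water
    volume of whatever container they were recorded in (enforced by the
    producers, checkable via :meth:`validate`).
    """

    fish_id: str
    times_s: np.ndarray
    positions_mm: np.ndarray
    states: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if self.times_s.ndim != 1 or self.times_s.size < 2:
            raise ValidationError("a trajectory needs >= 2 timestamps")
        if self.positions_mm.shape != (self.times_s.size, 3):
            raise ValidationError(
                f"positions_mm must have shape ({self.times_s.size}, 3), "
                f"got {self.positions_mm.shape}"
            )
        if not np.all(np.isfinite(self.times_s)):
            raise ValidationError("timestamps must be finite")
        if np.any(np.diff(self.times_s) <= 0):
            bad = int(np.argmax(np.diff(self.times_s) <= 0))
            raise ValidationError(
                f"timestamps must be strictly increasing "
                f"(violated at sample {bad + 1}, fish {self.fish_id!r})"
            )

    def __len__(self) -> int:
        return self.times_s.size

    @property
    def valid_mask(self) -> np.ndarray:
        """Samples with a finite 3D position."""
        return np.all(np.isfinite(self.positions_mm), axis=1)

    def validate(self, geometry: ContainerGeometry, atol: float = 1e-9) -> None:
        """Raise if any finite position falls outside the water volume."""
        m = self.valid_mask
        inside = geometry.contains(self.positions_mm[m], atol=atol)
        if not np.all(inside):
            k = int(np.argmin(inside))
            raise ValidationError(
                f"fish {self.fish_id!r}: position outside water volume at "
                f"t={self.times_s[m][k]:.3f} s: {self.positions_mm[m][k]}"
            )

    def dropna(self) -> "Trajectory3D":
        """Trajectory restricted to samples with finite positions."""
        m = self.valid_mask
        if m.sum() < 2:
            raise ValidationError(
                f"fish {self.fish_id!r}: fewer than 2 valid samples"
            )
        return Trajectory3D(
            fish_id=self.fish_id,
            times_s=self.times_s[m],
            positions_mm=self.positions_mm[m],
        )
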