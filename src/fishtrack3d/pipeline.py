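"""End-to-end pipeline: simulate → project → reconstruct → despike →
endpoints → pair summary → statistics, with a JSON run manifest.

Every stage writes plain CSV/TSV/JSON so each intermediate is auditable
and re-readable by this package's own readers.  Reruns with the same
configuration and seed reproduce identical artifact files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import ContainerGeometry, Trajectory3D, ValidationError
from .endpoints import (DetectorThresholds, compute_endpoints, summarize_pair)
from .io import (read_detections, read_endpoint_table, read_trajectories,
                 write_detections, write_endpoint_table, write_trajectories)
from .optics import (OpticalModel, despike_filter, project_to_views,
                     reconstruct_trajectory)
from .simulate import PairRecording, SimulationConfig, simulate_experiment
from .stats import AlphaScheme, analyze_experiment

__all__ = ["PipelineConfig", "run_pipeline", "build_endpoint_table",
           "pair_up_trajectories"]

logger = logging.getLogger(__name__)

QUADRANT_CONVENTION = ("quadrant 1 = front-left, 2 = front-right, "
                       "3 = back-right, 4 = back-left, seen from the camera")

MODES = ("simulate", "reconstruct", "endpoints", "stats", "all")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, JSON-round-trippable."""

    geometry: ContainerGeometry = field(default_factory=ContainerGeometry)
    optical: OpticalModel | None = None
    thresholds: DetectorThresholds = field(default_factory=DetectorThresholds)
    scheme: AlphaScheme = field(default_factory=AlphaScheme)
    groups: dict[str, SimulationConfig] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"
    despike_window_frames: int = 5
    despike_max_speed_mm_s: float = 1000.0
    io: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.optical is None:
            self.optical = OpticalModel.default(self.geometry)

    # -- JSON ---------------------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        geometry = ContainerGeometry(**doc.get("geometry", {}))
        optical = None
        opt_doc = doc.get("optical")
        if opt_doc:
            if "camera_position_mm" in opt_doc:
                optical = OpticalModel(**opt_doc)
            else:  # shorthand: kwargs of the default rig
                optical = OpticalModel.default(geometry, **opt_doc)
        groups = {
            name: SimulationConfig(**cfg)
            for name, cfg in doc.get("groups", {}).items()
        }
        return cls(
            geometry=geometry,
            optical=optical,
            thresholds=DetectorThresholds(**doc.get("thresholds", {})),
            scheme=AlphaScheme(**doc.get("scheme", {})),
            groups=groups,
            seed=int(doc.get("seed", 0)),
            log_level=doc.get("log_level", "INFO"),
            despike_window_frames=int(doc.get("despike_window_frames", 5)),
            despike_max_speed_mm_s=float(doc.get("despike_max_speed_mm_s", 1000.0)),
            io=dict(doc.get("io", {})),
        )

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v)
                        for k, v in dataclasses.asdict(obj).items()}
            if hasattr(obj, "tolist"):
                return obj.tolist()
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "geometry": plain(self.geometry),
            "optical": plain(self.optical),
            "thresholds": plain(self.thresholds),
            "scheme": plain(self.scheme),
            "groups": {k: plain(v) for k, v in self.groups.items()},
            "seed": self.seed,
            "log_level": self.log_level,
            "despike_window_frames": self.despike_window_frames,
            "despike_max_speed_mm_s": self.despike_max_speed_mm_s,
            "io": dict(self.io),
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def default_demo(cls, seed: int = 0) -> "PipelineConfig":
        """A small three-group demo: control, a mild group, and a group with
        the reduced-locomotion / more-freezing / quadrant-bias signature."""
        base = dict(n_pairs=6, duration_s=60.0, seed=seed)
        return cls(
            groups={
                "control": SimulationConfig(**base),
                "threo_like": SimulationConfig(**base),
                "erythro_like": SimulationConfig(
                    **base, locomotion_scale=0.6, freeze_rate_scale=3.0,
                    quadrant_bias=0.15),
            },
            seed=seed,
        )


# ---------------------------------------------------------------------------


def pair_up_trajectories(
    trajectories: list[Trajectory3D],
    pairs: pd.DataFrame | None = None,
) -> list[tuple[str, str, Trajectory3D, Trajectory3D]]:
    """Group fish into (pair_id, group, fish_a, fish_b) tuples.

    With no pairs manifest, fish ids must follow the ``<pair_id>_a`` /
    ``<pair_id>_b`` convention; a pair id with any other number of fish
    than two is an error (fish are tested in pairs — a lone juvenile
    goldfish in a novel tank mostly freezes).
    """
    by_id = {t.fish_id: t for t in trajectories}
    if pairs is not None:
        rows = pairs.to_dict("records")
        out = []
        for row in rows:
            for col in ("pair_id", "group", "fish_a", "fish_b"):
                if col not in row:
                    raise ValidationError(f"pairs manifest lacks column {col!r}")
            try:
                out.append((row["pair_id"], row["group"],
                            by_id[row["fish_a"]], by_id[row["fish_b"]]))
            except KeyError as exc:
                raise ValidationError(f"pairs manifest names unknown fish {exc}")
        return out

    grouped: dict[str, list[Trajectory3D]] = {}
    for t in trajectories:
        if t.fish_id.endswith(("_a", "_b")):
            grouped.setdefault(t.fish_id[:-2], []).append(t)
        else:
            grouped.setdefault(t.fish_id, []).append(t)
    out = []
    for pair_id, members in sorted(grouped.items()):
        if len(members) != 2:
            raise ValidationError(
                f"pair {pair_id!r} has {len(members)} fish; endpoints are "
                "computed per pair and require exactly two fish"
            )
        a, b = sorted(members, key=lambda t: t.fish_id)
        group = pair_id.rsplit("_p", 1)[0] if "_p" in pair_id else "unknown"
        out.append((pair_id, group, a, b))
    return out


def build_endpoint_table(
    paired: list[tuple[str, str, Trajectory3D, Trajectory3D]],
    geometry: ContainerGeometry,
    thresholds: DetectorThresholds = DetectorThresholds(),
) -> pd.DataFrame:
    """Per-pair endpoint table: pair-mean endpoints plus labels."""
    rows = []
    for pair_id, group, fish_a, fish_b in paired:
        ep = summarize_pair(
            compute_endpoints(fish_a, geometry, thresholds),
            compute_endpoints(fish_b, geometry, thresholds),
        )
        rows.append({"group": group, "pair_id": pair_id, **ep.as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, out: Path) -> list[PairRecording]:
    if not config.groups:
        raise ValidationError("no simulation groups configured")
    names = list(config.groups)
    if len(names) < 2:
        raise ValidationError("simulation needs a control plus >= 1 treated group")
    control = dataclasses.replace(config.groups[names[0]], seed=config.seed)
    treated = [config.groups[n] for n in names[1:]]
    recordings = simulate_experiment(control, treated, config.geometry,
                                     group_names=names)
    write_trajectories(
        [t for r in recordings for t in (r.fish_a, r.fish_b)],
        out / "trajectories_true.csv")
    pd.DataFrame([
        {"pair_id": r.pair_id, "group": r.group,
         "fish_a": r.fish_a.fish_id, "fish_b": r.fish_b.fish_id,
         "pair_seed": r.pair_seed}
        for r in recordings
    ]).to_csv(out / "pairs.csv", index=False)
    return recordings


def _stage_project(config: PipelineConfig, out: Path) -> None:
    trajectories = read_trajectories(out / "trajectories_true.csv")
    noise = {name: cfg.pixel_noise_sd for name, cfg in config.groups.items()}
    dets = []
    for i, traj in enumerate(trajectories):
        group = traj.fish_id.rsplit("_p", 1)[0]
        dets.append(project_to_views(
            traj, config.optical,
            noise_sd_px=noise.get(group, 0.5),
            seed=(config.seed + 7919 * i) % (2 ** 31),
        ))
    write_detections(dets, out / "detections.csv")


def _stage_reconstruct(config: PipelineConfig, out: Path) -> None:
    det_path = Path(config.io.get("detections", out / "detections.csv"))
    recs = []
    for det in read_detections(det_path):
        traj = reconstruct_trajectory(det, config.optical, config.geometry)
        recs.append(despike_filter(traj, config.despike_window_frames,
                                   config.despike_max_speed_mm_s))
    write_trajectories(recs, out / "trajectories_reconstructed.csv")


def _stage_endpoints(config: PipelineConfig, out: Path) -> None:
    traj_io = config.io.get("trajectories")
    if traj_io:
        traj_path = Path(traj_io)
    else:
        cand = out / "trajectories_reconstructed.csv"
        traj_path = cand if cand.exists() else out / "trajectories_true.csv"
    trajectories = read_trajectories(traj_path)
    pairs_path = out / "pairs.csv"
    pairs = pd.read_csv(pairs_path) if pairs_path.exists() else None
    paired = pair_up_trajectories(trajectories, pairs)
    table = build_endpoint_table(paired, config.geometry, config.thresholds)
    write_endpoint_table(table, out / "endpoints.tsv")


def _stage_stats(config: PipelineConfig, out: Path) -> None:
    table_path = Path(config.io.get("endpoints", out / "endpoints.tsv"))
    table = read_endpoint_table(table_path)
    report = analyze_experiment(table, config.scheme)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
    report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False,
                             float_format="%.9g")


def run_pipeline(config: PipelineConfig, mode: str, out_dir: str | Path) -> int:
    """Execute the requested stage(s); returns 0 on success.

    ``mode="all"`` runs simulate → project → reconstruct → despike →
    endpoints → pair summary → stats.  A run manifest (config hash, seed,
    versions, quadrant convention) is written alongside the artifacts.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; choose from {MODES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))

    stages = {
        "simulate": ["simulate"],
        "reconstruct": ["reconstruct"],
        "endpoints": ["endpoints"],
        "stats": ["stats"],
        "all": ["simulate", "project", "reconstruct", "endpoints", "stats"],
    }[mode]

    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            if stage == "simulate":
                _stage_simulate(config, out)
            elif stage == "project":
                _stage_project(config, out)
            elif stage == "reconstruct":
                _stage_reconstruct(config, out)
            elif stage == "endpoints":
                _stage_endpoints(config, out)
            elif stage == "stats":
                _stage_stats(config, out)
        except Exception:
            logger.exception("stage %s failed", stage)
            raise

    import numpy
    import scipy
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": mode,
        "quadrant_convention": QUADRANT_CONVENTION,
        "versions": {
            "fishtrack3d": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return 0
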