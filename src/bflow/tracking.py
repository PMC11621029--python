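"""Reading, calibrating and cleaning pose-estimation tracking tables.

Recordings are tables of per-frame x/y coordinates with a tracking
confidence ("likelihood") for each named body point, in the dialect
exported by markerless pose-estimation tools.  Coordinates follow image
convention: origin top-left, y increasing downward.  Arena geometry is
inferred from tracked corner points, which also yields the
pixel-to-centimeter conversion used by all metric readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.affinity import scale as _shapely_scale
from shapely.geometry import Polygon
from shapely import contains_xy


class PoseFormatError(ValueError):
    """Malformed pose table (header or column structure)."""


class GeometryError(ValueError):
    """Invalid arena geometry (too few corners, zero area, ...)."""


class UnrecoverableTrackError(ValueError):
    """A body point has no valid frames left after filtering."""


@dataclass
class BodyPointTrack:
    """Per-frame x/y position and tracking confidence of one body point."""

    point_name: str
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.likelihood)):
            raise PoseFormatError(
                f"track {self.point_name!r}: x/y/likelihood lengths differ"
            )

    def __len__(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class ArenaGeometry:
    """Arena polygon, named zones and the pixel-to-centimeter factor."""

    corner_polygon: np.ndarray  # (k, 2) ordered pixel vertices
    px_per_cm: float
    zones: dict[str, np.ndarray] = field(default_factory=dict)
    existence_scale: float = 1.3

    def __post_init__(self):
        self.corner_polygon = np.asarray(self.corner_polygon, dtype=float)
        if self.corner_polygon.shape[0] < 3:
            raise GeometryError("arena polygon needs >= 3 vertices")
        if Polygon(self.corner_polygon).area <= 0:
            raise GeometryError("arena polygon has zero area (collinear corners?)")
        if self.px_per_cm <= 0:
            raise GeometryError("px_per_cm must be > 0")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.corner_polygon)

    @property
    def existence_polygon(self) -> Polygon:
        return scale_polygon(self.polygon, self.existence_scale)

    def zone_polygon(self, name: str) -> Polygon:
        return Polygon(self.zones[name])


def scale_polygon(poly: Polygon, factor: float) -> Polygon:
    """Scale a polygon linearly about its centroid."""
    return _shapely_scale(poly, xfact=factor, yfact=factor, origin="centroid")


@dataclass
class TrackingRecording:
    """All tracked body points of one recording plus arena and kinematics."""

    recording_id: str
    fps: float
    tracks: dict[str, BodyPointTrack]
    arena: ArenaGeometry | None = None
    speed: dict[str, np.ndarray] = field(default_factory=dict)  # cm/s
    acceleration: dict[str, np.ndarray] = field(default_factory=dict)  # cm/s^2

    def __post_init__(self):
        lengths = {len(t) for t in self.tracks.values()}
        if len(lengths) > 1:
            raise PoseFormatError("tracks have inconsistent frame counts")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.tracks.values())))

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def point_names(self) -> list[str]:
        return list(self.tracks)


@dataclass
class ClassicalReadouts:
    """Conventional trajectory readouts: distance, zone times, transitions."""

    distance_moved_cm: float
    time_in_zone: dict[str, float]  # seconds
    zone_transitions: dict[tuple[str, str], int]


# ---------------------------------------------------------------------------
# I/O


def read_pose_table(path, dialect: str = "auto", fps: float = 25.0,
                    recording_id: str | None = None) -> TrackingRecording:
    """Read a pose-estimation CSV into a :class:`TrackingRecording`.

    Two dialects are supported: the three-header-row export
    (scorer / bodyparts / coords rows, per-point ``x``, ``y``,
    ``likelihood`` columns) and a flat single-header table with columns
    named ``<point>_x``, ``<point>_y``, ``<point>_likelihood``.  Missing
    likelihood columns default to 1.0.
    """
    path = str(path)
    if dialect == "auto":
        with open(path) as fh:
            first = fh.readline()
        dialect = "dlc" if first.lower().startswith("scorer") else "flat"

    if dialect == "dlc":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        tracks: dict[str, dict[str, np.ndarray]] = {}
        for col in df.columns:
            _, point, coord = col
            if coord not in ("x", "y", "likelihood"):
                raise PoseFormatError(f"unexpected coordinate column {col!r}")
            tracks.setdefault(point, {})[coord] = df[col].to_numpy(dtype=float)
    elif dialect == "flat":
        df = pd.read_csv(path)
        tracks = {}
        for name in df.columns:
            if name in ("frame", "index"):
                continue
            base, _, coord = name.rpartition("_")
            if coord not in ("x", "y", "likelihood") or not base:
                raise PoseFormatError(f"cannot parse column {name!r}")
            tracks.setdefault(base, {})[coord] = df[name].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    out: dict[str, BodyPointTrack] = {}
    for point, cols in tracks.items():
        if "x" not in cols or "y" not in cols:
            raise PoseFormatError(f"point {point!r} is missing x or y column")
        lik = cols.get("likelihood")
        if lik is None:
            lik = np.ones_like(cols["x"])
        out[point] = BodyPointTrack(point, cols["x"], cols["y"], lik)

    rid = recording_id or path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return TrackingRecording(recording_id=rid, fps=fps, tracks=out)


def write_pose_table(recording: TrackingRecording, path, dialect: str = "dlc",
                     scorer: str = "bflow") -> None:
    """Write a recording back to CSV in either supported dialect."""
    path = str(path)
    if dialect == "dlc":
        cols = {}
        for name, tr in recording.tracks.items():
            cols[(scorer, name, "x")] = tr.x
            cols[(scorer, name, "y")] = tr.y
            cols[(scorer, name, "likelihood")] = tr.likelihood
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(
            df.columns, names=["scorer", "bodyparts", "coords"])
        df.index.name = None
        df.to_csv(path, index_label="")
    elif dialect == "flat":
        cols = {}
        for name, tr in recording.tracks.items():
            cols[f"{name}_x"] = tr.x
            cols[f"{name}_y"] = tr.y
            cols[f"{name}_likelihood"] = tr.likelihood
        pd.DataFrame(cols).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Arena calibration


def infer_arena(recording: TrackingRecording, corner_names: list[str],
                real_size_cm2: float, existence_scale: float = 1.3,
                center_scale: float = 0.5,
                zones: dict[str, np.ndarray] | None = None) -> ArenaGeometry:
    """Infer arena geometry from tracked corner points.

    Each corner vertex is the per-coordinate median of that corner's
    track over all frames (robust to tracking jitter).  The conversion
    factor is ``px_per_cm = sqrt(pixel_area / real_size_cm2)``, i.e. the
    ratio of areas in pixels squared vs centimeters squared.

    When ``zones`` is not given, a ``center`` zone (the arena polygon
    scaled by ``center_scale`` about its centroid) and the complementary
    ``periphery`` are defined, as used for open-field readouts.
    """
    if len(corner_names) < 3:
        raise GeometryError("need at least 3 corner points")
    if real_size_cm2 <= 0:
        raise GeometryError("real arena size must be positive")
    verts = []
    for name in corner_names:
        if name not in recording.tracks:
            raise KeyError(f"corner point {name!r} not tracked")
        tr = recording.tracks[name]
        verts.append([np.nanmedian(tr.x), np.nanmedian(tr.y)])
    verts = np.asarray(verts)
    area_px = Polygon(verts).area
    if area_px <= 0:
        raise GeometryError("inferred arena polygon has zero area")
    px_per_cm = float(np.sqrt(area_px / real_size_cm2))

    if zones is None:
        center = scale_polygon(Polygon(verts), center_scale)
        zones = {
            "center": np.asarray(center.exterior.coords)[:-1],
            "periphery": verts,  # membership resolved in declaration order
        }
    return ArenaGeometry(corner_polygon=verts, px_per_cm=px_per_cm,
                         zones=zones, existence_scale=existence_scale)


# ---------------------------------------------------------------------------
# Cleaning and kinematics


def _interpolate(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation over invalid frames; edges filled by nearest."""
    s = pd.Series(np.where(valid, values, np.nan))
    return s.interpolate(method="linear", limit_direction="both").to_numpy()


def preprocess_recording(recording: TrackingRecording,
                         likelihood_threshold: float = 0.95,
                         existence_scale: float | None = None,
                         exclude_points: tuple[str, ...] = ()) -> TrackingRecording:
    """Filter unreliable frames and compute per-point kinematics.

    Frames where a point's likelihood falls below ``likelihood_threshold``
    or the point lies outside the existence polygon (the arena scaled by
    ``existence_scale``, default the arena's own setting of 1.3) are
    masked and refilled by linear interpolation in time; gaps at the
    edges take the nearest valid value.  Speed (cm/s) and acceleration
    (cm/s²) are first/second finite differences of the cleaned positions,
    with the first frame(s) padded by replication.

    ``exclude_points`` (e.g. arena corner points) are passed through
    unfiltered and get no kinematics.
    """
    if recording.arena is None:
        raise ValueError("arena must be inferred before preprocessing")
    arena = recording.arena
    if existence_scale is not None:
        arena = replace(arena, existence_scale=existence_scale)
    exist = arena.existence_polygon
    fps = recording.fps
    px_per_cm = arena.px_per_cm

    new_tracks: dict[str, BodyPointTrack] = {}
    speed: dict[str, np.ndarray] = {}
    accel: dict[str, np.ndarray] = {}
    for name, tr in recording.tracks.items():
        if name in exclude_points:
            new_tracks[name] = tr
            continue
        inside = contains_xy(exist, tr.x, tr.y)
        valid = (tr.likelihood >= likelihood_threshold) & inside & \
            np.isfinite(tr.x) & np.isfinite(tr.y)
        if not valid.any():
            raise UnrecoverableTrackError(
                f"point {name!r} has no valid frames after filtering")
        x = _interpolate(tr.x, valid)
        y = _interpolate(tr.y, valid)
        new_tracks[name] = BodyPointTrack(name, x, y, tr.likelihood.copy())

        dx = np.diff(x) / px_per_cm
        dy = np.diff(y) / px_per_cm
        v = np.hypot(dx, dy) * fps
        v = np.concatenate([[v[0]], v]) if len(v) else np.zeros(1)
        a = np.diff(v) * fps
        a = np.concatenate([[a[0]], a]) if len(a) else np.zeros(1)
        speed[name] = v
        accel[name] = a

    return TrackingRecording(
        recording_id=recording.recording_id, fps=fps, tracks=new_tracks,
        arena=arena, speed=speed, acceleration=accel)


# ---------------------------------------------------------------------------
# Classical readouts


def zone_membership(recording: TrackingRecording, reference_point: str) -> np.ndarray:
    """Per-frame zone name for the reference point.

    Zones are tested in declaration order and the first containing zone
    wins, so nested zone definitions (center inside arena) behave as a
    partition.  Frames outside every zone are labeled ``"<outside>"``.
    """
    if reference_point not in recording.tracks:
        raise KeyError(f"unknown reference point {reference_point!r}")
    arena = recording.arena
    if arena is None:
        raise ValueError("arena required for zone membership")
    tr = recording.tracks[reference_point]
    names = list(arena.zones)
    member = np.full(len(tr), "<outside>", dtype=object)
    unassigned = np.ones(len(tr), dtype=bool)
    for name in names:
        poly = arena.zone_polygon(name)
        inside = contains_xy(poly, tr.x, tr.y) & unassigned
        member[inside] = name
        unassigned &= ~inside
    return member


def classical_readouts(recording: TrackingRecording,
                       reference_point: str = "bodycenter") -> ClassicalReadouts:
    """Distance moved, per-zone times and zone-transition counts."""
    if reference_point not in recording.tracks:
        raise KeyError(f"unknown reference point {reference_point!r}")
    arena = recording.arena
    if arena is None:
        raise ValueError("arena required for classical readouts")
    tr = recording.tracks[reference_point]
    dist = float(np.hypot(np.diff(tr.x), np.diff(tr.y)).sum() / arena.px_per_cm)

    member = zone_membership(recording, reference_point)
    time_in_zone = {name: float((member == name).sum() / recording.fps)
                    for name in arena.zones}
    trans: dict[tuple[str, str], int] = {}
    changed = member[1:] != member[:-1]
    for a, b in zip(member[:-1][changed], member[1:][changed]):
        trans[(a, b)] = trans.get((a, b), 0) + 1
    return ClassicalReadouts(distance_moved_cm=dist, time_in_zone=time_in_zone,
                             zone_transitions=trans)
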