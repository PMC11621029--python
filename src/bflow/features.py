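"""Per-frame pose features and their temporal expansion.

Five feature kinds are computed from cleaned tracking: acceleration of a
point, Euclidean distance between a point pair, signed angle between two
point-pair vectors, distance of a point to the nearest arena border, and
the (shoelace) area of a polygon spanned by several points.  The default
registry defines m = 41 features over the 13 standard body points.
Per-recording normalization z-scores distances and areas, leaves angles
(radians) untouched, and scales border proximities by 0.1 and
accelerations by 4.  Each frame's feature vector is finally concatenated
with its neighbors over a symmetric window of ±h frames (t = 2h+1
frames; with the defaults m = 41, h = 15 this yields 1,271 columns),
encoding short behavioral sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from bflow.tracking import TrackingRecording

KINDS = ("point_acceleration", "pair_distance", "pairpair_angle",
         "border_proximity", "polygon_area")

#: linear scaling factors applied during per-recording normalization
LINEAR_FACTORS = {"border_proximity": 0.1, "point_acceleration": 4.0}

STANDARD_POINTS = (
    "nose", "headcenter", "neck", "earr", "earl", "bodycenter", "bcl",
    "bcr", "hipl", "hipr", "tailbase", "tailcenter", "tailtip",
)


class FeatureConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: its kind and the body points it operates on."""

    name: str
    kind: str
    operands: tuple  # points, or point pairs for pairpair_angle

    def __post_init__(self):
        if self.kind not in KINDS:
            raise FeatureConfigError(f"unknown feature kind {self.kind!r}")
        n = len(self.operands)
        ok = {"point_acceleration": n == 1, "pair_distance": n == 2,
              "pairpair_angle": n == 2, "border_proximity": n == 1,
              "polygon_area": n >= 3}[self.kind]
        if not ok:
            raise FeatureConfigError(
                f"feature {self.name!r}: wrong operand count for {self.kind}")

    @property
    def normalization(self) -> str:
        if self.kind in ("pair_distance", "polygon_area"):
            return "zscore"
        if self.kind == "pairpair_angle":
            return "raw"
        return f"linear({LINEAR_FACTORS[self.kind]})"


@dataclass
class FeatureRegistry:
    """Ordered, fixed list of feature specifications."""

    specs: list[FeatureSpec]

    @property
    def m(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def operand_points(self) -> set[str]:
        pts: set[str] = set()
        for s in self.specs:
            if s.kind == "pairpair_angle":
                for pair in s.operands:
                    pts.update(pair)
            else:
                pts.update(s.operands)
        return pts


@dataclass
class FeatureMatrix:
    recording_id: str
    values: np.ndarray  # N x m
    columns: list[str]
    kinds: list[str]
    fps: float = 25.0

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class TemporalFeatureMatrix:
    """Windowed feature matrix: row f holds frames f-h ... f+h concatenated."""

    recording_id: str
    values: np.ndarray  # N' x (m*t)
    halfwidth: int
    frame_offset: int
    columns: list[str] = field(default_factory=list)
    fps: float = 25.0

    @property
    def t(self) -> int:
        return 2 * self.halfwidth + 1


def _canonical_sort_key(spec: FeatureSpec):
    return (KINDS.index(spec.kind), spec.name)


def build_feature_registry(config: list[dict] | None = None) -> FeatureRegistry:
    """Build a registry from a list of feature dicts (canonically ordered).

    Each dict has keys ``name``, ``kind`` and ``operands`` (point names,
    or two [point, point] pairs for ``pairpair_angle``).  Entries are
    sorted into a canonical order (by kind, then name) so the registry is
    deterministic regardless of config file ordering.
    """
    if config is None:
        return default_feature_registry()
    specs = []
    seen = set()
    for entry in config:
        name = entry["name"]
        if name in seen:
            raise FeatureConfigError(f"duplicate feature name {name!r}")
        seen.add(name)
        kind = entry["kind"]
        ops = entry["operands"]
        if kind == "pairpair_angle":
            ops = tuple(tuple(p) for p in ops)
        else:
            ops = tuple(ops)
        specs.append(FeatureSpec(name=name, kind=kind, operands=ops))
    specs.sort(key=_canonical_sort_key)
    return FeatureRegistry(specs)


def default_feature_registry() -> FeatureRegistry:
    """The default 41-feature registry over the 13 standard body points.

    13 point accelerations, 12 pair distances, 6 pair-pair angles,
    6 border proximities and 4 polygon areas.
    """
    specs: list[FeatureSpec] = []
    for p in STANDARD_POINTS:
        specs.append(FeatureSpec(f"acc_{p}", "point_acceleration", (p,)))
    pairs = [
        ("nose", "neck"), ("nose", "tailbase"), ("neck", "bodycenter"),
        ("bodycenter", "tailbase"), ("earl", "earr"), ("bcl", "bcr"),
        ("hipl", "hipr"), ("nose", "bodycenter"), ("headcenter", "bodycenter"),
        ("tailbase", "tailcenter"), ("tailcenter", "tailtip"),
        ("headcenter", "tailbase"),
    ]
    for a, b in pairs:
        specs.append(FeatureSpec(f"dist_{a}_{b}", "pair_distance", (a, b)))
    angles = [
        (("neck", "nose"), ("bodycenter", "neck")),
        (("bodycenter", "neck"), ("tailbase", "bodycenter")),
        (("tailbase", "tailcenter"), ("tailcenter", "tailtip")),
        (("earl", "earr"), ("bcl", "bcr")),
        (("nose", "headcenter"), ("headcenter", "neck")),
        (("hipl", "hipr"), ("bcl", "bcr")),
    ]
    for (a1, a2), (b1, b2) in angles:
        specs.append(FeatureSpec(
            f"angle_{a1}{a2}_{b1}{b2}", "pairpair_angle", ((a1, a2), (b1, b2))))
    for p in ("nose", "headcenter", "bodycenter", "tailbase", "hipl", "hipr"):
        specs.append(FeatureSpec(f"border_{p}", "border_proximity", (p,)))
    polys = [
        ("head", ("nose", "earl", "neck", "earr")),
        ("torso", ("neck", "bcl", "tailbase", "bcr")),
        ("hind", ("bodycenter", "hipl", "tailbase", "hipr")),
        ("body", ("nose", "earl", "bcl", "hipl", "tailbase", "hipr", "bcr", "earr")),
    ]
    for name, pts in polys:
        specs.append(FeatureSpec(f"area_{name}", "polygon_area", pts))
    reg = FeatureRegistry(specs)
    assert reg.m == 41
    return reg


# ---------------------------------------------------------------------------
# Extraction


def _signed_angle(v1x, v1y, v2x, v2y):
    """Signed angle from vector 1 to vector 2, wrapped to (-pi, pi]."""
    ang = np.arctan2(v2y, v2x) - np.arctan2(v1y, v1x)
    ang = np.mod(ang + np.pi, 2 * np.pi) - np.pi
    # map -pi -> pi so the range is (-pi, pi]
    ang = np.where(ang == -np.pi, np.pi, ang)
    return ang


def _border_distance(arena_poly: Polygon, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Distance of each (x, y) to the nearest arena edge (pixels)."""
    from shapely import points as shapely_points, distance as shapely_distance
    boundary = arena_poly.exterior
    pts = shapely_points(np.column_stack([x, y]))
    return shapely_distance(boundary, pts)


def extract_features(recording: TrackingRecording,
                     registry: FeatureRegistry) -> FeatureMatrix:
    """Evaluate every registry feature per frame (metric units)."""
    if not recording.speed:
        raise ValueError("recording has no kinematics; run preprocess_recording")
    missing = registry.operand_points() - set(recording.tracks)
    if missing:
        raise FeatureConfigError(f"registry references untracked points: {sorted(missing)}")
    ppc = recording.arena.px_per_cm if recording.arena else 1.0
    n = recording.n_frames
    out = np.empty((n, registry.m))
    border_cache: dict[str, np.ndarray] = {}
    for j, spec in enumerate(registry.specs):
        if spec.kind == "point_acceleration":
            out[:, j] = recording.acceleration[spec.operands[0]]
        elif spec.kind == "pair_distance":
            a = recording.tracks[spec.operands[0]]
            b = recording.tracks[spec.operands[1]]
            out[:, j] = np.hypot(a.x - b.x, a.y - b.y) / ppc
        elif spec.kind == "pairpair_angle":
            (a1, a2), (b1, b2) = spec.operands
            t = recording.tracks
            out[:, j] = _signed_angle(
                t[a2].x - t[a1].x, t[a2].y - t[a1].y,
                t[b2].x - t[b1].x, t[b2].y - t[b1].y)
        elif spec.kind == "border_proximity":
            p = spec.operands[0]
            if p not in border_cache:
                tr = recording.tracks[p]
                border_cache[p] = _border_distance(
                    recording.arena.polygon, tr.x, tr.y) / ppc
            out[:, j] = border_cache[p]
        elif spec.kind == "polygon_area":
            pts = [recording.tracks[p] for p in spec.operands]
            xs = np.column_stack([p.x for p in pts])
            ys = np.column_stack([p.y for p in pts])
            # shoelace formula, vectorized over frames
            area = 0.5 * np.abs(
                np.sum(xs * np.roll(ys, -1, axis=1) - np.roll(xs, -1, axis=1) * ys,
                       axis=1))
            out[:, j] = area / ppc ** 2
    return FeatureMatrix(recording_id=recording.recording_id, values=out,
                         columns=registry.names,
                         kinds=[s.kind for s in registry.specs],
                         fps=recording.fps)


def normalize_per_recording(X: FeatureMatrix,
                            registry: FeatureRegistry) -> FeatureMatrix:
    """Per-recording normalization by feature kind.

    Distances and areas are z-scored within the recording; angles are
    left as raw radians; border proximities are multiplied by 0.1 and
    accelerations by 4.  A zero-variance distance/area column is set to 0
    (with a warning) rather than dividing by zero.
    """
    if X.columns != registry.names:
        raise ValueError("feature matrix columns do not match registry")
    vals = X.values.copy()
    for j, spec in enumerate(registry.specs):
        if spec.kind in ("pair_distance", "polygon_area"):
            sd = vals[:, j].std()
            if sd == 0:
                warnings.warn(
                    f"zero-variance column {spec.name!r}; set to 0", stacklevel=2)
                vals[:, j] = 0.0
            else:
                vals[:, j] = (vals[:, j] - vals[:, j].mean()) / sd
        elif spec.kind in LINEAR_FACTORS:
            vals[:, j] = vals[:, j] * LINEAR_FACTORS[spec.kind]
        # angles: raw
    return FeatureMatrix(recording_id=X.recording_id, values=vals,
                         columns=list(X.columns), kinds=list(X.kinds), fps=X.fps)


def temporal_expand(X: FeatureMatrix | np.ndarray, halfwidth: int = 15,
                    recording_id: str | None = None,
                    fps: float = 25.0) -> TemporalFeatureMatrix:
    """Concatenate each frame's features with its ±halfwidth neighbors.

    Row f of the result is the concatenation of the input rows
    f-h, ..., f+h (offset-major order).  Frames without a full window are
    dropped; ``frame_offset`` records the shift needed to re-align labels
    with original frame indices.
    """
    if isinstance(X, FeatureMatrix):
        vals, rid, cols, fps = X.values, X.recording_id, X.columns, X.fps
    else:
        vals = np.asarray(X, dtype=float)
        rid = recording_id or ""
        cols = [f"f{j}" for j in range(vals.shape[1])]
    n, m = vals.shape
    h = int(halfwidth)
    if h < 0:
        raise ValueError("halfwidth must be >= 0")
    if n <= 2 * h:
        raise ValueError(f"need more than {2 * h} frames for halfwidth {h}")
    t = 2 * h + 1
    n_out = n - 2 * h
    out = np.empty((n_out, m * t))
    colnames = []
    for w in range(t):
        out[:, w * m:(w + 1) * m] = vals[w:w + n_out]
        off = w - h
        colnames.extend(f"{c}@{off:+d}" for c in cols)
    return TemporalFeatureMatrix(recording_id=rid, values=out, halfwidth=h,
                                 frame_offset=h, columns=colnames, fps=fps)
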