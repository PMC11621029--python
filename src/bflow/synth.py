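"""Synthetic behavioral data with the structure the pipeline assumes.

Label sequences follow a run-then-switch process: a hidden Markov-style
kernel with geometric dwell times (mean run length defaults to 20
frames, long enough that ±5-frame modal smoothing rarely destroys true
runs) and a zero-diagonal inter-state transition matrix.  Per-animal
variability perturbs each kernel row with a Dirichlet draw; group
effects multiply selected transition probabilities and renormalize.
Pose recordings place a coarse 13-point body ellipse on a centroid that
moves with state-dependent kinematics inside an arena, with Gaussian
positional jitter, occasional low-likelihood frames, and four jittered
static corner points — enough structure to exercise every pipeline
stage, with no claim of biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bflow.flow import LabelSequence
from bflow.tracking import ArenaGeometry, BodyPointTrack, TrackingRecording

DEFAULT_N_FRAMES = 15_000
DEFAULT_MEAN_RUN = 20.0

# canonical 13-point body template: (forward, lateral) offsets in units of
# body length, image convention (lateral > 0 is the animal's left)
BODY_TEMPLATE = {
    "nose": (0.50, 0.00), "headcenter": (0.36, 0.00), "neck": (0.28, 0.00),
    "earr": (0.36, -0.09), "earl": (0.36, 0.09), "bodycenter": (0.00, 0.00),
    "bcl": (0.00, 0.13), "bcr": (0.00, -0.13), "hipl": (-0.20, 0.10),
    "hipr": (-0.20, -0.10), "tailbase": (-0.30, 0.00),
    "tailcenter": (-0.52, 0.00), "tailtip": (-0.74, 0.00),
}
CORNER_NAMES = ("corner_tl", "corner_tr", "corner_br", "corner_bl")


@dataclass
class BehaviorKernel:
    """Markov behavior generator: geometric dwells + inter-state matrix."""

    transition: np.ndarray  # zero diagonal, rows sum to 1
    mean_run_length: float = DEFAULT_MEAN_RUN

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        t = self.transition
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(np.diag(t) != 0):
            raise ValueError("inter-state matrix must have zero diagonal")
        if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1) > 1e-12):
            raise ValueError("rows must be probabilities summing to 1")
        if self.mean_run_length < 1:
            raise ValueError("mean run length must be >= 1 frame")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @classmethod
    def uniform(cls, n_states: int,
                mean_run_length: float = DEFAULT_MEAN_RUN) -> "BehaviorKernel":
        """Equal probability of switching to any other state."""
        t = np.full((n_states, n_states), 1.0 / (n_states - 1))
        np.fill_diagonal(t, 0.0)
        return cls(t, mean_run_length)

    @classmethod
    def random(cls, n_states: int, seed: int = 0, concentration: float = 1.0,
               mean_run_length: float = DEFAULT_MEAN_RUN) -> "BehaviorKernel":
        """Dirichlet-random off-diagonal rows."""
        rng = np.random.default_rng(seed)
        t = np.zeros((n_states, n_states))
        for i in range(n_states):
            off = [j for j in range(n_states) if j != i]
            t[i, off] = rng.dirichlet(np.full(n_states - 1, concentration))
        return cls(t, mean_run_length)

    @classmethod
    def cycle(cls, states: list[int], n_states: int | None = None,
              mean_run_length: float = DEFAULT_MEAN_RUN) -> "BehaviorKernel":
        """Deterministic cycle through ``states`` (other states unreachable)."""
        n = n_states or (max(states) + 1)
        t = np.zeros((n, n))
        for a, b in zip(states, states[1:] + states[:1]):
            t[a, b] = 1.0
        # unreachable states need valid rows; send them into the cycle
        for i in range(n):
            if t[i].sum() == 0:
                t[i, states[0] if states[0] != i else states[1]] = 1.0
        return cls(t, mean_run_length)


@dataclass
class GroupEffectSpec:
    """Multiplicative treatment effect on selected transitions."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    factors: list[float] = field(default_factory=list)

    def __post_init__(self):
        if len(self.pairs) != len(self.factors):
            raise ValueError("pairs and factors must have equal length")
        if any(f <= 0 for f in self.factors):
            raise ValueError("factors must be positive")

    def apply(self, kernel: BehaviorKernel) -> BehaviorKernel:
        """Scale the targeted probabilities and renormalize affected rows."""
        t = kernel.transition.copy()
        for (j, k), f in zip(self.pairs, self.factors):
            if j == k:
                raise ValueError("diagonal transitions do not exist")
            t[j, k] *= f
        rows = {j for j, _ in self.pairs}
        for j in rows:
            t[j] /= t[j].sum()
        return BehaviorKernel(t, kernel.mean_run_length)


@dataclass
class SyntheticExperiment:
    """Simulated two-group experiment with full ground truth."""

    recordings: list[LabelSequence]
    assignment: dict[str, str]  # recording_id -> "control" | "treated"
    kernels: dict[str, BehaviorKernel]
    master_seed: int

    def group_ids(self, group: str) -> list[str]:
        return [rid for rid, g in self.assignment.items() if g == group]


def simulate_labels(kernel: BehaviorKernel, n_frames: int = DEFAULT_N_FRAMES,
                    seed: int = 0, recording_id: str = "sim",
                    fps: float = 25.0) -> LabelSequence:
    """Sample a label sequence: geometric dwells, Markov state switches."""
    rng = np.random.default_rng(seed)
    p_switch = 1.0 / kernel.mean_run_length
    cum = np.cumsum(kernel.transition, axis=1)
    state = int(rng.integers(kernel.n_states))
    chunks = []
    total = 0
    while total < n_frames:
        dwell = int(rng.geometric(p_switch))
        chunks.append((state, min(dwell, n_frames - total)))
        total += dwell
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
    labels = np.concatenate([np.full(d, s, dtype=np.int64) for s, d in chunks])
    return LabelSequence(recording_id=recording_id, labels=labels,
                         alphabet=np.arange(kernel.n_states), fps=fps)


def _jitter_kernel(base: BehaviorKernel, concentration: float,
                   rng: np.random.Generator) -> BehaviorKernel:
    """Per-animal kernel: Dirichlet perturbation of each row."""
    if concentration <= 0:
        raise ValueError("jitter concentration must be positive")
    if np.isinf(concentration):
        return BehaviorKernel(base.transition.copy(), base.mean_run_length)
    n = base.n_states
    t = np.zeros_like(base.transition)
    for i in range(n):
        off = np.flatnonzero(np.arange(n) != i)
        alpha = base.transition[i, off] * concentration
        alpha = np.maximum(alpha, 1e-9)  # Dirichlet needs strictly positive
        t[i, off] = rng.dirichlet(alpha)
    return BehaviorKernel(t, base.mean_run_length)


def simulate_experiment(n_per_group: int, base_kernel: BehaviorKernel,
                        effect: GroupEffectSpec | None = None,
                        jitter_concentration: float = 200.0, seed: int = 0,
                        n_frames: int = DEFAULT_N_FRAMES,
                        fps: float = 25.0) -> SyntheticExperiment:
    """Two-group experiment: control vs effect-modified treated animals.

    Each animal's kernel is a seeded Dirichlet perturbation of its
    group's kernel (control = base, treated = base with the effect
    applied); an identity effect yields a null experiment with
    exchangeable groups.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 animals per group")
    rng = np.random.default_rng(seed)
    treated_kernel = effect.apply(base_kernel) if effect is not None \
        else base_kernel
    recordings, assignment, kernels = [], {}, {}
    for group, gkernel in (("control", base_kernel), ("treated", treated_kernel)):
        for i in range(n_per_group):
            rid = f"{group}_{i:02d}"
            animal = _jitter_kernel(gkernel, jitter_concentration, rng)
            seq = simulate_labels(animal, n_frames=n_frames,
                                  seed=int(rng.integers(2 ** 31)),
                                  recording_id=rid, fps=fps)
            recordings.append(seq)
            assignment[rid] = group
            kernels[rid] = animal
    return SyntheticExperiment(recordings=recordings, assignment=assignment,
                               kernels=kernels, master_seed=seed)


def simulate_feature_recordings(n_recordings: int, n_clusters: int,
                                dim: int = 50, n_frames: int = 400,
                                separation: float = 6.0, noise_sd: float = 1.0,
                                mean_run_length: float = DEFAULT_MEAN_RUN,
                                seed: int = 0):
    """Synthetic expanded-feature recordings with known cluster labels.

    Cluster centers are isotropic Gaussian draws scaled so that centers
    sit ``separation`` noise-SDs apart on average; every recording walks
    through clusters with the run-then-switch kernel and each frame's
    feature row is its cluster center plus Gaussian noise.  Returns a
    list of ``(recording_id, X, labels)`` suitable for recording-level
    cross-validation, plus the ground-truth centers.
    """
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_clusters, dim))
    # two iid N(0, s^2 I_d) centers are ~ s*sqrt(2d) apart; pick s so the
    # typical gap is separation * sqrt(dim) noise SDs
    centers *= separation / np.sqrt(2.0)
    kernel = BehaviorKernel.uniform(n_clusters, mean_run_length)
    recordings = []
    for r in range(n_recordings):
        seq = simulate_labels(kernel, n_frames=n_frames,
                              seed=int(rng.integers(2 ** 31)),
                              recording_id=f"rec_{r:02d}")
        X = centers[seq.labels] + noise_sd * rng.standard_normal(
            (n_frames, dim))
        recordings.append((seq.recording_id, X, seq.labels.copy()))
    return recordings, centers


@dataclass
class PoseStateStyle:
    """Per-state kinematics of the simulated animal."""

    speed_range: tuple[float, float]  # cm/s
    elongation: float = 1.0  # longitudinal body-template scale factor
    turn_sd: float = 0.4  # rad per frame, heading random walk
    width: float = 1.0  # lateral body-template scale factor


def default_styles(n_states: int) -> dict[int, PoseStateStyle]:
    """Coarse style ladder: slower, compact states to fast, stretched ones.

    Elongation and width move in opposite directions (a running animal
    stretches and narrows) so states differ along two shape axes.
    """
    styles = {}
    for s in range(n_states):
        t = s / max(n_states - 1, 1)
        lo = 1.0 + 6.0 * t
        styles[s] = PoseStateStyle(speed_range=(lo, lo + 2.0),
                                   elongation=0.8 + 0.4 * t,
                                   width=1.2 - 0.4 * t)
    return styles


def square_arena(side_cm: float = 40.0, px_per_cm: float = 10.0) -> ArenaGeometry:
    """Simple square arena in image coordinates."""
    s = side_cm * px_per_cm
    corners = np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=float)
    from bflow.tracking import Polygon, scale_polygon
    center = scale_polygon(Polygon(corners), 0.5)
    return ArenaGeometry(
        corner_polygon=corners, px_per_cm=px_per_cm,
        zones={"center": np.asarray(center.exterior.coords)[:-1],
               "periphery": corners})


def simulate_pose(labels: LabelSequence, arena: ArenaGeometry | None = None,
                  styles: dict[int, PoseStateStyle] | None = None,
                  seed: int = 0, body_length_cm: float = 8.0,
                  jitter_px: float = 0.5, likelihood_dip_rate: float = 0.02,
                  corner_jitter_px: float = 1.0) -> TrackingRecording:
    """Render a label sequence into a 13-point tracking recording.

    The centroid performs a state-driven correlated random walk inside
    the arena (reflected at a safety margin); the 13 body points follow a
    rigid ellipse template rotated to the heading with state-dependent
    longitudinal (elongation) and lateral (width) scaling.  Likelihood dips below 0.95 occur independently per point
    and frame at ``likelihood_dip_rate``.  Four static corner points with
    Gaussian jitter are appended for arena inference.
    """
    rng = np.random.default_rng(seed)
    if arena is None:
        arena = square_arena()
    styles = styles or default_styles(len(labels.alphabet))
    missing = set(labels.alphabet.tolist()) - set(styles)
    if missing:
        raise ValueError(f"styles missing for states {sorted(missing)}")

    n = len(labels)
    ppc = arena.px_per_cm
    fps = labels.fps
    verts = arena.corner_polygon
    lo = verts.min(axis=0) + 0.15 * (verts.max(axis=0) - verts.min(axis=0))
    hi = verts.max(axis=0) - 0.15 * (verts.max(axis=0) - verts.min(axis=0))

    pos = np.empty((n, 2))
    heading = np.empty(n)
    pos[0] = (lo + hi) / 2
    heading[0] = rng.uniform(-np.pi, np.pi)
    lab = np.asarray(labels.labels)
    for f in range(1, n):
        st = styles[int(lab[f])]
        heading[f] = heading[f - 1] + rng.normal(0.0, st.turn_sd)
        speed = rng.uniform(*st.speed_range)  # cm/s
        step = speed * ppc / fps
        cand = pos[f - 1] + step * np.array([np.cos(heading[f]),
                                             np.sin(heading[f])])
        for d in range(2):  # reflect at the margin box
            if cand[d] < lo[d]:
                cand[d] = 2 * lo[d] - cand[d]
                heading[f] += np.pi / 2
            elif cand[d] > hi[d]:
                cand[d] = 2 * hi[d] - cand[d]
                heading[f] += np.pi / 2
        pos[f] = np.clip(cand, lo, hi)

    body = body_length_cm * ppc
    long_scale = body * np.array([styles[int(s)].elongation for s in lab])
    lat_scale = body * np.array([styles[int(s)].width for s in lab])
    cos_h, sin_h = np.cos(heading), np.sin(heading)
    tracks: dict[str, BodyPointTrack] = {}
    for name, (fwd, lat) in BODY_TEMPLATE.items():
        x = pos[:, 0] + long_scale * fwd * cos_h - lat_scale * lat * sin_h
        y = pos[:, 1] + long_scale * fwd * sin_h + lat_scale * lat * cos_h
        if jitter_px > 0:
            x = x + rng.normal(0, jitter_px, n)
            y = y + rng.normal(0, jitter_px, n)
        lik = np.ones(n)
        if likelihood_dip_rate > 0:
            dips = rng.random(n) < likelihood_dip_rate
            lik[dips] = rng.uniform(0.0, 0.95, dips.sum())
        tracks[name] = BodyPointTrack(name, x, y, lik)

    for cname, (cx, cy) in zip(CORNER_NAMES, verts):
        x = np.full(n, cx) + rng.normal(0, corner_jitter_px, n)
        y = np.full(n, cy) + rng.normal(0, corner_jitter_px, n)
        tracks[cname] = BodyPointTrack(cname, x, y, np.ones(n))

    return TrackingRecording(recording_id=labels.recording_id, fps=fps,
                             tracks=tracks, arena=arena)
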