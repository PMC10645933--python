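"""Behavioral metrics from tracked-keypoint trajectories.

Computes the standard readouts of three rodent memory assays from a
pose-estimation trajectory (nose, head-center, body-center keypoints)
plus an arena geometry:

* novel object recognition (NORT): object-exploration detection and the
  discrimination index,
* Y-maze: arm-entry sequence and the spontaneous-alternation ratio,
* Morris water maze (MWM): escape latency, swim path length, speed,
  and — for the probe trial — quadrant occupancy and mean distance to
  the former platform location.

All coordinates are in cm with the origin at the arena center and the
y-axis pointing up.  Trajectories are consumed as produced by a tracking
network; pose estimation itself is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

__all__ = [
    "Trajectory",
    "ArenaSpec",
    "TrialMetrics",
    "nort_arena",
    "ymaze_arena",
    "mwm_arena",
    "detect_exploration",
    "exploration_times",
    "discrimination_index",
    "detect_arm_entries",
    "spontaneous_alternation",
    "mwm_trial_metrics",
    "mwm_probe_metrics",
]

#: keypoints below this confidence are treated as tracking dropouts
DEFAULT_LIKELIHOOD_CUTOFF = 0.6
#: dropout gaps up to this duration are linearly interpolated
DEFAULT_MAX_GAP_S = 0.5

KEYPOINTS = ("nose", "head", "body")


class UndefinedMetricError(ValueError):
    """A metric is undefined for this trial (e.g. zero exploration time).

    Trials raising this are excluded from group statistics rather than
    contributing a placeholder value.
    """


@dataclass
class Trajectory:
    """One trial's tracked keypoints, in cm.

    Parameters
    ----------
    time_s : ndarray, shape (n,)
        Strictly increasing per-frame timestamps in seconds.
    nose_xy, head_xy, body_xy : ndarray, shape (n, 2)
        Keypoint coordinates.  ``head_xy`` is the head center; the
        heading vector of frame *i* is ``nose_xy[i] - head_xy[i]``.
    likelihood : ndarray, shape (n, 3), optional
        Tracking confidence per keypoint (nose, head, body) in [0, 1].
        Defaults to all ones.
    """

    time_s: np.ndarray
    nose_xy: np.ndarray
    head_xy: np.ndarray
    body_xy: np.ndarray
    likelihood: np.ndarray | None = None
    #: frames excluded from time-based denominators (set by ``clean``)
    valid: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        for name in ("nose_xy", "head_xy", "body_xy"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.time_s), 2):
                raise ValueError(f"{name} must have shape (n_frames, 2)")
            setattr(self, name, arr)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.likelihood is None:
            self.likelihood = np.ones((len(self.time_s), 3))
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.likelihood.shape != (len(self.time_s), 3):
            raise ValueError("likelihood must have shape (n_frames, 3)")
        if self.valid is None:
            self.valid = np.ones(len(self.time_s), dtype=bool)

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def frame_period_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    def clean(
        self,
        likelihood_cutoff: float = DEFAULT_LIKELIHOOD_CUTOFF,
        max_gap_s: float = DEFAULT_MAX_GAP_S,
    ) -> "Trajectory":
        """Gap-fill low-confidence keypoints.

        Frames where any keypoint's likelihood falls below
        ``likelihood_cutoff`` are linearly interpolated from the
        neighbouring confident frames when the dropout gap lasts at most
        ``max_gap_s`` seconds; longer gaps are marked invalid and
        excluded from every time-based denominator downstream.
        """
        out = Trajectory(
            self.time_s.copy(),
            self.nose_xy.copy(),
            self.head_xy.copy(),
            self.body_xy.copy(),
            self.likelihood.copy(),
        )
        bad = self.likelihood < likelihood_cutoff  # (n, 3)
        valid = np.ones(len(self), dtype=bool)
        for k, name in enumerate(("nose_xy", "head_xy", "body_xy")):
            mask = bad[:, k]
            if not mask.any():
                continue
            arr = getattr(out, name)
            good_idx = np.flatnonzero(~mask)
            if len(good_idx) < 2:
                valid &= ~mask
                continue
            for lo, hi in _runs(mask):
                gap_s = self.time_s[hi - 1] - self.time_s[lo] + self.frame_period_s
                interior = lo > 0 and hi < len(self)
                if interior and gap_s <= max_gap_s:
                    for col in (0, 1):
                        arr[lo:hi, col] = np.interp(
                            self.time_s[lo:hi],
                            self.time_s[[lo - 1, hi]],
                            arr[[lo - 1, hi], col],
                        )
                else:
                    valid[lo:hi] = False
        out.valid = valid
        return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [lo, hi) index runs of consecutive True values."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


# ---------------------------------------------------------------------------
# Arena geometry
# ---------------------------------------------------------------------------

QUADRANT_LABELS = ("N", "E", "S", "W")


@dataclass
class ArenaSpec:
    """Geometry of one apparatus, in cm, origin at the arena center.

    ``kind`` selects which field group is meaningful:

    * ``"nort"`` — square open-field arena of side ``side_cm`` holding two
      objects; ``object_centers`` maps object id to (x, y) and
      ``novel_object_id`` names the novel one.
    * ``"ymaze"`` — three arms at 120° (labels in ``arm_labels``), each a
      rectangle ``arm_length_cm`` long and ``arm_width_cm`` wide attached
      to a central zone.
    * ``"mwm"`` / ``"mwm_probe"`` — circular pool with a platform circle and
      four quadrants N/E/S/W split by the diagonals; ``target_quadrant``
      holds the platform.
    """

    kind: str
    # nort
    side_cm: float = 40.0
    object_centers: dict[str, tuple[float, float]] | None = None
    object_radius_cm: float = 1.5
    novel_object_id: str | None = None
    # ymaze
    arm_labels: tuple[str, ...] = ("A", "B", "C")
    arm_length_cm: float = 35.0
    arm_width_cm: float = 5.0
    arm_angles_deg: tuple[float, ...] = (90.0, 210.0, 330.0)
    # mwm
    pool_radius_cm: float = 60.0
    platform_center: tuple[float, float] = (21.2, 21.2)
    platform_radius_cm: float = 5.0
    target_quadrant: str = "N"

    def __post_init__(self) -> None:
        if self.kind not in ("nort", "ymaze", "mwm", "mwm_probe"):
            raise ValueError(f"unknown arena kind {self.kind!r}")
        if self.kind == "nort" and self.object_centers is None:
            raise ValueError("nort arena requires object_centers")
        if self.kind in ("mwm", "mwm_probe"):
            if math.hypot(*self.platform_center) + self.platform_radius_cm > self.pool_radius_cm:
                raise ValueError("platform must lie inside the pool")

    # -- ymaze helpers ------------------------------------------------
    def arm_axis(self, label: str) -> np.ndarray:
        """Unit vector from the maze center along arm ``label``."""
        ang = math.radians(self.arm_angles_deg[self.arm_labels.index(label)])
        return np.array([math.cos(ang), math.sin(ang)])

    @property
    def center_zone_radius_cm(self) -> float:
        # arms of width w meeting at 120° leave a central zone whose
        # inscribed radius is w / (2 tan 60°) from each arm mouth; use the
        # circumradius so arm rectangles start clear of the junction
        return self.arm_width_cm / math.sqrt(3.0)

    def arm_polygon(self, label: str) -> Polygon:
        u = self.arm_axis(label)
        v = np.array([-u[1], u[0]])
        r0, r1 = self.center_zone_radius_cm, self.center_zone_radius_cm + self.arm_length_cm
        h = self.arm_width_cm / 2.0
        corners = [r0 * u + h * v, r1 * u + h * v, r1 * u - h * v, r0 * u - h * v]
        return Polygon([tuple(c) for c in corners])

    def maze_polygon(self) -> "shapely.Geometry":
        parts = [self.arm_polygon(a) for a in self.arm_labels]
        parts.append(Point(0.0, 0.0).buffer(self.center_zone_radius_cm * 1.5, quad_segs=16))
        return shapely.unary_union(parts)

    def arm_depth(self, xy: np.ndarray, label: str) -> np.ndarray:
        """Fractional penetration (0 at the mouth, 1 at the far end) of
        points ``xy`` into arm ``label``; meaningful only inside the arm."""
        u = self.arm_axis(label)
        proj = np.asarray(xy) @ u
        return (proj - self.center_zone_radius_cm) / self.arm_length_cm

    # -- mwm helpers --------------------------------------------------
    def quadrant_of(self, xy: np.ndarray) -> np.ndarray:
        """Quadrant label per point; quadrants split by the ±45° diagonals
        so each cardinal label spans 90° around its axis."""
        xy = np.atleast_2d(xy)
        ang = np.degrees(np.arctan2(xy[:, 1], xy[:, 0])) % 360.0
        labels = np.empty(len(xy), dtype="<U1")
        labels[(ang >= 45) & (ang < 135)] = "N"
        labels[(ang >= 135) & (ang < 225)] = "W"
        labels[(ang >= 225) & (ang < 315)] = "S"
        labels[(ang < 45) | (ang >= 315)] = "E"
        return labels


def nort_arena(
    side_cm: float = 40.0,
    object_offset_cm: float = 10.0,
    object_radius_cm: float = 1.5,
    novel_side: str = "right",
) -> ArenaSpec:
    """Square NORT arena with two symmetrically placed objects."""
    centers = {"left": (-object_offset_cm, 0.0), "right": (object_offset_cm, 0.0)}
    return ArenaSpec(
        kind="nort",
        side_cm=side_cm,
        object_centers=centers,
        object_radius_cm=object_radius_cm,
        novel_object_id=novel_side,
    )


def ymaze_arena(arm_length_cm: float = 35.0, arm_width_cm: float = 5.0) -> ArenaSpec:
    return ArenaSpec(kind="ymaze", arm_length_cm=arm_length_cm, arm_width_cm=arm_width_cm)


def mwm_arena(
    pool_radius_cm: float = 60.0,
    platform_radius_cm: float = 5.0,
    target_quadrant: str = "N",
    probe: bool = False,
) -> ArenaSpec:
    """Circular Morris water maze; the platform sits mid-radius in the
    target quadrant."""
    axis = {"N": (0.0, 1.0), "E": (1.0, 0.0), "S": (0.0, -1.0), "W": (-1.0, 0.0)}[target_quadrant]
    r = pool_radius_cm / 2.0
    return ArenaSpec(
        kind="mwm_probe" if probe else "mwm",
        pool_radius_cm=pool_radius_cm,
        platform_center=(axis[0] * r, axis[1] * r),
        platform_radius_cm=platform_radius_cm,
        target_quadrant=target_quadrant,
    )


# ---------------------------------------------------------------------------
# Metrics container
# ---------------------------------------------------------------------------


@dataclass
class TrialMetrics:
    """Per-trial behavioral readouts; unfilled fields stay ``None``."""

    discrimination_index: float | None = None
    exploration_time_novel_s: float | None = None
    exploration_time_old_s: float | None = None
    alternation_ratio: float | None = None
    arm_entries: int | None = None
    path_length_cm: float | None = None
    escape_latency_s: float | None = None
    mean_speed_cm_s: float | None = None
    quadrant_time_s: dict[str, float] | None = None
    mean_distance_to_platform_cm: float | None = None

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for key, val in self.__dict__.items():
            if val is None:
                continue
            if isinstance(val, dict):
                for sub, v in val.items():
                    out[f"{key}_{sub}"] = float(v)
            else:
                out[key] = float(val)
        return out


# ---------------------------------------------------------------------------
# NORT
# ---------------------------------------------------------------------------


def detect_exploration(
    traj: Trajectory,
    arena: ArenaSpec,
    facing_max_deg: float = 45.0,
    radius_cm: float = 5.0,
) -> dict[str, np.ndarray]:
    """Per-frame object-exploration flags.

    A frame counts as exploring an object iff the nose lies within
    ``radius_cm`` of the object's center and the heading vector
    (head-center → nose) points at the object center within
    ``facing_max_deg``.  Invalid (dropout) frames are never flagged.
    """
    if arena.kind != "nort":
        raise ValueError("detect_exploration requires a NORT arena")
    heading = traj.nose_xy - traj.head_xy
    out: dict[str, np.ndarray] = {}
    for obj_id, center in arena.object_centers.items():
        c = np.asarray(center, dtype=float)
        near = np.hypot(*(traj.nose_xy - c).T) <= radius_cm
        to_obj = c - traj.head_xy
        cosang = _row_cos(heading, to_obj)
        facing = cosang >= math.cos(math.radians(facing_max_deg))
        out[obj_id] = near & facing & traj.valid
    return out


def _row_cos(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = np.where((na > 0) & (nb > 0), na * nb, np.nan)
    with np.errstate(invalid="ignore"):
        return np.clip(np.einsum("ij,ij->i", a, b) / denom, -1.0, 1.0)


def exploration_times(
    traj: Trajectory, flags: dict[str, np.ndarray]
) -> dict[str, float]:
    """Seconds spent exploring each object (frame-duration weighted)."""
    dt = np.empty(len(traj))
    dt[:-1] = np.diff(traj.time_s)
    dt[-1] = traj.frame_period_s
    return {obj: float(dt[mask].sum()) for obj, mask in flags.items()}


def discrimination_index(t_novel_s: float, t_old_s: float) -> float:
    """(novel − old) / (novel + old) object-exploration time; in [−1, 1].

    Raises
    ------
    UndefinedMetricError
        If total exploration time is zero (the trial carries no
        information and must be excluded from group statistics).
    """
    total = t_novel_s + t_old_s
    if total <= 0:
        raise UndefinedMetricError("zero total object exploration time")
    return (t_novel_s - t_old_s) / total


def nort_metrics(
    traj: Trajectory,
    arena: ArenaSpec,
    facing_max_deg: float = 45.0,
    radius_cm: float = 5.0,
) -> TrialMetrics:
    flags = detect_exploration(traj, arena, facing_max_deg, radius_cm)
    times = exploration_times(traj, flags)
    novel = arena.novel_object_id
    t_novel = times[novel]
    t_old = sum(t for obj, t in times.items() if obj != novel)
    return TrialMetrics(
        discrimination_index=discrimination_index(t_novel, t_old),
        exploration_time_novel_s=t_novel,
        exploration_time_old_s=t_old,
    )


# ---------------------------------------------------------------------------
# Y-maze
# ---------------------------------------------------------------------------


def detect_arm_entries(
    traj: Trajectory,
    arena: ArenaSpec,
    entry_depth_frac: float = 0.5,
) -> list[str]:
    """Ordered arm-entry sequence from the body-center track.

    An entry is registered when the body-center penetrates an arm beyond
    ``entry_depth_frac`` of the arm length; consecutive duplicates are
    collapsed.  A trajectory that never leaves the center zone yields an
    empty sequence, which is valid.
    """
    if arena.kind != "ymaze":
        raise ValueError("detect_arm_entries requires a Y-maze arena")
    xy = traj.body_xy
    # frame-wise arm membership beyond the depth threshold
    frame_arm = np.full(len(traj), "", dtype="<U8")
    for label in arena.arm_labels:
        poly = arena.arm_polygon(label)
        inside = shapely.contains_xy(poly, xy[:, 0], xy[:, 1])
        deep = arena.arm_depth(xy, label) >= entry_depth_frac
        frame_arm[inside & deep & traj.valid] = label
    seq: list[str] = []
    for arm in frame_arm:
        if arm and (not seq or seq[-1] != arm):
            seq.append(str(arm))
    return seq


def spontaneous_alternation(arm_seq: list[str]) -> float:
    """Fraction of overlapping entry triplets visiting three distinct arms.

    The ratio is (number of consecutive triplets with three distinct
    arms) / (entries − 2); chance level for uniformly random three-arm
    sequences is 2/9 ≈ 22%.
    """
    n = len(arm_seq)
    if n < 3:
        raise UndefinedMetricError("alternation undefined for fewer than 3 entries")
    distinct = sum(
        len({arm_seq[i], arm_seq[i + 1], arm_seq[i + 2]}) == 3 for i in range(n - 2)
    )
    return distinct / (n - 2)


def ymaze_metrics(
    traj: Trajectory, arena: ArenaSpec, entry_depth_frac: float = 0.5
) -> TrialMetrics:
    seq = detect_arm_entries(traj, arena, entry_depth_frac)
    return TrialMetrics(
        alternation_ratio=spontaneous_alternation(seq),
        arm_entries=len(seq),
    )


# ---------------------------------------------------------------------------
# Morris water maze
# ---------------------------------------------------------------------------


def _check_in_pool(traj: Trajectory, arena: ArenaSpec, tol_cm: float = 2.0) -> None:
    r = np.hypot(*traj.body_xy[traj.valid].T)
    if np.any(r > arena.pool_radius_cm + tol_cm):
        raise ValueError(
            "trajectory leaves the pool boundary; check pixel-to-cm calibration"
        )


def mwm_trial_metrics(
    traj: Trajectory, arena: ArenaSpec, timeout_s: float = 120.0
) -> TrialMetrics:
    """Training-trial metrics: escape latency, path length, mean speed.

    Latency is the first time the body-center enters the platform circle
    (the timeout if it never does).  Path length sums body-center
    displacements up to escape; post-escape frames are excluded from the
    speed denominator.
    """
    if arena.kind not in ("mwm", "mwm_probe"):
        raise ValueError("mwm_trial_metrics requires an MWM arena")
    _check_in_pool(traj, arena)
    d = np.hypot(*(traj.body_xy - np.asarray(arena.platform_center)).T)
    on_platform = np.flatnonzero(d <= arena.platform_radius_cm)
    if len(on_platform):
        esc = int(on_platform[0])
        latency = float(min(traj.time_s[esc] - traj.time_s[0], timeout_s))
    else:
        esc = len(traj) - 1
        latency = float(timeout_s)
    steps = np.linalg.norm(np.diff(traj.body_xy[: esc + 1], axis=0), axis=1)
    path = float(steps.sum())
    swim_time = max(traj.time_s[esc] - traj.time_s[0], traj.frame_period_s)
    return TrialMetrics(
        path_length_cm=path,
        escape_latency_s=latency,
        mean_speed_cm_s=path / swim_time,
    )


def mwm_probe_metrics(
    traj: Trajectory, arena: ArenaSpec, duration_s: float = 60.0
) -> TrialMetrics:
    """Probe-trial metrics: per-quadrant occupancy and the time-averaged
    distance of the body-center to the former platform location."""
    if arena.kind not in ("mwm", "mwm_probe"):
        raise ValueError("mwm_probe_metrics requires an MWM arena")
    _check_in_pool(traj, arena)
    dt = np.empty(len(traj))
    dt[:-1] = np.diff(traj.time_s)
    dt[-1] = traj.frame_period_s
    labels = arena.quadrant_of(traj.body_xy)
    qt = {q: float(dt[(labels == q) & traj.valid].sum()) for q in QUADRANT_LABELS}
    d = np.hypot(*(traj.body_xy - np.asarray(arena.platform_center)).T)
    w = dt * traj.valid
    mean_dist = float((d * w).sum() / w.sum())
    return TrialMetrics(quadrant_time_s=qt, mean_distance_to_platform_cm=mean_dist)
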