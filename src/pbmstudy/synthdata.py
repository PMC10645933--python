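"""Synthetic trajectories and slide images with known ground truth.

Every downstream stage of the pipeline (behavioral metrics, plaque and
microglia quantification, the statistics harness) is exercised on data
from this module, so each generator exports the latent variables it drew
from — object-visit targets, arm-entry sequences, plaque centers and
radii, the true peri-plaque enrichment factor — as a ground-truth record.

Trajectories follow a discrete-time correlated random walk: at each bout
onset a target (object, arm, platform, or a random roam point) is drawn
from the programmed preference; the heading relaxes toward the target
with Gaussian angular noise each frame.  This is deliberately the
simplest motion model whose preference parameters (novelty preference,
alternation bias, goal bias) are identifiable from the downstream
metrics.

Slide images contain disk-shaped plaques, a microglia channel equal to a
baseline times a radial enrichment profile around each plaque (a plateau
of programmable width outside the plaque edge, then a linear falloff to
baseline), and nucleus-like blobs, at 0.6 μm/pixel by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely

from .behavior import ArenaSpec, Trajectory

__all__ = [
    "BehaviorSimParams",
    "HistoSimParams",
    "BehaviorGroundTruth",
    "HistoGroundTruth",
    "PackingError",
    "simulate_trajectory",
    "simulate_arm_sequence",
    "simulate_histology_image",
]

# body-center → head-center and head-center → nose distances, cm
HEAD_OFFSET_CM = 1.5
NOSE_OFFSET_CM = 1.0


@dataclass
class BehaviorSimParams:
    """Parameters of one simulated behavioral trial.

    ``novelty_preference`` is the probability that an object-exploration
    bout targets the novel object (NORT); ``alternation_bias`` the
    probability of choosing the least-recently-visited arm (Y-maze);
    ``goal_bias`` the weight of heading toward the platform versus
    heading persistence (MWM).
    """

    test_kind: str
    duration_s: float = 600.0
    frame_rate_hz: float = 30.0
    novelty_preference: float = 0.5
    alternation_bias: float = 0.5
    goal_bias: float = 0.5
    speed_mean: float = 10.0
    heading_noise: float = 0.15
    seed: int = 0
    dwell_s: float = 2.5  # dwell at an object / arm end

    def __post_init__(self) -> None:
        if self.test_kind not in ("nort", "ymaze", "mwm_training", "mwm_probe"):
            raise ValueError(f"unknown test_kind {self.test_kind!r}")
        for name in ("novelty_preference", "alternation_bias", "goal_bias"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not (self.duration_s > 0 and self.frame_rate_hz > 0 and self.speed_mean > 0):
            raise ValueError("duration_s, frame_rate_hz and speed_mean must be positive")
        if not all(
            np.isfinite(
                [self.duration_s, self.frame_rate_hz, self.speed_mean, self.heading_noise]
            )
        ):
            raise ValueError("non-finite simulation parameter")


@dataclass
class BehaviorGroundTruth:
    """Latent variables of one simulated trial."""

    test_kind: str
    bout_targets: list[str] = field(default_factory=list)  # NORT object ids
    arm_sequence: list[str] = field(default_factory=list)  # Y-maze entries
    platform_reached_s: float | None = None  # MWM training
    start_xy: tuple[float, float] = (0.0, 0.0)


_ARENA_FOR_KIND = {"nort": "nort", "ymaze": "ymaze", "mwm_training": "mwm", "mwm_probe": "mwm_probe"}


def simulate_trajectory(
    params: BehaviorSimParams, arena: ArenaSpec
) -> tuple[Trajectory, BehaviorGroundTruth]:
    """Simulate one trial; returns the keypoint trajectory and its latent
    ground truth.  Bit-identical for identical (params, arena)."""
    if arena.kind != _ARENA_FOR_KIND[params.test_kind]:
        raise ValueError(
            f"arena kind {arena.kind!r} does not match test_kind {params.test_kind!r}"
        )
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.frame_rate_hz))
    dt = 1.0 / params.frame_rate_hz
    sim = {
        "nort": _simulate_nort,
        "ymaze": _simulate_ymaze,
        "mwm_training": _simulate_mwm_training,
        "mwm_probe": _simulate_mwm_probe,
    }[params.test_kind]
    body, heading, truth = sim(params, arena, rng, n, dt)
    u = np.column_stack([np.cos(heading), np.sin(heading)])
    traj = Trajectory(
        time_s=np.arange(n) * dt,
        nose_xy=body + (HEAD_OFFSET_CM + NOSE_OFFSET_CM) * u,
        head_xy=body + HEAD_OFFSET_CM * u,
        body_xy=body,
    )
    truth.start_xy = (float(body[0, 0]), float(body[0, 1]))
    return traj, truth


def _step_heading(
    cur: float, target_ang: float, noise_sd: float, rng: np.random.Generator
) -> float:
    return target_ang + noise_sd * rng.standard_normal()


def _simulate_nort(params, arena, rng, n, dt):
    """Alternating roam / object bouts; object choice Bernoulli(novelty)."""
    half = arena.side_cm / 2.0
    margin = 4.0
    objects = arena.object_centers
    obj_ids = sorted(objects)
    stop_cm = 5.0  # body stops here from the object center → nose at 2.5 cm
    truth = BehaviorGroundTruth(test_kind="nort")
    body = np.empty((n, 2))
    heading = np.empty(n)
    pos = np.array([0.0, -half + margin])
    ang = math.pi / 2.0
    step = params.speed_mean * dt

    mode = "roam"  # roam → approach → dwell → roam …
    target = _roam_point(rng, half - margin, objects, pos)
    dwell_left = 0.0
    obj_target: str | None = None
    for i in range(n):
        if mode == "dwell":
            c = np.asarray(objects[obj_target])
            ang = math.atan2(*(c - pos)[::-1])
            body[i], heading[i] = pos, ang
            dwell_left -= dt
            if dwell_left <= 0:
                mode, target = "roam", _roam_point(rng, half - margin, objects, pos)
            continue
        goal = np.asarray(target)
        if mode == "approach":
            c = np.asarray(objects[obj_target])
            vec = pos - c
            dist = np.hypot(*vec)
            goal = c + vec / max(dist, 1e-9) * stop_cm if dist > stop_cm else pos
        to_goal = goal - pos
        d = np.hypot(*to_goal)
        if d < max(step * 1.5, 1.0):
            if mode == "approach":
                mode, dwell_left = "dwell", params.dwell_s
                truth.bout_targets.append(obj_target)
            else:
                if rng.random() < 0.5:  # next bout explores an object
                    novel = arena.novel_object_id
                    old = next(o for o in obj_ids if o != novel)
                    obj_target = novel if rng.random() < params.novelty_preference else old
                    mode = "approach"
                else:
                    target = _roam_point(rng, half - margin, objects, pos)
            body[i], heading[i] = pos, ang
            continue
        ang = _step_heading(ang, math.atan2(to_goal[1], to_goal[0]), params.heading_noise, rng)
        nxt = pos + step * np.array([math.cos(ang), math.sin(ang)])
        nxt = np.clip(nxt, -half + 1.0, half - 1.0)
        pos = nxt
        body[i], heading[i] = pos, ang
    return body, heading, truth


def _roam_point(rng, extent, objects, pos, min_obj_dist=9.0):
    """Random roam waypoint whose straight path from ``pos`` stays clear of
    both objects (beyond the first few cm of travel), so roam legs do not
    register as incidental object exploration."""
    pos = np.asarray(pos)
    for _ in range(200):
        p = rng.uniform(-extent, extent, 2)
        if any(np.hypot(*(p - np.asarray(c))) <= min_obj_dist for c in objects.values()):
            continue
        if _seg_clearance(pos, p, objects, skip_cm=8.0) > 7.0:
            return p
    return p  # pathological geometry: accept the last draw


def _seg_clearance(a, b, objects, skip_cm):
    """Minimum distance from the segment a→b (excluding the first
    ``skip_cm`` from a) to any object center."""
    length = np.hypot(*(b - a))
    if length <= skip_cm:
        return np.inf
    ts = np.linspace(skip_cm / length, 1.0, max(int(length), 2))
    pts = a + ts[:, None] * (b - a)
    return min(
        np.hypot(*(pts - np.asarray(c)).T).min() for c in objects.values()
    )


def next_arm(
    current: str,
    last_visit: dict[str, int],
    bias: float,
    labels: tuple[str, ...],
    rng: np.random.Generator,
) -> str:
    """Draw the next arm: with probability ``bias`` the least-recently
    visited of the two other arms, otherwise the other one."""
    others = [a for a in labels if a != current]
    others.sort(key=lambda a: last_visit.get(a, -1))
    least_recent, other = others[0], others[1]
    return least_recent if rng.random() < bias else other


def simulate_arm_sequence(
    n_entries: int,
    alternation_bias: float,
    seed: int | np.random.Generator = 0,
    labels: tuple[str, ...] = ("A", "B", "C"),
) -> list[str]:
    """Latent arm-entry sequence of the Y-maze walk model (no trajectory).

    ``alternation_bias`` = 1 forces perfect alternation; 0.5 chooses
    uniformly between the two arms other than the current one.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = [labels[rng.integers(len(labels))]]
    last_visit = {seq[0]: 0}
    while len(seq) < n_entries:
        arm = next_arm(seq[-1], last_visit, alternation_bias, labels, rng)
        last_visit[arm] = len(seq)
        seq.append(arm)
    return seq


def _simulate_ymaze(params, arena, rng, n, dt):
    """Walk between arm ends via the center; the visit order is the latent
    arm sequence, recorded exactly as walked."""
    truth = BehaviorGroundTruth(test_kind="ymaze")
    maze = arena.maze_polygon()
    shapely.prepare(maze)
    body = np.empty((n, 2))
    heading = np.empty(n)
    visit_depth = 0.8
    labels = arena.arm_labels
    start = labels[rng.integers(len(labels))]
    last_visit: dict[str, int] = {start: 0}
    truth.arm_sequence.append(start)
    arm_end = lambda a: (arena.center_zone_radius_cm + visit_depth * arena.arm_length_cm) * arena.arm_axis(a)
    pos = arm_end(start).copy()
    ang = math.atan2(-pos[1], -pos[0])
    step = params.speed_mean * dt
    waypoints: list[np.ndarray] = []
    dwell_left = params.dwell_s
    current = start
    for i in range(n):
        if dwell_left > 0:
            body[i], heading[i] = pos, ang
            dwell_left -= dt
            continue
        if not waypoints:
            nxt = next_arm(current, last_visit, params.alternation_bias, labels, rng)
            waypoints = [np.zeros(2), arm_end(nxt)]
            current = nxt
        goal = waypoints[0]
        to_goal = goal - pos
        d = np.hypot(*to_goal)
        if d < max(step * 1.5, 1.0):
            waypoints.pop(0)
            if not waypoints:  # reached the arm end → entry complete
                last_visit[current] = len(truth.arm_sequence)
                truth.arm_sequence.append(current)
                dwell_left = params.dwell_s
            body[i], heading[i] = pos, ang
            continue
        desired = math.atan2(to_goal[1], to_goal[0])
        cand_ang = _step_heading(ang, desired, params.heading_noise, rng)
        nxt_pos = pos + step * np.array([math.cos(cand_ang), math.sin(cand_ang)])
        if not shapely.contains_xy(maze, nxt_pos[0], nxt_pos[1]):
            cand_ang = desired  # wall: fall back to the direct line
            nxt_pos = pos + step * np.array([math.cos(cand_ang), math.sin(cand_ang)])
        pos, ang = nxt_pos, cand_ang
        body[i], heading[i] = pos, ang
    return body, heading, truth


def _simulate_mwm_training(params, arena, rng, n, dt):
    """Swim with heading pulled toward the platform by ``goal_bias``;
    parks on the platform once reached."""
    truth = BehaviorGroundTruth(test_kind="mwm_training")
    body = np.empty((n, 2))
    heading = np.empty(n)
    plat = np.asarray(arena.platform_center)
    r_start = arena.pool_radius_cm - 5.0
    # start facing the wall in a random position far from the platform
    theta = rng.uniform(0, 2 * math.pi)
    pos = r_start * np.array([math.cos(theta), math.sin(theta)])
    ang = math.atan2(-pos[1], -pos[0])
    step = params.speed_mean * dt
    parked = False
    for i in range(n):
        if parked:
            body[i], heading[i] = pos, ang
            continue
        to_plat = plat - pos
        goal_ang = math.atan2(to_plat[1], to_plat[0])
        persist = np.array([math.cos(ang), math.sin(ang)])
        goal_dir = np.array([math.cos(goal_ang), math.sin(goal_ang)])
        mix = params.goal_bias * goal_dir + (1.0 - params.goal_bias) * persist
        desired = math.atan2(mix[1], mix[0])
        ang = _step_heading(ang, desired, params.heading_noise, rng)
        pos = pos + step * np.array([math.cos(ang), math.sin(ang)])
        r = np.hypot(*pos)
        if r > arena.pool_radius_cm - 1.0:  # pool wall
            pos *= (arena.pool_radius_cm - 1.0) / r
            ang = math.atan2(-pos[1], -pos[0]) + 0.5 * rng.standard_normal()
        if np.hypot(*(pos - plat)) <= arena.platform_radius_cm:
            parked = True
            truth.platform_reached_s = i * dt
        body[i], heading[i] = pos, ang
    return body, heading, truth


def _simulate_mwm_probe(params, arena, rng, n, dt):
    """Probe swim: each bout targets the former platform location with
    probability ``goal_bias``, otherwise a random point in the pool."""
    truth = BehaviorGroundTruth(test_kind="mwm_probe")
    body = np.empty((n, 2))
    heading = np.empty(n)
    plat = np.asarray(arena.platform_center)
    R = arena.pool_radius_cm
    theta = rng.uniform(0, 2 * math.pi)
    pos = (R - 5.0) * np.array([math.cos(theta), math.sin(theta)])
    ang = math.atan2(-pos[1], -pos[0])
    step = params.speed_mean * dt

    def draw_target():
        if rng.random() < params.goal_bias:
            truth.bout_targets.append("platform")
            return plat + rng.uniform(-3, 3, 2)
        truth.bout_targets.append("random")
        rr = (R - 5.0) * math.sqrt(rng.random())
        tt = rng.uniform(0, 2 * math.pi)
        return rr * np.array([math.cos(tt), math.sin(tt)])

    target = draw_target()
    for i in range(n):
        to_goal = target - pos
        d = np.hypot(*to_goal)
        if d < max(step * 1.5, 1.0):
            target = draw_target()
            body[i], heading[i] = pos, ang
            continue
        desired = math.atan2(to_goal[1], to_goal[0])
        ang = _step_heading(ang, desired, params.heading_noise, rng)
        pos = pos + step * np.array([math.cos(ang), math.sin(ang)])
        r = np.hypot(*pos)
        if r > R - 1.0:
            pos *= (R - 1.0) / r
        body[i], heading[i] = pos, ang
    return body, heading, truth


# ---------------------------------------------------------------------------
# Histology images
# ---------------------------------------------------------------------------


class PackingError(RuntimeError):
    """Non-overlapping plaque placement is infeasible for these parameters."""


@dataclass
class HistoSimParams:
    """Parameters of one synthetic fluorescence section.

    The microglia channel is ``microglia_baseline`` multiplied by a radial
    profile around each plaque: ``enrichment_factor`` on a plateau from
    the plaque edge out to ``enrichment_decay_um``, then a linear falloff
    to 1 over ``falloff_um``.  With the defaults the plateau exactly
    covers the near annulus (edge → 12 μm) and the far annulus
    (18 → 60 μm) sits entirely on the baseline.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.6
    plaque_count: int = 5
    plaque_radius_um_range: tuple[float, float] = (8.0, 15.0)
    plaque_intensity: float = 3000.0
    background: float = 100.0
    microglia_baseline: float = 1000.0
    enrichment_factor: float = 2.0
    enrichment_decay_um: float = 12.0
    falloff_um: float = 4.0
    nucleus_count: int = 0
    nucleus_radius_um: float = 4.0
    nucleus_intensity: float = 2000.0
    noise_sd: float = 0.0
    poisson_noise: bool = False
    #: minimum edge-to-edge plaque distance; raise beyond the far-annulus
    #: outer bound (plus the falloff) to keep plaque neighbourhoods disjoint
    min_separation_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be positive")
        lo, hi = self.plaque_radius_um_range
        if lo <= 0 or hi < lo:
            raise ValueError("plaque radii must be positive and ordered")
        max_r_px = hi / self.pixel_size_um
        if self.plaque_count > 0 and 2 * max_r_px >= min(self.image_shape):
            raise PackingError("largest plaque does not fit in the image")


@dataclass
class HistoGroundTruth:
    """True generative parameters of one synthetic section."""

    plaque_centers_px: np.ndarray  # (n, 2) row, col
    plaque_radii_um: np.ndarray
    enrichment_factor: float
    nucleus_centers_px: np.ndarray  # (m, 2) row, col
    plaque_mask: np.ndarray  # bool, the exact generated disks


def _place_disks(rng, shape, radii_px, margin_px, min_gap_px=4.0, max_tries=20000):
    centers: list[np.ndarray] = []
    for r in radii_px:
        for _ in range(max_tries):
            c = rng.uniform(
                [r + margin_px, r + margin_px],
                [shape[0] - r - margin_px, shape[1] - r - margin_px],
            )
            ok = all(
                np.hypot(*(c - c2)) > r + r2 + min_gap_px
                for c2, r2 in zip(centers, radii_px)
            )
            if ok:
                centers.append(c)
                break
        else:
            raise PackingError(
                f"could not place {len(radii_px)} non-overlapping disks of radius "
                f"~{np.max(radii_px):.1f} px in a {shape} image"
            )
    return np.array(centers).reshape(-1, 2)


def simulate_histology_image(
    params: HistoSimParams,
) -> tuple[dict[str, np.ndarray], HistoGroundTruth]:
    """Generate one synthetic stained section.

    Returns
    -------
    images : dict
        ``plaque_channel``, ``microglia_channel``, ``nucleus_channel``
        (float64 intensity images) and ``nucleus_labels`` (instance label
        mask of the generated nuclei).
    truth : HistoGroundTruth
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.image_shape)
    px = params.pixel_size_um
    radii_um = rng.uniform(*params.plaque_radius_um_range, size=params.plaque_count)
    radii_px = radii_um / px
    # keep the whole enrichment + far-annulus neighbourhood inside the frame
    margin_px = 2.0
    centers = _place_disks(
        rng, shape, radii_px, margin_px, min_gap_px=params.min_separation_um / px
    )

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    plaque_mask = np.zeros(shape, dtype=bool)
    d_edge_um = np.full(shape, np.inf)
    for c, r_um in zip(centers, radii_um):
        d_um = np.hypot(rr - c[0], cc - c[1]) * px
        plaque_mask |= d_um <= r_um
        d_edge_um = np.minimum(d_edge_um, d_um - r_um)

    plaque_channel = np.full(shape, params.background, dtype=float)
    plaque_channel[plaque_mask] = params.plaque_intensity

    profile = np.ones(shape)
    if params.plaque_count:
        f, plateau, falloff = (
            params.enrichment_factor,
            params.enrichment_decay_um,
            params.falloff_um,
        )
        on_plateau = d_edge_um <= plateau
        profile[on_plateau] = f
        in_falloff = (d_edge_um > plateau) & (d_edge_um <= plateau + falloff)
        frac = (d_edge_um[in_falloff] - plateau) / falloff
        profile[in_falloff] = f + (1.0 - f) * frac
    microglia_channel = params.microglia_baseline * profile

    nucleus_channel = np.full(shape, params.background, dtype=float)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    if params.nucleus_count:
        nr_px = params.nucleus_radius_um / px
        nuc_centers = _place_disks(
            rng, shape, np.full(params.nucleus_count, nr_px), margin_px, min_gap_px=2.0
        )
        for k, c in enumerate(nuc_centers, start=1):
            disk = np.hypot(rr - c[0], cc - c[1]) <= nr_px
            nucleus_labels[disk] = k
            nucleus_channel[disk] = params.nucleus_intensity
    else:
        nuc_centers = np.empty((0, 2))

    images = {
        "plaque_channel": plaque_channel,
        "microglia_channel": microglia_channel,
        "nucleus_channel": nucleus_channel,
        "nucleus_labels": nucleus_labels,
    }
    if params.noise_sd > 0 or params.poisson_noise:
        for name in ("plaque_channel", "microglia_channel", "nucleus_channel"):
            img = images[name]
            if params.poisson_noise:
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if params.noise_sd > 0:
                img = img + params.noise_sd * rng.standard_normal(shape)
            images[name] = np.clip(img, 0.0, None)

    truth = HistoGroundTruth(
        plaque_centers_px=centers,
        plaque_radii_um=radii_um,
        enrichment_factor=params.enrichment_factor,
        nucleus_centers_px=nuc_centers,
        plaque_mask=plaque_mask,
    )
    return images, truth
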