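"""Virtual two-wheeled robot and circular arena.

The robot is a 5 px-radius differential-drive platform ("Braitenberg
vehicle") navigating a 400x400 px circular arena with round obstacles.
Six proximity sensors at +/-30, +/-45 and +/-90 degrees from the heading
ray-cast against the occupancy map; readings are normalized to 0 at
contact and toward 1 at the far end of the arena.  Collisions are
detected when the robot centre comes within its radius of any occupied
pixel; the post-collision rule relocates the robot to the most recent
pose of its trajectory with at least 20 px clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "Arena",
    "RobotState",
    "SensorReadings",
    "build_arena",
    "sense",
    "step_kinematics",
    "detect_collision",
    "relocate_after_collision",
    "SENSOR_ANGLES_DEG",
]

ARENA_SIZE_PX = 400
ROBOT_RADIUS_PX = 5.0
AXLE_WIDTH_PX = 10.0            # robot diameter; unstated, chosen = 2*radius
RELOCATION_CLEARANCE_PX = 20.0
# Positive angular offsets are the robot's left side under the kinematic
# convention dtheta/dt = (wR - wL)/L: a faster left wheel rotates the
# heading toward negative offsets, i.e. away from the left sensors.
SENSOR_ANGLES_DEG = (90.0, 45.0, 30.0, -30.0, -45.0, -90.0)  # first three = left
_RAY_STEP_PX = 0.5


@dataclass
class Arena:
    """400x400 px occupancy map with a circular boundary and round obstacles.

    ``occupancy[iy, ix]`` is True for wall/obstacle pixels; ``clearance``
    is the Euclidean distance (px) from each free pixel to the nearest
    occupied pixel, used for O(1) collision and relocation queries.
    """

    occupancy: np.ndarray
    obstacles: list[tuple[float, float, float]]      # (cx, cy, radius)
    seed: int | None = None
    clearance: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.clearance is None:
            self.clearance = ndimage.distance_transform_edt(~self.occupancy)

    @property
    def size(self) -> int:
        return self.occupancy.shape[0]

    def clearance_at(self, x: float, y: float) -> float:
        ix = int(np.clip(x, 0, self.size - 1))
        iy = int(np.clip(y, 0, self.size - 1))
        return float(self.clearance[iy, ix])

    def is_free(self, x: float, y: float) -> bool:
        ix = int(np.clip(x, 0, self.size - 1))
        iy = int(np.clip(y, 0, self.size - 1))
        return not bool(self.occupancy[iy, ix])

    # -- serialization ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write a PGM raster plus a text manifest (seed, obstacle list)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        occ = (~self.occupancy).astype(np.uint8) * 255
        with open(directory / "arena.pgm", "wb") as fh:
            fh.write(f"P5 {occ.shape[1]} {occ.shape[0]} 255\n".encode())
            fh.write(occ.tobytes())
        with open(directory / "arena.txt", "w") as fh:
            fh.write(f"seed\t{self.seed}\n")
            for cx, cy, r in self.obstacles:
                fh.write(f"obstacle\t{cx:.3f}\t{cy:.3f}\t{r:.3f}\n")


@dataclass
class RobotState:
    """Continuous pose and wheel speeds of the virtual robot."""

    x: float
    y: float
    heading: float                      # radians, wrapped to (-pi, pi]
    omega_left: float = 0.0             # px/s
    omega_right: float = 0.0            # px/s
    radius: float = ROBOT_RADIUS_PX
    axle_width: float = AXLE_WIDTH_PX

    def __post_init__(self) -> None:
        self.heading = _wrap_angle(self.heading)


@dataclass(frozen=True)
class SensorReadings:
    """Six normalized distance readings plus per-side proximity.

    ``readings`` follow :data:`SENSOR_ANGLES_DEG` order (left -90, -45,
    -30, then right 30, 45, 90).  A reading is 0 at contact and grows
    toward 1 with distance (normalized by the arena diameter); per-side
    proximity is ``r = 1 - mean(same-side readings)`` so r = 1 means an
    obstacle in contact.
    """

    readings: tuple[float, ...]
    mean_left: float
    mean_right: float

    @property
    def proximity_left(self) -> float:
        return 1.0 - self.mean_left

    @property
    def proximity_right(self) -> float:
        return 1.0 - self.mean_right


def _wrap_angle(a: float) -> float:
    a = (a + np.pi) % (2.0 * np.pi) - np.pi
    if a == -np.pi:
        a = np.pi
    return float(a)


# --------------------------------------------------------------------------
# Arena generation
# --------------------------------------------------------------------------


def build_arena(
    seed: int | None = None,
    n_obstacles: int = 3,
    radius_range: tuple[float, float] = (15.0, 30.0),
    size: int = ARENA_SIZE_PX,
    keep_centre_free_px: float = 40.0,
    max_tries: int = 2000,
) -> Arena:
    """Seeded circular arena with non-overlapping round obstacles.

    Obstacles are placed at uniformly random positions inside the boundary
    (rejection sampling, bounded retries), pairwise disjoint, and keep a
    free disc around the arena centre where runs start.
    """
    rng = np.random.default_rng(seed)
    c = size / 2.0
    # one-pixel margin so the outermost pixel ring is always occupied
    boundary_r = size / 2.0 - 1.0
    placed: list[tuple[float, float, float]] = []
    tries = 0
    while len(placed) < n_obstacles:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {n_obstacles} obstacles in {max_tries} tries")
        r = rng.uniform(*radius_range)
        rho = rng.uniform(0, boundary_r - r - 5.0)
        phi = rng.uniform(0, 2 * np.pi)
        cx, cy = c + rho * np.cos(phi), c + rho * np.sin(phi)
        if np.hypot(cx - c, cy - c) < r + keep_centre_free_px:
            continue
        if any(np.hypot(cx - ox, cy - oy) < r + orr + 2.0 for ox, oy, orr in placed):
            continue
        placed.append((float(cx), float(cy), float(r)))

    yy, xx = np.mgrid[0:size, 0:size]
    px, py = xx + 0.5, yy + 0.5
    occ = np.hypot(px - c, py - c) > boundary_r
    for cx, cy, r in placed:
        occ |= np.hypot(px - cx, py - cy) <= r
    return Arena(occupancy=occ, obstacles=placed, seed=seed)


# --------------------------------------------------------------------------
# Sensing
# --------------------------------------------------------------------------

_RAY_TS = np.arange(_RAY_STEP_PX, ARENA_SIZE_PX * 1.5, _RAY_STEP_PX)


def _ray_distance(arena: Arena, x: float, y: float, angle: float) -> float:
    """Distance from (x, y) to the first occupied pixel along ``angle``."""
    n = arena.size
    pxs = x + _RAY_TS * np.cos(angle)
    pys = y + _RAY_TS * np.sin(angle)
    ix = np.clip(pxs.astype(np.int64), 0, n - 1)
    iy = np.clip(pys.astype(np.int64), 0, n - 1)
    hit = arena.occupancy[iy, ix]
    k = int(np.argmax(hit))
    if not hit[k]:  # unreachable while the boundary ring is occupied
        return float(_RAY_TS[-1])
    return float(_RAY_TS[k])


def sense(arena: Arena, state: RobotState) -> SensorReadings:
    """Ray-cast the six proximity sensors.

    Each reading is ``clamp((d_center - radius) / arena_size, 0, 1)``:
    the centre-to-obstacle distance minus the robot radius (0 at contact),
    normalized by the arena diameter.
    """
    vals = []
    for deg in SENSOR_ANGLES_DEG:
        d = _ray_distance(arena, state.x, state.y, state.heading + np.deg2rad(deg))
        vals.append(float(np.clip((d - state.radius) / arena.size, 0.0, 1.0)))
    return SensorReadings(
        readings=tuple(vals),
        mean_left=float(np.mean(vals[:3])),
        mean_right=float(np.mean(vals[3:])),
    )


# --------------------------------------------------------------------------
# Kinematics
# --------------------------------------------------------------------------


def step_kinematics(state: RobotState, dt: float) -> RobotState:
    """Exact unicycle integration over ``dt`` with constant wheel speeds.

    v = (wL + wR)/2, dtheta/dt = (wR - wL)/L; straight-line motion when
    the wheels match, otherwise a circular arc.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = 0.5 * (state.omega_left + state.omega_right)
    w = (state.omega_right - state.omega_left) / state.axle_width
    th = state.heading
    if abs(w) < 1e-12:
        x = state.x + v * np.cos(th) * dt
        y = state.y + v * np.sin(th) * dt
        new_th = th
    else:
        new_th = th + w * dt
        x = state.x + (v / w) * (np.sin(new_th) - np.sin(th))
        y = state.y - (v / w) * (np.cos(new_th) - np.cos(th))
    return replace(state, x=float(x), y=float(y), heading=_wrap_angle(new_th))


# --------------------------------------------------------------------------
# Collision and relocation
# --------------------------------------------------------------------------


def detect_collision(arena: Arena, state: RobotState) -> tuple[bool, str | None]:
    """Collision iff the centre is within the robot radius of occupied space.

    Returns ``(flag, side)`` where side is the side with the larger
    proximity at contact ('left' on a tie, deterministically).
    """
    if arena.clearance_at(state.x, state.y) > state.radius:
        return False, None
    s = sense(arena, state)
    side = "left" if s.proximity_left >= s.proximity_right else "right"
    return True, side


def relocate_after_collision(
    arena: Arena,
    trajectory_history: np.ndarray,
    current: RobotState,
    fallback: RobotState | None = None,
) -> RobotState:
    """Move the robot back to the last pose with >= 20 px clearance.

    ``trajectory_history`` rows are (t, x, y, heading), oldest first; the
    heading of the chosen historical pose is preserved and wheel speeds
    are carried over from the current command.  If no pose qualifies the
    robot resets to ``fallback`` (the run start pose) or the oldest entry.
    """
    hist = np.asarray(trajectory_history, dtype=float)
    if hist.ndim != 2 or hist.shape[0] == 0:
        raise ValueError("trajectory history must be a non-empty (n, 4) array")
    for row in hist[::-1]:
        if arena.clearance_at(row[1], row[2]) >= RELOCATION_CLEARANCE_PX:
            return replace(current, x=float(row[1]), y=float(row[2]), heading=_wrap_angle(row[3]))
    if fallback is not None:
        return replace(current, x=fallback.x, y=fallback.y, heading=fallback.heading)
    row = hist[0]
    return replace(current, x=float(row[1]), y=float(row[2]), heading=_wrap_angle(row[3]))
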