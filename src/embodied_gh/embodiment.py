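"""Closed sensorimotor loop: arena, rays, collisions, motor decoding.

The agent is a point in a bounded rectangular arena.  Each epoch it
(1) senses: two rays offset +-10 degrees from the heading report wall
distance; distance < 2 world units forces that side's near-visual node,
distance in [2, 10] the far-visual node, and a wall collision on a side
forces that side's somatosensory node; (2) the network updates; (3) motor
nodes are decoded: an active rotate node turns the agent 30 degrees to its
side (both active cancel), forward nodes drive a move command of 0.5 (one
active) or 2.0 (both) world units smoothed as 7/8 new + 1/8 previous; and
(4) the agent moves, being clipped just inside the wall on collision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from embodied_gh.connectome import Connectome
from embodied_gh.dynamics import (
    EXCITED,
    STATE_CHARS,
    ModelConfig,
    NodeRoles,
    coupling_matrix,
    macro_balance,
    _advance,
)

__all__ = [
    "Arena",
    "AgentState",
    "SensorReading",
    "RunRecord",
    "cast_rays",
    "sensors_to_forcing",
    "decode_motors",
    "move_agent",
    "run_simulation",
    "NEAR_VISUAL_RANGE",
    "FAR_VISUAL_RANGE",
    "RAY_OFFSET",
    "TURN_ANGLE",
    "WALL_EPS",
]

#: visual distance thresholds, world units
NEAR_VISUAL_RANGE = 2.0
FAR_VISUAL_RANGE = 10.0
#: ray offset from the heading, radians (one ray per eye)
RAY_OFFSET = math.radians(10.0)
#: rotation per active rotate node, radians
TURN_ANGLE = math.pi / 6
#: move-command smoothing: v = SMOOTH_NEW * raw + (1 - SMOOTH_NEW) * previous
SMOOTH_NEW = 7.0 / 8.0
#: collision clipping distance inside the wall, world units
WALL_EPS = 1e-3
#: head-on tolerance for flagging both collision sides, radians
HEAD_ON_TOL = math.radians(1.0)


@dataclass(frozen=True)
class Arena:
    """Rectangular arena [0, width] x [0, height] bounded by four walls."""

    width: float = 20.0
    height: float = 20.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")

    def contains(self, x: float, y: float) -> bool:
        return 0.0 < x < self.width and 0.0 < y < self.height

    def wall_distance(self, x: float, y: float) -> float:
        """Minimum Euclidean distance to the four bounding walls."""
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside arena")
        return min(x, self.width - x, y, self.height - y)


@dataclass
class AgentState:
    """Agent pose plus the (smoothed) motor commands that produced it."""

    x: float
    y: float
    heading: float  # radians, wrapped to [0, 2*pi)
    move_command: float = 0.0  # v, world units per epoch
    turn_command: float = 0.0  # h, radians per epoch

    def __post_init__(self) -> None:
        self.heading = self.heading % (2 * math.pi)
        if self.move_command < 0:
            raise ValueError("move_command must be non-negative")


@dataclass(frozen=True)
class SensorReading:
    """Per-side ray distances (inf if nothing hit) and collision flags."""

    left_ray_distance: float
    right_ray_distance: float
    collided_left: bool = False
    collided_right: bool = False

    def __post_init__(self) -> None:
        if self.left_ray_distance < 0 or self.right_ray_distance < 0:
            raise ValueError("ray distances must be non-negative")


def _ray_to_walls(x: float, y: float, angle: float, arena: Arena) -> float:
    """Distance from (x, y) along ``angle`` to the first bounding wall."""
    dx, dy = math.cos(angle), math.sin(angle)
    best = math.inf
    # vertical walls x = 0 and x = width
    for wall_x in (0.0, arena.width):
        if dx != 0.0:
            t = (wall_x - x) / dx
            if t > 0:
                hit_y = y + t * dy
                if -1e-12 <= hit_y <= arena.height + 1e-12:
                    best = min(best, t)
    # horizontal walls y = 0 and y = height
    for wall_y in (0.0, arena.height):
        if dy != 0.0:
            t = (wall_y - y) / dy
            if t > 0:
                hit_x = x + t * dx
                if -1e-12 <= hit_x <= arena.width + 1e-12:
                    best = min(best, t)
    return best


def cast_rays(agent: AgentState, arena: Arena) -> SensorReading:
    """Exact ray-wall distances for the two eye rays.

    The left ray points at heading + 10 degrees, the right at heading - 10
    degrees; each reports the distance to its first intersection with a
    bounding wall.
    """
    if not arena.contains(agent.x, agent.y):
        raise ValueError("agent outside arena")
    left = _ray_to_walls(agent.x, agent.y, agent.heading + RAY_OFFSET, arena)
    right = _ray_to_walls(agent.x, agent.y, agent.heading - RAY_OFFSET, arena)
    return SensorReading(left_ray_distance=left, right_ray_distance=right)


def sensors_to_forcing(reading: SensorReading, roles: NodeRoles) -> frozenset[int]:
    """Map a sensor reading to the set of task-positive nodes forced excited.

    Per side: ray distance < 2 world units forces the near-visual node,
    distance in [2, 10] the far-visual node (mutually exclusive per side);
    a collision on a side forces that side's somatosensory node.
    """
    forced: set[int] = set()
    sides = (
        (reading.left_ray_distance, reading.collided_left, 0),
        (reading.right_ray_distance, reading.collided_right, 1),
    )
    for distance, collided, s in sides:
        if distance < NEAR_VISUAL_RANGE:
            forced.add(roles.near_visual[s])
        elif distance <= FAR_VISUAL_RANGE:
            forced.add(roles.far_visual[s])
        if collided:
            forced.add(roles.somatosensory[s])
    return frozenset(forced)


def decode_motors(
    state,
    roles: NodeRoles,
    prev: AgentState,
    smooth_turn: bool = False,
) -> tuple[float, float]:
    """Decode motor-node activity into (move v, turn h) commands.

    Raw turn is +30 degrees when only the left rotate node is excited,
    -30 degrees when only the right one is, and 0 when both or neither are
    (opposing rotations cancel).  Raw move is 0.5 world units for exactly
    one excited forward node and 2.0 for both.  The returned move command
    is smoothed, v = 7/8 raw + 1/8 previous; the turn command is returned
    raw unless ``smooth_turn``.
    """
    excited = state.states == EXCITED
    left_rot = bool(excited[roles.rotate_left])
    right_rot = bool(excited[roles.rotate_right])
    raw_turn = (TURN_ANGLE if left_rot else 0.0) - (TURN_ANGLE if right_rot else 0.0)

    n_forward = int(excited[roles.forward_left]) + int(excited[roles.forward_right])
    raw_move = {0: 0.0, 1: 0.5, 2: 2.0}[n_forward]

    v = SMOOTH_NEW * raw_move + (1 - SMOOTH_NEW) * prev.move_command
    h = SMOOTH_NEW * raw_turn + (1 - SMOOTH_NEW) * prev.turn_command if smooth_turn else raw_turn
    return v, h


_WALL_NORMALS = {  # wall id -> outward normal angle
    "x0": math.pi,  # x = 0
    "x1": 0.0,  # x = width
    "y0": -math.pi / 2,  # y = 0
    "y1": math.pi / 2,  # y = height
}


def _collision_sides(heading: float, wall: str) -> tuple[bool, bool]:
    """Attribute a wall hit to the agent's left or right side.

    Signed angle from the heading to the wall's outward normal: positive
    (counterclockwise) puts the wall on the agent's left, negative on the
    right; a head-on hit (|angle| < 1 degree) flags both sides.
    """
    a = (_WALL_NORMALS[wall] - heading + math.pi) % (2 * math.pi) - math.pi
    if abs(a) < HEAD_ON_TOL:
        return True, True
    return (a > 0, a < 0)


def move_agent(
    agent: AgentState,
    v: float,
    h: float,
    arena: Arena,
) -> tuple[AgentState, bool, bool]:
    """Advance the agent: rotate by h, move v units, resolve wall hits.

    If the displacement segment crosses a wall, the position is clipped to
    10^-3 world units inside that wall and a collision is flagged on the
    side the wall lies on (see :func:`_collision_sides`).
    """
    if v < 0:
        raise ValueError("move command must be non-negative")
    heading = (agent.heading + h) % (2 * math.pi)
    nx = agent.x + v * math.cos(heading)
    ny = agent.y + v * math.sin(heading)

    collided_left = collided_right = False
    if not arena.contains(nx, ny):
        # first wall crossed along the displacement segment
        crossings: list[tuple[float, str]] = []
        dx, dy = nx - agent.x, ny - agent.y
        if nx <= 0:
            crossings.append((-agent.x / dx, "x0"))
        if nx >= arena.width:
            crossings.append(((arena.width - agent.x) / dx, "x1"))
        if ny <= 0:
            crossings.append((-agent.y / dy, "y0"))
        if ny >= arena.height:
            crossings.append(((arena.height - agent.y) / dy, "y1"))
        t_hit, wall = min(crossings)
        nx = agent.x + t_hit * dx
        ny = agent.y + t_hit * dy
        collided_left, collided_right = _collision_sides(heading, wall)
        # clip strictly inside; clamp both coordinates for corner hits
        nx = min(max(nx, WALL_EPS), arena.width - WALL_EPS)
        ny = min(max(ny, WALL_EPS), arena.height - WALL_EPS)

    new = AgentState(x=nx, y=ny, heading=heading, move_command=v, turn_command=h)
    return new, collided_left, collided_right


@dataclass
class RunRecord:
    """Epoch-indexed record of one closed-loop run.

    Arrays are indexed by epoch t = 0 .. epochs-1 and hold the network
    state *after* epoch t's update, the thresholds after plasticity, the
    forcing masks applied during the update, the agent pose after the
    move, the motor commands, the pre-move ray distances that produced the
    forcing, and the post-move wall distance and collision flags.
    """

    config: ModelConfig
    roles: NodeRoles
    arena: Arena
    labels: list[str]
    states: np.ndarray  # (epochs, N) int8
    thresholds: np.ndarray  # (epochs, N) float
    forced_e: np.ndarray  # (epochs, N) bool
    forced_q: np.ndarray  # (epochs, N) bool
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    v: np.ndarray
    h: np.ndarray
    ray_left: np.ndarray
    ray_right: np.ndarray
    wall_distance: np.ndarray
    collided_left: np.ndarray  # bool
    collided_right: np.ndarray  # bool

    @property
    def epochs(self) -> int:
        return self.states.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]

    @property
    def activity(self) -> np.ndarray:
        """Epoch x node binarized activity (1 iff excited)."""
        return (self.states == EXCITED).astype(np.int8)

    @property
    def mean_activity_series(self) -> np.ndarray:
        """Network-mean activity per epoch."""
        return self.activity.mean(axis=1)

    @property
    def mean_threshold_series(self) -> np.ndarray:
        """Network-mean threshold per epoch."""
        return self.thresholds.mean(axis=1)

    @property
    def trajectory(self) -> np.ndarray:
        """(epochs, 2) array of agent positions."""
        return np.column_stack([self.x, self.y])

    # -- serialisation ----------------------------------------------------

    def states_frame(self) -> pd.DataFrame:
        cols = {"epoch": np.arange(self.epochs)}
        letters = STATE_CHARS[self.states]
        for j, lab in enumerate(self.labels):
            cols[f"state_{lab}"] = letters[:, j]
        for j, lab in enumerate(self.labels):
            cols[f"threshold_{lab}"] = self.thresholds[:, j]
        cols["forced_E"] = [";".join(map(str, np.flatnonzero(r))) for r in self.forced_e]
        cols["forced_Q"] = [";".join(map(str, np.flatnonzero(r))) for r in self.forced_q]
        return pd.DataFrame(cols)

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(self.epochs),
                "x": self.x,
                "y": self.y,
                "heading": self.heading,
                "v": self.v,
                "h": self.h,
                "ray_left": self.ray_left,
                "ray_right": self.ray_right,
                "wall_distance": self.wall_distance,
                "collided_left": self.collided_left.astype(int),
                "collided_right": self.collided_right.astype(int),
            }
        )

    def save(self, outdir: str | Path) -> None:
        """Write states.csv, trajectory.csv, and a config.json sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.states_frame().to_csv(outdir / "states.csv", index=False)
        self.trajectory_frame().to_csv(outdir / "trajectory.csv", index=False)
        sidecar = {
            "config": self.config.to_dict(),
            "roles": self.roles.to_dict(),
            "arena": {"width": self.arena.width, "height": self.arena.height},
            "labels": self.labels,
        }
        (outdir / "config.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, outdir: str | Path) -> "RunRecord":
        outdir = Path(outdir)
        sidecar = json.loads((outdir / "config.json").read_text())
        labels = sidecar["labels"]
        sf = pd.read_csv(outdir / "states.csv", keep_default_na=False)
        tf = pd.read_csv(outdir / "trajectory.csv")
        n = len(labels)
        epochs = len(sf)
        letters = np.stack([sf[f"state_{lab}"].to_numpy(dtype="U1") for lab in labels], axis=1)
        codes = np.zeros((epochs, n), dtype=np.int8)
        for code, char in enumerate(STATE_CHARS):
            codes[letters == char] = code
        thresholds = np.stack(
            [sf[f"threshold_{lab}"].to_numpy(dtype=float) for lab in labels], axis=1
        )

        def mask_col(col: pd.Series) -> np.ndarray:
            m = np.zeros((epochs, n), dtype=bool)
            for t, cell in enumerate(col):
                if isinstance(cell, str) and cell:
                    m[t, [int(i) for i in cell.split(";")]] = True
            return m

        return cls(
            config=ModelConfig.from_dict(sidecar["config"]),
            roles=NodeRoles.from_dict(sidecar["roles"]),
            arena=Arena(**sidecar["arena"]),
            labels=labels,
            states=codes,
            thresholds=thresholds,
            forced_e=mask_col(sf["forced_E"]),
            forced_q=mask_col(sf["forced_Q"]),
            x=tf["x"].to_numpy(float),
            y=tf["y"].to_numpy(float),
            heading=tf["heading"].to_numpy(float),
            v=tf["v"].to_numpy(float),
            h=tf["h"].to_numpy(float),
            ray_left=tf["ray_left"].to_numpy(float),
            ray_right=tf["ray_right"].to_numpy(float),
            wall_distance=tf["wall_distance"].to_numpy(float),
            collided_left=tf["collided_left"].to_numpy(bool),
            collided_right=tf["collided_right"].to_numpy(bool),
        )


def run_simulation(
    c: Connectome,
    roles: NodeRoles,
    config: ModelConfig,
    arena: Arena | None = None,
) -> RunRecord:
    """Run the full closed loop for ``config.epochs`` epochs.

    Per-epoch order: (1) sensory forcing computed from the previous pose
    and previous collision flags, (2) task-negative balancing when the
    variant enables it, (3) synchronous network update with both forcing
    sets, (4) local threshold plasticity when enabled, (5) motor decoding
    and agent movement.  The run is a pure function of (connectome, roles,
    config, arena): identical inputs give identical records.
    """
    if arena is None:
        arena = Arena()
    roles.validate_for(c.n_nodes)
    n = c.n_nodes
    epochs = config.epochs
    rng = np.random.default_rng(config.seed)
    interaction = coupling_matrix(c, config)

    states = np.zeros(n, dtype=np.int8)
    thresholds = np.full(n, float(config.initial_threshold))
    agent = AgentState(
        x=arena.width / 2.0,
        y=arena.height / 2.0,
        heading=rng.uniform(0.0, 2 * math.pi),
    )
    collided_l = collided_r = False

    role_indices = np.fromiter(roles.all_indices(), dtype=int)
    homeo = config.variant in ("local", "combined") and config.alpha > 0
    macro = config.variant in ("macro", "combined")

    rec_states = np.empty((epochs, n), dtype=np.int8)
    rec_thresh = np.empty((epochs, n))
    rec_fe = np.zeros((epochs, n), dtype=bool)
    rec_fq = np.zeros((epochs, n), dtype=bool)
    rec_x = np.empty(epochs)
    rec_y = np.empty(epochs)
    rec_heading = np.empty(epochs)
    rec_v = np.empty(epochs)
    rec_h = np.empty(epochs)
    rec_rayl = np.empty(epochs)
    rec_rayr = np.empty(epochs)
    rec_wall = np.empty(epochs)
    rec_cl = np.zeros(epochs, dtype=bool)
    rec_cr = np.zeros(epochs, dtype=bool)

    for t in range(epochs):
        # 1. sensation from the previous pose / previous collision
        rays = cast_rays(agent, arena)
        reading = SensorReading(
            left_ray_distance=rays.left_ray_distance,
            right_ray_distance=rays.right_ray_distance,
            collided_left=collided_l,
            collided_right=collided_r,
        )
        tp_forced = sensors_to_forcing(reading, roles)
        # 2. macroscopic task-negative balancing
        if macro:
            tn_e, tn_q = macro_balance(tp_forced, roles)
            forced_e = np.fromiter(tp_forced | set(tn_e), dtype=int) if tp_forced or tn_e else np.empty(0, int)
            forced_q = np.fromiter(tn_q, dtype=int)
        else:
            forced_e = np.fromiter(tp_forced, dtype=int)
            forced_q = np.empty(0, dtype=int)
        # 3. synchronous network update
        states = _advance(
            states, thresholds, interaction, config.p_spont, forced_e, forced_q, rng
        )
        # 4. local homeostatic plasticity (skipping exogenously clamped nodes
        #    by default: their activity is not produced by their own dynamics)
        if homeo:
            delta = config.alpha * ((states == EXCITED).astype(float) - config.rho)
            if config.homeostasis_scope == "unforced":
                delta[forced_e] = 0.0
                delta[forced_q] = 0.0
            elif config.homeostasis_scope == "exclude_roles":
                delta[role_indices] = 0.0
            thresholds = thresholds + delta
        # 5. motor decoding and movement
        excited = states == EXCITED
        raw_turn = (TURN_ANGLE if excited[roles.rotate_left] else 0.0) - (
            TURN_ANGLE if excited[roles.rotate_right] else 0.0
        )
        n_fwd = int(excited[roles.forward_left]) + int(excited[roles.forward_right])
        raw_move = (0.0, 0.5, 2.0)[n_fwd]
        v = SMOOTH_NEW * raw_move + (1 - SMOOTH_NEW) * agent.move_command
        h = (
            SMOOTH_NEW * raw_turn + (1 - SMOOTH_NEW) * agent.turn_command
            if config.smooth_turn
            else raw_turn
        )
        agent, collided_l, collided_r = move_agent(agent, v, h, arena)

        rec_states[t] = states
        rec_thresh[t] = thresholds
        rec_fe[t, forced_e] = True
        rec_fq[t, forced_q] = True
        rec_x[t], rec_y[t], rec_heading[t] = agent.x, agent.y, agent.heading
        rec_v[t], rec_h[t] = v, h
        rec_rayl[t], rec_rayr[t] = reading.left_ray_distance, reading.right_ray_distance
        rec_wall[t] = arena.wall_distance(agent.x, agent.y)
        rec_cl[t], rec_cr[t] = collided_l, collided_r

    return RunRecord(
        config=config,
        roles=roles,
        arena=arena,
        labels=c.labels,
        states=rec_states,
        thresholds=rec_thresh,
        forced_e=rec_fe,
        forced_q=rec_fq,
        x=rec_x,
        y=rec_y,
        heading=rec_heading,
        v=rec_v,
        h=rec_h,
        ray_left=rec_rayl,
        ray_right=rec_rayr,
        wall_distance=rec_wall,
        collided_left=rec_cl,
        collided_right=rec_cr,
    )
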