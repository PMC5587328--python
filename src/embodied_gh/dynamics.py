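"""Greenberg-Hastings dynamics on a connectome, with homeostasis.

Each node is in one of three states: excited (E), refractory (R), or
quiescent (Q).  Per synchronous update step ("epoch"):

* E -> R with probability 1,
* R -> Q with probability 1,
* Q -> E with probability ``p_spont``, or deterministically when the
  weighted input from currently excited neighbours exceeds the node's
  activation threshold:  g * sum_j (C_ij / max C) * b_j  >  T_i,
  where b_j = 1 iff node j is excited.

Two homeostatic mechanisms can be layered on top:

* **local** — inhibitory threshold plasticity, T_i <- T_i + alpha * (b_i - rho),
  driving each node's time-averaged firing toward the target rate rho;
* **macro** — task-negative balancing: a fixed pool of four task-negative
  nodes is forced excited/quiescent in complement to the number of
  sensorily forced task-positive nodes, keeping the count of exogenously
  activated nodes constant.

The ``variant`` field of :class:`ModelConfig` selects ``static`` (neither),
``local``, ``macro``, or ``combined``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np

from embodied_gh.connectome import Connectome

__all__ = [
    "QUIESCENT",
    "EXCITED",
    "REFRACTORY",
    "STATE_CHARS",
    "GHState",
    "ModelConfig",
    "NodeRoles",
    "default_roles",
    "coupling_matrix",
    "step_states",
    "update_thresholds",
    "macro_balance",
    "mean_activity",
    "node_correlation_matrix",
]

QUIESCENT: int = 0
EXCITED: int = 1
REFRACTORY: int = 2

#: state code -> single-letter label used in CSV serialisation
STATE_CHARS = np.array(["Q", "E", "R"])

VARIANTS = ("static", "local", "macro", "combined")


@dataclass
class GHState:
    """Network state at one epoch: per-node state codes and thresholds."""

    states: np.ndarray  # int8 codes in {QUIESCENT, EXCITED, REFRACTORY}
    thresholds: np.ndarray  # float activation thresholds T_i
    epoch: int = 0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.states.shape != self.thresholds.shape:
            raise ValueError("states and thresholds must have equal length")
        if not np.isin(self.states, (QUIESCENT, EXCITED, REFRACTORY)).all():
            raise ValueError("invalid state code; use QUIESCENT/EXCITED/REFRACTORY")
        if self.epoch < 0:
            raise ValueError("epoch must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.states.shape[0]

    @property
    def activity(self) -> np.ndarray:
        """Binarized activity b_i = 1 iff node i is excited."""
        return (self.states == EXCITED).astype(np.int8)

    @classmethod
    def all_quiescent(cls, n_nodes: int, initial_threshold: float) -> "GHState":
        return cls(
            states=np.zeros(n_nodes, dtype=np.int8),
            thresholds=np.full(n_nodes, float(initial_threshold)),
            epoch=0,
        )


@dataclass
class ModelConfig:
    """All run parameters of the simulator.

    Parameters
    ----------
    coupling
        Global gain g applied to the max-normalised connectivity matrix.
    initial_threshold
        Uniform activation threshold at epoch 0.
    p_spont
        Spontaneous Q -> E probability per epoch (default 0.1).
    alpha
        Homeostatic learning rate (ignored unless variant is local/combined).
    rho
        Homeostatic target activation rate in [0, 1].
    variant
        One of ``static``, ``local``, ``macro``, ``combined``.
    epochs
        Number of synchronous update steps to simulate.
    seed
        Master seed for the run's random stream.
    bin_dt
        Avalanche re-binning width in epochs (used by analysis).
    smooth_turn
        If True, the turn command is smoothed like the move command
        (default False: only the move command is smoothed).
    homeostasis_scope
        Which nodes the local threshold update applies to.  ``"unforced"``
        (default): every node except those whose state was exogenously
        clamped this epoch — a clamped node's activity is not produced by
        its own dynamics, and updating it would let a permanently forced
        task-negative node's threshold drift without bound.  ``"all"``:
        the rule applies to every node unconditionally.
        ``"exclude_roles"``: sensory/motor/task-negative nodes never
        update.
    """

    coupling: float = 1.0
    initial_threshold: float = 0.2
    p_spont: float = 0.1
    alpha: float = 0.1
    rho: float = 0.1
    variant: str = "static"
    epochs: int = 2000
    seed: int = 0
    bin_dt: int = 1
    smooth_turn: bool = False
    homeostasis_scope: str = "unforced"

    def __post_init__(self) -> None:
        if self.coupling <= 0:
            raise ValueError(f"coupling must be positive, got {self.coupling}")
        if not (0 <= self.p_spont <= 1):
            raise ValueError(f"p_spont must be in [0, 1], got {self.p_spont}")
        if not (0 <= self.rho <= 1):
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.bin_dt < 1:
            raise ValueError(f"bin_dt must be >= 1, got {self.bin_dt}")
        if self.homeostasis_scope not in ("unforced", "all", "exclude_roles"):
            raise ValueError(
                f"homeostasis_scope must be 'unforced', 'all', or 'exclude_roles', "
                f"got {self.homeostasis_scope!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass(frozen=True)
class NodeRoles:
    """Assignment of sensory, motor, and task-negative roles to nodes.

    The six task-positive (sensory) nodes are the near/far visual and
    somatosensory bilateral pairs; the four task-negative nodes are two
    bilateral pairs listed in the fixed forcing priority order
    (alternating left/right across the two pairs).
    """

    rotate_left: int
    rotate_right: int
    forward_left: int
    forward_right: int
    near_visual: tuple[int, int]  # (left, right)
    far_visual: tuple[int, int]
    somatosensory: tuple[int, int]
    task_negative: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        idx = self.all_indices()
        if len(set(idx)) != len(idx):
            raise ValueError("role node indices must be distinct")
        if any(i < 0 for i in idx):
            raise ValueError("role node indices must be non-negative")

    def all_indices(self) -> tuple[int, ...]:
        return (
            self.rotate_left,
            self.rotate_right,
            self.forward_left,
            self.forward_right,
            *self.near_visual,
            *self.far_visual,
            *self.somatosensory,
            *self.task_negative,
        )

    @property
    def task_positive(self) -> frozenset[int]:
        """The six sensory nodes forced by environmental input."""
        return frozenset((*self.near_visual, *self.far_visual, *self.somatosensory))

    def validate_for(self, n_nodes: int) -> None:
        if max(self.all_indices()) >= n_nodes:
            raise ValueError(f"role index out of range for {n_nodes}-node network")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NodeRoles":
        d = dict(d)
        for key in ("near_visual", "far_visual", "somatosensory", "task_negative"):
            d[key] = tuple(d[key])
        return cls(**d)


def default_roles(n_nodes: int = 66) -> NodeRoles:
    """Bilaterally mirrored role assignment for the default connectome.

    Node i in the left hemisphere (first half) mirrors node i + N/2 on the
    right.  The particular indices are arbitrary, mirroring the loose
    anatomical assignment of the model; only distinctness and bilaterality
    matter.
    """
    if n_nodes < 20 or n_nodes % 2:
        raise ValueError("default roles need an even n_nodes >= 20")
    half = n_nodes // 2
    return NodeRoles(
        rotate_left=0,
        rotate_right=half,
        forward_left=1,
        forward_right=half + 1,
        near_visual=(2, half + 2),
        far_visual=(3, half + 3),
        somatosensory=(4, half + 4),
        task_negative=(5, half + 5, 6, half + 6),
    )


def coupling_matrix(c: Connectome, config: ModelConfig) -> np.ndarray:
    """Effective interaction matrix g * C / max(C).

    Max-normalisation makes the (coupling, threshold) axes dimensionless
    and comparable across connectomes.
    """
    w_max = c.weights.max()
    if w_max == 0:
        return np.zeros_like(c.weights)
    return config.coupling * (c.weights / w_max)


def _as_index_array(nodes: Iterable[int] | None, n_nodes: int, name: str) -> np.ndarray:
    if nodes is None:
        return np.empty(0, dtype=int)
    arr = np.fromiter(nodes, dtype=int)
    if arr.size and (arr.min() < 0 or arr.max() >= n_nodes):
        raise ValueError(f"{name} contains node indices outside [0, {n_nodes})")
    return arr


def _advance(
    states: np.ndarray,
    thresholds: np.ndarray,
    interaction: np.ndarray,
    p_spont: float,
    forced_e: np.ndarray,
    forced_q: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous update on raw arrays; returns the new state codes.

    The random stream is always consumed (one uniform draw per node) so a
    run is reproducible independent of parameter values.
    """
    excited = states == EXCITED
    drive = interaction @ excited.astype(float)
    spont = rng.random(states.shape[0]) < p_spont
    fire = (drive > thresholds) | spont

    new = np.where(
        excited,
        REFRACTORY,
        np.where(states == REFRACTORY, QUIESCENT, np.where(fire, EXCITED, QUIESCENT)),
    ).astype(np.int8)
    # exogenous forcing overrides the computed state for this epoch only
    new[forced_e] = EXCITED
    new[forced_q] = QUIESCENT
    return new


def step_states(
    state: GHState,
    c: Connectome,
    config: ModelConfig,
    forced_E: Iterable[int] | None = None,
    forced_Q: Iterable[int] | None = None,
    rng: np.random.Generator | None = None,
) -> GHState:
    """One synchronous epoch of the three-state dynamics.

    All transitions read only the epoch-t states: every excited node
    becomes refractory, every refractory node quiescent, and a quiescent
    node becomes excited with probability ``p_spont`` or when its summed
    normalised input strictly exceeds its threshold.  Nodes in ``forced_E``
    / ``forced_Q`` are then overwritten regardless of the computed state
    (a node forced excited on consecutive epochs stays excited).
    Thresholds are returned unchanged.
    """
    n = state.n_nodes
    if c.n_nodes != n:
        raise ValueError("state and connectome dimensions differ")
    fe = _as_index_array(forced_E, n, "forced_E")
    fq = _as_index_array(forced_Q, n, "forced_Q")
    if np.intersect1d(fe, fq).size:
        raise ValueError("forced_E and forced_Q must be disjoint")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    new_states = _advance(
        state.states, state.thresholds, coupling_matrix(c, config),
        config.p_spont, fe, fq, rng,
    )
    return GHState(states=new_states, thresholds=state.thresholds.copy(),
                   epoch=state.epoch + 1)


def update_thresholds(
    state: GHState,
    config: ModelConfig,
    exclude: Iterable[int] | None = None,
) -> GHState:
    """Local homeostatic threshold plasticity T_i <- T_i + alpha (b_i - rho).

    Applies to every node (optionally excluding ``exclude``) when the
    variant enables local homeostasis; otherwise returns the state with
    thresholds untouched.  Thresholds are deliberately not clamped: under
    prolonged silence they may go negative, making any positive input
    supra-threshold — the printed rule's true fixed point.
    """
    if config.variant not in ("local", "combined") or config.alpha == 0:
        return GHState(states=state.states.copy(), thresholds=state.thresholds.copy(),
                       epoch=state.epoch)
    delta = config.alpha * (state.activity.astype(float) - config.rho)
    if exclude is not None:
        delta[_as_index_array(exclude, state.n_nodes, "exclude")] = 0.0
    return GHState(states=state.states.copy(), thresholds=state.thresholds + delta,
                   epoch=state.epoch)


def macro_balance(
    tp_forced: Iterable[int],
    roles: NodeRoles,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Task-negative complement of the currently forced sensory nodes.

    With B = 4 task-negative nodes and k = min(|tp_forced|, B) forced
    task-positive nodes, the first B - k task-negative nodes in the fixed
    priority order are forced excited and the remaining k forced
    quiescent, so the exogenously activated count
    min(|tp_forced|, B) + |forced_E_tn| equals B at every epoch.
    """
    tp = set(tp_forced)
    if not tp <= roles.task_positive:
        raise ValueError("tp_forced must be a subset of the task-positive nodes")
    tn = roles.task_negative
    k = min(len(tp), len(tn))
    return tn[: len(tn) - k], tn[len(tn) - k:]


def mean_activity(record: np.ndarray) -> float:
    """Grand mean of binarized activity over all nodes and epochs."""
    arr = np.asarray(record)
    if arr.size == 0:
        raise ValueError("activity record is empty")
    return float(arr.mean())


def node_correlation_matrix(record: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Pearson correlations between node activity time-courses.

    Parameters
    ----------
    record
        Epoch x node binarized activity matrix with at least two epochs.

    Returns
    -------
    corr
        N x N correlation matrix; rows/columns of constant series are set
        to 0 (diagonal 1) and flagged.
    mean_offdiag
        Mean of the off-diagonal entries (scalar coupling summary).
    constant_mask
        Boolean flag per node marking constant (undefined-correlation)
        series.
    """
    arr = np.asarray(record, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need an epoch x node matrix with >= 2 epochs")
    constant = arr.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    n = corr.shape[0]
    off = corr[~np.eye(n, dtype=bool)]
    mean_offdiag = float(off.mean()) if off.size else 0.0
    return corr, mean_offdiag, constant
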