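"""Automaton dynamics on a filament graph.

Two synchronous update rules over the node states resting/excited/refractory:

* rule ``G`` (semi-totalistic, two states): a resting node becomes excited
  when its weighted excited-neighbour ratio lies in ``[theta_rest_lo,
  theta_rest_hi]``; an excited node stays excited when the ratio lies in
  ``[theta_exc_lo, theta_exc_hi]``; otherwise the node rests.
* rule ``E`` (excitable, three states): a resting node becomes excited when
  the ratio lies in ``[theta_rest_lo, theta_rest_hi]``; excited nodes become
  refractory and refractory nodes become resting unconditionally.

The ratio for node ``p`` is ``(n_hard_excited + mu * n_soft_excited) /
(|hard(p)| + |soft(p)|)``, and 0 for isolated nodes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .graph import FilamentGraph

__all__ = [
    "RESTING",
    "EXCITED",
    "REFRACTORY",
    "AutomatonConfig",
    "resting_state",
    "excitation_ratio",
    "excitation_ratios",
    "step",
    "evolve",
    "activity_profile",
]

RESTING: int = 0
EXCITED: int = 1
REFRACTORY: int = 2


@dataclasses.dataclass(frozen=True)
class AutomatonConfig:
    """Rule species, threshold intervals and soft-neighbour weight."""

    rule: str
    theta_rest_lo: float
    theta_rest_hi: float
    theta_exc_lo: float | None = None
    theta_exc_hi: float | None = None
    mu: float = 0.9

    def __post_init__(self) -> None:
        if self.rule not in ("G", "E"):
            raise ValueError("rule must be 'G' or 'E'")
        if not 0.0 <= self.theta_rest_lo <= self.theta_rest_hi <= 1.0:
            raise ValueError("resting interval must satisfy 0 <= lo <= hi <= 1")
        if self.rule == "G":
            if self.theta_exc_lo is None or self.theta_exc_hi is None:
                raise ValueError("rule G requires a survival interval")
            if not 0.0 <= self.theta_exc_lo <= self.theta_exc_hi <= 1.0:
                raise ValueError("survival interval must satisfy 0 <= lo <= hi <= 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")

    @classmethod
    def rule_g(
        cls,
        birth: tuple[float, float] = (0.25, 0.375),
        survival: tuple[float, float] = (0.25, 0.375),
        mu: float = 0.9,
    ) -> "AutomatonConfig":
        return cls("G", birth[0], birth[1], survival[0], survival[1], mu)

    @classmethod
    def rule_e(
        cls, excite: tuple[float, float] = (0.15, 0.25), mu: float = 0.9
    ) -> "AutomatonConfig":
        return cls("E", excite[0], excite[1], mu=mu)


def resting_state(n_nodes: int) -> np.ndarray:
    """All-resting state vector."""
    return np.zeros(n_nodes, dtype=np.uint8)


def excitation_ratio(
    node: int, state: np.ndarray, graph: FilamentGraph, mu: float
) -> float:
    """Weighted excited-neighbour ratio of a single node (0 if isolated).

    Computed directly from the adjacency lists; the vectorised path used by
    :func:`step` is cross-checked against this in the test suite.
    """
    hard = graph.hard[node]
    soft = graph.soft[node]
    total = len(hard) + len(soft)
    if total == 0:
        return 0.0
    n_hard = int(np.count_nonzero(state[hard] == EXCITED))
    n_soft = int(np.count_nonzero(state[soft] == EXCITED))
    return (n_hard + mu * n_soft) / total


def excitation_ratios(
    state: np.ndarray, graph: FilamentGraph, mu: float
) -> np.ndarray:
    """Weighted excited-neighbour ratio of every node, vectorised."""
    excited = (state == EXCITED).astype(np.float64)
    weighted = graph.weighted_adjacency(mu) @ excited
    return np.divide(
        weighted,
        graph.total_degrees,
        out=np.zeros_like(weighted),
        where=graph.total_degrees > 0,
    )


def _validate_state(state: np.ndarray, graph: FilamentGraph, config: AutomatonConfig):
    state = np.asarray(state, dtype=np.uint8)
    if state.shape != (graph.n_nodes,):
        raise ValueError(
            f"state length {state.shape} does not match graph size {graph.n_nodes}"
        )
    if config.rule == "G" and np.any(state == REFRACTORY):
        raise ValueError("rule G admits only resting and excited states")
    if np.any(state > REFRACTORY):
        raise ValueError("state values must be in {0, 1, 2}")
    return state


def step(
    state: np.ndarray, graph: FilamentGraph, config: AutomatonConfig
) -> np.ndarray:
    """One synchronous update; all ratios are computed from the input state."""
    state = _validate_state(state, graph, config)
    gamma = excitation_ratios(state, graph, config.mu)
    in_rest = (gamma >= config.theta_rest_lo) & (gamma <= config.theta_rest_hi)
    new = np.zeros_like(state)
    if config.rule == "G":
        in_exc = (gamma >= config.theta_exc_lo) & (gamma <= config.theta_exc_hi)
        new[(state == RESTING) & in_rest] = EXCITED
        new[(state == EXCITED) & in_exc] = EXCITED
    else:
        new[(state == RESTING) & in_rest] = EXCITED
        new[state == EXCITED] = REFRACTORY
        # refractory nodes fall back to resting (already 0)
    return new


def evolve(
    state0: np.ndarray,
    graph: FilamentGraph,
    config: AutomatonConfig,
    steps: int,
    record: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[np.ndarray]]:
    """Apply :func:`step` ``steps`` times; optionally keep the trajectory.

    With ``record=True`` returns ``(final, trajectory)`` where the trajectory
    holds the ``steps + 1`` states from ``t = 0`` to ``t = steps``.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    state = _validate_state(state0, graph, config).copy()
    trajectory = [state.copy()] if record else None
    for done in range(steps):
        # the all-zero state is a fixed point whenever the birth interval
        # excludes 0, so the remaining steps are no-ops
        if config.theta_rest_lo > 0 and not state.any():
            if record:
                trajectory.extend(state.copy() for _ in range(steps - done))
            break
        state = step(state, graph, config)
        if record:
            trajectory.append(state.copy())
    return (state, trajectory) if record else state


def activity_profile(
    state: np.ndarray,
    graph: FilamentGraph,
    bin_width: float,
    origin: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Count excited nodes per x-coordinate bin of width ``bin_width``.

    Bins are anchored at ``origin`` and cover the full x-extent of the graph;
    returns ``(bin_edges, counts)`` with bin ``k`` spanning
    ``[edges[k], edges[k + 1])``.  The counts sum to the number of excited
    nodes.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    x = graph.coords[:, 0]
    first = int(np.floor((x.min() - origin) / bin_width))
    last = int(np.floor((x.max() - origin) / bin_width))
    edges = origin + np.arange(first, last + 2) * bin_width
    excited_x = x[np.asarray(state) == EXCITED]
    indices = np.floor((excited_x - origin) / bin_width).astype(np.int64) - first
    counts = np.bincount(indices, minlength=last - first + 1)
    return edges, counts
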