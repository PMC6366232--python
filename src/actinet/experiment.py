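"""Full input-to-output mapping experiment.

Runs every 8-bit input word for ``h`` stochastic trials, evolves each trial
for ``zeta`` steps and accumulates, per input, the frequency with which each
output domain reads 1 — the normalized 256 x 8 frequency matrix W.
"""

from __future__ import annotations

import dataclasses
import json
from typing import IO, Any

import numpy as np

from .domains import DomainLayout, TrialConfig, encode_input, index_to_bits, read_output
from .dynamics import AutomatonConfig, evolve
from .graph import FilamentGraph

__all__ = [
    "FrequencyMatrix",
    "run_experiment",
    "epsilon_ratio",
    "output_one_ratio",
    "save_frequency_matrix",
    "load_frequency_matrix",
    "write_mapping_image",
]


@dataclasses.dataclass
class FrequencyMatrix:
    """Normalized output frequencies per input word.

    ``W[r, i]`` is the fraction of the ``h`` trials of input word ``r``
    (bit 0 most significant) in which output bit ``i`` read 1; every entry
    is a multiple of ``1/h``.
    """

    W: np.ndarray
    h: int
    metadata: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-dimensional")
        if np.any((self.W < 0) | (self.W > 1)):
            raise ValueError("W entries must lie in [0, 1]")

    @property
    def n_inputs(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.W.shape[1]


def run_experiment(
    graph: FilamentGraph,
    config: AutomatonConfig,
    layout: DomainLayout,
    trial: TrialConfig,
    verbose: bool = False,
) -> FrequencyMatrix:
    """Accumulate W over all ``2**m`` inputs and ``h`` trials each.

    A master seed spawns one child seed per (input, trial) pair, so results
    are bit-reproducible and independent of execution order.
    """
    for i, nodes in enumerate(layout.members):
        if len(nodes) == 0:
            raise ValueError(f"domain {i} is empty; refusing to run the experiment")
    n_inputs = 1 << layout.m
    children = np.random.SeedSequence(trial.seed).spawn(n_inputs * trial.h)
    W = np.zeros((n_inputs, layout.m), dtype=np.float64)
    for r in range(n_inputs):
        bits = index_to_bits(r, layout.m)
        for t in range(trial.h):
            rng = np.random.default_rng(children[r * trial.h + t])
            state0 = encode_input(layout, bits, trial.p_excite, rng)
            state = evolve(state0, graph, config, trial.zeta)
            W[r] += read_output(state, layout, trial.kappa)
        if verbose and (r + 1) % 32 == 0:
            print(f"input {r + 1}/{n_inputs} done")
    W /= trial.h
    metadata = {
        "rule": config.rule,
        "theta_rest": [config.theta_rest_lo, config.theta_rest_hi],
        "theta_exc": [config.theta_exc_lo, config.theta_exc_hi],
        "mu": config.mu,
        "p_excite": trial.p_excite,
        "zeta": trial.zeta,
        "kappa": trial.kappa,
        "h": trial.h,
        "seed": trial.seed,
        "rho": graph.rho,
        "n_nodes": graph.n_nodes,
        "n_hard_edges": int(len(graph.hard_pairs)),
        "n_soft_edges": int(len(graph.soft_pairs)),
    }
    return FrequencyMatrix(W, trial.h, metadata)


def epsilon_ratio(W: FrequencyMatrix | np.ndarray, gamma: float) -> float:
    """Fraction of input rows whose largest frequency strictly exceeds gamma."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    matrix = W.W if isinstance(W, FrequencyMatrix) else np.asarray(W)
    return float(np.mean(matrix.max(axis=1) > gamma))


def output_one_ratio(truth_table: np.ndarray) -> float:
    """Fraction of 1 entries in a complete binary truth table."""
    table = np.asarray(truth_table)
    return float(np.count_nonzero(table)) / table.size


def save_frequency_matrix(
    fm: FrequencyMatrix, handle: IO[str], sidecar: IO[str] | None = None
) -> None:
    """Write W as delimited text (input bit-string + m frequency columns)."""
    m = fm.m
    handle.write("input\t" + "\t".join(f"w{i}" for i in range(m)) + "\n")
    for r in range(fm.n_inputs):
        bits = "".join(str(b) for b in index_to_bits(r, m))
        handle.write(bits + "\t" + "\t".join(f"{v:.6g}" for v in fm.W[r]) + "\n")
    if sidecar is not None:
        json.dump({"h": fm.h, "metadata": fm.metadata}, sidecar, indent=2)


def load_frequency_matrix(
    handle: IO[str], sidecar: IO[str] | None = None
) -> FrequencyMatrix:
    lines = [ln for ln in handle.read().splitlines() if ln.strip()]
    rows = [[float(v) for v in ln.split("\t")[1:]] for ln in lines[1:]]
    h, metadata = 0, {}
    if sidecar is not None:
        side = json.load(sidecar)
        h, metadata = side.get("h", 0), side.get("metadata", {})
    return FrequencyMatrix(np.array(rows), h, metadata)


def write_mapping_image(fm: FrequencyMatrix, path: str) -> None:
    """Greyscale image of the input-to-frequency mapping (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, fm.W.T, cmap="gray", vmin=0.0, vmax=1.0)
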