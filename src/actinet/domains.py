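"""Input/output domains: x-axis slabs used to write and read 8-bit words.

Domain ``i`` is the set of nodes with ``|x - centre(i)| < half_width`` where
``centre(i) = spacing * (i + 1)``.  An input bit 1 excites each node of its
domain independently with probability ``p_excite`` at ``t = 0``; an output
bit is 1 when the number of excited nodes in its domain strictly exceeds
``kappa`` at read time.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import IO, Sequence

import numpy as np

from .dynamics import EXCITED, resting_state
from .graph import FilamentGraph

__all__ = [
    "DomainLayout",
    "TrialConfig",
    "layout_domains",
    "encode_input",
    "read_output",
    "bits_to_index",
    "index_to_bits",
    "save_layout",
    "load_layout",
]


@dataclasses.dataclass
class DomainLayout:
    """Node membership of the m input/output domains."""

    n_nodes: int
    centres: np.ndarray
    half_width: float
    members: list[np.ndarray]

    @property
    def m(self) -> int:
        return len(self.members)


@dataclasses.dataclass(frozen=True)
class TrialConfig:
    """Stochastic write/read protocol of one mapping experiment."""

    p_excite: float = 0.5
    zeta: int = 40
    kappa: int = 0
    h: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_excite <= 1.0:
            raise ValueError("p_excite must lie in [0, 1]")
        if self.zeta < 1:
            raise ValueError("zeta must be >= 1")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.h < 1:
            raise ValueError("h must be >= 1")


def layout_domains(
    graph: FilamentGraph,
    spacing: float = 15.0,
    half_width: float = 7.5,
    m: int = 8,
) -> DomainLayout:
    """Assign nodes to ``m`` equally spaced x-slabs (strict inequality)."""
    if spacing <= 0 or half_width <= 0:
        raise ValueError("spacing and half_width must be > 0")
    centres = spacing * (np.arange(m) + 1)
    x = graph.coords[:, 0]
    members = [
        np.flatnonzero(np.abs(x - centre) < half_width).astype(np.int64)
        for centre in centres
    ]
    if all(len(d) == 0 for d in members):
        raise ValueError(
            "every domain is empty: layout does not intersect the structure "
            f"(x range {x.min():.1f}..{x.max():.1f}, centres {centres[0]}..{centres[-1]})"
        )
    for i, d in enumerate(members):
        if len(d) == 0:
            warnings.warn(f"domain {i} (centre {centres[i]}) is empty", stacklevel=2)
    return DomainLayout(graph.n_nodes, centres, float(half_width), members)


def _as_bits(bits: Sequence[int] | str | int, m: int) -> np.ndarray:
    if isinstance(bits, (int, np.integer)):
        return index_to_bits(int(bits), m)
    if isinstance(bits, str):
        bits = [int(c) for c in bits]
    arr = np.asarray(bits, dtype=np.int64)
    if arr.shape != (m,) or not np.all((arr == 0) | (arr == 1)):
        raise ValueError(f"bits must be {m} binary values")
    return arr


def bits_to_index(bits: Sequence[int] | str) -> int:
    """Interpret a bit word as an integer with bit 0 most significant."""
    arr = [int(b) for b in bits]
    value = 0
    for b in arr:
        value = (value << 1) | b
    return value


def index_to_bits(index: int, m: int = 8) -> np.ndarray:
    """Inverse of :func:`bits_to_index`."""
    if not 0 <= index < (1 << m):
        raise ValueError(f"index out of range for {m} bits")
    return np.array([(index >> (m - 1 - j)) & 1 for j in range(m)], dtype=np.int64)


def encode_input(
    layout: DomainLayout,
    bits: Sequence[int] | str | int,
    p_excite: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial state: domains carrying a 1-bit are excited with ``p_excite``."""
    if not 0.0 <= p_excite <= 1.0:
        raise ValueError("p_excite must lie in [0, 1]")
    word = _as_bits(bits, layout.m)
    state = resting_state(layout.n_nodes)
    for bit, nodes in zip(word, layout.members):
        if bit and len(nodes):
            chosen = nodes[rng.random(len(nodes)) < p_excite]
            state[chosen] = EXCITED
    return state


def read_output(
    state: np.ndarray, layout: DomainLayout, kappa: int = 0
) -> np.ndarray:
    """Output word: bit i is 1 iff excited nodes in domain i exceed ``kappa``."""
    state = np.asarray(state)
    return np.array(
        [
            1 if np.count_nonzero(state[nodes] == EXCITED) > kappa else 0
            for nodes in layout.members
        ],
        dtype=np.int64,
    )


def save_layout(layout: DomainLayout, handle: IO[str]) -> None:
    handle.write(f"# n_nodes\t{layout.n_nodes}\n")
    handle.write(f"# half_width\t{layout.half_width}\n")
    handle.write("# centres\t" + "\t".join(f"{c}" for c in layout.centres) + "\n")
    handle.write("domain_id\tnode_id\n")
    for i, nodes in enumerate(layout.members):
        for node in nodes:
            handle.write(f"{i}\t{node}\n")


def load_layout(handle: IO[str]) -> DomainLayout:
    n_nodes = half_width = centres = None
    rows: list[tuple[int, int]] = []
    for line in handle.read().splitlines():
        if line.startswith("# n_nodes"):
            n_nodes = int(line.split("\t")[1])
        elif line.startswith("# half_width"):
            half_width = float(line.split("\t")[1])
        elif line.startswith("# centres"):
            centres = np.array([float(v) for v in line.split("\t")[1:]])
        elif line and not line.startswith(("#", "domain_id")):
            d, node = line.split("\t")
            rows.append((int(d), int(node)))
    if n_nodes is None or half_width is None or centres is None:
        raise ValueError("layout file missing header lines")
    members = [
        np.array(sorted(n for d, n in rows if d == i), dtype=np.int64)
        for i in range(len(centres))
    ]
    return DomainLayout(n_nodes, centres, half_width, members)
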