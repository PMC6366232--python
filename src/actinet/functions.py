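"""Boolean function extraction and exact two-level minimization.

The frequency matrix is binarized at a reliability threshold gamma (strict
``w > gamma``) into a truth table, and every output column is expressed as a
minimal sum-of-products via Quine-McCluskey prime implicants followed by an
exact minimum-cover search with canonical tie-breaking, so repeated runs
print identical expressions.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Sequence

import numpy as np

from .experiment import FrequencyMatrix, epsilon_ratio, output_one_ratio

__all__ = [
    "BooleanExpression",
    "GammaReport",
    "threshold_truth_table",
    "minimize_sop",
    "format_expression",
    "parse_expression",
    "mine_functions",
]

# An implicant is a pair (mask, value): input word r is covered iff
# (r & mask) == value.  Variable j occupies bit (n_vars - 1 - j), matching
# the convention that bit 0 of the input word is most significant.


def _variable_bit(var: int, n_vars: int) -> int:
    return 1 << (n_vars - 1 - var)


@dataclasses.dataclass(frozen=True)
class BooleanExpression:
    """Sum-of-products over ``n_vars`` inputs in canonical term order."""

    n_vars: int
    terms: tuple[tuple[int, int], ...]
    output_index: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate product terms")
        full = (1 << self.n_vars) - 1
        for mask, value in self.terms:
            if mask & ~full or value & ~mask:
                raise ValueError(f"invalid implicant ({mask:#x}, {value:#x})")

    @property
    def is_constant_false(self) -> bool:
        return len(self.terms) == 0

    @property
    def is_constant_true(self) -> bool:
        return self.terms == ((0, 0),)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def n_literals(self) -> int:
        return sum(mask.bit_count() for mask, _ in self.terms)

    def evaluate(self, word: int) -> bool:
        return any((word & mask) == value for mask, value in self.terms)

    def truth_column(self) -> np.ndarray:
        """Evaluate over all ``2**n_vars`` input words."""
        r = np.arange(1 << self.n_vars)
        out = np.zeros(len(r), dtype=bool)
        for mask, value in self.terms:
            out |= (r & mask) == value
        return out

    def literals(self) -> list[list[tuple[int, bool]]]:
        """Terms as lists of ``(variable index, polarity)`` pairs."""
        result = []
        for mask, value in self.terms:
            term = []
            for var in range(self.n_vars):
                bit = _variable_bit(var, self.n_vars)
                if mask & bit:
                    term.append((var, bool(value & bit)))
            result.append(term)
        return result


def threshold_truth_table(
    W: FrequencyMatrix | np.ndarray, gamma: float
) -> np.ndarray:
    """Binary table: entry 1 iff the frequency strictly exceeds gamma."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    matrix = W.W if isinstance(W, FrequencyMatrix) else np.asarray(W)
    return (matrix > gamma).astype(np.int64)


def _prime_implicants(on_set: frozenset[int], n_vars: int) -> set[tuple[int, int]]:
    full = (1 << n_vars) - 1
    current = {(full, m) for m in on_set}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        next_level: set[tuple[int, int]] = set()
        for mask, value in current:
            bits = mask
            while bits:
                bit = bits & -bits
                bits ^= bit
                partner = (mask, value ^ bit)
                if partner in current:
                    merged.add((mask, value))
                    merged.add(partner)
                    next_level.add((mask ^ bit, value & ~bit))
        primes |= current - merged
        current = next_level
    return primes


def _canonical_key(term: tuple[int, int]) -> tuple[int, int, int]:
    mask, value = term
    return (mask.bit_count(), mask, value)


def _minimum_cover(
    primes: set[tuple[int, int]], on_set: frozenset[int]
) -> tuple[tuple[int, int], ...]:
    """Exact minimum-cardinality prime cover of the ON-set.

    Essential primes (the sole cover of some minterm) are selected first;
    the remaining cyclic core is solved as an exact binary set cover with
    HiGHS.  Primes are processed in canonical order, so the result is
    deterministic for a given column.
    """
    prime_list = sorted(primes, key=_canonical_key)
    cover = {p: frozenset(m for m in on_set if (m & p[0]) == p[1]) for p in prime_list}

    chosen: list[tuple[int, int]] = []
    uncovered = set(on_set)
    changed = True
    while changed and uncovered:
        changed = False
        for m in sorted(uncovered):
            candidates = [p for p in prime_list if m in cover[p]]
            if len(candidates) == 1:
                chosen.append(candidates[0])
                uncovered -= cover[candidates[0]]
                changed = True
                break

    if uncovered:
        from scipy import optimize, sparse

        live = [p for p in prime_list if cover[p] & uncovered]
        minterms = sorted(uncovered)
        row_index = {m: i for i, m in enumerate(minterms)}
        rows, cols = [], []
        for j, p in enumerate(live):
            for m in cover[p] & uncovered:
                rows.append(row_index[m])
                cols.append(j)
        matrix = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(minterms), len(live))
        )
        result = optimize.milp(
            c=np.ones(len(live)),
            constraints=optimize.LinearConstraint(matrix, lb=1.0),
            integrality=np.ones(len(live)),
            bounds=optimize.Bounds(0.0, 1.0),
        )
        if not result.success:  # pragma: no cover - 8-var covers always solve
            raise RuntimeError(f"set cover failed: {result.message}")
        chosen.extend(p for p, x in zip(live, result.x) if x > 0.5)

    return tuple(sorted(set(chosen), key=_canonical_key))


def minimize_sop(
    column: Sequence[int] | np.ndarray, output_index: int | None = None
) -> BooleanExpression:
    """Exact two-level minimization of a complete truth-table column.

    The column length must be a power of two (``2**n_vars`` entries in input
    word order).  The result is logically equivalent to the column on every
    input word; ties between minimum covers are broken canonically.
    """
    column = np.asarray(column, dtype=bool).ravel()
    n_vars = int(np.log2(len(column)))
    if 1 << n_vars != len(column):
        raise ValueError("column length must be a power of two")
    on_set = frozenset(int(i) for i in np.flatnonzero(column))
    if not on_set:
        return BooleanExpression(n_vars, (), output_index)
    if len(on_set) == len(column):
        return BooleanExpression(n_vars, ((0, 0),), output_index)
    primes = _prime_implicants(on_set, n_vars)
    terms = _minimum_cover(primes, on_set)
    return BooleanExpression(n_vars, terms, output_index)


def format_expression(expr: BooleanExpression, var_prefix: str = "I") -> str:
    """Render as e.g. ``O4 = ~I0·I1·~I2·I3·I4·I5·I6·I7``."""
    name = f"O{expr.output_index}" if expr.output_index is not None else "f"
    if expr.is_constant_false:
        return f"{name} = 0"
    if expr.is_constant_true:
        return f"{name} = 1"
    rendered = []
    for term in expr.literals():
        rendered.append(
            "·".join(
                ("" if positive else "~") + f"{var_prefix}{var}"
                for var, positive in term
            )
        )
    return f"{name} = " + " + ".join(rendered)


def parse_expression(
    text: str, n_vars: int, var_prefix: str = "I"
) -> BooleanExpression:
    """Parse the output of :func:`format_expression` back into an expression."""
    name, _, body = text.partition("=")
    name, body = name.strip(), body.strip()
    match = re.fullmatch(rf"O(\d+)", name)
    output_index = int(match.group(1)) if match else None
    if body == "0":
        return BooleanExpression(n_vars, (), output_index)
    if body == "1":
        return BooleanExpression(n_vars, ((0, 0),), output_index)
    terms = []
    for product in body.split("+"):
        mask = value = 0
        for token in re.split(r"[·*&]", product.strip()):
            token = token.strip()
            m = re.fullmatch(rf"(~?){re.escape(var_prefix)}(\d+)", token)
            if not m:
                raise ValueError(f"cannot parse literal {token!r}")
            var = int(m.group(2))
            if var >= n_vars:
                raise ValueError(f"variable index {var} out of range")
            bit = _variable_bit(var, n_vars)
            mask |= bit
            if m.group(1) != "~":
                value |= bit
        terms.append((mask, value))
    return BooleanExpression(
        n_vars, tuple(sorted(set(terms), key=_canonical_key)), output_index
    )


@dataclasses.dataclass
class GammaReport:
    """Functions mined at one reliability threshold, with summary ratios."""

    gamma: float
    functions: list[BooleanExpression]
    epsilon: float
    one_ratio: float


def mine_functions(
    W: FrequencyMatrix | np.ndarray, gammas: Sequence[float]
) -> list[GammaReport]:
    """Threshold W at each gamma and minimize every non-constant-zero output."""
    reports = []
    for gamma in gammas:
        table = threshold_truth_table(W, gamma)
        functions = []
        for i in range(table.shape[1]):
            expr = minimize_sop(table[:, i], output_index=i)
            if not expr.is_constant_false:
                functions.append(expr)
        reports.append(
            GammaReport(
                gamma=float(gamma),
                functions=functions,
                epsilon=epsilon_ratio(W, gamma),
                one_ratio=output_one_ratio(table),
            )
        )
    return reports
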