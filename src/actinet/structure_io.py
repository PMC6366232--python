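"""Structure input/output and synthetic filament generation.

Reads atomic structures from PDB text (ATOM/HETATM/CONECT/MODEL records),
infers covalent bonds from interatomic distances when connectivity records
are absent, and generates synthetic helical filaments whose bonded-degree
and spatial-packing statistics emulate a pseudo-atomic filament model, so
that every downstream stage can be exercised without external data.
"""

from __future__ import annotations

import dataclasses
import math
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomSet",
    "SynthParams",
    "DEFAULT_BOND_CUTOFF",
    "read_structure",
    "write_pdb",
    "infer_bonds",
    "generate_synthetic_filament",
]

#: Global fallback covalent cutoff (Å); covers C-C, C-N, C-O and C-S single bonds.
DEFAULT_BOND_CUTOFF = 1.9


@dataclasses.dataclass
class AtomSet:
    """A set of atoms with coordinates and optional explicit bonds.

    Parameters
    ----------
    ids
        Unique integer atom identifiers (PDB serials for parsed files).
    elements
        Chemical element symbol per atom.
    coords
        ``(n, 3)`` Cartesian coordinates in Å.
    bonds
        Unordered pairs of atom *ids* (not positional indices).
    """

    ids: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    bonds: list[tuple[int, int]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.elements = np.asarray(self.elements, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if len(self.ids) != len(self.coords) or len(self.elements) != len(self.coords):
            raise ValueError("ids, elements and coords must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("atom ids must be unique")
        known = set(self.ids.tolist())
        norm = []
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"bond ({a}, {b}) links an atom to itself")
            if a not in known or b not in known:
                raise ValueError(f"bond ({a}, {b}) references an unknown atom id")
            norm.append((min(a, b), max(a, b)))
        self.bonds = sorted(set(norm))

    @property
    def n_atoms(self) -> int:
        return len(self.ids)

    def index_of(self) -> dict[int, int]:
        """Map atom id -> positional index."""
        return {int(a): i for i, a in enumerate(self.ids)}


@dataclasses.dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic two-start helical filament generator."""

    n_monomers: int = 15
    atoms_per_monomer: int = 120
    helix_rise: float = 10.0
    helix_twist: float = -166.7
    monomer_radius: float = 6.5
    backbone_bond_length: float = 1.43
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_monomers < 1 or self.atoms_per_monomer < 1:
            raise ValueError("counts must be >= 1")
        for name in ("helix_rise", "monomer_radius", "backbone_bond_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _parse_float(field: str, lineno: int, what: str) -> float:
    try:
        return float(field)
    except ValueError:
        raise ValueError(
            f"PDB parse error at line {lineno}: bad {what} field {field.strip()!r}"
        ) from None


def read_structure(pdb_text: str | IO[str]) -> AtomSet:
    """Parse PDB text into an :class:`AtomSet`.

    Reads ATOM and HETATM records of the first MODEL only, skipping alternate
    locations other than blank or ``A``.  CONECT records are captured as
    explicit bonds.  Raises :class:`ValueError` naming the offending line on
    malformed records, and on files containing no atoms.
    """
    if hasattr(pdb_text, "read"):
        pdb_text = pdb_text.read()
    ids: list[int] = []
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    bonds: set[tuple[int, int]] = set()
    in_first_model = True
    seen_model = False
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            if seen_model:
                break
            seen_model = True
        elif record == "ENDMDL":
            in_first_model = False
        elif record in ("ATOM", "HETATM") and in_first_model:
            if len(line) < 54:
                raise ValueError(
                    f"PDB parse error at line {lineno}: record shorter than 54 columns"
                )
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            try:
                serial = int(line[6:11])
            except ValueError:
                raise ValueError(
                    f"PDB parse error at line {lineno}: bad serial field {line[6:11].strip()!r}"
                ) from None
            x = _parse_float(line[30:38], lineno, "x-coordinate")
            y = _parse_float(line[38:46], lineno, "y-coordinate")
            z = _parse_float(line[46:54], lineno, "z-coordinate")
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                # fall back on the atom-name column, e.g. " CA " -> C
                name = line[12:16].strip().lstrip("0123456789")
                element = name[:1] if name else "X"
            ids.append(serial)
            elements.append(element.capitalize())
            coords.append((x, y, z))
        elif record == "CONECT":
            fields = line.split()[1:]
            if not fields:
                continue
            try:
                serials = [int(f) for f in fields]
            except ValueError:
                raise ValueError(
                    f"PDB parse error at line {lineno}: non-integer CONECT field"
                ) from None
            origin = serials[0]
            for partner in serials[1:]:
                if partner != origin:
                    bonds.add((min(origin, partner), max(origin, partner)))
    if not ids:
        raise ValueError("no ATOM/HETATM records found in input")
    return AtomSet(np.array(ids), np.array(elements), np.array(coords), sorted(bonds))


def write_pdb(atoms: AtomSet, handle: IO[str]) -> None:
    """Write an :class:`AtomSet` as minimal PDB text, including CONECT records."""
    neighbours: dict[int, list[int]] = {}
    for a, b in atoms.bonds:
        neighbours.setdefault(a, []).append(b)
        neighbours.setdefault(b, []).append(a)
    for i in range(atoms.n_atoms):
        serial = int(atoms.ids[i])
        el = str(atoms.elements[i])
        x, y, z = atoms.coords[i]
        name = f" {el:<3s}"[:4]  # atom name cols 13-16, altloc col 17 blank
        handle.write(
            f"ATOM  {serial:>5d} {name} MON A{1 + i // 10000:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
        )
    for origin in sorted(neighbours):
        partners = sorted(neighbours[origin])
        for start in range(0, len(partners), 4):
            chunk = partners[start : start + 4]
            handle.write(
                "CONECT" + f"{origin:>5d}" + "".join(f"{p:>5d}" for p in chunk) + "\n"
            )
    handle.write("END\n")


def _pair_key(el_a: str, el_b: str) -> tuple[str, str]:
    return (el_a, el_b) if el_a <= el_b else (el_b, el_a)


def infer_bonds(
    atoms: AtomSet,
    cutoff_rules: Mapping[tuple[str, str], float] | None = None,
    default_cutoff: float = DEFAULT_BOND_CUTOFF,
) -> list[tuple[int, int]]:
    """Infer bonds as atom pairs closer than an element-pair distance cutoff.

    ``cutoff_rules`` maps unordered element pairs, e.g. ``("C", "S")``, to a
    maximum bond distance in Å; any pair without a rule uses
    ``default_cutoff``.  The result is a sorted list of unordered id pairs,
    symmetric and free of self-pairs by construction.
    """
    rules: dict[tuple[str, str], float] = {}
    if cutoff_rules:
        for (a, b), cut in cutoff_rules.items():
            if cut <= 0:
                raise ValueError("cutoff distances must be positive")
            rules[_pair_key(a, b)] = float(cut)
    if default_cutoff <= 0:
        raise ValueError("default_cutoff must be positive")
    if atoms.n_atoms < 2:
        return []
    search_radius = max([default_cutoff, *rules.values()])
    tree = cKDTree(atoms.coords)
    pairs = tree.query_pairs(search_radius, output_type="ndarray")
    bonds: list[tuple[int, int]] = []
    for i, j in pairs:
        cut = rules.get(
            _pair_key(str(atoms.elements[i]), str(atoms.elements[j])), default_cutoff
        )
        d = float(np.linalg.norm(atoms.coords[i] - atoms.coords[j]))
        if d <= cut:
            a, b = int(atoms.ids[i]), int(atoms.ids[j])
            bonds.append((min(a, b), max(a, b)))
    return sorted(bonds)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        norm = float(np.linalg.norm(v))
        if norm > 1e-9:
            return v / norm


def _walk_monomer(
    n: int,
    radius: float,
    bond: float,
    rng: np.random.Generator,
    branch_prob: float = 0.3,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Branching self-avoiding walk with fixed bond length inside a sphere.

    Every new atom is placed at exactly ``bond`` Å from its anchor — the walk
    head, or (with ``branch_prob``, and whenever the head jams) a random
    earlier atom of bonded degree <= 2.  Abandoned walk tips give degree-1
    atoms, branch points degree-3, so most atoms carry 1-3 bonds.
    """
    min_sep = 0.84 * bond
    points = np.empty((n, 3))
    points[0] = _random_unit(rng) * rng.uniform(0.0, radius / 2)
    bonds: list[tuple[int, int]] = []
    degree = np.zeros(n, dtype=np.int64)

    def try_place(i: int, anchor: int, tries: int) -> bool:
        for _ in range(tries):
            pos = points[anchor] + _random_unit(rng) * bond
            if pos @ pos > radius * radius:
                continue
            d2 = np.sum((points[:i] - pos) ** 2, axis=1)
            d2[anchor] = np.inf  # anchor sits at exactly one bond length
            if i > 1 and d2.min() < min_sep * min_sep:
                continue
            points[i] = pos
            bonds.append((anchor, i))
            degree[anchor] += 1
            degree[i] += 1
            return True
        return False

    head = 0
    for i in range(1, n):
        anchor = head
        if rng.random() < branch_prob:
            open_sites = np.flatnonzero(degree[:i] <= 2)
            if len(open_sites):
                anchor = int(rng.choice(open_sites))
        if not try_place(i, anchor, 30):
            placed = False
            for j in rng.permutation(i):  # jammed: branch from anywhere open
                if degree[j] <= 2 and try_place(i, int(j), 30):
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place atom {i} of {n} in a sphere of radius {radius}"
                )
        head = i
    return points, bonds


def _nearest_atom_pair(
    coords: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[int, int]:
    tree = cKDTree(coords[idx_b])
    dists, nearest = tree.query(coords[idx_a])
    best = int(np.argmin(dists))
    return int(idx_a[best]), int(idx_b[nearest[best]])


def generate_synthetic_filament(params: SynthParams) -> AtomSet:
    """Generate a synthetic filament as a two-start helix of packed monomers.

    Each pseudo-monomer is a branching self-avoiding walk with fixed bond
    length packed into a sphere; consecutive monomers alternate between the
    two helical strands (rotating by ``helix_twist`` and rising by
    ``helix_rise`` along x).
    Monomers are linked along each strand (m to m+2) and laterally (m to
    m+1).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n_total = params.n_monomers * params.atoms_per_monomer
    coords = np.empty((n_total, 3))
    bonds_idx: list[tuple[int, int]] = []
    degree = np.zeros(n_total, dtype=np.int64)
    bonded: set[tuple[int, int]] = set()

    def add_bond(i: int, j: int) -> None:
        key = (min(i, j), max(i, j))
        if key not in bonded:
            bonded.add(key)
            bonds_idx.append(key)
            degree[i] += 1
            degree[j] += 1

    axis_offset = max(params.monomer_radius * 0.3, 1.0)
    for m in range(params.n_monomers):
        local, local_bonds = _walk_monomer(
            params.atoms_per_monomer,
            params.monomer_radius,
            params.backbone_bond_length,
            rng,
        )
        angle = math.radians(params.helix_twist) * m
        centre = np.array(
            [
                m * params.helix_rise,
                axis_offset * math.cos(angle),
                axis_offset * math.sin(angle),
            ]
        )
        base = m * params.atoms_per_monomer
        coords[base : base + params.atoms_per_monomer] = local + centre
        for i, j in local_bonds:
            add_bond(base + i, base + j)

    def monomer_indices(m: int) -> np.ndarray:
        base = m * params.atoms_per_monomer
        return np.arange(base, base + params.atoms_per_monomer)

    for m in range(params.n_monomers):
        for other in (m + 1, m + 2):  # lateral contact and same-strand link
            if other >= params.n_monomers:
                continue
            i, j = _nearest_atom_pair(coords, monomer_indices(m), monomer_indices(other))
            if degree[i] <= 3 and degree[j] <= 3:
                add_bond(i, j)

    ids = np.arange(1, n_total + 1)
    elements = rng.choice(
        np.array(["C", "N", "O", "S"]), size=n_total, p=[0.62, 0.17, 0.20, 0.01]
    )
    bonds = [(int(ids[i]), int(ids[j])) for i, j in bonds_idx]
    return AtomSet(ids, elements, coords, bonds)
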