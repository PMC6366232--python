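# actinet

Automaton networks on atomic filament structures.

`actinet` turns an atomic structure (PDB) into a two-neighbourhood network —
every atom is a node with *hard* neighbours (covalently bonded partners) and
*soft* neighbours (non-bonded atoms within a radius `rho`, default 10 Å) —
and simulates two synchronous update rules on it:

* **rule G** (semi-totalistic, two states): a resting node becomes excited,
  and an excited node survives, when its weighted excited-neighbour ratio
  lies inside a configurable interval (default `[0.25, 0.375]` for both);
* **rule E** (excitable, three states): a resting node becomes excited when
  the ratio lies inside an interval (default `[0.15, 0.25]`); excited nodes
  become refractory and refractory nodes return to resting unconditionally.

The ratio of a node is `(hard excited + mu * soft excited) / (|hard| +
|soft|)` with soft-neighbour weight `mu = 0.9`.

On top of the dynamics, the package implements an 8-bit input/output mapping
experiment: eight x-axis slabs (centres `15·(i+1)` Å, half-width 7.5 Å) act
as I/O domains; an input bit 1 excites each node of its domain with
probability `p` at `t = 0`; outputs are read after `zeta = 40` steps (bit 1
when more than `kappa = 0` nodes of the domain are excited).  Running all
256 input words for `h` trials yields a 256 × 8 frequency matrix **W**,
which is binarized at a reliability threshold `gamma` and minimized column
by column (Quine–McCluskey + exact cover) into Boolean sum-of-products
expressions.

A synthetic filament generator (branching self-avoiding walks packed into a
two-start helix of pseudo-monomers) provides download-free structures whose
bonded-degree and packing statistics emulate a pseudo-atomic filament model,
so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic filament (PDB with CONECT records)
actinet synth -o filament.pdb

# build the two-neighbourhood graph and print structure statistics
actinet graph filament.pdb --rho 10

# evolve the automaton from a configurable initial excitation
actinet simulate filament.pdb --rule E --theta-rest 0.125 1.0 \
    --excite-x 0 15 --steps 40 --profile-out profile.tsv

# run the full 256-input mapping experiment
actinet run filament.pdb --rule G --trials 100 --seed 1 \
    -o W.tsv --sidecar W.json

# mine Boolean functions from the frequency matrix
actinet mine W.tsv --gamma 0.1 --gamma 0.25 --json-out functions.json
```

Real structures work the same way: pass any PDB file to `graph`, `simulate`
or `run`; bonds are taken from CONECT records when present and otherwise
inferred from interatomic distances (global cutoff 1.9 Å, per-element-pair
overrides available in the API).

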