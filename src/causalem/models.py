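"""Generators for the two study systems.

**Bipartite Markov chain.** The n_a + n_b microstates split into two
groups A and B and the dynamics oscillate between them: every A-state
transitions only into B and vice versa, so coarse-graining the two groups
into macrostates ON (= A) and OFF (= B) always yields the fully
deterministic two-state flip-flop [[0,1],[1,0]], whatever the microscale
parameters. Two knobs shape the microscale noise:

* ``dilution`` d in [0,1] — the determinism axis. Each state has a main
  target in the opposite group receiving probability d + (1−d)/n_opp
  while every other opposite-group state receives (1−d)/n_opp. d = 1 is
  fully deterministic; d = 0 is uniform within the group.
* ``rewiring`` g in [0,1] — the degeneracy axis. The main-target map is
  rewired so only t = max(1, round((1−g)·n_src)) distinct targets remain,
  assigned round-robin onto the first t states of the opposite group:
  g = 0 keeps the map bijective, g = 1 stacks every main transition onto
  a single shared target.

Binary labels follow the two-group convention: A counts up from all-zeros
(0000, 0001, ...) and B counts down from all-ones (1111, 1110, ...), so
in the symmetric 16-state model each A-state's main target at g = 0 is
its bitwise complement (0000 -> 1111).

**Noisy NAND network.** n binary gates where every gate outputs the NAND
of the full previous gate vector (its own value included), so the
deterministic update sends every state to all-ON except all-ON itself,
which goes to all-OFF — a bistable dynamic. Noise is applied at the state
level: the logical target keeps probability 1 − noise and the remaining
mass spreads uniformly over the other 2^n − 1 states (for two gates at
noise 0.1 this prints P(00|11) = 0.9). Degeneracy grows with the gate
count (ever more states converge on all-ON); determinism falls with the
noise level.

Both generators are pure functions of their spec: no hidden randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import StateSpace, Transition, TransitionModel
from .errors import InvalidInputError

__all__ = [
    "BipartiteSpec",
    "NandSpec",
    "bipartite_model",
    "bipartite_macro_mapping",
    "label_main_and_secondary",
    "nand_model",
    "nand_macro_mapping",
]


@dataclass(frozen=True)
class BipartiteSpec:
    """Bipartite-model recipe: group sizes and the two noise knobs."""

    n_a: int = 8
    n_b: int = 8
    dilution: float = 1.0
    rewiring: float = 0.0

    def __post_init__(self):
        if self.n_a < 1 or self.n_b < 1:
            raise InvalidInputError("group sizes must be at least 1")
        if not (0.0 <= self.dilution <= 1.0 and 0.0 <= self.rewiring <= 1.0):
            raise InvalidInputError("dilution and rewiring must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.n_a + self.n_b

    @property
    def bit_width(self) -> int:
        return max(1, math.ceil(math.log2(self.n)))

    def space(self) -> StateSpace:
        """A-labels ascend from all-zeros; B-labels descend from all-ones."""
        N = self.bit_width
        if self.n > 2**N:  # pragma: no cover - bit_width guarantees capacity
            raise InvalidInputError("state count exceeds label capacity")
        a = [format(i, f"0{N}b") for i in range(self.n_a)]
        b = [format(2**N - 1 - j, f"0{N}b") for j in range(self.n_b)]
        if set(a) & set(b):
            raise InvalidInputError(
                "groups overlap in label space; need n_a + n_b <= 2**bit_width"
            )
        return StateSpace(tuple(a + b), bit_width=N)

    def group_a(self) -> tuple[str, ...]:
        return self.space().labels[: self.n_a]

    def group_b(self) -> tuple[str, ...]:
        return self.space().labels[self.n_a:]


def _n_targets(g: float, n_src: int) -> int:
    """Distinct main targets after rewiring: round-robin onto the first
    t = max(1, round((1−g)·n_src)) opposite-group states."""
    return max(1, round((1.0 - g) * n_src))


def _main_target_index(spec: BipartiteSpec, src_index: int, from_a: bool) -> int:
    n_src = spec.n_a if from_a else spec.n_b
    return src_index % _n_targets(spec.rewiring, n_src)


def bipartite_model(spec: BipartiteSpec) -> TransitionModel:
    """Build the bipartite TPM for a given (dilution, rewiring) setting."""
    space = spec.space()
    n_a, n_b, d = spec.n_a, spec.n_b, spec.dilution
    matrix = np.zeros((spec.n, spec.n))
    for i in range(n_a):  # A -> B
        row = matrix[i]
        row[n_a:] = (1.0 - d) / n_b
        row[n_a + _main_target_index(spec, i, from_a=True)] += d
    for j in range(n_b):  # B -> A
        row = matrix[n_a + j]
        row[:n_a] = (1.0 - d) / n_a
        row[_main_target_index(spec, j, from_a=False)] += d
    return TransitionModel(space, matrix)


def bipartite_macro_mapping(spec: BipartiteSpec) -> dict[str, str]:
    """The two-group coarse-graining h(A) = ON, h(B) = OFF."""
    mapping = {s: "ON" for s in spec.group_a()}
    mapping.update({s: "OFF" for s in spec.group_b()})
    return mapping


def label_main_and_secondary(
    spec: BipartiteSpec, c: str, strict: bool = True
) -> tuple[Transition, Transition]:
    """The highest-probability (main) transition of a cause and its first
    secondary transition (the lowest-index opposite-group state that is
    not the main target).

    With ``strict=True`` a zero dilution is rejected, since every
    transition then ties and no main transition is unique; sweeps that
    include d = 0 pass ``strict=False`` to keep using the structural
    target map of the generator.
    """
    if strict and spec.dilution == 0.0:
        raise InvalidInputError(
            "d = 0 leaves no unique main transition (all transitions tie)"
        )
    space = spec.space()
    i = space.index(c)
    from_a = i < spec.n_a
    src_index = i if from_a else i - spec.n_a
    opposite = spec.group_b() if from_a else spec.group_a()
    main = opposite[_main_target_index(spec, src_index, from_a)]
    secondary = next(s for s in opposite if s != main)
    return Transition(c, main), Transition(c, secondary)


@dataclass(frozen=True)
class NandSpec:
    """NAND-network recipe: gate count and state-level noise."""

    n_nodes: int = 2
    noise: float = 0.1

    def __post_init__(self):
        if self.n_nodes < 2:
            raise InvalidInputError("need at least 2 gates")
        if not 0.0 <= self.noise <= 1.0:
            raise InvalidInputError("noise must lie in [0, 1]")

    def space(self) -> StateSpace:
        return StateSpace.hypercube(self.n_nodes)


def _nand_next(state: str) -> str:
    """Deterministic update: each gate NANDs the full previous gate vector,
    so the next state is all-OFF iff the current state is all-ON, else all-ON."""
    n = len(state)
    return "0" * n if state == "1" * n else "1" * n


def nand_model(spec: NandSpec) -> TransitionModel:
    """The noisy NAND TPM: logical target keeps 1 − noise, the rest of the
    mass spreads uniformly over the other states."""
    space = spec.space()
    n = space.n
    matrix = np.full((n, n), spec.noise / (n - 1))
    for i, s in enumerate(space.labels):
        j = space.index(_nand_next(s))
        matrix[i, :] = spec.noise / (n - 1)
        matrix[i, j] = 1.0 - spec.noise
    return TransitionModel(space, matrix)


def nand_macro_mapping(spec: NandSpec) -> dict[str, str]:
    """Group the all-ON microstate into macrostate ON; every other
    microstate into OFF."""
    ones = "1" * spec.n_nodes
    return {s: ("ON" if s == ones else "OFF") for s in spec.space().labels}
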