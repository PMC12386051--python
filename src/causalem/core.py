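"""State spaces, transition models and intervention distributions.

A discrete Markovian system is fully described by a row-stochastic
transition probability matrix (TPM) over a finite state space Omega: entry
``(c, e)`` holds ``P(e | do(c))``, the probability of effect state ``e`` at
time t+1 when cause state ``c`` is imposed by intervention at time t.

Every measure of causal strength additionally needs an *intervention
distribution* ``P_C`` over causes — the space of counterfactual
interventions considered. Three standard constructions are provided:

``maxent``
    Uniform over all states (all counterfactuals equally probed).
``observational``
    The stationary distribution ``pi = pi T`` of the chain itself.
``local``
    Uniform over the Hamming ball of radius ``delta`` around a center
    state (only "nearby possible worlds" are probed); requires binary
    state labels.

From a TPM and a ``P_C`` the two kernels every measure consumes follow:
the marginal effect distribution ``P(e|C)`` and the counterfactual effect
distribution ``P(e|C\\c)`` obtained by excluding a cause and renormalizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateCounterfactualError,
    InvalidInputError,
    NumericalFailureError,
)

#: tolerance for "sums to one" checks on probability vectors and TPM rows
PROB_TOL = 1e-9


def _is_binary(label: str) -> bool:
    return len(label) > 0 and set(label) <= {"0", "1"}


@dataclass(frozen=True)
class StateSpace:
    """The finite set Omega of n labeled system states.

    Labels are ordered and unique; all vectors and TPM rows/columns in the
    package follow this order. When every label is a fixed-width binary
    string, ``bit_width`` is set and Hamming-based constructions (local
    interventions, bit-flip perturbations, closest possible worlds) apply.
    """

    labels: tuple[str, ...]
    bit_width: int | None = None
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise InvalidInputError("a state space needs at least 2 states")
        if len(set(labels)) != len(labels):
            raise InvalidInputError("state labels must be unique")
        if self.bit_width is not None:
            N = self.bit_width
            if any(len(s) != N or not _is_binary(s) for s in labels):
                raise InvalidInputError(
                    f"bit_width={N} requires every label to be an {N}-bit string"
                )
            if len(labels) > 2**N:
                raise InvalidInputError("more labels than the hypercube holds")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(labels)})

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "StateSpace":
        """Build a space, auto-detecting equal-width binary labels."""
        labels = tuple(str(x) for x in labels)
        widths = {len(s) for s in labels}
        if len(widths) == 1 and all(_is_binary(s) for s in labels):
            return cls(labels, bit_width=widths.pop())
        return cls(labels)

    @classmethod
    def hypercube(cls, n_bits: int) -> "StateSpace":
        """The full 2**n_bits hypercube, labels in ascending binary order."""
        labels = tuple(format(i, f"0{n_bits}b") for i in range(2**n_bits))
        return cls(labels, bit_width=n_bits)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def is_hypercube(self) -> bool:
        return self.bit_width is not None and self.n == 2**self.bit_width

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise InvalidInputError(f"unknown state label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class Transition:
    """A single (cause, effect) state pair."""

    cause: str
    effect: str

    def __str__(self) -> str:  # used in result tables
        return f"{self.cause}->{self.effect}"


def hamming_distance(x: str, y: str) -> int:
    """Number of bit flips needed to turn binary string ``x`` into ``y``.

    >>> hamming_distance("0001", "0010")
    2
    """
    if len(x) != len(y):
        raise InvalidInputError(
            f"labels {x!r} and {y!r} have different lengths"
        )
    if not (_is_binary(x) and _is_binary(y)):
        raise InvalidInputError("hamming_distance needs binary string labels")
    return sum(a != b for a, b in zip(x, y))


class TransitionModel:
    """A row-stochastic matrix encoding ``P(e | do(c))`` for all (c, e).

    Rows are indexed by cause, columns by effect, both in the order of
    ``space.labels``. Rows off unity by more than ``PROB_TOL`` are
    rejected; smaller discrepancies are renormalized once on construction
    and the matrix is trusted thereafter.
    """

    def __init__(self, space: StateSpace, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        n = space.n
        if matrix.shape != (n, n):
            raise InvalidInputError(
                f"matrix shape {matrix.shape} does not match n={n}"
            )
        if np.any(matrix < -PROB_TOL) or np.any(matrix > 1 + PROB_TOL):
            raise InvalidInputError("matrix entries must lie in [0, 1]")
        row_sums = matrix.sum(axis=1)
        bad = np.where(np.abs(row_sums - 1.0) > PROB_TOL)[0]
        if bad.size:
            raise InvalidInputError(
                f"row {space.labels[bad[0]]!r} sums to {row_sums[bad[0]]!r}, not 1"
            )
        matrix = np.clip(matrix, 0.0, 1.0)
        self.space = space
        self.matrix = matrix / matrix.sum(axis=1, keepdims=True)
        self.matrix.setflags(write=False)

    @property
    def n(self) -> int:
        return self.space.n

    def prob(self, cause: str, effect: str) -> float:
        """P(effect | do(cause))."""
        return float(
            self.matrix[self.space.index(cause), self.space.index(effect)]
        )

    def row(self, cause: str) -> np.ndarray:
        """The effect distribution of one cause."""
        return self.matrix[self.space.index(cause)]

    def check_transition(self, t: Transition) -> Transition:
        self.space.index(t.cause)
        self.space.index(t.effect)
        return t

    def __repr__(self) -> str:
        return f"TransitionModel(n={self.n}, labels={self.space.labels[:4]}...)"


@dataclass(frozen=True)
class InterventionDistribution:
    """A probability vector P_C over causes plus the construction it came from.

    ``kind`` is one of ``maxent | observational | local | custom``; for
    ``local`` the parameters record the center state and Hamming radius.
    """

    space: StateSpace
    weights: np.ndarray
    kind: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.space.n,):
            raise InvalidInputError("weight vector length must equal n")
        if np.any(w < -PROB_TOL):
            raise InvalidInputError("intervention weights must be non-negative")
        if abs(w.sum() - 1.0) > PROB_TOL:
            raise InvalidInputError("intervention weights must sum to 1")
        w = np.clip(w, 0.0, None)
        w = w / w.sum()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    def prob(self, label: str) -> float:
        return float(self.weights[self.space.index(label)])


def maxent_distribution(space: StateSpace) -> InterventionDistribution:
    """The maximum-entropy intervention distribution: uniform over Omega."""
    n = space.n
    return InterventionDistribution(space, np.full(n, 1.0 / n), kind="maxent")


def observational_distribution(
    model: TransitionModel,
    tolerance: float = 1e-12,
    max_iter: int = 100_000,
) -> InterventionDistribution:
    """The stationary distribution pi = pi T of the chain.

    Computed by averaged power iteration from the uniform start:
    ``mu <- (mu + mu T) / 2``. Averaging the iterate with its image keeps
    the fixed points of T while damping every other eigenmode (eigenvalue
    lambda of T becomes (1 + lambda)/2, of modulus < 1 unless lambda = 1),
    so periodic oscillation dies out geometrically and, for reducible
    chains with several fixed points, the limit is the projection of the
    uniform start onto the stationary subspace — the same point the Cesaro
    average of the plain iteration converges to. Convergence is declared
    on the fixed-point residual ``max|mu T − mu|``.
    """
    T = model.matrix
    mu = np.full(model.n, 1.0 / model.n)
    for _ in range(max_iter):
        step = mu @ T
        residual = float(np.max(np.abs(step - mu)))
        if residual <= tolerance:
            mu = mu / mu.sum()
            return InterventionDistribution(
                model.space,
                mu,
                kind="observational",
                params={"tolerance": tolerance, "start": "uniform-cesaro"},
            )
        mu = 0.5 * (mu + step)
    raise NumericalFailureError(
        "stationary distribution did not converge", residual
    )


def local_distribution(
    space: StateSpace, center: str, delta: int
) -> InterventionDistribution:
    """Uniform weights on the Hamming ball of radius ``delta`` around ``center``.

    The support is Theta = {s in Omega : D_H(s, center) <= delta}, center
    included, mirroring a "local sampling of possible worlds".
    """
    if space.bit_width is None:
        raise InvalidInputError("local interventions need binary state labels")
    if delta < 0:
        raise InvalidInputError("delta must be a non-negative integer")
    center_i = space.index(center)
    center_label = space.labels[center_i]
    mask = np.array(
        [hamming_distance(s, center_label) <= delta for s in space.labels],
        dtype=float,
    )
    return InterventionDistribution(
        space,
        mask / mask.sum(),
        kind="local",
        params={"center": center_label, "delta": int(delta)},
    )


def make_intervention(
    model: TransitionModel,
    kind: str,
    center: str | None = None,
    delta: int = 1,
) -> InterventionDistribution:
    """Resolve an intervention-kind tag into a concrete distribution.

    ``local`` requires a ``center`` (usually the cause under scrutiny).
    """
    if kind == "maxent":
        return maxent_distribution(model.space)
    if kind == "observational":
        return observational_distribution(model)
    if kind == "local":
        if center is None:
            raise InvalidInputError("local interventions need a center state")
        return local_distribution(model.space, center, delta)
    raise InvalidInputError(f"unknown intervention kind {kind!r}")


def custom_distribution(
    space: StateSpace, weights: Sequence[float] | Mapping[str, float]
) -> InterventionDistribution:
    """A user-supplied intervention distribution (vector or label->weight map)."""
    if isinstance(weights, Mapping):
        w = np.zeros(space.n)
        for label, value in weights.items():
            w[space.index(label)] = value
    else:
        w = np.asarray(list(weights), dtype=float)
    return InterventionDistribution(space, w, kind="custom")


def _check_same_space(model: TransitionModel, pc: InterventionDistribution):
    if pc.space.labels != model.space.labels:
        raise InvalidInputError(
            "intervention distribution and model use different state spaces"
        )


def marginal_effect_distribution(
    model: TransitionModel, pc: InterventionDistribution
) -> np.ndarray:
    """P(e|C) = sum_c P_C(c) P(e|c) for every effect e."""
    _check_same_space(model, pc)
    return pc.weights @ model.matrix


def counterfactual_effect_distribution(
    model: TransitionModel, pc: InterventionDistribution, excluded: str
) -> np.ndarray:
    """P(e|C\\c): the effect distribution when cause ``excluded`` is ruled out.

    The remaining causes are renormalized by 1 − P_C(excluded). When the
    excluded cause carries no intervention mass the renormalization is the
    identity and the result equals P(e|C). When it carries all the mass
    there is no counterfactual to evaluate and a
    DegenerateCounterfactualError is raised.
    """
    _check_same_space(model, pc)
    i = model.space.index(excluded)
    keep = 1.0 - float(pc.weights[i])
    if keep <= PROB_TOL:
        raise DegenerateCounterfactualError(
            f"P_C({excluded!r}) = 1: no counterfactual mass remains"
        )
    w = pc.weights.copy()
    w[i] = 0.0
    return (w / keep) @ model.matrix
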