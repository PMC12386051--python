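"""The four causal primitives: sufficiency, necessity, determinism, degeneracy.

Sufficiency ``suff(e,c) = P(e|c)`` asks how reliably the cause produces
the effect; necessity ``nec(e,c) = 1 − P(e|C\\c)`` asks whether anything
other than the cause could have produced it. Their information-theoretic
extensions trade the single-transition probabilities for entropies:

* determinism ``det(c) = 1 − H(E|c)/log2 n`` — certainty of the cause's
  whole effect distribution (1 deterministic, 0 uniform noise);
* degeneracy ``deg = 1 − H(E|C)/log2 n`` — how strongly effects converge
  onto favored targets across all causes (the inverse of necessity).

All entropies are in bits and 0·log2(1/0) is taken as 0. Transition-level
coefficients at a zero probability are −inf (returned, not raised) so that
expectations, which weight them by zero, stay finite; the system-level
averages skip those zero-weight terms.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import entropy as _entropy

from .core import (
    InterventionDistribution,
    Transition,
    TransitionModel,
    counterfactual_effect_distribution,
    marginal_effect_distribution,
)

__all__ = [
    "sufficiency",
    "necessity",
    "nec_dagger",
    "determinism_state",
    "determinism_transition",
    "determinism_system",
    "degeneracy_effect",
    "degeneracy_system",
]


def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0 log 0 = 0 convention."""
    return float(_entropy(p, base=2))


def sufficiency(model: TransitionModel, t: Transition) -> float:
    """suff(e,c) = P(e|c)."""
    model.check_transition(t)
    return model.prob(t.cause, t.effect)


def necessity(
    model: TransitionModel, pc: InterventionDistribution, t: Transition
) -> float:
    """nec(e,c) = 1 − P(e|C\\c): 1 when only c can bring about e."""
    model.check_transition(t)
    cf = counterfactual_effect_distribution(model, pc, t.cause)
    return 1.0 - float(cf[model.space.index(t.effect)])

def nec_dagger(
    model: TransitionModel, pc: InterventionDistribution, e: str
) -> float:
    """nec†(e) = P(e|C), the softened (all-causes) form of necessity."""
    marg = marginal_effect_distribution(model, pc)
    return float(marg[model.space.index(e)])


def determinism_state(model: TransitionModel, c: str) -> float:
    """det(c) = 1 − H(E|c)/log2 n."""
    return 1.0 - _entropy_bits(model.row(c)) / math.log2(model.n)


def determinism_transition(model: TransitionModel, t: Transition) -> float:
    """det(e,c) = 1 − log2(1/P(e|c))/log2 n; −inf when P(e|c) = 0."""
    p = sufficiency(model, t)
    if p == 0.0:
        return -math.inf
    return 1.0 - math.log2(1.0 / p) / math.log2(model.n)


def determinism_system(
    model: TransitionModel, pc: InterventionDistribution
) -> float:
    """System determinism: the P_C-weighted mean of per-cause determinism."""
    logn = math.log2(model.n)
    h = np.array([_entropy_bits(row) for row in model.matrix])
    return float(1.0 - (pc.weights @ h) / logn)


def degeneracy_effect(
    model: TransitionModel, pc: InterventionDistribution, e: str
) -> float:
    """deg(e) = 1 − log2(1/P(e|C))/log2 n; −inf when P(e|C) = 0."""
    m = nec_dagger(model, pc, e)
    if m == 0.0:
        return -math.inf
    return 1.0 - math.log2(1.0 / m) / math.log2(model.n)


def degeneracy_system(
    model: TransitionModel, pc: InterventionDistribution
) -> float:
    """System degeneracy: 1 − H(E|C)/log2 n on the marginal effect distribution."""
    marg = marginal_effect_distribution(model, pc)
    return 1.0 - _entropy_bits(marg) / math.log2(model.n)
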