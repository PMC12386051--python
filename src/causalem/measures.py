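"""The catalogue of causal-strength measures.

Each measure scores a single (cause, effect) transition of a transition
model, given an intervention distribution P_C over causes. Writing
``s = suff(e,c) = P(e|c)``, ``v = nec(e,c) = 1 − P(e|C\\c)`` and
``m = nec†(e) = P(e|C)``, the catalogue is:

================  =============================================  ==========
name              formula                                        origin
================  =============================================  ==========
galton            P_C(c)(1−P_C(c))·(s + v − 1)                   covariance / regularity
eells             s + v − 1                                      probability raising
suppes            s − m                                          probability raising
cheng             (s + v − 1)/v                                  causal power
good              log2( v / (1 − s) )                            weight of evidence
lewis             (s + v − 1)/s                                  counterfactual (relative risk)
pearl_pns/pn/ps   aliases of eells / lewis / cheng               structural-model identities
lewis_cpw         (s − P(e|c̄_CPW))/s, c̄_CPW nearest by Hamming   closest possible world
bit_flip          mean Hamming displacement under one-bit flips  perturbation sensitivity
effect_info       log2(s/m) = log2 n·(det(e,c) − deg(e))         actual causation
================  =============================================  ==========

Two system-level (expectation-only) measures complete the set: the
effective information ``EI = E[effect_info] = log2 n·(det − deg)`` and its
normalization, the effectiveness ``eff = EI/log2 n``.

Negative values are reported as-is (preventive causes); ±inf is returned
flagged rather than raised, and genuinely indeterminate forms (0/0,
log(0/0)) yield ``defined=False`` with a NaN value. Expectations weight
transitions by a joint P(c,e) = P_w(c)·P(e|c), skip zero-weight terms,
exclude undefined terms with a logged warning, and propagate infinities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import primitives
from .core import (
    InterventionDistribution,
    Transition,
    TransitionModel,
    hamming_distance,
    make_intervention,
    marginal_effect_distribution,
    observational_distribution,
)
from .errors import InapplicableMeasureError, InvalidInputError

logger = logging.getLogger("causalem")

EXPECTATION = "expectation"


@dataclass(frozen=True)
class MeasureResult:
    """A named measure's value for one transition or for the expectation."""

    measure_name: str
    transition: Transition | str
    value: float
    defined: bool = True
    intervention_kind: str = "none"
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.defined and not math.isnan(self.value):
            object.__setattr__(self, "value", math.nan)

    @property
    def is_finite(self) -> bool:
        return self.defined and math.isfinite(self.value)


@dataclass(frozen=True)
class ExpectationPolicy:
    """How the joint weighting P(c,e) = P_w(c)·P(e|c) is built.

    ``weight_source`` picks P_w: the chain's stationary distribution
    (default, as used for system-level averages), the intervention
    distribution itself (the effective-information convention), or a
    custom vector.
    """

    weight_source: str = "stationary"
    custom_weights: np.ndarray | None = None


def _kind(pc: InterventionDistribution | None) -> str:
    return pc.kind if pc is not None else "none"


def _need_pc(pc: InterventionDistribution | None) -> InterventionDistribution:
    if pc is None:
        raise InvalidInputError("this measure requires an intervention distribution")
    return pc


def _svm(model, pc, t):
    s = primitives.sufficiency(model, t)
    v = primitives.necessity(model, pc, t)
    m = primitives.nec_dagger(model, pc, t.effect)
    return s, v, m


def _result(name, t, value, defined=True, pc=None, aliases=()):
    return MeasureResult(name, t, value, defined, _kind(pc), tuple(aliases))


def galton(model, pc, t) -> MeasureResult:
    """Observed covariance between cause and effect indicators."""
    pc = _need_pc(pc)
    s, v, _ = _svm(model, pc, t)
    p = pc.prob(t.cause)
    return _result("galton", t, p * (1.0 - p) * (s + v - 1.0), pc=pc)


def eells(model, pc, t) -> MeasureResult:
    """Probability raising as a difference: P(e|c) − P(e|C\\c)."""
    pc = _need_pc(pc)
    s, v, _ = _svm(model, pc, t)
    return _result("eells", t, s + v - 1.0, pc=pc, aliases=("pearl_pns",))


def suppes(model, pc, t) -> MeasureResult:
    """Probability raising against the marginal: P(e|c) − P(e|C)."""
    pc = _need_pc(pc)
    s = primitives.sufficiency(model, t)
    m = primitives.nec_dagger(model, pc, t.effect)
    return _result("suppes", t, s - m, pc=pc)


def cheng(model, pc, t) -> MeasureResult:
    """Causal power: (s + v − 1)/v; undefined when v = 0."""
    pc = _need_pc(pc)
    s, v, _ = _svm(model, pc, t)
    if v == 0.0:
        return _result("cheng", t, math.nan, defined=False, pc=pc,
                       aliases=("pearl_ps",))
    return _result("cheng", t, (s + v - 1.0) / v, pc=pc, aliases=("pearl_ps",))


def good(model, pc, t) -> MeasureResult:
    """Weight of evidence: log2(v/(1−s)), in bits."""
    pc = _need_pc(pc)
    s, v, _ = _svm(model, pc, t)
    if s == 1.0 and v == 0.0:
        return _result("good", t, math.nan, defined=False, pc=pc)
    if s == 1.0:
        return _result("good", t, math.inf, pc=pc)
    if v == 0.0:
        return _result("good", t, -math.inf, pc=pc)
    return _result("good", t, math.log2(v / (1.0 - s)), pc=pc)


def lewis(model, pc, t) -> MeasureResult:
    """Normalized relative risk: (s + v − 1)/s.

    At s = 0 the value is −inf when the counterfactual probability is
    positive (the cause prevents an otherwise possible effect) and
    undefined (0/0) when it is zero as well.
    """
    pc = _need_pc(pc)
    s, v, _ = _svm(model, pc, t)
    num = s + v - 1.0  # = s − P(e|C\c)
    if s == 0.0:
        if num == 0.0:
            return _result("lewis", t, math.nan, defined=False, pc=pc,
                           aliases=("pearl_pn",))
        return _result("lewis", t, -math.inf, pc=pc, aliases=("pearl_pn",))
    return _result("lewis", t, num / s, pc=pc, aliases=("pearl_pn",))


def pearl_pns(model, pc, t) -> MeasureResult:
    """Pearl's probability of necessity and sufficiency (= eells)."""
    r = eells(model, pc, t)
    return _result("pearl_pns", t, r.value, r.defined, pc=pc, aliases=("eells",))


def pearl_pn(model, pc, t) -> MeasureResult:
    """Pearl's probability of necessity (= lewis)."""
    r = lewis(model, pc, t)
    return _result("pearl_pn", t, r.value, r.defined, pc=pc, aliases=("lewis",))


def pearl_ps(model, pc, t) -> MeasureResult:
    """Pearl's probability of sufficiency (= cheng)."""
    r = cheng(model, pc, t)
    return _result("pearl_ps", t, r.value, r.defined, pc=pc, aliases=("cheng",))


def _nearest_neighbors(space, c: str) -> list[str]:
    if space.bit_width is None:
        raise InapplicableMeasureError(
            "closest-possible-world counterfactuals need binary labels"
        )
    others = [x for x in space.labels if x != c]
    dmin = min(hamming_distance(c, x) for x in others)
    return [x for x in others if hamming_distance(c, x) == dmin]


def lewis_cpw(model, pc, t) -> MeasureResult:
    """Closest-possible-world counterfactual: (s − P(e|c̄_CPW))/s.

    The counterfactual world is the state nearest to the cause in Hamming
    distance; equidistant minimizers are averaged.
    """
    model.check_transition(t)
    s = primitives.sufficiency(model, t)
    values = []
    for nb in _nearest_neighbors(model.space, t.cause):
        q = model.prob(nb, t.effect)
        if s == 0.0:
            if q == 0.0:
                return _result("lewis_cpw", t, math.nan, defined=False, pc=pc)
            values.append(-math.inf)
        else:
            values.append((s - q) / s)
    if any(math.isinf(x) for x in values):
        return _result("lewis_cpw", t, -math.inf, pc=pc)
    return _result("lewis_cpw", t, float(np.mean(values)), pc=pc)


def bit_flip(model, pc, t) -> MeasureResult:
    """Average Hamming displacement of the effect under single-bit flips
    of the cause: (1/N)·sum_i sum_e' P(e'|c[i])·D_H(e, e').

    Purely perturbation-based: no intervention distribution enters, and
    the full hypercube of binary labels is required so every flipped
    state exists. Sensitive to the (arbitrary) state labeling.
    """
    model.check_transition(t)
    space = model.space
    if not space.is_hypercube:
        raise InapplicableMeasureError(
            "bit_flip needs a full hypercube of binary state labels"
        )
    c, e = t.cause, t.effect
    N = space.bit_width
    dists = np.array([hamming_distance(e, x) for x in space.labels], dtype=float)
    total = 0.0
    for i in range(N):
        flipped = c[:i] + ("1" if c[i] == "0" else "0") + c[i + 1:]
        total += float(model.row(flipped) @ dists)
    return _result("bit_flip", t, total / N, pc=pc)


def effect_information(model, pc, t) -> MeasureResult:
    """ei(c,e) = log2(P(e|c)/P(e|C)), in bits."""
    pc = _need_pc(pc)
    s = primitives.sufficiency(model, t)
    m = primitives.nec_dagger(model, pc, t.effect)
    if s == 0.0 and m == 0.0:
        return _result("effect_information", t, math.nan, defined=False, pc=pc)
    if s == 0.0:
        return _result("effect_information", t, -math.inf, pc=pc)
    if m == 0.0:
        return _result("effect_information", t, math.inf, pc=pc)
    return _result("effect_information", t, math.log2(s / m), pc=pc)


def effective_information(model, pc) -> MeasureResult:
    """EI = sum_{c,e} P_C(c)P(e|c)·ei(c,e) = log2 n·(det − deg), in bits."""
    pc = _need_pc(pc)
    marg = marginal_effect_distribution(model, pc)
    total = 0.0
    for ci in range(model.n):
        wc = float(pc.weights[ci])
        if wc == 0.0:
            continue
        row = model.matrix[ci]
        nz = row > 0.0
        total += wc * float(row[nz] @ np.log2(row[nz] / marg[nz]))
    return _result("effective_information", EXPECTATION, total, pc=pc)


def effectiveness(model, pc) -> MeasureResult:
    """eff = EI / log2 n = det − deg."""
    ei = effective_information(model, pc)
    return _result("effectiveness", EXPECTATION, ei.value / math.log2(model.n),
                   pc=pc)


@dataclass(frozen=True)
class MeasureInfo:
    """Registry entry: the callable plus applicability flags."""

    name: str
    func: Callable
    per_transition: bool = True
    uses_intervention: bool = True
    needs_bits: bool = False
    needs_hypercube: bool = False
    alias_of: str | None = None


MEASURES: dict[str, MeasureInfo] = {
    m.name: m
    for m in [
        MeasureInfo("galton", galton),
        MeasureInfo("eells", eells),
        MeasureInfo("suppes", suppes),
        MeasureInfo("cheng", cheng),
        MeasureInfo("good", good),
        MeasureInfo("lewis", lewis),
        MeasureInfo("pearl_pns", pearl_pns, alias_of="eells"),
        MeasureInfo("pearl_pn", pearl_pn, alias_of="lewis"),
        MeasureInfo("pearl_ps", pearl_ps, alias_of="cheng"),
        MeasureInfo("lewis_cpw", lewis_cpw, needs_bits=True),
        MeasureInfo("bit_flip", bit_flip, uses_intervention=False,
                     needs_bits=True, needs_hypercube=True),
        MeasureInfo("effect_information", effect_information),
        MeasureInfo("effective_information", effective_information,
                     per_transition=False),
        MeasureInfo("effectiveness", effectiveness, per_transition=False),
    ]
}

#: the eight primitive-based per-transition measures used in parameter sweeps
DEFAULT_SWEEP_MEASURES: tuple[str, ...] = (
    "galton", "eells", "suppes", "cheng", "good", "lewis", "lewis_cpw",
    "effect_information",
)

#: the distinct per-transition measures (aliases folded away)
CATALOGUE: tuple[str, ...] = (
    "galton", "eells", "suppes", "cheng", "good", "lewis", "lewis_cpw",
    "bit_flip", "effect_information",
)


def compute_measure(
    name: str,
    model: TransitionModel,
    pc: InterventionDistribution | None,
    t: Transition | None = None,
) -> MeasureResult:
    """Evaluate one catalogued measure on a transition (or in expectation
    for the expectation-only measures)."""
    try:
        info = MEASURES[name]
    except KeyError:
        raise InvalidInputError(f"unknown measure {name!r}") from None
    if info.per_transition:
        if t is None:
            raise InvalidInputError(f"measure {name!r} needs a transition")
        return info.func(model, pc, t)
    return info.func(model, pc)


def _resolve_weights(
    model: TransitionModel,
    pc: InterventionDistribution | None,
    policy: ExpectationPolicy,
) -> np.ndarray:
    if policy.weight_source == "stationary":
        return observational_distribution(model).weights
    if policy.weight_source == "same-as-intervention":
        if pc is None:
            raise InvalidInputError(
                "same-as-intervention weighting needs a concrete distribution"
            )
        return pc.weights
    if policy.weight_source == "custom":
        if policy.custom_weights is None:
            raise InvalidInputError("custom weighting needs custom_weights")
        w = np.asarray(policy.custom_weights, dtype=float)
        if w.shape != (model.n,) or abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise InvalidInputError("custom_weights must be a probability vector")
        return w
    raise InvalidInputError(f"unknown weight source {policy.weight_source!r}")


def expectation(
    measure: str,
    model: TransitionModel,
    intervention: InterventionDistribution | str | None = "maxent",
    policy: ExpectationPolicy | None = None,
    delta: int = 1,
) -> MeasureResult:
    """The joint expectation sum_{c,e} P(c,e)·CS(e,c) of a per-transition measure.

    ``intervention`` may be a concrete distribution (used for every term)
    or a kind tag; the ``local`` kind is re-centered on each cause, the
    way local counterfactuals are probed around the state that actually
    occurred. Terms with zero joint weight are skipped; undefined terms
    are excluded with a warning; included infinities propagate (and an
    inf/−inf clash renders the expectation undefined).
    """
    info = MEASURES.get(measure)
    if info is None:
        raise InvalidInputError(f"unknown measure {measure!r}")
    if not info.per_transition:
        pc = _as_distribution(model, intervention, center=None, delta=delta)
        return info.func(model, pc)
    policy = policy or ExpectationPolicy()
    if isinstance(intervention, InterventionDistribution):
        fixed_pc = intervention
    elif intervention is not None and intervention != "local":
        # cause-independent kinds resolve once; local is re-centered per cause
        fixed_pc = make_intervention(model, intervention)
    else:
        fixed_pc = None
    weights = _resolve_weights(model, fixed_pc, policy)

    total = 0.0
    pos_inf = neg_inf = skipped_undefined = 0
    kind = fixed_pc.kind if fixed_pc is not None else (intervention or "none")
    for ci, c in enumerate(model.space.labels):
        wc = float(weights[ci])
        if wc == 0.0:
            continue
        pc_c = fixed_pc if fixed_pc is not None else _as_distribution(
            model, intervention, center=c, delta=delta
        )
        for ei_, e in enumerate(model.space.labels):
            p_ce = wc * float(model.matrix[ci, ei_])
            if p_ce == 0.0:
                continue
            r = info.func(model, pc_c, Transition(c, e))
            if not r.defined:
                skipped_undefined += 1
                continue
            if math.isinf(r.value):
                if r.value > 0:
                    pos_inf += 1
                else:
                    neg_inf += 1
                continue
            total += p_ce * r.value
    if skipped_undefined:
        logger.warning(
            "expectation of %s: excluded %d undefined transition(s)",
            measure, skipped_undefined,
        )
    if pos_inf and neg_inf:
        return MeasureResult(measure, EXPECTATION, math.nan, False, kind)
    if pos_inf:
        return MeasureResult(measure, EXPECTATION, math.inf, True, kind)
    if neg_inf:
        return MeasureResult(measure, EXPECTATION, -math.inf, True, kind)
    return MeasureResult(measure, EXPECTATION, total, True, kind)


def _as_distribution(model, intervention, center, delta):
    if intervention is None:
        return None
    if isinstance(intervention, InterventionDistribution):
        return intervention
    return make_intervention(model, intervention, center=center, delta=delta)


def measures_table(
    model: TransitionModel,
    names: Sequence[str],
    intervention: InterventionDistribution | str = "maxent",
    transitions: Sequence[Transition] | None = None,
    delta: int = 1,
    include_expectation: bool = True,
    policy: ExpectationPolicy | None = None,
) -> list[MeasureResult]:
    """Evaluate a list of measures over transitions (default: all pairs)
    plus, optionally, their expectations."""
    if transitions is None:
        transitions = [
            Transition(c, e)
            for c in model.space.labels
            for e in model.space.labels
        ]
    if isinstance(intervention, str) and intervention != "local":
        intervention = make_intervention(model, intervention)
    out: list[MeasureResult] = []
    for name in names:
        info = MEASURES[name]
        if not info.per_transition:
            pc = _as_distribution(model, intervention, center=None, delta=delta)
            out.append(info.func(model, pc))
            continue
        for t in transitions:
            pc = _as_distribution(model, intervention, center=t.cause, delta=delta)
            out.append(info.func(model, pc, t))
        if include_expectation:
            out.append(expectation(name, model, intervention, policy, delta))
    return out
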