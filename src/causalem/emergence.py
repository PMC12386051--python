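"""Coarse-graining and the causal-emergence statistic.

A macroscale is a total map h from micro states onto fewer macro states.
The macro TPM aggregates the micro rows of each macrostate (convex
combination under per-group aggregation weights) and sums the columns of
each target group. Causal emergence for a chosen measure is then simply

    CE = CS_macro − CS_micro

evaluated either on one micro transition against its macro image, or on
the joint expectation at each scale. CE > 0 is emergence (the macroscale
carries the stronger causal relationship), CE < 0 is reduction. A micro
transition with value −inf (e.g. a preventive cause under a log measure)
against a finite macro value yields CE = +inf — "infinite" emergence.

Macro state labels (ON, OFF, ...) carry no bit structure, so
Hamming-based constructions at the macroscale (local interventions,
closest possible worlds, bit flips) use fresh minimal-width binary codes
assigned in macrostate order; with two macrostates this makes the local
intervention coincide with maximum entropy, as any radius covers the
whole space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import measures as measures_mod
from .core import (
    InterventionDistribution,
    StateSpace,
    Transition,
    TransitionModel,
    local_distribution,
    make_intervention,
    observational_distribution,
)
from .errors import InapplicableMeasureError, InvalidInputError
from .measures import (
    DEFAULT_SWEEP_MEASURES,
    MEASURES,
    MeasureResult,
    expectation,
)
from .models import BipartiteSpec, bipartite_macro_mapping, bipartite_model, label_main_and_secondary

__all__ = [
    "CoarseGraining",
    "EmergenceReport",
    "coarse_grain",
    "binary_relabel",
    "macro_intervention",
    "causal_emergence",
    "sweep",
    "normalized_average_ce",
    "supervenience_check",
]


@dataclass(frozen=True)
class CoarseGraining:
    """A total, single-valued micro -> macro mapping (supervenience)."""

    micro_space: StateSpace
    macro_space: StateSpace
    mapping: Mapping[str, str]

    def __post_init__(self):
        missing = [s for s in self.micro_space.labels if s not in self.mapping]
        if missing:
            raise InvalidInputError(
                f"mapping is not total: micro state {missing[0]!r} unmapped"
            )
        bad = [
            s for s in self.micro_space.labels
            if self.mapping[s] not in self.macro_space
        ]
        if bad:
            raise InvalidInputError(
                f"micro state {bad[0]!r} maps to unknown macrostate "
                f"{self.mapping[bad[0]]!r}"
            )
        for y in self.macro_space.labels:
            if not any(self.mapping[s] == y for s in self.micro_space.labels):
                raise InvalidInputError(f"macrostate {y!r} has no micro members")

    @classmethod
    def from_mapping(
        cls, micro_space: StateSpace, mapping: Mapping[str, str]
    ) -> "CoarseGraining":
        """Macrostates ordered by first appearance in micro-label order."""
        missing = [s for s in micro_space.labels if s not in mapping]
        if missing:
            raise InvalidInputError(
                f"mapping is not total: micro state {missing[0]!r} unmapped"
            )
        macro_labels: list[str] = []
        for s in micro_space.labels:
            y = mapping[s]
            if y not in macro_labels:
                macro_labels.append(y)
        return cls(micro_space, StateSpace.from_labels(macro_labels), dict(mapping))

    def members(self, macro_label: str) -> list[str]:
        return [s for s in self.micro_space.labels if self.mapping[s] == macro_label]

    def image(self, t: Transition) -> Transition:
        return Transition(self.mapping[t.cause], self.mapping[t.effect])


def coarse_grain(
    model: TransitionModel,
    cg: CoarseGraining,
    weights: InterventionDistribution | None = None,
) -> TransitionModel:
    """Aggregate a micro TPM into the macro TPM.

    P_macro(y|x) = sum_{c in h^-1(x)} w_x(c) sum_{e in h^-1(y)} P(e|c),
    with per-macrostate aggregation weights w_x given by restricting and
    renormalizing ``weights`` within each group (uniform within the group
    by default, or when a group carries no weight mass).
    """
    if cg.micro_space.labels != model.space.labels:
        raise InvalidInputError("coarse-graining does not match the model's space")
    micro, macro = cg.micro_space, cg.macro_space
    w = weights.weights if weights is not None else np.full(micro.n, 1.0 / micro.n)
    col_of = np.array([macro.index(cg.mapping[s]) for s in micro.labels])
    out = np.zeros((macro.n, macro.n))
    for xi, x in enumerate(macro.labels):
        rows = [micro.index(c) for c in cg.members(x)]
        wx = w[rows]
        wx = wx / wx.sum() if wx.sum() > 0 else np.full(len(rows), 1.0 / len(rows))
        blended = wx @ model.matrix[rows]
        for yi in range(macro.n):
            out[xi, yi] = blended[col_of == yi].sum()
    return TransitionModel(macro, out)


def binary_codes(n: int) -> list[str]:
    """Minimal-width binary codes for n states, in order."""
    width = max(1, math.ceil(math.log2(n)))
    return [format(i, f"0{width}b") for i in range(n)]


def binary_relabel(model: TransitionModel) -> tuple[TransitionModel, dict[str, str]]:
    """A copy of the model whose states carry fresh minimal-width binary
    labels (in state order), for Hamming-based constructions on spaces
    without bit structure. Returns the relabeled model and the
    original-label -> code map."""
    codes = binary_codes(model.n)
    code_of = dict(zip(model.space.labels, codes))
    space = StateSpace(tuple(codes), bit_width=len(codes[0]))
    return TransitionModel(space, model.matrix.copy()), code_of


def macro_intervention(
    kind: str,
    macro_model: TransitionModel,
    delta: int = 1,
    center: str | None = None,
) -> InterventionDistribution:
    """An intervention distribution at the macroscale.

    maxent and observational are computed directly on the macro TPM. The
    local kind uses the macrostates' minimal-width binary codes; with two
    macrostates and delta >= 1 the Hamming ball is the whole space, so it
    degenerates to maximum entropy (as it should: the only counterfactual
    of one of two states is the other).
    """
    if kind in ("maxent", "observational"):
        return make_intervention(macro_model, kind)
    if kind == "local":
        if center is None:
            raise InvalidInputError("local interventions need a center state")
        coded, code_of = binary_relabel(macro_model)
        dist = local_distribution(coded.space, code_of[center], delta)
        return InterventionDistribution(
            macro_model.space, dist.weights, kind="local",
            params={"center": center, "delta": int(delta), "codes": "minimal-width"},
        )
    raise InvalidInputError(f"unknown intervention kind {kind!r}")


@dataclass(frozen=True)
class EmergenceReport:
    """Paired micro/macro values of one measure and their difference."""

    measure: str
    scope: str  # "transition" or "expectation"
    cs_micro: float
    cs_macro: float
    ce: float
    micro_defined: bool = True
    macro_defined: bool = True
    ce_defined: bool = True
    micro_transition: Transition | None = None
    macro_transition: Transition | None = None
    intervention: str = "maxent"
    params: dict = field(default_factory=dict)

    @property
    def sign(self) -> str:
        if not self.ce_defined or math.isnan(self.ce):
            return "undefined"
        if self.ce > 0:
            return "emergence"
        if self.ce < 0:
            return "reduction"
        return "neutral"


def _ce_difference(macro: MeasureResult, micro: MeasureResult) -> tuple[float, bool]:
    """macro − micro with infinity propagation; inf − inf is undefined."""
    if not (macro.defined and micro.defined):
        return math.nan, False
    a, b = macro.value, micro.value
    if math.isinf(a) and math.isinf(b) and (a > 0) == (b > 0):
        return math.nan, False
    return a - b, True


def _measure_at_scale(
    name: str,
    model: TransitionModel,
    t: Transition | None,
    kind: str,
    delta: int,
    scope: str,
) -> MeasureResult:
    """Evaluate a measure at one scale, relabeling to binary codes when a
    Hamming-based measure meets a space without bit labels."""
    info = MEASURES[name]
    needs_bits = info.needs_bits or info.needs_hypercube or kind == "local"
    working, code_of = model, None
    if needs_bits and model.space.bit_width is None:
        working, code_of = binary_relabel(model)
    if info.needs_hypercube and not working.space.is_hypercube:
        raise InapplicableMeasureError(
            f"{name} needs a full hypercube at this scale (n={model.n})"
        )
    if t is not None and code_of is not None:
        t = Transition(code_of[t.cause], code_of[t.effect])
    if scope == "expectation" or not info.per_transition:
        if not info.per_transition:
            if kind == "local":
                # no single local P_C exists (it is re-centered per cause):
                # lift EI as the stationary-weighted expectation of the
                # per-transition effect information with local centers
                r = expectation("effect_information", working, "local", delta=delta)
                value = r.value
                if name == "effectiveness" and r.defined and math.isfinite(value):
                    value = value / math.log2(working.n)
                return MeasureResult(name, measures_mod.EXPECTATION, value,
                                     r.defined, "local")
            return info.func(working, make_intervention(working, kind))
        return expectation(name, working, kind, delta=delta)
    pc = None
    if info.uses_intervention:
        if kind == "local":
            pc = local_distribution(working.space, t.cause, delta)
        else:
            pc = make_intervention(working, kind)
    return info.func(working, pc, t)


def causal_emergence(
    measure: str,
    micro: TransitionModel,
    cg: CoarseGraining,
    transition: Transition | None = None,
    intervention: str = "maxent",
    delta: int = 1,
    scope: str = "transition",
    aggregation: InterventionDistribution | None = None,
    params: dict | None = None,
) -> EmergenceReport:
    """CE = CS_macro − CS_micro for one measure.

    For transition scope the compared macro transition is the image of the
    micro transition under the coarse-graining. Micro and macro
    intervention distributions are paired by kind (maxent at both scales,
    etc.). Aggregation weights for the macro TPM default to uniform
    within each macrostate (for the bipartite family every choice agrees;
    see ``supervenience_check``), or to the observational distribution
    when the observational kind is probed.
    """
    if scope not in ("transition", "expectation"):
        raise InvalidInputError(f"unknown scope {scope!r}")
    if scope == "transition":
        if transition is None:
            raise InvalidInputError("transition scope needs a transition")
        micro.check_transition(transition)
    if aggregation is None and intervention == "observational":
        aggregation = observational_distribution(micro)
    macro_model = coarse_grain(micro, cg, weights=aggregation)
    t_micro = transition if scope == "transition" else None
    t_macro = cg.image(transition) if scope == "transition" else None
    r_micro = _measure_at_scale(measure, micro, t_micro, intervention, delta, scope)
    r_macro = _measure_at_scale(measure, macro_model, t_macro, intervention, delta, scope)
    ce, ce_defined = _ce_difference(r_macro, r_micro)
    return EmergenceReport(
        measure=measure,
        scope=scope,
        cs_micro=r_micro.value,
        cs_macro=r_macro.value,
        ce=ce,
        micro_defined=r_micro.defined,
        macro_defined=r_macro.defined,
        ce_defined=ce_defined,
        micro_transition=t_micro,
        macro_transition=t_macro,
        intervention=intervention,
        params=dict(params or {}),
    )


def sweep(
    template: BipartiteSpec = BipartiteSpec(),
    d_values: Sequence[float] = tuple(np.linspace(0, 1, 11)),
    g_values: Sequence[float] = tuple(np.linspace(0, 1, 11)),
    measures: Sequence[str] = DEFAULT_SWEEP_MEASURES,
    scopes: Sequence[str] = ("main", "secondary", "expectation"),
    intervention: str = "local",
    delta: int = 1,
) -> pd.DataFrame:
    """Causal emergence across the determinism x degeneracy grid.

    One row per measure x grid point x scope; scopes ``main`` and
    ``secondary`` score the reference cause's highest-probability
    transition and its first secondary transition, ``expectation`` the
    joint average. Deterministic given its inputs; infinities survive as
    ±inf and undefined cells carry NaN with ``ce_defined=False`` (no
    silent NaN leaks).
    """
    rows = []
    for d in d_values:
        for g in g_values:
            spec = BipartiteSpec(template.n_a, template.n_b, float(d), float(g))
            model = bipartite_model(spec)
            cg = CoarseGraining.from_mapping(
                spec.space(), bipartite_macro_mapping(spec)
            )
            c0 = spec.space().labels[0]
            main_t, secondary_t = label_main_and_secondary(spec, c0, strict=False)
            for scope in scopes:
                if scope == "main":
                    t, eff_scope = main_t, "transition"
                elif scope == "secondary":
                    t, eff_scope = secondary_t, "transition"
                elif scope == "expectation":
                    t, eff_scope = None, "expectation"
                else:
                    raise InvalidInputError(f"unknown sweep scope {scope!r}")
                for name in measures:
                    try:
                        rep = causal_emergence(
                            name, model, cg, transition=t,
                            intervention=intervention, delta=delta,
                            scope=eff_scope, params={"d": float(d), "g": float(g)},
                        )
                    except InapplicableMeasureError as exc:
                        rows.append({
                            "measure": name, "d": float(d), "g": float(g),
                            "scope": scope, "cause": getattr(t, "cause", ""),
                            "effect": getattr(t, "effect", ""),
                            "cs_micro": math.nan, "cs_macro": math.nan,
                            "ce": math.nan, "ce_defined": False,
                            "sign": "inapplicable", "intervention": intervention,
                            "note": str(exc),
                        })
                        continue
                    rows.append({
                        "measure": name, "d": float(d), "g": float(g),
                        "scope": scope,
                        "cause": getattr(rep.micro_transition, "cause", ""),
                        "effect": getattr(rep.micro_transition, "effect", ""),
                        "cs_micro": rep.cs_micro, "cs_macro": rep.cs_macro,
                        "ce": rep.ce, "ce_defined": rep.ce_defined,
                        "sign": rep.sign, "intervention": intervention,
                        "note": "",
                    })
    return pd.DataFrame(rows)


def normalized_average_ce(sweep_df: pd.DataFrame) -> pd.DataFrame:
    """Cross-measure average of CE after per-measure normalization.

    Each measure's finite CE values are divided by the measure's maximum
    absolute finite CE over the whole sweep, then averaged across
    measures (and scopes) at each (d, g) grid point. Infinite or
    undefined cells are left out of both the normalizer and the average.
    """
    df = sweep_df[sweep_df["ce_defined"] & np.isfinite(sweep_df["ce"])].copy()
    parts = []
    for name, grp in df.groupby("measure"):
        denom = grp["ce"].abs().max()
        if denom == 0 or not np.isfinite(denom):
            continue
        g2 = grp.copy()
        g2["ce_norm"] = g2["ce"] / denom
        parts.append(g2)
    merged = pd.concat(parts, ignore_index=True)
    return merged.groupby(["d", "g"], as_index=False)["ce_norm"].mean()


def supervenience_check(
    micro: TransitionModel, cg: CoarseGraining, tol: float = 1e-9
) -> tuple[bool, float]:
    """Minimal dynamical-consistency check.

    Besides the structural supervenience guarantee (the mapping is total
    and single-valued by construction), measure how much the macro row
    induced by each micro member of a macrostate disagrees with the
    others: the residual is the largest within-group spread of aggregated
    macro rows. Zero residual means the macroscale is independent of the
    aggregation weights, as in the bipartite family.
    """
    micro_space, macro = cg.micro_space, cg.macro_space
    if micro_space.labels != micro.space.labels:
        raise InvalidInputError("coarse-graining does not match the model's space")
    col_of = np.array([macro.index(cg.mapping[s]) for s in micro_space.labels])
    residual = 0.0
    for x in macro.labels:
        rows = np.array([
            [micro.row(c)[col_of == yi].sum() for yi in range(macro.n)]
            for c in cg.members(x)
        ])
        spread = float(np.max(rows.max(axis=0) - rows.min(axis=0)))
        residual = max(residual, spread)
    return residual <= tol, residual
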