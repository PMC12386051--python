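"""The causal-strength measure catalogue: values, flags, identities."""

import math

import numpy as np
import pytest

from causalem import (
    BipartiteSpec,
    ExpectationPolicy,
    NandSpec,
    StateSpace,
    Transition,
    TransitionModel,
    bipartite_model,
    compute_measure,
    custom_distribution,
    degeneracy_effect,
    degeneracy_system,
    determinism_system,
    determinism_transition,
    effective_information,
    effectiveness,
    expectation,
    label_main_and_secondary,
    maxent_distribution,
    nand_model,
    observational_distribution,
)
from causalem.errors import InvalidInputError

from conftest import make_random_model


def measure(name, model, t, pc=None):
    pc = pc or maxent_distribution(model.space)
    return compute_measure(name, model, pc, t)


class TestLightSwitchValues:
    """The two-state switch/bulb model: UP ('1') forces ON, DOWN forces OFF."""

    @pytest.mark.parametrize(
        "name, expected",
        [
            ("eells", 1.0),
            ("galton", 0.25),
            ("cheng", 1.0),
            ("lewis", 1.0),
            ("lewis_cpw", 1.0),
            ("suppes", 0.5),
            ("effect_information", 1.0),
        ],
    )
    def test_up_causes_on(self, light_switch, name, expected):
        r = measure(name, light_switch, Transition("1", "1"))
        assert r.defined and r.value == pytest.approx(expected)

    def test_good_is_infinite_for_the_perfect_cause(self, light_switch):
        r = measure("good", light_switch, Transition("1", "1"))
        assert r.defined and r.value == math.inf


class TestIndependenceZeroes:
    def test_identical_rows_give_zero_strength(self, rng):
        space = StateSpace.from_labels(["a", "b", "c"])
        row = rng.dirichlet(np.ones(3))
        m = TransitionModel(space, np.tile(row, (3, 1)))
        t = Transition("a", "b")
        for name in ("galton", "eells", "suppes"):
            assert measure(name, m, t).value == pytest.approx(0.0, abs=1e-12)


class TestGalton:
    def test_equals_indicator_covariance(self, rng):
        # Cov(X_c, Y_e) under the joint P_C(c) P(e|c), by brute force
        m = make_random_model(5, rng)
        pc = custom_distribution(m.space, rng.dirichlet(np.ones(5)))
        c0, e0 = "s1", "s3"
        cov = 0.0
        pe = sum(pc.prob(c) * m.prob(c, e0) for c in m.space.labels)
        for c in m.space.labels:
            for e in m.space.labels:
                joint = pc.prob(c) * m.prob(c, e)
                cov += joint * (c == c0) * (e == e0)
        cov -= pc.prob(c0) * pe
        r = compute_measure("galton", m, pc, Transition(c0, e0))
        assert r.value == pytest.approx(cov, abs=1e-12)


class TestCheng:
    def test_sufficient_cause_has_full_power(self, rng):
        m = make_random_model(4, rng)
        matrix = m.matrix.copy()
        matrix[0] = [0, 1, 0, 0]
        m2 = TransitionModel(m.space, matrix)
        r = measure("cheng", m2, Transition("s0", "s1"))
        assert r.value == pytest.approx(1.0)

    def test_zero_necessity_is_undefined(self):
        space = StateSpace.from_labels(["a", "b"])
        m = TransitionModel(space, [[0, 1], [0, 1]])
        r = measure("cheng", m, Transition("a", "b"))
        assert not r.defined and math.isnan(r.value)


class TestGood:
    def test_balanced_evidence_is_zero(self):
        # v = 1 - s makes the odds ratio one
        space = StateSpace.from_labels(["a", "b"])
        m = TransitionModel(space, [[0.3, 0.7], [0.3, 0.7]])
        r = measure("good", m, Transition("a", "b"))
        assert r.value == pytest.approx(0.0, abs=1e-12)

    def test_one_bit_of_evidence(self):
        space = StateSpace.from_labels(["a", "b"])
        m = TransitionModel(space, [[0.5, 0.5], [1, 0]])
        # s = P(b|a) = 0.5, counterfactual P(b|C\a) = P(b|b... ) = 0 => v = 1
        r = measure("good", m, Transition("a", "b"))
        assert r.value == pytest.approx(1.0)

    def test_log_zero_over_zero_is_undefined(self):
        space = StateSpace.from_labels(["a", "b"])
        m = TransitionModel(space, [[0, 1], [0, 1]])
        r = measure("good", m, Transition("a", "b"))
        assert not r.defined


class TestLewis:
    def test_fully_necessary_cause_scores_one(self, rng):
        space = StateSpace.from_labels(["a", "b", "c"])
        matrix = np.array([[0.2, 0.8, 0.0], [1, 0, 0], [1, 0, 0]])
        m = TransitionModel(space, matrix)
        r = measure("lewis", m, Transition("a", "b"))
        assert r.value == pytest.approx(1.0)

    def test_equals_one_minus_risk_ratio(self, rng):
        m = make_random_model(5, rng)
        pc = maxent_distribution(m.space)
        t = Transition("s0", "s2")
        q = sum(
            (1 / 4) * m.prob(c, "s2") for c in m.space.labels if c != "s0"
        )
        r = compute_measure("lewis", m, pc, t)
        assert r.value == pytest.approx(1 - q / m.prob("s0", "s2"), abs=1e-12)

    def test_preventive_cause_with_zero_sufficiency(self):
        space = StateSpace.from_labels(["a", "b"])
        m = TransitionModel(space, [[1, 0], [0, 1]])
        r = measure("lewis", m, Transition("a", "b"))
        assert r.defined and r.value == -math.inf


@pytest.mark.parametrize(
    "alias, original",
    [("pearl_pns", "eells"), ("pearl_pn", "lewis"), ("pearl_ps", "cheng")],
)
def test_pearl_measures_alias_bitwise(rng, alias, original):
    m = make_random_model(6, rng)
    pc = maxent_distribution(m.space)
    for c in m.space.labels[:3]:
        for e in m.space.labels[:3]:
            t = Transition(c, e)
            a = compute_measure(alias, m, pc, t)
            b = compute_measure(original, m, pc, t)
            assert a.defined == b.defined
            if a.defined:
                assert a.value == b.value  # bitwise, not approx


class TestLewisClosestPossibleWorld:
    def test_zero_when_nearest_neighbor_matches(self):
        space = StateSpace.hypercube(2)
        row = [0.1, 0.2, 0.3, 0.4]
        m = TransitionModel(space, np.tile(row, (4, 1)))
        r = measure("lewis_cpw", m, Transition("00", "11"))
        assert r.value == pytest.approx(0.0, abs=1e-12)

    def test_tie_average_over_equidistant_neighbors(self):
        # 00's neighbors 01 and 10 are both one flip away; average their scores
        space = StateSpace.hypercube(2)
        matrix = np.array([
            [0.0, 0.0, 0.0, 1.0],   # 00 -> 11
            [0.0, 0.0, 0.0, 1.0],   # 01 -> 11 (score 0)
            [0.5, 0.0, 0.0, 0.5],   # 10 -> 11 half the time (score 0.5)
            [1.0, 0.0, 0.0, 0.0],
        ])
        m = TransitionModel(space, matrix)
        r = measure("lewis_cpw", m, Transition("00", "11"))
        assert r.value == pytest.approx(0.25)


class TestBitFlip:
    def test_constant_target_scores_zero(self):
        space = StateSpace.hypercube(2)
        matrix = np.zeros((4, 4))
        matrix[:, 3] = 1.0
        m = TransitionModel(space, matrix)
        r = measure("bit_flip", m, Transition("00", "11"))
        assert r.value == pytest.approx(0.0)

    def test_identity_map_displaces_by_one(self):
        space = StateSpace.hypercube(3)
        m = TransitionModel(space, np.eye(8))
        r = measure("bit_flip", m, Transition("010", "010"))
        assert r.value == pytest.approx(1.0)

    def test_matches_triple_loop(self, rng):
        space = StateSpace.hypercube(3)
        m = TransitionModel(space, rng.dirichlet(np.ones(8), size=8))
        c, e = "011", "101"
        total = 0.0
        for i in range(3):
            flipped = c[:i] + ("1" if c[i] == "0" else "0") + c[i + 1:]
            for ep in space.labels:
                dh = sum(a != b for a, b in zip(e, ep))
                total += m.prob(flipped, ep) * dh
        r = measure("bit_flip", m, Transition(c, e))
        assert r.value == pytest.approx(total / 3, abs=1e-12)


class TestEffectInformation:
    def test_one_bit(self):
        space = StateSpace.from_labels(["a", "b"])
        m = TransitionModel(space, [[0, 1], [1, 0]])
        r = measure("effect_information", m, Transition("a", "b"))
        assert r.value == pytest.approx(1.0)

    def test_equals_primitive_identity(self, rng):
        # ei(c,e) = log2(n) * [det(e,c) - deg(e)]
        m = make_random_model(6, rng)
        pc = maxent_distribution(m.space)
        for c, e in [("s0", "s1"), ("s2", "s5"), ("s4", "s4")]:
            t = Transition(c, e)
            lhs = compute_measure("effect_information", m, pc, t).value
            rhs = math.log2(6) * (
                determinism_transition(m, t) - degeneracy_effect(m, pc, e)
            )
            assert lhs == pytest.approx(rhs, abs=1e-9)


class TestEffectiveInformation:
    def test_permutation_sixteen_states(self):
        space = StateSpace.from_labels([f"s{i}" for i in range(16)])
        m = TransitionModel(space, np.roll(np.eye(16), 3, axis=1))
        r = effective_information(m, maxent_distribution(space))
        assert r.value == pytest.approx(4.0)
        assert effectiveness(m, maxent_distribution(space)).value == pytest.approx(1.0)

    def test_identical_rows_carry_no_information(self, rng):
        space = StateSpace.from_labels(["a", "b", "c"])
        m = TransitionModel(space, np.tile(rng.dirichlet(np.ones(3)), (3, 1)))
        assert effective_information(m, maxent_distribution(space)).value == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_two_state_flip_flop(self):
        space = StateSpace.from_labels(["ON", "OFF"])
        m = TransitionModel(space, [[0, 1], [1, 0]])
        assert effective_information(m, maxent_distribution(space)).value == (
            pytest.approx(1.0)
        )

    def test_equals_determinism_minus_degeneracy(self, rng):
        m = make_random_model(7, rng)
        pc = custom_distribution(m.space, rng.dirichlet(np.ones(7)))
        ei = effective_information(m, pc).value
        expected = math.log2(7) * (
            determinism_system(m, pc) - degeneracy_system(m, pc)
        )
        assert ei == pytest.approx(expected, abs=1e-9)

    def test_equals_expectation_of_effect_information(self, rng):
        m = make_random_model(5, rng)
        pc = maxent_distribution(m.space)
        direct = effective_information(m, pc).value
        via_expectation = expectation(
            "effect_information", m, pc,
            ExpectationPolicy("same-as-intervention"),
        ).value
        assert direct == pytest.approx(via_expectation, abs=1e-9)

    def test_bipartite_effectiveness_quarter(self):
        spec = BipartiteSpec(8, 8, 0.0, 0.0)
        m = bipartite_model(spec)
        assert effectiveness(m, maxent_distribution(spec.space())).value == (
            pytest.approx(0.25)
        )

    def test_observational_ei_is_mutual_information(self, rng):
        # EI under the stationary distribution reduces to the mutual
        # information of the joint pi(c) P(e|c); oracle via the entropy
        # decomposition I(C;E) = H(C) + H(E) - H(C,E)
        from scipy.stats import entropy

        m = make_random_model(6, rng)
        pi = observational_distribution(m)
        ei = effective_information(m, pi).value
        joint = pi.weights[:, None] * m.matrix
        mi_bits = (
            entropy(joint.sum(axis=1), base=2)
            + entropy(joint.sum(axis=0), base=2)
            - entropy(joint.ravel(), base=2)
        )
        assert ei == pytest.approx(mi_bits, abs=1e-9)


class TestExpectation:
    def test_matches_double_loop(self, rng):
        m = make_random_model(4, rng)
        pc = maxent_distribution(m.space)
        got = expectation("eells", m, pc, ExpectationPolicy("same-as-intervention"))
        total = 0.0
        for c in m.space.labels:
            for e in m.space.labels:
                p_ce = pc.prob(c) * m.prob(c, e)
                if p_ce > 0:
                    total += p_ce * compute_measure("eells", m, pc, Transition(c, e)).value
        assert got.value == pytest.approx(total, abs=1e-12)

    def test_lewis_averages_to_zero_on_full_support(self, rng):
        # the relative-risk numerator telescopes when no row has zeros
        m = make_random_model(6, rng, full_support=True)
        for kind in ("maxent", "observational"):
            r = expectation("lewis", m, kind)
            assert abs(r.value) < 1e-9

    def test_lewis_averages_to_zero_on_nand(self):
        m = nand_model(NandSpec(2, 0.1))
        r = expectation("lewis", m, "local", delta=1)
        assert abs(r.value) < 1e-9

    def test_unknown_measure_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            expectation("nope", make_random_model(3, rng), "maxent")


class TestMonotonicityInDeterminism:
    """Along the dilution axis at g = 0, every primitive-based measure of
    the main transition is non-decreasing (the bit-flip measure is exempt:
    it tracks state labels, not causal primitives)."""

    D_GRID = np.linspace(0.1, 1.0, 10)

    @pytest.mark.parametrize(
        "name",
        ["galton", "eells", "suppes", "cheng", "good", "lewis",
         "lewis_cpw", "effect_information"],
    )
    @pytest.mark.parametrize("kind", ["maxent", "local"])
    def test_main_transition_nondecreasing(self, name, kind):
        from causalem import local_distribution

        values = []
        for d in self.D_GRID:
            spec = BipartiteSpec(8, 8, float(d), 0.0)
            m = bipartite_model(spec)
            main, _ = label_main_and_secondary(spec, "0000")
            if kind == "local":
                pc = local_distribution(m.space, "0000", 1)
            else:
                pc = maxent_distribution(m.space)
            r = compute_measure(name, m, pc, main)
            assert r.defined
            values.append(r.value)
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))


def test_relabeling_invariance(rng):
    """Permuting state identities (rows, columns, intervention weights
    together) leaves every non-Hamming measure unchanged."""
    m = make_random_model(5, rng)
    w = rng.dirichlet(np.ones(5))
    perm = rng.permutation(5)
    space2 = StateSpace.from_labels([m.space.labels[i] for i in perm])
    m2 = TransitionModel(space2, m.matrix[np.ix_(perm, perm)])
    pc1 = custom_distribution(m.space, w)
    pc2 = custom_distribution(space2, w[perm])
    for name in ("galton", "eells", "suppes", "cheng", "good", "lewis",
                 "effect_information"):
        t = Transition("s1", "s4")
        r1 = compute_measure(name, m, pc1, t)
        r2 = compute_measure(name, m2, pc2, t)
        assert r1.defined == r2.defined
        if r1.defined and math.isfinite(r1.value):
            assert r1.value == pytest.approx(r2.value, abs=1e-12)
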