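"""Unit and property tests for the three-state network dynamics."""

import itertools

import numpy as np
import pytest

from embodied_gh import (
    EXCITED,
    QUIESCENT,
    REFRACTORY,
    Connectome,
    GHState,
    ModelConfig,
    default_roles,
    macro_balance,
    mean_activity,
    node_correlation_matrix,
    step_states,
    update_thresholds,
)

E, Q, R = EXCITED, QUIESCENT, REFRACTORY


def oracle_step(states, thresholds, weights, coupling, forced_e, forced_q):
    """Independent per-node reference for the deterministic update (p_spont = 0).

    Written as an explicit loop over nodes straight from the transition
    rules, deliberately sharing no code with the vectorized implementation.
    """
    w_max = max(max(row) for row in weights)
    n = len(states)
    new = []
    for i in range(n):
        if states[i] == E:
            nxt = R
        elif states[i] == R:
            nxt = Q
        else:
            drive = sum(
                coupling * (weights[i][j] / w_max)
                for j in range(n)
                if states[j] == E
            )
            nxt = E if drive > thresholds[i] else Q
        if i in forced_e:
            nxt = E
        elif i in forced_q:
            nxt = Q
        new.append(nxt)
    return new


def make_connectome(weights):
    return Connectome(weights=np.asarray(weights, dtype=float))


CHAIN3 = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]


class TestStepStates:
    def test_agrees_with_exhaustive_oracle_on_three_nodes(self):
        """All 27 state vectors x all disjoint forcing pairs, p_spont = 0."""
        c = make_connectome([[0, 2.0, 0.5], [2.0, 0, 1.0], [0.5, 1.0, 0]])
        config = ModelConfig(coupling=1.3, p_spont=0.0, epochs=1)
        thresholds = np.array([0.3, 0.9, 0.1])
        nodes = range(3)
        subsets = [
            frozenset(s)
            for k in range(4)
            for s in itertools.combinations(nodes, k)
        ]
        rng = np.random.default_rng(0)
        for states in itertools.product([Q, E, R], repeat=3):
            for fe in subsets:
                for fq in subsets:
                    if fe & fq:
                        continue
                    gh = GHState(states=np.array(states, dtype=np.int8),
                                 thresholds=thresholds)
                    got = step_states(gh, c, config, fe, fq, rng)
                    want = oracle_step(list(states), thresholds.tolist(),
                                       c.weights.tolist(), 1.3, fe, fq)
                    assert got.states.tolist() == want, (states, fe, fq)

    def test_agrees_with_oracle_on_random_four_node_networks(self, rng):
        for trial in range(5):
            w = rng.uniform(0, 3, (4, 4))
            w = np.triu(w, 1) + np.triu(w, 1).T
            c = make_connectome(w)
            thresholds = rng.uniform(0, 1.5, 4)
            config = ModelConfig(coupling=float(rng.uniform(0.2, 3)), p_spont=0.0)
            for states in itertools.product([Q, E, R], repeat=4):
                gh = GHState(states=np.array(states, np.int8), thresholds=thresholds)
                got = step_states(gh, c, config, None, None, rng)
                want = oracle_step(list(states), thresholds.tolist(),
                                   w.tolist(), config.coupling, frozenset(), frozenset())
                assert got.states.tolist() == want

    def test_threshold_gate_worked_example(self):
        """Chain network: the middle node fires only if its threshold is beaten."""
        c = make_connectome(CHAIN3)
        s = GHState(states=np.array([E, Q, Q], np.int8),
                    thresholds=np.array([0.5, 1.5, 0.5]))
        config = ModelConfig(coupling=1.0, p_spont=0.0)
        out = step_states(s, c, config, rng=np.random.default_rng(0))
        assert out.states.tolist() == [R, Q, Q]  # input 1 is not > 1.5

        s2 = GHState(states=np.array([E, Q, Q], np.int8),
                     thresholds=np.array([0.5, 0.5, 0.5]))
        out2 = step_states(s2, c, config, rng=np.random.default_rng(0))
        assert out2.states.tolist() == [R, E, Q]

    def test_excited_always_refractory_next(self, rng):
        """E -> R is deterministic regardless of input or spontaneous rate."""
        c = make_connectome(CHAIN3)
        config = ModelConfig(coupling=5.0, p_spont=1.0)
        s = GHState(states=np.array([E, E, E], np.int8), thresholds=np.zeros(3))
        out = step_states(s, c, config, rng=rng)
        assert (out.states == R).all()

    def test_silence_absorbing_without_spontaneous_firing(self, rng):
        c = make_connectome(CHAIN3)
        config = ModelConfig(p_spont=0.0)
        s = GHState(states=np.zeros(3, np.int8), thresholds=np.zeros(3))
        for _ in range(10):
            s = step_states(s, c, config, rng=rng)
            assert (s.states == Q).all()

    def test_forcing_overrides_and_persists(self, rng):
        """A node forced E on consecutive epochs stays E (E->R suppressed)."""
        c = make_connectome(CHAIN3)
        config = ModelConfig(p_spont=0.0)
        s = GHState(states=np.zeros(3, np.int8), thresholds=np.ones(3))
        for _ in range(3):
            s = step_states(s, c, config, forced_E={0}, rng=rng)
            assert s.states[0] == E

    def test_forced_sets_validated(self, rng):
        c = make_connectome(CHAIN3)
        s = GHState(states=np.zeros(3, np.int8), thresholds=np.zeros(3))
        with pytest.raises(ValueError):
            step_states(s, c, ModelConfig(), forced_E={7}, rng=rng)
        with pytest.raises(ValueError):
            step_states(s, c, ModelConfig(), forced_E={1}, forced_Q={1}, rng=rng)

    def test_state_partition_preserved(self, rng):
        """Every node is in exactly one state at every epoch."""
        c = make_connectome(CHAIN3)
        config = ModelConfig(p_spont=0.3, coupling=2.0)
        s = GHState(states=np.array([E, Q, R], np.int8), thresholds=np.full(3, 0.2))
        for _ in range(50):
            s = step_states(s, c, config, rng=rng)
            counts = np.bincount(s.states, minlength=3)
            assert counts.sum() == 3


class TestUpdateThresholds:
    @pytest.mark.parametrize(
        "active,expected_delta",
        [(True, 0.1 * (1 - 0.1)), (False, 0.1 * (0 - 0.1))],
    )
    def test_threshold_increment(self, active, expected_delta):
        states = np.array([E if active else Q], np.int8)
        s = GHState(states=states, thresholds=np.array([1.0]))
        config = ModelConfig(variant="local", alpha=0.1, rho=0.1)
        out = update_thresholds(s, config)
        assert out.thresholds[0] == pytest.approx(1.0 + expected_delta)

    def test_zero_learning_rate_is_identity(self):
        s = GHState(states=np.array([E, Q], np.int8), thresholds=np.array([0.5, 0.5]))
        out = update_thresholds(s, ModelConfig(variant="local", alpha=0.0))
        assert (out.thresholds == s.thresholds).all()

    def test_noop_outside_local_variants(self):
        s = GHState(states=np.array([E], np.int8), thresholds=np.array([0.5]))
        out = update_thresholds(s, ModelConfig(variant="static", alpha=0.5))
        assert out.thresholds[0] == 0.5

    def test_thresholds_may_go_negative(self):
        """No clamping: prolonged silence drives thresholds below zero."""
        s = GHState(states=np.zeros(1, np.int8), thresholds=np.array([0.005]))
        config = ModelConfig(variant="local", alpha=0.1, rho=0.2)
        for _ in range(3):
            s = update_thresholds(s, config)
        assert s.thresholds[0] < 0


class TestMacroBalance:
    def test_all_sensors_quiet_forces_all_tn_excited(self, roles66):
        fe, fq = macro_balance(frozenset(), roles66)
        assert set(fe) == set(roles66.task_negative)
        assert fq == ()

    def test_partial_sensor_load_is_complemented(self, roles66):
        tp = set(list(roles66.task_positive)[:2])
        fe, fq = macro_balance(tp, roles66)
        assert len(fe) == 2 and len(fq) == 2

    def test_full_sensor_load_clamps_at_budget(self, roles66):
        fe, fq = macro_balance(roles66.task_positive, roles66)
        assert fe == () and len(fq) == 4

    @pytest.mark.parametrize("k", range(7))
    def test_budget_conserved_for_any_load(self, roles66, k):
        """min(|TP forced|, 4) + |TN forced E| = 4 over the whole range."""
        tp = set(sorted(roles66.task_positive)[:k])
        fe, fq = macro_balance(tp, roles66)
        assert min(len(tp), 4) + len(fe) == 4
        assert set(fe) | set(fq) == set(roles66.task_negative)

    def test_rejects_non_sensory_nodes(self, roles66):
        with pytest.raises(ValueError):
            macro_balance({roles66.rotate_left}, roles66)


class TestActivitySummaries:
    def test_mean_activity_examples(self):
        assert mean_activity(np.zeros((5, 4))) == 0.0
        alternating = np.array([[1, 1], [0, 0], [1, 1], [0, 0]])
        assert mean_activity(alternating) == 0.5
        rec = np.array([[1, 0], [1, 0], [1, 0], [0, 0]])
        assert mean_activity(rec) == pytest.approx(0.375)
        with pytest.raises(ValueError):
            mean_activity(np.empty((0, 4)))

    def test_correlation_identical_and_complement_series(self):
        a = np.array([1, 0, 1, 1, 0])
        rec = np.column_stack([a, a, 1 - a])
        corr, _, flags = node_correlation_matrix(rec)
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)
        assert not flags.any()

    def test_independent_series_nearly_uncorrelated(self, rng):
        rec = (rng.random((10_000, 2)) < 0.5).astype(int)
        corr, mean_off, _ = node_correlation_matrix(rec)
        assert abs(corr[0, 1]) < 0.05
        assert mean_off == pytest.approx(corr[0, 1])

    def test_constant_series_flagged_as_zero(self):
        rec = np.column_stack([np.ones(10), np.arange(10) % 2])
        corr, _, flags = node_correlation_matrix(rec)
        assert flags[0] and not flags[1]
        assert corr[0, 1] == 0.0


class TestHomeostaticFixedPoint:
    def test_local_rule_attains_target_rate(self, connectome66):
        """Time-averaged activity converges to rho (rho above the
        spontaneous floor p/(1+2p))."""
        from embodied_gh.dynamics import coupling_matrix, _advance

        config = ModelConfig(variant="local", alpha=0.05, rho=0.15,
                             initial_threshold=0.2, epochs=3000, seed=5)
        m = coupling_matrix(connectome66, config)
        rng = np.random.default_rng(config.seed)
        states = np.zeros(66, np.int8)
        thresholds = np.full(66, config.initial_threshold)
        none = np.empty(0, int)
        acts = np.empty(config.epochs)
        for t in range(config.epochs):
            states = _advance(states, thresholds, m, config.p_spont, none, none, rng)
            b = (states == EXCITED).astype(float)
            thresholds = thresholds + config.alpha * (b - config.rho)
            acts[t] = b.mean()
        attained = acts[config.epochs // 2 :].mean()
        assert attained == pytest.approx(config.rho, abs=0.03)
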