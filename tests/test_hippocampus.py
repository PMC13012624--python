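"""Hippocampal engrams, EC match gate, recall convergence and Sleep replay."""

import numpy as np
import pytest

from fearcons import (
    FearModel,
    ModelConfig,
    Route,
    USSchedule,
    blur_cue,
    ec_match,
    encode_sc,
    f1_score,
    make_similar,
    pattern_distance,
    sample_context,
)


class TestEngramFormation:
    def test_sparsity_is_four_percent(self, model, rng):
        sc = encode_sc(sample_context(rng))
        engram = model.hip.perceive(sc)
        assert engram.sum() == round(0.04 * model.cfg.n_hip) == 20

    def test_same_context_same_engram(self, model, rng):
        sc = encode_sc(sample_context(rng))
        e1 = model.hip.perceive(sc).copy()
        e2 = model.hip.perceive(sc)
        assert np.array_equal(e1, e2)

    def test_dissimilar_contexts_get_separated_engrams(self, model, rng):
        # hypergeometric oracle: chance intersection ~ k^2/N = 0.8 cells
        inters = []
        for _ in range(30):
            a = sample_context(rng)
            b = make_similar(a, 0.1, rng)
            ea = model.hip.perceive(encode_sc(a)).copy()
            eb = model.hip.perceive(encode_sc(b))
            inters.append(int((ea & eb).sum()))
        assert np.mean(inters) < 4.0  # near chance, far from k=20


class TestRecall:
    def test_stored_pattern_is_fixed_point(self, model, rng):
        c = sample_context(rng)
        model.perceive_episode(c, USSchedule.none(10))
        stored = model.hip.act.copy()
        final = model.hip.recall(encode_sc(c))
        assert np.array_equal(final, stored)

    def test_masked_cue_recalls_recent_memory(self, model, rng):
        c = sample_context(rng)
        model.perceive_episode(c, USSchedule.none(10))
        stored = model.hip.act.copy()
        cue = blur_cue(encode_sc(c), 0.10, rng)
        final = model.hip.recall(cue)
        assert f1_score(final, stored) >= 0.9

    def test_decayed_memory_fails_recall(self, model, rng):
        c = sample_context(rng)
        model.perceive_episode(c, USSchedule.none(10))
        stored = model.hip.act.copy()
        for _ in range(14):  # two weeks of forgetting
            model.hip.day_decay()
        final = model.hip.recall(blur_cue(encode_sc(c), 0.10, rng))
        assert f1_score(final, stored) < 0.9

    def test_attractor_fixed_point_on_toy_network(self):
        # exhaustive oracle on a 20-unit recurrent net with one stored engram
        cfg = ModelConfig(n_features=4, n_values=5, n_hip=20, hip_sparsity=0.2,
                          theta_hip_recall=2.0)
        m = FearModel(cfg, seed=0)
        rng = np.random.default_rng(0)
        c = sample_context(rng, 4, 5)
        for _ in range(10):
            m.hip.perceive(encode_sc(c))
        stored = m.hip.act.copy()
        act = stored.copy()
        from fearcons import kwta_activate
        for _ in range(5):
            act = kwta_activate(m.hip.W_rec.drive(act), m.hip.k,
                                theta=cfg.theta_hip_recall)
        assert np.array_equal(act, stored)


class TestEcMatch:
    def test_identical_patterns_route_hip(self):
        v = np.zeros(20, dtype=np.int8); v[:5] = 1
        f1, route = ec_match(v, v, theta_match=0.85)
        assert f1 == 1.0 and route is Route.HIP_ROUTE

    def test_disjoint_patterns_route_ctx(self):
        a = np.zeros(20, dtype=np.int8); a[:5] = 1
        b = np.zeros(20, dtype=np.int8); b[5:10] = 1
        f1, route = ec_match(a, b, theta_match=0.85)
        assert f1 == 0.0 and route is Route.CTX_ROUTE

    def test_empty_patterns_route_ctx(self):
        z = np.zeros(20, dtype=np.int8)
        f1, route = ec_match(z, z, theta_match=0.85)
        assert f1 == 0.0 and route is Route.CTX_ROUTE

    def test_symmetry(self, rng):
        a = (rng.random(30) < 0.3).astype(np.int8)
        b = (rng.random(30) < 0.3).astype(np.int8)
        assert ec_match(a, b, 0.5)[0] == ec_match(b, a, 0.5)[0]

    def test_ec_playback_recovers_input_pattern(self, model, rng):
        c = sample_context(rng)
        sc = encode_sc(c)
        model.perceive_episode(c, USSchedule.none(10))
        ec_out = model.hip.ec_output()
        assert f1_score(ec_out, sc) == 1.0


class TestReplay:
    def test_all_stored_engrams_visited(self):
        m = FearModel(seed=2)
        rng = np.random.default_rng(7)
        stored = []
        for _ in range(6):
            c = sample_context(rng)
            m.perceive_episode(c, USSchedule.none(25))
            stored.append(m.hip.act.copy())
        m.hip.start_sleep()
        visited = set()
        for _ in range(m.cfg.sleep_steps):
            act = m.hip.replay_step(m.rng)
            for i, s in enumerate(stored):
                if pattern_distance(act, s) <= 0.25:
                    visited.add(i)
        assert visited == set(range(6))

    def test_replay_selectivity_no_novel_mixtures(self):
        # patterns visited for >= 3 consecutive steps must be stored engrams
        m = FearModel(seed=3)
        rng = np.random.default_rng(11)
        stored = []
        for _ in range(5):
            c = sample_context(rng)
            m.perceive_episode(c, USSchedule.none(25))
            stored.append(m.hip.act.copy())
        m.hip.start_sleep()
        prev = prev2 = None
        stable_states = []
        for _ in range(m.cfg.sleep_steps):
            act = m.hip.replay_step(m.rng)
            if prev is not None and prev2 is not None and \
               np.array_equal(act, prev) and np.array_equal(prev, prev2):
                stable_states.append(act.copy())
            prev2, prev = prev, act
        assert stable_states, "no stable replay states observed"
        for act in stable_states:
            dmin = min(pattern_distance(act, s) for s in stored)
            assert dmin <= 0.25

    def test_empty_hippocampus_has_no_replay_events(self):
        m = FearModel(seed=4)
        m.hip.start_sleep()
        for _ in range(50):
            act = m.hip.replay_step(m.rng)
            # activity is noise-driven; recurrent drive carries no structure
        assert m.hip.W_rec.W.max() <= m.cfg.hip_bg_scale

    def test_recency_bias_of_recall(self):
        # P(success) non-increasing in age under default decay
        m = FearModel(seed=5)
        rng = np.random.default_rng(13)
        stored = []
        for day in range(12):
            c = sample_context(rng)
            m.perceive_episode(c, USSchedule.none(15))
            stored.append((day, m.hip.act.copy(), c))
            m.run_sleep(0)  # decay only; keep the test fast
        young = [s for s in stored if 12 - s[0] <= 4]
        old = [s for s in stored if 12 - s[0] >= 9]
        def rate(group):
            ok = [f1_score(m.hip.recall(blur_cue(encode_sc(c), 0.1, rng)), e) >= 0.9
                  for _, e, c in group]
            return np.mean(ok)
        assert rate(young) >= rate(old)
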