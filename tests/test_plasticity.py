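"""The reward-gated cluster rule, training, and the concept-extraction demo."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minicol import (
    ExperimentConfig,
    PlasticityRule,
    RewardSignal,
    apply_reward_rule,
    build_network,
    cluster_active,
    extend_activity,
    make_pattern_set,
    place_objects,
    run_concept_extraction,
    train,
    training_episode,
)
from minicol.plasticity import (
    INSIGNIFICANT,
    NEGATIVE,
    POSITIVE,
    TrainingEpisode,
    active_cluster_mask,
    fired_cells_for,
)


def _total_weights(network):
    return {
        (mc.id, cell.layer): cell.tree.weights.copy()
        for mc in network.minicolumns
        for cell in mc.learners()
    }


class TestClusterActive:
    def test_threshold_semantics(self):
        activity = np.zeros(10, dtype=bool)
        activity[[3, 4, 6, 7]] = True
        sources = np.array([3, 4, 5, 6])
        assert not cluster_active(sources, activity, G=4)
        assert cluster_active(sources, activity, G=3)
        activity[5] = True
        assert cluster_active(sources, activity, G=4)

    def test_unknown_source_is_integrity_error(self):
        with pytest.raises(KeyError):
            cluster_active(np.array([1, 20]), np.zeros(10, dtype=bool), G=1)


class TestApplyRewardRule:
    def test_unit_increment_on_positive_reward(self):
        assert apply_reward_rule(0, True, POSITIVE) == 1

    def test_reset_on_negative_reward(self):
        assert apply_reward_rule(3, True, NEGATIVE) == 0

    def test_no_coincidence_no_change(self):
        assert apply_reward_rule(5, False, NEGATIVE) == 5
        assert apply_reward_rule(5, False, POSITIVE) == 5

    def test_insignificant_reward_enhances_like_unit_positive(self):
        for w in (0, 2, 7):
            assert apply_reward_rule(w, True, INSIGNIFICANT) == apply_reward_rule(
                w, True, POSITIVE
            )

    def test_magnitude_scales_potentiation(self):
        strong = RewardSignal("positive", 3.0)
        assert apply_reward_rule(1, True, strong) == 1 + 1 * 3

    def test_graded_decrement_floors_at_zero(self):
        rule = PlasticityRule(weakening_mode="decrement", decrement_step=2.0)
        assert apply_reward_rule(5, True, NEGATIVE, rule) == 3
        assert apply_reward_rule(1, True, NEGATIVE, rule) == 0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            apply_reward_rule(-1, True, POSITIVE)


class TestExtendActivity:
    def test_hierarchical_detector_bits(self, small_hierarchical_config, rng):
        net = build_network(small_hierarchical_config, rng)
        solid = place_objects(100, "XXXXX", 3, rng)
        ext = extend_activity(solid, net.minicolumns[0])
        assert ext.size == 102
        assert ext[100]  # XXXXX detector
        assert not ext[101]  # XXOXX detector (no unit-gap junction here)

    def test_internal_rep_map_is_external_only(self, small_internal_config, rng):
        net = build_network(small_internal_config, rng)
        p = place_objects(100, "XXXXX", 2, rng)
        ext = extend_activity(p, net.minicolumns[0])
        assert ext.size == 100
        assert np.array_equal(ext, p.activity)

    def test_silence_maps_to_all_inactive(self, small_hierarchical_config, rng):
        net = build_network(small_hierarchical_config, rng)
        p = place_objects(100, "XXXXX", 0, rng)
        assert not extend_activity(p, net.minicolumns[0]).any()


class TestTrainingEpisode:
    def test_matches_scalar_rule_cluster_by_cluster(self, small_hierarchical_config, rng):
        """Dual route: the vectorised tree update must equal the scalar
        reference rule applied to every cluster independently."""
        net = build_network(small_hierarchical_config, rng)
        pattern = place_objects(100, "XXXXX", 16, rng)  # dense: 80 active inputs
        mc = net.minicolumns[2]
        ext = extend_activity(pattern, mc)
        G = small_hierarchical_config.g_threshold
        expected = np.array(
            [
                apply_reward_rule(0, cluster_active(row, ext, G), POSITIVE)
                for row in mc.l5.tree.sources
            ]
        )
        training_episode(
            net, TrainingEpisode(pattern, {(2, "L5")}, POSITIVE)
        )
        assert np.array_equal(mc.l5.tree.weights, expected)
        assert expected.sum() > 0  # the episode actually potentiated something

    def test_non_fired_cells_untouched(self, small_internal_config, rng):
        net = build_network(small_internal_config, rng)
        before = _total_weights(net)
        pattern = place_objects(100, "XXXXX", 5, rng)
        training_episode(net, TrainingEpisode(pattern, {(0, "L5"), (0, "L23")}))
        after = _total_weights(net)
        for key in before:
            if key[0] != 0:
                assert np.array_equal(before[key], after[key])

    def test_silent_pattern_changes_nothing(self, small_internal_config, rng):
        net = build_network(small_internal_config, rng)
        before = _total_weights(net)
        silent = place_objects(100, "XXXXX", 0, rng)
        training_episode(net, TrainingEpisode(silent, {(1, "L5")}))
        after = _total_weights(net)
        for key in before:
            assert np.array_equal(before[key], after[key])


class TestTrain:
    def test_order_invariance_of_final_weights(self, small_internal_config, rng):
        config = small_internal_config
        ps = make_pattern_set(config, rng)
        nets = []
        for order_seed in range(6):
            net = build_network(config, np.random.default_rng(config.seed))
            order = np.random.default_rng(order_seed).permutation(len(ps))
            shuffled = type(ps)(
                [ps.patterns[i] for i in order], [ps.assigned_mc[i] for i in order]
            )
            train(net, shuffled)
            nets.append(_total_weights(net))
        for other in nets[1:]:
            for key in nets[0]:
                assert np.array_equal(nets[0][key], other[key])

    def test_second_epoch_doubles_deltas(self, small_internal_config, rng):
        config = small_internal_config
        ps = make_pattern_set(config, rng)
        net = build_network(config, np.random.default_rng(config.seed))
        train(net, ps)
        once = _total_weights(net)
        train(net, ps)
        twice = _total_weights(net)
        for key in once:
            assert np.array_equal(twice[key], 2 * once[key])

    def test_cross_induction_couples_l23_to_l5(self, small_internal_config, rng):
        # the set of episodes updating a minicolumn's L2/3 equals the set
        # updating its L5: both fire exactly when the column is selected
        net = build_network(small_internal_config, rng)
        for mc_id in range(small_internal_config.n_mc):
            fired = fired_cells_for(net, mc_id)
            assert fired == {(mc_id, "L5"), (mc_id, "L23")}

    def test_positive_only_training_is_monotone(self, small_internal_config, rng):
        net = build_network(small_internal_config, rng)
        ps = make_pattern_set(small_internal_config, rng)
        snapshots = [_total_weights(net)]
        for pattern, mc_id in zip(ps.patterns, ps.assigned_mc):
            training_episode(net, TrainingEpisode(pattern, fired_cells_for(net, mc_id)))
            snapshots.append(_total_weights(net))
        for prev, cur in zip(snapshots, snapshots[1:]):
            for key in prev:
                assert (cur[key] >= prev[key]).all()
                assert (cur[key] >= 0).all()


class TestConceptExtraction:
    def test_canonical_sequence_extracts_the_pair(self):
        sequence = [({2, 3, 4}, "+"), ({2, 4}, "-"), ({3, 4}, "-")]
        assert run_concept_extraction(sequence) == {(2, 3)}

    def test_empty_sequence(self):
        assert run_concept_extraction([]) == set()

    def test_single_rewarded_presentation_enhances_all_active_pairs(self):
        assert run_concept_extraction([({2, 3, 4}, "+")]) == {(2, 3), (2, 4), (3, 4)}

    def test_result_robust_to_extra_punishments_missing_the_concept(self):
        base = [({2, 3, 4}, "+"), ({2, 4}, "-"), ({3, 4}, "-")]
        extras = [({1, 2}, "-"), ({4}, "-"), ({1, 3, 4}, "-")]
        for i in range(len(base) + 1):
            for extra in extras:
                sequence = base[:i] + [extra] + base[i:]
                assert run_concept_extraction(sequence) == {(2, 3)}

    def test_inputs_outside_range_rejected(self):
        with pytest.raises(ValueError):
            run_concept_extraction([({0, 2}, "+")])
        with pytest.raises(ValueError):
            run_concept_extraction([({2, 5}, "+")])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sets(st.integers(min_value=1, max_value=4), max_size=4),
                st.sampled_from(["+", "-"]),
            ),
            max_size=12,
        )
    )
    def test_enhancement_stays_binary_and_consistent(self, sequence):
        enhanced, history = run_concept_extraction(sequence, return_history=True)
        if history:
            assert enhanced == history[-1]
        # a pair is enhanced only if some rewarded step activated it jointly
        rewarded = set()
        for active, sign in sequence:
            if sign == "+":
                rewarded |= {
                    (a, b)
                    for a in active
                    for b in active
                    if a < b
                }
        assert enhanced <= rewarded
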