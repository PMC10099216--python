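"""Alignment, concatenation, decision rules and the arbitration NN."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmldms.classifiers import ProbabilityVector
from mmldms.fusion import (
    AlignedRow,
    ConcatenatedFeature,
    DecisionNn,
    DecisionNnConfig,
    align_multimodal,
    concatenate_probabilities,
    decide_average_probability,
    decide_majority_vote,
    decide_max_probability,
    decide_nn,
    predict_nn_batch,
    train_decision_nn,
)
from oracles import ap_oracle, mp_oracle, mv_oracle, random_instances


def make_vector(rng, cid, task, modality, key, k, stage="W", disorder="N"):
    return ProbabilityVector(
        classifier_id=cid, task=task, modality=modality,
        probs=rng.dirichlet(np.ones(k)),
        record_id=key[0], epoch_index=key[1], offset_s=key[2],
        stage=stage, disorder=disorder,
    )


def make_row(rng, ks: dict[str, int], key=("r0", 0, 0.0)):
    vectors = {
        cid: make_vector(rng, cid, "stage", "EEG", key, k)
        for cid, k in ks.items()
    }
    return AlignedRow(key=key, vectors=vectors, stage="W", disorder="N")


class TestAlignment:
    def test_inner_join_drops_extras(self, rng):
        keys = [("r", i, 0.0) for i in range(100)]
        sets = {}
        for cid in ("stage-EEG", "stage-ECG", "stage-EMG"):
            extra = [("x", i, 0.0) for i in range(30)] if cid == "stage-EEG" else []
            sets[cid] = [
                make_vector(rng, cid, "stage", cid[-3:], k, 6)
                for k in keys + extra
            ]
        rows = align_multimodal(sets)
        assert len(rows) == 100
        assert all(len(r.vectors) == 3 for r in rows)

    def test_disjoint_keys_name_offender(self, rng):
        sets = {
            "stage-EEG": [make_vector(rng, "stage-EEG", "stage", "EEG",
                                      ("a", i, 0.0), 6) for i in range(5)],
            "stage-ECG": [make_vector(rng, "stage-ECG", "stage", "ECG",
                                      ("b", i, 0.0), 6) for i in range(5)],
        }
        with pytest.raises(ValueError, match="no window keys"):
            align_multimodal(sets)

    def test_seeded_subsample_reproducible(self, rng):
        keys = [("r", i, 0.0) for i in range(50)]
        sets = {
            cid: [make_vector(rng, cid, "stage", "EEG", k, 6) for k in keys]
            for cid in ("a", "b")
        }
        r1 = align_multimodal(sets, seed=4, max_rows=20)
        r2 = align_multimodal(sets, seed=4, max_rows=20)
        assert [r.key for r in r1] == [r.key for r in r2]
        assert len(r1) == 20


class TestConcatenation:
    @pytest.mark.parametrize(
        "ks,expected",
        [
            ({"stage-EEG": 6, "stage-ECG": 6, "stage-EMG": 6}, 18),
            ({"disorder-EEG": 8, "disorder-ECG": 8, "disorder-EMG": 8}, 24),
            (
                {"stage-EEG": 6, "stage-ECG": 6, "stage-EMG": 6,
                 "disorder-EEG": 8, "disorder-ECG": 8, "disorder-EMG": 8},
                42,
            ),
        ],
    )
    def test_lengths_and_block_sums(self, rng, ks, expected):
        row = make_row(rng, ks)
        order = list(ks)
        feat = concatenate_probabilities(row, order)
        assert feat.values.size == expected
        pos = 0
        for cid in order:
            k = ks[cid]
            block = feat.values[pos : pos + k]
            np.testing.assert_array_equal(block, row.vectors[cid].probs)
            assert abs(block.sum() - 1.0) <= 1e-6
            pos += k

    def test_single_classifier_is_identity(self, rng):
        row = make_row(rng, {"stage-EEG": 6})
        feat = concatenate_probabilities(row, ["stage-EEG"])
        np.testing.assert_array_equal(feat.values, row.vectors["stage-EEG"].probs)

    def test_absent_classifier_rejected(self, rng):
        row = make_row(rng, {"stage-EEG": 6})
        with pytest.raises(KeyError, match="stage-ECG"):
            concatenate_probabilities(row, ["stage-EEG", "stage-ECG"])

    def test_block_sum_validated(self):
        with pytest.raises(ValueError, match="sum"):
            ConcatenatedFeature(
                values=np.array([0.5, 0.1]), blocks=(("a", 2),), key=("r", 0, 0.0)
            )


class TestDecisionRules:
    def test_worked_examples(self):
        # global max 0.7 sits in class 0 ("class 1")
        assert decide_max_probability(
            [np.array([0.7, 0.3]), np.array([0.4, 0.6])]) == 0
        # exact tie resolves to the lowest class index
        assert decide_max_probability(
            [np.array([0.5, 0.5]), np.array([0.5, 0.5])]) == 0
        # plurality (votes 0, 0, 1)
        assert decide_majority_vote(
            [np.array([0.6, 0.3, 0.1]), np.array([0.5, 0.2, 0.3]),
             np.array([0.1, 0.8, 0.1])]) == 0
        # all three disagree -> MP fallback picks the 0.9
        assert decide_majority_vote(
            [np.array([0.5, 0.3, 0.2]), np.array([0.1, 0.6, 0.3]),
             np.array([0.05, 0.05, 0.9])]) == 2
        # averaging: mean [0.4, 0.6] -> class 1 ("class 2")
        assert decide_average_probability(
            [np.array([0.6, 0.4]), np.array([0.2, 0.8])]) == 1

    def test_unequal_lengths_rejected(self):
        for rule in (decide_max_probability, decide_majority_vote,
                     decide_average_probability):
            with pytest.raises(ValueError, match="unequal"):
                rule([np.ones(3) / 3, np.ones(4) / 4])

    @pytest.mark.parametrize(
        "rule,oracle",
        [
            (decide_max_probability, mp_oracle),
            (decide_majority_vote, mv_oracle),
            (decide_average_probability, ap_oracle),
        ],
        ids=["mp", "mv", "ap"],
    )
    def test_matches_bruteforce_oracle(self, rule, oracle):
        for vecs in random_instances(1000, seed=17):
            assert rule(vecs) == oracle(vecs)

    @given(st.integers(2, 6), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_single_classifier_rules_agree(self, k, seed):
        v = [np.random.default_rng(seed).dirichlet(np.ones(k))]
        arg = int(np.argmax(v[0]))
        assert decide_max_probability(v) == arg
        assert decide_majority_vote(v) == arg
        assert decide_average_probability(v) == arg

    def test_rules_invariant_to_classifier_order(self, rng):
        for vecs in random_instances(200, seed=3):
            perm = list(reversed(vecs))
            assert decide_max_probability(vecs) == decide_max_probability(perm)
            assert decide_majority_vote(vecs) == decide_majority_vote(perm)
            assert decide_average_probability(vecs) == decide_average_probability(perm)


def sharp_features(rng, n, k_blocks, n_classes, sharpness=20.0):
    """Features whose first block points at the true class."""
    feats, labels = [], []
    for i in range(n):
        y = int(rng.integers(0, n_classes))
        blocks = []
        for _ in range(k_blocks):
            alpha = np.ones(n_classes)
            alpha[y] = sharpness
            blocks.append(rng.dirichlet(alpha))
        feats.append(
            ConcatenatedFeature(
                values=np.concatenate(blocks),
                blocks=tuple((f"c{j}", n_classes) for j in range(k_blocks)),
                key=(f"r{i}", i, 0.0),
            )
        )
        labels.append(y)
    return feats, labels


class TestDecisionNn:
    def test_architecture_widths(self):
        nn = DecisionNn(DecisionNnConfig(input_dim=18, output_dim=6))
        assert nn.widths == [18, 128, 128, 6]

    def test_learns_separable_features(self, rng):
        feats, labels = sharp_features(rng, 500, 3, 6)
        cfg = DecisionNnConfig(input_dim=18, output_dim=6, learning_rate=0.01,
                               max_epochs=60, early_stopping_patience=60, seed=0)
        nn, history = train_decision_nn(feats, labels, cfg)
        preds = predict_nn_batch(nn, feats)
        assert np.mean(preds == np.array(labels)) >= 0.99
        assert history.n_epochs >= 1

    def test_dimension_mismatch_rejected_before_training(self, rng):
        feats, labels = sharp_features(rng, 10, 3, 6)
        cfg = DecisionNnConfig(input_dim=42, output_dim=6)
        with pytest.raises(ValueError, match="length"):
            train_decision_nn(feats, labels, cfg)

    def test_decide_nn_contract(self, rng):
        feats, labels = sharp_features(rng, 60, 3, 6)
        cfg = DecisionNnConfig(input_dim=18, output_dim=6, learning_rate=0.01,
                               max_epochs=10, seed=2)
        nn, _ = train_decision_nn(feats, labels, cfg)
        label1, probs1 = decide_nn(nn, feats[0])
        label2, probs2 = decide_nn(nn, feats[0])
        assert label1 == label2 == int(np.argmax(probs1))
        np.testing.assert_array_equal(probs1, probs2)
        assert abs(probs1.sum() - 1.0) <= 1e-6
        with pytest.raises(ValueError, match="input"):
            bad = ConcatenatedFeature(
                values=np.ones(6) / 6, blocks=(("a", 6),), key=("r", 0, 0.0)
            )
            _ = decide_nn(
                DecisionNn(DecisionNnConfig(input_dim=18, output_dim=6)), bad
            )

    def test_checkpoint_initialisation(self, rng, tmp_path):
        from mmldms.fusion import save_nn_checkpoint

        cfg = DecisionNnConfig(input_dim=18, output_dim=6, seed=11)
        nn = DecisionNn(cfg)
        path = save_nn_checkpoint(nn, tmp_path / "nn.npz")
        warm = DecisionNn(
            DecisionNnConfig(input_dim=18, output_dim=6, seed=99, init=str(path))
        )
        for a, b in zip(nn.net.get_weights(), warm.net.get_weights()):
            np.testing.assert_array_equal(a, b)
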