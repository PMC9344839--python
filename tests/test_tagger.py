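import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _bruteforce import best_path_score, log_partition_enum
from tagqa import annotation
from tagqa.annotation import IGNORE, LabeledSequence, O
from tagqa.tagger import (
    BiLSTMCRFHead,
    BiLSTMHead,
    HashEmbeddingEncoder,
    LinearHead,
    Tensor,
    TrainConfig,
    crf_log_likelihood,
    log_partition,
    masked_loss,
    path_score,
    score_tokens,
    train,
    viterbi_decode,
)
from tagqa.pipeline import build_instances
from tagqa.synthetic import SyntheticSpec, generate
from tagqa.tagger.crf import crf_nll_op, marginals
from tagqa.tagger.loss import masked_ce_sum_op


def random_crf(rng, L, K=3, scale=2.0):
    return (
        rng.normal(size=(L, K)) * scale,
        rng.normal(size=(K, K)) * scale,
        rng.normal(size=K) * scale,
        rng.normal(size=K) * scale,
    )


class TestEncoder:
    def test_deterministic_given_seed(self, subword_tokenizer):
        packed = annotation.tokenize_and_pack(
            "Which?", "aspirin works fine", subword_tokenizer
        )
        a = HashEmbeddingEncoder(seed=5).encode(packed).data
        b = HashEmbeddingEncoder(seed=5).encode(packed).data
        np.testing.assert_array_equal(a, b)

    def test_output_length_and_dim(self, subword_tokenizer):
        packed = annotation.tokenize_and_pack(
            "Which?", "aspirin works fine", subword_tokenizer
        )
        enc = HashEmbeddingEncoder(embed_dim=8, window=2, seed=0)
        out = enc.encode(packed)
        assert out.data.shape == (len(packed), enc.dim)
        assert enc.dim == 5 * 8


class TestScoreTokens:
    def test_zero_linear_head_scores_zero(self):
        head = LinearHead(4)
        head.weight.data[:] = 0.0
        head.bias.data[:] = 0.0
        scores = score_tokens(head, Tensor(np.random.default_rng(0).normal(size=(6, 4))))
        np.testing.assert_array_equal(scores.data, np.zeros((6, 3)))

    def test_linear_head_position_independent(self, rng):
        head = LinearHead(4, rng=rng)
        x = rng.normal(size=(1, 4))
        enc = Tensor(np.vstack([x, x]))
        scores = score_tokens(head, enc).data
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="dim"):
            LinearHead(4).score(Tensor(rng.normal(size=(2, 5))))

    def test_bilstm_single_step_matches_manual_recurrence(self, rng):
        head = BiLSTMHead(3, hidden=4, rng=rng)
        x = rng.normal(size=(1, 3))
        got = head.score(Tensor(x)).data

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        halves = []
        for d in (head.forward, head.backward):
            i = sig(x @ d.wx["i"].data + d.b["i"].data)
            f = sig(x @ d.wx["f"].data + d.b["f"].data)
            o = sig(x @ d.wx["o"].data + d.b["o"].data)
            g = np.tanh(x @ d.wx["g"].data + d.b["g"].data)
            c = i * g  # c_prev = 0, so f*c_prev vanishes
            halves.append(o * np.tanh(c))
        h = np.concatenate(halves, axis=1)
        expected = h @ head.out_weight.data + head.out_bias.data
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_bilstm_deterministic(self, rng):
        x = rng.normal(size=(5, 3))
        a = BiLSTMHead(3, hidden=4, rng=np.random.default_rng(9)).score(Tensor(x)).data
        b = BiLSTMHead(3, hidden=4, rng=np.random.default_rng(9)).score(Tensor(x)).data
        np.testing.assert_array_equal(a, b)


class TestMaskedLoss:
    def test_uniform_scores_give_ln3(self):
        scores = np.zeros((4, 3))
        labels = LabeledSequence((O, O, O, O))
        assert masked_loss(scores, labels) == pytest.approx(math.log(3), abs=1e-12)

    def test_relabeling_ignore_positions_is_bit_identical(self, rng):
        scores = rng.normal(size=(6, 3))
        base = np.array([O, IGNORE, 0, IGNORE, 1, O])
        mask = base != IGNORE
        a = masked_loss(scores, base)
        for replacement in (0, 1, 2):
            flipped = base.copy()
            flipped[~mask] = replacement
            assert masked_loss(scores, flipped, mask=mask) == a

    def test_all_ignore_is_error(self):
        with pytest.raises(ValueError, match="supervised"):
            masked_loss(np.zeros((3, 3)), LabeledSequence((IGNORE,) * 3))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            masked_loss(np.zeros((3, 3)), LabeledSequence((O, O)))

    def test_batch_reduction_is_weighted_mean(self, rng):
        # the documented batch reduction: sum of per-position CE divided
        # by total supervised positions == mean of per-sample losses
        # weighted by their supervised-token counts
        samples = []
        for n_sup in (2, 5, 3):
            scores = rng.normal(size=(n_sup + 2, 3))
            labels = [IGNORE] * (n_sup + 2)
            for k in range(1, n_sup + 1):
                labels[k] = int(rng.integers(0, 3))
            samples.append((scores, LabeledSequence(tuple(labels))))
        total, count = 0.0, 0
        for scores, labels in samples:
            op, n = masked_ce_sum_op(Tensor(scores), labels)
            total += float(op.data)
            count += n
        explicit = sum(
            masked_loss(s, l) * l.supervised_count for s, l in samples
        ) / sum(l.supervised_count for s, l in samples)
        assert total / count == pytest.approx(explicit, rel=1e-12)

    def test_ignore_gradient_is_exactly_zero(self, rng):
        scores = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        labels = LabeledSequence((O, IGNORE, 0, IGNORE))
        op, _ = masked_ce_sum_op(scores, labels)
        op.backward()
        np.testing.assert_array_equal(scores.grad[1], np.zeros(3))
        np.testing.assert_array_equal(scores.grad[3], np.zeros(3))


class TestCRF:
    def test_length_one_closed_form(self, rng):
        scores, trans, start, end = random_crf(rng, 1)
        for y in range(3):
            ll = crf_log_likelihood(scores, trans, start, end, [y])
            z = scores[0] + start + end
            expected = z[y] - (np.log(np.sum(np.exp(z - z.max()))) + z.max())
            assert ll == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("L", [1, 2, 3, 4, 5, 6])
    def test_partition_matches_enumeration(self, rng, L):
        scores, trans, start, end = random_crf(rng, L)
        got = log_partition(scores, trans, start, end)
        expected = log_partition_enum(scores, trans, start, end)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_gold_path_never_exceeds_partition(self, rng):
        for _ in range(20):
            L = int(rng.integers(1, 7))
            scores, trans, start, end = random_crf(rng, L)
            labels = rng.integers(0, 3, size=L).tolist()
            assert path_score(scores, trans, start, end, labels) <= log_partition(
                scores, trans, start, end
            ) + 1e-12

    def test_nonfinite_rejected(self):
        scores = np.zeros((2, 3))
        scores[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            log_partition(scores, np.zeros((3, 3)), np.zeros(3), np.zeros(3))

    def test_nll_op_gradients_match_numerical(self, rng):
        L = 4
        s, t, a, b = random_crf(rng, L, scale=0.5)
        scores = Tensor(s, requires_grad=True)
        trans = Tensor(t, requires_grad=True)
        start = Tensor(a, requires_grad=True)
        end = Tensor(b, requires_grad=True)
        labels = [0, 1, 2, 1]
        out = crf_nll_op(scores, trans, start, end, labels)
        out.backward()
        eps = 1e-6
        for tensor in (scores, trans, start, end):
            num = np.zeros_like(tensor.data)
            it = np.nditer(tensor.data, flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index
                orig = tensor.data[idx]
                tensor.data[idx] = orig + eps
                hi = -crf_log_likelihood(scores.data, trans.data, start.data, end.data, labels)
                tensor.data[idx] = orig - eps
                lo = -crf_log_likelihood(scores.data, trans.data, start.data, end.data, labels)
                tensor.data[idx] = orig
                num[idx] = (hi - lo) / (2 * eps)
                it.iternext()
            np.testing.assert_allclose(tensor.grad, num, rtol=1e-5, atol=1e-7)

    def test_marginals_sum_to_one(self, rng):
        scores, trans, start, end = random_crf(rng, 5)
        unary, _ = marginals(scores, trans, start, end)
        np.testing.assert_allclose(unary.sum(axis=1), np.ones(5), rtol=1e-10)


class TestViterbi:
    def test_zero_transitions_is_per_token_argmax(self, rng):
        scores = rng.normal(size=(6, 3))
        path, _ = viterbi_decode(scores, np.zeros((3, 3)), np.zeros(3), np.zeros(3))
        assert path == list(np.argmax(scores, axis=1))

    def test_length_one(self, rng):
        scores, trans, start, end = random_crf(rng, 1)
        path, score = viterbi_decode(scores, trans, start, end)
        combined = scores[0] + start + end
        assert path == [int(np.argmax(combined))]
        assert score == pytest.approx(float(np.max(combined)))

    def test_empty_sequence(self):
        path, score = viterbi_decode(np.zeros((0, 3)), np.zeros((3, 3)))
        assert path == [] and score == 0.0

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_bruteforce(self, trial):
        rng = np.random.default_rng(1000 + trial)
        L = int(rng.integers(1, 9))
        scores, trans, start, end = random_crf(rng, L)
        path, score = viterbi_decode(scores, trans, start, end)
        assert score == pytest.approx(best_path_score(scores, trans, start, end), rel=1e-12)
        assert path_score(scores, trans, start, end, path) == pytest.approx(score, rel=1e-12)

    def test_tie_break_deterministic(self):
        scores = np.zeros((4, 3))  # every path ties
        path, _ = viterbi_decode(scores, np.zeros((3, 3)), np.zeros(3), np.zeros(3))
        assert path == [0, 0, 0, 0]


def _tiny_instances(n_questions=10, seed=0, answers=(1, 2)):
    corpus = generate(
        SyntheticSpec(
            n_questions=n_questions,
            answers_per_question=answers,
            passages_per_question=1,
            seed=seed,
        )
    )
    tok = annotation.WordPieceLikeTokenizer(max_piece_len=10, lowercase=True)
    return build_instances(corpus.questions, corpus.passages, tok)


class TestTrain:
    def test_config_defaults_match_reference_settings(self):
        config = TrainConfig()
        assert config.batch_size == 18
        assert config.learning_rate == pytest.approx(5e-6)
        assert config.transfer_learning_rate == pytest.approx(5e-5)
        assert config.shuffle_each_epoch is True

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)

    def test_identical_seed_identical_log(self):
        instances = _tiny_instances()
        config = TrainConfig(learning_rate=0.01, batch_size=4, max_steps=15, seed=7)
        logs = []
        for _ in range(2):
            encoder = HashEmbeddingEncoder(embed_dim=8, seed=config.seed)
            _, log = train(instances, encoder, config)
            logs.append(log)
        assert logs[0] == logs[1]

    def test_different_seed_different_log(self):
        instances = _tiny_instances()
        logs = []
        for seed in (1, 2):
            config = TrainConfig(learning_rate=0.01, batch_size=4, max_steps=15, seed=seed)
            encoder = HashEmbeddingEncoder(embed_dim=8, seed=seed)
            _, log = train(instances, encoder, config)
            logs.append(log)
        assert logs[0] != logs[1]

    def test_learnable_within_budget(self):
        # 50-sample separable synthetic set: loss < 0.1 within 2000 steps
        instances = _tiny_instances(n_questions=50, seed=3)
        assert len(instances) == 50
        config = TrainConfig(learning_rate=0.05, batch_size=18, max_steps=2000, seed=0)
        encoder = HashEmbeddingEncoder(seed=0)
        model, log = train(instances, encoder, config)
        losses = [l for _, l in log]
        assert min(losses) < 0.1

    def test_empty_instances_rejected(self):
        with pytest.raises(ValueError, match="no training"):
            train([], HashEmbeddingEncoder(), TrainConfig())

    def test_crf_head_trains_and_decodes(self):
        instances = _tiny_instances(n_questions=6, answers=(2,))
        config = TrainConfig(
            learning_rate=0.03, batch_size=3, max_steps=25, seed=0,
            head="bilstm_crf", hidden=6,
        )
        encoder = HashEmbeddingEncoder(embed_dim=6, seed=0)
        model, log = train(instances, encoder, config)
        assert log[-1][1] < log[0][1]
        tagging = model.predict(instances[0].tokenized)
        assert len(tagging.labels) == len(instances[0].tokenized.supervised_indices)

    def test_crf_masked_variant_supported(self):
        instances = _tiny_instances(n_questions=4, answers=(1,))
        config = TrainConfig(
            learning_rate=0.03, batch_size=2, max_steps=5, seed=0,
            head="bilstm_crf", hidden=4, crf_mask_supervision=True,
        )
        encoder = HashEmbeddingEncoder(embed_dim=4, seed=0)
        _, log = train(instances, encoder, config)
        assert len(log) == 5


class TestStrictBio:
    def test_strict_transitions_penalize_o_to_i(self):
        head = BiLSTMCRFHead(4, hidden=4, strict_bio=True)
        trans, start, _ = head.transition_arrays()
        assert trans[annotation.O, annotation.I] < -1e3
        assert start[annotation.I] < -1e3
        relaxed = BiLSTMCRFHead(4, hidden=4, strict_bio=False).transition_arrays()
        assert relaxed[0][annotation.O, annotation.I] == 0.0


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=20, deadline=None)
def test_property_viterbi_oracle(seed):
    rng = np.random.default_rng(seed)
    L = int(rng.integers(1, 7))
    scores, trans, start, end = random_crf(rng, L)
    _, score = viterbi_decode(scores, trans, start, end)
    assert score == pytest.approx(best_path_score(scores, trans, start, end), rel=1e-10)
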