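import numpy as np
import pytest

from infersentppi.corpus import ProteinSentence
from infersentppi.model import (
    InferSentPN,
    ModelConfig,
    PairModel,
    _init_params,
    combine_features,
    encode_sentence,
    predict,
    train,
)


def _sentence(matrix, pid="P1"):
    matrix = np.asarray(matrix, dtype=float)
    return ProteinSentence(protein_id=pid, term_ids=[f"GO:{i:07d}" for i in range(len(matrix))], matrix=matrix)


def _toy_model(dim=4, seed=0, **kw):
    cfg = ModelConfig(embed_dim=dim, conv_channels=(8,), kernel_size=1,
                      hidden_dim=8, dropout=0.0, seed=seed, **kw)
    rng = np.random.default_rng(seed)
    return PairModel(cfg, _init_params(cfg, rng))


def _separable_corpus(rng, n=8, dim=6):
    """Pairs are positive iff the two sentences share the planted direction."""
    e = np.eye(dim)
    examples = []
    for i in range(n):
        axis = i % 2  # class-defining direction
        si = _sentence([e[axis] * 2.0, e[2 + (i % 3)]], pid=f"A{i}")
        sj = _sentence([e[axis] * 2.0, e[3 + (i % 2)]], pid=f"B{i}")
        lab = 1 if axis == 0 else 0
        examples.append((si, sj, lab))
    return examples


class TestCombineFeatures:
    def test_hand_example(self):
        out = combine_features(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        np.testing.assert_array_equal(out, [1, 0, 0, 1, 1, 1, 0, 0])

    def test_identical_inputs_zero_difference_block(self):
        u = np.array([0.5, -1.0, 2.0])
        out = combine_features(u, u)
        np.testing.assert_array_equal(out[6:9], np.zeros(3))
        assert len(out) == 12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            combine_features(np.ones(3), np.ones(4))


class TestEncodeSentence:
    def test_fixed_size_regardless_of_length(self):
        m = _toy_model()
        e1 = encode_sentence(m, _sentence(np.random.default_rng(0).random((1, 4))))
        e40 = encode_sentence(m, _sentence(np.random.default_rng(1).random((40, 4))))
        assert e1.shape == e40.shape == (8,)

    def test_kernel1_permutation_invariance(self):
        m = _toy_model()
        rng = np.random.default_rng(2)
        mat = rng.random((7, 4))
        e = encode_sentence(m, _sentence(mat))
        for _ in range(5):
            perm = rng.permutation(7)
            np.testing.assert_allclose(encode_sentence(m, _sentence(mat[perm])), e)

    def test_deterministic(self):
        m = _toy_model()
        mat = np.random.default_rng(3).random((5, 4))
        np.testing.assert_array_equal(
            encode_sentence(m, _sentence(mat)), encode_sentence(m, _sentence(mat))
        )

    def test_dimension_mismatch_raises(self):
        m = _toy_model(dim=4)
        with pytest.raises(ValueError):
            encode_sentence(m, _sentence(np.ones((3, 5))))

    def test_kernel2_sees_token_repetition(self):
        # with kernel 2, a duplicated token creates an (x, x) window that a
        # singleton sentence lacks, so repetition can change the embedding —
        # the mechanism by which annotation weights reach the encoder
        cfg = ModelConfig(embed_dim=2, conv_channels=(1,), kernel_size=2,
                          hidden_dim=8, dropout=0.0, seed=5)
        m = PairModel(cfg, _init_params(cfg, np.random.default_rng(5)))
        # channel sums both window tokens along the first axis
        m.params["convW0"] = np.array([[[1.0], [0.0]], [[1.0], [0.0]]])
        m.params["convb0"] = np.zeros(1)
        x, y = np.array([1.0, 0.0]), np.array([0.2, 0.0])
        once = encode_sentence(m, _sentence([x, y]))  # windows: (x,y) -> 1.2
        twice = encode_sentence(m, _sentence([x, x, y]))  # (x,x) -> 2.0
        assert once[0] == pytest.approx(1.2)
        assert twice[0] == pytest.approx(2.0)


class TestTrain:
    def test_learns_separable_toy_corpus(self):
        rng = np.random.default_rng(0)
        corpus = _separable_corpus(rng)
        cfg = ModelConfig(embed_dim=6, conv_channels=(8,), hidden_dim=8,
                          dropout=0.0, epochs=200, batch_size=2, seed=3)
        model, losses = train(corpus, cfg)
        preds = [predict(model, si, sj).label for si, sj, _ in corpus]
        assert preds == [lab for _, _, lab in corpus]
        assert losses[-1] <= losses[0]

    def test_seeded_determinism(self):
        corpus = _separable_corpus(np.random.default_rng(1))
        cfg = ModelConfig(embed_dim=6, conv_channels=(8,), hidden_dim=8,
                          epochs=20, seed=7)
        m1, l1 = train(corpus, cfg)
        m2, l2 = train(corpus, cfg)
        assert l1 == l2
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_single_class_rejected(self):
        corpus = [(s, t, 1) for s, t, _ in _separable_corpus(np.random.default_rng(2))]
        with pytest.raises(ValueError):
            train(corpus, ModelConfig(embed_dim=6))


class TestPredict:
    def test_probabilities_normalised(self):
        m = _toy_model()
        rng = np.random.default_rng(4)
        r = predict(m, _sentence(rng.random((3, 4))), _sentence(rng.random((5, 4))))
        assert r.p_positive + r.p_negative == pytest.approx(1.0, abs=1e-6)
        assert r.label == int(r.p_positive > 0.5)

    def test_exact_tie_is_negative(self):
        # zeroed output layer forces logits (0, 0) -> p = (0.5, 0.5);
        # the strict decision rule calls the tie negative
        m = _toy_model()
        m.params["W2"][:] = 0.0
        m.params["b2"][:] = 0.0
        r = predict(m, _sentence(np.ones((2, 4))), _sentence(np.ones((2, 4))))
        assert r.p_positive == 0.5
        assert r.label == 0

    def test_symmetric_option_averages_orders(self):
        m = _toy_model(seed=9)
        rng = np.random.default_rng(9)
        si, sj = _sentence(rng.random((3, 4))), _sentence(rng.random((4, 4)))
        r_sym_ij = predict(m, si, sj, symmetric=True)
        r_sym_ji = predict(m, sj, si, symmetric=True)
        assert r_sym_ij.p_positive == pytest.approx(r_sym_ji.p_positive)


class TestModelResultsApi:
    def test_fit_summary_and_checkpoint_roundtrip(self, tmp_path):
        corpus = _separable_corpus(np.random.default_rng(5))
        cfg = ModelConfig(embed_dim=6, conv_channels=(8,), hidden_dim=8,
                          epochs=30, seed=2)
        res = InferSentPN(corpus, cfg).fit()
        text = res.summary()
        assert "InferSent_PN" in text and "epochs=30" in text
        prefix = str(tmp_path / "model")
        res.pair_model.save(prefix)
        loaded = PairModel.load(prefix)
        si, sj, _ = corpus[0]
        assert predict(loaded, si, sj).p_positive == pytest.approx(
            res.predict(si, sj).p_positive
        )

    def test_evaluate_reports_both_aucs(self):
        corpus = _separable_corpus(np.random.default_rng(6))
        cfg = ModelConfig(embed_dim=6, conv_channels=(8,), hidden_dim=8,
                          epochs=100, seed=4)
        res = InferSentPN(corpus, cfg).fit()
        rep = res.evaluate(corpus)
        assert rep.auc_roc is not None and rep.auc_pr is not None
        assert rep.n_pos + rep.n_neg == len(corpus)
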