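import numpy as np
import pytest

from synergyshot import (
    BackboneSpec,
    TrainConfig,
    WordTokenizer,
    auroc,
    encode_batch,
    finetune,
    verbalizer_zero_shot,
)
from synergyshot import nn
from synergyshot.lm_classifier import LmClassifier, TinyCausalLM, verbalizer_log_likelihood


class TestTokenizer:
    def test_splits_words_and_punctuation(self):
        tok = WordTokenizer.fit(["The drug is drug017-mechC. Synergy:"])
        toks = [tok.itos[i] for i in tok.encode("drug017-mechC. Synergy:")]
        assert toks == ["drug017", "-", "mechC", ".", "Synergy", ":"]

    def test_unknown_words_map_to_unk(self):
        tok = WordTokenizer.fit(["alpha beta"])
        assert tok.encode("alpha gamma") == [tok.stoi["alpha"], tok.unk_id]


class TestEncodeBatch:
    def test_left_pad_by_construction(self):
        tok = WordTokenizer.fit(["a b c d"])
        ids, mask = encode_batch(["a b", "a b c d"], tok, 16)
        assert ids.shape == (2, 4)
        assert list(ids[0][:2]) == [0, 0] and mask[0].tolist() == [0, 0, 1, 1]
        assert mask[1].tolist() == [1, 1, 1, 1]

    def test_single_prompt_no_padding(self):
        tok = WordTokenizer.fit(["x y z"])
        ids, mask = encode_batch(["x y z"], tok, 8)
        assert (mask == 1).all()

    def test_mask_is_suffix_of_ones(self):
        rng = np.random.default_rng(0)
        words = [f"w{i}" for i in range(30)]
        tok = WordTokenizer.fit([" ".join(words)])
        prompts = [" ".join(rng.choice(words, size=rng.integers(1, 20))) for _ in range(50)]
        _, mask = encode_batch(prompts, tok, 32)
        for row in mask:
            first_one = int(np.argmax(row))
            assert row[first_one:].all() and not row[:first_one].any()

    def test_overlong_prompt_names_offender(self):
        tok = WordTokenizer.fit(["a b c d e f"])
        with pytest.raises(ValueError, match="prompt 1"):
            encode_batch(["a b", "a b c d e f"], tok, 4)

    def test_last_column_always_real(self):
        tok = WordTokenizer.fit(["p q r s"])
        _, mask = encode_batch(["p", "p q", "p q r s"], tok, 8)
        assert (mask[:, -1] == 1).all()


class TestForwardContracts:
    def test_left_padding_invariance_of_head_logits(self, tiny_lm):
        tok = tiny_lm.backbone.tokenizer
        text = "alpha beta gamma"
        base = tiny_lm.predict_proba([text])[0]
        toks = tok.encode(text)
        for extra in (1, 5):
            ids = np.array([[0] * extra + toks])
            mask = np.array([[0] * extra + [1] * len(toks)])
            h = tiny_lm.backbone.forward(ids, mask)
            padded = nn.softmax(tiny_lm.head(h[:, -1, :]), axis=-1)[0, 1]
            assert padded == pytest.approx(base, abs=1e-5)

    def test_batch_invariance_of_scores(self, tiny_lm):
        prompts = ["alpha beta", "gamma delta one two", "three Positive", "alpha"]
        batched = tiny_lm.predict_proba(prompts)
        single = np.array([tiny_lm.predict_proba([p])[0] for p in prompts])
        np.testing.assert_allclose(batched, single, atol=1e-5)

    def test_repeated_prompt_identical_scores_and_softmax_norm(self, tiny_lm):
        scores = tiny_lm.predict_proba(["alpha beta"] * 3)
        assert len(set(scores.tolist())) == 1
        assert 0.0 <= scores[0] <= 1.0

    def test_save_load_round_trip(self, tiny_lm, tmp_path):
        tiny_lm.save(tmp_path / "ckpt")
        back = LmClassifier.load(tmp_path / "ckpt")
        p = ["alpha beta gamma", "delta one"]
        np.testing.assert_array_equal(tiny_lm.predict_proba(p), back.predict_proba(p))


class TestFinetune:
    def _separable_shots(self, n=32):
        # the token 'toxic' marks positives: linearly separable from names
        shots = []
        for i in range(n):
            word = "toxic" if i % 2 else "inert"
            shots.append((f"pair {i % 8} is {word} . Synergy:", i % 2))
        return shots

    def test_learns_separable_shots(self):
        shots = self._separable_shots()
        tok = WordTokenizer.fit([p for p, _ in shots])
        spec = BackboneSpec(layer_count=2, hidden_size=32, head_count=4, max_length=16)
        model = LmClassifier(TinyCausalLM(spec, tok, seed=0), seed=0)
        cfg = TrainConfig.tiny_backbone_defaults(seed=0, epochs=4)
        tuned = finetune(model, shots, cfg)
        preds = tuned.predict_proba([p for p, _ in shots])
        labels = np.array([y for _, y in shots])
        assert np.mean((preds > 0.5) == labels) >= 0.9
        assert tuned.epoch_losses_[-1] < tuned.epoch_losses_[0]

    def test_deterministic_given_seed_and_base_untouched(self, tiny_lm):
        shots = [("alpha beta", 1), ("gamma delta", 0), ("one two", 1), ("three", 0)]
        cfg = TrainConfig.tiny_backbone_defaults(seed=5, epochs=2)
        before = tiny_lm.predict_proba(["alpha beta"])[0]
        a = finetune(tiny_lm, shots, cfg).predict_proba(["alpha beta", "three"])
        after = tiny_lm.predict_proba(["alpha beta"])[0]
        b = finetune(tiny_lm, shots, cfg).predict_proba(["alpha beta", "three"])
        np.testing.assert_array_equal(a, b)
        assert before == after  # finetune works on a copy

    def test_empty_shots_rejected(self, tiny_lm):
        with pytest.raises(ValueError, match="zero-shot"):
            finetune(tiny_lm, [], TrainConfig())


class TestVerbalizerZeroShot:
    def test_hand_computed_ratio_on_toy_vocab(self):
        # uniform next-token logits: every token equally likely at each step;
        # with vocab size V, L("Positive") = 1/V and L("Not positive") = 1/V^2,
        # so p = (1/V) / (1/V + 1/V^2) = V / (V + 1)
        tok = WordTokenizer.fit(["cue Positive Not positive"])
        spec = BackboneSpec(layer_count=1, hidden_size=8, head_count=1, max_length=8)
        backbone = TinyCausalLM(spec, tok, seed=0)
        backbone.wte.W.v[...] = 0.0  # uniform distributions everywhere
        backbone.wpe.W.v[...] = 0.0
        V = len(tok)
        p = verbalizer_zero_shot(backbone, "cue")
        assert p == pytest.approx(V / (V + 1), abs=1e-9)

    def test_probability_strictly_inside_unit_interval(self, tiny_lm):
        p = verbalizer_zero_shot(tiny_lm.backbone, "alpha beta gamma Synergy :")
        assert 0.0 < p < 1.0

    def test_likelihood_sums_token_steps(self, tiny_lm):
        # two-token verbalizer log-likelihood equals the sum of its two
        # teacher-forced next-token log-probabilities
        b = tiny_lm.backbone
        ll = verbalizer_log_likelihood(b, "alpha beta", "Not positive")
        tok = b.tokenizer
        ids = tok.encode("alpha beta") + tok.encode("Not positive")
        arr = np.array([ids])
        logp = b.next_token_log_probs(arr, np.ones_like(arr))[0]
        expected = logp[1, ids[2]] + logp[2, ids[3]]
        assert ll == pytest.approx(float(expected), abs=1e-9)

    def test_untrained_head_is_chance_level(self):
        # a random head on random prompts: AUROC statistically near 0.5
        rng = np.random.default_rng(3)
        words = [f"w{i}" for i in range(40)]
        tok = WordTokenizer.fit([" ".join(words)])
        spec = BackboneSpec(layer_count=2, hidden_size=16, head_count=2, max_length=24)
        model = LmClassifier(TinyCausalLM(spec, tok, seed=3), seed=3)
        prompts = [" ".join(rng.choice(words, size=10)) for _ in range(200)]
        labels = rng.integers(0, 2, size=200)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = auroc(model.predict_proba(prompts), labels)
        assert abs(a - 0.5) < 0.15  # ~3 sigma for n=200 balanced


def test_backbone_spec_validation():
    with pytest.raises(ValueError):
        BackboneSpec(hidden_size=30, head_count=4)
    with pytest.raises(NotImplementedError):
        TinyCausalLM(BackboneSpec(source="gpt2-124m"), WordTokenizer.fit(["a"]))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-1)
    with pytest.raises(ValueError):
        TrainConfig(padding_side="right")
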