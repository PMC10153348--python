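"""Causal-language-model classification stack.

A decoder-only transformer backbone is paired with a linear 2-logit head read
off the hidden state of the *last* token. Batches are padded on the left so
the last position always holds a prompt token; position ids are computed from
the attention mask, which makes head logits exactly invariant to the amount
of left padding. Fine-tuning minimizes cross-entropy with AdamW (decoupled
weight decay, gradient clipping at 1.0), 4 epochs by default.

Zero-shot scoring without a trained head uses verbalizer likelihoods: the
probability the backbone assigns to "Positive" continuing the prompt,
normalized against "Not positive".

The backbone is a contract, not a fixed model: the shipped implementation is
a from-scratch tiny decoder trained on the task corpus (no downloads). A
pretrained-checkpoint source is part of the ``BackboneSpec`` interface but is
not bundled.
"""

from __future__ import annotations

import copy
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .serializer import PromptText, prompt_for_record, VERBALIZERS

log = logging.getLogger("synergyshot")

PAD, UNK = "<pad>", "<unk>"
_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


class WordTokenizer:
    """Whitespace/punctuation word-level tokenizer built from a corpus.

    Words and single punctuation marks are tokens; unknown words map to
    ``<unk>``. Index 0 is the pad token.
    """

    def __init__(self, vocab: list[str]):
        if vocab[:2] != [PAD, UNK]:
            vocab = [PAD, UNK] + [t for t in vocab if t not in (PAD, UNK)]
        self.itos = list(vocab)
        self.stoi = {t: i for i, t in enumerate(self.itos)}
        self.pad_id = 0
        self.unk_id = 1

    @classmethod
    def fit(cls, texts) -> "WordTokenizer":
        seen: dict[str, None] = {}
        for t in texts:
            for tok in _TOKEN_RE.findall(t):
                seen.setdefault(tok, None)
        return cls([PAD, UNK] + sorted(seen))

    def __len__(self) -> int:
        return len(self.itos)

    def encode(self, text: str) -> list[int]:
        return [self.stoi.get(t, self.unk_id) for t in _TOKEN_RE.findall(text)]

    def decode(self, ids) -> str:
        return " ".join(self.itos[i] for i in ids if i != self.pad_id)

    def to_dict(self) -> dict:
        return {"vocab": self.itos}


@dataclass
class BackboneSpec:
    """Architecture of the causal-LM backbone.

    ``source`` is either ``"from_scratch"`` (a tiny decoder trained on the
    task corpus) or a pretrained checkpoint identifier, which this package
    accepts as an interface but does not bundle.
    """

    source: str = "from_scratch"
    layer_count: int = 2
    hidden_size: int = 64
    head_count: int = 4
    max_length: int = 128

    def __post_init__(self):
        if self.hidden_size % self.head_count:
            raise ValueError("hidden_size must be divisible by head_count")


@dataclass
class TrainConfig:
    """Fine-tuning hyperparameters.

    The defaults (4 epochs, lr 5e-5, weight decay 0.01) suit a pretrained
    backbone; ``tiny_backbone_defaults`` raises the learning rate for the
    from-scratch tiny decoder, which barely moves at 5e-5 over a few hundred
    steps.
    """

    epochs: int = 4
    learning_rate: float = 5e-5
    weight_decay: float = 0.01
    batch_size: int = 8
    seed: int = 0
    padding_side: str = "left"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.padding_side != "left":
            raise ValueError("padding_side is fixed to 'left'")

    @classmethod
    def tiny_backbone_defaults(cls, seed: int = 0, **kw) -> "TrainConfig":
        kw.setdefault("learning_rate", 1e-3)
        return cls(seed=seed, **kw)


def encode_batch(
    prompts: list[str], tokenizer: WordTokenizer, max_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Tokenize and left-pad a batch of prompts.

    Returns (ids, mask), both (B, T) with T the batch maximum length. Padding
    sits on the left, so the final column holds only real tokens and the mask
    of every row is a suffix of ones.
    """
    if not prompts:
        raise ValueError("prompts must be non-empty")
    encoded = [tokenizer.encode(p) for p in prompts]
    for i, toks in enumerate(encoded):
        if len(toks) > max_length:
            raise ValueError(
                f"prompt {i} tokenizes to {len(toks)} tokens, exceeding max_length={max_length}"
            )
        if not toks:
            raise ValueError(f"prompt {i} tokenizes to zero tokens")
    T = max(len(t) for t in encoded)
    ids = np.zeros((len(encoded), T), dtype=int)
    mask = np.zeros((len(encoded), T), dtype=int)
    for i, toks in enumerate(encoded):
        ids[i, T - len(toks):] = toks
        mask[i, T - len(toks):] = 1
    return ids, mask


class TinyCausalLM:
    """From-scratch decoder-only transformer with tied LM head.

    Position ids are the cumulative count of real tokens (from the attention
    mask), so left padding never shifts the positional encoding of real
    tokens.
    """

    def __init__(self, spec: BackboneSpec, tokenizer: WordTokenizer, seed: int = 0):
        if spec.source != "from_scratch":
            raise NotImplementedError(
                f"pretrained backbone source {spec.source!r} is an interface only; "
                "this package bundles the from_scratch tiny decoder"
            )
        self.spec = spec
        self.tokenizer = tokenizer
        rng = np.random.default_rng(seed)
        d = spec.hidden_size
        self.wte = nn.Embedding(rng, len(tokenizer), d)
        self.wpe = nn.Embedding(rng, spec.max_length, d)
        self.blocks = [
            nn.TransformerBlock(rng, d, spec.head_count) for _ in range(spec.layer_count)
        ]
        self.ln_f = nn.LayerNorm(d)

    def params(self) -> list[tuple[str, nn.Param]]:
        out = [("wte.W", self.wte.W), ("wpe.W", self.wpe.W)]
        for i, b in enumerate(self.blocks):
            out += [(f"h{i}.{n}", p) for n, p in b.params()]
        out += [(f"ln_f.{n}", p) for n, p in self.ln_f.params()]
        return out

    @staticmethod
    def position_ids(mask: np.ndarray) -> np.ndarray:
        return np.maximum(np.cumsum(mask, axis=1) - 1, 0)

    def forward(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        pos = self.position_ids(mask)
        x = self.wte(ids) + self.wpe(pos)
        bias = nn.causal_attn_bias(mask)
        for b in self.blocks:
            x = b(x, bias)
        return self.ln_f(x)  # (B, T, d)

    def backward(self, dh: np.ndarray) -> None:
        dx = self.ln_f.backward(dh)
        for b in reversed(self.blocks):
            dx = b.backward(dx)
        self.wte.backward(dx)
        self.wpe.backward(dx)

    def lm_logits(self, hidden: np.ndarray) -> np.ndarray:
        # tied output embedding
        return hidden @ self.wte.W.v.T

    def next_token_log_probs(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        h = self.forward(ids, mask)
        return nn.log_softmax(self.lm_logits(h), axis=-1)


class LmClassifier:
    """Backbone + linear head over the last (left-padded) token."""

    def __init__(self, backbone: TinyCausalLM, seed: int = 0):
        self.backbone = backbone
        rng = np.random.default_rng(seed ^ 0xC1A55)
        self.head = nn.Linear(rng, backbone.spec.hidden_size, 2)

    # -- state management ---------------------------------------------------
    def params(self) -> list[tuple[str, nn.Param]]:
        return self.backbone.params() + [(f"head.{n}", p) for n, p in self.head.params()]

    def clone(self) -> "LmClassifier":
        other = copy.copy(self)
        other.backbone = copy.copy(self.backbone)
        other.backbone.blocks = [copy.deepcopy(b) for b in self.backbone.blocks]
        other.backbone.wte = copy.deepcopy(self.backbone.wte)
        other.backbone.wpe = copy.deepcopy(self.backbone.wpe)
        other.backbone.ln_f = copy.deepcopy(self.backbone.ln_f)
        other.head = copy.deepcopy(self.head)
        return other

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **{n: p.v for n, p in self.params()})
        (directory / "config.json").write_text(
            json.dumps({"backbone": asdict(self.backbone.spec)}, indent=1)
        )
        (directory / "tokenizer.json").write_text(
            json.dumps(self.backbone.tokenizer.to_dict())
        )

    @classmethod
    def load(cls, directory) -> "LmClassifier":
        directory = Path(directory)
        cfg = json.loads((directory / "config.json").read_text())
        tok = WordTokenizer(json.loads((directory / "tokenizer.json").read_text())["vocab"])
        model = cls(TinyCausalLM(BackboneSpec(**cfg["backbone"]), tok))
        with np.load(directory / "weights.npz") as zf:
            for n, p in model.params():
                p.v[...] = zf[n]
        return model

    # -- forward paths ------------------------------------------------------
    def _logits(self, prompts: list[str]) -> np.ndarray:
        ids, mask = encode_batch(prompts, self.backbone.tokenizer, self.backbone.spec.max_length)
        h = self.backbone.forward(ids, mask)
        return self.head(h[:, -1, :])  # last column is always a real token

    def predict_proba(self, prompts: list[PromptText | str], batch_size: int = 32) -> np.ndarray:
        """Positive-class probability per prompt, order-preserving."""
        texts = [p.full_prompt if isinstance(p, PromptText) else p for p in prompts]
        out = []
        for i in range(0, len(texts), batch_size):
            logits = self._logits(texts[i : i + batch_size])
            out.append(nn.softmax(logits, axis=-1)[:, 1])
        return np.concatenate(out)


def finetune(
    model: LmClassifier,
    shots: list[tuple[PromptText | str, int]],
    config: TrainConfig,
    in_place: bool = False,
) -> LmClassifier:
    """Cross-entropy fine-tuning of backbone + head on the shot set.

    Returns a trained copy (the input model is untouched unless ``in_place``),
    after exactly ``config.epochs`` shuffled passes with AdamW. Deterministic
    for a fixed config.seed.
    """
    if not shots:
        raise ValueError("shots must be non-empty; use the zero-shot path for k=0")
    model = model if in_place else model.clone()
    texts = [p.full_prompt if isinstance(p, PromptText) else p for p, _ in shots]
    labels = np.array([y for _, y in shots], dtype=int)
    opt = nn.AdamW(model.params(), lr=config.learning_rate, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    tok, max_len = model.backbone.tokenizer, model.backbone.spec.max_length
    epoch_losses = []
    for _ in range(config.epochs):
        order = rng.permutation(len(texts))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            ids, mask = encode_batch([texts[i] for i in idx], tok, max_len)
            h = model.backbone.forward(ids, mask)
            logits = model.head(h[:, -1, :])
            loss, dlogits = nn.cross_entropy_with_logits(logits, labels[idx])
            losses.append(loss)
            opt.zero_grad()
            dlast = model.head.backward(dlogits)
            dh = np.zeros_like(h)
            dh[:, -1, :] = dlast
            model.backbone.backward(dh)
            opt.step()
        epoch_losses.append(float(np.mean(losses)))
    log.info("finetune: %d shots, epoch losses %s", len(shots), [round(l, 4) for l in epoch_losses])
    model.epoch_losses_ = epoch_losses
    return model


def verbalizer_log_likelihood(
    backbone: TinyCausalLM, prompt_text: str, verbalizer: str
) -> float:
    """Log-likelihood of the verbalizer tokens continuing the prompt."""
    tok = backbone.tokenizer
    prompt_ids = tok.encode(prompt_text)
    verb_ids = tok.encode(" " + verbalizer)
    if not verb_ids:
        raise ValueError(f"verbalizer {verbalizer!r} tokenizes to zero tokens")
    ids = np.array([prompt_ids + verb_ids])
    mask = np.ones_like(ids)
    logp = backbone.next_token_log_probs(ids, mask)[0]
    total = 0.0
    for j, v in enumerate(verb_ids):
        total += float(logp[len(prompt_ids) - 1 + j, v])
    return total


def verbalizer_zero_shot(backbone: TinyCausalLM, prompt: PromptText | str) -> float:
    """Zero-shot positive-class probability from verbalizer likelihoods.

    p = L("Positive") / (L("Positive") + L("Not positive")), with L the
    backbone's sequence likelihood of each verbalizer continuing the prompt.
    """
    if isinstance(prompt, PromptText):
        text, (pos, neg) = prompt.full_prompt, prompt.verbalizers
    else:
        text, (pos, neg) = prompt, ("Positive", "Not positive")
    lp = verbalizer_log_likelihood(backbone, text, pos)
    ln_ = verbalizer_log_likelihood(backbone, text, neg)
    m = max(lp, ln_)
    ep, en = np.exp(lp - m), np.exp(ln_ - m)
    return float(ep / (ep + en))


def _stratified_holdout(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    val_idx: list[int] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        n_val = max(1, int(round(fraction * len(members))))
        val_idx.extend(int(i) for i in rng.choice(members, size=n_val, replace=False))
    val = sorted(val_idx)
    train = sorted(set(range(len(labels))) - set(val))
    return train, val


def train_two_stage(
    common_examples: list[tuple[PromptText | str, int]],
    config: TrainConfig,
    backbone_factory,
    val_fraction: float = 0.2,
) -> LmClassifier:
    """Stage-1 training on common tissues with best-validation checkpointing.

    The common pool is split 80/20 stratified; the model is trained for
    ``config.epochs`` and the epoch-end checkpoint with the best validation
    AUPRC is returned. The result serves directly for zero-shot scoring on
    rare tissues or as the base state for k-shot fine-tuning.
    """
    from .evaluation import auprc  # local import to avoid a cycle

    labels = np.array([y for _, y in common_examples], dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("stage-1 training requires both classes in the common data")
    rng = np.random.default_rng((config.seed ^ 0x2B2B2B) & 0x7FFFFFFF)
    train_idx, val_idx = _stratified_holdout(labels, val_fraction, rng)
    train = [common_examples[i] for i in train_idx]
    val_prompts = [common_examples[i][0] for i in val_idx]
    val_labels = labels[val_idx]
    model: LmClassifier = backbone_factory()
    best, best_score, best_epoch = None, -np.inf, -1
    one_epoch = TrainConfig(
        epochs=1,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        batch_size=config.batch_size,
        seed=config.seed,
    )
    work = model.clone()
    for epoch in range(config.epochs):
        one_epoch.seed = (config.seed + 1000003 * epoch) & 0x7FFFFFFF
        work = finetune(work, train, one_epoch, in_place=True)
        score = auprc(work.predict_proba(val_prompts), val_labels)
        if score > best_score:
            best, best_score, best_epoch = work.clone(), score, epoch
    log.info("stage-1: selected epoch %d (val AUPRC %.4f)", best_epoch, best_score)
    best.selected_epoch_ = best_epoch
    best.val_auprc_ = float(best_score)
    return best


def _ensure_prompt(example) -> str:
    """Serialize a labelled example once, caching the prompt on the example."""
    if example.prompt is None:
        example.prompt = prompt_for_record(example.record).full_prompt
    return example.prompt


class LmFewShotMethod:
    """Few-shot method adapter over the LM classification stack.

    ``two_stage=False`` is the direct path: a backbone fine-tuned only on the
    k shots of the rare tissue, with verbalizer likelihood scoring at k=0
    (``zero_shot="head"`` switches to the untrained head instead).
    ``two_stage=True`` first trains on pooled common-tissue data (stage 1,
    best-validation checkpoint) and fine-tunes that model on the shots; its
    k=0 uses the stage-1 head.

    The tokenizer vocabulary is built from the common-tissue prompt corpus
    plus the verbalizers; rare-tissue words outside it map to ``<unk>``,
    mirroring the unseen-category handling of the tabular baselines.
    """

    def __init__(
        self,
        name: str = "lm",
        two_stage: bool = False,
        backbone_spec: BackboneSpec | None = None,
        train_config: TrainConfig | None = None,
        zero_shot: str = "verbalizer",
        shot_epochs: int | None = None,
    ):
        if zero_shot not in ("verbalizer", "head"):
            raise ValueError("zero_shot must be 'verbalizer' or 'head'")
        self.name = name
        self.two_stage = two_stage
        self.spec = backbone_spec or BackboneSpec()
        self.train_config = train_config or TrainConfig.tiny_backbone_defaults()
        self.zero_shot = zero_shot
        # a randomly initialized backbone needs more k-shot passes than one
        # warmed up on common tissues; None keeps the config's epoch count
        if shot_epochs is None and not two_stage:
            shot_epochs = 4 * self.train_config.epochs
        self.shot_epochs = shot_epochs

    def _fresh(self, tokenizer: WordTokenizer, seed: int) -> LmClassifier:
        return LmClassifier(TinyCausalLM(self.spec, tokenizer, seed=seed), seed=seed)

    def prepare(self, common_examples, seed: int) -> None:
        from dataclasses import replace

        self.seed = seed
        prompts = [_ensure_prompt(e) for e in common_examples]
        self.tokenizer = WordTokenizer.fit(prompts + [" ".join(VERBALIZERS)])
        longest = max((len(self.tokenizer.encode(p)) for p in prompts), default=0)
        if longest + 4 > self.spec.max_length:
            self.spec = replace(self.spec, max_length=longest + 16)
        self.config = replace(self.train_config, seed=seed)
        if self.two_stage:
            pairs = [(p, e.label) for p, e in zip(prompts, common_examples)]
            self.base = train_two_stage(
                pairs, self.config, lambda: self._fresh(self.tokenizer, seed)
            )
        else:
            self.base = self._fresh(self.tokenizer, seed)

    def evaluate_shots(self, shot_examples, test_examples) -> np.ndarray:
        test_prompts = [_ensure_prompt(e) for e in test_examples]
        if shot_examples:
            from dataclasses import replace

            cfg = self.config
            if self.shot_epochs is not None:
                cfg = replace(cfg, epochs=self.shot_epochs)
            shots = [(_ensure_prompt(e), e.label) for e in shot_examples]
            model = finetune(self.base, shots, cfg)
            return model.predict_proba(test_prompts)
        if self.two_stage or self.zero_shot == "head":
            return self.base.predict_proba(test_prompts)
        return np.array(
            [verbalizer_zero_shot(self.base.backbone, p) for p in test_prompts]
        )
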