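"""Tabular baselines sharing the LM classifier's predict-probability contract.

Two models, both trained on pooled common-tissue rows and then k-shot adapted
per rare tissue:

* a gradient-boosted tree ensemble (XGBoost) on one-hot drug / cell-line
  indicators plus the two raw sensitivities — k-shot adaptation is continued
  boosting from the common-tissue ensemble;
* a TabTransformer-style network — learned embeddings for (drug1, drug2,
  cell line) contextualized by multi-head self-attention, concatenated with
  standardized sensitivities and passed through a feed-forward 2-logit head;
  k-shot adaptation is one further epoch at the same learning rate.

Tissue is never a feature: models are tested on a tissue absent from
training, so its indicator would carry no information. Categories unseen at
rare-tissue time encode as an all-zero block (one-hot) or a reserved unknown
embedding (TabTransformer).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, replace

import numpy as np
import xgboost as xgb

from . import nn
from .schema_io import LabeledExample, SynergyRecord

log = logging.getLogger("synergyshot")


# --------------------------------------------------------------------------
# One-hot encoding
# --------------------------------------------------------------------------

@dataclass
class OneHotEncoding:
    """Feature layout [onehot(d1) | onehot(d2) | onehot(cell) | s1 | s2].

    Vocabularies come from common-tissue training data only; unseen
    categories encode as an all-zero block.
    """

    drug_vocabulary: list[str]
    cell_vocabulary: list[str]

    @property
    def n_features(self) -> int:
        return 2 * len(self.drug_vocabulary) + len(self.cell_vocabulary) + 2

    def drug_index(self, name: str) -> int | None:
        return self._drug_idx.get(name)

    def cell_index(self, name: str) -> int | None:
        return self._cell_idx.get(name)

    def __post_init__(self):
        self._drug_idx = {d: i for i, d in enumerate(self.drug_vocabulary)}
        self._cell_idx = {c: i for i, c in enumerate(self.cell_vocabulary)}


def fit_encoding(common_examples: list[LabeledExample]) -> OneHotEncoding:
    if not common_examples:
        raise ValueError("common_examples must be non-empty")
    drugs: dict[str, None] = {}
    cells: dict[str, None] = {}
    for e in common_examples:
        drugs.setdefault(e.record.drug1_name, None)
        drugs.setdefault(e.record.drug2_name, None)
        cells.setdefault(e.record.cell_line_name, None)
    return OneHotEncoding(sorted(drugs), sorted(cells))


def encode(example: LabeledExample | SynergyRecord, enc: OneHotEncoding) -> np.ndarray:
    r = example.record if isinstance(example, LabeledExample) else example
    nd, nc = len(enc.drug_vocabulary), len(enc.cell_vocabulary)
    v = np.zeros(enc.n_features)
    i1, i2, ic = enc.drug_index(r.drug1_name), enc.drug_index(r.drug2_name), enc.cell_index(r.cell_line_name)
    if i1 is not None:
        v[i1] = 1.0
    if i2 is not None:
        v[nd + i2] = 1.0
    if ic is not None:
        v[2 * nd + ic] = 1.0
    v[-2], v[-1] = r.sensitivity1, r.sensitivity2
    return v


def encode_matrix(examples: list[LabeledExample], enc: OneHotEncoding) -> np.ndarray:
    unseen = 0
    X = np.zeros((len(examples), enc.n_features))
    for i, e in enumerate(examples):
        X[i] = encode(e, enc)
        r = e.record
        unseen += sum(
            idx is None
            for idx in (
                enc.drug_index(r.drug1_name),
                enc.drug_index(r.drug2_name),
                enc.cell_index(r.cell_line_name),
            )
        )
    if unseen:
        log.info("encode_matrix: %d unseen-category cells zero-encoded", unseen)
    return X


# --------------------------------------------------------------------------
# Gradient-boosted trees
# --------------------------------------------------------------------------

GBT_PARAMS = {"rate": 0.3, "trees": 1000, "depth": 20}
GBT_SHOT_ROUNDS = 50


def _xgb_params(rate: float, depth: int, seed: int) -> dict:
    return {
        "objective": "binary:logistic",
        "eta": rate,
        "max_depth": depth,
        "tree_method": "hist",
        "seed": seed & 0x7FFFFFFF,
        "nthread": 1,
        "verbosity": 0,
    }


def train_gbt(
    features: np.ndarray,
    labels: np.ndarray,
    rate: float = GBT_PARAMS["rate"],
    trees: int = GBT_PARAMS["trees"],
    depth: int = GBT_PARAMS["depth"],
    seed: int = 0,
) -> xgb.Booster:
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("training labels contain a single class")
    dtrain = xgb.DMatrix(np.asarray(features), label=labels)
    return xgb.train(_xgb_params(rate, depth, seed), dtrain, num_boost_round=trees)


def gbt_shot_update(
    booster: xgb.Booster,
    shot_features: np.ndarray,
    shot_labels: np.ndarray,
    rounds: int = GBT_SHOT_ROUNDS,
    rate: float = GBT_PARAMS["rate"],
    depth: int = GBT_PARAMS["depth"],
    seed: int = 0,
) -> xgb.Booster:
    """Continued boosting from the common-tissue ensemble on the shot set.

    Trees admit no gradient fine-tuning, so the few-shot update adds boosting
    rounds fit on the shots while the input ensemble is left untouched. With
    zero shots the ensemble is returned unchanged.
    """
    if len(shot_labels) == 0:
        return booster
    base = copy.copy(booster)
    dshots = xgb.DMatrix(np.asarray(shot_features), label=np.asarray(shot_labels, dtype=int))
    return xgb.train(_xgb_params(rate, depth, seed), dshots, num_boost_round=rounds, xgb_model=base)


def gbt_predict_proba(booster: xgb.Booster, features: np.ndarray) -> np.ndarray:
    return booster.predict(xgb.DMatrix(np.asarray(features)))


class GbtFewShotMethod:
    """XGBoost few-shot method: common-tissue training + continued boosting.

    ``retrain_from_scratch`` instead refits the ensemble on common + shots at
    every k, the alternative reading of tabular "fine-tuning".
    """

    def __init__(self, name: str = "xgb", retrain_from_scratch: bool = False, **params):
        self.name = name
        self.retrain = retrain_from_scratch
        self.params = {**GBT_PARAMS, **params}

    def prepare(self, common_examples: list[LabeledExample], seed: int) -> None:
        self.seed = seed
        self.enc = fit_encoding(common_examples)
        self.common = common_examples
        X = encode_matrix(common_examples, self.enc)
        y = np.array([e.label for e in common_examples])
        self.base = train_gbt(
            X, y, self.params["rate"], self.params["trees"], self.params["depth"], seed
        )

    def evaluate_shots(self, shot_examples, test_examples) -> np.ndarray:
        Xt = encode_matrix(test_examples, self.enc)
        if not shot_examples:
            return gbt_predict_proba(self.base, Xt)
        Xs = encode_matrix(shot_examples, self.enc)
        ys = np.array([e.label for e in shot_examples])
        if self.retrain:
            Xc = encode_matrix(self.common, self.enc)
            yc = np.array([e.label for e in self.common])
            model = train_gbt(
                np.vstack([Xc, Xs]), np.concatenate([yc, ys]),
                self.params["rate"], self.params["trees"], self.params["depth"], self.seed,
            )
        else:
            model = gbt_shot_update(
                self.base, Xs, ys,
                rate=self.params["rate"], depth=self.params["depth"], seed=self.seed,
            )
        return gbt_predict_proba(model, Xt)


# --------------------------------------------------------------------------
# TabTransformer
# --------------------------------------------------------------------------

@dataclass
class TabTransformerConfig:
    embed_dim: int = 32
    attention_layers: int = 6
    head_count: int = 8
    ff_hidden: int = 64
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    common_epochs: int = 50
    shot_epochs: int = 1
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.head_count:
            raise ValueError("embed_dim must be divisible by head_count")
        for f in ("embed_dim", "attention_layers", "head_count", "ff_hidden",
                  "common_epochs", "shot_epochs", "batch_size"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")


class TabTransformer:
    """Attention over three categorical tokens, then a feed-forward head.

    Token = shared drug embedding (slots 1 and 2) or cell embedding, plus a
    slot embedding; index 0 of each table is the reserved unknown token for
    categories absent from the common-tissue vocabularies. Sensitivities are
    standardized with common-tissue moments before concatenation.
    """

    def __init__(self, enc: OneHotEncoding, config: TabTransformerConfig):
        self.enc = enc
        self.config = config
        rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
        e = config.embed_dim
        self.drug_emb = nn.Embedding(rng, len(enc.drug_vocabulary) + 1, e)
        self.cell_emb = nn.Embedding(rng, len(enc.cell_vocabulary) + 1, e)
        self.slot_emb = nn.Embedding(rng, 3, e)
        self.blocks = [
            nn.TransformerBlock(rng, e, config.head_count, mlp_hidden=2 * e)
            for _ in range(config.attention_layers)
        ]
        self.fc = nn.Linear(rng, 3 * e + 2, config.ff_hidden)
        self.out = nn.Linear(rng, config.ff_hidden, 2)
        self.cont_mean = np.zeros(2)
        self.cont_std = np.ones(2)

    def params(self) -> list[tuple[str, nn.Param]]:
        named = [
            ("drug_emb.W", self.drug_emb.W),
            ("cell_emb.W", self.cell_emb.W),
            ("slot_emb.W", self.slot_emb.W),
        ]
        for i, b in enumerate(self.blocks):
            named += [(f"h{i}.{n}", p) for n, p in b.params()]
        named += [(f"fc.{n}", p) for n, p in self.fc.params()]
        named += [(f"out.{n}", p) for n, p in self.out.params()]
        return named

    def clone(self) -> "TabTransformer":
        other = copy.copy(self)
        for attr in ("drug_emb", "cell_emb", "slot_emb", "fc", "out"):
            setattr(other, attr, copy.deepcopy(getattr(self, attr)))
        other.blocks = [copy.deepcopy(b) for b in self.blocks]
        return other

    def _ids(self, examples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        def shift(idx: int | None) -> int:
            return 0 if idx is None else idx + 1  # 0 = unknown token

        d1 = np.array([shift(self.enc.drug_index(e.record.drug1_name)) for e in examples])
        d2 = np.array([shift(self.enc.drug_index(e.record.drug2_name)) for e in examples])
        c = np.array([shift(self.enc.cell_index(e.record.cell_line_name)) for e in examples])
        return d1, d2, c

    def _continuous(self, examples) -> np.ndarray:
        s = np.array([[e.record.sensitivity1, e.record.sensitivity2] for e in examples])
        return (s - self.cont_mean) / self.cont_std

    def forward(self, examples) -> np.ndarray:
        d1, d2, c = self._ids(examples)
        B = len(examples)
        slots = np.broadcast_to(np.arange(3), (B, 3))
        x = np.stack(
            [self.drug_emb.W.v[d1], self.drug_emb.W.v[d2], self.cell_emb.W.v[c]], axis=1
        ) + self.slot_emb(slots)
        self._cat_ids = (d1, d2, c)
        bias = np.zeros((1, 1, 3, 3))
        for b in self.blocks:
            x = b(x, bias)
        self._ctx_shape = x.shape
        flat = x.reshape(B, -1)
        cont = self._continuous(examples)
        h = np.concatenate([flat, cont], axis=1)
        self._pre = None
        z = self.fc(h)
        self._fc_pre = z
        return self.out(nn.gelu(z))

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.out.backward(dlogits) * nn.gelu_grad(self._fc_pre)
        dh = self.fc.backward(dz)
        B, T, e = self._ctx_shape
        dflat = dh[:, : 3 * e].reshape(B, T, e)
        for b in reversed(self.blocks):
            dflat = b.backward(dflat)
        d1, d2, c = self._cat_ids
        np.add.at(self.drug_emb.W.g, d1, dflat[:, 0, :])
        np.add.at(self.drug_emb.W.g, d2, dflat[:, 1, :])
        np.add.at(self.cell_emb.W.g, c, dflat[:, 2, :])
        self.slot_emb.backward(dflat)

    def save(self, directory) -> None:
        """Checkpoint layout mirrors the LM classifier: weights + JSON config."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "weights.npz",
            **{n: p.v for n, p in self.params()},
            cont_mean=self.cont_mean,
            cont_std=self.cont_std,
        )
        (directory / "config.json").write_text(
            json.dumps(
                {
                    "config": asdict(self.config),
                    "drug_vocabulary": self.enc.drug_vocabulary,
                    "cell_vocabulary": self.enc.cell_vocabulary,
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, directory) -> "TabTransformer":
        import json
        from pathlib import Path

        directory = Path(directory)
        payload = json.loads((directory / "config.json").read_text())
        enc = OneHotEncoding(payload["drug_vocabulary"], payload["cell_vocabulary"])
        model = cls(enc, TabTransformerConfig(**payload["config"]))
        with np.load(directory / "weights.npz") as zf:
            for n, p in model.params():
                p.v[...] = zf[n]
            model.cont_mean = zf["cont_mean"]
            model.cont_std = zf["cont_std"]
        return model

    def predict_proba(self, examples, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(examples), batch_size):
            logits = self.forward(examples[i : i + batch_size])
            out.append(nn.softmax(logits, axis=-1)[:, 1])
        return np.concatenate(out)


def _train_epochs(
    model: TabTransformer,
    examples: list[LabeledExample],
    epochs: int,
    config: TabTransformerConfig,
    rng: np.random.Generator,
) -> None:
    labels = np.array([e.label for e in examples])
    opt = nn.AdamW(model.params(), lr=config.learning_rate, weight_decay=config.weight_decay)
    for _ in range(epochs):
        order = rng.permutation(len(examples))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [examples[i] for i in idx]
            logits = model.forward(batch)
            _, dlogits = nn.cross_entropy_with_logits(logits, labels[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()


def train_tabtransformer(
    common_examples: list[LabeledExample],
    config: TabTransformerConfig,
    val_fraction: float = 0.2,
) -> TabTransformer:
    """Common-tissue training with best-validation-AUPRC checkpointing."""
    from .evaluation import auprc
    from .lm_classifier import _stratified_holdout

    labels = np.array([e.label for e in common_examples])
    if labels.min() == labels.max():
        raise ValueError("common data contains a single class")
    rng = np.random.default_rng((config.seed ^ 0x7AB7AB) & 0x7FFFFFFF)
    train_idx, val_idx = _stratified_holdout(labels, val_fraction, rng)
    train = [common_examples[i] for i in train_idx]
    val = [common_examples[i] for i in val_idx]
    val_labels = labels[val_idx]
    enc = fit_encoding(common_examples)
    model = TabTransformer(enc, config)
    s = np.array([[e.record.sensitivity1, e.record.sensitivity2] for e in train])
    model.cont_mean = s.mean(axis=0)
    model.cont_std = np.where(s.std(axis=0) > 0, s.std(axis=0), 1.0)
    best, best_score, best_epoch = None, -np.inf, -1
    for epoch in range(config.common_epochs):
        _train_epochs(model, train, 1, config, rng)
        score = auprc(model.predict_proba(val), val_labels)
        if score > best_score:
            best, best_score, best_epoch = model.clone(), score, epoch
    log.info("tabtransformer: selected epoch %d (val AUPRC %.4f)", best_epoch, best_score)
    best.selected_epoch_ = best_epoch
    best.val_auprc_ = float(best_score)
    return best


def tt_shot_finetune(
    model: TabTransformer, shots: list[LabeledExample], config: TabTransformerConfig
) -> TabTransformer:
    """One-epoch (by default) fine-tune on the shot set; base left untouched."""
    if not shots:
        return model
    tuned = model.clone()
    rng = np.random.default_rng((config.seed ^ 0x517357) & 0x7FFFFFFF)
    _train_epochs(tuned, shots, config.shot_epochs, config, rng)
    return tuned


def tt_predict_proba(model: TabTransformer, examples: list[LabeledExample]) -> np.ndarray:
    return model.predict_proba(examples)


class TabTransformerFewShotMethod:
    def __init__(self, name: str = "tabtransformer", config: TabTransformerConfig | None = None):
        self.name = name
        self.config = config or TabTransformerConfig()

    def prepare(self, common_examples: list[LabeledExample], seed: int) -> None:
        self.cfg = replace(self.config, seed=seed)
        self.base = train_tabtransformer(common_examples, self.cfg)

    def evaluate_shots(self, shot_examples, test_examples) -> np.ndarray:
        model = tt_shot_finetune(self.base, shot_examples, self.cfg)
        return tt_predict_proba(model, test_examples)


def export_design_matrix(
    examples: list[LabeledExample], enc: OneHotEncoding, path, delimiter: str = "\t"
) -> None:
    """Dump the dense one-hot design matrix with a header row, for debugging."""
    header = (
        [f"d1={d}" for d in enc.drug_vocabulary]
        + [f"d2={d}" for d in enc.drug_vocabulary]
        + [f"cell={c}" for c in enc.cell_vocabulary]
        + ["sensitivity1", "sensitivity2", "label"]
    )
    X = encode_matrix(examples, enc)
    y = np.array([[e.label] for e in examples])
    body = np.hstack([X, y])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(header) + "\n")
        for row in body:
            fh.write(delimiter.join(format(v, "g") for v in row) + "\n")
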