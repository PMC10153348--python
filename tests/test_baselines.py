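import numpy as np
import pytest

from synergyshot import (
    LabeledExample,
    SynergyRecord,
    TabTransformerConfig,
    auroc,
    encode,
    encode_matrix,
    fit_encoding,
    gbt_predict_proba,
    gbt_shot_update,
    train_gbt,
    train_tabtransformer,
    tt_predict_proba,
    tt_shot_finetune,
)
from synergyshot.baselines import GbtFewShotMethod, TabTransformerFewShotMethod
from .conftest import make_examples


def _ex(d1, d2, cell, s1=0.5, s2=1.0, label=0, tissue="lung"):
    return LabeledExample(
        SynergyRecord(d1, d2, cell, tissue, s1, s2, 20.0 if label else -10.0), label
    )


class TestOneHotEncoding:
    def test_definitional_layout(self):
        enc = fit_encoding([_ex("A", "B", "X"), _ex("B", "A", "X")])
        v = encode(_ex("A", "B", "X", 0.5, 1.0), enc)
        assert v.tolist() == [1, 0, 0, 1, 1, 0.5, 1.0]

    def test_unseen_drug_zero_block(self):
        enc = fit_encoding([_ex("A", "B", "X")])
        v = encode(_ex("C", "B", "X"), enc)
        assert v[: len(enc.drug_vocabulary)].sum() == 0
        assert v[len(enc.drug_vocabulary) : 2 * len(enc.drug_vocabulary)].sum() == 1

    def test_block_sums_on_random_examples(self):
        common = make_examples(100, 0.2, seed=1, tissue="lung")
        enc = fit_encoding(common)
        rare = make_examples(200, 0.2, seed=9, tissue="bone")
        X = encode_matrix(rare, enc)
        nd, nc = len(enc.drug_vocabulary), len(enc.cell_vocabulary)
        for block in (X[:, :nd], X[:, nd : 2 * nd], X[:, 2 * nd : 2 * nd + nc]):
            sums = block.sum(axis=1)
            assert set(np.unique(sums)) <= {0.0, 1.0}

    def test_row_order_invariance(self):
        common = make_examples(50, 0.3, seed=2, tissue="lung")
        enc = fit_encoding(common)
        X = encode_matrix(common, enc)
        perm = np.random.default_rng(0).permutation(len(common))
        Xp = encode_matrix([common[i] for i in perm], enc)
        np.testing.assert_array_equal(X[perm], Xp)


class TestGbt:
    def test_separable_training_auroc_is_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 2))
        y = (X[:, 0] > 0).astype(int)
        booster = train_gbt(X, y, trees=20, depth=3, seed=0)
        assert auroc(gbt_predict_proba(booster, X), y) == 1.0

    def test_zero_shots_leave_scorer_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        booster = train_gbt(X, y, trees=10, depth=3, seed=0)
        same = gbt_shot_update(booster, np.empty((0, 3)), np.empty(0))
        np.testing.assert_array_equal(
            gbt_predict_proba(booster, X), gbt_predict_proba(same, X)
        )

    def test_continued_boosting_extends_ensemble(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = (X[:, 1] > 0).astype(int)
        booster = train_gbt(X, y, trees=10, depth=3, seed=0)
        Xs, ys = rng.normal(size=(8, 3)), np.array([0, 1] * 4)
        updated = gbt_shot_update(booster, Xs, ys, rounds=5, depth=3, seed=0)
        assert updated.num_boosted_rounds() == 15
        assert booster.num_boosted_rounds() == 10  # base untouched

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            train_gbt(np.zeros((5, 2)), np.ones(5))

    def test_unseen_cell_lines_ablate_to_zero_block(self):
        # rare-tissue cells never occur in common data: their one-hot block
        # is all zero, so zeroing it explicitly cannot change predictions
        common = make_examples(300, 0.2, seed=3, tissue="lung")
        method = GbtFewShotMethod()
        method.params.update(trees=30, depth=4)
        method.prepare(common, seed=0)
        rare = make_examples(40, 0.25, seed=4, tissue="bone")
        X = encode_matrix(rare, method.enc)
        nd, nc = len(method.enc.drug_vocabulary), len(method.enc.cell_vocabulary)
        assert X[:, 2 * nd : 2 * nd + nc].sum() == 0
        X_zeroed = X.copy()
        X_zeroed[:, 2 * nd : 2 * nd + nc] = 0
        np.testing.assert_array_equal(
            gbt_predict_proba(method.base, X), gbt_predict_proba(method.base, X_zeroed)
        )


@pytest.fixture(scope="module")
def tt_setup():
    common = make_examples(200, 0.25, seed=6, tissue="lung")
    cfg = TabTransformerConfig(
        embed_dim=16, attention_layers=2, head_count=4, ff_hidden=32,
        learning_rate=1e-3, common_epochs=4, seed=11,
    )
    return common, cfg


class TestTabTransformer:
    def test_untrained_scores_are_probabilities(self, tt_setup):
        common, cfg = tt_setup
        from synergyshot.baselines import TabTransformer, fit_encoding

        model = TabTransformer(fit_encoding(common), cfg)
        scores = model.predict_proba(common[:16])
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_checkpoint_selection_deterministic_per_seed(self, tt_setup):
        common, cfg = tt_setup
        a = train_tabtransformer(common, cfg)
        b = train_tabtransformer(common, cfg)
        assert a.selected_epoch_ == b.selected_epoch_
        np.testing.assert_array_equal(
            tt_predict_proba(a, common[:20]), tt_predict_proba(b, common[:20])
        )

    def test_shot_finetune_returns_new_model(self, tt_setup):
        common, cfg = tt_setup
        model = train_tabtransformer(common, cfg)
        before = tt_predict_proba(model, common[:10]).copy()
        shots = make_examples(8, 0.5, seed=7, tissue="bone")
        tuned = tt_shot_finetune(model, shots, cfg)
        np.testing.assert_array_equal(tt_predict_proba(model, common[:10]), before)
        assert tuned is not model

    def test_zero_shots_return_base(self, tt_setup):
        common, cfg = tt_setup
        model = train_tabtransformer(common, cfg)
        assert tt_shot_finetune(model, [], cfg) is model

    def test_single_class_common_rejected(self, tt_setup):
        _, cfg = tt_setup
        with pytest.raises(ValueError):
            train_tabtransformer(make_examples(20, 0.0, tissue="lung"), cfg)

    def test_save_load_round_trip(self, tt_setup, tmp_path):
        common, cfg = tt_setup
        from synergyshot.baselines import TabTransformer

        model = train_tabtransformer(common, cfg)
        model.save(tmp_path / "ckpt")
        back = TabTransformer.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(
            tt_predict_proba(model, common[:20]), tt_predict_proba(back, common[:20])
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TabTransformerConfig(embed_dim=30, head_count=8)
        with pytest.raises(ValueError):
            TabTransformerConfig(common_epochs=0)


def test_method_adapters_share_predict_contract():
    """Both baselines expose prepare/evaluate_shots and emit [0,1] scores."""
    common = make_examples(150, 0.25, seed=8, tissue="lung")
    rare = make_examples(30, 0.3, seed=9, tissue="bone")
    shots, test = rare[:6], rare[6:]
    gbt = GbtFewShotMethod()
    gbt.params.update(trees=20, depth=3)
    tt = TabTransformerFewShotMethod(
        config=TabTransformerConfig(embed_dim=8, attention_layers=1, head_count=2,
                                    ff_hidden=16, common_epochs=2)
    )
    for method in (gbt, tt):
        method.prepare(common, seed=0)
        scores = method.evaluate_shots(shots, test)
        assert scores.shape == (len(test),)
        assert ((scores >= 0) & (scores <= 1)).all()


@pytest.mark.timeout(300)
def test_baselines_transfer_above_null_with_shared_pair_effects():
    """Trained only on common tissues whose drug-pair effects are shared with
    the rare tissue, both tabular baselines rank the rare test set above the
    95% permutation band at k=0 — the cross-tissue transfer premise."""
    from synergyshot import (
        generate,
        label_records,
        make_tissue_split,
        permutation_null_band,
        preset,
    )

    aurocs: dict[str, list[float]] = {}
    band_highs = []
    for seed in range(3):
        cfg = preset("strong_signal")
        cfg.seed = 100 + seed
        records, _ = generate(cfg)
        ex = {}
        for e in label_records(records):
            ex.setdefault(e.record.tissue_name, []).append(e)
        common = [e for t in ("lung", "breast") for e in ex[t]]
        rare = ex["bone"]
        split = make_tissue_split(rare, 0.2, seed=seed, tissue_name="bone")
        test = [rare[i] for i in split.test_set]
        ylab = np.array([e.label for e in test])
        band_highs.append(permutation_null_band(ylab, n_permutations=1000, seed=0)[1])
        for method in (GbtFewShotMethod(), TabTransformerFewShotMethod()):
            method.prepare(common, seed=seed)
            aurocs.setdefault(method.name, []).append(
                auroc(method.evaluate_shots([], test), ylab)
            )
    for name, vals in aurocs.items():
        assert np.mean(vals) > np.mean(band_highs), (
            f"{name}: mean k=0 AUROC {np.mean(vals):.3f} not above "
            f"mean null band high ({np.mean(band_highs):.3f})"
        )


def test_design_matrix_export(tmp_path):
    from synergyshot.baselines import export_design_matrix

    common = make_examples(30, 0.3, seed=1, tissue="lung")
    enc = fit_encoding(common)
    p = tmp_path / "design.tsv"
    export_design_matrix(common, enc, p)
    lines = p.read_text().splitlines()
    assert len(lines) == 31
    header = lines[0].split("\t")
    assert header[-1] == "label" and header[-3] == "sensitivity1"
    assert len(header) == enc.n_features + 1
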