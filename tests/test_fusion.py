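"""Cross-attention algebra, fusion strategies, toy training and evaluation."""

import warnings

import numpy as np
import pytest

from hemofuse.fusion import (
    CrossAttentionParams,
    FeatureExtractor,
    FusionConfig,
    clinical_text_features,
    cross_attention,
    evaluate,
    fuse,
    load_model,
    save_model,
    train_toy,
)
from hemofuse.metrics import classification_metrics, ConfusionCounts
from hemofuse.synthetic_data import build_manifest

TINY_COUNTS = {
    "train": {s: 4 for s in ("ICH", "SDH", "EDH", "IVH", "SAH")},
    "validation": {s: 1 for s in ("ICH", "SDH", "EDH", "IVH", "SAH")},
    "test": {s: 2 for s in ("ICH", "SDH", "EDH", "IVH", "SAH")},
}

TINY_CONFIG = dict(n_epochs=3, ensemble_size=1, image_embed_dim=16, hidden_dim=16)


@pytest.fixture(scope="module")
def tiny_manifest():
    return build_manifest(TINY_COUNTS, frames_per_case=10, seed=3)


class TestCrossAttention:
    def test_single_key_is_value_passthrough(self, rng):
        params = CrossAttentionParams.seeded(4, 6, 5, seed=0)
        text = rng.normal(size=(3, 4))
        patch = rng.normal(size=(1, 6))
        result = cross_attention(text, patch, params)
        assert np.allclose(result.fused, (patch @ params.wv)[0])
        assert np.allclose(result.weights, 1.0)

    def test_uniform_keys_give_uniform_attention(self, rng):
        params = CrossAttentionParams.seeded(4, 6, 5, seed=1)
        text = rng.normal(size=(3, 4))
        image = np.tile(rng.normal(size=(1, 6)), (7, 1))
        result = cross_attention(text, image, params)
        assert np.allclose(result.weights, 1.0 / 7.0, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        params = CrossAttentionParams.seeded(8, 8, 8, seed=2)
        result = cross_attention(rng.normal(size=(5, 8)), rng.normal(size=(9, 8)), params)
        assert np.allclose(result.weights.sum(axis=1), 1.0, atol=1e-9)

    def test_two_by_two_hand_arithmetic(self):
        params = CrossAttentionParams(wq=np.eye(2), wk=np.eye(2), wv=np.eye(2))
        text = np.array([[1.0, 0.0], [0.0, 1.0]])
        image = np.array([[2.0, 0.0], [0.0, 2.0]])
        result = cross_attention(text, image, params)
        s = np.sqrt(2.0)
        logits = np.array([[2 / s, 0.0], [0.0, 2 / s]])
        expected_w = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert np.allclose(result.weights, expected_w, atol=1e-12)
        assert np.allclose(result.attended, expected_w @ image, atol=1e-12)
        assert np.allclose(result.fused, (expected_w @ image).mean(axis=0), atol=1e-12)

    def test_swapping_identical_modalities_is_symmetric(self, rng):
        w = rng.normal(size=(4, 4))
        params = CrossAttentionParams(wq=w, wk=w, wv=w)
        seq = rng.normal(size=(3, 4))
        a = cross_attention(seq, seq, params)
        b = cross_attention(seq.copy(), seq.copy(), params)
        assert np.allclose(a.fused, b.fused)

    def test_dim_mismatch_rejected(self, rng):
        params = CrossAttentionParams.seeded(4, 6, 5, seed=0)
        with pytest.raises(ValueError):
            cross_attention(rng.normal(size=(3, 5)), rng.normal(size=(2, 6)), params)

    def test_empty_sequence_rejected(self):
        params = CrossAttentionParams.seeded(4, 6, 5, seed=0)
        with pytest.raises(ValueError):
            cross_attention(np.empty((0, 4)), np.ones((2, 6)), params)


class TestClinicalFeatures:
    def test_mention_and_lexicon_counts(self):
        text = (
            "subdural hemorrhage with favorable outcome ; differential includes "
            "extradural hemorrhage and midline shift"
        )
        feats = clinical_text_features(text)
        # order ICH, SDH, EDH, IVH, SAH then pos, neg, neu, EA/100
        assert feats[1] == 1.0 and feats[2] == 1.0
        assert feats[0] == 0.0 and feats[3] == 0.0 and feats[4] == 0.0
        assert feats[5] == 1.0  # favorable outcome
        assert feats[7] == 1.0  # midline shift
        assert 0.0 <= feats[8] <= 1.0


class TestFuse:
    @pytest.fixture(scope="class")
    def extractor_and_feats(self, tiny_manifest):
        config = FusionConfig(seed=1, **TINY_CONFIG)
        ex = FeatureExtractor(config)
        case = tiny_manifest.cases[0]
        return ex, ex.features(case)

    def test_early_vector_length(self, extractor_and_feats):
        ex, feats = extractor_and_feats
        rep = fuse(feats, "early", ex)
        assert rep.vector.shape == (ex.patch_config.patch_size**2 + ex.config.text_embed_dim,)

    def test_joint_vector_composition(self, extractor_and_feats):
        ex, feats = extractor_and_feats
        d = ex.config.image_embed_dim
        rep = fuse(feats, "joint", ex)
        assert rep.vector.shape == (2 * d + 4 * d + 9 + d,)
        assert np.all(np.isfinite(rep.vector))

    def test_unknown_strategy_rejected(self, extractor_and_feats):
        ex, feats = extractor_and_feats
        with pytest.raises(ValueError, match="strategy"):
            fuse(feats, "middle", ex)

    def test_evidence_alignment(self, extractor_and_feats):
        ex, feats = extractor_and_feats
        ev = ex.class_evidence(feats, "subtype")
        assert ev.shape == (5,)
        assert set(np.unique(ev)) <= {0.0, -1.0}
        sent = ex.class_evidence(feats, "prognosis")
        assert sent.shape == (4,) and sent[3] == 0.0


class TestTraining:
    def test_loss_decreases_and_determinism(self, tiny_manifest):
        config = FusionConfig(strategy="joint", seed=5, **TINY_CONFIG)
        model_a, report = train_toy(tiny_manifest, config)
        for name, losses in report.train_loss.items():
            assert losses[-1] <= losses[0]
        model_b, _ = train_toy(tiny_manifest, config)
        for task in model_a.heads:
            for ha, hb in zip(model_a.heads[task], model_b.heads[task]):
                for k, v in ha.state().items():
                    assert np.array_equal(v, hb.state()[k])

    def test_zero_epochs_is_chance_level(self, tiny_manifest):
        config = FusionConfig(strategy="image", seed=2, n_epochs=0,
                              ensemble_size=1, image_embed_dim=16, hidden_dim=16)
        model, _ = train_toy(tiny_manifest, config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = evaluate(model, tiny_manifest, "test")
        assert report.overall["subtype"] <= 0.6  # untrained model near chance (0.2)

    def test_empty_split_rejected(self):
        manifest = build_manifest({"train": {"ICH": 2}}, seed=0)
        with pytest.raises(ValueError, match="validation"):
            train_toy(manifest, FusionConfig(**TINY_CONFIG))

    def test_late_fusion_probabilities_normalized(self, tiny_manifest):
        config = FusionConfig(strategy="late", seed=4, **TINY_CONFIG)
        model, _ = train_toy(tiny_manifest, config)
        proba = model.predict_proba(tiny_manifest.split_cases("test"), "subtype")
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)


class TestEvaluate:
    @pytest.fixture(scope="class")
    def trained(self, tiny_manifest):
        config = FusionConfig(strategy="joint", seed=7, **TINY_CONFIG)
        model, _ = train_toy(tiny_manifest, config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = evaluate(model, tiny_manifest, "test")
        return model, report

    def test_row_structure_mirrors_tasks_by_subtype(self, trained):
        _, report = trained
        assert len(report.table) == 5 * 3  # subtypes x tasks
        assert set(report.table["task"]) == {"subtype", "prognosis", "therapeutic"}

    def test_confusions_conserve_counts(self, trained, tiny_manifest):
        _, report = trained
        n_test = len(tiny_manifest.split_cases("test"))
        for task, matrix in report.confusions.items():
            assert matrix.sum() == n_test

    def test_subtype_rows_recompute_from_confusion(self, trained):
        model, report = trained
        cm = report.confusions["subtype"]
        order = model.class_orders["subtype"]
        for j, subtype in enumerate(order):
            tp = cm[j, j]
            fp = cm[:, j].sum() - tp
            fn = cm[j, :].sum() - tp
            tn = cm.sum() - tp - fp - fn
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = classification_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            row = report.table[(report.table.subtype == subtype)
                               & (report.table.task == "subtype")].iloc[0]
            assert row.accuracy == pytest.approx(m.accuracy, abs=1e-9)
            assert row.precision == pytest.approx(m.precision, abs=1e-9)
            assert row.recall == pytest.approx(m.recall, abs=1e-9)
            assert row.f1 == pytest.approx(m.f1, abs=1e-9)

    def test_perfect_predictions_give_unit_accuracy(self, trained, tiny_manifest):
        model, _ = trained
        cases = tiny_manifest.split_cases("test")
        preds = model.predict(cases, "subtype")
        truths = [c.subtype for c in cases]
        agreement = np.mean([p == t for p, t in zip(preds, truths)])
        report_overall = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report_overall = evaluate(model, tiny_manifest, "test").overall["subtype"]
        assert report_overall == pytest.approx(agreement)


class TestPersistence:
    def test_save_load_roundtrip_predictions(self, tiny_manifest, tmp_path):
        config = FusionConfig(strategy="joint", seed=11, **TINY_CONFIG)
        model, _ = train_toy(tiny_manifest, config)
        save_model(model, tmp_path / "model.npz")
        loaded = load_model(tmp_path / "model.npz")
        cases = tiny_manifest.split_cases("test")
        for task in ("subtype", "prognosis", "therapeutic"):
            assert np.allclose(
                model.predict_proba(cases, task), loaded.predict_proba(cases, task)
            )

    def test_save_load_late_strategy(self, tiny_manifest, tmp_path):
        config = FusionConfig(strategy="late", seed=13, **TINY_CONFIG)
        model, _ = train_toy(tiny_manifest, config)
        save_model(model, tmp_path / "late.npz")
        loaded = load_model(tmp_path / "late.npz")
        cases = tiny_manifest.split_cases("test")[:3]
        assert np.allclose(
            model.predict_proba(cases, "subtype"), loaded.predict_proba(cases, "subtype")
        )
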