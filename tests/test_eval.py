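"""Metrics, aggregation, probe and latent diagnostics against oracles."""

import numpy as np
import pandas as pd
import pytest

from salr.corpus import build_loso_folds
from salr.encoder import EmbeddingBatch, EncoderConfig, init_params
from salr.evaluate import (
    FoldResult,
    aggregate_loso,
    confusion_counts,
    evaluate_fold,
    export_embeddings,
    latent_distance_ratio,
    load_embeddings,
    macro_f1,
    normalise_confusion,
    probe_speaker_identity,
)


def _fold_result(truths, preds, speaker="S1"):
    n = len(truths)
    return FoldResult(speaker, [f"u{i}" for i in range(n)], np.array(truths), np.array(preds))


class TestFoldMetrics:
    def test_all_correct_gives_diagonal_confusion(self):
        r = _fold_result([0, 1, 2, 3, 3], [0, 1, 2, 3, 3])
        assert r.speaker_accuracy == 1.0
        counts = r.confusion
        assert counts.sum() == 5
        assert np.all(counts == np.diag(np.diag(counts)))

    def test_constant_prediction_accuracy_is_class_fraction(self):
        truths = [0, 0, 2, 2, 2, 3, 1, 2, 2, 0]
        r = _fold_result(truths, [2] * 10)
        assert r.speaker_accuracy == truths.count(2) / 10

    def test_confusion_matches_manual_tally(self):
        truths = [0, 0, 1, 1, 2, 2, 3, 3, 0, 1]
        preds = [0, 1, 1, 1, 3, 2, 3, 0, 0, 2]
        counts = confusion_counts(truths, preds)
        manual = np.zeros((4, 4), dtype=int)
        for t, p in zip(truths, preds):
            manual[t, p] += 1
        np.testing.assert_array_equal(counts, manual)

    def test_metrics_match_sklearn_on_random_sets(self):
        """Accuracy/per-class F1/macro-F1/normalised confusion vs sklearn, 20x."""
        from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            truths = rng.integers(0, 4, size=n)
            preds = rng.integers(0, 4, size=n)
            r = _fold_result(truths, preds)
            assert r.speaker_accuracy == pytest.approx(accuracy_score(truths, preds))
            counts = confusion_counts(truths, preds)
            np.testing.assert_array_equal(
                counts, confusion_matrix(truths, preds, labels=[0, 1, 2, 3])
            )
            present = sorted(set(truths) | set(preds))
            expected_f1 = f1_score(
                truths, preds, labels=present, average="macro", zero_division=0
            )
            assert macro_f1(counts) == pytest.approx(expected_f1)
            norm = normalise_confusion(counts)
            sums = counts.sum(axis=1)
            for i in range(4):
                if sums[i]:
                    assert norm[i].sum() == pytest.approx(1.0, abs=1e-9)
                else:
                    assert norm[i].sum() == 0.0


class TestAggregation:
    def test_single_repeat_two_speakers(self):
        rep = [_fold_result([0, 0], [0, 0], "A"), _fold_result([1, 1], [0, 2], "B")]
        report = aggregate_loso([rep])
        assert report.overall_accuracy == 0.5
        assert report.overall_accuracy_sd == 0.0
        assert report.single_repeat

    def test_perfect_predictions_macro_f1_is_one(self):
        rep = [
            _fold_result([0, 1], [0, 1], "A"),
            _fold_result([2, 3], [2, 3], "B"),
        ]
        report = aggregate_loso([rep])
        assert report.macro_f1_mean == 1.0

    def test_two_class_pooled_f1_matches_hand_computation(self):
        # pooled confusion [[5,1],[2,4]] over classes {0,1}; classes 2,3 empty
        truths = [0] * 6 + [1] * 6
        preds = [0] * 5 + [1] + [0] * 2 + [1] * 4
        rep = [_fold_result(truths, preds, "A")]
        report = aggregate_loso([rep])
        f1_0 = 2 * 5 / (2 * 5 + 1 + 2)  # tp=5, fn=1, fp=2
        f1_1 = 2 * 4 / (2 * 4 + 2 + 1)
        assert report.macro_f1_mean == pytest.approx((f1_0 + f1_1) / 2)

    def test_mean_and_sd_across_repeats(self):
        reps = [
            [_fold_result([0, 0], [0, 0], "A"), _fold_result([1], [1], "B")],
            [_fold_result([0, 0], [0, 1], "A"), _fold_result([1], [1], "B")],
        ]
        report = aggregate_loso(reps)
        row = report.per_speaker.set_index("speaker").loc["A"]
        assert row.mean_accuracy == pytest.approx(0.75)
        assert row.sd_accuracy == pytest.approx(np.std([1.0, 0.5], ddof=1))
        assert report.overall_accuracy == pytest.approx((1.0 + 0.75) / 2)

    def test_missing_fold_raises(self):
        reps = [
            [_fold_result([0], [0], "A"), _fold_result([1], [1], "B")],
            [_fold_result([0], [0], "A")],
        ]
        with pytest.raises(ValueError, match="missing"):
            aggregate_loso(reps)


def _embedding_batch(vectors, speakers, words=None, severities=None):
    n = len(speakers)
    meta = pd.DataFrame(
        {
            "utterance_id": [f"u{i}" for i in range(n)],
            "speaker_id": speakers,
            "word_id": words if words is not None else [f"w{i}" for i in range(n)],
            "severity": severities if severities is not None else [0] * n,
        }
    )
    return EmbeddingBatch(np.asarray(vectors, dtype=float), meta)


class TestSpeakerProbe:
    def test_uninformative_embeddings_probe_at_chance(self):
        emb = _embedding_batch(
            np.ones((40, 3)), [f"S{i % 4}" for i in range(40)]
        )
        res = probe_speaker_identity(emb, split_seed=1)
        assert res.chance_level == 0.25
        assert abs(res.accuracy - res.chance_level) < 0.3

    def test_one_hot_speaker_codes_probe_perfectly(self):
        speakers = [f"S{i % 4}" for i in range(40)]
        vec = np.eye(4)[[int(s[1]) for s in speakers]]
        res = probe_speaker_identity(_embedding_batch(vec, speakers), split_seed=1)
        assert res.accuracy == 1.0

    def test_severity_only_codes_cap_below_one(self):
        # speakers within a severity class share identical embeddings, so the
        # probe cannot exceed the within-class collision bound
        speakers = [f"S{i % 4}" for i in range(80)]
        sev_of = {"S0": 0, "S1": 0, "S2": 1, "S3": 1}  # 2 speakers per class
        vec = np.eye(2)[[sev_of[s] for s in speakers]]
        res = probe_speaker_identity(_embedding_batch(vec, speakers), split_seed=1)
        assert res.accuracy < 1.0
        assert res.accuracy <= 0.5 + 0.2  # collision rate 1/2 plus slack

    def test_single_utterance_speaker_rejected(self):
        emb = _embedding_batch(np.ones((3, 2)), ["A", "A", "B"])
        with pytest.raises(ValueError, match="single utterance"):
            probe_speaker_identity(emb)


class TestLatentDiagnostics:
    def _triplet_metadata(self):
        # two same-severity speakers, two shared words
        return dict(
            speakers=["S1", "S1", "S2", "S2"],
            words=["w1", "w2", "w1", "w2"],
            severities=[1, 1, 1, 1],
        )

    def test_identical_embeddings_flagged_undefined(self):
        emb = _embedding_batch(np.ones((4, 3)), **self._triplet_metadata())
        diag = latent_distance_ratio(emb, rng_seed=0)
        assert diag.d1_mean == 0.0 and diag.d2_mean == 0.0
        assert diag.ratio is None

    def test_speaker_one_hot_geometry(self):
        # embeddings = speaker one-hots: d1 = 0 (same speaker), d2 = sqrt(2)
        md = self._triplet_metadata()
        vec = np.eye(2)[[0, 0, 1, 1]]
        diag = latent_distance_ratio(_embedding_batch(vec, **md), rng_seed=0)
        assert diag.d1_mean == pytest.approx(0.0)
        assert diag.d2_mean == pytest.approx(np.sqrt(2.0))
        assert diag.ratio == pytest.approx(0.0)

    def test_word_one_hot_geometry(self):
        # embeddings = word one-hots: the anchor (word A) is sqrt(2) from both
        # the negative (word B, same speaker) and the positive (word B, other
        # speaker), so d1 = d2 = sqrt(2) and the ratio is exactly 1 — the
        # speaker-agnostic ideal
        md = self._triplet_metadata()
        vec = np.eye(2)[[0, 1, 0, 1]]
        diag = latent_distance_ratio(_embedding_batch(vec, **md), rng_seed=0)
        assert diag.d1_mean == pytest.approx(np.sqrt(2.0))
        assert diag.d2_mean == pytest.approx(np.sqrt(2.0))
        assert diag.ratio == pytest.approx(1.0)

    def test_no_valid_triplet_raises_with_guidance(self):
        emb = _embedding_batch(
            np.ones((2, 2)), ["S1", "S2"], words=["w1", "w2"], severities=[0, 1]
        )
        with pytest.raises(ValueError, match="no valid triplet"):
            latent_distance_ratio(emb)


class TestEmbeddingExport:
    def test_shape_and_round_trip(self, tmp_path):
        emb = _embedding_batch(
            np.arange(6.0).reshape(3, 2), ["A", "B", "C"], severities=[0, 1, 2]
        )
        path = export_embeddings(emb, tmp_path / "emb.csv")
        df = pd.read_csv(path)
        assert df.shape == (3, 5)  # id, speaker, severity, e0, e1
        loaded = load_embeddings(path)
        np.testing.assert_allclose(loaded.vectors, emb.vectors)

    def test_empty_batch_writes_header_only(self, tmp_path):
        emb = EmbeddingBatch(
            np.empty((0, 2)),
            pd.DataFrame(columns=["utterance_id", "speaker_id", "severity"]),
        )
        path = export_embeddings(emb, tmp_path / "empty.csv")
        assert len(path.read_text().strip().splitlines()) == 1


class TestEvaluateFold:
    def test_predictions_align_with_truths(self, small_corpus):
        config, manifest, store = small_corpus
        fold = build_loso_folds(manifest)[0]
        enc = EncoderConfig(input_dim=config.feature_dim, hidden_dim=8,
                            embedding_dim=8, head_hidden=8)
        params = init_params(enc, 0)
        result = evaluate_fold(params, fold, manifest, store, enc)
        assert len(result.truths) == len(fold.test_utterances)
        by_utt = manifest.by_utterance()
        expected = [int(by_utt[u].severity) for u in fold.test_utterances]
        np.testing.assert_array_equal(result.truths, expected)
        assert set(result.preds) <= {0, 1, 2, 3}
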