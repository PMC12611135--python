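"""Model/Results objects presenting the training + evaluation pipeline.

``SeverityModel`` is constructed from data (a corpus manifest, its signal
store and one leave-one-subject-out fold); ``fit()`` runs the optimisation
and returns a ``SeverityResults`` carrying the trained parameters, the
training log, held-out predictions and the latent-space diagnostics, with a
``summary()`` table.  ``loso()`` repeats the fit over every fold (and over
independent repeats) and aggregates into an ``EvalReport``.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import CorpusManifest, FoldSpec, build_loso_folds
from .encoder import (
    EmbeddingBatch,
    EncoderConfig,
    forward_embed,
    init_params,
    load_params,
    save_params,
)
from .evaluate import (
    EvalReport,
    FoldResult,
    LatentDiagnostics,
    ProbeResult,
    aggregate_loso,
    evaluate_fold,
    latent_distance_ratio,
    probe_speaker_identity,
)
from .synth import SignalStore, load_corpus
from .train import TrainConfig, train
from ._utils import derive_seed

logger = logging.getLogger(__name__)

__all__ = ["SeverityModel", "SeverityResults", "loso"]


class SeverityModel:
    """Severity classifier for one training fold of a corpus.

    Parameters
    ----------
    manifest, signals
        The corpus and its signal store.
    fold
        The leave-one-subject-out fold to train on.  ``None`` trains on all
        utterances (no held-out evaluation available).
    encoder_config, train_config
        Architecture and optimisation settings; sensible small defaults.
    """

    def __init__(
        self,
        manifest: CorpusManifest,
        signals: SignalStore,
        fold: FoldSpec | None = None,
        encoder_config: EncoderConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.manifest = manifest
        self.signals = signals
        if fold is None:
            ids = tuple(r.utterance_id for r in manifest.records)
            fold = FoldSpec(
                held_out_speaker="",
                train_utterances=ids,
                test_utterances=(),
                test_mode="all_words",
            )
        self.fold = fold
        if encoder_config is None:
            encoder_config = EncoderConfig(
                input_mode=signals.mode,
                input_dim=(
                    signals[manifest.records[0].utterance_id].shape[0]
                    if signals.mode == "feature"
                    else 64
                ),
            )
        self.encoder_config = encoder_config
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_corpus(cls, corpus_dir: str | Path, fold: FoldSpec | None = None,
                    **kwargs) -> "SeverityModel":
        manifest, signals = load_corpus(corpus_dir)
        return cls(manifest, signals, fold=fold, **kwargs)

    def fit(self, init_seed: int | None = None) -> "SeverityResults":
        """Train encoder + head on the fold's training utterances."""
        seed = self.train_config.seed if init_seed is None else init_seed
        params = init_params(self.encoder_config, init_seed=derive_seed(seed, "init"))
        params, log = train(
            params,
            self.fold,
            self.manifest,
            self.signals,
            self.encoder_config,
            self.train_config,
        )
        return SeverityResults(self, params, log)


class SeverityResults:
    """Fitted parameters plus evaluation and diagnostic views."""

    def __init__(self, model: SeverityModel, params: dict, train_log: pd.DataFrame):
        self.model = model
        self.params = params
        self.train_log = train_log

    # -- prediction / evaluation ------------------------------------------

    def evaluate(self) -> FoldResult:
        """Held-out-speaker predictions and accuracy for the model's fold."""
        return evaluate_fold(
            self.params,
            self.model.fold,
            self.model.manifest,
            self.model.signals,
            self.model.encoder_config,
        )

    def embed(self, utterance_ids=None) -> EmbeddingBatch:
        """Embeddings (with aligned metadata) for the given utterances.

        Defaults to every utterance in the manifest — the pooled view used
        by the probe and distance diagnostics.
        """
        manifest = self.model.manifest
        by_utt = manifest.by_utterance()
        if utterance_ids is None:
            utterance_ids = [r.utterance_id for r in manifest.records]
        cfg = self.model.encoder_config
        if cfg.input_mode == "feature":
            X = np.stack([self.model.signals[u] for u in utterance_ids])
        else:
            X = [self.model.signals[u] for u in utterance_ids]
        Z, _ = forward_embed(self.params, cfg, X)
        meta = pd.DataFrame(
            {
                "utterance_id": utterance_ids,
                "speaker_id": [by_utt[u].speaker_id for u in utterance_ids],
                "word_id": [by_utt[u].word_id for u in utterance_ids],
                "severity": [int(by_utt[u].severity) for u in utterance_ids],
            }
        )
        return EmbeddingBatch(vectors=Z, metadata=meta)

    def probe_speaker_identity(self, split_seed: int = 0,
                               max_utterances: int | None = 4000,
                               **kwargs) -> ProbeResult:
        """Speaker-predictability probe on pooled corpus embeddings.

        ``max_utterances`` subsamples the pooled set (seeded) to keep the
        probe fit cheap on full-protocol corpora.
        """
        emb = self.embed()
        if max_utterances is not None and len(emb) > max_utterances:
            rng = np.random.default_rng(derive_seed(split_seed, "probe-subsample"))
            idx = np.sort(rng.choice(len(emb), size=max_utterances, replace=False))
            emb = EmbeddingBatch(
                vectors=emb.vectors[idx],
                metadata=emb.metadata.iloc[idx].reset_index(drop=True),
            )
        return probe_speaker_identity(emb, split_seed=split_seed, **kwargs)

    def latent_diagnostics(self, n_samples: int = 2000,
                           rng_seed: int = 0) -> LatentDiagnostics:
        """d1/d2 and intra/inter-severity distance structure of the space."""
        return latent_distance_ratio(self.embed(), n_samples=n_samples,
                                     rng_seed=rng_seed)

    # -- persistence / reporting ------------------------------------------

    def save(self, path: str | Path) -> Path:
        return save_params(self.params, self.model.encoder_config, path)

    def summary(self) -> str:
        cfg = self.model.train_config
        fold = self.model.fold
        last = self.train_log.iloc[-1]
        lines = [
            "Severity classification model",
            "=" * 48,
            f"mode:              {cfg.mode}",
            f"held-out speaker:  {fold.held_out_speaker or '(none)'}",
            f"train utterances:  {len(fold.train_utterances)}",
            f"test utterances:   {len(fold.test_utterances)}",
            f"steps:             {cfg.total_steps} "
            f"(warm-up {cfg.loss_config.gamma_warmup_steps})",
            f"final L_CE:        {last['loss_ce']:.4f}",
            f"final L_reg:       {last['loss_reg']:.4f}",
            f"final total loss:  {last['loss_total']:.4f}",
        ]
        if fold.test_utterances:
            res = self.evaluate()
            lines.append(
                f"held-out accuracy: {100 * res.speaker_accuracy:.2f} % "
                f"({len(res.truths)} utterances)"
            )
        return "\n".join(lines)


def loso(
    manifest: CorpusManifest,
    signals: SignalStore,
    mode: str = "salr",
    repeats: int = 1,
    seed: int = 0,
    test_mode: str = "uncommon_only",
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
    keep_results: bool = False,
):
    """Full leave-one-subject-out experiment, repeated ``repeats`` times.

    Per repeat r and fold f the training seed is derived deterministically
    from ``seed``, r and the held-out speaker.  Returns ``(EvalReport,
    fold_results)`` where ``fold_results[r]`` is that repeat's list of
    FoldResult; with ``keep_results`` the fitted SeverityResults of the
    *first* repeat are returned as a third element (one per fold), for
    diagnostics.
    """
    base_train = train_config or TrainConfig(mode=mode)
    base_train = replace(base_train, mode=mode)
    folds = build_loso_folds(manifest, test_mode=test_mode)
    all_results: list[list[FoldResult]] = []
    kept: list[SeverityResults] = []
    for r in range(repeats):
        rep_results = []
        for fold in folds:
            fold_seed = derive_seed(seed, f"repeat{r}:{fold.held_out_speaker}")
            tc = replace(base_train, seed=fold_seed)
            model = SeverityModel(
                manifest,
                signals,
                fold=fold,
                encoder_config=encoder_config,
                train_config=tc,
            )
            fitted = model.fit()
            rep_results.append(fitted.evaluate())
            if keep_results and r == 0:
                kept.append(fitted)
        all_results.append(rep_results)
        logger.info(
            "repeat %d/%d: mean held-out accuracy %.3f",
            r + 1,
            repeats,
            float(np.mean([x.speaker_accuracy for x in rep_results])),
        )
    report = aggregate_loso(all_results)
    if keep_results:
        return report, all_results, kept
    return report, all_results
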