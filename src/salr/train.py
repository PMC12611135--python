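"""Optimisation loop joining encoder, losses and the warm-up schedule.

Two training modes:

- ``ce_only``: plain cross-entropy fine-tuning (the comparator baseline).
- ``salr``: the multi-task regime — each step draws one classification batch
  and one triplet batch mined from the whole training fold, and minimises
  ``epsilon * L_reg + gamma(step) * L_CE``.  During the warm-up phase
  (gamma = 0) only the contrastive regulariser shapes the encoder.

Training is step-based (not epoch-based) to honour the step-indexed gamma
schedule.  A seeded validation split is drawn from training speakers only;
the held-out speaker is never touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus import CorpusManifest, FoldSpec
from .encoder import (
    EncoderConfig,
    N_CLASSES,
    backward_embed,
    forward_embed,
    head_backward,
    head_forward,
)
from .losses import (
    LossConfig,
    TripletMiner,
    combined_loss,
    gamma_schedule,
    triplet_margin_loss_batch,
)

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "Adam", "train", "cross_entropy"]


@dataclass
class TrainConfig:
    """Optimisation settings.

    Defaults follow the reference fine-tuning recipe: batch size 4, Adam
    with learning rate 5e-4, betas (0.9, 0.98), eps 1e-8.  ``total_steps``
    and the warm-up budget inside ``loss_config`` are expressed as absolute
    step counts; desk-scale runs use proportionally small values.
    """

    mode: str = "salr"  # "salr" | "ce_only"
    batch_size: int = 4
    triplet_batch_size: int = 16
    learning_rate: float = 5e-4
    betas: tuple[float, float] = (0.9, 0.98)
    eps_opt: float = 1e-8
    total_steps: int = 1000
    loss_config: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    validation_fraction: float = 0.1
    val_interval: int = 100

    def __post_init__(self) -> None:
        if self.mode not in ("salr", "ce_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.batch_size < 1 or self.triplet_batch_size < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.total_steps <= 0:
            raise ValueError("total_steps must be > 0")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


class Adam:
    """Plain Adam over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.98), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    logits = np.atleast_2d(logits)
    shifted = logits - logits.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logZ
    n = logits.shape[0]
    loss = -float(np.mean(logp[np.arange(n), labels]))
    probs = np.exp(logp)
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits


def _signal_batch(store, config: EncoderConfig, ids):
    if config.input_mode == "feature":
        return np.stack([store[u] for u in ids])
    return [store[u] for u in ids]


def train(
    params: dict[str, np.ndarray],
    fold: FoldSpec,
    manifest: CorpusManifest,
    signals,
    encoder_config: EncoderConfig,
    config: TrainConfig,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Train encoder + head on one fold; returns (params, TrainLog).

    ``params`` is updated in place and also returned.  The TrainLog has one
    row per step with columns step, loss_ce, loss_reg, gamma, loss_total and
    a sparse val_loss column (cross-entropy on the validation split every
    ``val_interval`` steps).  Everything is deterministic given the seed.
    In salr mode, if no severity class in the training fold has two or more
    speakers, training degrades to ce_only with a logged warning.
    """
    if not fold.train_utterances:
        raise ValueError("empty training fold")
    rng = np.random.default_rng(config.seed)
    by_utt = manifest.by_utterance()
    train_ids = list(fold.train_utterances)

    # validation split: training speakers only, never the held-out speaker
    n_val = int(round(config.validation_fraction * len(train_ids)))
    perm = rng.permutation(len(train_ids))
    val_ids = [train_ids[i] for i in perm[:n_val]]
    fit_ids = [train_ids[i] for i in perm[n_val:]]
    if not fit_ids:
        raise ValueError("validation split left no training utterances")

    labels = np.array([int(by_utt[u].severity) for u in fit_ids])
    X_fit = _signal_batch(signals, encoder_config, fit_ids)
    X_val = _signal_batch(signals, encoder_config, val_ids) if val_ids else None
    y_val = np.array([int(by_utt[u].severity) for u in val_ids]) if val_ids else None

    mode = config.mode
    loss_cfg = config.loss_config
    miner = None
    if mode == "salr":
        meta = pd.DataFrame(
            {
                "utterance_id": fit_ids,
                "speaker_id": [by_utt[u].speaker_id for u in fit_ids],
                "word_id": [by_utt[u].word_id for u in fit_ids],
                "severity": [int(by_utt[u].severity) for u in fit_ids],
            }
        )
        miner = TripletMiner(meta)
        if miner.total_count == 0:
            logger.warning(
                "no severity class with >=2 speakers in training fold %s; "
                "degrading to ce_only",
                fold.held_out_speaker,
            )
            mode = "ce_only"
            miner = None
    if mode == "ce_only":
        # the baseline reduces the combined loss to L_CE exactly
        loss_cfg = replace(loss_cfg, epsilon=0.0, gamma_warmup_steps=0)

    opt = Adam(params, config.learning_rate, config.betas, config.eps_opt)
    index_of = {u: i for i, u in enumerate(fit_ids)}
    rows = []
    n_fit = len(fit_ids)
    for step in range(config.total_steps):
        grads: dict[str, np.ndarray] = {}
        gamma = gamma_schedule(step, loss_cfg)

        # classification batch
        batch = rng.integers(n_fit, size=config.batch_size)
        if encoder_config.input_mode == "feature":
            xb = X_fit[batch]
        else:
            xb = [X_fit[i] for i in batch]
        yb = labels[batch]
        Z, cache = forward_embed(params, encoder_config, xb)
        logits, head_cache = head_forward(params, Z)
        l_ce, dlogits = cross_entropy(logits, yb)
        if gamma > 0.0:
            dZ = head_backward(params, head_cache, gamma * dlogits, grads)
            backward_embed(params, encoder_config, cache, dZ, grads)

        # triplet batch
        l_reg = 0.0
        if mode == "salr":
            triplets = miner.sample(config.triplet_batch_size, rng)
            T = len(triplets)
            trip_ids = [t.anchor_id for t in triplets] + [
                t.positive_id for t in triplets
            ] + [t.negative_id for t in triplets]
            # one shared pass over anchors|positives|negatives
            if encoder_config.input_mode == "feature":
                xt = np.stack(
                    [
                        X_fit[index_of[u]] if u in index_of else signals[u]
                        for u in trip_ids
                    ]
                )
            else:
                xt = [signals[u] for u in trip_ids]
            Zt, cache_t = forward_embed(params, encoder_config, xt)
            A, P, N = Zt[:T], Zt[T : 2 * T], Zt[2 * T :]
            losses_t, (dA, dP, dN) = triplet_margin_loss_batch(A, P, N, loss_cfg)
            l_reg = float(losses_t.mean())
            scale = loss_cfg.epsilon / T
            dZt = np.concatenate([dA, dP, dN]) * scale
            backward_embed(params, encoder_config, cache_t, dZt, grads)

        total = combined_loss(l_reg, l_ce, step, loss_cfg)
        if not np.isfinite(total):
            raise RuntimeError(
                f"non-finite loss at step {step}: L_CE={l_ce}, L_reg={l_reg}"
            )
        if grads:
            opt.step(params, grads)

        val_loss = np.nan
        if X_val is not None and (
            step % config.val_interval == 0 or step == config.total_steps - 1
        ):
            Zv, _ = forward_embed(params, encoder_config, X_val)
            logits_v, _ = head_forward(params, Zv)
            val_loss, _ = cross_entropy(logits_v, y_val)
        rows.append(
            {
                "step": step,
                "loss_ce": l_ce,
                "loss_reg": l_reg,
                "gamma": gamma,
                "loss_total": total,
                "val_loss": val_loss,
            }
        )
    log = pd.DataFrame(rows)
    return params, log
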