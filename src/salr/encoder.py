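"""Small trainable encoder and severity-classification head.

A stand-in for a large pretrained speech transformer, exposing the same
contract: inputs in, one fixed-dimension embedding per utterance out, plus a
classification head of two linear layers with a ReLU in between producing
one logit per severity class.  The embedding handed to the head is the same
vector exposed to all latent-space diagnostics (a single pooling point), and
no L2 normalisation is applied before distance computations.

Implemented directly in numpy with hand-written backward passes; the
analytic gradients are validated against finite differences in the test
suite.  A pluggable encoder is anything mapping a batch of inputs to an
(n, embedding_dim) float matrix — drop-in replacements (e.g. a pretrained
transformer's pooled output) can reuse the head, losses and evaluation
unchanged.

Feature mode:   x -> ReLU(x W1 + b1) W2 + b2                    -> embedding
Waveform mode:  non-overlapping frames -> ReLU(frames Wc + bc)
                -> mean over frames -> same trunk as above      -> embedding
Head:           ReLU(z W3 + b3) W4 + b4                         -> 4 logits
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

N_CLASSES = 4

__all__ = [
    "EncoderConfig",
    "EmbeddingBatch",
    "init_params",
    "encode",
    "classify",
    "predict_severity",
    "save_params",
    "load_params",
    "N_CLASSES",
]

CHECKPOINT_VERSION = 1


@dataclass
class EncoderConfig:
    """Architecture of the stand-in encoder.

    ``embedding_dim`` defaults to 64 (large pretrained speech transformers
    use 768; the stand-in is deliberately small).  ``frame_size`` only
    matters in waveform mode, where the front-end projects non-overlapping
    sample frames before mean-pooling over time.
    """

    input_mode: str = "feature"  # "feature" | "waveform"
    input_dim: int = 64  # feature-vector dimension (feature mode)
    frame_size: int = 64  # samples per frame (waveform mode)
    hidden_dim: int = 64
    embedding_dim: int = 64
    head_hidden: int = 32

    def __post_init__(self) -> None:
        if self.input_mode not in ("feature", "waveform"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        for name in ("input_dim", "frame_size", "hidden_dim", "head_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def trunk_input_dim(self) -> int:
        return self.input_dim if self.input_mode == "feature" else self.hidden_dim


@dataclass
class EmbeddingBatch:
    """(n, embedding_dim) latent vectors aligned to utterance metadata.

    ``metadata`` has one row per embedding with at least utterance_id,
    speaker_id, word_id and severity (ordinal code) columns.
    """

    vectors: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if len(self.metadata) != self.vectors.shape[0]:
            raise ValueError(
                f"metadata rows ({len(self.metadata)}) != embedding rows "
                f"({self.vectors.shape[0]})"
            )
        if self.vectors.size and not np.all(np.isfinite(self.vectors)):
            raise ValueError("embeddings contain non-finite entries")

    def __len__(self) -> int:
        return self.vectors.shape[0]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / (fan_in + fan_out))


def init_params(config: EncoderConfig, init_seed: int = 0) -> dict[str, np.ndarray]:
    """Deterministic Glorot-style initialisation keyed by ``init_seed``."""
    rng = np.random.default_rng(init_seed)
    params: dict[str, np.ndarray] = {}
    if config.input_mode == "waveform":
        params["Wc"] = _glorot(rng, config.frame_size, config.hidden_dim)
        params["bc"] = np.zeros(config.hidden_dim)
    params["W1"] = _glorot(rng, config.trunk_input_dim, config.hidden_dim)
    params["b1"] = np.zeros(config.hidden_dim)
    params["W2"] = _glorot(rng, config.hidden_dim, config.embedding_dim)
    params["b2"] = np.zeros(config.embedding_dim)
    params["W3"] = _glorot(rng, config.embedding_dim, config.head_hidden)
    params["b3"] = np.zeros(config.head_hidden)
    params["W4"] = _glorot(rng, config.head_hidden, N_CLASSES)
    params["b4"] = np.zeros(N_CLASSES)
    return params


def _pool_waveform(params: dict, config: EncoderConfig, wave: np.ndarray):
    """Frame a 1-D waveform, project+ReLU each frame, mean-pool over time."""
    fs = config.frame_size
    n = len(wave)
    if n < fs:
        wave = np.pad(wave, (0, fs - n))
        n = fs
    frames = wave[: (n // fs) * fs].reshape(-1, fs)
    pre = frames @ params["Wc"] + params["bc"]
    act = np.maximum(pre, 0.0)
    pooled = act.mean(axis=0)
    return pooled, (frames, pre, act)


def _forward_trunk(params: dict, X: np.ndarray):
    H_pre = X @ params["W1"] + params["b1"]
    H = np.maximum(H_pre, 0.0)
    Z = H @ params["W2"] + params["b2"]
    return Z, (X, H_pre, H)


def _backward_trunk(params: dict, cache, dZ: np.ndarray, grads: dict) -> np.ndarray:
    X, H_pre, H = cache
    grads["W2"] = grads.get("W2", 0.0) + H.T @ dZ
    grads["b2"] = grads.get("b2", 0.0) + dZ.sum(axis=0)
    dH = (dZ @ params["W2"].T) * (H_pre > 0.0)
    grads["W1"] = grads.get("W1", 0.0) + X.T @ dH
    grads["b1"] = grads.get("b1", 0.0) + dH.sum(axis=0)
    return dH @ params["W1"].T


def forward_embed(params: dict, config: EncoderConfig, inputs):
    """Embed a batch; returns (Z, cache) where Z is (n, embedding_dim).

    ``inputs`` is an (n, input_dim) matrix in feature mode, or a sequence of
    1-D waveforms (possibly different lengths) in waveform mode.
    """
    if config.input_mode == "feature":
        X = np.asarray(inputs, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != config.input_dim:
            raise ValueError(
                f"expected inputs of shape (n, {config.input_dim}), got {X.shape}"
            )
        Z, trunk_cache = _forward_trunk(params, X)
        return Z, ("feature", trunk_cache)
    pooled_rows, wave_caches = [], []
    for wave in inputs:
        pooled, cache = _pool_waveform(params, config, np.asarray(wave, dtype=np.float64))
        pooled_rows.append(pooled)
        wave_caches.append(cache)
    X = np.stack(pooled_rows) if pooled_rows else np.empty((0, config.hidden_dim))
    Z, trunk_cache = _forward_trunk(params, X)
    return Z, ("waveform", trunk_cache, wave_caches)


def backward_embed(params: dict, config: EncoderConfig, cache, dZ: np.ndarray,
                   grads: dict) -> None:
    """Accumulate parameter gradients for a forward_embed pass into ``grads``."""
    if cache[0] == "feature":
        _backward_trunk(params, cache[1], dZ, grads)
        return
    _, trunk_cache, wave_caches = cache
    dX = _backward_trunk(params, trunk_cache, dZ, grads)
    for i, (frames, pre, _act) in enumerate(wave_caches):
        T = frames.shape[0]
        dact = np.tile(dX[i] / T, (T, 1)) * (pre > 0.0)
        grads["Wc"] = grads.get("Wc", 0.0) + frames.T @ dact
        grads["bc"] = grads.get("bc", 0.0) + dact.sum(axis=0)


def encode(params: dict, config: EncoderConfig, inputs,
           metadata: pd.DataFrame | None = None):
    """Deterministic embeddings for a batch of inputs.

    Returns an (n, embedding_dim) array, or an EmbeddingBatch when aligned
    ``metadata`` is supplied.
    """
    Z, _ = forward_embed(params, config, inputs)
    if metadata is None:
        return Z
    return EmbeddingBatch(vectors=Z, metadata=metadata.reset_index(drop=True))


def head_forward(params: dict, Z: np.ndarray):
    G_pre = Z @ params["W3"] + params["b3"]
    G = np.maximum(G_pre, 0.0)
    logits = G @ params["W4"] + params["b4"]
    return logits, (Z, G_pre, G)


def head_backward(params: dict, cache, dlogits: np.ndarray, grads: dict) -> np.ndarray:
    """Backprop through the head; returns gradient w.r.t. the embeddings."""
    Z, G_pre, G = cache
    grads["W4"] = grads.get("W4", 0.0) + G.T @ dlogits
    grads["b4"] = grads.get("b4", 0.0) + dlogits.sum(axis=0)
    dG = (dlogits @ params["W4"].T) * (G_pre > 0.0)
    grads["W3"] = grads.get("W3", 0.0) + Z.T @ dG
    grads["b3"] = grads.get("b3", 0.0) + dG.sum(axis=0)
    return dG @ params["W3"].T


def classify(params: dict, embeddings: np.ndarray) -> np.ndarray:
    """Head logits (n, 4): linear -> ReLU -> linear on the embeddings."""
    Z = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if Z.shape[1] != params["W3"].shape[0]:
        raise ValueError(
            f"embedding dim {Z.shape[1]} does not match head ({params['W3'].shape[0]})"
        )
    logits, _ = head_forward(params, Z)
    return logits


def predict_severity(params: dict, embeddings: np.ndarray) -> np.ndarray:
    """Predicted ordinal severity codes: argmax over the head logits."""
    return np.argmax(classify(params, embeddings), axis=1)


def save_params(params: dict, config: EncoderConfig, path: str | Path) -> Path:
    """Save a parameter checkpoint (single .npz archive with a version tag)."""
    import json

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez(
        path,
        __version__=np.array(CHECKPOINT_VERSION),
        __config__=np.array(json.dumps(asdict(config))),
        **params,
    )
    return path


def load_params(path: str | Path) -> tuple[dict[str, np.ndarray], EncoderConfig]:
    import json

    with np.load(Path(path), allow_pickle=False) as archive:
        version = int(archive["__version__"])
        if version != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        config = EncoderConfig(**json.loads(str(archive["__config__"])))
        params = {k: archive[k] for k in archive.files if not k.startswith("__")}
    return params, config
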