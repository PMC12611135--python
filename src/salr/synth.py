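"""Synthetic corpus generator with a built-in speaker-severity confound.

The generator emulates the structure of an isolated-word dysarthria corpus:
15 speakers distributed 5/2/2/6 over four severity bands, each reading
``n_blocks`` blocks of ``n_common_words`` repeated common words plus
``n_uncommon_per_block`` block-unique uncommon words (defaults: 3 blocks,
155 common, 100 uncommon -> 765 utterances and 455 distinct words per
speaker).

Feature mode draws each utterance vector from an additive latent factor
model::

    x = beta_word * W_w
      + beta_severity * c_w * v_s * D
      + beta_speaker * U_s
      + kappa * c_w * v_s * M_s
      + noise_sigma * e

where ``W_w`` is a word template, ``c_w > 0`` a word-complexity scalar
(uncommon words are drawn more complex, so severity manifests more strongly
on them), ``v_s`` the ordinal severity code of the speaker (0..3), ``D`` a
unit severity direction shared by everyone, ``U_s`` a speaker offset, and
``M_s`` a per-speaker unit "manifestation" direction that makes the
expression of severity speaker-idiosyncratic (the kappa interaction).  With
``kappa = 0`` the model reduces to the three pure factors plus noise.
Because every speaker has exactly one severity, speaker identity perfectly
predicts severity — the shortcut the training regulariser is meant to
suppress.

Waveform mode synthesises a harmonic stack with a speaker-specific
fundamental, word-specific partial amplitudes, severity-scaled phase jitter
and additive noise; it exists to exercise the framing front-end and WAV I/O,
not to sound like speech.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .corpus import (
    CorpusManifest,
    SeverityLevel,
    UtteranceRecord,
    read_manifest,
    write_manifest,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "LatentFactors",
    "SignalStore",
    "generate_corpus",
    "describe_difficulty",
    "save_corpus",
    "load_corpus",
]

_SEVERITY_PREFIX = {
    SeverityLevel.VERY_LOW: "VL",
    SeverityLevel.LOW: "LO",
    SeverityLevel.MEDIUM: "ME",
    SeverityLevel.HIGH: "HI",
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    Defaults reproduce the reference protocol (15 speakers split 5/2/2/6
    across severity bands; 3 blocks x (155 common + 100 uncommon) words).
    Effect sizes are chosen so that, on raw features, same-speaker
    different-word pairs sit closer than same-word different-speaker pairs
    (speaker offsets dominate word templates) while severity stays linearly
    decodable along D — i.e. the confounded geometry the method targets.
    """

    speakers_per_severity: tuple[int, int, int, int] = (5, 2, 2, 6)
    n_blocks: int = 3
    n_common_words: int = 155
    n_uncommon_per_block: int = 100
    mode: str = "feature"  # "feature" | "waveform"
    feature_dim: int = 64
    beta_word: float = 0.6
    beta_speaker: float = 1.2
    beta_severity: float = 0.5
    kappa: float = 0.3
    noise_sigma: float = 0.15
    sample_rate: int = 8000
    duration: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        self.speakers_per_severity = tuple(int(k) for k in self.speakers_per_severity)
        if len(self.speakers_per_severity) != 4:
            raise ValueError("speakers_per_severity needs one count per severity band")
        if any(k < 0 for k in self.speakers_per_severity):
            raise ValueError("speaker counts must be nonnegative")
        if sum(self.speakers_per_severity) < 2:
            raise ValueError("need at least 2 speakers in total")
        for name in ("n_blocks", "n_common_words", "n_uncommon_per_block", "feature_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("beta_word", "beta_speaker", "beta_severity", "kappa", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.mode not in ("feature", "waveform"):
            raise ValueError(f"mode must be 'feature' or 'waveform', got {self.mode!r}")
        if any(k == 0 for k in self.speakers_per_severity):
            warnings.warn("a severity band has zero speakers", stacklevel=2)

    @property
    def n_speakers(self) -> int:
        return sum(self.speakers_per_severity)

    @property
    def utterances_per_speaker(self) -> int:
        return self.n_blocks * (self.n_common_words + self.n_uncommon_per_block)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["speakers_per_severity"] = list(self.speakers_per_severity)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


@dataclass
class LatentFactors:
    """The factor draws behind a generated corpus (reproducible from seed)."""

    word_templates: dict[str, np.ndarray]
    word_complexity: dict[str, float]
    speaker_offsets: dict[str, np.ndarray]
    speaker_manifestations: dict[str, np.ndarray]
    severity_direction: np.ndarray
    severity_centroids: np.ndarray  # (4, feature_dim): beta_severity * mean(c) * v * D

    def __post_init__(self) -> None:
        assert abs(float(np.linalg.norm(self.severity_direction)) - 1.0) < 1e-9
        assert all(c > 0 for c in self.word_complexity.values())


class SignalStore:
    """In-memory utterance_id -> signal map with optional access tracking.

    Feature mode stores fixed-dimension vectors; waveform mode stores 1-D
    float arrays in [-1, 1] at ``sample_rate``.  Access tracking lets tests
    assert that held-out speakers are never touched during training.
    """

    def __init__(self, mode: str, sample_rate: int | None = None):
        self.mode = mode
        self.sample_rate = sample_rate
        self._data: dict[str, np.ndarray] = {}
        self.track_access = False
        self.accessed: set[str] = set()

    def put(self, utterance_id: str, signal: np.ndarray) -> None:
        self._data[utterance_id] = signal

    def __getitem__(self, utterance_id: str) -> np.ndarray:
        if self.track_access:
            self.accessed.add(utterance_id)
        return self._data[utterance_id]

    def __contains__(self, utterance_id: str) -> bool:
        return utterance_id in self._data

    def __len__(self) -> int:
        return len(self._data)

    def ids(self) -> list[str]:
        return sorted(self._data)

    def matrix(self, utterance_ids) -> np.ndarray:
        """Stack feature vectors for the given ids into an (n, d) matrix."""
        if self.mode != "feature":
            raise ValueError("matrix() is only defined in feature mode")
        return np.stack([self[u] for u in utterance_ids]) if len(utterance_ids) else (
            np.empty((0, 0))
        )


def _unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def _draw_factors(config: GeneratorConfig, rng: np.random.Generator,
                  speaker_ids: list[str], speaker_severity: dict[str, SeverityLevel],
                  common_words: list[str], uncommon_words: list[str]) -> LatentFactors:
    d = config.feature_dim
    scale = 1.0 / np.sqrt(d)
    word_templates = {w: rng.standard_normal(d) * scale for w in common_words + uncommon_words}
    # Uncommon words are drawn ~30% more complex on average: rarer vocabulary
    # stresses articulation more, so severity expresses more strongly on it.
    word_complexity = {w: float(rng.lognormal(0.0, 0.25)) for w in common_words}
    word_complexity.update(
        {w: float(rng.lognormal(np.log(1.3), 0.25)) for w in uncommon_words}
    )
    direction = _unit(rng, d)
    speaker_offsets = {s: rng.standard_normal(d) * scale for s in speaker_ids}
    speaker_manifestations = {s: _unit(rng, d) for s in speaker_ids}
    mean_c = float(np.mean(list(word_complexity.values())))
    centroids = np.stack(
        [config.beta_severity * mean_c * v * direction for v in range(4)]
    )
    return LatentFactors(
        word_templates=word_templates,
        word_complexity=word_complexity,
        speaker_offsets=speaker_offsets,
        speaker_manifestations=speaker_manifestations,
        severity_direction=direction,
        severity_centroids=centroids,
    )


def _feature_signal(config: GeneratorConfig, factors: LatentFactors,
                    speaker: str, word: str, severity: SeverityLevel,
                    rng: np.random.Generator) -> np.ndarray:
    c = factors.word_complexity[word]
    v = float(int(severity))
    x = (
        config.beta_word * factors.word_templates[word]
        + config.beta_severity * c * v * factors.severity_direction
        + config.beta_speaker * factors.speaker_offsets[speaker]
        + config.kappa * c * v * factors.speaker_manifestations[speaker]
    )
    return x + config.noise_sigma * rng.standard_normal(config.feature_dim)


def _waveform_signal(config: GeneratorConfig, factors: LatentFactors,
                     f0: float, word: str, severity: SeverityLevel,
                     rng: np.random.Generator) -> np.ndarray:
    n = int(round(config.sample_rate * config.duration))
    t = np.arange(n) / config.sample_rate
    c = factors.word_complexity[word]
    v = float(int(severity))
    # word-specific partial amplitudes from the first 8 template coordinates
    raw = factors.word_templates[word][:8]
    amps = np.abs(raw) + 0.1
    amps /= amps.sum()
    jitter_std = 0.01 * (1.0 + v * c)
    x = np.zeros(n)
    for k, a in enumerate(amps, start=1):
        phase_noise = np.cumsum(rng.normal(0.0, jitter_std, n))
        x += a * np.sin(2 * np.pi * k * f0 * t + phase_noise)
    x += config.noise_sigma * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    return (0.9 * x / peak) if peak > 0 else x


def generate_corpus(config: GeneratorConfig) -> tuple[CorpusManifest, SignalStore]:
    """Generate a manifest plus its signal store, bit-reproducible from seed.

    Speaker ids carry a severity prefix (VL/LO/ME/HI); common word ids are
    shared by all speakers and blocks; uncommon word ids are shared across
    speakers but unique to one block, so each occurs exactly once per
    speaker.
    """
    rng = np.random.default_rng(config.seed)
    levels = list(SeverityLevel)
    speaker_ids: list[str] = []
    speaker_severity: dict[str, SeverityLevel] = {}
    for level, count in zip(levels, config.speakers_per_severity):
        for i in range(count):
            sid = f"{_SEVERITY_PREFIX[level]}{i + 1:02d}"
            speaker_ids.append(sid)
            speaker_severity[sid] = level
    if any(k == 0 for k in config.speakers_per_severity):
        logger.warning("severity bands with zero speakers: %s",
                       [lv.label for lv, k in zip(levels, config.speakers_per_severity) if k == 0])

    common_words = [f"C{i + 1:03d}" for i in range(config.n_common_words)]
    uncommon_words = [
        f"U{b}_{i + 1:03d}"
        for b in range(1, config.n_blocks + 1)
        for i in range(config.n_uncommon_per_block)
    ]

    # Fixed draw order: intelligibilities, factors, then per-utterance noise.
    speakers_table: dict[str, tuple[SeverityLevel, float]] = {}
    for sid in speaker_ids:
        lo, hi = speaker_severity[sid].intelligibility_range
        intel = float(np.round(rng.uniform(lo, hi), 1))
        speakers_table[sid] = (speaker_severity[sid], intel)

    factors = _draw_factors(config, rng, speaker_ids, speaker_severity,
                            common_words, uncommon_words)
    f0s = {s: float(rng.uniform(90.0, 220.0)) for s in speaker_ids}

    store = SignalStore(config.mode, config.sample_rate if config.mode == "waveform" else None)
    records: list[UtteranceRecord] = []
    for sid in speaker_ids:
        sev, intel = speakers_table[sid]
        for b in range(1, config.n_blocks + 1):
            block_words = [(w, "common") for w in common_words] + [
                (w, "uncommon")
                for w in uncommon_words
                if w.startswith(f"U{b}_")
            ]
            for word, cat in block_words:
                uid = f"{sid}_B{b}_{word}"
                if config.mode == "feature":
                    sig = _feature_signal(config, factors, sid, word, sev, rng)
                else:
                    sig = _waveform_signal(config, factors, f0s[sid], word, sev, rng)
                store.put(uid, sig)
                records.append(
                    UtteranceRecord(
                        utterance_id=uid,
                        speaker_id=sid,
                        word_id=word,
                        word_category=cat,
                        block=b,
                        severity=sev,
                        intelligibility=intel,
                        signal_ref=f"{uid}.wav" if config.mode == "waveform" else uid,
                    )
                )
    manifest = CorpusManifest(records=records, speakers=speakers_table)
    manifest._factors = factors  # type: ignore[attr-defined]  # exposed for tests
    return manifest, store


def describe_difficulty(
    manifest: CorpusManifest,
    store: SignalStore,
    seed: int = 0,
    test_fraction: float = 0.2,
    max_utterances: int = 4000,
) -> dict:
    """Oracle linear separability of severity and speaker on raw features.

    Fits multinomial logistic models on a seeded held-out utterance split
    (optionally subsampled for speed) and reports held-out accuracies next
    to their chance levels, confirming that a generated corpus actually
    carries the confound before any training is attempted.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    if store.mode != "feature":
        raise ValueError("describe_difficulty requires a feature-mode corpus")
    rng = np.random.default_rng(seed)
    ids = [r.utterance_id for r in manifest.records]
    if len(ids) > max_utterances:
        ids = list(rng.choice(ids, size=max_utterances, replace=False))
    by_utt = manifest.by_utterance()
    X = store.matrix(ids)
    spk = np.array([by_utt[u].speaker_id for u in ids])
    sev = np.array([int(by_utt[u].severity) for u in ids])

    def _probe(labels: np.ndarray) -> float:
        Xtr, Xte, ytr, yte = train_test_split(
            X, labels, test_size=test_fraction, random_state=seed, stratify=labels
        )
        clf = LogisticRegression(max_iter=1000)
        clf.fit(Xtr, ytr)
        return float(np.mean(clf.predict(Xte) == yte))

    n_speakers = len(manifest.speakers)
    return {
        "n_utterances": len(ids),
        "severity_accuracy": _probe(sev),
        "severity_chance": 0.25,
        "speaker_accuracy": _probe(spk),
        "speaker_chance": 1.0 / n_speakers,
        "n_speakers": n_speakers,
    }


def save_corpus(manifest: CorpusManifest, store: SignalStore,
                out_dir: str | Path, config: GeneratorConfig | None = None) -> Path:
    """Write manifest.csv plus signals (features.npy+index or WAV files)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_manifest(manifest, out_dir / "manifest.csv")
    if store.mode == "feature":
        ids = [r.utterance_id for r in manifest.records]
        np.save(out_dir / "features.npy", store.matrix(ids))
        pd.DataFrame({"utterance_id": ids, "row": np.arange(len(ids))}).to_csv(
            out_dir / "features_index.csv", index=False
        )
    else:
        wav_dir = out_dir / "wav"
        wav_dir.mkdir(exist_ok=True)
        for r in manifest.records:
            x = store[r.utterance_id]
            pcm = np.clip(np.round(x * 32767.0), -32768, 32767).astype(np.int16)
            wavfile.write(wav_dir / f"{r.utterance_id}.wav", store.sample_rate, pcm)
    if config is not None:
        (out_dir / "generator_config.json").write_text(
            json.dumps(config.to_dict(), indent=2) + "\n"
        )
    return out_dir


def load_corpus(corpus_dir: str | Path) -> tuple[CorpusManifest, SignalStore]:
    """Load a corpus written by save_corpus (feature or waveform layout)."""
    corpus_dir = Path(corpus_dir)
    manifest = read_manifest(corpus_dir / "manifest.csv")
    if (corpus_dir / "features.npy").exists():
        store = SignalStore("feature")
        X = np.load(corpus_dir / "features.npy")
        index = pd.read_csv(corpus_dir / "features_index.csv")
        for uid, row in zip(index["utterance_id"].astype(str), index["row"]):
            store.put(uid, X[int(row)])
    else:
        sample_rate = None
        store = SignalStore("waveform")
        for r in manifest.records:
            sr, pcm = wavfile.read(corpus_dir / "wav" / f"{r.utterance_id}.wav")
            sample_rate = sr
            store.put(r.utterance_id, pcm.astype(np.float64) / 32767.0)
        store.sample_rate = sample_rate
    return manifest, store
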