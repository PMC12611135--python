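"""Leave-one-subject-out evaluation, metrics, probes and latent diagnostics.

Metric conventions (documented because "macro-averaged" is ambiguous):

- overall accuracy = the unweighted mean of per-test-speaker accuracies
  (each held-out speaker counts equally, regardless of test-set size);
- macro-F1 = the unweighted mean of the four per-class F1 scores on the
  predictions pooled over all folds of a repeat; classes absent from the
  pooled truth AND predictions are excluded (with a note) rather than
  counted as zero;
- repeat mean +/- SD are computed per speaker and for the overall numbers
  across independent repeats of the whole cross-validation.

Accuracy, F1 and confusion matrices are computed directly here (numpy);
the speaker-predictability probe uses a multinomial logistic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import CorpusManifest, FoldSpec, SeverityLevel
from .encoder import EmbeddingBatch, EncoderConfig, N_CLASSES, forward_embed, head_forward
from .losses import TripletMiner

logger = logging.getLogger(__name__)

__all__ = [
    "FoldResult",
    "EvalReport",
    "ProbeResult",
    "LatentDiagnostics",
    "evaluate_fold",
    "aggregate_loso",
    "confusion_counts",
    "per_class_f1",
    "macro_f1",
    "normalise_confusion",
    "probe_speaker_identity",
    "latent_distance_ratio",
    "export_embeddings",
    "load_embeddings",
]


def confusion_counts(truths, preds, n_classes: int = N_CLASSES) -> np.ndarray:
    """(n_classes, n_classes) counts; rows are true class, columns predicted."""
    truths = np.asarray(truths, dtype=np.int64)
    preds = np.asarray(preds, dtype=np.int64)
    if truths.shape != preds.shape:
        raise ValueError("truths and preds must have the same length")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (truths, preds), 1)
    return counts


def per_class_f1(counts: np.ndarray) -> np.ndarray:
    """F1 per class from a confusion-count matrix (nan where undefined)."""
    tp = np.diag(counts).astype(np.float64)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore"):
        f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), np.nan)
    return f1


def macro_f1(counts: np.ndarray, exclude_empty: bool = True) -> float:
    """Unweighted mean of per-class F1; empty classes excluded with a note."""
    f1 = per_class_f1(counts)
    present = (counts.sum(axis=1) + counts.sum(axis=0)) > 0
    if exclude_empty and not present.all():
        logger.info(
            "macro-F1 excludes empty classes %s", list(np.flatnonzero(~present))
        )
        f1 = f1[present]
    return float(np.nanmean(f1))


def normalise_confusion(counts: np.ndarray) -> np.ndarray:
    """Row-normalised confusion matrix; empty rows stay all-zero."""
    counts = np.asarray(counts, dtype=np.float64)
    sums = counts.sum(axis=1, keepdims=True)
    return np.divide(counts, np.where(sums > 0, sums, 1.0))


@dataclass
class FoldResult:
    """Predictions for one held-out speaker."""

    held_out_speaker: str
    utterance_ids: list[str]
    truths: np.ndarray  # ordinal severity codes
    preds: np.ndarray

    def __post_init__(self) -> None:
        self.truths = np.asarray(self.truths, dtype=np.int64)
        self.preds = np.asarray(self.preds, dtype=np.int64)
        if len(self.truths) != len(self.preds) or len(self.truths) != len(
            self.utterance_ids
        ):
            raise ValueError("utterance_ids, truths and preds must align")

    @property
    def speaker_accuracy(self) -> float:
        return float(np.mean(self.truths == self.preds))

    @property
    def confusion(self) -> np.ndarray:
        return confusion_counts(self.truths, self.preds)


def evaluate_fold(
    params: dict,
    fold: FoldSpec,
    manifest: CorpusManifest,
    signals,
    encoder_config: EncoderConfig,
) -> FoldResult:
    """Predict severity (argmax of head logits) on a fold's test utterances."""
    if not fold.test_utterances:
        raise ValueError("fold test set is empty")
    by_utt = manifest.by_utterance()
    ids = list(fold.test_utterances)
    if encoder_config.input_mode == "feature":
        X = np.stack([signals[u] for u in ids])
    else:
        X = [signals[u] for u in ids]
    Z, _ = forward_embed(params, encoder_config, X)
    logits, _ = head_forward(params, Z)
    preds = np.argmax(logits, axis=1)
    truths = np.array([int(by_utt[u].severity) for u in ids])
    return FoldResult(
        held_out_speaker=fold.held_out_speaker,
        utterance_ids=ids,
        truths=truths,
        preds=preds,
    )


@dataclass
class EvalReport:
    """Aggregate of a repeated leave-one-subject-out experiment."""

    per_speaker: pd.DataFrame  # speaker, mean_accuracy, sd_accuracy, n_test
    overall_accuracy: float  # mean over repeats of (mean over speakers)
    overall_accuracy_sd: float
    macro_f1_mean: float  # mean over repeats of pooled macro-F1
    macro_f1_sd: float
    confusion_normalised: np.ndarray  # pooled over repeats and folds
    n_repeats: int
    single_repeat: bool  # SDs reported as 0 with this flag set

    def summary(self) -> str:
        lines = [
            "Leave-one-subject-out evaluation",
            "=" * 48,
            f"repeats: {self.n_repeats}"
            + ("  (single repeat: SDs reported as 0)" if self.single_repeat else ""),
            f"overall accuracy (mean over speakers): "
            f"{100 * self.overall_accuracy:.2f} +/- {100 * self.overall_accuracy_sd:.2f} %",
            f"macro-F1 (pooled over folds):          "
            f"{100 * self.macro_f1_mean:.2f} +/- {100 * self.macro_f1_sd:.2f} %",
            "",
            "per-speaker accuracy (mean +/- SD over repeats):",
        ]
        for row in self.per_speaker.itertuples(index=False):
            lines.append(
                f"  {row.speaker:<6} {100 * row.mean_accuracy:6.2f} +/- "
                f"{100 * row.sd_accuracy:.2f} %  (n={row.n_test})"
            )
        lines.append("")
        lines.append("normalised confusion matrix (rows = true class):")
        labels = [s.label for s in SeverityLevel]
        for i, lab in enumerate(labels):
            cells = "  ".join(f"{v:.3f}" for v in self.confusion_normalised[i])
            lines.append(f"  {lab:<9} {cells}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "overall_accuracy_sd": self.overall_accuracy_sd,
            "macro_f1_mean": self.macro_f1_mean,
            "macro_f1_sd": self.macro_f1_sd,
            "n_repeats": self.n_repeats,
            "single_repeat": self.single_repeat,
            "per_speaker": self.per_speaker.to_dict(orient="records"),
            "confusion_normalised": self.confusion_normalised.tolist(),
        }


def aggregate_loso(results_by_repeat: list[list[FoldResult]]) -> EvalReport:
    """Aggregate fold results over repeats into an EvalReport.

    Every repeat must contain the same set of held-out speakers (one fold
    each); a missing fold raises.
    """
    if not results_by_repeat:
        raise ValueError("no repeats supplied")
    speaker_sets = [sorted(r.held_out_speaker for r in rep) for rep in results_by_repeat]
    speakers = speaker_sets[0]
    if len(set(speakers)) != len(speakers):
        raise ValueError("duplicate folds for a speaker within a repeat")
    for s in speaker_sets[1:]:
        if s != speakers:
            raise ValueError(f"missing/mismatched folds across repeats: {s} vs {speakers}")

    n_repeats = len(results_by_repeat)
    acc = {
        spk: [
            next(r for r in rep if r.held_out_speaker == spk).speaker_accuracy
            for rep in results_by_repeat
        ]
        for spk in speakers
    }
    n_test = {
        spk: len(next(r for r in results_by_repeat[0] if r.held_out_speaker == spk).truths)
        for spk in speakers
    }
    single = n_repeats == 1

    def _sd(values) -> float:
        return 0.0 if single else float(np.std(values, ddof=1))

    per_speaker = pd.DataFrame(
        {
            "speaker": speakers,
            "mean_accuracy": [float(np.mean(acc[s])) for s in speakers],
            "sd_accuracy": [_sd(acc[s]) for s in speakers],
            "n_test": [n_test[s] for s in speakers],
        }
    )
    overall_per_repeat = [
        float(np.mean([r.speaker_accuracy for r in rep])) for rep in results_by_repeat
    ]
    f1_per_repeat = []
    pooled_counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for rep in results_by_repeat:
        counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
        for r in rep:
            counts += r.confusion
        pooled_counts += counts
        f1_per_repeat.append(macro_f1(counts))
    return EvalReport(
        per_speaker=per_speaker,
        overall_accuracy=float(np.mean(overall_per_repeat)),
        overall_accuracy_sd=_sd(overall_per_repeat),
        macro_f1_mean=float(np.mean(f1_per_repeat)),
        macro_f1_sd=_sd(f1_per_repeat),
        confusion_normalised=normalise_confusion(pooled_counts),
        n_repeats=n_repeats,
        single_repeat=single,
    )


@dataclass
class ProbeResult:
    """Speaker-predictability probe: identity leakage in the latent space."""

    accuracy: float
    chance_level: float
    n_speakers: int
    split_seed: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "chance_level": self.chance_level,
            "n_speakers": self.n_speakers,
            "split_seed": self.split_seed,
        }


def probe_speaker_identity(
    embeddings: EmbeddingBatch,
    split_seed: int = 0,
    test_fraction: float = 0.2,
    max_iter: int = 300,
) -> ProbeResult:
    """Linear classifier predicting speaker identity from embeddings.

    A stratified within-speaker split (default 80/20, seeded) trains a
    multinomial logistic model with default regularisation; the held-out
    accuracy quantifies how much speaker information the embeddings leak.
    Chance level is 1/n_speakers.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    speakers = embeddings.metadata["speaker_id"].to_numpy()
    uniq, counts = np.unique(speakers, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("probe needs at least 2 speakers")
    if counts.min() < 2:
        raise ValueError(
            f"cannot stratify: speaker(s) {uniq[counts < 2].tolist()} have a "
            "single utterance"
        )
    Xtr, Xte, ytr, yte = train_test_split(
        embeddings.vectors,
        speakers,
        test_size=test_fraction,
        random_state=split_seed,
        stratify=speakers,
    )
    clf = LogisticRegression(max_iter=max_iter)
    clf.fit(Xtr, ytr)
    return ProbeResult(
        accuracy=float(np.mean(clf.predict(Xte) == yte)),
        chance_level=1.0 / len(uniq),
        n_speakers=int(len(uniq)),
        split_seed=split_seed,
    )


@dataclass
class LatentDiagnostics:
    """Distance structure of the latent space around valid triplets.

    d1 = mean distance anchor <-> same-speaker different-word negative;
    d2 = mean distance anchor <-> different-speaker same-severity positive.
    A speaker-agnostic space has d1 approximately equal to d2.  Also carries
    the intra-severity vs inter-severity mean pairwise distance ratio.
    """

    d1_mean: float
    d2_mean: float
    ratio: float | None  # d1/d2, None when d2 == 0
    intra_severity_mean: float
    inter_severity_mean: float
    intra_inter_ratio: float | None
    n_triplets: int
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "d1_mean": self.d1_mean,
            "d2_mean": self.d2_mean,
            "ratio": self.ratio,
            "intra_severity_mean": self.intra_severity_mean,
            "inter_severity_mean": self.inter_severity_mean,
            "intra_inter_ratio": self.intra_inter_ratio,
            "n_triplets": self.n_triplets,
            "n_pairs": self.n_pairs,
        }


def latent_distance_ratio(
    embeddings: EmbeddingBatch,
    n_samples: int = 2000,
    rng_seed: int = 0,
) -> LatentDiagnostics:
    """Sample valid triplets among the embedded utterances and measure d1, d2.

    Triplets are mined from the embedding batch's own metadata (which must
    carry speaker_id, word_id and severity).  Raises when no valid triplet
    exists — diagnose on a set of utterances spanning at least two speakers
    of one severity class.
    """
    meta = embeddings.metadata
    miner = TripletMiner(meta)
    if miner.total_count == 0:
        raise ValueError(
            "no valid triplet among these utterances; include at least two "
            "same-severity speakers sharing a word"
        )
    rng = np.random.default_rng(rng_seed)
    if n_samples >= miner.total_count:
        triplets = miner.enumerate_all()
    else:
        triplets = miner.sample(n_samples, rng)
    pos = {u: i for i, u in enumerate(meta["utterance_id"])}
    V = embeddings.vectors
    a = np.array([pos[t.anchor_id] for t in triplets])
    p = np.array([pos[t.positive_id] for t in triplets])
    n = np.array([pos[t.negative_id] for t in triplets])
    d1 = float(np.mean(np.linalg.norm(V[a] - V[n], axis=1)))
    d2 = float(np.mean(np.linalg.norm(V[a] - V[p], axis=1)))
    ratio = (d1 / d2) if d2 > 0 else None

    sev = meta["severity"].to_numpy()
    n_utt = len(meta)
    n_pairs = min(n_samples, n_utt * (n_utt - 1) // 2)
    i = rng.integers(n_utt, size=2 * n_pairs)
    j = rng.integers(n_utt, size=2 * n_pairs)
    keep = i != j
    i, j = i[keep][:n_pairs], j[keep][:n_pairs]
    dists = np.linalg.norm(V[i] - V[j], axis=1)
    same = sev[i] == sev[j]
    intra = float(dists[same].mean()) if same.any() else float("nan")
    inter = float(dists[~same].mean()) if (~same).any() else float("nan")
    return LatentDiagnostics(
        d1_mean=d1,
        d2_mean=d2,
        ratio=ratio,
        intra_severity_mean=intra,
        inter_severity_mean=inter,
        intra_inter_ratio=(intra / inter) if inter and np.isfinite(inter) and inter > 0 else None,
        n_triplets=len(triplets),
        n_pairs=int(len(i)),
    )


def export_embeddings(embeddings: EmbeddingBatch, path: str | Path) -> Path:
    """CSV export: utterance_id, speaker_id, severity, then e0..e{d-1}."""
    path = Path(path)
    d = embeddings.vectors.shape[1] if len(embeddings) else 0
    cols = {
        "utterance_id": embeddings.metadata.get(
            "utterance_id", pd.Series([], dtype=str)
        ),
        "speaker_id": embeddings.metadata.get("speaker_id", pd.Series([], dtype=str)),
        "severity": embeddings.metadata.get("severity", pd.Series([], dtype=int)),
    }
    df = pd.DataFrame(cols)
    for k in range(d):
        df[f"e{k}"] = embeddings.vectors[:, k]
    df.to_csv(path, index=False)
    return path


def load_embeddings(path: str | Path) -> EmbeddingBatch:
    """Read an export back into an EmbeddingBatch (round-trip of the matrix)."""
    df = pd.read_csv(path)
    e_cols = [c for c in df.columns if c.startswith("e") and c[1:].isdigit()]
    vectors = df[e_cols].to_numpy(dtype=np.float64) if len(df) else np.empty((0, len(e_cols)))
    meta = df[["utterance_id", "speaker_id", "severity"]].copy()
    meta["utterance_id"] = meta["utterance_id"].astype(str)
    meta["speaker_id"] = meta["speaker_id"].astype(str)
    return EmbeddingBatch(vectors=vectors, metadata=meta)
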