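"""Constrained triplet mining and the speaker-agnostic multi-task loss.

The regulariser operates on triplets of utterances chosen so that speaker
identity is the only nuisance factor separating positive from negative:

- anchor   = word A spoken by speaker X
- negative = word B spoken by the *same* speaker X
- positive = word B spoken by a *different* speaker Y with the same severity

Minimising the hinge ``max(0, d(anchor, positive) - d(anchor, negative) + m)``
pushes the same-speaker negative away and pulls the same-severity positive
closer; with a small margin (default 0.05) the two distances end up
approximately equal, so embeddings encode word content and severity rather
than speaker identity.  Distances are raw L2 Euclidean.

The total training loss is ``epsilon * L_reg + gamma(step) * L_CE`` with
``epsilon = 0.01`` and a step schedule in which gamma stays 0 for a warm-up
budget (default 3000 steps) — training first shapes the latent geometry,
then adds the cross-entropy classification objective.

Two hinge variants are provided because the convention in which the
anchor-negative distance appears with a positive sign would, if minimised
literally, pull the same-speaker negative *closer*: ``stated_aims`` (the
default, matching the mechanism described above) and ``literal_printed``
(term order reversed), selectable via ``LossConfig.formula_variant``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Triplet",
    "LossConfig",
    "TripletMiner",
    "mine_triplets",
    "triplet_margin_loss",
    "triplet_margin_loss_batch",
    "gamma_schedule",
    "combined_loss",
    "triplets_to_frame",
]


@dataclass(frozen=True)
class Triplet:
    """Identifier triple (anchor, positive, negative).

    Validity constraints against the corpus metadata:
    speaker(anchor) == speaker(negative), word(anchor) != word(negative),
    word(positive) == word(negative), speaker(positive) != speaker(anchor),
    severity(positive) == severity(anchor).
    """

    anchor_id: str
    positive_id: str
    negative_id: str


@dataclass
class LossConfig:
    """Hinge margin, loss weighting and warm-up schedule.

    margin: triplet hinge margin m (default 0.05 — deliberately small so the
        anchor-positive and anchor-negative distances become approximately
        equal rather than widely separated).
    epsilon: weight on the triplet regulariser in the combined loss (0.01).
    gamma_warmup_steps: steps during which the cross-entropy weight gamma is
        held at 0 (default 3000; desk-scale runs use a proportionally small
        absolute budget).
    distance: only "l2" (raw Euclidean) is supported.
    formula_variant: "stated_aims" (default) or "literal_printed".
    """

    margin: float = 0.05
    epsilon: float = 0.01
    gamma_warmup_steps: int = 3000
    distance: str = "l2"
    formula_variant: str = "stated_aims"

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.gamma_warmup_steps < 0:
            raise ValueError("gamma_warmup_steps must be >= 0")
        if self.distance != "l2":
            raise ValueError("only the L2 Euclidean distance is supported")
        if self.formula_variant not in ("stated_aims", "literal_printed"):
            raise ValueError(f"unknown formula_variant {self.formula_variant!r}")


def _metadata_frame(metadata) -> pd.DataFrame:
    """Accept a CorpusManifest or a DataFrame with the metadata columns."""
    if hasattr(metadata, "to_frame") and not isinstance(metadata, pd.DataFrame):
        df = metadata.to_frame()
        df["severity"] = [int(r.severity) for r in metadata.records]
        return df[["utterance_id", "speaker_id", "word_id", "severity"]]
    df = metadata
    required = {"utterance_id", "speaker_id", "word_id", "severity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns {sorted(missing)}")
    out = df[["utterance_id", "speaker_id", "word_id", "severity"]].copy()
    if out["severity"].dtype == object:
        from .corpus import SeverityLevel

        out["severity"] = [int(SeverityLevel.from_label(s)) for s in out["severity"]]
    return out


class TripletMiner:
    """Precomputed index over corpus metadata for constrained triplet sampling.

    An anchor utterance (speaker s, word w) is valid iff s shares its severity
    class with at least one other speaker and s has recorded some word
    w' != w that one of those same-severity speakers also recorded.  A
    completion of an anchor is a (negative, positive) utterance pair with
    negative = (s, w') and positive = (s', w') for a same-severity s' != s.

    Sampling is hierarchical and uniform at each stage: first uniform over
    valid anchor utterances, then uniform over that anchor's completions.
    Severity classes with fewer than two speakers can contribute no triplets
    and are logged.
    """

    def __init__(self, metadata):
        df = _metadata_frame(metadata)
        self.df = df
        spk_sev = df.drop_duplicates("speaker_id").set_index("speaker_id")["severity"]
        self._sev_of = spk_sev.to_dict()
        speakers_by_sev: dict[int, set[str]] = {}
        for s, v in self._sev_of.items():
            speakers_by_sev.setdefault(v, set()).add(s)
        skipped = sorted(v for v, ss in speakers_by_sev.items() if len(ss) < 2)
        if skipped:
            logger.info(
                "severity classes with <2 speakers contribute no triplets: %s", skipped
            )
        self.skipped_severities = skipped

        # utterance ids per (speaker, word)
        self._utts: dict[tuple[str, str], list[str]] = {}
        for uid, s, w in zip(df["utterance_id"], df["speaker_id"], df["word_id"]):
            self._utts.setdefault((s, w), []).append(uid)
        words_of: dict[str, list[str]] = {}
        for (s, w) in self._utts:
            words_of.setdefault(s, []).append(w)

        # positives per (speaker, word): same-severity other speakers' utterances
        # of that word; pos_count drives the completion-count arithmetic.
        self._positives: dict[tuple[str, str], list[str]] = {}
        pos_count: dict[tuple[str, str], int] = {}
        for s, words in words_of.items():
            peers = speakers_by_sev[self._sev_of[s]] - {s}
            for w in words:
                plist = [u for p in sorted(peers) for u in self._utts.get((p, w), [])]
                self._positives[(s, w)] = plist
                pos_count[(s, w)] = len(plist)

        # per-speaker word lists with completion weights
        self._neg_words: dict[str, list[str]] = {}
        self._neg_weights: dict[str, np.ndarray] = {}
        totals: dict[str, int] = {}
        for s, words in words_of.items():
            ws = sorted(words)
            weights = np.array(
                [len(self._utts[(s, w)]) * pos_count[(s, w)] for w in ws], dtype=np.int64
            )
            self._neg_words[s] = ws
            self._neg_weights[s] = weights
            totals[s] = int(weights.sum())

        # valid anchors with their completion counts
        self._anchors: list[str] = []
        anchor_completions: list[int] = []
        for uid, s, w in zip(df["utterance_id"], df["speaker_id"], df["word_id"]):
            own = len(self._utts[(s, w)]) * pos_count[(s, w)]
            n_comp = totals[s] - own
            if n_comp > 0:
                self._anchors.append(uid)
                anchor_completions.append(n_comp)
        self._anchor_completions = np.array(anchor_completions, dtype=np.int64)
        self._anchor_info = {
            uid: (s, w)
            for uid, s, w in zip(df["utterance_id"], df["speaker_id"], df["word_id"])
        }

    @property
    def n_valid_anchors(self) -> int:
        return len(self._anchors)

    @property
    def total_count(self) -> int:
        """Exact number of distinct valid triplets."""
        return int(self._anchor_completions.sum())

    def _completion(self, anchor_uid: str, rng: np.random.Generator) -> Triplet:
        s, w = self._anchor_info[anchor_uid]
        words = self._neg_words[s]
        weights = self._neg_weights[s].astype(np.float64).copy()
        if w in words:
            weights[words.index(w)] = 0.0
        total = weights.sum()
        # uniform over (negative, positive) pairs == word choice weighted by
        # reps(word) * positives(word), then uniform negative rep and positive
        w_neg = words[int(rng.choice(len(words), p=weights / total))]
        neg = self._utts[(s, w_neg)][int(rng.integers(len(self._utts[(s, w_neg)])))]
        plist = self._positives[(s, w_neg)]
        pos = plist[int(rng.integers(len(plist)))]
        return Triplet(anchor_id=anchor_uid, positive_id=pos, negative_id=neg)

    def sample(self, n: int, rng: np.random.Generator) -> list[Triplet]:
        """Draw n triplets (uniform anchors, then uniform completions)."""
        if self.total_count == 0 or n <= 0:
            return []
        idx = rng.integers(len(self._anchors), size=n)
        return [self._completion(self._anchors[i], rng) for i in idx]

    def enumerate_all(self) -> list[Triplet]:
        """Every valid triplet, in deterministic order."""
        out: list[Triplet] = []
        for anchor in self._anchors:
            s, w = self._anchor_info[anchor]
            for w_neg in self._neg_words[s]:
                if w_neg == w:
                    continue
                plist = self._positives[(s, w_neg)]
                if not plist:
                    continue
                for neg in self._utts[(s, w_neg)]:
                    for pos in plist:
                        out.append(Triplet(anchor, pos, neg))
        return out


def mine_triplets(metadata, n_triplets: int, rng_seed: int = 0) -> list[Triplet]:
    """Sample valid triplets from corpus metadata, reproducibly.

    If ``n_triplets`` is at least the total number of distinct valid
    triplets, the full deterministic enumeration is returned instead of a
    sample.  When no valid triplet exists anywhere a warning is issued and
    an empty list returned.
    """
    miner = TripletMiner(metadata)
    if miner.total_count == 0:
        warnings.warn("no valid triplet exists in this metadata", stacklevel=2)
        return []
    if n_triplets >= miner.total_count:
        return miner.enumerate_all()
    rng = np.random.default_rng(rng_seed)
    return miner.sample(n_triplets, rng)


def triplets_to_frame(triplets: list[Triplet]) -> pd.DataFrame:
    """Audit export: one row per triplet (anchor_id, positive_id, negative_id)."""
    return pd.DataFrame(
        [(t.anchor_id, t.positive_id, t.negative_id) for t in triplets],
        columns=["anchor_id", "positive_id", "negative_id"],
    )


def _pair_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum((A - B) ** 2, axis=-1))


def triplet_margin_loss(anchor, positive, negative, config: LossConfig) -> float:
    """Hinge loss for one triplet of embedding vectors (L2 distances).

    ``stated_aims``:     max(0, d(a, p) - d(a, n) + m)
    ``literal_printed``: max(0, d(a, n) - d(a, p) + m)
    """
    a = np.asarray(anchor, dtype=np.float64)
    p = np.asarray(positive, dtype=np.float64)
    n = np.asarray(negative, dtype=np.float64)
    if not (a.shape == p.shape == n.shape):
        raise ValueError(f"shape mismatch: {a.shape}, {p.shape}, {n.shape}")
    losses, _ = triplet_margin_loss_batch(
        a[None, :], p[None, :], n[None, :], config, with_grads=False
    )
    return float(losses[0])


def triplet_margin_loss_batch(
    A: np.ndarray,
    P: np.ndarray,
    N: np.ndarray,
    config: LossConfig,
    with_grads: bool = True,
):
    """Vectorised triplet hinge over (T, d) batches.

    Returns ``(losses, grads)`` where ``losses`` is (T,) and ``grads`` is
    ``(dA, dP, dN)`` of per-triplet loss gradients (or None when
    ``with_grads`` is false).  Zero-distance pairs take a zero subgradient.
    """
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    N = np.atleast_2d(np.asarray(N, dtype=np.float64))
    if not (A.shape == P.shape == N.shape):
        raise ValueError(f"shape mismatch: {A.shape}, {P.shape}, {N.shape}")
    d_ap = _pair_distance(A, P)
    d_an = _pair_distance(A, N)
    sign = 1.0 if config.formula_variant == "stated_aims" else -1.0
    hinge = sign * (d_ap - d_an) + config.margin
    losses = np.maximum(hinge, 0.0)
    if not with_grads:
        return losses, None
    active = (hinge > 0.0).astype(np.float64)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        u_ap = np.where(d_ap[:, None] > 0.0, (A - P) / d_ap[:, None], 0.0)
        u_an = np.where(d_an[:, None] > 0.0, (A - N) / d_an[:, None], 0.0)
    dA = active * sign * (u_ap - u_an)
    dP = active * sign * (-u_ap)
    dN = active * sign * u_an
    return losses, (dA, dP, dN)


def gamma_schedule(step: int, config: LossConfig) -> float:
    """Cross-entropy weight: 0 during warm-up, 1 from step gamma_warmup_steps."""
    if step < 0:
        raise ValueError(f"step must be >= 0, got {step}")
    return 0.0 if step < config.gamma_warmup_steps else 1.0


def combined_loss(l_reg: float, l_ce: float, step: int, config: LossConfig) -> float:
    """Total loss epsilon * L_reg + gamma(step) * L_CE."""
    if not (np.isfinite(l_reg) and np.isfinite(l_ce)):
        raise ValueError(f"non-finite loss inputs: L_reg={l_reg}, L_CE={l_ce}")
    return config.epsilon * float(l_reg) + gamma_schedule(step, config) * float(l_ce)
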