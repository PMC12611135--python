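"""Corpus data model, manifest I/O and leave-one-subject-out fold construction.

The corpus layout mirrors the isolated-word protocol used in dysarthric-speech
studies: each speaker reads several blocks of words, each block containing a
fixed set of *common* words (repeated in every block) plus a set of *uncommon*
words that occur exactly once per speaker.  Every speaker carries exactly one
severity label derived from an intelligibility percentage, which is what makes
speaker identity a shortcut for severity (the speaker-severity confound).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SeverityLevel",
    "UtteranceRecord",
    "CorpusManifest",
    "FoldSpec",
    "SchemaError",
    "IntegrityError",
    "read_manifest",
    "write_manifest",
    "validate_manifest",
    "build_loso_folds",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "utterance_id",
    "speaker_id",
    "word_id",
    "word_category",
    "block",
    "severity",
    "intelligibility",
    "signal_ref",
]


class SchemaError(ValueError):
    """Manifest file does not follow the documented CSV schema."""


class IntegrityError(ValueError):
    """Manifest contents violate a corpus invariant."""


class SeverityLevel(enum.IntEnum):
    """Four ordinal severity bands defined by speech-intelligibility ranges.

    Higher ordinal code means more severe dysarthria (lower intelligibility):
    very_low (76-100%], low (51-75%], medium (26-50%], high [0-25%].
    """

    VERY_LOW = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @property
    def intelligibility_range(self) -> tuple[float, float]:
        """(low, high] intelligibility band in percent; HIGH includes 0."""
        return {
            SeverityLevel.VERY_LOW: (76.0, 100.0),
            SeverityLevel.LOW: (51.0, 75.0),
            SeverityLevel.MEDIUM: (26.0, 50.0),
            SeverityLevel.HIGH: (0.0, 25.0),
        }[self]

    @classmethod
    def from_label(cls, label: str) -> "SeverityLevel":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown severity label {label!r}; expected one of "
                f"{[s.label for s in cls]}"
            ) from None

    @classmethod
    def from_intelligibility(cls, percent: float) -> "SeverityLevel":
        """Map an intelligibility percentage onto its severity band.

        Band edges belong to the upper (milder) band, so the four bands
        partition [0, 100]: >=76 very_low, >=51 low, >=26 medium, else high.
        """
        if not 0.0 <= percent <= 100.0:
            raise ValueError(f"intelligibility must be in [0, 100], got {percent}")
        if percent >= 76.0:
            return cls.VERY_LOW
        if percent >= 51.0:
            return cls.LOW
        if percent >= 26.0:
            return cls.MEDIUM
        return cls.HIGH


@dataclass(frozen=True)
class UtteranceRecord:
    """One isolated-word utterance by one speaker in one block."""

    utterance_id: str
    speaker_id: str
    word_id: str
    word_category: str  # "common" | "uncommon"
    block: int
    severity: SeverityLevel
    intelligibility: float
    signal_ref: str

    def __post_init__(self) -> None:
        if self.word_category not in ("common", "uncommon"):
            raise ValueError(
                f"word_category must be 'common' or 'uncommon', got {self.word_category!r}"
            )
        if self.block < 1:
            raise ValueError(f"block must be a positive integer, got {self.block}")


@dataclass
class CorpusManifest:
    """All utterance records plus the authoritative per-speaker severity table.

    The speaker table maps speaker_id -> (severity, intelligibility percent)
    and is the single source of truth for severity; record-level severities
    are a denormalised copy of it.
    """

    records: list[UtteranceRecord] = field(default_factory=list)
    speakers: dict[str, tuple[SeverityLevel, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def speaker_ids(self) -> list[str]:
        return sorted(self.speakers)

    def severity_of(self, speaker_id: str) -> SeverityLevel:
        return self.speakers[speaker_id][0]

    def by_utterance(self) -> dict[str, UtteranceRecord]:
        return {r.utterance_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per record, columns as in the CSV schema."""
        return pd.DataFrame(
            [
                {
                    "utterance_id": r.utterance_id,
                    "speaker_id": r.speaker_id,
                    "word_id": r.word_id,
                    "word_category": r.word_category,
                    "block": r.block,
                    "severity": r.severity.label,
                    "intelligibility": r.intelligibility,
                    "signal_ref": r.signal_ref,
                }
                for r in self.records
            ],
            columns=MANIFEST_COLUMNS,
        )

    def validate(self) -> list[str]:
        return validate_manifest(self)


def validate_manifest(manifest: CorpusManifest) -> list[str]:
    """Check every corpus invariant; return human-readable violations.

    An empty list means the manifest is valid.  Reported rules:

    - unique utterance_id and unique (speaker_id, word_id, block)
    - every record's speaker is in the speaker table
    - record severity/intelligibility agree with the speaker table
    - a common word of a speaker appears in every block that speaker uses
    - an uncommon word occurs exactly once per speaker
    """
    violations: list[str] = []
    seen_utt: set[str] = set()
    seen_key: set[tuple[str, str, int]] = set()
    blocks_by_speaker: dict[str, set[int]] = {}
    word_blocks: dict[tuple[str, str], list[int]] = {}
    word_category: dict[tuple[str, str], str] = {}

    for r in manifest.records:
        if r.utterance_id in seen_utt:
            violations.append(f"duplicate utterance_id {r.utterance_id!r}")
        seen_utt.add(r.utterance_id)
        key = (r.speaker_id, r.word_id, r.block)
        if key in seen_key:
            violations.append(
                f"duplicate (speaker, word, block) {key!r} at record {r.utterance_id!r}"
            )
        seen_key.add(key)
        if r.speaker_id not in manifest.speakers:
            violations.append(
                f"record {r.utterance_id!r}: speaker {r.speaker_id!r} missing from speaker table"
            )
        else:
            sev, intel = manifest.speakers[r.speaker_id]
            if r.severity is not sev:
                violations.append(
                    f"record {r.utterance_id!r}: severity {r.severity.label} disagrees "
                    f"with speaker table ({sev.label}) for speaker {r.speaker_id!r}"
                )
            if r.intelligibility != intel:
                violations.append(
                    f"record {r.utterance_id!r}: intelligibility {r.intelligibility} "
                    f"disagrees with speaker table ({intel})"
                )
        blocks_by_speaker.setdefault(r.speaker_id, set()).add(r.block)
        word_blocks.setdefault((r.speaker_id, r.word_id), []).append(r.block)
        word_category[(r.speaker_id, r.word_id)] = r.word_category

    for (spk, word), blocks in word_blocks.items():
        if word_category[(spk, word)] == "common":
            if set(blocks) != blocks_by_speaker.get(spk, set()):
                violations.append(
                    f"common word {word!r} of speaker {spk!r} does not recur in "
                    f"every block of that speaker"
                )
        else:
            if len(blocks) != 1:
                violations.append(
                    f"uncommon word {word!r} of speaker {spk!r} occurs {len(blocks)} "
                    f"times (must occur exactly once per speaker)"
                )
    return violations


def read_manifest(path: str | Path) -> CorpusManifest:
    """Read and fully validate a manifest CSV (schema in MANIFEST_COLUMNS).

    Raises SchemaError on a malformed header and IntegrityError on any
    invariant violation (inconsistent per-speaker severity, duplicated
    (speaker, word, block), unknown severity label, ...).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"utterance_id": str, "speaker_id": str, "word_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path} is missing columns {missing}")

    speakers: dict[str, tuple[SeverityLevel, float]] = {}
    records: list[UtteranceRecord] = []
    for row in df.itertuples(index=False):
        sev = SeverityLevel.from_label(str(row.severity))
        intel = float(row.intelligibility)
        if not 0.0 <= intel <= 100.0:
            raise IntegrityError(
                f"intelligibility {intel} out of [0, 100] for utterance {row.utterance_id!r}"
            )
        prev = speakers.get(str(row.speaker_id))
        if prev is not None and prev != (sev, intel):
            raise IntegrityError(
                f"speaker {row.speaker_id!r} has inconsistent severity/intelligibility "
                f"across rows: {prev[0].label}/{prev[1]} vs {sev.label}/{intel}"
            )
        speakers[str(row.speaker_id)] = (sev, intel)
        records.append(
            UtteranceRecord(
                utterance_id=str(row.utterance_id),
                speaker_id=str(row.speaker_id),
                word_id=str(row.word_id),
                word_category=str(row.word_category),
                block=int(row.block),
                severity=sev,
                intelligibility=intel,
                signal_ref=str(row.signal_ref),
            )
        )
    manifest = CorpusManifest(records=records, speakers=speakers)
    violations = manifest.validate()
    if violations:
        raise IntegrityError("; ".join(violations))
    return manifest


def write_manifest(manifest: CorpusManifest, path: str | Path) -> Path:
    """Write the manifest as CSV; read_manifest(write_manifest(m)) == m."""
    path = Path(path)
    manifest.to_frame().to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class FoldSpec:
    """One leave-one-subject-out fold.

    In ``uncommon_only`` mode the training set is every common-word utterance
    of the non-held-out speakers and the test set is every uncommon-word
    utterance of the held-out speaker, so both the voice and the vocabulary
    are novel at test time.  In ``all_words`` mode the test set is every
    utterance of the held-out speaker.
    """

    held_out_speaker: str
    train_utterances: tuple[str, ...]
    test_utterances: tuple[str, ...]
    test_mode: str  # "uncommon_only" | "all_words"

    def __post_init__(self) -> None:
        if self.test_mode not in ("uncommon_only", "all_words"):
            raise ValueError(f"unknown test_mode {self.test_mode!r}")
        overlap = set(self.train_utterances) & set(self.test_utterances)
        if overlap:
            raise ValueError(f"train/test overlap in fold: {sorted(overlap)[:3]} ...")


def build_loso_folds(
    manifest: CorpusManifest, test_mode: str = "uncommon_only"
) -> list[FoldSpec]:
    """One fold per speaker, deterministic (speakers in sorted order).

    Training always uses only the other speakers; in ``uncommon_only`` mode
    it is further restricted to their common-word utterances, matching the
    protocol in which each training subject contributes blocks x common-words
    utterances and the held-out subject is tested on its uncommon words.
    """
    speakers = manifest.speaker_ids
    if len(speakers) < 2:
        raise ValueError("leave-one-subject-out requires at least 2 speakers")
    if test_mode not in ("uncommon_only", "all_words"):
        raise ValueError(f"unknown test_mode {test_mode!r}")
    if test_mode == "uncommon_only":
        for spk in speakers:
            cats = {r.word_category for r in manifest.records if r.speaker_id == spk}
            if cats != {"common", "uncommon"}:
                raise ValueError(
                    f"uncommon_only mode needs both word categories for every "
                    f"speaker; speaker {spk!r} has {sorted(cats)}"
                )
    folds = []
    for held_out in speakers:
        if test_mode == "uncommon_only":
            train = [
                r.utterance_id
                for r in manifest.records
                if r.speaker_id != held_out and r.word_category == "common"
            ]
            test = [
                r.utterance_id
                for r in manifest.records
                if r.speaker_id == held_out and r.word_category == "uncommon"
            ]
        else:
            train = [r.utterance_id for r in manifest.records if r.speaker_id != held_out]
            test = [r.utterance_id for r in manifest.records if r.speaker_id == held_out]
        folds.append(
            FoldSpec(
                held_out_speaker=held_out,
                train_utterances=tuple(train),
                test_utterances=tuple(test),
                test_mode=test_mode,
            )
        )
    return folds
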