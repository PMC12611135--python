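"""Shared fixtures: tiny hand-built manifests and small generated corpora."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from salr.corpus import CorpusManifest, SeverityLevel, UtteranceRecord
from salr.synth import GeneratorConfig, generate_corpus


def make_manifest(rows: list[tuple], speakers: dict[str, tuple[str, float]]) -> CorpusManifest:
    """Build a manifest from (speaker, word, category, block) tuples."""
    table = {
        s: (SeverityLevel.from_label(sev), intel) for s, (sev, intel) in speakers.items()
    }
    records = []
    for spk, word, cat, block in rows:
        sev, intel = table[spk]
        records.append(
            UtteranceRecord(
                utterance_id=f"{spk}_B{block}_{word}",
                speaker_id=spk,
                word_id=word,
                word_category=cat,
                block=block,
                severity=sev,
                intelligibility=intel,
                signal_ref=f"{spk}_B{block}_{word}",
            )
        )
    return CorpusManifest(records=records, speakers=table)


@pytest.fixture
def two_speaker_manifest() -> CorpusManifest:
    """Two same-severity speakers, two shared words, one block each."""
    return make_manifest(
        rows=[
            ("S1", "w1", "uncommon", 1),
            ("S1", "w2", "uncommon", 1),
            ("S2", "w1", "uncommon", 1),
            ("S2", "w2", "uncommon", 1),
        ],
        speakers={"S1": ("low", 60.0), "S2": ("low", 55.0)},
    )


@pytest.fixture(scope="session")
def small_corpus():
    """Reduced-protocol corpus: 6 speakers (2/1/1/2), 2 blocks, 8+3 words."""
    config = GeneratorConfig(
        speakers_per_severity=(2, 1, 1, 2),
        n_blocks=2,
        n_common_words=8,
        n_uncommon_per_block=3,
        feature_dim=16,
        seed=11,
    )
    manifest, store = generate_corpus(config)
    return config, manifest, store


@pytest.fixture(scope="session")
def default_corpus():
    """Full default-protocol corpus (15 speakers, 765 utterances each)."""
    config = GeneratorConfig(seed=5)
    manifest, store = generate_corpus(config)
    return config, manifest, store


def metadata_frame(manifest: CorpusManifest) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "utterance_id": [r.utterance_id for r in manifest.records],
            "speaker_id": [r.speaker_id for r in manifest.records],
            "word_id": [r.word_id for r in manifest.records],
            "severity": [int(r.severity) for r in manifest.records],
        }
    )
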