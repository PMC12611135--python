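"""Independent reference implementations used only to cross-check the package."""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_triplets(metadata: pd.DataFrame) -> set[tuple[str, str, str]]:
    """Triple loop over all utterance triples, checking every constraint.

    Returns the set of (anchor, positive, negative) utterance-id triples with:
    speaker(a) == speaker(n), word(a) != word(n), word(p) == word(n),
    speaker(p) != speaker(a), severity(p) == severity(a).
    """
    rows = list(metadata.itertuples(index=False))
    out = set()
    for a in rows:
        for p in rows:
            for n in rows:
                if (
                    a.speaker_id == n.speaker_id
                    and a.word_id != n.word_id
                    and p.word_id == n.word_id
                    and p.speaker_id != a.speaker_id
                    and p.severity == a.severity
                ):
                    out.add((a.utterance_id, p.utterance_id, n.utterance_id))
    return out


def random_small_metadata(rng: np.random.Generator) -> pd.DataFrame:
    """A random metadata table with <=6 speakers, <=4 words, <=2 blocks."""
    n_speakers = int(rng.integers(2, 7))
    n_words = int(rng.integers(2, 5))
    n_blocks = int(rng.integers(1, 3))
    speakers = [f"S{i}" for i in range(n_speakers)]
    severities = {s: int(rng.integers(0, 4)) for s in speakers}
    words = [f"w{i}" for i in range(n_words)]
    rows = []
    for s in speakers:
        for w in words:
            for b in range(1, n_blocks + 1):
                if rng.random() < 0.7:
                    rows.append(
                        {
                            "utterance_id": f"{s}_B{b}_{w}",
                            "speaker_id": s,
                            "word_id": w,
                            "severity": severities[s],
                        }
                    )
    return pd.DataFrame(rows, columns=["utterance_id", "speaker_id", "word_id", "severity"])
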