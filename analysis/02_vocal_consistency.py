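#!/usr/bin/env python
"""Measure vocal consistency of every simulated song from its audio.

Reads the WAV clips, label tracks and metadata written by
01_simulate_dawn_sessions.py, assembles annotated songs, and scores each
song's trill by spectrogram cross-correlation (512-sample Hann window, 90%
overlap, max offset 20 ms).  Writes the per-song table consumed by the bout
and warm-up analysis.
"""

import sys
from pathlib import Path

import pandas as pd

from bluetitsong import (
    assemble_songs,
    read_label_track,
    read_wav,
    song_consistency_from_annotations,
)

SCRATCH = Path("scratch/dawn_sessions")
RESULTS = Path("results")


def main() -> int:
    if not (SCRATCH / "metadata.csv").exists():
        print("run analysis/01_simulate_dawn_sessions.py first", file=sys.stderr)
        return 1
    metadata = pd.read_csv(SCRATCH / "metadata.csv")
    clips = {sid: read_wav(SCRATCH / f"{sid}.wav") for sid in metadata.song_id}
    tracks = {sid: read_label_track(SCRATCH / f"{sid}.txt") for sid in metadata.song_id}
    songs = assemble_songs(clips, tracks, metadata)

    rows = []
    for song in songs:
        if song.excluded:
            continue
        res = song_consistency_from_annotations(song)
        rows.append(
            {
                "song_id": song.song_id,
                "male_id": song.male_id,
                "song_type": song.song_type,
                "timestamp": song.timestamp.isoformat(),
                "context": song.context,
                "n_trill_notes": song.trill_length,
                "vocal_consistency": res.song_score,
            }
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "consistency.csv", index=False)
    by_male = table.groupby("male_id").vocal_consistency.agg(["mean", "std", "count"])
    print(f"scored {len(table)} songs -> {RESULTS / 'consistency.csv'}")
    print("mean vocal consistency per male (higher = more precise trills):")
    print(by_male.round(4).to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
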