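#!/usr/bin/env python
"""Generate synthetic dawn-song sessions as WAV + label-track + metadata files.

Three simulated males each sing a dawn session of song-type bouts (two song
types, bouts separated by >1 min pauses or type switches).  Audio and
Audacity-style label tracks go to scratch/dawn_sessions/ (regenerable,
excluded from version control); the ground-truth table (which bout every
song belongs to, with its injected jitter) goes to results/.
"""

import sys
from pathlib import Path

import pandas as pd

from bluetitsong import (
    SynthSessionConfig,
    SynthSongConfig,
    synth_dawn_session,
    write_label_track,
    write_wav,
)

SCRATCH = Path("scratch/dawn_sessions")
RESULTS = Path("results")

MALES = {
    "m01": (0, SynthSessionConfig(
        song_types={"A": SynthSongConfig(freq_jitter_sd=40.0),
                    "B": SynthSongConfig(f0=5400.0, n_trill=10, freq_jitter_sd=40.0)},
        bout_types=("A", "A", "B"), bout_lengths=(10, 8, 12))),
    "m02": (1, SynthSessionConfig(
        song_types={"A": SynthSongConfig(freq_jitter_sd=120.0),
                    "B": SynthSongConfig(f0=6600.0, n_trill=6, freq_jitter_sd=120.0)},
        bout_types=("A", "B", "B"), bout_lengths=(8, 9, 7))),
    "m03": (2, SynthSessionConfig(
        song_types={"A": SynthSongConfig(freq_jitter_sd=250.0),
                    "B": SynthSongConfig(f0=5000.0, n_trill=8, freq_jitter_sd=250.0)},
        bout_types=("B", "A", "A"), bout_lengths=(12, 6, 9))),
}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    truth_tables = []
    meta_rows = []
    n_songs = 0
    for male_id, (seed, cfg) in MALES.items():
        songs, truth = synth_dawn_session(cfg, seed=seed, male_id=male_id)
        truth["male_id"] = male_id
        truth_tables.append(truth)
        for song in songs:
            sid = song.song_id
            write_wav(SCRATCH / f"{sid}.wav", song.clip)
            write_label_track(SCRATCH / f"{sid}.txt", song.notes)
            meta_rows.append(
                {
                    "song_id": sid,
                    "male_id": male_id,
                    "timestamp": song.timestamp.isoformat(),
                    "context": song.context,
                    "song_type": song.song_type,
                }
            )
            n_songs += 1
    pd.concat(truth_tables).to_csv(RESULTS / "sessions_ground_truth.csv", index=False)
    pd.DataFrame(meta_rows).to_csv(SCRATCH / "metadata.csv", index=False)
    print(f"wrote {n_songs} songs for {len(MALES)} males under {SCRATCH}/")
    print(f"ground truth -> {RESULTS / 'sessions_ground_truth.csv'}")


if __name__ == "__main__":
    sys.exit(main())
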