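#!/usr/bin/env python
"""Build one complete playback trial stimulus from two synthetic song types.

Selects one exemplar song per song type, repeats each at its measured song
rate into 75 s song-type bouts, arranges 12 five-minute rounds (150 s song +
150 s silence, order randomised per round) after a 5 min lead silence, and
renders the hour-long stimulus peak-normalised to -3 dBFS.  The schedule and
cue tables go to results/; the WAV goes to scratch/.
"""

import sys
from pathlib import Path

import numpy as np

from bluetitsong import (
    SynthSongConfig,
    build_schedule,
    build_song_type_bout,
    render_schedule,
    schedule_bout_table,
    synth_song,
    write_wav,
)

RESULTS = Path("results")
SCRATCH = Path("scratch")
SEED = 2020


def main() -> int:
    rng = np.random.default_rng(SEED)
    song_a = synth_song(SynthSongConfig(freq_jitter_sd=40.0), rng, song_type="A")
    song_b = synth_song(SynthSongConfig(f0=5400.0, n_trill=10, freq_jitter_sd=40.0), rng,
                        song_type="B")
    # measured song rates (songs/min) for each type, as in the field protocol
    rate_a, rate_b = 14.0, 12.0
    bout_a = build_song_type_bout(song_a.clip, rate_a, song_type="A")
    bout_b = build_song_type_bout(song_b.clip, rate_b, song_type="B")
    sched = build_schedule("A", "B", seed=SEED)
    audio, cues = render_schedule(sched, {"A": bout_a, "B": bout_b})

    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    sched.to_frame().to_csv(RESULTS / "playback_schedule.csv", index=False)
    schedule_bout_table(sched).to_csv(RESULTS / "playback_bouts.csv", index=False)
    cues.to_csv(RESULTS / "playback_cues.csv", index=False)
    write_wav(SCRATCH / "playback_stimulus.wav", audio)

    tab = schedule_bout_table(sched)
    print(
        f"schedule: {len(sched.song_bouts)} song-type bouts in 12 rounds, "
        f"total {sched.duration / 60:.0f} min (lead silence {sched.lead_silence:.0f} s)"
    )
    print(
        f"bouts preceded by silence: {(tab.preceded_by == 'silence_gap').sum()}, "
        f"by a song-type switch: {(tab.preceded_by == 'type_switch').sum()}"
    )
    print(
        f"song onsets cued: {len(cues)} "
        f"({len(bout_a.onsets)}/bout for type A at {rate_a}/min, "
        f"{len(bout_b.onsets)}/bout for type B at {rate_b}/min)"
    )
    print(f"stimulus audio -> {SCRATCH / 'playback_stimulus.wav'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
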