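"""Construction of the dual-song-type playback stimulus.

The female-choice trial presents one hour of structured audio after a lead-in
silence of at least 5 min: 12 five-minute rounds, each containing one 150 s
song section (two 75 s song-type bouts, one of each of the male's two song
types) and one 150 s silence section, the song/silence order drawn at random
per round.  A song-type bout repeats one exemplar song at the male's measured
song rate for that type.  Rendering replaces field SPL calibration with
digital peak normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AudioClip

__all__ = [
    "PlaybackSegment",
    "PlaybackSchedule",
    "BoutAudio",
    "build_song_type_bout",
    "song_onsets",
    "build_schedule",
    "render_schedule",
]

ROUNDS = 12
BOUT_DURATION_S = 75.0
SECTION_DURATION_S = 2 * BOUT_DURATION_S  # 150 s of song or silence
ROUND_DURATION_S = 2 * SECTION_DURATION_S  # 5 min
CORE_DURATION_S = ROUNDS * ROUND_DURATION_S  # 1 h


@dataclass(frozen=True)
class PlaybackSegment:
    """One contiguous schedule element: a song-type bout or silence."""

    kind: str  # "song" | "silence"
    song_type: str | None
    start: float  # seconds from trial start
    duration: float

    def __post_init__(self) -> None:
        if self.kind not in ("song", "silence"):
            raise ValueError(f"bad segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.kind == "song" and self.song_type is None:
            raise ValueError("song segments need a song_type")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class PlaybackSchedule:
    """Ordered, contiguous segments of one trial stimulus."""

    segments: tuple[PlaybackSegment, ...]
    seed: int
    lead_silence: float

    @property
    def duration(self) -> float:
        return self.segments[-1].end

    @property
    def song_bouts(self) -> list[PlaybackSegment]:
        return [s for s in self.segments if s.kind == "song"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [s.kind for s in self.segments],
                "song_type": [s.song_type for s in self.segments],
                "start_s": [s.start for s in self.segments],
                "duration_s": [s.duration for s in self.segments],
            }
        )


@dataclass(frozen=True)
class BoutAudio:
    """A rendered 75 s song-type bout plus its song onset times."""

    clip: AudioClip
    onsets: tuple[float, ...]  # seconds from bout start
    song_type: str | None = None


def song_onsets(song_duration: float, measured_rate: float, bout_duration: float) -> tuple[float, ...]:
    """Song onset times at the measured rate: 0, 60/rate, 120/rate, ... while
    the whole song still fits inside the bout (no truncated final song)."""
    if measured_rate <= 0:
        raise ValueError("measured_rate must be positive")
    interval = 60.0 / measured_rate
    if song_duration > interval:
        raise ValueError(
            f"song of {song_duration:.2f} s exceeds the {interval:.2f} s inter-onset interval"
        )
    onsets = []
    k = 0
    while k * interval + song_duration <= bout_duration + 1e-9:
        onsets.append(k * interval)
        k += 1
    return tuple(onsets)


def build_song_type_bout(
    song: AudioClip,
    measured_rate: float,
    bout_duration: float = BOUT_DURATION_S,
    song_type: str | None = None,
) -> BoutAudio:
    """Repeat one exemplar song at its measured rate for a fixed-length bout.

    The bout is exactly ``bout_duration`` seconds; the remainder after the
    last complete song is silence.
    """
    onsets = song_onsets(song.duration, measured_rate, bout_duration)
    n = int(round(bout_duration * song.rate))
    out = np.zeros(n)
    for onset in onsets:
        i0 = int(round(onset * song.rate))
        out[i0 : i0 + song.samples.size] += song.samples
    return BoutAudio(AudioClip(out, song.rate), onsets, song_type)


def build_schedule(
    type_a: str,
    type_b: str,
    seed: int,
    lead_silence: float = 300.0,
) -> PlaybackSchedule:
    """Seeded trial schedule: 12 rounds of one song and one silence section.

    Per round the song/silence order is a fair draw, as is the order of the
    two song types within the song section — except that when two song
    sections abut (song-last round followed by song-first round), the later
    section is forced to open with the other song type, so that every bout is
    unambiguously preceded by either silence or a type switch.  The schedule
    is a pure function of its arguments.
    """
    if type_a == type_b:
        raise ValueError("the two song types must be distinct")
    if lead_silence < 300.0:
        raise ValueError("lead silence must be at least 300 s")
    rng = np.random.default_rng(seed)
    segments: list[PlaybackSegment] = [
        PlaybackSegment("silence", None, 0.0, lead_silence)
    ]
    t = lead_silence
    last_song_type: str | None = None  # type of the bout immediately before t
    prev_ended_with_song = False
    for _ in range(ROUNDS):
        song_first = bool(rng.integers(2))
        ab = bool(rng.integers(2))
        first, second = (type_a, type_b) if ab else (type_b, type_a)
        for section_kind in ("song", "silence") if song_first else ("silence", "song"):
            if section_kind == "silence":
                segments.append(PlaybackSegment("silence", None, t, SECTION_DURATION_S))
                t += SECTION_DURATION_S
                prev_ended_with_song = False
            else:
                if prev_ended_with_song and last_song_type == first:
                    first, second = second, first
                for st in (first, second):
                    segments.append(PlaybackSegment("song", st, t, BOUT_DURATION_S))
                    t += BOUT_DURATION_S
                last_song_type = second
                prev_ended_with_song = True
    return PlaybackSchedule(tuple(segments), seed, lead_silence)


def schedule_bout_table(schedule: PlaybackSchedule) -> pd.DataFrame:
    """Per-bout table with the habituation predictor ``preceded_by``:
    silence_gap if the preceding segment is silence, else type_switch."""
    rows = []
    prev: PlaybackSegment | None = None
    bout_index = 0
    for seg in schedule.segments:
        if seg.kind == "song":
            preceded = "silence_gap" if (prev is None or prev.kind == "silence") else "type_switch"
            rows.append(
                {
                    "bout_index": bout_index,
                    "song_type": seg.song_type,
                    "start_s": seg.start,
                    "duration_s": seg.duration,
                    "preceded_by": preceded,
                }
            )
            bout_index += 1
        prev = seg
    return pd.DataFrame(rows)


def render_schedule(
    schedule: PlaybackSchedule,
    bouts: dict[str, BoutAudio],
    peak_dbfs: float = -3.0,
) -> tuple[AudioClip, pd.DataFrame]:
    """Render a schedule to audio plus a cue table of every song onset.

    ``bouts`` maps each song type to its 75 s :class:`BoutAudio`.  The output
    is peak-normalised to ``peak_dbfs`` (digital stand-in for speaker SPL
    calibration), so clipping is impossible by construction.  The cue table
    lists trial-relative onset time, bout index, song type, position within
    the bout (1-based) and the bout's ``preceded_by`` state.
    """
    rates = {b.clip.rate for b in bouts.values()}
    if len(rates) != 1:
        raise ValueError("all bout clips must share one sample rate")
    rate = rates.pop()
    n = int(round(schedule.duration * rate))
    audio = np.zeros(n)
    cue_rows = []
    bout_table = schedule_bout_table(schedule)
    for row in bout_table.itertuples(index=False):
        bout = bouts[row.song_type]
        i0 = int(round(row.start_s * rate))
        audio[i0 : i0 + bout.clip.samples.size] = bout.clip.samples
        for pos, onset in enumerate(bout.onsets, start=1):
            cue_rows.append(
                {
                    "bout_index": row.bout_index,
                    "song_type": row.song_type,
                    "preceded_by": row.preceded_by,
                    "position": pos,
                    "onset_s": row.start_s + onset,
                }
            )
    peak = np.max(np.abs(audio))
    if peak > 0:
        audio *= 10 ** (peak_dbfs / 20.0) / peak
    return AudioClip(audio, rate), pd.DataFrame(cue_rows)
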