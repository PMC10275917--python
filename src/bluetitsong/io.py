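"""Audio and annotation I/O for trilled-song analysis.

Field recordings arrive as PCM WAV files plus note-level annotations made in a
spectrogram editor and exported as tab-separated label tracks
(``start<TAB>end<TAB>label``, times in seconds).  This module reads those
formats, slices annotated notes out of a clip, and assembles the
:class:`AnnotatedSong` objects the measurement modules consume.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "NoteSegment",
    "AnnotatedSong",
    "CallEvent",
    "read_label_track",
    "write_label_track",
    "read_wav",
    "write_wav",
    "slice_note",
    "assemble_songs",
    "read_call_events",
]


@dataclass(frozen=True)
class AudioClip:
    """Mono waveform with amplitudes in [-1, 1] and a sample rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("AudioClip requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioClip samples must be finite")
        if not self.rate > 0:
            raise ValueError("AudioClip rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.samples.size / self.rate


@dataclass(frozen=True)
class NoteSegment:
    """One annotated note: [start, end) in seconds plus its label."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid note segment [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AnnotatedSong:
    """A song clip with its ordered note annotations and metadata.

    The trill — the repeated terminal section on which vocal consistency is
    measured — is the suffix of ``notes`` starting at ``trill_index``.
    """

    song_id: str
    male_id: str
    timestamp: _dt.datetime
    context: str  # "dawn" or "daytime"
    song_type: str
    notes: list[NoteSegment]
    trill_index: int
    clip: AudioClip | None = None
    excluded: bool = field(default=False)
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.context not in ("dawn", "daytime"):
            raise ValueError(f"context must be 'dawn' or 'daytime', got {self.context!r}")
        starts = [n.start for n in self.notes]
        if starts != sorted(starts):
            raise ValueError("notes must be ordered by start time")
        for a, b in zip(self.notes, self.notes[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping notes at {a.end:.4f}/{b.start:.4f} s")
        if not 0 <= self.trill_index <= len(self.notes):
            raise ValueError("trill_index out of range")

    @property
    def trill_notes(self) -> list[NoteSegment]:
        return self.notes[self.trill_index:]

    @property
    def trill_length(self) -> int:
        """Number of notes in the trill."""
        return len(self.trill_notes)

    @property
    def duration(self) -> float:
        """Span from first note start to last note end (0 if unannotated)."""
        if not self.notes:
            return 0.0
        return self.notes[-1].end - self.notes[0].start


CALL_CLASSES = (
    "copulation",
    "twittering",
    "chattering",
    "churring",
    "screaming",
    "unclassified",
)


@dataclass(frozen=True)
class CallEvent:
    """A classified female call at ``time`` seconds from trial start."""

    time: float
    call_class: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("call time must be >= 0")
        if self.call_class not in CALL_CLASSES:
            raise ValueError(f"unknown call class {self.call_class!r}")


def read_label_track(path: str | Path) -> list[NoteSegment]:
    """Read a tab-separated label track (``start\\tend\\tlabel`` per line).

    Blank lines are skipped; segments are returned sorted by start time.
    Malformed lines raise ``ValueError`` naming the line number.
    """
    segments = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric start/end time") from None
            try:
                segments.append(NoteSegment(start, end, parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    segments.sort(key=lambda s: s.start)
    return segments


def write_label_track(path: str | Path, segments: Iterable[NoteSegment]) -> None:
    """Write segments in the same 3-column tab-separated dialect (6 decimals)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.start:.6f}\t{seg.end:.6f}\t{seg.label}\n")


_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path: str | Path) -> AudioClip:
    """Read a PCM WAV file as a mono clip with samples in [-1, 1].

    Stereo files are averaged across channels.  16-bit and 24/32-bit integer
    PCM are scaled by 2**15 and 2**31 respectively (24-bit data arrives
    left-justified in int32); float WAVs are taken as-is.
    """
    rate, data = wavfile.read(path)
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding: {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioClip(samples, float(rate))


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV (values clipped to full scale)."""
    scaled = np.clip(clip.samples, -1.0, 32767 / 32768) * 32768
    wavfile.write(path, int(round(clip.rate)), scaled.astype(np.int16))


def _sample_index(t: float, rate: float) -> int:
    # round-half-up so segment end k and next segment start k agree exactly
    return int(np.floor(t * rate + 0.5))


def slice_note(clip: AudioClip, seg: NoteSegment) -> AudioClip:
    """Extract the half-open sample interval [round(start*rate), round(end*rate)).

    Slicing a clip by any partition of [0, duration) and concatenating the
    pieces reproduces the original sample sequence exactly.
    """
    i0 = _sample_index(seg.start, clip.rate)
    i1 = _sample_index(seg.end, clip.rate)
    if i0 < 0 or i1 > clip.samples.size:
        raise ValueError(
            f"segment [{seg.start}, {seg.end}) s outside clip of {clip.duration:.6f} s"
        )
    if i1 <= i0:
        raise ValueError(f"segment [{seg.start}, {seg.end}) rounds to zero samples")
    return AudioClip(clip.samples[i0:i1], clip.rate)


def assemble_songs(
    clips: Mapping[str, AudioClip],
    label_tracks: Mapping[str, Sequence[NoteSegment]],
    metadata: pd.DataFrame,
    trill_label: str = "trill",
    min_trill_notes: int = 2,
) -> list[AnnotatedSong]:
    """Join clips, label tracks and a metadata table into AnnotatedSongs.

    ``metadata`` needs columns song_id, male_id, timestamp (ISO-8601), context
    and song_type.  The trill is identified by ``trill_label``: the trailing
    run of notes carrying that label.  Songs whose trill has fewer than
    ``min_trill_notes`` notes (pairwise consistency undefined below 2) are
    returned flagged ``excluded`` rather than dropped, so totals stay auditable.
    """
    meta = metadata.set_index("song_id")
    missing = sorted(set(clips) - set(meta.index))
    if missing:
        raise KeyError(f"song_ids missing from metadata: {missing}")
    missing_tracks = sorted(set(clips) - set(label_tracks))
    if missing_tracks:
        raise KeyError(f"song_ids missing label tracks: {missing_tracks}")

    songs = []
    for song_id in sorted(clips):
        clip = clips[song_id]
        notes = sorted(label_tracks[song_id], key=lambda s: s.start)
        trill_index = len(notes)
        for i in range(len(notes) - 1, -1, -1):
            if notes[i].label == trill_label:
                trill_index = i
            else:
                break
        row = meta.loc[song_id]
        song = AnnotatedSong(
            song_id=song_id,
            male_id=str(row["male_id"]),
            timestamp=pd.Timestamp(row["timestamp"]).to_pydatetime(),
            context=str(row["context"]),
            song_type=str(row["song_type"]),
            notes=notes,
            trill_index=trill_index,
            clip=clip,
        )
        n_trill = song.trill_length
        if n_trill < min_trill_notes:
            song = replace_excluded(song, f"trill has {n_trill} note(s), need >= {min_trill_notes}")
        songs.append(song)
    return songs


def replace_excluded(song: AnnotatedSong, reason: str) -> AnnotatedSong:
    song = replace(song)
    song.excluded = True
    song.exclusion_reason = reason
    return song


def read_call_events(path: str | Path) -> list[CallEvent]:
    """Read female call events from CSV with columns time_s, call_class."""
    table = pd.read_csv(path)
    return [
        CallEvent(float(row.time_s), str(row.call_class))
        for row in table.itertuples(index=False)
    ]
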