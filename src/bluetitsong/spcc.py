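"""Spectrogram cross-correlation (SPCC) and vocal consistency.

Vocal consistency scores how precisely a bird repeats the same note within a
trill.  Each note is turned into a magnitude spectrogram (512-sample Hann
window, 90% overlap by default); every pair of trill notes is compared by
sliding one spectrogram against the other over temporal offsets up to
+/-20 ms and taking the maximum Pearson correlation over the overlapping
time-frequency cells; a note's consistency is the mean of its pairwise scores
against every other trill note, and the song's consistency is the mean over
notes.  Scores live in [-1, 1], with 1 for perfectly repeated notes.

Implementation notes
--------------------
* The offset grid is +/-``max_offset`` at ``offset_step`` resolution, rounded
  to the native spectrogram frame grid and deduplicated — with the default
  512-sample window and 90% overlap at 48 kHz the native hop is ~1.06 ms, the
  closest realizable version of a 1 ms search grid.
* At each lag the correlation is computed over the overlapping frame range
  only, after dropping frame columns that are entirely zero in *both*
  spectrograms.  Silent margins therefore carry no weight, which makes the
  score exactly invariant to shifting a note within its silent padding (up to
  the lag-search range).
* Notes shorter than one FFT window are zero-padded up to a single window so
  very short notes stay computable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import AudioClip, AnnotatedSong, slice_note

__all__ = [
    "SpectrogramMatrix",
    "ConsistencyResult",
    "spectrogram",
    "spcc_pair",
    "note_consistency",
    "song_consistency",
    "song_consistency_from_annotations",
    "resample_clip",
]


@dataclass(frozen=True)
class SpectrogramMatrix:
    """Non-negative magnitude spectrogram (freq bins x time frames)."""

    values: np.ndarray
    frame_step: float  # seconds per frame
    freq_step: float  # Hz per bin

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (freq x time)")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("spectrogram values must be finite and non-negative")
        if not self.frame_step > 0:
            raise ValueError("frame_step must be positive")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConsistencyResult:
    """Pairwise SPCC matrix with per-note and song-level consistency."""

    pair_matrix: np.ndarray  # symmetric, diagonal 1
    note_scores: np.ndarray  # mean of each row excluding the diagonal
    song_score: float  # mean of note_scores

    @property
    def n_notes(self) -> int:
        return self.pair_matrix.shape[0]


def spectrogram(
    clip: AudioClip,
    window_samples: int = 512,
    overlap_fraction: float = 0.9,
    window_shape: str = "hann",
) -> SpectrogramMatrix:
    """Magnitude spectrogram with the analysis windowing used throughout.

    Frames advance by ``window_samples * (1 - overlap_fraction)`` samples and
    no boundary padding is applied, so the frame count is
    ``floor((N - window) / hop) + 1``.  Clips shorter than one window raise;
    callers that must handle very short notes should zero-pad first (see
    :func:`song_consistency`).
    """
    n = clip.samples.size
    if n < window_samples:
        raise ValueError(
            f"clip of {n} samples is shorter than one {window_samples}-sample window; "
            "zero-pad at the caller"
        )
    hop = max(1, int(round(window_samples * (1.0 - overlap_fraction))))
    freqs, _, sxx = signal.spectrogram(
        clip.samples,
        fs=clip.rate,
        window=window_shape,
        nperseg=window_samples,
        noverlap=window_samples - hop,
        detrend=False,
        mode="magnitude",
    )
    return SpectrogramMatrix(sxx, frame_step=hop / clip.rate, freq_step=float(freqs[1] - freqs[0]))


def _lag_grid(frame_step: float, max_offset: float, offset_step: float) -> np.ndarray:
    n_steps = int(np.floor(max_offset / offset_step + 1e-9))
    offsets = np.arange(-n_steps, n_steps + 1) * offset_step
    lags = np.unique(np.rint(offsets / frame_step).astype(int))
    # keep only lags whose realized offset stays within the search range
    return lags[np.abs(lags * frame_step) <= max_offset + 0.5 * frame_step]


def _pearson_flat(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson r over flattened cells; None if either side has zero variance."""
    x = a.ravel()
    y = b.ravel()
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        return None
    return float(np.clip((x @ y) / denom, -1.0, 1.0))


def spcc_pair(
    a: SpectrogramMatrix,
    b: SpectrogramMatrix,
    max_offset: float = 0.020,
    offset_step: float = 0.001,
    min_overlap_frames: int = 3,
) -> float:
    """Maximum Pearson correlation between two spectrograms over bounded lags.

    For each candidate lag the two matrices are aligned, frame columns that
    are all-zero in both are dropped, and the correlation is computed over the
    remaining overlapping cells (minimum ``min_overlap_frames`` frames, else
    the lag is skipped).  Symmetric in its arguments.  If every lag has
    zero-variance overlap (e.g. silence vs silence) the result is defined as
    0.0 and a warning is emitted.
    """
    if abs(a.frame_step - b.frame_step) > 1e-12 or abs(a.freq_step - b.freq_step) > 1e-9:
        raise ValueError("spectrograms must share frame_step and freq_step")
    if a.values.shape[0] != b.values.shape[0]:
        raise ValueError("spectrograms must share the frequency-bin grid")

    na, nb = a.n_frames, b.n_frames
    best: float | None = None
    for lag in _lag_grid(a.frame_step, max_offset, offset_step):
        # pair a[:, i] with b[:, i - lag]
        i0 = max(0, lag)
        i1 = min(na, nb + lag)
        if i1 - i0 < min_overlap_frames:
            continue
        wa = a.values[:, i0:i1]
        wb = b.values[:, i0 - lag : i1 - lag]
        keep = (wa.any(axis=0)) | (wb.any(axis=0))
        if keep.sum() < min_overlap_frames:
            continue
        r = _pearson_flat(wa[:, keep], wb[:, keep])
        if r is not None and (best is None or r > best):
            best = r
    if best is None:
        warnings.warn("zero-variance overlap at every lag; SPCC defined as 0", stacklevel=2)
        return 0.0
    return best


def note_consistency(pair_matrix: np.ndarray, i: int) -> float:
    """Mean SPCC of note ``i`` against every other note (row mean, no diagonal)."""
    m = np.asarray(pair_matrix, dtype=np.float64)
    n = m.shape[0]
    if n < 2:
        raise ValueError("consistency undefined for fewer than 2 notes")
    row = np.delete(m[i], i)
    return float(row.mean())


def _pad_to_window(clip: AudioClip, window_samples: int) -> AudioClip:
    if clip.samples.size >= window_samples:
        return clip
    pad = window_samples - clip.samples.size
    return AudioClip(np.pad(clip.samples, (0, pad)), clip.rate)


def resample_clip(clip: AudioClip, rate: float) -> AudioClip:
    """Resample to a common analysis rate (polyphase) so spectrogram grids match."""
    if clip.rate == rate:
        return clip
    from fractions import Fraction

    frac = Fraction(int(round(rate)), int(round(clip.rate))).limit_denominator(1000)
    out = signal.resample_poly(clip.samples, frac.numerator, frac.denominator)
    peak = np.max(np.abs(out))
    if peak > 1.0:  # resampling ripple can exceed full scale slightly
        out = out / peak
    return AudioClip(out, rate)


def song_consistency(
    trill_notes: list[AudioClip],
    window_samples: int = 512,
    overlap_fraction: float = 0.9,
    max_offset: float = 0.020,
    offset_step: float = 0.001,
    analysis_rate: float = 48_000.0,
) -> ConsistencyResult:
    """Vocal consistency of a song from its trill-note clips.

    Builds all pairwise SPCC scores, per-note means, and the song score (mean
    of note scores).  By symmetry the song score equals the mean over
    unordered note pairs.  Notes are resampled to ``analysis_rate`` and
    zero-padded to at least one FFT window.
    """
    n = len(trill_notes)
    if n < 2:
        raise ValueError("song consistency requires at least 2 trill notes")
    specs = [
        spectrogram(
            _pad_to_window(resample_clip(c, analysis_rate), window_samples),
            window_samples,
            overlap_fraction,
        )
        for c in trill_notes
    ]
    pair = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = spcc_pair(specs[i], specs[j], max_offset, offset_step)
            pair[i, j] = pair[j, i] = s
    note_scores = np.array([note_consistency(pair, i) for i in range(n)])
    return ConsistencyResult(pair, note_scores, float(note_scores.mean()))


def song_consistency_from_annotations(song: AnnotatedSong, **kwargs) -> ConsistencyResult:
    """Convenience: slice the trill notes out of an annotated song and score them."""
    if song.clip is None:
        raise ValueError(f"song {song.song_id} has no audio clip")
    notes = [slice_note(song.clip, seg) for seg in song.trill_notes]
    return song_consistency(notes, **kwargs)
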