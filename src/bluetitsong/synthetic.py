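"""Synthetic trilled songs, dawn-song sessions, and female responses.

Field recordings for this analysis are not redistributable, so every pipeline
stage is exercised on synthetic data carrying the statistical structure the
analysis assumes:

* a *song* is a few high-pitched introductory notes followed by a trill of
  one repeated note (frequency-swept sine bursts with raised-cosine ramps);
* note-to-note acoustic jitter (frequency, duration, amplitude, additive
  white noise) degrades measured vocal consistency monotonically — the
  generator's core realism property;
* dawn sessions consist of song-type bouts separated by >1 min pauses or
  type switches, with an optional within-bout *warm-up* (consistency rising
  per repetition), injected by shrinking the frequency jitter across
  repetitions because consistency is a derived measurement, not a dial;
* binary female responses follow the logistic habituation process (log song
  position, song-type-switch indicator, their interaction, and a per-female
  random intercept), sharing its design-matrix convention with the fitter.

Defaults approximate the study species: trill notes near 6 kHz with a
downward sweep, intro notes a fifth higher, ~10 notes/s trills, and song
rates around 14 songs/min (bouts of 75 s hold >15 songs).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AnnotatedSong, AudioClip, NoteSegment
from .response_stats import habituation_design
from .spcc import song_consistency

__all__ = [
    "SynthSongConfig",
    "SynthSessionConfig",
    "SimResponseConfig",
    "synth_note",
    "synth_song",
    "synth_dawn_session",
    "simulate_responses",
    "simulate_warmup_bouts",
    "calibrate_freq_jitter",
]


@dataclass(frozen=True)
class SynthSongConfig:
    """Parameters of one synthetic song type.

    Frequencies in Hz, durations in seconds, amplitude jitter as a ratio,
    noise level as an RMS ratio relative to the tone amplitude.
    """

    n_intro: int = 2
    n_trill: int = 8
    note_duration: float = 0.060
    inter_note_gap: float = 0.040
    f0: float = 6000.0
    sweep: float = -20000.0  # Hz/s, downward sweep typical of trill notes
    intro_multiplier: float = 1.35  # intro notes sit above the trill
    freq_jitter_sd: float = 50.0
    duration_jitter_sd: float = 0.003
    amp_jitter_sd: float = 0.05
    noise_level: float = 0.01
    rate: float = 48_000.0

    def __post_init__(self) -> None:
        if min(self.freq_jitter_sd, self.duration_jitter_sd, self.amp_jitter_sd, self.noise_level) < 0:
            raise ValueError("jitter SDs and noise level must be >= 0")
        if self.n_trill < 3:
            raise ValueError("n_trill must be >= 3 (shorter trills are screened out)")
        if self.note_duration <= 0 or self.inter_note_gap < 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class SynthSessionConfig:
    """A dawn-song session: bouts of given lengths over one or more song types.

    ``bout_types[i]`` names the song type of bout ``i`` (keys of
    ``song_types``); ``bout_lengths[i]`` its number of repetitions.
    ``warmup_slope`` is the target rise of measured consistency per
    repetition, injected via a per-repetition decline of the frequency
    jitter (see :func:`calibrate_freq_jitter`).
    """

    song_types: dict[str, SynthSongConfig] = field(
        default_factory=lambda: {"A": SynthSongConfig(), "B": SynthSongConfig(f0=5400.0, n_trill=10)}
    )
    bout_types: tuple[str, ...] = ("A", "A", "B")
    bout_lengths: tuple[int, ...] = (10, 8, 12)
    pause_between_bouts: float = 90.0
    inter_song_gap: float = 3.0
    warmup_slope: float = 0.0

    def __post_init__(self) -> None:
        if len(self.bout_types) != len(self.bout_lengths):
            raise ValueError("bout_types and bout_lengths must align")
        if any(n < 3 for n in self.bout_lengths):
            raise ValueError("bouts must have >= 3 repetitions")
        if self.pause_between_bouts <= 60.0:
            raise ValueError("pause_between_bouts must exceed 60 s to encode a bout boundary")


@dataclass(frozen=True)
class SimResponseConfig:
    """Logistic habituation process for binary female responses.

    Coefficient defaults are the fitted habituation/dishabituation estimates
    (logit scale): intercept 0.052, song-type switch -0.813, log song
    position -1.039, interaction 0.532, female random-intercept SD 0.87.
    """

    intercept: float = 0.052
    beta_switch: float = -0.813
    beta_logpos: float = -1.039
    beta_interaction: float = 0.532
    female_sd: float = 0.87
    n_females: int = 100
    bouts_per_female: int = 8
    positions_per_bout: int = 15
    switch_fraction: float = 60.0 / 94.0  # observed share of switch-preceded bouts

    def __post_init__(self) -> None:
        if self.positions_per_bout < 1 or self.female_sd < 0:
            raise ValueError("positions_per_bout >= 1 and female_sd >= 0 required")


def _tone(
    duration: float, f_start: float, sweep: float, rate: float, ramp: float = 0.005
) -> np.ndarray:
    n = max(int(round(duration * rate)), 8)
    t = np.arange(n) / rate
    phase = 2.0 * np.pi * (f_start * t + 0.5 * sweep * t**2)
    x = np.sin(phase)
    n_ramp = min(int(ramp * rate), n // 2)
    if n_ramp > 0:
        env = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        x[:n_ramp] *= env
        x[-n_ramp:] *= env[::-1]
    return x


def synth_note(config: SynthSongConfig, rng: np.random.Generator, f_base: float | None = None) -> AudioClip:
    """One jittered note: swept sinusoid with raised-cosine ramps plus noise.

    Frequency is ``f_base + N(0, freq_jitter_sd)``; duration is jittered and
    clamped at 25% of nominal; white noise is added at ``noise_level`` RMS.
    """
    f = (f_base if f_base is not None else config.f0) + (
        rng.normal(0.0, config.freq_jitter_sd) if config.freq_jitter_sd > 0 else 0.0
    )
    dur = config.note_duration + (
        rng.normal(0.0, config.duration_jitter_sd) if config.duration_jitter_sd > 0 else 0.0
    )
    dur = max(dur, 0.25 * config.note_duration)
    amp = 1.0 + (rng.normal(0.0, config.amp_jitter_sd) if config.amp_jitter_sd > 0 else 0.0)
    amp = float(np.clip(amp, 0.1, 2.0))
    x = amp * _tone(dur, f, config.sweep, config.rate)
    if config.noise_level > 0:
        x = x + rng.normal(0.0, config.noise_level, x.size)
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x = x / peak
    return AudioClip(x, config.rate)


def synth_song(
    config: SynthSongConfig,
    rng: np.random.Generator,
    song_id: str = "synth-000",
    male_id: str = "m00",
    timestamp: _dt.datetime | None = None,
    context: str = "dawn",
    song_type: str = "A",
) -> AnnotatedSong:
    """A full annotated song: intro notes above the trill pitch, then the trill.

    The emitted note annotations align with the rendered audio to the sample
    (segment times are exact sample counts divided by the rate).
    """
    rate = config.rate
    gap = int(round(config.inter_note_gap * rate))
    pieces: list[np.ndarray] = []
    segs: list[NoteSegment] = []
    cursor = 0
    for i in range(config.n_intro + config.n_trill):
        is_intro = i < config.n_intro
        f_base = config.f0 * config.intro_multiplier if is_intro else config.f0
        note = synth_note(config, rng, f_base=f_base)
        start = cursor
        end = cursor + note.samples.size
        segs.append(NoteSegment(start / rate, end / rate, "intro" if is_intro else "trill"))
        pieces.append(note.samples)
        pieces.append(np.zeros(gap))
        cursor = end + gap
    samples = np.concatenate(pieces)
    return AnnotatedSong(
        song_id=song_id,
        male_id=male_id,
        timestamp=timestamp or _dt.datetime(2020, 4, 20, 5, 0, 0),
        context=context,
        song_type=song_type,
        notes=segs,
        trill_index=config.n_intro,
        clip=AudioClip(samples, rate),
    )


def calibrate_freq_jitter(
    config: SynthSongConfig,
    target_slope: float,
    max_positions: int = 15,
    n_probe: int = 12,
    seed: int = 12345,
    jitter_grid: Sequence[float] = (0.0, 25.0, 50.0, 100.0, 150.0, 200.0, 300.0),
) -> np.ndarray:
    """Map a target consistency-per-repetition slope to a jitter schedule.

    Measures mean consistency at each frequency-jitter level by Monte Carlo
    (``n_probe`` songs per level), builds the monotone jitter->consistency
    curve, and returns per-position jitter SDs whose expected consistency
    rises by ``target_slope`` per repetition, starting from the config's
    baseline jitter.  Stored alongside the seed so sessions are reproducible.
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(jitter_grid, dtype=float)
    means = []
    for j in grid:
        cfg = replace(config, freq_jitter_sd=float(j))
        scores = []
        for _ in range(n_probe):
            song = synth_song(cfg, rng)
            clips = [
                AudioClip(
                    song.clip.samples[
                        int(round(s.start * cfg.rate)) : int(round(s.end * cfg.rate))
                    ],
                    cfg.rate,
                )
                for s in song.trill_notes
            ]
            scores.append(song_consistency(clips).song_score)
        means.append(np.mean(scores))
    means = np.asarray(means)
    # enforce monotone decrease before inverting (Monte Carlo wiggle)
    means = np.minimum.accumulate(means)
    base = float(np.interp(config.freq_jitter_sd, grid, means))
    targets = base + target_slope * np.arange(max_positions)
    hi = means[0]
    targets = np.clip(targets, means[-1], hi)
    # invert the decreasing curve: consistency target -> jitter SD
    return np.interp(targets, means[::-1], grid[::-1])


def synth_dawn_session(
    config: SynthSessionConfig, seed: int = 0, male_id: str = "m00"
) -> tuple[list[AnnotatedSong], pd.DataFrame]:
    """A dawn-song session: time-stamped annotated songs plus ground truth.

    Songs carry real timestamps so that bout segmentation (>60 s pause or
    type switch) can be re-run on the output; the ground-truth table lists
    each song's bout number, type, repetition index and injected jitter SD.
    Consecutive bouts of the *same* type are separated by
    ``pause_between_bouts`` of silence (that is the only way they can be
    distinct bouts); a type change is rendered as continuous singing, so the
    boundary is a type switch.  Feeding the songs through consistency
    measurement and bout segmentation must recover every bout boundary
    exactly.
    """
    rng = np.random.default_rng(seed)
    t = _dt.datetime(2020, 4, 20, 4, 30, 0)
    songs: list[AnnotatedSong] = []
    truth_rows = []
    male = male_id
    jitter_schedules: dict[str, np.ndarray] = {}
    for bout_no, (type_name, n_rep) in enumerate(zip(config.bout_types, config.bout_lengths)):
        cfg = config.song_types[type_name]
        if config.warmup_slope != 0.0 and type_name not in jitter_schedules:
            jitter_schedules[type_name] = calibrate_freq_jitter(
                cfg, config.warmup_slope, max_positions=max(config.bout_lengths), seed=seed + 7
            )
        for rep in range(n_rep):
            if config.warmup_slope != 0.0:
                sched = jitter_schedules[type_name]
                jit = float(sched[min(rep, sched.size - 1)])
                cfg_rep = replace(cfg, freq_jitter_sd=jit)
            else:
                cfg_rep = cfg
                jit = cfg.freq_jitter_sd
            song = synth_song(
                cfg_rep,
                rng,
                song_id=f"{male}-s{len(songs):04d}",
                male_id=male,
                timestamp=t,
                song_type=type_name,
            )
            songs.append(song)
            truth_rows.append(
                {
                    "song_id": song.song_id,
                    "bout": bout_no,
                    "song_type": type_name,
                    "repetition": rep + 1,
                    "freq_jitter_sd": jit,
                    "onset": t,
                }
            )
            t += _dt.timedelta(seconds=song.duration + config.inter_song_gap)
        next_type = config.bout_types[bout_no + 1] if bout_no + 1 < len(config.bout_types) else None
        if next_type == type_name:
            t += _dt.timedelta(seconds=config.pause_between_bouts - config.inter_song_gap)
    return songs, pd.DataFrame(truth_rows)


def simulate_warmup_bouts(
    n_individuals: int = 18,
    bouts_per_individual: int = 4,
    positions: int = 15,
    slope: float = 0.002,
    individual_sd: float = 0.028,
    noise_sd: float = 0.074,
    baseline: float = 0.80,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw per-song consistencies from the within-bout warm-up process.

    Consistency of song at repetition p in a bout of individual i is
    ``baseline + b_i + slope * p + eps`` with ``b_i ~ N(0, individual_sd^2)``
    and song-level noise ``eps ~ N(0, noise_sd^2)``.  Defaults are the fitted
    warm-up trend values (slope 0.002/repetition, individual SD 0.028,
    residual SD 0.074) at the observed sample size (18 individuals).
    Returns a long table (male_id, bout_id, position, consistency) meant to
    be passed through first-song standardisation and the trend fit.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_individuals):
        b = rng.normal(0.0, individual_sd)
        for j in range(bouts_per_individual):
            eps = rng.normal(0.0, noise_sd, positions)
            for p in range(1, positions + 1):
                rows.append(
                    {
                        "male_id": f"m{i:02d}",
                        "bout_id": f"m{i:02d}-b{j:02d}",
                        "position": p,
                        "consistency": baseline + b + slope * p + eps[p - 1],
                    }
                )
    return pd.DataFrame(rows)


def simulate_responses(config: SimResponseConfig, seed: int = 0) -> pd.DataFrame:
    """Binary per-position female responses from the habituation process.

    Each female gets a random intercept ``b ~ N(0, female_sd^2)``; each bout
    is switch-preceded with probability ``switch_fraction``; the response at
    position p is Bernoulli with logit ``intercept + b + beta_switch*s +
    beta_logpos*log(p) + beta_interaction*s*log(p)``, built with the same
    design convention the fitter uses (:func:`habituation_design`).  Returns
    a long table with columns female_id, bout, switch, position, response.
    """
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    betas = np.array(
        [config.intercept, config.beta_switch, config.beta_logpos, config.beta_interaction]
    )
    rows = []
    for f in range(config.n_females):
        b = rng.normal(0.0, config.female_sd) if config.female_sd > 0 else 0.0
        for bout in range(config.bouts_per_female):
            s = int(rng.random() < config.switch_fraction)
            positions = np.arange(1, config.positions_per_bout + 1)
            X = habituation_design(positions, np.full(positions.size, s)).to_numpy()
            p = expit(X @ betas + b)
            resp = (rng.random(p.size) < p).astype(int)
            for pos, r in zip(positions, resp):
                rows.append(
                    {
                        "female_id": f"f{f:03d}",
                        "bout": bout,
                        "switch": s,
                        "position": int(pos),
                        "response": int(r),
                    }
                )
    return pd.DataFrame(rows)
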