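"""Song-type bout segmentation and within-bout warm-up analysis.

Blue tits are discontinuous singers: the same song type is repeated many
times (a *song-type bout*, at least three renditions) before the bird pauses
or switches type.  A silent pause longer than 60 s starts a new bout even
without a type switch.  Within a bout, vocal consistency tends to rise over
the first repetitions — the *warm-up effect* — quantified here as a linear
mixed-effects trend of first-song-standardised consistency on repetition
number, with a random intercept per individual.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import AnnotatedSong

__all__ = [
    "SongTypeBout",
    "WarmupSeries",
    "SeasonalPoint",
    "WarmupTrendFit",
    "segment_bouts",
    "warmup_series",
    "warmup_trend",
    "song_rate",
    "repertoire_size",
    "seasonal_table",
]

MIN_BOUT_SONGS = 3
SILENCE_GAP_S = 60.0


@dataclass
class SongTypeBout:
    """A run of consecutive same-type songs from one male.

    ``preceded_by`` records what triggered the bout: the session start, a
    silent pause > 60 s, or a song-type switch during continuous singing.
    Runs of fewer than three songs are kept but flagged ``sub_minimal`` and
    excluded from warm-up analysis.
    """

    bout_id: str
    male_id: str
    songs: list[AnnotatedSong]
    preceded_by: str  # session_start | silence_gap | type_switch

    def __post_init__(self) -> None:
        if self.preceded_by not in ("session_start", "silence_gap", "type_switch"):
            raise ValueError(f"bad preceded_by {self.preceded_by!r}")
        types = {s.song_type for s in self.songs}
        if len(types) > 1:
            raise ValueError(f"bout {self.bout_id} mixes song types {types}")

    @property
    def song_type(self) -> str:
        return self.songs[0].song_type

    @property
    def n_songs(self) -> int:
        return len(self.songs)

    @property
    def sub_minimal(self) -> bool:
        return self.n_songs < MIN_BOUT_SONGS


@dataclass(frozen=True)
class WarmupSeries:
    """First-song-standardised consistency by repetition number (1-based).

    ``std_consistency[k]`` is the consistency at ``positions[k]`` minus the
    first-song consistency, so the value at position 1 is exactly 0.
    """

    bout_id: str
    male_id: str
    positions: tuple[int, ...]
    std_consistency: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.positions[0] != 1 or self.std_consistency[0] != 0.0:
            raise ValueError("warm-up series must start at position 1 with value 0")


@dataclass(frozen=True)
class SeasonalPoint:
    """Within-individual normalised consistency by week relative to first egg."""

    male_id: str
    weeks_to_first_egg: int
    context: str
    norm_consistency: float


@dataclass(frozen=True)
class WarmupTrendFit:
    """Per-repetition consistency trend (mixed-model slope with 95% CI)."""

    slope: float
    ci_low: float
    ci_high: float
    intercept: float
    individual_var: float
    residual_var: float
    n_obs: int
    n_individuals: int
    method: str  # "mixed" or "ols"


def _song_interval(song: AnnotatedSong) -> tuple[_dt.datetime, _dt.datetime]:
    start = song.timestamp
    return start, start + _dt.timedelta(seconds=song.duration)


def segment_bouts(songs: Sequence[AnnotatedSong]) -> list[SongTypeBout]:
    """Partition a time-ordered single-male session into song-type bouts.

    A new bout starts at the session start, at any song-type change, or after
    a silent pause (end of one song to start of the next) longer than 60 s —
    a long pause starts a new bout even without a type switch, and takes
    precedence over a simultaneous type change when labelling ``preceded_by``.
    Every input song lands in exactly one returned bout; runs shorter than
    three songs come back flagged ``sub_minimal``.
    """
    if not songs:
        return []
    males = {s.male_id for s in songs}
    if len(males) > 1:
        raise ValueError(f"songs from multiple males: {sorted(males)}")
    times = [s.timestamp for s in songs]
    if times != sorted(times):
        raise ValueError("songs must be ordered by timestamp")

    bouts: list[SongTypeBout] = []
    current: list[AnnotatedSong] = [songs[0]]
    cause = "session_start"

    def flush(next_cause: str) -> None:
        nonlocal current, cause
        male = current[0].male_id
        bouts.append(
            SongTypeBout(f"{male}-b{len(bouts):03d}", male, current, cause)
        )
        current = []
        cause = next_cause

    for prev, song in zip(songs, songs[1:]):
        gap = (song.timestamp - _song_interval(prev)[1]).total_seconds()
        if gap > SILENCE_GAP_S:
            flush("silence_gap")
        elif song.song_type != prev.song_type:
            flush("type_switch")
        current.append(song)
    flush("session_start")  # dummy next cause; loop ends here
    return bouts


def warmup_series(
    bout: SongTypeBout,
    consistency_by_song: Mapping[str, float],
    max_positions: int = 15,
) -> WarmupSeries | None:
    """Standardise a bout's consistencies by its first song.

    Only the first ``max_positions`` repetitions are kept.  Songs without a
    consistency value (e.g. masked by extraneous noise) are dropped but keep
    their repetition numbers.  If the first song is missing the baseline is
    undefined: the bout is skipped with a warning (returns None).
    """
    if bout.sub_minimal:
        raise ValueError(f"bout {bout.bout_id} is sub-minimal; no warm-up series")
    songs = bout.songs[:max_positions]
    if songs[0].song_id not in consistency_by_song:
        warnings.warn(
            f"bout {bout.bout_id}: first song has no consistency; skipped", stacklevel=2
        )
        return None
    base = consistency_by_song[songs[0].song_id]
    positions, values = [], []
    for pos, song in enumerate(songs, start=1):
        if song.song_id in consistency_by_song:
            positions.append(pos)
            values.append(consistency_by_song[song.song_id] - base)
    values[0] = 0.0  # exact, not subject to float subtraction
    return WarmupSeries(bout.bout_id, bout.male_id, tuple(positions), tuple(values))


def warmup_series_from_table(
    table: pd.DataFrame, max_positions: int = 15
) -> list[WarmupSeries]:
    """Build warm-up series from a long table (male_id, bout_id, position,
    consistency) — the tabular route used when consistencies come from a
    simulation or a prior measurement pass rather than bout objects."""
    series = []
    for bout_id, grp in table.groupby("bout_id", sort=True):
        grp = grp.sort_values("position")
        grp = grp[grp["position"] <= max_positions]
        if int(grp["position"].iloc[0]) != 1:
            warnings.warn(f"bout {bout_id}: first song missing; skipped", stacklevel=2)
            continue
        vals = grp["consistency"].to_numpy(dtype=float)
        std = vals - vals[0]
        std[0] = 0.0
        series.append(
            WarmupSeries(
                str(bout_id),
                str(grp["male_id"].iloc[0]),
                tuple(int(p) for p in grp["position"]),
                tuple(std),
            )
        )
    return series


def warmup_trend(series: Sequence[WarmupSeries], alpha: float = 0.05) -> WarmupTrendFit:
    """Mixed-effects warm-up slope: std consistency ~ repetition + (1 | male).

    Falls back to ordinary least squares (with a warning) when only one
    individual is present and the grouping variance is unidentifiable.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 bouts to estimate a warm-up trend")
    rows = [
        {"male_id": s.male_id, "position": p, "std_consistency": v}
        for s in series
        for p, v in zip(s.positions, s.std_consistency)
    ]
    data = pd.DataFrame(rows)
    n_ind = data["male_id"].nunique()
    if n_ind < 2:
        warnings.warn("single individual; falling back to OLS", stacklevel=2)
        res = smf.ols("std_consistency ~ position", data).fit()
        lo, hi = res.conf_int(alpha).loc["position"]
        return WarmupTrendFit(
            slope=float(res.params["position"]),
            ci_low=float(lo),
            ci_high=float(hi),
            intercept=float(res.params["Intercept"]),
            individual_var=0.0,
            residual_var=float(res.mse_resid),
            n_obs=len(data),
            n_individuals=n_ind,
            method="ols",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance estimates are expected
        model = sm.MixedLM.from_formula(
            "std_consistency ~ position", groups="male_id", data=data
        )
        res = model.fit(reml=True)
    lo, hi = res.conf_int(alpha).loc["position"]
    return WarmupTrendFit(
        slope=float(res.params["position"]),
        ci_low=float(lo),
        ci_high=float(hi),
        intercept=float(res.params["Intercept"]),
        individual_var=float(res.cov_re.iloc[0, 0]),
        residual_var=float(res.scale),
        n_obs=len(data),
        n_individuals=n_ind,
        method="mixed",
    )


def song_rate(n_songs: int, window_seconds: float) -> float:
    """Songs per minute over an observation window."""
    if window_seconds <= 0:
        raise ValueError("window must be positive")
    return n_songs / window_seconds * 60.0


def repertoire_size(songs: Sequence[AnnotatedSong]) -> int:
    """Number of distinct song types recorded for one male."""
    return len({s.song_type for s in songs})


def seasonal_table(
    songs_with_consistency: Sequence[tuple[AnnotatedSong, float]],
    first_egg_dates: Mapping[str, _dt.date],
) -> list[SeasonalPoint]:
    """Per-song seasonal points: week index relative to first egg, and
    consistency normalised (mean-centred) within each individual.

    Week 0 is the week beginning on the first-egg date (floor division by 7
    days, so a song 10 days earlier falls in week -2).  Males without a
    first-egg date are excluded with a warning.  Positive values mean the
    male sang above his own seasonal average.
    """
    usable: list[tuple[AnnotatedSong, float]] = []
    skipped = set()
    for song, cons in songs_with_consistency:
        if song.male_id in first_egg_dates:
            usable.append((song, cons))
        else:
            skipped.add(song.male_id)
    if skipped:
        warnings.warn(f"no first-egg date for males {sorted(skipped)}; excluded", stacklevel=2)

    by_male: dict[str, list[float]] = {}
    for song, cons in usable:
        by_male.setdefault(song.male_id, []).append(cons)
    means = {m: float(np.mean(v)) for m, v in by_male.items()}

    points = []
    for song, cons in usable:
        delta_days = (song.timestamp.date() - first_egg_dates[song.male_id]).days
        week = int(np.floor(delta_days / 7.0))
        points.append(
            SeasonalPoint(song.male_id, week, song.context, cons - means[song.male_id])
        )
    return points
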