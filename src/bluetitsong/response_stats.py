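"""Female-response scoring and the preference/habituation models.

The playback experiment measures female arousal as a binary response per
song-type bout (and per song position within a bout): 1 if at least one call
associated with copulation solicitation (copulation, twittering or chattering
classes) occurred, 0 otherwise; churring, screaming and unclassified calls
are ignored.  Three analyses sit on top of that scoring:

* a paired Wilcoxon signed-rank comparison of per-female response proportions
  under song vs silence;
* a binomial random-intercept GLMM of per-bout response on the acoustic
  predictors of the playback song (vocal consistency, song rate, trill
  length; predictors z-scored), the *preference* model;
* a binomial random-intercept GLMM of per-position response on log song
  position, a song-type-switch indicator, and their interaction, the
  *habituation/dishabituation* model.  Position is 1-based and log position
  is left uncentred so the intercept is the response at the first song of a
  silence-preceded bout.

Model selection utilities (AICc, Akaike weights, full-model averaging over
the dAICc < 2 set, relative importance, VIF screening) follow the
information-theoretic workflow used for the preference analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .glmm import BinomialGLMMResult, fit_binomial_glmm
from .io import CallEvent

__all__ = [
    "SOLICITATION_CLASSES",
    "BoutResponse",
    "HabituationFit",
    "SignedRankResult",
    "ModelSelectionReport",
    "score_responses",
    "inverse_logit",
    "habituation_design",
    "treatment_comparison",
    "fit_preference_model",
    "fit_habituation_model",
    "aicc",
    "model_average",
    "vif",
]

SOLICITATION_CLASSES = frozenset({"copulation", "twittering", "chattering"})


@dataclass(frozen=True)
class BoutResponse:
    """Binary female response per song position within one playback bout."""

    trial_id: str
    female_id: str
    bout_index: int
    song_type: str
    preceded_by: str  # silence_gap | type_switch
    per_position: tuple[int, ...]
    in_box: float  # fraction of the bout the female was inside

    def __post_init__(self) -> None:
        if self.preceded_by not in ("silence_gap", "type_switch"):
            raise ValueError(f"bad preceded_by {self.preceded_by!r}")
        if not all(v in (0, 1) for v in self.per_position):
            raise ValueError("per_position must be binary")

    @property
    def any_response(self) -> int:
        return int(any(self.per_position))


@dataclass(frozen=True)
class HabituationFit:
    """Habituation/dishabituation model estimates, logit and probability scale.

    Coefficient order: intercept, switch, log_position, log_position:switch.
    ``back_transformed`` is the elementwise inverse logit of the coefficients,
    mirroring the two halves of the published table layout.
    """

    coefficients: pd.Series
    back_transformed: pd.Series
    ci95: pd.DataFrame  # logit scale, columns low/high
    ci95_back: pd.DataFrame
    z: pd.Series
    female_sd: float
    glmm: BinomialGLMMResult

    def predicted_probability(self, position: float, switch: int) -> float:
        c = self.coefficients
        eta = (
            c["intercept"]
            + c["switch"] * switch
            + c["log_position"] * np.log(position)
            + c["log_position:switch"] * np.log(position) * switch
        )
        return float(inverse_logit(eta))


@dataclass(frozen=True)
class SignedRankResult:
    """Paired Wilcoxon signed-rank test with a Hodges-Lehmann CI."""

    v: float  # sum of ranks of positive differences (second - first)
    p_value: float
    n_pairs: int  # nonzero differences used
    median_difference: float  # Hodges-Lehmann pseudomedian
    ci_low: float
    ci_high: float
    method: str  # "exact" | "approx"


@dataclass(frozen=True)
class ModelSelectionReport:
    """AICc candidate ranking with full-model averaging over dAICc < 2."""

    table: pd.DataFrame  # per candidate: terms, k, loglik, aicc, delta, weight, in_set
    averaged: pd.Series  # full-average coefficients (0 substituted when absent)
    importance: pd.Series  # relative importance per term
    vif: pd.Series | None = None


def inverse_logit(x):
    """Logistic back-transform 1 / (1 + exp(-x))."""
    return special.expit(x)


# ---------------------------------------------------------------------------
# response scoring


def score_responses(
    call_events: Sequence[CallEvent],
    cue_table: pd.DataFrame,
    occupancy_intervals: Sequence[tuple[float, float]],
    trial_id: str = "trial",
    female_id: str = "female",
    bout_duration: float = 75.0,
    min_in_box: float = 1e-9,
) -> list[BoutResponse]:
    """Score per-position binary responses against a playback cue table.

    ``cue_table`` is the output of :func:`bluetitsong.playback.render_schedule`
    (columns bout_index, song_type, preceded_by, position, onset_s).  A song
    position scores 1 if at least one solicitation-class call falls inside
    its window (onset to next onset, capped at the bout end).  Bouts whose
    in-box occupancy fraction is below ``min_in_box`` — i.e. bouts played
    while the female was absent — are removed.  Calls after the last bout
    window are ignored with a warning.
    """
    sol_times = np.array(
        sorted(ev.time for ev in call_events if ev.call_class in SOLICITATION_CLASSES)
    )
    trial_end = float(cue_table["onset_s"].max()) + bout_duration
    late = [ev for ev in call_events if ev.time > trial_end]
    if late:
        warnings.warn(f"{len(late)} call(s) outside the trial window ignored", stacklevel=2)

    def occupied_fraction(t0: float, t1: float) -> float:
        total = 0.0
        for a, b in occupancy_intervals:
            total += max(0.0, min(b, t1) - max(a, t0))
        return total / (t1 - t0)

    responses = []
    for bout_index, cues in cue_table.groupby("bout_index"):
        cues = cues.sort_values("position")
        bout_start = float(cues["onset_s"].iloc[0])
        bout_end = bout_start + bout_duration
        frac = occupied_fraction(bout_start, bout_end)
        if frac < min_in_box:
            continue
        onsets = cues["onset_s"].to_numpy()
        windows_end = np.append(onsets[1:], bout_end)
        per_pos = tuple(
            int(np.any((sol_times >= t0) & (sol_times < t1)))
            for t0, t1 in zip(onsets, windows_end)
        )
        responses.append(
            BoutResponse(
                trial_id=trial_id,
                female_id=female_id,
                bout_index=int(bout_index),
                song_type=str(cues["song_type"].iloc[0]),
                preceded_by=str(cues["preceded_by"].iloc[0]),
                per_position=per_pos,
                in_box=frac,
            )
        )
    return responses


# ---------------------------------------------------------------------------
# paired signed-rank comparison


def _signed_rank_null_cdf(n: int, v: int) -> float:
    """P(V <= v) under the null, by the standard DP over rank inclusion."""
    # counts[w] = number of sign assignments with positive-rank sum w
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return float(counts[: v + 1].sum() / 2.0**n)


def treatment_comparison(
    first: Sequence[float],
    second: Sequence[float],
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> SignedRankResult:
    """Paired Wilcoxon signed-rank test on differences ``second - first``.

    Zero differences are dropped.  The statistic V is the sum of the ranks of
    the positive differences (the R convention).  The p-value uses the exact
    permutation distribution for n <= 25 without ties and the normal
    approximation otherwise.  The CI is the Hodges-Lehmann interval from
    Walsh averages with exact (DP) or approximate null quantiles.
    """
    x = np.asarray(first, dtype=float)
    y = np.asarray(second, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = y - x
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise ValueError("all differences are zero; signed-rank test undefined")

    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    ties = np.unique(np.abs(d)).size < m
    method = "exact" if (m <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method, correction=method == "approx")
    p = float(res.pvalue)

    # Hodges-Lehmann estimate and CI from Walsh averages
    walsh = np.sort([(d[i] + d[j]) / 2.0 for i in range(m) for j in range(i, m)])
    hl = float(np.median(walsh))
    total = m * (m + 1) // 2
    if method == "exact":
        k = 0
        while k < total and _signed_rank_null_cdf(m, k) <= alpha / 2.0:
            k += 1
        k = max(k - 1, -1)
    else:
        mu = m * (m + 1) / 4.0  # null mean of the positive-rank sum
        sd = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
        k = int(np.floor(mu + stats.norm.ppf(alpha / 2.0) * sd))
        k = max(min(k, total), -1)
    if k < 0:
        lo, hi = float(walsh[0]), float(walsh[-1])
        warnings.warn("too few pairs for the requested confidence level", stacklevel=2)
    else:
        lo = float(walsh[k])
        hi = float(walsh[total - 1 - k])
    return SignedRankResult(v, p, m, hl, lo, hi, method)


# ---------------------------------------------------------------------------
# GLMMs


def zscore(x: np.ndarray) -> np.ndarray:
    """Scale-and-centre a predictor (sample SD, ddof 0)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance predictor cannot be z-scored")
    return (x - x.mean()) / sd


def fit_preference_model(
    data: pd.DataFrame,
    predictors: Sequence[str] = ("vocal_consistency", "song_rate", "trill_length"),
    successes: str = "successes",
    failures: str = "failures",
    female: str = "female_id",
) -> BinomialGLMMResult:
    """Preference GLMM: bout successes/failures vs acoustic song predictors.

    One row per song type per trial; predictors are z-scored before fitting;
    female identity is the random intercept.  Returns the logit-scale fit
    (back-transform with :func:`inverse_logit`).
    """
    X = pd.DataFrame({"intercept": np.ones(len(data))})
    for name in predictors:
        try:
            X[name] = zscore(data[name].to_numpy())
        except ValueError:
            raise ValueError(f"predictor {name!r} has zero variance") from None
    y = data[successes].to_numpy(dtype=float)
    n = y + data[failures].to_numpy(dtype=float)
    return fit_binomial_glmm(y, n, X, data[female].to_numpy())


def habituation_design(positions: np.ndarray, switch: np.ndarray) -> pd.DataFrame:
    """Shared design matrix for the habituation model and its simulator.

    ``log_position`` is the natural log of the 1-based song position, left
    uncentred so the intercept is position 1 of a silence-preceded bout;
    ``switch`` is a raw 0/1 indicator (silence_gap is the reference level).
    """
    positions = np.asarray(positions, dtype=float)
    if np.any(positions < 1):
        raise ValueError("positions are 1-based")
    switch = np.asarray(switch, dtype=float)
    logp = np.log(positions)
    return pd.DataFrame(
        {
            "intercept": np.ones(positions.size),
            "switch": switch,
            "log_position": logp,
            "log_position:switch": logp * switch,
        }
    )


def _habituation_rows(responses: Sequence[BoutResponse]) -> pd.DataFrame:
    rows = []
    for r in responses:
        for pos, val in enumerate(r.per_position, start=1):
            rows.append(
                {
                    "female_id": r.female_id,
                    "switch": int(r.preceded_by == "type_switch"),
                    "position": pos,
                    "response": val,
                }
            )
    return pd.DataFrame(rows)


def fit_habituation_model(
    responses: Sequence[BoutResponse] | pd.DataFrame,
) -> HabituationFit:
    """Habituation/dishabituation GLMM on per-position binary responses.

    Accepts BoutResponse objects or a long table with columns female_id,
    switch (0/1), position (1-based) and response (0/1).  Rows are aggregated
    to binomial counts per (female, switch, position) before fitting — the
    model's likelihood depends only on those cells.  If only one
    ``preceded_by`` level is present the switch terms are dropped with a
    warning.
    """
    if isinstance(responses, pd.DataFrame):
        data = responses.copy()
    else:
        data = _habituation_rows(responses)
    grouped = (
        data.groupby(["female_id", "switch", "position"])["response"]
        .agg(successes="sum", trials="count")
        .reset_index()
    )
    one_level = grouped["switch"].nunique() < 2
    X = habituation_design(grouped["position"].to_numpy(), grouped["switch"].to_numpy())
    if one_level:
        warnings.warn("only one preceded_by level; switch terms dropped", stacklevel=2)
        X = X[["intercept", "log_position"]]
    fit = fit_binomial_glmm(
        grouped["successes"].to_numpy(),
        grouped["trials"].to_numpy(),
        X,
        grouped["female_id"].to_numpy(),
    )
    coefs = fit.params
    ci = fit.conf_int
    return HabituationFit(
        coefficients=coefs,
        back_transformed=pd.Series(inverse_logit(coefs.to_numpy()), index=coefs.index),
        ci95=ci,
        ci95_back=pd.DataFrame(
            {"low": inverse_logit(ci["low"].to_numpy()), "high": inverse_logit(ci["high"].to_numpy())},
            index=ci.index,
        ),
        z=fit.wald_z(),
        female_sd=fit.random_sd,
        glmm=fit,
    )


# ---------------------------------------------------------------------------
# information-theoretic model selection


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def model_average(
    candidates: Mapping[str, tuple[float, pd.Series]],
    delta_threshold: float = 2.0,
    report_threshold: float = 7.0,
) -> ModelSelectionReport:
    """Akaike-weight full-model averaging over the dAICc < ``delta_threshold`` set.

    ``candidates`` maps a model name to ``(aicc_value, coefficients)``.
    Weights are renormalised within the averaging set; full averaging
    substitutes 0 where a model omits a term; a term's relative importance is
    the summed weight of the in-set models containing it.  The table lists
    every candidate with dAICc < ``report_threshold`` (all, by dAICc, with
    in-set flags).
    """
    if not candidates:
        raise ValueError("empty candidate set")
    names = list(candidates)
    aiccs = np.array([candidates[nm][0] for nm in names])
    delta = aiccs - aiccs.min()
    in_set = delta < delta_threshold
    rel = np.exp(-delta[in_set] / 2.0)
    weights_in = rel / rel.sum()

    all_terms: list[str] = []
    for nm in names:
        for t in candidates[nm][1].index:
            if t not in all_terms:
                all_terms.append(t)

    averaged = pd.Series(0.0, index=all_terms)
    importance = pd.Series(0.0, index=all_terms)
    for w, nm in zip(weights_in, np.array(names)[in_set]):
        coefs = candidates[nm][1]
        for t in all_terms:
            if t in coefs.index:
                averaged[t] += w * coefs[t]
                importance[t] += w

    weight_col = np.zeros(len(names))
    weight_col[in_set] = weights_in
    table = pd.DataFrame(
        {
            "model": names,
            "aicc": aiccs,
            "delta_aicc": delta,
            "weight": weight_col,
            "in_average_set": in_set,
        }
    ).sort_values("delta_aicc", ignore_index=True)
    table = table[table["delta_aicc"] < report_threshold].reset_index(drop=True)
    return ModelSelectionReport(table=table, averaged=averaged, importance=importance)


def all_subset_candidates(terms: Sequence[str]) -> list[tuple[str, ...]]:
    """All subsets of ``terms`` (including the empty, intercept-only model)."""
    out: list[tuple[str, ...]] = []
    for r in range(len(terms) + 1):
        out.extend(itertools.combinations(terms, r))
    return out


def vif(design: pd.DataFrame, flag_threshold: float = 3.0) -> pd.Series:
    """Variance inflation factors per predictor (intercept added internally).

    VIF_j = 1 / (1 - R2_j) from regressing predictor j on the others.
    Values above ``flag_threshold`` indicate problematic collinearity
    (duplicated columns give inf).
    """
    X = pd.DataFrame(design).astype(float)
    mat = np.column_stack([np.ones(len(X)), X.to_numpy()])
    out = {}
    with np.errstate(divide="ignore"):
        for j, name in enumerate(X.columns, start=1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[name] = float(variance_inflation_factor(mat, j))
    result = pd.Series(out, name="vif")
    result.attrs["flagged"] = list(result.index[result > flag_threshold])
    return result
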