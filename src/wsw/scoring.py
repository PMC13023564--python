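"""Categorization scores and chance-level analyses for WSW recall errors.

Only incorrect trials are informative: a correct match may reflect true
memory, category information, or guessing, so correct responses are
dropped (with a logged count) before scoring.  For each cue an error is
*within-category* when the chosen face shares that cue with the true
speaker and *between-category* otherwise; binary cues partition the
alternatives, so within + between equals the participant's error count for
every cue.  The per-participant proportional categorization score is

    score_c = (within_c - between_c) / total errors  in [-1, 1],

computed independently per cue (an error can be within-category for
several cues at once).  Scores are undefined - flagged, never imputed 0 -
for participants without errors, and no base-rate correction is applied;
the analytic chance level (-1/7 in the 2x2x2 design) is reported
alongside instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import FaceSet, feature_overlap_probability
from .simulate import TRIAL_COLUMNS, _match_tensor

__all__ = [
    "classify_errors",
    "categorization_scores",
    "overlap_statistics",
    "one_sample_test",
    "OneSampleTest",
    "OverlapStats",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# array kernels shared with the null simulation (single code path: the
# resampling replicates call exactly these, so observed and null statistics
# can never drift apart)
# ---------------------------------------------------------------------------

def _error_arrays(trials: pd.DataFrame, face_set: FaceSet):
    """Split a trial table into aligned arrays for the error trials.

    Returns (participant_ids, pidx, true_rows, chosen_rows, n_errors_per)
    where participant_ids is the sorted unique id vector over *all* trials,
    pidx indexes error rows into it, and n_errors_per counts errors per
    participant (zeros included).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns {missing}")
    pids = np.unique(trials["participant_id"].to_numpy())
    errors = trials.loc[~trials["correct"].astype(bool)]
    pidx = np.searchsorted(pids, errors["participant_id"].to_numpy())
    row_of = np.vectorize(face_set.row, otypes=[np.int64])
    if len(errors):
        true_rows = row_of(errors["true_face_id"].to_numpy())
        chosen_rows = row_of(errors["chosen_face_id"].to_numpy())
    else:
        true_rows = chosen_rows = np.empty(0, dtype=np.int64)
    n_err = np.bincount(pidx, minlength=len(pids))
    return pids, pidx, true_rows, chosen_rows, n_err


def _within_counts(
    pidx: np.ndarray, flags: np.ndarray, n_participants: int
) -> np.ndarray:
    """(P, k) within-category error counts from per-error match flags."""
    k = flags.shape[1]
    out = np.empty((n_participants, k), dtype=np.int64)
    for c in range(k):
        out[:, c] = np.bincount(pidx, weights=flags[:, c], minlength=n_participants)
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def classify_errors(trials: pd.DataFrame, face_set: FaceSet) -> pd.DataFrame:
    """One row per incorrect trial with a shares-cue flag per cue.

    Correct trials are dropped (their count is logged); the ``any_overlap``
    column records whether the chosen face shares at least one cue with
    the true speaker.
    """
    n_correct = int(trials["correct"].astype(bool).sum())
    log.info("classify_errors: ignoring %d correct trials", n_correct)
    errors = trials.loc[~trials["correct"].astype(bool)].copy()
    _, _, true_rows, chosen_rows, _ = _error_arrays(trials, face_set)
    flags = _match_tensor(face_set)[true_rows, chosen_rows, :].astype(bool)
    for j, name in enumerate(face_set.cue_names):
        errors[name] = flags[:, j] if len(errors) else np.empty(0, dtype=bool)
    errors["any_overlap"] = flags.any(axis=1) if len(errors) else np.empty(0, dtype=bool)
    return errors.reset_index(drop=True)


def categorization_scores(trials: pd.DataFrame, face_set: FaceSet) -> pd.DataFrame:
    """Per-participant within/between counts and proportional scores.

    Returns one row per participant with ``n_errors`` and, per cue,
    ``<cue>_within``, ``<cue>_between`` and ``<cue>_score``; scores are NaN
    for zero-error participants, which downstream aggregates must exclude.
    """
    pids, pidx, true_rows, chosen_rows, n_err = _error_arrays(trials, face_set)
    flags = _match_tensor(face_set)[true_rows, chosen_rows, :]
    within = _within_counts(pidx, flags, len(pids))
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (2 * within - n_err[:, None]) / n_err[:, None]
    out = {"participant_id": pids, "n_errors": n_err}
    for j, name in enumerate(face_set.cue_names):
        out[f"{name}_within"] = within[:, j]
        out[f"{name}_between"] = n_err - within[:, j]
        out[f"{name}_score"] = scores[:, j]
    n_zero = int((n_err == 0).sum())
    if n_zero:
        log.info("categorization_scores: %d zero-error participants flagged", n_zero)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class OneSampleTest:
    """One-sample t-test of a mean against mu0, with Cohen's d."""

    n: int
    mean: float
    sd: float
    t: float
    df: int
    p: float
    d: float

    def __str__(self) -> str:  # M, SD, t(df), p, d - journal style
        return (
            f"M = {self.mean:.2f}, SD = {self.sd:.2f}, "
            f"t({self.df}) = {self.t:.2f}, p = {self.p:.3g}, d = {self.d:.2f}"
        )


def one_sample_test(values, mu0: float = 0.0) -> OneSampleTest:
    """t = (m - mu0)/(s/sqrt(n)), df = n - 1, two-sided p, d = (m - mu0)/s."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 finite values, got {n}")
    m = float(x.mean())
    s = float(x.std(ddof=1))
    if s == 0.0:
        raise ValueError("values are constant; the t statistic is undefined")
    t = (m - mu0) / (s / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return OneSampleTest(n=n, mean=m, sd=s, t=t, df=n - 1, p=float(p), d=(m - mu0) / s)


@dataclass(frozen=True)
class OverlapStats:
    """Feature-overlap of errors against the design's chance baseline.

    Participant level: unweighted mean (over participants with >= 1 error)
    of the proportion of their errors whose chosen face shares >= 1 cue
    with the true speaker, tested with a one-sample t against ``baseline``.
    Trial level: pooled overlap count with an exact binomial test
    (one-sided 'greater' by default: the question is elevation above
    chance).
    """

    baseline: float
    n_participants: int
    participant_mean: float
    participant_sd: float
    t: float
    df: int
    t_p: float
    d: float
    n_overlap: int
    n_total_errors: int
    pooled_proportion: float
    binomial_p: float
    binomial_alternative: str

    def __str__(self) -> str:
        return (
            f"participant-level overlap: M = {100 * self.participant_mean:.1f}% "
            f"(SD = {100 * self.participant_sd:.1f}%), "
            f"t({self.df}) = {self.t:.2f}, p = {self.t_p:.3g}, d = {self.d:.2f}; "
            f"trial-level: {self.n_overlap} of {self.n_total_errors} "
            f"({100 * self.pooled_proportion:.1f}%) vs {100 * self.baseline:.1f}% "
            f"(exact binomial, {self.binomial_alternative}, p = {self.binomial_p:.3g})"
        )


def overlap_statistics(
    trials: pd.DataFrame,
    face_set: FaceSet,
    baseline: float | None = None,
    alternative: str = "greater",
) -> OverlapStats:
    """Do errors share features with the true speaker above chance?

    ``baseline`` defaults to the design's exact overlap probability
    (6/7 for 2x2x2).  Raises if no participant made an error.
    """
    if baseline is None:
        baseline = float(feature_overlap_probability(face_set))
    if not 0.0 < baseline < 1.0:
        raise ValueError(f"baseline must be in (0, 1), got {baseline}")
    errors = classify_errors(trials, face_set)
    if not len(errors):
        raise ValueError("no error trials: overlap statistics are undefined")
    per = errors.groupby("participant_id")["any_overlap"].agg(["mean", "count"])
    props = per["mean"].to_numpy()
    if len(props) >= 2 and props.std(ddof=1) > 0:
        tt = one_sample_test(props, baseline)
    else:
        # degenerate participant-level sample (ceiling/floor or n=1): the
        # t-test is undefined; keep the descriptives, flag the test as NaN
        nan = float("nan")
        tt = OneSampleTest(
            n=len(props), mean=float(props.mean()),
            sd=0.0 if len(props) >= 2 else nan,
            t=nan, df=len(props) - 1, p=nan, d=nan,
        )
    n_overlap = int(errors["any_overlap"].sum())
    n_total = int(len(errors))
    binom = stats.binomtest(n_overlap, n_total, baseline, alternative=alternative)
    return OverlapStats(
        baseline=float(baseline),
        n_participants=tt.n,
        participant_mean=tt.mean,
        participant_sd=tt.sd,
        t=tt.t,
        df=tt.df,
        t_p=tt.p,
        d=tt.d,
        n_overlap=n_overlap,
        n_total_errors=n_total,
        pooled_proportion=n_overlap / n_total,
        binomial_p=float(binom.pvalue),
        binomial_alternative=alternative,
    )
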