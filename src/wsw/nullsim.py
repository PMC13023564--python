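"""Constrained resampling null for categorization-score statistics.

Categorization scores for different cues are computed from one finite pool
of memory errors per participant, so they are not statistically
independent: a participant whose errors happen to pile up within one
category necessarily has fewer between-category errors available for the
others.  Regression structure among the scores can therefore arise
mechanically, without any cue-based encoding.

This module quantifies that artifact with a constrained Monte-Carlo null:
each participant's correct trials and error *positions* are held fixed
(preserving every zero-sum constraint, in particular the per-participant
error count), and only the chosen face on each error trial is redrawn
uniformly from the 2^k - 1 incorrect alternatives.  Scores and the
interaction regression are then recomputed with exactly the same kernels
as the primary analysis, replicate after replicate, building empirical
null distributions for R-squared and every coefficient.  Observed values
are compared with add-one corrected tail probabilities
(p = (1 + #extreme) / (1 + R), never zero) and order-statistic quantiles
with linear interpolation (numpy's default, type-7 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import FaceSet
from .inference import FitError, _ols_core, fit_interaction_model
from .scoring import _error_arrays, _within_counts, categorization_scores
from .simulate import _match_tensor

__all__ = [
    "NullSimConfig",
    "NullSimResult",
    "resample_errors",
    "run_null_simulation",
    "tail_probability",
    "empirical_quantile",
]

log = logging.getLogger(__name__)


@dataclass
class NullSimConfig:
    """Settings for the constrained resampling null.

    ``tail_mode`` applies to coefficients: ``"magnitude"`` counts
    replicates with |b*| >= |b_obs| (the default, matching the question
    "how often does chance produce an effect of comparable magnitude"),
    ``"signed"`` counts one-sided in the observed direction.  R-squared is
    always assessed with the upper tail.
    """

    n_replicates: int = 5000
    seed: int = 0
    quantiles: tuple[float, ...] = (0.5, 0.95, 0.999)
    tail_mode: str = "magnitude"
    max_failed_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.tail_mode not in ("magnitude", "signed"):
            raise ValueError(f"unknown tail_mode {self.tail_mode!r}")
        if not all(0.0 < q < 1.0 for q in self.quantiles):
            raise ValueError("quantiles must lie strictly in (0, 1)")


def empirical_quantile(samples, q: float) -> float:
    """Order-statistic quantile with linear interpolation (type 7)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    return float(np.quantile(x, q, method="linear"))


def tail_probability(samples, observed: float, mode: str = "magnitude") -> float:
    """Add-one corrected Monte-Carlo p-value: (1 + #extreme) / (1 + R).

    ``mode``: "magnitude" -> |x| >= |observed|; "signed" -> x <= observed
    for negative observed and x >= observed otherwise; "upper" -> x >=
    observed (used for R-squared).
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if mode == "magnitude":
        extreme = np.abs(x) >= abs(observed)
    elif mode == "signed":
        extreme = (x <= observed) if observed < 0 else (x >= observed)
    elif mode == "upper":
        extreme = x >= observed
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float((1 + int(extreme.sum())) / (1 + x.size))


def _alternative_table(face_set: FaceSet) -> np.ndarray:
    """(n, n-1) row indices of the alternatives to each true face."""
    n = face_set.n_faces
    return np.array(
        [[j for j in range(n) if j != i] for i in range(n)], dtype=np.int64
    )


def resample_errors(
    trials: pd.DataFrame, face_set: FaceSet, rng: np.random.Generator
) -> pd.DataFrame:
    """One null replicate of a trial table.

    Correct trials are returned unchanged; each error trial's chosen face
    is replaced by a uniform draw over the alternatives to its true face,
    so per-participant error counts are preserved exactly.
    """
    out = trials.copy()
    err = ~out["correct"].astype(bool).to_numpy()
    if not err.any():
        return out
    row_of = np.vectorize(face_set.row, otypes=[np.int64])
    true_rows = row_of(out.loc[err, "true_face_id"].to_numpy())
    alt = _alternative_table(face_set)
    draw = rng.integers(0, face_set.n_faces - 1, size=len(true_rows))
    chosen_rows = alt[true_rows, draw]
    ids = np.asarray(face_set.face_ids)
    out.loc[err, "chosen_face_id"] = ids[chosen_rows]
    return out


class NullSimResult:
    """Replicate draws, observed values, quantiles and tail probabilities."""

    def __init__(
        self,
        samples: pd.DataFrame,
        observed: dict[str, float],
        config: NullSimConfig,
        n_failed: int,
        coef_names: tuple[str, ...],
    ) -> None:
        self.samples = samples
        self.observed = observed
        self.config = config
        self.n_failed = n_failed
        self.coef_names = coef_names

    def quantile(self, stat: str, q: float) -> float:
        return empirical_quantile(self.samples[stat].to_numpy(), q)

    def tail_probability(self, stat: str, mode: str | None = None) -> float:
        """Add-one p for ``stat``; R-squared defaults to the upper tail."""
        if mode is None:
            mode = "upper" if stat == "r2" else self.config.tail_mode
        return tail_probability(
            self.samples[stat].to_numpy(), self.observed[stat], mode
        )

    def summary_dict(self) -> dict:
        stats_out = {}
        for stat in self.samples.columns:
            if stat == "replicate":
                continue
            stats_out[stat] = {
                "observed": self.observed[stat],
                "quantiles": [
                    [q, self.quantile(stat, q)] for q in self.config.quantiles
                ],
                "tail_p": self.tail_probability(stat),
                "tail_mode": "upper" if stat == "r2" else self.config.tail_mode,
            }
        return {
            "n_replicates": self.config.n_replicates,
            "n_failed_fits": self.n_failed,
            "seed": self.config.seed,
            "tail_correction": "add-one",
            "quantile_convention": "linear interpolation (type 7)",
            "statistics": stats_out,
        }

    def __str__(self) -> str:
        lines = [
            f"Constrained null: {self.config.n_replicates} replicates "
            f"(seed {self.config.seed}, {self.n_failed} failed fits)"
        ]
        for stat in self.samples.columns:
            if stat == "replicate":
                continue
            q999 = self.quantile(stat, 0.999)
            lines.append(
                f"  {stat}: observed = {self.observed[stat]:.3f}, "
                f"null 99.9% quantile = {q999:.3f}, "
                f"p = {self.tail_probability(stat):.4g}"
            )
        return "\n".join(lines)

    def plot(self, stat: str = "r2", ax=None):
        """Histogram of the null draws with the observed value marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.samples[stat], bins=50, color="steelblue", alpha=0.8)
        ax.axvline(self.observed[stat], color="crimson", lw=2, label="observed")
        ax.set_xlabel(stat)
        ax.set_ylabel("null replicates")
        ax.legend()
        return ax


def run_null_simulation(
    trials: pd.DataFrame,
    face_set: FaceSet,
    config: NullSimConfig,
    outcome_cue: str = "scar",
    predictor_cues: tuple[str, str] = ("race", "sex"),
) -> NullSimResult:
    """Build the empirical null of the interaction regression.

    Observed values come from the unpermuted data through the public
    scoring + fitting path; every replicate then reruns the identical
    kernels on resampled error choices.  Replicate r uses the
    counter-derived stream ``[seed, r]``, so runs are reproducible and
    order-independent.  Replicates whose fit fails (rank-deficient by
    chance) are recorded and excluded; more than
    ``config.max_failed_frac`` of them is an error.
    """
    scores = categorization_scores(trials, face_set)
    observed_fit = fit_interaction_model(scores, outcome_cue, predictor_cues)
    coef_names = tuple(observed_fit.params.index)
    observed = {"r2": observed_fit.rsquared} | {
        f"b_{name}": float(v) for name, v in observed_fit.params.items()
    }

    pids, pidx, true_rows, _, n_err = _error_arrays(trials, face_set)
    if len(true_rows) == 0:
        raise ValueError("no error trials: the null simulation is undefined")
    match = _match_tensor(face_set)
    alt = _alternative_table(face_set)
    cue_names = list(face_set.cue_names)
    j_out = cue_names.index(outcome_cue)
    j_a = cue_names.index(predictor_cues[0])
    j_b = cue_names.index(predictor_cues[1])
    has_err = n_err > 0
    ne = n_err[has_err][:, None].astype(float)

    rows = []
    n_failed = 0
    n_alt = face_set.n_faces - 1
    for rep in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, rep])
        chosen_rows = alt[true_rows, rng.integers(0, n_alt, size=len(true_rows))]
        flags = match[true_rows, chosen_rows, :]
        within = _within_counts(pidx, flags, len(pids))[has_err]
        s = (2 * within - ne) / ne
        a, b, y = s[:, j_a], s[:, j_b], s[:, j_out]
        X = np.column_stack([np.ones(len(y)), a, b, a * b])
        try:
            core = _ols_core(X, y)
        except FitError:
            n_failed += 1
            continue
        rows.append((rep, core.r2, *core.beta))

    if n_failed > config.max_failed_frac * config.n_replicates:
        raise FitError(
            f"{n_failed} of {config.n_replicates} null replicates failed to fit"
        )
    if n_failed:
        log.warning("null simulation: %d failed replicates excluded", n_failed)
    samples = pd.DataFrame(
        rows, columns=["replicate", "r2"] + [f"b_{n}" for n in coef_names]
    )
    return NullSimResult(samples, observed, config, n_failed, coef_names)
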