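"""Cue-interdependence regression for participant-level categorization scores.

The central question this module answers is whether use of one social cue
trades off against use of others: the scar-based categorization score is
regressed, by ordinary least squares, on the race and sex scores and their
product,

    scar_i = b0 + b1 * race_i + b2 * sex_i + b3 * (race_i * sex_i) + e_i ,

on *uncentered* scores, so the interaction is probed with simple slopes
evaluated at raw moderator levels (mean and mean +/- 1 SD by default):

    slope(v)  = b1 + b3 * v
    SE(v)     = sqrt( Var(b1) + v^2 Var(b3) + 2 v Cov(b1, b3) )

with t on the residual degrees of freedom, and slope contrasts
b3 * (v_b - v_a) whose |t| equals the interaction's t identically.
Covariates (exposure, age, ...) enter the same machinery, and nested models
are compared with the incremental F test on R-squared.

The API follows the Model -> fit() -> Results idiom: build a
:class:`CueRegressionModel` from a scores table (or ``from_trials``), call
``fit()``, and read estimates, ``summary()``, ``simple_slopes()``, and
``compare()`` off the results object.  The OLS core is a small shared
kernel (QR-free normal equations with an explicit rank check) that the
constrained null simulation reuses verbatim, so observed and null fits go
through one code path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import FaceSet
from .scoring import categorization_scores

__all__ = [
    "FitError",
    "CueRegressionModel",
    "CueRegressionResults",
    "SimpleSlopes",
    "NestedComparison",
    "fit_interaction_model",
    "fit_covariate_model",
    "simple_slopes",
    "slope_contrast",
    "nested_model_comparison",
]

log = logging.getLogger(__name__)


class FitError(ValueError):
    """Raised when a regression cannot be estimated (e.g. rank deficiency)."""


class _OLS(NamedTuple):
    beta: np.ndarray
    cov: np.ndarray        # sigma^2 (X'X)^-1
    r2: float
    fvalue: float
    df_model: int
    df_resid: int


def _ols_core(X: np.ndarray, y: np.ndarray) -> _OLS:
    """Plain OLS with intercept in column 0; raises FitError if singular."""
    n, p = X.shape
    if n <= p:
        raise FitError(f"need more rows ({n}) than parameters ({p})")
    xtx = X.T @ X
    # scale-invariant rank check on the correlation-like normalization
    d = np.sqrt(np.diag(xtx))
    if d.min() <= 0 or np.linalg.cond(xtx / np.outer(d, d)) > 1e12:
        raise FitError("design matrix is rank deficient (constant or collinear term)")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_resid = n - p
    sigma2 = rss / df_resid
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    df_model = p - 1
    if df_model > 0 and rss > 0:
        fvalue = (tss - rss) / df_model / sigma2
    else:
        fvalue = float("inf") if df_model > 0 else float("nan")
    return _OLS(beta, sigma2 * xtx_inv, r2, fvalue, df_model, df_resid)


def _resolve_column(data: pd.DataFrame, name: str) -> str:
    """Accept either a raw column name or a cue name (-> '<cue>_score')."""
    if name in data.columns:
        return name
    if f"{name}_score" in data.columns:
        return f"{name}_score"
    raise FitError(f"no column {name!r} or {name + '_score'!r} in the data")


class CueRegressionModel:
    """OLS of one categorization score on others, with an interaction.

    Parameters
    ----------
    data : DataFrame
        One row per participant.  Cue names resolve to ``<cue>_score``
        columns of a scores table; raw column names also work.
    outcome : str
        The dependent cue/column (canonically ``"scar"``).
    predictors : (str, str)
        The two interacting cue/column names (canonically ``("race", "sex")``).
    extra_terms : sequence of str, optional
        Additional main-effect columns, or ``"a:b"`` pairwise products.
    include_interaction : bool
        Whether to include the ``predictors`` product term (default True).
    subset : boolean Series/array, optional
        Row filter applied before listwise deletion (e.g. ``data["age"] >= 30``).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str = "scar",
        predictors: tuple[str, str] = ("race", "sex"),
        extra_terms: Sequence[str] = (),
        include_interaction: bool = True,
        subset=None,
    ) -> None:
        if len(predictors) != 2:
            raise FitError("exactly two interacting predictors are required")
        if outcome in predictors:
            raise FitError("outcome must differ from the predictors")
        if subset is not None:
            data = data.loc[np.asarray(subset, dtype=bool)]
        ycol = _resolve_column(data, outcome)
        a, b = (_resolve_column(data, p) for p in predictors)

        cols: dict[str, np.ndarray] = {}
        self.term_names: list[str] = ["Intercept", predictors[0], predictors[1]]
        cols[predictors[0]] = data[a].to_numpy(dtype=float)
        cols[predictors[1]] = data[b].to_numpy(dtype=float)
        inter = f"{predictors[0]}:{predictors[1]}"
        if include_interaction:
            cols[inter] = cols[predictors[0]] * cols[predictors[1]]
            self.term_names.append(inter)
        for term in extra_terms:
            if ":" in term:
                u, v = term.split(":", 1)
                cu, cv = _resolve_column(data, u), _resolve_column(data, v)
                cols[term] = data[cu].to_numpy(float) * data[cv].to_numpy(float)
            else:
                cols[term] = data[_resolve_column(data, term)].to_numpy(float)
            self.term_names.append(term)

        y = data[ycol].to_numpy(dtype=float)
        M = np.column_stack([y] + [cols[t] for t in self.term_names[1:]])
        keep = np.isfinite(M).all(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            log.info("CueRegressionModel: listwise deletion dropped %d rows", n_drop)
        self.n_dropped = n_drop
        M = M[keep]
        if M.shape[0] < len(self.term_names) + 1:
            raise FitError(
                f"only {M.shape[0]} complete rows for {len(self.term_names)} parameters"
            )
        self.endog = M[:, 0]
        self.exog = np.column_stack([np.ones(M.shape[0]), M[:, 1:]])
        self.outcome = outcome
        self.predictors = tuple(predictors)
        self.interaction_name = inter if include_interaction else None
        self.participant_ids = (
            data.loc[keep, "participant_id"].to_numpy()
            if "participant_id" in data.columns
            else None
        )

    @classmethod
    def from_trials(
        cls, trials: pd.DataFrame, face_set: FaceSet, **kwargs
    ) -> "CueRegressionModel":
        """Score a trial table and build the model in one step."""
        return cls(categorization_scores(trials, face_set), **kwargs)

    def fit(self) -> "CueRegressionResults":
        core = _ols_core(self.exog, self.endog)
        return CueRegressionResults(self, core)


@dataclass(frozen=True)
class SlopeContrast:
    level_a: float
    level_b: float
    estimate: float
    se: float
    t: float
    p: float


class SimpleSlopes:
    """Simple slopes of the focal predictor at fixed moderator levels."""

    def __init__(self, table: pd.DataFrame, contrasts: pd.DataFrame,
                 focal: str, moderator: str) -> None:
        self.table = table
        self.contrasts = contrasts
        self.focal = focal
        self.moderator = moderator

    def __str__(self) -> str:
        lines = [
            f"Simple slopes of {self.focal} at levels of {self.moderator}",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "Slope contrasts",
            self.contrasts.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def plot(self, results: "CueRegressionResults | None" = None, ax=None):
        """Predicted-value lines of the focal predictor at each level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.linspace(-1, 1, 50)
        for _, row in self.table.iterrows():
            b0 = 0.0
            if results is not None:
                b0 = (
                    results.params["Intercept"]
                    + results.params[self.moderator] * row["level"]
                )
            ax.plot(xs, b0 + row["slope"] * xs, label=f"{row['label']} ({row['level']:.3f})")
        ax.set_xlabel(f"{self.focal} score")
        ax.set_ylabel("predicted outcome score")
        ax.legend(title=f"{self.moderator} level")
        return ax


@dataclass(frozen=True)
class NestedComparison:
    """Incremental F test between two nested OLS fits."""

    delta_r2: float
    delta_f: float
    df_num: int
    df_den: int
    p: float

    def __str__(self) -> str:
        return (
            f"dF({self.df_num}, {self.df_den}) = {self.delta_f:.2f}, "
            f"p = {self.p:.3g}, dR^2 = {self.delta_r2:.3f}"
        )


class CueRegressionResults:
    """Fitted cue-interdependence regression.

    Exposes ``params``, ``bse``, ``tvalues``, ``pvalues`` (two-sided),
    ``cov_params``, ``rsquared``, ``fvalue``/``f_pvalue``, ``nobs``,
    ``df_resid``, a text ``summary()``, ``simple_slopes()``,
    ``slope_contrast()`` and ``compare()``.
    """

    def __init__(self, model: CueRegressionModel, core: _OLS) -> None:
        self.model = model
        names = model.term_names
        self.params = pd.Series(core.beta, index=names, name="estimate")
        self.cov_params = pd.DataFrame(core.cov, index=names, columns=names)
        self.bse = pd.Series(np.sqrt(np.diag(core.cov)), index=names, name="SE")
        self.df_resid = core.df_resid
        self.df_model = core.df_model
        self.nobs = int(core.df_resid + len(names))
        self.rsquared = core.r2
        self.fvalue = core.fvalue
        self.f_pvalue = float(stats.f.sf(core.fvalue, core.df_model, core.df_resid))
        self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid),
            index=names,
            name="p",
        )

    # -- simple slopes -----------------------------------------------------
    def _slope_terms(self, moderator: str) -> tuple[str, str]:
        if self.model.interaction_name is None:
            raise FitError("model has no interaction term")
        if moderator not in self.model.predictors:
            raise FitError(
                f"moderator {moderator!r} is not one of {self.model.predictors}"
            )
        focal = next(p for p in self.model.predictors if p != moderator)
        return focal, self.model.interaction_name

    def moderator_levels(self, moderator: str) -> dict[str, float]:
        """Default probe levels: mean - 1 SD, mean, mean + 1 SD (fitted data)."""
        if moderator not in self.model.predictors:
            raise FitError(f"moderator {moderator!r} not in the model")
        col = self.model.exog[:, self.model.term_names.index(moderator)]
        m, s = float(col.mean()), float(col.std(ddof=1))
        return {"-1 SD (Low)": m - s, "Mean": m, "+1 SD (High)": m + s}

    def slope_at(self, moderator: str, level: float) -> tuple[float, float]:
        """(slope, SE) of the focal predictor at one moderator value."""
        focal, inter = self._slope_terms(moderator)
        b1, b3 = self.params[focal], self.params[inter]
        v11 = self.cov_params.loc[focal, focal]
        v33 = self.cov_params.loc[inter, inter]
        v13 = self.cov_params.loc[focal, inter]
        slope = b1 + b3 * level
        se = math.sqrt(v11 + level**2 * v33 + 2 * level * v13)
        return float(slope), float(se)

    def simple_slopes(
        self, moderator: str | None = None, levels: dict[str, float] | Sequence[float] | None = None
    ) -> SimpleSlopes:
        """Slopes, SEs, t and p at each moderator level, plus all contrasts."""
        if moderator is None:
            moderator = self.model.predictors[1]
        focal, _ = self._slope_terms(moderator)
        if levels is None:
            levels = self.moderator_levels(moderator)
        if not isinstance(levels, dict):
            levels = {f"{v:g}": float(v) for v in levels}
        rows = []
        for label, v in levels.items():
            slope, se = self.slope_at(moderator, v)
            t = slope / se if se > 0 else float("nan")
            rows.append(
                {
                    "label": label,
                    "level": v,
                    "slope": slope,
                    "se": se,
                    "t": t,
                    "p": 2.0 * stats.t.sf(abs(t), self.df_resid),
                }
            )
        table = pd.DataFrame(rows)
        items = list(levels.items())
        crows = []
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                (la, va), (lb, vb) = items[i], items[j]
                c = self.slope_contrast(moderator, va, vb)
                crows.append(
                    {
                        "contrast": f"{la} ~ {lb}",
                        "estimate": c.estimate,
                        "se": c.se,
                        "t": c.t,
                        "p": c.p,
                    }
                )
        return SimpleSlopes(table, pd.DataFrame(crows), focal, moderator)

    def slope_contrast(
        self, moderator: str, level_a: float, level_b: float
    ) -> SlopeContrast:
        """Difference slope(level_b) - slope(level_a) = b3 (v_b - v_a).

        Its |t| equals the interaction coefficient's t for any distinct
        pair of levels; swapping the levels flips the sign only.
        """
        if level_a == level_b:
            raise FitError("slope contrast requires two distinct levels")
        _, inter = self._slope_terms(moderator)
        b3 = self.params[inter]
        se3 = self.bse[inter]
        est = float(b3 * (level_b - level_a))
        se = float(abs(level_b - level_a) * se3)
        t = est / se if se > 0 else float("nan")
        p = 2.0 * stats.t.sf(abs(t), self.df_resid)
        return SlopeContrast(level_a, level_b, est, se, float(t), float(p))

    # -- model comparison ----------------------------------------------------
    def compare(self, reduced: "CueRegressionResults") -> NestedComparison:
        """Incremental F for this (full) fit over a nested reduced fit.

        dF = ((R2_full - R2_red)/q) / ((1 - R2_full)/df_resid_full).
        """
        if reduced.model.outcome != self.model.outcome:
            raise FitError("nested comparison requires the same outcome")
        if reduced.nobs != self.nobs:
            raise FitError(
                f"models were fit on different rows ({reduced.nobs} vs {self.nobs})"
            )
        if not set(reduced.params.index) <= set(self.params.index):
            raise FitError("reduced model terms are not a subset of the full model's")
        q = len(self.params) - len(reduced.params)
        dr2 = self.rsquared - reduced.rsquared
        if q == 0:
            return NestedComparison(0.0, 0.0, 0, self.df_resid, 1.0)
        df = (dr2 / q) / ((1.0 - self.rsquared) / self.df_resid)
        p = float(stats.f.sf(df, q, self.df_resid))
        return NestedComparison(float(dr2), float(df), q, self.df_resid, p)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        head = (
            f"OLS: {self.model.outcome} score ~ "
            + " + ".join(self.params.index[1:])
            + f"\nn = {self.nobs}, R^2 = {self.rsquared:.3f}, "
            f"F({self.df_model}, {self.df_resid}) = {self.fvalue:.2f}, "
            f"p = {self.f_pvalue:.3g}"
        )
        tab = pd.DataFrame(
            {
                "Estimate": self.params,
                "SE": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )
        return head + "\n\n" + tab.to_string(float_format=lambda v: f"{v:.4f}")

    def to_dict(self) -> dict:
        """JSON-ready dump of the fit (used by the CLI's model summary)."""
        return {
            "outcome": self.model.outcome,
            "terms": list(self.params.index),
            "params": self.params.tolist(),
            "bse": self.bse.tolist(),
            "tvalues": self.tvalues.tolist(),
            "pvalues": self.pvalues.tolist(),
            "cov_params": self.cov_params.to_numpy().tolist(),
            "rsquared": self.rsquared,
            "fvalue": self.fvalue,
            "f_pvalue": self.f_pvalue,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "nobs": self.nobs,
        }


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_interaction_model(
    scores: pd.DataFrame,
    outcome_cue: str = "scar",
    predictor_cues: tuple[str, str] = ("race", "sex"),
) -> CueRegressionResults:
    """OLS of ``outcome_cue`` score on two predictor scores and their product."""
    return CueRegressionModel(scores, outcome_cue, predictor_cues).fit()


def fit_covariate_model(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    extra_terms: Sequence[str] = (),
    outcome_cue: str = "scar",
    predictor_cues: tuple[str, str] = ("race", "sex"),
    include_interaction: bool = True,
    subset=None,
) -> CueRegressionResults:
    """Interaction core plus participant covariates (dummy-coded, listwise).

    ``covariates`` must carry ``participant_id``; categorical columns named
    in ``extra_terms`` are dummy-coded against their modal category.
    Unmatched participants are dropped with a logged count.
    """
    if "participant_id" not in covariates.columns:
        raise FitError("covariates table must have a participant_id column")
    merged = scores.merge(covariates, on="participant_id", how="left", validate="1:1")
    n_unmatched = int(
        merged[[c for c in covariates.columns if c != "participant_id"]]
        .isna()
        .all(axis=1)
        .sum()
    )
    if n_unmatched:
        log.info("fit_covariate_model: %d participants missing covariates", n_unmatched)

    terms = list(extra_terms)
    for term in list(terms):
        if ":" in term or term not in merged.columns:
            continue
        col = merged[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            mode = col.mode().iloc[0]
            dummies = pd.get_dummies(col, prefix=term, dtype=float)
            ref = f"{term}_{mode}"
            dummies = dummies.drop(columns=[ref])
            dummies[col.isna()] = np.nan
            merged = pd.concat([merged, dummies], axis=1)
            i = terms.index(term)
            terms[i : i + 1] = list(dummies.columns)
    return CueRegressionModel(
        merged,
        outcome_cue,
        predictor_cues,
        extra_terms=terms,
        include_interaction=include_interaction,
        subset=subset,
    ).fit()


def simple_slopes(fit: CueRegressionResults, moderator: str, levels=None) -> SimpleSlopes:
    return fit.simple_slopes(moderator, levels)


def slope_contrast(
    fit: CueRegressionResults, moderator: str, level_a: float, level_b: float
) -> SlopeContrast:
    return fit.slope_contrast(moderator, level_a, level_b)


def nested_model_comparison(
    fit_full: CueRegressionResults, fit_reduced: CueRegressionResults
) -> NestedComparison:
    return fit_full.compare(fit_reduced)
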