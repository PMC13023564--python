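"""Synthetic Who-Said-What cohorts with known latent structure.

Each simulated participant has a memory accuracy (the probability a recall
trial is answered correctly) and one latent weight per cue.  On an error
trial the chosen face is drawn from a softmax over the 2^k - 1 alternatives
in which each cue shared with the true speaker adds its weight to the
face's utility:

    P(choose f | true t)  propto  exp( sum_c w_c * 1[f matches t on c] )

Zero weights recover uniform guessing; a large positive weight confines
errors to same-category faces.  This is the minimal exponential-family
confusion model that produces graded within-category confusion, and it
gives every downstream stage (scoring, regression, null simulation) a
ground truth to be tested against.

Defaults emulate a realistic online WSW cohort: 500 participants, 24 recall
trials over the 8-face 2x2x2 design, accuracy ~ Beta(6, 4) (mean 0.6, i.e.
roughly 10 errors of 24), and cue-weight means (1.0, 0.15, -0.15) for
(sex, race, scar) with unit variances - a strong sex cue, a weak race cue,
and a weak, slightly contrastive scar cue.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .design import (
    DesignError,
    EncodingPlan,
    FaceSet,
    build_encoding_plan,
    default_face_set,
    default_statements,
)

__all__ = [
    "ConfigError",
    "ParticipantLatent",
    "GeneratorConfig",
    "choice_probabilities",
    "simulate_recall",
    "simulate_cohort",
]

TRIAL_COLUMNS = (
    "participant_id",
    "trial_index",
    "statement_id",
    "true_face_id",
    "chosen_face_id",
    "correct",
)


class ConfigError(ValueError):
    """Raised when a generator configuration is invalid."""


@dataclass(frozen=True)
class ParticipantLatent:
    """Latent memory parameters of one simulated participant."""

    participant_id: int
    accuracy: float
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ConfigError(f"accuracy must be in [0, 1], got {self.accuracy}")
        if not np.all(np.isfinite(self.weights)):
            raise ConfigError(f"weights must be finite, got {self.weights}")


@dataclass
class GeneratorConfig:
    """Cohort-level generator settings (see module docstring for defaults)."""

    n_participants: int = 500
    trials_per_participant: int = 24
    accuracy_alpha: float = 6.0
    accuracy_beta: float = 4.0
    weight_means: tuple[float, ...] = (1.0, 0.15, -0.15)
    weight_cov: np.ndarray | None = None  # defaults to the identity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_participant < 1:
            raise ConfigError("n_participants and trials_per_participant must be >= 1")
        k = len(self.weight_means)
        if self.weight_cov is None:
            self.weight_cov = np.eye(k)
        cov = np.asarray(self.weight_cov, dtype=float)
        if cov.shape != (k, k):
            raise ConfigError(f"weight_cov must be {k}x{k}, got {cov.shape}")
        if not np.allclose(cov, cov.T):
            raise ConfigError("weight_cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ConfigError("weight_cov must be positive semidefinite")
        self.weight_cov = cov
        if min(self.accuracy_alpha, self.accuracy_beta) <= 0:
            raise ConfigError("Beta parameters must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weight_means"] = list(self.weight_means)
        d["weight_cov"] = np.asarray(self.weight_cov).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "weight_means" in d:
            d["weight_means"] = tuple(d["weight_means"])
        if d.get("weight_cov") is not None:
            d["weight_cov"] = np.asarray(d["weight_cov"], dtype=float)
        return cls(**d)


def _match_tensor(face_set: FaceSet) -> np.ndarray:
    """(n, n, k) boolean tensor: face i matches face j on cue c."""
    codes = face_set.codes
    return (codes[:, None, :] == codes[None, :, :]).astype(np.int8)


def _choice_matrix(weights, face_set: FaceSet) -> np.ndarray:
    """(n, n) row-stochastic matrix of error-choice probabilities.

    Row t gives P(choose column f | true face t, error); the diagonal is 0.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (face_set.n_cues,):
        raise ConfigError(
            f"need one weight per cue ({face_set.n_cues}), got shape {w.shape}"
        )
    util = _match_tensor(face_set) @ w
    util -= util.max(axis=1, keepdims=True)  # stabilize exp
    p = np.exp(util)
    np.fill_diagonal(p, 0.0)
    return p / p.sum(axis=1, keepdims=True)


def choice_probabilities(
    latent: ParticipantLatent, true_face: int, face_set: FaceSet
) -> pd.Series:
    """Error-choice distribution over the alternatives to ``true_face``.

    Returns a Series indexed by the alternative face ids, summing to 1.
    """
    r = face_set.row(true_face)
    p = _choice_matrix(latent.weights, face_set)[r]
    keep = [i for i in range(face_set.n_faces) if i != r]
    return pd.Series(p[keep], index=[face_set.face_ids[i] for i in keep], name="p")


def simulate_recall(
    latent: ParticipantLatent,
    plan: EncodingPlan,
    face_set: FaceSet,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one participant's surprise recall phase.

    Statements are presented in a randomized order; each is answered
    correctly with probability ``latent.accuracy``, otherwise the chosen
    face is drawn from the softmax confusion model.  Reproducible given
    the generator state.
    """
    for sid, _ in plan.statements:
        if plan.face_of(sid) not in face_set._row_of:
            raise DesignError(f"plan references unknown face {plan.face_of(sid)}")
    sids = np.array([sid for sid, _ in plan.statements])
    order = rng.permutation(len(sids))
    sids = sids[order]
    true_rows = np.array([face_set.row(plan.face_of(int(s))) for s in sids])
    n = len(sids)

    chosen_rows = true_rows.copy()
    is_err = rng.random(n) >= latent.accuracy
    if is_err.any():
        cum = np.cumsum(_choice_matrix(latent.weights, face_set), axis=1)
        u = rng.random(int(is_err.sum()))
        err_true = true_rows[is_err]
        chosen_rows[is_err] = np.array(
            [int(np.searchsorted(cum[t], x, side="right")) for t, x in zip(err_true, u)]
        )

    ids = np.asarray(face_set.face_ids)
    return pd.DataFrame(
        {
            "participant_id": latent.participant_id,
            "trial_index": np.arange(n),
            "statement_id": sids,
            "true_face_id": ids[true_rows],
            "chosen_face_id": ids[chosen_rows],
            "correct": chosen_rows == true_rows,
        }
    )


def draw_latents(config: GeneratorConfig, face_set: FaceSet) -> list[ParticipantLatent]:
    """Draw per-participant accuracies and cue weights from the config.

    Accuracy ~ Beta(alpha, beta); weights ~ MVN(weight_means, weight_cov),
    independent of accuracy.  Drawn from a dedicated substream of the
    cohort seed so trial noise does not perturb the latent draw.
    """
    k = face_set.n_cues
    if len(config.weight_means) != k:
        raise ConfigError(
            f"weight_means has {len(config.weight_means)} entries for {k} cues"
        )
    rng = np.random.default_rng([config.seed, 0])
    acc = rng.beta(config.accuracy_alpha, config.accuracy_beta, config.n_participants)
    w = rng.multivariate_normal(
        np.asarray(config.weight_means, dtype=float),
        config.weight_cov,
        size=config.n_participants,
        method="eigh",
    )
    return [
        ParticipantLatent(pid, float(acc[pid]), tuple(w[pid]))
        for pid in range(config.n_participants)
    ]


def simulate_cohort(
    config: GeneratorConfig,
    plan: EncodingPlan | None = None,
    face_set: FaceSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trials, latents) tables.

    The latents table carries the planted parameters so recovery can be
    tested.  Each participant's recall uses a counter-derived substream
    ``[seed, 1, participant_id]``, so any participant can be regenerated
    independently of the rest of the cohort.
    """
    if face_set is None:
        face_set = default_face_set()
    if plan is None:
        texts = default_statements()
        per_face = config.trials_per_participant // face_set.n_faces
        if per_face * face_set.n_faces != config.trials_per_participant:
            raise ConfigError(
                "trials_per_participant must be a multiple of the number of faces"
            )
        if len(texts) != config.trials_per_participant:
            texts = tuple(
                f"statement {i}" for i in range(config.trials_per_participant)
            )
        plan = build_encoding_plan(face_set, texts, per_face, config.seed)
    if plan.n_statements != config.trials_per_participant:
        raise ConfigError(
            f"plan has {plan.n_statements} statements but config expects "
            f"{config.trials_per_participant} trials per participant"
        )

    latents = draw_latents(config, face_set)
    frames = [
        simulate_recall(
            lat, plan, face_set, np.random.default_rng([config.seed, 1, lat.participant_id])
        )
        for lat in latents
    ]
    trials = pd.concat(frames, ignore_index=True)

    lat_table = pd.DataFrame(
        {
            "participant_id": [l.participant_id for l in latents],
            "accuracy": [l.accuracy for l in latents],
        }
        | {
            f"w_{name}": [l.weights[j] for l in latents]
            for j, name in enumerate(face_set.cue_names)
        }
    )
    return trials, lat_table
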