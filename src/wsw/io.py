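"""CSV/JSON/YAML interchange and validation for WSW pipelines.

All tables are plain UTF-8 comma-separated files with a header row and
``.`` decimals; face and statement ids are 0-based integers everywhere.
Trial tables are validated on read: required columns present, face ids
known, and the ``correct`` flag cross-checked against the ids (a row
claiming correct while chosen differs from true is rejected by row
number).  Face tables must be balanced full factorials; an unbalanced
table is rejected with an explicit message rather than silently
mis-scored.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignError, EncodingPlan, FaceSet
from .simulate import TRIAL_COLUMNS, GeneratorConfig

__all__ = [
    "ValidationError",
    "read_faces",
    "write_faces",
    "read_statements",
    "write_statements",
    "read_trials",
    "write_trials",
    "read_scores",
    "write_scores",
    "read_covariates",
    "load_generator_config",
    "write_meta",
]


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


# -- faces ------------------------------------------------------------------

def write_faces(face_set: FaceSet, path) -> None:
    face_set.to_frame().to_csv(path, index=False)


def read_faces(path, require_factorial: bool = True) -> FaceSet:
    frame = pd.read_csv(path)
    try:
        fs = FaceSet.from_frame(frame)
    except DesignError as e:
        raise ValidationError(f"{path}: {e}") from e
    if require_factorial and not fs.is_full_factorial():
        raise ValidationError(
            f"{path}: face table is not a balanced full factorial "
            f"({fs.n_faces} faces over {fs.n_cues} binary cues); "
            "scores against the analytic chance level would be invalid"
        )
    return fs


# -- statements / encoding plan ---------------------------------------------

def write_statements(plan: EncodingPlan, path) -> None:
    pd.DataFrame(
        {
            "statement_id": [sid for sid, _ in plan.statements],
            "face_id": [plan.face_of(sid) for sid, _ in plan.statements],
            "text": [text for _, text in plan.statements],
        }
    ).to_csv(path, index=False)


def read_statements(path, face_set: FaceSet | None = None) -> EncodingPlan:
    frame = pd.read_csv(path)
    required = {"statement_id", "face_id", "text"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if face_set is not None:
        bad = set(frame["face_id"]) - set(face_set.face_ids)
        if bad:
            raise ValidationError(f"{path}: unknown face ids {sorted(bad)}")
    statements = tuple(
        (int(r.statement_id), str(r.text)) for r in frame.itertuples()
    )
    pairing = {int(r.statement_id): int(r.face_id) for r in frame.itertuples()}
    return EncodingPlan(statements=statements, pairing=pairing)


# -- trials -----------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path) -> None:
    out = trials[list(TRIAL_COLUMNS)].copy()
    out["correct"] = out["correct"].astype(int)
    out.to_csv(path, index=False)


def read_trials(path, face_set: FaceSet) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    known = set(face_set.face_ids)
    for col in ("true_face_id", "chosen_face_id"):
        bad = frame.index[~frame[col].isin(known)]
        if len(bad):
            raise ValidationError(
                f"{path}: row {int(bad[0])}: unknown face id in {col!r}"
            )
    recomputed = frame["true_face_id"].to_numpy() == frame["chosen_face_id"].to_numpy()
    stated = frame["correct"].astype(bool).to_numpy()
    mismatch = np.nonzero(recomputed != stated)[0]
    if len(mismatch):
        raise ValidationError(
            f"{path}: row {int(mismatch[0])}: 'correct' flag contradicts the face ids"
        )
    frame["correct"] = recomputed
    return frame


# -- scores / covariates ----------------------------------------------------

def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "participant_id" not in frame.columns:
        raise ValidationError(f"{path}: missing participant_id column")
    return frame


def read_covariates(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "participant_id" not in frame.columns:
        raise ValidationError(f"{path}: missing participant_id column")
    return frame


# -- config / provenance ----------------------------------------------------

def load_generator_config(path) -> GeneratorConfig:
    """Read a YAML (or JSON) file mirroring GeneratorConfig field-for-field."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    try:
        return GeneratorConfig.from_dict(data)
    except (TypeError, ValueError) as e:
        raise ValidationError(f"{path}: {e}") from e


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_meta(out_dir, stage: str, seed, config: dict) -> Path:
    """Sidecar provenance record: stage, seed, and a hash of the config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
    }
    path = out_dir / f"{stage}_meta.json"
    path.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return path
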