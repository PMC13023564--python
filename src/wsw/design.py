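"""Factorial stimulus designs for the Who-Said-What paradigm.

The Who-Said-What (WSW) task presents a small set of target faces that vary
on binary social cues (in the canonical design: sex, race, and presence of a
facial scar, fully crossed into 8 faces), each paired with a few short
statements.  Spontaneous categorization is later read out of recall errors.
This module represents that factorial design and provides its exact
combinatorial baselines:

* the probability that two distinct faces share at least one cue
  (the chance level for "feature overlap" among errors), and
* the expected proportional categorization score under uniform random
  error choice (the analytic chance level for each cue's score).

Both baselines are exact rationals; the closed forms are cross-checked
against exhaustive pair enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations, product

import numpy as np

__all__ = [
    "DesignError",
    "Cue",
    "FaceSet",
    "EncodingPlan",
    "build_factorial_faces",
    "match_vector",
    "feature_overlap_probability",
    "expected_random_score",
    "build_encoding_plan",
    "default_face_set",
    "default_statements",
    "DEFAULT_STATEMENTS",
]


class DesignError(ValueError):
    """Raised when a stimulus design violates its structural invariants."""


@dataclass(frozen=True)
class Cue:
    """A binary social cue (e.g., sex, race, scar) with two named levels.

    The level at index 0 codes as 0 and the level at index 1 codes as 1.
    """

    name: str
    levels: tuple[str, str] = ("0", "1")

    def __post_init__(self) -> None:
        if len(self.levels) != 2:
            raise DesignError(
                f"cue {self.name!r} must have exactly 2 levels, got {len(self.levels)}"
            )
        if len(set(self.levels)) != 2:
            raise DesignError(f"cue {self.name!r} has duplicate level labels")


class FaceSet:
    """A set of stimulus faces with binary attribute codes on each cue.

    Parameters
    ----------
    cues : sequence of Cue
        The binary cues, in a fixed order.  Names must be unique.
    face_ids : sequence of int
        Unique integer keys for the faces.
    codes : array-like of shape (n_faces, n_cues)
        0/1 attribute code of each face on each cue.
    """

    def __init__(self, cues, face_ids, codes) -> None:
        cues = tuple(cues)
        names = [c.name for c in cues]
        if len(set(names)) != len(names):
            raise DesignError(f"duplicate cue names: {names}")
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2 or codes.shape[1] != len(cues):
            raise DesignError(
                f"codes must have shape (n_faces, {len(cues)}), got {codes.shape}"
            )
        if not np.isin(codes, (0, 1)).all():
            raise DesignError("attribute codes must be 0 or 1")
        face_ids = tuple(int(i) for i in face_ids)
        if len(face_ids) != codes.shape[0]:
            raise DesignError("face_ids and codes disagree on the number of faces")
        if len(set(face_ids)) != len(face_ids):
            raise DesignError(f"face_ids are not unique: {face_ids}")
        self.cues = cues
        self.face_ids = face_ids
        codes.setflags(write=False)
        self.codes = codes
        self._row_of = {fid: i for i, fid in enumerate(face_ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_faces(self) -> int:
        return len(self.face_ids)

    @property
    def n_cues(self) -> int:
        return len(self.cues)

    @property
    def cue_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.cues)

    def row(self, face_id: int) -> int:
        try:
            return self._row_of[face_id]
        except KeyError:
            raise DesignError(f"unknown face_id {face_id!r}") from None

    def attributes(self, face_id: int) -> dict[str, int]:
        """Cue-name -> 0/1 code for one face."""
        r = self.row(face_id)
        return {c.name: int(v) for c, v in zip(self.cues, self.codes[r])}

    def is_full_factorial(self) -> bool:
        """True iff every attribute combination appears exactly once."""
        if self.n_faces != 2**self.n_cues:
            return False
        seen = {tuple(r) for r in self.codes.tolist()}
        return len(seen) == self.n_faces

    # -- interchange -------------------------------------------------------
    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"face_id": list(self.face_ids)}
            | {c.name: self.codes[:, j] for j, c in enumerate(self.cues)}
        )

    @classmethod
    def from_frame(cls, frame, cue_names=None) -> "FaceSet":
        if "face_id" not in frame.columns:
            raise DesignError("faces table must have a 'face_id' column")
        if cue_names is None:
            cue_names = [c for c in frame.columns if c not in ("face_id", "label")]
        cues = [Cue(name) for name in cue_names]
        return cls(cues, frame["face_id"].tolist(), frame[list(cue_names)].to_numpy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FaceSet({self.n_faces} faces, cues={list(self.cue_names)})"


def build_factorial_faces(cues) -> FaceSet:
    """Fully cross 1-8 binary cues into a balanced face set.

    Face ids are 0-based integers in binary-counting order over the cue
    order, with the first cue as the most significant bit; this makes ids
    deterministic and independent of any file layout.
    """
    cues = tuple(cues)
    k = len(cues)
    if not 1 <= k <= 8:
        raise DesignError(f"need between 1 and 8 cues, got {k}")
    codes = np.array(list(product((0, 1), repeat=k)), dtype=np.int8)
    return FaceSet(cues, range(2**k), codes)


def match_vector(face_set: FaceSet, face_a: int, face_b: int) -> dict[str, bool]:
    """Per-cue equality between two faces (a face vs itself is all-True)."""
    ra, rb = face_set.row(face_a), face_set.row(face_b)
    eq = face_set.codes[ra] == face_set.codes[rb]
    return {name: bool(v) for name, v in zip(face_set.cue_names, eq)}


def _overlap_by_enumeration(face_set: FaceSet) -> Fraction:
    n = face_set.n_faces
    if n < 2:
        raise DesignError("need at least 2 faces to draw a distinct pair")
    pairs = list(combinations(range(n), 2))
    share = sum(
        1 for i, j in pairs if (face_set.codes[i] == face_set.codes[j]).any()
    )
    return Fraction(share, len(pairs))


def feature_overlap_probability(face_set: FaceSet, method: str = "auto") -> Fraction:
    """Probability that two distinct faces, drawn uniformly, share >=1 cue.

    For a full factorial of k binary cues every face has exactly one
    all-differing complement, so the closed form is 1 - 1/(2^k - 1)
    (6/7 for the canonical 2x2x2 design).  ``method`` selects
    ``"closed_form"``, ``"enumeration"``, or ``"auto"`` (both, verified
    equal, on factorial sets; enumeration otherwise).
    """
    if method not in ("auto", "closed_form", "enumeration"):
        raise ValueError(f"unknown method {method!r}")
    factorial = face_set.is_full_factorial()
    if method == "closed_form" or (method == "auto" and factorial):
        if not factorial:
            raise DesignError("closed form requires a balanced full-factorial set")
        k = face_set.n_cues
        closed = 1 - Fraction(1, 2**k - 1)
        if method == "auto":
            enum = _overlap_by_enumeration(face_set)
            assert closed == enum, "closed form disagrees with enumeration"
        return closed
    return _overlap_by_enumeration(face_set)


def expected_random_score(face_set: FaceSet, cue: str) -> Fraction:
    """Expected proportional categorization score under uniform guessing.

    When an error's chosen face is uniform over the 2^k - 1 alternatives,
    each error contributes +1 (cue shared) or -1 (cue differs); in a
    balanced factorial set a face has s = 2^(k-1) - 1 same-cue and
    d = 2^(k-1) different-cue alternatives, so the expectation is
    (s - d)/(2^k - 1): -1/7 for k = 3.  No base-rate correction is applied
    to observed scores, so this value is the chance level they should be
    read against.
    """
    if cue not in face_set.cue_names:
        raise DesignError(f"unknown cue {cue!r}; have {list(face_set.cue_names)}")
    if not face_set.is_full_factorial():
        raise DesignError("expected_random_score requires a balanced factorial set")
    j = face_set.cue_names.index(cue)
    # exact enumeration over ordered (true, chosen) pairs
    total = Fraction(0)
    n = face_set.n_faces
    for a in range(n):
        same = sum(
            1 for b in range(n) if b != a and face_set.codes[a, j] == face_set.codes[b, j]
        )
        total += Fraction(2 * same - (n - 1), n - 1)
    enum = total / n
    k = face_set.n_cues
    s, d = 2 ** (k - 1) - 1, 2 ** (k - 1)
    assert enum == Fraction(s - d, 2**k - 1)
    return enum


@dataclass(frozen=True)
class EncodingPlan:
    """The face-statement pairing shown during encoding.

    Each statement belongs to exactly one face and every face receives the
    same number of statements (3 in the canonical 24-statement design).
    """

    statements: tuple[tuple[int, str], ...]
    pairing: dict[int, int] = field(compare=False)

    def __post_init__(self) -> None:
        sids = [sid for sid, _ in self.statements]
        if len(set(sids)) != len(sids):
            raise DesignError("statement ids are not unique")
        if set(self.pairing) != set(sids):
            raise DesignError("pairing must cover every statement exactly once")

    @property
    def n_statements(self) -> int:
        return len(self.statements)

    def face_of(self, statement_id: int) -> int:
        return self.pairing[statement_id]

    def statements_of(self, face_id: int) -> list[int]:
        return [sid for sid, fid in self.pairing.items() if fid == face_id]


def build_encoding_plan(
    face_set: FaceSet, statement_texts, per_face: int, rng_seed: int
) -> EncodingPlan:
    """Randomly assign ``per_face`` statements to every face, by seed.

    The assignment is a seeded permutation, so the same seed always yields
    the same plan; different cohorts can re-randomize which statements each
    face delivers, as the statement-face pairing is counterbalanced across
    participants rather than fixed.
    """
    texts = list(statement_texts)
    need = face_set.n_faces * per_face
    if len(texts) != need:
        raise DesignError(
            f"need {need} statements ({face_set.n_faces} faces x {per_face}), got {len(texts)}"
        )
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(texts))
    pairing = {
        int(sid): face_set.face_ids[slot // per_face]
        for slot, sid in enumerate(order)
    }
    statements = tuple((i, t) for i, t in enumerate(texts))
    return EncodingPlan(statements=statements, pairing=pairing)


#: Short first-person everyday statements in the style used in WSW studies.
DEFAULT_STATEMENTS: tuple[str, ...] = (
    "I read poetry",
    "I read the newspaper daily",
    "I have a pet dog",
    "I enjoy hiking on weekends",
    "I bake bread on Sundays",
    "I ride my bike to work",
    "I collect old postcards",
    "I drink tea every morning",
    "I grow tomatoes in my garden",
    "I play chess online",
    "I listen to jazz records",
    "I jog in the park",
    "I do crossword puzzles",
    "I cook dinner most nights",
    "I watch nature documentaries",
    "I paint with watercolors",
    "I volunteer at the library",
    "I take photos of birds",
    "I play the guitar",
    "I swim twice a week",
    "I knit scarves in winter",
    "I write in a journal",
    "I shop at the farmers market",
    "I fold origami animals",
)


def default_statements() -> tuple[str, ...]:
    return DEFAULT_STATEMENTS


def default_face_set() -> FaceSet:
    """The canonical 2x2x2 design: sex x race x scar, 8 faces."""
    return build_factorial_faces(
        [
            Cue("sex", ("female", "male")),
            Cue("race", ("Black", "White")),
            Cue("scar", ("absent", "present")),
        ]
    )
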