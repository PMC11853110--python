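"""Enrolment database and cosine-threshold open-set identification.

Enrolled 64-dimensional identity codes are standardized per dimension,
(x - mu) / sigma, with mu and sigma fitted over the enrolled vectors only
(population convention, variance floored at epsilon).  A query is
standardized with the enrolment-time parameters, scored by cosine
similarity against each enrolled subject's gallery summary (per-subject
mean standardized vector by default, max-over-vectors optionally) and
accepted as the best-matching subject only when the best similarity
reaches the decision threshold; otherwise the verdict is "unknown".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureRecord",
    "StandardizationParams",
    "FeatureDatabase",
    "IdentificationResult",
    "fit_standardization",
    "cosine_similarity",
    "enroll",
    "identify",
    "UNKNOWN",
]

FEATURE_DIM = 64
EPSILON = 1e-8

#: Sentinel verdict for rejected (unauthorized) queries.
UNKNOWN = "unknown"


@dataclass(frozen=True)
class FeatureRecord:
    """One enrolled 64-dim identity code with its provenance."""

    subject_id: int
    vector: np.ndarray = field(repr=False)
    condition: str = "type_i"
    cycle_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=np.float64)
        if v.shape != (FEATURE_DIM,):
            raise ValueError(f"vector must have dimension {FEATURE_DIM}")
        if not np.isfinite(v).all():
            raise ValueError("vector entries must be finite")
        object.__setattr__(self, "vector", v)


@dataclass(frozen=True)
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray
    epsilon: float = EPSILON

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
        return (v - self.mean) / np.maximum(self.sd, self.epsilon)


def fit_standardization(records: Sequence[FeatureRecord],
                        epsilon: float = EPSILON) -> StandardizationParams:
    """Per-dimension mean and population standard deviation."""
    if len(records) < 2:
        raise ValueError("standardization needs at least 2 records")
    mat = np.stack([r.vector for r in records])
    return StandardizationParams(
        mean=mat.mean(axis=0), sd=mat.std(axis=0), epsilon=epsilon
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(theta) = a.b / (|a||b|), in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclass
class IdentificationResult:
    subject_id: int | str  # matched id, or UNKNOWN
    best_subject_id: int
    best_similarity: float
    threshold: float
    tie: bool = False
    similarities: dict[int, float] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return self.subject_id != UNKNOWN


class FeatureDatabase:
    """Gallery of enrolled identity codes with cached standardization."""

    def __init__(self, summary: str = "mean", standardize: bool = True,
                 epsilon: float = EPSILON):
        if summary not in ("mean", "max"):
            raise ValueError("summary must be 'mean' or 'max'")
        self.summary = summary
        self.standardize = standardize
        self.epsilon = epsilon
        self.records: list[FeatureRecord] = []
        self.params: StandardizationParams | None = None
        self._standardized: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subject_ids(self) -> list[int]:
        return sorted({r.subject_id for r in self.records})

    def _refit(self) -> None:
        if len(self.records) >= 2:
            if self.standardize:
                self.params = fit_standardization(self.records, self.epsilon)
            else:
                self.params = StandardizationParams(
                    mean=np.zeros(FEATURE_DIM), sd=np.ones(FEATURE_DIM),
                    epsilon=self.epsilon,
                )
            mat = np.stack([r.vector for r in self.records])
            self._standardized = self.params.apply(mat)

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        """Standardize query vectors with enrolment-time parameters."""
        if self.params is None:
            raise ValueError("database has no fitted standardization")
        return self.params.apply(vectors)

    def gallery(self) -> dict[int, np.ndarray]:
        """Per-subject standardized gallery matrices."""
        if self._standardized is None:
            raise ValueError("database is empty or unfitted")
        out: dict[int, np.ndarray] = {}
        sids = np.array([r.subject_id for r in self.records])
        for sid in self.subject_ids:
            out[sid] = self._standardized[sids == sid]
        return out

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path / "gallery.npz",
            vectors=np.stack([r.vector for r in self.records]),
            subject_ids=np.array([r.subject_id for r in self.records]),
            cycle_index=np.array([r.cycle_index for r in self.records]),
        )
        meta = {
            "summary": self.summary,
            "standardize": self.standardize,
            "epsilon": self.epsilon,
            "conditions": [r.condition for r in self.records],
        }
        (path / "db_config.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureDatabase":
        path = Path(path)
        meta = json.loads((path / "db_config.json").read_text())
        db = cls(summary=meta["summary"], standardize=meta["standardize"],
                 epsilon=meta["epsilon"])
        with np.load(path / "gallery.npz") as data:
            records = [
                FeatureRecord(
                    subject_id=int(sid), vector=vec,
                    condition=cond, cycle_index=int(ci),
                )
                for sid, vec, cond, ci in zip(
                    data["subject_ids"], data["vectors"],
                    meta["conditions"], data["cycle_index"],
                )
            ]
        return enroll(db, records)


def enroll(db: FeatureDatabase, records: Sequence[FeatureRecord]
           ) -> FeatureDatabase:
    """Append records and refit standardization over the full gallery."""
    db.records.extend(records)
    db._refit()
    return db


def identify(db: FeatureDatabase, query: np.ndarray, threshold: float = 0.85
             ) -> IdentificationResult:
    """Best-gallery-match identification with threshold rejection.

    The query is standardized with the database parameters, compared by
    cosine similarity to every subject's gallery summary, and rejected as
    ``UNKNOWN`` when the best similarity falls below ``threshold``.  Exact
    ties resolve to the lowest subject id and are flagged.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    if len(db) == 0:
        raise ValueError("cannot identify against an empty database")
    scores = score_query(db, query)
    best_sid = min(scores, key=lambda s: (-scores[s], s))
    best = scores[best_sid]
    tie = sum(1 for s in scores.values() if s == best) > 1
    verdict: int | str = best_sid if best >= threshold else UNKNOWN
    return IdentificationResult(
        subject_id=verdict,
        best_subject_id=best_sid,
        best_similarity=best,
        threshold=threshold,
        tie=tie,
        similarities=scores,
    )


def score_query(db: FeatureDatabase, query: np.ndarray,
                *, pre_standardized: bool = False) -> dict[int, float]:
    """Per-subject cosine similarities for one query vector."""
    q = np.asarray(query, dtype=np.float64).reshape(-1)
    if q.shape != (FEATURE_DIM,):
        raise ValueError(f"query must have dimension {FEATURE_DIM}")
    qs = q if pre_standardized else db.transform(q)[0]
    scores: dict[int, float] = {}
    for sid, mat in db.gallery().items():
        if db.summary == "mean":
            scores[sid] = cosine_similarity(qs, mat.mean(axis=0))
        else:
            scores[sid] = max(cosine_similarity(qs, v) for v in mat)
    return scores


def score_queries(db: FeatureDatabase, queries: np.ndarray) -> np.ndarray:
    """Best (max over subjects) similarity for each query row.

    Vectorised scoring used by the threshold sweeps; equivalent to taking
    ``identify(...).best_similarity`` per row.
    """
    q = db.transform(queries)
    gallery = db.gallery()
    summaries = np.stack([
        mat.mean(axis=0) if db.summary == "mean" else mat[0]
        for mat in gallery.values()
    ])
    if db.summary == "max":
        # max summary needs all vectors; fall back to per-query loop
        return np.array([
            max(score_query(db, row, pre_standardized=True).values())
            for row in q
        ])
    qn = q / np.linalg.norm(q, axis=1, keepdims=True)
    sn = summaries / np.linalg.norm(summaries, axis=1, keepdims=True)
    return (qn @ sn.T).max(axis=1)
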