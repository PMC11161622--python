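"""Semantic distance and the forward-flow statistic.

Forward flow quantifies how far each successive thought in a
free-association stream moves away from everything said before it.  With
``D[i, j]`` the semantic distance between thoughts ``i`` and ``j`` (both
1-based) and ``n`` thoughts in the stream, the score is

    ( sum_{i=2..n}  sum_{j=1..i-1} D[i, j] / (i - 1) ) / (n - 1)

i.e. the mean, over positions 2..n, of the average distance from thought
``i`` to all preceding thoughts.  Distances are 1 − cosine similarity
between word-embedding vectors, the convention of the forward-flow
literature.

Associative ability is the cohort-standardized forward flow, averaged over
task items (e.g. the "cake" and "snowflake" cues), one score per
participant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import DegenerateDataError

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSpace",
    "ThoughtStream",
    "cosine_distance",
    "distance_matrix",
    "forward_flow",
    "associative_ability",
]


@dataclass
class EmbeddingSpace:
    """A word -> vector map with a fixed dimension.

    Lookup is case-insensitive (keys are stored case-folded).  Zero vectors
    are rejected because cosine distance is undefined for them.
    """

    vectors: dict[str, np.ndarray]
    dim: int = field(init=False)

    def __post_init__(self):
        if not self.vectors:
            raise ValueError("embedding space must contain at least one word")
        folded: dict[str, np.ndarray] = {}
        dims = set()
        for word, vec in self.vectors.items():
            v = np.asarray(vec, dtype=float).ravel()
            if not np.any(v):
                raise ValueError(f"zero vector for word {word!r}")
            dims.add(v.size)
            folded[word.casefold()] = v
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")
        self.vectors = folded
        self.dim = dims.pop()

    def __contains__(self, word: str) -> bool:
        return word.casefold() in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word.casefold()]

    @property
    def vocabulary(self) -> set[str]:
        return set(self.vectors)


@dataclass
class ThoughtStream:
    """One participant's ordered word responses to one cue item."""

    participant_id: str
    item_id: str
    cue: str
    responses: list[str]

    def __post_init__(self):
        if len(self.responses) < 1:
            raise ValueError("a thought stream needs at least one response")

    def resolved(self, space: EmbeddingSpace, on_oov: str = "drop") -> list[str]:
        """Responses resolvable in ``space``.

        ``on_oov='drop'`` removes out-of-vocabulary words with a warning;
        ``'error'`` raises instead.
        """
        kept, missing = [], []
        for w in self.responses:
            (kept if w in space else missing).append(w)
        if missing:
            if on_oov == "error":
                raise KeyError(
                    f"out-of-vocabulary responses for participant "
                    f"{self.participant_id!r}, item {self.item_id!r}: {missing}"
                )
            logger.warning(
                "dropped %d out-of-vocabulary response(s) for participant %s "
                "item %s: %s", len(missing), self.participant_id, self.item_id,
                missing,
            )
        return kept


def cosine_distance(u, v) -> float:
    """1 − cosine similarity; 0 for parallel vectors, 1 for orthogonal,
    up to 2 for anti-parallel."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError(f"dimension mismatch: {u.size} vs {v.size}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - (u @ v) / (nu * nv))


def distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise cosine-distance matrix for row vectors (symmetric, zero
    diagonal, entries in [0, 2])."""
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("cosine distance undefined for zero vectors")
    unit = vectors / norms[:, None]
    d = 1.0 - unit @ unit.T
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def forward_flow(
    stream: ThoughtStream, space: EmbeddingSpace, on_oov: str = "drop"
) -> float:
    """Forward-flow score of one thought stream.

    Each position i (from the second thought on) contributes the average
    distance to all preceding thoughts; the score is the mean contribution.
    Requires at least two in-vocabulary responses.
    """
    words = stream.resolved(space, on_oov=on_oov)
    n = len(words)
    if n < 2:
        raise DegenerateDataError(
            f"forward flow undefined for fewer than 2 resolvable thoughts "
            f"(participant {stream.participant_id!r}, item {stream.item_id!r})"
        )
    vecs = np.stack([space[w] for w in words])
    d = distance_matrix(vecs)
    # mean over i=2..n of mean_{j<i} D[i, j]
    per_position = [d[i, :i].mean() for i in range(1, n)]
    return float(np.mean(per_position))


def associative_ability(
    streams: list[ThoughtStream],
    space: EmbeddingSpace,
    on_oov: str = "drop",
    ddof: int = 1,
) -> pd.Series:
    """Per-participant associative-ability score.

    Forward flow is computed per (participant, item), z-scored across the
    cohort within each item, then averaged over items per participant.
    ``ddof=1`` (sample SD) is the default standardization convention;
    ``ddof=0`` gives the population convention.
    """
    rows = [
        (s.participant_id, s.item_id, forward_flow(s, space, on_oov=on_oov))
        for s in streams
    ]
    df = pd.DataFrame(rows, columns=["participant_id", "item_id", "flow"])
    if df["participant_id"].nunique() < 2:
        raise ValueError("standardization needs at least 2 participants")

    zs = []
    for item, grp in df.groupby("item_id"):
        sd = grp["flow"].std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateDataError(
                f"zero variance of forward flow within item {item!r}"
            )
        zs.append((grp["flow"] - grp["flow"].mean()) / sd)
    df["z"] = pd.concat(zs)
    scores = df.groupby("participant_id")["z"].mean()
    scores.name = "assoc"
    return scores
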