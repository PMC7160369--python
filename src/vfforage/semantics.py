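"""Pairwise semantic relatedness and the same-cluster predicates.

Two representations drive cluster/switch decisions:

* **Embedding mode (ESA-style)** — each animal name is a vector; adjacent
  words belong to the same cluster when their cosine similarity reaches a
  threshold.  The threshold is either fixed or adapted per subject: the
  adjacent-pair similarities of the response are min-max normalized to
  [0, 1] and the threshold is a fraction (default 0.75) of their mean, on
  that normalized scale.
* **Category-table mode (Troyer-style)** — two names share a cluster when
  their subcategory sets intersect.

Throughout we speak of cosine *similarity* (higher = more related); a
switch occurs when the similarity falls below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (DegenerateThresholdError, MissingEmbeddingError,
                     ParseError, UndefinedMetricError, ValidationError)
from .lexicon import CategoryTable


@dataclass
class EmbeddingStore:
    """Word -> vector map; all vectors share one dimension, none is zero."""

    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValidationError(f"inconsistent vector dimensions: {dims}")
        for word, vec in self.vectors.items():
            if not np.any(vec):
                raise ValidationError(f"zero vector for {word!r}")

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).shape[0]

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        try:
            return self.vectors[word]
        except KeyError:
            raise MissingEmbeddingError(
                f"no embedding for word {word!r}") from None

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingStore":
        """Read word2vec text format: header ``N D`` then ``word v1 .. vD``."""
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ParseError(f"{path}: expected 'N D' header line")
            try:
                n, dim = int(header[0]), int(header[1])
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer header {header}") from exc
            vectors: dict[str, np.ndarray] = {}
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ParseError(
                        f"{path}:{lineno}: expected 1 word + {dim} values, "
                        f"got {len(parts)} fields")
                word = parts[0].replace("_", " ")
                vectors[word] = np.asarray(parts[1:], dtype=float)
        if len(vectors) != n:
            raise ParseError(
                f"{path}: header promises {n} words, file has {len(vectors)}")
        return cls(vectors=vectors)

    def save_word2vec(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for word, vec in self.vectors.items():
                vals = " ".join(f"{v:.8g}" for v in vec)
                fh.write(f"{word.replace(' ', '_')} {vals}\n")


@dataclass
class SimilaritySequence:
    """Adjacent-pair cosine similarities d(W_{i-1}, W_i) of one response."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (np.nanmax(self.values) > 1 + 1e-9
                                 or np.nanmin(self.values) < -1 - 1e-9):
            raise ValidationError("cosine similarities must lie in [-1, 1]")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SemanticThresholdConfig:
    mode: str = "adaptive"            # adaptive | fixed
    fixed_value: float = 0.05
    adaptive_fraction: float = 0.75
    pair_scope: str = "adjacent"      # adjacent | all (normalization basis)

    def __post_init__(self) -> None:
        if self.mode not in ("adaptive", "fixed"):
            raise ValidationError(f"unknown threshold mode {self.mode!r}")
        if not 0 < self.adaptive_fraction <= 1:
            raise ValidationError("adaptive_fraction must be in (0, 1]")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedMetricError("cosine similarity undefined for zero vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def adjacent_similarities(names: Sequence[str],
                          store: EmbeddingStore,
                          subject_id: str = "") -> SimilaritySequence:
    """Cosine similarity of each successive word pair; length n-1."""
    values = [cosine_similarity(store[a], store[b])
              for a, b in zip(names, names[1:])]
    return SimilaritySequence(values=np.asarray(values), subject_id=subject_id)


def all_pairs_similarities(names: Sequence[str],
                           store: EmbeddingStore) -> np.ndarray:
    """Cosine similarity of every unordered token pair (C(n,2) values)."""
    vals = [cosine_similarity(store[names[i]], store[names[j]])
            for i in range(len(names)) for j in range(i + 1, len(names))]
    return np.asarray(vals)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Map values affinely onto [0, 1]; degenerate input raises."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateThresholdError(
            "all similarity values identical; adaptive threshold undefined")
    return (values - lo) / (hi - lo)


def adaptive_threshold(sims: SimilaritySequence,
                       cfg: SemanticThresholdConfig | None = None) -> float:
    """Subject-specific threshold: fraction x mean of min-max normalized sims.

    The returned threshold lives on the *normalized* scale; compare it with
    ``minmax_normalize(sims.values)``, not the raw similarities.
    """
    cfg = cfg or SemanticThresholdConfig()
    if len(sims) < 2:
        raise ValidationError(
            "adaptive threshold needs at least 2 similarity values")
    normalized = minmax_normalize(sims.values)
    return float(cfg.adaptive_fraction * normalized.mean())


def same_cluster_esa(similarity: float, threshold: float) -> bool:
    """Adjacent pair shares a cluster iff similarity >= threshold."""
    return similarity >= threshold


def same_cluster_troyer(a: str, b: str, table: CategoryTable) -> bool:
    """Two names share a cluster iff their subcategory sets intersect."""
    return bool(table.subcategories_of(a) & table.subcategories_of(b))
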