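"""Greedy left-to-right segmentation of a word sequence into semantic clusters.

A token joins the current cluster iff the same-cluster predicate holds for
the adjacent pair (previous token, this token); otherwise a *switch* is
recorded at its position and a new cluster opens.  This pairwise rule is
exactly what the adjacent-similarity sequence d(W_{i-1}, W_i) supports; no
multi-category chain rules are applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import EmptySequenceError, ValidationError
from .lexicon import CategoryTable
from .semantics import SimilaritySequence, same_cluster_esa, same_cluster_troyer


@dataclass
class Segmentation:
    """Ordered partition of token indices 0..n-1 into semantic clusters.

    ``switch_indices[k]`` is the position of the first token of cluster
    ``k+1``; there is always one more cluster than switches.
    """

    clusters: list[list[int]]
    switch_indices: list[int]
    method: str = "generic"

    def __post_init__(self) -> None:
        flat = [i for cl in self.clusters for i in cl]
        if flat != list(range(len(flat))) or not all(self.clusters):
            raise ValidationError(
                "clusters must partition 0..n-1 in order with no empty cluster")
        if len(self.clusters) != len(self.switch_indices) + 1:
            raise ValidationError(
                "number of clusters must equal number of switches + 1")
        if self.switch_indices != [cl[0] for cl in self.clusters[1:]]:
            raise ValidationError(
                "switch indices must be the first index of each later cluster")

    @property
    def n_tokens(self) -> int:
        return sum(len(cl) for cl in self.clusters)

    @property
    def n_switches(self) -> int:
        return len(self.switch_indices)


def segment_from_adjacency(same_as_previous: Sequence[bool],
                           method: str = "generic") -> Segmentation:
    """Build a segmentation from the boolean adjacent-pair vector.

    ``same_as_previous[i-1]`` says whether token i continues the cluster of
    token i-1; its length is n-1 for an n-token sequence.
    """
    n = len(same_as_previous) + 1
    clusters: list[list[int]] = [[0]]
    switches: list[int] = []
    for i in range(1, n):
        if same_as_previous[i - 1]:
            clusters[-1].append(i)
        else:
            switches.append(i)
            clusters.append([i])
    return Segmentation(clusters=clusters, switch_indices=switches,
                        method=method)


def segment(names: Sequence[str],
            predicate: Callable[[str, str], bool],
            method: str = "generic") -> Segmentation:
    """Segment a name sequence with an arbitrary same-cluster predicate."""
    if len(names) == 0:
        raise EmptySequenceError("cannot segment an empty sequence")
    adjacency = [predicate(a, b) for a, b in zip(names, names[1:])]
    return segment_from_adjacency(adjacency, method=method)


def segment_esa(sims: SimilaritySequence, threshold: float) -> Segmentation:
    """Threshold the adjacent-similarity sequence (n-1 values -> n tokens).

    ``sims`` and ``threshold`` must live on the same scale: raw similarities
    with a fixed threshold, or min-max normalized similarities with an
    adaptive one.
    """
    adjacency = [same_cluster_esa(float(s), threshold) for s in sims.values]
    return segment_from_adjacency(adjacency, method="esa")


def segment_troyer(names: Sequence[str], table: CategoryTable) -> Segmentation:
    """Segment by subcategory-set intersection of adjacent names."""
    if len(names) == 0:
        raise EmptySequenceError("cannot segment an empty sequence")
    adjacency = [same_cluster_troyer(a, b, table)
                 for a, b in zip(names, names[1:])]
    return segment_from_adjacency(adjacency, method="troyer")


def single_cluster(n: int, method: str = "generic") -> Segmentation:
    """Degenerate fallback: all n tokens in one cluster (0 switches)."""
    if n < 1:
        raise EmptySequenceError("cannot segment an empty sequence")
    return Segmentation(clusters=[list(range(n))], switch_indices=[],
                        method=method)


def cluster_sizes(seg: Segmentation) -> list[int]:
    return [len(cl) for cl in seg.clusters]
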