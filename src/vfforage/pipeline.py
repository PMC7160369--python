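"""End-to-end feature extraction: raw responses -> per-subject feature rows.

Wires classification of tokens, timeline trimming, segmentation (embedding
or category-table mode), and the count + timing feature extractors into a
single :class:`~vfforage.ml.FeatureMatrix`.  Degenerate responses (no
animal words, undefined adaptive threshold, too few words) fall back to
conservative defaults with a warning rather than dropping the subject.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import segmentation as seg_mod
from .count_features import COUNT_FEATURES, WordResources, count_feature_set
from .errors import DegenerateThresholdError, EmptySequenceError
from .lexicon import AnimalLexicon, CategoryTable, classify_tokens
from .ml import FeatureMatrix
from .semantics import (EmbeddingStore, SemanticThresholdConfig,
                        SimilaritySequence, adjacent_similarities,
                        adaptive_threshold, minmax_normalize)
from .time_features import (AnimalSequence, aggregate_timing,
                            compute_switch_timing, trim_and_renormalize)
from .vf_io import Response

logger = logging.getLogger(__name__)


def segment_sequence(seq: AnimalSequence,
                     method: str,
                     store: Optional[EmbeddingStore] = None,
                     table: Optional[CategoryTable] = None,
                     threshold: Optional[SemanticThresholdConfig] = None
                     ) -> tuple[seg_mod.Segmentation,
                                Optional[SimilaritySequence], AnimalSequence]:
    """Segment one animal sequence under the requested method.

    Returns (segmentation, adjacent similarities or None, the possibly
    filtered sequence).  In category-table mode, names absent from the
    table are treated as non-animal and dropped before segmentation.
    """
    threshold = threshold or SemanticThresholdConfig()
    if method == "troyer":
        if table is None:
            raise ValueError("category-table mode requires a table")
        keep = [i for i, n in enumerate(seq.names) if n in table]
        dropped = len(seq) - len(keep)
        if dropped:
            logger.warning("%s: %d name(s) unknown to the category table "
                           "dropped for table-mode segmentation",
                           seq.subject_id, dropped)
        if not keep:
            raise EmptySequenceError(
                f"{seq.subject_id}: no in-table names to segment")
        seq = AnimalSequence(subject_id=seq.subject_id,
                             names=[seq.names[i] for i in keep],
                             onsets=seq.onsets[keep],
                             original_duration=seq.original_duration,
                             shortened_duration=seq.shortened_duration)
        sims = (adjacent_similarities(seq.names, store, seq.subject_id)
                if store is not None and len(seq) >= 2 else None)
        return seg_mod.segment_troyer(seq.names, table), sims, seq
    if method != "esa":
        raise ValueError(f"unknown segmentation method {method!r}")
    if store is None:
        raise ValueError("embedding mode requires an embedding store")
    if len(seq) == 1:
        return seg_mod.single_cluster(1, method="esa"), None, seq
    sims = adjacent_similarities(seq.names, store, seq.subject_id)
    if threshold.mode == "fixed":
        seg = seg_mod.segment_esa(sims, threshold.fixed_value)
    else:
        try:
            thr = adaptive_threshold(sims, threshold)
            normalized = SimilaritySequence(
                values=np.clip(minmax_normalize(sims.values), 0.0, 1.0),
                subject_id=seq.subject_id)
            seg = seg_mod.segment_esa(normalized, thr)
        except DegenerateThresholdError:
            logger.warning("%s: degenerate adaptive threshold; falling back "
                           "to a single cluster", seq.subject_id)
            seg = seg_mod.single_cluster(len(seq), method="esa")
    return seg, sims, seq


def extract_features(responses: Iterable[Response],
                     lexicon: AnimalLexicon,
                     method: str = "esa",
                     store: Optional[EmbeddingStore] = None,
                     table: Optional[CategoryTable] = None,
                     resources: Optional[WordResources] = None,
                     threshold: Optional[SemanticThresholdConfig] = None,
                     time_norm: str = "collapse",
                     include_time: bool = True) -> FeatureMatrix:
    """Extract the full count (+ timing) feature matrix for a cohort.

    Subjects whose responses contain no animal words are skipped with a
    warning; every other degenerate case yields NaN cells that downstream
    model fitting imputes.
    """
    rows: dict[str, dict[str, float]] = {}
    labels: dict[str, str] = {}
    for response in responses:
        classified = classify_tokens(response, lexicon)
        try:
            seq = trim_and_renormalize(classified, mode=time_norm)
            seg, sims, used = segment_sequence(seq, method, store=store,
                                               table=table,
                                               threshold=threshold)
        except EmptySequenceError as exc:
            logger.warning("skipping subject: %s", exc)
            continue
        row = count_feature_set(used, seg, resources=resources, sims=sims,
                                store=store)
        if include_time:
            row.update(aggregate_timing(compute_switch_timing(used, seg)))
        rows[response.subject_id] = row
        labels[response.subject_id] = response.label or "CI"
    if not rows:
        raise EmptySequenceError("no usable responses in the cohort")
    data = pd.DataFrame.from_dict(rows, orient="index")
    return FeatureMatrix(data=data,
                         labels=pd.Series(labels).loc[data.index])
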