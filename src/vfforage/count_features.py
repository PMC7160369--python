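"""Count-based features of a fluency response.

These summarize *what* was produced (productivity, lexical properties,
semantic structure) as opposed to the timing features, which summarize
*when*.  The emitted set, per response:

== ====================== ====================================================
1  af_score               unique canonical animal names (the standard score)
2  n_switches             number of cluster switches
3  anwc                   average number of words per cluster
4  n_duplicates           total tokens minus unique names (perseverations)
5  freq_log_mean/sd       natural-log word frequency, mean and population sd
6  syll_mean/sd           syllable counts
7  typ_mean/sd            typicality scores
8  mesa                   mean adjacent-pair cosine similarity
9  maesa                  mean all-pairs cosine similarity
10 mesa_maesa_ratio       mesa / maesa
11 n_single_word_clusters singleton-cluster count
12 scr                    single-cluster ratio (singletons / clusters)
== ====================== ====================================================

"Unique animal words" and "unique words" coincide on a normalized sequence,
so a single ``af_score`` column carries both.  Lexical features average over
*tokens* (duplicates included) that have a resource entry; tokens without an
entry — or with non-positive frequency — are excluded from that feature and
counted in the returned coverage warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParseError
from .segmentation import Segmentation, cluster_sizes
from .semantics import EmbeddingStore, SimilaritySequence, all_pairs_similarities
from .time_features import AnimalSequence

logger = logging.getLogger(__name__)

COUNT_FEATURES = (
    "af_score", "n_switches", "anwc", "n_duplicates",
    "freq_log_mean", "freq_log_sd", "syll_mean", "syll_sd",
    "typ_mean", "typ_sd", "mesa", "maesa", "mesa_maesa_ratio",
    "n_single_word_clusters", "scr",
)


@dataclass
class WordResources:
    """Optional per-word lookup tables; lookups are partial."""

    frequency: dict[str, float] = field(default_factory=dict)
    syllables: dict[str, int] = field(default_factory=dict)
    typicality: dict[str, float] = field(default_factory=dict)

    @classmethod
    def load(cls, frequency: Optional[str | Path] = None,
             syllables: Optional[str | Path] = None,
             typicality: Optional[str | Path] = None) -> "WordResources":
        def read(path, column, cast):
            if path is None:
                return {}
            df = pd.read_csv(path, sep="\t", dtype={"name": str})
            if not {"name", column} <= set(df.columns):
                raise ParseError(f"{path}: expected columns name, {column}")
            return {str(n).lower(): cast(v)
                    for n, v in zip(df["name"], df[column])}

        return cls(frequency=read(frequency, "frequency", float),
                   syllables=read(syllables, "syllables", int),
                   typicality=read(typicality, "typicality", float))


def af_score(seq: AnimalSequence) -> int:
    """Standard animal-fluency score: count of distinct canonical names."""
    return len(set(seq.names))


def single_cluster_ratio(seg: Segmentation) -> float:
    """Fraction of clusters that contain exactly one word (SCR)."""
    sizes = cluster_sizes(seg)
    return sum(1 for s in sizes if s == 1) / len(sizes)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    if not values:
        return math.nan, math.nan
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std())  # population sd


def count_feature_set(seq: AnimalSequence,
                      seg: Segmentation,
                      resources: WordResources | None = None,
                      sims: SimilaritySequence | None = None,
                      store: EmbeddingStore | None = None) -> dict[str, float]:
    """Compute the full count-feature dictionary for one response.

    ``sims`` supplies mesa; ``store`` supplies maesa (all-pairs).  Either may
    be omitted (e.g., category-table mode without embeddings), in which case
    the corresponding features are NaN.
    """
    resources = resources or WordResources()
    n = len(seq)
    sizes = cluster_sizes(seg)
    features: dict[str, float] = {
        "af_score": float(af_score(seq)),
        "n_switches": float(seg.n_switches),
        "anwc": n / len(sizes),
        "n_duplicates": float(n - af_score(seq)),
        "n_single_word_clusters": float(sum(1 for s in sizes if s == 1)),
        "scr": single_cluster_ratio(seg),
    }

    log_freqs = []
    skipped = 0
    for name in seq.names:
        freq = resources.frequency.get(name)
        if freq is None or freq <= 0:
            skipped += 1 if resources.frequency else 0
            continue
        log_freqs.append(math.log(freq))
    if skipped:
        logger.warning("%s: %d token(s) without a positive frequency entry "
                       "excluded from frequency features", seq.subject_id,
                       skipped)
    features["freq_log_mean"], features["freq_log_sd"] = _mean_sd(log_freqs)

    sylls = [float(resources.syllables[n_]) for n_ in seq.names
             if n_ in resources.syllables]
    features["syll_mean"], features["syll_sd"] = _mean_sd(sylls)
    typs = [resources.typicality[n_] for n_ in seq.names
            if n_ in resources.typicality]
    features["typ_mean"], features["typ_sd"] = _mean_sd(typs)

    mesa = maesa = math.nan
    if n >= 2:
        if sims is not None and len(sims):
            mesa = float(np.mean(sims.values))
        if store is not None:
            maesa = float(np.mean(all_pairs_similarities(seq.names, store)))
    features["mesa"] = mesa
    features["maesa"] = maesa
    features["mesa_maesa_ratio"] = (
        mesa / maesa if not math.isnan(mesa) and not math.isnan(maesa)
        and maesa != 0 else math.nan)
    return features


def syllable_count_heuristic(word: str) -> int:
    """Vowel-group fallback syllable estimate (off by default in pipelines)."""
    groups = 0
    prev_vowel = False
    for ch in word.lower():
        is_vowel = ch in "aeiouy"
        if is_vowel and not prev_vowel:
            groups += 1
        prev_vowel = is_vowel
    if word.lower().endswith("e") and groups > 1 and not word.lower().endswith(("le", "ee")):
        groups -= 1
    return max(groups, 1)
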