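"""Timeline trimming and the foraging-style timing features SD, ICRT, OSR.

The marginal-value-theorem analogy treats semantic memory as patchy
foraging: a cluster is a patch, a switch is travel between patches.  Three
per-switch quantities capture how well a subject times those departures:

* **SD** (switching duration) — onset gap between the last word of a
  cluster and the first word of the next.
* **ICRT** (intra-cluster retrieval time) — onset gap between the first two
  words of the newly entered cluster; undefined when that cluster has only
  one word.
* **OSR** (optimal switch rate) — |SD - ICRT| per switch; smaller means the
  cost of switching was better matched to the payoff of the new patch.

Before any timing is measured, non-animal speech (fillers, examiner
interruptions) is trimmed and the timeline *collapsed*: each removed
token's duration is subtracted from all later onsets, so gaps between
animal words that had no interruption between them are preserved exactly.
Missing values are represented as NaN throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptySequenceError, ValidationError
from .segmentation import Segmentation
from .vf_io import ANIMAL, Response

TIMING_AGGREGATES = ("mean", "median", "var", "min", "max")


@dataclass
class AnimalSequence:
    """Ordered canonical animal names with collapsed (renormalized) onsets."""

    subject_id: str
    names: list[str]
    onsets: np.ndarray
    original_duration: float
    shortened_duration: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if len(self.names) != self.onsets.size:
            raise ValidationError("names and onsets must have equal length")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValidationError(
                f"{self.subject_id}: onsets must be strictly increasing")
        if self.shortened_duration > self.original_duration + 1e-9:
            raise ValidationError(
                "shortened duration cannot exceed original duration")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class SwitchTiming:
    """Per-switch SD / ICRT / OSR values; NaN marks an undefined entry."""

    sd: np.ndarray
    icrt: np.ndarray
    osr: np.ndarray

    def __post_init__(self) -> None:
        self.sd = np.asarray(self.sd, dtype=float)
        self.icrt = np.asarray(self.icrt, dtype=float)
        self.osr = np.asarray(self.osr, dtype=float)
        if not (self.sd.size == self.icrt.size == self.osr.size):
            raise ValidationError("sd/icrt/osr must be aligned per switch")


def trim_and_renormalize(response: Response,
                         mode: str = "collapse") -> AnimalSequence:
    """Remove non-animal tokens and renormalize the remaining onsets.

    ``collapse`` subtracts each removed token's duration from all later
    onsets, yielding a shortened timeline of length
    ``original_duration - sum(removed durations)``.  ``fraction``
    additionally divides the collapsed onsets by the shortened duration
    (unitless timestamps for sensitivity analysis).

    The response must already be classified by
    :func:`vfforage.lexicon.classify_tokens`.
    """
    if mode not in ("collapse", "fraction"):
        raise ValidationError(f"unknown time normalization mode {mode!r}")
    if any(t.token_class is None for t in response.tokens):
        raise ValidationError(
            f"{response.subject_id}: classify tokens before trimming")
    removed = 0.0
    names: list[str] = []
    onsets: list[float] = []
    for tok in response.tokens:
        if tok.token_class == ANIMAL:
            names.append(tok.word)
            onsets.append(tok.onset - removed)
        else:
            removed += tok.duration
    if not names:
        raise EmptySequenceError(
            f"{response.subject_id}: no animal tokens after trimming")
    original = float(response.total_duration)
    shortened = original - removed
    onset_arr = np.asarray(onsets)
    if mode == "fraction":
        if shortened <= 0:
            raise ValidationError(
                f"{response.subject_id}: non-positive shortened duration")
        onset_arr = onset_arr / shortened
    return AnimalSequence(subject_id=response.subject_id, names=names,
                          onsets=onset_arr, original_duration=original,
                          shortened_duration=shortened)


def switching_durations(seq: AnimalSequence, seg: Segmentation) -> np.ndarray:
    """SD per switch: onset of the new cluster's first word minus the onset
    of the previous cluster's last word."""
    _check_alignment(seq, seg)
    return np.asarray([seq.onsets[i] - seq.onsets[i - 1]
                       for i in seg.switch_indices])


def intra_cluster_retrieval_times(seq: AnimalSequence,
                                  seg: Segmentation) -> np.ndarray:
    """ICRT per switch: onset gap of the first two words of the entered
    cluster; NaN when that cluster is a singleton."""
    _check_alignment(seq, seg)
    out = []
    for cluster in seg.clusters[1:]:
        if len(cluster) >= 2:
            out.append(seq.onsets[cluster[1]] - seq.onsets[cluster[0]])
        else:
            out.append(math.nan)
    return np.asarray(out)


def optimal_switch_rates(timing_sd: np.ndarray,
                         timing_icrt: np.ndarray) -> np.ndarray:
    """OSR per switch: |SD - ICRT|; NaN wherever ICRT is undefined."""
    sd = np.asarray(timing_sd, dtype=float)
    icrt = np.asarray(timing_icrt, dtype=float)
    if sd.size != icrt.size:
        raise ValidationError("sd and icrt must be aligned per switch")
    return np.abs(sd - icrt)


def compute_switch_timing(seq: AnimalSequence,
                          seg: Segmentation) -> SwitchTiming:
    sd = switching_durations(seq, seg)
    icrt = intra_cluster_retrieval_times(seq, seg)
    return SwitchTiming(sd=sd, icrt=icrt, osr=optimal_switch_rates(sd, icrt))


def _aggregate(values: np.ndarray) -> dict[str, float]:
    present = values[~np.isnan(values)]
    if present.size == 0:
        return {agg: math.nan for agg in TIMING_AGGREGATES}
    return {
        "mean": float(present.mean()),
        "median": float(np.median(present)),
        "var": float(present.var()),     # population variance
        "min": float(present.min()),
        "max": float(present.max()),
    }


def aggregate_timing(timing: SwitchTiming) -> dict[str, float]:
    """Fixed-dimension summary of the variable-length timing vectors.

    Emits mean/median/var/min/max over the present (non-NaN) values of each
    of sd, icrt, osr — 15 named features.  A feature family with no present
    values yields all-NaN aggregates (e.g., a response with no switches).
    """
    out: dict[str, float] = {}
    for prefix, values in (("sd", timing.sd), ("icrt", timing.icrt),
                           ("osr", timing.osr)):
        for agg, val in _aggregate(values).items():
            out[f"{prefix}_{agg}"] = val
    return out


def _check_alignment(seq: AnimalSequence, seg: Segmentation) -> None:
    if seg.n_tokens != len(seq):
        raise ValidationError(
            f"segmentation covers {seg.n_tokens} tokens but sequence has "
            f"{len(seq)}")
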