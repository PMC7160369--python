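"""Reading and writing transcripts, feature tables, and run configuration.

The transcript transport format is CTM (time-marked conversation): one token
per line, whitespace delimited::

    <recording-id> <channel> <onset-seconds> <duration-seconds> <word> [<speaker>]

The optional sixth column marks the speaker as participant (``P``, default)
or examiner (``E``); examiner speech is carried through so the trimming stage
can subtract its duration from the timeline.  This module does no science —
all semantic and timing logic lives downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .errors import ParseError, ValidationError

PARTICIPANT = "participant"
EXAMINER = "examiner"

ANIMAL = "animal"
NON_ANIMAL = "non_animal"

_SPEAKER_CODES = {"P": PARTICIPANT, "E": EXAMINER,
                  PARTICIPANT: PARTICIPANT, EXAMINER: EXAMINER}


@dataclass(frozen=True)
class Token:
    """One spoken word with its onset time (seconds from recording start)."""

    word: str
    onset: float
    duration: float
    speaker: str = PARTICIPANT
    token_class: Optional[str] = None  # ANIMAL / NON_ANIMAL / None = unclassified

    def __post_init__(self) -> None:
        if not self.word:
            raise ValidationError("Token word must be non-empty")
        if self.onset < 0 or self.duration < 0:
            raise ValidationError(
                f"Token {self.word!r}: onset and duration must be non-negative "
                f"(got onset={self.onset}, duration={self.duration})")
        if self.speaker not in (PARTICIPANT, EXAMINER):
            raise ValidationError(f"Unknown speaker {self.speaker!r}")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def replace(self, **kw) -> "Token":
        return dataclasses.replace(self, **kw)


@dataclass
class Response:
    """One subject's verbal response: an onset-ordered token stream.

    ``total_duration`` defaults to the end of the last token; it may be set
    explicitly when the recording length is known (it usually extends past
    the last word).  ``label`` is the diagnostic group (``MCI`` or ``CI``)
    when known.
    """

    subject_id: str
    tokens: list[Token]
    total_duration: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        onsets = [t.onset for t in self.tokens]
        if onsets != sorted(onsets):
            # stable sort keeps input order among equal onsets
            self.tokens = sorted(self.tokens, key=lambda t: t.onset)
        if self.tokens:
            last_end = max(t.end for t in self.tokens)
            if self.total_duration is None:
                self.total_duration = last_end
            elif self.total_duration < last_end - 1e-9:
                raise ValidationError(
                    f"Response {self.subject_id}: total_duration "
                    f"{self.total_duration} ends before the last token "
                    f"({last_end})")
        elif self.total_duration is None:
            self.total_duration = 0.0
        if self.label is not None and self.label not in ("MCI", "CI"):
            raise ValidationError(f"Unknown label {self.label!r}")

    def participant_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.speaker == PARTICIPANT]


def read_ctm(path: str | Path) -> list[Response]:
    """Read a CTM transcript file into one :class:`Response` per recording id.

    Lines starting with ``#`` or ``;;`` are comments.  Responses are returned
    in order of first appearance; tokens are ordered by onset.
    """
    path = Path(path)
    by_subject: dict[str, list[Token]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith(";;"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ParseError(
                    f"{path}:{lineno}: expected >=5 whitespace-delimited "
                    f"fields, got {len(fields)}: {line!r}")
            rec_id, _channel, onset_s, dur_s, word = fields[:5]
            try:
                onset, duration = float(onset_s), float(dur_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric onset/duration: {line!r}"
                ) from exc
            if onset < 0 or duration < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative onset or duration: {line!r}")
            speaker = PARTICIPANT
            if len(fields) >= 6:
                code = fields[5]
                if code not in _SPEAKER_CODES:
                    raise ParseError(
                        f"{path}:{lineno}: unknown speaker code {code!r} "
                        f"(expected P or E)")
                speaker = _SPEAKER_CODES[code]
            by_subject.setdefault(rec_id, []).append(
                Token(word=word.lower(), onset=onset, duration=duration,
                      speaker=speaker))
    return [Response(subject_id=sid, tokens=toks)
            for sid, toks in by_subject.items()]


def write_ctm(responses: Iterable[Response], path: str | Path) -> None:
    """Write responses in the 6-column CTM dialect read by :func:`read_ctm`."""
    code = {PARTICIPANT: "P", EXAMINER: "E"}
    with open(path, "w") as fh:
        for resp in responses:
            for tok in resp.tokens:
                fh.write(f"{resp.subject_id} 1 {tok.onset:.3f} "
                         f"{tok.duration:.3f} {tok.word} {code[tok.speaker]}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``subject_id<TAB>label`` into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"subject_id", "label"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns subject_id, label")
    return dict(zip(df["subject_id"], df["label"]))


def write_labels(responses: Iterable[Response], path: str | Path) -> None:
    rows = [(r.subject_id, r.label) for r in responses]
    pd.DataFrame(rows, columns=["subject_id", "label"]).to_csv(
        path, sep="\t", index=False)


def write_feature_table(matrix, path: str | Path) -> None:
    """Write a :class:`~vfforage.ml.FeatureMatrix` as TSV.

    Header row of feature names with ``label`` last; one subject per row;
    missing cells rendered as ``NA``.  Round-trips with
    :func:`read_feature_table` to 6 decimal places.
    """
    cols = list(matrix.data.columns)
    if len(set(cols)) != len(cols):
        raise ValidationError("feature column names must be unique")
    out = matrix.data.copy()
    out.insert(0, "subject_id", matrix.data.index)
    out["label"] = matrix.labels.values
    out.to_csv(path, sep="\t", index=False, na_rep="NA",
               float_format="%.6f")


def read_feature_table(path: str | Path):
    """Read a feature TSV written by :func:`write_feature_table`."""
    from .ml import FeatureMatrix  # local import: ml is heavyweight

    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "subject_id" not in df.columns or "label" not in df.columns:
        raise ParseError(f"{path}: expected subject_id and label columns")
    df = df.set_index("subject_id")
    df.index.name = None
    labels = df.pop("label").astype(str)
    return FeatureMatrix(data=df.astype(float), labels=labels)


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run (loaded from YAML or JSON)."""

    transcripts: str = "transcripts.ctm"
    labels: str = "labels.tsv"
    lexicon: str = "lexicon.tsv"
    category_table: str = "category_table.tsv"
    embeddings: str = "embeddings.txt"
    frequency: Optional[str] = None
    syllables: Optional[str] = None
    typicality: Optional[str] = None
    method: str = "esa"                # esa | troyer
    threshold_mode: str = "adaptive"   # adaptive | fixed
    threshold_fraction: float = 0.75
    fixed_threshold: float = 0.05
    time_norm: str = "collapse"        # collapse | fraction
    cv_repeats: int = 500
    seed: int = 0
    base_dir: str = "."

    def path(self, name: str) -> Optional[Path]:
        value = getattr(self, name)
        if value is None:
            return None
        p = Path(value)
        return p if p.is_absolute() else Path(self.base_dir) / p


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if "base_dir" not in raw:
        cfg.base_dir = str(path.parent)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
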