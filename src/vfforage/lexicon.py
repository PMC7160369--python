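"""Animal-name normalization and token classification.

Raw fluency transcripts contain plural forms ("pigs"), irregular plurals
("hippopotami", "oxen"), multi-word names ("mountain lion", "great white
shark"), fillers and examiner speech.  This module maps raw tokens onto
canonical singular animal names using purely local resources: an
:class:`AnimalLexicon` (canonical names + irregular-plural map + multi-word
names) and, for rule-based clustering, a :class:`CategoryTable` assigning
each name to 1-4 semantic subcategories.

Stemming is deliberately conservative: a suffix rule (-s, -es, -ies) is
accepted only when the stemmed form is itself in the lexicon, so names like
"moose" are never corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import ParseError, ValidationError
from .vf_io import ANIMAL, NON_ANIMAL, PARTICIPANT, Response, Token

MAX_SUBCATEGORIES = 4


@dataclass
class AnimalLexicon:
    canonical_names: set[str]
    plural_map: dict[str, str] = field(default_factory=dict)
    multiword_names: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for plural, singular in self.plural_map.items():
            if singular not in self.canonical_names:
                raise ValidationError(
                    f"plural {plural!r} maps to {singular!r}, which is not a "
                    f"canonical name")
        for name in self.multiword_names:
            if len(name.split()) < 2:
                raise ValidationError(
                    f"multiword entry {name!r} has fewer than 2 words")

    @property
    def max_phrase_len(self) -> int:
        if not self.multiword_names:
            return 1
        return max(len(n.split()) for n in self.multiword_names)


@dataclass
class CategoryTable:
    """Assignment of canonical animal names to semantic subcategories."""

    assignments: dict[str, frozenset[str]]
    subcategories: frozenset[str]

    def __post_init__(self) -> None:
        for name, cats in self.assignments.items():
            if not 1 <= len(cats) <= MAX_SUBCATEGORIES:
                raise ValidationError(
                    f"{name!r} has {len(cats)} subcategories; expected 1-"
                    f"{MAX_SUBCATEGORIES}")
            stray = cats - self.subcategories
            if stray:
                raise ValidationError(
                    f"{name!r} uses undeclared subcategories {sorted(stray)}")

    def __contains__(self, name: str) -> bool:
        return name in self.assignments

    def subcategories_of(self, name: str) -> frozenset[str]:
        try:
            return self.assignments[name]
        except KeyError:
            raise LookupError(f"{name!r} is not in the category table") from None


def _stem_candidates(word: str) -> list[str]:
    """Conservative singular candidates for a possibly-plural English noun."""
    cands = []
    if word.endswith("ies") and len(word) > 3:
        cands.append(word[:-3] + "y")
    if word.endswith("es") and len(word) > 2:
        cands.append(word[:-2])
    if word.endswith("s") and len(word) > 1:
        cands.append(word[:-1])
    return cands


def normalize_name(raw_tokens: Sequence[str],
                   lexicon: AnimalLexicon) -> Optional[str]:
    """Map a lower-cased word sequence to a canonical singular animal name.

    Lookup order: multi-word match (with a stemmed last word as fallback),
    irregular-plural map, exact lookup, then conservative suffix stemming.
    Returns ``None`` for anything that is not an animal name.
    """
    if not raw_tokens:
        raise ValidationError("normalize_name requires a non-empty sequence")
    words = [w.lower() for w in raw_tokens]
    phrase = " ".join(words)
    if len(words) > 1:
        if phrase in lexicon.multiword_names:
            return phrase
        for cand in _stem_candidates(words[-1]):
            stemmed = " ".join(words[:-1] + [cand])
            if stemmed in lexicon.multiword_names:
                return stemmed
        return None
    word = words[0]
    if word in lexicon.plural_map:
        return lexicon.plural_map[word]
    if word in lexicon.canonical_names:
        return word
    for cand in _stem_candidates(word):
        if cand in lexicon.canonical_names:
            return cand
    return None


def classify_tokens(response: Response, lexicon: AnimalLexicon) -> Response:
    """Tag every token animal / non-animal; merge multi-word animal names.

    Examiner tokens are always non-animal.  A run of consecutive participant
    tokens forming a multi-word name (longest match first) is merged into a
    single token whose word is the canonical name, whose onset is the first
    word's onset, and whose duration is the sum of the constituent durations.
    Unmerged tokens keep their onsets; animal tokens get their canonical
    (singular) word form.
    """
    tokens = response.tokens
    out: list[Token] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok.speaker != PARTICIPANT:
            out.append(tok.replace(token_class=NON_ANIMAL))
            i += 1
            continue
        matched = False
        max_len = min(lexicon.max_phrase_len, len(tokens) - i)
        for span in range(max_len, 0, -1):
            window = tokens[i:i + span]
            if any(t.speaker != PARTICIPANT for t in window):
                continue
            name = normalize_name([t.word for t in window], lexicon)
            if name is None:
                continue
            if span == 1:
                out.append(tok.replace(word=name, token_class=ANIMAL))
            else:
                out.append(Token(word=name, onset=window[0].onset,
                                 duration=sum(t.duration for t in window),
                                 speaker=PARTICIPANT, token_class=ANIMAL))
            i += span
            matched = True
            break
        if not matched:
            out.append(tok.replace(token_class=NON_ANIMAL))
            i += 1
    return Response(subject_id=response.subject_id, tokens=out,
                    total_duration=response.total_duration,
                    label=response.label)


def load_lexicon(path: str | Path) -> AnimalLexicon:
    """Read a lexicon TSV with columns ``name`` and optional ``plural``.

    ``name`` may contain spaces (multi-word names); ``plural`` holds
    irregular plural surface forms, ``|``-separated when there are several.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "name" not in df.columns:
        raise ParseError(f"{path}: expected a 'name' column")
    canonical: set[str] = set()
    multiword: set[str] = set()
    plural_map: dict[str, str] = {}
    for _, row in df.iterrows():
        name = str(row["name"]).strip().lower()
        if not name or name == "nan":
            continue
        canonical.add(name)
        if len(name.split()) > 1:
            multiword.add(name)
        plural = row.get("plural")
        if isinstance(plural, str) and plural.strip():
            for form in plural.split("|"):
                plural_map[form.strip().lower()] = name
    if not canonical:
        raise ParseError(f"{path}: lexicon is empty")
    return AnimalLexicon(canonical_names=canonical, plural_map=plural_map,
                         multiword_names=multiword)


def write_lexicon(lexicon: AnimalLexicon, path: str | Path) -> None:
    by_name: dict[str, list[str]] = {n: [] for n in sorted(lexicon.canonical_names)}
    for plural, singular in lexicon.plural_map.items():
        by_name[singular].append(plural)
    rows = [(n, "|".join(sorted(p))) for n, p in by_name.items()]
    pd.DataFrame(rows, columns=["name", "plural"]).to_csv(
        path, sep="\t", index=False)


def load_category_table(path: str | Path) -> CategoryTable:
    """Read a TSV with one (name, subcategory) pair per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"name", "subcategory"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns name, subcategory")
    if df.empty:
        raise ParseError(f"{path}: category table is empty")
    assignments: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        assignments.setdefault(str(row["name"]).lower(), set()).add(
            str(row["subcategory"]))
    subcats = frozenset(str(s) for s in df["subcategory"].unique())
    return CategoryTable(
        assignments={n: frozenset(c) for n, c in assignments.items()},
        subcategories=subcats)


def write_category_table(table: CategoryTable, path: str | Path) -> None:
    rows = [(name, cat)
            for name in sorted(table.assignments)
            for cat in sorted(table.assignments[name])]
    pd.DataFrame(rows, columns=["name", "subcategory"]).to_csv(
        path, sep="\t", index=False)
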