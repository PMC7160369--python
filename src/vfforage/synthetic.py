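"""Seeded synthetic fluency cohorts, fixture embeddings and word resources.

No public corpus of time-aligned fluency recordings exists, so every
pipeline stage is exercised against generated data.  The generator
emulates a 60-second animal-naming session: a subject works through
semantic "patches" (subcategories of a fixture category table), producing
words separated by log-normal intra-cluster gaps and longer log-normal
switch gaps, until time runs out.  Examiner interruptions and participant
fillers occupy real duration on the timeline, exercising the trimming /
interval-collapse path; plural surface forms and multi-word names exercise
normalization.

Group differences follow the study design this package targets: the MCI
parameterization produces fewer words and a larger mismatch between
switching duration and intra-cluster retrieval time (larger OSR), while
the intact (CI) parameterization switches with gaps commensurate to the
payoff.  The gap scale is *derived* from the target mean word count
(defaults 17.3 CI / 13.3 MCI, matching published animal-fluency means for
matched groups of advanced age) via a closed-form calibration, so
productivity targets are conditions of the generator, not fitted values.

The fixture category table is a synthetic stand-in for curated instruments
of the Troyer type: real animal names, invented (but plausible)
subcategory structure, built programmatically — it reproduces no
copyrighted table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .count_features import WordResources, syllable_count_heuristic
from .errors import ValidationError
from .lexicon import AnimalLexicon, CategoryTable
from .semantics import EmbeddingStore, SimilaritySequence
from .vf_io import ANIMAL, EXAMINER, PARTICIPANT, Response, Token

# --------------------------------------------------------------------------
# Fixture vocabulary: real animal names, synthetic subcategory assignments.

_SUBCATEGORY_NAMES: dict[str, list[str]] = {
    "domestic": ["dog", "cat", "cow", "horse", "pig", "goat", "sheep",
                 "ox", "guinea pig", "donkey", "chicken", "duck", "rabbit",
                 "llama", "turkey", "mule"],
    "feline": ["cat", "lion", "tiger", "leopard", "cheetah", "lynx",
               "mountain lion", "jaguar", "bobcat", "panther", "ocelot"],
    "canine": ["dog", "wolf", "fox", "coyote", "jackal", "dingo",
               "poodle", "beagle", "bulldog", "terrier", "husky"],
    "bird": ["falcon", "eagle", "sparrow", "robin", "owl", "goose",
             "penguin", "ostrich", "crow", "hawk", "parrot", "pigeon",
             "swan", "flamingo", "pelican", "hummingbird"],
    "fish": ["shark", "salmon", "trout", "tuna", "cod", "eel",
             "great white shark", "bass", "catfish", "goldfish",
             "mackerel", "swordfish", "pike"],
    "marine": ["dolphin", "whale", "seal", "octopus", "walrus",
               "shark", "great white shark", "orca", "manatee", "squid",
               "crab", "lobster", "sea lion", "otter"],
    "african": ["elephant", "giraffe", "zebra", "hippopotamus", "rhinoceros",
                "lion", "antelope", "gazelle", "buffalo", "warthog",
                "meerkat", "baboon", "gorilla", "chimpanzee"],
    "rodent": ["mouse", "rat", "squirrel", "beaver", "hamster", "chipmunk",
               "porcupine", "gerbil", "guinea pig", "gopher", "vole",
               "lemming"],
    "reptile": ["snake", "lizard", "turtle", "crocodile", "alligator",
                "iguana", "gecko", "tortoise", "chameleon", "python",
                "cobra", "rattlesnake"],
    "insect": ["ant", "bee", "beetle", "butterfly", "moth", "grasshopper",
               "dragonfly", "fly", "mosquito", "wasp", "cricket",
               "ladybug", "termite"],
    "nocturnal": ["bat", "owl", "raccoon", "opossum", "hedgehog", "skunk",
                  "badger", "mole", "aardvark"],
}

_IRREGULAR_PLURALS: dict[str, str] = {
    "oxen": "ox",
    "hippopotami": "hippopotamus",
    "geese": "goose",
    "mice": "mouse",
    "wolves": "wolf",
    "foxes": "fox",
}

_EXAMINER_PHRASES = [
    ["good"],
    ["keep", "going"],
    ["you", "still", "have", "ten", "seconds", "left"],
    ["that's", "fine"],
]
_FILLER_PHRASES = [["um"], ["uh"], ["let's", "see"], ["hmm"]]

# Figure-style worked example: 7 words, printed onsets and adjacent
# similarities; fixed threshold 0.05 yields clusters
# {dog,cat} {falcon,bat,elephant} {shark,dolphin}.
EXAMPLE_WORDS = ["dog", "cat", "falcon", "bat", "elephant", "shark", "dolphin"]
EXAMPLE_ONSETS = [1.0, 1.5, 2.2, 2.4, 2.9, 3.8, 4.2]
EXAMPLE_SIMILARITIES = [0.077, 0.012, 0.053, 0.055, 0.007, 0.067]
EXAMPLE_THRESHOLD = 0.05


def default_category_table() -> CategoryTable:
    assignments: dict[str, set[str]] = {}
    for cat, names in _SUBCATEGORY_NAMES.items():
        for name in names:
            assignments.setdefault(name, set()).add(cat)
    return CategoryTable(
        assignments={n: frozenset(c) for n, c in assignments.items()},
        subcategories=frozenset(_SUBCATEGORY_NAMES))


def default_lexicon() -> AnimalLexicon:
    names = {n for lst in _SUBCATEGORY_NAMES.values() for n in lst}
    return AnimalLexicon(
        canonical_names=names,
        plural_map={p: s for p, s in _IRREGULAR_PLURALS.items() if s in names},
        multiword_names={n for n in names if " " in n})


def pluralize(name: str) -> str:
    """Plural surface form of an animal name (irregulars included)."""
    for plural, singular in _IRREGULAR_PLURALS.items():
        if singular == name:
            return plural
    if name.endswith(("s", "x", "z", "ch", "sh")):
        return name + "es"
    if name.endswith("y") and name[-2] not in "aeiou":
        return name[:-1] + "ies"
    return name + "s"


# --------------------------------------------------------------------------
# Cohort specification

@dataclass(frozen=True)
class GroupParams:
    """Timing/productivity parameters of one diagnostic group.

    ``mean_words`` is the target expected word count in a full-length test;
    ``subject_sigma`` the log-scale between-subject spread of overall pace
    (driving the word-count spread); ``switch_ratio`` the mean switch gap
    relative to the mean intra-cluster gap; ``switch_sigma`` /
    ``intra_sigma`` the log-normal shape parameters of the two gap types.
    A larger ``switch_ratio`` and ``switch_sigma`` inflate |SD - ICRT|
    (the OSR mismatch).
    """

    mean_words: float
    subject_sigma: float
    switch_ratio: float
    switch_sigma: float
    mean_cluster_size: float
    intra_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.mean_words < 2 or self.mean_cluster_size < 1:
            raise ValidationError("infeasible group parameters")


#: Intact controls: ~17.3 words, switch gaps modestly above intra gaps.
CI_PARAMS = GroupParams(mean_words=17.3, subject_sigma=0.29,
                        switch_ratio=1.5, switch_sigma=0.3,
                        mean_cluster_size=2.5)
#: MCI: ~13.3 words, long and erratic switch gaps (poor patch-leaving).
MCI_PARAMS = GroupParams(mean_words=13.3, subject_sigma=0.31,
                         switch_ratio=2.5, switch_sigma=0.7,
                         mean_cluster_size=2.2)


@dataclass(frozen=True)
class CohortSpec:
    n_mci: int = 28
    n_ci: int = 42
    test_duration: float = 60.0
    mci: GroupParams = MCI_PARAMS
    ci: GroupParams = CI_PARAMS
    interruption_rate: float = 0.15
    filler_rate: float = 0.08
    perseveration_rate: float = 0.05
    plural_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mci < 1 or self.n_ci < 1:
            raise ValidationError("cohort needs >=1 subject per group")
        if self.test_duration <= 5:
            raise ValidationError("test duration too short to be feasible")


def null_spec(seed: int = 0, **kw) -> CohortSpec:
    """A spec with zero group differences (MCI params == CI params)."""
    return CohortSpec(mci=CI_PARAMS, ci=CI_PARAMS, seed=seed, **kw)


# --------------------------------------------------------------------------
# Generation

def _gap_scale(g: GroupParams, test_duration: float, first_onset: float,
               perseveration_rate: float = 0.0) -> float:
    """Closed-form calibration of the gap scale to the target word count.

    Expected *unique* count ~ (1 - p) * (1 + N(T - t0)) with p the
    perseveration rate and N the renewal count of the gap process.  The
    renewal expectation E[N(t)] = t / mu + (c^2 - 1) / 2 (c = coefficient
    of variation of one gap) and the subject pace multiplier M (log-normal,
    E[1/M] = exp(sigma^2/2)) both enter the closed form; solving for the
    scale s at the target mean count gives the expression below.  E[G]
    mixes one switch gap per cluster with (size-1) unit-mean intra gaps.
    """
    m = g.mean_cluster_size
    w_switch = 1.0 / m
    e_gap = w_switch * g.switch_ratio + (1.0 - w_switch)
    e_gap2 = (w_switch * g.switch_ratio ** 2 * math.exp(g.switch_sigma ** 2)
              + (1.0 - w_switch) * math.exp(g.intra_sigma ** 2))
    cv2 = e_gap2 / e_gap ** 2 - 1.0
    budget = test_duration - first_onset
    if budget <= 0:
        raise ValidationError("first onset exceeds the test duration")
    effective_target = g.mean_words / (1.0 - perseveration_rate)
    n_gaps = effective_target - 1.0 - (cv2 - 1.0) / 2.0
    if n_gaps <= 0:
        raise ValidationError("infeasible word-count target")
    return budget * math.exp(g.subject_sigma ** 2 / 2) / (n_gaps * e_gap)


def _lognormal_unit_mean(rng: np.random.Generator, mean: float,
                         sigma: float) -> float:
    """Log-normal draw with the given mean and log-scale sigma."""
    mu = math.log(mean) - sigma ** 2 / 2
    return float(rng.lognormal(mu, sigma))


def _sample_clean_sequence(g: GroupParams, duration: float,
                           table: CategoryTable,
                           rng: np.random.Generator,
                           perseveration_rate: float
                           ) -> tuple[list[str], list[float]]:
    """Animal names + onsets on the interruption-free (shortened) timeline."""
    subcats = sorted(table.subcategories)
    by_cat = {c: sorted(n for n, cats in table.assignments.items()
                        if c in cats) for c in subcats}
    first_onset = float(rng.uniform(0.8, 1.6))
    scale = _gap_scale(g, duration, 1.2, perseveration_rate) * math.exp(
        rng.normal(0.0, g.subject_sigma))

    names: list[str] = []
    onsets: list[float] = []
    t = first_onset
    current_cat = None
    remaining_in_cluster = 0
    cluster_words: list[str] = []
    while True:
        if remaining_in_cluster == 0:
            prev = current_cat
            choices = [c for c in subcats if c != prev]
            current_cat = choices[rng.integers(len(choices))]
            pool = [w for w in by_cat[current_cat] if w not in names]
            if not pool:
                pool = by_cat[current_cat]
            size = int(rng.geometric(1.0 / g.mean_cluster_size))
            remaining_in_cluster = min(size, len(pool))
            cluster_words = list(rng.permutation(pool))
            is_switch = len(names) > 0
        else:
            is_switch = False
        if names:  # every word after the first is preceded by a gap
            if is_switch:
                gap = scale * _lognormal_unit_mean(rng, g.switch_ratio,
                                                   g.switch_sigma)
            else:
                gap = scale * _lognormal_unit_mean(rng, 1.0, g.intra_sigma)
            t = t + gap
            if t > duration:
                break
        if names and rng.random() < perseveration_rate:
            word = names[int(rng.integers(len(names)))]
        else:
            word = cluster_words.pop()
        names.append(word)
        onsets.append(round(t, 3))
        remaining_in_cluster -= 1
        if len(names) > 200:  # safety valve against infeasible specs
            raise ValidationError("generated sequence implausibly long; "
                                  "check the group parameters")
    if not names:
        raise ValidationError("no words fit inside the test duration")
    return names, onsets


def _surface_tokens(name: str, onset: float, rng: np.random.Generator,
                    plural_rate: float) -> list[Token]:
    """Render a canonical name as one or more raw participant tokens."""
    parts = name.split()
    if len(parts) == 1 and rng.random() < plural_rate:
        parts = [pluralize(name)]
    dur_total = float(rng.uniform(0.25, 0.45))
    part_dur = dur_total / len(parts)
    toks = []
    t = onset
    for part in parts:
        toks.append(Token(word=part, onset=round(t, 3),
                          duration=round(part_dur, 3), speaker=PARTICIPANT))
        t += part_dur + 0.02
    return toks


def generate_cohort(spec: CohortSpec,
                    table: CategoryTable | None = None) -> list[Response]:
    """Generate raw (unclassified) responses for a two-group cohort.

    Fully deterministic given ``spec.seed``.  Interruptions and fillers are
    inserted *into* the timeline — later tokens are shifted by exactly the
    inserted duration — so trimming with interval collapse recovers the
    clean timing structure.
    """
    table = table or default_category_table()
    rng = np.random.default_rng(spec.seed)
    responses = []
    groups = ([("MCI", spec.mci)] * spec.n_mci
              + [("CI", spec.ci)] * spec.n_ci)
    for idx, (label, params) in enumerate(groups, start=1):
        sid = f"{label}{idx:03d}"
        names, onsets = _sample_clean_sequence(
            params, spec.test_duration, table, rng, spec.perseveration_rate)
        tokens: list[Token] = []
        shift = 0.0
        for k, (name, onset) in enumerate(zip(names, onsets)):
            word_toks = _surface_tokens(name, onset + shift, rng,
                                        spec.plural_rate)
            tokens.extend(word_toks)
            # interruption / filler inside the gap to the next animal word
            next_gap = (onsets[k + 1] - onset) if k + 1 < len(names) else 0.0
            anchor = word_toks[-1]
            if next_gap > anchor.duration + 0.4:
                phrase = None
                speaker = EXAMINER
                if rng.random() < spec.interruption_rate:
                    phrase = _EXAMINER_PHRASES[
                        int(rng.integers(len(_EXAMINER_PHRASES)))]
                elif rng.random() < spec.filler_rate:
                    phrase = _FILLER_PHRASES[
                        int(rng.integers(len(_FILLER_PHRASES)))]
                    speaker = PARTICIPANT
                if phrase:
                    t = anchor.end + 0.05
                    for w in phrase:
                        d = float(rng.uniform(0.15, 0.3))
                        tokens.append(Token(word=w, onset=round(t, 3),
                                            duration=round(d, 3),
                                            speaker=speaker))
                        t += d
                        shift += d
        # last word's duration may run past the nominal stop time
        total = max(spec.test_duration + shift,
                    max(t.end for t in tokens))
        responses.append(Response(subject_id=sid, tokens=tokens,
                                  total_duration=total, label=label))
    return responses


def generate_embeddings(table: CategoryTable, dim: int = 16,
                        seed: int = 0, noise: float = 0.25) -> EmbeddingStore:
    """Fixture embeddings: near-orthogonal subcategory centroids + noise.

    Words in the same subcategory end up with high mutual cosine
    similarity; words in disjoint subcategories are near-orthogonal in
    expectation.  Multi-category words sit on the mean of their centroids.
    """
    if dim < 2:
        raise ValidationError("embedding dimension must be >= 2")
    rng = np.random.default_rng(seed)
    subcats = sorted(table.subcategories)
    k = len(subcats)
    raw = rng.standard_normal((max(k, dim), dim))
    if dim >= k:
        q, _ = np.linalg.qr(raw.T)
        centroids = q.T[:k]
    else:
        centroids = raw[:k] / np.linalg.norm(raw[:k], axis=1, keepdims=True)
    cent = dict(zip(subcats, centroids))
    vectors = {}
    for name, cats in sorted(table.assignments.items()):
        base = np.mean([cent[c] for c in sorted(cats)], axis=0)
        vec = base + noise / math.sqrt(dim) * rng.standard_normal(dim)
        if not np.any(vec):  # pragma: no cover - measure-zero event
            vec = base
        vectors[name] = vec
    return EmbeddingStore(vectors=vectors)


def generate_word_resources(table: CategoryTable,
                            seed: int = 0) -> WordResources:
    """Plausible frequency / syllable / typicality tables for the fixture
    vocabulary (synthetic: real psycholinguistic norms are not shipped)."""
    rng = np.random.default_rng(seed)
    names = sorted(table.assignments)
    freq = {n: float(max(1, round(rng.lognormal(8.0, 1.5)))) for n in names}
    syll = {n: sum(syllable_count_heuristic(p) for p in n.split())
            for n in names}
    typ = {n: float(np.clip(rng.beta(2.0, 2.0), 0.01, 0.99)) for n in names}
    return WordResources(frequency=freq, syllables=syll, typicality=typ)


# --------------------------------------------------------------------------
# Worked-example fixture

def make_worked_example() -> tuple[Response, SimilaritySequence]:
    """The 7-word worked example with its printed onsets and similarities."""
    tokens = [Token(word=w, onset=t, duration=0.15, speaker=PARTICIPANT,
                    token_class=ANIMAL)
              for w, t in zip(EXAMPLE_WORDS, EXAMPLE_ONSETS)]
    response = Response(subject_id="example", tokens=tokens, total_duration=5.0)
    sims = SimilaritySequence(values=np.asarray(EXAMPLE_SIMILARITIES),
                              subject_id="example")
    return response, sims


def worked_example_embeddings(dim: int = 8) -> EmbeddingStore:
    """Embeddings whose adjacent cosines reproduce the printed similarities.

    Built by the chained construction v_{i+1} = c_i * v_i + sqrt(1 - c_i^2)
    * e_{i+1} on orthonormal axes, which makes cos(v_i, v_{i+1}) = c_i
    exactly (all vectors are unit norm and e_{i+1} is orthogonal to v_i).
    """
    n = len(EXAMPLE_WORDS)
    if dim < n:
        raise ValidationError(f"need dim >= {n}")
    vectors = {}
    v = np.zeros(dim)
    v[0] = 1.0
    vectors[EXAMPLE_WORDS[0]] = v.copy()
    for i, c in enumerate(EXAMPLE_SIMILARITIES):
        e = np.zeros(dim)
        e[i + 1] = 1.0
        v = c * v + math.sqrt(1.0 - c * c) * e
        vectors[EXAMPLE_WORDS[i + 1]] = v.copy()
    return EmbeddingStore(vectors=vectors)
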