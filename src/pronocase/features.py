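"""Grammatical-case classification of first-person singular pronouns (FPSPs)
and extraction of the 12 linguistic-feature percentages per participant.

In Cantonese the FPSP has a single surface form (我); its grammatical case —
subjective, objective, dative or possessive — is recovered from the token's
dependency relation:

* nominal subject (``nsubj``, ``nsubjpass``, ``top``) -> subjective;
* direct object (``dobj``) -> objective;
* indirect object (``iobj``) -> dative;
* associative modifier (``assmod``, incl. the FPSP + genitive particle 嘅/的
  construction modifying a nominal) -> possessive.

Every other relation is resolved by an explicit fallback table so that no
FPSP token is left unclassified (the four case percentages must partition the
total FPSP percentage exactly): prepositional objects (``pobj``) and all
remaining relations default to objective — the object-like, self-as-target
reading — and conjuncts inherit the case of their coordination head.
Fallback use is counted so it can be surfaced per transcript.

The remaining features are tallied from CTB POS tags: first-person plural
pronouns (FPPPs) by surface lexicon, verbs {VV, VC, VE, VA}, prepositions
{P}, temporal nouns {NT}, etcetera particles {ETC}, interjections {IJ} and
passive markers {LB, SB}.  Percentages divide each count by the total number
of tokens (punctuation included by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import pandas as pd

from .annotation import AnnotatedToken, ParsedUtterance

__all__ = [
    "CaseLabel",
    "PronounLexicon",
    "TagMap",
    "FeatureVector",
    "FeatureCounts",
    "EmptyTranscriptError",
    "classify_fpsp_case",
    "tally_features",
    "to_percentages",
    "extract_features",
    "feature_matrix",
    "write_feature_matrix",
    "FEATURE_NAMES",
    "CASE_FEATURES",
]


class EmptyTranscriptError(ValueError):
    """Percentages are undefined for a transcript with zero tokens."""


class CaseLabel(str, Enum):
    SUBJECTIVE = "subjective"
    OBJECTIVE = "objective"
    DATIVE = "dative"
    POSSESSIVE = "possessive"


# anchored relation -> case mapping
_CASE_BY_RELATION = {
    "nsubj": CaseLabel.SUBJECTIVE,
    "nsubjpass": CaseLabel.SUBJECTIVE,
    "top": CaseLabel.SUBJECTIVE,
    "dobj": CaseLabel.OBJECTIVE,
    "iobj": CaseLabel.DATIVE,
    "assmod": CaseLabel.POSSESSIVE,
}

#: genitive particles marking the possessive construction
_GENITIVE_PARTICLES = {"嘅", "的"}


@dataclass(frozen=True)
class PronounLexicon:
    """Surface forms of the first-person pronouns."""

    fpsp_forms: frozenset = frozenset({"我"})
    fppp_forms: frozenset = frozenset({"我哋", "我地", "我們", "我们"})

    def __post_init__(self):
        object.__setattr__(self, "fpsp_forms", frozenset(self.fpsp_forms))
        object.__setattr__(self, "fppp_forms", frozenset(self.fppp_forms))
        if self.fpsp_forms & self.fppp_forms:
            raise ValueError("FPSP and FPPP lexica must be disjoint")


@dataclass(frozen=True)
class TagMap:
    """CTB POS tag sets defining the non-pronoun features.

    ``count_punctuation`` controls whether PU tokens enter the token total.
    """

    verb: frozenset = frozenset({"VV", "VC", "VE", "VA"})
    preposition: frozenset = frozenset({"P"})
    temporal_noun: frozenset = frozenset({"NT"})
    etcetera: frozenset = frozenset({"ETC"})
    interjection: frozenset = frozenset({"IJ"})
    passive_marker: frozenset = frozenset({"LB", "SB"})
    count_punctuation: bool = True

    def __post_init__(self):
        for f in dc_fields(self):
            if f.name != "count_punctuation":
                object.__setattr__(self, f.name, frozenset(getattr(self, f.name)))


#: report row order (snake_case labels)
FEATURE_NAMES = (
    "total_fpsp",
    "possessive_fpsp",
    "subjective_fpsp",
    "objective_fpsp",
    "dative_fpsp",
    "fppp",
    "verb",
    "preposition",
    "temporal_noun",
    "etcetera",
    "interjection",
    "passive_marker",
)

CASE_FEATURES = ("possessive_fpsp", "subjective_fpsp", "objective_fpsp", "dative_fpsp")

_CASE_TO_FEATURE = {
    CaseLabel.POSSESSIVE: "possessive_fpsp",
    CaseLabel.SUBJECTIVE: "subjective_fpsp",
    CaseLabel.OBJECTIVE: "objective_fpsp",
    CaseLabel.DATIVE: "dative_fpsp",
}


@dataclass
class FeatureCounts:
    """Raw feature tallies plus the token total and fallback-rule counter."""

    counts: Dict[str, int]
    token_total: int
    fallback_count: int = 0


@dataclass(frozen=True)
class FeatureVector:
    """The 12 feature percentages (of total tokens) for one participant."""

    total_fpsp: float
    possessive_fpsp: float
    subjective_fpsp: float
    objective_fpsp: float
    dative_fpsp: float
    fppp: float
    verb: float
    preposition: float
    temporal_noun: float
    etcetera: float
    interjection: float
    passive_marker: float
    token_total: int

    def __post_init__(self):
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} = {v} outside [0, 100]")
        if self.token_total < 0:
            raise ValueError("token_total must be >= 0")

    def as_dict(self) -> Dict[str, float]:
        d = {name: getattr(self, name) for name in FEATURE_NAMES}
        d["token_total"] = self.token_total
        return d


def _has_genitive_dependent(token: AnnotatedToken, utterance: ParsedUtterance) -> bool:
    return any(
        t.head == token.index and t.surface in _GENITIVE_PARTICLES
        for t in utterance.tokens
    )


def classify_fpsp_case(
    token: AnnotatedToken,
    utterance: ParsedUtterance,
    lexicon: PronounLexicon | None = None,
    _counter: dict | None = None,
) -> CaseLabel:
    """Assign the grammatical case of one FPSP token from its dependency
    relation (see module docstring for the mapping and fallback table)."""
    lexicon = lexicon or PronounLexicon()
    if token.surface not in lexicon.fpsp_forms:
        raise ValueError(
            f"token {token.surface!r} is not a first-person singular pronoun"
        )
    rel = token.relation
    if rel in _CASE_BY_RELATION:
        return _CASE_BY_RELATION[rel]
    # FPSP + genitive particle modifying a nominal is possessive even when
    # the backend labelled the edge with a generic relation
    if _has_genitive_dependent(token, utterance):
        return CaseLabel.POSSESSIVE
    if _counter is not None:
        _counter["fallback"] = _counter.get("fallback", 0) + 1
    if rel == "conj" and 1 <= token.head <= len(utterance.tokens):
        head = utterance.tokens[token.head - 1]
        if head.surface in lexicon.fpsp_forms and head.index != token.index:
            return classify_fpsp_case(head, utterance, lexicon, _counter=None)
    return CaseLabel.OBJECTIVE


def tally_features(
    utterances: Iterable[ParsedUtterance],
    lexicon: PronounLexicon | None = None,
    tagmap: TagMap | None = None,
) -> FeatureCounts:
    """Tally the raw feature counts over a participant's parses."""
    lexicon = lexicon or PronounLexicon()
    tagmap = tagmap or TagMap()
    counts = {name: 0 for name in FEATURE_NAMES}
    token_total = 0
    counter: dict = {}
    for u in utterances:
        for t in u.tokens:
            if not tagmap.count_punctuation and t.pos == "PU":
                continue
            token_total += 1
            if t.surface in lexicon.fpsp_forms:
                case = classify_fpsp_case(t, u, lexicon, _counter=counter)
                counts["total_fpsp"] += 1
                counts[_CASE_TO_FEATURE[case]] += 1
            elif t.surface in lexicon.fppp_forms:
                counts["fppp"] += 1
            if t.pos in tagmap.verb:
                counts["verb"] += 1
            elif t.pos in tagmap.preposition:
                counts["preposition"] += 1
            elif t.pos in tagmap.temporal_noun:
                counts["temporal_noun"] += 1
            elif t.pos in tagmap.etcetera:
                counts["etcetera"] += 1
            elif t.pos in tagmap.interjection:
                counts["interjection"] += 1
            elif t.pos in tagmap.passive_marker:
                counts["passive_marker"] += 1
    return FeatureCounts(counts, token_total, counter.get("fallback", 0))


def to_percentages(counts: FeatureCounts) -> FeatureVector:
    """Convert raw tallies into percentages of the token total."""
    if counts.token_total <= 0:
        raise EmptyTranscriptError("cannot compute percentages of an empty transcript")
    pct = {
        name: 100.0 * counts.counts[name] / counts.token_total
        for name in FEATURE_NAMES
    }
    return FeatureVector(token_total=counts.token_total, **pct)


def extract_features(
    utterances: Iterable[ParsedUtterance],
    lexicon: PronounLexicon | None = None,
    tagmap: TagMap | None = None,
) -> FeatureVector:
    """Tally and convert in one step."""
    return to_percentages(tally_features(utterances, lexicon, tagmap))


def feature_matrix(vectors: Dict[str, FeatureVector]) -> pd.DataFrame:
    """One row per participant, 12 feature columns + token_total."""
    frame = pd.DataFrame.from_dict(
        {pid: fv.as_dict() for pid, fv in vectors.items()}, orient="index"
    )
    frame.index.name = "participant_id"
    return frame[list(FEATURE_NAMES) + ["token_total"]]


def write_feature_matrix(vectors: Dict[str, FeatureVector], path: str | Path) -> None:
    feature_matrix(vectors).to_csv(path, encoding="utf-8")
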