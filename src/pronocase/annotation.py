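"""Tokenized, POS-tagged, dependency-parsed utterances.

Parses follow the Chinese (Penn) Treebank POS tagset (PN pronoun, VV/VC/VE/VA
verbs, P preposition, NT temporal noun, ETC etcetera particle, IJ interjection,
LB/SB passive markers, PU punctuation) and Chinese Stanford-Dependencies-style
relation labels (nsubj, nsubjpass, top, dobj, iobj, pobj, assmod, root, ...).

Two parser backends are provided:

* :class:`TemplateAnnotator` — a deterministic annotator over a fixed inventory
  of Cantonese sentence templates with hand-built gold parses.  It covers the
  four worked case constructions (subjective / objective / dative / possessive
  first-person singular pronouns), first-person-plural and pro-drop variants,
  and filler patterns for verbs, prepositions, temporal nouns, etcetera
  particles, interjections and passive markers.  It is the backend used by the
  test suite and the synthetic corpus generator.
* :class:`HanLPBackend` — a thin adapter around the HanLP toolkit (optional;
  imported lazily, never used by the default test suite) that maps HanLP's
  native dependency labels onto the dialect above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Protocol, Sequence

__all__ = [
    "AnnotatedToken",
    "ParsedUtterance",
    "AnnotationError",
    "UnsupportedSentenceError",
    "ParserBackend",
    "TemplateAnnotator",
    "HanLPBackend",
    "annotate",
    "validate_parse",
    "to_conll",
    "from_conll",
    "TEMPLATE_INVENTORY",
]


class AnnotationError(RuntimeError):
    """A parser backend failed on a piece of text."""

    def __init__(self, message: str, text: str = ""):
        super().__init__(message)
        self.text = text


class UnsupportedSentenceError(AnnotationError):
    """The template annotator met a sentence outside its inventory."""


@dataclass(frozen=True)
class AnnotatedToken:
    """One token of a dependency parse.

    ``index`` is 1-based; ``head`` points at the index of the governing token,
    with 0 marking the root.  ``pos`` is a CTB tag and ``relation`` a Chinese
    Stanford-Dependencies label.
    """

    index: int
    surface: str
    pos: str
    head: int
    relation: str

    def __post_init__(self):
        if self.index < 1:
            raise ValueError(f"token index must be >= 1, got {self.index}")
        if self.head < 0:
            raise ValueError(f"head must be >= 0, got {self.head}")
        if self.head == self.index:
            raise ValueError(f"token {self.index} cannot head itself")


@dataclass(frozen=True)
class ParsedUtterance:
    """An ordered sequence of :class:`AnnotatedToken` forming one parse tree."""

    tokens: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "tokens", tuple(self.tokens))

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    @property
    def text(self) -> str:
        return "".join(t.surface for t in self.tokens)


def validate_parse(utterance: ParsedUtterance) -> bool:
    """Check the tree invariants: exactly one root, in-range acyclic heads."""
    tokens = utterance.tokens
    n = len(tokens)
    if n == 0:
        return False
    if [t.index for t in tokens] != list(range(1, n + 1)):
        return False
    roots = [t for t in tokens if t.head == 0]
    if len(roots) != 1:
        return False
    for t in tokens:
        if not 0 <= t.head <= n or t.head == t.index:
            return False
    # walk each token to the root; a cycle would loop forever within n steps
    for t in tokens:
        seen = set()
        cur = t.index
        while cur != 0:
            if cur in seen:
                return False
            seen.add(cur)
            cur = tokens[cur - 1].head
    return True


# ---------------------------------------------------------------------------
# CoNLL-style serialization
# ---------------------------------------------------------------------------

def to_conll(utterances: Sequence[ParsedUtterance]) -> str:
    """Serialize parses as tab-separated (index, surface, pos, head, relation)
    rows, one token per line, blank line between utterances."""
    blocks = []
    for u in utterances:
        blocks.append(
            "\n".join(
                f"{t.index}\t{t.surface}\t{t.pos}\t{t.head}\t{t.relation}"
                for t in u.tokens
            )
        )
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def from_conll(text: str) -> List[ParsedUtterance]:
    """Inverse of :func:`to_conll`."""
    utterances = []
    for block in text.strip("\n").split("\n\n"):
        if not block.strip():
            continue
        tokens = []
        for line in block.splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise AnnotationError(f"malformed CoNLL line: {line!r}", line)
            idx, surface, pos, head, rel = parts
            tokens.append(
                AnnotatedToken(int(idx), surface, pos, int(head), rel)
            )
        utterances.append(ParsedUtterance(tokens))
    return utterances


# ---------------------------------------------------------------------------
# Template inventory
# ---------------------------------------------------------------------------

def _utt(rows: Iterable[tuple]) -> ParsedUtterance:
    return ParsedUtterance(
        [AnnotatedToken(i + 1, s, p, h, r) for i, (s, p, h, r) in enumerate(rows)]
    )


# Each entry maps the exact sentence string to its gold parse.  The first four
# are the worked case constructions; the rest are minimal variants used for
# testing and synthesis.  Sentence keys must never be a prefix of a *wrong*
# segmentation: the annotator segments greedily by longest matching key.
TEMPLATE_INVENTORY = {
    # "I want to commit suicide" — subjective FPSP (nominal subject of 想)
    "我想自殺": _utt([
        ("我", "PN", 2, "nsubj"),
        ("想", "VV", 0, "root"),
        ("自殺", "VV", 2, "ccomp"),
    ]),
    # "Everyone hates me" — objective FPSP (direct object of 憎)
    "大家都好憎我": _utt([
        ("大家", "PN", 4, "nsubj"),
        ("都", "AD", 4, "advmod"),
        ("好", "AD", 4, "advmod"),
        ("憎", "VV", 0, "root"),
        ("我", "PN", 4, "dobj"),
    ]),
    # "He gave me a chance" — dative FPSP (indirect object of 俾)
    "佢俾我一個機會": _utt([
        ("佢", "PN", 2, "nsubj"),
        ("俾", "VV", 0, "root"),
        ("我", "PN", 2, "iobj"),
        ("一個", "CD", 5, "nummod"),
        ("機會", "NN", 2, "dobj"),
    ]),
    # "Wanting to commit suicide is my idea" — possessive FPSP
    # (associative modifier of 諗法 via the genitive particle 嘅)
    "想自殺係我嘅諗法": _utt([
        ("想", "VV", 3, "top"),
        ("自殺", "VV", 1, "ccomp"),
        ("係", "VC", 0, "root"),
        ("我", "PN", 6, "assmod"),
        ("嘅", "DEG", 4, "assm"),
        ("諗法", "NN", 3, "attr"),
    ]),
    # minimal case variants -------------------------------------------------
    # "I am very tired" — subjective, single (adjectival) verb
    "我好攰": _utt([
        ("我", "PN", 3, "nsubj"),
        ("好", "AD", 3, "advmod"),
        ("攰", "VA", 0, "root"),
    ]),
    # pro-drop variant of the above (subject omitted)
    "好攰": _utt([
        ("好", "AD", 2, "advmod"),
        ("攰", "VA", 0, "root"),
    ]),
    # pro-drop variant of 我想自殺
    "想自殺": _utt([
        ("想", "VV", 0, "root"),
        ("自殺", "VV", 1, "ccomp"),
    ]),
    # "He hates me" — objective
    "佢憎我": _utt([
        ("佢", "PN", 2, "nsubj"),
        ("憎", "VV", 0, "root"),
        ("我", "PN", 2, "dobj"),
    ]),
    # "He gave me a chance" (bare) — dative
    "佢俾我機會": _utt([
        ("佢", "PN", 2, "nsubj"),
        ("俾", "VV", 0, "root"),
        ("我", "PN", 2, "iobj"),
        ("機會", "NN", 2, "dobj"),
    ]),
    # "my idea" — possessive noun phrase, verb-free
    "我嘅諗法": _utt([
        ("我", "PN", 3, "assmod"),
        ("嘅", "DEG", 1, "assm"),
        ("諗法", "NN", 0, "root"),
    ]),
    # FPPP variants ---------------------------------------------------------
    # "our home" — first-person plural, verb-free
    "我哋嘅屋企": _utt([
        ("我哋", "PN", 3, "assmod"),
        ("嘅", "DEG", 1, "assm"),
        ("屋企", "NN", 0, "root"),
    ]),
    # "we eat together"
    "我哋一齊食飯": _utt([
        ("我哋", "PN", 3, "nsubj"),
        ("一齊", "AD", 3, "advmod"),
        ("食飯", "VV", 0, "root"),
    ]),
    # fillers ---------------------------------------------------------------
    # "at home" — preposition phrase fragment
    "喺屋企": _utt([
        ("喺", "P", 0, "root"),
        ("屋企", "NN", 1, "pobj"),
    ]),
    # "with me" — FPSP under a preposition (pobj, exercises the fallback)
    "同我": _utt([
        ("同", "P", 0, "root"),
        ("我", "PN", 1, "pobj"),
    ]),
    # "today" — temporal noun
    "今日": _utt([("今日", "NT", 0, "root")]),
    # "apples and so on" — etcetera particle
    "蘋果等等": _utt([
        ("蘋果", "NN", 0, "root"),
        ("等等", "ETC", 1, "etc"),
    ]),
    # "sigh" — interjection
    "唉": _utt([("唉", "IJ", 0, "root")]),
    # "he was scolded by someone" — passive marker 被 (LB)
    "佢被人鬧": _utt([
        ("佢", "PN", 4, "nsubjpass"),
        ("被", "LB", 4, "auxpass"),
        ("人", "NN", 4, "agent"),
        ("鬧", "VV", 0, "root"),
    ]),
    # "I was scolded by someone" — passive subject FPSP (nsubjpass)
    "我被人鬧": _utt([
        ("我", "PN", 4, "nsubjpass"),
        ("被", "LB", 4, "auxpass"),
        ("人", "NN", 4, "agent"),
        ("鬧", "VV", 0, "root"),
    ]),
    # "eat" — bare verb filler
    "食飯": _utt([("食飯", "VV", 0, "root")]),
    # "stuff" — bare noun filler
    "嘢": _utt([("嘢", "NN", 0, "root")]),
    # "lots of stuff." — noun filler with sentence-final punctuation
    "好多嘢。": _utt([
        ("好多", "CD", 2, "nummod"),
        ("嘢", "NN", 0, "root"),
        ("。", "PU", 2, "punct"),
    ]),
}

for _key, _parse in TEMPLATE_INVENTORY.items():
    assert _parse.text == _key and validate_parse(_parse)


class ParserBackend(Protocol):
    """Contract for parser backends: text in, validated parses out."""

    def __call__(self, text: str) -> List[ParsedUtterance]: ...


class TemplateAnnotator:
    """Deterministic annotator over :data:`TEMPLATE_INVENTORY`.

    Input text is segmented greedily: at each position the longest inventory
    sentence that prefixes the remaining text is consumed.  Whitespace between
    sentences is ignored.  Text not covered by the inventory raises
    :class:`UnsupportedSentenceError`.
    """

    def __init__(self, inventory: dict | None = None):
        self.inventory = dict(inventory or TEMPLATE_INVENTORY)
        # longest-first key order makes greedy matching well defined
        self._keys = sorted(self.inventory, key=len, reverse=True)

    def __call__(self, text: str) -> List[ParsedUtterance]:
        out: List[ParsedUtterance] = []
        rest = text.strip()
        while rest:
            for key in self._keys:
                if rest.startswith(key):
                    out.append(self.inventory[key])
                    rest = rest[len(key):].lstrip()
                    break
            else:
                raise UnsupportedSentenceError(
                    f"sentence outside the template inventory near: {rest[:20]!r}",
                    rest,
                )
        return out


def annotate(text: str, backend: ParserBackend | None = None) -> List[ParsedUtterance]:
    """Sentence-tokenize, POS-tag and dependency-parse ``text``.

    The concatenated token surfaces of the result reconstruct the input
    (ignoring whitespace) and every parse satisfies :func:`validate_parse`.
    """
    if backend is None:
        backend = TemplateAnnotator()
    if not text.strip():
        return []
    try:
        utterances = backend(text)
    except AnnotationError:
        raise
    except Exception as exc:  # backend-internal failure
        raise AnnotationError(f"parser backend failed: {exc}", text) from exc
    for u in utterances:
        if not validate_parse(u):
            raise AnnotationError("backend produced an invalid parse tree", text)
    return utterances


class HanLPBackend:
    """Adapter around the HanLP toolkit (optional dependency).

    Maps HanLP's native Chinese-Stanford-Dependencies label set onto the
    dialect used here.  Labels are mostly shared already; the translation
    table below covers the divergent ones.
    """

    #: HanLP native relation -> local dialect
    LABEL_MAP = {
        "de": "assm",
        "att": "assmod",
        "pass": "auxpass",
    }

    def __init__(self, model: str = "CTB9_TOK_POS_DEP"):
        try:
            import hanlp  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional backend
            raise ImportError(
                "the HanLP backend requires the optional 'hanlp' package "
                "(pip install pronocase[hanlp])"
            ) from exc
        self._pipeline = hanlp.load(model)  # pragma: no cover

    def __call__(self, text: str) -> List[ParsedUtterance]:  # pragma: no cover
        doc = self._pipeline(text)
        utterances = []
        for toks, tags, heads, rels in zip(
            doc["tok"], doc["pos"], doc["dep_head"], doc["dep_rel"]
        ):
            tokens = [
                AnnotatedToken(
                    i + 1, s, p, h, self.LABEL_MAP.get(r, r)
                )
                for i, (s, p, h, r) in enumerate(zip(toks, tags, heads, rels))
            ]
            utterances.append(ParsedUtterance(tokens))
        return utterances
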