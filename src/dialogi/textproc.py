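"""Text pre-processing and concept-annotation handling.

Offset convention (used everywhere in the package): 0-based, half-open
character offsets over ``raw_text = title + " " + abstract``.  PubTator files
that separate title and abstract with a newline need no conversion, since the
separator is one character either way.

The lemmatizer is a pluggable interface.  The shipped backend
(:class:`RuleLemmatizer`) is deterministic and dependency-free: whitespace
tokenization, identity (lowercased) lemmas and lexicon-based POS tags — good
enough for the synthetic vocabulary and for tests.  A model-backed adapter can
be dropped in by implementing ``__call__(text) -> list[Token]``.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Protocol

logger = logging.getLogger(__name__)

CONTENT_POS = frozenset({"NOUN", "VERB", "ADJ", "ADV"})
CATEGORIES = ("disease", "chemical")

# closed-class words the rule backend tags as non-content
_FUNCTION_POS = {
    "the": "DET", "a": "DET", "an": "DET", "this": "DET", "these": "DET", "those": "DET",
    "of": "ADP", "in": "ADP", "for": "ADP", "with": "ADP", "to": "ADP", "by": "ADP",
    "at": "ADP", "on": "ADP", "from": "ADP",
    "and": "CCONJ", "or": "CCONJ", "but": "CCONJ",
    "is": "AUX", "was": "AUX", "were": "AUX", "been": "AUX", "be": "AUX", "are": "AUX",
    "not": "PART", "no": "DET",
}


class InputError(ValueError):
    """Malformed or inconsistent user input."""


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    upos: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty token span [{self.start},{self.end})")


@dataclass
class ConceptMention:
    concept_id: str
    category: str
    start: int
    end: int
    text: str = ""
    matched_tokens: list[int] = field(default_factory=list)
    aligned: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if self.start >= self.end:
            raise ValueError(f"empty mention span [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedDocument:
    doc_id: str
    raw_text: str
    tokens: list[Token]
    mentions: list[ConceptMention]
    rel_freq: dict[str, dict[str, float]]
    label: int | None = None


class Lemmatizer(Protocol):
    def __call__(self, text: str) -> list[Token]: ...


class RuleLemmatizer:
    """Deterministic fixture backend: whitespace tokens, identity lemmas,
    lexicon POS (unknown alphabetic words default to NOUN)."""

    _TOKEN_RE = re.compile(r"\S+")

    def __init__(self, lexicon: dict[str, str] | None = None) -> None:
        self.lexicon = dict(_FUNCTION_POS)
        if lexicon:
            self.lexicon.update({k.lower(): v for k, v in lexicon.items()})

    def _pos(self, lemma: str) -> str:
        if lemma in self.lexicon:
            return self.lexicon[lemma]
        if not any(c.isalpha() for c in lemma):
            return "NUM" if any(c.isdigit() for c in lemma) else "PUNCT"
        return "NOUN"

    def __call__(self, text: str) -> list[Token]:
        out = []
        for m in self._TOKEN_RE.finditer(text):
            surface = m.group()
            lemma = surface.lower().strip(".,;:!?()[]\"'")
            if not lemma:
                lemma = surface.lower()
            out.append(Token(surface=surface, lemma=lemma, upos=self._pos(lemma),
                             start=m.start(), end=m.end()))
        return out


def load_stopwords() -> frozenset[str]:
    """Bundled stopword list (standard NLP list merged with the PubMed list)."""
    data = resources.files("dialogi.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w.strip() for w in data.splitlines() if w.strip())


def preprocess(raw_text: str, lemmatizer: Lemmatizer | None = None,
               stopwords: Iterable[str] | None = None,
               min_lemma_len: int = 3) -> list[Token]:
    """Tokenize/lemmatize and keep content lemmas only.

    A token survives iff its POS is noun/verb/adjective/adverb, its lowercased
    lemma is at least ``min_lemma_len`` characters and not a stopword.
    Numerals and punctuation drop out implicitly via the POS filter.
    """
    if not raw_text:
        return []
    lemmatizer = lemmatizer or RuleLemmatizer()
    stop = frozenset(stopwords) if stopwords is not None else load_stopwords()
    kept = []
    for tok in lemmatizer(raw_text):
        lemma = tok.lemma.lower()
        if tok.upos not in CONTENT_POS:
            continue
        if len(lemma) < min_lemma_len or lemma in stop:
            continue
        kept.append(Token(tok.surface, lemma, tok.upos, tok.start, tok.end))
    return kept


_PUBTATOR_TEXT_RE = re.compile(r"^(\S+)\|([ta])\|(.*)$")


def parse_pubtator(source: str, strict: bool = False,
                   ) -> dict[str, dict]:
    """Parse PubTator text (a path or the raw content itself).

    Returns ``{doc_id: {"title": str, "abstract": str, "mentions": [...]}}``.
    Identifiers are normalized by stripping a ``MESH:`` prefix; annotation
    types other than Chemical/Disease are discarded.  Malformed lines are
    skipped with a warning, or raise when ``strict`` is set.
    """
    if "\n" not in source and "|" not in source:
        with open(source, encoding="utf-8") as fh:
            source = fh.read()
    docs: dict[str, dict] = {}
    problems: list[str] = []
    for lineno, line in enumerate(source.splitlines(), start=1):
        if not line.strip():
            continue
        m = _PUBTATOR_TEXT_RE.match(line)
        if m:
            doc_id, kind, text = m.groups()
            entry = docs.setdefault(doc_id, {"title": "", "abstract": "", "mentions": []})
            entry["title" if kind == "t" else "abstract"] = text
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            problems.append(f"line {lineno}: expected >=6 tab-separated fields")
            continue
        doc_id, start, end, text, kind, concept_id = parts[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            problems.append(f"line {lineno}: non-integer offsets {start!r}/{end!r}")
            continue
        kind_l = kind.strip().lower()
        if kind_l not in CATEGORIES:
            continue
        concept_id = concept_id.strip()
        if concept_id.upper().startswith("MESH:"):
            concept_id = concept_id[5:]
        entry = docs.setdefault(doc_id, {"title": "", "abstract": "", "mentions": []})
        try:
            entry["mentions"].append(ConceptMention(concept_id=concept_id, category=kind_l,
                                                    start=start_i, end=end_i, text=text))
        except ValueError as exc:
            problems.append(f"line {lineno}: {exc}")
    if problems:
        if strict:
            raise InputError("; ".join(problems))
        for p in problems:
            logger.warning("skipped malformed annotation (%s)", p)
    return docs


def align(mentions: list[ConceptMention], tokens: list[Token],
          min_overlap: float = 0.9) -> list[ConceptMention]:
    """Match mentions to kept tokens by character overlap.

    A mention is aligned iff the kept-token spans cover at least
    ``min_overlap`` of its characters.  Unaligned mentions are retained (they
    still count toward relative frequencies) but carry ``aligned=False``.
    """
    out = []
    for m in mentions:
        covered = 0
        matched = []
        for idx, tok in enumerate(tokens):
            ov = min(m.end, tok.end) - max(m.start, tok.start)
            if ov > 0:
                covered += ov
                matched.append(idx)
        aligned = covered >= min_overlap * m.length - 1e-12
        out.append(ConceptMention(concept_id=m.concept_id, category=m.category,
                                  start=m.start, end=m.end, text=m.text,
                                  matched_tokens=matched if aligned else [],
                                  aligned=aligned))
    return out


def relative_frequencies(mentions: list[ConceptMention]) -> dict[str, dict[str, float]]:
    """Per-category relative mention frequency of each concept in one document."""
    counts: dict[str, Counter] = {c: Counter() for c in CATEGORIES}
    for m in mentions:
        counts[m.category][m.concept_id] += 1
    rel: dict[str, dict[str, float]] = {}
    for category, counter in counts.items():
        total = sum(counter.values())
        rel[category] = {cid: n / total for cid, n in counter.items()} if total else {}
    return rel


def _resolve_token_claims(mentions: list[ConceptMention]) -> dict[int, ConceptMention]:
    """Token -> owning mention; conflicts go to the longer mention, ties to the
    earlier start."""
    owner: dict[int, ConceptMention] = {}
    for m in sorted((m for m in mentions if m.aligned and m.matched_tokens),
                    key=lambda m: (-m.length, m.start)):
        if any(t in owner for t in m.matched_tokens):
            continue
        for t in m.matched_tokens:
            owner[t] = m
    return owner


EXPORT_MODES = ("plain", "replace_id", "replace_category")


def export_processed(doc: AnnotatedDocument, mode: str = "plain") -> list[str]:
    """Kept lemmas with aligned mentions optionally collapsed to one symbol
    (the concept id or the category name)."""
    if mode not in EXPORT_MODES:
        raise ValueError(f"mode must be one of {EXPORT_MODES}, got {mode!r}")
    if mode == "plain":
        return [t.lemma for t in doc.tokens]
    owner = _resolve_token_claims(doc.mentions)
    out: list[str] = []
    emitted: set[int] = set()
    for idx, tok in enumerate(doc.tokens):
        m = owner.get(idx)
        if m is None:
            out.append(tok.lemma)
        elif id(m) not in emitted:
            out.append(m.concept_id if mode == "replace_id" else m.category)
            emitted.add(id(m))
    return out


def process_documents(docs, annotations: dict[str, dict] | str | None = None,
                      lemmatizer: Lemmatizer | None = None,
                      stopwords: Iterable[str] | None = None,
                      min_overlap: float = 0.9) -> list[AnnotatedDocument]:
    """Full per-document pipeline: preprocess, align annotations, rel. freqs.

    ``docs`` is a DataFrame with id/title/abstract (and optionally label);
    ``annotations`` is a PubTator file/content or the dict from
    :func:`parse_pubtator`.
    """
    lemmatizer = lemmatizer or RuleLemmatizer()
    stop = frozenset(stopwords) if stopwords is not None else load_stopwords()
    anns: dict[str, dict] = {}
    if annotations is not None:
        anns = annotations if isinstance(annotations, dict) else parse_pubtator(annotations)
    out = []
    for row in docs.itertuples(index=False):
        doc_id = str(row.id)
        raw_text = f"{row.title} {row.abstract}"
        mentions = anns.get(doc_id, {}).get("mentions", [])
        for m in mentions:
            if m.end > len(raw_text):
                raise InputError(f"doc {doc_id}: mention span [{m.start},{m.end}) "
                                 f"exceeds text length {len(raw_text)}")
        tokens = preprocess(raw_text, lemmatizer, stop)
        aligned = align(mentions, tokens, min_overlap=min_overlap)
        label = int(row.label) if hasattr(row, "label") and row.label is not None else None
        out.append(AnnotatedDocument(doc_id=doc_id, raw_text=raw_text, tokens=tokens,
                                     mentions=aligned,
                                     rel_freq=relative_frequencies(aligned), label=label))
    return out
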