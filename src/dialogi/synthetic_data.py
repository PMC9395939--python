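"""Synthetic corpora with planted lexical and concept signal.

Generates every input the pipeline needs: a two-class document table,
PubTator-format concept annotations with exact character offsets, a random
term hierarchy, block-structured bipartite association tables and random
word vectors.  All generators are pure functions of (config, seed).

Document text uses a two-level token model: a shared Zipf-distributed
background vocabulary plus class-specific discriminative tokens.  Concept
terms (diseases/chemicals) are grouped into blocks; blocks carry class
affinity, so documents of a class preferentially mention concepts from that
class's blocks.  The same block structure drives the hierarchy and the
association tables, which makes block recovery by the embedding pipeline a
testable ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


# words the fixture POS tagger marks as non-content; sprinkled into abstracts
# so the POS/stopword/length filters in textproc have something to remove.
FUNCTION_WORDS = ("the", "of", "and", "in", "was", "is", "for", "with", "were", "been",
                  "a", "an", "to", "by", "or", "at")

DISEASE_ID_BASE = 1        # disease ids D000001..; chemicals from a disjoint range
CHEMICAL_ID_BASE = 500001


def _mesh_id(n: int) -> str:
    return f"D{n:06d}"


@dataclass(frozen=True)
class SynthConfig:
    n_docs: int = 200
    class_balance: float = 0.5
    vocab_size: int = 5000
    n_disease_terms: int = 60
    n_chem_terms: int = 60
    n_blocks: int = 4
    signal_strength: float = 0.8        # lexical discriminative-token emission rate
    concept_signal: float | None = None  # defaults to signal_strength
    noise_rate: float = 0.05
    fraction_unannotated: float = 0.2
    n_disc_tokens: int = 25             # discriminative lexical tokens per class
    n_disc_concepts: int = 8            # discriminative concepts per class per category
    title_len: tuple[int, int] = (4, 8)
    abstract_len: tuple[int, int] = (120, 180)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {"n_docs": self.n_docs, "vocab_size": self.vocab_size,
                  "n_disease_terms": self.n_disease_terms, "n_chem_terms": self.n_chem_terms,
                  "n_blocks": self.n_blocks, "n_disc_tokens": self.n_disc_tokens,
                  "n_disc_concepts": self.n_disc_concepts}
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigError(f"class_balance must be in (0,1), got {self.class_balance}")
        for name in ("signal_strength", "noise_rate", "fraction_unannotated"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {value}")
        if self.concept_signal is not None and not 0.0 <= self.concept_signal <= 1.0:
            raise ConfigError(f"concept_signal must be in [0,1], got {self.concept_signal}")

    @property
    def effective_concept_signal(self) -> float:
        return self.signal_strength if self.concept_signal is None else self.concept_signal


@dataclass
class Manifest:
    """Ground truth for the planted structure; held out from the pipeline."""

    disc_tokens: dict[int, list[str]]                 # class label -> lexical tokens
    disc_concepts: dict[int, dict[str, list[str]]]    # label -> category -> concept ids
    concept_surface: dict[str, str]                   # concept id -> in-text token
    concept_category: dict[str, str]                  # concept id -> disease|chemical
    concept_block: dict[str, int]                     # concept id -> block index


@dataclass
class Mention:
    start: int
    end: int
    text: str
    category: str
    concept_id: str


@dataclass
class SynthCorpus:
    documents: pd.DataFrame                # id, title, abstract, label
    mentions: dict[str, list[Mention]]     # doc id -> planted concept mentions
    manifest: Manifest
    config: SynthConfig = field(repr=False, default=None)


def _background_probs(vocab_size: int) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=np.float64)
    probs = 1.0 / ranks  # Zipf(1)
    return probs / probs.sum()


def _build_manifest(config: SynthConfig, rng: np.random.Generator) -> Manifest:
    disc_tokens = {
        1: [f"sigpos{i:03d}" for i in range(config.n_disc_tokens)],
        0: [f"signeg{i:03d}" for i in range(config.n_disc_tokens)],
    }
    concept_surface: dict[str, str] = {}
    concept_category: dict[str, str] = {}
    concept_block: dict[str, int] = {}
    disease_ids, chem_ids = [], []
    for i in range(config.n_disease_terms):
        cid = _mesh_id(DISEASE_ID_BASE + i)
        disease_ids.append(cid)
        concept_surface[cid] = f"dis{i:04d}"
        concept_category[cid] = "disease"
        concept_block[cid] = i * config.n_blocks // config.n_disease_terms
    for i in range(config.n_chem_terms):
        cid = _mesh_id(CHEMICAL_ID_BASE + i)
        chem_ids.append(cid)
        concept_surface[cid] = f"chem{i:04d}"
        concept_category[cid] = "chemical"
        concept_block[cid] = i * config.n_blocks // config.n_chem_terms
    # blocks 0..n/2-1 carry positive affinity, the rest negative
    pos_blocks = set(range((config.n_blocks + 1) // 2))
    disc_concepts: dict[int, dict[str, list[str]]] = {0: {}, 1: {}}
    for category, ids in (("disease", disease_ids), ("chemical", chem_ids)):
        pos_pool = [c for c in ids if concept_block[c] in pos_blocks]
        neg_pool = [c for c in ids if concept_block[c] not in pos_blocks]
        k = config.n_disc_concepts
        disc_concepts[1][category] = list(rng.choice(pos_pool, size=min(k, len(pos_pool)),
                                                     replace=False))
        disc_concepts[0][category] = list(rng.choice(neg_pool, size=min(k, len(neg_pool)),
                                                     replace=False)) if neg_pool else []
    return Manifest(disc_tokens=disc_tokens, disc_concepts=disc_concepts,
                    concept_surface=concept_surface, concept_category=concept_category,
                    concept_block=concept_block)


def gen_documents(config: SynthConfig, manifest: Manifest | None = None) -> SynthCorpus:
    """Generate the document table plus gold labels and planted-mention offsets.

    Passing an existing ``manifest`` reuses its discriminative tokens/concepts,
    which is how distribution-shifted evaluation corpora are produced (same
    planted structure, different emission rates via the config).
    """
    rng = np.random.default_rng(config.seed)
    if manifest is None:
        manifest = _build_manifest(config, rng)
    bg_vocab = np.array([f"w{i:05d}" for i in range(config.vocab_size)])
    bg_probs = _background_probs(config.vocab_size)

    n_pos = round(config.n_docs * config.class_balance)
    labels = np.array([1] * n_pos + [0] * (config.n_docs - n_pos))
    rng.shuffle(labels)

    p_sig, p_concept, p_noise = (config.signal_strength, config.effective_concept_signal,
                                 config.noise_rate)
    records = []
    mentions: dict[str, list[Mention]] = {}
    for i, label in enumerate(labels):
        doc_id = str(1000 + i)
        title_tokens = list(rng.choice(bg_vocab, size=rng.integers(*config.title_len,
                                                                   endpoint=True), p=bg_probs))
        n_abs = int(rng.integers(*config.abstract_len, endpoint=True))
        abstract_tokens = []
        for _ in range(n_abs):
            if rng.random() < 0.12:
                abstract_tokens.append(FUNCTION_WORDS[rng.integers(len(FUNCTION_WORDS))])
            else:
                abstract_tokens.append(str(rng.choice(bg_vocab, p=bg_probs)))
        # lexical signal: each discriminative token fires independently
        for cls in (1, 0):
            rate = p_sig if cls == label else p_noise
            for tok in manifest.disc_tokens[cls]:
                if rng.random() < rate:
                    abstract_tokens.insert(int(rng.integers(len(abstract_tokens) + 1)), tok)
        # concept signal: plant surfaces of discriminative concepts
        planted: list[str] = []
        for cls in (1, 0):
            rate = p_concept if cls == label else p_noise
            for category in ("disease", "chemical"):
                for cid in manifest.disc_concepts[cls][category]:
                    if rng.random() < rate:
                        planted.append(cid)
        # a couple of random non-discriminative concepts for realism
        all_ids = list(manifest.concept_surface)
        for _ in range(int(rng.integers(0, 3))):
            planted.append(all_ids[int(rng.integers(len(all_ids)))])
        for cid in planted:
            copies = 1 + int(rng.random() < 0.3)
            for _ in range(copies):
                abstract_tokens.insert(int(rng.integers(len(abstract_tokens) + 1)),
                                       manifest.concept_surface[cid])
        title = " ".join(title_tokens)
        abstract = " ".join(abstract_tokens)
        mentions[doc_id] = _locate_mentions(title, abstract, manifest)
        records.append((doc_id, title, abstract, int(label)))

    documents = pd.DataFrame(records, columns=["id", "title", "abstract", "label"])
    return SynthCorpus(documents=documents, mentions=mentions, manifest=manifest, config=config)


def _locate_mentions(title: str, abstract: str, manifest: Manifest) -> list[Mention]:
    """Exact character offsets of concept surfaces over ``title + ' ' + abstract``."""
    raw = title + " " + abstract
    surface_to_id = {v: k for k, v in manifest.concept_surface.items()}
    found = []
    pos = 0
    for token in raw.split(" "):
        cid = surface_to_id.get(token)
        if cid is not None:
            found.append(Mention(start=pos, end=pos + len(token), text=token,
                                 category=manifest.concept_category[cid], concept_id=cid))
        pos += len(token) + 1
    return found


def gen_annotations(corpus: SynthCorpus, config: SynthConfig | None = None) -> str:
    """Render planted mentions as PubTator text; a fixed fraction of documents
    (``fraction_unannotated``, chosen deterministically from the seed) gets no
    annotation lines at all, emulating annotator misses."""
    config = config or corpus.config
    rng = np.random.default_rng(config.seed + 104729)
    doc_ids = list(corpus.documents["id"])
    n_drop = round(config.fraction_unannotated * len(doc_ids))
    dropped = set(rng.choice(doc_ids, size=n_drop, replace=False)) if n_drop else set()

    chunks = []
    for row in corpus.documents.itertuples(index=False):
        raw_len = len(row.title) + 1 + len(row.abstract)
        lines = [f"{row.id}|t|{row.title}", f"{row.id}|a|{row.abstract}"]
        if row.id not in dropped:
            for m in corpus.mentions[row.id]:
                if m.end > raw_len:  # generator bug guard
                    raise RuntimeError(f"doc {row.id}: mention offset {m.end} > {raw_len}")
                kind = "Disease" if m.category == "disease" else "Chemical"
                lines.append(f"{row.id}\t{m.start}\t{m.end}\t{m.text}\t{kind}\t{m.concept_id}")
        chunks.append("\n".join(lines))
    return "\n\n".join(chunks) + "\n"


def gen_hierarchy(n_terms: int, depth: int = 4, branching: int = 3, seed: int = 0,
                  n_blocks: int = 4, root_code: str = "C") -> tuple[pd.DataFrame, dict[str, int]]:
    """Random tree-number table: each block owns a root subtree, so block
    co-membership correlates with shared path prefixes.

    Returns (table with one row per (term_id, tree_number), term -> block map).
    """
    if depth < 2:
        raise ConfigError(f"depth must be >= 2, got {depth}")
    if n_terms < 1 or branching < 1 or n_blocks < 1:
        raise ConfigError("n_terms, branching and n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    blocks: dict[str, int] = {}

    def random_path(block: int) -> str:
        parts = [f"{root_code}{block + 1:02d}"]
        parts += [f"{100 + int(rng.integers(branching))}" for _ in range(depth - 1)]
        return ".".join(parts)

    for i in range(n_terms):
        term = _mesh_id(DISEASE_ID_BASE + i)
        block = i * n_blocks // n_terms
        blocks[term] = block
        rows.append((term, random_path(block)))
        if rng.random() < 0.25:  # some terms carry multiple tree numbers
            alt_block = block if rng.random() < 0.7 else int(rng.integers(n_blocks))
            rows.append((term, random_path(alt_block)))
    return pd.DataFrame(rows, columns=["term_id", "tree_number"]), blocks


def gen_association_tables(n_terms: int, n_partners: int, n_blocks: int = 4,
                           within_p: float = 0.6, between_p: float = 0.05, seed: int = 0,
                           n_tables: int = 1, id_base: int = DISEASE_ID_BASE,
                           ) -> tuple[list[pd.DataFrame], dict[str, int]]:
    """Block-structured bipartite tables: same-block (term, partner) pairs link
    at rate ``within_p``, cross-block at ``between_p``."""
    if within_p <= between_p:
        raise ConfigError(f"within_p ({within_p}) must exceed between_p ({between_p})")
    rng = np.random.default_rng(seed)
    terms = [_mesh_id(id_base + i) for i in range(n_terms)]
    blocks = {t: i * n_blocks // n_terms for i, t in enumerate(terms)}
    tables = []
    for t in range(n_tables):
        rows = []
        partner_block = np.arange(n_partners) * n_blocks // n_partners
        draws = rng.random((n_terms, n_partners))
        for i, term in enumerate(terms):
            probs = np.where(partner_block == blocks[term], within_p, between_p)
            for j in np.nonzero(draws[i] < probs)[0]:
                rows.append((term, f"P{t}{j:05d}"))
        tables.append(pd.DataFrame(rows, columns=["term_id", "partner_id"]))
    return tables, blocks


VALID_VECTOR_DIMS = (50, 100, 200, 300)


def gen_word_vectors(vocab: list[str], dim: int = 50, seed: int = 0) -> str:
    """Random word-vector text: Gaussian entries scaled by 1/sqrt(dim)."""
    if not vocab:
        raise ConfigError("vocabulary is empty")
    if dim not in VALID_VECTOR_DIMS:
        raise ConfigError(f"dim must be one of {VALID_VECTOR_DIMS}, got {dim}")
    rng = np.random.default_rng(seed)
    matrix = rng.standard_normal((len(vocab), dim)) / np.sqrt(dim)
    lines = [w + " " + " ".join(f"{v:.6f}" for v in row) for w, row in zip(vocab, matrix)]
    return "\n".join(lines) + "\n"


def corpus_vocabulary(config: SynthConfig, manifest: Manifest) -> list[str]:
    """Every token type the generator can emit (background + signal + surfaces)."""
    vocab = [f"w{i:05d}" for i in range(config.vocab_size)]
    vocab += manifest.disc_tokens[1] + manifest.disc_tokens[0]
    vocab += list(manifest.concept_surface.values())
    vocab += list(FUNCTION_WORDS)
    return vocab


def shifted_config(config: SynthConfig, seed: int, signal_strength: float = 0.0,
                   concept_signal: float | None = None) -> SynthConfig:
    """Config for a distribution-shifted evaluation corpus: same planted
    structure (reuse the manifest via gen_documents), different emission rates."""
    return dataclasses.replace(
        config, seed=seed, signal_strength=signal_strength,
        concept_signal=config.effective_concept_signal if concept_signal is None
        else concept_signal)
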