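"""Character n-gram skip-gram embeddings for query expansion.

Vocabulary mismatch — query words absent from the metadata — is tackled by
expanding query chunks with their nearest neighbours in an embedding space
trained on the corpus itself. The model follows the subword skip-gram idea:
each word is a bag of character n-grams (plus a whole-word symbol), its
vector is the *sum* of the n-gram vectors, and training is skip-gram with
negative sampling over those sums. Out-of-vocabulary words therefore still
receive vectors from their subwords, and morphological relatives
("glycolysis" / "glycolytic") land close together.

A small window (default 1) models word *function* rather than topic, which
suits retrieval expansion. Multiword phrases are first merged into single
underscore-joined tokens by collocation scoring, so expansion can return
phrases ("glycolytic_pathway") as well as words.

The expansion backend is pluggable: :class:`LexiconExpander` provides a
deterministic synonym-table backend, since trained neighbour lists are
corpus-dependent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbeddingConfig",
    "ExpansionResult",
    "CharNgramSkipGram",
    "LexiconExpander",
    "detect_phrases",
    "train_embeddings",
    "expand_top_k",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    dim: int = 100
    window: int = 1
    min_count: int = 5
    char_ngram_min: int = 3
    char_ngram_max: int = 6
    epochs: int = 5
    negative: int = 5
    learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim <= 0 or self.window < 1:
            raise ValueError("dim must be positive and window >= 1")
        if self.char_ngram_min > self.char_ngram_max:
            raise ValueError("char_ngram_min must be <= char_ngram_max")


@dataclass
class ExpansionResult:
    source_phrase: str
    candidates: list[tuple[str, float]] = field(default_factory=list)


def detect_phrases(
    sentences: list[list[str]], min_count: int = 5, score_threshold: float = 10.0
) -> list[list[str]]:
    """Merge adjacent collocations into underscore-joined phrase tokens.

    Pair score is ``(count(ab) - min_count) * N / (count(a) * count(b))``
    with N the total token count; one merge pass per call.
    """
    unigram: dict[str, int] = {}
    bigram: dict[tuple[str, str], int] = {}
    total = 0
    for sentence in sentences:
        for i, token in enumerate(sentence):
            unigram[token] = unigram.get(token, 0) + 1
            total += 1
            if i + 1 < len(sentence):
                pair = (token, sentence[i + 1])
                bigram[pair] = bigram.get(pair, 0) + 1
    merged: set[tuple[str, str]] = set()
    for (a, b), count in bigram.items():
        if count < min_count:
            continue
        score = (count - min_count) * total / (unigram[a] * unigram[b])
        if score > score_threshold:
            merged.add((a, b))
    out: list[list[str]] = []
    for sentence in sentences:
        row: list[str] = []
        i = 0
        while i < len(sentence):
            if i + 1 < len(sentence) and (sentence[i], sentence[i + 1]) in merged:
                row.append(f"{sentence[i]}_{sentence[i + 1]}")
                i += 2
            else:
                row.append(sentence[i])
                i += 1
        out.append(row)
    return out


def _char_ngrams(word: str, nmin: int, nmax: int) -> list[str]:
    """Subword keys of a word: boundary-marked n-grams plus the whole word."""
    marked = f"<{word}>"
    grams = [f"={word}="]  # whole-word symbol, distinct from any n-gram
    for n in range(nmin, nmax + 1):
        for i in range(0, len(marked) - n + 1):
            grams.append(marked[i : i + n])
    return grams


class CharNgramSkipGram:
    """Subword skip-gram with negative sampling, trained with plain SGD.

    Word vectors are sums of their character-n-gram vectors; context vectors
    are per-vocabulary-word output embeddings. Deterministic for a fixed seed
    (single worker, fixed iteration order).
    """

    def __init__(self, config: EmbeddingConfig):
        self.config = config
        self.vocab: list[str] = []
        self.word_index: dict[str, int] = {}
        self.ngram_index: dict[str, int] = {}
        self.ngram_vectors: np.ndarray | None = None  # (n_ngrams, dim)
        self.out_vectors: np.ndarray | None = None  # (n_vocab, dim)
        self._word_ngram_ids: list[np.ndarray] = []

    # -- training

    def fit(self, sentences: list[list[str]]) -> "CharNgramSkipGram":
        cfg = self.config
        counts: dict[str, int] = {}
        for sentence in sentences:
            for token in sentence:
                counts[token] = counts.get(token, 0) + 1
        self.vocab = sorted(w for w, c in counts.items() if c >= cfg.min_count)
        if not self.vocab:
            raise ValueError("empty corpus: no token reaches min_count")
        self.word_index = {w: i for i, w in enumerate(self.vocab)}

        for word in self.vocab:
            ids = []
            for gram in _char_ngrams(word, cfg.char_ngram_min, cfg.char_ngram_max):
                if gram not in self.ngram_index:
                    self.ngram_index[gram] = len(self.ngram_index)
                ids.append(self.ngram_index[gram])
            self._word_ngram_ids.append(np.array(sorted(set(ids)), dtype=np.int64))

        rng = np.random.default_rng(cfg.seed)
        n_grams = len(self.ngram_index)
        self.ngram_vectors = rng.uniform(
            -0.5 / cfg.dim, 0.5 / cfg.dim, size=(n_grams, cfg.dim)
        )
        self.out_vectors = np.zeros((len(self.vocab), cfg.dim))

        # negative-sampling table: unigram^0.75
        freqs = np.array([counts[w] for w in self.vocab], dtype=float) ** 0.75
        neg_probs = freqs / freqs.sum()

        encoded = [
            np.array([self.word_index[t] for t in s if t in self.word_index], dtype=np.int64)
            for s in sentences
        ]
        encoded = [s for s in encoded if len(s) > 1]
        lr0 = cfg.learning_rate
        total_steps = max(1, cfg.epochs * sum(len(s) for s in encoded))
        step = 0
        for _epoch in range(cfg.epochs):
            for sentence in encoded:
                for center_pos, center in enumerate(sentence):
                    lr = lr0 * max(0.05, 1.0 - step / total_steps)
                    step += 1
                    lo = max(0, center_pos - cfg.window)
                    hi = min(len(sentence), center_pos + cfg.window + 1)
                    contexts = [
                        sentence[j] for j in range(lo, hi) if j != center_pos
                    ]
                    if not contexts:
                        continue
                    gram_ids = self._word_ngram_ids[center]
                    center_vec = self.ngram_vectors[gram_ids].sum(axis=0)
                    grad_center = np.zeros(cfg.dim)
                    for context in contexts:
                        negatives = rng.choice(
                            len(self.vocab), size=cfg.negative, p=neg_probs
                        )
                        targets = np.concatenate(([context], negatives))
                        labels = np.zeros(len(targets))
                        labels[0] = 1.0
                        out = self.out_vectors[targets]  # (t, dim)
                        scores = 1.0 / (1.0 + np.exp(-out @ center_vec))
                        delta = (scores - labels)[:, None] * lr  # (t, 1)
                        grad_center += -(delta * out).sum(axis=0)
                        np.add.at(self.out_vectors, targets, -delta * center_vec)
                    self.ngram_vectors[gram_ids] += grad_center
        return self

    # -- lookup

    def vector(self, phrase: str) -> np.ndarray | None:
        """Sum of subword vectors; None if no subword of the phrase is known."""
        assert self.ngram_vectors is not None, "model not trained"
        ids = [
            self.ngram_index[g]
            for g in _char_ngrams(
                phrase, self.config.char_ngram_min, self.config.char_ngram_max
            )
            if g in self.ngram_index
        ]
        if not ids:
            return None
        return self.ngram_vectors[sorted(set(ids))].sum(axis=0)

    def _vocab_matrix(self) -> np.ndarray:
        assert self.ngram_vectors is not None
        return np.stack(
            [self.ngram_vectors[ids].sum(axis=0) for ids in self._word_ngram_ids]
        )

    def expand(self, phrase: str, k: int = 5) -> ExpansionResult:
        return expand_top_k(self, phrase, k)

    # -- persistence

    def save(self, path: str) -> None:
        assert self.ngram_vectors is not None and self.out_vectors is not None
        payload = {
            "config": self.config.__dict__,
            "vocab": self.vocab,
            "ngram_index": self.ngram_index,
            "ngram_vectors": self.ngram_vectors.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "CharNgramSkipGram":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        model = cls(EmbeddingConfig(**payload["config"]))
        model.vocab = payload["vocab"]
        model.word_index = {w: i for i, w in enumerate(model.vocab)}
        model.ngram_index = payload["ngram_index"]
        model.ngram_vectors = np.array(payload["ngram_vectors"])
        model.out_vectors = np.zeros((len(model.vocab), model.config.dim))
        model._word_ngram_ids = []
        for word in model.vocab:
            ids = {
                model.ngram_index[g]
                for g in _char_ngrams(
                    word, model.config.char_ngram_min, model.config.char_ngram_max
                )
                if g in model.ngram_index
            }
            model._word_ngram_ids.append(np.array(sorted(ids), dtype=np.int64))
        return model


def train_embeddings(
    sentences: list[list[str]], config: EmbeddingConfig | None = None
) -> CharNgramSkipGram:
    """Train a subword skip-gram model on a tokenized, lowercased corpus."""
    return CharNgramSkipGram(config or EmbeddingConfig()).fit(sentences)


def expand_top_k(model: CharNgramSkipGram, phrase: str, k: int) -> ExpansionResult:
    """The k nearest vocabulary phrases by cosine, excluding the phrase itself."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    query = model.vector(phrase)
    if query is None or not np.any(query):
        import warnings

        warnings.warn(f"phrase {phrase!r} has no known subwords; empty expansion")
        return ExpansionResult(source_phrase=phrase)
    matrix = model._vocab_matrix()
    norms = np.linalg.norm(matrix, axis=1)
    norms[norms == 0] = 1.0
    sims = (matrix @ query) / (norms * np.linalg.norm(query))
    order = [
        i
        for i in sorted(range(len(model.vocab)), key=lambda i: (-sims[i], model.vocab[i]))
        if model.vocab[i] != phrase
    ]
    return ExpansionResult(
        source_phrase=phrase,
        candidates=[(model.vocab[i], float(sims[i])) for i in order[:k]],
    )


class LexiconExpander:
    """Deterministic exact-match synonym-table expansion backend."""

    def __init__(self, table: dict[str, list[tuple[str, float]]]):
        self.table = {
            source: sorted(cands, key=lambda c: (-c[1], c[0]))
            for source, cands in table.items()
        }

    def expand(self, phrase: str, k: int = 5) -> ExpansionResult:
        candidates = [c for c in self.table.get(phrase, []) if c[0] != phrase][:k]
        return ExpansionResult(source_phrase=phrase, candidates=candidates)
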