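"""Embedding-based semantic similarity between essays and compositional words.

Each novel compositional word is built from two known component words.  The
semantic score of an essay is the mean, over its tokens, of the larger of the
token's cosine similarities to the two components — tokens identical to a
component are excluded, out-of-vocabulary tokens are skipped and counted.  A
*lower* score means the essay leapt further from the components (greater
creative distance).

Vectors come from any word2vec-text-format file; the synthetic module can
build a toy clustered embedding with known geometry for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from selacq.stats import GroupComparison, compare_groups

logger = logging.getLogger(__name__)


class EmbeddingParseError(ValueError):
    """Malformed word2vec text file."""


@dataclass(frozen=True)
class CompositionalWord:
    """A novel word and its two source components."""

    word_id: str
    component_a: str
    component_b: str

    def __post_init__(self):
        if not self.component_a or not self.component_b:
            raise ValueError("components must be nonempty")
        if self.component_a == self.component_b:
            raise ValueError("components must be distinct")

    @property
    def components(self) -> tuple[str, str]:
        return (self.component_a, self.component_b)


@dataclass
class EssaySimilarity:
    """Mean max-component cosine of an essay's usable tokens."""

    word_id: str
    n_tokens_used: int
    mean_similarity: float  # NaN when no usable tokens
    n_oov: int = 0

    @property
    def defined(self) -> bool:
        return self.n_tokens_used >= 1


class EmbeddingModel:
    """Token -> vector map with a cosine-similarity contract."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("empty embedding")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")
        self._vectors = {t: np.asarray(v, dtype=float) for t, v in vectors.items()}
        self.dim = dims.pop()

    @property
    def vocabulary(self) -> set[str]:
        return set(self._vectors)

    def __contains__(self, token: str) -> bool:
        return token in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def vector(self, token: str) -> np.ndarray:
        return self._vectors[token]

    def similarity(self, token_a: str, token_b: str) -> float:
        return cosine_similarity(self.vector(token_a), self.vector(token_b))

    def save_word2vec_text(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self._vectors)} {self.dim}\n")
            for tok, vec in self._vectors.items():
                fh.write(tok + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")


def load_embedding(path) -> EmbeddingModel:
    """Read a word2vec text file: header ``count dim``, then one token and
    ``dim`` floats per line.  Duplicate tokens: last occurrence wins, with a
    warning.  Dimension or count mismatches raise
    :class:`EmbeddingParseError` with the offending line number.
    """
    vectors: dict[str, np.ndarray] = {}
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingParseError("line 1: expected header 'count dim'")
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError:
            raise EmbeddingParseError("line 1: header fields must be integers")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            token, values = parts[0], parts[1:]
            if len(values) != dim:
                raise EmbeddingParseError(
                    f"line {lineno}: expected {dim} values, got {len(values)}"
                )
            try:
                vec = np.array([float(x) for x in values])
            except ValueError:
                raise EmbeddingParseError(f"line {lineno}: non-numeric value")
            if token in vectors:
                logger.warning("duplicate token %r at line %d: last wins", token, lineno)
            vectors[token] = vec
            n_rows += 1
    if n_rows != count:
        raise EmbeddingParseError(
            f"header declares {count} tokens but file contains {n_rows}"
        )
    return EmbeddingModel(vectors)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u| |v|); raises on a zero vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(u @ v / (nu * nv))


def token_component_similarity(
    model: EmbeddingModel, token: str, word: CompositionalWord
) -> float:
    """max over the two components of cos(token, component)."""
    return max(
        model.similarity(token, word.component_a),
        model.similarity(token, word.component_b),
    )


def essay_similarity(
    model: EmbeddingModel, essay_tokens: Sequence[str], word: CompositionalWord
) -> EssaySimilarity:
    """Mean token-component similarity over usable tokens.

    Tokens equal to either component (exact string match) are excluded;
    out-of-vocabulary tokens are skipped and counted.  Duplicate tokens score
    once per occurrence.  With no usable token the score is NaN and
    ``defined`` is False.
    """
    if len(essay_tokens) == 0:
        raise ValueError("essay_tokens must be nonempty")
    if word.component_a not in model or word.component_b not in model:
        raise KeyError(f"components of {word.word_id!r} missing from the embedding")
    sims = []
    n_oov = 0
    for tok in essay_tokens:
        if tok in word.components:
            continue
        if tok not in model:
            n_oov += 1
            continue
        sims.append(token_component_similarity(model, tok, word))
    if n_oov:
        logger.debug("essay for %s: skipped %d OOV tokens", word.word_id, n_oov)
    if not sims:
        return EssaySimilarity(word.word_id, 0, float("nan"), n_oov)
    return EssaySimilarity(word.word_id, len(sims), float(np.mean(sims)), n_oov)


def compare_semantic_groups(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    mode: str = "paired",
    seed: Optional[int] = None,
    n_boot: int = 10_000,
) -> GroupComparison:
    """One-sided t-test that group ``a`` is *less* similar (more dissimilar)
    than group ``b``; paired (d_z) or independent (Cohen's d)."""
    if mode == "paired":
        test = "t-paired"
    elif mode == "independent":
        test = "t-independent"
    else:
        raise ValueError("mode must be 'paired' or 'independent'")
    return compare_groups(
        scores_a, scores_b, test=test, alternative="less", n_boot=n_boot, seed=seed
    )
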