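"""Static word-embedding tables: text-format readers, lexeme resolution, cosine.

Supports the two interchange text formats in which pretrained GloVe and
FastText vectors are distributed:

* ``glove_txt`` — one ``word v1 v2 ... vd`` row per line, no header;
* ``word2vec_txt`` — the same body preceded by a ``count dim`` header line.

Multiword lexemes ("artificial intelligence") are resolved to the unweighted
mean of their component-token vectors; every component must be in vocabulary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import ContentError, DegenerateInputError, FormatError, OOVError
from .lexicons import normalize_lexeme

logger = logging.getLogger(__name__)

EmbeddingFormat = Literal["glove_txt", "word2vec_txt"]


@dataclass
class EmbeddingModel:
    """A vocabulary → vector table with a fixed dimension."""

    id: str
    dimension: int
    vectors: dict[str, np.ndarray]
    metadata: str = ""

    def __post_init__(self):
        if not self.vectors:
            raise ContentError(f"embedding model '{self.id}' has empty vocabulary")
        for word, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise FormatError(
                    f"model '{self.id}': vector for '{word}' has length "
                    f"{vec.shape[0]}, expected {self.dimension}")
            if not np.all(np.isfinite(vec)):
                raise ContentError(f"model '{self.id}': non-finite vector for '{word}'")

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


def _parse_rows(lines, path, dimension=None, start_line=1):
    vectors: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(lines, start=start_line):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split(" ")
        # GloVe files may contain tokens with embedded unicode spaces; the
        # format contract here is plain single-space separation.
        word, values = parts[0], parts[1:]
        if dimension is None:
            dimension = len(values)
            if dimension == 0:
                raise FormatError(f"{path}:{lineno}: row has no vector values")
        if len(values) != dimension:
            raise FormatError(
                f"{path}:{lineno}: row has {len(values)} values, expected {dimension}")
        try:
            vec = np.array([float(v) for v in values], dtype=np.float64)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
        word = normalize_lexeme(word)
        if word in vectors:
            logger.warning("%s:%d: duplicate vocabulary entry '%s'; keeping first",
                           path, lineno, word)
            continue
        vectors[word] = vec
    return vectors, dimension


def load_embeddings(path: str | Path, format: EmbeddingFormat = "glove_txt",
                    model_id: str | None = None) -> EmbeddingModel:
    """Read an embedding table from a text file.

    Duplicate vocabulary entries keep the first occurrence and log a warning.
    ``word2vec_txt`` headers are checked against the body (count and
    dimension); mismatches raise :class:`FormatError` with a line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    if not lines or all(not ln.strip() for ln in lines):
        raise ContentError(f"{path}: empty embedding file")
    if format == "word2vec_txt":
        header = lines[0].split()
        if len(header) != 2:
            raise FormatError(f"{path}:1: word2vec header must be 'count dim'")
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError:
            raise FormatError(f"{path}:1: non-integer word2vec header") from None
        vectors, _ = _parse_rows(lines[1:], path, dimension=dim, start_line=2)
        n_rows = sum(1 for ln in lines[1:] if ln.strip())
        if n_rows != count:
            raise FormatError(
                f"{path}: header declares {count} rows but body has {n_rows}")
        dimension = dim
    elif format == "glove_txt":
        vectors, dimension = _parse_rows(lines, path)
    else:
        raise FormatError(f"unknown embedding format {format!r}")
    return EmbeddingModel(id=model_id or path.stem, dimension=dimension,
                          vectors=vectors, metadata=f"loaded from {path.name}")


def write_embeddings(model: EmbeddingModel, path: str | Path,
                     format: EmbeddingFormat = "glove_txt") -> None:
    """Write an embedding table in GloVe or word2vec text format."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if format == "word2vec_txt":
            fh.write(f"{len(model.vectors)} {model.dimension}\n")
        for word, vec in model.vectors.items():
            fh.write(word + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def resolve_vector(model: EmbeddingModel, lexeme: str) -> np.ndarray:
    """Resolve a (possibly multiword) lexeme to a vector.

    Single tokens are exact table lookups. Multiword lexemes return the
    unweighted mean of their component-token vectors; any out-of-vocabulary
    component raises :class:`OOVError` naming the token.
    """
    lexeme = normalize_lexeme(lexeme)
    tokens = lexeme.split(" ")
    parts = []
    for tok in tokens:
        if tok not in model.vectors:
            raise OOVError(tok, model.id)
        parts.append(model.vectors[tok])
    if len(parts) == 1:
        return parts[0]
    return np.mean(parts, axis=0)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity u·v / (|u||v|), in [-1, 1].

    Symmetric and invariant to positive rescaling of either argument.
    Zero vectors are degenerate (direction undefined).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise DegenerateInputError(
            f"cosine of vectors with different lengths ({u.shape} vs {v.shape})")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateInputError("cosine of a zero vector is undefined")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
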