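"""Per-spot language-model embeddings through a pluggable provider interface.

The external single-cell language model (e.g. scGPT) is never run here: its
output is consumed as a precomputed per-spot matrix. Two weight-free providers
make every downstream path testable — ``zero`` (the ablation in which the
embedding is an all-zeros matrix, isolating its contribution) and ``mock``
(a seeded random linear projection of the normalized expression, informative
by construction). ``pca_fallback`` reuses the PCA embedding of the RNA
modality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import EmbeddingMatrix, OmicsMatrix
from .errors import FormatError, ValidationError
from .io import pca_reduce

PROVIDER_KINDS = ("external_file", "zero", "mock", "pca_fallback")


@dataclass
class GeneVocabulary:
    """Set of gene symbols an external model understands."""

    symbols: set[str]
    name: str = "vocabulary"
    case_sensitive: bool = True

    def __post_init__(self) -> None:
        if not self.symbols:
            warnings.warn(f"vocabulary {self.name!r} is empty", stacklevel=2)
        if not self.case_sensitive:
            self.symbols = {s.upper() for s in self.symbols}

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None,
                  case_sensitive: bool = True) -> "GeneVocabulary":
        path = Path(path)
        if not path.exists():
            raise FormatError(f"no such vocabulary file: {path}")
        symbols = {line.strip() for line in path.read_text().splitlines() if line.strip()}
        return cls(symbols, name or path.stem, case_sensitive)

    def __contains__(self, symbol: str) -> bool:
        return (symbol if self.case_sensitive else symbol.upper()) in self.symbols


def match_vocabulary(
    feature_names: list[str], vocab: GeneVocabulary
) -> tuple[list[str], list[str]]:
    """Split feature names into (matched, unmatched) against the vocabulary.

    Order is preserved within each list; matching is exact symbol equality
    after the vocabulary's case policy.
    """
    matched = [f for f in feature_names if f in vocab]
    unmatched = [f for f in feature_names if f not in vocab]
    if feature_names and not matched:
        warnings.warn(
            f"no features matched vocabulary {vocab.name!r}", stacklevel=2
        )
    return matched, unmatched


@dataclass
class EmbeddingProvider:
    """Source of the per-spot language-model embedding.

    kinds:
      * ``external_file`` — precomputed N x dim matrix on disk (``path`` param)
      * ``zero``          — all-zeros N x dim (the zero-embedding ablation)
      * ``mock``          — seeded random projection of expression + noise
      * ``pca_fallback``  — PCA of the modality, tagged ``pca``
    """

    kind: str
    dim: int = 64
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PROVIDER_KINDS:
            raise ValidationError(
                f"provider kind must be one of {PROVIDER_KINDS}, got {self.kind!r}"
            )
        if self.dim < 1:
            raise ValidationError("provider dim must be positive")


def embed_spots(provider: EmbeddingProvider, m: OmicsMatrix) -> EmbeddingMatrix:
    """Produce the N x dim per-spot embedding for one modality.

    ``m`` should already be normalized for the ``mock`` provider (it projects
    whatever values it is given).
    """
    n = m.n_spots
    if provider.kind == "zero":
        return EmbeddingMatrix(np.zeros((n, provider.dim)), source_tag="zero")
    if provider.kind == "mock":
        seed = int(provider.params.get("seed", 0))
        noise_sd = float(provider.params.get("noise_sd", 0.0))
        rng = np.random.default_rng(seed)
        proj = rng.standard_normal((m.n_features, provider.dim)) / np.sqrt(m.n_features)
        values = m.values @ proj
        if noise_sd > 0:
            values = values + noise_sd * rng.standard_normal(values.shape)
        return EmbeddingMatrix(values, source_tag="mock")
    if provider.kind == "pca_fallback":
        e = pca_reduce(m, min(provider.dim, min(m.n_spots, m.n_features)),
                       seed=int(provider.params.get("seed", 0)))
        return e
    # external_file
    path = provider.params.get("path")
    if path is None:
        raise ValidationError("external_file provider needs a 'path' param")
    e = import_embedding(path, expected_n=n, source_tag="llm")
    return e


def export_embedding(e: EmbeddingMatrix, path: str | Path) -> Path:
    """Write an embedding as tab-delimited text (or ``.npy``). Round-trips
    through :func:`import_embedding` within 1e-12."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, e.values)
    else:
        np.savetxt(path, e.values, delimiter="\t", fmt="%.17g")
    return path


def import_embedding(
    path: str | Path, expected_n: int, source_tag: str = "llm"
) -> EmbeddingMatrix:
    """Read an embedding written by :func:`export_embedding` (or any
    delimited/``.npy`` N x dim matrix), checking the row count."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such embedding file: {path}")
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
    if values.shape[0] != expected_n:
        raise ValidationError(
            f"embedding file {path} has {values.shape[0]} rows but {expected_n} spots expected"
        )
    return EmbeddingMatrix(values, source_tag=source_tag)
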