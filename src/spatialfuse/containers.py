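"""In-memory containers shared across the package.

Every matrix is spot-major: rows are capture spots, columns are features
(genes, ATAC peaks, ADT proteins) or latent dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError

MODALITY_TAGS = ("rna", "atac", "adt")
EMBEDDING_SOURCES = ("pca", "llm", "zero", "mock")


@dataclass
class OmicsMatrix:
    """One modality's spot x feature matrix with names attached.

    ``values`` holds raw counts before :func:`spatialfuse.io.normalize_modality`
    and may hold signed values afterwards (e.g. CLR output).
    """

    values: np.ndarray
    feature_names: list[str]
    spot_ids: list[str]
    modality_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_names = [str(f) for f in self.feature_names]
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.values.ndim != 2:
            raise ValidationError(f"omics values must be 2-D, got {self.values.ndim}-D")
        if self.values.shape[0] != len(self.spot_ids):
            raise ValidationError(
                f"{len(self.spot_ids)} spot IDs for {self.values.shape[0]} rows"
            )
        if self.values.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"{len(self.feature_names)} feature names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.spot_ids)) != len(self.spot_ids):
            dupes = sorted({s for s in self.spot_ids if self.spot_ids.count(s) > 1})
            raise ValidationError(f"duplicate spot IDs: {dupes[:5]}")
        if self.modality_tag not in MODALITY_TAGS:
            raise ValidationError(
                f"modality_tag must be one of {MODALITY_TAGS}, got {self.modality_tag!r}"
            )

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def check_counts(self) -> None:
        """Assert the count-matrix invariant (no negative entries)."""
        if np.any(self.values < 0):
            raise ValidationError("count matrix has negative entries")


@dataclass
class SpotCoordinates:
    """2-D spot positions in platform units."""

    coords: np.ndarray
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError(f"coordinates must be N x 2, got {self.coords.shape}")
        if self.coords.shape[0] != len(self.spot_ids):
            raise ValidationError("coordinate rows and spot IDs differ in length")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValidationError("duplicate spot IDs in coordinates")
        # duplicate positions (within 1e-9) are a platform impossibility
        rounded = np.round(self.coords / 1e-9).astype(np.int64)
        if len(np.unique(rounded, axis=0)) != len(rounded):
            raise ValidationError("duplicate coordinate rows (within 1e-9)")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]


@dataclass
class EmbeddingMatrix:
    """Dense per-spot embedding (PCA of a modality, LLM output, or mock)."""

    values: np.ndarray
    source_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("embedding must be 2-D")
        if self.source_tag not in EMBEDDING_SOURCES:
            raise ValidationError(
                f"source_tag must be one of {EMBEDDING_SOURCES}, got {self.source_tag!r}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("embedding contains non-finite entries")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class NeighborGraph:
    """Sparse binary spot adjacency from kNN construction.

    ``knn`` is the directed graph before symmetrization (each row has exactly
    ``k`` ones, or N-1 if the graph is too small); ``adjacency`` is its
    logical-OR symmetrization with zero diagonal. ``normalized_form``, when
    present, is D^{-1/2} (A + I) D^{-1/2}.
    """

    adjacency: sp.csr_matrix
    knn: sp.csr_matrix
    k: int
    kind: str  # "spatial" | "embedding"
    symmetrized: bool = True
    normalized_form: sp.csr_matrix | None = None

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    def operator(self, use_normalized: bool = True) -> sp.csr_matrix:
        """Matrix the graph-convolution layers multiply by."""
        if use_normalized:
            if self.normalized_form is None:
                raise ValidationError("graph has no normalized form; call normalize_adjacency")
            return self.normalized_form
        return self.adjacency


@dataclass
class DomainAssignment:
    """Per-spot integer domain labels in [0, n_domains)."""

    labels: np.ndarray
    n_domains: int
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be 1-D")
        if self.n_domains < 1:
            raise ValidationError("n_domains must be positive")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_domains):
            raise ValidationError("labels outside [0, n_domains)")

    @property
    def n_spots(self) -> int:
        return self.labels.size


@dataclass
class AttentionResult:
    """Output of one attention-fusion site."""

    fused: np.ndarray          # N x latent
    weights: np.ndarray        # N x M, rows sum to 1
    modalities: list[str] = field(default_factory=list)


@dataclass
class LatentSet:
    """All intermediate latents of one forward pass.

    Six encoder outputs (LLM branch through the spatial and embedding graphs,
    each omics branch likewise) and the four attention products leading to the
    final fused embedding.
    """

    R_fs: np.ndarray
    R_fe: np.ndarray
    R_os1: np.ndarray
    R_oe1: np.ndarray
    R_os2: np.ndarray
    R_oe2: np.ndarray
    EA_s: np.ndarray
    EA_e: np.ndarray
    EA_1: np.ndarray
    EA_2: np.ndarray
    Emb_final: np.ndarray
    attention_weights: dict[str, AttentionResult] = field(default_factory=dict)

    ATTENTION_VIEWS = ("s", "e", "1", "2", "final")
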