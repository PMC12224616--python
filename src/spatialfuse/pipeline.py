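"""End-to-end spatial-domain detection pipeline.

``SpatialDomainPipeline`` chains the whole method: spot alignment,
per-modality normalization, PCA reduction, language-model embedding (via a
provider), spatial and correlation graph construction, training of the
attention-fused graph autoencoder, and GMM clustering of the final latent
embedding.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import (
    DomainAssignment,
    EmbeddingMatrix,
    OmicsMatrix,
    SpotCoordinates,
)
from .downstream import cluster_embedding, summarize_attention
from .embedding import EmbeddingProvider, embed_spots
from .errors import ValidationError
from .graphs import (
    DEFAULT_K_EMBEDDING,
    DEFAULT_K_SPATIAL,
    build_embedding_graph,
    build_spatial_graph,
    normalize_adjacency,
)
from .io import align_spots, normalize_modality, pca_reduce, select_hvf
from .model import (
    DEFAULT_HIDDEN_DIMS,
    DEFAULT_LATENT_DIM,
    FusionInputs,
    GraphAttentionAutoencoder,
)


class SpatialDomainPipeline(ClusterMixin, BaseEstimator):
    """Detect spatial domains in a two-modality spatial section.

    Parameters follow the method's defaults: ``k1=3`` spatial neighbors,
    ``k2=20`` correlation neighbors, 50 principal components per modality,
    latent width 64. ``provider`` selects the source of the per-spot
    language-model embedding (an :class:`EmbeddingProvider`; None means the
    zero-embedding ablation).

    Fitted attributes: ``labels_``, ``embedding_`` (N x latent_dim),
    ``latent_set_``, ``model_``, ``inputs_``, ``spot_ids_``.
    """

    def __init__(
        self,
        n_domains: int = 4,
        k1: int = DEFAULT_K_SPATIAL,
        k2: int = DEFAULT_K_EMBEDDING,
        pca_dim: int = 50,
        hidden_dims: tuple[int, ...] = DEFAULT_HIDDEN_DIMS,
        latent_dim: int = DEFAULT_LATENT_DIM,
        epochs: int = 200,
        learning_rate: float = 1e-3,
        alpha1: float = 1.0,
        alpha2: float = 1.0,
        alpha3: float = 1.0,
        alpha4: float = 1.0,
        beta1: float = 1.0,
        beta2: float = 1.0,
        provider: EmbeddingProvider | None = None,
        normalize: bool = True,
        hvf_top_k: int | None = None,
        use_normalized_adjacency: bool = True,
        gmm_n_init: int = 10,
        random_state: int = 0,
    ) -> None:
        self.n_domains = n_domains
        self.k1 = k1
        self.k2 = k2
        self.pca_dim = pca_dim
        self.hidden_dims = hidden_dims
        self.latent_dim = latent_dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.alpha3 = alpha3
        self.alpha4 = alpha4
        self.beta1 = beta1
        self.beta2 = beta2
        self.provider = provider
        self.normalize = normalize
        self.hvf_top_k = hvf_top_k
        self.use_normalized_adjacency = use_normalized_adjacency
        self.gmm_n_init = gmm_n_init
        self.random_state = random_state

    # ------------------------------------------------------------------
    def prepare_inputs(
        self,
        m1: OmicsMatrix,
        m2: OmicsMatrix,
        coords: SpotCoordinates,
        llm_embedding: EmbeddingMatrix | None = None,
    ) -> FusionInputs:
        """Run everything up to (but not including) model training."""
        m1, m2, coords = align_spots(m1, m2, coords)
        if self.normalize:
            m1 = normalize_modality(m1)
            m2 = normalize_modality(m2)
        if self.hvf_top_k:
            m1 = select_hvf(m1, self.hvf_top_k)
            m2 = select_hvf(m2, self.hvf_top_k)
        d1 = min(self.pca_dim, m1.n_spots - 1, m1.n_features)
        d2 = min(self.pca_dim, m2.n_spots - 1, m2.n_features)
        emb1 = pca_reduce(m1, d1, seed=self.random_state)
        emb2 = pca_reduce(m2, d2, seed=self.random_state)

        if llm_embedding is not None:
            emb_f = llm_embedding
        else:
            provider = self.provider or EmbeddingProvider(kind="zero", dim=64)
            emb_f = embed_spots(provider, m1)
        if emb_f.n_spots != m1.n_spots:
            raise ValidationError(
                f"embedding has {emb_f.n_spots} rows but {m1.n_spots} spots are aligned"
            )

        g_s = normalize_adjacency(build_spatial_graph(coords, self.k1))
        g_f = normalize_adjacency(build_embedding_graph(emb_f, self.k2))
        g_1 = normalize_adjacency(build_embedding_graph(emb1, self.k2))
        g_2 = normalize_adjacency(build_embedding_graph(emb2, self.k2))
        self.spot_ids_ = list(m1.spot_ids)
        return FusionInputs(
            emb_llm=emb_f.values,
            emb_omics1=emb1.values,
            emb_omics2=emb2.values,
            g_spatial=g_s,
            g_llm=g_f,
            g_omics1=g_1,
            g_omics2=g_2,
        )

    def fit(
        self,
        m1: OmicsMatrix,
        m2: OmicsMatrix | None = None,
        coords: SpotCoordinates | None = None,
        llm_embedding: EmbeddingMatrix | None = None,
    ) -> "SpatialDomainPipeline":
        if m2 is None or coords is None:
            raise ValidationError("fit needs both modalities and coordinates")
        inputs = self.prepare_inputs(m1, m2, coords, llm_embedding)
        self.model_ = GraphAttentionAutoencoder(
            hidden_dims=tuple(self.hidden_dims),
            latent_dim=self.latent_dim,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            alpha1=self.alpha1,
            alpha2=self.alpha2,
            alpha3=self.alpha3,
            alpha4=self.alpha4,
            beta1=self.beta1,
            beta2=self.beta2,
            use_normalized=self.use_normalized_adjacency,
            random_state=self.random_state,
        ).fit(inputs)
        self.inputs_ = inputs
        self.latent_set_ = self.model_.latent_set_
        self.embedding_ = self.model_.embedding_
        self.assignment_ = cluster_embedding(
            self.embedding_,
            self.n_domains,
            seed=self.random_state,
            n_init=self.gmm_n_init,
        )
        self.labels_ = self.assignment_.labels
        return self

    def fit_predict(self, m1, m2=None, coords=None, llm_embedding=None) -> np.ndarray:
        return self.fit(m1, m2, coords, llm_embedding).labels_

    def attention_summary(self, views: list[str] | None = None):
        """Long-format attention table + per-cluster means (see
        :func:`spatialfuse.downstream.summarize_attention`)."""
        if not hasattr(self, "labels_"):
            raise ValidationError("pipeline is not fitted")
        return summarize_attention(
            self.latent_set_, self.assignment_, views=views, spot_ids=self.spot_ids_
        )


def run_pipeline(
    m1: OmicsMatrix,
    m2: OmicsMatrix,
    coords: SpotCoordinates,
    n_domains: int,
    llm_embedding: EmbeddingMatrix | None = None,
    **params,
) -> tuple[DomainAssignment, np.ndarray]:
    """Functional wrapper: returns (assignment, final embedding)."""
    pipe = SpatialDomainPipeline(n_domains=n_domains, **params)
    pipe.fit(m1, m2, coords, llm_embedding)
    return pipe.assignment_, pipe.embedding_
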