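import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spatialfuse as sf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic section: 20x20 grid, 4 block domains,
    effect size 2.0, seed 0."""
    spec = sf.SyntheticSpec()
    m1, m2, coords, truth = sf.generate(spec)
    return spec, m1, m2, coords, truth


def make_fusion_inputs(
    n: int = 15, d_f: int = 6, d1: int = 5, d2: int = 4, seed: int = 0,
    k1: int = 2, k2: int = 3,
) -> sf.FusionInputs:
    """Small random model inputs with valid normalized graphs."""
    rng = np.random.default_rng(seed)
    coords = sf.SpotCoordinates(
        rng.uniform(0, 10, size=(n, 2)), [f"s{i}" for i in range(n)]
    )
    emb_f = rng.standard_normal((n, d_f))
    emb_1 = rng.standard_normal((n, d1))
    emb_2 = rng.standard_normal((n, d2))
    return sf.FusionInputs(
        emb_llm=emb_f,
        emb_omics1=emb_1,
        emb_omics2=emb_2,
        g_spatial=sf.normalize_adjacency(sf.build_spatial_graph(coords, k1)),
        g_llm=sf.normalize_adjacency(sf.build_embedding_graph(emb_f, k2)),
        g_omics1=sf.normalize_adjacency(sf.build_embedding_graph(emb_1, k2)),
        g_omics2=sf.normalize_adjacency(sf.build_embedding_graph(emb_2, k2)),
    )


@pytest.fixture(scope="session")
def small_inputs():
    return make_fusion_inputs()


@pytest.fixture(scope="session")
def trained_small_model(small_inputs):
    """A short training run on the small random inputs, shared across tests."""
    est = sf.GraphAttentionAutoencoder(
        hidden_dims=(8,), latent_dim=6, epochs=30, random_state=0
    )
    est.fit(small_inputs)
    return est


@pytest.fixture(scope="session")
def recovery_run(default_fixture):
    """Full-pipeline fit on the default fixture with the informative
    embedding; reused by the parameter-recovery and attention tests."""
    spec, m1, m2, coords, truth = default_fixture
    emb = sf.make_informative_embedding(truth, dim=64, noise_sd=0.1, seed=spec.seed)
    pipe = sf.SpatialDomainPipeline(n_domains=spec.n_domains, random_state=spec.seed)
    pipe.fit(m1, m2, coords, emb)
    return pipe, truth
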