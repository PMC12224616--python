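"""Synthetic spatial multi-omics with known domain structure.

The generator emulates the shape of sequencing-based spatial multi-omics
sections: spots on a 2-D lattice, contiguous spatial domains (stripes,
rectangular blocks, or Voronoi cells), an RNA modality of negative-binomial
counts with dropout, and a second modality that is either continuous
log-normal protein abundance (ADT) or sparse binarized accessibility (ATAC).
Domain identity shifts each feature's (log-)mean; ``effect_size`` measures
that shift in units of the feature's within-domain noise SD, so 0 is an
exact null and ~2 is a strongly structured tissue.

A companion helper fabricates an informative per-spot embedding (per-domain
anchor vectors plus Gaussian noise) standing in for a language-model
embedding when testing the embedding branch's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DomainAssignment, EmbeddingMatrix, OmicsMatrix, SpotCoordinates
from .errors import ValidationError

LAYOUTS = ("stripes", "blocks", "voronoi")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic section."""

    grid_shape: tuple[int, int] = (20, 20)
    n_domains: int = 4
    domain_layout: str = "blocks"
    rna_features: int = 120
    mod2_features: int = 40
    modality2_kind: str = "adt"
    effect_size: float = 2.0
    dropout_rate: float = 0.2
    seed: int = 0
    nb_dispersion: float = 0.5
    mod2_effect_size: float | None = None  # None -> same as effect_size

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows * cols < self.n_domains:
            raise ValidationError(
                f"n_domains={self.n_domains} exceeds N={rows * cols}"
            )
        if self.domain_layout not in LAYOUTS:
            raise ValidationError(f"layout must be one of {LAYOUTS}")
        if self.modality2_kind not in ("adt", "atac"):
            raise ValidationError("modality2_kind must be 'adt' or 'atac'")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")

    @property
    def n_spots(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]


def _layout_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if spec.domain_layout == "stripes":
        labels = (cc * spec.n_domains) // cols
    elif spec.domain_layout == "blocks":
        nr = int(np.sqrt(spec.n_domains))
        while spec.n_domains % nr:
            nr -= 1
        nc = spec.n_domains // nr
        labels = ((rr * nr) // rows) * nc + (cc * nc) // cols
    else:  # voronoi
        centers = rng.uniform(0, [rows, cols], size=(spec.n_domains, 2))
        pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
        d = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d.argmin(axis=1).reshape(rows, cols)
    return labels.ravel().astype(np.int64)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    # var = m + dispersion * m^2  ->  NB(r, p) with r = 1/dispersion
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.float64)


def generate(
    spec: SyntheticSpec,
) -> tuple[OmicsMatrix, OmicsMatrix, SpotCoordinates, DomainAssignment]:
    """Draw one synthetic section, fully deterministic per ``spec.seed``."""
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    rng_layout, rng_means, rng_rna, rng_mod2, rng_drop = (
        np.random.default_rng(s) for s in streams
    )
    rows, cols = spec.grid_shape
    n = spec.n_spots
    labels = _layout_labels(spec, rng_layout)
    spot_ids = [f"spot_{i:04d}" for i in range(n)]
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = SpotCoordinates(
        np.stack([cc.ravel(), rr.ravel()], axis=1).astype(float), spot_ids
    )

    # RNA: negative binomial around domain-specific log-means
    base_log = rng_means.normal(np.log(5.0), 0.4, size=spec.rna_features)
    base_mean = np.exp(base_log)
    # within-domain SD of log1p(counts), delta method on NB variance
    sd_log = np.sqrt(base_mean + spec.nb_dispersion * base_mean**2) / (1.0 + base_mean)
    delta = rng_means.standard_normal((spec.n_domains, spec.rna_features))
    log_mu = base_log[None, :] + spec.effect_size * sd_log[None, :] * delta
    rna = _nb_counts(rng_rna, np.exp(log_mu)[labels], spec.nb_dispersion)
    if spec.dropout_rate > 0:
        rna *= rng_drop.random(rna.shape) >= spec.dropout_rate
    m_rna = OmicsMatrix(
        rna, [f"gene_{j}" for j in range(spec.rna_features)], spot_ids, "rna"
    )

    # modality 2
    eff2 = spec.effect_size if spec.mod2_effect_size is None else spec.mod2_effect_size
    delta2 = rng_means.standard_normal((spec.n_domains, spec.mod2_features))
    if spec.modality2_kind == "adt":
        sigma = 0.5  # within-domain log-normal SD
        base2 = rng_means.normal(np.log(50.0), 0.5, size=spec.mod2_features)
        log_mu2 = base2[None, :] + eff2 * sigma * delta2
        mod2 = rng_mod2.lognormal(mean=log_mu2[labels], sigma=sigma)
        feat_prefix = "protein"
    else:  # atac: sparse binarized accessibility
        base_logit = np.log(0.1 / 0.9) + rng_means.normal(0.0, 0.5, size=spec.mod2_features)
        logits = base_logit[None, :] + eff2 * delta2
        p_open = 1.0 / (1.0 + np.exp(-logits))
        mod2 = (rng_mod2.random((n, spec.mod2_features)) < p_open[labels]).astype(float)
        feat_prefix = "peak"
    m_mod2 = OmicsMatrix(
        mod2,
        [f"{feat_prefix}_{j}" for j in range(spec.mod2_features)],
        spot_ids,
        spec.modality2_kind,
    )
    truth = DomainAssignment(labels=labels, n_domains=spec.n_domains, method_tag="truth")
    return m_rna, m_mod2, coords, truth


def make_informative_embedding(
    truth: DomainAssignment, dim: int = 64, noise_sd: float = 0.1, seed: int = 0
) -> EmbeddingMatrix:
    """Per-domain anchors plus per-spot Gaussian noise: a stand-in for a
    language-model embedding that carries domain signal."""
    if dim < 2:
        raise ValidationError("embedding dim must be >= 2")
    rng = np.random.default_rng(seed)
    anchors = rng.standard_normal((truth.n_domains, dim))
    values = anchors[truth.labels]
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(values.shape)
    return EmbeddingMatrix(values, source_tag="mock")


def write_fixture_dir(
    spec: SyntheticSpec, out_dir, embedding_dim: int = 64, embedding_noise_sd: float = 0.1
):
    """Write a generated section in the delimited layout ``io`` reads,
    plus truth labels and an informative embedding; used by the CLI."""
    import pandas as pd
    from pathlib import Path

    from .embedding import export_embedding

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m1, m2, coords, truth = generate(spec)
    for m, name in ((m1, "rna.csv"), (m2, "mod2.csv")):
        pd.DataFrame(m.values, index=m.spot_ids, columns=m.feature_names).to_csv(
            out / name, index_label="spot_id"
        )
    pd.DataFrame(
        {"spot_id": coords.spot_ids, "x": coords.coords[:, 0], "y": coords.coords[:, 1]}
    ).to_csv(out / "coordinates.csv", index=False)
    pd.DataFrame({"spot_id": coords.spot_ids, "label": truth.labels}).to_csv(
        out / "truth_labels.csv", index=False
    )
    emb = make_informative_embedding(
        truth, dim=embedding_dim, noise_sd=embedding_noise_sd, seed=spec.seed
    )
    export_embedding(emb, out / "embedding.tsv")
    return out
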