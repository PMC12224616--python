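"""Spatial-domain clustering and evaluation of the fused embedding.

Clustering follows the mclust EEE convention: a Gaussian mixture whose
components share one full covariance matrix (equal volume, shape, and
orientation), fitted by EM with multiple seeded restarts and the best
solution kept by likelihood. Implemented as a thin subclass of sklearn's
tied-covariance ``GaussianMixture`` that additionally records the
log-likelihood path of every EM restart so monotonicity is checkable.

Agreement with ground-truth annotation is scored with five supervised
metrics: homogeneity, v-measure, adjusted mutual information (max-normalized),
normalized mutual information (arithmetic-mean normalized), and adjusted
Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.mixture import GaussianMixture

from .containers import DomainAssignment, LatentSet
from .errors import ValidationError


class SharedCovarianceGMM(GaussianMixture):
    """Tied-covariance Gaussian mixture with recorded EM likelihood paths.

    ``loglik_paths_`` holds, after ``fit``, one list of per-iteration mean
    log-likelihoods per EM restart (each non-decreasing up to numerical
    noise). Singular covariances are handled by sklearn's ``reg_covar``
    diagonal jitter.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_init: int = 10,
        max_iter: int = 300,
        reg_covar: float = 1e-6,
        random_state: int | None = 0,
    ) -> None:
        super().__init__(
            n_components=n_components,
            covariance_type="tied",
            n_init=n_init,
            max_iter=max_iter,
            reg_covar=reg_covar,
            random_state=random_state,
            init_params="kmeans",
        )

    def _initialize_parameters(self, X, random_state, **kwargs) -> None:
        if not hasattr(self, "loglik_paths_"):
            self.loglik_paths_: list[list[float]] = []
        self.loglik_paths_.append([])
        super()._initialize_parameters(X, random_state, **kwargs)

    def _e_step(self, X, **kwargs):
        log_prob_norm, log_resp = super()._e_step(X, **kwargs)
        self.loglik_paths_[-1].append(float(log_prob_norm))
        return log_prob_norm, log_resp

    def fit(self, X, y=None):
        self.loglik_paths_ = []
        return super().fit(X, y)


def cluster_embedding(
    e: np.ndarray, n_domains: int, seed: int = 0, n_init: int = 10
) -> DomainAssignment:
    """Partition spots into ``n_domains`` by the shared-covariance GMM."""
    e = np.asarray(e, dtype=np.float64)
    if n_domains < 2:
        raise ValidationError(f"n_domains must be >= 2, got {n_domains}")
    if n_domains > e.shape[0]:
        raise ValidationError(
            f"n_domains={n_domains} exceeds spot count {e.shape[0]}"
        )
    gmm = SharedCovarianceGMM(
        n_components=n_domains, n_init=n_init, random_state=seed
    )
    labels = gmm.fit_predict(e)
    return DomainAssignment(labels=labels, n_domains=n_domains, method_tag="gmm_eee")


@dataclass
class MetricReport:
    """Five supervised clustering-agreement scores."""

    homogeneity: float
    v_measure: float
    ami: float
    nmi: float
    ari: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def compute_metrics(
    pred: DomainAssignment | np.ndarray, truth: DomainAssignment | np.ndarray
) -> MetricReport:
    """Score a predicted partition against ground truth."""
    p = pred.labels if isinstance(pred, DomainAssignment) else np.asarray(pred)
    t = truth.labels if isinstance(truth, DomainAssignment) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValidationError(
            f"prediction has {p.shape[0]} labels but truth has {t.shape[0]}"
        )
    return MetricReport(
        homogeneity=float(skm.homogeneity_score(t, p)),
        v_measure=float(skm.v_measure_score(t, p)),
        ami=float(skm.adjusted_mutual_info_score(t, p, average_method="max")),
        nmi=float(skm.normalized_mutual_info_score(t, p, average_method="arithmetic")),
        ari=float(skm.adjusted_rand_score(t, p)),
    )


def summarize_attention(
    ls: LatentSet,
    d: DomainAssignment,
    views: list[str] | None = None,
    spot_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format attention-weight table for violin plots, plus per-cluster
    modality means.

    Returns ``(long, means)`` where ``long`` has columns
    spot, cluster, view, modality, weight and ``means`` has columns
    cluster, view, modality, mean_weight.
    """
    views = views or list(LatentSet.ATTENTION_VIEWS)
    unknown = [v for v in views if v not in ls.attention_weights]
    if unknown:
        raise ValidationError(
            f"unknown view(s) {unknown}; valid views: {sorted(ls.attention_weights)}"
        )
    n = d.labels.size
    ids = spot_ids if spot_ids is not None else [str(i) for i in range(n)]
    rows = []
    for view in views:
        res = ls.attention_weights[view]
        if res.weights.shape[0] != n:
            raise ValidationError("attention weights and labels differ in spot count")
        for k, modality in enumerate(res.modalities):
            rows.append(
                pd.DataFrame(
                    {
                        "spot": ids,
                        "cluster": d.labels,
                        "view": view,
                        "modality": modality,
                        "weight": res.weights[:, k],
                    }
                )
            )
    long = pd.concat(rows, ignore_index=True)
    means = (
        long.groupby(["cluster", "view", "modality"], observed=True)["weight"]
        .mean()
        .rename("mean_weight")
        .reset_index()
    )
    return long, means


def export_umap_coords(
    e: np.ndarray, seed: int = 0, n_neighbors: int = 15, path=None
) -> np.ndarray:
    """2-D UMAP of the latent embedding, for plotting outside the package."""
    e = np.asarray(e, dtype=np.float64)
    if e.shape[0] < 10:
        raise ValidationError(f"need at least 10 spots for UMAP, got {e.shape[0]}")
    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, e.shape[0] - 1),
        random_state=seed,
    )
    coords = np.asarray(reducer.fit_transform(e), dtype=np.float64)
    if path is not None:
        np.savetxt(path, coords, delimiter="\t", fmt="%.8g")
    return coords
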