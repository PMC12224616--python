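"""Six-branch graph autoencoder with hierarchical multi-view attention.

Architecture
------------
Three graph-convolutional encoders produce six latents, each of width
``latent_dim`` (64 by default):

* ``Enc_f`` encodes the language-model embedding through the spatial graph
  (-> ``R_fs``) and through its own correlation graph (-> ``R_fe``); the two
  branches share weights.
* ``Enc_o1`` encodes the first omics PCA embedding through the spatial graph
  (-> ``R_os1``) and its correlation graph (-> ``R_oe1``).
* ``Enc_o2`` does the same for the second modality (-> ``R_os2``, ``R_oe2``).

Each encoder layer computes ``Z <- act(A (Z W))`` where ``A`` is the
(normalized) adjacency; the final layer is linear. Decoders mirror the
encoder widths in reverse, final layer linear.

Five attention sites fuse the latents hierarchically: per spot, scores
``tanh(R_k W_w) . mu_w`` are softmaxed over the inputs ``k`` and the fused
latent is the weighted sum. Sites: (R_fs, R_os1) -> EA_s; (R_fe, R_oe1) ->
EA_e; (EA_s, EA_e) -> EA_1; (R_os2, R_oe2) -> EA_2; (EA_1, EA_2) -> the
final embedding.

Training minimizes a weighted sum of four reconstruction terms (the LLM
embedding from R_fs and R_fe; each omics embedding from the final embedding
through its own decoder) and two cross-modality correspondence terms (EA_1
decoded by the *other* modality's decoder, re-encoded, and compared to
itself; likewise EA_2), all mean-squared errors averaged over spots.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import autodiff as ad
from .containers import AttentionResult, EmbeddingMatrix, LatentSet, NeighborGraph
from .errors import TrainingError, ValidationError

DEFAULT_LATENT_DIM = 64
DEFAULT_HIDDEN_DIMS = (256, 64)

ATTENTION_MODALITIES = {
    "s": ["llm_spatial", "omics1_spatial"],
    "e": ["llm_feature", "omics1_feature"],
    "1": ["spatial_view", "feature_view"],
    "2": ["omics2_spatial", "omics2_feature"],
    "final": ["modality1", "modality2"],
}


@dataclass
class FusionInputs:
    """Aligned embeddings and graphs the model consumes."""

    emb_llm: np.ndarray      # N x D_f
    emb_omics1: np.ndarray   # N x D1
    emb_omics2: np.ndarray   # N x D2
    g_spatial: NeighborGraph
    g_llm: NeighborGraph
    g_omics1: NeighborGraph
    g_omics2: NeighborGraph

    def __post_init__(self) -> None:
        self.emb_llm = np.asarray(self.emb_llm, dtype=np.float64)
        self.emb_omics1 = np.asarray(self.emb_omics1, dtype=np.float64)
        self.emb_omics2 = np.asarray(self.emb_omics2, dtype=np.float64)
        n = self.emb_llm.shape[0]
        for name in ("emb_omics1", "emb_omics2"):
            if getattr(self, name).shape[0] != n:
                raise ValidationError(f"{name} has a different spot count than emb_llm")
        for name in ("g_spatial", "g_llm", "g_omics1", "g_omics2"):
            if getattr(self, name).n_spots != n:
                raise ValidationError(f"{name} size differs from the embeddings' N={n}")

    @property
    def n_spots(self) -> int:
        return self.emb_llm.shape[0]


@dataclass
class LossConfig:
    """Loss weights and optimizer settings.

    The six weights multiply, in order: reconstruction of omics-1 and omics-2
    embeddings from the final latent (``alpha1``, ``alpha2``), reconstruction
    of the LLM embedding from its spatial- and feature-graph latents
    (``alpha3``, ``alpha4``), and the two correspondence terms (``beta1``,
    ``beta2``).
    """

    alpha1: float = 1.0
    alpha2: float = 1.0
    alpha3: float = 1.0
    alpha4: float = 1.0
    beta1: float = 1.0
    beta2: float = 1.0
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        w = (self.alpha1, self.alpha2, self.alpha3, self.alpha4, self.beta1, self.beta2)
        if any(x < 0 for x in w):
            raise ValidationError("loss weights must be nonnegative")
        if not any(x > 0 for x in w):
            raise ValidationError("at least one loss weight must be positive")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")


@dataclass
class LossReport:
    """Six loss terms of one epoch and their weighted total."""

    L_rec_1: float
    L_rec_2: float
    L_rec_fs: float
    L_rec_fe: float
    L_cor_1: float
    L_cor_2: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class ModelParams:
    """All trainable tensors, keyed by role."""

    tensors: dict[str, ad.Tensor] = field(default_factory=dict)

    def as_list(self) -> list[ad.Tensor]:
        return [self.tensors[k] for k in sorted(self.tensors)]

    def numpy(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.tensors.items()}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _layer_widths(d_in: int, hidden_dims: tuple[int, ...], latent_dim: int) -> list[int]:
    return [d_in, *hidden_dims, latent_dim]


def init_params(
    d_llm: int,
    d_omics1: int,
    d_omics2: int,
    hidden_dims: tuple[int, ...] = DEFAULT_HIDDEN_DIMS,
    latent_dim: int = DEFAULT_LATENT_DIM,
    use_bias: bool = False,
    seed: int = 0,
) -> ModelParams:
    """Glorot-uniform initialization of every encoder, decoder, and attention
    site, deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    params = ModelParams()

    def add_stack(prefix: str, widths: list[int]) -> None:
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            params.tensors[f"{prefix}_W{i}"] = ad.parameter(_glorot(rng, a, b))
            if use_bias:
                params.tensors[f"{prefix}_b{i}"] = ad.parameter(np.zeros((1, b)))

    for prefix, d_in in (("enc_f", d_llm), ("enc_o1", d_omics1), ("enc_o2", d_omics2)):
        widths = _layer_widths(d_in, hidden_dims, latent_dim)
        add_stack(prefix, widths)
        add_stack(prefix.replace("enc", "dec"), widths[::-1])
    for view in LatentSet.ATTENTION_VIEWS:
        params.tensors[f"att_{view}_W"] = ad.parameter(_glorot(rng, latent_dim, latent_dim))
        params.tensors[f"att_{view}_mu"] = ad.parameter(_glorot(rng, latent_dim, 1))
    return params


def _stack_weights(params: ModelParams, prefix: str) -> list[tuple[ad.Tensor, ad.Tensor | None]]:
    out = []
    i = 0
    while f"{prefix}_W{i}" in params.tensors:
        out.append((params.tensors[f"{prefix}_W{i}"], params.tensors.get(f"{prefix}_b{i}")))
        i += 1
    if not out:
        raise ValidationError(f"no weights found for {prefix!r}")
    return out


def _gcn_t(
    A, x: ad.Tensor, stack: list[tuple[ad.Tensor, ad.Tensor | None]]
) -> ad.Tensor:
    """act(A (Z W)) per layer; final layer has no activation."""
    z = x
    for i, (W, b) in enumerate(stack):
        if z.data.shape[1] != W.data.shape[0]:
            raise ValidationError(
                f"layer {i}: input width {z.data.shape[1]} != weight rows {W.data.shape[0]}"
            )
        z = ad.spmm(A, ad.matmul(z, W))
        if b is not None:
            z = ad.add_bias(z, b)
        if i < len(stack) - 1:
            z = ad.relu(z)
    return z


def _attention_t(
    inputs: list[ad.Tensor], W: ad.Tensor, mu: ad.Tensor, epsilon: float
) -> tuple[ad.Tensor, ad.Tensor]:
    if len(inputs) < 2:
        raise ValidationError("attention needs at least 2 inputs")
    shape = inputs[0].data.shape
    for r in inputs[1:]:
        if r.data.shape != shape:
            raise ValidationError(
                f"attention inputs disagree in shape: {shape} vs {r.data.shape}"
            )
    scores = [
        ad.add_scalar(ad.matmul(ad.tanh(ad.matmul(r, W)), mu), epsilon) for r in inputs
    ]
    alpha = ad.softmax_rows(ad.concat_cols(scores))
    fused = ad.add_n([ad.rowscale(r, ad.col(alpha, k)) for k, r in enumerate(inputs)])
    return fused, alpha


# ---------------------------------------------------------------------------
# functional surface (numpy in / numpy out)
# ---------------------------------------------------------------------------

def encoder_forward(
    x: np.ndarray | EmbeddingMatrix,
    g: NeighborGraph,
    weights: list[np.ndarray],
    biases: list[np.ndarray] | None = None,
    use_normalized: bool = True,
) -> np.ndarray:
    """Run one encoder stack on plain arrays (used by oracle tests and the
    correspondence cycle)."""
    X = x.values if isinstance(x, EmbeddingMatrix) else np.asarray(x, float)
    if X.shape[0] != g.n_spots:
        raise ValidationError(f"x has {X.shape[0]} rows but graph has {g.n_spots} spots")
    stack = [
        (ad.constant(W), ad.constant(biases[i]) if biases else None)
        for i, W in enumerate(weights)
    ]
    return _gcn_t(g.operator(use_normalized), ad.constant(X), stack).data


def decoder_forward(
    z: np.ndarray,
    g: NeighborGraph,
    weights: list[np.ndarray],
    biases: list[np.ndarray] | None = None,
    use_normalized: bool = True,
) -> np.ndarray:
    """Decoder stack; identical propagation rule to the encoder with widths
    reversed, so this shares the implementation."""
    return encoder_forward(z, g, weights, biases, use_normalized)


def attention_fuse(
    inputs: list[np.ndarray],
    W_omega: np.ndarray,
    mu_omega: np.ndarray,
    epsilon: float = 1e-8,
) -> AttentionResult:
    """Fuse M same-shape latents into one, returning per-spot weights."""
    tensors = [ad.constant(np.asarray(r, float)) for r in inputs]
    fused, alpha = _attention_t(
        tensors, ad.constant(W_omega), ad.constant(mu_omega), epsilon
    )
    return AttentionResult(fused=fused.data, weights=alpha.data)


def _forward_t(
    params: ModelParams,
    data: FusionInputs,
    attention_epsilon: float,
    use_normalized: bool,
) -> dict[str, ad.Tensor]:
    A_s = data.g_spatial.operator(use_normalized)
    A_f = data.g_llm.operator(use_normalized)
    A_1 = data.g_omics1.operator(use_normalized)
    A_2 = data.g_omics2.operator(use_normalized)
    enc_f = _stack_weights(params, "enc_f")
    enc_o1 = _stack_weights(params, "enc_o1")
    enc_o2 = _stack_weights(params, "enc_o2")

    x_f = ad.constant(data.emb_llm)
    x_1 = ad.constant(data.emb_omics1)
    x_2 = ad.constant(data.emb_omics2)

    t: dict[str, ad.Tensor] = {}
    t["R_fs"] = _gcn_t(A_s, x_f, enc_f)
    t["R_fe"] = _gcn_t(A_f, x_f, enc_f)
    t["R_os1"] = _gcn_t(A_s, x_1, enc_o1)
    t["R_oe1"] = _gcn_t(A_1, x_1, enc_o1)
    t["R_os2"] = _gcn_t(A_s, x_2, enc_o2)
    t["R_oe2"] = _gcn_t(A_2, x_2, enc_o2)

    def att(view: str, inputs: list[ad.Tensor]) -> ad.Tensor:
        fused, alpha = _attention_t(
            inputs,
            params.tensors[f"att_{view}_W"],
            params.tensors[f"att_{view}_mu"],
            attention_epsilon,
        )
        t[f"alpha_{view}"] = alpha
        return fused

    t["EA_s"] = att("s", [t["R_fs"], t["R_os1"]])
    t["EA_e"] = att("e", [t["R_fe"], t["R_oe1"]])
    t["EA_1"] = att("1", [t["EA_s"], t["EA_e"]])
    t["EA_2"] = att("2", [t["R_os2"], t["R_oe2"]])
    t["Emb_final"] = att("final", [t["EA_1"], t["EA_2"]])
    return t


def _losses_t(
    params: ModelParams,
    data: FusionInputs,
    t: dict[str, ad.Tensor],
    cfg: LossConfig,
    use_normalized: bool,
) -> tuple[ad.Tensor, LossReport]:
    A_s = data.g_spatial.operator(use_normalized)
    A_f = data.g_llm.operator(use_normalized)
    dec_f = _stack_weights(params, "dec_f")
    enc_o1 = _stack_weights(params, "enc_o1")
    enc_o2 = _stack_weights(params, "enc_o2")
    dec_o1 = _stack_weights(params, "dec_o1")
    dec_o2 = _stack_weights(params, "dec_o2")

    x_f = ad.constant(data.emb_llm)
    x_1 = ad.constant(data.emb_omics1)
    x_2 = ad.constant(data.emb_omics2)

    l_rec_fs = ad.mse(x_f, _gcn_t(A_s, t["R_fs"], dec_f))
    l_rec_fe = ad.mse(x_f, _gcn_t(A_f, t["R_fe"], dec_f))
    l_rec_1 = ad.mse(x_1, _gcn_t(A_s, t["Emb_final"], dec_o1))
    l_rec_2 = ad.mse(x_2, _gcn_t(A_s, t["Emb_final"], dec_o2))
    # correspondence cycles: decode with the OTHER modality's decoder,
    # re-encode, compare to the input latent; both legs use the spatial graph
    l_cor_1 = ad.mse(t["EA_1"], _gcn_t(A_s, _gcn_t(A_s, t["EA_1"], dec_o2), enc_o2))
    l_cor_2 = ad.mse(t["EA_2"], _gcn_t(A_s, _gcn_t(A_s, t["EA_2"], dec_o1), enc_o1))

    total_t = ad.add(
        ad.add(
            ad.add(
                ad.add(
                    ad.add(ad.scale(l_rec_1, cfg.alpha1), ad.scale(l_rec_2, cfg.alpha2)),
                    ad.scale(l_rec_fs, cfg.alpha3),
                ),
                ad.scale(l_rec_fe, cfg.alpha4),
            ),
            ad.scale(l_cor_1, cfg.beta1),
        ),
        ad.scale(l_cor_2, cfg.beta2),
    )
    terms = {
        "L_rec_1": l_rec_1.item(),
        "L_rec_2": l_rec_2.item(),
        "L_rec_fs": l_rec_fs.item(),
        "L_rec_fe": l_rec_fe.item(),
        "L_cor_1": l_cor_1.item(),
        "L_cor_2": l_cor_2.item(),
    }
    for name, value in terms.items():
        if not np.isfinite(value):
            raise TrainingError(f"loss term {name} is non-finite ({value})")
    report = LossReport(**terms, total=total_t.item())
    return total_t, report


def _latent_set_from(t: dict[str, ad.Tensor]) -> LatentSet:
    weights = {
        view: AttentionResult(
            fused=t[f"EA_{view}" if view != "final" else "Emb_final"].data.copy(),
            weights=t[f"alpha_{view}"].data.copy(),
            modalities=list(ATTENTION_MODALITIES[view]),
        )
        for view in LatentSet.ATTENTION_VIEWS
    }
    return LatentSet(
        R_fs=t["R_fs"].data.copy(),
        R_fe=t["R_fe"].data.copy(),
        R_os1=t["R_os1"].data.copy(),
        R_oe1=t["R_oe1"].data.copy(),
        R_os2=t["R_os2"].data.copy(),
        R_oe2=t["R_oe2"].data.copy(),
        EA_s=t["EA_s"].data.copy(),
        EA_e=t["EA_e"].data.copy(),
        EA_1=t["EA_1"].data.copy(),
        EA_2=t["EA_2"].data.copy(),
        Emb_final=t["Emb_final"].data.copy(),
        attention_weights=weights,
    )


def forward_pass(
    params: ModelParams,
    data: FusionInputs,
    attention_epsilon: float = 1e-8,
    use_normalized: bool = True,
) -> LatentSet:
    """One full forward pass; returns all latents and attention weights."""
    t = _forward_t(params, data, attention_epsilon, use_normalized)
    return _latent_set_from(t)


def compute_losses(
    params: ModelParams,
    data: FusionInputs,
    cfg: LossConfig,
    attention_epsilon: float = 1e-8,
    use_normalized: bool = True,
) -> LossReport:
    """Evaluate the six loss terms and their weighted total at fixed params."""
    t = _forward_t(params, data, attention_epsilon, use_normalized)
    _, report = _losses_t(params, data, t, cfg, use_normalized)
    return report


def train(
    data: FusionInputs,
    cfg: LossConfig | None = None,
    hidden_dims: tuple[int, ...] = DEFAULT_HIDDEN_DIMS,
    latent_dim: int = DEFAULT_LATENT_DIM,
    attention_epsilon: float = 1e-8,
    use_bias: bool = False,
    use_normalized: bool = True,
    params: ModelParams | None = None,
) -> tuple[ModelParams, LatentSet, list[LossReport]]:
    """Full-graph gradient training of all parameters.

    Returns the trained parameters, the final-state latent set, and one
    :class:`LossReport` per epoch. Deterministic under ``cfg.seed``.
    """
    cfg = cfg or LossConfig()
    if params is None:
        params = init_params(
            data.emb_llm.shape[1],
            data.emb_omics1.shape[1],
            data.emb_omics2.shape[1],
            hidden_dims=hidden_dims,
            latent_dim=latent_dim,
            use_bias=use_bias,
            seed=cfg.seed,
        )
    opt = ad.Adam(
        params.as_list(), learning_rate=cfg.learning_rate, weight_decay=cfg.weight_decay
    )
    history: list[LossReport] = []
    for _ in range(cfg.epochs):
        ad.zero_grads(params.as_list())
        t = _forward_t(params, data, attention_epsilon, use_normalized)
        total_t, report = _losses_t(params, data, t, cfg, use_normalized)
        if not np.isfinite(report.total):
            raise TrainingError(
                "total loss diverged (NaN/inf); try a lower learning rate"
            )
        ad.backward(total_t)
        opt.step()
        history.append(report)
    final = forward_pass(params, data, attention_epsilon, use_normalized)
    return params, final, history


class GraphAttentionAutoencoder(TransformerMixin, BaseEstimator):
    """Sklearn-style estimator around :func:`train`.

    ``fit`` takes a :class:`FusionInputs`; fitted attributes are ``params_``
    (trained tensors), ``latent_set_`` (all intermediate latents),
    ``embedding_`` (the final N x latent_dim fusion), and ``loss_history_``.
    ``transform`` re-runs the forward pass with fitted parameters.
    """

    def __init__(
        self,
        hidden_dims: tuple[int, ...] = DEFAULT_HIDDEN_DIMS,
        latent_dim: int = DEFAULT_LATENT_DIM,
        epochs: int = 200,
        learning_rate: float = 1e-3,
        weight_decay: float = 0.0,
        alpha1: float = 1.0,
        alpha2: float = 1.0,
        alpha3: float = 1.0,
        alpha4: float = 1.0,
        beta1: float = 1.0,
        beta2: float = 1.0,
        attention_epsilon: float = 1e-8,
        use_bias: bool = False,
        use_normalized: bool = True,
        random_state: int = 0,
    ) -> None:
        self.hidden_dims = hidden_dims
        self.latent_dim = latent_dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.alpha3 = alpha3
        self.alpha4 = alpha4
        self.beta1 = beta1
        self.beta2 = beta2
        self.attention_epsilon = attention_epsilon
        self.use_bias = use_bias
        self.use_normalized = use_normalized
        self.random_state = random_state

    def _loss_config(self) -> LossConfig:
        return LossConfig(
            alpha1=self.alpha1,
            alpha2=self.alpha2,
            alpha3=self.alpha3,
            alpha4=self.alpha4,
            beta1=self.beta1,
            beta2=self.beta2,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            epochs=self.epochs,
            seed=self.random_state,
        )

    def fit(self, X: FusionInputs, y=None) -> "GraphAttentionAutoencoder":
        self.params_, self.latent_set_, self.loss_history_ = train(
            X,
            self._loss_config(),
            hidden_dims=tuple(self.hidden_dims),
            latent_dim=self.latent_dim,
            attention_epsilon=self.attention_epsilon,
            use_bias=self.use_bias,
            use_normalized=self.use_normalized,
        )
        self.embedding_ = self.latent_set_.Emb_final
        return self

    def transform(self, X: FusionInputs | None = None) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise ValidationError("estimator is not fitted")
        if X is None:
            return self.embedding_
        return forward_pass(
            self.params_, X, self.attention_epsilon, self.use_normalized
        ).Emb_final

    def config_hash(self) -> str:
        payload = json.dumps(self.get_params(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save_checkpoint(self, path) -> None:
        if not hasattr(self, "params_"):
            raise ValidationError("estimator is not fitted")
        np.savez(path, __config_hash__=self.config_hash(), **self.params_.numpy())

    def load_checkpoint(self, path) -> "GraphAttentionAutoencoder":
        archive = np.load(path)
        params = ModelParams()
        for key in archive.files:
            if key == "__config_hash__":
                continue
            params.tensors[key] = ad.parameter(archive[key])
        self.params_ = params
        return self
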