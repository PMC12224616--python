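"""Loading, alignment, normalization, and PCA reduction of omics inputs.

Three on-disk layouts are accepted per modality:

``delimited``
    Comma- or tab-separated table, header row = feature names, first column =
    spot IDs.
``matrix_market``
    10x-style triplet layout: ``matrix.mtx`` (features x spots) with companion
    ``features.tsv`` and ``barcodes.tsv`` in the same directory.
``annotated_container``
    One ``.h5ad`` AnnData file per modality; spatial coordinates, when
    present, live in ``obsm["spatial"]``.

Coordinates on their own are a delimited file with columns ``spot_id,x,y``.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .containers import EmbeddingMatrix, OmicsMatrix, SpotCoordinates
from .errors import AlignmentError, FormatError, ValidationError

logger = logging.getLogger(__name__)

FORMATS = ("delimited", "matrix_market", "annotated_container")


def _sep_for(path: Path) -> str | None:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def load_modality(path: str | Path, format: str, modality_tag: str = "rna") -> OmicsMatrix:
    """Read one modality's spot x feature matrix from disk."""
    path = Path(path)
    if format not in FORMATS:
        raise ValidationError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FormatError(f"no such file: {path}")

    if format == "delimited":
        try:
            df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        except Exception as exc:  # pandas raises many flavours
            raise FormatError(f"could not parse delimited file {path}: {exc}") from exc
        values = df.to_numpy(dtype=np.float64)
        return OmicsMatrix(values, list(df.columns), list(df.index.astype(str)), modality_tag)

    if format == "matrix_market":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise FormatError(f"could not parse Matrix Market file {path}: {exc}") from exc
        feats_path = path.parent / "features.tsv"
        spots_path = path.parent / "barcodes.tsv"
        for p in (feats_path, spots_path):
            if not p.exists():
                raise FormatError(f"missing companion file {p}")
        feature_names = feats_path.read_text().split()
        spot_ids = spots_path.read_text().split()
        dense = np.asarray(sp.csr_matrix(mat).todense(), dtype=np.float64).T  # -> spot x feature
        if dense.shape != (len(spot_ids), len(feature_names)):
            raise FormatError(
                f"{path}: matrix is {mat.shape} (features x spots) but companions list "
                f"{len(feature_names)} features / {len(spot_ids)} barcodes"
            )
        return OmicsMatrix(dense, feature_names, spot_ids, modality_tag)

    # annotated_container
    import anndata as ad

    try:
        adata = ad.read_h5ad(path)
    except Exception as exc:
        raise FormatError(f"could not read annotated container {path}: {exc}") from exc
    X = adata.X
    values = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
    return OmicsMatrix(
        values, list(adata.var_names), list(adata.obs_names), modality_tag
    )


def load_coordinates(path: str | Path) -> SpotCoordinates:
    """Read a delimited ``spot_id,x,y`` coordinate table, or an ``.h5ad``
    container carrying ``obsm["spatial"]``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix == ".h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        if "spatial" not in adata.obsm:
            raise FormatError(f"{path} has no obsm['spatial'] field")
        return SpotCoordinates(np.asarray(adata.obsm["spatial"], float), list(adata.obs_names))
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:
        raise FormatError(f"could not parse coordinates {path}: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    for need in ("spot_id", "x", "y"):
        if need not in cols:
            raise FormatError(f"{path}: coordinate file needs columns spot_id,x,y")
    return SpotCoordinates(
        df[[cols["x"], cols["y"]]].to_numpy(float), list(df[cols["spot_id"]].astype(str))
    )


def align_spots(
    m1: OmicsMatrix, m2: OmicsMatrix, p: SpotCoordinates
) -> tuple[OmicsMatrix, OmicsMatrix, SpotCoordinates]:
    """Inner-join the two modalities and the coordinates on spot ID.

    Output ordering follows ``m1``; spots missing from any input are dropped
    with a logged count.
    """
    s1, s2, sp_ = set(m1.spot_ids), set(m2.spot_ids), set(p.spot_ids)
    shared = s1 & s2 & sp_
    if not shared:
        raise AlignmentError("no spot IDs shared by both modalities and the coordinates")
    keep = [s for s in m1.spot_ids if s in shared]
    dropped = (len(s1) - len(shared)) + (len(s2) - len(shared)) + (len(sp_) - len(shared))
    if dropped:
        logger.info("align_spots: dropped %d spot entries absent from some input", dropped)

    def take(values: np.ndarray, ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(ids)}
        return values[[pos[s] for s in keep]]

    out1 = OmicsMatrix(take(m1.values, m1.spot_ids), m1.feature_names, keep, m1.modality_tag)
    out2 = OmicsMatrix(take(m2.values, m2.spot_ids), m2.feature_names, keep, m2.modality_tag)
    outp = SpotCoordinates(take(p.coords, p.spot_ids), keep)
    assert out1.n_spots == out2.n_spots == outp.n_spots
    return out1, out2, outp


def normalize_modality(
    m: OmicsMatrix, method: str | None = None, target_sum: float | None = None
) -> OmicsMatrix:
    """Normalize one modality's counts.

    ``library_size_log1p`` scales each spot to a common library size
    (``target_sum``, default the median observed library) then applies
    log1p — the convention for RNA and ATAC counts. ``clr`` is the centered
    log-ratio across features within each spot, computed on log1p values —
    the convention for ADT counts. ``none`` passes values through.

    When ``method`` is None the modality's conventional default is used.
    """
    if method is None:
        method = "clr" if m.modality_tag == "adt" else "library_size_log1p"
    if method == "none":
        return OmicsMatrix(m.values.copy(), m.feature_names, m.spot_ids, m.modality_tag)
    m.check_counts()
    X = m.values
    if method == "library_size_log1p":
        lib = X.sum(axis=1)
        zero_rows = lib == 0
        if zero_rows.any():
            warnings.warn(
                f"{int(zero_rows.sum())} spot(s) have zero library size; left as zeros",
                stacklevel=2,
            )
        if target_sum is None:
            nz = lib[~zero_rows]
            target_sum = float(np.median(nz)) if nz.size else 1.0
        scale = np.where(zero_rows, 1.0, target_sum / np.where(zero_rows, 1.0, lib))
        out = np.log1p(X * scale[:, None])
    elif method == "clr":
        logged = np.log1p(X)
        out = logged - logged.mean(axis=1, keepdims=True)
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    if not np.all(np.isfinite(out)):
        raise ValidationError("normalization produced non-finite values")
    return OmicsMatrix(out, m.feature_names, m.spot_ids, m.modality_tag)


def select_hvf(m: OmicsMatrix, top_k: int) -> OmicsMatrix:
    """Keep the ``top_k`` highest-variance features (optional filter, off by
    default in the pipeline)."""
    if top_k >= m.n_features:
        return m
    var = m.values.var(axis=0)
    order = np.argsort(-var, kind="stable")[:top_k]
    order.sort()
    return OmicsMatrix(
        m.values[:, order],
        [m.feature_names[i] for i in order],
        m.spot_ids,
        m.modality_tag,
    )


def pca_reduce(m: OmicsMatrix, n_components: int, seed: int = 0) -> EmbeddingMatrix:
    """Project a (normalized) modality onto its top principal components.

    Components are sign-fixed so the largest-magnitude loading of each
    component is positive, making the output reproducible across runs and
    BLAS builds.
    """
    bound = min(m.n_spots, m.n_features)
    if not 1 <= n_components <= bound:
        raise ValidationError(
            f"n_components={n_components} outside [1, min(N, D)={bound}]"
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(m.values)
    flip = np.sign(
        pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    return EmbeddingMatrix(scores * flip, source_tag="pca")
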