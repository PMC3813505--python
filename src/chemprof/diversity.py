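"""Descriptor-space diversity comparison via PCA.

Libraries are compared in a common physico-chemical descriptor space
(default panel: MW, HBA, HBD, NCC, NO, NRB, log P, NR, TPSA).  Columns
are standardized to mean 0 and sample variance 1, then decomposed by
principal component analysis on the correlation structure; the first
three PC scores give the chemical-space picture a practitioner plots,
and the cumulative variance fraction quantifies how much structure those
three axes capture.

Sign convention: within each component, the largest-magnitude loading is
made positive, so exported scores are reproducible across runs and
platforms.  For two-library overlays the standardization and PCA are
fitted on the pooled matrix by default — fitting per library would place
the two clouds in incomparable coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .chemio import Library
from .vector import DescriptorVector

logger = logging.getLogger(__name__)

DEFAULT_PANEL = ("MW", "HBA", "HBD", "NCC", "NO", "NRB", "logP", "NR", "TPSA")


@dataclass
class DescriptorMatrix:
    """Records x descriptors value matrix with standardization bookkeeping."""

    data: pd.DataFrame  # index: record ids; columns: descriptor names
    column_means: pd.Series | None = None  # set by standardize()
    column_sds: pd.Series | None = None
    standardized: bool = False

    @property
    def n_records(self) -> int:
        return self.data.shape[0]

    @property
    def panel(self) -> tuple[str, ...]:
        return tuple(self.data.columns)


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # descriptors x components, orthonormal columns
    scores: pd.DataFrame  # records x components
    variance_fractions: np.ndarray  # descending eigenvalue shares
    n_components: int


def build_matrix(
    library: Library,
    descriptors: dict[str, DescriptorVector],
    panel: tuple[str, ...] = DEFAULT_PANEL,
    completion: str = "drop_record",
) -> DescriptorMatrix:
    """Assemble the descriptor matrix for a library.

    ``completion`` handles missing cells: ``drop_record`` removes
    incomplete rows, ``impute_mean`` fills each hole with the column mean
    of the complete values.  Fewer than 3 complete records is fatal.
    """
    if completion not in ("drop_record", "impute_mean"):
        raise ValueError(f"unknown completion policy {completion!r}")
    rows = {}
    for rec in library.records:
        dv = descriptors.get(rec.record_id, DescriptorVector())
        rows[rec.record_id] = [dv.get(d, np.nan) for d in panel]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(panel))
    n_incomplete = int(df.isna().any(axis=1).sum())
    if completion == "drop_record":
        df = df.dropna()
        if n_incomplete:
            logger.info("dropped %d incomplete record(s)", n_incomplete)
    else:
        df = df.fillna(df.mean())
        df = df.dropna()  # columns that were entirely missing stay NaN
        if n_incomplete:
            logger.info("imputed cells in %d record(s) with column means",
                        n_incomplete)
    if df.shape[0] < 3:
        raise ValueError(
            f"need at least 3 complete records for a descriptor matrix, "
            f"have {df.shape[0]}"
        )
    return DescriptorMatrix(data=df)


def standardize(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Center to mean 0 and scale to sample variance 1 (ddof = 1).

    Constant columns carry no comparative information and are dropped
    with a warning; if every column is constant that is fatal.
    """
    df = matrix.data
    means = df.mean()
    sds = df.std(ddof=1)
    constant = sds[(sds == 0) | sds.isna()].index.tolist()
    if constant:
        if len(constant) == df.shape[1]:
            raise ValueError("all columns are constant; nothing to standardize")
        logger.warning("dropping constant column(s): %s", ", ".join(constant))
        df = df.drop(columns=constant)
        means = means.drop(constant)
        sds = sds.drop(constant)
    out = (df - means) / sds
    return DescriptorMatrix(
        data=out, column_means=means, column_sds=sds, standardized=True
    )


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Flip components so each one's largest-|loading| entry is positive."""
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]


def pca(matrix: DescriptorMatrix, k: int | None = None) -> PCAResult:
    """PCA of a standardized descriptor matrix (correlation-matrix PCA).

    Components are ordered by decreasing eigenvalue; ``variance_fractions``
    are the eigenvalue shares of the total variance across *all* columns,
    so they sum to 1 when every component is kept.
    """
    if not matrix.standardized:
        raise ValueError("pca() expects a standardized matrix; call standardize()")
    n, p = matrix.data.shape
    if k is None:
        k = min(n - 1, p)
    if k > p:
        raise ValueError(f"k={k} exceeds the {p} available columns")
    if n <= p:
        logger.warning("only %d records for %d descriptors; PCA is ill-conditioned",
                       n, p)
    X = matrix.data.to_numpy()
    model = _SKPCA(n_components=min(n - 1, p), svd_solver="full")
    all_scores = model.fit_transform(X)
    loadings = model.components_.T.copy()  # p x m
    fractions = model.explained_variance_ratio_.copy()
    _fix_signs(loadings, all_scores)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        loadings=pd.DataFrame(
            loadings[:, :k], index=matrix.data.columns, columns=comp_names
        ),
        scores=pd.DataFrame(
            all_scores[:, :k], index=matrix.data.index, columns=comp_names
        ),
        variance_fractions=fractions[:k],
        n_components=k,
    )


def variance_explained(result: PCAResult, k: int) -> float:
    """Cumulative variance fraction of the first k retained components."""
    if k > result.n_components:
        raise ValueError(
            f"k={k} exceeds the {result.n_components} retained components"
        )
    return float(result.variance_fractions[:k].sum())


def overlay_scores(
    a: Library,
    b: Library,
    descriptors_a: dict[str, DescriptorVector],
    descriptors_b: dict[str, DescriptorVector],
    panel: tuple[str, ...] = DEFAULT_PANEL,
    k: int = 3,
    completion: str = "drop_record",
    standardization: str = "pooled",
    mahalanobis_radius: float = np.inf,
) -> dict:
    """Project two libraries into one PCA space and label the scores.

    Standardization and PCA are fitted on the pooled matrix (default) so
    both clouds share coordinates; ``standardization="per_library"``
    standardizes each library on its own moments before pooling.  Outliers
    per library are records whose Mahalanobis distance in PC space
    (score_j / sqrt(eigenvalue_j)) exceeds ``mahalanobis_radius``.
    """
    ma = build_matrix(a, descriptors_a, panel, completion)
    mb = build_matrix(b, descriptors_b, panel, completion)
    if ma.panel != mb.panel:
        raise ValueError(f"panel mismatch: {ma.panel} vs {mb.panel}")
    label_a = a.name or "A"
    label_b = b.name if (b.name and b.name != a.name) else "B"
    if standardization == "pooled":
        pooled = DescriptorMatrix(data=pd.concat([ma.data, mb.data]))
        std = standardize(pooled)
    elif standardization == "per_library":
        std = DescriptorMatrix(
            data=pd.concat([standardize(ma).data, standardize(mb).data]),
            standardized=True,
        )
    else:
        raise ValueError(f"unknown standardization {standardization!r}")
    result = pca(std, k=k)
    labels = [label_a] * ma.n_records + [label_b] * mb.n_records
    scores = result.scores.copy()
    scores.insert(0, "library", labels)
    scores.insert(0, "record_id", scores.index)
    scores = scores.reset_index(drop=True)

    # Mahalanobis distance in the retained-PC subspace
    ev = result.variance_fractions.copy()
    score_sd = result.scores.to_numpy().std(axis=0, ddof=1)
    score_sd[score_sd == 0] = 1.0
    d = np.sqrt(((result.scores.to_numpy() / score_sd) ** 2).sum(axis=1))
    outliers = {
        label_a: int((d[: ma.n_records] > mahalanobis_radius).sum()),
        label_b: int((d[ma.n_records :] > mahalanobis_radius).sum()),
    }
    return {
        "scores": scores,
        "loadings": result.loadings,
        "variance_fractions": ev,
        "outliers": outliers,
        "labels": (label_a, label_b),
    }


def export_scores(overlay: dict, scores_path, loadings_path=None) -> None:
    """Write the overlay score table (and optionally loadings + variance
    fractions) as tab-separated text."""
    overlay["scores"].to_csv(scores_path, sep="\t", index=False)
    if loadings_path is not None:
        df = overlay["loadings"].copy()
        df.loc["__variance_fraction__"] = overlay["variance_fractions"]
        df.to_csv(loadings_path, sep="\t")
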