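"""First-round correlation: score every single cell against every LCM reference.

Each cell's expression vector (default: logCPM over the genes shared with
the reference set) is correlated against every reference profile. A cell
that resembles, say, a vessel element yields its highest coefficients
against the vessel-element reference replicates. References are kept per
replicate — never averaged — so the second round can form replicate-level
groups for its between-type tests.

Spearman (Pearson on mid-ranks) is the default: it is invariant to
monotone transforms and robust to the mean–variance mismatch between bulk
and single-cell profiles. Pearson on logCPM is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .errors import ValidationError
from .matrix import GeneExpressionMatrix, LcmReferenceSet
from .preprocess import align_genes

log = logging.getLogger(__name__)

METHODS = ("pearson", "spearman")


def pearson_cross_correlation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlation of two observation matrices.

    ``x`` is (n_obs, p), ``y`` is (n_obs, q); returns a (p, q) coefficient
    matrix. Columns with zero variance give NaN (undefined correlation),
    which callers flag rather than coerce to a number.
    """
    if x.shape[0] != y.shape[0]:
        raise ValidationError("observation counts differ between the two sides")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xnorm = np.sqrt((xc**2).sum(axis=0))
    ynorm = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / np.outer(xnorm, ynorm)
    # clip numeric overshoot |r| = 1 + eps; leave NaN in place
    return np.clip(r, -1.0, 1.0)


def cross_correlation(x: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    """Pearson or Spearman (mid-rank) cross-correlation matrix."""
    if method not in METHODS:
        raise ValidationError(f"unknown correlation method {method!r}")
    if method == "spearman":
        x = rankdata(x, axis=0)
        y = rankdata(y, axis=0)
    return pearson_cross_correlation(np.asarray(x, float), np.asarray(y, float))


def correlation(x, y, method: str = "pearson") -> float:
    """Correlation coefficient of two vectors.

    Returns NaN — the undefined-correlation signal, distinct from a numeric
    error — when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    return float(cross_correlation(x[:, None], y[:, None], method)[0, 0])


@dataclass
class CellSimilarityTable:
    """Cells x reference-samples correlation coefficients.

    ``data`` rows are cell ids, columns reference sample ids; ``ref_meta``
    (indexed by sample id) carries ``cell_type`` and ``replicate``.
    Undefined coefficients (constant cell vectors) are NaN.
    """

    data: pd.DataFrame
    ref_meta: pd.DataFrame
    method: str
    n_genes_used: int

    @property
    def cell_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.ref_meta["cell_type"]))

    def columns_of_type(self, cell_type: str) -> list[str]:
        meta = self.ref_meta
        return meta.index[meta["cell_type"] == cell_type].tolist()

    def mean_by_type(self) -> pd.DataFrame:
        """Cells x cell-types mean coefficient (replicates averaged)."""
        return self.data.T.groupby(self.ref_meta["cell_type"], sort=False).mean().T

    def to_tsv(self, path: str | Path) -> None:
        """Write with a two-row header carrying cell_type and replicate."""
        out = self.data.copy()
        out.columns = pd.MultiIndex.from_arrays(
            [self.ref_meta["cell_type"], self.ref_meta["replicate"]],
            names=["cell_type", "replicate"],
        )
        out.rename_axis("cell").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, method: str = "unknown") -> "CellSimilarityTable":
        df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
        ctypes = df.columns.get_level_values(0).astype(str)
        reps = df.columns.get_level_values(1).astype(int)
        sample_ids = [f"{c}_r{r}" for c, r in zip(ctypes, reps)]
        data = df.set_axis(sample_ids, axis=1)
        meta = pd.DataFrame({"cell_type": ctypes, "replicate": reps}, index=sample_ids)
        return cls(data, meta, method=method, n_genes_used=-1)


class CellSimilarityScorer(BaseEstimator):
    """Score cells against a fitted LCM reference set (first-round correlation).

    Parameters
    ----------
    method : {"spearman", "pearson"}
        Correlation coefficient; Spearman by default.
    min_shared_genes : int
        Minimum size of the gene intersection between cells and references.
    gene_subset : collection of str or None
        Optional gene ids to restrict the correlation to (e.g. a
        variable-gene selection); default uses all aligned genes.
    top_n_variable : int or None
        If set, restrict to the N reference genes with highest variance
        across reference samples (computed on the fitted layer).

    Examples
    --------
    >>> scorer = CellSimilarityScorer(method="spearman").fit(refs)
    >>> sim = scorer.transform(cells)   # CellSimilarityTable
    """

    def __init__(
        self,
        method: str = "spearman",
        min_shared_genes: int = 50,
        gene_subset=None,
        top_n_variable: int | None = None,
    ):
        self.method = method
        self.min_shared_genes = min_shared_genes
        self.gene_subset = gene_subset
        self.top_n_variable = top_n_variable

    def fit(self, refs: LcmReferenceSet, y=None) -> "CellSimilarityScorer":
        if self.method not in METHODS:
            raise ValidationError(f"unknown correlation method {self.method!r}")
        if not isinstance(refs, LcmReferenceSet):
            raise ValidationError("fit expects an LcmReferenceSet")
        self.references_ = refs
        self.layer_ = refs.matrix.layer
        return self

    def transform(self, cells: GeneExpressionMatrix) -> CellSimilarityTable:
        if not hasattr(self, "references_"):
            raise NotFittedError("CellSimilarityScorer is not fitted")
        if not isinstance(cells, GeneExpressionMatrix):
            raise ValidationError("transform expects a GeneExpressionMatrix")
        refs = self.references_
        if cells.layer != self.layer_:
            raise ValidationError(
                f"layer mismatch: cells are {cells.layer!r}, references {self.layer_!r}"
            )
        cells_a, refs_a = align_genes(cells, refs.matrix)
        if self.gene_subset is not None:
            keep = sorted(set(self.gene_subset) & set(cells_a.gene_ids))
            if not keep:
                raise ValidationError("gene_subset shares no genes with aligned data")
            cells_a = GeneExpressionMatrix(cells_a.values.loc[keep], cells_a.layer)
            refs_a = GeneExpressionMatrix(refs_a.values.loc[keep], refs_a.layer)
        if self.top_n_variable is not None:
            var = refs_a.values.var(axis=1)
            keep = sorted(var.nlargest(int(self.top_n_variable)).index)
            cells_a = GeneExpressionMatrix(cells_a.values.loc[keep], cells_a.layer)
            refs_a = GeneExpressionMatrix(refs_a.values.loc[keep], refs_a.layer)
        n_genes = cells_a.n_genes
        if n_genes < self.min_shared_genes:
            raise ValidationError(
                f"only {n_genes} shared genes; need >= {self.min_shared_genes}"
            )
        coeffs = cross_correlation(
            cells_a.values.to_numpy(), refs_a.values.to_numpy(), self.method
        )
        n_undefined = int(np.isnan(coeffs).any(axis=1).sum())
        if n_undefined:
            log.warning(
                "%d cell(s) have a constant aligned expression vector; "
                "their coefficients are reported as missing", n_undefined,
            )
        data = pd.DataFrame(
            coeffs, index=cells_a.sample_ids, columns=refs.matrix.sample_ids
        )
        return CellSimilarityTable(
            data, refs.sample_meta.copy(), method=self.method, n_genes_used=n_genes
        )

    def fit_transform(self, refs: LcmReferenceSet, cells: GeneExpressionMatrix):
        return self.fit(refs).transform(cells)


def compute_cell_similarity(
    cells: GeneExpressionMatrix,
    refs: LcmReferenceSet,
    method: str = "spearman",
    gene_subset=None,
    min_shared_genes: int = 50,
    top_n_variable: int | None = None,
) -> CellSimilarityTable:
    """Functional wrapper over :class:`CellSimilarityScorer`."""
    scorer = CellSimilarityScorer(
        method=method,
        min_shared_genes=min_shared_genes,
        gene_subset=gene_subset,
        top_n_variable=top_n_variable,
    )
    return scorer.fit(refs).transform(cells)
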