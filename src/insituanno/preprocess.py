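"""Normalization, gene-space alignment, and expressed-gene detection.

All correlation stages in this package operate, by default, on logCPM
(``log2(counts-per-million + 1)``): column scaling removes library-size
differences between single cells and bulk profiles, and the log transform
stabilizes the variance of highly expressed genes so that correlations are
not dominated by a handful of abundant transcripts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import GeneExpressionMatrix

log = logging.getLogger(__name__)


def normalize(m: GeneExpressionMatrix, method: str = "logcpm") -> GeneExpressionMatrix:
    """Scale columns to counts-per-million, optionally log-transform.

    ``cpm`` scales every column to a total of 1e6; ``logcpm`` additionally
    applies ``log2(x + 1)``. Columns with a zero total carry no information
    and are dropped with a logged warning.

    Input must be on the ``raw`` (integer counts) or ``linear``
    (continuous bulk) layer.
    """
    if method not in ("cpm", "logcpm"):
        raise ValidationError(f"unknown normalization method {method!r}")
    if m.layer not in ("raw", "linear"):
        raise ValidationError(
            f"normalize expects a raw or linear layer, got {m.layer!r}"
        )
    values = m.values
    sums = values.sum(axis=0)
    zero = sums == 0
    if zero.any():
        dropped = values.columns[zero].tolist()
        log.warning(
            "dropping %d zero-total column(s): %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
        values = values.loc[:, ~zero]
        sums = sums[~zero]
    cpm = values.div(sums, axis=1) * 1e6
    if method == "cpm":
        return GeneExpressionMatrix(cpm, layer="cpm")
    return GeneExpressionMatrix(np.log2(cpm + 1.0), layer="logcpm")


def align_genes(
    a: GeneExpressionMatrix, b: GeneExpressionMatrix
) -> tuple[GeneExpressionMatrix, GeneExpressionMatrix]:
    """Restrict both matrices to their shared genes, rows sorted lexicographically.

    Gene ids are matched by exact, case-sensitive string equality; silent
    fuzzy matching across gene-model namespaces is dangerous.
    """
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise ValidationError("no shared genes between the two matrices")
    log.info("align_genes: %d shared genes (a=%d, b=%d)", len(shared), a.n_genes, b.n_genes)
    return (
        GeneExpressionMatrix(a.values.loc[shared], a.layer),
        GeneExpressionMatrix(b.values.loc[shared], b.layer),
    )


def detect_expressed_genes(
    m: GeneExpressionMatrix, min_count: int = 1, min_samples: int = 1
) -> set[str]:
    """Genes with value >= ``min_count`` in >= ``min_samples`` columns.

    Operates on raw counts; the thresholds define what "expressed" means
    for the dataset-overlap comparison.
    """
    if m.layer != "raw":
        raise ValidationError("detect_expressed_genes expects raw counts")
    if min_count < 1 or min_samples < 1:
        raise ValidationError("min_count and min_samples must be >= 1")
    prevalence = (m.values >= min_count).sum(axis=1)
    return set(m.values.index[prevalence >= min_samples])
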