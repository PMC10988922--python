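"""In-memory containers for expression data.

The central object is :class:`GeneExpressionMatrix`, a genes-by-samples table
with an explicit *layer* tag recording what the values mean:

``raw``
    integer sequencing counts (single-cell UMI counts or bulk read counts);
``linear``
    continuous non-negative values on a linear scale with arbitrary units
    (e.g. laser-capture-microdissection reference profiles);
``cpm``
    counts per million — every non-empty column sums to 1e6;
``logcpm``
    ``log2(cpm + 1)``.

Keeping the tag on the object lets downstream correlation stages refuse to
mix incompatible layers instead of silently correlating counts with
log-space values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

LAYERS = ("raw", "linear", "cpm", "logcpm")

#: default cell-type names for the three-type differentiating-xylem design
DEFAULT_TYPE_NAMES = ("fiber", "vessel", "ray")


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} id(s): {dup[:5]}")


@dataclass
class GeneExpressionMatrix:
    """Genes x samples expression values with a layer tag.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample (cell or bulk) ids
        as columns. Gene and sample ids must be unique.
    layer
        One of ``raw``, ``linear``, ``cpm``, ``logcpm``.
    """

    values: pd.DataFrame
    layer: str = "raw"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        if self.layer not in LAYERS:
            raise ValidationError(
                f"unknown layer {self.layer!r}; expected one of {LAYERS}"
            )
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if arr.size and arr.min() < 0:
            raise ValidationError("expression values must be non-negative")
        if self.layer == "raw" and arr.size and not np.allclose(arr, np.round(arr)):
            raise ValidationError("layer 'raw' requires integer counts")
        if self.layer == "cpm" and arr.size:
            sums = arr.sum(axis=0)
            ok = np.isclose(sums, 1e6, rtol=1e-6) | (sums == 0)
            if not ok.all():
                bad = self.values.columns[~ok].tolist()
                raise ValidationError(f"cpm columns not summing to 1e6: {bad[:5]}")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "GeneExpressionMatrix":
        return GeneExpressionMatrix(self.values.copy(), self.layer)

    def equals(self, other: "GeneExpressionMatrix") -> bool:
        return self.layer == other.layer and self.values.equals(other.values)


@dataclass
class LcmReferenceSet:
    """Bulk reference profiles, one column per (cell type, replicate).

    ``sample_meta`` is indexed by sample id with columns ``cell_type`` and
    ``replicate`` (integer, unique within a type).
    """

    matrix: GeneExpressionMatrix
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        meta = self.sample_meta
        required = {"cell_type", "replicate"}
        if not required.issubset(meta.columns):
            raise ValidationError(
                f"sample_meta needs columns {sorted(required)}, got {list(meta.columns)}"
            )
        if list(meta.index) != self.matrix.sample_ids:
            raise ValidationError("sample_meta index must match matrix sample ids")
        for ctype, grp in meta.groupby("cell_type"):
            if grp["replicate"].duplicated().any():
                raise ValidationError(
                    f"replicate indices not unique within cell type {ctype!r}"
                )

    @property
    def cell_types(self) -> list[str]:
        # preserve first-appearance order
        return list(dict.fromkeys(self.sample_meta["cell_type"]))

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    def samples_of_type(self, cell_type: str) -> list[str]:
        meta = self.sample_meta
        return meta.index[meta["cell_type"] == cell_type].tolist()

    def with_matrix(self, matrix: GeneExpressionMatrix) -> "LcmReferenceSet":
        """Same metadata, new matrix (e.g. after normalization)."""
        return LcmReferenceSet(matrix, self.sample_meta.copy())


@dataclass
class MarkerCatalog:
    """Claimed marker genes: gene id, claimed cell type, source study label."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "claimed_type", "source"])
    )

    def __post_init__(self) -> None:
        required = ["gene", "claimed_type", "source"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"marker catalog missing columns {missing}")
        self.table = self.table[required].reset_index(drop=True)
        for source, grp in self.table.groupby("source"):
            if grp["gene"].duplicated().any():
                dup = grp.loc[grp["gene"].duplicated(), "gene"].tolist()
                raise ValidationError(
                    f"duplicate marker gene(s) within source {source!r}: {dup[:5]}"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    @property
    def sources(self) -> list[str]:
        return list(dict.fromkeys(self.table["source"]))

    def check_types(self, known_types: list[str]) -> None:
        """Every claimed type must exist among the reference cell types."""
        unknown = sorted(set(self.table["claimed_type"]) - set(known_types))
        if unknown:
            raise ValidationError(
                f"claimed_type(s) {unknown} not present in reference cell types "
                f"{list(known_types)}"
            )
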