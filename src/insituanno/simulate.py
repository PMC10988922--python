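"""Synthetic paired LCM-reference / single-cell datasets with planted truth.

The generator emulates the study design the validation procedure was built
for: a small number of transcriptionally distinct cell types (default three,
the differentiating-xylem types fiber / vessel / ray), a handful of bulk
reference profiles per type obtained by cell-type-pure microdissection
(default three replicates per type), and a single-cell count matrix drawn
from the same type mean profiles.

Model
-----
* Baseline gene means are lognormal: ``exp(N(0, base_mean_log_sd))`` per
  gene, shared by all types.
* Each type's mean profile equals the baseline except at its own planted
  marker genes, which are multiplied by ``2**log2_fold_change``. Marker
  sets of different types are disjoint, so the planted log2 fold change is
  exactly the expected log-scale difference between a marker's own type
  and every other type.
* LCM replicates multiply the type mean profile gene-wise by lognormal
  noise ``exp(N(0, replicate_noise_sd))`` — multiplicative measurement
  noise on a bulk profile.
* Single-cell counts are negative binomial with mean
  ``mean_depth * profile / profile.sum()`` and a gene-shared dispersion
  ``a`` (variance ``mu + a * mu**2``), the standard overdispersed count
  model for scRNA-seq UMI data. Per-cell depth is held at ``mean_depth``
  so that planted effects are not diluted by library-size variation.

Every operation takes an integer seed and is bit-reproducible; the
convenience wrapper :func:`simulate_dataset` derives one sub-seed per stage
from its single seed, in a fixed order (truth, references, cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import (
    DEFAULT_TYPE_NAMES,
    GeneExpressionMatrix,
    LcmReferenceSet,
    MarkerCatalog,
)
from . import io

SYNTHETIC_SOURCE = "synthetic"


def _type_names(n_types: int) -> list[str]:
    if n_types <= len(DEFAULT_TYPE_NAMES):
        return list(DEFAULT_TYPE_NAMES[:n_types])
    extra = [f"type{k}" for k in range(len(DEFAULT_TYPE_NAMES) + 1, n_types + 1)]
    return list(DEFAULT_TYPE_NAMES) + extra


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment.

    ``type_mean_profile`` is a genes x types DataFrame of expected linear-
    scale expression; ``marker_table`` has one row per planted marker with
    columns ``gene``, ``true_type``, ``log2_fold_change``.
    """

    type_mean_profile: pd.DataFrame
    marker_table: pd.DataFrame
    seed: int

    @property
    def gene_ids(self) -> list[str]:
        return self.type_mean_profile.index.tolist()

    @property
    def type_names(self) -> list[str]:
        return self.type_mean_profile.columns.tolist()

    @property
    def n_types(self) -> int:
        return self.type_mean_profile.shape[1]

    def marker_catalog(self, source: str = SYNTHETIC_SOURCE) -> MarkerCatalog:
        """The planted markers as a claimed-marker catalog (all claims true)."""
        df = pd.DataFrame(
            {
                "gene": self.marker_table["gene"],
                "claimed_type": self.marker_table["true_type"],
                "source": source,
            }
        )
        return MarkerCatalog(df)


def simulate_truth(
    n_types: int = 3,
    n_genes: int = 2000,
    markers_per_type: int = 20,
    log2_fold_change: float = 3.0,
    base_mean_log_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw baseline gene means and plant disjoint marker sets per type."""
    if n_types < 2:
        raise ValidationError("n_types must be >= 2")
    if markers_per_type < 0:
        raise ValidationError("markers_per_type must be >= 0")
    if log2_fold_change < 0:
        raise ValidationError("log2_fold_change must be >= 0")
    if base_mean_log_sd < 0:
        raise ValidationError("base_mean_log_sd must be >= 0")
    n_markers = n_types * markers_per_type
    if n_genes < n_markers:
        raise ValidationError(
            f"n_genes={n_genes} too small for {n_markers} requested markers"
        )
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    types = _type_names(n_types)
    baseline = rng.lognormal(mean=0.0, sigma=base_mean_log_sd, size=n_genes)
    profile = pd.DataFrame(
        np.tile(baseline[:, None], (1, n_types)), index=gene_ids, columns=types
    )
    marker_genes = rng.choice(n_genes, size=n_markers, replace=False)
    rows = []
    fold = 2.0 ** log2_fold_change
    for t_idx, ctype in enumerate(types):
        for g_idx in marker_genes[t_idx * markers_per_type:(t_idx + 1) * markers_per_type]:
            gene = gene_ids[g_idx]
            profile.loc[gene, ctype] = baseline[g_idx] * fold
            rows.append(
                {"gene": gene, "true_type": ctype, "log2_fold_change": log2_fold_change}
            )
    marker_table = pd.DataFrame(rows, columns=["gene", "true_type", "log2_fold_change"])
    return SyntheticTruth(profile, marker_table, seed)


def simulate_lcm_references(
    truth: SyntheticTruth,
    n_replicates: int = 3,
    replicate_noise_sd: float = 0.2,
    seed: int = 0,
) -> LcmReferenceSet:
    """Replicate bulk profiles per type: mean profile x lognormal noise."""
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if replicate_noise_sd < 0:
        raise ValidationError("replicate_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_genes = len(truth.gene_ids)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for ctype in truth.type_names:
        mean = truth.type_mean_profile[ctype].to_numpy()
        for rep in range(1, n_replicates + 1):
            noise = rng.lognormal(mean=0.0, sigma=replicate_noise_sd, size=n_genes)
            sid = f"{ctype}_r{rep}"
            cols[sid] = mean * noise
            meta_rows.append({"cell_type": ctype, "replicate": rep})
    values = pd.DataFrame(cols, index=truth.gene_ids)
    meta = pd.DataFrame(meta_rows, index=list(cols))
    return LcmReferenceSet(GeneExpressionMatrix(values, layer="linear"), meta)


def simulate_cells(
    truth: SyntheticTruth,
    cells_per_type: int = 300,
    mean_depth: float = 5000.0,
    nb_dispersion: float = 0.5,
    seed: int = 0,
) -> tuple[GeneExpressionMatrix, pd.Series]:
    """Draw negative-binomial counts per cell; returns (counts, true labels).

    For a cell of type ``T`` the per-gene mean is ``mean_depth`` times the
    type mean profile normalized to sum 1, so the expected library size of
    every cell is exactly ``mean_depth``.
    """
    if cells_per_type < 1:
        raise ValidationError("cells_per_type must be >= 1")
    if mean_depth <= 0:
        raise ValidationError("mean_depth must be > 0")
    if nb_dispersion <= 0:
        raise ValidationError("nb_dispersion must be > 0")
    rng = np.random.default_rng(seed)
    size_param = 1.0 / nb_dispersion  # NB 'number of failures' parameter
    blocks, labels, cell_ids = [], [], []
    for ctype in truth.type_names:
        profile = truth.type_mean_profile[ctype].to_numpy()
        mu = mean_depth * profile / profile.sum()
        p = size_param / (size_param + mu)
        counts = rng.negative_binomial(
            size_param, p[:, None], size=(len(mu), cells_per_type)
        )
        blocks.append(counts)
        labels.extend([ctype] * cells_per_type)
        cell_ids.extend(f"{ctype}_cell{i:04d}" for i in range(1, cells_per_type + 1))
    values = pd.DataFrame(
        np.hstack(blocks), index=truth.gene_ids, columns=cell_ids
    )
    cells = GeneExpressionMatrix(values, layer="raw")
    return cells, pd.Series(labels, index=cell_ids, name="true_type")


def write_synthetic_dataset(
    truth: SyntheticTruth,
    refs: LcmReferenceSet,
    cells: GeneExpressionMatrix,
    cell_labels: pd.Series,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the full dataset: MTX triplet, references TSV, markers TSV, truth TSV.

    Round-trips losslessly through the package readers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_mtx_triplet(cells, out_dir)
    paths = {
        "matrix": out_dir / io.MTX_NAME,
        "features": out_dir / io.FEATURES_NAME,
        "barcodes": out_dir / io.BARCODES_NAME,
        "references": out_dir / "lcm_references.tsv",
        "markers": out_dir / "markers.tsv",
        "truth": out_dir / "truth.tsv",
    }
    io.write_lcm_references(refs, paths["references"])
    io.write_marker_catalog(truth.marker_catalog(), paths["markers"])
    cell_labels.rename_axis("cell").to_frame().to_csv(paths["truth"], sep="\t")
    return paths


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    truth: SyntheticTruth
    references: LcmReferenceSet
    cells: GeneExpressionMatrix
    cell_labels: pd.Series


def simulate_dataset(
    n_types: int = 3,
    n_genes: int = 2000,
    markers_per_type: int = 20,
    log2_fold_change: float = 3.0,
    base_mean_log_sd: float = 1.0,
    n_replicates: int = 3,
    replicate_noise_sd: float = 0.2,
    cells_per_type: int = 300,
    mean_depth: float = 5000.0,
    nb_dispersion: float = 0.5,
    seed: int = 0,
) -> SyntheticDataset:
    """One-call simulation of truth, LCM references and single cells.

    Sub-seeds for the three stages are derived from ``seed`` in a fixed
    order, so the whole dataset is reproducible from the one integer.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)
    truth = simulate_truth(
        n_types=n_types,
        n_genes=n_genes,
        markers_per_type=markers_per_type,
        log2_fold_change=log2_fold_change,
        base_mean_log_sd=base_mean_log_sd,
        seed=int(sub[0]),
    )
    refs = simulate_lcm_references(
        truth,
        n_replicates=n_replicates,
        replicate_noise_sd=replicate_noise_sd,
        seed=int(sub[1]),
    )
    cells, labels = simulate_cells(
        truth,
        cells_per_type=cells_per_type,
        mean_depth=mean_depth,
        nb_dispersion=nb_dispersion,
        seed=int(sub[2]),
    )
    return SyntheticDataset(truth, refs, cells, labels)
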