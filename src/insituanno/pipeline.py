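"""End-to-end orchestration: config in, TSV/JSON/report out.

A single declarative config (YAML file or plain dict) names either input
files or a ``simulate`` block, plus analysis options. Every option —
including defaults the user never touched — is echoed into
``run_log.json`` so no analysis choice is silent, and all randomness flows
from the seeds recorded there, making reruns byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .concordance import MarkerConcordance
from .errors import ComputeError, InsituAnnoError, ValidationError
from .matrix import GeneExpressionMatrix, LcmReferenceSet, MarkerCatalog
from .overlap import expressed_gene_overlap
from .preprocess import normalize
from .similarity import CellSimilarityScorer
from .simulate import simulate_dataset
from .stats import significance_stars

log = logging.getLogger(__name__)

DEFAULT_OPTIONS = {
    "layer": "logcpm",           # working layer for both correlation rounds
    "method": "spearman",        # first-round correlation
    "second_round_method": "spearman",
    "min_shared_genes": 50,
    "top_n_variable": None,
    "alpha": 0.05,
    "test": "student",
    "comparison": "pairwise",
    "replicate_mode": "per_replicate",
    "bh": False,
    "min_count": 1,              # expressed-gene detection for overlap
    "min_samples": 1,
}

DEFAULT_SIMULATE = {
    "n_types": 3,
    "n_genes": 2000,
    "markers_per_type": 20,
    "log2_fold_change": 3.0,
    "base_mean_log_sd": 1.0,
    "n_replicates": 3,
    "replicate_noise_sd": 0.2,
    "cells_per_type": 300,
    "mean_depth": 5000.0,
    "nb_dispersion": 0.5,
    "seed": 0,
}


def load_config(config) -> dict:
    """Accept a dict or a YAML file path."""
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        with open(path) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValidationError("config must be a mapping")
    return config


def _resolve(config: dict) -> dict:
    """Merge defaults and validate the config shape before any compute."""
    cfg = dict(config)
    options = {**DEFAULT_OPTIONS, **(cfg.get("options") or {})}
    unknown = set(options) - set(DEFAULT_OPTIONS)
    if unknown:
        raise ValidationError(f"unknown option(s): {sorted(unknown)}")
    resolved = {
        "out_dir": cfg.get("out_dir"),
        "options": options,
        "simulate": None,
        "inputs": None,
        "compare_to": cfg.get("compare_to"),
        "compare_to_seed": cfg.get("compare_to_seed"),
    }
    if "simulate" in cfg and cfg["simulate"] is not None:
        sim = {**DEFAULT_SIMULATE, **(cfg["simulate"] or {})}
        unknown = set(sim) - set(DEFAULT_SIMULATE)
        if unknown:
            raise ValidationError(f"unknown simulate option(s): {sorted(unknown)}")
        resolved["simulate"] = sim
    else:
        inputs = cfg.get("inputs") or {}
        for key in ("cells", "references", "markers"):
            if key not in inputs:
                raise ValidationError(
                    f"config must provide a 'simulate' block or inputs.{key}"
                )
        resolved["inputs"] = {
            "cells": str(inputs["cells"]),
            "references": str(inputs["references"]),
            "markers": str(inputs["markers"]),
            "transpose": bool(inputs.get("transpose", False)),
        }
    if resolved["out_dir"] is None:
        raise ValidationError("config must provide out_dir")
    return resolved


def _load_inputs(resolved) -> tuple[GeneExpressionMatrix, LcmReferenceSet, MarkerCatalog]:
    if resolved["simulate"] is not None:
        ds = simulate_dataset(**resolved["simulate"])
        return ds.cells, ds.references, ds.truth.marker_catalog()
    inputs = resolved["inputs"]
    cells = io.read_matrix(inputs["cells"], transpose=inputs["transpose"])
    refs = io.read_lcm_references(inputs["references"])
    catalog = io.read_marker_catalog(inputs["markers"])
    return cells, refs, catalog


def _to_layer(m: GeneExpressionMatrix, layer: str) -> GeneExpressionMatrix:
    if layer == m.layer:
        return m
    if layer in ("cpm", "logcpm"):
        return normalize(m, method=layer)
    raise ValidationError(
        f"cannot convert layer {m.layer!r} to requested working layer {layer!r}"
    )


def _concordance_wide(est: MarkerConcordance) -> pd.DataFrame:
    """One row per marker: mean r per type, replicate r's, p + stars vs others."""
    types = est.cell_types_
    wide = est.calls_.copy()
    mean_r = est.mean_r_.rename(columns={t: f"mean_r_{t}" for t in types})
    wide = wide.merge(mean_r, on=["gene", "source"], how="left")
    rep_cols = [c for c in est.correlations_.columns if c not in ("gene", "source")]
    reps = est.correlations_.rename(columns={c: f"r_{c}" for c in rep_cols})
    wide = wide.merge(reps, on=["gene", "source"], how="left")
    if len(est.tests_):
        for col, name in (("p", "p_vs"), ("stars", "stars_vs")):
            piv = est.tests_.pivot_table(
                index=["gene", "source"], columns="type_b", values=col,
                aggfunc="first",
            ).rename(columns=lambda t: f"{name}_{t}")
            wide = wide.merge(piv.reset_index(), on=["gene", "source"], how="left")
    return wide


def write_text_report(
    summary: pd.DataFrame,
    calls: pd.DataFrame,
    tests: pd.DataFrame,
    overlap_results: list | None = None,
    path: str | Path | None = None,
) -> str:
    """Human-readable per-source tables: claimed vs called type with stars."""
    lines = ["Marker concordance report", "=" * 25, ""]
    if not len(calls):
        lines.append("no markers evaluated")
    for source in list(dict.fromkeys(calls["source"])) if len(calls) else []:
        sub = calls[calls["source"] == source]
        lines.append(f"Source: {source}")
        lines.append("-" * (8 + len(str(source))))
        header = f"{'gene':<16}{'claimed':<12}{'called':<20}{'status':<11}{'consistent':<11}comparisons"
        lines.append(header)
        for _, row in sub.iterrows():
            gene_tests = tests[(tests["gene"] == row["gene"]) & (tests["source"] == source)] if len(tests) else tests
            stars = ",".join(
                f"{r['type_a']}>{r['type_b']}:{significance_stars(r['p'])}"
                for _, r in gene_tests.iterrows()
            )
            called = row["call_set"] if row["status"] == "ambiguous" else (row["call"] or "-")
            lines.append(
                f"{row['gene']:<16}{row['claimed_type']:<12}{called:<20}"
                f"{row['status']:<11}{str(row['consistent']):<11}{stars}"
            )
        lines.append("")
    if len(summary):
        lines.append("Summary by source")
        lines.append("-" * 17)
        lines.append(summary.to_string(index=False))
        lines.append("")
    for res in overlap_results or []:
        lines.append(
            f"Expressed-gene overlap ({res.metric}): {res.value:.4f} "
            f"(|A|={res.n_genes_a}, |B|={res.n_genes_b}, "
            f"|A∩B|={res.n_intersection}, min_count={res.min_count}, "
            f"min_samples={res.min_samples})"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def analyze(
    cells_raw: GeneExpressionMatrix,
    refs: LcmReferenceSet,
    catalog: MarkerCatalog,
    **options,
):
    """In-memory pipeline: normalize, score, and evaluate a marker catalog.

    Returns ``(similarity_table, fitted MarkerConcordance)``. Accepts the
    same keys as the config ``options`` block.
    """
    opts = {**DEFAULT_OPTIONS, **options}
    unknown = set(opts) - set(DEFAULT_OPTIONS)
    if unknown:
        raise ValidationError(f"unknown option(s): {sorted(unknown)}")
    cells = _to_layer(cells_raw, opts["layer"])
    refs_n = refs.with_matrix(_to_layer(refs.matrix, opts["layer"]))
    sim = CellSimilarityScorer(
        method=opts["method"],
        min_shared_genes=opts["min_shared_genes"],
        top_n_variable=opts["top_n_variable"],
    ).fit(refs_n).transform(cells)
    est = MarkerConcordance(
        method=opts["second_round_method"],
        test=opts["test"],
        alpha=opts["alpha"],
        comparison=opts["comparison"],
        replicate_mode=opts["replicate_mode"],
        bh=opts["bh"],
    ).fit(cells, sim, catalog)
    return sim, est


def run_pipeline(config, out_dir: str | Path | None = None) -> Path:
    """Execute preprocess -> similarity -> concordance (-> overlap); write outputs.

    Returns the output directory. On failure a ``MANIFEST`` file marking
    the run incomplete is left behind and the stage error propagates.
    """
    cfg = load_config(config)
    if out_dir is not None:
        cfg = {**cfg, "out_dir": str(out_dir)}
    resolved = _resolve(cfg)
    out = Path(resolved["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"status": "incomplete", "outputs": []}
    stage = "setup"

    def _done(name: str) -> None:
        manifest["outputs"].append(name)

    try:
        stage = "load"
        cells_raw, refs, catalog = _load_inputs(resolved)
        opts = resolved["options"]

        stage = "normalize"
        layer = opts["layer"]
        cells = _to_layer(cells_raw, layer)
        refs_n = refs.with_matrix(_to_layer(refs.matrix, layer))

        stage = "similarity"
        scorer = CellSimilarityScorer(
            method=opts["method"],
            min_shared_genes=opts["min_shared_genes"],
            top_n_variable=opts["top_n_variable"],
        ).fit(refs_n)
        sim = scorer.transform(cells)
        sim.to_tsv(out / "similarity.tsv")
        _done("similarity.tsv")

        stage = "concordance"
        est = MarkerConcordance(
            method=opts["second_round_method"],
            test=opts["test"],
            alpha=opts["alpha"],
            comparison=opts["comparison"],
            replicate_mode=opts["replicate_mode"],
            bh=opts["bh"],
        ).fit(cells, sim, catalog)
        _concordance_wide(est).to_csv(out / "concordance.tsv", sep="\t", index=False)
        _done("concordance.tsv")
        est.summary_.to_csv(out / "summary_by_source.tsv", sep="\t", index=False)
        _done("summary_by_source.tsv")

        stage = "overlap"
        overlap_results = []
        other = None
        if resolved["compare_to"] is not None:
            other = io.read_matrix(resolved["compare_to"])
        elif resolved["compare_to_seed"] is not None and resolved["simulate"] is not None:
            sim_cfg = {**resolved["simulate"], "seed": int(resolved["compare_to_seed"])}
            other = simulate_dataset(**sim_cfg).cells
        if other is not None:
            if cells_raw.layer != "raw":
                raise ValidationError("overlap requires raw counts on both sides")
            for metric in ("min_denominator", "jaccard"):
                overlap_results.append(
                    expressed_gene_overlap(
                        cells_raw, other, metric=metric,
                        min_count=opts["min_count"], min_samples=opts["min_samples"],
                    )
                )
            pd.DataFrame([r.as_dict() for r in overlap_results]).to_csv(
                out / "overlap.tsv", sep="\t", index=False
            )
            _done("overlap.tsv")

        stage = "report"
        run_log = {
            "options": opts,
            "simulate": resolved["simulate"],
            "inputs": resolved["inputs"],
            "compare_to": resolved["compare_to"],
            "compare_to_seed": resolved["compare_to_seed"],
            "n_cells": cells.n_samples,
            "n_reference_samples": refs.n_samples,
            "n_genes_used": sim.n_genes_used,
            "n_markers_evaluated": int(len(est.calls_)),
            "n_markers_skipped": int(len(est.skipped_)),
            "note": "overlap is computed over detected gene sets, not cell barcodes",
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
        _done("run_log.json")
        write_text_report(
            est.summary_, est.calls_, est.tests_, overlap_results,
            path=out / "report.txt",
        )
        _done("report.txt")

        manifest["status"] = "complete"
        return out
    except InsituAnnoError as err:
        raise type(err)(f"[stage: {stage}] {err}") from err
    except Exception as err:  # pragma: no cover - defensive
        raise ComputeError(f"[stage: {stage}] {err}") from err
    finally:
        (out / "MANIFEST").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
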