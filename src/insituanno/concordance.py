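"""Second-round correlation, between-type tests, marker calls, consistency.

Given the first-round similarity table (cells x LCM reference samples) and
the expression of each claimed marker gene across the same cells, the
second round asks: *do cells that express this marker also resemble the
cell type the marker supposedly labels?* For marker ``g`` and reference
sample ``s``,

    r(g, s) = corr over cells( expression of g, similarity to s )

A genuine fiber marker has high ``r`` against every fiber replicate and
low ``r`` against vessel and ray replicates. The replicate-level ``r``
values (three per type in the default design) form the groups for a
two-sample Student's t-test between types, and the resulting p-values are
rendered with the asterisk convention (``p < 0.05/0.01/0.001``, strict).

The marker's **call** is the set of cell types it actually annotates:
starting from the type with the highest mean ``r`` (required positive),
every type not significantly below it is included; a singleton set is a
unique call, a larger set an ambiguous one, a non-positive maximum no call
at all. A marker is **consistent** only when its unique call equals its
claimed type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .errors import ValidationError
from .matrix import GeneExpressionMatrix, MarkerCatalog
from .similarity import METHODS, CellSimilarityTable, cross_correlation
from .stats import bh_adjust, significance_stars, two_sample_ttest

log = logging.getLogger(__name__)

CALL_STATUSES = ("unique", "ambiguous", "none", "skipped")


@dataclass
class MarkerCall:
    """Outcome of the call rule for one marker."""

    status: str  # unique | ambiguous | none
    call_set: tuple[str, ...]  # empty for "none"

    @property
    def call(self) -> str | None:
        """The called type when unique, else None."""
        return self.call_set[0] if self.status == "unique" else None


def call_marker_type(
    per_type_r: dict[str, np.ndarray],
    alpha: float = 0.05,
    variant: str = "student",
    comparison: str = "pairwise",
) -> MarkerCall:
    """Decide which cell type(s) a marker annotates.

    ``per_type_r`` maps each cell type to its replicate-level second-round
    correlations (>= 2 replicates each). The type with maximal mean r
    anchors the call; with a non-positive maximum the marker annotates
    nothing ("none"). Otherwise every type whose replicate values are not
    significantly below the anchor (two-sided p >= ``alpha``) joins the
    call set; exact mean ties always join (ambiguity, never order, breaks
    ties). ``comparison="pooled"`` tests the anchor against all other
    types' replicates pooled into one group.
    """
    if len(per_type_r) < 2:
        raise ValidationError("need at least 2 cell types to call a marker")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    if comparison not in ("pairwise", "pooled"):
        raise ValidationError(f"unknown comparison mode {comparison!r}")
    groups = {t: np.asarray(v, dtype=float) for t, v in per_type_r.items()}
    for t, v in groups.items():
        if v.size < 2:
            raise ValidationError(f"cell type {t!r} has < 2 replicate values")
        if np.isnan(v).any():
            raise ValidationError(f"cell type {t!r} has undefined correlations")
    means = {t: float(v.mean()) for t, v in groups.items()}
    max_mean = max(means.values())
    if max_mean <= 0.0:
        return MarkerCall("none", ())
    tied = [t for t, m in means.items() if m == max_mean]
    anchor = tied[0]
    call_set = list(tied)
    others = [t for t in groups if t not in tied]
    if comparison == "pooled" and others:
        pooled = np.concatenate([groups[t] for t in others])
        _, p = two_sample_ttest(groups[anchor], pooled, variant=variant)
        if p >= alpha:
            call_set.extend(others)
    else:
        for t in others:
            _, p = two_sample_ttest(groups[anchor], groups[t], variant=variant)
            if p >= alpha:
                call_set.append(t)
    # preserve the type order of the input mapping
    ordered = tuple(t for t in groups if t in set(call_set))
    status = "unique" if len(ordered) == 1 else "ambiguous"
    return MarkerCall(status, ordered)


@dataclass
class ConcordanceTable:
    """All second-round results for a marker catalog.

    ``correlations``: markers x reference samples r-matrix;
    ``mean_r``: markers x cell types (replicates averaged);
    ``tests``: long table of between-type t-tests with stars;
    ``calls``: one row per catalog marker with call, status, consistency;
    ``skipped``: markers not evaluated, with the reason.
    """

    correlations: pd.DataFrame
    mean_r: pd.DataFrame
    tests: pd.DataFrame
    calls: pd.DataFrame
    skipped: pd.DataFrame = field(default_factory=pd.DataFrame)


class MarkerConcordance(BaseEstimator):
    """Second-round concordance analysis as a fit-once estimator.

    Parameters
    ----------
    method : {"spearman", "pearson"}
        Correlation between marker expression and similarity columns.
    test : {"student", "welch"}
        Between-type two-sample test variant (pooled-variance Student by
        default).
    alpha : float
        Significance level for the call rule.
    comparison : {"pairwise", "pooled"}
        Test the top type against each other type, or against all others
        pooled.
    replicate_mode : {"per_replicate", "averaged"}
        Correlate against each reference replicate separately (default;
        enables the replicate-level t-tests) or against type-averaged
        similarity columns (no significance testing: calls reduce to the
        positive-maximum rule).
    bh : bool
        Additionally report Benjamini–Hochberg adjusted p-values in the
        ``tests_`` table; calls always use raw p-values.

    Attributes (after ``fit``)
    --------------------------
    result_ : ConcordanceTable
    correlations_, mean_r_, tests_, calls_ : its components
    summary_ : per-source consistency summary (see :func:`evaluate_catalog`)
    """

    def __init__(
        self,
        method: str = "spearman",
        test: str = "student",
        alpha: float = 0.05,
        comparison: str = "pairwise",
        replicate_mode: str = "per_replicate",
        bh: bool = False,
    ):
        self.method = method
        self.test = test
        self.alpha = alpha
        self.comparison = comparison
        self.replicate_mode = replicate_mode
        self.bh = bh

    # ------------------------------------------------------------------
    def fit(
        self,
        cells: GeneExpressionMatrix,
        sim: CellSimilarityTable,
        catalog: MarkerCatalog,
    ) -> "MarkerConcordance":
        if self.method not in METHODS:
            raise ValidationError(f"unknown correlation method {self.method!r}")
        if self.replicate_mode not in ("per_replicate", "averaged"):
            raise ValidationError(f"unknown replicate_mode {self.replicate_mode!r}")
        if list(sim.data.index) != cells.sample_ids:
            raise ValidationError("similarity table and cells must share identical cell ids")
        types = sim.cell_types
        catalog.check_types(types)

        cat = catalog.table
        present = cat["gene"].isin(cells.values.index)
        skipped_rows = [
            {"gene": g, "claimed_type": ct, "source": s, "reason": "missing"}
            for g, ct, s in cat.loc[~present, ["gene", "claimed_type", "source"]].itertuples(index=False)
        ]
        if skipped_rows:
            log.warning(
                "%d catalog gene(s) absent from the cell matrix; skipped",
                len(skipped_rows),
            )
        found = cat.loc[present].reset_index(drop=True)

        # drop cells whose first-round similarity is undefined
        sim_values = sim.data.to_numpy()
        good_cells = ~np.isnan(sim_values).any(axis=1)
        if not good_cells.all():
            log.warning(
                "%d cell(s) with undefined similarity excluded from round two",
                int((~good_cells).sum()),
            )
        expr = cells.values.loc[found["gene"]].to_numpy().T[good_cells]
        sim_used = sim.data.loc[good_cells]
        if self.replicate_mode == "averaged":
            sim_used = sim.mean_by_type().loc[good_cells]
            ref_groups = {t: [t] for t in types}
        else:
            ref_groups = {t: sim.columns_of_type(t) for t in types}
            for t, cols in ref_groups.items():
                if len(cols) < 2:
                    raise ValidationError(
                        f"cell type {t!r} has {len(cols)} reference replicate(s); "
                        "per-replicate testing needs >= 2"
                    )

        r = cross_correlation(expr, sim_used.to_numpy(), self.method)
        # one row per catalog entry (a gene may recur across sources)
        corr = pd.DataFrame(r, columns=sim_used.columns)
        corr.insert(0, "gene", found["gene"].to_numpy())
        corr.insert(1, "source", found["source"].to_numpy())

        undefined = corr.drop(columns=["gene", "source"]).isna().any(axis=1)
        for _, row in found.loc[undefined.to_numpy()].iterrows():
            skipped_rows.append(
                {"gene": row["gene"], "claimed_type": row["claimed_type"],
                 "source": row["source"], "reason": "constant"}
            )
        if undefined.any():
            log.warning(
                "%d marker(s) constant across cells; excluded from tests",
                int(undefined.sum()),
            )
        evaluable = found.loc[~undefined.to_numpy()].reset_index(drop=True)
        corr_eval = corr.loc[~undefined.to_numpy()].reset_index(drop=True)

        mean_rows, test_rows, call_rows = [], [], []
        for i, row in evaluable.iterrows():
            rvals = corr_eval.loc[i]
            per_type = {
                t: np.asarray([rvals[c] for c in cols], dtype=float)
                for t, cols in ref_groups.items()
            }
            means = {t: float(v.mean()) for t, v in per_type.items()}
            mean_rows.append({"gene": row["gene"], "source": row["source"], **means})
            if self.replicate_mode == "per_replicate":
                mc = call_marker_type(
                    per_type, alpha=self.alpha, variant=self.test,
                    comparison=self.comparison,
                )
                anchor = max(means, key=means.get)
                for t in types:
                    if t == anchor:
                        continue
                    if self.comparison == "pooled":
                        other = np.concatenate(
                            [per_type[u] for u in types if u != anchor]
                        )
                        tstat, p = two_sample_ttest(per_type[anchor], other, self.test)
                        test_rows.append(
                            {"gene": row["gene"], "source": row["source"],
                             "type_a": anchor, "type_b": "rest",
                             "t": tstat, "p": p, "stars": significance_stars(p)}
                        )
                        break
                    tstat, p = two_sample_ttest(per_type[anchor], per_type[t], self.test)
                    test_rows.append(
                        {"gene": row["gene"], "source": row["source"],
                         "type_a": anchor, "type_b": t,
                         "t": tstat, "p": p, "stars": significance_stars(p)}
                    )
            else:
                max_mean = max(means.values())
                if max_mean <= 0:
                    mc = MarkerCall("none", ())
                else:
                    tied = tuple(t for t in types if means[t] == max_mean)
                    mc = MarkerCall("unique" if len(tied) == 1 else "ambiguous", tied)
            consistent = mc.status == "unique" and mc.call == row["claimed_type"]
            call_rows.append(
                {"gene": row["gene"], "claimed_type": row["claimed_type"],
                 "source": row["source"], "status": mc.status,
                 "call": mc.call if mc.call is not None else "",
                 "call_set": "|".join(mc.call_set),
                 "consistent": bool(consistent)}
            )

        tests = pd.DataFrame(
            test_rows, columns=["gene", "source", "type_a", "type_b", "t", "p", "stars"]
        )
        if self.bh and len(tests):
            tests["p_bh"] = bh_adjust(tests["p"].to_numpy())
        calls = pd.DataFrame(
            call_rows,
            columns=["gene", "claimed_type", "source", "status", "call",
                     "call_set", "consistent"],
        )
        skipped = pd.DataFrame(
            skipped_rows, columns=["gene", "claimed_type", "source", "reason"]
        )
        mean_r = pd.DataFrame(mean_rows, columns=["gene", "source", *types])

        self.cell_types_ = types
        self.result_ = ConcordanceTable(corr_eval, mean_r, tests, calls, skipped)
        self.correlations_ = corr_eval
        self.mean_r_ = mean_r
        self.tests_ = tests
        self.calls_ = calls
        self.skipped_ = skipped
        self.summary_ = summarize_calls(calls, skipped)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise NotFittedError("MarkerConcordance is not fitted")


def summarize_calls(calls: pd.DataFrame, skipped: pd.DataFrame) -> pd.DataFrame:
    """Per-source counts of consistent / inconsistent / ambiguous / none / skipped."""
    sources = list(dict.fromkeys(
        list(calls.get("source", pd.Series(dtype=str)))
        + list(skipped.get("source", pd.Series(dtype=str)))
    ))
    rows = []
    for source in sources:
        sub = calls[calls["source"] == source] if len(calls) else calls
        unique = sub[sub["status"] == "unique"] if len(sub) else sub
        rows.append(
            {
                "source": source,
                "n_markers": int(len(sub)) + int(
                    (skipped["source"] == source).sum() if len(skipped) else 0
                ),
                "consistent": int(unique["consistent"].sum()) if len(unique) else 0,
                "inconsistent": int((~unique["consistent"]).sum()) if len(unique) else 0,
                "ambiguous": int((sub["status"] == "ambiguous").sum()) if len(sub) else 0,
                "none": int((sub["status"] == "none").sum()) if len(sub) else 0,
                "skipped": int((skipped["source"] == source).sum()) if len(skipped) else 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["source", "n_markers", "consistent", "inconsistent",
                 "ambiguous", "none", "skipped"],
    )


def second_round_correlations(
    sim: CellSimilarityTable,
    cells: GeneExpressionMatrix,
    catalog: MarkerCatalog,
    method: str = "spearman",
) -> pd.DataFrame:
    """Raw marker x reference-sample r-matrix (functional wrapper)."""
    est = MarkerConcordance(method=method).fit(cells, sim, catalog)
    return est.correlations_


def evaluate_catalog(
    concordance: ConcordanceTable, catalog: MarkerCatalog | None = None
) -> pd.DataFrame:
    """Per-source consistency summary of a fitted concordance result.

    The catalog argument is accepted for symmetry with the pipeline call
    sites; the claimed types are already recorded in the calls table.
    """
    return summarize_calls(concordance.calls, concordance.skipped)
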