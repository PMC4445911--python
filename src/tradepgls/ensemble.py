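"""Repeating analyses over a sample of candidate phylogenies.

The true phylogeny is never known exactly, so each analysis is repeated
over an ensemble of plausible trees and every statistic is summarized as
its median with 5th and 95th percentiles across trees (percentiles use
linear interpolation, numpy's default).  Three drivers:

* :func:`run_univariate_ensemble` — one single-predictor PGLS per tree;
* :func:`identify_candidates` — a full all-subsets dredge per tree on a
  small tree sample, keeping models whose median Delta-AICc is below a
  threshold;
* :func:`refit_ensemble` — refit of the candidate models on a larger
  tree sample, with per-model coefficient summaries, Akaike-weight and
  importance summaries, and top-rank tallies across trees.

A fit that fails on one tree is recorded and that tree skipped; the
failure count is always disclosed alongside the summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .data_ingest import TraitTable
from .model_inference import (
    DesignInfo, ModelSet, ModelSpec, build_design, candidate_set,
    enumerate_submodels, fit_submodels, rank_models, variable_importance,
)
from .pgls import PGLSFit, fit_pgls
from .phylo import VCV, prune_to_taxa, vcv_from_tree

logger = logging.getLogger(__name__)

PCTL = (5.0, 50.0, 95.0)


def percentile_summary(values) -> dict[str, float]:
    """Median with 5th/95th percentiles (linear interpolation)."""
    a = np.asarray(values, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return {"p5": np.nan, "median": np.nan, "p95": np.nan}
    p5, med, p95 = np.percentile(a, PCTL)
    return {"p5": float(p5), "median": float(med), "p95": float(p95)}


@dataclass
class EnsembleSummary:
    """Across-tree summary of one model (or one univariate predictor)."""

    stats: pd.DataFrame           # index: statistic name; cols p5/median/p95
    trees_used: int
    failures: int
    seed: int | None = None
    per_tree: pd.DataFrame | None = None

    def __getitem__(self, stat: str) -> dict[str, float]:
        return self.stats.loc[stat].to_dict()


def subsample_trees(trees: list[dendropy.Tree], k: int,
                    seed: int | None = None) -> list[dendropy.Tree]:
    """Seeded uniform draw of k trees without replacement."""
    if k >= len(trees):
        return list(trees)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(trees), size=k, replace=False)
    return [trees[i] for i in sorted(idx)]


def vcv_for_table(table: TraitTable, tree: dendropy.Tree) -> tuple[VCV, pd.DataFrame]:
    """Prune a tree to the table's species and align rows to its tip order.

    Species absent from the tree are dropped from the returned frame (the
    mismatch is logged); the VCV rows match the frame rows one-to-one.
    """
    pruned, missing = prune_to_taxa(tree, table.species)
    if missing:
        logger.warning("%d species absent from tree: %s", len(missing),
                       ", ".join(missing[:5]))
    V = vcv_from_tree(pruned)
    df = table.df.set_index("species_id").loc[V.taxa].reset_index()
    return V, df


def fit_on_tree(table: TraitTable, tree: dendropy.Tree, response: str,
                terms: list[str],
                factor_columns: dict[str, list[str]] | None = None,
                **fit_kwargs) -> PGLSFit:
    """Convenience: align table to one tree and fit a single PGLS model."""
    V, df = vcv_for_table(table, tree)
    design = build_design(TraitTable(df), response, terms, factor_columns)
    if design.species and design.n < V.n:
        V = V.submatrix(design.species)
    Xs = design.X
    return fit_pgls(design.y, Xs, V, terms=design.columns, **fit_kwargs)


def run_univariate_ensemble(table: TraitTable, trees: list[dendropy.Tree],
                            predictor: str, response: str = "ln_price",
                            factor_columns: dict[str, list[str]] | None = None,
                            ) -> EnsembleSummary:
    """Fit the single-predictor PGLS on every tree and summarize.

    For a numeric predictor, the summarized statistics are the slope
    estimate, its t and p, and lambda-hat.  For a factor block, each
    level coefficient is summarized separately alongside the block F test.
    """
    if len(trees) < 1:
        raise ValueError("need at least one tree")
    rows, failures = [], 0
    for i, tree in enumerate(trees):
        try:
            fit = fit_on_tree(table, tree, response, [predictor], factor_columns)
        except Exception as exc:
            failures += 1
            logger.warning("tree %d: fit failed (%s)", i, exc)
            continue
        row = {"tree": i, "lambda": fit.lambda_hat, "n": fit.n,
               "r2": fit.r2, "adj_r2": fit.adj_r2, "F": fit.F, "F_p": fit.F_p,
               "aicc": fit.aicc}
        for name, b, t, p in zip(fit.terms, fit.beta, fit.t, fit.p):
            if name == "(Intercept)":
                continue
            row[f"estimate[{name}]"] = b
            row[f"t[{name}]"] = t
            row[f"p[{name}]"] = p
        rows.append(row)
    if not rows:
        raise RuntimeError(f"all {len(trees)} per-tree fits failed")
    per_tree = pd.DataFrame(rows)
    stat_cols = [c for c in per_tree.columns if c != "tree"]
    stats = pd.DataFrame(
        {c: percentile_summary(per_tree[c]) for c in stat_cols}
    ).T[["p5", "median", "p95"]]
    return EnsembleSummary(stats=stats, trees_used=len(rows),
                           failures=failures, per_tree=per_tree)


def identify_candidates(table: TraitTable, trees_small: list[dendropy.Tree],
                        response: str, terms: list[str],
                        factor_columns: dict[str, list[str]] | None = None,
                        threshold: float = 4.0, mode: str = "median",
                        **fit_kwargs) -> tuple[list[ModelSpec], pd.DataFrame]:
    """Dredge the global model on each tree; keep well-supported submodels.

    ``mode="median"`` keeps models whose median Delta-AICc across trees is
    below ``threshold`` (the default); ``mode="union"`` keeps any model
    inside the threshold on at least one tree.  Returns the candidate
    specs (ordered by median Delta-AICc) and the per-model summary frame.
    """
    if not trees_small:
        raise ValueError("need at least one tree")
    if mode not in {"median", "union"}:
        raise ValueError("mode must be 'median' or 'union'")
    specs = enumerate_submodels(terms)
    deltas: dict[ModelSpec, list[float]] = {s: [] for s in specs}
    failures = 0
    for i, tree in enumerate(trees_small):
        try:
            V, df = vcv_for_table(table, tree)
            design = build_design(TraitTable(df), response, terms, factor_columns)
            if design.species and design.n < V.n:
                V = V.submatrix(design.species)
            mset = fit_submodels(design, V, specs, **fit_kwargs)
        except Exception as exc:
            failures += 1
            logger.warning("tree %d: dredge failed (%s)", i, exc)
            continue
        for spec, d in zip(mset.table["model"], mset.table["delta_aicc"]):
            deltas[spec].append(float(d))
    if failures == len(trees_small):
        raise RuntimeError("dredge failed on every tree")
    rows = []
    for spec in specs:
        ds = deltas[spec]
        summ = percentile_summary(ds)
        keep = (summ["median"] < threshold if mode == "median"
                else bool(np.min(ds) < threshold))
        rows.append({"model": spec, "terms": str(spec),
                     "median_delta_aicc": summ["median"],
                     "p5_delta_aicc": summ["p5"], "p95_delta_aicc": summ["p95"],
                     "candidate": keep})
    tab = pd.DataFrame(rows).sort_values(
        "median_delta_aicc", kind="mergesort").reset_index(drop=True)
    cands = tab.loc[tab["candidate"], "model"].tolist()
    logger.info("identify_candidates: %d of %d models kept (%s mode)",
                len(cands), len(specs), mode)
    return cands, tab


@dataclass
class RefitReport:
    """Across-tree report for the candidate model set (Table-4 style)."""

    coefficients: pd.DataFrame    # model x term -> p5/median/p95
    model_stats: pd.DataFrame     # per model: delta_aicc, weight, lambda summaries
    importance: pd.DataFrame      # per term: p5/median/p95 of importance
    rank_tallies: pd.DataFrame    # per model: count of trees at rank 1/2/3
    trees_used: int
    failures: int


def refit_ensemble(candidates: list[ModelSpec], table: TraitTable,
                   trees: list[dendropy.Tree], response: str,
                   factor_columns: dict[str, list[str]] | None = None,
                   top_ranks: int = 3, **fit_kwargs) -> RefitReport:
    """Refit each candidate model on each tree and summarize across trees.

    Within each tree the candidate set is re-ranked by AICc, giving
    per-tree Delta-AICc, Akaike weights, and term importances *within the
    candidate set*; rank tallies count how often each model came 1st,
    2nd, ... across trees.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    per_tree_rows, rank_counts = [], {}
    failures, used = 0, 0
    all_terms = sorted({t for s in candidates for t in s.terms})
    for i, tree in enumerate(trees):
        try:
            V, df = vcv_for_table(table, tree)
            terms = list(dict.fromkeys(t for s in candidates for t in s.terms))
            design = build_design(TraitTable(df), response, terms, factor_columns)
            if design.species and design.n < V.n:
                V = V.submatrix(design.species)
            fits = {}
            for spec in candidates:
                Xs, cols = design.design_for(spec)
                fits[spec] = fit_pgls(design.y, Xs, V, terms=cols, **fit_kwargs)
            mset = rank_models(fits)
            mset.terms = terms
        except Exception as exc:
            failures += 1
            logger.warning("tree %d: refit failed (%s)", i, exc)
            continue
        used += 1
        for _, r in mset.table.iterrows():
            spec = r["model"]
            rank = int(r["rank"])
            if rank <= top_ranks:
                rank_counts.setdefault(spec, {}).setdefault(rank, 0)
                rank_counts[spec][rank] += 1
            fit = mset.fits[spec]
            row = {"tree": i, "model": spec, "delta_aicc": r["delta_aicc"],
                   "weight": r["weight"], "lambda": fit.lambda_hat}
            for name, b in zip(fit.terms, fit.beta):
                row[f"beta[{name}]"] = float(b)
            per_tree_rows.append(row)
        imp_row = {"tree": i, "model": None}
        for t in all_terms:
            imp_row[f"importance[{t}]"] = variable_importance(mset, t)
        per_tree_rows.append(imp_row)
    if used == 0:
        raise RuntimeError("refit failed on every tree")
    per_tree = pd.DataFrame(per_tree_rows)

    coef_rows, stat_rows = [], []
    for spec in candidates:
        sub = per_tree[per_tree["model"] == spec]
        srow = {"model": spec, "terms": str(spec)}
        for stat in ("delta_aicc", "weight", "lambda"):
            summ = percentile_summary(sub[stat])
            for key, v in summ.items():
                srow[f"{stat}_{key}"] = v
        stat_rows.append(srow)
        for col in sub.columns:
            if col.startswith("beta[") and sub[col].notna().any():
                term = col[5:-1]
                summ = percentile_summary(sub[col])
                coef_rows.append({"model": str(spec), "term": term, **summ})
    imp_sub = per_tree[per_tree["model"].isna()]
    imp_rows = []
    for t in all_terms:
        summ = percentile_summary(imp_sub[f"importance[{t}]"])
        imp_rows.append({"term": t, **summ})

    order = sorted(
        stat_rows, key=lambda r: (r["delta_aicc_median"], r["terms"])
    )
    model_stats = pd.DataFrame(order).reset_index(drop=True)
    tally_rows = []
    for r in model_stats.itertuples():
        counts = rank_counts.get(r.model, {})
        tally_rows.append({"terms": r.terms, **{
            f"rank{j}": counts.get(j, 0) for j in range(1, top_ranks + 1)
        }})
    return RefitReport(
        coefficients=pd.DataFrame(coef_rows),
        model_stats=model_stats,
        importance=pd.DataFrame(imp_rows).set_index("term"),
        rank_tallies=pd.DataFrame(tally_rows),
        trees_used=used,
        failures=failures,
    )
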