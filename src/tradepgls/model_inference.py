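"""All-subsets model enumeration, AICc ranking and multi-model inference.

Given a global predictor set, every subset (with intercept) is fitted,
models are ranked by AICc, and relative support is expressed as Akaike
weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2).  From the weights:

* variable importance — the summed weight of all models containing a
  predictor;
* model-averaged coefficients — conditional (averaged over models
  containing the term, weights renormalized) and full (absent term
  counts as beta = 0);
* the candidate set — models within a Delta-AICc threshold of the best.

Multi-level factors enter and leave models as indivisible blocks.  The
Bonferroni helper adjusts the per-test significance level when the same
response is screened against a family of predictors (the 11 colours).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_ingest import TraitTable
from .pgls import PGLSFit, fit_pgls
from .phylo import VCV

__all__ = [
    "ModelSpec", "ModelSet", "DesignInfo", "build_design",
    "enumerate_submodels", "fit_submodels", "rank_models",
    "variable_importance", "model_average", "candidate_set", "bonferroni",
]

MAX_PREDICTORS = 20  # 2^20 submodels; refuse beyond this


@dataclass(frozen=True)
class ModelSpec:
    """A submodel: the predictor blocks it includes (intercept implicit)."""

    terms: tuple[str, ...]

    def __str__(self) -> str:
        return " + ".join(("1",) + self.terms)

    def includes(self, term: str) -> bool:
        return term in self.terms


@dataclass
class DesignInfo:
    """Response and global design with predictor-block -> column bookkeeping.

    Complete-case rows are fixed by the *global* predictor set before any
    enumeration so every submodel is fitted to the same observations;
    information criteria are not comparable otherwise.
    """

    y: np.ndarray
    X: np.ndarray                       # full design incl. intercept col 0
    columns: list[str]
    blocks: dict[str, list[int]]        # term -> column indices in X
    species: list[str]

    @property
    def n(self) -> int:
        return len(self.y)

    def design_for(self, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
        idx = [0]
        for term in spec.terms:
            idx.extend(self.blocks[term])
        return self.X[:, idx], [self.columns[j] for j in idx]


def build_design(table: TraitTable | pd.DataFrame, response: str,
                 terms: list[str],
                 factor_columns: dict[str, list[str]] | None = None) -> DesignInfo:
    """Assemble the response and global design matrix from a trait table.

    ``terms`` are predictor block names; a block maps to one numeric
    column of the same name unless ``factor_columns`` lists the dummy
    columns it spans (multi-level factors).
    """
    df = table.df if isinstance(table, TraitTable) else table
    factor_columns = factor_columns or {}
    used_cols: list[str] = [response]
    for term in terms:
        cols = factor_columns.get(term, [term])
        for c in cols:
            if c not in df.columns:
                raise KeyError(f"column {c!r} (term {term!r}) not in table")
        used_cols.extend(cols)
    complete = df[used_cols].notna().all(axis=1)
    sub = df.loc[complete]
    y = sub[response].to_numpy(dtype=float)
    blocks: dict[str, list[int]] = {}
    mats = [np.ones((len(sub), 1))]
    columns = ["(Intercept)"]
    j = 1
    for term in terms:
        cols = factor_columns.get(term, [term])
        blocks[term] = list(range(j, j + len(cols)))
        mats.append(sub[cols].to_numpy(dtype=float))
        columns.extend(cols)
        j += len(cols)
    X = np.hstack(mats)
    species = sub["species_id"].tolist() if "species_id" in sub.columns else []
    return DesignInfo(y=y, X=X, columns=columns, blocks=blocks, species=species)


def enumerate_submodels(terms: list[str],
                        max_predictors: int = MAX_PREDICTORS) -> list[ModelSpec]:
    """All 2^m subsets of the m predictor blocks, each with intercept.

    Returned in a deterministic order: by subset size, then lexicographic.
    """
    m = len(terms)
    if m > max_predictors:
        raise ValueError(
            f"{m} predictors would give {2**m} submodels; raise "
            f"max_predictors explicitly if you mean it"
        )
    specs = []
    for r in range(m + 1):
        for combo in itertools.combinations(terms, r):
            specs.append(ModelSpec(tuple(combo)))
    return specs


@dataclass
class ModelSet:
    """Fitted submodels with their AICc ranking and Akaike weights."""

    specs: list[ModelSpec]
    fits: dict[ModelSpec, PGLSFit]
    table: pd.DataFrame = field(default=None)  # ranked selection table
    terms: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.specs)

    def fit(self, spec: ModelSpec) -> PGLSFit:
        return self.fits[spec]

    @property
    def best(self) -> ModelSpec:
        return self.specs[0]

    def weights(self) -> pd.Series:
        return self.table.set_index("model")["weight"]


def fit_submodels(design: DesignInfo, V: VCV | np.ndarray,
                  specs: list[ModelSpec] | None = None,
                  **fit_kwargs) -> ModelSet:
    """Fit every submodel (lambda re-estimated by ML in each) and rank them."""
    terms = list(design.blocks)
    if specs is None:
        specs = enumerate_submodels(terms)
    fits = {}
    for spec in specs:
        Xs, cols = design.design_for(spec)
        fits[spec] = fit_pgls(design.y, Xs, V, terms=cols, **fit_kwargs)
    mset = rank_models(fits)
    mset.terms = terms
    return mset


def rank_models(fits: dict[ModelSpec, PGLSFit]) -> ModelSet:
    """Rank models by AICc; compute Delta-AICc and Akaike weights.

    Ties are broken by fewer parameters, then by the lexicographic term
    list, so the ordering is deterministic.
    """
    if not fits:
        raise ValueError("need at least one fitted model")
    rows = []
    for spec, fit in fits.items():
        rows.append({
            "model": spec, "terms": str(spec), "k": fit.k, "K": fit.K,
            "loglik": fit.loglik, "aicc": fit.aicc, "lambda": fit.lambda_hat,
            "n": fit.n,
        })
    tab = pd.DataFrame(rows)
    best = tab["aicc"].min()
    tab["delta_aicc"] = tab["aicc"] - best
    w = np.exp(-0.5 * tab["delta_aicc"].to_numpy())
    tab["weight"] = w / w.sum()
    tab["_spec_key"] = [tuple(s.terms) for s in tab["model"]]
    tab = tab.sort_values(
        ["delta_aicc", "K", "_spec_key"], kind="mergesort"
    ).drop(columns="_spec_key").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return ModelSet(specs=tab["model"].tolist(), fits=dict(fits), table=tab)


def variable_importance(mset: ModelSet, term: str) -> float:
    """Summed Akaike weight of all models containing ``term``."""
    known = mset.terms or sorted({t for s in mset.specs for t in s.terms})
    if term not in known:
        raise KeyError(f"unknown predictor {term!r}")
    mask = np.array([spec.includes(term) for spec in mset.table["model"]])
    return float(mset.table.loc[mask, "weight"].sum())


def importance_table(mset: ModelSet) -> pd.Series:
    terms = mset.terms or sorted({t for s in mset.specs for t in s.terms})
    return pd.Series({t: variable_importance(mset, t) for t in terms},
                     name="importance")


def model_average(mset: ModelSet) -> pd.DataFrame:
    """Model-averaged coefficients over the set.

    ``conditional`` averages each coefficient over the models that contain
    it, with weights renormalized within that subset (the natural
    average); ``full`` shrinks toward zero by treating a term absent from
    a model as beta = 0.
    """
    acc: dict[str, dict[str, float]] = {}
    for spec in mset.specs:
        fit = mset.fits[spec]
        w = float(mset.table.loc[
            mset.table["model"] == spec, "weight"].iloc[0])
        for name, b in zip(fit.terms, fit.beta):
            d = acc.setdefault(name, {"wsum": 0.0, "wbsum": 0.0})
            d["wsum"] += w
            d["wbsum"] += w * float(b)
    rows = []
    for name, d in acc.items():
        rows.append({
            "term": name,
            "conditional": d["wbsum"] / d["wsum"] if d["wsum"] > 0 else np.nan,
            "full": d["wbsum"],  # total weight over all models is 1
            "weight_containing": d["wsum"],
        })
    return pd.DataFrame(rows).set_index("term")


def candidate_set(mset: ModelSet, threshold: float = 4.0) -> ModelSet:
    """Models with Delta-AICc strictly below ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    flagged = mset.table[mset.table["delta_aicc"] < threshold]
    specs = flagged["model"].tolist()
    sub = ModelSet(
        specs=specs,
        fits={s: mset.fits[s] for s in specs},
        table=flagged.reset_index(drop=True),
        terms=list(mset.terms),
    )
    return sub


def bonferroni(p_values, m: int, alpha: float = 0.05) -> dict:
    """Bonferroni-adjusted significance calls for a family of m tests.

    Each p-value is called significant iff p < alpha / m.  Used for the
    univariate colour screens, where the same response is tested against
    each of the 11 colours.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    p = np.asarray(p_values, dtype=float)
    return {
        "alpha": alpha,
        "m": m,
        "threshold": threshold,
        "significant": (p < threshold).tolist(),
    }
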