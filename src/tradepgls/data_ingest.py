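"""Reading, validating and transforming the species trait table.

The analysis consumes one row per species: sale price (TWD), number of
individuals displayed for sale, native/alien status, biogeographic realm
of origin, IUCN Red List category, CITES listing, body mass (g), breeding
range size (km^2), number of song recordings, and plumage colour scores.

Derived predictors built here:

* colour coverage — for each of 11 colours, the fraction of 14 scored
  body parts on which the colour is present;
* colour diversity — the number of colours covering at least 3% of the
  body;
* song attractiveness — the residual of ln(song recordings + 1) regressed
  on ln(breeding range), i.e. how over-recorded a species is for its
  range size, a proxy for how attractive people find its song.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

BODY_PARTS: tuple[str, ...] = (
    "bill", "face", "cheek", "head", "throat", "breast", "belly",
    "flank", "back", "wings", "tail", "rump", "vent", "legs",
)
COLOURS: tuple[str, ...] = (
    "blue", "green", "red", "orange", "brown", "pink",
    "yellow", "black", "grey", "white", "ivory",
)
# pink subsumes purple and violet as one category

IUCN_LEVELS: tuple[str, ...] = ("LC", "NT", "VU", "EN")
REALM_LEVELS: tuple[str, ...] = (
    "Afrotropic", "Australasia", "Indo-Malay", "Neotropic", "Palearctic", "none",
)
STATUS_LEVELS: tuple[str, ...] = ("native", "alien")

REQUIRED_COLUMNS: tuple[str, ...] = (
    "species_id", "price_twd", "n_for_sale", "status", "realm", "iucn",
    "cites_listed", "body_mass_g", "range_km2", "song_count",
)
_NUMERIC_COLUMNS = ("price_twd", "n_for_sale", "body_mass_g", "range_km2",
                    "song_count")

COVERAGE_THRESHOLD = 0.03  # colours below 3% body coverage do not count


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


@dataclass
class TraitTable:
    """Validated species trait table.

    ``df`` holds one row per species; ``transform_log`` records which
    columns carry natural-log (or arcsine-square-root) transformed values
    after :func:`transform_predictors`.
    """

    df: pd.DataFrame
    transform_log: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return self.df["species_id"].tolist()

    def copy(self) -> "TraitTable":
        return TraitTable(self.df.copy(), dict(self.transform_log))


def read_species_table(path: str | os.PathLike) -> TraitTable:
    """Read and validate a species trait table from CSV.

    Rows with missing values are retained (complete-case subsetting is
    done per fitted model downstream); a missing required column or a
    non-numeric value in a numeric column is an error.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return validate_table(df)


def validate_table(df: pd.DataFrame) -> TraitTable:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    for col in _NUMERIC_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise SchemaError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
                f"at row {row}"
            )
        df[col] = parsed
    dup = df["species_id"].duplicated()
    if dup.any():
        raise SchemaError(
            f"duplicate species_id: {df.loc[dup, 'species_id'].iloc[0]!r}"
        )
    if (df["price_twd"].dropna() <= 0).any():
        raise SchemaError("price_twd must be positive")
    df["has_missing"] = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    return TraitTable(df.reset_index(drop=True))


def apply_exclusions(table: TraitTable, drop_ids: list[str]) -> TraitTable:
    """Drop the listed species (taxonomy mismatches, out-of-region records).

    Ids absent from the table raise a warning, not an error, so the same
    exclusion list can be applied across taxonomies that drift.
    """
    present = set(table.df["species_id"])
    absent = [d for d in drop_ids if d not in present]
    for d in absent:
        warnings.warn(f"exclusion id {d!r} not present in table", stacklevel=2)
    kept = table.df[~table.df["species_id"].isin(drop_ids)].reset_index(drop=True)
    n_removed = table.n - len(kept)
    logger.info("apply_exclusions: removed %d of %d rows", n_removed, table.n)
    return TraitTable(kept, dict(table.transform_log))


# ---------------------------------------------------------------- colour

def read_colour_scores(path: str | os.PathLike) -> pd.DataFrame:
    """Read a long-format colour score sheet (species_id, part, colour, present).

    Returns a wide frame indexed by species_id with a (part, colour)
    MultiIndex on columns, each cell 0/1.
    """
    long = pd.read_csv(path)
    need = {"species_id", "part", "colour", "present"}
    if not need.issubset(long.columns):
        raise SchemaError(f"colour sheet needs columns {sorted(need)}")
    wide = long.pivot_table(
        index="species_id", columns=["part", "colour"], values="present",
        fill_value=0, aggfunc="max",
    )
    return wide


def sheet_for_species(wide: pd.DataFrame, species_id: str) -> pd.DataFrame:
    """Extract one species' 14-part x 11-colour binary sheet."""
    row = wide.loc[species_id]
    sheet = row.unstack(level="colour").reindex(
        index=list(BODY_PARTS), columns=list(COLOURS), fill_value=0
    )
    return sheet.fillna(0).astype(int)


def colour_coverage(sheet: pd.DataFrame) -> pd.Series:
    """Per-colour body coverage: parts where present / 14.

    ``sheet`` is a binary body-part x colour frame; body parts are
    equally weighted.  Parts may carry several colours, so coverages can
    sum to more than 1 across colours.
    """
    sheet = sheet.reindex(columns=list(COLOURS), fill_value=0)
    if sheet.shape[0] != len(BODY_PARTS):
        raise ValueError(
            f"colour sheet must have {len(BODY_PARTS)} body parts, "
            f"got {sheet.shape[0]}"
        )
    vals = sheet.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("colour sheet cells must be 0 or 1")
    return pd.Series(vals.sum(axis=0) / len(BODY_PARTS), index=list(COLOURS))


def colour_diversity(coverage: pd.Series | np.ndarray,
                     threshold: float = COVERAGE_THRESHOLD) -> int:
    """Number of colours covering at least ``threshold`` of the body."""
    cov = np.asarray(coverage, dtype=float)
    if ((cov < 0) | (cov > 1)).any():
        raise ValueError("coverages must lie in [0, 1]")
    return int(np.sum(cov >= threshold))


def attach_colour_metrics(table: TraitTable, wide: pd.DataFrame) -> TraitTable:
    """Join per-colour coverage and colour diversity onto the trait table."""
    out = table.df.copy()
    covs = {}
    for sp in out["species_id"]:
        if sp not in wide.index:
            raise SchemaError(f"species {sp!r} missing from colour sheet")
        covs[sp] = colour_coverage(sheet_for_species(wide, sp))
    cov_df = pd.DataFrame(covs).T
    cov_df.columns = [f"cov_{c}" for c in cov_df.columns]
    cov_df["colour_diversity"] = [
        colour_diversity(covs[sp]) for sp in cov_df.index
    ]
    out = out.merge(cov_df, left_on="species_id", right_index=True, how="left")
    return TraitTable(out, dict(table.transform_log))


# ------------------------------------------------------------------ song

def song_attractiveness(song_counts: np.ndarray,
                        range_km2: np.ndarray) -> np.ndarray:
    """Residuals of ln(song recordings + 1) on ln(breeding range).

    Species with more recordings than their range size predicts get
    positive residuals; larger residuals track songs people find more
    attractive.  Residuals from an intercept OLS sum to zero.
    """
    counts = np.asarray(song_counts, dtype=float)
    ranges = np.asarray(range_km2, dtype=float)
    if (counts < 0).any():
        raise ValueError("song counts must be non-negative")
    if (ranges <= 0).any():
        raise ValueError("range sizes must be positive")
    if len(counts) < 3:
        raise ValueError("need at least 3 species to fit the song regression")
    x = np.log(ranges)
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all range sizes identical")
    y = np.log1p(counts)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return np.asarray(model.resid)


def attach_song_attractiveness(table: TraitTable) -> TraitTable:
    out = table.df.copy()
    ok = out[["song_count", "range_km2"]].notna().all(axis=1)
    resid = song_attractiveness(
        out.loc[ok, "song_count"].to_numpy(), out.loc[ok, "range_km2"].to_numpy()
    )
    out["song_attractiveness"] = np.nan
    out.loc[ok, "song_attractiveness"] = resid
    return TraitTable(out, dict(table.transform_log))


# ------------------------------------------------------------ transforms

def transform_predictors(table: TraitTable) -> TraitTable:
    """Build the design-ready columns.

    Natural logs for price, body mass, number for sale and range size
    (counts for sale are >= 1 for every recorded species, so no offset is
    needed there; song counts already got the +1 inside
    :func:`song_attractiveness`); arcsine-square-root for each colour
    coverage; reference-coded indicators for the categorical predictors.
    """
    df = table.df.copy()
    tlog = dict(table.transform_log)

    for src, dst in (("price_twd", "ln_price"), ("body_mass_g", "ln_mass"),
                     ("n_for_sale", "ln_numbers"), ("range_km2", "ln_range")):
        if (df[src].dropna() <= 0).any():
            raise ValueError(f"{src} must be positive for log transform")
        df[dst] = np.log(df[src])
        tlog[dst] = f"ln({src})"

    for colour in COLOURS:
        col = f"cov_{colour}"
        if col in df.columns:
            p = df[col].to_numpy(dtype=float)
            if np.nanmin(p) < 0 or np.nanmax(p) > 1:
                raise ValueError(f"{col} outside [0, 1]")
            df[f"asin_{colour}"] = np.arcsin(np.sqrt(p))
            tlog[f"asin_{colour}"] = f"arcsin(sqrt({col}))"

    # binary recodes (reference level first)
    df["status_alien"] = (df["status"] == "alien").astype(float)
    df["cites_listed"] = df["cites_listed"].astype(float)
    df["iucn_threatened"] = (~df["iucn"].isin(["LC"])).astype(float)
    # multi-level factors for univariate models (reference = first level seen
    # in the canonical ordering)
    for colname, levels in (("iucn", IUCN_LEVELS), ("realm", REALM_LEVELS)):
        present = [lv for lv in levels if (df[colname] == lv).any()]
        for lv in present[1:]:
            df[f"{colname}_{lv}"] = (df[colname] == lv).astype(float)
    return TraitTable(df, tlog)


FACTOR_BLOCKS = {
    "iucn": lambda df: [c for c in df.columns
                        if c.startswith("iucn_") and c != "iucn_threatened"],
    "realm": lambda df: [c for c in df.columns if c.startswith("realm_")],
}


# --------------------------------------------------------------- tallies

def summary_tallies(table: TraitTable, top_k: int = 10,
                    twd_per_usd: float = 30.0) -> dict:
    """Descriptive market tallies: totals, alien share, top-k dominance.

    Returns total individuals for sale, counts of alien individuals and
    species, the abundance ranking, the share of individuals contributed
    by the ``top_k`` most abundant species, price extremes converted to
    USD at ``twd_per_usd``, and total displayed market value.
    """
    df = table.df
    total = float(df["n_for_sale"].sum())
    alien = df[df["status"] == "alien"]
    ranking = df.sort_values(
        ["n_for_sale", "species_id"], ascending=[False, True]
    )[["species_id", "n_for_sale", "price_twd", "status"]].reset_index(drop=True)
    top = ranking.head(top_k)
    top_share = float(top["n_for_sale"].sum()) / total if total else np.nan
    prices = df["price_twd"].dropna()
    value_twd = float((df["price_twd"] * df["n_for_sale"]).sum())
    return {
        "n_species": int(len(df)),
        "total_individuals": int(total),
        "alien_individuals": int(alien["n_for_sale"].sum()),
        "alien_species": int(len(alien)),
        "top_k": int(top_k),
        "top_k_individuals": int(top["n_for_sale"].sum()),
        "top_k_share": top_share,
        "top_k_share_pct": 100.0 * top_share,
        "ranking": ranking,
        "min_price_usd": float(prices.min()) / twd_per_usd if len(prices) else np.nan,
        "max_price_usd": float(prices.max()) / twd_per_usd if len(prices) else np.nan,
        "total_value_twd": value_twd,
        "total_value_usd": value_twd / twd_per_usd,
        "twd_per_usd": twd_per_usd,
    }
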