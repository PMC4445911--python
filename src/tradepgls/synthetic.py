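"""Synthetic trees and trait tables with the structure the analysis assumes.

The generator produces (i) pure-birth (Yule) phylogenies and (ii) trait
tables in the same CSV schema the ingest module reads, with the response
drawn from the PGLS generating model

    ln price = X beta + eps,   eps ~ N(0, sigma^2 * V(lambda)),

so that estimation can be validated by parameter recovery: simulate with
known (beta, lambda, sigma^2), fit, and check the estimates.  Marginals
of the nuisance columns (abundances, masses, ranges, IUCN categories...)
are stylized to span realistic market-survey ranges; they make no claim
to match any particular survey's distributions.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .data_ingest import (
    BODY_PARTS, COLOURS, IUCN_LEVELS, REALM_LEVELS, TraitTable,
    song_attractiveness, validate_table,
)
from .phylo import VCV, lambda_transform, vcv_from_tree

__all__ = [
    "SimulationSpec", "simulate_yule_tree", "yule_lineages_at",
    "simulate_traits", "build_synthetic_study", "jitter_branch_lengths",
]


def yule_lineages_at(t: float, birth_rate: float,
                     rng: np.random.Generator) -> int:
    """Lineage count of a pure-birth process started from 1 lineage at time t.

    Exposes the process itself (not a tree) so the exponential-growth
    expectation E[N(t)] = exp(birth_rate * t) can be checked by Monte
    Carlo.
    """
    n, clock = 1, 0.0
    while True:
        clock += rng.exponential(1.0 / (birth_rate * n))
        if clock > t:
            return n
        n += 1


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int | np.random.Generator | None = None,
                       rescale_height: float | None = 1.0) -> dendropy.Tree:
    """Simulate a pure-birth tree with ``n_tips`` tips.

    Waiting times between speciations are exponential with rate
    ``birth_rate * k`` for k extant lineages; the lineage to split is
    chosen uniformly.  After the last split the simulation runs one more
    exponential waiting time so terminal branches have positive length,
    which makes the tree ultrametric.  Tips are labelled ``sp0001``...
    By default the tree is rescaled to unit root-to-tip height so lambda
    and sigma^2 are comparable across simulated trees.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    # active lineages: (node, birth_time)
    root = tree.seed_node
    t = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active: list[tuple[dendropy.Node, float]] = [(c1, 0.0), (c2, 0.0)]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.edge.length = t - born
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        active.append((a, t))
        active.append((b, t))
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    labels = [f"sp{i + 1:04d}" for i in range(n_tips)]
    for (node, born), lab in zip(active, labels):
        node.edge.length = t - born
        node.taxon = taxa.new_taxon(label=lab)
    root.edge.length = 0.0
    if rescale_height is not None:
        scale = rescale_height / t
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= scale
    return tree


def jitter_branch_lengths(tree: dendropy.Tree, sd: float,
                          rng: np.random.Generator) -> dendropy.Tree:
    """Multiply each branch length by an independent lognormal(0, sd) factor.

    A cheap stand-in for topologically-identical posterior tree samples:
    the relative divergence times wobble while the topology stays fixed.
    """
    out = tree.clone(depth=1)
    out.migrate_taxon_namespace(dendropy.TaxonNamespace())
    for e in out.preorder_edge_iter():
        if e.length:
            e.length *= float(np.exp(rng.normal(0.0, sd)))
    return out


@dataclass
class SimulationSpec:
    """Parameters of the trait-table generating model.

    ``beta_true`` maps design column names to coefficients; every named
    column must be one the generator produces (``ln_numbers``,
    ``ln_mass``, ``ln_range``, ``status_alien``, ``cites_listed``,
    ``iucn_threatened``, ``song_attractiveness``, ``asin_<colour>``).
    The intercept is ``beta_true["(Intercept)"]``.
    """

    n_tips: int = 217
    birth_rate: float = 1.0
    lambda_true: float = 0.9
    sigma2_true: float = 0.3
    beta_true: dict[str, float] = field(default_factory=lambda: {
        "(Intercept)": 4.0,
        "ln_numbers": -0.5,
        "ln_mass": 0.6,
        "status_alien": 0.5,
        "song_attractiveness": -0.1,
    })
    # nuisance marginals
    mean_ln_mass: float = 4.0        # ~55 g median body mass
    sd_ln_mass: float = 1.2
    mean_ln_numbers: float = 2.5     # counts for sale, heavy-tailed
    sd_ln_numbers: float = 1.6
    max_numbers: int = 7420
    mean_ln_range: float = 14.5      # ~2e6 km^2 median breeding range
    sd_ln_range: float = 1.5
    p_cites: float = 0.25
    p_threatened: float = 0.15
    alien_clade_fraction: float = 0.55  # alien status is clade-blocked
    song_slope: float = 0.35         # ln(songs+1) per ln(km^2)
    song_resid_sd: float = 0.8
    colour_mean_parts: float = 3.0   # mean body parts per colour
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.birth_rate <= 0 or self.sigma2_true < 0:
            raise ValueError("rates and variances must be positive")
        if not (0.0 <= self.lambda_true <= 1.0):
            raise ValueError("lambda_true must lie in [0, 1]")


def _brownian_on_tree(V: VCV, rng: np.random.Generator,
                      mean: float = 0.0, scale: float = 1.0) -> np.ndarray:
    L = np.linalg.cholesky(V.matrix + 1e-12 * np.eye(V.n))
    return mean + scale * (L @ rng.standard_normal(V.n))


def _clade_blocked_binary(tree: dendropy.Tree, taxa: list[str],
                          fraction: float, rng: np.random.Generator,
                          flip_p: float = 0.05) -> np.ndarray:
    """Binary trait concentrated in one clade (plus a little leakage).

    Grows a clade set from a random internal node until about ``fraction``
    of the tips are covered, then flips a few labels so the trait is
    clumped but not perfectly monophyletic.
    """
    n = len(taxa)
    target = int(round(fraction * n))
    idx = {lab: i for i, lab in enumerate(taxa)}
    flags = np.zeros(n, dtype=bool)
    internals = [nd for nd in tree.preorder_internal_node_iter()]
    rng.shuffle(internals)
    covered = 0
    for nd in internals:
        tips = [lf.taxon.label for lf in nd.leaf_iter()]
        new = [t for t in tips if not flags[idx[t]]]
        if covered >= target:
            break
        if 0 < len(new) <= target - covered + max(3, n // 20):
            for t in new:
                flags[idx[t]] = True
            covered += len(new)
    flips = rng.random(n) < flip_p
    flags = np.where(flips, ~flags, flags)
    return flags.astype(float)


def _colour_sheets(n: int, taxa: list[str], rng: np.random.Generator,
                   mean_parts: float,
                   boost: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Random binary colour sheets, long-to-wide as the ingest module expects.

    Each (species, colour) pair gets a number of covered body parts drawn
    around ``mean_parts``; every part is guaranteed at least one colour.
    ``boost`` can push selected colours' coverage up for chosen species.
    """
    n_parts, n_col = len(BODY_PARTS), len(COLOURS)
    sheets = np.zeros((n, n_parts, n_col), dtype=int)
    base_p = min(mean_parts / n_parts, 0.95)
    for s in range(n):
        for c, colour in enumerate(COLOURS):
            p = base_p
            if boost and colour in boost:
                p = min(0.95, base_p + boost[colour][s])
            sheets[s, :, c] = rng.random(n_parts) < p
        # every part must show at least one colour
        empty = sheets[s].sum(axis=1) == 0
        for part in np.nonzero(empty)[0]:
            sheets[s, part, int(rng.integers(n_col))] = 1
    cols = pd.MultiIndex.from_product(
        [list(BODY_PARTS), list(COLOURS)], names=["part", "colour"])
    return pd.DataFrame(sheets.reshape(n, -1), index=taxa, columns=cols)


def simulate_traits(tree: dendropy.Tree, spec: SimulationSpec) -> tuple[TraitTable, pd.DataFrame]:
    """Simulate a full trait table (and colour sheet) on a tree.

    The design columns named in ``spec.beta_true`` are assembled on the
    transformed scale, the response is drawn as
    ln price = X beta + eps with eps ~ N(0, sigma2 * V(lambda)), and the
    table is back-transformed to the raw CSV schema (price in TWD,
    counts, masses in g, ...).  Returns the validated table and the wide
    colour sheet.
    """
    rng = np.random.default_rng(spec.seed)
    V = vcv_from_tree(tree)
    taxa = V.taxa
    n = V.n

    # raw columns first (with the rounding and clipping the CSV schema
    # implies), then the design is derived from the *stored* values, so
    # refitting the ingested table targets exactly the generating model.
    height = float(np.max(np.diag(V.matrix)))
    ln_mass_latent = _brownian_on_tree(
        V, rng, mean=spec.mean_ln_mass,
        scale=spec.sd_ln_mass / np.sqrt(max(height, 1e-12)))
    body_mass_g = np.exp(ln_mass_latent)
    n_for_sale = np.clip(
        np.round(np.exp(rng.normal(spec.mean_ln_numbers,
                                   spec.sd_ln_numbers, n))),
        1, spec.max_numbers).astype(int)
    range_km2 = np.exp(rng.normal(spec.mean_ln_range, spec.sd_ln_range, n))
    status_alien = _clade_blocked_binary(tree, taxa,
                                         spec.alien_clade_fraction, rng)
    cites = (rng.random(n) < spec.p_cites).astype(float)
    threatened = (rng.random(n) < spec.p_threatened).astype(float)
    iucn = np.where(threatened == 1,
                    rng.choice(["NT", "VU", "EN"], size=n), "LC")
    realm = np.where(
        status_alien == 1,
        rng.choice([r for r in REALM_LEVELS if r != "none"], size=n),
        "none")
    # song counts follow the range-size regression plus residual noise
    ln_range = np.log(range_km2)
    ln_songs_p1 = np.clip(
        0.5 + spec.song_slope * (ln_range - spec.mean_ln_range)
        + rng.normal(0.0, spec.song_resid_sd, n),
        0.0, None)
    song_count = np.maximum(np.expm1(ln_songs_p1), 0.0).round().astype(int)

    # design columns as the ingest pipeline will reconstruct them
    ln_numbers = np.log(n_for_sale.astype(float))
    ln_mass = np.log(body_mass_g)
    song_resid = song_attractiveness(song_count, range_km2)

    # colour sheets; colours named in beta_true get species-level boosts so
    # their arcsine coverages carry signal
    boost = {}
    for key in spec.beta_true:
        if key.startswith("asin_"):
            colour = key[5:]
            boost[colour] = rng.random(n) * 0.5
    sheet = _colour_sheets(n, taxa, rng, spec.colour_mean_parts, boost or None)
    coverage = {
        colour: sheet.xs(colour, axis=1, level="colour").to_numpy().sum(axis=1)
        / len(BODY_PARTS)
        for colour in COLOURS
    }

    columns = {
        "ln_numbers": ln_numbers,
        "ln_mass": ln_mass,
        "ln_range": ln_range,
        "status_alien": status_alien,
        "cites_listed": cites,
        "iucn_threatened": threatened,
        "song_attractiveness": song_resid,
    }
    for colour in COLOURS:
        columns[f"asin_{colour}"] = np.arcsin(np.sqrt(coverage[colour]))

    X_parts, names = [np.ones(n)], ["(Intercept)"]
    for name, b in spec.beta_true.items():
        if name == "(Intercept)":
            continue
        if name not in columns:
            raise KeyError(f"beta_true names unknown column {name!r}")
        X_parts.append(columns[name])
        names.append(name)
    X = np.column_stack(X_parts)
    beta = np.array([spec.beta_true.get("(Intercept)", 0.0)]
                    + [spec.beta_true[nm] for nm in names[1:]])
    W = lambda_transform(V.matrix, spec.lambda_true)
    if spec.sigma2_true > 0:
        Lw = np.linalg.cholesky(W + 1e-12 * np.eye(n))
        eps = np.sqrt(spec.sigma2_true) * (Lw @ rng.standard_normal(n))
    else:
        eps = np.zeros(n)
    ln_price = X @ beta + eps

    df = pd.DataFrame({
        "species_id": taxa,
        "family": [f"fam{(i % 25) + 1:02d}" for i in range(n)],
        "order": np.where(rng.random(n) < 0.6, "Passeriformes",
                          "Psittaciformes"),
        "price_twd": np.exp(ln_price),
        "n_for_sale": n_for_sale,
        "status": np.where(status_alien == 1, "alien", "native"),
        "realm": realm,
        "iucn": iucn,
        "cites_listed": cites.astype(int),
        "body_mass_g": body_mass_g,
        "range_km2": range_km2,
        "song_count": song_count,
    })
    table = validate_table(df)
    table.df.attrs["true_ln_price"] = ln_price
    return table, sheet


def build_synthetic_study(seed: int = 0, n_species: int = 217,
                          n_trees_univariate: int = 100,
                          n_trees_candidate: int = 10,
                          jitter_sd: float = 0.08,
                          spec: SimulationSpec | None = None,
                          ) -> tuple[TraitTable, pd.DataFrame,
                                     list[dendropy.Tree], list[dendropy.Tree]]:
    """One self-contained synthetic study: a trait table plus tree samples.

    Simulates a base Yule tree with ``n_species`` tips, draws the traits
    on it under the default generating model (strong abundance and mass
    effects), and emits two tree ensembles — ``n_trees_univariate`` and
    ``n_trees_candidate`` branch-length-jittered copies — emulating
    samples of plausible phylogenies.  Every species appears in every
    tree.  Returns (table, colour sheet, large ensemble, small ensemble).
    """
    rng = np.random.default_rng(seed)
    base = simulate_yule_tree(n_species, seed=rng)
    if spec is None:
        spec = SimulationSpec(n_tips=n_species)
    spec = replace(spec, n_tips=n_species,
                   seed=int(rng.integers(2**31 - 1)))
    table, sheet = simulate_traits(base, spec)
    trees_large = [jitter_branch_lengths(base, jitter_sd, rng)
                   for _ in range(n_trees_univariate)]
    trees_small = [jitter_branch_lengths(base, jitter_sd, rng)
                   for _ in range(n_trees_candidate)]
    return table, sheet, trees_large, trees_small
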