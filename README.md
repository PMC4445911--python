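# tradepgls

Phylogenetic comparative analysis of species sale prices in wildlife
markets — or of any cross-species response measured alongside species
traits.

Market surveys record one price per species, but species are not
independent data points: close relatives tend to command similar prices
because the traits that drive price (body size, coloration, threat
status, availability) are themselves phylogenetically conserved.
`tradepgls` fits phylogenetic generalized least squares (PGLS)
regressions

&nbsp;&nbsp;&nbsp;&nbsp;*y* = *X*β + ε,&nbsp;&nbsp; ε ~ N(0, σ² **V**(λ)),

where **V** is the phylogenetic variance–covariance matrix of the tips
and Pagel's λ ∈ [0, 1] scales its off-diagonal — λ = 0 means independent
species, λ = 1 full Brownian-motion signal. λ is estimated per model by
maximum likelihood (profile likelihood over a bounded 1-D search). On
top of the fits the package runs AICc all-subsets model selection with
Akaike weights w<sub>i</sub> = exp(−Δ<sub>i</sub>/2)/Σ exp(−Δ<sub>j</sub>/2),
per-predictor importance (summed weights), conditional and full model
averaging, and a ΔAICc < 4 candidate set — and repeats everything over
an ensemble of candidate phylogenies, summarizing each statistic as its
median [5th, 95th percentile] across trees.

It also builds the survey-specific derived predictors: per-colour body
coverage from a 14-body-part × 11-colour presence sheet, colour
diversity (colours covering ≥ 3% of the body), and song attractiveness
(residuals of log(song recordings + 1) on log breeding-range size), plus
descriptive market tallies. A synthetic-data module generates Yule trees
and trait tables from the exact PGLS generating model, so the whole
pipeline is testable by parameter recovery with no external data.

## Worked example

Simulate a 120-species study (trait table, colour sheet, 100 + 10
jittered trees), build the derived predictors, and run the univariate
ensemble for abundance:

```python
import tradepgls as tp
from tradepgls import data_ingest as di
from tradepgls.ensemble import (identify_candidates, refit_ensemble,
                                run_univariate_ensemble)
from tradepgls.synthetic import build_synthetic_study

table, sheet, trees100, trees10 = build_synthetic_study(seed=1, n_species=120)
table = di.attach_colour_metrics(table, sheet)
table = di.attach_song_attractiveness(table)
table = di.transform_predictors(table)

summ = run_univariate_ensemble(table, trees100, "ln_numbers")
print(summ.stats.loc[["estimate[ln_numbers]", "t[ln_numbers]",
                      "p[ln_numbers]", "lambda"]].round(3))
```

```
                          p5  median     p95
estimate[ln_numbers]  -0.483  -0.481  -0.479
t[ln_numbers]        -18.244 -18.060 -17.880
p[ln_numbers]          0.000   0.000   0.000
lambda                 0.914   0.918   0.923
```

The generating model used a log-abundance effect of −0.5 and λ = 0.9:
the ensemble recovers a slope of −0.481 (the species-for-sale count is
strongly negatively related to price) and strong phylogenetic signal
(λ̂ ≈ 0.92), with tight percentile bands because the trees differ only
by branch-length jitter.

All-subsets selection over five predictors (32 models per tree) on the
small tree sample, then refitting the candidates across the 100 trees:

```python
terms = ["ln_numbers", "ln_mass", "status_alien",
         "song_attractiveness", "cites_listed"]
cands, sel = identify_candidates(table, trees10, "ln_price", terms)
print(f"{len(cands)} candidate models (median dAICc < 4)")
report = refit_ensemble(cands, table, trees100, "ln_price")
print(report.importance.round(2))
```

```
4 candidate models (median dAICc < 4)
                       p5  median   p95
term                                   
cites_listed         0.47    0.49  0.51
ln_mass              1.00    1.00  1.00
ln_numbers           1.00    1.00  1.00
song_attractiveness  0.84    0.86  0.88
status_alien         1.00    1.00  1.00
```

The three strong generating effects (abundance, mass, status) appear in
every candidate model, so their importance is exactly 1 on every tree;
the weak song effect gets intermediate support, and `cites_listed` —
which carries no effect in the generating model — hovers near 0.5, the
signature of an uninformative predictor.

## Command line

The same pipeline runs from a shell, driven by a YAML config (flags
override config values; every output embeds the seed and config hash):

```sh
tradepgls simulate --seed 1 --n-species 217 --outdir study
tradepgls describe   --trait-csv study/traits.csv --outdir out
tradepgls univariate --config cfg.yaml            # Bonferroni-flagged colour screens
tradepgls dredge     --config cfg.yaml            # candidate set + refit ensemble
tradepgls passeriformes --config cfg.yaml         # song model, songbirds only
```

Input formats: a species trait CSV (one row per species: price, count
for sale, status, realm, IUCN, CITES, mass, range, song recordings), an
optional long-format colour CSV (`species_id, part, colour, present`),
and Newick/NEXUS tree files.

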