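import numpy as np
import pytest

import tradepgls as tp
from tradepgls import data_ingest as di
from tradepgls.synthetic import SimulationSpec, build_synthetic_study, simulate_traits


@pytest.fixture(scope="session")
def three_tip_tree():
    return tp.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule50():
    return tp.simulate_yule_tree(50, seed=11)


@pytest.fixture(scope="session")
def small_study():
    """A compact end-to-end study: 80 species, 12 + 4 jittered trees.

    The generating model has strong abundance/mass/status effects and a
    weak song effect (the package defaults), so selection and importance
    behave predictably.
    """
    table, sheet, large, small = build_synthetic_study(
        seed=42, n_species=80, n_trees_univariate=12, n_trees_candidate=4)
    table = di.attach_colour_metrics(table, sheet)
    table = di.attach_song_attractiveness(table)
    table = di.transform_predictors(table)
    return {"table": table, "sheet": sheet, "large": large, "small": small}


@pytest.fixture(scope="session")
def fitted_design(small_study):
    from tradepgls.model_inference import build_design

    table = small_study["table"]
    tree = small_study["large"][0]
    V, df = __import__("tradepgls.ensemble", fromlist=["vcv_for_table"]) \
        .vcv_for_table(table, tree)
    design = build_design(di.TraitTable(df), "ln_price",
                          ["ln_numbers", "ln_mass", "status_alien",
                           "song_attractiveness"])
    if design.species and design.n < V.n:
        V = V.submatrix(design.species)
    return design, V
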