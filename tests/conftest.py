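"""Shared fixtures: a seeded synthetic study and a strain tree."""

from __future__ import annotations

import pytest

from microsocial.growth import build_fitness_table, extract_all
from microsocial.plate_io import StrainPanel
from microsocial.synthetic import SimulationConfig, simulate_experiment, study_panel

#: seven-tip rooted tree over the default panel's strain IDs
TREE7_NEWICK = (
    "((A5:0.02,(DD1:0.015,EE6:0.018):0.005):0.01,"
    "(A6:0.03,(DD8:0.025,(MS2:0.04,SH7:0.035):0.01):0.008):0.012);"
)


@pytest.fixture(scope="session")
def panel7() -> StrainPanel:
    return StrainPanel(("A5", "A6", "DD1", "DD8", "EE6", "MS2", "SH7"))


@pytest.fixture(scope="session")
def study_sim():
    """One full two-condition triplicate experiment from the default study panel."""
    config = SimulationConfig(panel=study_panel(), seed=7, conditions=("MTBE", "ETBE"), replicates=3)
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def study_table(study_sim):
    return build_fitness_table(extract_all(study_sim.series), study_sim.layout)


@pytest.fixture(scope="session")
def strain_tree():
    from microsocial.phylo import StrainTree

    return StrainTree.from_newick(TREE7_NEWICK)
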