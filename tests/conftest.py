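import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from salsa.local_alignment import Superposition, iterative_superpose, map_site_positions
from salsa.salsa_core import build_salsa_table
from salsa.site_prediction import select_top_fraction
from salsa.synthetic_fixtures import default_site_spec, load_paper_fixture, make_toy_family


@pytest.fixture(scope="session")
def table2():
    return load_paper_fixture("omdc_table2")


@pytest.fixture(scope="session")
def table3():
    return load_paper_fixture("gh16_table3")


@pytest.fixture(scope="session")
def table4():
    return load_paper_fixture("ech_table4")


@pytest.fixture(scope="session")
def table5():
    return load_paper_fixture("abdh_table5")


@pytest.fixture
def toy_family():
    """Deterministic 5-structure family, 50 residues, 8 planted sites, 0.3 A jitter."""
    return make_toy_family(5, 50, default_site_spec(jitter_sigma=0.3), seed=11)


def run_family_pipeline(family, threshold=4.0):
    """Generator family -> sites -> superpositions -> position map -> table."""
    structures = family.structures
    sites = [select_top_fraction(r, family.site_fraction) for r in family.rankings]
    reference = structures[0]
    superpositions = {reference.structure_id: Superposition.identity()}
    for structure in structures[1:]:
        superpositions[structure.structure_id] = iterative_superpose(structure, reference)
    position_map = map_site_positions(
        structures, sites, superpositions,
        reference_id=reference.structure_id, threshold=threshold,
    )
    table = build_salsa_table(position_map, sites, structures)
    return structures, sites, superpositions, position_map, table
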