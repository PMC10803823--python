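import pandas as pd
import pytest

from bvitpath import catalog as cat
from bvitpath.complement import MagGeneSet
from bvitpath.taxa import AbundanceTable


@pytest.fixture(scope="session")
def defs():
    """The bundled eight-pathway reference catalog."""
    return cat.default_pathway_definitions()


@pytest.fixture
def five_gene_pathway():
    return cat.PathwayDefinition(
        vitamin_code="B3",
        metacyc_id="PYRIDNUCSYN-PWY",
        gene_refs=("g1", "g2", "g3", "g4", "g5"),
    )


@pytest.fixture
def counts_table():
    values = pd.DataFrame(
        {
            "s1": [2.0, 2.0, 0.0],
            "s2": [5.0, 0.0, 0.0],
            "s3": [1.0, 2.0, 7.0],
        },
        index=["Prevotella copri", "Roseburia intestinalis", "Blautia schinkii"],
    )
    return AbundanceTable(values=values, unit="counts")


def gene_set(mag_id, vitamin, genes, transporters=()):
    return MagGeneSet(
        mag_id=mag_id,
        present={vitamin: frozenset(genes)},
        transporters=frozenset(transporters),
    )
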