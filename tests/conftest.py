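import numpy as np
import pytest

from chemorep.intronless import V1R_PROFILE
from chemorep.synth import PlantSpec, make_donor_cds, plant_genome

SPECIES_NEWICK = "((A:1.0,B:1.0)AB:1.0,(C:1.0,D:1.0)CD:1.0)R;"


@pytest.fixture(scope="session")
def donor_pool():
    """Receptor-like donor CDSs derived from the V1R reference profile.

    Donors diverge ~10% from the reference so profile alignments are
    meaningful and search identity stays well above the seed threshold.
    """
    rng = np.random.default_rng(7)
    return [
        make_donor_cds(rng, template=V1R_PROFILE.reference_seq, divergence=0.1)
        for _ in range(12)
    ]


@pytest.fixture(scope="session")
def planted_genome(donor_pool):
    """The flagship fixture: 5 intact / 3 pseudogene / 2 truncated plants."""
    spec = PlantSpec(seed=3, n_intact=5, n_pseudogene=3, n_truncated=2)
    assembly, truth = plant_genome(spec, donor_pool)
    return assembly, truth


@pytest.fixture(scope="session")
def v1r_queries():
    return {V1R_PROFILE.reference_id: V1R_PROFILE.reference_seq}
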