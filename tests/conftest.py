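import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pedrisk.simulate import (
    SimulationConfig,
    founder_couples_for_cohort,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_sim():
    """Bundle + latent truth for a ~1000-person cohort (fast unit tests)."""
    cfg = SimulationConfig(n_founder_couples=300, seed=11)
    bundle, truth = simulate_population(cfg, return_truth=True)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def medium_sim():
    """Bundle + truth for a ~50k cohort (prevalence / correlation checks)."""
    cfg = SimulationConfig(
        n_founder_couples=founder_couples_for_cohort(50_000), seed=29
    )
    bundle, truth = simulate_population(cfg, return_truth=True)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_links(small_sim):
    from pedrisk.pedigree import attach_cohab_years, relative_links

    cfg, bundle, _ = small_sim
    cohort = bundle.persons.loc[
        bundle.cohort_mask(cfg.birth_year_range), "id"
    ].to_numpy(np.int64)
    links = relative_links(bundle.pedigree, probands=cohort)
    return attach_cohab_years(links, bundle.cohab)
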