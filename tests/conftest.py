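import numpy as np
import pytest

import markerimpute as mi


@pytest.fixture(scope="session")
def small_population():
    """A small but structured inbred panel: 4 families x 6 lines, 60 markers."""
    pop = mi.simulate_population(
        n_founders=8,
        n_families=4,
        lines_per_family=6,
        n_markers=60,
        n_chromosomes=3,
        seed=101,
    )
    return mi.simulate_phenotypes(pop, n_qtl=12, h2=0.5, seed=102)


@pytest.fixture(scope="session")
def small_masked(small_population):
    spec = mi.default_missingness_distribution("NA50", seed=103)
    return mi.mask_missing(small_population.genotypes, spec)


def toy_matrix(values, coding=mi.Coding.MINUS1_1, continuous=False):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return mi.GenotypeMatrix(
        values=values,
        individual_ids=[f"ind{i}" for i in range(m)],
        marker_ids=[f"mk{j}" for j in range(n)],
        coding=coding,
        continuous=continuous,
    )
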