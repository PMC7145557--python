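"""Shared fixtures: family-templated hairpins, poses and small networks.

Everything is generated programmatically and seeded; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from hairpin7sk import (build_hairpin, place_peptide, planted_network)


@pytest.fixture(scope="session")
def m1_conf():
    conf, truth = build_hairpin(template="M1", seed=1)
    return conf, truth


@pytest.fixture(scope="session")
def m2_conf():
    conf, truth = build_hairpin(template="M2", seed=1)
    return conf, truth


@pytest.fixture(scope="session")
def m2star_conf():
    conf, truth = build_hairpin(template="M2STAR", seed=1)
    return conf, truth


@pytest.fixture(scope="session")
def e_conf():
    conf, truth = build_hairpin(template="E", seed=1)
    return conf, truth


@pytest.fixture(scope="session")
def all_templates(m1_conf, m2_conf, m2star_conf, e_conf):
    return {"M1": m1_conf, "M2": m2_conf, "M2STAR": m2star_conf, "E": e_conf}


@pytest.fixture(scope="session")
def groove_complex(m2_conf):
    rna, _ = m2_conf
    return place_peptide(rna, mode="groove", seed=3)


@pytest.fixture(scope="session")
def surface_complex(m1_conf):
    rna, _ = m1_conf
    return place_peptide(rna, mode="surface", seed=3)


@pytest.fixture(scope="session")
def two_funnel_network():
    return planted_network([(8, 0.0, 1.5), (8, 3.0, 1.5)],
                           inter_barrier=20.0, seed=5,
                           families=["E", "M2"])


def random_small_network(rng, n_min=None, n_funnels=2):
    """Helper for oracle tests: a random planted network.

    Barriers are kept moderate so that the slowest relaxation rate stays
    within the dynamic range a dense eigensolver can resolve; the
    eigen-decomposition then serves as a trustworthy reference.
    """
    while True:
        sizes = rng.integers(2, 7, size=n_funnels) if n_min is None else n_min
        funnels = [(int(s), float(rng.uniform(0, 3)),
                    float(rng.uniform(0.3, 1.2)))
                   for s in np.atleast_1d(sizes)]
        try:
            return planted_network(funnels, inter_barrier=12.0,
                                   seed=int(rng.integers(0, 2**31 - 1)))
        except ValueError:  # a rare draw put an intra barrier above 12
            continue
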