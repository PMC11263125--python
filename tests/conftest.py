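"""Shared fixtures: small hand-built metacommunities with known answers."""

import numpy as np
import pytest

from coprune import (
    CooccurrenceFrequencyMatrix,
    Dataset,
    InteractionRecordSet,
    SiteSpeciesTable,
)


def make_freq(N):
    """Wrap an integer matrix as a frequency matrix with generic labels."""
    N = np.asarray(N)
    return CooccurrenceFrequencyMatrix(
        consumers=tuple(f"c{j}" for j in range(N.shape[0])),
        resources=tuple(f"r{j}" for j in range(N.shape[1])),
        N=N,
    )


@pytest.fixture
def toy_tables():
    """Two sites, two consumers, two resources, with hand-checkable overlap.

    Site occupancy:
        s1: c1, r1, r2
        s2: c1, c2, r2
    Shared-site counts N (consumers x resources):
        c1: r1 -> 1 (s1), r2 -> 2 (s1, s2)
        c2: r1 -> 0,      r2 -> 1 (s2)
    """
    consumers = SiteSpeciesTable(
        guild="consumer",
        species_ids=("c1", "c2"),
        site_ids=("s1", "s2"),
        presence=np.array([[True, False], [True, True]]),
    )
    resources = SiteSpeciesTable(
        guild="resource",
        species_ids=("r1", "r2"),
        site_ids=("s1", "s2"),
        presence=np.array([[True, True], [False, True]]),
    )
    return consumers, resources


@pytest.fixture
def toy_dataset(toy_tables):
    """The toy tables plus two observed interactions (c1-r1 at s1, c2-r2 at s2)."""
    consumers, resources = toy_tables
    records = InteractionRecordSet((("s1", "c1", "r1"), ("s2", "c2", "r2")))
    return Dataset(
        name="toy",
        interaction_type="PP",
        consumers=consumers,
        resources=resources,
        interactions=records,
    )
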