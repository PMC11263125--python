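import numpy as np
import pytest

from coprune import (
    MetacommunityParams,
    SiteSpeciesTable,
    cooccurrence_frequencies,
    cooccurrence_network,
    generate_dataset,
    generate_interactions,
    generate_occupancy,
    interaction_probability,
)
from coprune.errors import DegenerateInputError

SMALL = dict(n_sites=25, n_consumers=10, n_resources=15)


def test_same_seed_same_dataset():
    a = generate_dataset(MetacommunityParams(seed=5, **SMALL))
    b = generate_dataset(MetacommunityParams(seed=5, **SMALL))
    assert a.dataset.consumers == b.dataset.consumers
    assert a.dataset.resources == b.dataset.resources
    assert a.dataset.interactions.records == b.dataset.interactions.records
    c = generate_dataset(MetacommunityParams(seed=6, **SMALL))
    assert a.dataset.interactions.records != c.dataset.interactions.records


def test_full_occupancy_gives_complete_cooccurrence():
    params = MetacommunityParams(seed=0, consumer_q=1.0, resource_q=1.0, **SMALL)
    syn = generate_dataset(params)
    freq = cooccurrence_frequencies(syn.dataset.consumers, syn.dataset.resources)
    assert (freq.N == params.n_sites).all()


def test_truth_network_is_conditioned_subset():
    syn = generate_dataset(MetacommunityParams(seed=1, **SMALL))
    cooc = cooccurrence_network(
        cooccurrence_frequencies(syn.dataset.consumers, syn.dataset.resources))
    assert syn.true_network.is_subset_of(cooc)
    # per-consumer conditioning: nobody ends up with zero interactions
    assert (syn.true_network.adjacency.sum(axis=1) >= 1).all()


def test_occupancy_tables_are_valid_and_probabilities_match_shape():
    params = MetacommunityParams(seed=2, **SMALL)
    table, q = generate_occupancy(params, "resource")
    assert table.n_species == params.n_resources
    assert table.n_sites == params.n_sites
    assert q.shape == (params.n_resources,)
    assert ((q > 0) & (q <= 1)).all()
    assert table.presence.any(axis=0).all()  # every species somewhere


def test_interactions_require_copresence():
    consumers = SiteSpeciesTable(
        guild="consumer", species_ids=("c1",), site_ids=("s1", "s2"),
        presence=np.array([[True], [False]]))
    resources = SiteSpeciesTable(
        guild="resource", species_ids=("r1",), site_ids=("s1", "s2"),
        presence=np.array([[False], [True]]))  # never shares a site with c1
    with pytest.raises(DegenerateInputError, match="co-occurs with no resource"):
        generate_interactions(consumers, resources, 0.5, seed=0)


def test_conditional_pair_frequencies_match_model():
    """Monte Carlo check that rejection conditioning realizes the model's
    conditional law: P(link to i | >= 1 link) = P_ai / (1 - (1-p)^N_a)."""
    consumers = SiteSpeciesTable(
        guild="consumer", species_ids=("c1",), site_ids=("s1", "s2", "s3"),
        presence=np.array([[True], [True], [True]]))
    resources = SiteSpeciesTable(
        guild="resource", species_ids=("r1", "r2"), site_ids=("s1", "s2", "s3"),
        presence=np.array([[True, False], [True, False], [False, True]]))
    p = 0.3
    n_alpha = 3  # N = (2, 1)
    denom = 1 - (1 - p) ** n_alpha
    want = np.array([interaction_probability(p, 2),
                     interaction_probability(p, 1)]) / denom
    n_trials = 4000
    hits = np.zeros(2)
    for s in range(n_trials):
        pairs = generate_interactions(consumers, resources, p, seed=s).pairs()
        hits += [("c1", "r1") in pairs, ("c1", "r2") in pairs]
    got = hits / n_trials
    se = np.sqrt(want * (1 - want) / n_trials)
    assert np.all(np.abs(got - want) < 4 * se + 1e-9)


def test_parameter_validation():
    with pytest.raises(DegenerateInputError):
        MetacommunityParams(true_p=0.0)
    with pytest.raises(DegenerateInputError):
        MetacommunityParams(n_sites=1)
    with pytest.raises(DegenerateInputError):
        MetacommunityParams(consumer_q=1.5)
    with pytest.raises(DegenerateInputError):
        MetacommunityParams(coupling_exponent=-0.1)


def test_heterogeneous_preset_overrides():
    params = MetacommunityParams.frequency_heterogeneous(seed=9, true_p=0.05)
    assert params.n_sites == 50
    assert params.resource_occupancy_b == 4.0
    assert params.true_p == 0.05
    assert params.seed == 9


def test_coupled_rates_generate_valid_dataset():
    syn = generate_dataset(
        MetacommunityParams(seed=3, coupling_exponent=1.0, **SMALL))
    assert (syn.true_network.adjacency.sum(axis=1) >= 1).all()
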