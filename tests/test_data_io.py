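import numpy as np
import pytest

from coprune import (
    Dataset,
    InteractionRecordSet,
    SiteSpeciesTable,
    cooccurrence_network,
    cooccurrence_frequencies,
    load_dataset,
    read_network,
    write_dataset,
    write_network,
)
from coprune.errors import ConsistencyError, FormatError


def test_table_rejects_species_with_no_site():
    with pytest.raises(ConsistencyError, match="occupy no site"):
        SiteSpeciesTable(
            guild="consumer",
            species_ids=("a", "b"),
            site_ids=("s1",),
            presence=np.array([[True, False]]),
        )


def test_table_rejects_duplicate_ids():
    with pytest.raises(ConsistencyError, match="duplicate species"):
        SiteSpeciesTable(
            guild="consumer",
            species_ids=("a", "a"),
            site_ids=("s1",),
            presence=np.ones((1, 2), dtype=bool),
        )


def test_table_shape_mismatch():
    with pytest.raises(ConsistencyError, match="shape"):
        SiteSpeciesTable(
            guild="resource",
            species_ids=("a",),
            site_ids=("s1", "s2"),
            presence=np.ones((1, 1), dtype=bool),
        )


def test_sites_of(toy_tables):
    consumers, _ = toy_tables
    assert consumers.sites_of("c1") == frozenset({"s1", "s2"})
    assert consumers.sites_of("c2") == frozenset({"s2"})


def test_records_deduplicate_and_collapse_to_pairs():
    rec = InteractionRecordSet(
        (("s1", "c1", "r1"), ("s1", "c1", "r1"), ("s2", "c1", "r1"))
    )
    assert len(rec) == 2
    assert rec.pairs() == {("c1", "r1")}


def test_dataset_rejects_interaction_where_partner_absent(toy_tables):
    consumers, resources = toy_tables
    with pytest.raises(ConsistencyError, match="absent"):
        Dataset(
            name="bad",
            interaction_type="PP",
            consumers=consumers,
            resources=resources,
            # c2 is not present at s1
            interactions=InteractionRecordSet((("s1", "c2", "r1"),)),
        )


def test_dataset_rejects_unknown_species(toy_tables):
    consumers, resources = toy_tables
    with pytest.raises(ConsistencyError, match="unknown consumer"):
        Dataset(
            name="bad",
            interaction_type="PP",
            consumers=consumers,
            resources=resources,
            interactions=InteractionRecordSet((("s1", "ghost", "r1"),)),
        )


def test_dataset_rejects_mismatched_site_lists(toy_tables):
    consumers, _ = toy_tables
    other = SiteSpeciesTable(
        guild="resource",
        species_ids=("r1",),
        site_ids=("s1", "s3"),
        presence=np.array([[True], [True]]),
    )
    with pytest.raises(ConsistencyError, match="site list"):
        Dataset(
            name="bad",
            interaction_type="PP",
            consumers=consumers,
            resources=other,
            interactions=InteractionRecordSet(()),
        )


def test_dataset_round_trip(tmp_path, toy_dataset):
    occ = tmp_path / "occurrences.csv"
    inter = tmp_path / "interactions.csv"
    write_dataset(toy_dataset, occ, inter)
    back = load_dataset(occ, inter, name="toy", interaction_type="PP")
    assert back.consumers == toy_dataset.consumers
    assert back.resources == toy_dataset.resources
    assert back.interactions.records == toy_dataset.interactions.records


def test_load_rejects_missing_column(tmp_path):
    occ = tmp_path / "occ.csv"
    occ.write_text("site,species\ns1,a\n")
    inter = tmp_path / "int.csv"
    inter.write_text("site,consumer,resource\n")
    with pytest.raises(FormatError, match="missing required columns"):
        load_dataset(occ, inter, name="x", interaction_type="PP")


def test_load_rejects_unknown_guild(tmp_path):
    occ = tmp_path / "occ.csv"
    occ.write_text("site,guild,species\ns1,plant,a\ns1,consumer,b\n")
    inter = tmp_path / "int.csv"
    inter.write_text("site,consumer,resource\n")
    with pytest.raises(FormatError, match="unknown guild"):
        load_dataset(occ, inter, name="x", interaction_type="PP")


def test_network_round_trip(tmp_path, toy_tables):
    consumers, resources = toy_tables
    net = cooccurrence_network(cooccurrence_frequencies(consumers, resources))
    path = tmp_path / "net.csv"
    write_network(net, path, dataset="toy", seed=7)
    back = read_network(path)
    assert back == net
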