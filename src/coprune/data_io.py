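"""Reading, validating and writing site-level occurrence and interaction
records.

On-disk formats are long-format CSV:

* ``occurrences.csv`` — columns ``site,guild,species`` with
  ``guild ∈ {consumer, resource}``;
* ``interactions.csv`` — columns ``site,consumer,resource``.

Identifiers are opaque strings, matched exactly and case-sensitively.
Records are unweighted: duplicate rows collapse to one observation.
Validation order is schema → referential integrity → the biological
constraint that an interaction recorded at a site implies both partners
are present at that site (co-occurrence is a necessary condition for
interaction in the consumer–resource systems this package targets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

GUILDS = ("consumer", "resource")
INTERACTION_TYPES = ("PP", "HP")

__all__ = [
    "SiteSpeciesTable",
    "InteractionRecordSet",
    "Dataset",
    "load_dataset",
    "write_dataset",
    "write_network",
    "read_network",
]


@dataclass(frozen=True)
class SiteSpeciesTable:
    """Boolean incidence of one guild's species across sites.

    ``presence[s, j]`` is True when species ``species_ids[j]`` occupies
    site ``site_ids[s]``. Every species must occupy at least one site:
    the table is the species' abiotic-niche footprint and an all-absent
    species carries no information.
    """

    guild: str
    species_ids: tuple[str, ...]
    site_ids: tuple[str, ...]
    presence: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.guild not in GUILDS:
            raise ConsistencyError(f"unknown guild {self.guild!r}")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ConsistencyError(f"duplicate species ids in {self.guild} table")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ConsistencyError(f"duplicate site ids in {self.guild} table")
        pres = np.asarray(self.presence, dtype=bool)
        object.__setattr__(self, "presence", pres)
        if pres.shape != (len(self.site_ids), len(self.species_ids)):
            raise ConsistencyError(
                f"presence matrix shape {pres.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        occupied = pres.any(axis=0)
        if len(self.species_ids) and not occupied.all():
            missing = [s for s, ok in zip(self.species_ids, occupied) if not ok]
            raise ConsistencyError(
                f"{self.guild} species occupy no site: {missing}"
            )

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def sites_of(self, species: str) -> frozenset[str]:
        j = self.species_ids.index(species)
        return frozenset(
            s for s, here in zip(self.site_ids, self.presence[:, j]) if here
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SiteSpeciesTable):
            return NotImplemented
        return (
            self.guild == other.guild
            and self.species_ids == other.species_ids
            and self.site_ids == other.site_ids
            and np.array_equal(self.presence, other.presence)
        )


@dataclass(frozen=True)
class InteractionRecordSet:
    """Deduplicated (site, consumer, resource) triples.

    Each triple records one empirically observed interaction event at one
    spatial unit; multiplicity within a site carries no weight.
    """

    records: tuple[tuple[str, str, str], ...]

    def __post_init__(self):
        dedup = tuple(sorted(set(map(tuple, self.records))))
        object.__setattr__(self, "records", dedup)

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        """Site-collapsed (consumer, resource) pairs — the metaweb edges."""
        return {(a, i) for _, a, i in self.records}


@dataclass(frozen=True)
class Dataset:
    """A validated bipartite metacommunity: two guilds over a shared set of
    spatial units, plus site-level interaction records.

    The same spatial grain is used for occurrences and interactions, so the
    interaction network is directly comparable to (and a subset of) the
    co-occurrence network.
    """

    name: str
    interaction_type: str
    consumers: SiteSpeciesTable
    resources: SiteSpeciesTable
    interactions: InteractionRecordSet

    def __post_init__(self):
        if self.interaction_type not in INTERACTION_TYPES:
            raise ConsistencyError(
                f"interaction_type must be one of {INTERACTION_TYPES}, "
                f"got {self.interaction_type!r}"
            )
        if self.consumers.guild != "consumer" or self.resources.guild != "resource":
            raise ConsistencyError("guild roles of the two tables are swapped")
        if self.consumers.site_ids != self.resources.site_ids:
            raise ConsistencyError(
                "consumer and resource tables must share the same site list"
            )
        if not self.consumers.species_ids or not self.resources.species_ids:
            raise ConsistencyError("each guild needs at least one species")
        _validate_records(self)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return self.consumers.site_ids


def _validate_records(ds: Dataset) -> None:
    cons_idx = {s: j for j, s in enumerate(ds.consumers.species_ids)}
    res_idx = {s: j for j, s in enumerate(ds.resources.species_ids)}
    site_idx = {s: j for j, s in enumerate(ds.site_ids)}
    for site, alpha, i in ds.interactions.records:
        if site not in site_idx:
            raise ConsistencyError(f"interaction at unknown site: {(site, alpha, i)}")
        if alpha not in cons_idx:
            raise ConsistencyError(f"unknown consumer in record {(site, alpha, i)}")
        if i not in res_idx:
            raise ConsistencyError(f"unknown resource in record {(site, alpha, i)}")
        s = site_idx[site]
        if not ds.consumers.presence[s, cons_idx[alpha]]:
            raise ConsistencyError(
                f"interaction {(site, alpha, i)} recorded where consumer "
                f"{alpha!r} is absent"
            )
        if not ds.resources.presence[s, res_idx[i]]:
            raise ConsistencyError(
                f"interaction {(site, alpha, i)} recorded where resource "
                f"{i!r} is absent"
            )


def _read_csv(path, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise FormatError(f"cannot parse {path}: {e}") from e
    missing = set(columns) - set(df.columns)
    if missing:
        raise FormatError(f"{path} is missing required columns {sorted(missing)}")
    if df[list(columns)].isna().any().any():
        raise FormatError(f"{path} contains empty cells in required columns")
    return df[list(columns)].drop_duplicates()


def _table_from_long(occ: pd.DataFrame, guild: str, site_ids: tuple[str, ...]):
    sub = occ[occ["guild"] == guild]
    if sub.empty:
        raise ConsistencyError(f"no occurrence rows for guild {guild!r}")
    species = tuple(dict.fromkeys(sub["species"]))
    site_pos = {s: j for j, s in enumerate(site_ids)}
    pres = np.zeros((len(site_ids), len(species)), dtype=bool)
    sp_pos = {s: j for j, s in enumerate(species)}
    for site, sp in zip(sub["site"], sub["species"]):
        pres[site_pos[site], sp_pos[sp]] = True
    return SiteSpeciesTable(guild=guild, species_ids=species,
                            site_ids=site_ids, presence=pres)


def load_dataset(occurrence_path, interaction_path, name: str,
                 interaction_type: str) -> Dataset:
    """Load and validate a dataset from the canonical long-format CSVs.

    Duplicate rows collapse; any referential or presence violation raises a
    :class:`~coprune.errors.ConsistencyError` naming the offending record.
    """
    occ = _read_csv(occurrence_path, ("site", "guild", "species"))
    bad = set(occ["guild"]) - set(GUILDS)
    if bad:
        raise FormatError(f"unknown guild values in {occurrence_path}: {sorted(bad)}")
    inter = _read_csv(interaction_path, ("site", "consumer", "resource"))
    site_ids = tuple(dict.fromkeys(occ["site"]))
    consumers = _table_from_long(occ, "consumer", site_ids)
    resources = _table_from_long(occ, "resource", site_ids)
    records = InteractionRecordSet(tuple(
        (s, a, i) for s, a, i in zip(inter["site"], inter["consumer"],
                                     inter["resource"])
    ))
    return Dataset(name=name, interaction_type=interaction_type,
                   consumers=consumers, resources=resources,
                   interactions=records)


def write_dataset(ds: Dataset, occurrence_path, interaction_path) -> None:
    """Write a dataset back to the canonical CSVs (inverse of
    :func:`load_dataset` up to row order)."""
    rows = []
    for table in (ds.consumers, ds.resources):
        sites_arr, sp_arr = np.nonzero(table.presence)
        for s, j in zip(sites_arr, sp_arr):
            rows.append((table.site_ids[s], table.guild, table.species_ids[j]))
    pd.DataFrame(rows, columns=["site", "guild", "species"]).to_csv(
        occurrence_path, index=False)
    pd.DataFrame(list(ds.interactions.records),
                 columns=["site", "consumer", "resource"]).to_csv(
        interaction_path, index=False)


def write_network(net, path, *, dataset: str = "", seed=None) -> None:
    """Write a bipartite network as an edge-list CSV plus a JSON sidecar.

    The sidecar (``<path>.json``) records guild sizes, link count, network
    kind and provenance so a directory of realizations stays
    self-describing. ``read_network(write_network(x)) == x``.
    """
    path = Path(path)
    rows_i, cols_i = np.nonzero(net.adjacency)
    pd.DataFrame(
        {"consumer": [net.consumers[r] for r in rows_i],
         "resource": [net.resources[c] for c in cols_i]}
    ).to_csv(path, index=False)
    sidecar = {
        "dataset": dataset,
        "kind": net.kind,
        "n_consumers": len(net.consumers),
        "n_resources": len(net.resources),
        "n_links": int(net.adjacency.sum()),
        "seed": seed,
        "consumers": list(net.consumers),
        "resources": list(net.resources),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_network(path):
    """Load a network written by :func:`write_network`."""
    from .network_build import BipartiteNetwork  # avoid import cycle

    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    edges = pd.read_csv(path, dtype=str)
    consumers = tuple(sidecar["consumers"])
    resources = tuple(sidecar["resources"])
    adj = np.zeros((len(consumers), len(resources)), dtype=bool)
    ci = {c: k for k, c in enumerate(consumers)}
    ri = {r: k for k, r in enumerate(resources)}
    for a, i in zip(edges["consumer"], edges["resource"]):
        if a not in ci or i not in ri:
            raise ConsistencyError(f"edge ({a}, {i}) references unknown species")
        adj[ci[a], ri[i]] = True
    return BipartiteNetwork(consumers=consumers, resources=resources,
                            adjacency=adj, kind=sidecar["kind"])
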