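"""Building co-occurrence and interaction networks from site-level records.

The co-occurrence network links a consumer and a resource when they share
at least one spatial unit; it is read as the network of *potential*
interactions. Its weighted precursor is the co-occurrence frequency matrix
``N``, with ``N[α, i]`` the number of sites where consumer α and resource i
are both present — the quantity the interaction-rate model is built on.
The empirical interaction network links pairs observed interacting in at
least one unit and is always a subset of the co-occurrence network; the
fraction of co-occurrence links it realizes is ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import Dataset, SiteSpeciesTable
from .errors import ConsistencyError, DegenerateInputError

NETWORK_KINDS = ("cooccurrence", "interaction", "ir_realization", "random_pruned")

__all__ = [
    "CooccurrenceFrequencyMatrix",
    "BipartiteNetwork",
    "LinkFraction",
    "cooccurrence_frequencies",
    "cooccurrence_network",
    "interaction_network",
    "link_fraction",
    "degree_sequences",
]


@dataclass(frozen=True)
class CooccurrenceFrequencyMatrix:
    """Integer matrix of shared-site counts per consumer–resource pair."""

    consumers: tuple[str, ...]
    resources: tuple[str, ...]
    N: np.ndarray = field(repr=False)

    def __post_init__(self):
        N = np.asarray(self.N)
        if not np.issubdtype(N.dtype, np.integer):
            if not np.array_equal(N, np.round(N)):
                raise ConsistencyError("co-occurrence counts must be integers")
            N = N.astype(np.int64)
        if (N < 0).any():
            raise ConsistencyError("co-occurrence counts must be non-negative")
        if N.shape != (len(self.consumers), len(self.resources)):
            raise ConsistencyError(
                f"N has shape {N.shape}, expected "
                f"({len(self.consumers)}, {len(self.resources)})"
            )
        object.__setattr__(self, "N", N)

    @property
    def N_alpha(self) -> np.ndarray:
        """Per-consumer total co-occurrence count, N_α = Σ_i N_αi."""
        return self.N.sum(axis=1)


@dataclass(frozen=True)
class BipartiteNetwork:
    """Binary consumer × resource adjacency with a provenance tag."""

    consumers: tuple[str, ...]
    resources: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)
    kind: str = "cooccurrence"

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (len(self.consumers), len(self.resources)):
            raise ConsistencyError(
                f"adjacency has shape {adj.shape}, expected "
                f"({len(self.consumers)}, {len(self.resources)})"
            )
        if self.kind not in NETWORK_KINDS:
            raise ConsistencyError(f"unknown network kind {self.kind!r}")
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum())

    def is_subset_of(self, other: "BipartiteNetwork") -> bool:
        return (
            self.consumers == other.consumers
            and self.resources == other.resources
            and bool((~self.adjacency | other.adjacency).all())
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (
            self.consumers == other.consumers
            and self.resources == other.resources
            and self.kind == other.kind
            and np.array_equal(self.adjacency, other.adjacency)
        )


@dataclass(frozen=True)
class LinkFraction:
    """Realized-link fraction f = L_int / L_c for one dataset."""

    L_c: int
    L_int: int

    def __post_init__(self):
        if self.L_c <= 0:
            raise DegenerateInputError("co-occurrence network has no links")
        if not 0 <= self.L_int <= self.L_c:
            raise ConsistencyError(
                f"L_int={self.L_int} outside [0, L_c={self.L_c}]"
            )

    @property
    def f(self) -> float:
        return self.L_int / self.L_c


def cooccurrence_frequencies(consumers: SiteSpeciesTable,
                             resources: SiteSpeciesTable,
                             ) -> CooccurrenceFrequencyMatrix:
    """Count, for every consumer–resource pair, the sites both occupy.

    ``N[α, i]`` is the cardinality of the intersection of the two species'
    site sets — the inner product of their incidence columns.
    """
    if consumers.site_ids != resources.site_ids:
        raise ConsistencyError("tables do not share the same site list")
    N = consumers.presence.astype(np.int64).T @ resources.presence.astype(np.int64)
    return CooccurrenceFrequencyMatrix(
        consumers=consumers.species_ids, resources=resources.species_ids, N=N)


def cooccurrence_network(freq: CooccurrenceFrequencyMatrix) -> BipartiteNetwork:
    """Binarize the frequency matrix: linked iff co-present somewhere."""
    return BipartiteNetwork(consumers=freq.consumers, resources=freq.resources,
                            adjacency=freq.N >= 1, kind="cooccurrence")


def interaction_network(ds: Dataset) -> BipartiteNetwork:
    """Site-collapsed empirical interaction network (the metaweb)."""
    ci = {c: k for k, c in enumerate(ds.consumers.species_ids)}
    ri = {r: k for k, r in enumerate(ds.resources.species_ids)}
    adj = np.zeros((len(ci), len(ri)), dtype=bool)
    for a, i in ds.interactions.pairs():
        adj[ci[a], ri[i]] = True
    return BipartiteNetwork(consumers=ds.consumers.species_ids,
                            resources=ds.resources.species_ids,
                            adjacency=adj, kind="interaction")


def link_fraction(cooc: BipartiteNetwork, inter: BipartiteNetwork) -> LinkFraction:
    """Fraction of potential (co-occurrence) links that are realized."""
    if cooc.consumers != inter.consumers or cooc.resources != inter.resources:
        raise ConsistencyError("networks are over different species orderings")
    if not inter.is_subset_of(cooc):
        raise ConsistencyError(
            "interaction network is not a subset of the co-occurrence network")
    return LinkFraction(L_c=cooc.n_links, L_int=inter.n_links)


def degree_sequences(net: BipartiteNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Consumer degrees (row sums) and resource degrees (column sums)."""
    adj = net.adjacency
    return adj.sum(axis=1).astype(np.int64), adj.sum(axis=0).astype(np.int64)
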