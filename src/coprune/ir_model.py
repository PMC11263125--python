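"""The interaction-rate (IR) pruning model and the random-pruning null.

The IR model assumes a single per-site interaction rate p: a consumer α and
a resource i that co-occur in N_αi sites interact with probability

    P_αi = 1 − (1 − p)^N_αi,

so frequently co-occurring pairs are more likely to interact. Conditioning
each consumer on retaining at least one resource (no consumer survives
without one), the expected number of links is

    E[L(p)] = Σ_α Σ_i (1 − (1−p)^N_αi) / (1 − (1−p)^N_α),   N_α = Σ_i N_αi,

which is continuous and strictly increasing in p, from the number of
consumers (as p → 0 each consumer keeps exactly its one conditioned link)
up to the number of co-occurrence links L_c at p = 1. Calibration solves
E[L(p)] = f·L_c for the observed realized-link fraction f by bisection.

The random-pruning null keeps every co-occurrence link independently with
probability f, ignoring co-occurrence frequency — equivalent to setting
N_αi = 1 for all pairs — and applies no consumer conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InfeasibleTargetError
from .network_build import BipartiteNetwork, CooccurrenceFrequencyMatrix, LinkFraction

__all__ = [
    "IRCalibration",
    "EnsembleResult",
    "interaction_probability",
    "expected_links",
    "calibrate_p",
    "realize_ir",
    "random_prune",
    "ensemble",
]


@dataclass(frozen=True)
class IRCalibration:
    """Calibrated per-site interaction rate for one dataset."""

    p: float
    f_target: float
    expected_L_at_p: float
    L_c: int
    converged: bool
    tolerance: float


@dataclass(frozen=True)
class EnsembleResult:
    """A reproducible batch of pruned-network realizations."""

    realizations: tuple[BipartiteNetwork, ...]
    seeds: tuple[int, ...]
    mode: str
    per_consumer_mean_degree: np.ndarray = field(repr=False)
    per_resource_mean_degree: np.ndarray = field(repr=False)

    @property
    def n_realizations(self) -> int:
        return len(self.realizations)

    def mean_links(self) -> float:
        return float(np.mean([net.n_links for net in self.realizations]))


def interaction_probability(p: float, n) -> np.ndarray | float:
    """P_αi = 1 − (1 − p)^n, vectorized over co-occurrence counts n.

    Computed as −expm1(n · log1p(−p)) so small rates over many sites do
    not underflow.
    """
    if not 0.0 <= p <= 1.0:
        raise DegenerateInputError(f"interaction rate p={p} outside [0, 1]")
    n_arr = np.asarray(n, dtype=float)
    if (n_arr < 0).any() or not np.array_equal(n_arr, np.floor(n_arr)):
        raise DegenerateInputError("co-occurrence counts must be non-negative integers")
    if p == 1.0:
        out = np.where(n_arr > 0, 1.0, 0.0)
    else:
        out = -np.expm1(n_arr * np.log1p(-p))
    return float(out) if np.isscalar(n) else out


def expected_links(freq: CooccurrenceFrequencyMatrix, p: float) -> float:
    """Conditional expected link count E[L(p)] of the IR model.

    Each consumer's row is conditioned on at least one realized link,
    dividing by 1 − (1−p)^N_α; consumers therefore each contribute at
    least 1 and at most their count of co-occurring resources.
    """
    if not 0.0 < p <= 1.0:
        raise DegenerateInputError(f"expected_links requires p in (0, 1], got {p}")
    n_alpha = freq.N_alpha
    if (n_alpha == 0).any():
        bad = [c for c, na in zip(freq.consumers, n_alpha) if na == 0]
        raise DegenerateInputError(
            f"consumers with no co-occurring resource (conditioning undefined): {bad}")
    P = interaction_probability(p, freq.N)
    denom = interaction_probability(p, n_alpha)
    return float((P.sum(axis=1) / denom).sum())


def calibrate_p(freq: CooccurrenceFrequencyMatrix, f: LinkFraction | float,
                tolerance: float = 1e-10) -> IRCalibration:
    """Solve E[L(p)] = f·L_c for the per-site rate p by bisection.

    E[L] is strictly increasing on (0, 1], so the root is unique. The
    target must lie strictly above the conditioning floor (one link per
    consumer as p → 0) and at or below L_c.
    """
    f_val = f.f if isinstance(f, LinkFraction) else float(f)
    if not 0.0 < f_val <= 1.0:
        raise DegenerateInputError(f"f={f_val} outside (0, 1]")
    L_c = int((freq.N >= 1).sum())
    if L_c == 0:
        raise DegenerateInputError("empty co-occurrence network")
    target = f_val * L_c
    n_consumers = len(freq.consumers)
    if target <= n_consumers:
        raise InfeasibleTargetError(
            f"target f*L_c = {target:.4g} does not exceed the conditioning "
            f"floor of {n_consumers} consumers: as p -> 0 every consumer still "
            "keeps one link, so lower expectations are unreachable")
    if target > L_c:
        raise InfeasibleTargetError(
            f"target {target:.4g} exceeds the {L_c} co-occurrence links")

    if f_val == 1.0:
        return IRCalibration(p=1.0, f_target=1.0, expected_L_at_p=float(L_c),
                             L_c=L_c, converged=True, tolerance=tolerance)

    lo, hi = 1e-12, 1.0
    g = lambda p: expected_links(freq, p) - target
    # expected_links(·, hi) = L_c >= target; floor < target by the guard above
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15:
            break
    p_hat = 0.5 * (lo + hi)
    e_at_p = expected_links(freq, p_hat)
    converged = abs(e_at_p - target) <= max(tolerance * L_c, 1e-9)
    return IRCalibration(p=p_hat, f_target=f_val, expected_L_at_p=e_at_p,
                         L_c=L_c, converged=converged, tolerance=tolerance)


def realize_ir(freq: CooccurrenceFrequencyMatrix, p: float,
               seed: int | np.random.SeedSequence) -> BipartiteNetwork:
    """Draw one pruned network from the conditional IR model.

    Links are independent Bernoulli(P_αi) draws; any consumer whose row
    comes up empty is redrawn until it has at least one link, which is
    exactly the per-consumer conditioning in E[L(p)].
    """
    if p <= 0.0:
        raise DegenerateInputError(
            "p must be positive: at p=0 the conditioning (every consumer keeps "
            "a link) can never be satisfied")
    n_alpha = freq.N_alpha
    if (n_alpha == 0).any():
        raise DegenerateInputError(
            "every consumer needs at least one co-occurring resource")
    rng = np.random.default_rng(seed)
    P = interaction_probability(p, freq.N)
    adj = rng.random(P.shape) < P
    empty = ~adj.any(axis=1)
    while empty.any():
        rows = np.flatnonzero(empty)
        adj[rows] = rng.random((rows.size, P.shape[1])) < P[rows]
        empty[rows] = ~adj[rows].any(axis=1)
    return BipartiteNetwork(consumers=freq.consumers, resources=freq.resources,
                            adjacency=adj, kind="ir_realization")


def random_prune(cooc: BipartiteNetwork, f: LinkFraction | float,
                 seed: int | np.random.SeedSequence) -> BipartiteNetwork:
    """Null model: keep each co-occurrence link independently with
    probability f, blind to co-occurrence frequency and unconditioned."""
    f_val = f.f if isinstance(f, LinkFraction) else float(f)
    if not 0.0 < f_val <= 1.0:
        raise DegenerateInputError(f"f={f_val} outside (0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(cooc.adjacency.shape) < f_val
    return BipartiteNetwork(consumers=cooc.consumers, resources=cooc.resources,
                            adjacency=cooc.adjacency & keep, kind="random_pruned")


def ensemble(freq_or_net, p_or_f: float, mode: str, n_realizations: int = 100,
             seed: int = 0) -> EnsembleResult:
    """Run ``n_realizations`` prunings with per-realization seeds spawned
    deterministically from the master seed.

    ``mode='ir'`` expects a :class:`CooccurrenceFrequencyMatrix` and an
    interaction rate p; ``mode='random'`` expects the binary co-occurrence
    :class:`BipartiteNetwork` and a keep-fraction f.
    """
    if mode not in ("ir", "random"):
        raise ValueError(f"mode must be 'ir' or 'random', got {mode!r}")
    if n_realizations < 1:
        raise DegenerateInputError("n_realizations must be >= 1")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_realizations)
    child_ids = tuple(int(c.generate_state(1)[0]) for c in children)
    nets = []
    for child in children:
        if mode == "ir":
            nets.append(realize_ir(freq_or_net, p_or_f, child))
        else:
            nets.append(random_prune(freq_or_net, p_or_f, child))
    cons_deg = np.mean([n.adjacency.sum(axis=1) for n in nets], axis=0)
    res_deg = np.mean([n.adjacency.sum(axis=0) for n in nets], axis=0)
    return EnsembleResult(realizations=tuple(nets), seeds=child_ids, mode=mode,
                          per_consumer_mean_degree=cons_deg,
                          per_resource_mean_degree=res_deg)
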