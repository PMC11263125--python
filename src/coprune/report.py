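"""End-to-end pipeline: networks → f → calibration → ensembles → fits.

``run_pipeline`` reproduces, for one dataset, the comparison surfaces of
the analysis: the realized-link fraction f, degree-distribution model
selection on the co-occurrence and interaction networks, the calibrated
interaction rate p, IR and random-pruning ensembles with per-realization
fits, and per-species summaries from which the superlinearity of realized
vs potential degree and the frequency–generalism coupling are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import Dataset
from .degree_fit import DegreeSample, FitReport, select_best
from .errors import DegenerateInputError
from .ir_model import EnsembleResult, IRCalibration, calibrate_p, ensemble
from .network_build import (
    BipartiteNetwork,
    cooccurrence_frequencies,
    cooccurrence_network,
    degree_sequences,
    interaction_network,
    link_fraction,
)

__all__ = [
    "DatasetReport",
    "run_pipeline",
    "superlinearity_exponent",
    "frequency_generalism_stat",
    "p_vs_f_correlation",
    "species_summaries",
    "ensemble_slopes",
]

SUMMARY_COLUMNS = ("species", "guild", "potential_degree", "realized_degree",
                   "mean_cooc_frequency", "predicted_degree")


@dataclass(frozen=True)
class DatasetReport:
    """Everything the analysis computes for one dataset."""

    name: str
    f: float
    p_calibrated: float
    calibration: IRCalibration
    fit_reports: dict[tuple[str, str], FitReport]  # (guild, network_kind) -> report
    species_summaries: pd.DataFrame = field(repr=False)
    superlinearity_exponent: float | None
    ensemble_fit_reports: dict[tuple[str, str], tuple[str, ...]]
    ir_ensemble: EnsembleResult = field(repr=False)
    random_ensemble: EnsembleResult = field(repr=False)
    seed: int = 0

    def to_json(self) -> str:
        """Deterministic JSON serialization (same input + seed → same bytes)."""
        payload = {
            "name": self.name,
            "seed": self.seed,
            "f": self.f,
            "p_calibrated": self.p_calibrated,
            "superlinearity_exponent": self.superlinearity_exponent,
            "fit_reports": {
                f"{guild}/{kind}": rep.to_dict()
                for (guild, kind), rep in sorted(self.fit_reports.items())
            },
            "ensemble_best_families": {
                f"{mode}/{guild}": list(v)
                for (mode, guild), v in sorted(self.ensemble_fit_reports.items())
            },
            "species_summaries": self.species_summaries.to_dict("records"),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def species_summaries(freq, cooc: BipartiteNetwork, inter: BipartiteNetwork,
                      ir_ens: EnsembleResult | None = None) -> pd.DataFrame:
    """Per-species table of potential degree, realized degree, mean
    co-occurrence frequency over potential partners, and (optionally) the
    IR-ensemble mean realized degree."""
    rows = []
    cons_pot, res_pot = degree_sequences(cooc)
    cons_real, res_real = degree_sequences(inter)
    with np.errstate(invalid="ignore"):
        cons_freq = np.where(cons_pot > 0,
                             freq.N.sum(axis=1) / np.maximum(cons_pot, 1), np.nan)
        res_freq = np.where(res_pot > 0,
                            freq.N.sum(axis=0) / np.maximum(res_pot, 1), np.nan)
    cons_pred = (ir_ens.per_consumer_mean_degree if ir_ens is not None
                 else np.full(len(cooc.consumers), np.nan))
    res_pred = (ir_ens.per_resource_mean_degree if ir_ens is not None
                else np.full(len(cooc.resources), np.nan))
    for j, sp in enumerate(cooc.consumers):
        rows.append((sp, "consumer", int(cons_pot[j]), int(cons_real[j]),
                     float(cons_freq[j]), float(cons_pred[j])))
    for j, sp in enumerate(cooc.resources):
        rows.append((sp, "resource", int(res_pot[j]), int(res_real[j]),
                     float(res_freq[j]), float(res_pred[j])))
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def superlinearity_exponent(summaries: pd.DataFrame) -> float:
    """OLS slope of log(realized degree) on log(potential degree).

    A slope of 1 is proportional pruning (every species realizes the same
    fraction of its potential partners); above 1, generalists keep a
    disproportionate share — the super-generalist signature. Species with
    zero realized links are excluded (log undefined).
    """
    sub = summaries[summaries["realized_degree"] >= 1]
    if len(sub) < 3:
        raise DegenerateInputError(
            "need at least 3 species with a realized link")
    x = np.log(sub["potential_degree"].to_numpy(dtype=float))
    y = np.log(sub["realized_degree"].to_numpy(dtype=float))
    if np.unique(x).size < 2:
        raise DegenerateInputError(
            "potential degrees are constant; slope undefined")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def frequency_generalism_stat(summaries: pd.DataFrame) -> float:
    """Spearman correlation between a species' number of potential partners
    and its mean co-occurrence frequency with them.

    Positive values mean generalists in the abiotic niche also co-occur
    *more often* with each partner — the coupling that powers the IR
    model's superlinear pruning.
    """
    sub = summaries.dropna(subset=["mean_cooc_frequency"])
    if len(sub) < 3:
        raise DegenerateInputError("need at least 3 species")
    pot = sub["potential_degree"].to_numpy(dtype=float)
    frq = sub["mean_cooc_frequency"].to_numpy(dtype=float)
    if np.unique(pot).size < 2 or np.unique(frq).size < 2:
        raise DegenerateInputError(
            "constant inputs: rank correlation undefined")
    rho = stats.spearmanr(pot, frq).statistic
    return float(rho)


def p_vs_f_correlation(reports: list[DatasetReport]) -> float:
    """Pearson correlation between calibrated p and observed f across
    datasets."""
    if len(reports) < 3:
        raise DegenerateInputError("need at least 3 dataset reports")
    p = np.array([r.p_calibrated for r in reports], dtype=float)
    f = np.array([r.f for r in reports], dtype=float)
    if np.unique(p).size < 2 or np.unique(f).size < 2:
        raise DegenerateInputError("constant p or f: correlation undefined")
    return float(stats.pearsonr(p, f).statistic)


def ensemble_slopes(summaries: pd.DataFrame, ens: EnsembleResult,
                    guild: str = "consumer") -> list[float]:
    """Superlinearity slope of each realization in an ensemble."""
    sub = summaries[summaries["guild"] == guild]
    pot = sub["potential_degree"].to_numpy(dtype=float)
    out = []
    for net in ens.realizations:
        deg = net.adjacency.sum(axis=1) if guild == "consumer" \
            else net.adjacency.sum(axis=0)
        mask = (deg >= 1) & (pot >= 1)
        x, y = np.log(pot[mask]), np.log(deg[mask].astype(float))
        if mask.sum() >= 3 and np.unique(x).size >= 2:
            out.append(float(np.polyfit(x, y, 1)[0]))
    return out


def _guild_sample(net: BipartiteNetwork, guild: str) -> DegreeSample | None:
    cons, res = degree_sequences(net)
    deg = cons if guild == "consumer" else res
    deg = deg[deg >= 1]
    if deg.size == 0:
        return None
    return DegreeSample(degrees=deg, guild=guild, network_kind=net.kind)


def run_pipeline(ds: Dataset, n_realizations: int = 100, seed: int = 0,
                 fit_ensembles: bool = True) -> DatasetReport:
    """Run the full analysis on one dataset, reproducibly.

    Stages: co-occurrence frequencies → binary networks → f → calibration
    of p → IR and random ensembles (``n_realizations`` each) → degree-fit
    model selection on the empirical networks and, if ``fit_ensembles``,
    on every realization separately → species summaries and the
    superlinearity slope.
    """
    freq = cooccurrence_frequencies(ds.consumers, ds.resources)
    cooc = cooccurrence_network(freq)
    inter = interaction_network(ds)
    lf = link_fraction(cooc, inter)
    cal = calibrate_p(freq, lf)
    seq = np.random.SeedSequence(seed).spawn(2)
    ir_seed = int(seq[0].generate_state(1)[0] % (2**31))
    rnd_seed = int(seq[1].generate_state(1)[0] % (2**31))
    ir_ens = ensemble(freq, cal.p, "ir", n_realizations, ir_seed)
    rnd_ens = ensemble(cooc, lf.f, "random", n_realizations, rnd_seed)

    fit_reports: dict[tuple[str, str], FitReport] = {}
    for guild in ("consumer", "resource"):
        for net in (cooc, inter):
            sample = _guild_sample(net, guild)
            if sample is None:
                continue
            try:
                fit_reports[(guild, net.kind)] = select_best(sample)
            except DegenerateInputError:
                pass  # e.g. every degree equal to 1: no family identifiable

    ens_best: dict[tuple[str, str], tuple[str, ...]] = {}
    if fit_ensembles:
        for mode, ens_res in (("ir", ir_ens), ("random", rnd_ens)):
            for guild in ("consumer", "resource"):
                best = []
                for net in ens_res.realizations:
                    sample = _guild_sample(net, guild)
                    if sample is None:
                        continue
                    try:
                        best.append(select_best(sample).best_family)
                    except DegenerateInputError:
                        continue
                ens_best[(mode, guild)] = tuple(best)

    summaries = species_summaries(freq, cooc, inter, ir_ens)
    try:
        slope = superlinearity_exponent(
            summaries[summaries["guild"] == "consumer"])
    except DegenerateInputError:
        slope = None

    return DatasetReport(
        name=ds.name, f=lf.f, p_calibrated=cal.p, calibration=cal,
        fit_reports=fit_reports, species_summaries=summaries,
        superlinearity_exponent=slope, ensemble_fit_reports=ens_best,
        ir_ensemble=ir_ens, random_ensemble=rnd_ens, seed=seed)
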