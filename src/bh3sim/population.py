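"""Heterogeneous cell populations under fractional BH3-mimetic inhibition.

Fractional killing is modelled as the deterministic consequence of
cell-to-cell variability: each simulated cell starts from the line's fitted
steady state with every protein total independently scaled by a lognormal
factor (mean 1, configurable CV), then re-equilibrated by a short drug-free
pre-run so complexes match the perturbed totals.  Treatment introduces the
groove-binding drug species for each target at a total amount calibrated so
the requested fraction of the target is drug-bound in the mean cell, and a
cell is scored dead at the first time its MOMP signal (summed pore
concentration) crosses a threshold slightly above the naive population's
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .canonical import ANTI_APOPTOTIC, BH3_ONLY, EFFECTORS, drug_name
from .lines import VirtualCellLine
from .network import NetworkModel
from .simulate import IntegrationError, SteadyStateError, simulate, steady_state

DEFAULT_N_CELLS = 100
DEFAULT_CV = 0.32
DEFAULT_DURATION_H = 72.0
DEFAULT_THRESHOLD_FACTOR = 1.10
PRE_RUN_H = 10.0  # drug-free complex re-equilibration, excluded from the clock
OUTPUT_GRID_H = 0.1


class CalibrationError(RuntimeError):
    """Drug-amount bisection failed to reach the requested occupancy."""


# ---------------------------------------------------------------------------
# population sampling


@dataclass
class CellPopulation:
    """n seeded per-cell initial-condition vectors for one line."""

    line: VirtualCellLine
    n_cells: int
    cv: float
    seed: int
    initial_states: np.ndarray  # (cell, species), raw scaled states

    _equilibrated: np.ndarray | None = field(default=None, repr=False)

    def model(self) -> NetworkModel:
        return self.line.effective_model()

    def equilibrated_states(self, pre_run_h: float = PRE_RUN_H) -> np.ndarray:
        """Per-cell states after the drug-free pre-run (cached)."""
        if self._equilibrated is None:
            model = self.model()
            out = np.empty_like(self.initial_states)
            for i, x0 in enumerate(self.initial_states):
                out[i] = simulate(model, x0, pre_run_h).final_state()
            self._equilibrated = out
        return self._equilibrated


def lognormal_factors(cv: float, size: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Mean-1 lognormal scale factors with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def sample_population(
    line: VirtualCellLine,
    n_cells: int = DEFAULT_N_CELLS,
    cv: float = DEFAULT_CV,
    seed: int = 0,
) -> CellPopulation:
    """Sample per-cell initial conditions around the fitted steady state.

    Each protein monomer total receives an independent lognormal factor
    (mean 1, coefficient of variation ``cv``); a species is scaled by the
    product of its constituents' factors, so complexes co-vary with their
    members.  The clamped signaling input is not varied.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    model = line.model
    monomers = model.monomers()
    rng = np.random.default_rng(seed)
    factors = lognormal_factors(cv, (n_cells, len(monomers)), rng)
    base = np.maximum(line.fitted_state.state, 0.0)
    scale = np.ones((n_cells, model.n_species))
    for j, s in enumerate(model.species):
        for c in dict.fromkeys(s.constituents):  # distinct constituents
            if c in monomers:
                scale[:, j] *= factors[:, monomers.index(c)]
    states = base[None, :] * scale
    return CellPopulation(line=line, n_cells=n_cells, cv=cv, seed=seed, initial_states=states)


def mix_populations(
    major: CellPopulation, minor: CellPopulation, minor_proportion: float
) -> CellPopulation:
    """Mixed population of two parameterisations of the same topology.

    Models a line harbouring a subclone (e.g. a MYC-overexpressing
    fraction): the first ``round(n * minor_proportion)`` cells of the minor
    population replace cells of the major one.  Both populations must share
    the network topology; treatment simulation uses the major line's
    kinetics, the subclone enters through its initial conditions.
    """
    if not 0.0 <= minor_proportion <= 1.0:
        raise ValueError("minor_proportion must be in [0, 1]")
    if major.model().species_names() != minor.model().species_names():
        raise ValueError("populations must share the same (pruned) topology")
    n_minor = int(round(major.n_cells * minor_proportion))
    states = major.initial_states.copy()
    states[:n_minor] = minor.initial_states[:n_minor]
    return CellPopulation(
        line=major.line,
        n_cells=major.n_cells,
        cv=major.cv,
        seed=major.seed,
        initial_states=states,
    )


# ---------------------------------------------------------------------------
# fractional inhibition


def _occupancy_weights(model: NetworkModel, target: str) -> tuple[np.ndarray, np.ndarray]:
    w_total = model.monomer_weights(target)
    w_bound = np.zeros_like(w_total)
    dname = drug_name(target)
    for i, s in enumerate(model.species):
        if dname in s.constituents:
            w_bound[i] = s.constituents.count(target)
    return w_total, w_bound


def target_occupancy(model: NetworkModel, state: np.ndarray, target: str) -> float:
    """Fraction of the target protein currently drug-bound."""
    w_total, w_bound = _occupancy_weights(model, target)
    total = w_total @ state
    return float(w_bound @ state / total) if total > 0 else 0.0


@dataclass
class InhibitedSystem:
    """A line plus calibrated drug amounts realising fractional inhibition."""

    line: VirtualCellLine
    drug_amounts: dict[str, float]  # target -> total drug added per cell

    def dose_state(self, state: np.ndarray) -> np.ndarray:
        model = self.line.effective_model()
        x = state.copy()
        for target, amount in self.drug_amounts.items():
            x[model.species_index(drug_name(target))] += amount
        return x


def calibrate_drug_amount(
    line: VirtualCellLine,
    target: str,
    fraction: float,
    tol: float = 1e-3,
    max_amount: float = 1e8,
) -> float:
    """Bisection on total drug so mean-cell steady-state occupancy = fraction.

    Full inhibition (``fraction`` = 1) is calibrated to 99.95% occupancy,
    the practical ceiling for a competitive, reversible binder.
    """
    model = line.effective_model()
    if target not in model.monomers():
        raise KeyError(f"target {target!r} absent from (pruned) model")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("inhibition fraction must be in [0, 1]")
    if fraction == 0.0:
        return 0.0
    goal = min(fraction, 0.9995)
    base = np.maximum(line.fitted_state.state, 0.0)
    didx = model.species_index(drug_name(target))

    def occ(amount: float) -> float:
        x = base.copy()
        x[didx] += amount
        try:
            ss_state = steady_state(model, x, tol=1e-6, t_max=1e5).state
        except SteadyStateError:
            # drug binding equilibrates fast; a residual slow drift in the
            # permeabilization machinery does not move occupancy
            ss_state = simulate(model, x, 2000.0).final_state()
        return target_occupancy(model, ss_state, target)

    lo, hi = 0.0, float(model.monomer_weights(target) @ base)  # start near target total
    occ_hi = occ(hi)
    while occ_hi < goal:
        hi *= 4.0
        if hi > max_amount:
            raise CalibrationError(
                f"occupancy {occ_hi:.4f} < {goal:.4f} even at drug amount {hi:.3g}"
            )
        occ_hi = occ(hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if occ(mid) < goal:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol * max(hi, 1.0):
            break
    return hi


def apply_inhibition(
    line: VirtualCellLine, target: str, fraction: float
) -> InhibitedSystem:
    """Competitive-drug realisation of fractional target inhibition."""
    amount = calibrate_drug_amount(line, target, fraction)
    return InhibitedSystem(line=line, drug_amounts={target: amount} if amount > 0 else {})


# ---------------------------------------------------------------------------
# treatment


@dataclass
class TreatmentSpec:
    """Targets with inhibition fractions, horizon, and death threshold.

    ``baseline_stat`` selects the naive-population MOMP level the death
    threshold multiplies: ``"max"`` (default; the highest level present in
    any naive cell, so an untreated population never scores deaths),
    ``"mean"``, or ``"per_cell"`` (each cell thresholds its own baseline).
    """

    targets: list[tuple[str, float]]
    duration: float = DEFAULT_DURATION_H
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR
    baseline_stat: str = "max"

    def __post_init__(self) -> None:
        if self.threshold_factor <= 1.0:
            raise ValueError("threshold_factor must be > 1")
        for t, f in self.targets:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"inhibition fraction for {t!r} outside [0, 1]")
        if self.baseline_stat not in ("max", "mean", "per_cell"):
            raise ValueError("baseline_stat must be 'max', 'mean' or 'per_cell'")


@dataclass
class TreatmentResult:
    """Per-cell death times and the population viability readout."""

    times: np.ndarray  # output grid, hours since treatment start
    death_times: np.ndarray  # hours, NaN = survived the horizon
    viability_curve: np.ndarray  # V(t) on ``times``
    viability_72h: float
    baseline: float | np.ndarray  # scalar, or per-cell for per_cell mode
    threshold: float | np.ndarray
    momp_traces: np.ndarray  # (cell, time) MOMP signal

    @property
    def n_cells(self) -> int:
        return len(self.death_times)

    def survivors(self) -> np.ndarray:
        return np.isnan(self.death_times)

    def viability_at(self, t: float) -> float:
        dead = np.sum(self.death_times <= t)
        return 1.0 - dead / self.n_cells


def _first_crossing(times: np.ndarray, momp: np.ndarray, threshold: float) -> float:
    """Earliest crossing time, linearly interpolated; NaN if never."""
    above = momp >= threshold
    if not above.any():
        return np.nan
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    t0, t1 = times[i - 1], times[i]
    m0, m1 = momp[i - 1], momp[i]
    if m1 == m0:
        return float(t1)
    return float(t0 + (threshold - m0) * (t1 - t0) / (m1 - m0))


def death_times_from_traces(
    times: np.ndarray,
    momp_traces: np.ndarray,
    threshold: float | np.ndarray,
) -> np.ndarray:
    thr = np.broadcast_to(np.asarray(threshold, dtype=float), (momp_traces.shape[0],))
    return np.array(
        [_first_crossing(times, trace, t) for trace, t in zip(momp_traces, thr)]
    )


def viability_curve(times: np.ndarray, death_times: np.ndarray) -> np.ndarray:
    dt = death_times[~np.isnan(death_times)]
    return 1.0 - np.searchsorted(np.sort(dt), times, side="right") / len(death_times)


def run_treatment(
    population: CellPopulation,
    treatment: TreatmentSpec,
    system: InhibitedSystem | None = None,
) -> TreatmentResult:
    """Simulate every cell under the treatment and score threshold deaths.

    The naive baseline is measured on the pre-run-equilibrated, drug-free
    population; the death threshold is ``threshold_factor`` times the
    configured baseline statistic.  Death time is the earliest (linearly
    interpolated) crossing of the cell's MOMP signal.
    """
    if not treatment.targets and system is None:
        raise ValueError("treatment must specify at least one target")
    model = population.model()
    if system is None:
        amounts: dict[str, float] = {}
        for target, f in treatment.targets:
            amt = calibrate_drug_amount(population.line, target, f)
            if amt > 0:
                amounts[target] = amt
        system = InhibitedSystem(line=population.line, drug_amounts=amounts)

    states = population.equilibrated_states()
    pore = model.pore_indices()
    baselines = states[:, pore].sum(axis=1) if pore.size else np.zeros(len(states))
    if treatment.baseline_stat == "max":
        baseline: float | np.ndarray = float(baselines.max())
    elif treatment.baseline_stat == "mean":
        baseline = float(baselines.mean())
    else:
        baseline = baselines
    threshold = treatment.threshold_factor * np.asarray(baseline, dtype=float)

    times = np.arange(0.0, treatment.duration + OUTPUT_GRID_H / 2, OUTPUT_GRID_H)
    momp_traces = np.empty((population.n_cells, len(times)))
    for i, x in enumerate(states):
        try:
            traj = simulate(model, system.dose_state(x), treatment.duration, t_eval=times)
        except IntegrationError as err:
            raise IntegrationError(f"cell {i}: {err}", err.last_time) from err
        momp_traces[i] = traj.momp()

    death = death_times_from_traces(times, momp_traces, threshold)
    vcurve = viability_curve(times, death)
    return TreatmentResult(
        times=times,
        death_times=death,
        viability_curve=vcurve,
        viability_72h=1.0 - np.sum(death <= DEFAULT_DURATION_H) / population.n_cells,
        baseline=baseline,
        threshold=threshold if np.ndim(threshold) else float(threshold),
        momp_traces=momp_traces,
    )


# ---------------------------------------------------------------------------
# dose response


@dataclass
class DoseResponseGrid:
    target: str
    fractions: np.ndarray
    viability: np.ndarray  # viability at 72 h per fraction

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fraction": self.fractions, "viability_72h": self.viability})


def dose_response(
    line: VirtualCellLine,
    target: str,
    n_cells: int = DEFAULT_N_CELLS,
    seed: int = 0,
    cv: float = DEFAULT_CV,
    n_fractions: int = 10,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    population: CellPopulation | None = None,
) -> DoseResponseGrid:
    """Viability at 72 h across equally spaced inhibition fractions 0..1.

    One shared population sample (common random numbers) is reused for all
    fractions so the dose–response reflects dynamics, not sampling noise.
    """
    pop = population or sample_population(line, n_cells=n_cells, cv=cv, seed=seed)
    fractions = np.linspace(0.0, 1.0, n_fractions)
    viability = np.empty_like(fractions)
    for k, f in enumerate(fractions):
        spec = TreatmentSpec(targets=[(target, float(f))], threshold_factor=threshold_factor)
        viability[k] = run_treatment(pop, spec).viability_72h
    return DoseResponseGrid(target=target, fractions=fractions, viability=viability)


# ---------------------------------------------------------------------------
# survivor-vs-dying contrast


def _derived_quantities(model: NetworkModel, states: np.ndarray) -> dict[str, np.ndarray]:
    pro = list(EFFECTORS) + list(BH3_ONLY)
    w_pro = np.zeros(model.n_species)
    w_mom = np.zeros(model.n_species)
    w_anti = np.zeros(model.n_species)
    for i, s in enumerate(model.species):
        n_pro = sum(1 for c in s.constituents if c in pro)
        w_pro[i] = n_pro
        if s.compartment == "MOM":
            w_mom[i] = n_pro
        w_anti[i] = sum(1 for c in s.constituents if c in ANTI_APOPTOTIC)
    return {
        "total_pro_apoptotic": states @ w_pro,
        "MOM_bound_pro_apoptotic": states @ w_mom,
        "total_anti_apoptotic": states @ w_anti,
    }


def compare_survivors(
    population: CellPopulation,
    result: TreatmentResult,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-test the pre-treatment state of dying vs surviving cells.

    For every species and the derived pro-/anti-apoptotic load quantities,
    returns group means, effect direction, Mann-Whitney p-values and
    Benjamini-Hochberg adjusted q-values.
    """
    surv = result.survivors()
    if surv.all() or not surv.any():
        raise ValueError("no contrast: need both surviving and dying cells")
    model = population.model()
    states = population.equilibrated_states()
    columns = {name: states[:, i] for i, name in enumerate(model.species_names())}
    columns.update(_derived_quantities(model, states))
    rows = []
    for name, values in columns.items():
        a, b = values[~surv], values[surv]  # dying, surviving
        if np.ptp(values) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "quantity": name,
                "mean_dying": float(a.mean()),
                "mean_surviving": float(b.mean()),
                "direction": "higher_in_dying" if a.mean() > b.mean() else "higher_in_surviving",
                "p_value": p,
            }
        )
    frame = pd.DataFrame(rows)
    frame["q_value"] = stats.false_discovery_control(frame["p_value"].to_numpy())
    frame["significant"] = frame["q_value"] < alpha
    return frame.sort_values("q_value", kind="stable").reset_index(drop=True)
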