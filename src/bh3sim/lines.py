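"""Virtual cell lines: profile-constrained parameterisation of the network.

A cell line is characterised experimentally by semi-quantitative
immunoprecipitation (IP) densitometry — total abundance of each BCL2-family
protein, normalised to the most abundant anti-apoptotic protein — and by
co-immunoprecipitation (co-IP) densitometry giving, for each anti-apoptotic
protein, the fraction of each partner protein bound to it.

A :class:`VirtualCellLine` is the canonical network with line-specific
synthesis rates and per-heterodimer efflux rates chosen so that the model's
pre-treatment steady state reproduces both measurements.  Undetected
proteins are pruned from the network together with every complex and
reaction that involves them.  Genetic lesions are named multiplicative
modifiers of expression/degradation rates applied on top of a fitted line.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .canonical import (
    ACTIVE_EFFECTOR_PARTNERS,
    ANTI_APOPTOTIC,
    BH3_ONLY,
    BH3_PARTNERS,
    EFFECTORS,
    MONOMERS,
    default_initial_state,
)
from .network import NetworkModel, NetworkValidationError
from .simulate import SteadyState, SteadyStateError, steady_state

#: reference total abundance (a.u.) assigned to the most abundant
#: anti-apoptotic protein; fixes the scale that normalised densitometry
#: leaves free.
REFERENCE_TOTAL = 300.0

#: (anti-apoptotic, partner) pairs with a fitted heterodimer-efflux rate.
COIP_PAIRS: list[tuple[str, str]] = [
    (a, b) for a in ANTI_APOPTOTIC for b in BH3_PARTNERS[a]
] + [(a, e) for a in ANTI_APOPTOTIC for e in ACTIVE_EFFECTOR_PARTNERS[a]]


def efflux_parameter(anti: str, partner: str) -> str:
    """Name of the efflux rate for the (anti, partner) heterodimer."""
    if partner in EFFECTORS:
        return f"ke_{anti}_{partner}a"
    return f"ke_{anti}_{partner}"


class ProfileError(ValueError):
    """Raised for structurally invalid or infeasible densitometry profiles."""


@dataclass
class DensitometryProfile:
    """Normalised IP/co-IP summary of one cell line.

    ``abundances`` maps protein name to relative total abundance with the
    most abundant anti-apoptotic protein at 1.0; ``coip_fractions`` maps
    (anti-apoptotic, partner) to the fraction of the partner's total pool
    bound to that anti-apoptotic protein.
    """

    abundances: dict[str, float]
    coip_fractions: dict[tuple[str, str], float] = field(default_factory=dict)
    detected: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.detected:
            self.detected = frozenset(p for p, v in self.abundances.items() if v > 0)
        self.validate()

    def validate(self) -> None:
        for p, v in self.abundances.items():
            if p not in MONOMERS:
                raise ProfileError(f"unknown protein {p!r} in profile")
            if v < 0 or not np.isfinite(v):
                raise ProfileError(f"abundance of {p!r} must be finite and >= 0")
        antis = [a for a in ANTI_APOPTOTIC if a in self.detected]
        if antis:
            top = max(self.abundances.get(a, 0.0) for a in antis)
            if abs(top - 1.0) > 1e-6:
                raise ProfileError(
                    f"most abundant detected anti-apoptotic protein must be 1.0, got {top}"
                )
        for p in self.abundances:
            if p not in self.detected and self.abundances[p] != 0:
                raise ProfileError(f"undetected protein {p!r} has nonzero abundance")
        per_partner: dict[str, float] = {}
        for (a, b), f in self.coip_fractions.items():
            if (a, b) not in COIP_PAIRS:
                raise ProfileError(f"no heterodimer for pair ({a}, {b})")
            if f < 0 or f > 1:
                raise ProfileError(f"co-IP fraction for ({a}, {b}) outside [0, 1]: {f}")
            per_partner[b] = per_partner.get(b, 0.0) + f
        for b, total in per_partner.items():
            if total > 1 + 1e-9:
                raise ProfileError(
                    f"co-IP fractions for partner {b!r} sum to {total:.3f} > 1 (infeasible)"
                )

    # -- config dialects ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DensitometryProfile":
        """Read a cell-line config: ``densitometry:`` protein->value,
        ``coip:`` anti->partner->fraction."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        abundances = {p: float(v) for p, v in (payload.get("densitometry") or {}).items()}
        coip = {
            (a, b): float(f)
            for a, partners in (payload.get("coip") or {}).items()
            for b, f in partners.items()
        }
        return cls(abundances=abundances, coip_fractions=coip)

    @classmethod
    def from_csvs(cls, profile_csv: str | Path, coip_csv: str | Path | None = None):
        abundances: dict[str, float] = {}
        detected: set[str] = set()
        with open(profile_csv, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                p = row["protein"].strip()
                abundances[p] = float(row["abundance"])
                if row.get("detected", "true").strip().lower() in ("1", "true", "yes"):
                    detected.add(p)
        coip: dict[tuple[str, str], float] = {}
        if coip_csv is not None:
            with open(coip_csv, newline="", encoding="utf-8") as fh:
                for row in csv.DictReader(fh):
                    coip[(row["anti_apoptotic"].strip(), row["partner"].strip())] = float(
                        row["fraction"]
                    )
        return cls(abundances=abundances, coip_fractions=coip, detected=frozenset(detected))

    def to_csvs(self, profile_csv: str | Path, coip_csv: str | Path) -> None:
        with open(profile_csv, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["protein", "abundance", "detected"])
            for p in MONOMERS:
                if p in self.abundances:
                    w.writerow([p, repr(self.abundances[p]), p in self.detected])
        with open(coip_csv, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["anti_apoptotic", "partner", "fraction"])
            for (a, b), f in self.coip_fractions.items():
                w.writerow([a, b, repr(f)])


# ---------------------------------------------------------------------------
# steady-state summaries (the quantities IP/co-IP densitometry reports)


def protein_totals(model: NetworkModel, state: np.ndarray) -> dict[str, float]:
    """Total copies of each protein monomer (free + complexed + oligomeric)."""
    return {p: float(model.monomer_weights(p) @ state) for p in model.monomers()}


def bound_pair_total(model: NetworkModel, state: np.ndarray, anti: str, partner: str) -> float:
    """Summed abundance of all drug-free complexes containing anti & partner."""
    total = 0.0
    for i, s in enumerate(model.species):
        cons = s.constituents
        if anti in cons and partner in cons and not any(c.startswith("dg_") for c in cons):
            total += state[i]
    return float(total)


def coip_fractions_of_state(
    model: NetworkModel, state: np.ndarray
) -> dict[tuple[str, str], float]:
    """Fraction of each partner bound per anti-apoptotic protein at ``state``."""
    totals = protein_totals(model, state)
    out: dict[tuple[str, str], float] = {}
    for a, b in COIP_PAIRS:
        if a in totals and b in totals and totals[b] > 0:
            out[(a, b)] = bound_pair_total(model, state, a, b) / totals[b]
    return out


def normalized_abundances(model: NetworkModel, state: np.ndarray) -> dict[str, float]:
    totals = protein_totals(model, state)
    antis = [a for a in ANTI_APOPTOTIC if a in totals]
    top = max((totals[a] for a in antis), default=0.0)
    if top <= 0:
        raise ValueError("no anti-apoptotic protein present; cannot normalise")
    return {p: totals[p] / top for p in totals}


def profile_of_state(model: NetworkModel, state: np.ndarray) -> DensitometryProfile:
    """Noise-free densitometry summary of a model state."""
    return DensitometryProfile(
        abundances=normalized_abundances(model, state),
        coip_fractions=coip_fractions_of_state(model, state),
    )


# ---------------------------------------------------------------------------
# pruning


def prune_network(model: NetworkModel, profile: DensitometryProfile) -> NetworkModel:
    """Remove undetected proteins, species containing them, and their reactions."""
    undetected = {p for p in model.monomers() if p not in profile.detected}
    if not undetected:
        return model
    removed = {
        s.name for s in model.species if any(c in undetected for c in s.constituents)
    }
    reactions = [
        r
        for r in model.reactions
        if not (set(r.reactants) | set(r.products)) & removed
    ]
    used = set()
    for r in reactions:
        used.update(r.reactants)
        used.update(r.products)
    species = [
        s for s in model.species if s.name not in removed and (s.name in used or s.role != "drug")
    ]
    if not any(s.role == "pore" for s in species):
        raise NetworkValidationError(
            "pruning removed all effectors; model cannot exhibit MOMP"
        )
    return NetworkModel(species, reactions, model.parameters)


# ---------------------------------------------------------------------------
# virtual cell line


@dataclass
class LesionSpec:
    """Named multiplicative modifiers of kinetic rates (all factors > 0)."""

    name: str
    modifiers: dict[str, float]

    def __post_init__(self) -> None:
        for p, f in self.modifiers.items():
            if f <= 0 or not np.isfinite(f):
                raise ValueError(f"lesion {self.name!r}: factor for {p!r} must be > 0")


#: directions taken from known lesion biology; magnitudes are study defaults.
LESION_REGISTRY: dict[str, LesionSpec] = {
    "MYC_translocation": LesionSpec("MYC_translocation", {"s_BAX": 2.0, "s_BIM": 2.0}),
    "BCL2_amplification": LesionSpec("BCL2_amplification", {"s_BCL2": 2.0}),
    "TP53_mutant": LesionSpec("TP53_mutant", {"s_MCL1": 0.5}),
    "p300_truncation": LesionSpec(
        "p300_truncation", {"d_MCL1_c": 2.0, "d_MCL1_m": 2.0, "d_cpx_MCL1_BIM": 2.0}
    ),
}

_OVERRIDE_PREFIXES = ("s_", "d_", "ke_", "d_cpx_")


@dataclass
class VirtualCellLine:
    """A parameterised (possibly pruned) network plus its fitted steady state."""

    name: str
    model: NetworkModel  # topology with base parameters
    overrides: dict[str, float]
    fitted_state: SteadyState
    lesions: list[LesionSpec] = field(default_factory=list)
    fit_objective: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        for p in self.overrides:
            if not p.startswith(_OVERRIDE_PREFIXES):
                raise ValueError(
                    f"override {p!r} is not an expression/degradation/efflux rate"
                )

    def effective_model(self) -> NetworkModel:
        return self.model.with_parameters(self.overrides)

    def profile(self) -> DensitometryProfile:
        return profile_of_state(self.model, self.fitted_state.state)


def apply_lesion(line: VirtualCellLine, lesion: LesionSpec | str) -> VirtualCellLine:
    """Return a new line with lesion factors applied and state re-equilibrated."""
    if isinstance(lesion, str):
        try:
            lesion = LESION_REGISTRY[lesion]
        except KeyError:
            raise KeyError(f"unknown lesion {lesion!r}") from None
    base = line.effective_model()
    overrides = dict(line.overrides)
    for p, f in lesion.modifiers.items():
        if p not in base.parameters.values:
            raise KeyError(f"lesion {lesion.name!r}: unknown parameter {p!r}")
        overrides[p] = base.parameters[p] * f
    model = line.model.with_parameters(overrides)
    ss = steady_state(model, np.maximum(line.fitted_state.state, 0.0))
    return VirtualCellLine(
        name=line.name,
        model=line.model,
        overrides=overrides,
        fitted_state=ss,
        lesions=line.lesions + [lesion],
        fit_objective=line.fit_objective,
        converged=line.converged,
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitConfig:
    """Settings for the automated steady-state-constrained fit."""

    objective_ceiling: float = 0.12  # sum of squared residuals flagged OK
    max_starts: int = 3
    warm_iterations: int = 10
    max_nfev: int = 200
    ss_tol: float = 1e-8
    efflux_bounds: tuple[float, float] = (1e-6, 2.0)


class _FitProblem:
    """Residuals of simulated vs measured densitometry, in log/linear mix."""

    def __init__(self, model: NetworkModel, profile: DensitometryProfile, cfg: FitConfig):
        self.model = model
        self.profile = profile
        self.cfg = cfg
        present = set(model.monomers())
        self.synth_proteins = [p for p in MONOMERS if p in present]
        self.efflux_pairs = [
            (a, b)
            for (a, b) in COIP_PAIRS
            if a in present and b in present
        ]
        self.abund_targets = [
            (p, profile.abundances[p])
            for p in self.synth_proteins
            if profile.abundances.get(p, 0.0) > 0
        ]
        self.frac_targets = [
            ((a, b), f)
            for (a, b), f in profile.coip_fractions.items()
            if a in present and b in present
        ]
        self.antis = [a for a in ANTI_APOPTOTIC if a in present]
        self._x0 = default_initial_state(model)

    def param_names(self) -> list[str]:
        return [f"s_{p}" for p in self.synth_proteins] + [
            efflux_parameter(a, b) for (a, b) in self.efflux_pairs
        ]

    def steady(self, theta: np.ndarray) -> tuple[NetworkModel, np.ndarray]:
        # always equilibrate from the cold start: bistable parameterisations
        # would otherwise let the optimiser fit a different stable branch
        # than the one the returned line reports
        values = dict(zip(self.param_names(), np.exp(theta)))
        m = self.model.with_parameters(values)
        try:
            ss = steady_state(m, self._x0, tol=self.cfg.ss_tol, t_max=3e4)
            state = ss.state
        except SteadyStateError:
            # pathological corners of parameter space relax very slowly; an
            # approximate state keeps the optimiser moving
            from .simulate import simulate

            state = simulate(m, self._x0, 3e4).final_state()
        return m, state

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        m, x = self.steady(theta)
        totals = protein_totals(m, x)
        top = max(totals[a] for a in self.antis)
        res = [np.log(max(totals[p] / top, 1e-12) / d) for p, d in self.abund_targets]
        fracs = coip_fractions_of_state(m, x)
        res += [fracs.get(pair, 0.0) - f for pair, f in self.frac_targets]
        res.append(np.log(top / REFERENCE_TOTAL))  # gauge anchor
        return np.asarray(res)

    def initial_theta(self) -> np.ndarray:
        # synthesis proportional to target abundance; mid-range efflux
        s0 = []
        for p in self.synth_proteins:
            target = max(self.profile.abundances.get(p, 0.0), 1e-3)
            s0.append(np.log(max(0.05 * REFERENCE_TOTAL * target * 0.05, 1e-4) / 0.05))
        e0 = [np.log(0.02)] * len(self.efflux_pairs)
        return np.array(s0 + e0)

    def warm_start(self, theta: np.ndarray) -> np.ndarray:
        """Multiplicative fixed-point pass before gradient-based polishing."""
        ns = len(self.synth_proteins)
        lo, hi = np.log(self.cfg.efflux_bounds)
        for _ in range(self.cfg.warm_iterations):
            m, x = self.steady(theta)
            totals = protein_totals(m, x)
            top = max(totals[a] for a in self.antis)
            for i, p in enumerate(self.synth_proteins):
                target = self.profile.abundances.get(p, 0.0)
                if target > 0:
                    ratio = target / max(totals[p] / top, 1e-12)
                    theta[i] += 0.8 * np.clip(np.log(ratio), -2.0, 2.0)
            theta[: ns] += -0.5 * np.clip(np.log(top / REFERENCE_TOTAL), -2.0, 2.0)
            fracs = coip_fractions_of_state(m, x)
            for j, (a, b) in enumerate(self.efflux_pairs):
                target = self.profile.coip_fractions.get((a, b))
                if target is not None and target > 1e-6:
                    sim = max(fracs.get((a, b), 0.0), 1e-9)
                    theta[ns + j] += np.clip(np.log(sim / target), -1.5, 1.5)
                    theta[ns + j] = np.clip(theta[ns + j], lo, hi)
        return theta


def fit_cell_line(
    model: NetworkModel,
    profile: DensitometryProfile,
    config: FitConfig | None = None,
    name: str = "line",
    seed: int = 0,
) -> VirtualCellLine:
    """Fit per-protein synthesis and per-heterodimer efflux rates to a profile.

    Minimises squared log-abundance error plus squared co-IP-fraction error
    at the model's steady state, with a gauge anchor pinning the most
    abundant anti-apoptotic protein to :data:`REFERENCE_TOTAL`.  A damped
    multiplicative fixed-point pass warm-starts a bounded least-squares
    polish; additional seeded restarts run only if the objective stays above
    ``config.objective_ceiling``.
    """
    cfg = config or FitConfig()
    detected_antis = [a for a in ANTI_APOPTOTIC if a in profile.detected]
    detected_eff = [e for e in EFFECTORS if e in profile.detected]
    if not detected_antis or not detected_eff:
        raise ProfileError(
            "profile must detect at least one anti-apoptotic protein and one effector"
        )
    prob = _FitProblem(model, profile, cfg)
    ns = len(prob.synth_proteins)
    lo = np.concatenate(
        [np.full(ns, np.log(1e-4)), np.full(len(prob.efflux_pairs), np.log(cfg.efflux_bounds[0]))]
    )
    hi = np.concatenate(
        [np.full(ns, np.log(1e3)), np.full(len(prob.efflux_pairs), np.log(cfg.efflux_bounds[1]))]
    )
    rng = np.random.default_rng(seed)
    best = None
    for start in range(cfg.max_starts):
        theta0 = prob.initial_theta()
        if start > 0:
            theta0 = theta0 + rng.normal(0.0, 0.5, size=theta0.shape)
        theta0 = np.clip(prob.warm_start(theta0), lo, hi)
        sol = least_squares(
            prob.residuals,
            theta0,
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            ftol=1e-6,
            xtol=1e-6,
            max_nfev=cfg.max_nfev,
        )
        cost = 2.0 * sol.cost  # sum of squared residuals
        if best is None or cost < best[0]:
            best = (cost, sol.x)
        if best[0] <= cfg.objective_ceiling:
            break
    cost, theta = best
    overrides = dict(zip(prob.param_names(), np.exp(theta)))
    fitted_model = model.with_parameters(overrides)
    ss = steady_state(fitted_model, default_initial_state(fitted_model), tol=cfg.ss_tol)
    converged = cost <= cfg.objective_ceiling
    if not converged:
        import warnings

        warnings.warn(
            f"fit for {name!r} did not reach objective ceiling "
            f"({cost:.4g} > {cfg.objective_ceiling:.4g})",
            stacklevel=2,
        )
    return VirtualCellLine(
        name=name,
        model=model,
        overrides=overrides,
        fitted_state=ss,
        fit_objective=cost,
        converged=converged,
    )


def save_line(line: VirtualCellLine, path: str | Path) -> None:
    """Persist a line as YAML (detected proteins + parameter overrides)."""
    import yaml

    payload = {
        "name": line.name,
        "detected": sorted(line.model.monomers()),
        "overrides": {k: float(v) for k, v in line.overrides.items()},
        "lesions": [
            {"name": l.name, "modifiers": {k: float(v) for k, v in l.modifiers.items()}}
            for l in line.lesions
        ],
        "fit_objective": None if line.fit_objective is None else float(line.fit_objective),
        "converged": bool(line.converged),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_line(path: str | Path, base_model: NetworkModel | None = None) -> VirtualCellLine:
    """Rebuild a saved line: prune to its detected set, apply overrides,
    re-equilibrate."""
    import yaml

    from .canonical import canonical_model

    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    model = base_model or canonical_model()
    detected = set(payload.get("detected") or model.monomers())
    if detected != set(model.monomers()):
        profile = DensitometryProfile(
            abundances={p: (0.5 if p in detected else 0.0) for p in model.monomers()},
            detected=frozenset(detected),
        )
        model = prune_network(model, profile)
    overrides = {k: float(v) for k, v in (payload.get("overrides") or {}).items()}
    fitted = model.with_parameters(overrides)
    ss = steady_state(fitted, default_initial_state(fitted))
    line = VirtualCellLine(
        name=payload.get("name", Path(path).stem),
        model=model,
        overrides=overrides,
        fitted_state=ss,
        fit_objective=payload.get("fit_objective"),
        converged=payload.get("converged", True),
    )
    for spec in payload.get("lesions") or []:
        line = apply_lesion(line, LesionSpec(spec["name"], spec["modifiers"]))
    return line


def build_cell_line(
    model: NetworkModel,
    profile: DensitometryProfile,
    config: FitConfig | None = None,
    name: str = "line",
    seed: int = 0,
) -> VirtualCellLine:
    """Prune undetected proteins, then fit: the standard line-building path."""
    return fit_cell_line(prune_network(model, profile), profile, config, name=name, seed=seed)
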