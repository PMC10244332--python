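"""Synthetic ground-truth lines and densitometry data.

Real IP/co-IP densitometry for the published lymphoma lines is external to
this package, so every pipeline stage is exercised against synthetic ground
truths instead: seeded random parameterisations of the canonical network
whose steady state exhibits a named dependence archetype, summarised into
densitometry profiles with a configurable semi-quantitative noise model.

Archetypes mirror the clinically annotated dependence categories: a line is
"mainly X dependent" when anti-apoptotic protein X sequesters at least half
of the total bound activator/effector load at steady state, and broadly
resistant when no single protein holds 40% or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .canonical import (
    ACTIVATORS,
    ANTI_APOPTOTIC,
    BH3_ONLY,
    EFFECTORS,
    MONOMERS,
    canonical_model,
    default_initial_state,
)
from .lines import (
    COIP_PAIRS,
    DensitometryProfile,
    VirtualCellLine,
    bound_pair_total,
    coip_fractions_of_state,
    efflux_parameter,
    normalized_abundances,
    protein_totals,
)
from .network import NetworkModel
from .simulate import SteadyState, steady_state

ARCHETYPES = ("BCL2_dependent", "BCLxL_dependent", "MCL1_dependent", "broadly_resistant")

_ARCHETYPE_ANTI = {
    "BCL2_dependent": "BCL2",
    "BCLxL_dependent": "BCLXL",
    "MCL1_dependent": "MCL1",
}

#: secondary dependence per archetype: the annotated dependence categories
#: come with a weaker second vulnerability (lines dependent mainly on one
#: guardian still respond to a second target at high doses), so dependent
#: archetypes carry a defined secondary guardian holding an intermediate
#: share of the load.
_ARCHETYPE_SECONDARY = {
    "BCL2_dependent": "MCL1",
    "BCLxL_dependent": "MCL1",
    "MCL1_dependent": "BCLXL",
}

#: log-uniform synthesis-rate sampling ranges (a.u./h) per archetype.
#: The dominant anti-apoptotic protein is drawn high, the secondary one
#: intermediate and the rest low so that rejection sampling on the
#: load-share criterion converges quickly; the criterion itself is always
#: enforced on the realised steady state.
SYNTHESIS_RANGES: dict[str, dict[str, tuple[float, float]]] = {}
for _arch, _dom in _ARCHETYPE_ANTI.items():
    _sec = _ARCHETYPE_SECONDARY[_arch]
    _r: dict[str, tuple[float, float]] = {}
    for _a in ANTI_APOPTOTIC:
        if _a == _dom:
            _r[f"s_{_a}"] = (4.0, 12.0)
        elif _a == _sec:
            _r[f"s_{_a}"] = (0.5, 1.2)
        else:
            _r[f"s_{_a}"] = (0.05, 0.4)
    for _e in EFFECTORS:
        _r[f"s_{_e}"] = (3.0, 10.0)
    for _b in BH3_ONLY:
        _r[f"s_{_b}"] = (0.2, 1.2)
    SYNTHESIS_RANGES[_arch] = _r
SYNTHESIS_RANGES["broadly_resistant"] = {
    # unprimed co-dependence pattern: the buffering reserve is concentrated
    # in BCL2 and MCL1, each able to absorb the load freed by inhibiting
    # the other, while their joint inhibition overwhelms the small
    # BCL-xL/BCL2A1 remainder
    "s_BCL2": (3.5, 7.0),
    "s_MCL1": (4.5, 9.0),
    "s_BCLXL": (0.9, 1.8),
    "s_BCL2A1": (0.9, 1.8),
    **{f"s_{e}": (1.0, 2.0) for e in EFFECTORS},
    **{f"s_{b}": (0.5, 1.5) for b in ("BID", "BIM", "PUMA")},
    "s_NOXA": (0.2, 0.6),
}

#: log-uniform range for per-heterodimer efflux rates (h^-1)
EFFLUX_RANGE = (1e-3, 0.2)

DEPENDENT_SHARE = 0.5
SECONDARY_SHARE_BAND = (0.075, 0.10)
RESISTANT_SHARE_CAP = 0.4

#: accepted naive MOMP baseline of the mean cell (a.u. of pore signal):
#: high enough to be numerically meaningful against solver tolerances,
#: low enough to leave an order-of-magnitude of permeabilization headroom
#: (compressed headroom makes every cell peak at the same saturated level).
#: Dependent lines are primed; broadly resistant lines are unprimed, with
#: guardian capacity far in excess of the BH3/effector load.
BASELINE_MOMP_BAND = (0.05, 0.8)
BASELINE_MOMP_BAND_RESISTANT = (1e-6, 1e-4)

#: naive-baseline poise target of the calibration, per archetype class
POISE_TARGET = 0.25
POISE_TARGET_RESISTANT = 1e-5


@dataclass
class NoiseModel:
    """Semi-quantitative densitometry noise.

    ``measurement_cv``: multiplicative lognormal CV on abundances;
    ``fraction_noise_sd``: additive Gaussian noise on co-IP fractions,
    clipped to [0, 1]; ``detection_limit``: normalised abundance below which
    a protein is reported undetected.  ``NoiseModel(0, 0, 0)`` is noiseless.
    """

    measurement_cv: float = 0.0
    fraction_noise_sd: float = 0.0
    detection_limit: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.measurement_cv, self.fraction_noise_sd, self.detection_limit) < 0:
            raise ValueError("noise magnitudes must be nonnegative")


@dataclass
class GroundTruthLine:
    """A sampled parameterisation with known overrides and steady state."""

    archetype: str
    true_parameters: dict[str, float]
    true_state: SteadyState
    line: VirtualCellLine
    seed: int
    load_shares: dict[str, float] = field(default_factory=dict)


class ArchetypeRejectionError(RuntimeError):
    """Rejection budget exhausted before the archetype invariant held."""


def load_shares(model: NetworkModel, state: np.ndarray) -> dict[str, float]:
    """Share of total bound activator/effector load held by each guardian."""
    partners = set(ACTIVATORS) | set(EFFECTORS)
    loads = {}
    for a in ANTI_APOPTOTIC:
        if a not in model.monomers():
            continue
        loads[a] = sum(bound_pair_total(model, state, a, p) for p in partners)
    total = sum(loads.values())
    if total <= 0:
        return {a: 0.0 for a in loads}
    return {a: v / total for a, v in loads.items()}


def _matches(archetype: str, shares: dict[str, float]) -> bool:
    if archetype == "broadly_resistant":
        return bool(shares) and max(shares.values()) < RESISTANT_SHARE_CAP
    dom = _ARCHETYPE_ANTI[archetype]
    sec = _ARCHETYPE_SECONDARY[archetype]
    others = [v for a, v in shares.items() if a not in (dom, sec)]
    lo, hi = SECONDARY_SHARE_BAND
    return (
        shares.get(dom, 0.0) >= DEPENDENT_SHARE
        and lo <= shares.get(sec, 0.0) <= hi
        and all(v <= 0.5 * shares.get(sec, 0.0) for v in others)
    )


def _calibrate_poise(
    base: NetworkModel,
    overrides: dict[str, float],
    target_momp: float,
    max_iter: int = 40,
) -> tuple[dict[str, float], SteadyState]:
    """Scale activator synthesis so the naive MOMP baseline hits ``target_momp``.

    Real lines sit primed but uncommitted: constitutive pore formation is
    present yet far below the committed level.  The sampled parameter shape
    sets abundances and load pattern; this bisection on a common multiplier
    of the direct activators (BID, BIM, PUMA) pins the poise without
    disturbing the pattern.  NOXA, a pure sensitizer, keeps its drawn rate.
    """
    bh3_params = [f"s_{b}" for b in ACTIVATORS]

    def momp_at(log_lambda: float) -> tuple[float, dict[str, float], SteadyState]:
        ov = dict(overrides)
        for p in bh3_params:
            ov[p] = overrides[p] * float(np.exp(log_lambda))
        m = base.with_parameters(ov)
        ss = steady_state(m, default_initial_state(m))
        return ss.momp_baseline, ov, ss

    lo, hi = -6.0, 4.0
    m_lo, ov_lo, ss_lo = momp_at(lo)
    m_hi, ov_hi, ss_hi = momp_at(hi)
    if m_hi < target_momp:
        return ov_hi, ss_hi
    if m_lo > target_momp:
        return ov_lo, ss_lo
    best = (ov_lo, ss_lo)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m_mid, ov_mid, ss_mid = momp_at(mid)
        best = (ov_mid, ss_mid)
        if abs(np.log(max(m_mid, 1e-30) / target_momp)) < 0.05:
            break
        if m_mid < target_momp:
            lo = mid
        else:
            hi = mid
    return best


def generate_ground_truth(
    archetype: str,
    seed: int,
    model: NetworkModel | None = None,
    max_draws: int = 100,
) -> GroundTruthLine:
    """Sample a ground-truth line of the requested archetype (seeded).

    Synthesis and efflux rates are drawn log-uniformly from the documented
    ranges; draws are rejected until the steady-state load-share invariant
    of the archetype holds.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; choose from {ARCHETYPES}")
    base = model or canonical_model()
    rng = np.random.default_rng(seed)
    ranges = SYNTHESIS_RANGES[archetype]
    tried = []
    for draw in range(max_draws):
        overrides: dict[str, float] = {}
        for pname, (lo, hi) in ranges.items():
            overrides[pname] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        for a, b in COIP_PAIRS:
            overrides[efflux_parameter(a, b)] = float(
                np.exp(rng.uniform(np.log(EFFLUX_RANGE[0]), np.log(EFFLUX_RANGE[1])))
            )
        resistant = archetype == "broadly_resistant"
        poise = POISE_TARGET_RESISTANT if resistant else POISE_TARGET
        target_momp = float(np.exp(rng.normal(np.log(poise), 0.3)))
        # cheap pre-filter: a draw whose uncalibrated load pattern is far
        # from the archetype cannot be rescued by the poise calibration
        m_raw = base.with_parameters(overrides)
        ss_raw = steady_state(m_raw, default_initial_state(m_raw))
        raw_shares = load_shares(m_raw, ss_raw.state)
        if raw_shares:
            top = max(raw_shares.values())
            if resistant:
                if top >= RESISTANT_SHARE_CAP + 0.1:
                    tried.append(raw_shares)
                    continue
            elif raw_shares.get(_ARCHETYPE_ANTI[archetype], 0.0) < DEPENDENT_SHARE - 0.15:
                tried.append(raw_shares)
                continue
        overrides, ss = _calibrate_poise(base, overrides, target_momp)
        m = base.with_parameters(overrides)
        shares = load_shares(m, ss.state)
        tried.append(shares)
        lo, hi = BASELINE_MOMP_BAND_RESISTANT if resistant else BASELINE_MOMP_BAND
        if _matches(archetype, shares) and lo <= ss.momp_baseline <= hi:
            line = VirtualCellLine(
                name=f"{archetype}_seed{seed}",
                model=base,
                overrides=overrides,
                fitted_state=ss,
            )
            return GroundTruthLine(
                archetype=archetype,
                true_parameters=overrides,
                true_state=ss,
                line=line,
                seed=seed,
                load_shares=shares,
            )
    raise ArchetypeRejectionError(
        f"no {archetype} draw within {max_draws} attempts (seed {seed}); "
        f"last load shares: { {k: round(v, 3) for k, v in tried[-1].items()} }"
    )


def synth_densitometry(
    line: GroundTruthLine | VirtualCellLine,
    noise: NoiseModel | None = None,
) -> DensitometryProfile:
    """Summarise a line's steady state as a (noisy) densitometry profile."""
    noise = noise or NoiseModel()
    if isinstance(line, GroundTruthLine):
        model, state = line.line.model, line.true_state.state
    else:
        model, state = line.model, line.fitted_state.state
    rng = np.random.default_rng(noise.seed)
    abund = normalized_abundances(model, state)
    if noise.measurement_cv > 0:
        sigma = np.sqrt(np.log1p(noise.measurement_cv**2))
        for p in list(abund):
            abund[p] *= float(rng.lognormal(-0.5 * sigma**2, sigma))
    detected = {p for p, v in abund.items() if v > noise.detection_limit}
    abund = {p: (v if p in detected else 0.0) for p, v in abund.items()}
    antis = [a for a in ANTI_APOPTOTIC if a in detected]
    top = max((abund[a] for a in antis), default=0.0)
    if top > 0:
        abund = {p: v / top for p, v in abund.items()}
    fracs = {}
    for (a, b), f in coip_fractions_of_state(model, state).items():
        if a in detected and b in detected:
            if noise.fraction_noise_sd > 0:
                f = float(np.clip(f + rng.normal(0.0, noise.fraction_noise_sd), 0.0, 1.0))
            fracs[(a, b)] = f
    # renormalise per-partner sums that noise pushed past feasibility
    per_partner: dict[str, float] = {}
    for (a, b), f in fracs.items():
        per_partner[b] = per_partner.get(b, 0.0) + f
    for b, total in per_partner.items():
        if total > 1.0:
            for a in ANTI_APOPTOTIC:
                if (a, b) in fracs:
                    fracs[(a, b)] /= total
    return DensitometryProfile(
        abundances=abund, coip_fractions=fracs, detected=frozenset(detected)
    )


#: seeds of the shipped fixture archetypes (see :func:`fixture_line`)
FIXTURE_SEEDS = {
    "BCL2_dependent": 11,
    "BCLxL_dependent": 21,
    "MCL1_dependent": 31,
    "broadly_resistant": 41,
}


def fixture_line(archetype: str, model: NetworkModel | None = None) -> GroundTruthLine:
    """Named fixture line: the archetype generated at its shipped seed."""
    return generate_ground_truth(archetype, FIXTURE_SEEDS[archetype], model=model)


# ---------------------------------------------------------------------------
# combination-therapy fixtures

#: synthesis rates (a.u./h) of the BCL-xL/MCL1 co-dependence fixture: a
#: BAX-driven line buffered by large BCL2 and BCL2A1 pools in which BCL-xL
#: and MCL1 — the only guardians able to sequester active BAK — each hold a
#: small load share.  Either alone absorbs the BAK load freed by inhibiting
#: the other; inhibiting both leaves BAK unguarded.
CODEPENDENT_SYNTHESIS = {
    "s_BCL2": 6.0,
    "s_BCL2A1": 6.0,
    "s_BCLXL": 0.4,
    "s_MCL1": 0.4,
    "s_BAX": 8.0,
    "s_BAK": 1.3,
    "s_BID": 0.6,
    "s_BIM": 1.0,
    "s_PUMA": 0.6,
    "s_NOXA": 0.2,
}
CODEPENDENT_EFFLUX = 0.02


def codependent_line(model: NetworkModel | None = None) -> GroundTruthLine:
    """BCL-xL/MCL1 co-dependence fixture (see :data:`CODEPENDENT_SYNTHESIS`).

    Deterministic: the documented rates are poise-calibrated to the standard
    naive baseline.  Combining BCL-xL and MCL1 inhibition on this line kills
    far in excess of Bliss independence; either agent alone is buffered.
    """
    base = model or canonical_model()
    overrides = dict(CODEPENDENT_SYNTHESIS)
    for a, b in COIP_PAIRS:
        overrides[efflux_parameter(a, b)] = CODEPENDENT_EFFLUX
    overrides, ss = _calibrate_poise(base, overrides, POISE_TARGET)
    m = base.with_parameters(overrides)
    line = VirtualCellLine("XL_MCL1_codependent", base, overrides, ss)
    return GroundTruthLine(
        archetype="XL_MCL1_codependent",
        true_parameters=overrides,
        true_state=ss,
        line=line,
        seed=0,
        load_shares=load_shares(m, ss.state),
    )


def bak_null_model(base: NetworkModel | None = None) -> NetworkModel:
    """Canonical network with BAK undetected and pruned.

    Lines built on this model run intrinsic apoptosis through BAX alone, so
    BCL-xL and MCL1 lose their joint BAK-guarding function; it is the
    single-dependence comparator for combination analyses of that pair.
    """
    from .lines import prune_network

    profile = DensitometryProfile(
        abundances={
            p: (0.0 if p == "BAK" else (1.0 if p == "BCL2" else 0.5)) for p in MONOMERS
        }
    )
    return prune_network(base or canonical_model(), profile)
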