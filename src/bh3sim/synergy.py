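"""Drug-combination dose matrices and Bliss-independence synergy scoring.

Effect is the fraction of the population affected, ``e = 1 - viability``.
The Bliss independence null expects two non-interacting drugs to combine as
``e_ab = e_a + e_b - e_a e_b``; the excess of the observed combination
effect over this expectation, in percentage points, is the synergy score.
The summary score averages the excess over all matrix cells where both
doses are nonzero (margins are excluded so single agents cannot contribute).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lines import VirtualCellLine
from .population import (
    DEFAULT_CV,
    DEFAULT_N_CELLS,
    CellPopulation,
    InhibitedSystem,
    TreatmentSpec,
    calibrate_drug_amount,
    run_treatment,
    sample_population,
)

DEFAULT_COMBO_FRACTIONS = np.linspace(0.0, 1.0, 5)


def bliss_expected(e_a: float | np.ndarray, e_b: float | np.ndarray) -> float | np.ndarray:
    """Bliss-independent expected effect of two non-interacting drugs."""
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    if np.any((e_a < 0) | (e_a > 1)) or np.any((e_b < 0) | (e_b > 1)):
        raise ValueError("effects must lie in [0, 1]")
    out = e_a + e_b - e_a * e_b
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseMatrix:
    """Observed viability over a full (fraction_a x fraction_b) grid."""

    drug_a: str
    drug_b: str
    fractions_a: np.ndarray
    fractions_b: np.ndarray
    viability: np.ndarray  # (len(fractions_a), len(fractions_b))

    @property
    def effect(self) -> np.ndarray:
        return 1.0 - self.viability

    def equimolar_diagonal(self) -> pd.DataFrame:
        """Viability along equal inhibition fractions of both drugs."""
        shared = [f for f in self.fractions_a if any(np.isclose(f, self.fractions_b))]
        rows = []
        for f in shared:
            i = int(np.argmin(np.abs(self.fractions_a - f)))
            j = int(np.argmin(np.abs(self.fractions_b - f)))
            rows.append({"fraction": f, "viability": self.viability[i, j]})
        return pd.DataFrame(rows)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i, fa in enumerate(self.fractions_a):
            for j, fb in enumerate(self.fractions_b):
                rows.append(
                    {"fa": fa, "fb": fb, "viability": self.viability[i, j],
                     "effect": 1.0 - self.viability[i, j]}
                )
        return pd.DataFrame(rows)


@dataclass
class SynergyResult:
    """Bliss excess (percentage points) and its combination-cell mean."""

    excess: np.ndarray  # same shape as the dose matrix; margins are 0
    summary_score: float
    expected_effect: np.ndarray


def combination_matrix(
    line: VirtualCellLine,
    drug_a: str,
    drug_b: str,
    seed: int = 0,
    fractions_a: np.ndarray | None = None,
    fractions_b: np.ndarray | None = None,
    n_cells: int = DEFAULT_N_CELLS,
    cv: float = DEFAULT_CV,
    population: CellPopulation | None = None,
) -> DoseMatrix:
    """Run every (f_a, f_b) treatment on one shared population sample.

    The (0, 0) entry is the untreated population; row f_b = 0 and column
    f_a = 0 reproduce the single-agent dose responses at the same seed.
    """
    fa = np.asarray(DEFAULT_COMBO_FRACTIONS if fractions_a is None else fractions_a, float)
    fb = np.asarray(DEFAULT_COMBO_FRACTIONS if fractions_b is None else fractions_b, float)
    pop = population or sample_population(line, n_cells=n_cells, cv=cv, seed=seed)
    amounts_a = {f: calibrate_drug_amount(line, drug_a, float(f)) for f in fa}
    amounts_b = {f: calibrate_drug_amount(line, drug_b, float(f)) for f in fb}
    viability = np.empty((len(fa), len(fb)))
    for i, f_a in enumerate(fa):
        for j, f_b in enumerate(fb):
            amounts = {}
            if amounts_a[f_a] > 0:
                amounts[drug_a] = amounts_a[f_a]
            if amounts_b[f_b] > 0:
                amounts[drug_b] = amounts_b[f_b]
            spec = TreatmentSpec(targets=[(drug_a, float(f_a)), (drug_b, float(f_b))])
            system = InhibitedSystem(line=line, drug_amounts=amounts)
            viability[i, j] = run_treatment(pop, spec, system=system).viability_72h
    return DoseMatrix(
        drug_a=drug_a, drug_b=drug_b, fractions_a=fa, fractions_b=fb, viability=viability
    )


def synergy_score(matrix: DoseMatrix) -> SynergyResult:
    """Bliss excess per combination cell, and the mean over those cells.

    Requires the single-agent margins (first row/column at fraction 0) to be
    present: they define the marginal effects the Bliss null combines.
    """
    if not (np.isclose(matrix.fractions_a[0], 0.0) and np.isclose(matrix.fractions_b[0], 0.0)):
        raise ValueError("dose matrix must include the fraction-0 margins")
    e = matrix.effect
    e_a = e[:, 0]  # single-agent effects of drug_a (column at f_b = 0)
    e_b = e[0, :]
    expected = bliss_expected(e_a[:, None], e_b[None, :])
    excess = np.zeros_like(e)
    excess[1:, 1:] = 100.0 * (e[1:, 1:] - expected[1:, 1:])
    summary = float(excess[1:, 1:].mean()) if excess[1:, 1:].size else 0.0
    return SynergyResult(excess=excess, summary_score=summary, expected_effect=expected)
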