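"""Reaction-network core: species/reaction/parameter registry and ODE compilation.

A :class:`NetworkModel` is an immutable description of a mass-action reaction
network read from four CSV files (species, reactions, rate laws, parameters).
The model compiles to a deterministic ODE right-hand side ``dx/dt = S v(x)``
where ``S`` is the integer stoichiometry matrix and the flux of reaction *j*
is ``v_j = k_j * prod_i x_i^{m_ij}`` with ``m_ij`` the reactant stoichiometry.

Only mass-action kinetics are supported: the rate-law file exists to mirror
the three-file model-definition convention and must declare ``massaction``
for every reaction.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

COMPARTMENTS = ("cytosol", "MOM")
ROLES = ("effector", "anti_apoptotic", "bh3_only", "complex", "pore", "drug", "input")

#: rate classes understood by the dialect; all are mass action, the class is
#: metadata used for model restriction (e.g. conservation checks) and pruning.
RATE_CLASSES = (
    "synthesis",
    "degradation",
    "translocation_in",
    "translocation_out",
    "binding",
    "unbinding",
    "activation",
    "auto_activation",
    "oligomerization",
    "complex_efflux",
    "drug_binding",
    "drug_unbinding",
)

#: rate classes that create or destroy protein mass; stripping them leaves a
#: closed subsystem in which every monomer total is conserved.
OPEN_RATE_CLASSES = frozenset({"synthesis", "degradation", "complex_efflux"})


class NetworkValidationError(ValueError):
    """Raised when a network definition violates the dialect contract."""


@dataclass(frozen=True)
class Species:
    """A molecular species (one ODE state variable).

    ``constituents`` lists the monomer (or drug) names the species carries:
    one entry for a monomeric protein state, two or more for complexes, four
    identical effector entries for a pore.  The empty list is reserved for
    pure inputs (the lumped apoptotic-signal species) and free drugs.
    """

    name: str
    compartment: str
    role: str
    constituents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkValidationError(
                f"species {self.name!r}: unknown compartment {self.compartment!r}"
            )
        if self.role not in ROLES:
            raise NetworkValidationError(
                f"species {self.name!r}: unknown role {self.role!r}"
            )
        if self.role == "complex" and len(self.constituents) < 2:
            raise NetworkValidationError(
                f"complex {self.name!r} must list >=2 constituents"
            )
        if self.role == "pore" and len(self.constituents) < 2:
            raise NetworkValidationError(
                f"pore {self.name!r} must list its effector constituents"
            )


@dataclass(frozen=True)
class Reaction:
    """A single mass-action reaction. Reactants/products are multisets."""

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_class: str
    parameter: str

    def __post_init__(self) -> None:
        if self.rate_class not in RATE_CLASSES:
            raise NetworkValidationError(
                f"reaction {self.id!r}: unknown rate class {self.rate_class!r}"
            )

    @property
    def order(self) -> int:
        return len(self.reactants)


@dataclass
class ParameterSet:
    """Nonnegative named rate constants (plus free standalone constants)."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.values.items():
            if not np.isfinite(value) or value < 0:
                raise NetworkValidationError(
                    f"parameter {name!r} must be finite and >= 0, got {value!r}"
                )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def updated(self, overrides: Mapping[str, float]) -> "ParameterSet":
        merged = dict(self.values)
        for name, value in overrides.items():
            if name not in merged:
                raise KeyError(f"unknown parameter {name!r}")
            merged[name] = float(value)
        return ParameterSet(merged)


class NetworkModel:
    """Validated reaction network with a compiled stoichiometry matrix.

    Species and reactions keep declaration order; the state vector is ordered
    like ``model.species``.
    """

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        parameters: ParameterSet,
    ) -> None:
        self.species = list(species)
        self.reactions = list(reactions)
        self.parameters = parameters
        self._index = {s.name: i for i, s in enumerate(self.species)}
        self._validate()
        self.stoichiometry = self._build_stoichiometry()
        self._compiled: _CompiledRHS | None = None

    # -- structure ---------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters.values)

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}") from None

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def monomers(self) -> list[str]:
        """Protein monomer names appearing in any species' constituents."""
        seen: dict[str, None] = {}
        for s in self.species:
            for c in s.constituents:
                if not c.startswith("dg_"):
                    seen.setdefault(c)
        return list(seen)

    def monomer_weights(self, monomer: str) -> np.ndarray:
        """Copies of ``monomer`` carried per unit of each species (pore = 4)."""
        if monomer not in self.monomers():
            raise KeyError(f"unknown monomer {monomer!r}")
        w = np.zeros(self.n_species)
        for i, s in enumerate(self.species):
            w[i] = sum(1 for c in s.constituents if c == monomer)
        return w

    def pore_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.species) if s.role == "pore"], dtype=int
        )

    def _validate(self) -> None:
        names = [s.name for s in self.species]
        dup = [n for n, c in Counter(names).items() if c > 1]
        if dup:
            raise NetworkValidationError(f"duplicate species declaration: {dup}")
        if not self.reactions:
            raise NetworkValidationError("no reactions defined")
        rids = [r.id for r in self.reactions]
        dup = [n for n, c in Counter(rids).items() if c > 1]
        if dup:
            raise NetworkValidationError(f"duplicate reaction id: {dup}")
        for r in self.reactions:
            for side, members in (("reactant", r.reactants), ("product", r.products)):
                for name in members:
                    if name not in self._index:
                        raise NetworkValidationError(
                            f"reaction {r.id!r}: undeclared {side} species {name!r}"
                        )
            if r.parameter not in self.parameters.values:
                raise NetworkValidationError(
                    f"reaction {r.id!r}: undeclared parameter {r.parameter!r}"
                )
            if r.rate_class == "synthesis" and len(r.reactants) not in (0, 1):
                raise NetworkValidationError(
                    f"synthesis reaction {r.id!r} must have order 0 or 1"
                )

    def _build_stoichiometry(self) -> np.ndarray:
        S = np.zeros((self.n_species, self.n_reactions), dtype=int)
        for j, r in enumerate(self.reactions):
            for name in r.reactants:
                S[self._index[name], j] -= 1
            for name in r.products:
                S[self._index[name], j] += 1
        return S

    # -- parameterisation --------------------------------------------------

    def with_parameters(self, overrides: Mapping[str, float]) -> "NetworkModel":
        """New model sharing the topology with updated parameter values."""
        return NetworkModel(self.species, self.reactions, self.parameters.updated(overrides))

    def rate_vector(self) -> np.ndarray:
        return np.array([self.parameters[r.parameter] for r in self.reactions])

    # -- restriction -------------------------------------------------------

    def closed_subsystem(self) -> "NetworkModel":
        """Model with synthesis/degradation/efflux reactions removed.

        The remaining reactions (binding, unbinding, translocation,
        activation, oligomerization, drug exchange) conserve every monomer
        total, which :func:`conservation_check` exploits.
        """
        kept = [r for r in self.reactions if r.rate_class not in OPEN_RATE_CLASSES]
        return NetworkModel(self.species, kept, self.parameters)

    # -- compiled RHS ------------------------------------------------------

    def _compile(self) -> "_CompiledRHS":
        if self._compiled is None:
            self._compiled = _CompiledRHS(self)
        return self._compiled

    def rhs(self) -> Callable[[np.ndarray], np.ndarray]:
        """Pure function mapping a state vector to its time derivative."""
        comp = self._compile()
        k = self.rate_vector()
        n = self.n_species

        def f(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            if x.shape != (n,):
                raise ValueError(f"state vector must have length {n}, got {x.shape}")
            return comp.deriv(x, k)

        return f

    def jacobian(self) -> Callable[[np.ndarray], np.ndarray]:
        comp = self._compile()
        k = self.rate_vector()
        return lambda x: comp.jac(np.asarray(x, dtype=float), k)


class _CompiledRHS:
    """Index-array compilation of mass-action fluxes (orders 0..2)."""

    def __init__(self, model: NetworkModel) -> None:
        idx = model.species_index
        a, b = [], []
        for r in model.reactions:
            if r.order > 2:
                raise NetworkValidationError(
                    f"reaction {r.id!r}: mass-action order {r.order} > 2 unsupported"
                )
            factors = [idx(name) for name in r.reactants]
            a.append(factors[0] if len(factors) > 0 else -1)
            b.append(factors[1] if len(factors) > 1 else -1)
        self.a = np.array(a, dtype=int)
        self.b = np.array(b, dtype=int)
        self.S = model.stoichiometry.astype(float)
        self.has_a = self.a >= 0
        self.has_b = self.b >= 0
        self.n_rx = len(model.reactions)
        self.n_sp = model.n_species

    def flux(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        v = k.copy()
        v[self.has_a] *= x[self.a[self.has_a]]
        v[self.has_b] *= x[self.b[self.has_b]]
        return v

    def deriv(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        return self.S @ self.flux(x, k)

    def jac(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        # dv_j/dx_i: product rule over the (<=2) reactant factors.
        W = np.zeros((self.n_rx, self.n_sp))
        rows = np.arange(self.n_rx)
        ra, rb = self.a, self.b
        ka = k.copy()
        ka[self.has_b] *= x[rb[self.has_b]]
        W[rows[self.has_a], ra[self.has_a]] += ka[self.has_a]
        kb = k.copy()
        kb[self.has_a] *= x[ra[self.has_a]]
        W[rows[self.has_b], rb[self.has_b]] += kb[self.has_b]
        return self.S @ W


# ---------------------------------------------------------------------------
# operations


def build_rhs(model: NetworkModel) -> Callable[[np.ndarray], np.ndarray]:
    """Compile ``model`` to the derivative function ``x -> S v(x)``."""
    return model.rhs()


def conservation_check(model: NetworkModel, monomer: str) -> Callable[[np.ndarray], float]:
    """Return the conserved-total functional for ``monomer``.

    Call on the :meth:`NetworkModel.closed_subsystem` restriction: the
    returned total (copies of the monomer summed over all species, weighted
    by constituent counts) is then constant along trajectories.
    """
    w = model.monomer_weights(monomer)
    return lambda x: float(w @ np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# CSV dialect


def _parse_side(token: str, where: str) -> tuple[str, ...]:
    """Parse a ``;``-separated list of ``stoich*name`` tokens into a multiset."""
    token = token.strip()
    if not token:
        return ()
    out: list[str] = []
    for part in token.split(";"):
        part = part.strip()
        if not part:
            continue
        if "*" in part:
            mult_s, name = part.split("*", 1)
            try:
                mult = int(mult_s)
            except ValueError:
                raise NetworkValidationError(f"{where}: bad stoichiometry {part!r}")
            if mult < 1:
                raise NetworkValidationError(f"{where}: stoichiometry must be >=1 in {part!r}")
        else:
            mult, name = 1, part
        out.extend([name.strip()] * mult)
    return tuple(out)


def _format_side(names: Iterable[str]) -> str:
    counts = Counter(names)
    return ";".join(
        name if mult == 1 else f"{mult}*{name}" for name, mult in counts.items()
    )


def _read_csv(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise NetworkValidationError(f"{path}: empty file, header required")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise NetworkValidationError(f"{path}: missing columns {missing}")
        return [row for row in reader]


def load_network(
    reactions_file: str | Path,
    ratelaws_file: str | Path,
    parameters_file: str | Path,
    species_file: str | Path | None = None,
) -> NetworkModel:
    """Load and validate a network from its CSV definition files.

    ``species_file`` defaults to ``species.csv`` next to the reactions file.
    Declaration order in the files fixes species/reaction ordering.
    """
    reactions_file = Path(reactions_file)
    if species_file is None:
        species_file = reactions_file.parent / "species.csv"

    sp_rows = _read_csv(Path(species_file), ["name", "compartment", "role", "constituents"])
    species = [
        Species(
            name=row["name"].strip(),
            compartment=row["compartment"].strip(),
            role=row["role"].strip(),
            constituents=tuple(
                c.strip() for c in row["constituents"].split(";") if c.strip()
            ),
        )
        for row in sp_rows
    ]

    law_rows = _read_csv(Path(ratelaws_file), ["id", "law", "parameter"])
    laws = {}
    for row in law_rows:
        if row["law"].strip() != "massaction":
            raise NetworkValidationError(
                f"reaction {row['id']!r}: unsupported rate law {row['law']!r}"
            )
        laws[row["id"].strip()] = row["parameter"].strip()

    rx_rows = _read_csv(Path(reactions_file), ["id", "reactants", "products", "rate_class", "parameter"])
    if not rx_rows:
        raise NetworkValidationError(f"{reactions_file}: no reactions")
    reactions = []
    for row in rx_rows:
        rid = row["id"].strip()
        if rid in laws and laws[rid] != row["parameter"].strip():
            raise NetworkValidationError(
                f"reaction {rid!r}: parameter mismatch between reactions and rate-law files"
            )
        reactions.append(
            Reaction(
                id=rid,
                reactants=_parse_side(row["reactants"], f"reaction {rid!r}"),
                products=_parse_side(row["products"], f"reaction {rid!r}"),
                rate_class=row["rate_class"].strip(),
                parameter=row["parameter"].strip(),
            )
        )

    par_rows = _read_csv(Path(parameters_file), ["name", "value"])
    values: dict[str, float] = {}
    for row in par_rows:
        name = row["name"].strip()
        if name in values:
            raise NetworkValidationError(f"duplicate parameter {name!r}")
        try:
            value = float(row["value"])
        except ValueError:
            raise NetworkValidationError(f"parameter {name!r}: bad value {row['value']!r}")
        if value < 0:
            raise NetworkValidationError(f"parameter {name!r} is negative ({value})")
        values[name] = value

    return NetworkModel(species, reactions, ParameterSet(values))


def write_network(model: NetworkModel, directory: str | Path) -> dict[str, Path]:
    """Write a model to the four-file CSV dialect; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": directory / "species.csv",
        "reactions": directory / "reactions.csv",
        "ratelaws": directory / "ratelaws.csv",
        "parameters": directory / "parameters.csv",
    }
    with open(paths["species"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "compartment", "role", "constituents"])
        for s in model.species:
            w.writerow([s.name, s.compartment, s.role, ";".join(s.constituents)])
    with open(paths["reactions"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "reactants", "products", "rate_class", "parameter"])
        for r in model.reactions:
            w.writerow([r.id, _format_side(r.reactants), _format_side(r.products), r.rate_class, r.parameter])
    with open(paths["ratelaws"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "law", "parameter"])
        for r in model.reactions:
            w.writerow([r.id, "massaction", r.parameter])
    with open(paths["parameters"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "value", "units", "description"])
        for name, value in model.parameters.values.items():
            w.writerow([name, repr(value), "", ""])
    return paths


def load_network_dir(directory: str | Path) -> NetworkModel:
    directory = Path(directory)
    return load_network(
        directory / "reactions.csv",
        directory / "ratelaws.csv",
        directory / "parameters.csv",
        directory / "species.csv",
    )
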