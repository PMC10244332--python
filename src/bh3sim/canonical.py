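"""Canonical BCL2-family apoptosis network.

The model tracks the intrinsic-apoptosis commitment machinery at the
mitochondrial outer membrane (MOM):

* effectors BAX and BAK, which once activated dimerise and then tetramerise
  into MOM pores (the permeabilization readout);
* the four anti-apoptotic guardians BCL2, BCL-xL, MCL1 and BCL2A1, which
  shuttle between cytosol and MOM and sequester both BH3-only proteins and
  active effectors;
* the BH3-only proteins BID, BIM, PUMA (direct activators) and NOXA (a
  sensitizer restricted to MCL1/BCL2A1);
* one high-affinity groove-binding drug per anti-apoptotic protein,
  representing a BH3-mimetic.

Upstream death-receptor/stress signaling is lumped into a single constant
input species (``APOSIG``) that mobilises BH3-only proteins to the MOM.

Binding selectivity follows the standard interaction map: BID/BIM/PUMA
engage all four anti-apoptotic proteins, NOXA only MCL1 and BCL2A1, active
BAX is held by BCL2/BCL-xL/BCL2A1, active BAK by BCL-xL/MCL1, and inactive
membrane effectors are bound loosely by every guardian (the
retrotranslocation mode).  All kinetics are mass action.

The compiled network has 80 species, 202 reactions and 203 parameters.
"""

from __future__ import annotations

from pathlib import Path

from .network import NetworkModel, ParameterSet, Reaction, Species

EFFECTORS = ("BAX", "BAK")
ANTI_APOPTOTIC = ("BCL2", "BCLXL", "MCL1", "BCL2A1")
BH3_ONLY = ("BID", "BIM", "PUMA", "NOXA")
ACTIVATORS = ("BID", "BIM", "PUMA")
MONOMERS = EFFECTORS + ANTI_APOPTOTIC + BH3_ONLY

#: which BH3-only proteins each anti-apoptotic protein can sequester
BH3_PARTNERS: dict[str, tuple[str, ...]] = {
    "BCL2": ("BID", "BIM", "PUMA"),
    "BCLXL": ("BID", "BIM", "PUMA"),
    "MCL1": ("BID", "BIM", "PUMA", "NOXA"),
    "BCL2A1": ("BID", "BIM", "PUMA", "NOXA"),
}

#: which active effectors each anti-apoptotic protein can sequester
ACTIVE_EFFECTOR_PARTNERS: dict[str, tuple[str, ...]] = {
    "BCL2": ("BAX",),
    "BCLXL": ("BAX", "BAK"),
    "MCL1": ("BAK",),
    "BCL2A1": ("BAX",),
}

#: (anti, partner) pairs with a MOM heterodimer subject to fitted efflux
HETERODIMER_PAIRS: list[tuple[str, str]] = [
    (a, b) for a in ANTI_APOPTOTIC for b in BH3_PARTNERS[a]
] + [(a, f"{e}a") for a in ANTI_APOPTOTIC for e in ACTIVE_EFFECTOR_PARTNERS[a]]


def drug_name(target: str) -> str:
    return f"dg_{target}"


# ---------------------------------------------------------------------------
# default kinetic parameters
#
# Units: concentration in arbitrary abundance units (a.u.; the reference
# anti-apoptotic protein sits near 100 a.u.), time in hours.  Binding
# constants are a.u.^-1 h^-1, first-order rates h^-1, synthesis a.u. h^-1.

DEFAULT_SYNTHESIS = {
    "BAX": 6.0,
    "BAK": 6.0,
    "BCL2": 5.0,
    "BCLXL": 5.0,
    "MCL1": 5.0,
    "BCL2A1": 5.0,
    "BID": 0.6,
    "BIM": 1.0,
    "PUMA": 0.6,
    "NOXA": 0.6,
}

DEG_MONOMER = 0.05  # h^-1, ~14 h protein half-life
DEG_COMPLEX = 0.05  # h^-1, shared default for MOM heterodimers
DEG_OLIGOMER = 0.25  # h^-1, faster turnover of activated/oligomeric effectors

KON_BH3 = 0.5  # tight groove binding at the MOM
KOFF_BH3_ACTIVATOR = 0.1
KOFF_BH3_SENSITIZER = 0.5
KON_AEFF = 0.5
KOFF_AEFF = 0.02
KON_CYT = 0.05  # weaker cytosolic association
KOFF_CYT = 0.5
KON_MODE1 = 0.005  # retrotranslocation-mode capture of inactive effectors
D_RETRO = 0.1  # turnover of the captured effector (guardian recycled)
KON_DRUG = 100.0
KOFF_DRUG = 0.01  # effective Kd 1e-4 a.u. — far below protein abundances

K_ACT = 0.1  # BH3-activator catalysed effector activation
K_AUTO = 0.12  # active-effector autocatalysis
K_DIM = 0.5
K_PORE = 2.0

APOPTOTIC_SIGNAL = 1.0  # clamped level of the lumped upstream input


def canonical_model() -> NetworkModel:
    """Build the canonical 80-species / 202-reaction / 203-parameter model."""
    species: list[Species] = []
    reactions: list[Reaction] = []
    params: dict[str, float] = {}

    def sp(name: str, compartment: str, role: str, constituents: tuple[str, ...] = ()):
        species.append(Species(name, compartment, role, constituents))

    def rx(rid: str, reactants, products, rate_class: str, pname: str, value: float):
        reactions.append(Reaction(rid, tuple(reactants), tuple(products), rate_class, pname))
        params[pname] = value

    # ---- monomeric protein states ------------------------------------
    sp("BAX_c", "cytosol", "effector", ("BAX",))
    sp("BAX_m", "MOM", "effector", ("BAX",))
    sp("BAX_a", "MOM", "effector", ("BAX",))
    sp("BAX_d", "MOM", "complex", ("BAX", "BAX"))
    sp("BAX_p", "MOM", "pore", ("BAX",) * 4)
    sp("BAK_c", "cytosol", "effector", ("BAK",))
    sp("BAK_m", "MOM", "effector", ("BAK",))
    sp("BAK_a", "MOM", "effector", ("BAK",))
    sp("BAK_d", "MOM", "complex", ("BAK", "BAK"))
    sp("BAK_p", "MOM", "pore", ("BAK",) * 4)
    for a in ANTI_APOPTOTIC:
        sp(f"{a}_c", "cytosol", "anti_apoptotic", (a,))
        sp(f"{a}_m", "MOM", "anti_apoptotic", (a,))
    for b in BH3_ONLY:
        sp(f"{b}_c", "cytosol", "bh3_only", (b,))
        sp(f"{b}_m", "MOM", "bh3_only", (b,))
    sp("APOSIG", "cytosol", "input", ())

    # ---- complexes ----------------------------------------------------
    for a in ANTI_APOPTOTIC:
        for b in BH3_PARTNERS[a]:
            sp(f"{a}_{b}_m", "MOM", "complex", (a, b))
    for a in ANTI_APOPTOTIC:
        for e in ACTIVE_EFFECTOR_PARTNERS[a]:
            sp(f"{a}_{e}a_m", "MOM", "complex", (a, e))
    for a in ANTI_APOPTOTIC:
        for b in BH3_PARTNERS[a]:
            sp(f"{a}_{b}_c", "cytosol", "complex", (a, b))
    for a in ANTI_APOPTOTIC:
        for e in EFFECTORS:
            sp(f"{a}_{e}i_m", "MOM", "complex", (a, e))

    # ---- drugs --------------------------------------------------------
    for a in ANTI_APOPTOTIC:
        d = drug_name(a)
        sp(d, "cytosol", "drug", (d,))
        sp(f"{d}_{a}_m", "MOM", "complex", (d, a))
        sp(f"{d}_{a}_c", "cytosol", "complex", (d, a))

    # ---- synthesis (zero order, into the cytosol) ---------------------
    for p in MONOMERS:
        rx(f"syn_{p}", (), (f"{p}_c",), "synthesis", f"s_{p}", DEFAULT_SYNTHESIS[p])

    # ---- degradation of monomeric states ------------------------------
    for name in ("BAX_c", "BAX_m", "BAX_a", "BAK_m", "BAK_a"):
        rx(f"deg_{name}", (name,), (), "degradation", f"d_{name}", DEG_MONOMER)
    for name in ("BAX_d", "BAX_p", "BAK_d", "BAK_p"):
        rx(f"deg_{name}", (name,), (), "degradation", f"d_{name}", DEG_OLIGOMER)
    for a in ANTI_APOPTOTIC:
        for c in ("c", "m"):
            rx(f"deg_{a}_{c}", (f"{a}_{c}",), (), "degradation", f"d_{a}_{c}", DEG_MONOMER)
    for b in BH3_ONLY:
        for c in ("c", "m"):
            rx(f"deg_{b}_{c}", (f"{b}_{c}",), (), "degradation", f"d_{b}_{c}", DEG_MONOMER)

    # ---- translocation -------------------------------------------------
    rx("tin_BAX", ("BAX_c",), ("BAX_m",), "translocation_in", "kin_BAX", 0.05)
    rx("tout_BAX", ("BAX_m",), ("BAX_c",), "translocation_out", "kout_BAX", 0.5)
    # BAK inserts constitutively; import is fast and effectively one-way
    rx("tin_BAK", ("BAK_c",), ("BAK_m",), "translocation_in", "kin_BAK", 2.0)
    for a in ANTI_APOPTOTIC:
        rx(f"tin_{a}", (f"{a}_c",), (f"{a}_m",), "translocation_in", f"kin_{a}", 0.5)
        rx(f"tout_{a}", (f"{a}_m",), (f"{a}_c",), "translocation_out", f"kout_{a}", 0.5)
    # BH3-only mobilisation to the MOM is driven by the lumped upstream input
    for b in BH3_ONLY:
        rx(
            f"imp_{b}",
            ("APOSIG", f"{b}_c"),
            ("APOSIG", f"{b}_m"),
            "activation",
            f"k_imp_{b}",
            0.5,
        )
        rx(f"tout_{b}", (f"{b}_m",), (f"{b}_c",), "translocation_out", f"kout_{b}", 0.5)

    # ---- effector activation ------------------------------------------
    for b in ACTIVATORS:
        for e in EFFECTORS:
            rx(
                f"act_{b}_{e}",
                (f"{b}_m", f"{e}_m"),
                (f"{b}_m", f"{e}_a"),
                "activation",
                f"k_act_{b}_{e}",
                K_ACT,
            )
    for e in EFFECTORS:
        rx(
            f"auto_{e}",
            (f"{e}_a", f"{e}_m"),
            (f"{e}_a", f"{e}_a"),
            "auto_activation",
            f"k_auto_{e}",
            K_AUTO,
        )

    # ---- oligomerization: dimers, then tetramer pores -----------------
    for e in EFFECTORS:
        rx(f"dim_{e}", (f"{e}_a", f"{e}_a"), (f"{e}_d",), "oligomerization", f"k_dim_{e}", K_DIM)
        rx(f"pore_{e}", (f"{e}_d", f"{e}_d"), (f"{e}_p",), "oligomerization", f"k_pore_{e}", K_PORE)

    # ---- MOM heterodimers: anti-apoptotic x BH3-only ------------------
    for a in ANTI_APOPTOTIC:
        for b in BH3_PARTNERS[a]:
            cpx = f"{a}_{b}_m"
            koff = KOFF_BH3_SENSITIZER if b == "NOXA" else KOFF_BH3_ACTIVATOR
            rx(f"on_{cpx}", (f"{a}_m", f"{b}_m"), (cpx,), "binding", f"kon_{a}_{b}_m", KON_BH3)
            rx(f"off_{cpx}", (cpx,), (f"{a}_m", f"{b}_m"), "unbinding", f"koff_{a}_{b}_m", koff)
            rx(f"degc_{cpx}", (cpx,), (), "degradation", f"d_cpx_{a}_{b}", DEG_COMPLEX)
            rx(f"eff_{cpx}", (cpx,), (), "complex_efflux", f"ke_{a}_{b}", 0.0)

    # ---- MOM heterodimers: anti-apoptotic x active effector -----------
    for a in ANTI_APOPTOTIC:
        for e in ACTIVE_EFFECTOR_PARTNERS[a]:
            cpx = f"{a}_{e}a_m"
            rx(f"on_{cpx}", (f"{a}_m", f"{e}_a"), (cpx,), "binding", f"kon_{a}_{e}a", KON_AEFF)
            rx(f"off_{cpx}", (cpx,), (f"{a}_m", f"{e}_a"), "unbinding", f"koff_{a}_{e}a", KOFF_AEFF)
            rx(f"degc_{cpx}", (cpx,), (), "degradation", f"d_cpx_{a}_{e}a", DEG_COMPLEX)
            rx(f"eff_{cpx}", (cpx,), (), "complex_efflux", f"ke_{a}_{e}a", 0.0)

    # ---- cytosolic heterodimers (transient shuttling pools) ------------
    for a in ANTI_APOPTOTIC:
        for b in BH3_PARTNERS[a]:
            cpx = f"{a}_{b}_c"
            rx(f"on_{cpx}", (f"{a}_c", f"{b}_c"), (cpx,), "binding", f"kon_{a}_{b}_c", KON_CYT)
            rx(f"off_{cpx}", (cpx,), (f"{a}_c", f"{b}_c"), "unbinding", f"koff_{a}_{b}_c", KOFF_CYT)

    # ---- retrotranslocation-mode clearance of inactive effectors ------
    # guardians capture inactive membrane effectors and extract them from
    # the MOM; the extracted effector is turned over and the guardian
    # recycled, so guardian abundance sets the effector clearance rate
    for a in ANTI_APOPTOTIC:
        for e in EFFECTORS:
            cpx = f"{a}_{e}i_m"
            rx(f"on_{cpx}", (f"{a}_m", f"{e}_m"), (cpx,), "binding", f"kon_{a}_{e}i", KON_MODE1)
            rx(f"ret_{cpx}", (cpx,), (f"{a}_m",), "degradation", f"d_{a}_{e}i", D_RETRO)

    # ---- BH3-mimetic drugs --------------------------------------------
    for a in ANTI_APOPTOTIC:
        d = drug_name(a)
        for c in ("m", "c"):
            cpx = f"{d}_{a}_{c}"
            rx(f"bnd_{cpx}", (d, f"{a}_{c}"), (cpx,), "drug_binding", f"kon_{d}_{c}", KON_DRUG)
            rx(f"ubd_{cpx}", (cpx,), (d, f"{a}_{c}"), "drug_unbinding", f"koff_{d}_{c}", KOFF_DRUG)

    # standalone constant: clamped level of the lumped upstream input
    params["apoptotic_signal"] = APOPTOTIC_SIGNAL

    return NetworkModel(species, reactions, ParameterSet(params))


def default_initial_state(model: NetworkModel) -> "np.ndarray":
    """All-zero state with the apoptotic-signal input at its clamped level."""
    import numpy as np

    x0 = np.zeros(model.n_species)
    if "APOSIG" in model.species_names():
        x0[model.species_index("APOSIG")] = model.parameters.values.get(
            "apoptotic_signal", APOPTOTIC_SIGNAL
        )
    return x0


def write_canonical_network(directory: str | Path) -> dict[str, Path]:
    """Write the canonical model's CSV definition files to ``directory``."""
    from .network import write_network

    return write_network(canonical_model(), directory)
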