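"""Ionic solutions, Nernst potentials and Henderson liquid-junction potentials.

Whole-cell reversal potentials are only interpretable after correcting the
command voltage for the liquid-junction potential (LJP) between pipette and
bath and after comparing the corrected reversal with the Nernst equilibrium
potential of the candidate ion.  The LJP is computed with the generalized
Henderson equation from limiting ionic mobilities.

Mobility convention
-------------------
The embedded table stores limiting equivalent conductivities λ° (S·cm²/eq at
25 °C, infinite dilution).  Relative mobilities are formed as
``u_i = λ°_i / (|z_i| · λ°_K)``, the convention used by the JPCalc family of
LJP calculators (so Ca²⁺ has relative mobility 0.405, not 0.81).  For large
organic anions without well-measured conductivities (nucleotides,
phosphocreatine) a generic polyanion value is assigned and declared here
rather than hidden; these species are minor contributors next to the
dominant K⁺/gluconate⁻ vs Na⁺/Cl⁻ asymmetry.

Dissociation rules
------------------
Salt recipes are mapped to free ions by an editable dissociation table:
K-gluconate → K⁺ + gluconate⁻; chloride salts fully; Na₂-ATP → 2 Na⁺ + ATP²⁻;
Na-GTP → Na⁺ + GTP²⁻ (mobility class only; stoichiometric Na as printed);
Na₂-phosphocreatine → 2 Na⁺ + PCr²⁻; ascorbate as its sodium salt;
NaH₂PO₄ → Na⁺ + H₂PO₄⁻; HEPES is split between neutral and anionic forms by
its pKa (7.5) at the solution pH; glucose, EGTA (0.2 mM) and free acids are
treated as electroneutral spectators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import rt_over_f_mv

__all__ = [
    "SolutionComposition",
    "MOBILITY_TABLE",
    "DISSOCIATION_TABLE",
    "nernst_potential",
    "permeability_ratio",
    "henderson_ljp",
]

#: limiting equivalent conductivity λ° in S·cm²/eq (25 °C) and signed charge
#: sources: standard electrochemical tables for the inorganic ions;
#: gluconate and HEPES from the JPCalc relative-mobility set (0.33 and 0.30
#: of K⁺); nucleotides/phosphocreatine/ascorbate assigned the generic large
#: organic-anion value 24 (≈0.33 of K⁺).
MOBILITY_TABLE: dict = {
    "K": (73.48, +1),
    "Na": (50.08, +1),
    "Li": (38.66, +1),
    "Cs": (77.2, +1),
    "H": (349.8, +1),
    "NMDG": (24.0, +1),
    "Cl": (76.31, -1),
    "Br": (78.1, -1),
    "I": (76.8, -1),
    "F": (55.4, -1),
    "NO3": (71.42, -1),
    "OH": (198.0, -1),
    "Ca": (59.47, +2),
    "Mg": (53.0, +2),
    "Ba": (63.6, +2),
    "gluconate": (24.25, -1),
    "HEPES-": (22.05, -1),
    "MES-": (26.8, -1),
    "H2PO4": (36.0, -1),
    "HCO3": (44.5, -1),
    "SO4": (80.0, -2),
    "acetate": (40.9, -1),
    "aspartate": (30.0, -1),
    "glutamate": (28.0, -1),
    "methanesulfonate": (48.8, -1),
    "ascorbate": (24.0, -1),
    "ATP": (48.0, -2),  # λ° per mole for ATP²⁻ (24 per eq)
    "GTP": (48.0, -2),
    "phosphocreatine": (48.0, -2),
    "EGTA": (48.0, -2),
}

HEPES_PKA = 7.5

#: salt/species name → list of (ion name, stoichiometry); "HEPES(pH)" and
#: neutral species are resolved dynamically in dissociate()
DISSOCIATION_TABLE: dict = {
    "K-gluconate": [("K", 1), ("gluconate", 1)],
    "KCl": [("K", 1), ("Cl", 1)],
    "NaCl": [("Na", 1), ("Cl", 1)],
    "CaCl2": [("Ca", 1), ("Cl", 2)],
    "MgCl2": [("Mg", 1), ("Cl", 2)],
    "BaCl2": [("Ba", 1), ("Cl", 2)],
    "Na2-ATP": [("Na", 2), ("ATP", 1)],
    "Na-ATP": [("Na", 1), ("ATP", 1)],
    "Na-GTP": [("Na", 1), ("GTP", 1)],
    "Na2-phosphocreatine": [("Na", 2), ("phosphocreatine", 1)],
    "NaH2PO4": [("Na", 1), ("H2PO4", 1)],
    "Na-HEPES": [("Na", 1), ("HEPES", 1)],
    "Na-ascorbate": [("Na", 1), ("ascorbate", 1)],
    "ascorbate": [("Na", 1), ("ascorbate", 1)],  # printed as the sodium salt
    "Na-gluconate": [("Na", 1), ("gluconate", 1)],
    "KOH": [("K", 1), ("OH", 1)],
    "NaOH": [("Na", 1), ("OH", 1)],
    "HEPES": [("HEPES", 1)],
    "EGTA": [],  # heavily chelated / negligible at sub-mM; neutral spectator
    "glucose": [],
    "d-glucose": [],
    "sucrose": [],
}


@dataclass
class SolutionComposition:
    """An electrolyte recipe: named species with concentrations in mM."""

    components: tuple  # ((species, mM), ...)
    ph: float = 7.4
    temperature_c: float = 25.0
    label: str = ""
    dissociation: dict = field(default_factory=lambda: DISSOCIATION_TABLE)

    def __post_init__(self):
        comps = tuple((str(n), float(c)) for n, c in self.components)
        for n, c in comps:
            if c < 0:
                raise ValueError(f"negative concentration for {n!r}")
        self.components = comps

    def free_ions(self) -> dict:
        """Resolve the recipe to free-ion concentrations {ion: mM}.

        HEPES is partitioned into its anionic form by pH; unresolvable
        species raise a KeyError naming the offender.
        """
        ions: dict = {}
        for name, conc in self.components:
            if name not in self.dissociation:
                raise KeyError(f"no dissociation rule for species {name!r}")
            for ion, stoich in self.dissociation[name]:
                if ion == "HEPES":
                    frac = 1.0 / (1.0 + 10.0 ** (HEPES_PKA - self.ph))
                    ions["HEPES-"] = ions.get("HEPES-", 0.0) + conc * stoich * frac
                else:
                    ions[ion] = ions.get(ion, 0.0) + conc * stoich
        for ion in ions:
            if ion not in MOBILITY_TABLE:
                raise KeyError(f"no mobility entry for ion {ion!r}")
        return ions


def nernst_potential(c_out: float, c_in: float, z: int, temperature_c: float = 24.0) -> float:
    """Nernst equilibrium potential E = (RT/zF)·ln(c_out/c_in) in mV."""
    if z == 0:
        raise ValueError("z must be non-zero")
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be positive")
    return rt_over_f_mv(temperature_c) / z * np.log(c_out / c_in)


def permeability_ratio(delta_e_rev: float, z: int, temperature_c: float = 24.0) -> float:
    """Bi-ionic relative permeability P_test/P_ref from a reversal shift.

    ``delta_e_rev = E_rev(test) - E_rev(reference)`` in mV after full
    replacement of the reference ion by the test ion on one side.  The sign
    convention is fixed so that the more permeant ion gives a ratio > 1: for
    an anion (z = -1) a negative reversal shift (more permeant test anion)
    yields ``exp(-delta_e/RT_F) > 1``, i.e.

        P_test/P_ref = exp(z · F · ΔE_rev / (R T)).
    """
    return float(np.exp(z * delta_e_rev / rt_over_f_mv(temperature_c)))


def henderson_ljp(pipette: SolutionComposition, bath: SolutionComposition) -> float:
    """Generalized Henderson liquid-junction potential in mV.

    Returned with the pipette-referenced sign convention used by acquisition
    software: the value is *added* to command potentials as a correction, and
    a K-gluconate pipette against a NaCl-based bath gives a negative value.
    The function is antisymmetric under swapping its arguments.

        V = -(RT/F) · [Σ z_i u_i Δc_i / Σ z_i² u_i Δc_i]
                    · ln[Σ z_i² u_i c_i^pip / Σ z_i² u_i c_i^bath]

    with Δc_i = c_i^bath − c_i^pip and u_i = λ°_i/|z_i| the ionic mobility
    (so z_i² u_i c_i is proportional to the molar conductivity contribution
    and the log term compares total solution conductivities).
    """
    t_c = pipette.temperature_c
    ions_p = pipette.free_ions()
    ions_b = bath.free_ions()
    names = sorted(set(ions_p) | set(ions_b))
    num = den = sum_p = sum_b = 0.0
    for name in names:
        lam, z = MOBILITY_TABLE[name]
        u = lam / abs(z)
        cp = ions_p.get(name, 0.0)
        cb = ions_b.get(name, 0.0)
        num += z * u * (cb - cp)
        den += z * z * u * (cb - cp)
        sum_p += z * z * u * cp
        sum_b += z * z * u * cb
    if sum_p <= 0 or sum_b <= 0:
        raise ValueError("degenerate solution pair for Henderson equation")
    if abs(den) < 1e-12 * (sum_p + sum_b):
        return 0.0  # identical (or mobility-balanced) solutions: no junction potential
    v_bath_minus_pip = rt_over_f_mv(t_c) * (num / den) * np.log(sum_p / sum_b)
    return -v_bath_minus_pip
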