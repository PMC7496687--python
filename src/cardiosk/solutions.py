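"""Free-ion equilibrium solver for pipette/bath recipes.

Patch-pipette solutions quote *total* concentrations; the physiologically
relevant quantities are the free ion concentrations after equilibration with
the chelating ligands (ATP, GTP, EGTA, fluorescent indicator).  This module
solves the coupled 1:1 mass-action system

    cation_i:  T_i = x_i * (1 + sum_j K_ij * L_j)
    ligand_j:  L_j_tot = L_j * (1 + sum_i K_ij * x_i)

where x_i, L_j are free concentrations and K_ij are *apparent* association
constants at the recipe's pH and temperature (proton competition and higher
complexes such as MgHATP are folded into the apparent constants, in the style
of the standard chelator calculators).  The solver is a damped fixed-point
iteration on the free cation concentrations, run to a mass-conservation
residual below 1e-12 mM.

The shipped default table carries literature stability constants corrected to
pH 7.2, 22 C, ~0.15 M ionic strength; every constant has a provenance note
and all of them can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SolutionRecipe",
    "BindingTable",
    "free_ion",
    "bound_ledger",
    "default_binding_table",
    "pipette_recipe",
    "ConvergenceError",
]

CATIONS = ("Mg", "Ca")
LIGANDS = ("ATP", "GTP", "EGTA", "Rhod2")


class ConvergenceError(RuntimeError):
    def __init__(self, residual: float, iterations: int):
        super().__init__(
            f"free-ion solver did not converge in {iterations} iterations "
            f"(residual {residual:.3e} mM)")
        self.residual = residual


@dataclass
class SolutionRecipe:
    """Total concentrations (mM) of cations and ligands at a stated pH/T."""

    totals: dict[str, float]
    ph: float = 7.2
    temperature: float = 22.0

    def __post_init__(self) -> None:
        for k, v in self.totals.items():
            if v < 0:
                raise ValueError(f"negative total for {k}")
        if not (5.0 <= self.ph <= 9.0):
            raise ValueError("pH must be within [5, 9]")

    def cations(self) -> list[str]:
        return [s for s in self.totals if s in CATIONS]

    def ligands(self) -> list[str]:
        return [s for s in self.totals if s not in CATIONS]


@dataclass
class BindingTable:
    """Apparent 1:1 association constants K_app (per M) per (cation, ligand)."""

    k_app: dict[tuple[str, str], float]
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)
    ph: float = 7.2
    temperature: float = 22.0

    def __post_init__(self) -> None:
        for pair, k in self.k_app.items():
            if not k > 0:
                raise ValueError(f"K_app must be > 0 for {pair}")

    def k_per_mM(self, cation: str, ligand: str) -> float:
        return self.k_app.get((cation, ligand), 0.0) * 1e-3


def default_binding_table() -> BindingTable:
    """Apparent constants at pH 7.2, 22 C, I ~ 0.15 M.

    Nucleotide constants are absolute log K ~ 4.0-4.1 reduced by proton
    competition at the terminal phosphate (pKa2 ~ 6.95 at this ionic
    strength): K_app = K / (1 + 10^(pKa2 - pH)).  EGTA constants use the
    classic log K (Ca 10.86, Mg 5.21) with the two amine protonations (pKa
    9.40, 8.79) competing at pH 7.2.  Rhod-2's Ca2+ affinity is the
    calibration Kd of 1.58 uM; its Mg2+ affinity is weak and approximate.
    """
    proton_nt = 1.0 + 10 ** (6.95 - 7.2)        # terminal-phosphate competition
    proton_egta = 10 ** (9.40 - 7.2) * (1.0 + 10 ** (8.79 - 7.2))
    k = {
        ("Mg", "ATP"): 10 ** 4.06 / proton_nt,
        ("Ca", "ATP"): 10 ** 3.98 / proton_nt,
        ("Mg", "GTP"): 10 ** 4.02 / proton_nt,
        ("Ca", "GTP"): 10 ** 3.96 / proton_nt,
        ("Mg", "EGTA"): 10 ** 5.21 / proton_egta,
        ("Ca", "EGTA"): 10 ** 10.86 / proton_egta,
        ("Ca", "Rhod2"): 1.0 / 1.58e-6,
        ("Mg", "Rhod2"): 1.0e2,
    }
    prov = {
        ("Mg", "ATP"): "log K 4.06 (I=0.1), pKa2(ATP) 6.95 competition at pH 7.2",
        ("Ca", "ATP"): "log K 3.98 (I=0.1), pKa2(ATP) 6.95 competition at pH 7.2",
        ("Mg", "GTP"): "log K 4.02, treated as ATP-like; pKa2 6.95 competition",
        ("Ca", "GTP"): "log K 3.96, treated as ATP-like; pKa2 6.95 competition",
        ("Mg", "EGTA"): "log K 5.21; amine pKa 9.40/8.79 competition at pH 7.2",
        ("Ca", "EGTA"): "log K 10.86; amine pKa 9.40/8.79 competition at pH 7.2",
        ("Ca", "Rhod2"): "indicator calibration Kd 1.58 uM",
        ("Mg", "Rhod2"): "weak Mg binding of BAPTA-family indicators, approximate",
    }
    return BindingTable(k_app=k, provenance=prov)


def pipette_recipe() -> SolutionRecipe:
    """The nominally Ca2+-free pipette solution used for the SK recordings.

    6 mM total Mg (5 Mg-ATP + 1 MgCl2), 5 mM ATP, 0.1 mM Tris-GTP and 0.1 mM
    Rhod-2 K+ salt at pH 7.2, room temperature.
    """
    return SolutionRecipe(
        totals={"Mg": 6.0, "ATP": 5.0, "GTP": 0.1, "Rhod2": 0.1},
        ph=7.2, temperature=22.0)


def _solve(recipe: SolutionRecipe, table: BindingTable,
           tol: float = 1e-12, max_iter: int = 10_000,
           damping: float = 0.5):
    cations = recipe.cations()
    ligands = recipe.ligands()
    for lig in ligands:
        if not any((cat, lig) in table.k_app for cat in CATIONS):
            raise ValueError(f"ligand {lig!r} not covered by the binding table")
    T = np.array([recipe.totals[c] for c in cations])
    Ltot = np.array([recipe.totals[lig] for lig in ligands])
    K = np.array([[table.k_per_mM(c, lig) for lig in ligands] for c in cations])

    x = T.copy()  # start from fully free
    residual = np.inf
    for it in range(max_iter):
        L = Ltot / (1.0 + K.T @ x) if ligands else Ltot
        x_new = T / (1.0 + K @ L) if cations else T
        x = damping * x_new + (1.0 - damping) * x
        L = Ltot / (1.0 + K.T @ x) if ligands else Ltot
        residual = float(np.max(np.abs(x * (1.0 + K @ L) - T))) if cations else 0.0
        if residual <= tol:
            return cations, ligands, x, L, K
    raise ConvergenceError(residual, max_iter)


def free_ion(recipe: SolutionRecipe, table: BindingTable | None = None,
             ion: str = "Mg") -> float:
    """Free concentration (mM) of ``ion`` in the equilibrated recipe."""
    if table is None:
        table = default_binding_table()
    if ion not in recipe.totals:
        raise ValueError(f"ion {ion!r} not present in the recipe")
    cations, _, x, _, _ = _solve(recipe, table)
    return float(x[cations.index(ion)])


def bound_ledger(recipe: SolutionRecipe, table: BindingTable | None = None
                 ) -> dict[str, dict[str, float]]:
    """Free and per-ligand bound concentrations (mM) for every cation."""
    if table is None:
        table = default_binding_table()
    cations, ligands, x, L, K = _solve(recipe, table)
    out: dict[str, dict[str, float]] = {}
    for i, cat in enumerate(cations):
        entry = {"free": float(x[i])}
        for j, lig in enumerate(ligands):
            entry[f"bound_{lig}"] = float(K[i, j] * x[i] * L[j])
        out[cat] = entry
    for j, lig in enumerate(ligands):
        out.setdefault("ligands_free", {})[lig] = float(L[j])
    return out
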