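"""Gibbs free-energy feasibility of anaerobic conversions.

ΔG = ΔG°′ + RT ln Q, with ΔG°′ assembled from standard transformed
formation energies (pH 7 convention; the proton is carried as a species
entry at RT ln 1e-7) and Q the product of species activities raised to
their signed stoichiometric coefficients (products positive). A reaction is
classified *favorable* iff ΔG is strictly below the threshold (default 0):
ΔG = 0 is equilibrium, not a driving force.

The shipped constants table is an illustrative set of approximate
literature values; the module's contract is the calculation, and the table
is editable/replaceable. Under it, anoxic oxidation of ethanol to acetate
plus hydrogen is endergonic (~ +9.7 kJ/mol at unit activities), which is
why hydrogen accumulation makes the conversion infeasible without a
syntrophic partner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "R_KJ",
    "ReactionThermo",
    "load_constants",
    "delta_g0_prime",
    "delta_g",
    "feasibility",
    "ethanol_to_acetate",
]

R_KJ = 8.314e-3  # kJ / mol / K


@dataclass(frozen=True)
class ReactionThermo:
    """A reaction plus everything needed to evaluate its ΔG.

    ``stoichiometry``: species -> signed coefficient (products positive).
    ``dg0_prime``: standard transformed formation energy per species, kJ/mol.
    ``activities``: dimensionless activities relative to the standard state
    (molar concentration / 1 M, partial pressure / 1 bar); water is
    conventionally 1. Missing species default to activity 1.
    """

    stoichiometry: dict
    dg0_prime: dict
    activities: dict = field(default_factory=dict)
    temperature: float = 310.15

    def __post_init__(self) -> None:
        missing = set(self.stoichiometry) - set(self.dg0_prime)
        if missing:
            raise ValueError(f"no formation energy for species: {sorted(missing)}")
        for sp, a in self.activities.items():
            if a <= 0:
                raise ValueError(f"activity of {sp!r} must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")

    def reversed(self) -> "ReactionThermo":
        return ReactionThermo(
            stoichiometry={s: -c for s, c in self.stoichiometry.items()},
            dg0_prime=self.dg0_prime,
            activities=self.activities,
            temperature=self.temperature,
        )


def load_constants() -> pd.DataFrame:
    """Shipped standard transformed formation energies (kJ/mol, pH 7)."""
    with resources.files("acetotrace.data").joinpath("thermo_constants.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="species")


def constants_dict() -> dict[str, float]:
    return load_constants()["dg0_prime_kj_mol"].to_dict()


def delta_g0_prime(rxn: ReactionThermo) -> float:
    """ΔG°′ = Σ coefficient x formation energy (kJ/mol)."""
    return sum(coef * rxn.dg0_prime[sp] for sp, coef in rxn.stoichiometry.items())


def delta_g(rxn: ReactionThermo) -> float:
    """ΔG = ΔG°′ + RT ln Q (kJ/mol), Q = Π activity^coefficient."""
    ln_q = sum(
        coef * math.log(rxn.activities.get(sp, 1.0))
        for sp, coef in rxn.stoichiometry.items()
    )
    return delta_g0_prime(rxn) + R_KJ * rxn.temperature * ln_q


def feasibility(rxn: ReactionThermo, threshold: float = 0.0) -> str:
    """Classify a conversion: "favorable" iff ΔG < threshold (strict)."""
    return "favorable" if delta_g(rxn) < threshold else "unfavorable"


def ethanol_to_acetate(
    activities: dict | None = None, temperature: float = 310.15
) -> ReactionThermo:
    """The anoxic ethanol oxidation the gut-microbiome argument hinges on:

    ethanol + H2O -> acetate- + H+ + 2 H2

    Endergonic at standard conditions; only hydrogen-scavenging partners
    could pull it forward.
    """
    return ReactionThermo(
        stoichiometry={"ethanol": -1, "H2O": -1, "acetate": 1, "H+": 1, "H2": 2},
        dg0_prime=constants_dict(),
        activities={"H2O": 1.0, **(activities or {})},
        temperature=temperature,
    )
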