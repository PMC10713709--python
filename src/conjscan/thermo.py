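"""Reaction thermochemistry bookkeeping.

Free energies and enthalpies are assembled from an electronic energy in
solvent plus thermal correction sums, G = E_sol + G_therm and
H = E_sol + H_therm; reaction deltas are products-minus-reactants sums;
and the summary table reports, for each ligand-exchange reaction, ΔG, ΔH,
ΔTPIE and the relative columns against a reference reaction.  The
TPIE-difference estimator is validated by comparing its per-reaction
offset from ΔH and the spread of the relative columns.

All values are kcal/mol; inputs are taken at face value (a flagged
Hartree→kcal/mol conversion helper is provided, nothing is converted
implicitly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .fmo_energetics import relative_series

__all__ = [
    "HARTREE_TO_KCAL",
    "hartree_to_kcal",
    "ThermoRecord",
    "ReactionResult",
    "assemble",
    "reaction_delta",
    "table1",
    "compare_dtpie_dh",
]

HARTREE_TO_KCAL = 627.5095


def hartree_to_kcal(value_hartree: float) -> float:
    """Explicit Hartree → kcal/mol conversion (1 Ha = 627.5095 kcal/mol)."""
    return value_hartree * HARTREE_TO_KCAL


@dataclass
class ThermoRecord:
    """Assembled G and H of one species (kcal/mol)."""

    label: str
    E_sol: float
    G_therm: float
    H_therm: float
    G: float
    H: float

    def __post_init__(self) -> None:
        if abs(self.G - (self.E_sol + self.G_therm)) > 1e-9:
            raise ValueError(f"{self.label}: G != E_sol + G_therm")
        if abs(self.H - (self.E_sol + self.H_therm)) > 1e-9:
            raise ValueError(f"{self.label}: H != E_sol + H_therm")


def assemble(E_sol: float, G_therm: float, H_therm: float,
             label: str = "") -> ThermoRecord:
    """Build a ThermoRecord with G = E_sol + G_therm, H = E_sol + H_therm."""
    return ThermoRecord(
        label=label, E_sol=E_sol, G_therm=G_therm, H_therm=H_therm,
        G=E_sol + G_therm, H=E_sol + H_therm,
    )


def reaction_delta(products: Sequence[ThermoRecord],
                   reactants: Sequence[ThermoRecord]) -> tuple[float, float]:
    """(dG, dH) = Σ products − Σ reactants."""
    if not products or not reactants:
        raise ValueError("need at least one product and one reactant")
    dg = sum(r.G for r in products) - sum(r.G for r in reactants)
    dh = sum(r.H for r in products) - sum(r.H for r in reactants)
    return dg, dh


@dataclass
class ReactionResult:
    """One row of the ligand-exchange summary table (kcal/mol)."""

    label: str
    dG: float
    dH: float
    dH_rel: float
    dTPIE: float
    dTPIE_rel: float


def table1(
    reactions: Sequence[tuple[float, float, float]],
    reference: int = 0,
    labels: Sequence[str] | None = None,
) -> list[ReactionResult]:
    """Summary rows from (dG, dH, dTPIE) triples.

    Relative columns are taken against the reference reaction (by default
    the first, conventionally the most exergonic exchange), whose relative
    entries are 0.0 by construction.
    """
    if not reactions:
        raise ValueError("empty reaction list")
    if not 0 <= reference < len(reactions):
        raise IndexError("reference reaction out of range")
    labels = labels or [f"reaction {i + 1}" for i in range(len(reactions))]
    dh_rel = relative_series([r[1] for r in reactions], reference)
    dtpie_rel = relative_series([r[2] for r in reactions], reference)
    return [
        ReactionResult(label=lab, dG=dg, dH=dh, dH_rel=hr,
                       dTPIE=dt, dTPIE_rel=tr)
        for lab, (dg, dh, dt), hr, tr
        in zip(labels, reactions, dh_rel, dtpie_rel)
    ]


def compare_dtpie_dh(
    results: Sequence[ReactionResult], reference: int = 0,
) -> dict:
    """Agreement of the TPIE-difference estimator with ΔH.

    Returns the per-reaction offset ΔTPIE − ΔH, its mean, and the largest
    absolute discrepancy between the relative columns over the
    non-reference reactions (the reference is 0 − 0 by construction).
    """
    if len(results) < 2:
        raise ValueError("need at least two reactions to compare")
    offsets = [r.dTPIE - r.dH for r in results]
    rel_err = [
        abs(r.dTPIE_rel - r.dH_rel)
        for i, r in enumerate(results) if i != reference
    ]
    return {
        "offsets": offsets,
        "mean_offset": sum(offsets) / len(offsets),
        "max_rel_discrepancy": max(rel_err),
    }
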