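"""Reconstruction quality control.

Three independent audits catch the classic defects of draft
reconstructions:

* **Mass/charge balance** — every internal reaction must conserve each
  element and the net charge; biomass and boundary pseudo-reactions are
  inherently unbalanced and are skipped (listed separately).
* **Energy-generating cycles** — with every exchange closed, a model
  must not be able to produce ATP, NADH or NADPH from nothing.  A
  dissipation reaction for the currency couple is temporarily added and
  maximized; any positive optimum exposes a thermodynamically impossible
  cycle.
* **GPR logic** — gene-deletion screens evaluate each reaction's boolean
  gene association against a knockout set and re-run FBA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

from .core_model import (
    DiazogemError,
    GprTree,
    Medium,
    MetabolicModel,
    ReactionRecord,
    apply_medium,
)
from .fba import REPORT_TOL, fba, pfba

__all__ = [
    "BalanceReport",
    "EnergyCycleReport",
    "element_balance",
    "energy_cycle_check",
    "eval_gpr",
    "gene_deletion_screen",
    "CURRENCY_DISSIPATION",
]


@dataclass
class ReactionImbalance:
    elements: Dict[str, float]
    charge: float

    @property
    def balanced(self) -> bool:
        return not self.elements and self.charge == 0

    @property
    def minor(self) -> bool:
        """Only protons (H) and charge are off — typical of transport steps."""
        return not self.balanced and set(self.elements) <= {"H"}


@dataclass
class BalanceReport:
    imbalances: Dict[str, ReactionImbalance] = field(default_factory=dict)
    skipped: List[str] = field(default_factory=list)
    unauditable: List[str] = field(default_factory=list)

    def is_balanced(self, rxn_id: str) -> bool:
        imb = self.imbalances.get(rxn_id)
        return imb is not None and imb.balanced

    @property
    def unbalanced(self) -> List[str]:
        return [r for r, imb in self.imbalances.items() if not imb.balanced]

    @property
    def all_balanced(self) -> bool:
        return not self.unbalanced and not self.unauditable


def element_balance(
    model: MetabolicModel, biomass_ids: Optional[Iterable[str]] = None
) -> BalanceReport:
    """Audit element and charge conservation of every internal reaction.

    ``imbalance(e) = sum_i s_i * atoms_e(i)`` over the stoichiometry; a
    reaction is balanced iff every element and the charge net to exactly
    zero.  Reactions with a formula-less participant are flagged
    ``unauditable``, never silently passed.
    """
    if biomass_ids is None:
        biomass_ids = {model.objective_id} if model.objective_id else set()
        biomass_ids |= {
            r.id
            for r in model.reactions.values()
            if "biomass" in r.subsystem.lower()
        }
    biomass_ids = set(biomass_ids)
    report = BalanceReport()
    for rxn in model.reactions.values():
        if rxn.is_boundary or rxn.id in biomass_ids:
            report.skipped.append(rxn.id)
            continue
        if any(not model.metabolites[m].formula for m in rxn.stoichiometry):
            report.unauditable.append(rxn.id)
            continue
        net: Dict[str, float] = {}
        charge = 0.0
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            for element, count in met.elements.items():
                net[element] = net.get(element, 0.0) + coeff * count
            charge += coeff * met.charge
        net = {e: v for e, v in net.items() if abs(v) > 1e-9}
        charge = 0.0 if abs(charge) <= 1e-9 else charge
        report.imbalances[rxn.id] = ReactionImbalance(elements=net, charge=charge)
    return report


#: community-standard dissipation reactions for the three currency couples;
#: NAD(P)H oxidation leaves the two electrons implicit.
CURRENCY_DISSIPATION = {
    "ATP": {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
    "NADH": {"nadh_c": -1.0, "nad_c": 1.0, "h_c": 1.0},
    "NADPH": {"nadph_c": -1.0, "nadp_c": 1.0, "h_c": 1.0},
}


@dataclass
class EnergyCycleReport:
    currency: str
    dissipation_flux: float
    cycle_reactions: List[str]

    @property
    def passed(self) -> bool:
        return self.dissipation_flux <= REPORT_TOL


def energy_cycle_check(model: MetabolicModel, currency: str) -> EnergyCycleReport:
    """Closed-exchange free-energy test for ATP, NADH or NADPH.

    All boundary bounds are set to (0, 0), a dissipation reaction is
    added and maximized (parsimoniously, so the reported cycle support is
    minimal).  A well-built model dissipates nothing.
    """
    if currency not in CURRENCY_DISSIPATION:
        raise DiazogemError(
            f"unknown currency {currency!r}; expected one of "
            f"{sorted(CURRENCY_DISSIPATION)}"
        )
    stoich = CURRENCY_DISSIPATION[currency]
    missing = sorted(m for m in stoich if m not in model.metabolites)
    if missing:
        raise DiazogemError(
            f"{currency} dissipation impossible: metabolites {missing} absent"
        )
    closed = model.copy()
    for rxn in closed.reactions.values():
        if rxn.is_boundary:
            rxn.lower_bound = rxn.upper_bound = 0.0
    probe_id = f"DISSIPATION_{currency}"
    closed.add_reaction(
        ReactionRecord(
            id=probe_id,
            stoichiometry=dict(stoich),
            lower_bound=0.0,
            upper_bound=1000.0,
            name=f"{currency} dissipation probe",
            subsystem="QC probe",
        )
    )
    sol = pfba(closed, probe_id)
    if sol.status != "optimal":
        return EnergyCycleReport(currency, 0.0, [])
    support = [
        rid
        for rid, v in sol.fluxes.items()
        if abs(v) > REPORT_TOL and rid != probe_id
    ]
    return EnergyCycleReport(
        currency=currency,
        dissipation_flux=float(sol.objective_value),
        cycle_reactions=sorted(support),
    )


def eval_gpr(gpr: Optional[GprTree], knocked: Iterable[str]) -> bool:
    """True iff the reaction remains catalyzed after knocking out ``knocked``.

    An empty (orphan) GPR is always active.
    """
    if gpr is None:
        return True
    return gpr.evaluate(knocked)


def gene_deletion_screen(
    model: MetabolicModel,
    genes: Optional[Iterable[str]] = None,
    medium: Optional[Medium] = None,
) -> Dict[str, float]:
    """Single-gene deletion growth rates.

    For each gene, every reaction whose GPR evaluates inactive is closed
    (bounds (0, 0)) and FBA is re-run; the input model is never mutated.
    """
    genes = list(genes) if genes is not None else list(model.genes)
    unknown = sorted(set(genes) - set(model.genes))
    if unknown:
        raise DiazogemError(f"genes not in model: {unknown}")
    base = apply_medium(model, medium) if medium is not None else model
    growth: Dict[str, float] = {}
    for gene in genes:
        knocked = base.copy()
        for rxn in knocked.reactions.values():
            if not eval_gpr(rxn.gpr, {gene}):
                rxn.lower_bound = rxn.upper_bound = 0.0
        sol = fba(knocked)
        growth[gene] = float(sol.objective_value) if sol.status == "optimal" else 0.0
    return growth
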