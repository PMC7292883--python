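"""Elemental flux partitioning and biopolymer production analysis.

Carbon/nitrogen partitioning converts a (parsimonious) flux distribution
into per-subsystem element throughput: for each reaction the moles of
the element crossing it per hour, |v| times the element content of the
product side (equal to the substrate side for balanced reactions), then
averaged over the reactions of each subsystem.  Tables across conditions
are compared between diazotrophic and non-diazotrophic regimes with a
per-subsystem Pearson correlation (r > 0.9 flags a conserved
distribution) and a global percent change.

Production analysis covers growth-coupled polymer secretion (alginate,
through the augmented biomass function) and sink-based storage (PHB):
two-step LPs maximize growth, hold it at a chosen fraction of the
optimum and then maximize product flux.  Flux maps are normalized to an
anchor uptake (e.g. glucose = 100) before percent-error comparison with
reference fluxomic maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .core_model import (
    DiazogemError,
    Medium,
    MetabolicModel,
    Metabolite,
    ReactionRecord,
    apply_medium,
    parse_formula,
)
from .fba import FluxDistribution, REPORT_TOL, fba, pfba

__all__ = [
    "element_throughput",
    "partition_fluxes",
    "ElementFluxTable",
    "build_element_flux_table",
    "SubsystemCorrelation",
    "compare_conditions",
    "add_sink",
    "production_rate",
    "normalize_flux_map",
    "FluxComparison",
    "compare_flux_maps",
]

#: subsystem labels excluded from headline partitioning summaries
EXCLUDED_SUBSYSTEM_KEYWORDS = ("transport", "exchange")


def element_throughput(
    reaction: ReactionRecord,
    flux: float,
    element: str,
    metabolites: Mapping[str, Metabolite],
) -> float:
    """mmol of ``element`` moved through ``reaction`` at ``flux``.

    Defined on the product side: |v| * sum over products of s_i *
    atoms_element(i).  For a balanced reaction this equals the
    substrate-side sum; boundary reactions with no product side fall back
    to the substrate side.
    """
    if flux == 0:
        return 0.0

    def side_atoms(side: Dict[str, float]) -> float:
        total = 0.0
        for met_id, coeff in side.items():
            met = metabolites[met_id]
            if not met.formula:
                raise DiazogemError(
                    f"metabolite {met_id!r} has no formula; cannot count {element}"
                )
            total += coeff * parse_formula(met.formula).get(element, 0)
        return total

    products = reaction.products()
    atoms = side_atoms(products) if products else side_atoms(reaction.substrates())
    return abs(flux) * atoms


@dataclass
class PartitionTable:
    """Per-subsystem average element throughput for one condition."""

    element: str
    averages: Dict[str, float]
    excluded: Set[str] = field(default_factory=set)

    def headline(self) -> Dict[str, float]:
        """Averages without transport/exchange subsystems."""
        return {s: v for s, v in self.averages.items() if s not in self.excluded}


def partition_fluxes(
    model: MetabolicModel,
    flux: FluxDistribution,
    element: str,
    include_zero: bool = True,
) -> PartitionTable:
    """Arithmetic-mean element throughput per subsystem.

    ``include_zero`` keeps zero-flux member reactions in the mean (the
    literal reading of an average over a subsystem's reactions); pass
    False for an active-reactions-only mean.  Transport and exchange
    subsystems are computed but flagged excluded from headline summaries.
    """
    per_subsystem: Dict[str, List[float]] = {}
    for rxn in model.reactions.values():
        v = flux.fluxes.get(rxn.id, 0.0)
        try:
            t = element_throughput(rxn, v, element, model.metabolites)
        except DiazogemError:
            if abs(v) > REPORT_TOL:
                raise
            t = 0.0
        bucket = per_subsystem.setdefault(rxn.subsystem, [])
        if include_zero or abs(v) > REPORT_TOL:
            bucket.append(t)
    averages = {
        sub: (sum(vals) / len(vals) if vals else 0.0)
        for sub, vals in per_subsystem.items()
    }
    excluded = {
        sub
        for sub in averages
        if any(k in sub.lower() for k in EXCLUDED_SUBSYSTEM_KEYWORDS)
    }
    return PartitionTable(element=element, averages=averages, excluded=excluded)


@dataclass
class ElementFluxTable:
    """Subsystem x condition matrix of average element throughput
    (mmol element/gDW/h), with condition metadata."""

    element: str
    data: pd.DataFrame  # index: subsystem, columns: condition ids
    metadata: Dict[str, Dict[str, str]] = field(default_factory=dict)
    excluded_subsystems: Set[str] = field(default_factory=set)


def build_element_flux_table(
    model: MetabolicModel,
    distributions: Mapping[str, FluxDistribution],
    element: str,
    metadata: Optional[Dict[str, Dict[str, str]]] = None,
) -> ElementFluxTable:
    columns: Dict[str, Dict[str, float]] = {}
    excluded: Set[str] = set()
    for cond_id, dist in distributions.items():
        table = partition_fluxes(model, dist, element)
        columns[cond_id] = table.averages
        excluded |= table.excluded
    df = pd.DataFrame(columns).fillna(0.0).sort_index()
    return ElementFluxTable(
        element=element,
        data=df,
        metadata=metadata or {},
        excluded_subsystems=excluded,
    )


@dataclass
class SubsystemCorrelation:
    """Pearson r per subsystem across paired condition vectors; r is None
    for constant vectors.  ``similar`` flags r > 0.9."""

    r: Dict[str, Optional[float]]
    similar: Set[str]
    global_percent_change: float


def compare_conditions(
    table_a: ElementFluxTable, table_b: ElementFluxTable
) -> SubsystemCorrelation:
    """Compare two condition tables (e.g. diazotrophic vs not).

    Both tables must share subsystems and condition lists.  The global
    percent change is (sum_a - sum_b) / sum_b * 100.
    """
    if list(table_a.data.index) != list(table_b.data.index) or list(
        table_a.data.columns
    ) != list(table_b.data.columns):
        raise DiazogemError("tables differ in subsystem set or condition list")
    from scipy import stats

    r: Dict[str, Optional[float]] = {}
    similar: Set[str] = set()
    for sub in table_a.data.index:
        x = table_a.data.loc[sub].to_numpy(dtype=float)
        y = table_b.data.loc[sub].to_numpy(dtype=float)
        if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            r[sub] = None
            continue
        r[sub] = float(stats.pearsonr(x, y).statistic)
        if r[sub] > 0.9:
            similar.add(sub)
    total_b = float(table_b.data.to_numpy().sum())
    if total_b == 0:
        raise DiazogemError("reference table sums to zero; percent change undefined")
    total_a = float(table_a.data.to_numpy().sum())
    return SubsystemCorrelation(
        r=r,
        similar=similar,
        global_percent_change=(total_a - total_b) / total_b * 100.0,
    )


# ---------------------------------------------------------------------------
# production


def add_sink(model: MetabolicModel, met_id: str) -> MetabolicModel:
    """Add an irreversible sink ``SK_<met>``: met -> (bounds 0..1000).

    Idempotent: a second call returns an unchanged copy.
    """
    if met_id not in model.metabolites:
        raise DiazogemError(f"unknown metabolite {met_id!r}")
    sink_id = f"SK_{met_id}"
    out = model.copy()
    if sink_id in out.reactions:
        return out
    out.add_reaction(
        ReactionRecord(
            id=sink_id,
            stoichiometry={met_id: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            name=f"{met_id} sink",
            subsystem="Exchange",
        )
    )
    return out


def production_rate(
    model: MetabolicModel,
    product_id: str,
    medium: Optional[Medium] = None,
    growth_fraction: float = 1.0,
    objective_id: Optional[str] = None,
) -> Tuple[float, float]:
    """Two-step LP: maximize growth, hold it at ``growth_fraction`` of the
    optimum, then maximize the flux of ``product_id`` (an exchange or
    sink reaction).  Returns (realized growth rate, production flux).

    ``growth_fraction`` 1 gives growth-coupled production; 0 gives the
    maximum theoretical yield.
    """
    if not 0 <= growth_fraction <= 1:
        raise DiazogemError("growth fraction must lie in [0, 1]")
    if product_id not in model.reactions:
        raise DiazogemError(f"product reaction {product_id!r} not in model")
    work = apply_medium(model, medium) if medium is not None else model.copy()
    objective_id = objective_id or work.objective_id
    growth_sol = fba(work, objective_id)
    if growth_sol.status != "optimal":
        return 0.0, 0.0
    mu_opt = growth_sol.objective_value
    work.reactions[objective_id].lower_bound = growth_fraction * mu_opt
    prod_sol = pfba(work, product_id)
    if prod_sol.status != "optimal":
        return mu_opt, 0.0
    return float(prod_sol.fluxes[objective_id]), float(prod_sol.objective_value)


# ---------------------------------------------------------------------------
# flux-map normalization and comparison


def normalize_flux_map(
    flux: FluxDistribution, anchor: str, scale: float = 100.0
) -> Dict[str, float]:
    """Rescale every flux so the anchor reaction maps to +/-``scale``."""
    if anchor not in flux.fluxes:
        raise DiazogemError(f"anchor reaction {anchor!r} absent from distribution")
    anchor_flux = flux.fluxes[anchor]
    if anchor_flux == 0:
        raise DiazogemError(f"anchor reaction {anchor!r} carries zero flux")
    factor = scale / abs(anchor_flux)
    return {rid: v * factor for rid, v in flux.fluxes.items()}


@dataclass
class FluxComparison:
    """Per-reaction percent error between normalized predicted and
    reference fluxes; ``agree`` flags error <= threshold."""

    percent_error: Dict[str, float]
    agree: Dict[str, bool]
    infinite: Set[str]
    threshold: float

    @property
    def n_agree(self) -> int:
        return sum(self.agree.values())

    @property
    def n_disagree(self) -> int:
        return len(self.agree) - self.n_agree


def compare_flux_maps(
    predicted: Mapping[str, float],
    reference: Mapping[str, float],
    threshold: float = 20.0,
) -> FluxComparison:
    """Percent error |pred - ref| / |ref| * 100 over shared reactions.

    ref = 0 with pred = 0 scores 0%; ref = 0 with pred != 0 is flagged
    infinite (and disagrees).
    """
    shared = sorted(set(predicted) & set(reference))
    if not shared:
        raise DiazogemError("no shared reactions between predicted and reference maps")
    errors: Dict[str, float] = {}
    agree: Dict[str, bool] = {}
    infinite: Set[str] = set()
    for rid in shared:
        ref = reference[rid]
        pred = predicted[rid]
        if ref == 0:
            if pred == 0:
                errors[rid] = 0.0
            else:
                errors[rid] = math.inf
                infinite.add(rid)
        else:
            errors[rid] = abs(pred - ref) / abs(ref) * 100.0
        agree[rid] = errors[rid] <= threshold
    return FluxComparison(
        percent_error=errors, agree=agree, infinite=infinite, threshold=threshold
    )
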