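"""Curation and gap-filling of draft reconstructions.

Draft models built from template organisms carry exogenous genes in
their GPR associations.  Curation proceeds by (1) filtering BLASTp-style
homology hits at the acceptance thresholds (identity >= 40%, e-value <=
1e-4, query coverage >= 85%, all inclusive), (2) remapping template
genes in each GPR to their best target-organism homolog, (3) pruning
reactions that remain exogenous-only *and* carry no flux under any
experimental condition, and (4) classifying dead-end metabolites and
gap-filling from a universal reaction pool to restore growth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .core_model import (
    DiazogemError,
    GprTree,
    Medium,
    MetabolicModel,
    apply_medium,
)
from .fba import REPORT_TOL, blocked_reactions, fba

__all__ = [
    "HomologyHit",
    "read_hits",
    "write_hits",
    "filter_hits",
    "best_hit_mapping",
    "remap_gpr",
    "RemappedGpr",
    "prune_exogenous",
    "DeadEndReport",
    "classify_dead_ends",
    "GapfillSolution",
    "gapfill",
    "GROWTH_THRESHOLD",
]

#: growth rate (1/h) above which a model "grows"; the only numeric
#: threshold printed for the growth calls.
GROWTH_THRESHOLD = 0.001


@dataclass(frozen=True)
class HomologyHit:
    """One BLASTp-style hit: template (query) protein vs target protein."""

    query: str
    subject: str
    identity: float
    evalue: float
    coverage: float

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise DiazogemError(
                f"hit {self.query}->{self.subject}: identity/coverage outside [0, 100]"
            )
        if self.evalue < 0:
            raise DiazogemError(f"hit {self.query}->{self.subject}: negative e-value")


#: BLAST outfmt-6 style column names used in hit TSV files
HIT_COLUMNS = ["qseqid", "sseqid", "pident", "evalue", "qcovs"]


def read_hits(path) -> List[HomologyHit]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise DiazogemError(f"hit table {path} lacks columns {missing}")
    return [
        HomologyHit(
            query=str(row.qseqid),
            subject=str(row.sseqid),
            identity=float(row.pident),
            evalue=float(row.evalue),
            coverage=float(row.qcovs),
        )
        for row in df.itertuples()
    ]


def write_hits(hits: Iterable[HomologyHit], path) -> None:
    pd.DataFrame(
        [(h.query, h.subject, h.identity, h.evalue, h.coverage) for h in hits],
        columns=HIT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def filter_hits(
    hits: Iterable[HomologyHit],
    min_identity: float = 40.0,
    max_evalue: float = 1e-4,
    min_coverage: float = 85.0,
) -> List[HomologyHit]:
    """Keep hits meeting all three thresholds; every threshold is inclusive."""
    return [
        h
        for h in hits
        if h.identity >= min_identity
        and h.evalue <= max_evalue
        and h.coverage >= min_coverage
    ]


def best_hit_mapping(hits: Iterable[HomologyHit]) -> Dict[str, str]:
    """Best accepted hit per template gene.

    Ranking: lowest e-value, ties broken by highest identity, then
    lexicographic subject id.
    """
    best: Dict[str, HomologyHit] = {}
    for hit in hits:
        current = best.get(hit.query)
        if current is None or (hit.evalue, -hit.identity, hit.subject) < (
            current.evalue,
            -current.identity,
            current.subject,
        ):
            best[hit.query] = hit
    return {q: h.subject for q, h in best.items()}


@dataclass
class RemappedGpr:
    gpr: Optional[GprTree]
    exogenous_only: bool


def remap_gpr(
    gpr: Optional[GprTree],
    mapping: Dict[str, str],
    policy: str = "strict",
) -> RemappedGpr:
    """Rename mapped template genes; drop (or invalidate) unmapped leaves.

    Under ``strict`` policy an unmapped leaf inside an AND removes the
    whole AND branch — an enzyme complex is never asserted with a missing
    subunit.  Under ``permissive`` only the leaf is dropped.  An empty
    result is flagged ``exogenous_only``.
    """
    if policy not in ("strict", "permissive"):
        raise DiazogemError(f"unknown remap policy {policy!r}")
    if gpr is None:
        return RemappedGpr(None, False)

    def walk(node: GprTree) -> Optional[GprTree]:
        if node.kind == "gene":
            target = mapping.get(node.gene)
            return GprTree.leaf(target) if target is not None else None
        kept = [walk(c) for c in node.children]
        if node.kind == "and":
            if policy == "strict" and any(k is None for k in kept):
                return None
            kept = [k for k in kept if k is not None]
        else:
            kept = [k for k in kept if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return GprTree(node.kind, children=tuple(kept))

    remapped = walk(gpr)
    return RemappedGpr(remapped, remapped is None)


def prune_exogenous(
    model: MetabolicModel,
    conditions: Sequence[Medium],
    exogenous_only: Iterable[str],
) -> Tuple[MetabolicModel, List[str]]:
    """Remove exogenous-only reactions blocked under *every* condition.

    A reaction flagged ``exogenous_only`` survives if it can carry flux
    under any supplied condition; native reactions are never pruned
    (orphans are conserved).  The returned model attains the same optimum
    as the input under each condition (asserted to 1e-6 relative).
    """
    exogenous_only = set(exogenous_only)
    unknown = sorted(exogenous_only - set(model.reactions))
    if unknown:
        raise DiazogemError(f"exogenous-only flags name unknown reactions: {unknown}")
    blocked_everywhere = set(exogenous_only)
    for medium in conditions:
        blocked_everywhere &= blocked_reactions(model, medium)
        if not blocked_everywhere:
            break
    removed = sorted(blocked_everywhere)
    pruned = model.copy()
    for rid in removed:
        pruned.remove_reaction(rid)
    for medium in conditions:
        before = fba(apply_medium(model, medium))
        after = fba(apply_medium(pruned, medium))
        b = before.objective_value or 0.0
        a = after.objective_value or 0.0
        if abs(a - b) > REPORT_TOL * max(1.0, abs(b)):
            raise DiazogemError(
                f"pruning changed a condition optimum ({b} -> {a}); refusing"
            )
    return pruned, removed


@dataclass
class DeadEndReport:
    """Structural dead ends: metabolites that can only be produced, only be
    consumed, or that participate in no reaction at all.  Reversible
    reactions count as both producers and consumers of every participant.
    Metabolites touched by exactly one (reversible) reaction are not dead
    ends but are flagged ``single_reaction``."""

    classes: Dict[str, str] = field(default_factory=dict)
    single_reaction: Set[str] = field(default_factory=set)

    def __contains__(self, met_id: str) -> bool:
        return met_id in self.classes


def classify_dead_ends(model: MetabolicModel) -> DeadEndReport:
    producers: Dict[str, int] = {m: 0 for m in model.metabolites}
    consumers: Dict[str, int] = {m: 0 for m in model.metabolites}
    touched: Dict[str, int] = {m: 0 for m in model.metabolites}
    for rxn in model.reactions.values():
        for met_id, coeff in rxn.stoichiometry.items():
            touched[met_id] += 1
            forward_produces = coeff > 0
            if rxn.upper_bound > 0:
                if forward_produces:
                    producers[met_id] += 1
                else:
                    consumers[met_id] += 1
            if rxn.lower_bound < 0:  # reversibility expansion
                if forward_produces:
                    consumers[met_id] += 1
                else:
                    producers[met_id] += 1
    report = DeadEndReport()
    for met_id in model.metabolites:
        if touched[met_id] == 0:
            report.classes[met_id] = "disconnected"
        elif producers[met_id] and not consumers[met_id]:
            report.classes[met_id] = "produced-only"
        elif consumers[met_id] and not producers[met_id]:
            report.classes[met_id] = "consumed-only"
        if touched[met_id] == 1 and met_id not in report.classes:
            report.single_reaction.add(met_id)
    return report


@dataclass
class GapfillSolution:
    added: List[str]
    objective_value: float
    filled: bool
    closest_dead_ends: List[str] = field(default_factory=list)


def _growth_with(
    model: MetabolicModel,
    pool: MetabolicModel,
    subset: Sequence[str],
    target: str,
    medium: Optional[Medium],
) -> float:
    candidate = model.copy()
    for met in pool.metabolites.values():
        if met.id not in candidate.metabolites:
            candidate.add_metabolite(met)
    for rid in subset:
        candidate.add_reaction(pool.reactions[rid].copy())
    if medium is not None:
        candidate = apply_medium(candidate, medium)
    sol = fba(candidate, target)
    return sol.objective_value if sol.status == "optimal" else 0.0


def gapfill(
    model: MetabolicModel,
    pool: MetabolicModel,
    target: Optional[str] = None,
    medium: Optional[Medium] = None,
    threshold: float = GROWTH_THRESHOLD,
) -> GapfillSolution:
    """Smallest set of pool reactions restoring growth above ``threshold``.

    For pools of <= 12 reactions the search enumerates subsets by
    increasing size (lexicographic order within a size), so the result is
    the provably smallest set with a deterministic tie-break.  Larger
    pools use add-all-then-greedy-deletion, which still guarantees
    deletion-minimality.  Reactions added this way should be tagged
    ``gapfilled`` by the caller when committed to a model.
    """
    target = target or model.objective_id
    if target is None:
        raise DiazogemError("gapfill needs a target objective reaction")
    overlap = sorted(set(pool.reactions) & set(model.reactions))
    if overlap:
        raise DiazogemError(f"pool reactions already in model: {overlap}")

    if _growth_with(model, pool, [], target, medium) > threshold:
        return GapfillSolution(added=[], objective_value=_growth_with(
            model, pool, [], target, medium), filled=True)

    pool_ids = sorted(pool.reactions)
    if _growth_with(model, pool, pool_ids, target, medium) <= threshold:
        dead = classify_dead_ends(model)
        return GapfillSolution(
            added=[],
            objective_value=0.0,
            filled=False,
            closest_dead_ends=sorted(dead.classes),
        )

    if len(pool_ids) <= 12:
        for size in range(1, len(pool_ids) + 1):
            for subset in itertools.combinations(pool_ids, size):
                mu = _growth_with(model, pool, subset, target, medium)
                if mu > threshold:
                    return GapfillSolution(
                        added=list(subset), objective_value=mu, filled=True
                    )

    # greedy deletion from the full pool (deletion-minimal result)
    kept = list(pool_ids)
    for rid in pool_ids:
        trial = [r for r in kept if r != rid]
        if _growth_with(model, pool, trial, target, medium) > threshold:
            kept = trial
    mu = _growth_with(model, pool, kept, target, medium)
    return GapfillSolution(added=kept, objective_value=mu, filled=True)
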