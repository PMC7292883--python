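"""Domain types for constraint-based metabolic models.

A genome-scale metabolic model (M-model) is a stoichiometric network over
metabolites distributed across compartments (cytoplasm ``c``, periplasm
``p``, extracellular space ``e``), with flux bounds in mmol/gDW/h and
boolean gene-protein-reaction (GPR) associations gating each reaction.
Identifiers follow the BiGG convention: metabolite ids carry a
compartment suffix (``glc__D_c``), exchange reactions are prefixed
``EX_`` and touch exactly one extracellular metabolite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

__all__ = [
    "DiazogemError",
    "ModelParseError",
    "ValidationError",
    "parse_formula",
    "GprTree",
    "Metabolite",
    "ReactionRecord",
    "MetabolicModel",
    "Medium",
    "load_medium",
    "save_medium",
    "stoich_matrix",
    "apply_medium",
    "summarize_model",
    "ModelSummary",
    "DEFAULT_BOUND",
    "COMPARTMENTS",
]

DEFAULT_BOUND = 1000.0
COMPARTMENTS = {"c": "cytoplasm", "p": "periplasm", "e": "extracellular space"}

#: Exchange/sink/demand prefixes; boundary reactions touch exactly one metabolite.
BOUNDARY_PREFIXES = ("EX_", "SK_", "DM_")


class DiazogemError(Exception):
    """Base class for all package errors."""


class ModelParseError(DiazogemError):
    """A model file could not be parsed; the message names the offending entity."""


class ValidationError(DiazogemError):
    """A model or one of its components violates a structural invariant."""


# ---------------------------------------------------------------------------
# chemical formulas

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-notation formula into an element -> atom-count map.

    Raises :class:`ValidationError` on anything that is not a sequence of
    element symbols with optional non-negative integer counts.
    """
    if formula is None:
        raise ValidationError("formula is None")
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValidationError(f"unparsable formula {formula!r} at position {pos}")
        pos = m.end()
        element = m.group(1)
        n = int(m.group(2)) if m.group(2) else 1
        counts[element] = counts.get(element, 0) + n
    if pos != len(formula):
        raise ValidationError(f"unparsable formula {formula!r} at position {pos}")
    return counts


# ---------------------------------------------------------------------------
# GPR trees

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class GprTree:
    """Boolean AND/OR tree over gene identifiers.

    ``kind`` is one of ``"gene"``, ``"and"``, ``"or"``.  GENE leaves carry
    exactly one gene id; AND/OR nodes carry >= 2 children.
    """

    kind: str
    gene: Optional[str] = None
    children: Tuple["GprTree", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "gene":
            if not self.gene or self.children:
                raise ValidationError("GENE leaf must carry exactly one gene id")
        elif self.kind in ("and", "or"):
            if self.gene is not None or len(self.children) < 2:
                raise ValidationError(f"{self.kind.upper()} node needs >= 2 children")
        else:
            raise ValidationError(f"unknown GPR node kind {self.kind!r}")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def leaf(gene: str) -> "GprTree":
        return GprTree("gene", gene=gene)

    @staticmethod
    def all_of(*children: "GprTree") -> "GprTree":
        return GprTree("and", children=tuple(children))

    @staticmethod
    def any_of(*children: "GprTree") -> "GprTree":
        return GprTree("or", children=tuple(children))

    @classmethod
    def from_string(cls, rule: str) -> Optional["GprTree"]:
        """Parse a cobra-style rule string like ``(g1 and g2) or g3``.

        Returns ``None`` for an empty rule (orphan reaction).
        """
        tokens = _GPR_TOKEN.findall(rule)
        if not tokens:
            return None
        pos = 0

        def peek() -> Optional[str]:
            return tokens[pos] if pos < len(tokens) else None

        def take() -> str:
            nonlocal pos
            tok = tokens[pos]
            pos += 1
            return tok

        def parse_or() -> "GprTree":
            terms = [parse_and()]
            while peek() is not None and peek().lower() == "or":
                take()
                terms.append(parse_and())
            return terms[0] if len(terms) == 1 else GprTree("or", children=tuple(terms))

        def parse_and() -> "GprTree":
            terms = [parse_atom()]
            while peek() is not None and peek().lower() == "and":
                take()
                terms.append(parse_atom())
            return terms[0] if len(terms) == 1 else GprTree("and", children=tuple(terms))

        def parse_atom() -> "GprTree":
            tok = take()
            if tok == "(":
                node = parse_or()
                if peek() != ")":
                    raise ModelParseError(f"unbalanced parenthesis in GPR rule {rule!r}")
                take()
                return node
            if tok == ")" or tok.lower() in ("and", "or"):
                raise ModelParseError(f"unexpected token {tok!r} in GPR rule {rule!r}")
            return GprTree.leaf(tok)

        tree = parse_or()
        if pos != len(tokens):
            raise ModelParseError(f"trailing tokens in GPR rule {rule!r}")
        return tree

    # -- queries -----------------------------------------------------------
    def genes(self) -> frozenset:
        if self.kind == "gene":
            return frozenset((self.gene,))
        out: set = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)

    def evaluate(self, knocked: Iterable[str]) -> bool:
        """True iff the catalyst is still available with ``knocked`` genes removed."""
        knocked = set(knocked)
        if self.kind == "gene":
            return self.gene not in knocked
        if self.kind == "and":
            return all(c.evaluate(knocked) for c in self.children)
        return any(c.evaluate(knocked) for c in self.children)

    def to_string(self) -> str:
        if self.kind == "gene":
            return self.gene
        joiner = f" {self.kind} "
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.kind in ("and", "or") and child.kind != self.kind:
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)


# ---------------------------------------------------------------------------
# metabolites and reactions


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = "c"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if not self.id.endswith(f"_{self.compartment}"):
            raise ValidationError(
                f"metabolite id {self.id!r} does not carry compartment suffix "
                f"_{self.compartment}"
            )
        if self.formula:
            parse_formula(self.formula)

    @property
    def elements(self) -> Dict[str, int]:
        return parse_formula(self.formula) if self.formula else {}


#: provenance tags: where a reaction entered the reconstruction.
PROVENANCE_TAGS = ("native", "gapfilled", "orphan")


@dataclass
class ReactionRecord:
    """A reaction with stoichiometry (negative coefficient = substrate),
    bounds in mmol/gDW/h, a subsystem label, an optional GPR tree and a
    provenance tag (``native``, ``template:<model-id>``, ``gapfilled``,
    ``orphan``)."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    subsystem: str = ""
    gpr: Optional[GprTree] = None
    provenance: str = "native"

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not (
            self.provenance in PROVENANCE_TAGS or self.provenance.startswith("template:")
        ):
            raise ValidationError(
                f"reaction {self.id!r}: unknown provenance {self.provenance!r}"
            )
        if self.is_boundary and len(self.stoichiometry) != 1:
            raise ValidationError(
                f"boundary reaction {self.id!r} must touch exactly one metabolite"
            )

    @property
    def is_boundary(self) -> bool:
        """Exchange/sink/demand pseudo-reaction crossing the system boundary."""
        return self.id.startswith(BOUNDARY_PREFIXES) or len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def substrates(self) -> Dict[str, float]:
        return {m: -s for m, s in self.stoichiometry.items() if s < 0}

    def products(self) -> Dict[str, float]:
        return {m: s for m, s in self.stoichiometry.items() if s > 0}

    def copy(self) -> "ReactionRecord":
        return replace(self, stoichiometry=dict(self.stoichiometry))


# ---------------------------------------------------------------------------
# the model


@dataclass
class MetabolicModel:
    id: str
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, ReactionRecord] = field(default_factory=dict)
    genes: List[str] = field(default_factory=list)
    objective_id: Optional[str] = None
    compartments: Dict[str, str] = field(default_factory=lambda: dict(COMPARTMENTS))

    # -- construction ------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: ReactionRecord) -> None:
        if rxn.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn
        if rxn.gpr is not None:
            for g in rxn.gpr.genes():
                if g not in self.genes:
                    self.genes.append(g)

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]

    # -- queries -----------------------------------------------------------
    @property
    def exchanges(self) -> List[str]:
        return [r.id for r in self.reactions.values() if r.is_boundary]

    def validate(self) -> None:
        """Check every structural invariant; raise :class:`ValidationError`."""
        gene_set = set(self.genes)
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
            if rxn.gpr is not None and not rxn.gpr.genes() <= gene_set:
                missing = sorted(rxn.gpr.genes() - gene_set)
                raise ValidationError(
                    f"reaction {rxn.id!r} GPR references genes absent from the "
                    f"gene list: {missing}"
                )
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ValidationError(f"objective reaction {self.objective_id!r} not in model")
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ValidationError(
                    f"metabolite {met.id!r}: compartment {met.compartment!r} not "
                    "declared in the model"
                )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            genes=list(self.genes),
            objective_id=self.objective_id,
            compartments=dict(self.compartments),
        )


# ---------------------------------------------------------------------------
# media

#: Exchange-reaction id -> (lower_bound, upper_bound); uptake = negative lb.
Medium = Dict[str, Tuple[float, float]]


def load_medium(path) -> Medium:
    """Read a medium from YAML: mapping exchange id -> [lb, ub]."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ModelParseError(f"medium file {path} must be a mapping")
    medium: Medium = {}
    for rxn_id, bounds in raw.items():
        lb, ub = float(bounds[0]), float(bounds[1])
        medium[str(rxn_id)] = (lb, ub)
    return medium


def save_medium(medium: Medium, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({k: [float(v[0]), float(v[1])] for k, v in medium.items()}, fh)


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy with exchange bounds replaced by ``medium``.

    Unreferenced exchanges have their uptake closed (lb -> 0) while
    secretion stays open; internal bounds are untouched.
    """
    for rxn_id in medium:
        if rxn_id not in model.reactions:
            raise ValidationError(f"medium references unknown exchange {rxn_id!r}")
        if not model.reactions[rxn_id].is_boundary:
            raise ValidationError(f"medium references non-boundary reaction {rxn_id!r}")
    out = model.copy()
    for rxn in out.reactions.values():
        if not rxn.is_boundary:
            continue
        if rxn.id in medium:
            rxn.lower_bound, rxn.upper_bound = medium[rxn.id]
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out


# ---------------------------------------------------------------------------
# stoichiometric matrix


def stoich_matrix(model: MetabolicModel):
    """Sparse stoichiometric matrix S (metabolites x reactions).

    Returns ``(S, met_ids, rxn_ids)`` with S in CSC format; entry (i, j)
    is the signed coefficient of metabolite i in reaction j.
    """
    import numpy as np
    from scipy import sparse

    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met_id, coeff in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(float(coeff))
    S = sparse.csc_matrix(
        (np.asarray(data), (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    return S, met_ids, rxn_ids


# ---------------------------------------------------------------------------
# summaries


@dataclass
class ModelSummary:
    reactions: int
    metabolites: int
    genes: int
    orphan_reactions: int
    reactions_per_subsystem: Dict[str, int]


def summarize_model(model: MetabolicModel) -> ModelSummary:
    """Exact counts; the subsystem histogram sums to the reaction count."""
    per_subsystem: Dict[str, int] = {}
    orphans = 0
    for rxn in model.reactions.values():
        per_subsystem[rxn.subsystem] = per_subsystem.get(rxn.subsystem, 0) + 1
        if rxn.gpr is None and not rxn.is_boundary:
            orphans += 1
    return ModelSummary(
        reactions=len(model.reactions),
        metabolites=len(model.metabolites),
        genes=len(model.genes),
        orphan_reactions=orphans,
        reactions_per_subsystem=per_subsystem,
    )
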