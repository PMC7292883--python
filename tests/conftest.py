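"""Shared fixtures: the TOY3 three-metabolite chain, the toy diazotroph,
and a generator of random small LP models for oracle cross-checks."""

from __future__ import annotations

import numpy as np
import pytest

from diazogem.core_model import (
    MetabolicModel,
    Metabolite,
    ReactionRecord,
)
from diazogem.synth import make_toy_diazotroph

TOY3_JSON = {
    "id": "TOY3",
    "compartments": {"c": "cytoplasm", "e": "extracellular space"},
    "metabolites": [
        {"id": "A_e", "compartment": "e", "formula": "C2H4O2", "charge": 0},
        {"id": "A_c", "compartment": "c", "formula": "C2H4O2", "charge": 0},
        {"id": "B_c", "compartment": "c", "formula": "C2H4O2", "charge": 0},
    ],
    "reactions": [
        {"id": "EX_A", "metabolites": {"A_e": -1},
         "lower_bound": -10, "upper_bound": 1000},
        {"id": "TA", "metabolites": {"A_e": -1, "A_c": 1},
         "lower_bound": 0, "upper_bound": 1000},
        {"id": "R1", "metabolites": {"A_c": -1, "B_c": 1},
         "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": "g1"},
        {"id": "BIO", "metabolites": {"B_c": -1},
         "lower_bound": 0, "upper_bound": 1000, "objective_coefficient": 1},
    ],
    "genes": [{"id": "g1"}],
}


def build_toy3() -> MetabolicModel:
    """The 4-reaction, 3-metabolite chain: EX_A -> TA -> R1 -> BIO."""
    import json
    from diazogem.io import read_model

    import tempfile, os

    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "toy3.json")
        with open(path, "w") as fh:
            json.dump(TOY3_JSON, fh)
        return read_model(path)


@pytest.fixture
def toy3() -> MetabolicModel:
    return build_toy3()


@pytest.fixture(scope="session")
def toy_pair():
    return make_toy_diazotroph()


@pytest.fixture
def toy(toy_pair):
    model, _ = toy_pair
    return model.copy()


@pytest.fixture
def toy_manifest(toy_pair):
    return toy_pair[1]


def random_small_model(rng: np.random.Generator) -> MetabolicModel:
    """A random feasible chain-with-branches model, <= 12 reactions.

    Structure: uptake EX_in -> conversion chain with random yield
    coefficients and optional parallel branches -> sink EX_out (the
    objective).  The optimum is finite by construction (uptake bounded).
    """
    n_chain = int(rng.integers(2, 5))
    model = MetabolicModel(id="rand")
    mets = [f"M{i}_c" for i in range(n_chain + 1)]
    for mid in mets:
        model.add_metabolite(Metabolite(id=mid, compartment="c"))
    uptake = float(rng.uniform(1, 20))
    model.add_reaction(
        ReactionRecord(id="EX_in", stoichiometry={mets[0]: -1.0},
                       lower_bound=-uptake, upper_bound=1000.0)
    )
    for i in range(n_chain):
        coeff = float(rng.choice([0.5, 1.0, 2.0]))
        reversible = bool(rng.random() < 0.3)
        model.add_reaction(
            ReactionRecord(
                id=f"R{i}",
                stoichiometry={mets[i]: -1.0, mets[i + 1]: coeff},
                lower_bound=-1000.0 if reversible else 0.0,
                upper_bound=1000.0,
            )
        )
    # parallel branch with a different yield, possibly rate-limited
    if rng.random() < 0.7 and n_chain >= 2:
        j = int(rng.integers(0, n_chain - 1))
        model.add_reaction(
            ReactionRecord(
                id="RB",
                stoichiometry={mets[j]: -1.0, mets[j + 2]: float(rng.choice([0.5, 1.0, 3.0]))},
                lower_bound=0.0,
                upper_bound=float(rng.uniform(0.5, 5.0)),
            )
        )
    model.add_reaction(
        ReactionRecord(id="EX_out", stoichiometry={mets[-1]: -1.0},
                       lower_bound=0.0, upper_bound=1000.0)
    )
    model.objective_id = "EX_out"
    return model


def cobra_optimum(model: MetabolicModel):
    """Independent LP oracle: rebuild the model in cobrapy (different
    codebase, different solver) and return its optimal objective value."""
    import cobra

    cm = cobra.Model(model.id)
    cm.add_metabolites(
        [cobra.Metabolite(mid, compartment=met.compartment)
         for mid, met in model.metabolites.items()]
    )
    rxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        rxns.append((cr, rxn.stoichiometry))
    cm.add_reactions([cr for cr, _ in rxns])
    for cr, stoich in rxns:
        cr.add_metabolites({cm.metabolites.get_by_id(m): c for m, c in stoich.items()})
    cm.objective = model.objective_id
    sol = cm.optimize()
    if sol.status != "optimal":
        return None
    return float(sol.objective_value)
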