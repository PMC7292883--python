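"""Biomass objective function (BOF) construction from proteome composition.

The amino-acid block of the BOF is derived from the theoretical
amino-acid abundance of the proteome: residues are pooled across all
proteins (each protein counted once), and the stoichiometric coefficient
of amino acid *a* is

    coeff_a = 1000 * P * f_a / sum_b f_b * m_b        [mmol/gDW]

where ``P`` is the protein mass fraction of biomass (default 0.55
g/gDW), ``f_a`` the molar fraction and ``m_b`` the *residue* (dehydrated)
average mass in g/mol — polymerized protein is what the mass fraction
refers to, so one water (18.02 g/mol) is subtracted from each free amino
acid mass.  By construction ``sum_a coeff_a * m_a = 1000 * P`` mg/gDW.

Non-amino-acid constituents (nucleotides, lipids, cofactors, the ATP
polymerization/maintenance cost) are copied unchanged from a template
BOF.  A second, alginate-augmented BOF adds periplasmic alginate
monomer consumption to couple polymer secretion to growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple, Union

from Bio import SeqIO

from .core_model import DiazogemError, MetabolicModel, ReactionRecord

__all__ = [
    "RESIDUE_MASSES",
    "AA_METABOLITES",
    "aa_frequencies",
    "BiomassComposition",
    "build_bof",
    "build_alginate_bof",
]

#: average residue (dehydrated) masses, g/mol — free amino acid minus one water
RESIDUE_MASSES: Dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0513, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: default BiGG-style cytosolic metabolite id per amino acid (free acids)
AA_METABOLITES: Dict[str, str] = {
    "A": "ala__L_c", "R": "arg__L_c", "N": "asn__L_c", "D": "asp__L_c",
    "C": "cys__L_c", "E": "glu__L_c", "Q": "gln__L_c", "G": "gly_c",
    "H": "his__L_c", "I": "ile__L_c", "L": "leu__L_c", "K": "lys__L_c",
    "M": "met__L_c", "F": "phe__L_c", "P": "pro__L_c", "S": "ser__L_c",
    "T": "thr__L_c", "W": "trp__L_c", "Y": "tyr__L_c", "V": "val__L_c",
}

_SKIPPED = set("XBZUJO*")


def aa_frequencies(proteome: Union[str, Iterable]) -> Dict[str, float]:
    """Molar amino-acid fractions of a proteome.

    ``proteome`` is a FASTA path or an iterable of sequence strings /
    Biopython records.  Residues are pooled across proteins with each
    protein counted once; ambiguous letters (X/B/Z/U...) are skipped with
    a warning.  The returned fractions sum to 1.
    """
    import warnings

    if isinstance(proteome, str):
        sequences = [str(rec.seq) for rec in SeqIO.parse(proteome, "fasta")]
    else:
        sequences = [
            str(getattr(item, "seq", item)) for item in proteome
        ]
    counts: Dict[str, int] = {}
    skipped = 0
    for seq in sequences:
        for letter in seq.upper():
            if letter in RESIDUE_MASSES:
                counts[letter] = counts.get(letter, 0) + 1
            elif letter in _SKIPPED:
                skipped += 1
            else:
                raise DiazogemError(f"unknown amino-acid letter {letter!r}")
    if skipped:
        warnings.warn(f"skipped {skipped} ambiguous residues (X/B/Z/U)")
    total = sum(counts.values())
    if total == 0:
        raise DiazogemError("proteome contains no standard residues")
    return {aa: n / total for aa, n in counts.items()}


@dataclass
class BiomassComposition:
    """Amino-acid coefficients (mmol/gDW), the protein mass fraction
    (g/gDW) and the pass-through non-protein constituents."""

    aa_coefficients: Dict[str, float]
    protein_mass_fraction: float
    non_protein: Dict[str, float] = field(default_factory=dict)

    def protein_mass(self) -> float:
        """g of polymerized protein per gDW implied by the coefficients."""
        return sum(
            coeff * RESIDUE_MASSES[aa] for aa, coeff in self.aa_coefficients.items()
        ) / 1000.0


def build_bof(
    frequencies: Dict[str, float],
    protein_mass_fraction: float = 0.55,
    template_bof: Optional[ReactionRecord] = None,
    aa_metabolites: Optional[Dict[str, str]] = None,
    bof_id: str = "BOF",
) -> Tuple[BiomassComposition, ReactionRecord]:
    """Build a biomass reaction from amino-acid fractions.

    The amino-acid block consumes free amino acids at the mass-closed
    coefficients; everything in ``template_bof`` that is not an
    amino-acid metabolite (ATP/GTP polymerization cost, nucleotides,
    lipids, and the product side) is copied through unchanged.
    """
    if not frequencies:
        raise DiazogemError("empty amino-acid frequency table")
    unknown = sorted(set(frequencies) - set(RESIDUE_MASSES))
    if unknown:
        raise DiazogemError(f"unknown amino acids in frequency table: {unknown}")
    total = sum(frequencies.values())
    if abs(total - 1.0) > 1e-9:
        raise DiazogemError(
            f"amino-acid fractions must sum to 1 (got {total:.12f}); normalize first"
        )
    if not 0 <= protein_mass_fraction <= 1:
        raise DiazogemError("protein mass fraction must lie in [0, 1]")
    aa_metabolites = aa_metabolites or AA_METABOLITES

    mean_residue_mass = sum(
        f * RESIDUE_MASSES[aa] for aa, f in frequencies.items()
    )
    coefficients = {
        aa: (
            1000.0 * protein_mass_fraction * f / mean_residue_mass
            if mean_residue_mass > 0
            else 0.0
        )
        for aa, f in frequencies.items()
    }

    stoich: Dict[str, float] = {}
    non_protein: Dict[str, float] = {}
    aa_met_ids = set(aa_metabolites.values())
    if template_bof is not None:
        for met_id, coeff in template_bof.stoichiometry.items():
            if met_id not in aa_met_ids:
                stoich[met_id] = coeff
                non_protein[met_id] = coeff
    for aa, coeff in coefficients.items():
        if coeff > 0:
            met_id = aa_metabolites[aa]
            stoich[met_id] = stoich.get(met_id, 0.0) - coeff
    if not stoich:
        raise DiazogemError(
            "biomass reaction would be empty (zero protein fraction and no template)"
        )
    reaction = ReactionRecord(
        id=bof_id,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        name="biomass objective function",
        subsystem="Biomass and maintenance",
    )
    composition = BiomassComposition(
        aa_coefficients=coefficients,
        protein_mass_fraction=protein_mass_fraction,
        non_protein=non_protein,
    )
    return composition, reaction


def build_alginate_bof(
    bof: ReactionRecord,
    alginate_coefficient: float,
    alginate_metabolite: str = "alg_p",
    model: Optional[MetabolicModel] = None,
    bof_id: Optional[str] = None,
) -> ReactionRecord:
    """Derive the alginate-augmented second BOF.

    The new reaction carries the original BOF stoichiometry plus
    consumption of the periplasmic alginate monomer at
    ``alginate_coefficient`` mmol/gDW, forcing polymer synthesis to scale
    with growth.  If ``model`` is given the metabolite must exist and the
    reaction is added alongside the original BOF (exactly one of the two
    should be the active objective per simulation).
    """
    if alginate_coefficient < 0:
        raise DiazogemError("alginate coefficient must be non-negative")
    if model is not None and alginate_metabolite not in model.metabolites:
        raise DiazogemError(
            f"alginate metabolite {alginate_metabolite!r} absent from model"
        )
    stoich = dict(bof.stoichiometry)
    if alginate_coefficient > 0:
        stoich[alginate_metabolite] = (
            stoich.get(alginate_metabolite, 0.0) - alginate_coefficient
        )
    second = ReactionRecord(
        id=bof_id or f"{bof.id}_alg",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=bof.upper_bound,
        name="biomass objective function with alginate",
        subsystem=bof.subsystem,
        gpr=bof.gpr,
        provenance=bof.provenance,
    )
    if model is not None and second.id not in model.reactions:
        model.add_reaction(second)
    return second
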