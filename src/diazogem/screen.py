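"""Biolog-style phenotype-array simulation and confusion statistics.

Carbon screens (PM1/PM2 plates) open one carbon source at a time on a
mineral base medium, with nitrogen supplied either as ammonium
(non-diazotrophic) or as N2 through nitrogenase (diazotrophic).
Nitrogen screens (PM3) fix pyruvate as the sole carbon source and vary
the nitrogen source.  A condition "grows" when the FBA growth rate
exceeds 0.001 1/h (strict).  Predicted calls against experimental
ground truth yield the full confusion panel: accuracy, sensitivity,
specificity, PPV, NPV and the Matthews correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .core_model import (
    DEFAULT_BOUND,
    DiazogemError,
    Medium,
    MetabolicModel,
    apply_medium,
    parse_formula,
)
from .fba import fba
from .reconstruction import GROWTH_THRESHOLD

__all__ = [
    "ScreenCondition",
    "SourceNotInModel",
    "build_condition",
    "run_screen",
    "call_growth",
    "ConfusionCounts",
    "ScreenStats",
    "confusion_stats",
    "confusion_from_calls",
    "growth_rate_accuracy",
    "percent",
    "read_plate",
    "read_calls",
]


class SourceNotInModel(DiazogemError):
    """The source metabolite has no exchange reaction in the model; the
    condition is excluded from the screen (reason code ``not-in-model``)."""


@dataclass(frozen=True)
class ScreenCondition:
    """One well of a phenotype array.

    ``source`` is the exchange metabolite id (extracellular), ``role``
    is ``carbon`` or ``nitrogen``, ``nitrogen_mode`` selects diazotrophic
    (N2 open, ammonium closed) or non-diazotrophic (ammonium open, N2
    closed).  ``uptake_bound`` is the source uptake capacity in
    mmol/gDW/h.
    """

    source: str
    role: str = "carbon"
    nitrogen_mode: str = "non-diazotrophic"
    uptake_bound: float = 10.0
    well: str = ""
    plate: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("carbon", "nitrogen"):
            raise DiazogemError(f"unknown screen role {self.role!r}")
        if self.nitrogen_mode not in ("diazotrophic", "non-diazotrophic"):
            raise DiazogemError(f"unknown nitrogen mode {self.nitrogen_mode!r}")

    @property
    def id(self) -> str:
        return f"{self.source}|{self.role}|{self.nitrogen_mode}"


AMMONIUM_EXCHANGE = "EX_nh4_e"
N2_EXCHANGE = "EX_n2_e"
PYRUVATE_EXCHANGE = "EX_pyr_e"
PYRUVATE_UPTAKE = 10.0


def _exchange_for(model: MetabolicModel, met_id: str) -> Optional[str]:
    for rxn in model.reactions.values():
        if rxn.is_boundary and met_id in rxn.stoichiometry and rxn.id.startswith("EX_"):
            return rxn.id
    return None


def _element_count(model: MetabolicModel, met_id: str, element: str) -> int:
    formula = model.metabolites[met_id].formula
    if not formula:
        return 0
    return parse_formula(formula).get(element, 0)


def build_condition(model: MetabolicModel, cond: ScreenCondition) -> Medium:
    """Translate a screen condition into a medium.

    Mineral base exchanges (metabolites containing neither C nor N) stay
    open; every other uptake is closed except the source and, per mode,
    ammonium or N2.  Nitrogen screens additionally open pyruvate as the
    sole carbon source.  Raises :class:`SourceNotInModel` when the
    source has no exchange reaction.
    """
    source_ex = _exchange_for(model, cond.source)
    if source_ex is None:
        raise SourceNotInModel(
            f"source {cond.source!r} has no exchange reaction (not-in-model)"
        )
    medium: Medium = {}
    for rxn in model.reactions.values():
        if not rxn.is_boundary:
            continue
        met_id = next(iter(rxn.stoichiometry))
        has_c = _element_count(model, met_id, "C") > 0
        has_n = _element_count(model, met_id, "N") > 0
        if not has_c and not has_n:
            medium[rxn.id] = (-DEFAULT_BOUND, DEFAULT_BOUND)
        else:
            medium[rxn.id] = (0.0, DEFAULT_BOUND)  # secretion only

    if cond.role == "carbon":
        if cond.nitrogen_mode == "diazotrophic":
            if N2_EXCHANGE in model.reactions:
                medium[N2_EXCHANGE] = (-DEFAULT_BOUND, DEFAULT_BOUND)
        else:
            if AMMONIUM_EXCHANGE in model.reactions:
                medium[AMMONIUM_EXCHANGE] = (-DEFAULT_BOUND, DEFAULT_BOUND)
    else:
        if PYRUVATE_EXCHANGE not in model.reactions:
            raise DiazogemError(
                "nitrogen screens need a pyruvate exchange as sole carbon source"
            )
        medium[PYRUVATE_EXCHANGE] = (-PYRUVATE_UPTAKE, DEFAULT_BOUND)
    medium[source_ex] = (-abs(cond.uptake_bound), DEFAULT_BOUND)
    return medium


@dataclass
class ScreenResult:
    condition: ScreenCondition
    growth_rate: float
    status: str
    excluded: bool = False
    reason: str = ""

    @property
    def grew(self) -> bool:
        return not self.excluded and call_growth(self.growth_rate)


def run_screen(
    model: MetabolicModel, conditions: Sequence[ScreenCondition]
) -> Dict[str, ScreenResult]:
    """One FBA per condition; infeasible solves record mu = 0 with a flag.

    Results are keyed by condition id in a deterministic (input) order;
    sources without an exchange reaction are excluded with reason code
    ``not-in-model`` (they never enter confusion counts).
    """
    results: Dict[str, ScreenResult] = {}
    for cond in conditions:
        try:
            medium = build_condition(model, cond)
        except SourceNotInModel:
            results[cond.id] = ScreenResult(
                cond, 0.0, "excluded", excluded=True, reason="not-in-model"
            )
            continue
        sol = fba(apply_medium(model, medium))
        if sol.status != "optimal":
            results[cond.id] = ScreenResult(cond, 0.0, sol.status)
        else:
            results[cond.id] = ScreenResult(cond, float(sol.objective_value), "optimal")
    return results


def call_growth(mu: float, threshold: float = GROWTH_THRESHOLD) -> bool:
    """Growth call: strictly greater than the 0.001 1/h threshold."""
    if mu < 0:
        raise DiazogemError(f"negative growth rate {mu}")
    return mu > threshold


# ---------------------------------------------------------------------------
# confusion statistics


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise DiazogemError("confusion counts must be non-negative")
        if self.n == 0:
            raise DiazogemError("confusion counts sum to zero")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class ScreenStats:
    """Derived panel; any 0/0 ratio is undefined and reported as None,
    never as 0."""

    accuracy: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    mcc: Optional[float]


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def confusion_stats(counts: ConfusionCounts) -> ScreenStats:
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None
    return ScreenStats(
        accuracy=(tp + tn) / counts.n,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        mcc=mcc,
    )


def confusion_from_calls(
    predicted: Dict[str, bool], experimental: Dict[str, bool]
) -> ConfusionCounts:
    """Count TP/FP/TN/FN over the keys shared by both call sets."""
    keys = sorted(set(predicted) & set(experimental))
    if not keys:
        raise DiazogemError("no shared conditions between predictions and experiments")
    tp = sum(1 for k in keys if predicted[k] and experimental[k])
    fp = sum(1 for k in keys if predicted[k] and not experimental[k])
    tn = sum(1 for k in keys if not predicted[k] and not experimental[k])
    fn = sum(1 for k in keys if not predicted[k] and experimental[k])
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def percent(value: float) -> int:
    """Round a 0-1 ratio to an integer percent, half away from zero."""
    x = value * 100.0
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# growth-rate accuracy against paired experimental values


@dataclass
class GrowthRateComparison:
    percent_errors: List[float]
    accuracies: List[float]
    mean_percent_error: float
    mean_accuracy: float
    excluded_pairs: List[int]


def growth_rate_accuracy(
    predicted: Sequence[float],
    experimental: Sequence[Union[float, Tuple[float, float]]],
) -> GrowthRateComparison:
    """Per-pair percent error |pred - exp| / exp * 100 and accuracy
    100 - percent error; pairs with exp = 0 are excluded with a flag.

    Experimental entries may be plain means or (mean, sd) pairs; the sd
    is informational only.
    """
    if len(predicted) != len(experimental):
        raise DiazogemError("predicted and experimental lists differ in length")
    errors, accs, excluded = [], [], []
    for i, (pred, exp) in enumerate(zip(predicted, experimental)):
        mean = exp[0] if isinstance(exp, (tuple, list)) else float(exp)
        if mean == 0:
            excluded.append(i)
            continue
        pe = abs(pred - mean) / abs(mean) * 100.0
        errors.append(pe)
        accs.append(100.0 - pe)
    if not errors:
        raise DiazogemError("no pairs with a nonzero experimental value")
    return GrowthRateComparison(
        percent_errors=errors,
        accuracies=accs,
        mean_percent_error=sum(errors) / len(errors),
        mean_accuracy=sum(accs) / len(accs),
        excluded_pairs=excluded,
    )


# ---------------------------------------------------------------------------
# plate-layout and experimental-call files


def read_plate(path) -> List[ScreenCondition]:
    """Plate layout CSV: well, source_metabolite_id, role, plate_id."""
    df = pd.read_csv(path)
    needed = {"well", "source_metabolite_id", "role", "plate_id"}
    missing = needed - set(df.columns)
    if missing:
        raise DiazogemError(f"plate file {path} lacks columns {sorted(missing)}")
    return [
        ScreenCondition(
            source=str(row.source_metabolite_id),
            role=str(row.role),
            well=str(row.well),
            plate=str(row.plate_id),
        )
        for row in df.itertuples()
    ]


def read_calls(path) -> Dict[str, bool]:
    """Experimental calls CSV: well, grew (0/1)."""
    df = pd.read_csv(path)
    if not {"well", "grew"} <= set(df.columns):
        raise DiazogemError(f"calls file {path} needs columns well, grew")
    return {str(row.well): bool(int(row.grew)) for row in df.itertuples()}
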