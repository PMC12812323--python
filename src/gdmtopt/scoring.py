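"""Medication Optimization Score (MOS) and comparator GDMT scores.

The MOS summarizes, for a single patient encounter, how close the current
regimen is to guideline target dosing across the four HFrEF GDMT classes.
Each class contributes one point when its best prescribed drug is at target,
a fractional point (dose/target) below target, and zero when absent; classes
with a documented intolerance or a firing contraindication rule are removed
from both numerator and denominator, and a class whose up-titration is blocked
by vitals earns its full point at the current dose. The score is the earned
fraction of possible points expressed as a percentage (0 = no GDMT on board,
100 = fully optimized given what the patient can tolerate).

The comparator scores implemented alongside it are the Heart Failure
Collaboratory score (HFC, 0-7 points, threshold-based), its modification
(mHFC, 0-8 points, ARNI split into sacubitril and valsartan components and
rescalable to 0-100) and the Kansas City Medical Optimization score (KCMO,
mean prescribed-to-target dose proportion over eligible classes with the
MRA counted as present/absent).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .formulary import (
    BETA_BLOCKER,
    GDMT_CLASSES,
    MRA,
    RASI,
    SGLT2I,
    DrugEntry,
    EligibilityRules,
    Formulary,
)

logger = logging.getLogger(__name__)

# Eligibility statuses
ELIGIBLE = "ELIGIBLE"
INTOLERANT = "INTOLERANT"
CONTRAINDICATED = "CONTRAINDICATED"
ESCALATION_BLOCKED = "ESCALATION_BLOCKED"

# Recommendations
INITIATE = "INITIATE"
TITRATE = "TITRATE"
CONTINUE = "CONTINUE"
NONE = "NONE"

_EXCLUDED_STATUSES = frozenset({INTOLERANT, CONTRAINDICATED})


@dataclass(frozen=True)
class PatientSnapshot:
    """One patient-encounter's regimen, vitals, labs and intolerances.

    ``orders`` holds (drug name, total daily dose in mg) pairs; later orders
    for the same drug on the same date supersede earlier ones. Missing vitals
    or labs are ``None`` and are handled conservatively by the eligibility
    rules (an unobservable rule does not fire).
    """

    patient_id: str
    date: Optional[str] = None
    age: Optional[float] = None
    sex: Optional[str] = None
    race: Optional[str] = None
    ethnicity: Optional[str] = None
    orders: Sequence[tuple[str, float]] = ()
    sbp: Optional[float] = None
    pulse: Optional[float] = None
    scr: Optional[float] = None
    potassium: Optional[float] = None
    egfr: Optional[float] = None
    nyha: Optional[int] = None
    intolerant_classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.nyha is not None and self.nyha not in (1, 2, 3, 4):
            raise ValueError(f"NYHA class must be 1-4, got {self.nyha}")
        for drug, dose in self.orders:
            if dose < 0:
                raise ValueError(f"negative daily dose for {drug!r}")
        bad = set(self.intolerant_classes) - set(GDMT_CLASSES)
        if bad:
            raise ValueError(f"unknown intolerant classes {sorted(bad)}")


@dataclass(frozen=True)
class ClassDose:
    """Best-scoring prescription within one GDMT class."""

    drug: Optional[DrugEntry]
    daily_dose: float
    fraction: float  # min(dose/target, 1); 0 when no order

    @property
    def subtype(self) -> Optional[str]:
        return None if self.drug is None else self.drug.subtype


@dataclass(frozen=True)
class RegimenClassification:
    """Per-class best orders plus per-RASI-subtype detail."""

    by_class: Mapping[str, ClassDose]
    rasi_by_subtype: Mapping[str, ClassDose]
    unknown_drugs: tuple[str, ...] = ()

    def __getitem__(self, gdmt_class: str) -> ClassDose:
        return self.by_class[gdmt_class]


@dataclass(frozen=True)
class ClassAssessment:
    gdmt_class: str
    dose: ClassDose
    status: str
    points_possible: float
    points_earned: float
    recommendation: str
    recommended_dose: Optional[float] = None
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScoreResult:
    """MOS with per-class detail plus the HFC/mHFC/KCMO comparator scores.

    ``mos`` (and ``kcmo``) are ``None`` with ``undefined=True`` when every
    class is excluded from the denominator — the caller decides what to do
    with such patients; the score is never silently 0 or 100.
    """

    mos: Optional[float]
    assessments: tuple[ClassAssessment, ...]
    hfc: int
    mhfc_points: int
    mhfc_scaled: float
    kcmo: Optional[float]
    undefined: bool = False

    def assessment(self, gdmt_class: str) -> ClassAssessment:
        for a in self.assessments:
            if a.gdmt_class == gdmt_class:
                return a
        raise KeyError(gdmt_class)


_NO_DOSE = ClassDose(drug=None, daily_dose=0.0, fraction=0.0)


def classify_regimen(
    orders: Iterable[tuple[str, float]], formulary: Formulary
) -> RegimenClassification:
    """Reduce raw medication orders to the best order per GDMT class.

    Within a class (and within the RASI slot across ACEI/ARB/ARNI subtypes)
    the order with the highest fraction of its own drug's target dose wins;
    fractions are never summed across drugs or subtypes. Drugs not in the
    formulary are ignored and reported in ``unknown_drugs``.
    """
    best: dict[str, ClassDose] = {c: _NO_DOSE for c in GDMT_CLASSES}
    rasi_sub: dict[str, ClassDose] = {}
    unknown: list[str] = []
    seen_rasi_subtypes: set[str] = set()

    for drug, dose in orders:
        entry = formulary.get(drug)
        if entry is None:
            unknown.append(drug)
            logger.info("ignoring non-GDMT order %r", drug)
            continue
        if dose <= 0:
            continue
        cand = ClassDose(drug=entry, daily_dose=float(dose), fraction=entry.dose_fraction(dose))
        if cand.fraction > best[entry.gdmt_class].fraction:
            best[entry.gdmt_class] = cand
        if entry.gdmt_class == RASI:
            seen_rasi_subtypes.add(entry.subtype)
            prev = rasi_sub.get(entry.subtype, _NO_DOSE)
            if cand.fraction > prev.fraction:
                rasi_sub[entry.subtype] = cand

    if len(seen_rasi_subtypes) > 1:
        warnings.warn(
            "multiple RASI subtypes prescribed simultaneously "
            f"({sorted(seen_rasi_subtypes)}); scoring the highest-fraction subtype only",
            stacklevel=2,
        )
    return RegimenClassification(
        by_class=best, rasi_by_subtype=rasi_sub, unknown_drugs=tuple(unknown)
    )


_MEASURES = {"sbp": "SBP", "pulse": "pulse", "potassium": "K+", "egfr": "eGFR", "scr": "SCr"}


def _evaluate_rule_set(
    snapshot: PatientSnapshot, rules_for_class: Mapping[str, float]
) -> tuple[bool, list[str], list[str]]:
    """Return (any rule fired, reasons, missing-data annotations)."""
    fired, reasons, missing = False, [], []
    for key, threshold in rules_for_class.items():
        measure, _, direction = key.rpartition("_")
        if measure not in _MEASURES or direction not in ("gt", "lt"):
            raise ValueError(f"malformed eligibility rule key {key!r}")
        value = getattr(snapshot, measure)
        if value is None:
            missing.append(f"missing-data: {_MEASURES[measure]} needed by rule {key}")
            continue
        if (direction == "gt" and value > threshold) or (direction == "lt" and value < threshold):
            fired = True
            reasons.append(f"{_MEASURES[measure]} {value:g} vs {key} {threshold:g}")
    return fired, reasons, missing


def assess_eligibility(
    snapshot: PatientSnapshot,
    gdmt_class: str,
    rules: EligibilityRules,
    dose_fraction: float = 0.0,
) -> tuple[str, tuple[str, ...]]:
    """Eligibility status of one GDMT class for one encounter.

    Precedence: documented intolerance, then contraindication rules, then
    (only for a class prescribed below target) escalation-blocking rules.
    Missing vitals/labs are conservative: an unevaluable rule never fires,
    and the gap is annotated in the returned reasons.
    """
    if gdmt_class not in GDMT_CLASSES:
        raise ValueError(f"unknown GDMT class {gdmt_class!r}")
    if gdmt_class in snapshot.intolerant_classes:
        return INTOLERANT, ("documented intolerance or allergy",)

    annotations: list[str] = []
    fired, reasons, missing = _evaluate_rule_set(
        snapshot, rules.contraindication.get(gdmt_class, {})
    )
    annotations.extend(missing)
    if fired:
        return CONTRAINDICATED, tuple(reasons + annotations)

    if 0.0 < dose_fraction < 1.0:
        fired, reasons, missing = _evaluate_rule_set(
            snapshot, rules.escalation_block.get(gdmt_class, {})
        )
        annotations.extend(missing)
        if fired:
            return ESCALATION_BLOCKED, tuple(reasons + annotations)

    return ELIGIBLE, tuple(annotations)


def _recommendation(
    status: str, dose: ClassDose, formulary: Formulary, gdmt_class: str
) -> tuple[str, Optional[float], str]:
    if status in _EXCLUDED_STATUSES:
        return NONE, None, f"class excluded ({status.lower()})"
    if status == ESCALATION_BLOCKED:
        return CONTINUE, None, "up-titration blocked by vitals; continue current dose"
    if dose.fraction == 0.0:
        first = formulary.drugs_in_class(gdmt_class)
        start = first[0].titration_steps[0] if first and first[0].titration_steps else None
        return INITIATE, start, "eligible and untreated"
    if dose.fraction < 1.0:
        nxt = dose.drug.next_step(dose.daily_dose) if dose.drug else None
        return TITRATE, nxt, "eligible and below target dose"
    return CONTINUE, None, "at or above target dose"


def compute_mos(
    snapshot: PatientSnapshot,
    formulary: Optional[Formulary] = None,
    rules: Optional[EligibilityRules] = None,
) -> ScoreResult:
    """Score one encounter: MOS plus HFC, mHFC and KCMO comparators.

    Each of the four classes offers one possible point. Eligible classes earn
    their dose fraction; intolerant/contraindicated classes leave both the
    numerator and the denominator; an escalation-blocked class already on
    drug earns its full point (the patient is not penalized for being
    clinically unable to up-titrate). MOS = 100 x earned / possible.
    """
    formulary = formulary or Formulary.default()
    rules = rules or EligibilityRules.default()
    classification = classify_regimen(snapshot.orders, formulary)

    assessments = []
    for gdmt_class in GDMT_CLASSES:
        dose = classification[gdmt_class]
        status, reasons = assess_eligibility(snapshot, gdmt_class, rules, dose.fraction)
        if status in _EXCLUDED_STATUSES:
            possible, earned = 0.0, 0.0
        elif status == ESCALATION_BLOCKED and dose.fraction > 0.0:
            possible, earned = 1.0, 1.0
        else:
            possible, earned = 1.0, dose.fraction
        rec, rec_dose, why = _recommendation(status, dose, formulary, gdmt_class)
        assessments.append(
            ClassAssessment(
                gdmt_class=gdmt_class,
                dose=dose,
                status=status,
                points_possible=possible,
                points_earned=earned,
                recommendation=rec,
                recommended_dose=rec_dose,
                reasons=reasons + (why,),
            )
        )

    possible_total = sum(a.points_possible for a in assessments)
    undefined = possible_total == 0.0
    mos = None if undefined else 100.0 * sum(a.points_earned for a in assessments) / possible_total
    if undefined:
        logger.warning(
            "all four GDMT classes excluded for patient %s; MOS undefined", snapshot.patient_id
        )

    contraindicated = frozenset(a.gdmt_class for a in assessments if a.status in _EXCLUDED_STATUSES)
    hfc = compute_hfc(classification, contraindicated)
    mhfc_points, mhfc_scaled = compute_mhfc(classification, contraindicated)
    statuses = {a.gdmt_class: a.status for a in assessments}
    kcmo = compute_kcmo(classification, statuses)

    return ScoreResult(
        mos=mos,
        assessments=tuple(assessments),
        hfc=hfc,
        mhfc_points=mhfc_points,
        mhfc_scaled=mhfc_scaled,
        kcmo=kcmo,
        undefined=undefined,
    )


def _threshold_points(fraction: float) -> int:
    """0 for no treatment, 1 below 50% of target, 2 at or above 50%."""
    if fraction <= 0.0:
        return 0
    return 2 if fraction >= 0.5 else 1


def compute_hfc(
    classification: RegimenClassification,
    contraindicated: frozenset[str] = frozenset(),
) -> int:
    """Heart Failure Collaboratory score, 0-7 points over BB/RASI/MRA slots.

    Beta-blockers and ACEI/ARB score 0/1/2 by the 50%-of-target threshold; any
    MRA dose scores 2; any ARNI dose scores 3 and supersedes ACEI/ARB scoring
    in the RASI slot. A contraindicated class is treated as guideline-adherent
    therapy and earns its slot maximum (BB 2, RASI 3, MRA 2). SGLT2 inhibitors
    are not part of this score.
    """
    slot_max = {BETA_BLOCKER: 2, RASI: 3, MRA: 2}
    total = 0
    for gdmt_class, cap in slot_max.items():
        if gdmt_class in contraindicated:
            total += cap
            continue
        dose = classification[gdmt_class]
        if gdmt_class == BETA_BLOCKER:
            total += _threshold_points(dose.fraction)
        elif gdmt_class == MRA:
            total += 2 if dose.fraction > 0.0 else 0
        else:  # RASI slot
            arni = classification.rasi_by_subtype.get("ARNI", _NO_DOSE)
            if arni.fraction > 0.0:
                total += 3
            else:
                total += _threshold_points(dose.fraction)
    return total


def compute_mhfc(
    classification: RegimenClassification,
    contraindicated: frozenset[str] = frozenset(),
) -> tuple[int, float]:
    """Modified HFC score: 0-8 points and its 0-100 rescaling.

    Like HFC but the ARNI is scored as two components (sacubitril and
    valsartan, 0-2 points each by the 50% threshold on the component dose), so
    a target-dose ARNI alone yields 4 of the 8 possible points, and the MRA
    uses the same 0/1/2 threshold rule as the other classes. The scaled value
    is points / 8 x 100.
    """
    slot_max = {BETA_BLOCKER: 2, RASI: 4, MRA: 2}
    total = 0
    for gdmt_class, cap in slot_max.items():
        if gdmt_class in contraindicated:
            total += cap
            continue
        dose = classification[gdmt_class]
        if gdmt_class == RASI:
            arni = classification.rasi_by_subtype.get("ARNI", _NO_DOSE)
            if arni.fraction > 0.0:
                # Fixed-ratio combination: each component sits at the same
                # fraction of its own component target as the total dose.
                total += 2 * _threshold_points(arni.fraction)
            else:
                total += _threshold_points(dose.fraction)
        else:
            total += _threshold_points(dose.fraction)
    return total, total / 8.0 * 100.0


def compute_kcmo(
    classification: RegimenClassification,
    statuses: Mapping[str, str],
) -> Optional[float]:
    """Kansas City Medical Optimization score, 0-100.

    Mean over eligible classes of the prescribed-to-target dose proportion
    (capped at 1), with the MRA contributing 1 if any dose is prescribed and
    0 otherwise, multiplied by 100. Intolerant/contraindicated classes are
    excluded from the average; returns None if no class is eligible.
    """
    contributions = []
    for gdmt_class in GDMT_CLASSES:
        if statuses.get(gdmt_class, ELIGIBLE) in _EXCLUDED_STATUSES:
            continue
        dose = classification[gdmt_class]
        if gdmt_class == MRA:
            contributions.append(1.0 if dose.fraction > 0.0 else 0.0)
        else:
            contributions.append(dose.fraction)
    if not contributions:
        return None
    return 100.0 * math.fsum(contributions) / len(contributions)
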