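"""Comorbidity and heart-failure severity indices.

Implements the Charlson Comorbidity Index (CCI) over a packaged dictionary of
17 weighted condition groups (original weights), the mild/moderate/severe
categorization used for outcome adjustment, and the Heart Failure Patient
Severity Index (HFPSI) — an ordinal 1-4 severity class built from BUN, BNP,
NYHA class, diabetes, atrial fibrillation/flutter history and recent
hospitalization via a configurable integer point map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import yaml

from .formulary import _read_packaged_yaml

logger = logging.getLogger(__name__)

MILD = "MILD"
MODERATE = "MODERATE"
SEVERE = "SEVERE"
CCI_CATEGORIES = (MILD, MODERATE, SEVERE)

MISSING = "MISSING"


class CharlsonDictionary:
    """Condition-group weights plus hierarchy rules for the CCI."""

    def __init__(self, weights: Mapping[str, int], hierarchies: Iterable[tuple[str, str]]):
        self.weights = dict(weights)
        self.hierarchies = [tuple(h) for h in hierarchies]
        for low, high in self.hierarchies:
            if low not in self.weights or high not in self.weights:
                raise ValueError(f"hierarchy ({low}, {high}) references unknown condition group")

    @classmethod
    def default(cls) -> "CharlsonDictionary":
        payload = _read_packaged_yaml("charlson_weights.yaml")
        return cls(payload["weights"], payload["hierarchies"])

    @classmethod
    def from_yaml(cls, path: str) -> "CharlsonDictionary":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(payload["weights"], payload["hierarchies"])


def compute_cci(
    conditions: Iterable[str], dictionary: Optional[CharlsonDictionary] = None
) -> int:
    """Sum of Charlson weights over distinct condition groups present.

    Unknown condition codes are ignored (logged); for hierarchical pairs
    (e.g. diabetes with vs without complications) only the higher-weighted
    member counts.
    """
    dictionary = dictionary or CharlsonDictionary.default()
    present = set()
    for code in conditions:
        if code in dictionary.weights:
            present.add(code)
        else:
            logger.info("ignoring unknown Charlson condition code %r", code)
    for low, high in dictionary.hierarchies:
        if low in present and high in present:
            present.discard(low)
    return sum(dictionary.weights[c] for c in present)


def categorize_cci(score: int) -> str:
    """Map a CCI score onto mild (1-2), moderate (3-4), severe (>= 5).

    A score of 0 falls below the published bins and is grouped with MILD
    (annotated via log) rather than dropped.
    """
    if score < 0:
        raise ValueError(f"CCI score must be >= 0, got {score}")
    if score == 0:
        logger.debug("CCI score 0 binned with MILD (below the published 1-2 bin)")
        return MILD
    if score <= 2:
        return MILD
    if score <= 4:
        return MODERATE
    return SEVERE


@dataclass(frozen=True)
class HfpsiComponents:
    """The six inputs of the HFPSI; any ``None`` renders the index missing."""

    bun: Optional[float] = None  # mg/dL
    bnp: Optional[float] = None  # pg/mL
    nyha: Optional[int] = None
    diabetes: Optional[bool] = None
    af_flutter: Optional[bool] = None
    recent_hospitalization: Optional[bool] = None  # within prior 6 months

    def is_complete(self) -> bool:
        return all(
            v is not None
            for v in (
                self.bun,
                self.bnp,
                self.nyha,
                self.diabetes,
                self.af_flutter,
                self.recent_hospitalization,
            )
        )


class HfpsiMap:
    """Integer point map turning HFPSI components into the 1-4 severity class.

    Points accrue per BUN/BNP threshold exceeded plus flat points for
    NYHA >= ``nyha_point_at``, diabetes, AF/flutter and recent
    hospitalization; ``cuts`` maps the total onto classes 1-4
    (class = 1 + number of cuts at or below the total). The default map is a
    configurable stand-in with monotone structure, not the published
    derivation weights.
    """

    def __init__(self, payload: Mapping):
        self.bun_thresholds = sorted(float(x) for x in payload["bun_thresholds_mg_dl"])
        self.bnp_thresholds = sorted(float(x) for x in payload["bnp_thresholds_pg_ml"])
        self.nyha_point_at = int(payload["nyha_point_at"])
        self.point_for_diabetes = int(payload["point_for_diabetes"])
        self.point_for_af_flutter = int(payload["point_for_af_flutter"])
        self.point_for_recent_hospitalization = int(payload["point_for_recent_hospitalization"])
        self.cuts = sorted(int(x) for x in payload["cuts"])
        if len(self.cuts) != 3:
            raise ValueError("HFPSI map needs exactly 3 cut points (classes 1-4)")
        if min(self.point_for_diabetes, self.point_for_af_flutter,
               self.point_for_recent_hospitalization) < 0:
            raise ValueError("HFPSI flag points must be non-negative")

    @classmethod
    def default(cls) -> "HfpsiMap":
        return cls(_read_packaged_yaml("hfpsi_map.yaml"))

    @classmethod
    def from_yaml(cls, path: str) -> "HfpsiMap":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))

    def points(self, c: HfpsiComponents) -> int:
        total = sum(c.bun > t for t in self.bun_thresholds)
        total += sum(c.bnp > t for t in self.bnp_thresholds)
        total += self.point_for_diabetes * bool(c.diabetes)
        total += self.point_for_af_flutter * bool(c.af_flutter)
        total += self.point_for_recent_hospitalization * bool(c.recent_hospitalization)
        total += 1 if c.nyha >= self.nyha_point_at else 0
        return int(total)


def compute_hfpsi(
    components: HfpsiComponents, scoring_map: Optional[HfpsiMap] = None
) -> Union[int, str]:
    """Ordinal HFPSI severity class 1 (least severe) to 4 (most severe).

    Returns the string ``"MISSING"`` when any component is absent — such
    patients are excluded from the outcome analysis cohort.
    """
    if not components.is_complete():
        return MISSING
    scoring_map = scoring_map or HfpsiMap.default()
    total = scoring_map.points(components)
    return 1 + sum(total >= cut for cut in scoring_map.cuts)
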