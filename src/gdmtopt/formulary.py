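"""GDMT formulary and eligibility-rule configuration.

The four scored guideline-directed medical therapy (GDMT) classes for HFrEF
are the renin-angiotensin-system inhibitors (ACEI/ARB/ARNI, one shared slot),
beta-blockers, mineralocorticoid receptor antagonists and SGLT2 inhibitors.
The formulary maps drug names to a class/subtype, a guideline target total
daily dose and a titration ladder; eligibility rules hold the vital/lab
thresholds that gate initiation and up-titration.

Defaults ship as editable YAML under ``gdmtopt/data`` and can be replaced via
:meth:`Formulary.from_yaml` / :meth:`EligibilityRules.from_yaml`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

RASI = "RASI"
BETA_BLOCKER = "BETA_BLOCKER"
MRA = "MRA"
SGLT2I = "SGLT2I"
GDMT_CLASSES = (RASI, BETA_BLOCKER, MRA, SGLT2I)

RASI_SUBTYPES = ("ACEI", "ARB", "ARNI")


def _read_packaged_yaml(name: str) -> dict:
    with resources.files("gdmtopt.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class DrugEntry:
    """One formulary drug: class membership, target dose and titration ladder."""

    name: str
    gdmt_class: str
    subtype: str  # ACEI | ARB | ARNI | none
    target_daily_dose: float  # mg/day
    titration_steps: tuple[float, ...]
    component_ratio: Optional[Mapping[str, float]] = None  # ARNI only

    def __post_init__(self) -> None:
        if self.gdmt_class not in GDMT_CLASSES:
            raise ValueError(f"unknown GDMT class {self.gdmt_class!r} for {self.name!r}")
        if self.target_daily_dose <= 0:
            raise ValueError(f"target dose must be > 0 for {self.name!r}")
        steps = tuple(float(s) for s in self.titration_steps)
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError(f"titration steps must be strictly increasing for {self.name!r}")
        if steps and steps[-1] != self.target_daily_dose:
            raise ValueError(f"titration steps must end at the target dose for {self.name!r}")
        object.__setattr__(self, "titration_steps", steps)

    def dose_fraction(self, daily_dose: float) -> float:
        """Fraction of target achieved by ``daily_dose``, capped at 1."""
        return min(max(daily_dose, 0.0) / self.target_daily_dose, 1.0)

    def next_step(self, daily_dose: float) -> Optional[float]:
        """Lowest titration step strictly above ``daily_dose`` (None at/above target)."""
        for step in self.titration_steps:
            if step > daily_dose:
                return step
        return None


class Formulary:
    """Lookup table from drug name to :class:`DrugEntry` (case-insensitive)."""

    def __init__(self, entries: Sequence[DrugEntry]):
        if not entries:
            raise ValueError("formulary must contain at least one drug")
        self._by_name: dict[str, DrugEntry] = {}
        for entry in entries:
            key = entry.name.lower()
            if key in self._by_name:
                raise ValueError(f"duplicate formulary drug {entry.name!r}")
            self._by_name[key] = entry

    def get(self, drug: str) -> Optional[DrugEntry]:
        return self._by_name.get(drug.lower())

    def __contains__(self, drug: str) -> bool:
        return drug.lower() in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def drugs_in_class(self, gdmt_class: str, subtype: Optional[str] = None) -> list[DrugEntry]:
        out = [e for e in self if e.gdmt_class == gdmt_class]
        if subtype is not None:
            out = [e for e in out if e.subtype == subtype]
        return out

    def first_in_class(self, gdmt_class: str, subtype: Optional[str] = None) -> DrugEntry:
        drugs = self.drugs_in_class(gdmt_class, subtype)
        if not drugs:
            raise KeyError(f"no formulary drug in class {gdmt_class}/{subtype}")
        return drugs[0]

    @classmethod
    def from_dict(cls, payload: Mapping) -> "Formulary":
        entries = []
        for raw in payload["drugs"]:
            entries.append(
                DrugEntry(
                    name=raw["name"],
                    gdmt_class=raw["gdmt_class"],
                    subtype=str(raw.get("subtype", "none")),
                    target_daily_dose=float(raw["target_daily_dose"]),
                    titration_steps=tuple(raw["titration_steps"]),
                    component_ratio=raw.get("component_ratio"),
                )
            )
        return cls(entries)

    @classmethod
    def from_yaml(cls, path: str) -> "Formulary":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "Formulary":
        return cls.from_dict(_read_packaged_yaml("formulary.yaml"))


@dataclass(frozen=True)
class EligibilityRules:
    """Vital/lab thresholds gating GDMT initiation and up-titration.

    ``contraindication`` rules remove a class from the score denominator;
    ``escalation_block`` rules only freeze up-titration of a class already
    prescribed below target. Threshold keys are ``<measure>_gt``/``<measure>_lt``
    with measures in {sbp, pulse, potassium, egfr, scr} and are evaluated
    strictly (e.g. ``potassium_gt: 5.0`` fires at K+ > 5.0, not at 5.0).
    """

    contraindication: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    escalation_block: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "EligibilityRules":
        return cls(
            contraindication={k: dict(v) for k, v in (payload.get("contraindication") or {}).items()},
            escalation_block={k: dict(v) for k, v in (payload.get("escalation_block") or {}).items()},
        )

    @classmethod
    def from_yaml(cls, path: str) -> "EligibilityRules":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "EligibilityRules":
        return cls.from_dict(_read_packaged_yaml("eligibility_rules.yaml"))
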