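"""Analysis covariates derived from veterinary-visit records and the calendar.

Covers body-condition handling (BCS scale translation, overweight correction
of recorded weights), breed-size categorisation from corrected adult weights,
the binary weight-status variable, the healthy/unhealthy/injury visit
classification, and the meteorological-season / day-type calendar variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

__all__ = [
    "BCS_WEIGHT_CORRECTION",
    "BreedSizeScale",
    "DEFAULT_SIZE_SCALE",
    "HealthRuleSet",
    "correct_weight",
    "map_bcs9_to_5",
    "assign_breed_size",
    "derive_weight_status",
    "classify_visit_health",
    "assign_calendar_vars",
    "season_of",
    "day_type_of",
]

#: Multipliers applied to recorded weights of overweight (4/5) and markedly
#: obese (5/5) dogs so that the corrected value approximates ideal weight.
BCS_WEIGHT_CORRECTION: dict[int, float] = {4: 0.8, 5: 0.6}

#: 9-point to 5-point body condition score translation: two points on the
#: 9-point scale per unit on the 5-point scale (4-5/9 ideal -> 3/5,
#: 6-7/9 overweight -> 4/5, 8-9/9 obese -> 5/5; 1/9 -> 1/5, 2-3/9 -> 2/5).
_BCS9_TO_5 = {1: 1, 2: 2, 3: 2, 4: 3, 5: 3, 6: 4, 7: 4, 8: 5, 9: 5}


def correct_weight(weight_kg: float, bcs5: int) -> float:
    """Correct a recorded body weight for overweight condition.

    Weights recorded at BCS 4/5 and 5/5 are multiplied by 0.8 and 0.6
    respectively; BCS 1-3 weights pass through unchanged.
    """
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if bcs5 not in range(1, 6):
        raise ValueError(f"bcs5 must be in 1..5, got {bcs5}")
    return weight_kg * BCS_WEIGHT_CORRECTION.get(bcs5, 1.0)


def map_bcs9_to_5(bcs9: int) -> int:
    """Translate a 9-point body condition score to the 5-point scale."""
    if bcs9 not in _BCS9_TO_5:
        raise ValueError(f"bcs9 must be in 1..9, got {bcs9}")
    return _BCS9_TO_5[bcs9]


def derive_weight_status(bcs5: int) -> str:
    """Binary weight status: BCS 1-3 -> ``ideal``, 4-5 -> ``overweight``."""
    if bcs5 not in range(1, 6):
        raise ValueError(f"bcs5 must be in 1..5, got {bcs5}")
    return "ideal" if bcs5 <= 3 else "overweight"


@dataclass(frozen=True)
class BreedSizeScale:
    """Ordered kg cut-points mapping mean corrected adult weight to a breed
    size category.  Intervals are left-open right-closed except the ends:
    ``<= thresholds[0]`` maps to the first label, ``> thresholds[-1]`` to the
    last."""

    thresholds: tuple[float, ...] = (6.5, 9.0, 15.0, 30.0, 40.0)
    labels: tuple[str, ...] = (
        "toy",
        "small",
        "medium_small",
        "medium_large",
        "large",
        "giant",
    )

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("need exactly one more label than thresholds")

    def classify(self, weight_kg: float) -> str:
        for cut, label in zip(self.thresholds, self.labels):
            if weight_kg <= cut:
                return label
        return self.labels[-1]


DEFAULT_SIZE_SCALE = BreedSizeScale()


def assign_breed_size(
    adult_weights: list[tuple[float, int]],
    scale: BreedSizeScale = DEFAULT_SIZE_SCALE,
) -> str:
    """Breed-size category from the mean of BCS-corrected adult weights.

    ``adult_weights`` is a list of ``(weight_kg, bcs5)`` measurement pairs;
    each weight is corrected for overweight condition before averaging.
    """
    if not adult_weights:
        raise ValueError("need at least one adult weight measurement")
    corrected = [correct_weight(w, b) for w, b in adult_weights]
    return scale.classify(sum(corrected) / len(corrected))


# ---------------------------------------------------------------------------
# visit health classification


@dataclass(frozen=True)
class HealthRuleSet:
    """Editable code dictionary behind the healthy/unhealthy/injury visit
    classification.  The defaults cover chronic illness (organ failure,
    cardiovascular, musculoskeletal, metabolic and endocrine disorders,
    neoplasia), mobility-affecting events (fracture, road traffic accident,
    surgery, anesthesia) and general preventive-care visit reasons."""

    unhealthy_codes: frozenset[str] = frozenset(
        {
            "organ_failure",
            "chronic_kidney_disease",
            "heart_disease",
            "cardiovascular_disorder",
            "osteoarthritis",
            "musculoskeletal_disorder",
            "diabetes_mellitus",
            "metabolic_disorder",
            "hypothyroidism",
            "endocrine_disorder",
            "neoplasia",
        }
    )
    injury_codes: frozenset[str] = frozenset(
        {
            "fracture",
            "road_traffic_accident",
            "surgery",
            "anesthesia",
            "cruciate_rupture",
        }
    )
    healthy_reasons: frozenset[str] = frozenset(
        {
            "vaccination",
            "anthelmintic",
            "grooming",
            "preventive_care",
            "wellness_exam",
        }
    )

    def __post_init__(self) -> None:
        overlap = self.unhealthy_codes & self.healthy_reasons
        if overlap:
            raise ValueError(f"codes cannot be both unhealthy and healthy: {overlap}")

    @classmethod
    def from_yaml(cls, path) -> "HealthRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            unhealthy_codes=frozenset(raw["unhealthy_codes"]),
            injury_codes=frozenset(raw["injury_codes"]),
            healthy_reasons=frozenset(raw["healthy_reasons"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "unhealthy_codes": sorted(self.unhealthy_codes),
                    "injury_codes": sorted(self.injury_codes),
                    "healthy_reasons": sorted(self.healthy_reasons),
                },
                fh,
            )


DEFAULT_HEALTH_RULES = HealthRuleSet()


def classify_visit_health(
    diagnoses: list[str] | set[str],
    visit_reason: str,
    rules: HealthRuleSet = DEFAULT_HEALTH_RULES,
) -> tuple[str, bool]:
    """Classify a visit as ``(status, injury_flag)``.

    Status is ``unhealthy`` when any diagnosis is a chronic-illness code,
    else ``healthy`` when the visit reason is a general preventive-care
    reason, else ``other``.  The injury flag is independent of status and is
    true when any code indicates a mobility-affecting ailment or procedure.
    """
    codes = set(diagnoses)
    injury = bool(codes & rules.injury_codes)
    if codes & rules.unhealthy_codes:
        return "unhealthy", injury
    if visit_reason in rules.healthy_reasons:
        return "healthy", injury
    return "other", injury


# ---------------------------------------------------------------------------
# calendar variables

_SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def season_of(dates: pd.Series) -> pd.Series:
    """Northern-hemisphere meteorological season for each date."""
    return pd.to_datetime(dates).dt.month.map(_SEASON_BY_MONTH)


def day_type_of(dates: pd.Series) -> pd.Series:
    """``weekend`` for Saturday/Sunday, else ``weekday``."""
    wd = pd.to_datetime(dates).dt.dayofweek
    return wd.map(lambda d: "weekend" if d >= 5 else "weekday")


def assign_calendar_vars(date) -> tuple[str, str]:
    """(season, day_type) for a single calendar date."""
    ts = pd.Timestamp(date)
    return _SEASON_BY_MONTH[ts.month], "weekend" if ts.dayofweek >= 5 else "weekday"
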