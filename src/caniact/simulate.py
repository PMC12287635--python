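"""Two-source synthetic cohort generator with recorded ground truth.

Emulates the study's data situation: an activity source (per-dog demographics
plus daily active-minute records from a collar accelerometer) and an EHR
source (the same dogs, imperfectly keyed, with veterinary visit records).
The daily activity outcome is generated multiplicatively from a log-scale
linear model over dog, owner, environmental and calendar covariates with a
per-dog random intercept, plus two measurement artefacts the cleaning
pipeline must handle: out-of-range daily records and dogs whose match keys
disagree between the sources.

Default effect sizes are presets following the sign/magnitude patterns of
published population-scale dog-activity estimates; they are study conditions
for the synthetic experiments, not reproductions of any real-data fit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .derive import day_type_of, derive_weight_status, season_of
from .design import ModelSpec, build_design

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_cohort",
    "simulate_visits",
    "simulate_activity",
    "source_views",
    "make_analysis_table",
    "stage_rng",
    "full_generating_spec",
    "dog_attribute_spec",
    "environmental_spec",
    "DEFAULT_EFFECTS",
]

DAYS_PER_YEAR = 365.25

#: Log-scale main-effect presets (treatment coding, reference levels:
#: medium_large / male / intact / ideal / rural / cold / spring / weekday /
#: 18-30).  "latitude" is a slope per degree north.
DEFAULT_EFFECTS: dict = {
    "breed_size": {
        "toy": -0.242,
        "small": -0.202,
        "medium_small": -0.051,
        "large": 0.054,
        "giant": -0.031,
    },
    "sex": {"female": -0.045},
    "neuter_status": {"neutered": -0.017},
    "weight_status": {"overweight": -0.002},
    "location_type": {"urban": -0.004},
    "owner_age_band": {"30-45": -0.031, "45-60": -0.027, "60+": -0.029},
    "season": {"summer": -0.009, "autumn": -0.012, "winter": -0.082},
    "climate": {"hot_humid": -0.006, "hot_dry": 0.060, "marine": 0.061},
    "day_type": {"weekend": 0.114},
    "latitude": 0.005,
}

#: Deviation of each breed size's linear age slope from the reference slope.
DEFAULT_SIZE_AGE_INTERACTION: dict[str, float] = {
    "toy": 0.033,
    "small": 0.028,
    "medium_small": 0.010,
    "large": -0.005,
    "giant": -0.016,
}

DEFAULT_SEASON_CLIMATE_INTERACTION: dict[tuple[str, str], float] = {
    ("summer", "hot_humid"): -0.039,
    ("summer", "hot_dry"): -0.047,
    ("summer", "marine"): 0.025,
    ("autumn", "hot_humid"): -0.004,
    ("autumn", "hot_dry"): -0.012,
    ("autumn", "marine"): -0.010,
    ("winter", "hot_humid"): 0.043,
    ("winter", "hot_dry"): 0.059,
    ("winter", "marine"): 0.010,
}

DEFAULT_DAY_OWNER_INTERACTION: dict[tuple[str, str], float] = {
    ("weekend", "30-45"): -0.018,
    ("weekend", "45-60"): -0.030,
    ("weekend", "60+"): -0.064,
}

_SIZE_WEIGHT_RANGE_KG = {
    "toy": (3.5, 6.4),
    "small": (6.6, 8.9),
    "medium_small": (9.2, 14.8),
    "medium_large": (15.3, 29.5),
    "large": (30.3, 39.5),
    "giant": (40.5, 60.0),
}

_NAME_POOL = (
    "bella max luna charlie lucy cooper daisy milo bailey sadie rocky molly "
    "buddy stella tucker bear duke zoey harley ruby jack lola oliver maggie "
    "teddy riley winston penny murphy nala finn gracie leo rosie koda willow "
    "ollie piper zeus hazel"
).split()


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator derived from one run seed by stable name hashing,
    so each pipeline stage is individually reproducible."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


@dataclass
class SimulationConfig:
    """Data-generating-process parameters for the synthetic cohort.

    Scale parameters default to the study-like conditions used throughout
    the test suite: ~3 visits per dog-year, a two-year study window, log-scale
    effect presets, dog random-intercept variance ``tau2`` and residual
    variance ``sigma2`` of 0.2 each, 21% out-of-range daily records and 10%
    of dogs with perturbed match keys.
    """

    n_dogs: int = 500
    start_date: str = "2021-01-01"
    n_days: int = 730
    records_per_dog_mean: float = 100.0
    records_per_dog_dispersion: float | None = 2.0  # NegBin shape; None = fixed
    visit_rate: float = 3.0  # visits per dog-year
    intercept: float = 3.40
    beta_age_inv_sq: float = 2.432
    age_slope: float = -0.023
    effects: dict = field(default_factory=lambda: _deepcopy_effects(DEFAULT_EFFECTS))
    size_age_interaction: dict = field(
        default_factory=lambda: dict(DEFAULT_SIZE_AGE_INTERACTION)
    )
    season_climate_interaction: dict = field(
        default_factory=lambda: dict(DEFAULT_SEASON_CLIMATE_INTERACTION)
    )
    day_owner_interaction: dict = field(
        default_factory=lambda: dict(DEFAULT_DAY_OWNER_INTERACTION)
    )
    tau2: float = 0.2
    sigma2: float = 0.2
    anomaly_prob: float = 0.21
    unlinkable_prob: float = 0.10
    size_probs: dict = field(
        default_factory=lambda: {
            "toy": 0.178,
            "small": 0.116,
            "medium_small": 0.132,
            "medium_large": 0.372,
            "large": 0.162,
            "giant": 0.040,
        }
    )
    male_prob: float = 0.526
    neutered_prob: float = 0.9
    bcs_probs: dict = field(
        default_factory=lambda: {1: 0.02, 2: 0.08, 3: 0.56, 4: 0.27, 5: 0.07}
    )
    owner_age_probs: dict = field(
        default_factory=lambda: {"18-30": 0.20, "30-45": 0.35, "45-60": 0.30, "60+": 0.15}
    )
    urban_prob: float = 0.6
    climate_probs: dict = field(
        default_factory=lambda: {
            "cold": 0.30,
            "hot_humid": 0.40,
            "hot_dry": 0.15,
            "marine": 0.15,
        }
    )
    chronic_illness_prob: float = 0.12  # per dog (carried on all its visits)
    injury_prob: float = 0.05  # per visit
    healthy_reason_prob: float = 0.7  # per visit, given no other reason drawn
    min_age_years: float = 0.8  # age at window start, lower bound
    max_age_years: float = 13.0
    multi_dog_household_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dogs < 1:
            raise ValueError("n_dogs must be >= 1")
        if self.tau2 < 0 or self.sigma2 < 0:
            raise ValueError("variances must be non-negative")
        for name in ("anomaly_prob", "unlinkable_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for probs in (self.size_probs, self.owner_age_probs, self.climate_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-8:
                raise ValueError("category probabilities must sum to 1")

    # -- serialisation ------------------------------------------------------
    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        for key in ("season_climate_interaction", "day_owner_interaction"):
            if key in raw and raw[key] and isinstance(
                next(iter(raw[key])), str
            ):
                raw[key] = {
                    tuple(k.split(":")): v for k, v in raw[key].items()
                }
        if "bcs_probs" in raw:
            raw["bcs_probs"] = {int(k): v for k, v in raw["bcs_probs"].items()}
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def coefficient_truth(self) -> dict[str, float]:
        """Generating coefficients keyed by canonical design term name."""
        coefs: dict[str, float] = {
            "intercept": self.intercept,
            "age_inv_sq": self.beta_age_inv_sq,
            "age": self.age_slope,
            "latitude": float(self.effects.get("latitude", 0.0)),
        }
        for var, levels in self.effects.items():
            if not isinstance(levels, dict):
                continue
            for level, beta in levels.items():
                coefs[f"{var}[{level}]"] = beta
        for size, dev in self.size_age_interaction.items():
            coefs[f"breed_size[{size}]:age"] = dev
        for (season, climate), beta in self.season_climate_interaction.items():
            coefs[f"season[{season}]:climate[{climate}]"] = beta
        for (day, band), beta in self.day_owner_interaction.items():
            coefs[f"day_type[{day}]:owner_age_band[{band}]"] = beta
        return coefs


def _deepcopy_effects(effects: dict) -> dict:
    return {k: (dict(v) if isinstance(v, dict) else v) for k, v in effects.items()}


@dataclass
class SimulationTruth:
    """Ground truth recorded at generation time for recovery tests."""

    coefficients: dict[str, float]
    tau2: float
    sigma2: float
    random_intercepts: pd.Series
    unlinkable_ids: list[str]
    chronic_ids: list[str]
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "coefficients": self.coefficients,
            "tau2": self.tau2,
            "sigma2": self.sigma2,
            "random_intercepts": {
                str(k): float(v) for k, v in self.random_intercepts.items()
            },
            "unlinkable_ids": list(self.unlinkable_ids),
            "chronic_ids": list(self.chronic_ids),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# model specs


def dog_attribute_spec() -> ModelSpec:
    """LMM structure for the dog-attribute analysis (age, size, weight
    status, sex, neuter status; adjusted for owner age and location)."""
    return ModelSpec(
        fixed_effects=(
            "age_inv_sq",
            "age",
            "breed_size",
            "weight_status",
            "sex",
            "neuter_status",
            "owner_age_band",
            "location_type",
        ),
        interactions=(("breed_size", "age"),),
    )


def environmental_spec() -> ModelSpec:
    """LMM structure for the environmental analysis (latitude, climate,
    season, day type, location, owner age)."""
    return ModelSpec(
        fixed_effects=(
            "latitude",
            "climate",
            "season",
            "day_type",
            "location_type",
            "owner_age_band",
        ),
        interactions=(("season", "climate"), ("day_type", "owner_age_band")),
    )


def full_generating_spec() -> ModelSpec:
    """The union model containing every term of the data-generating process."""
    return ModelSpec(
        fixed_effects=(
            "age_inv_sq",
            "age",
            "breed_size",
            "weight_status",
            "sex",
            "neuter_status",
            "owner_age_band",
            "location_type",
            "latitude",
            "climate",
            "season",
            "day_type",
        ),
        interactions=(
            ("breed_size", "age"),
            ("season", "climate"),
            ("day_type", "owner_age_band"),
        ),
    )


# ---------------------------------------------------------------------------
# generation


_CLIMATE_LATITUDE = {  # mean degrees north per climate zone
    "cold": 44.0,
    "hot_humid": 31.0,
    "hot_dry": 33.0,
    "marine": 41.0,
}

_CHRONIC_CODES = (
    "osteoarthritis",
    "heart_disease",
    "diabetes_mellitus",
    "hypothyroidism",
    "chronic_kidney_disease",
    "neoplasia",
)
_INJURY_CODES = ("fracture", "road_traffic_accident", "surgery", "anesthesia")
_HEALTHY_REASONS = ("vaccination", "anthelmintic", "grooming", "preventive_care")
_NEUTRAL_CODES = ("dental_calculus", "dermatitis", "otitis_externa", "healthy_pet")


def _draw_categories(rng, probs: Mapping, size: int) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return rng.choice(np.asarray(keys, dtype=object), size=size, p=p / p.sum())


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw the dog-level table and the ground truth object.

    The returned frame is the *master* table carrying the true attributes of
    every dog together with both sources' keys; :func:`source_views` projects
    it into the imperfectly-overlapping activity-source and EHR-source
    demographic tables.
    """
    cfg = config
    rng = stage_rng(cfg.seed, "cohort")
    n = cfg.n_dogs
    idx = np.arange(n)
    dog_id = np.array([f"D{i:05d}" for i in idx])

    households = [f"H{i:05d}" for i in idx]
    share = rng.random(n) < cfg.multi_dog_household_prob
    for i in range(1, n):
        if share[i]:
            households[i] = households[i - 1]

    size = _draw_categories(rng, cfg.size_probs, n)
    lo = np.array([_SIZE_WEIGHT_RANGE_KG[s][0] for s in size])
    hi = np.array([_SIZE_WEIGHT_RANGE_KG[s][1] for s in size])
    ideal_weight = rng.uniform(lo, hi)
    sex = np.where(rng.random(n) < cfg.male_prob, "male", "female")
    neutered = rng.random(n) < cfg.neutered_prob
    bcs = _draw_categories(rng, cfg.bcs_probs, n).astype(int)
    weight_status = np.array([derive_weight_status(b) for b in bcs])
    owner_age = _draw_categories(rng, cfg.owner_age_probs, n)
    location = np.where(rng.random(n) < cfg.urban_prob, "urban", "rural")
    climate = _draw_categories(rng, cfg.climate_probs, n)
    latitude = np.clip(
        np.array([_CLIMATE_LATITUDE[c] for c in climate])
        + rng.normal(0.0, 2.5, n),
        24.0,
        49.0,
    )
    start = pd.Timestamp(cfg.start_date)
    age_at_start = rng.uniform(cfg.min_age_years, cfg.max_age_years, n)
    birth_date = start - pd.to_timedelta(
        np.round(age_at_start * DAYS_PER_YEAR), unit="D"
    )
    names = rng.choice(np.asarray(_NAME_POOL, dtype=object), size=n)
    chronic = rng.random(n) < cfg.chronic_illness_prob
    unlinkable = rng.random(n) < cfg.unlinkable_prob
    u = rng.normal(0.0, np.sqrt(cfg.tau2), n)

    dogs = pd.DataFrame(
        {
            "dog_id": dog_id,
            "activity_key": [f"W{i:05d}" for i in idx],
            "ehr_key": [f"B{i:05d}" for i in idx],
            "household": households,
            "name": names,
            "sex": sex,
            "birth_date": birth_date,
            "neutered": neutered,
            "breed_size": size,
            "ideal_weight_kg": ideal_weight,
            "bcs5": bcs,
            "weight_status": weight_status,
            "owner_age_band": owner_age,
            "location_type": location,
            "climate": climate,
            "latitude": latitude,
            "chronic_illness": chronic,
            "unlinkable": unlinkable,
        }
    )
    truth = SimulationTruth(
        coefficients=cfg.coefficient_truth(),
        tau2=cfg.tau2,
        sigma2=cfg.sigma2,
        random_intercepts=pd.Series(u, index=dog_id, name="u"),
        unlinkable_ids=list(dog_id[unlinkable]),
        chronic_ids=list(dog_id[chronic]),
        seed=cfg.seed,
    )
    return dogs, truth


def source_views(
    dogs: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project the master table into the two sources' demographic tables.

    Both carry the match-key fields (household, species, sex, name, birth
    month and year).  Unlinkable dogs get a perturbed key on the EHR side:
    alternately a variant name spelling or a birth month off by one.
    """
    rng = stage_rng(config.seed, "source-keys")
    base = pd.DataFrame(
        {
            "household": dogs["household"],
            "species": "dog",
            "sex": dogs["sex"],
            "name": dogs["name"],
            "birth_year": dogs["birth_date"].dt.year,
            "birth_month": dogs["birth_date"].dt.month,
        }
    )
    activity_dogs = base.copy()
    activity_dogs.insert(0, "dog_key", dogs["activity_key"])

    ehr_dogs = base.copy()
    ehr_dogs.insert(0, "dog_key", dogs["ehr_key"])
    ehr_dogs["birth_date"] = dogs["birth_date"]
    ehr_dogs["neutered"] = dogs["neutered"]
    ehr_dogs["owner_age_band"] = dogs["owner_age_band"]
    ehr_dogs["location_type"] = dogs["location_type"]
    ehr_dogs["climate"] = dogs["climate"]
    ehr_dogs["latitude"] = dogs["latitude"]

    mask = dogs["unlinkable"].to_numpy()
    perturb_name = rng.random(len(dogs)) < 0.5
    for i in np.flatnonzero(mask):
        if perturb_name[i]:
            ehr_dogs.iat[i, ehr_dogs.columns.get_loc("name")] = (
                str(ehr_dogs.iat[i, ehr_dogs.columns.get_loc("name")]) + "y"
            )
        else:
            m = int(ehr_dogs.iat[i, ehr_dogs.columns.get_loc("birth_month")])
            ehr_dogs.iat[i, ehr_dogs.columns.get_loc("birth_month")] = m % 12 + 1
    return activity_dogs, ehr_dogs


def simulate_visits(dogs: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Draw veterinary visit records for each dog.

    Visit counts are Poisson around ``visit_rate`` visits per dog-year over
    the study window extended one year back (so early activity records can
    have a prior visit).  Recorded weight is ideal weight inflated by the
    inverse of the published BCS correction (x1/0.8 at BCS 4, x1/0.6 at
    BCS 5) times small lognormal measurement noise.
    """
    if dogs.empty:
        raise ValueError("dog table is empty")
    cfg = config
    rng = stage_rng(cfg.seed, "visits")
    window_days = cfg.n_days + 365
    years = window_days / DAYS_PER_YEAR
    counts = rng.poisson(cfg.visit_rate * years, len(dogs))
    rows = []
    start = pd.Timestamp(cfg.start_date) - pd.Timedelta(days=365)
    inflate = {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0 / 0.8, 5: 1.0 / 0.6}
    for dog, k in zip(dogs.itertuples(index=False), counts):
        if k == 0:
            continue
        offs = np.sort(rng.integers(0, window_days, size=k))
        bcs = int(dog.bcs5)
        weights = (
            dog.ideal_weight_kg
            * inflate[bcs]
            * np.exp(rng.normal(0.0, 0.03, size=k))
        )
        for off, w in zip(offs, weights):
            codes: list[str] = []
            if dog.chronic_illness and cfg.chronic_illness_prob > 0:
                codes.append(str(rng.choice(_CHRONIC_CODES)))
            if rng.random() < cfg.injury_prob:
                codes.append(str(rng.choice(_INJURY_CODES)))
            if rng.random() < 0.3:
                codes.append(str(rng.choice(_NEUTRAL_CODES)))
            reason = (
                str(rng.choice(_HEALTHY_REASONS))
                if rng.random() < cfg.healthy_reason_prob
                else "consultation"
            )
            rows.append(
                (
                    dog.ehr_key,
                    start + pd.Timedelta(days=int(off)),
                    float(w),
                    bcs,
                    ";".join(codes),
                    reason,
                    bool(dog.neutered),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "dog_key",
            "visit_date",
            "weight_kg",
            "bcs5",
            "diagnoses",
            "visit_reason",
            "neutered_at_visit",
        ],
    )


def _covariate_frame(
    dogs: pd.DataFrame, dog_index: np.ndarray, dates: pd.Series
) -> pd.DataFrame:
    d = dogs.iloc[dog_index].reset_index(drop=True)
    age = (
        (pd.to_datetime(dates).reset_index(drop=True) - d["birth_date"]).dt.days
        / DAYS_PER_YEAR
    )
    out = pd.DataFrame(
        {
            "dog_id": d["dog_id"],
            "date": pd.to_datetime(dates).reset_index(drop=True),
            "age": age,
            "age_inv_sq": age**-2.0,
            "breed_size": d["breed_size"],
            "weight_status": d["weight_status"],
            "sex": d["sex"],
            "neuter_status": np.where(d["neutered"], "neutered", "intact"),
            "owner_age_band": d["owner_age_band"],
            "location_type": d["location_type"],
            "climate": d["climate"],
            "latitude": d["latitude"],
        }
    )
    out["season"] = season_of(out["date"])
    out["day_type"] = day_type_of(out["date"])
    return out


def simulate_activity(
    dogs: pd.DataFrame,
    truth: SimulationTruth,
    config: SimulationConfig,
    visits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw daily activity records.

    For dog *i* on date *j* the log of active minutes is the linear predictor
    over the full generating model (age^-2 and linear-age terms, dog and
    environmental main effects, the three interaction blocks) plus the dog's
    random intercept and Gaussian residual noise; minutes are its exponential.
    With probability ``anomaly_prob`` a record is replaced by a draw outside
    the plausible 10-600 minute range (device artefact channel).

    ``visits`` is accepted for interface symmetry but unused: all generating
    covariates are dog-level or calendar-derived.
    """
    cfg = config
    rng = stage_rng(cfg.seed, "activity")
    n = len(dogs)
    if cfg.records_per_dog_dispersion is None:
        counts = np.full(n, int(round(cfg.records_per_dog_mean)))
    else:
        r = cfg.records_per_dog_dispersion
        p = r / (r + cfg.records_per_dog_mean)
        counts = rng.negative_binomial(r, p, size=n)
    counts = np.clip(counts, 1, cfg.n_days)

    dog_index = np.repeat(np.arange(n), counts)
    day_offsets = np.concatenate(
        [rng.choice(cfg.n_days, size=k, replace=False) for k in counts]
    )
    start = pd.Timestamp(cfg.start_date)
    dates = start + pd.to_timedelta(day_offsets, unit="D")

    cov = _covariate_frame(dogs, dog_index, pd.Series(dates))
    X, names = build_design(cov, full_generating_spec())
    beta = np.array([truth.coefficients.get(nm, 0.0) for nm in names])
    u = truth.random_intercepts.reindex(cov["dog_id"]).to_numpy()
    eps = rng.normal(0.0, np.sqrt(cfg.sigma2), len(cov))
    minutes = np.exp(X @ beta + u + eps)

    if cfg.anomaly_prob > 0:
        bad = rng.random(len(cov)) < cfg.anomaly_prob
        low = rng.random(len(cov)) < 0.5
        repl = np.where(
            low,
            rng.uniform(0.0, 9.5, len(cov)),
            rng.uniform(600.5, 900.0, len(cov)),
        )
        minutes = np.where(bad, repl, minutes)

    activity_key = dogs["activity_key"].to_numpy()[dog_index]
    return pd.DataFrame(
        {
            "dog_key": activity_key,
            "date": dates,
            "active_minutes": minutes,
        }
    )


def make_analysis_table(
    dogs: pd.DataFrame, activity: pd.DataFrame
) -> pd.DataFrame:
    """Join activity records straight onto the master dog table.

    A shortcut past record linkage for inference experiments: the returned
    frame carries the true covariates (exactly those used in generation) plus
    ``active_minutes``, keyed by ``dog_id``.
    """
    key_to_index = pd.Series(np.arange(len(dogs)), index=dogs["activity_key"])
    dog_index = key_to_index.reindex(activity["dog_key"]).to_numpy()
    cov = _covariate_frame(dogs, dog_index, activity["date"])
    cov["active_minutes"] = activity["active_minutes"].to_numpy()
    return cov
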