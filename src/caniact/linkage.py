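"""Two-source record linkage and the data-cleaning filter cascade.

Dogs are matched across the activity and EHR sources by exact agreement on
the normalised key (household, species, sex, name, birth month and year);
ambiguous keys (zero or multiple candidates) are excluded rather than
guessed.  Each daily activity record is then joined to the closest prior
veterinary visit within one year, and the cleaning cascade applies, in
order: the 10-600 active-minute bounds filter, the 5:1 activity-to-visit
ratio filter, the adult-age window (>1.5 and <12 years at both record
dates), and the minimum-records floor (more than seven surviving records
per dog).  Every stage logs row and dog counts into a provenance trail so
the flow of the cleaning can be audited.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MATCH_KEY_FIELDS",
    "FilterConfig",
    "LinkedDataset",
    "MatchResult",
    "normalize_name",
    "match_dogs",
    "link_activity_to_visit",
    "apply_filters",
    "split_healthy",
]

MATCH_KEY_FIELDS = ("household", "species", "sex", "name", "birth_year", "birth_month")

_PUNCT = re.compile(r"[^a-z0-9 ]+")


def normalize_name(name: str) -> str:
    """Lowercase, trim and strip punctuation; idempotent."""
    s = _PUNCT.sub("", str(name).lower().strip())
    return " ".join(s.split())


@dataclass
class FilterConfig:
    """Thresholds of the cleaning cascade (defaults = study rules)."""

    min_minutes: float = 10.0
    max_minutes: float = 600.0
    min_ratio: float = 5.0  # activity records per distinct linked visit
    min_age_years: float = 1.5  # exclusive lower bound
    max_age_years: float = 12.0  # exclusive upper bound
    min_records: int = 7  # dogs must have MORE than this many rows
    max_link_days: int = 365


@dataclass
class MatchResult:
    mapping: dict[str, str]  # activity dog_key -> ehr dog_key
    unmatched_activity: list[str]
    unmatched_ehr: list[str]
    ambiguous: list[str]  # normalised key reprs excluded as ambiguous


@dataclass
class LinkedDataset:
    """Analysis-ready linked rows plus the per-stage provenance trail."""

    rows: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def log_stage(self, name: str, rows_in: int, rows_out: int, dogs_in: int, dogs_out: int) -> None:
        self.provenance.append(
            {
                "stage": name,
                "rows_in": int(rows_in),
                "rows_out": int(rows_out),
                "dogs_in": int(dogs_in),
                "dogs_out": int(dogs_out),
            }
        )

    def copy(self) -> "LinkedDataset":
        return LinkedDataset(self.rows.copy(), [dict(p) for p in self.provenance])

    def healthy_rows(self) -> pd.DataFrame:
        return self.rows[self.rows["in_healthy_visits"]]


def _normalised_key(df: pd.DataFrame) -> pd.Series:
    missing = [c for c in MATCH_KEY_FIELDS if c not in df.columns]
    if missing:
        raise KeyError(f"match key fields missing: {missing}")
    return (
        df["household"].astype(str).str.strip().str.lower()
        + "|"
        + df["species"].astype(str).str.strip().str.lower()
        + "|"
        + df["sex"].astype(str).str.strip().str.lower()
        + "|"
        + df["name"].map(normalize_name)
        + "|"
        + df["birth_year"].astype(int).astype(str)
        + "-"
        + df["birth_month"].astype(int).astype(str).str.zfill(2)
    )


def match_dogs(activity_dogs: pd.DataFrame, ehr_dogs: pd.DataFrame) -> MatchResult:
    """Deterministic exact matching on the full normalised key.

    A dog is matched only when its key occurs exactly once in each source;
    keys with multiple candidates on either side (e.g. same-name littermates
    in one household) are excluded as ambiguous and reported.
    """
    a_key = _normalised_key(activity_dogs)
    e_key = _normalised_key(ehr_dogs)
    a_counts = a_key.value_counts()
    e_counts = e_key.value_counts()
    ambiguous = sorted(
        set(a_counts[a_counts > 1].index) | set(e_counts[e_counts > 1].index)
    )
    amb = set(ambiguous)
    a_unique = {k: d for k, d in zip(a_key, activity_dogs["dog_key"]) if k not in amb}
    e_unique = {k: d for k, d in zip(e_key, ehr_dogs["dog_key"]) if k not in amb}
    mapping = {
        a_unique[k]: e_unique[k] for k in a_unique.keys() & e_unique.keys()
    }
    matched_a = set(mapping)
    matched_e = set(mapping.values())
    return MatchResult(
        mapping=mapping,
        unmatched_activity=sorted(
            set(activity_dogs["dog_key"]) - matched_a
        ),
        unmatched_ehr=sorted(set(ehr_dogs["dog_key"]) - matched_e),
        ambiguous=ambiguous,
    )


def link_activity_to_visit(
    activity: pd.DataFrame,
    visits: pd.DataFrame,
    mapping: dict[str, str] | None = None,
    max_link_days: int = 365,
) -> LinkedDataset:
    """Join each activity record to its closest prior visit within one year.

    ``mapping`` translates activity-source dog keys to EHR keys (output of
    :func:`match_dogs`); records of unmatched dogs are dropped and logged.
    A record joins the visit with the greatest ``visit_date <= date`` and
    ``date - visit_date <= max_link_days`` days; records with no qualifying
    visit are dropped and logged.
    """
    act = activity.copy()
    act["date"] = pd.to_datetime(act["date"])
    rows_in, dogs_in = len(act), act["dog_key"].nunique()
    ds = LinkedDataset(rows=act)
    if mapping is not None:
        act["dog_id"] = act["dog_key"].map(mapping)
        act = act[act["dog_id"].notna()]
        ds.log_stage("match-dogs", rows_in, len(act), dogs_in, act["dog_id"].nunique())
    else:
        act["dog_id"] = act["dog_key"]

    vis = visits.copy()
    vis["visit_date"] = pd.to_datetime(vis["visit_date"])
    vis = vis.rename(columns={"dog_key": "dog_id"})
    if "visit_id" not in vis.columns:
        vis["visit_id"] = np.arange(len(vis))
    rows_in, dogs_in = len(act), act["dog_id"].nunique()
    merged = pd.merge_asof(
        act.sort_values("date", kind="stable"),
        vis.sort_values("visit_date", kind="stable"),
        left_on="date",
        right_on="visit_date",
        by="dog_id",
        direction="backward",
        tolerance=pd.Timedelta(days=max_link_days),
        allow_exact_matches=True,
    )
    merged = merged[merged["visit_id"].notna()].reset_index(drop=True)
    merged["visit_id"] = merged["visit_id"].astype(int)
    ds.rows = merged
    ds.log_stage(
        "link-within-one-year",
        rows_in,
        len(merged),
        dogs_in,
        merged["dog_id"].nunique(),
    )
    return ds


def apply_filters(linked: LinkedDataset, config: FilterConfig | None = None) -> LinkedDataset:
    """Apply the cleaning cascade, logging per-stage counts.

    Order: minute bounds -> activity:visit ratio -> adult-age window ->
    minimum records per dog.  Rows surviving all stages get
    ``in_all_visits = True``.  The cascade is idempotent: applied to its own
    output it removes nothing.
    """
    cfg = config or FilterConfig()
    ds = linked.copy()
    df = ds.rows

    def stage(name: str, keep: pd.Series) -> None:
        nonlocal df
        rows_in, dogs_in = len(df), df["dog_id"].nunique()
        df = df[keep.to_numpy()]
        ds.log_stage(name, rows_in, len(df), dogs_in, df["dog_id"].nunique())

    m = df["active_minutes"]
    stage("minute-bounds", (m >= cfg.min_minutes) & (m <= cfg.max_minutes))

    # the per-dog ratio is frozen into a column the first time the cascade
    # runs, so re-applying the cascade to its own output is a no-op even
    # though later stages may remove more of a dog's rows
    if "link_ratio" not in df.columns:
        df = df.copy()
        df["link_ratio"] = df.groupby("dog_id")["visit_id"].transform(
            lambda v: len(v) / v.nunique()
        )
    stage("activity-visit-ratio", df["link_ratio"] >= cfg.min_ratio)

    for col in ("age", "age_at_visit"):
        if col not in df.columns:
            raise KeyError(f"age column {col!r} required before the age filter")
    keep_age = (
        (df["age"] > cfg.min_age_years)
        & (df["age"] < cfg.max_age_years)
        & (df["age_at_visit"] > cfg.min_age_years)
        & (df["age_at_visit"] < cfg.max_age_years)
    )
    stage("adult-age-window", keep_age)

    n_per_dog = df.groupby("dog_id")["dog_id"].transform("size")
    stage("min-records-per-dog", n_per_dog > cfg.min_records)

    df = df.copy()
    df["in_all_visits"] = True
    ds.rows = df.reset_index(drop=True)
    return ds


def split_healthy(linked: LinkedDataset) -> LinkedDataset:
    """Flag the healthy-visits subset.

    A row is in the healthy-visits dataset iff it is in the all-visits
    dataset and its linked visit is classified healthy with no injury flag.
    Requires ``health_status`` and ``injury`` columns (see
    :func:`caniact.derive.classify_visit_health`); unclassified visits raise.
    """
    ds = linked.copy()
    df = ds.rows
    for col in ("health_status", "injury"):
        if col not in df.columns:
            raise KeyError(f"visit classification column {col!r} missing")
    bad = df["health_status"].isna()
    if bad.any():
        vids = sorted(df.loc[bad, "visit_id"].unique()[:5])
        raise ValueError(f"unclassified visits (first few ids): {vids}")
    if "in_all_visits" not in df.columns:
        df = df.copy()
        df["in_all_visits"] = True
    healthy = (
        df["in_all_visits"]
        & (df["health_status"] == "healthy")
        & (~df["injury"].astype(bool))
    )
    df = df.copy()
    df["in_healthy_visits"] = healthy
    rows_in, dogs_in = int(df["in_all_visits"].sum()), df.loc[df["in_all_visits"], "dog_id"].nunique()
    ds.rows = df
    ds.log_stage(
        "healthy-visits-subset",
        rows_in,
        int(healthy.sum()),
        dogs_in,
        df.loc[healthy, "dog_id"].nunique() if healthy.any() else 0,
    )
    return ds
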