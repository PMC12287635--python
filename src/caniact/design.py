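"""Model specification and fixed-effects design-matrix construction.

A :class:`ModelSpec` names the outcome, the fixed-effect predictor columns,
interaction pairs and the grouping (dog) column.  Categorical predictors are
treatment-coded against an explicit reference level; interactions are formed
as products of the encoded blocks.  Term names are canonical
(``var[level]``, ``a[la]:b[lb]``, ``var[level]:cont``) and are shared by the
synthetic-data generator, so generating coefficients and fitted coefficients
line up name-for-name in recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ModelSpec", "build_design", "LEVELS", "DEFAULT_REFERENCES"]

#: Canonical level order per categorical analysis variable (reference first).
LEVELS: dict[str, list[str]] = {
    "breed_size": ["medium_large", "toy", "small", "medium_small", "large", "giant"],
    "sex": ["male", "female"],
    "neuter_status": ["intact", "neutered"],
    "weight_status": ["ideal", "overweight"],
    "location_type": ["rural", "urban"],
    "climate": ["cold", "hot_humid", "hot_dry", "marine"],
    "season": ["spring", "summer", "autumn", "winter"],
    "day_type": ["weekday", "weekend"],
    "owner_age_band": ["18-30", "30-45", "45-60", "60+"],
}

DEFAULT_REFERENCES: dict[str, str] = {var: lv[0] for var, lv in LEVELS.items()}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effects + random-intercept model specification.

    ``outcome`` is logged before fitting when ``log_outcome`` is set (the
    default, matching the log-transformed active-minutes analysis).  The age
    predictor enters through the ``age_inv_sq`` column (age in years to the
    power −2), which callers are expected to have materialised.
    """

    outcome: str = "active_minutes"
    fixed_effects: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    group: str = "dog_id"
    reference_levels: dict[str, str] = field(default_factory=dict)
    log_outcome: bool = True

    def __post_init__(self) -> None:
        if self.group in self.fixed_effects:
            raise ValueError("grouping column cannot also be a fixed effect")
        for a, b in self.interactions:
            for m in (a, b):
                if m not in self.fixed_effects:
                    raise ValueError(
                        f"interaction member {m!r} must appear as a main effect"
                    )
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))
        object.__setattr__(
            self, "interactions", tuple((a, b) for a, b in self.interactions)
        )

    def reference(self, var: str) -> str:
        return self.reference_levels.get(var, DEFAULT_REFERENCES.get(var, ""))

    def with_interaction(self, pair: tuple[str, str]) -> "ModelSpec":
        return replace(self, interactions=self.interactions + (tuple(pair),))

    @classmethod
    def from_dict(cls, raw: dict) -> "ModelSpec":
        return cls(
            outcome=raw.get("outcome", "active_minutes"),
            fixed_effects=tuple(raw.get("fixed_effects", ())),
            interactions=tuple(tuple(p) for p in raw.get("interactions", ())),
            group=raw.get("group", "dog_id"),
            reference_levels=dict(raw.get("reference_levels", {})),
            log_outcome=bool(raw.get("log_outcome", True)),
        )


def _is_categorical(series: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(series) or isinstance(
        series.dtype, pd.CategoricalDtype
    )


def _encode_main(
    data: pd.DataFrame, var: str, spec: ModelSpec
) -> tuple[np.ndarray, list[str], list[str] | None]:
    """Return (columns, names, levels-or-None) for one predictor."""
    s = data[var]
    if not _is_categorical(s):
        return np.asarray(s, dtype=float)[:, None], [var], None
    ref = spec.reference(var)
    known = LEVELS.get(var)
    present = list(pd.unique(s.astype(str)))
    if known:
        levels = [lv for lv in known if lv in present]
        extra = sorted(set(present) - set(known))
        levels += extra
    else:
        levels = sorted(present)
    if ref not in levels:
        ref = levels[0]
    nonref = [lv for lv in levels if lv != ref]
    arr = np.asarray(s.astype(str))
    if nonref:
        cols = np.column_stack([(arr == lv).astype(float) for lv in nonref])
    else:
        cols = np.empty((len(arr), 0))
    names = [f"{var}[{lv}]" for lv in nonref]
    return cols, names, nonref


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Build the fixed-effects design matrix (with leading intercept column).

    Returns ``(X, names)`` where ``names[0] == "intercept"``.
    """
    n = len(data)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    encoded: dict[str, tuple[np.ndarray, list[str]]] = {}
    for var in spec.fixed_effects:
        if var not in data.columns:
            raise KeyError(f"fixed effect {var!r} not a column")
        cols, nm, _ = _encode_main(data, var, spec)
        encoded[var] = (cols, nm)
        blocks.append(cols)
        names.extend(nm)
    for a, b in spec.interactions:
        ca, na = encoded[a]
        cb, nb = encoded[b]
        for i, nai in enumerate(na):
            for j, nbj in enumerate(nb):
                blocks.append((ca[:, i] * cb[:, j])[:, None])
                # continuous member keeps its bare name in the term label
                names.append(f"{nai}:{nbj}")
    X = np.hstack(blocks)
    return X, names


def evaluate_terms(
    frame: pd.DataFrame, names: Sequence[str]
) -> np.ndarray:
    """Evaluate named design terms on a (typically small) covariate frame.

    Term grammar mirrors :func:`build_design`: ``intercept``, bare continuous
    columns, ``var[level]`` indicators, and ``:``-joined products.  Used for
    prediction grids, which may not contain every level the fit saw.
    """

    def one(term: str) -> np.ndarray:
        if term == "intercept":
            return np.ones(len(frame))
        if "[" in term:
            var, level = term[:-1].split("[", 1)
            return (frame[var].astype(str) == level).to_numpy(dtype=float)
        return np.asarray(frame[term], dtype=float)

    cols = []
    for name in names:
        parts = name.split(":")
        col = one(parts[0])
        for p in parts[1:]:
            col = col * one(p)
        cols.append(col)
    return np.column_stack(cols)


def outcome_vector(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Extract the (optionally log-transformed) outcome."""
    y = np.asarray(data[spec.outcome], dtype=float)
    if spec.log_outcome:
        if np.any(y <= 0):
            raise ValueError("outcome must be strictly positive before logging")
        y = np.log(y)
    return y


def groups_vector(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    return np.asarray(data[spec.group])
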