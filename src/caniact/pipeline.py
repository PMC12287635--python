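"""End-to-end orchestration: simulate -> match -> link -> derive -> filter ->
DAG checks -> mixed-model inference -> flexible validation.

The run is driven by a single :class:`RunConfig`; one seed fans out into
per-stage generators (stable hashing of the stage name) so every stage is
individually reproducible and the whole run is byte-identical under a fixed
configuration.  The product is a machine-readable report carrying the
cleaning provenance, the DAG-derived adjustment sets and consistency tests,
selected model structures, aggregated coefficients, marginal means and the
flexible-model agreement summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dag as dag_mod
from .derive import (
    DEFAULT_HEALTH_RULES,
    HealthRuleSet,
    assign_breed_size,
    classify_visit_health,
    day_type_of,
    derive_weight_status,
    season_of,
)
from .design import ModelSpec
from .linkage import (
    FilterConfig,
    LinkedDataset,
    apply_filters,
    link_activity_to_visit,
    match_dogs,
    split_healthy,
)
from .lmm import (
    check_multicollinearity,
    estimate_marginal_means,
    resampled_inference,
    select_interactions,
)
from .flexible import compare_marginal_curves, fit_flexible_model
from .simulate import (
    DAYS_PER_YEAR,
    SimulationConfig,
    simulate_activity,
    simulate_cohort,
    simulate_visits,
    source_views,
    stage_rng,
)

__all__ = ["RunConfig", "run_pipeline", "prepare_linked_table", "packaged_dag_path", "DAG_NODE_COLUMNS"]


def packaged_dag_path() -> Path:
    """Path of the shipped activity DAG fixture."""
    return Path(resources.files("caniact.data") / "activity_dag.txt")


#: DAG node -> analysis column(s).  ``dog_age`` maps to both age predictors.
DAG_NODE_COLUMNS: dict[str, tuple[str, ...]] = {
    "active_minutes": ("active_minutes",),
    "dog_age": ("age_inv_sq", "age"),
    "breed_size": ("breed_size",),
    "weight_status": ("weight_status",),
    "sex": ("sex",),
    "neuter_status": ("neuter_status",),
    "owner_age": ("owner_age_band",),
    "location_type": ("location_type",),
    "climate": ("climate",),
    "season": ("season",),
    "day_type": ("day_type",),
    "latitude": ("latitude",),
    "unhealthy_diagnosis": ("unhealthy_flag",),
    "injury": ("injury",),
}

_DOG_EXPOSURES = ("dog_age", "breed_size", "weight_status", "sex", "neuter_status")
_ENV_EXPOSURES = ("season", "climate", "day_type", "owner_age", "location_type", "latitude")

_DOG_CANDIDATES = (
    ("breed_size", "age"),
    ("weight_status", "age"),
    ("neuter_status", "age"),
    ("owner_age_band", "age"),
    ("breed_size", "weight_status"),
    ("breed_size", "owner_age_band"),
    ("weight_status", "neuter_status"),
    ("neuter_status", "sex"),
)
_ENV_CANDIDATES = (
    ("season", "climate"),
    ("day_type", "season"),
    ("day_type", "location_type"),
    ("day_type", "owner_age_band"),
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; seeds are explicit."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    health_rules: HealthRuleSet = field(default_factory=lambda: DEFAULT_HEALTH_RULES)
    dag_path: str | None = None
    K: int = 50
    R: int = 1000
    alpha: float = 0.05
    healthy_only: bool = False
    bias_correction: bool = False
    flexible_validation: bool = True
    age_grid: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "sim" in raw:
            kwargs["sim"] = SimulationConfig.from_dict(raw.pop("sim"))
        if "filters" in raw:
            kwargs["filters"] = FilterConfig(**raw.pop("filters"))
        if "health_rules" in raw:
            kwargs["health_rules"] = HealthRuleSet.from_yaml(raw.pop("health_rules"))
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        kwargs.update(raw)
        if "age_grid" in kwargs:
            kwargs["age_grid"] = tuple(kwargs["age_grid"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# derive stage


def prepare_linked_table(
    linked: LinkedDataset,
    ehr_dogs: pd.DataFrame,
    visits: pd.DataFrame,
    rules: HealthRuleSet = DEFAULT_HEALTH_RULES,
    adult_age_years: float = 1.5,
) -> LinkedDataset:
    """Attach dog attributes and construct every derived analysis column.

    Adds: ages at activity and linked visit (fractional years), season and
    day type, visit weight status (from the linked visit's BCS), the per-dog
    breed-size category (mean BCS-corrected *adult* visit weights), the
    visit health classification and injury flag.  Dogs without any adult
    weight measurement cannot be sized and are dropped (logged).
    """
    ds = linked.copy()
    df = ds.rows
    attrs = ehr_dogs.set_index("dog_key")[
        ["birth_date", "sex", "owner_age_band", "location_type", "climate", "latitude"]
    ]
    df = df.join(attrs, on="dog_id")
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["age"] = (df["date"] - df["birth_date"]).dt.days / DAYS_PER_YEAR
    df["age_inv_sq"] = df["age"] ** -2.0
    df["age_at_visit"] = (df["visit_date"] - df["birth_date"]).dt.days / DAYS_PER_YEAR
    df["season"] = season_of(df["date"])
    df["day_type"] = day_type_of(df["date"])
    df["neuter_status"] = np.where(
        df["neutered_at_visit"].astype(bool), "neutered", "intact"
    )
    df["weight_status"] = df["bcs5"].astype(int).map(
        lambda b: derive_weight_status(b)
    )

    # visit health classification (per distinct visit, mapped onto rows)
    vis = visits.copy()
    if "visit_id" not in vis.columns:
        vis["visit_id"] = np.arange(len(vis))
    diag_lists = vis["diagnoses"].fillna("").map(
        lambda s: [c for c in str(s).split(";") if c]
    )
    cls = [
        classify_visit_health(d, r, rules)
        for d, r in zip(diag_lists, vis["visit_reason"])
    ]
    vis_cls = pd.DataFrame(
        {
            "visit_id": vis["visit_id"],
            "health_status": [c[0] for c in cls],
            "injury": [c[1] for c in cls],
        }
    ).set_index("visit_id")
    df = df.join(vis_cls, on="visit_id")
    df["unhealthy_flag"] = df["health_status"] == "unhealthy"

    # breed size from adult visit weights, per dog over ALL its visits
    birth = ehr_dogs.set_index("dog_key")["birth_date"]
    vage = (
        pd.to_datetime(vis["visit_date"])
        - pd.to_datetime(vis["dog_key"].map(birth))
    ).dt.days / DAYS_PER_YEAR
    adult = vis[vage > adult_age_years]
    size_by_dog = (
        adult.groupby("dog_key")[["weight_kg", "bcs5"]]
        .apply(
            lambda g: assign_breed_size(
                list(zip(g["weight_kg"], g["bcs5"].astype(int)))
            )
        )
        .rename("breed_size")
    )
    df["breed_size"] = df["dog_id"].map(size_by_dog)
    rows_in, dogs_in = len(df), df["dog_id"].nunique()
    df = df[df["breed_size"].notna()]
    ds.rows = df.reset_index(drop=True)
    ds.log_stage("breed-size-assignable", rows_in, len(df), dogs_in, df["dog_id"].nunique())
    return ds


# ---------------------------------------------------------------------------
# DAG checks


def _node_frame(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One randomly chosen row per dog, columns renamed to DAG node names.

    Collapsing to one row per dog keeps the conditional-independence tests
    calibrated: repeated rows of the same dog are not independent draws.
    """
    rng = stage_rng(seed, "dag-test-rows")
    picks = (
        table.groupby("dog_id", sort=True)
        .sample(n=1, random_state=int(rng.integers(2**31 - 1)))
        .reset_index(drop=True)
    )
    out = pd.DataFrame(index=picks.index)
    for node, cols in DAG_NODE_COLUMNS.items():
        col = cols[-1] if node == "dog_age" else cols[0]
        if col in picks.columns:
            s = picks[col]
            if node == "active_minutes":
                s = np.log(np.asarray(s, dtype=float))
            out[node] = s
    return out


def dag_consistency_report(
    dag: dag_mod.CausalDag, table: pd.DataFrame, alpha: float, seed: int
) -> dict:
    claims = dag_mod.implied_independences(dag, observed_only=True)
    frame = _node_frame(table, seed)
    testable = [
        c for c in claims if {c.x, c.y, *c.given} <= set(frame.columns)
    ]
    tested = dag_mod.test_independences(testable, frame, alpha=alpha)
    return {
        "n_claims": len(claims),
        "n_tested": len(tested),
        "n_rejected": int(sum(bool(c.rejected) for c in tested)),
        "alpha": alpha,
        "claims": [
            {
                "x": c.x,
                "y": c.y,
                "given": sorted(c.given),
                "p_value": c.p_value,
                "rejected": c.rejected,
                "warning": c.warning,
            }
            for c in tested
        ],
    }


def _adjustment_columns(dag: dag_mod.CausalDag, exposures: tuple[str, ...]) -> tuple[list[str], dict]:
    """Union of each exposure's first minimal backdoor set (other exposures
    excluded — they are already in the model)."""
    detail: dict = {}
    union: set[str] = set()
    for exp in exposures:
        sets = dag_mod.minimal_adjustment_sets(dag, exp, "active_minutes")
        detail[exp] = [sorted(s.members) for s in sets]
        if sets:
            union |= set(sets[0].members)
    extra = sorted(union - set(exposures))
    cols: list[str] = []
    for node in extra:
        cols.extend(DAG_NODE_COLUMNS.get(node, ()))
    return cols, detail


# ---------------------------------------------------------------------------
# model stage helpers


def _dog_model_spec(adjust_cols: list[str]) -> ModelSpec:
    fixed = ["age_inv_sq", "age", "breed_size", "weight_status", "sex", "neuter_status"]
    fixed += [c for c in adjust_cols if c not in fixed]
    return ModelSpec(fixed_effects=tuple(fixed))


def _env_model_spec() -> ModelSpec:
    return ModelSpec(
        fixed_effects=(
            "latitude",
            "climate",
            "season",
            "day_type",
            "location_type",
            "owner_age_band",
        )
    )


def _fit_block(
    table: pd.DataFrame,
    base: ModelSpec,
    candidates,
    cfg: RunConfig,
    label: str,
    focal_categoricals: tuple[str, ...],
) -> dict:
    spec = select_interactions(table, base, candidates, alpha=cfg.alpha)
    agg = resampled_inference(
        table,
        spec,
        K=cfg.K,
        R=cfg.R,
        seed=int(stage_rng(cfg.seed, f"resample-{label}").integers(2**31 - 1)),
    )
    marginals = {}
    for focal in focal_categoricals:
        if focal not in spec.fixed_effects:
            continue
        grid = sorted(map(str, pd.unique(table[focal].astype(str))))
        mm = estimate_marginal_means(
            agg, table, focal, grid, spec, bias_correction=cfg.bias_correction
        )
        marginals[focal] = mm.table.to_dict(orient="list")
    if "age" in spec.fixed_effects:
        mm = estimate_marginal_means(
            agg, table, "age", list(cfg.age_grid), spec,
            bias_correction=cfg.bias_correction,
        )
        marginals["age"] = mm.table.to_dict(orient="list")
    return {
        "selected_interactions": [list(p) for p in spec.interactions],
        "coefficients": agg.to_frame().round(6).to_dict(orient="index"),
        "mean_var_random": agg.mean_var_random,
        "mean_var_residual": agg.mean_var_residual,
        "n_skipped": agg.n_skipped,
        "marginal_means": marginals,
        "_agg": agg,
        "_spec": spec,
    }


# ---------------------------------------------------------------------------
# the run


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Execute all stages; returns (and optionally writes) the run report.

    A stage failure marks the stage failed in the report and skips the
    stages downstream of it.
    """
    cfg = config
    report: dict = {"seed": cfg.seed, "stages": {}, "failed_stage": None}
    state: dict = {}
    order = [
        ("simulate", _stage_simulate),
        ("match", _stage_match),
        ("link-derive-filter", _stage_link),
        ("dag-checks", _stage_dag),
        ("multicollinearity", _stage_collinearity),
        ("models", _stage_models),
        ("flexible-validation", _stage_flexible),
    ]
    for name, fn in order:
        if name == "flexible-validation" and not cfg.flexible_validation:
            report["stages"][name] = {"status": "skipped"}
            continue
        try:
            fn(cfg, state, report)
            report["stages"].setdefault(name, {})["status"] = "ok"
        except Exception as exc:  # stage failure: record, stop downstream
            report["stages"].setdefault(name, {})["status"] = "failed"
            report["stages"][name]["error"] = f"{type(exc).__name__}: {exc}"
            report["failed_stage"] = name
            break
    if out_dir is not None:
        _write_outputs(report, state, Path(out_dir))
    return report


def _stage_simulate(cfg: RunConfig, state: dict, report: dict) -> None:
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    dogs, truth = simulate_cohort(sim)
    visits = simulate_visits(dogs, sim)
    activity = simulate_activity(dogs, truth, sim)
    activity_dogs, ehr_dogs = source_views(dogs, sim)
    state.update(
        dogs=dogs, truth=truth, visits=visits, activity=activity,
        activity_dogs=activity_dogs, ehr_dogs=ehr_dogs, sim=sim,
    )
    report["stages"]["simulate"] = {
        "n_dogs": len(dogs),
        "n_visits": len(visits),
        "n_activity_records": len(activity),
    }


def _stage_match(cfg: RunConfig, state: dict, report: dict) -> None:
    res = match_dogs(state["activity_dogs"], state["ehr_dogs"])
    state["match"] = res
    report["stages"]["match"] = {
        "n_matched": len(res.mapping),
        "n_unmatched_activity": len(res.unmatched_activity),
        "n_unmatched_ehr": len(res.unmatched_ehr),
        "n_ambiguous_keys": len(res.ambiguous),
    }


def _stage_link(cfg: RunConfig, state: dict, report: dict) -> None:
    linked = link_activity_to_visit(
        state["activity"],
        state["visits"],
        state["match"].mapping,
        max_link_days=cfg.filters.max_link_days,
    )
    linked = prepare_linked_table(
        linked, state["ehr_dogs"], state["visits"], cfg.health_rules,
        adult_age_years=cfg.filters.min_age_years,
    )
    linked = apply_filters(linked, cfg.filters)
    linked = split_healthy(linked)
    state["linked"] = linked
    report["stages"]["link-derive-filter"] = {
        "provenance": linked.provenance,
        "rows_all_visits": int(linked.rows["in_all_visits"].sum()),
        "rows_healthy_visits": int(linked.rows["in_healthy_visits"].sum()),
        "dogs_all_visits": int(linked.rows["dog_id"].nunique()),
        "dogs_healthy_visits": int(
            linked.rows.loc[linked.rows["in_healthy_visits"], "dog_id"].nunique()
        ),
    }


def _stage_dag(cfg: RunConfig, state: dict, report: dict) -> None:
    path = cfg.dag_path or packaged_dag_path()
    dag = dag_mod.load_dag(path)
    table = state["linked"].rows
    adjust_cols, detail = _adjustment_columns(dag, _DOG_EXPOSURES)
    env_detail = {
        e: [sorted(s.members) for s in dag_mod.minimal_adjustment_sets(dag, e, "active_minutes")]
        for e in _ENV_EXPOSURES
    }
    state["dag"] = dag
    state["adjust_cols"] = adjust_cols
    report["stages"]["dag-checks"] = {
        "dog_attribute_adjustment_columns": adjust_cols,
        "dog_attribute_minimal_sets": detail,
        "environmental_minimal_sets": env_detail,
        "independence_tests": dag_consistency_report(dag, table, cfg.alpha, cfg.seed),
    }


def _stage_collinearity(cfg: RunConfig, state: dict, report: dict) -> None:
    table = state["linked"].rows
    preds = [
        "age", "breed_size", "weight_status", "sex", "neuter_status",
        "owner_age_band", "location_type", "climate", "latitude",
    ]
    rep = check_multicollinearity(table, preds)
    report["stages"]["multicollinearity"] = {
        "flagged": [[a, b, round(v, 4)] for a, b, v in rep.flagged],
        "degenerate": rep.degenerate,
    }


def _stage_models(cfg: RunConfig, state: dict, report: dict) -> None:
    linked = state["linked"]
    all_rows = linked.rows[linked.rows["in_all_visits"]]
    healthy_rows = linked.healthy_rows()
    dog_base = _dog_model_spec(state.get("adjust_cols", []))
    out: dict = {}
    datasets = [("all_visits", all_rows)]
    if len(healthy_rows):
        datasets.append(("healthy_visits", healthy_rows))
    if cfg.healthy_only:
        datasets = [d for d in datasets if d[0] == "healthy_visits"]
    for ds_name, rows in datasets:
        out[ds_name] = {
            "dog_attributes": _fit_block(
                rows, dog_base, _DOG_CANDIDATES, cfg, f"dog-{ds_name}",
                ("breed_size", "weight_status", "sex", "neuter_status"),
            )
        }
    # environmental model: no confounders beyond the model variables, so
    # the all-visits dataset alone is analysed
    if not cfg.healthy_only:
        out["all_visits"]["environmental"] = _fit_block(
            all_rows, _env_model_spec(), _ENV_CANDIDATES, cfg, "env-all",
            ("climate", "season", "day_type", "owner_age_band", "location_type"),
        )
    state["models"] = out
    report["stages"]["models"] = {
        ds: {
            m: {k: v for k, v in block.items() if not k.startswith("_")}
            for m, block in models.items()
        }
        for ds, models in out.items()
    }


def _stage_flexible(cfg: RunConfig, state: dict, report: dict) -> None:
    linked = state["linked"]
    rows = linked.rows[linked.rows["in_all_visits"]]
    predictors = [
        "age", "breed_size", "weight_status", "sex", "neuter_status",
        "owner_age_band", "location_type", "climate", "latitude",
        "season", "day_type",
    ]
    model = fit_flexible_model(
        rows, predictors, group="dog_id",
        seed=int(stage_rng(cfg.seed, "flexible").integers(2**31 - 1)),
    )
    dog_block = state["models"]["all_visits"]["dog_attributes"]
    agg, spec = dog_block["_agg"], dog_block["_spec"]
    comparisons = {}
    grids = {"age": list(cfg.age_grid), "breed_size": None, "sex": None}
    for focal, grid in grids.items():
        if focal not in spec.fixed_effects:
            continue
        if grid is None:
            grid = sorted(map(str, pd.unique(rows[focal].astype(str))))
        mm = estimate_marginal_means(
            agg, rows, focal, grid, spec, bias_correction=cfg.bias_correction
        )
        comp = compare_marginal_curves(mm, model, rows, focal, grid)
        comparisons[focal] = {
            "grid": [str(g) for g in comp.grid],
            "lmm": [round(float(v), 3) for v in comp.lmm_predictions],
            "flexible": [round(float(v), 3) for v in comp.flexible_predictions],
            "max_abs_diff": round(comp.max_abs_diff, 3),
            "rank_correlation": None
            if np.isnan(comp.rank_correlation)
            else round(comp.rank_correlation, 3),
        }
    report["stages"]["flexible-validation"] = {
        "backend": model.backend,
        "comparisons": comparisons,
    }


# ---------------------------------------------------------------------------
# outputs


def _write_outputs(report: dict, state: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    if "linked" in state:
        with open(out_dir / "flow.json", "w") as fh:
            json.dump(state["linked"].provenance, fh, indent=1)
    for ds_name, models in state.get("models", {}).items():
        for m_name, block in models.items():
            block["_agg"].to_frame().to_csv(
                out_dir / f"coefficients_{ds_name}_{m_name}.csv"
            )
    lines = ["# Pipeline run report", ""]
    for name, st in report["stages"].items():
        status = st.get("status", "?") if isinstance(st, dict) else "?"
        lines.append(f"- **{name}**: {status}")
    with open(out_dir / "report.md", "w") as fh:
        fh.write("\n".join(lines) + "\n")
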