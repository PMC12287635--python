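"""Linear mixed-model inference for log active minutes.

The model throughout is a Gaussian linear mixed model on log-transformed
daily active minutes with fixed effects from a :class:`~caniact.design.ModelSpec`
and a single random intercept per dog:

    log A_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, tau2),  e_ij ~ N(0, sigma2)

Because the headline inference procedure refits the model on hundreds to
thousands of per-dog subsamples, the fitter is a purpose-built profiled
(RE)ML routine for the random-intercept case: for a given variance ratio
lambda = tau2/sigma2 the GLS solution and profiled variance have closed
forms from per-group sufficient statistics, leaving a one-dimensional
likelihood maximisation.  It matches statsmodels' general-purpose ``MixedLM``
to numerical precision (see the test suite) at a small fraction of the cost.

On top of the fitter sit the analysis steps: multicollinearity screening,
AIC/likelihood-ratio interaction selection, the repeated-subsample
aggregation (mean coefficients, mean CI endpoints, p = fraction of
repetitions whose confidence interval includes zero), response-scale
marginal means, and the grouped k-fold consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import (
    LEVELS,
    ModelSpec,
    build_design,
    evaluate_terms,
    groups_vector,
    outcome_vector,
)

__all__ = [
    "Coefficient",
    "SingleFit",
    "AggregatedInference",
    "MarginalMeansTable",
    "fit_lmm",
    "aggregate_intervals",
    "check_multicollinearity",
    "select_interactions",
    "resampled_inference",
    "estimate_marginal_means",
    "grouped_kfold_consistency",
]

Z95 = 1.959963984540054


class Coefficient(NamedTuple):
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class SingleFit:
    """One (restricted) maximum-likelihood fit of the random-intercept LMM."""

    coefficients: dict[str, Coefficient]
    names: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray
    var_random: float
    var_residual: float
    aic: float
    loglik_reml: float
    loglik_ml: float
    r2_conditional: float
    rmse: float
    random_effect_share: float
    n_obs: int
    n_groups: int
    singular: bool
    converged: bool = True

    @property
    def n_params(self) -> int:
        return len(self.names)


class LmmError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# core profiled fitter


class _Suff(NamedTuple):
    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    S: np.ndarray  # per-group column sums of X (G x p)
    t: np.ndarray  # per-group sums of y (G,)
    counts: np.ndarray
    n: int
    p: int


def _sufficient_stats(X: np.ndarray, y: np.ndarray, codes: np.ndarray, G: int) -> _Suff:
    n, p = X.shape
    counts = np.bincount(codes, minlength=G).astype(float)
    S = np.empty((G, p))
    for j in range(p):
        S[:, j] = np.bincount(codes, weights=X[:, j], minlength=G)
    t = np.bincount(codes, weights=y, minlength=G)
    return _Suff(X.T @ X, X.T @ y, float(y @ y), S, t, counts, n, p)


def _profile(suff: _Suff, lam: float):
    """GLS pieces at variance ratio lam (V ∝ I + lam * Z Z')."""
    c = lam / (1.0 + suff.counts * lam)
    A = suff.XtX - (suff.S.T * c) @ suff.S
    b = suff.Xty - suff.S.T @ (c * suff.t)
    beta = np.linalg.solve(A, b)
    q = suff.yty - (c * suff.t) @ suff.t
    rss = max(q - beta @ b, 1e-300)
    logdet_v = float(np.log1p(suff.counts * lam).sum())
    return A, beta, rss, logdet_v


_LOG2PI = np.log(2.0 * np.pi)


def _neg2_reml(suff: _Suff, lam: float) -> float:
    A, _, rss, logdet_v = _profile(suff, lam)
    m = suff.n - suff.p
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return m * np.log(rss / m) + logdet_v + logdet_a + m * (1.0 + _LOG2PI)


def _neg2_ml(suff: _Suff, lam: float) -> float:
    _, _, rss, logdet_v = _profile(suff, lam)
    n = suff.n
    return n * np.log(rss / n) + logdet_v + n * (1.0 + _LOG2PI)


_LAM_LO, _LAM_HI = 1e-10, 1e6


def _optimise(suff: _Suff, crit) -> float:
    res = optimize.minimize_scalar(
        lambda th: crit(suff, np.exp(th)),
        bounds=(np.log(_LAM_LO), np.log(_LAM_HI)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    # boundary case: variance ratio indistinguishable from zero
    if crit(suff, 0.0) <= res.fun:
        lam = 0.0
    return lam


def _fit_arrays(
    X: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    G: int,
    names: Sequence[str],
) -> SingleFit:
    suff = _sufficient_stats(X, y, codes, G)
    if G < 2:
        raise LmmError("need at least two dogs (grouping levels)")
    if suff.n <= suff.p + 2:
        raise LmmError(f"too few rows ({suff.n}) for {suff.p} fixed effects")
    try:
        lam = _optimise(suff, _neg2_reml)
        A, beta, rss, _ = _profile(suff, lam)
        m = suff.n - suff.p
        sigma2 = rss / m
        tau2 = lam * sigma2
        cov = sigma2 * np.linalg.inv(A)
        lam_ml = _optimise(suff, _neg2_ml)
        ll_ml = -0.5 * _neg2_ml(suff, lam_ml)
        ll_reml = -0.5 * _neg2_reml(suff, lam)
    except np.linalg.LinAlgError as exc:
        raise LmmError(
            f"singular design; non-convergence for terms {list(names)}"
        ) from exc
    aic = -2.0 * ll_ml + 2.0 * (suff.p + 2)

    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    coefs = {
        nm: Coefficient(
            float(b), float(s), float(b - Z95 * s), float(b + Z95 * s), float(pv)
        )
        for nm, b, s, pv in zip(names, beta, se, pvals)
    }

    # conditional diagnostics: BLUPs, fixed-effect variance, Nakagawa-style R2
    fitted_fixed = X @ beta
    resid = y - fitted_fixed
    r_sum = np.bincount(codes, weights=resid, minlength=G)
    blup = lam * r_sum / (1.0 + suff.counts * lam)
    cond_resid = resid - blup[codes]
    rmse = float(np.sqrt(np.mean(cond_resid**2)))
    var_fixed = float(np.var(fitted_fixed))
    total = var_fixed + tau2 + sigma2
    r2c = (var_fixed + tau2) / total if total > 0 else np.nan
    share = tau2 / total if total > 0 else np.nan

    return SingleFit(
        coefficients=coefs,
        names=list(names),
        beta=beta,
        cov_beta=cov,
        var_random=float(tau2),
        var_residual=float(sigma2),
        aic=float(aic),
        loglik_reml=float(ll_reml),
        loglik_ml=float(ll_ml),
        r2_conditional=float(r2c),
        rmse=rmse,
        random_effect_share=float(share),
        n_obs=suff.n,
        n_groups=G,
        singular=bool(lam <= _LAM_LO * 10),
    )


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> SingleFit:
    """REML fit of the random-intercept LMM described by ``spec``.

    Returns Wald 95% confidence intervals per term, AIC from a maximum-
    likelihood refit of the variance ratio (the form comparable across
    fixed-effect structures), conditional pseudo-R², the log-scale RMSE of
    conditional residuals, and the variance components.  A fit whose random
    intercept variance collapses to zero is returned with ``singular=True``
    rather than raising.
    """
    X, names = build_design(data, spec)
    y = outcome_vector(data, spec)
    codes, uniques = pd.factorize(groups_vector(data, spec))
    return _fit_arrays(X, y, codes, len(uniques), names)


# ---------------------------------------------------------------------------
# multicollinearity screen


@dataclass
class MulticollinearityReport:
    matrix: pd.DataFrame
    flagged: list[tuple[str, str, float]]
    degenerate: list[str]
    threshold: float = 0.5


def check_multicollinearity(
    data: pd.DataFrame, predictors: Sequence[str], threshold: float = 0.5
) -> MulticollinearityReport:
    """Pairwise association matrix over candidate predictors.

    |Pearson r| for continuous pairs, Cramér's V for categorical pairs, and
    the multiple-correlation coefficient (square root of the OLS R² of the
    continuous variable on indicator contrasts) for mixed pairs.  Cells above
    ``threshold`` are flagged; constant columns are marked degenerate and
    their cells left NaN.
    """
    cols = list(predictors)
    for c in cols:
        if c not in data.columns:
            raise KeyError(f"predictor {c!r} not a column")
    is_cat = {
        c: not pd.api.types.is_numeric_dtype(data[c])
        or isinstance(data[c].dtype, pd.CategoricalDtype)
        for c in cols
    }
    degenerate = [c for c in cols if data[c].nunique(dropna=True) < 2]
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    flagged: list[tuple[str, str, float]] = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if a in degenerate or b in degenerate:
                val = np.nan
            elif not is_cat[a] and not is_cat[b]:
                val = abs(float(np.corrcoef(data[a], data[b])[0, 1]))
            elif is_cat[a] and is_cat[b]:
                tab = pd.crosstab(data[a], data[b]).to_numpy()
                val = float(
                    stats.contingency.association(tab, method="cramer")
                )
            else:
                cat, cont = (a, b) if is_cat[a] else (b, a)
                d = pd.get_dummies(data[cat].astype(str), drop_first=True, dtype=float)
                zmat = np.hstack([np.ones((len(data), 1)), d.to_numpy()])
                yv = np.asarray(data[cont], dtype=float)
                coef, *_ = np.linalg.lstsq(zmat, yv, rcond=None)
                fit = zmat @ coef
                sst = float(((yv - yv.mean()) ** 2).sum())
                val = float(np.sqrt(max(1.0 - ((yv - fit) ** 2).sum() / sst, 0.0))) if sst > 0 else np.nan
            mat.loc[a, b] = mat.loc[b, a] = val
            if np.isfinite(val) and val > threshold:
                flagged.append((a, b, val))
    return MulticollinearityReport(mat, flagged, degenerate, threshold)


# ---------------------------------------------------------------------------
# interaction selection


def select_interactions(
    data: pd.DataFrame,
    base: ModelSpec,
    candidates: Sequence[tuple[str, str]],
    alpha: float = 0.05,
) -> ModelSpec:
    """Forward selection of interaction terms by likelihood ratio + AIC.

    Candidates are evaluated one at a time, in the listed order, against the
    current specification using maximum-likelihood refits; a candidate is
    kept iff the likelihood-ratio test is significant at ``alpha`` *and* the
    AIC decreases.
    """
    spec = base
    for pair in candidates:
        for m in pair:
            if m not in spec.fixed_effects:
                raise ValueError(f"candidate {pair} references absent main effect {m!r}")
        without = fit_lmm(data, spec)
        trial = spec.with_interaction(tuple(pair))
        try:
            with_ = fit_lmm(data, trial)
        except LmmError:
            # empty/collinear interaction cells: candidate not estimable
            continue
        df = with_.n_params - without.n_params
        lr = 2.0 * (with_.loglik_ml - without.loglik_ml)
        p = float(stats.chi2.sf(max(lr, 0.0), df)) if df > 0 else 1.0
        if p < alpha and with_.aic < without.aic:
            spec = trial
    return spec


# ---------------------------------------------------------------------------
# repeated-subsample aggregation


class AggregatedCoefficient(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float
    p: float


def aggregate_intervals(
    estimates: np.ndarray, lows: np.ndarray, highs: np.ndarray
) -> AggregatedCoefficient:
    """Aggregate one term over repetitions: mean estimate, mean CI endpoints,
    p = fraction of repetitions whose interval includes zero."""
    est = np.asarray(estimates, dtype=float)
    lo = np.asarray(lows, dtype=float)
    hi = np.asarray(highs, dtype=float)
    return AggregatedCoefficient(
        float(est.mean()),
        float(lo.mean()),
        float(hi.mean()),
        float(((lo <= 0.0) & (hi >= 0.0)).mean()),
    )


@dataclass
class AggregatedInference:
    """Aggregate of R repeated-subsample LMM fits.

    Per term: the mean estimate, the means of the per-fit 95% CI endpoints,
    and p = fraction of repetitions whose CI includes zero.
    """

    terms: dict[str, AggregatedCoefficient]
    R: int
    K: int
    seed: int
    n_skipped: int
    mean_var_random: float
    mean_var_residual: float
    per_repetition: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"term": k, "estimate": v.estimate, "ci_low": v.ci_low,
                 "ci_high": v.ci_high, "p": v.p}
                for k, v in self.terms.items()
            ]
        ).set_index("term")


def resampled_inference(
    data: pd.DataFrame,
    spec: ModelSpec,
    K: int = 50,
    R: int = 1000,
    seed: int = 0,
) -> AggregatedInference:
    """Repeated per-dog subsampling inference.

    Each repetition draws ``K`` activity records per dog without replacement
    (dogs with fewer than ``K`` records contribute all of them), fits the
    LMM, and collects coefficients and CI endpoints.  Repetitions whose fit
    fails are skipped and counted; more than 10% skipped aborts the run.
    Fully reproducible from ``seed``.
    """
    if K < 1 or R < 1:
        raise ValueError("K and R must be >= 1")
    X, names = build_design(data, spec)
    y = outcome_vector(data, spec)
    codes, uniques = pd.factorize(groups_vector(data, spec))
    G = len(uniques)
    order = np.argsort(codes, kind="stable")
    bounds = np.searchsorted(codes[order], np.arange(G + 1))
    group_rows = [order[bounds[g] : bounds[g + 1]] for g in range(G)]

    rng = np.random.default_rng(seed)
    p = X.shape[1]
    est = np.empty((R, p))
    lo = np.empty((R, p))
    hi = np.empty((R, p))
    vr = np.empty(R)
    ve = np.empty(R)
    ok = np.zeros(R, dtype=bool)
    for r in range(R):
        take = [
            rows if len(rows) <= K else rng.choice(rows, size=K, replace=False)
            for rows in group_rows
        ]
        idx = np.concatenate(take)
        try:
            fit = _fit_arrays(X[idx], y[idx], codes[idx], G, names)
        except LmmError:
            continue
        est[r] = fit.beta
        se = np.sqrt(np.maximum(np.diag(fit.cov_beta), 0.0))
        lo[r] = fit.beta - Z95 * se
        hi[r] = fit.beta + Z95 * se
        vr[r], ve[r] = fit.var_random, fit.var_residual
        ok[r] = True

    n_skipped = int(R - ok.sum())
    if n_skipped > 0.1 * R:
        raise LmmError(f"{n_skipped}/{R} repetitions failed to fit")
    est, lo, hi, vr, ve = est[ok], lo[ok], hi[ok], vr[ok], ve[ok]
    terms = {
        nm: aggregate_intervals(est[:, j], lo[:, j], hi[:, j])
        for j, nm in enumerate(names)
    }
    return AggregatedInference(
        terms=terms,
        R=R,
        K=K,
        seed=seed,
        n_skipped=n_skipped,
        mean_var_random=float(vr.mean()),
        mean_var_residual=float(ve.mean()),
        per_repetition=pd.DataFrame(est, columns=names),
    )


# ---------------------------------------------------------------------------
# marginal means


@dataclass
class MarginalMeansTable:
    focal: str
    table: pd.DataFrame  # columns: level, prediction, ci_low, ci_high
    bias_corrected: bool


_DERIVED_PAIRS = {"age": ("age_inv_sq", lambda a: a**-2.0), }


def _reference_row(
    data: pd.DataFrame, spec: ModelSpec, grid_len: int
) -> pd.DataFrame:
    """Reference grid: categoricals at reference level, continuous at means."""
    row: dict[str, object] = {}
    for var in spec.fixed_effects:
        s = data[var]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            row[var] = float(np.mean(s))
        else:
            row[var] = spec.reference(var)
    return pd.DataFrame({k: [v] * grid_len for k, v in row.items()})


def estimate_marginal_means(
    result: "SingleFit | AggregatedInference",
    data: pd.DataFrame,
    focal: str,
    grid: Sequence,
    spec: ModelSpec,
    bias_correction: bool = False,
) -> MarginalMeansTable:
    """Predicted active minutes by focal level on the response scale.

    Other categoricals sit at their reference levels and continuous
    predictors at their data means; the random effect is zero.  Predictions
    are ``exp`` of the log-scale linear predictor; with ``bias_correction``
    they are multiplied by ``exp((tau2 + sigma2)/2)`` (log-normal mean
    correction, off by default).

    Intervals: delta-method Wald for a single fit; the 2.5/97.5 percentiles
    of per-repetition predictions for an aggregated result.
    """
    if focal not in spec.fixed_effects:
        raise ValueError(f"focal {focal!r} is not in the model")
    grid = list(grid)
    frame = _reference_row(data, spec, len(grid))
    s = data[focal]
    focal_cat = not pd.api.types.is_numeric_dtype(s) or isinstance(
        s.dtype, pd.CategoricalDtype
    )
    if focal_cat:
        known = set(LEVELS.get(focal, [])) | set(map(str, pd.unique(s)))
        bad = [g for g in grid if str(g) not in known]
        if bad:
            raise ValueError(f"grid levels absent from model: {bad}")
    frame[focal] = grid
    if focal in _DERIVED_PAIRS:
        derived, fn = _DERIVED_PAIRS[focal]
        if derived in frame.columns:
            frame[derived] = [fn(v) for v in frame[focal]]
    names = (
        list(result.terms)
        if isinstance(result, AggregatedInference)
        else list(result.names)
    )
    X = evaluate_terms(frame, names)

    if isinstance(result, AggregatedInference):
        beta = np.array([result.terms[nm].estimate for nm in names])
        lp = X @ beta
        reps = result.per_repetition[names].to_numpy()
        lp_reps = reps @ X.T  # R x grid
        lo = np.percentile(lp_reps, 2.5, axis=0)
        hi = np.percentile(lp_reps, 97.5, axis=0)
        corr = (
            0.5 * (result.mean_var_random + result.mean_var_residual)
            if bias_correction
            else 0.0
        )
    else:
        beta = np.array([result.coefficients[nm].estimate for nm in names])
        lp = X @ beta
        var = np.einsum("ij,jk,ik->i", X, result.cov_beta, X)
        half = Z95 * np.sqrt(np.maximum(var, 0.0))
        lo, hi = lp - half, lp + half
        corr = (
            0.5 * (result.var_random + result.var_residual)
            if bias_correction
            else 0.0
        )
    table = pd.DataFrame(
        {
            "level": grid,
            "prediction": np.exp(lp + corr),
            "ci_low": np.exp(lo + corr),
            "ci_high": np.exp(hi + corr),
        }
    )
    return MarginalMeansTable(focal=focal, table=table, bias_corrected=bias_correction)


# ---------------------------------------------------------------------------
# grouped k-fold consistency


@dataclass
class KFoldConsistency:
    per_fold: pd.DataFrame  # fold x (coefficients + r2 + rmse)
    sd: pd.Series
    degenerate: bool


def grouped_kfold_consistency(
    data: pd.DataFrame,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
) -> KFoldConsistency:
    """Fit the model on k dog-grouped partitions and report spread.

    Dogs are shuffled and split into ``k`` near-equal groups; all records of
    a dog land in the same fold.  Per-fold coefficients, conditional R² and
    RMSE are returned with their across-fold standard deviations.  ``k=1``
    yields the degenerate single fit with undefined SDs.
    """
    dogs = pd.unique(groups_vector(data, spec))
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(dogs) < k:
        raise ValueError(f"fewer dogs ({len(dogs)}) than folds ({k})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dogs))
    folds = np.array_split(perm, k)
    rows = []
    for fi, fold in enumerate(folds):
        sub = data[data[spec.group].isin(dogs[fold])]
        fit = fit_lmm(sub, spec)
        row = {nm: c.estimate for nm, c in fit.coefficients.items()}
        row["r2"] = fit.r2_conditional
        row["rmse"] = fit.rmse
        rows.append(pd.Series(row, name=fi))
    per_fold = pd.DataFrame(rows)
    sd = per_fold.std(ddof=1) if k > 1 else per_fold.iloc[0] * np.nan
    return KFoldConsistency(per_fold=per_fold, sd=sd, degenerate=k == 1)
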