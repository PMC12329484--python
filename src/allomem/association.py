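"""White-matter association analysis.

Per-trial scores are aggregated to subject level (failed trials excluded),
then each tract x measure (FA or MD) is modeled separately: the tract
measure is the response, behavioral and nuisance covariates are candidate
fixed effects, and a random intercept across participants absorbs
between-subject level differences (two hemispheres per subject for
bilateral tracts).  Fits use maximum likelihood (not REML) so models with
different fixed effects are AIC-comparable; fixed effects are chosen by
greedy forward selection on AIC.  Significance of the selected terms is
assessed jointly across all models with a Benjamini-Hochberg correction
whose denominator is the total number of candidate explanatory variables
across all models, and collinearity is checked with variance inflation
factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

BEHAVIORAL_TERMS = (
    "mean_pattern_accuracy",
    "mean_environmental_geometry",
    "mean_object_identity",
    "objects_association_rate",
    "objects_room_rate",
)
NUISANCE_TERMS = ("dropout", "pvf", "age", "in_scanner")


@dataclass
class AssociationConfig:
    """Candidate terms and inference settings for the mixed-model stage."""

    behavioral_terms: tuple[str, ...] = BEHAVIORAL_TERMS
    nuisance_terms: tuple[str, ...] = NUISANCE_TERMS
    include_hemisphere: bool = True     # for bilateral tracts only
    standardize: bool = True            # z-score behavioral predictors
    q: float = 0.05                     # FDR level
    df_method: str = "residual"         # t-test df: n_obs - n_fixed_params


@dataclass
class ModelResult:
    """One fitted mixed model's reporting surface."""

    model_id: str
    terms: pd.DataFrame          # term, estimate, se, t, p (intercept included)
    aic: float
    loglik: float
    n_obs: int
    n_params: int
    vif: dict[str, float] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)
    candidates: list[str] = field(default_factory=list)
    converged: bool = True


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_scores(scores: pd.DataFrame,
                     outcomes: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Subject-level behavioral summary over non-failed trials.

    ``scores`` is the per-trial score table (one row per trial with
    ``failed`` flags applied).  Failed trials would only add noise, so the
    allocentric means cover non-failed trials only; the failed count is
    kept.  A subject whose trials all failed gets missing means.
    """
    if scores.empty:
        raise InvalidInputError("empty score table: nothing to aggregate")
    rows = []
    for sid, grp in scores.groupby("subject_id", sort=True):
        ok = grp[~grp["failed"].astype(bool)]
        row = {
            "subject_id": sid,
            "n_trials": int(len(grp)),
            "n_failed": int(grp["failed"].astype(bool).sum()),
            "mean_pattern_accuracy": float(ok["pattern_accuracy"].mean())
            if len(ok) else np.nan,
            "mean_environmental_geometry":
                float(ok["environmental_geometry"].mean()) if len(ok) else np.nan,
            "mean_object_identity": float(ok["object_identity"].mean())
            if len(ok) else np.nan,
        }
        rows.append(row)
    out = pd.DataFrame(rows)
    if outcomes is not None and not outcomes.empty:
        rates = outcomes.groupby("subject_id", sort=True).agg(
            objects_association_rate=("objects_association", "mean"),
            objects_room_rate=("objects_room", "mean"),
        ).reset_index()
        out = out.merge(rates, on="subject_id", how="left")
    else:
        out["objects_association_rate"] = np.nan
        out["objects_room_rate"] = np.nan
    return out


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------


def _design(data: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(data))]
    for t in terms:
        cols.append(np.asarray(data[t], dtype=float))
    return np.column_stack(cols)


def _profiled_ml(endog: np.ndarray, exog: np.ndarray,
                 groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact ML for a random-intercept linear mixed model.

    With V = sigma^2 (I + lambda J) block-diagonal over groups, beta and
    sigma^2 profile out in closed form per group; the likelihood is then a
    1-D function of the variance ratio lambda = tau^2 / sigma^2, maximized
    by bounded scalar search (with the lambda = 0 boundary, i.e. plain OLS,
    always evaluated).  Returns (beta, se(beta), loglik).
    """
    from scipy.optimize import minimize_scalar

    n, p = exog.shape
    _, inv = np.unique(groups, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    inv_sorted = inv[order]
    X, y = exog[order], endog[order]
    bounds = np.flatnonzero(np.r_[True, np.diff(inv_sorted) != 0, True])
    slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    sizes = np.array([s.stop - s.start for s in slices])

    XtX = np.stack([X[s].T @ X[s] for s in slices])          # (g, p, p)
    Xty = np.stack([X[s].T @ y[s] for s in slices])          # (g, p)
    s1 = np.stack([X[s].sum(axis=0) for s in slices])        # (g, p) = X'1
    y1 = np.array([y[s].sum() for s in slices])              # 1'y
    yy = np.array([y[s] @ y[s] for s in slices])

    def solve(lam: float):
        w = lam / (1.0 + sizes * lam)                        # per-group downdate
        A = XtX.sum(axis=0) - np.einsum("g,gi,gj->ij", w, s1, s1)
        b = Xty.sum(axis=0) - (w * y1) @ s1
        q = yy.sum() - np.sum(w * y1 * y1)
        beta = np.linalg.solve(A, b)
        rss = max(q - beta @ b, 1e-300)
        sigma2 = rss / n
        llf = (-0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
               - 0.5 * np.sum(np.log1p(sizes * lam)))
        return beta, A, sigma2, llf

    def neg_llf(phi: float) -> float:
        try:
            return -solve(np.exp(phi))[3]
        except np.linalg.LinAlgError:
            return np.inf

    _, _, _, llf0 = solve(0.0)
    res = minimize_scalar(neg_llf, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x)) if np.isfinite(res.fun) and -res.fun > llf0 else 0.0
    beta, A, sigma2, llf = solve(lam)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(A)))
    return beta, se, float(llf)


def fit_lmm(data: pd.DataFrame, terms: Sequence[str],
            model_id: str = "model",
            df_method: str = "residual") -> ModelResult:
    """ML fit of ``value ~ 1 + terms + (1 | subject_id)``.

    ``data`` must carry ``value``, ``subject_id`` and every term as a
    numeric column, with no missing values.  t statistics use a residual
    df approximation (n_obs - number of fixed-effect parameters); AIC is
    2k - 2*loglik with k counting fixed effects plus the two variance
    parameters.  Non-convergence / a singular design is reported on the
    result, never raised.
    """
    terms = list(terms)
    exog = _design(data, terms)
    endog = np.asarray(data["value"], dtype=float)
    groups = np.asarray(data["subject_id"])
    names = ["intercept"] + terms
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fe, se, llf = _profiled_ml(endog, exog, groups)
        if not np.all(np.isfinite(fe)) or not np.isfinite(llf):
            raise np.linalg.LinAlgError("non-finite fit")
    except Exception as exc:  # singular designs etc.
        logger.debug("mixed-model fit failed for %s: %s", model_id, exc)
        k = len(names) + 2
        return ModelResult(
            model_id=model_id,
            terms=pd.DataFrame({
                "term": names,
                "estimate": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
            }),
            aic=np.nan, loglik=np.nan, n_obs=len(data), n_params=k,
            converged=False,
        )

    n_obs = len(endog)
    k_fixed = exog.shape[1]
    k = k_fixed + 2  # + random-intercept variance + residual variance
    if df_method == "residual":
        df = max(n_obs - k_fixed, 1)
    else:
        raise InvalidInputError(f"unknown df method {df_method!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = fe / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    table = pd.DataFrame({
        "term": names, "estimate": fe, "se": se, "t": tvals, "p": pvals,
    })
    return ModelResult(
        model_id=model_id,
        terms=table,
        aic=2.0 * k - 2.0 * llf,
        loglik=llf,
        n_obs=n_obs,
        n_params=k,
        converged=converged,
    )


def stepwise_aic(data: pd.DataFrame, candidate_terms: Sequence[str],
                 model_id: str = "model",
                 df_method: str = "residual") -> ModelResult:
    """Greedy forward selection of fixed effects by AIC.

    Starting from the intercept-plus-random-intercept model, every round
    fits each remaining candidate on top of the current model and adds the
    one with the largest AIC decrease; selection stops when no candidate
    decreases AIC.  Deterministic: ties resolve to the earliest candidate.
    """
    candidates = list(candidate_terms)
    current: list[str] = []
    best = fit_lmm(data, current, model_id=model_id, df_method=df_method)
    while True:
        trials = []
        for c in candidates:
            if c in current:
                continue
            trial = fit_lmm(data, current + [c], model_id=model_id,
                            df_method=df_method)
            if np.isfinite(trial.aic):
                trials.append((trial.aic, c, trial))
        if not trials:
            break
        best_aic = min(t[0] for t in trials)
        if best_aic >= best.aic - 1e-9:
            break
        winner = next(t for t in trials if t[0] <= best_aic + 1e-12)
        current.append(winner[1])
        best = winner[2]
    best.selected = list(current)
    best.candidates = candidates
    if len(current) >= 2:
        best.vif = compute_vif(data[current])
    return best


# ---------------------------------------------------------------------------
# diagnostics and multiplicity
# ---------------------------------------------------------------------------


def compute_vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per column: 1/(1-R^2) of each term regressed
    (with intercept) on the remaining terms.  Exact collinearity gives inf."""
    cols = list(design.columns)
    if len(cols) < 2:
        raise InvalidInputError("VIF needs at least two fixed-effect terms")
    out: dict[str, float] = {}
    X = design.astype(float)
    for c in cols:
        others = [o for o in cols if o != c]
        exog = sm.add_constant(X[others].to_numpy(), has_constant="add")
        res = sm.OLS(X[c].to_numpy(), exog).fit()
        r2 = min(float(res.rsquared), 1.0)
        out[c] = float("inf") if r2 > 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def fdr_bh(pvalues: Sequence[float], q: float = 0.05,
           m_total: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``.

    ``m_total`` overrides the correction denominator, e.g. the total number
    of candidate explanatory variables across all models when only the
    selected terms contribute p-values.
    """
    p = np.asarray(list(pvalues), dtype=float)
    n = p.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    m = int(m_total) if m_total is not None else n
    if m < n:
        raise InvalidInputError(f"m_total={m} smaller than number of p-values {n}")
    order = np.argsort(p, kind="stable")
    flags = np.zeros(n, dtype=bool)
    thresh = q * (np.arange(1, n + 1)) / m
    passing = np.flatnonzero(p[order] <= thresh)
    if passing.size:
        flags[order[: passing.max() + 1]] = True
    return flags


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _model_frame(tract_df: pd.DataFrame, summaries: pd.DataFrame,
                 tract: str, measure: str,
                 config: AssociationConfig) -> tuple[pd.DataFrame, list[str]]:
    sub = tract_df[(tract_df["tract"] == tract)
                   & (tract_df["measure"] == measure)].copy()
    if sub.empty:
        return sub, []
    sub = sub.merge(summaries, on="subject_id", how="inner")
    bilateral = sub["hemisphere"].nunique() > 1
    sub["hemisphere_right"] = (sub["hemisphere"] == "right").astype(float)
    candidates = list(config.behavioral_terms)
    candidates += list(config.nuisance_terms)
    if bilateral and config.include_hemisphere:
        candidates.append("hemisphere_right")
    sub = sub.dropna(subset=["value"] + [c for c in candidates
                                         if c in sub.columns]).copy()
    if config.standardize:
        for term in config.behavioral_terms:
            if term in sub.columns:
                sd = sub[term].std(ddof=1)
                mu = sub[term].mean()
                sub[term] = 0.0 if not sd or not np.isfinite(sd) \
                    else (sub[term] - mu) / sd
    sub = sub.sort_values(["subject_id", "hemisphere"]).reset_index(drop=True)
    return sub, candidates


def association_pipeline(summaries: pd.DataFrame, tract_df: pd.DataFrame,
                         config: AssociationConfig | None = None
                         ) -> pd.DataFrame:
    """Stepwise mixed models per tract x measure, pooled FDR, VIF.

    Returns one row per candidate term per model with estimate, t, p, VIF,
    selection and FDR-significance flags, plus a convergence status.
    """
    config = config or AssociationConfig()
    if summaries is None or summaries.empty:
        raise InvalidInputError(
            "empty behavioral summary table: run scoring/aggregation first"
        )
    if tract_df is None or tract_df.empty:
        raise InvalidInputError("empty tract table: nothing to model")

    models: list[tuple[str, ModelResult]] = []
    total_candidates = 0
    for tract in sorted(tract_df["tract"].unique()):
        for measure in sorted(tract_df[tract_df["tract"] == tract]["measure"]
                              .unique()):
            frame, candidates = _model_frame(tract_df, summaries, tract,
                                             measure, config)
            model_id = f"{tract}:{measure}"
            if frame.empty or len(candidates) == 0:
                logger.warning("no usable rows for %s; skipped", model_id)
                continue
            total_candidates += len(candidates)
            result = stepwise_aic(frame, candidates, model_id=model_id,
                                  df_method=config.df_method)
            models.append((model_id, result))

    # pooled BH across every selected term of every model, corrected for the
    # total number of candidate explanatory variables across all models
    pooled: list[tuple[str, str, float]] = []
    for model_id, result in models:
        tbl = result.terms.set_index("term")
        for term in result.selected:
            pooled.append((model_id, term, float(tbl.loc[term, "p"])))
    flags = fdr_bh([p for _, _, p in pooled], q=config.q, m_total=total_candidates)
    sig = {(mid, term): bool(f) for (mid, term, _), f in zip(pooled, flags)}

    rows = []
    for model_id, result in models:
        tbl = result.terms.set_index("term")
        for term in result.candidates:
            in_model = term in result.selected
            rows.append({
                "model_id": model_id,
                "term": term,
                "estimate": float(tbl.loc[term, "estimate"]) if in_model else np.nan,
                "se": float(tbl.loc[term, "se"]) if in_model else np.nan,
                "t": float(tbl.loc[term, "t"]) if in_model else np.nan,
                "p": float(tbl.loc[term, "p"]) if in_model else np.nan,
                "vif": result.vif.get(term, np.nan),
                "selected": in_model,
                "fdr_significant": sig.get((model_id, term), False),
                "converged": result.converged,
                "aic": result.aic,
                "n_obs": result.n_obs,
            })
    return pd.DataFrame(rows)
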