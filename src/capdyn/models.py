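"""Prediction layer: linear, logistic and random-intercept mixed models.

Five model families link frontoparietal (FPN) state dynamics to attention
and executive scores:

* Model 1 - random-intercept linear mixed model of longitudinal scores on
  deficit status, timepoint, FPN temporal metrics and their interactions;
* Model 2 - logistic model of post-surgical deficit on presurgical
  transition properties (IN-/OUT-degree);
* Model 3 - logistic model of deficit on presurgical stability properties
  (occurrence, resilience);
* Models 4 and 5 - linear models of post-surgical scores on presurgical
  IN-degree (4) and on both transition degrees (5).

The mixed model is Gaussian with a subject random intercept, fitted by
REML: the variance ratio lambda = sigma2_subject / sigma2_residual is
profiled by one-dimensional optimization of the restricted likelihood,
then fixed effects come from GLS; Wald tests use residual degrees of
freedom (a documented approximation at this scale).  Logistic fits use
iteratively reweighted least squares with explicit detection of complete
separation.  Predictors are standardized before fitting so coefficients
are comparable across metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from scipy.special import expit


@dataclass
class FitResult:
    """Coefficients and inference for one fitted model."""

    method: str
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    statistics: np.ndarray
    p_values: np.ndarray
    n_obs: int
    df_resid: float
    converged: bool = True
    separation: bool = False
    sigma2_subject: float | None = None
    sigma2_residual: float | None = None
    loglik_reml: float | None = None
    log_likelihood: float | None = None
    response: str = ""

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "response": self.response,
                "method": self.method,
                "term": self.terms,
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "statistic": self.statistics,
                "p_value": self.p_values,
            }
        )

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def p(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])


def _check_design(x: np.ndarray, terms: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name a minimal set of columns whose removal restores full rank
        bad = []
        for j in range(x.shape[1]):
            keep = [c for c in range(x.shape[1]) if c != j and c not in bad]
            if np.linalg.matrix_rank(x[:, keep]) == rank:
                bad.append(j)
        raise ValueError(f"rank-deficient design; collinear columns: {[terms[j] for j in bad]}")


def fit_linear(
    design: np.ndarray, response: np.ndarray, terms: list[str] | None = None,
    response_name: str = "",
) -> FitResult:
    """Ordinary least squares with t-tests on coefficients (statsmodels)."""
    import statsmodels.api as sm

    x = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if terms is None:
        terms = [f"x{j}" for j in range(x.shape[1])]
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need n > p observations")
    _check_design(x, terms)
    res = sm.OLS(y, x).fit()
    return FitResult(
        method="ols",
        terms=list(terms),
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        statistics=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        n_obs=int(res.nobs),
        df_resid=float(res.df_resid),
        log_likelihood=float(res.llf),
        response=response_name,
    )


def _irls(
    x: np.ndarray, y: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, bool, float]:
    """IRLS core; returns (beta, converged, log-likelihood at beta)."""
    beta = np.zeros(x.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = x @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        xtw = x.T * w
        try:
            new = np.linalg.solve(xtw @ x, xtw @ z)
        except np.linalg.LinAlgError:
            break
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e3:
            break
    p = expit(x @ beta)
    eps = 1e-12
    ll = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return beta, converged, ll


def fit_logistic(
    design: np.ndarray,
    response: np.ndarray,
    terms: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    response_name: str = "",
) -> FitResult:
    """Maximum-likelihood logistic regression via IRLS.

    Reported statistics are Wald z, but per-coefficient p-values come from
    drop-one Rao score tests: at the cohort sizes this package targets,
    Wald inference loses power exactly when effects are large
    (Hauck-Donner) and the likelihood-ratio chi-square runs visibly
    anticonservative, while the score test stays calibrated without losing
    power.  Complete separation is detected (fitted probabilities
    collapsing to the observed classes / diverging coefficients) and
    reported with a warning instead of silently diverging.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if terms is None:
        terms = [f"x{j}" for j in range(x.shape[1])]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("logistic response must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    _check_design(x, terms)
    beta, converged, ll = _irls(x, y, max_iter, tol)
    p = expit(x @ beta)
    separation = bool(np.max(np.abs(beta)) > 30 or np.max(np.abs(y - p)) < 1e-6)
    if separation:
        warnings.warn(
            "complete or quasi-complete separation detected; coefficients and "
            "Wald tests are unreliable"
        )
    w = np.clip(p * (1 - p), 1e-10, None)
    cov = np.linalg.inv((x.T * w) @ x)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    # drop-one Rao score test per coefficient, chi-square with 1 df
    pvals = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        keep = [c for c in range(x.shape[1]) if c != j]
        if keep:
            b0, _, _ = _irls(x[:, keep], y, max_iter, tol)
            eta0 = x[:, keep] @ b0
        else:
            eta0 = np.zeros(y.size)
        p0 = expit(eta0)
        w0 = np.clip(p0 * (1 - p0), 1e-10, None)
        score = x.T @ (y - p0)
        info = (x.T * w0) @ x
        stat = float(score @ np.linalg.solve(info, score))
        pvals[j] = sps.chi2.sf(max(stat, 0.0), 1)
    return FitResult(
        method="logistic",
        terms=list(terms),
        coefficients=beta,
        standard_errors=se,
        statistics=zstat,
        p_values=pvals,
        n_obs=y.size,
        df_resid=float(y.size - x.shape[1]),
        converged=converged or separation,
        separation=separation,
        log_likelihood=ll,
        response=response_name,
    )


def _reml_pieces(
    x: np.ndarray, y: np.ndarray, group_idx: list[np.ndarray], lam: float
):
    """GLS quantities under V = I + lam * ZZ' (block-diagonal by subject)."""
    p = x.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for idx in group_idx:
        xi, yi = x[idx], y[idx]
        ni = idx.size
        shrink = lam / (1.0 + lam * ni)
        sx = xi.sum(axis=0)
        sy = yi.sum()
        xtvx += xi.T @ xi - shrink * np.outer(sx, sx)
        xtvy += xi.T @ yi - shrink * sx * sy
        ytvy += yi @ yi - shrink * sy * sy
        logdet += np.log1p(lam * ni)
    return xtvx, xtvy, ytvy, logdet


def fit_random_intercept(
    design: np.ndarray,
    response: np.ndarray,
    subject_ids,
    terms: list[str] | None = None,
    lam_max: float = 1e4,
    response_name: str = "",
) -> FitResult:
    """Gaussian random-intercept model fitted by profiled REML.

    Profiles lambda = sigma2_subject / sigma2_residual over [0, lam_max] by
    minimizing the restricted likelihood, then estimates fixed effects by
    GLS at the optimum.  Reduces exactly to OLS at lambda = 0.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    subjects = np.asarray([str(s) for s in subject_ids])
    if terms is None:
        terms = [f"x{j}" for j in range(x.shape[1])]
    if x.shape[0] != y.size or subjects.size != y.size:
        raise ValueError("design, response and subject_ids must align")
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need n > p observations")
    _check_design(x, terms)
    group_idx = [np.flatnonzero(subjects == s) for s in np.unique(subjects)]
    n, p = x.shape

    def neg2_reml(lam: float) -> float:
        xtvx, xtvy, ytvy, logdet = _reml_pieces(x, y, group_idx, lam)
        beta = np.linalg.solve(xtvx, xtvy)
        rss = ytvy - beta @ xtvy
        rss = max(rss, 1e-300)
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf
        return (n - p) * np.log(rss / (n - p)) + logdet + logdet_xtvx

    res = minimize_scalar(
        neg2_reml, bounds=(0.0, lam_max), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"REML profile optimization failed: {res}")
    lam = float(res.x)
    # the bounded minimizer never lands exactly on the boundary; take 0 when
    # it is at least as good, so the OLS limit is exact
    if neg2_reml(0.0) <= res.fun + 1e-10:
        lam = 0.0
    xtvx, xtvy, ytvy, logdet = _reml_pieces(x, y, group_idx, lam)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - beta @ xtvy
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    df = float(n - p)
    pvals = 2.0 * sps.t.sf(np.abs(tstat), df)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    neg2 = (n - p) * np.log(sigma2) + logdet + logdet_xtvx
    loglik_reml = -0.5 * (neg2 + (n - p) * (1 + np.log(2 * np.pi)))
    return FitResult(
        method="reml_random_intercept",
        terms=list(terms),
        coefficients=beta,
        standard_errors=se,
        statistics=tstat,
        p_values=pvals,
        n_obs=n,
        df_resid=df,
        sigma2_subject=float(lam * sigma2),
        sigma2_residual=float(sigma2),
        loglik_reml=float(loglik_reml),
        response=response_name,
    )


def _standardize(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        sd = out[c].std(ddof=0)
        if sd == 0:
            raise ValueError(f"predictor {c!r} has zero variance")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


@dataclass
class ModelSuiteReport:
    """Results of Models 1-5 plus the scatter data behind them."""

    fits: dict[str, FitResult]
    skipped: dict[str, str] = field(default_factory=dict)
    scatter: pd.DataFrame | None = None

    def tidy(self) -> pd.DataFrame:
        frames = []
        for name, fit in sorted(self.fits.items()):
            t = fit.tidy()
            t.insert(0, "model", name)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def significance_table(self, alpha: float = 0.05) -> pd.DataFrame:
        t = self.tidy()
        t["significant"] = t["p_value"] < alpha
        return t


def run_model_suite(
    metrics: pd.DataFrame,
    behavior_table,
    deficit_flags: pd.DataFrame,
    fpn_state: int,
    scores: tuple[str, ...] = ("TMTA", "TMTB", "TMTBA", "AttentionalMatrices"),
    mixed_score: str = "TMTB",
) -> ModelSuiteReport:
    """Fit the five-model prediction suite from tidy pipeline tables.

    ``metrics`` is the tidy per-(subject, session, state) metric table,
    ``behavior_table`` a :class:`~capdyn.io.BehavioralTable`, and
    ``deficit_flags`` the output of :func:`capdyn.neuro.classify_deficit`.
    """
    fits: dict[str, FitResult] = {}
    skipped: dict[str, str] = {}
    fpn = metrics[metrics["state"] == fpn_state]
    pre = fpn[fpn["session"] == "pre"].set_index("subject")
    post = fpn[fpn["session"] == "post3m"].set_index("subject")
    flags = deficit_flags.set_index("subject")["deficit"].astype(float)
    beh = behavior_table.table
    metric_cols = ["occurrence", "resilience", "in_degree", "out_degree", "betweenness"]

    # --- Model 1: mixed model of longitudinal scores ---------------------
    rows = []
    for subject in pre.index:
        for tp in ("pre", "1w", "3m"):
            val = beh[
                (beh["subject"] == subject)
                & (beh["timepoint"] == tp)
                & (beh["score"] == mixed_score)
            ]["value"]
            if val.empty or subject not in flags.index:
                continue
            # imaging exists at pre and 3 months only: pre metrics describe
            # the network state at pre and 1 week, post metrics at 3 months
            src = post if (tp == "3m" and subject in post.index) else pre
            rows.append(
                {
                    "subject": subject,
                    "timepoint": tp,
                    "value": float(val.iloc[0]),
                    "deficit": float(flags.loc[subject]),
                    **{c: float(src.loc[subject, c]) for c in metric_cols},
                }
            )
    long = pd.DataFrame(rows)
    if long.empty or long["timepoint"].nunique() < 2:
        skipped["model1"] = "missing timepoints for the longitudinal mixed model"
    else:
        # out_degree excluded: collinear with in_degree by flow conservation
        m1_cols = [
            c for c in metric_cols
            if c != "out_degree" and long[c].std(ddof=0) > 0
        ]
        dropped = sorted(set(metric_cols) - set(m1_cols))
        if dropped:
            warnings.warn(f"model1: dropping constant predictor(s) {dropped}")
        long = _standardize(long, m1_cols)
        long["t_1w"] = (long["timepoint"] == "1w").astype(float)
        long["t_3m"] = (long["timepoint"] == "3m").astype(float)
        long["deficit_x_1w"] = long["deficit"] * long["t_1w"]
        long["deficit_x_3m"] = long["deficit"] * long["t_3m"]
        terms = (
            ["intercept", "deficit", "t_1w", "t_3m"]
            + m1_cols
            + ["deficit_x_1w", "deficit_x_3m"]
        )
        design = np.column_stack(
            [np.ones(len(long))]
            + [long[t].to_numpy() for t in terms[1:]]
        )
        fits["model1"] = fit_random_intercept(
            design, long["value"].to_numpy(), long["subject"], terms=terms,
            response_name=mixed_score,
        )

    # --- Models 2 and 3: presurgical dynamics -> deficit ------------------
    # IN- and OUT-degree are collinear by flow conservation (entries and
    # exits of a state differ by at most one), so transition models carry
    # one degree each rather than both.
    common = pre.index.intersection(flags.index)
    base = pre.loc[common, metric_cols].copy()
    base["deficit"] = flags.loc[common]
    for name, cols in (
        ("model2", ["out_degree"]),
        ("model3", ["occurrence", "resilience"]),
    ):
        try:
            dat = _standardize(base, cols)
            design = np.column_stack([np.ones(len(dat))] + [dat[c].to_numpy() for c in cols])
            fits[name] = fit_logistic(
                design, dat["deficit"].to_numpy(), terms=["intercept"] + cols,
                response_name="deficit",
            )
        except ValueError as exc:
            skipped[name] = str(exc)

    # --- Models 4 and 5: presurgical dynamics -> post-surgical scores -----
    post_scores = beh[beh["timepoint"] == "1w"].pivot(
        index="subject", columns="score", values="value"
    )
    for name, cols, score in (
        ("model4", ["in_degree"], "TMTA"),
        ("model5", ["out_degree"], "TMTB"),
    ):
        idx = pre.index.intersection(post_scores.index)
        if score not in post_scores.columns or idx.empty:
            skipped[name] = f"missing post-surgical {score} scores"
            continue
        dat = _standardize(pre.loc[idx, metric_cols].copy(), cols)
        design = np.column_stack([np.ones(len(idx))] + [dat[c].to_numpy() for c in cols])
        fits[name] = fit_linear(
            design, post_scores.loc[idx, score].to_numpy(),
            terms=["intercept"] + cols, response_name=f"{score}_1w",
        )

    # --- scatter data behind the degree-vs-score panels -------------------
    scat_rows = []
    for subject in pre.index:
        if subject not in flags.index:
            continue
        for score in scores:
            for tp in ("pre", "1w", "3m"):
                val = beh[
                    (beh["subject"] == subject)
                    & (beh["timepoint"] == tp)
                    & (beh["score"] == score)
                ]["value"]
                if val.empty:
                    continue
                scat_rows.append(
                    {
                        "subject": subject,
                        "score": score,
                        "timepoint": tp,
                        "value": float(val.iloc[0]),
                        "in_degree_pre": float(pre.loc[subject, "in_degree"]),
                        "out_degree_pre": float(pre.loc[subject, "out_degree"]),
                        "deficit": bool(flags.loc[subject]),
                    }
                )
    scatter = pd.DataFrame(scat_rows)
    # scores in normalized z-score form per score name
    if not scatter.empty:
        scatter["value_z"] = scatter.groupby("score")["value"].transform(
            lambda v: (v - v.mean()) / (v.std(ddof=0) if v.std(ddof=0) > 0 else 1.0)
        )
    return ModelSuiteReport(fits=fits, skipped=skipped, scatter=scatter)
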