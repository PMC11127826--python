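"""Group comparisons and binomial mixed-effects selection models.

The two canonical models mirror a two-stage elite pathway:

* junior model — team-16 selection ~ z of %AH + year of collection, with a
  random intercept for high-school region;
* adult model — NHL selection ~ z of %AH + year of collection + team-16/18/20
  membership, with the same random intercept.

Both are binomial GLMMs with a logit link.  The single-random-intercept
marginal likelihood is maximised under the Laplace approximation (the
standard default for binomial GLMMs); fixed-effect confidence intervals are
Wald.  Fixed-effects-only specifications (``random_intercept=None``) fall
back to an ordinary logistic GLM and serve as likelihood-ratio-test nulls.

Classical group comparisons (Welch t-test, one-way ANOVA, chi-square) and
the descriptive tables (success crosstabs, maturity-category distributions)
live here too.
"""

from __future__ import annotations

import logging
import math
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1

from .maturity import EARLY, LATE, ON_TIME, QC_EXCLUDED, estimates_frame

__all__ = [
    "SelectionModelSpec",
    "SelectionModelFit",
    "team16_spec",
    "nhl_spec",
    "univariable_spec",
    "cohort_frame",
    "fit_selection_model",
    "likelihood_ratio_test",
    "predicted_probabilities",
    "compare_groups",
    "crosstab_success",
    "category_distribution",
]

logger = logging.getLogger(__name__)

_ALLOWED_FIXED = {"z_pah", "pah", "year_of_collection", "team16", "team18", "team20"}
_TEAM_COVARIATES = {"team16", "team18", "team20"}
_BETA_DIVERGENCE_LIMIT = 15.0  # |log-odds| beyond this signals quasi-separation

LRTResult = namedtuple("LRTResult", ["statistic", "df", "p"])
GroupComparison = namedtuple("GroupComparison", ["statistic", "p", "effect"])
EffectEstimate = namedtuple("EffectEstimate", ["estimate", "ci_low", "ci_high"])


@dataclass(frozen=True)
class SelectionModelSpec:
    """A binomial selection model: response, fixed effects, optional random intercept."""

    response: str
    fixed_effects: tuple = ("z_pah", "year_of_collection")
    random_intercept: Optional[str] = "region"

    def __post_init__(self):
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))
        if self.response not in {"team16", "nhl", "team18", "team20"}:
            raise ValueError(f"unknown response {self.response!r}")
        unknown = set(self.fixed_effects) - _ALLOWED_FIXED
        if unknown:
            raise ValueError(f"unknown fixed effects {sorted(unknown)}")
        if self.response == "team16" and set(self.fixed_effects) & _TEAM_COVARIATES:
            raise ValueError(
                "the junior (team16) model must not include team-membership covariates"
            )

    @property
    def terms(self) -> tuple:
        return ("intercept",) + self.fixed_effects


def team16_spec(maturity_term: str = "z_pah") -> SelectionModelSpec:
    """The junior-success model specification."""
    return SelectionModelSpec("team16", (maturity_term, "year_of_collection"), "region")


def nhl_spec(maturity_term: str = "z_pah") -> SelectionModelSpec:
    """The adult-success model, additionally adjusted for junior-team membership."""
    return SelectionModelSpec(
        "nhl",
        (maturity_term, "year_of_collection", "team16", "team18", "team20"),
        "region",
    )


def univariable_spec(response: str, maturity_term: str = "z_pah") -> SelectionModelSpec:
    """Intercept + maturity fixed-effects-only logistic model (the LRT null)."""
    return SelectionModelSpec(response, (maturity_term,), None)


@dataclass
class SelectionModelFit:
    """Fitted coefficients, intervals, AIC and diagnostics for one model."""

    spec: SelectionModelSpec
    coefficients: pd.DataFrame  # index term; estimate, ci_low, ci_high, p_value
    random_intercept_sd: Optional[float]
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool
    group_effects: dict = field(default_factory=dict)  # region label -> BLUP

    @property
    def k_params(self) -> int:
        return len(self.coefficients) + (1 if self.random_intercept_sd is not None else 0)

    def summary_frame(self) -> pd.DataFrame:
        return self.coefficients.reset_index(names="term")


def cohort_frame(records, estimates) -> pd.DataFrame:
    """Merge player records with maturity estimates into one modelling table.

    One row per player with a non-excluded maturity estimate; carries the
    maturity quantities, career flags, region and year of collection.
    """
    est = estimates_frame(estimates if not isinstance(estimates, dict) else estimates.values())
    est = est[est["qc_flag"] != QC_EXCLUDED]
    meta = pd.DataFrame(
        {
            "player_id": [r.player_id for r in records],
            "region": [r.region for r in records],
            "year_of_collection": [r.year_of_collection for r in records],
            "team16": [float(r.team16) for r in records],
            "team18": [float(r.team18) for r in records],
            "team20": [float(r.team20) for r in records],
            "nhl": [float(r.nhl) for r in records],
        }
    )
    return est.merge(meta, on="player_id", how="inner")


def _design(frame: pd.DataFrame, spec: SelectionModelSpec):
    cols = [spec.response, *spec.fixed_effects]
    if spec.random_intercept:
        cols.append(spec.random_intercept)
    data = frame[cols].dropna()
    y = data[spec.response].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(float) for c in spec.fixed_effects]
    )
    return data, y, X


def _center_columns(X: np.ndarray):
    """Center non-intercept columns for optimisation stability."""
    means = X.mean(axis=0)
    means[0] = 0.0
    return X - means, means


def _wald_table(terms, est, se) -> pd.DataFrame:
    zcrit = stats.norm.ppf(0.975)
    zval = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
    return pd.DataFrame(
        {
            "estimate": est,
            "ci_low": est - zcrit * se,
            "ci_high": est + zcrit * se,
            "p_value": 2.0 * stats.norm.sf(np.abs(zval)),
        },
        index=pd.Index(terms, name="term"),
    )


def _laplace_negll(theta, y, Xc, gidx, ngroups, u_state):
    beta, logsig = theta[:-1], theta[-1]
    sig2 = math.exp(2.0 * logsig)
    eta0 = Xc @ beta
    u = u_state["u"].copy()
    for _ in range(100):  # per-group 1-D Newton for the conditional modes
        eta = eta0 + u[gidx]
        p = expit(eta)
        grad = np.bincount(gidx, weights=y - p, minlength=ngroups) - u / sig2
        W = np.bincount(gidx, weights=p * (1.0 - p), minlength=ngroups)
        H = W + 1.0 / sig2
        step = np.clip(grad / H, -5.0, 5.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-11:
            break
    u_state["u"] = u
    eta = eta0 + u[gidx]
    p = expit(eta)
    W = np.bincount(gidx, weights=p * (1.0 - p), minlength=ngroups)
    H = W + 1.0 / sig2
    ll = (
        float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        - float(np.sum(u**2)) / (2.0 * sig2)
        - ngroups * logsig
        - 0.5 * float(np.sum(np.log(H)))
    )
    return -ll


def fit_selection_model(frame: pd.DataFrame, spec: SelectionModelSpec) -> SelectionModelFit:
    """Maximum-likelihood fit of a binomial selection model.

    Mixed specifications use the Laplace approximation to the
    random-intercept integral; fixed-effects-only specifications use an
    ordinary logistic GLM.  Deterministic given data and spec.  A
    non-converged fit (quasi-separation, optimiser failure) is returned
    with ``converged=False`` and a warning, never a silent estimate.
    """
    data, y, X = _design(frame, spec)
    if len(data) == 0:
        raise ValueError("no complete rows to fit")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"response {spec.response!r} has a single class")

    if spec.random_intercept is None:
        return _fit_glm(data, y, X, spec)

    groups, glabels = pd.factorize(data[spec.random_intercept], sort=True)
    ngroups = len(glabels)
    if ngroups < 2:
        raise ValueError("need at least 2 groups for a random intercept")

    Xc, means = _center_columns(X)
    # fixed-effects start values from a plain logistic fit
    glm = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=200)
    x0 = np.concatenate([glm.params, [math.log(0.3)]])
    u_state = {"u": np.zeros(ngroups)}
    bounds = [(None, None)] * X.shape[1] + [(math.log(1e-4), math.log(5.0))]
    res = optimize.minimize(
        _laplace_negll,
        x0,
        args=(y, Xc, groups, ngroups, u_state),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    theta = res.x
    ll = -_laplace_negll(theta, y, Xc, groups, ngroups, u_state)
    hess = approx_hess1(theta, _laplace_negll, args=(y, Xc, groups, ngroups, u_state))
    se = np.full(theta.size, np.nan)
    hess_ok = True
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        hess_ok = bool(np.all(diag[: X.shape[1]] > 0))
        se = np.sqrt(np.maximum(diag, 0.0))
    except np.linalg.LinAlgError:
        hess_ok = False

    beta_c = theta[:-1]
    sigma = math.exp(theta[-1])
    # undo centering: only the intercept changes
    beta = beta_c.copy()
    beta[0] = beta_c[0] - float(means[1:] @ beta_c[1:])
    se_beta = se[:-1].copy()  # slope SEs unaffected; intercept SE approximate
    converged = bool(res.success) and hess_ok and float(np.max(np.abs(beta_c))) < _BETA_DIVERGENCE_LIMIT
    if not converged:
        logger.warning(
            "mixed model for %r did not converge cleanly (%s); treat estimates with caution",
            spec.response,
            res.message,
        )
    table = _wald_table(spec.terms, beta, se_beta)
    k = X.shape[1] + 1
    return SelectionModelFit(
        spec=spec,
        coefficients=table,
        random_intercept_sd=sigma,
        log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        n_obs=len(data),
        converged=converged,
        group_effects={str(lbl): float(uv) for lbl, uv in zip(glabels, u_state["u"])},
    )


def _fit_glm(data, y, X, spec) -> SelectionModelFit:
    Xc, means = _center_columns(X)
    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    beta = res.params.copy()
    beta[0] = res.params[0] - float(means[1:] @ res.params[1:])
    converged = bool(res.converged) and float(np.max(np.abs(res.params))) < _BETA_DIVERGENCE_LIMIT
    if not converged:
        logger.warning("logistic model for %r did not converge cleanly", spec.response)
    table = _wald_table(spec.terms, beta, res.bse)
    k = X.shape[1]
    ll = float(res.llf)
    return SelectionModelFit(
        spec=spec,
        coefficients=table,
        random_intercept_sd=None,
        log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        n_obs=len(data),
        converged=converged,
        group_effects={},
    )


def likelihood_ratio_test(fit_full: SelectionModelFit, fit_null: SelectionModelFit) -> LRTResult:
    """2·(llf_full − llf_null) against chi-square with the parameter-count difference.

    The null must be nested in the full model (terms a subset, same rows).
    """
    if fit_full.n_obs != fit_null.n_obs:
        raise ValueError(
            f"models fitted on different row counts ({fit_full.n_obs} vs {fit_null.n_obs})"
        )
    if not set(fit_null.coefficients.index) <= set(fit_full.coefficients.index):
        raise ValueError("null model terms are not a subset of the full model terms")
    df = fit_full.k_params - fit_null.k_params
    if df < 0:
        raise ValueError("null model has more parameters than the full model")
    statistic = 2.0 * (fit_full.log_likelihood - fit_null.log_likelihood)
    p = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df))
    return LRTResult(statistic=statistic, df=df, p=p)


def predicted_probabilities(fit: SelectionModelFit, frame: pd.DataFrame) -> pd.Series:
    """Per-player selection probability from the fitted linear predictor.

    Includes the region's estimated random intercept; players from regions
    unseen at fit time fall back to the population level (zero random
    effect) with a warning.
    """
    if not fit.converged:
        raise ValueError("refusing to predict from a non-converged fit")
    spec = fit.spec
    beta = fit.coefficients["estimate"].to_numpy()
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[c].to_numpy(float) for c in spec.fixed_effects]
    )
    lp = X @ beta
    if spec.random_intercept is not None:
        regions = frame[spec.random_intercept].astype(str)
        known = regions.isin(fit.group_effects)
        if not known.all():
            logger.warning(
                "%d row(s) from unseen region(s); using population-level prediction",
                int((~known).sum()),
            )
        lp = lp + np.array([fit.group_effects.get(r, 0.0) for r in regions])
    return pd.Series(expit(lp), index=frame.index, name=f"p_{spec.response}")


def compare_groups(groups, kind: str) -> GroupComparison:
    """Two-sided classical tests between groups.

    ``kind='t_test'`` — Welch two-sample t-test on two arrays; the effect is
    the mean difference (first − second) with its Welch 95% CI.
    ``kind='anova'`` — one-way ANOVA across ≥2 arrays.
    ``kind='chi_square'`` — Pearson chi-square (no continuity correction) on
    a contingency table of counts.
    """
    if kind == "t_test":
        if len(groups) != 2:
            raise ValueError("t_test requires exactly two groups")
        a, b = (np.asarray(g, dtype=float) for g in groups)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs at least 2 observations")
        res = stats.ttest_ind(a, b, equal_var=False)
        ci = res.confidence_interval(0.95)
        effect = EffectEstimate(
            estimate=float(a.mean() - b.mean()),
            ci_low=float(ci.low),
            ci_high=float(ci.high),
        )
        return GroupComparison(float(res.statistic), float(res.pvalue), effect)
    if kind == "anova":
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
            raise ValueError("anova requires >=2 groups with >=2 observations each")
        res = stats.f_oneway(*arrays)
        return GroupComparison(float(res.statistic), float(res.pvalue), None)
    if kind == "chi_square":
        table = np.asarray(groups, dtype=float)
        if table.ndim != 2 or np.any(table < 1):
            raise ValueError("chi_square requires a contingency table with all cells >= 1")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison(float(chi2), float(p), None)
    raise ValueError(f"unknown test kind {kind!r}")


def _pct(n: int, total: int) -> int:
    return int(math.floor(100.0 * n / total + 0.5)) if total else 0


def crosstab_success(records) -> pd.DataFrame:
    """Junior-team selection counts and within-column percentages by NHL status.

    One row per junior team × selected yes/no; percentages are of the NHL
    (resp. non-NHL) column totals, rounded to integer percent.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    nhl_total = sum(r.nhl for r in records)
    non_total = len(records) - nhl_total
    rows = []
    for team in ("team16", "team18", "team20"):
        for selected in (True, False):
            n_nhl = sum(1 for r in records if r.nhl and bool(getattr(r, team)) == selected)
            n_non = sum(1 for r in records if not r.nhl and bool(getattr(r, team)) == selected)
            rows.append(
                {
                    "junior_team": team,
                    "selected": "yes" if selected else "no",
                    "nhl_n": n_nhl,
                    "nhl_pct": _pct(n_nhl, nhl_total),
                    "non_nhl_n": n_non,
                    "non_nhl_pct": _pct(n_non, non_total),
                }
            )
    return pd.DataFrame(rows)


def category_distribution(
    estimates,
    by: str = "category_z",
    group: Optional[Sequence[bool]] = None,
) -> pd.DataFrame:
    """Counts and proportions of early / on-time / late in a (sub)group.

    ``estimates`` is a list of maturity estimates or a DataFrame carrying the
    ``by`` column; ``group`` optionally masks rows.  Proportions sum to 1.
    """
    if by not in {"category_z", "category_offset"}:
        raise ValueError(f"unknown category column {by!r}")
    frame = estimates if isinstance(estimates, pd.DataFrame) else estimates_frame(estimates)
    cats = frame[by]
    if group is not None:
        cats = cats[np.asarray(group, dtype=bool)]
    cats = cats.dropna()
    if len(cats) == 0:
        raise ValueError("empty group")
    order = [EARLY, ON_TIME, LATE]
    counts = cats.value_counts().reindex(order, fill_value=0)
    out = pd.DataFrame(
        {"count": counts, "proportion": counts / counts.sum()},
    )
    out.index.name = by
    return out
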