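"""Variance-based sensitivity indices and regression analyses.

Two complementary views of the simulation experiment:

* **Sobol indices** partition output variance across input factors.
  First-order indices use the Saltelli estimator
  ``S_i = E[y_B (y_ABi - y_A)] / V(y)`` and total indices the Jansen
  estimator ``S_Ti = E[(y_A - y_ABi)^2] / (2 V(y))`` on the radial
  A/B/AB blocks of the design; percentile-bootstrap confidence intervals
  resample the base-sample rows jointly across blocks.
* **Regressions** quantify direction and magnitude of effects.  Global
  (landscape-scale) models are GLMs — Gamma with log link for positive
  densities and application counts, binomial for application presence —
  over standardized covariates with all second-order interactions as
  candidates, selected stepwise by BIC under the marginality (hierarchy)
  rule.  Local (patch-scale) models are mixed models with a random
  intercept per landscape simulation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm

__all__ = [
    "SensitivityResult",
    "RegressionResult",
    "sobol_indices",
    "sobol_from_table",
    "fit_global_glm",
    "fit_local_glmm",
    "sign_table",
]


# ---------------------------------------------------------------------------
# Sobol indices


@dataclass
class SensitivityResult:
    """First-order and total Sobol indices with bootstrap 95% CIs."""

    factors: list[str]
    first_order: np.ndarray
    total: np.ndarray
    first_order_ci: np.ndarray  # (k, 2)
    total_ci: np.ndarray  # (k, 2)
    channel: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": self.factors,
                "S1": self.first_order,
                "S1_lo": self.first_order_ci[:, 0],
                "S1_hi": self.first_order_ci[:, 1],
                "ST": self.total,
                "ST_lo": self.total_ci[:, 0],
                "ST_hi": self.total_ci[:, 1],
            }
        )

    def ranking(self, which: str = "total") -> list[str]:
        vals = self.total if which == "total" else self.first_order
        order = np.argsort(vals)[::-1]
        return [self.factors[i] for i in order]


def _estimate(y_a: np.ndarray, y_b: np.ndarray, y_ab: np.ndarray):
    var = np.concatenate([y_a, y_b]).var(ddof=0)
    s1 = np.mean(y_b[:, None] * (y_ab - y_a[:, None]), axis=0) / var
    st = np.mean((y_a[:, None] - y_ab) ** 2, axis=0) / (2.0 * var)
    return s1, st


def sobol_indices(
    y_a: np.ndarray,
    y_b: np.ndarray,
    y_ab: np.ndarray,
    factors: list[str] | None = None,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    channel: str = "",
) -> SensitivityResult:
    """Saltelli first-order and Jansen total indices from radial blocks.

    ``y_a``, ``y_b`` have shape (N,), ``y_ab`` shape (N, k) with column i
    evaluated at A rows whose i-th factor was replaced from B.
    """
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    y_ab = np.asarray(y_ab, dtype=float)
    if y_ab.ndim != 2 or len(y_a) != len(y_b) or len(y_a) != y_ab.shape[0]:
        raise ValueError("block shapes inconsistent")
    k = y_ab.shape[1]
    factors = factors or [f"x{i}" for i in range(k)]
    if np.concatenate([y_a, y_b]).var(ddof=0) == 0:
        raise ValueError(
            "output variance is zero over the design; Sobol indices are "
            "undefined for a constant response"
        )
    s1, st = _estimate(y_a, y_b, y_ab)
    rng = np.random.default_rng(seed)
    n = len(y_a)
    boots1 = np.empty((n_bootstrap, k))
    bootst = np.empty((n_bootstrap, k))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        boots1[b], bootst[b] = _estimate(y_a[idx], y_b[idx], y_ab[idx])
    ci1 = np.percentile(boots1, [2.5, 97.5], axis=0).T
    cit = np.percentile(bootst, [2.5, 97.5], axis=0).T
    return SensitivityResult(
        factors=list(factors),
        first_order=s1,
        total=st,
        first_order_ci=ci1,
        total_ci=cit,
        channel=channel,
    )


def sobol_from_table(
    agg: pd.DataFrame,
    value_col: str,
    factors: list[str],
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> SensitivityResult:
    """Indices for one output channel of an aggregated results table.

    ``agg`` is the per-configuration table from
    :func:`hedgescape.experiment.aggregate_replicates` (or any frame with
    ``block``/``base_index`` columns and the value column).
    """
    pivot = agg.pivot(index="base_index", columns="block", values=value_col)
    missing = pivot.isna().any()
    if missing.any():
        raise ValueError(
            f"incomplete blocks for {value_col}: "
            f"{list(pivot.columns[missing])} contain missing configurations"
        )
    y_a = pivot["A"].to_numpy()
    y_b = pivot["B"].to_numpy()
    y_ab = np.column_stack([pivot[f"AB_{f}"].to_numpy() for f in factors])
    return sobol_indices(
        y_a, y_b, y_ab, factors, n_bootstrap, seed, channel=value_col
    )


# ---------------------------------------------------------------------------
# regressions


@dataclass
class RegressionResult:
    """A fitted (possibly mixed) regression with its selection trace."""

    family: str  # "gamma" | "binomial" | "lmm-log"
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    bic_trace: list[float] = field(default_factory=list)
    converged: bool = True
    separation: bool = False
    random_effect_sd: float | None = None
    notes: str = ""

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse})


def _design_columns(
    df: pd.DataFrame, covariates: list[str], standardize: bool
) -> pd.DataFrame:
    x = df[covariates].astype(float).copy()
    if standardize:
        std = x.std(ddof=0)
        std = std.replace(0.0, 1.0)
        x = (x - x.mean()) / std
    return x


def _term_matrix(x: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(x))]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(x[a].to_numpy() * x[b].to_numpy())
        else:
            cols.append(x[t].to_numpy())
    return np.column_stack(cols)


def _fit_glm(y, X, family: str):
    fam = (
        sm.families.Gamma(link=sm.families.links.Log())
        if family == "gamma"
        else sm.families.Binomial()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, X, family=fam).fit(maxiter=200)


def _bic(res, n: int) -> float:
    # -2 logL + k log n; the Gamma dispersion adds one parameter but is
    # present in every candidate model, so it cancels in comparisons
    return float(-2.0 * res.llf + len(res.params) * np.log(n))


def _hierarchy_ok(term: str, active: set[str]) -> bool:
    if ":" not in term:
        return True
    a, b = term.split(":")
    return a in active and b in active


def _removable(term: str, active: set[str]) -> bool:
    if ":" in term:
        return True
    return not any(
        ":" in t and term in t.split(":") for t in active if t != term
    )


def fit_global_glm(
    results: pd.DataFrame,
    response: str,
    covariates: list[str],
    family: str = "gamma",
    interactions: bool = True,
    standardize: bool = True,
    stepwise: bool = True,
) -> RegressionResult:
    """BIC-stepwise GLM of one output channel on the design covariates.

    Gamma (log link) channels keep strictly positive responses only;
    presence/absence channels use the binomial family.  Candidate terms
    are the main effects plus all pairwise interactions; bidirectional
    stepwise selection starts from the main-effects model and respects
    marginality (an interaction needs both parents in the model).
    """
    if family not in ("gamma", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    df = results.copy()
    y = df[response].astype(float)
    if family == "gamma":
        keep = y > 0
        df, y = df[keep], y[keep]
    x = _design_columns(df, covariates, standardize)
    n = len(x)
    if n <= len(covariates) + 2:
        raise ValueError(f"too few rows ({n}) to fit {len(covariates)} covariates")

    mains = list(covariates)
    inters = (
        [f"{a}:{b}" for a, b in itertools.combinations(covariates, 2)]
        if interactions
        else []
    )
    active = list(mains)
    yv = y.to_numpy()

    def fit(terms: list[str]):
        return _fit_glm(yv, _term_matrix(x, terms), family)

    res = fit(active)
    trace = [_bic(res, n)]
    if stepwise:
        candidates = mains + inters
        improved = True
        while improved:
            improved = False
            best_bic, best_terms = trace[-1], None
            aset = set(active)
            moves = []
            for t in candidates:
                if t not in aset and _hierarchy_ok(t, aset):
                    moves.append(active + [t])
            for t in active:
                if _removable(t, aset):
                    moves.append([u for u in active if u != t])
            for terms in moves:
                try:
                    cand = fit(terms)
                except Exception:  # noqa: BLE001 - skip non-convergent moves
                    continue
                b = _bic(cand, n)
                if b < best_bic - 1e-9:
                    best_bic, best_terms, best_res = b, terms, cand
            if best_terms is not None:
                active, res = best_terms, best_res
                trace.append(best_bic)
                improved = True

    names = ["intercept"] + active
    params = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse, index=names)
    separation = bool(
        family == "binomial"
        and (np.abs(res.params).max() > 15 or not np.isfinite(res.bse).all())
    )
    return RegressionResult(
        family=family,
        terms=active,
        params=params,
        bse=bse,
        bic_trace=trace,
        converged=bool(getattr(res, "converged", True)),
        separation=separation,
        notes="perfect separation suspected" if separation else "",
    )


def fit_local_glmm(
    fields: pd.DataFrame,
    response: str,
    covariates: list[str] = (
        "log_area",
        "log_perimeter",
        "adj_crop",
        "adj_hedges",
        "adj_treatments",
    ),
    family: str = "binomial",
    group_col: str = "landscape_id",
    offset: np.ndarray | None = None,
    standardize: bool = True,
) -> RegressionResult:
    """Patch-scale mixed model with a per-landscape random intercept.

    ``fields`` is the per-field long table (one row per crop field and
    simulation run); ``log_area``/``log_perimeter`` are derived here if
    absent.  Presence/absence uses a variational-Bayes binomial mixed
    GLM; a supplied offset is entered as an additional fixed covariate
    because that fitter takes no offset term.  Application counts
    (positive rows) are fit as a linear mixed model on the log counts —
    the log-normal approximation of a Gamma log-link — with the offset
    subtracted from the response.  A singular random effect is reported
    via ``notes`` (the fit degenerates to the fixed-effects model).
    """
    df = fields.copy()
    if "log_area" in covariates and "log_area" not in df:
        df["log_area"] = np.log(df["area"])
    if "log_perimeter" in covariates and "log_perimeter" not in df:
        df["log_perimeter"] = np.log(df["perimeter"])
    covariates = list(covariates)

    if family == "gamma":
        keep = df[response] > 0
        df = df[keep]
        if offset is not None:
            offset = np.asarray(offset)[np.asarray(keep)]
    x = _design_columns(df, covariates, standardize)
    groups, group_idx = np.unique(df[group_col].to_numpy(), return_inverse=True)
    n, n_groups = len(df), len(groups)

    if family == "binomial":
        exog_names = ["intercept"] + covariates
        exog = _term_matrix(x, covariates)
        if offset is not None:
            exog = np.column_stack([exog, np.asarray(offset, dtype=float)])
            exog_names = exog_names + ["global_offset"]
        vc = sp.csr_matrix(
            (np.ones(n), (np.arange(n), group_idx)), shape=(n, n_groups)
        )
        model = sm.BinomialBayesMixedGLM(
            df[response].to_numpy().astype(float),
            exog,
            exog_vc=vc,
            ident=np.zeros(n_groups, dtype=int),
            vcp_p=2.0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit_vb()
        params = pd.Series(fit.fe_mean, index=exog_names)
        bse = pd.Series(fit.fe_sd, index=exog_names)
        re_sd = float(np.exp(fit.vcp_mean[0]))
        return RegressionResult(
            family="binomial",
            terms=covariates,
            params=params,
            bse=bse,
            random_effect_sd=re_sd,
            notes="" if re_sd > 1e-4 else "singular random effect",
        )

    # counts: log-normal approximation to the Gamma log-link
    y = np.log(df[response].astype(float).to_numpy())
    if offset is not None:
        y = y - np.asarray(offset, dtype=float)
    exog = _term_matrix(x, covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=group_idx)
        fit = model.fit(method="lbfgs", maxiter=200)
    names = ["intercept"] + covariates
    k = len(names)
    params = pd.Series(np.asarray(fit.params)[:k], index=names)
    bse = pd.Series(np.asarray(fit.bse)[:k], index=names)
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    singular = re_var <= 1e-8
    return RegressionResult(
        family="lmm-log",
        terms=covariates,
        params=params,
        bse=bse,
        converged=bool(fit.converged),
        random_effect_sd=float(np.sqrt(max(re_var, 0.0))),
        notes="singular random effect; equivalent to the fixed-effects fit"
        if singular
        else "",
    )


def sign_table(
    results: dict[str, RegressionResult] | RegressionResult,
    level: float = 0.95,
) -> pd.DataFrame:
    """Qualitative effect-direction matrix: ``+``, ``-`` or ``NS``.

    A coefficient is called significant when its normal-approximation
    confidence interval at ``level`` excludes zero.
    """
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    if isinstance(results, RegressionResult):
        results = {"model": results}
    rows = {}
    for name, res in results.items():
        col = {}
        for term in res.params.index:
            if term == "intercept":
                continue
            est, se = res.params[term], res.bse[term]
            if est - z * se > 0:
                col[term] = "+"
            elif est + z * se < 0:
                col[term] = "-"
            else:
                col[term] = "NS"
        rows[name] = col
    return pd.DataFrame(rows).fillna("")
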