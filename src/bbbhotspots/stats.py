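"""Cohort statistics: SVD scoring, agreement, descriptives and models.

Covers the composite small-vessel-disease burden score, linearly weighted
Cohen's kappa for intra-rater agreement, descriptive cohort tables, group
comparisons with automatic test selection, the p < 0.1 univariable screen,
multivariable logistic (presence) and proportional-odds ordinal (count)
regressions with pre-established adjustment sets, and VIF collinearity
screening (acceptable below 5).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.miscmodels.ordinal_model import OrderedModel

VIF_ACCEPTABLE = 5.0

#: pre-established adjustment covariates (model 1); model 2 adds SVD type.
MODEL1_COVARIATES = ("age", "log10_wmh_norm", "lacune_count", "cmb_count")
MODEL2_EXTRA = ("svd_type_cadasil",)


class UndefinedKappaError(ValueError):
    """Kappa undefined: fewer than 2 distinct categories across both raters."""


# ---------------------------------------------------------------------------
# composite score and agreement


def total_svd_score(
    lacune_count: int,
    cmb_count: int,
    fazekas_dwmh: int,
    fazekas_pvh: int,
    pvs_bg: int,
) -> int:
    """Total SVD burden score, ordinal 0-4.

    One point each for: one or more lacunes; one or more microbleeds;
    confluent deep WMH (deep Fazekas 2-3) or periventricular WMH extending
    into deep WM (periventricular Fazekas 3); moderate-to-severe basal
    ganglia perivascular spaces (grade 2-4).
    """
    if lacune_count < 0 or cmb_count < 0:
        raise ValueError("lesion counts must be >= 0")
    if fazekas_dwmh not in (0, 1, 2, 3) or fazekas_pvh not in (0, 1, 2, 3):
        raise ValueError("Fazekas grades must be in 0..3")
    if pvs_bg not in (0, 1, 2, 3, 4):
        raise ValueError("basal ganglia PVS grade must be in 0..4")
    score = 0
    score += lacune_count >= 1
    score += cmb_count >= 1
    score += fazekas_dwmh in (2, 3) or fazekas_pvh == 3
    score += pvs_bg in (2, 3, 4)
    return int(score)


def weighted_kappa(ratings_a, ratings_b, weighting: str = "linear") -> float:
    """Weighted Cohen's kappa between two ordinal rating vectors.

    kappa = 1 - sum(w*O) / sum(w*E) with disagreement weights
    w_ij = |i-j|/(k-1) (linear) or (|i-j|/(k-1))^2 (quadratic), observed
    proportions O and chance-expected proportions E from the marginals.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be equal-length non-empty 1D vectors")
    cats = np.unique(np.concatenate([a, b]))
    k = len(cats)
    if k < 2:
        raise UndefinedKappaError("fewer than 2 distinct categories across both raters")
    index = {c: i for i, c in enumerate(cats)}
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[index[x], index[y]] += 1
    obs /= obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = np.abs(i - j) / (k - 1)
    if weighting == "quadratic":
        w = w**2
    elif weighting != "linear":
        raise ValueError(f"unknown weighting {weighting!r}")
    denom = (w * exp).sum()
    if denom == 0:
        raise UndefinedKappaError("degenerate marginals: expected disagreement is zero")
    return float(1.0 - (w * obs).sum() / denom)


# ---------------------------------------------------------------------------
# descriptive tables and group comparisons

VariableKind = str  # "continuous" | "ordinal" | "binary"


def _is_normal(values: np.ndarray, alpha: float = 0.05) -> bool:
    values = values[np.isfinite(values)]
    if len(values) < 4:  # too small for a normality check; report mean (SD)
        return True
    if np.ptp(values) == 0:
        return False
    return sps.shapiro(values).pvalue >= alpha


def summarize_variable(values, kind: VariableKind, n_total: int | None = None) -> str:
    """Format one variable the way cohort tables print it.

    Continuous normal: ``mean (SD)``; ordinal / non-normal: ``median (IQR)``;
    binary: ``n (%)`` with the percentage to one decimal.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty group")
    if kind == "binary":
        n = int(v.sum())
        total = n_total if n_total is not None else v.size
        return f"{n} ({100.0 * n / total:.1f})"
    if kind == "ordinal" or (kind == "continuous" and not _is_normal(v)):
        med = np.median(v)
        q1, q3 = np.percentile(v, [25, 75])
        return f"{_fmt(med)} ({_fmt(q1)}–{_fmt(q3)})"
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return f"{v.mean():.1f} ({sd:.1f})"


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:.1f}"


def cohort_table(
    records: pd.DataFrame,
    variables: dict[str, VariableKind],
    group: str | None = None,
) -> pd.DataFrame:
    """Descriptive table, overall and per group level."""
    if records.empty:
        raise ValueError("empty cohort")
    cols: dict[str, list[str]] = {"all": []}
    groups = {}
    if group is not None:
        for level, sub in records.groupby(group):
            if sub.empty:
                raise ValueError(f"empty group {level!r}")
            groups[str(level)] = sub
            cols[str(level)] = []
    for var, kind in variables.items():
        cols["all"].append(summarize_variable(records[var].dropna(), kind))
        for level, sub in groups.items():
            cols[level].append(summarize_variable(sub[var].dropna(), kind))
    return pd.DataFrame(cols, index=list(variables))


@dataclass
class ComparisonResult:
    variable: str
    test: str
    statistic: float
    p: float

    @property
    def applicable(self) -> bool:
        return self.test != "not_applicable"


def compare_groups(
    records: pd.DataFrame,
    variable: str,
    group: str,
    kind: VariableKind = "continuous",
) -> ComparisonResult:
    """Two-sided group comparison with conventional test selection.

    Continuous normal: Student t (2 groups) or one-way ANOVA; continuous
    non-normal and ordinal: Mann-Whitney U / Kruskal-Wallis; binary:
    Pearson chi-square, or Fisher's exact when any expected 2x2 cell < 5.
    """
    sub = records[[variable, group]].dropna()
    levels = [g[variable].to_numpy(dtype=float) for _, g in sub.groupby(group)]
    if len(levels) < 2:
        raise ValueError("grouping must yield at least 2 groups")
    pooled = np.concatenate(levels)
    if np.ptp(pooled) == 0:
        return ComparisonResult(variable, "not_applicable", float("nan"), float("nan"))

    if kind == "binary":
        table = pd.crosstab(sub[group], sub[variable]).to_numpy()
        if table.shape[1] < 2:
            return ComparisonResult(variable, "not_applicable", float("nan"), float("nan"))
        expected = sps.contingency.expected_freq(table)
        if table.shape == (2, 2) and (expected < 5).any():
            stat, p = sps.fisher_exact(table)
            return ComparisonResult(variable, "fisher_exact", float(stat), float(p))
        chi2 = sps.chi2_contingency(table, correction=False)
        return ComparisonResult(variable, "chi_square", float(chi2.statistic), float(chi2.pvalue))

    if kind == "ordinal" or not all(_is_normal(v) for v in levels):
        if len(levels) == 2:
            res = sps.mannwhitneyu(levels[0], levels[1], alternative="two-sided")
            return ComparisonResult(variable, "mann_whitney_u", float(res.statistic), float(res.pvalue))
        res = sps.kruskal(*levels)
        return ComparisonResult(variable, "kruskal_wallis", float(res.statistic), float(res.pvalue))

    if len(levels) == 2:
        res = sps.ttest_ind(levels[0], levels[1])
        return ComparisonResult(variable, "student_t", float(res.statistic), float(res.pvalue))
    res = sps.f_oneway(*levels)
    return ComparisonResult(variable, "anova", float(res.statistic), float(res.pvalue))


def spearman_association(records: pd.DataFrame, var_a: str, var_b: str) -> ComparisonResult:
    """Spearman rank correlation for ordinal-vs-ordinal associations."""
    sub = records[[var_a, var_b]].dropna()
    rho, p = sps.spearmanr(sub[var_a], sub[var_b])
    return ComparisonResult(f"{var_a}~{var_b}", "spearman", float(rho), float(p))


def univariable_screen(
    results: pd.DataFrame,
    alpha: float = 0.1,
    always_include: tuple[str, ...] = (),
) -> list[str]:
    """Candidate covariates: p strictly below alpha, plus the vascular
    function measures that enter regardless of the screen."""
    if not {"variable", "p"} <= set(results.columns):
        raise ValueError("results must have 'variable' and 'p' columns")
    selected = [str(v) for v, p in zip(results["variable"], results["p"]) if np.isfinite(p) and p < alpha]
    for extra in always_include:
        if extra not in selected:
            selected.append(extra)
    return selected


# ---------------------------------------------------------------------------
# multivariable models


@dataclass
class RegressionResult:
    """One fitted model: coefficient/OR table plus diagnostics."""

    model_label: str
    outcome: str
    table: pd.DataFrame  # index: covariate; columns: estimate, se, or, ci_low, ci_high, p
    n_used: int
    vif: pd.DataFrame
    converged: bool
    separation: bool = False
    notes: list[str] = field(default_factory=list)


def vif_screen(design: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor per covariate: 1/(1-R^2) from regressing
    each column on the others (with intercept).  Exact linear dependence is
    reported as infinite VIF."""
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 covariates")
    if n <= p:
        raise ValueError("VIF needs more observations than covariates")
    rows = []
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            vif = float("inf")
        else:
            r2 = 1.0 - np.sum(resid**2) / ss_tot
            vif = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"covariate": design.columns[j], "vif": vif, "acceptable": vif < VIF_ACCEPTABLE})
    return pd.DataFrame(rows).set_index("covariate")


def _collapse_count_outcome(counts: np.ndarray, top_percentile: float = 90.0) -> np.ndarray:
    """Ordinal levels for count outcomes: raw counts, with the tail above the
    cohort's 90th percentile collapsed into one top category."""
    cap = np.percentile(counts, top_percentile)
    return np.minimum(counts, np.ceil(cap)).astype(int)


def fit_models(
    records: pd.DataFrame,
    outcome: str,
    candidate_covariates: tuple[str, ...] = (),
    model_version: int = 1,
    outcome_type: str = "presence",
) -> RegressionResult:
    """Fit the multivariable model for one hotspot outcome.

    Presence outcomes (0/1) use logistic regression; count outcomes use a
    proportional-odds ordinal model.  Model 1 adjusts for age, log10
    normalized WMH volume, lacune and CMB counts; model 2 additionally for
    SVD type.  Missing covariate values (e.g. CVR) are handled complete-case
    and the n actually used is recorded.  Non-convergence and separation are
    flagged, never silently returned.
    """
    if model_version not in (1, 2):
        raise ValueError("model_version must be 1 or 2")
    if outcome_type not in ("presence", "count"):
        raise ValueError("outcome_type must be 'presence' or 'count'")
    base = list(MODEL1_COVARIATES) + (list(MODEL2_EXTRA) if model_version == 2 else [])
    covariates = base + [c for c in candidate_covariates if c not in base]
    missing_cols = [c for c in covariates + [outcome] if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records missing columns: {missing_cols}")

    data = records[[outcome, *covariates]].dropna()
    # drop constant covariates (e.g. no CADASIL patients in a subgroup)
    notes = []
    kept = []
    for c in covariates:
        if data[c].nunique() > 1:
            kept.append(c)
        else:
            notes.append(f"dropped constant covariate {c}")
    covariates = kept
    n_used = len(data)
    y = data[outcome].to_numpy()
    X = data[covariates].astype(float)

    label = f"{'logistic' if outcome_type == 'presence' else 'ordinal'}|model{model_version}"
    vif = vif_screen(X) if len(covariates) >= 2 and n_used > len(covariates) else pd.DataFrame()

    converged, separation = True, False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if outcome_type == "presence":
                model = sm.Logit(y.astype(float), sm.add_constant(X))
                fit = model.fit(disp=0, maxiter=200)
                params = fit.params.drop("const")
                se = fit.bse.drop("const")
                pvals = fit.pvalues.drop("const")
                conf = fit.conf_int().drop("const")
            else:
                y_ord = _collapse_count_outcome(y)
                model = OrderedModel(y_ord, X, distr="logit")
                fit = model.fit(method="bfgs", disp=0, maxiter=500)
                params = fit.params[covariates]
                se = fit.bse[covariates]
                pvals = fit.pvalues[covariates]
                conf = fit.conf_int().loc[covariates]
            converged = bool(getattr(fit.mle_retvals, "get", lambda *a: True)("converged", True)) if hasattr(fit, "mle_retvals") else True
            if hasattr(fit, "mle_retvals") and isinstance(fit.mle_retvals, dict):
                converged = bool(fit.mle_retvals.get("converged", True))
    except Exception as exc:  # separation or optimizer failure
        notes.append(f"fit failed: {exc}")
        empty = pd.DataFrame(columns=["estimate", "se", "odds_ratio", "ci_low", "ci_high", "p"])
        return RegressionResult(label, outcome, empty, n_used, vif, converged=False,
                                separation="separat" in str(exc).lower(), notes=notes)

    if np.any(np.abs(params.to_numpy()) > 15) or np.any(~np.isfinite(se.to_numpy())):
        separation = True
        notes.append("suspected separation: extreme coefficient or unstable standard error")

    table = pd.DataFrame(
        {
            "estimate": params,
            "se": se,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(conf[0]),
            "ci_high": np.exp(conf[1]),
            "p": pvals,
        }
    )
    return RegressionResult(label, outcome, table, n_used, vif, converged=converged,
                            separation=separation, notes=notes)
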