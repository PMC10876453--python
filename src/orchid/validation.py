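"""Construct-validity analysis: quartile tables, correlations, group tests.

The validity battery mirrors standard practice for diet-quality indices:
describe variables across score quartiles (survey-weighted means with 95 %
CIs), correlate the score with its components, with food-group intakes and
with external diet-quality measures, label correlation strengths, test sex
effects, and cross-tabulate socio-demographics against score quartiles.

Correlation-strength labels: high when |r| > 0.5, moderate when
0.2 <= |r| <= 0.5 (the boundary 0.2 is closed on the moderate side, by
symmetry with the closed 0.5 boundary), low when |r| < 0.2.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import CohortError

Z95 = 1.959963984540054  # two-sided 95 % normal quantile


def strength_label(r: float) -> str:
    """Label a correlation coefficient's strength (high/moderate/low)."""
    if r is None or (isinstance(r, float) and math.isnan(r)):
        return "undefined"
    a = abs(r)
    if a > 0.5:
        return "high"
    if a >= 0.2:
        return "moderate"
    return "low"


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    method: str
    r: float
    p_value: float
    n: int
    strength: str


def correlate(
    scores, variable, method: str = "spearman", name: str = ""
) -> CorrelationResult:
    """Correlate the score with one variable (Spearman or Pearson).

    NaN pairs are dropped; a constant input yields an undefined result
    (r = NaN) rather than an error.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(variable, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise CohortError("correlation needs at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(name, method, float("nan"), float("nan"), int(x.size), "undefined")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method '{method}'")
    return CorrelationResult(name, method, float(r), float(p), int(x.size), strength_label(r))


def assign_quartiles(scores, weights=None) -> np.ndarray:
    """Assign score quartiles 1..4 from the (weighted) empirical CDF.

    Each individual's midpoint cumulative weight along the score order
    determines its quartile; with equal weights the four groups differ in
    size by at most one.
    """
    x = np.asarray(scores, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise CohortError("sampling weights must be > 0")
    order = np.argsort(x, kind="mergesort")
    cw = np.cumsum(w[order])
    mid = (cw - w[order] / 2.0) / cw[-1]
    # tiny slack so float noise at exact quarter boundaries cannot flip bins
    q_sorted = np.minimum(np.floor(mid * 4 - 1e-9).astype(int) + 1, 4)
    q_sorted = np.maximum(q_sorted, 1)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def weighted_mean_ci(values, weights=None, clusters=None) -> dict:
    """Survey-weighted mean with SD and a 95 % CI.

    The variance of the weighted mean uses Taylor linearisation of the
    ratio estimator; when cluster identifiers are supplied the linearised
    terms are summed within clusters first (cluster-robust).
    """
    x = np.asarray(values, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise CohortError("sampling weights must be > 0")
    wsum = w.sum()
    mean = float(np.sum(w * x) / wsum)
    sd = float(np.sqrt(np.sum(w * (x - mean) ** 2) / wsum))
    z = w * (x - mean) / wsum  # linearised influence terms
    if clusters is not None:
        z = pd.Series(z).groupby(np.asarray(clusters)).sum().values
    m = z.size
    var = m / (m - 1) * float(np.sum(z**2)) if m > 1 else 0.0
    se = math.sqrt(var)
    return {
        "mean": mean,
        "sd": sd,
        "se": se,
        "ci_low": mean - Z95 * se,
        "ci_high": mean + Z95 * se,
        "n": int(x.size),
    }


def quartile_table(
    scores: pd.Series,
    variables: pd.DataFrame,
    weights: pd.Series | None = None,
    clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-quartile (and overall) weighted means, SDs and 95 % CIs.

    Returns a tidy frame ``variable, quartile, mean, sd, ci_low, ci_high, n``
    with quartile in {Q1..Q4, overall}.
    """
    if len(scores) < 8:
        raise CohortError("quartile summaries need at least 8 individuals")
    q = assign_quartiles(scores.values, None if weights is None else weights.values)
    rows = []
    for var in variables.columns:
        v = variables[var].values
        for qi in (1, 2, 3, 4):
            sel = q == qi
            res = weighted_mean_ci(
                v[sel],
                None if weights is None else weights.values[sel],
                None if clusters is None else clusters.values[sel],
            )
            rows.append({"variable": var, "quartile": f"Q{qi}", **res})
        res = weighted_mean_ci(
            v,
            None if weights is None else weights.values,
            None if clusters is None else clusters.values,
        )
        rows.append({"variable": var, "quartile": "overall", **res})
    return pd.DataFrame(rows)


def wilcoxon_sex_test(values, sex) -> dict:
    """Two-sample Wilcoxon rank-sum test of a sex effect."""
    sex = np.asarray(sex)
    groups = pd.unique(sex)
    if len(groups) != 2:
        raise CohortError(f"expected 2 sex groups, got {len(groups)}")
    v = np.asarray(values, dtype=float)
    a, b = v[sex == groups[0]], v[sex == groups[1]]
    if a.size == 0 or b.size == 0:
        raise CohortError("empty sex group")
    stat, p = stats.ranksums(a, b)
    return {"kind": "wilcoxon", "statistic": float(stat), "p_value": float(p)}


def anova_sex_adjusted(values, sex, quartile) -> dict:
    """ANOVA of a variable on sex, adjusted on score quartile; sex effect."""
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "sex": np.asarray(sex), "q": np.asarray(quartile)}
    )
    if df["sex"].nunique() < 2:
        raise CohortError("need at least 2 sex groups")
    fit = smf.ols("y ~ C(sex) + C(q)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return {
        "kind": "anova_adjusted",
        "statistic": float(table.loc["C(sex)", "F"]),
        "p_value": float(table.loc["C(sex)", "PR(>F)"]),
    }


def chi_square(table: np.ndarray | pd.DataFrame) -> dict:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise CohortError("contingency table has an empty row or column")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return {"kind": "chisq", "statistic": float(stat), "p_value": float(p), "dof": int(dof)}


def group_tests(values, group, kind: str, quartile=None) -> dict:
    """Dispatch the three test kinds used in the validity battery."""
    if kind == "wilcoxon":
        return wilcoxon_sex_test(values, group)
    if kind == "anova_adjusted":
        if quartile is None:
            raise CohortError("anova_adjusted requires score quartiles")
        return anova_sex_adjusted(values, group, quartile)
    if kind == "chisq":
        return chi_square(pd.crosstab(np.asarray(group), np.asarray(values)))
    raise ValueError(f"unknown test kind '{kind}'")


# ---------------------------------------------------------------------------
# Full validity report
# ---------------------------------------------------------------------------

REPORT_SCHEMA = {
    "score_summary": dict,
    "component_correlations": list,
    "intake_correlations": list,
    "metric_correlations": list,
    "quartile_tables": list,
    "sex_tests": list,
    "sociodemographic_tests": list,
    "notes": list,
}


def validate_report(report: dict) -> None:
    """Structural check of a validity report against the shipped schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise CohortError(f"report missing section '{key}'")
        if not isinstance(report[key], typ):
            raise CohortError(f"report section '{key}' must be {typ.__name__}")
    for section in ("component_correlations", "intake_correlations", "metric_correlations"):
        for entry in report[section]:
            for field in ("variable", "method", "r", "p_value", "n", "strength"):
                if field not in entry:
                    raise CohortError(f"{section} entry missing '{field}'")


def _corr_entry(scores, variable, method, name) -> dict:
    entry = asdict(correlate(scores, variable, method, name))
    if math.isnan(entry["r"]):
        entry["r"] = None
        entry["p_value"] = None
    return entry


def validity_report(
    scores: pd.DataFrame,
    group_intakes: pd.DataFrame,
    metrics: pd.DataFrame,
    covariates: pd.DataFrame,
    weights: pd.Series | None = None,
) -> dict:
    """Assemble the full construct-validity battery as a JSON-ready dict.

    Parameters
    ----------
    scores:
        Output of :func:`orchid.scoring.compute_orchid` (components + total,
        indexed by individual_id).
    group_intakes:
        Per-individual mean daily grams per food group (columns = groups).
    metrics:
        Output of :func:`orchid.diet_quality.cohort_diet_quality`.
    covariates:
        Must include individual_id, sex; categorical columns among
        education/smoking/physical_activity are cross-tabulated.
    weights:
        Optional sampling weights indexed like ``scores``.
    """
    notes: list[str] = []
    total = scores["total"]
    idx = total.index
    metrics = metrics.set_index("individual_id").reindex(idx)
    cov = covariates.set_index("individual_id").reindex(idx)
    group_intakes = group_intakes.reindex(idx)
    w = None if weights is None else pd.Series(weights).reindex(idx)

    if total.nunique() == 1:
        notes.append("score is constant; correlations and quartiles undefined")
        report = {
            "score_summary": {
                "mean": float(total.mean()),
                "sd": 0.0,
                "min": float(total.min()),
                "max": float(total.max()),
                "n": int(len(total)),
            },
            "component_correlations": [],
            "intake_correlations": [],
            "metric_correlations": [],
            "quartile_tables": [],
            "sex_tests": [],
            "sociodemographic_tests": [],
            "notes": notes,
        }
        validate_report(report)
        return report

    component_cols = [c for c in scores.columns if c != "total"]
    comp_corr = [
        _corr_entry(total, scores[c], "spearman", c) for c in component_cols
    ]
    intake_corr = [
        _corr_entry(total, group_intakes[c], "spearman", c)
        for c in group_intakes.columns
    ]
    metric_corr = [
        _corr_entry(total, metrics[c], "pearson", c)
        for c in ("energy_kcal", "sed", "mar", "pandiet", "pandiet_adequacy", "pandiet_moderation")
        if c in metrics.columns
    ]

    qt = quartile_table(
        total,
        metrics[[c for c in metrics.columns if metrics[c].dtype.kind in "fi"]],
        w,
    )
    quartiles = assign_quartiles(total.values, None if w is None else w.values)

    sex_tests = []
    if cov["sex"].nunique() == 2:
        sex_tests.append({"variable": "total", **wilcoxon_sex_test(total.values, cov["sex"].values)})
        for c in ("sed", "mar", "pandiet", "energy_kcal"):
            if c in metrics.columns:
                sex_tests.append(
                    {
                        "variable": c,
                        **anova_sex_adjusted(metrics[c].values, cov["sex"].values, quartiles),
                    }
                )
    else:
        notes.append("single sex present; sex tests skipped")

    socio_tests = []
    for c in ("sex", "education", "smoking", "physical_activity"):
        if c in cov.columns and cov[c].nunique() > 1:
            res = chi_square(pd.crosstab(cov[c].values, quartiles))
            socio_tests.append({"variable": c, **res})

    report = {
        "score_summary": {
            "mean": float(total.mean()),
            "sd": float(total.std(ddof=1)),
            "min": float(total.min()),
            "max": float(total.max()),
            "n": int(len(total)),
        },
        "component_correlations": comp_corr,
        "intake_correlations": intake_corr,
        "metric_correlations": metric_corr,
        "quartile_tables": qt.to_dict(orient="records"),
        "sex_tests": sex_tests,
        "sociodemographic_tests": socio_tests,
        "notes": notes,
    }
    validate_report(report)
    return report
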