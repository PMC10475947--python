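"""Group-comparison layer: transforms, assumption checks, ANOVA with compact
letters, t-tests and a mixed-model screen.

These are the standard tools a field study uses to compare species and
habitats after the index computations: rank-based inverse-normal scores for
bounded indices, log transforms for strictly positive variables, one-way
ANOVA with Tukey-HSD compact letter displays for habitat contrasts within a
species, two-sample t-tests for between-species contrasts, one-sample
t-tests of preference indices against zero, and a linear mixed model with
habitat × species fixed effects and quadrats nested within sites as random
terms.  Ordinary fits delegate to scipy/statsmodels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "quantile_transform",
    "log_transform",
    "assumption_checks",
    "oneway_anova_letters",
    "welch_or_student_t",
    "one_sample_t",
    "compact_letter_display",
    "mixed_model_screen",
]


def quantile_transform(values) -> np.ndarray:
    """Rank-based inverse-normal scores with the Blom offset (r − 3/8)/(n + 1/4).

    Ties receive average ranks.  The result is a deterministic function of
    the ranks only, symmetric about zero for untied data.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ValueError("need a 1-d array of at least 3 values")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.ptp(values) == 0:
        raise ValueError("all values tied — quantile transform is degenerate")
    ranks = sps.rankdata(values, method="average")
    n = len(values)
    return sps.norm.ppf((ranks - 0.375) / (n + 0.25))


def log_transform(values, base: str = "e") -> tuple[np.ndarray, np.ndarray]:
    """Log-transform positive values; non-positive rows are flagged, not fatal.

    Returns ``(transformed, ok_mask)`` where excluded rows hold NaN.
    """
    values = np.asarray(values, dtype=float)
    ok = values > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("log transform: excluded %d non-positive value(s)", n_bad)
    out = np.full_like(values, np.nan, dtype=float)
    if base == "e":
        out[ok] = np.log(values[ok])
    elif base == "10":
        out[ok] = np.log10(values[ok])
    elif base == "2":
        out[ok] = np.log2(values[ok])
    else:
        raise ValueError("base must be 'e', '10' or '2'")
    return out, ok


def assumption_checks(values, groups) -> dict:
    """Shapiro-Wilk normality per group and Levene (median-centred) across groups.

    Advisory only — reports p-values and degeneracy flags, never raises on
    a failed assumption.  Groups with n < 3 are skipped with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    report: dict = {"shapiro": {}, "levene_p": np.nan, "degenerate": False, "skipped": []}
    samples = []
    for g in pd.unique(groups):
        vals = values[groups == g]
        vals = vals[np.isfinite(vals)]
        if len(vals) < 3:
            report["skipped"].append(g)
            logger.warning("assumption checks: group %r has n < 3, skipped", g)
            continue
        samples.append(vals)
        if np.ptp(vals) == 0:
            report["shapiro"][g] = np.nan
            report["degenerate"] = True
        else:
            report["shapiro"][g] = float(sps.shapiro(vals).pvalue)
    if len(samples) >= 2 and all(np.ptp(s) > 0 for s in samples):
        report["levene_p"] = float(sps.levene(*samples, center="median").pvalue)
    elif len(samples) >= 2:
        report["degenerate"] = True
        report["levene_p"] = 1.0
    return report


def compact_letter_display(labels, pvals: dict, alpha: float = 0.05) -> dict:
    """Insert-and-absorb compact letter display from pairwise p-values.

    ``pvals`` maps unordered label pairs (frozenset) to p-values.  Groups
    sharing a letter are not significantly different at ``alpha``.
    """
    labels = list(labels)
    letter_sets: list[set] = [set(labels)]
    for (a, b), p in sorted(
        ((tuple(sorted(k)), v) for k, v in pvals.items()), key=lambda kv: kv[0]
    ):
        if p >= alpha:
            continue
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        letter_sets = [
            s
            for i, s in enumerate(new_sets)
            if s and not any(s < t or (s == t and i > j) for j, t in enumerate(new_sets) if j != i)
        ]
    letter_sets.sort(key=lambda s: min(labels.index(x) for x in s))
    out = {lab: "" for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, s in enumerate(letter_sets):
        for lab in labels:
            if lab in s:
                out[lab] += alphabet[i % len(alphabet)]
    return out


@dataclass
class AnovaLetters:
    """One-way ANOVA with Tukey-HSD pairwise tests and compact letters."""

    f_statistic: float
    p_value: float
    letters: dict
    pairwise_p: dict = field(default_factory=dict)
    group_means: dict = field(default_factory=dict)


def oneway_anova_letters(values, groups, alpha: float = 0.05) -> AnovaLetters:
    """Classical one-way ANOVA plus Tukey HSD feeding a compact letter display."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    means = {g: float(np.mean(s)) for g, s in zip(labels, samples)}

    if all(np.ptp(s) == 0 for s in samples) and np.ptp(values) == 0:
        # Zero variance everywhere: no detectable differences by convention.
        letters = {g: "a" for g in labels}
        return AnovaLetters(0.0, 1.0, letters, {}, means)

    f_stat, p = sps.f_oneway(*samples)
    tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    res = pd.DataFrame(tk._results_table.data[1:], columns=tk._results_table.data[0])
    pairwise = {
        frozenset((r["group1"], r["group2"])): float(r["p-adj"]) for _, r in res.iterrows()
    }
    letters = compact_letter_display(labels, pairwise, alpha=alpha)
    return AnovaLetters(float(f_stat), float(p), letters, pairwise, means)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_or_student_t(a, b, *, equal_var: bool = True, paired: bool = False) -> TTestResult:
    """Two-sample t-test; pooled variance by default, Welch via ``equal_var=False``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if np.mean(a) == np.mean(b):
            # Zero variance, equal means: no evidence of difference by convention.
            return TTestResult(0.0, len(a) + len(b) - 2, 1.0, degenerate=True)
        return TTestResult(np.inf, len(a) + len(b) - 2, 0.0, degenerate=True)
    if paired:
        res = sps.ttest_rel(a, b)
        df = len(a) - 1
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        df = float(res.df)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def one_sample_t(values, popmean: float = 0.0) -> TTestResult:
    """One-sample t-test against ``popmean`` (used for β_NF vs 0)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need n >= 2")
    if np.ptp(values) == 0:
        if values[0] == popmean:
            return TTestResult(0.0, len(values) - 1, 1.0, degenerate=True)
        return TTestResult(np.inf if values[0] > popmean else -np.inf, len(values) - 1, 0.0, True)
    res = sps.ttest_1samp(values, popmean)
    return TTestResult(float(res.statistic), float(len(values) - 1), float(res.pvalue))


def mixed_model_screen(
    data: pd.DataFrame,
    response: str,
    *,
    fixed: str = "C(habitat) * C(species)",
    site_col: str = "site",
    quadrat_col: str = "quadrat",
) -> pd.DataFrame:
    """Fixed-effect screen from a mixed model with quadrats nested in sites.

    Fits ``response ~ habitat * species`` with a random site intercept and a
    variance component for quadrats nested within sites (REML via
    statsmodels MixedLM), then reports a Wald chi-square table for the fixed
    terms.  When the random structure is unidentifiable (a single site) or
    the fit is singular/non-convergent, the screen downgrades to a
    fixed-effects-only OLS ANOVA with a warning, flagged in the output.

    Returns a tidy DataFrame: term, statistic, df, p_value, method.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    data = data.copy()
    vals = data[response].to_numpy(dtype=float)
    if np.ptp(vals[np.isfinite(vals)]) == 0:
        logger.warning("mixed model: response is constant — degenerate report")
        return pd.DataFrame(
            {
                "term": [fixed],
                "statistic": [np.nan],
                "df": [np.nan],
                "p_value": [np.nan],
                "method": ["degenerate"],
            }
        )

    n_sites = data[site_col].nunique()
    use_mixed = n_sites >= 2
    if not use_mixed:
        logger.warning("mixed model: single site — random structure unidentifiable, using OLS")

    if use_mixed:
        data["_quadrat_in_site"] = (
            data[site_col].astype(str) + ":" + data["habitat"].astype(str) + ":" + data[quadrat_col].astype(str)
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                model = smf.mixedlm(
                    f"{response} ~ {fixed}",
                    data=data,
                    groups=data[site_col],
                    vc_formula={"quadrat": "0 + C(_quadrat_in_site)"},
                )
                fit = model.fit(reml=True)
            wald = fit.wald_test_terms(scalar=True)
            table = wald.table.reset_index().rename(
                columns={
                    "index": "term",
                    "pvalue": "p_value",
                    "P>chi2": "p_value",
                    "chi2": "statistic",
                    "df constraint": "df",
                    "df_constraint": "df",
                }
            )
            table = table.loc[:, ~table.columns.duplicated()]
            table = table[table["term"] != "Intercept"]
            table["method"] = "mixedlm_wald"
            return table[["term", "statistic", "df", "p_value", "method"]].reset_index(drop=True)
        except (ConvergenceWarning, np.linalg.LinAlgError, ValueError) as err:
            logger.warning("mixed model fit failed (%s) — downgrading to OLS ANOVA", err)

    ols = smf.ols(f"{response} ~ {fixed}", data=data).fit()
    an = sm.stats.anova_lm(ols, typ=2).reset_index().rename(columns={"index": "term"})
    an = an[an["term"] != "Residual"]
    out = pd.DataFrame(
        {
            "term": an["term"],
            "statistic": an["F"],
            "df": an["df"],
            "p_value": an["PR(>F)"],
            "method": "ols_anova",
        }
    )
    return out
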