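"""Statistics layer: panel preprocessing, the donor-random-intercept
mixed model, and the paired-test / repeated-measures ANOVA toolkit.

Multiplex chemokine panels are preprocessed by stripping asterisk
annotations, substituting below-range readings ("OOR <") with 50% of
the analyte's minimum detected value, and restricting analysis to
analytes inside the assay's working range. Per analyte, concentration
is modeled on the natural-log scale with a linear mixed model::

    log(Value) ~ Condition + Oxygen + Condition:Oxygen + (1 | Donor)

with DMSO and 2% oxygen as reference levels, fitted by REML; per-
contrast p-values come from t statistics on residual degrees of
freedom and are pooled across analytes with a Benjamini-Hochberg
adjustment. Colonoid sizes, ELISA (on log2 data) and blot folds use
paired t-tests or repeated-measures one-way ANOVA with Šídák-adjusted
pairwise contrasts. Because inter-donor variability is large, reports
list every comparison with p < 0.2 alongside the usual significance
tiers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .design import Condition, resolve_condition

__all__ = [
    "PanelTable",
    "LmmFit",
    "TestResult",
    "preprocess_panel",
    "filter_detection_range",
    "fit_lmm",
    "adjust_fits_bh",
    "bh_adjust",
    "sidak_adjust",
    "paired_t",
    "rm_anova_sidak",
    "log2_elisa",
    "report_pvalues",
]

OOR_LOW = re.compile(r"^\s*OOR\s*<\s*$", re.IGNORECASE)
OOR_HIGH = re.compile(r"^\s*OOR\s*>\s*$", re.IGNORECASE)


#: A preprocessed panel is a tidy DataFrame with columns
#: donor, oxygen, condition, analyte, value, oor_low, oor_high.
PanelTable = pd.DataFrame


def preprocess_panel(raw: pd.DataFrame, token_column: str = "token") -> PanelTable:
    """Convert raw plate-reader tokens to numeric concentrations.

    Rules: asterisks are stripped ("45.2*" -> 45.2); "OOR <" readings
    are replaced with 50% of the minimum *detected* value of that
    analyte (across all its rows) and flagged ``oor_low``; "OOR >"
    readings are flagged ``oor_high`` with no substituted value. An
    analyte with only below-range readings has no minimum to halve and
    raises.
    """
    if token_column not in raw.columns:
        raise ValueError(f"no column {token_column!r} in panel table")
    df = raw.copy()

    def parse(token) -> tuple[float | None, bool, bool]:
        text = str(token).strip()
        if OOR_LOW.match(text):
            return None, True, False
        if OOR_HIGH.match(text):
            return None, False, True
        return float(text.replace("*", "")), False, False

    parsed = [parse(t) for t in df[token_column]]
    df["value"] = [v for v, _, _ in parsed]
    df["oor_low"] = [lo for _, lo, _ in parsed]
    df["oor_high"] = [hi for _, _, hi in parsed]

    for analyte, group in df.groupby("analyte"):
        if group["oor_low"].any():
            detected = group.loc[~group["oor_low"] & ~group["oor_high"], "value"]
            if detected.empty:
                raise ValueError(
                    f"analyte {analyte!r} has only out-of-range readings; "
                    "the 50%-of-minimum substitution is undefined"
                )
            sub = 0.5 * float(detected.min())
            df.loc[(df["analyte"] == analyte) & df["oor_low"], "value"] = sub
    return df


def filter_detection_range(
    panel: PanelTable,
    lower: float = 10.0,
    upper: dict[str, float] | float | None = None,
    max_oor_high_fraction: float = 0.1,
) -> tuple[PanelTable, list[str]]:
    """Restrict the panel to analytes within the assay's working range.

    An analyte is retained when its median observed concentration is at
    least ``lower`` (pg/mL), at most its upper detection limit when one
    is supplied, and no more than ``max_oor_high_fraction`` of its rows
    are above-range. Returns the filtered panel and the retained
    analyte names.
    """
    retained = []
    for analyte, group in panel.groupby("analyte"):
        values = group.loc[group["value"].notna(), "value"]
        if values.empty:
            continue
        med = float(values.median())
        if med < lower:
            continue
        if upper is not None:
            limit = upper.get(analyte) if isinstance(upper, dict) else upper
            if limit is not None and med > limit:
                continue
        if group["oor_high"].mean() > max_oor_high_fraction:
            continue
        retained.append(analyte)
    filtered = panel[panel["analyte"].isin(retained) & ~panel["oor_high"]].copy()
    return filtered, sorted(retained)


@dataclass
class LmmFit:
    """Fixed effects, variance components and contrast tests for one
    analyte's mixed model."""

    analyte: str
    contrasts: pd.DataFrame  # term, estimate, se, df, t, p_raw [, p_adj]
    donor_intercept_sd: float
    residual_sd: float
    n_obs: int
    singular: bool = False
    residual_normality_p: float = float("nan")
    method: str = "MixedLM-REML"


def _design_formula() -> str:
    return (
        "log_value ~ C(condition, Treatment('DMSO')) "
        "* C(oxygen, Treatment('2%'))"
    )


_TERM_CLEANER = re.compile(r"C\((condition|oxygen), Treatment\('[^']*'\)\)\[T\.([^\]]+)\]")


def _clean_term(term: str) -> str:
    out = _TERM_CLEANER.sub(lambda m: f"{m.group(1)}[{m.group(2)}]", term)
    return out.replace(":", " : ")


def fit_lmm(rows: pd.DataFrame, analyte: str | None = None) -> LmmFit:
    """Fit ``log(Value) ~ Condition * Oxygen + (1 | Donor)`` by REML.

    ``rows`` holds one analyte's data with columns donor, oxygen,
    condition, value (> 0). DMSO and 2% oxygen are the reference
    levels. Contrast p-values are two-sided t tests on the Wald
    statistic with residual degrees of freedom n - p (a pragmatic
    approximation to Satterthwaite df; conservative directionally for
    balanced designs of this size). A boundary fit with zero donor
    variance — including exactly collinear, noise-free data, where the
    model reduces to ordinary least squares — is returned flagged
    ``singular`` rather than raised.
    """
    df = rows.copy()
    if analyte is None:
        analyte = str(df["analyte"].iloc[0]) if "analyte" in df.columns else "analyte"
    df = df[df["value"].notna()]
    if (df["value"] <= 0).any():
        raise ValueError("all concentrations must be > 0 for the log transform")
    df["condition"] = df["condition"].map(lambda c: resolve_condition(c).label)
    if df["donor"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 donors")
    if df["condition"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 conditions")
    df["log_value"] = np.log(df["value"].astype(float))

    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(_design_formula(), groups="donor", data=df)
        try:
            fit = model.fit(reml=True)
            params = fit.fe_params
            bse = fit.bse_fe
            resid = np.asarray(fit.resid)
            donor_var = float(np.squeeze(fit.cov_re))
            resid_var = float(fit.scale)
            if donor_var <= 1e-10 * max(resid_var, 1e-12):
                singular = True
        except (np.linalg.LinAlgError, ValueError):
            # zero-variance/collinear data: fall back to OLS, flag it
            import statsmodels.formula.api as smf

            ols = smf.ols(_design_formula(), data=df).fit()
            params, bse, resid = ols.params, ols.bse, np.asarray(ols.resid)
            donor_var, resid_var = 0.0, float(ols.scale)
            singular = True

    n = len(df)
    p = len(params)
    dof = max(n - p, 1)
    terms, est, se_list, tval, pval = [], [], [], [], []
    for term in params.index:
        if term == "Intercept":
            continue
        e, s = float(params[term]), float(bse[term])
        t = e / s if s > 0 else np.inf * np.sign(e) if e else 0.0
        terms.append(_clean_term(term))
        est.append(e)
        se_list.append(s)
        tval.append(t)
        pval.append(float(2.0 * sps.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0)
    contrasts = pd.DataFrame(
        {"term": terms, "estimate": est, "se": se_list, "df": dof, "t": tval, "p_raw": pval}
    )
    norm_p = float(sps.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 and np.ptp(resid) > 0 else float("nan")
    return LmmFit(
        analyte=analyte,
        contrasts=contrasts,
        donor_intercept_sd=float(np.sqrt(max(donor_var, 0.0))),
        residual_sd=float(np.sqrt(max(resid_var, 0.0))),
        n_obs=n,
        singular=singular,
        residual_normality_p=norm_p,
    )


def adjust_fits_bh(fits: list[LmmFit]) -> pd.DataFrame:
    """Pool contrast p-values across analytes and BH-adjust them.

    Returns one tidy frame (analyte, term, estimate, se, df, t, p_raw,
    p_adj); each fit's ``contrasts`` frame also gains a ``p_adj``
    column in place.
    """
    frames = []
    for fit in fits:
        f = fit.contrasts.copy()
        f.insert(0, "analyte", fit.analyte)
        frames.append(f)
    pooled = pd.concat(frames, ignore_index=True)
    pooled["p_adj"] = bh_adjust(pooled["p_raw"].to_list())
    for fit in fits:
        mask = pooled["analyte"] == fit.analyte
        fit.contrasts["p_adj"] = pooled.loc[mask, "p_adj"].to_numpy()
    return pooled


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= rank(i)} p_(j) * m / j, capped at 1;
    stable under input permutation (up to the same reordering).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sidak_adjust(p: float, m: int) -> float:
    """Šídák familywise adjustment 1 - (1 - p)^m for m comparisons."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


@dataclass
class TestResult:
    """One hypothesis test, with its adjustment provenance tagged."""

    __test__ = False  # not a pytest collectible

    comparison: str
    statistic: float
    df: float | tuple
    p_raw: float
    p_adjusted: float | None = None
    method: str = ""


def paired_t(
    group_a: pd.Series | np.ndarray,
    group_b: pd.Series | np.ndarray,
    label: str = "A vs B",
) -> TestResult:
    """Two-sided paired t-test on key-matched measurements.

    When both inputs are Series they are aligned on their index; raises
    when fewer than 3 complete pairs remain or the differences are all
    identical (zero variance, t undefined).
    """
    if isinstance(group_a, pd.Series) and isinstance(group_b, pd.Series):
        a, b = group_a.align(group_b, join="inner")
    else:
        a, b = pd.Series(np.asarray(group_a, float)), pd.Series(np.asarray(group_b, float))
    mask = a.notna() & b.notna()
    d = (a[mask] - b[mask]).to_numpy(dtype=float)
    if d.size < 3:
        raise ValueError(f"paired t-test needs >= 3 complete pairs, got {d.size}")
    if np.ptp(d) == 0:
        raise ValueError("all paired differences are identical; t statistic undefined")
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TestResult(comparison=label, statistic=float(t), df=n - 1, p_raw=p, method="paired t")


def rm_anova_sidak(
    data: pd.DataFrame,
    contrasts: list[tuple[str, str]] | None = None,
    subject: str = "donor",
    within: str = "condition",
    value: str = "value",
) -> tuple[TestResult, list[TestResult]]:
    """Repeated-measures one-way ANOVA with Šídák-adjusted contrasts.

    The subject is a blocking factor: F = MS_within-factor / MS_error
    with df (k-1) and (k-1)(n-1) from the classical sum-of-squares
    decomposition. Requires a complete subject × condition grid.
    Requested pairwise contrasts are paired t-tests with the Šídák
    familywise adjustment over the m requested comparisons. A grid with
    no condition variation at all returns F = 0, p = 1.
    """
    wide = data.pivot_table(index=subject, columns=within, values=value, aggfunc="mean")
    if wide.isna().any().any():
        missing = [
            (s, c) for s in wide.index for c in wide.columns if pd.isna(wide.loc[s, c])
        ]
        raise ValueError(f"incomplete subject×condition grid; missing cells: {missing}")
    x = wide.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = x.mean()
    ss_cond = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    scale = max(ss_total, 1.0)
    if ss_cond <= 1e-12 * scale:
        f_stat, p = 0.0, 1.0
    elif ss_err <= 1e-12 * scale:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_cond / df_cond) / (ss_err / df_err)
        p = float(sps.f.sf(f_stat, df_cond, df_err))
    anova = TestResult(
        comparison=f"RM one-way ANOVA ({within})",
        statistic=f_stat,
        df=(df_cond, df_err),
        p_raw=p,
        method="RM one-way ANOVA",
    )

    posthoc = []
    if contrasts:
        m = len(contrasts)
        for ca, cb in contrasts:
            for c in (ca, cb):
                if c not in wide.columns:
                    raise ValueError(f"contrast level {c!r} absent from the grid")
            res = paired_t(wide[ca], wide[cb], label=f"{ca} vs {cb}")
            posthoc.append(
                TestResult(
                    comparison=res.comparison,
                    statistic=res.statistic,
                    df=res.df,
                    p_raw=res.p_raw,
                    p_adjusted=sidak_adjust(res.p_raw, m),
                    method="paired t + Sidak",
                )
            )
    return anova, posthoc


def log2_elisa(values) -> np.ndarray:
    """log2-transform ELISA concentrations (all must be > 0)."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise ValueError("ELISA values must be positive and finite for log2")
    return np.log2(v)


def significance_tier(p: float) -> str:
    """Asterisk tier: **** <1e-4, *** <1e-3, * <0.05 (figure-legend
    convention; no two-asterisk tier is used)."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def report_pvalues(results: list[TestResult], threshold: float = 0.2) -> pd.DataFrame:
    """Report every comparison with p below ``threshold``.

    Inter-donor differences are large in this system, so the reporting
    threshold is deliberately loose (default 0.2); each row is
    annotated with its significance tier. Adjusted p-values are used
    when present, raw otherwise.
    """
    rows = []
    for res in results:
        p = res.p_adjusted if res.p_adjusted is not None else res.p_raw
        if p < threshold:
            rows.append(
                {
                    "comparison": res.comparison,
                    "method": res.method,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": p,
                    "tier": significance_tier(p),
                }
            )
    return pd.DataFrame(rows, columns=["comparison", "method", "statistic", "df", "p", "tier"])
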