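"""Monthly summaries, seasonal linear models, and annual sinusoid fits.

Seasonality of each sleep parameter is quantified three ways:

* a monthly mean +/- SEM table;
* a Gaussian-identity linear model with categorical month, age group and
  gender (age x gender interaction screened at p < 0.01), followed by
  Bonferroni-adjusted pairwise contrasts of every month against July;
* a least-squares cosine with a 12-month period fitted to the monthly means
  (cosinor: mesor + amplitude * cos(2*pi*(m - phase)/12)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .scoring import SLEEP_PARAMETERS, elapsed_to_clock

ALPHA = 0.01  # study-wide significance threshold
N_MONTH_CONTRASTS = 11  # Bonferroni family: each month vs July, per parameter

CLOCK_PARAMETERS = ("in_bed", "get_up")


def monthly_summary(records: pd.DataFrame, parameters=None) -> pd.DataFrame:
    """Per-month n, mean and SEM for each sleep parameter.

    Months absent from the data are reported as missing rows (NaN), not as
    zeros; single-record months have undefined (NaN) SEM. Clock parameters
    get an extra hh:mm rendering of the mean.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    params = list(parameters or [p for p in SLEEP_PARAMETERS if p in records.columns])
    grouped = records.groupby("month")
    out = pd.DataFrame(index=pd.Index(range(1, 13), name="month"))
    out["n"] = grouped.size().reindex(out.index)
    for p in params:
        out[f"{p}_mean"] = grouped[p].mean().reindex(out.index)
        out[f"{p}_sem"] = grouped[p].sem().reindex(out.index)
        if p in CLOCK_PARAMETERS:
            out[f"{p}_clock"] = out[f"{p}_mean"].map(
                lambda v: elapsed_to_clock(v) if pd.notna(v) else ""
            )
    return out


@dataclass
class GLMResult:
    parameter: str
    coefficients: pd.DataFrame           # term, estimate, se, p
    interaction_significant: bool
    interaction_p: float
    pairwise: pd.DataFrame               # month, diff, p_raw, p_adj, significant
    model: object = field(repr=False, default=None)
    strata: dict = field(repr=False, default_factory=dict)


def _formula(parameter: str, interaction: bool) -> str:
    base = (
        f"{parameter} ~ C(month, Treatment(7)) + C(age_group, Treatment('60s'))"
        " + C(gender, Treatment('male'))"
    )
    if interaction:
        base += " + C(age_group, Treatment('60s')):C(gender, Treatment('male'))"
    return base


def _month_contrasts(fit) -> pd.DataFrame:
    """Each month vs July from a Treatment(7)-coded fit, Bonferroni-adjusted."""
    rows = []
    for term, est in fit.params.items():
        if term.startswith("C(month, Treatment(7))"):
            month = int(term.split("T.")[1].rstrip("]"))
            p_raw = float(fit.pvalues[term])
            p_adj = min(1.0, p_raw * N_MONTH_CONTRASTS)
            rows.append(
                {
                    "month": month,
                    "diff": float(est),
                    "se": float(fit.bse[term]),
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                    "significant": p_adj < ALPHA,
                }
            )
    return pd.DataFrame(rows).sort_values("month").reset_index(drop=True)


def fit_seasonality_glm(records: pd.DataFrame, parameter: str, alpha: float = ALPHA) -> GLMResult:
    """Linear model of one parameter on month + age group + gender.

    The age x gender interaction is screened first; if not significant at
    ``alpha`` the model is refit without it. If it is significant, monthly
    contrasts are additionally computed within gender strata.
    """
    data = records[records["gender"] != "unknown"].copy()
    if data["month"].nunique() < 2:
        raise ValueError("need at least two months of data")
    if data["gender"].nunique() < 2 or data["age_group"].nunique() < 2:
        raise ValueError("need both genders and at least two age groups")
    cells = data.groupby(["age_group", "gender"]).size().unstack(fill_value=0)
    if (cells == 0).any().any():
        empty = [(a, g) for a in cells.index for g in cells.columns if cells.loc[a, g] == 0]
        raise ValueError(f"empty age x gender cell(s): {empty}")

    full = smf.ols(_formula(parameter, True), data=data).fit()
    reduced = smf.ols(_formula(parameter, False), data=data).fit()
    comparison = sm.stats.anova_lm(reduced, full)
    inter_p = float(comparison["Pr(>F)"].iloc[1])
    significant = bool(inter_p < alpha)

    fit = full if significant else reduced
    coef = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "p": fit.pvalues}
    ).rename_axis("term").reset_index()

    strata: dict[str, pd.DataFrame] = {}
    if significant:
        for g, sub in data.groupby("gender"):
            sfit = smf.ols(
                f"{parameter} ~ C(month, Treatment(7)) + C(age_group, Treatment('60s'))",
                data=sub,
            ).fit()
            strata[str(g)] = _month_contrasts(sfit)

    return GLMResult(
        parameter=parameter,
        coefficients=coef,
        interaction_significant=significant,
        interaction_p=inter_p,
        pairwise=_month_contrasts(fit),
        model=fit,
        strata=strata,
    )


def pairwise_vs_july(result: GLMResult) -> pd.DataFrame:
    """The 11 month-vs-July contrasts of a fitted seasonal model."""
    if result.pairwise.empty:
        raise ValueError("model has no month term (July reference missing?)")
    return result.pairwise


@dataclass(frozen=True)
class SinusoidFit:
    """Annual cosine fitted to 12 monthly means.

    ``phase`` is the peak month on a [0, 12) scale (fractional months);
    the nadir sits at phase + 6 (mod 12).
    """

    mesor: float
    amplitude: float
    phase: float
    rss: float

    @property
    def nadir(self) -> float:
        return (self.phase + 6.0) % 12.0


def fit_annual_sinusoid(summary: pd.DataFrame, parameter: str) -> SinusoidFit:
    """Least-squares fit of mesor + A*cos(2*pi*(m - phase)/12) to monthly means.

    Fitted linearly via sine/cosine regressors (exact for this model); needs
    at least three observed months.
    """
    col = f"{parameter}_mean" if f"{parameter}_mean" in summary.columns else parameter
    y = summary[col].to_numpy(dtype=float)
    months = summary.index.to_numpy(dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least three months with means to fit a sinusoid")
    y, m = y[ok], months[ok]
    w = 2 * np.pi * m / 12.0
    X = np.column_stack([np.ones_like(m), np.cos(w), np.sin(w)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    amplitude = float(np.hypot(beta[1], beta[2]))
    phase = float((12.0 / (2 * np.pi)) * np.arctan2(beta[2], beta[1]) % 12.0)
    return SinusoidFit(mesor=float(beta[0]), amplitude=amplitude, phase=phase,
                       rss=float(resid @ resid))
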