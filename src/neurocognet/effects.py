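"""Covariate-adjusted treatment-effect estimation (ANCOVA) and friends.

For any scalar outcome (a domain score, a global network parameter, a
node's hubness) the treatment effect is estimated with a Gaussian
identity-link model of the day-91 value on treatment arm, sex, baseline
value and age:

    d91 ~ arm + sex + baseline + age

The arm coefficient (with its Wald 95% CI) is the adjusted mean
difference; by default it is reported as placebo − active, so with
higher-is-better outcomes a *negative* value favours the active arm.
Estimated marginal means evaluate the fitted model per arm at the sample
means of the remaining design columns.  The standardized mean difference
divides the |adjusted difference| by the baseline pooled SD.  Treatment ×
moderator interactions are tested with likelihood-ratio tests, and change
scores are related to behaviour with Spearman correlations.

No multiple-testing correction is applied by default (the analyses are
exploratory); a Benjamini–Hochberg helper is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class EffectEstimate:
    outcome: str
    adjusted_mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_placebo: int
    n_active: int
    emm_placebo: float
    emm_active: float
    smd: float
    convention: str = "placebo_minus_active"

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "adjusted_mean_difference": self.adjusted_mean_difference,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_placebo": self.n_placebo,
            "n_active": self.n_active,
            "emm_placebo": self.emm_placebo,
            "emm_active": self.emm_active,
            "smd": self.smd,
        }


def standardized_mean_difference(
    adjusted_md: float, sd_placebo: float, n_placebo: int, sd_active: float, n_active: int
) -> float:
    """|adjusted difference| / baseline pooled SD (variances weighted n−1)."""
    num = (n_placebo - 1) * sd_placebo**2 + (n_active - 1) * sd_active**2
    den = n_placebo + n_active - 2
    pooled = np.sqrt(num / den)
    if pooled <= 0:
        raise ValueError("pooled baseline SD must be positive")
    return float(abs(adjusted_md) / pooled)


def _design(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    active = (df["arm"] == "active").to_numpy(dtype=float)
    female = (df["sex"] == "F").to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(df)), active, female,
        df["baseline"].to_numpy(dtype=float), df["age"].to_numpy(dtype=float),
    ])
    y = df["d91"].to_numpy(dtype=float)
    return X, y, active


def fit_treatment_model(
    df: pd.DataFrame,
    outcome: str = "outcome",
    convention: str = "placebo_minus_active",
) -> EffectEstimate:
    """ANCOVA on a tidy frame with columns d91, baseline, arm, sex, age.

    Complete-case per outcome; requires at least 3 participants per arm.
    """
    if convention not in ("placebo_minus_active", "active_minus_placebo"):
        raise ValueError(f"unknown sign convention {convention!r}")
    needed = ["d91", "baseline", "arm", "sex", "age"]
    df = df[needed].replace([np.inf, -np.inf], np.nan).dropna()
    n_p = int((df["arm"] == "placebo").sum())
    n_a = int((df["arm"] == "active").sum())
    if n_p < 3 or n_a < 3:
        raise ValueError("need at least 3 complete participants per arm")
    if n_p + n_a != len(df):
        raise ValueError("arm labels must be 'placebo' or 'active'")

    X, y, active = _design(df)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (e.g. one-arm data)")
    model = sm.OLS(y, X).fit()
    coef = float(model.params[1])  # active − placebo

    if model.ssr < 1e-12:  # degenerate: outcome fits exactly
        if abs(coef) < 1e-10:
            coef = 0.0
            lo = hi = 0.0
            p = 1.0
        else:
            lo = hi = coef
            p = 0.0
    else:
        ci = model.conf_int(alpha=0.05)
        lo, hi = float(ci[1][0]), float(ci[1][1])
        p = float(model.pvalues[1])

    # estimated marginal means at design-column means
    xbar = X.mean(axis=0)
    x_pl, x_ac = xbar.copy(), xbar.copy()
    x_pl[1], x_ac[1] = 0.0, 1.0
    emm_pl, emm_ac = float(x_pl @ model.params), float(x_ac @ model.params)

    md, lo_c, hi_c = coef, lo, hi
    if convention == "placebo_minus_active":
        md, lo_c, hi_c = -coef, -hi, -lo

    base = df.groupby("arm")["baseline"]
    sd_p = float(base.std(ddof=1).get("placebo", np.nan))
    sd_a = float(base.std(ddof=1).get("active", np.nan))
    try:
        smd = standardized_mean_difference(md, sd_p, n_p, sd_a, n_a)
    except (ValueError, FloatingPointError):
        smd = float("nan")

    return EffectEstimate(
        outcome=outcome,
        adjusted_mean_difference=float(np.round(md, 12) + 0.0),
        ci_low=lo_c,
        ci_high=hi_c,
        p_value=p,
        n_placebo=n_p,
        n_active=n_a,
        emm_placebo=emm_pl,
        emm_active=emm_ac,
        smd=smd,
        convention=convention,
    )


def interaction_lrt(df: pd.DataFrame, moderator: str) -> dict:
    """Likelihood-ratio test of arm × moderator against the base model.

    ``moderator`` is 'sex', 'age', or any numeric column of ``df``.
    """
    needed = ["d91", "baseline", "arm", "sex", "age"]
    cols = needed + ([moderator] if moderator not in needed else [])
    df = df[cols].replace([np.inf, -np.inf], np.nan).dropna()
    X, y, active = _design(df)
    if moderator == "sex":
        mod = (df["sex"] == "F").to_numpy(dtype=float)
    else:
        mod = df[moderator].to_numpy(dtype=float)
    if np.std(mod) == 0:
        raise ValueError(f"moderator {moderator!r} has zero variance")
    X_full = np.column_stack([X, active * mod])
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(X):
        raise ValueError("interaction term is collinear with the base model")
    reduced = sm.OLS(y, X).fit()
    full = sm.OLS(y, X_full).fit()
    lr = 2.0 * (full.llf - reduced.llf)
    df_diff = X_full.shape[1] - X.shape[1]
    return {"lr_statistic": float(max(lr, 0.0)), "df": int(df_diff),
            "p_value": float(stats.chi2.sf(max(lr, 0.0), df_diff))}


def change_correlation(network_change: np.ndarray, behavior_change: np.ndarray) -> dict:
    """Spearman rank correlation of paired change scores (ties handled)."""
    x = np.asarray(network_change, dtype=float)
    y = np.asarray(behavior_change, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 4:
        raise ValueError("need at least 4 complete pairs")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return {"rho": float(rho), "p_value": float(p), "n": int(ok.sum())}


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def effect_table(
    outcomes: pd.DataFrame,
    demographics: pd.DataFrame,
    convention: str = "placebo_minus_active",
) -> pd.DataFrame:
    """ANCOVA every outcome column of a tidy (id, timepoint)-indexed frame.

    ``outcomes`` must carry columns per outcome with a MultiIndex
    (id, timepoint); ``demographics`` is id-indexed with arm, sex, age.
    Returns one row per outcome: arm means (SD) at both timepoints,
    adjusted difference, CI, p and SMD.
    """
    rows = []
    for col in outcomes.columns:
        wide = outcomes[col].unstack("timepoint")
        if not {"baseline", "d91"} <= set(wide.columns):
            continue
        df = pd.DataFrame({
            "baseline": wide["baseline"],
            "d91": wide["d91"],
        }).join(demographics[["arm", "sex", "age"]])
        try:
            est = fit_treatment_model(df, outcome=str(col), convention=convention)
        except ValueError:
            continue
        summary = {}
        for arm in ("placebo", "active"):
            sub = df[df["arm"] == arm]
            for t in ("baseline", "d91"):
                summary[f"{arm}_{t}_mean"] = float(sub[t].mean())
                summary[f"{arm}_{t}_sd"] = float(sub[t].std(ddof=1))
        rows.append({**est.as_dict(), **summary})
    return pd.DataFrame(rows)
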