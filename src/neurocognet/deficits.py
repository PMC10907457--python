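"""Norm-referenced deficit profiling.

Baseline scores are converted to z-scores against neurotypical norms
(mean/SD per variable per age band), oriented so that negative means
worse.  A participant is *deviant* on a variable when z ≤ −1 (inclusive).
Under a normal model ~16% of a neurotypical population falls below that
cutoff, so each variable's observed deviance rate is tested against the
16% expectation with a one-sample Pearson chi-square on the 2-cell table
{deviant, not deviant}, 1 df, no continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

NORM_P0 = 0.16  #: expected deviance proportion (z <= -1) in the norm population


@dataclass
class NormTable:
    """Neurotypical reference means/SDs per variable per age band.

    ``table`` columns: variable, age_min, age_max, mean, sd (natural scale,
    unoriented).  Bands cover ``age_min <= age < age_max``; bands need not
    cover the whole study age range — participants outside coverage get a
    missing z for that variable.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"variable", "age_min", "age_max", "mean", "sd"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"norm table missing columns: {sorted(missing)}")
        if (self.table["sd"] <= 0).any():
            raise ValueError("norm SDs must be positive")
        for v, grp in self.table.groupby("variable"):
            bands = grp.sort_values("age_min")[["age_min", "age_max"]].to_numpy()
            if (bands[:, 1] <= bands[:, 0]).any():
                raise ValueError(f"empty age band for {v}")
            if (bands[1:, 0] < bands[:-1, 1]).any():
                raise ValueError(f"overlapping age bands for {v}")

    @property
    def variables(self) -> list[str]:
        return sorted(self.table["variable"].unique())

    def lookup(self, variable: str, age: float) -> Optional[tuple[float, float]]:
        sub = self.table[self.table["variable"] == variable]
        hit = sub[(sub["age_min"] <= age) & (age < sub["age_max"])]
        if hit.empty:
            return None
        row = hit.iloc[0]
        return float(row["mean"]), float(row["sd"])

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "NormTable":
        return cls(pd.read_csv(path))


def zscore_vs_norms(data, norms: NormTable, spec) -> pd.DataFrame:
    """Baseline z-scores vs norms, one column per normed raw variable.

    ``data`` must be oriented; the norm mean is oriented with the same sign
    convention before standardizing, so negative z always means worse.
    Missing where no age band covers the participant.
    """
    from .battery import Direction

    if not data.oriented:
        raise ValueError("orient scores before norm-referenced z-scoring")
    base = data.timepoint("baseline")
    missing_norms = [v for v in spec.norm_names if v not in norms.variables]
    if missing_norms:
        raise ValueError(f"variables flagged has_norms but absent from norm table: {missing_norms}")

    out = pd.DataFrame(index=base.index, columns=spec.norm_names, dtype=float)
    ages = data.demographics["age"]
    for v in spec.norm_names:
        lower_better = spec.variable(v).direction == Direction.lower_better
        for pid in base.index:
            score = base.at[pid, v]
            if pd.isna(score):
                continue
            band = norms.lookup(v, float(ages[pid]))
            if band is None:
                continue
            mean, sd = band
            oriented_mean = -mean if lower_better else mean
            out.at[pid, v] = (score - oriented_mean) / sd
    return out


def chisq_vs_norm(n_deviant: int, n_valid: int, p0: float = NORM_P0) -> tuple[float, float]:
    """One-sample Pearson goodness-of-fit on {deviant, not deviant}, 1 df."""
    if n_valid <= 0:
        raise ValueError("n_valid must be positive")
    if not (0 <= n_deviant <= n_valid):
        raise ValueError("need 0 <= n_deviant <= n_valid")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    e_dev = p0 * n_valid
    e_not = (1.0 - p0) * n_valid
    chi2 = (n_deviant - e_dev) ** 2 / e_dev + ((n_valid - n_deviant) - e_not) ** 2 / e_not
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def deviance_rate(z: pd.DataFrame, cutoff: float = -1.0, p0: float = NORM_P0) -> pd.DataFrame:
    """Per-variable deviance rates with chi-square tests vs ``p0``.

    The cutoff is inclusive (z == cutoff counts as deviant).  Rows are
    sorted from highest to lowest rate.  Complete-case n per variable.
    """
    rows = []
    for v in z.columns:
        col = z[v].dropna()
        n_valid = int(len(col))
        n_dev = int((col <= cutoff).sum())
        if n_valid == 0:
            warnings.warn(f"no valid z-scores for {v}; skipped")
            continue
        chi2, p = chisq_vs_norm(n_dev, n_valid, p0)
        rows.append({
            "variable": v, "n_valid": n_valid, "n_deviant": n_dev,
            "rate": n_dev / n_valid, "chi_square": chi2, "df": 1, "p_value": p,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["rate", "variable"], ascending=[False, True]).reset_index(drop=True)
    return out
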