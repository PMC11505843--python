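"""Statistical comparisons on pipeline output tables.

Fixed-effects factorial ANOVA on trial-level tables (trials pooled across
participants, matching the original denominators' trial-level degrees of
freedom), Tukey HSD post hoc comparisons, and the cross-phase correlation of
condition-mean muscle activities (Pearson r across the 7 muscles).  No
multiple-testing correction is applied across ANOVA families, mirroring the
source analysis; the report notes this.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import MUSCLES

ALPHA = 0.05


def anova(table: pd.DataFrame, response: str, factors: list[str],
          interactions: bool = True) -> dict:
    """Fixed-effects factorial ANOVA (type II sums of squares).

    Parameters
    ----------
    table : DataFrame
        Trial-level tidy table; one row per observation.
    response : str
        Response column (finite values required; NaN rows are dropped).
    factors : list of str
        Categorical factor columns, each with >= 2 observed levels.
    interactions : bool
        Include all two-way (and higher) interactions via a full factorial
        model; main effects only when False.

    Returns
    -------
    dict mapping term -> {"F": ..., "df": (num, den), "p": ...}, plus a
    ``"residual_df"`` entry.
    """
    df = table.dropna(subset=[response]).copy()
    if not np.isfinite(df[response]).all():
        raise ValueError("response contains non-finite values")
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    counts = df.groupby(factors, observed=True).size()
    full = np.prod([df[f].nunique() for f in factors])
    if len(counts) < full or (counts == 0).any():
        missing = counts[counts == 0].index.tolist() if (counts == 0).any() else "absent combination"
        raise ValueError(f"empty cell in design: {missing}")

    op = " * " if interactions else " + "
    formula = f"{response} ~ " + op.join(f"C({f})" for f in factors)
    fit = ols(formula, data=df).fit()
    tab = anova_lm(fit, typ=2)
    resid_df = float(tab.loc["Residual", "df"])
    out: dict = {"residual_df": resid_df, "terms": {}}
    for term in tab.index:
        if term == "Residual":
            continue
        clean = term.replace("C(", "").replace(")", "")
        out["terms"][clean] = {
            "F": float(tab.loc[term, "F"]),
            "df": (float(tab.loc[term, "df"]), resid_df),
            "p": float(tab.loc[term, "PR(>F)"]),
        }
    return out


def tukey_hsd(table: pd.DataFrame, response: str, factor: str,
              alpha: float = ALPHA) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for one factor (familywise alpha).

    Returns one row per unordered level pair with the mean difference
    (group2 - group1), adjusted p-value and rejection flag.
    """
    df = table.dropna(subset=[response])
    if factor not in df.columns:
        raise ValueError(f"factor {factor!r} absent from table")
    if df[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} needs at least 2 levels")
    res = pairwise_tukeyhsd(df[response].to_numpy(float),
                            df[factor].astype(str).to_numpy(), alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return frame.rename(columns={"p-adj": "p_adj"})


def phase_correlation(activity: pd.DataFrame, condition: tuple[str, str],
                      phase_a: str, phase_b: str) -> dict:
    """Cross-phase correlation of muscle activity within one condition.

    Correlates, across the 7 muscles, the condition-mean normalized intensity
    in ``phase_a`` against ``phase_b``; each condition therefore yields one
    (r, R^2, p) per phase pair with n = 7.
    """
    height, vision = condition
    sub = activity[(activity["height"] == height) & (activity["vision"] == vision)]
    means = (sub.groupby(["phase", "muscle"], observed=True)["intensity"]
             .mean().unstack("muscle"))
    for phase in (phase_a, phase_b):
        if phase not in means.index:
            raise ValueError(f"no activity rows for phase {phase!r} in condition {condition}")
    a = means.loc[phase_a].reindex(list(MUSCLES))
    b = means.loc[phase_b].reindex(list(MUSCLES))
    if a.isna().any() or b.isna().any():
        missing = [m for m in MUSCLES if np.isnan(a[m]) or np.isnan(b[m])]
        raise ValueError(f"missing muscle means for {missing}")
    if phase_a == phase_b:
        return {"condition": condition, "phases": (phase_a, phase_b),
                "r": 1.0, "r2": 1.0, "p": 0.0, "n": len(MUSCLES)}
    r, p = sps.pearsonr(a.to_numpy(float), b.to_numpy(float))
    return {"condition": condition, "phases": (phase_a, phase_b),
            "r": float(r), "r2": float(r * r), "p": float(p), "n": len(MUSCLES)}


def correlation_table(activity: pd.DataFrame) -> pd.DataFrame:
    """All cross-phase correlations: one row per condition x phase pair."""
    rows = []
    conditions = (activity[["height", "vision"]].drop_duplicates()
                  .itertuples(index=False, name=None))
    for cond in conditions:
        for pa, pb in combinations(("APA", "OPA", "CPA"), 2):
            res = phase_correlation(activity, cond, pa, pb)
            rows.append({"height": cond[0], "vision": cond[1],
                         "phase_a": pa, "phase_b": pb,
                         "r": res["r"], "r2": res["r2"], "p": res["p"], "n": res["n"]})
    return pd.DataFrame(rows)
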