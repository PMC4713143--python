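"""Group-level inference: mixed ANOVA with Greenhouse-Geisser correction,
Tukey HSD pairwise tests, and Huber robust regression.

Network and PAC measures are compared with a two-way mixed ANOVA (between:
group, within: sedation level); within-subject and interaction p-values are
sphericity-corrected with the Greenhouse-Geisser epsilon.  Associations of
brain measures with behaviour or blood drug concentration use iteratively
reweighted least squares with Huber weights.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

LONG_COLUMNS = ("participant", "group", "level", "measure", "value")


def make_long_table(rows) -> pd.DataFrame:
    """Assemble a long-format table of (participant, group, level, measure,
    value) rows and check the one-value-per-cell invariant."""
    df = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
    if df.duplicated(["participant", "level", "measure"]).any():
        raise ValueError("duplicate participant x level x measure cell")
    return df


def mixed_anova_gg(table: pd.DataFrame, measure: str) -> dict:
    """Two-way mixed ANOVA (between: group, within: level) with
    Greenhouse-Geisser correction.

    Returns F, uncorrected dfs, epsilon, and GG-corrected p-values for the
    within and interaction terms (the epsilon of the shared within-subject
    error term scales both).  Participants with incomplete level data are
    removed listwise with a warning.
    """
    df = table[table["measure"] == measure].copy()
    if df.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    n_levels = df["level"].nunique()
    counts = df.groupby("participant")["level"].nunique()
    incomplete = counts[counts < n_levels].index
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} participants with incomplete levels",
            stacklevel=2,
        )
        df = df[~df["participant"].isin(incomplete)]
    if df.groupby("group")["participant"].nunique().min() < 2:
        raise ValueError("need at least 2 participants per group")
    if df["value"].var() == 0:
        nan = float("nan")
        return {
            "F_group": nan, "p_group": nan,
            "F_level": nan, "df_level": (n_levels - 1, 0), "p_level_gg": nan,
            "F_interaction": nan, "df_interaction": (n_levels - 1, 0),
            "p_interaction_gg": nan, "epsilon": nan,
        }

    aov = pg.mixed_anova(
        data=df,
        dv="value",
        within="level",
        subject="participant",
        between="group",
        correction=True,
    ).set_index("Source")
    eps = float(aov.loc[aov.index != "Interaction", "eps"].dropna().iloc[0])

    def gg_p(row) -> float:
        return float(
            sps.f.sf(row["F"], eps * row["DF1"], eps * row["DF2"])
        )

    within_source = aov.index[aov["eps"].notna()][0]
    between_source = [
        s for s in aov.index if s not in (within_source, "Interaction")
    ][0]
    within_row = aov.loc[within_source]
    inter_row = aov.loc["Interaction"]
    between_row = aov.loc[between_source]
    return {
        "F_group": float(between_row["F"]),
        "p_group": float(between_row["p_unc"]),
        "F_level": float(within_row["F"]),
        "df_level": (int(within_row["DF1"]), int(within_row["DF2"])),
        "p_level_gg": gg_p(within_row),
        "F_interaction": float(inter_row["F"]),
        "df_interaction": (int(inter_row["DF1"]), int(inter_row["DF2"])),
        "p_interaction_gg": gg_p(inter_row),
        "epsilon": eps,
    }


def pairwise_tukey(table: pd.DataFrame, measure: str, at_level: str) -> pd.DataFrame:
    """Tukey HSD comparisons between groups at one sedation level."""
    df = table[(table["measure"] == measure) & (table["level"] == at_level)]
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    res = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy())
    return pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )


def robust_regression(x: np.ndarray, y: np.ndarray) -> dict:
    """Huber-weighted IRLS regression of y on x.

    Tuning constant 1.345, convergence tolerance 1e-8, max 50 iterations.
    R^2 is computed on the weighted fit; the slope p-value refers the
    robust test statistic to a t distribution with n - 2 degrees of freedom
    (the asymptotic normal reference is anticonservative at the cohort
    sizes this package targets).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    exog = sm.add_constant(x)
    fit = sm.RLM(y, exog, M=sm.robust.norms.HuberT(t=1.345)).fit(
        conv="coefs", tol=1e-8, maxiter=50
    )
    w = fit.weights
    yhat = fit.fittedvalues
    ybar = np.average(y, weights=w)
    ss_res = np.sum(w * (y - yhat) ** 2)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if fit.bse[1] > 0:
        t_stat = fit.params[1] / fit.bse[1]
    else:  # exact fit: zero standard error
        t_stat = np.inf * np.sign(fit.params[1]) if fit.params[1] else 0.0
    p = 2.0 * sps.t.sf(abs(t_stat), df=x.size - 2)
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(r2),
        "t_statistic": float(t_stat),
        "p_value": float(p),
        "n": int(x.size),
    }


def pac_drug_correlation(pac: np.ndarray, drug: np.ndarray) -> dict:
    """Robust regression of per-participant signed PAC on blood drug
    concentration (one sedation level at a time)."""
    return robust_regression(np.asarray(drug, float), np.asarray(pac, float))
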