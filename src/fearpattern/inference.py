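"""Group-level factorial inference on excess classification accuracies.

The decoding pipeline yields one excess accuracy per participant x context x
complexity x hemisphere cell.  Because every participant contributes every
cell, the within-subject factorial decomposition can be computed as a
repeated-measures ANOVA; a pooled-error variant (ordinary least squares with
participant intercepts, equivalent to a random-intercept model for
within-subject effects in balanced designs) is available for comparison with
mixed-model reporting conventions.  Post hoc paired comparisons use the
Wilcoxon signed-rank test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "check_balanced",
    "factorial_accuracy_model",
    "crossdecoding_model",
    "mixed_effects_model",
    "paired_signed_rank",
]


def check_balanced(
    table: pd.DataFrame,
    subject: str = "participant",
    within: tuple[str, ...] = ("context", "complexity", "hemisphere"),
) -> None:
    """Raise if any participant x factor-cell combination is missing or duplicated."""
    counts = table.groupby([subject, *within], observed=True).size()
    levels = [table[f].unique() for f in (subject, *within)]
    expected = int(np.prod([len(l) for l in levels]))
    if len(counts) != expected or not (counts == 1).all():
        raise ValueError(
            "accuracy table is unbalanced (every participant must contribute every "
            "factor cell exactly once); fit mixed_effects_model instead"
        )


def factorial_accuracy_model(
    table: pd.DataFrame,
    value: str = "excess_accuracy",
    subject: str = "participant",
    within: tuple[str, ...] = ("context", "complexity", "hemisphere"),
    error: str = "stratified",
) -> pd.DataFrame:
    """Within-subject factorial decomposition of excess accuracies.

    ``error='stratified'`` is the classical repeated-measures ANOVA: each
    effect is tested against its own effect-by-subject interaction stratum
    (denominator df = n_subjects - 1 per effect).  ``error='pooled'`` tests
    all effects against a single pooled residual (OLS with participant
    intercepts), which for balanced designs matches the Wald tests of a
    random-intercept mixed model.  Requires a balanced table with >= 2
    participants.  Returns a tidy frame with effect, df1, df2, F, p.
    """
    if table[subject].nunique() < 2:
        raise ValueError("at least 2 participants are required")
    check_balanced(table, subject, within)
    if error == "stratified":
        from statsmodels.stats.anova import AnovaRM

        fit = AnovaRM(table, depvar=value, subject=subject, within=list(within)).fit()
        out = fit.anova_table.reset_index().rename(
            columns={
                "index": "effect",
                "F Value": "F",
                "Num DF": "df1",
                "Den DF": "df2",
                "Pr > F": "p",
            }
        )
        out["effect"] = out["effect"].str.replace(":", " x ")
        return out[["effect", "df1", "df2", "F", "p"]]
    if error == "pooled":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        terms = " * ".join(f"C({f})" for f in within)
        df = table.rename(columns={value: "_y"})
        model = smf.ols(f"_y ~ C({subject}) + {terms}", data=df).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        rows = []
        resid_df = aov.loc["Residual", "df"]
        for name, row in aov.iterrows():
            if name in ("Residual", f"C({subject})"):
                continue
            effect = name.replace("C(", "").replace(")", "").replace(":", " x ")
            rows.append(
                {
                    "effect": effect,
                    "df1": row["df"],
                    "df2": resid_df,
                    "F": row["F"],
                    "p": row["PR(>F)"],
                }
            )
        return pd.DataFrame(rows)
    raise ValueError("error must be 'stratified' or 'pooled'")


def crossdecoding_model(
    table: pd.DataFrame,
    value: str = "excess_accuracy",
    subject: str = "participant",
) -> pd.DataFrame:
    """Factorial model for cross-decoding: stimulus class (CS vs NS) x direction.

    Replicate cells (e.g. the two hemispheres) are averaged per participant x
    cell before the two-factor repeated-measures model.
    """
    within = ("stimulus_class", "direction")
    cells = (
        table.groupby([subject, *within], observed=True)[value].mean().reset_index()
    )
    return factorial_accuracy_model(cells, value=value, subject=subject, within=within)


def mixed_effects_model(
    table: pd.DataFrame,
    value: str = "excess_accuracy",
    subject: str = "participant",
    within: tuple[str, ...] = ("context", "complexity", "hemisphere"),
) -> pd.DataFrame:
    """Random-intercept mixed model with Wald F tests per factorial term.

    Handles unbalanced tables; on balanced tables its F ratios agree with the
    pooled-error factorial decomposition.
    """
    import statsmodels.formula.api as smf

    terms = " * ".join(f"C({f}, Sum)" for f in within)
    df = table.rename(columns={value: "_y"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(f"_y ~ {terms}", data=df, groups=df[subject]).fit(reml=True)
        wt = fit.wald_test_terms(skip_single=False).table
    rows = []
    for term, row in wt.iterrows():
        if term == "Intercept":
            continue
        effect = " x ".join(
            part.replace("C(", "").replace(", Sum)", "") for part in term.split(":")
        )
        rows.append(
            {
                "effect": effect,
                "df1": int(row["df_constraint"]),
                "F": float(np.squeeze(row["statistic"])) / int(row["df_constraint"]),
                "p_wald_chi2": float(np.squeeze(row["pvalue"])),
            }
        )
    return pd.DataFrame(rows)


def paired_signed_rank(values_a, values_b) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Uses the exact null distribution for n <= 25 (when there are no zero
    differences or ties) and the normal approximation otherwise.  If all
    differences are zero the test is degenerate; returns p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if len(a) < 5:
        raise ValueError("at least 5 pairs are required")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; test is degenerate", RuntimeWarning)
        return 0.0, 1.0
    method = "exact" if (len(d) <= 25 and _exact_ok(d)) else "approx"
    res = stats.wilcoxon(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def _exact_ok(d: np.ndarray) -> bool:
    """Exact distribution is valid without zero differences or tied magnitudes."""
    nz = d[d != 0]
    if len(nz) != len(d):
        return False
    return len(np.unique(np.abs(nz))) == len(nz)
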