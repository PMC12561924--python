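"""Group-level inference: repeated-measures ANOVA and companion tests.

The study design is fully within-subjects: every subject contributes one
pre-averaged value per posture x stimulus-type cell.  Metrics are compared
with a two-factor repeated-measures ANOVA; when Mauchly's test flags a
sphericity violation (alpha = .05) the degrees of freedom are
Greenhouse-Geisser corrected, and effect sizes are generalized eta-squared
(all factors manipulated).  Post-hoc level comparisons are paired t-tests
with Bonferroni correction; latitude biases are one-sample t-tests against
the equator with Cohen's d = mean/sd (so d = t/sqrt(n) exactly).

The ANOVA machinery is delegated to pingouin; every knob that matters
(epsilon type, correction gate, ddof) is pinned here rather than left to
library defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "IncompleteDesignError",
    "aggregate",
    "rm_anova",
    "bonferroni_pairwise",
    "one_sample_bias_test",
    "OneSampleResult",
]

ALPHA_SPHERICITY = 0.05


class IncompleteDesignError(ValueError):
    """The subject x condition crossing has missing cells."""


@dataclass(frozen=True)
class OneSampleResult:
    t: float
    df: int
    p: float
    d: float
    mean: float
    zero_variance: bool = False


def aggregate(trial_metrics: pd.DataFrame, dv: str, factors=("posture", "stimulus_type")) -> pd.DataFrame:
    """Average trial-level metric values into one value per subject x cell.

    Raises :class:`IncompleteDesignError` naming every missing cell, since a
    repeated-measures ANOVA needs the complete crossing.
    """
    factors = list(factors)
    table = (
        trial_metrics.groupby(["subject"] + factors, observed=True)[dv].mean().reset_index()
    )
    levels = [table[f].unique() for f in factors]
    subjects = table["subject"].unique()
    expected = len(subjects) * int(np.prod([len(l) for l in levels]))
    if len(table) != expected:
        have = set(map(tuple, table[["subject"] + factors].to_numpy()))
        missing = [
            (s, *cell)
            for s in subjects
            for cell in _product(levels)
            if (s, *cell) not in have
        ]
        raise IncompleteDesignError(f"missing cells: {missing}")
    return table


def _product(levels):
    if len(levels) == 1:
        for a in levels[0]:
            yield (a,)
    else:
        for a in levels[0]:
            for rest in _product(levels[1:]):
                yield (a, *rest)


def _mauchly_p(data: pd.DataFrame, dv: str, within: str, subject: str) -> float:
    try:
        res = pg.sphericity(data, dv=dv, within=within, subject=subject)
        return float(res.pval)
    except ZeroDivisionError:  # too few subjects for the test
        return 1.0


def rm_anova(table: pd.DataFrame, dv: str, within=("posture", "stimulus_type"), subject: str = "subject") -> pd.DataFrame:
    """One- or two-factor within-subjects ANOVA with sphericity handling.

    Returns one row per effect with columns ``F``, ``df1``, ``df2`` (possibly
    non-integer after correction), ``p``, ``p_uncorrected``, ``eta_g2``,
    ``epsilon``, ``sphericity_violated``.  The Greenhouse-Geisser correction
    is applied to an effect only when Mauchly's test rejects sphericity for
    it; both corrected and raw p-values are reported either way.  A
    zero-variance dependent variable is rejected as degenerate.
    """
    within = [within] if isinstance(within, str) else list(within)
    if np.allclose(table[dv].to_numpy().std(), 0.0):
        raise ValueError(f"dependent variable {dv!r} has zero variance")
    res = pg.rm_anova(
        data=table, dv=dv, within=within if len(within) > 1 else within[0],
        subject=subject, correction=True, detailed=True, effsize="ng2",
    )
    err_df = None
    if "DF" in res.columns:  # one-way layout carries an explicit error row
        err = res[res["Source"] == "Error"]
        err_df = float(err["DF"].iloc[0]) if len(err) else None
    rows = []
    for _, r in res.iterrows():
        effect = r["Source"]
        if effect.startswith("Error") or effect == "Subject":
            continue
        eps = float(r.get("eps", 1.0)) if not pd.isna(r.get("eps", np.nan)) else 1.0
        if "ddof1" in r.index:
            df1, df2 = float(r["ddof1"]), float(r["ddof2"])
        else:
            df1, df2 = float(r["DF"]), err_df
        # Mauchly per main effect (needs >2 levels to be testable)
        violated = False
        if not pd.isna(r.get("p_spher", np.nan)):
            violated = float(r["p_spher"]) < ALPHA_SPHERICITY
        elif "*" not in effect and table[effect].nunique() > 2:
            collapsed = table.groupby([subject, effect], observed=True)[dv].mean().reset_index()
            violated = _mauchly_p(collapsed, dv, effect, subject) < ALPHA_SPHERICITY
        elif "*" in effect and df1 > 1:
            violated = eps < 1.0 - 1e-9  # interaction: gate on estimated epsilon
        p_unc = float(r["p_unc"])
        p_gg = float(r["p_GG_corr"]) if "p_GG_corr" in r.index and not pd.isna(r["p_GG_corr"]) else p_unc
        use_gg = violated and df1 > 1
        rows.append(
            {
                "effect": effect,
                "F": float(r["F"]),
                "df1": df1 * eps if use_gg else df1,
                "df2": df2 * eps if use_gg else df2,
                "p": p_gg if use_gg else p_unc,
                "p_uncorrected": p_unc,
                "eta_g2": float(r["ng2"]),
                "epsilon": eps,
                "sphericity_violated": violated,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_pairwise(table: pd.DataFrame, dv: str, factor: str, subject: str = "subject") -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests between all levels of a factor.

    Works on subject means (collapsing other factors); the raw p of each of
    the m pairwise comparisons is multiplied by m and capped at 1.
    """
    means = table.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    levels = list(means.columns)
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        diff = means[a].to_numpy() - means[b].to_numpy()
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0  # identical paired values: no evidence either way
        else:
            t, p = sps.ttest_rel(means[a], means[b])
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_a": float(means[a].mean()),
                "mean_b": float(means[b].mean()),
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": min(float(p) * m, 1.0),
                "significant": float(p) * m < 0.05,
            }
        )
    return pd.DataFrame(rows)


def one_sample_bias_test(values, null: float = 0.0) -> OneSampleResult:
    """One-sample t-test of subject means against ``null`` with Cohen's d.

    ``d = mean/sd``, so ``d = t/sqrt(n)`` holds exactly.  A zero-variance
    sample is flagged rather than producing an infinite statistic.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two subjects")
    sd = x.std(ddof=1)
    mean = float(x.mean())
    if sd == 0.0:
        return OneSampleResult(float("nan"), n - 1, float("nan"), float("nan"), mean, True)
    t = (mean - null) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return OneSampleResult(float(t), n - 1, float(p), float((mean - null) / sd), mean)
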