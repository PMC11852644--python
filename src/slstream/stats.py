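"""Inferential layer: chance tests, mixed repeated-measures ANOVA with
Greenhouse-Geisser correction, Bonferroni post hocs, partial eta squared and
retrospective observed power.

One-sample tests against the 50% chance level are one-tailed (H1: accuracy
above chance). Observed power follows the retrospective convention
lambda = F * df1 evaluated against the central critical value — a
descriptive companion to the F statistic, not a prospective power analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lexicon import DesignError


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    tail: Literal["one", "two"]
    mean: float
    sd: float
    n: int
    mu0: float


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    epsilon: float
    eta_p2: float
    pw: float
    posthoc: dict[str, float] | None = None


def one_sample_t(
    values: Sequence[float] | None = None,
    mu0: float = 50.0,
    tail: Literal["one", "two"] = "one",
    mean: float | None = None,
    sd: float | None = None,
    n: int | None = None,
) -> TTestResult:
    """One-sample t test against `mu0`, from raw values or printed summaries.

    With `tail="one"` the alternative is mean > mu0. Passing (mean, sd, n)
    reproduces a test from published summary statistics.
    """
    if values is not None:
        values = np.asarray(values, dtype=float)
        n = len(values)
        if n < 2:
            raise DesignError("need at least two observations")
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
    elif mean is None or sd is None or n is None:
        raise DesignError("provide either raw values or (mean, sd, n)")
    if n < 2:
        raise DesignError("need n >= 2")
    se = sd / np.sqrt(n)
    if se == 0:
        if mean == mu0:
            raise DesignError("undefined t: zero variance at the null value")
        t = np.inf if mean > mu0 else -np.inf
    else:
        t = (mean - mu0) / se
    df = n - 1
    p = float(sps.t.sf(t, df)) if tail == "one" else float(2 * sps.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, tail, float(mean), float(sd), int(n), mu0)


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a within-factor covariance matrix.

    Computed from the double-centered covariance; clamped to
    [1/(k-1), 1] for a k-level factor.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise DesignError("covariance must be square")
    k = cov.shape[0]
    if k < 2:
        raise DesignError("need at least two levels")
    if not np.all(np.isfinite(cov)):
        raise DesignError("covariance contains non-finite entries")
    center = np.eye(k) - np.ones((k, k)) / k
    s = center @ cov @ center
    denom = (k - 1) * np.trace(s @ s)
    scale = max(1.0, float(np.abs(cov).max()) ** 2)
    if denom <= 1e-12 * scale:
        raise DesignError("singular within-factor covariance")
    eps = np.trace(s) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def effect_size_and_power(
    F: float, df1: float, df2: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Partial eta squared and observed power for an F test.

    eta_p2 = F*df1 / (F*df1 + df2); power is the probability that a
    noncentral F(df1, df2, lambda=F*df1) exceeds the central critical value.
    """
    if df1 < 1 or df2 < 1:
        raise DesignError("degrees of freedom must be >= 1")
    if F < 0:
        raise DesignError("F must be non-negative")
    eta_p2 = F * df1 / (F * df1 + df2)
    crit = sps.f.ppf(1 - alpha, df1, df2)
    pw = float(sps.ncf.sf(crit, df1, df2, F * df1)) if F > 0 else alpha
    return float(eta_p2), pw


def bonferroni(pvals: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p values: min(1, p * m)."""
    pvals = list(pvals)
    m = len(pvals) if m is None else m
    if m < 1:
        raise DesignError("m must be >= 1")
    if any(not 0 <= p <= 1 for p in pvals):
        raise DesignError("p values must lie in [0, 1]")
    return [min(1.0, p * m) for p in pvals]


def _attach(row: pd.Series, epsilon: float, alpha: float) -> AnovaResult:
    F, df1, df2 = float(row["F"]), float(row["df1"]), float(row["df2"])
    if -1e-9 < F < 0:  # floating-point residue from sums-of-squares
        F = 0.0
    # GG correction scales both dfs; F is unchanged
    df1_c, df2_c = df1 * epsilon, df2 * epsilon
    p = float(sps.f.sf(F, df1_c, df2_c))
    eta_p2, pw = effect_size_and_power(F, df1, df2, alpha)
    return AnovaResult(str(row["effect"]), F, df1_c, df2_c, p, epsilon, eta_p2, pw)


def mixed_rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str | None = None,
    within: Sequence[str] = (),
    alpha: float = 0.05,
) -> list[AnovaResult]:
    """Mixed (between x within) or fully-within repeated-measures ANOVA.

    Requires a complete balanced design: every subject measured once in
    every within-cell. Greenhouse-Geisser epsilon is computed for each
    within effect and applied when the factor has more than two levels
    (epsilon is exactly 1 at two levels). Missing cells raise an error
    naming them.
    """
    import pingouin as pg
    from statsmodels.stats.anova import AnovaRM

    within = list(within)
    if not within:
        raise DesignError("at least one within-subject factor required")
    counts = data.groupby([subject, *within], observed=True)[dv].count()
    expected = pd.MultiIndex.from_product(
        [sorted(data[subject].unique())]
        + [sorted(data[f].unique()) for f in within],
        names=[subject, *within],
    )
    missing = expected.difference(counts.index)
    if len(missing) or (counts != 1).any():
        bad = list(missing[:5]) + counts[counts != 1].index.tolist()[:5]
        raise DesignError(f"design not balanced; offending cells: {bad}")
    if between is not None:
        n_per = data.groupby(between, observed=True)[subject].nunique()
        if (n_per < 2).any():
            raise DesignError("need >= 2 participants per between-subject level")

    results: list[AnovaResult] = []
    if between is not None and len(within) == 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            aov = pg.mixed_anova(
                data=data,
                dv=dv,
                within=within[0],
                subject=subject,
                between=between,
                correction=False,
            )
        for _, row in aov.iterrows():
            name = str(row["Source"])
            if name == "Interaction":
                name = f"{between}:{within[0]}"
            # constant data yields 0/0; all sums of squares are 0, so F = 0
            F = float(row["F"]) if "F" in row and np.isfinite(row["F"]) else 0.0
            eps = 1.0
            if name != between and data[within[0]].nunique() > 2:
                # within main effect or interaction with >2 levels
                eps = _gg_epsilon_from_table(data, dv, subject, within[0])
            results.append(
                _attach(
                    pd.Series(
                        {
                            "effect": name,
                            "F": F,
                            "df1": row["DF1"],
                            "df2": row["DF2"],
                        }
                    ),
                    eps,
                    alpha,
                )
            )
        return results
    if between is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            aov = AnovaRM(
                data, depvar=dv, subject=subject, within=within
            ).fit().anova_table
        for effect, row in aov.iterrows():
            # sphericity is automatic for single-df effects
            if float(row["Num DF"]) > 1:
                eps = _gg_epsilon_composite(data, dv, subject, effect.split(":"))
            else:
                eps = 1.0
            F = row["F Value"] if np.isfinite(row["F Value"]) else 0.0
            results.append(
                _attach(
                    pd.Series(
                        {
                            "effect": effect,
                            "F": F,
                            "df1": row["Num DF"],
                            "df2": row["Den DF"],
                        }
                    ),
                    eps,
                    alpha,
                )
            )
        return results
    raise DesignError(
        "supported designs: one between x one within, or fully within"
    )


def _gg_epsilon_from_table(
    data: pd.DataFrame, dv: str, subject: str, within: str
) -> float:
    wide = data.pivot_table(index=subject, columns=within, values=dv, observed=True)
    return gg_epsilon(np.cov(wide.to_numpy(), rowvar=False))


def _gg_epsilon_composite(
    data: pd.DataFrame, dv: str, subject: str, factors: list[str]
) -> float:
    key = data[factors].astype(str).agg("|".join, axis=1)
    tmp = data.assign(_cell=key)
    return _gg_epsilon_from_table(tmp, dv, subject, "_cell")


def pairwise_bonferroni(
    data: pd.DataFrame,
    dv: str,
    group: str,
    paired_by: str | None = None,
) -> pd.DataFrame:
    """All pairwise comparisons on a factor with Bonferroni-adjusted p values.

    Independent-samples t tests for between-subject factors; paired tests
    when `paired_by` names the subject column.
    """
    levels = sorted(data[group].unique())
    rows = []
    raw_ps = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a = data.loc[data[group] == levels[i], dv].to_numpy()
            b = data.loc[data[group] == levels[j], dv].to_numpy()
            if paired_by is not None:
                wa = data[data[group] == levels[i]].set_index(paired_by)[dv]
                wb = data[data[group] == levels[j]].set_index(paired_by)[dv]
                common = wa.index.intersection(wb.index)
                t, p = sps.ttest_rel(wa.loc[common], wb.loc[common])
            else:
                t, p = sps.ttest_ind(a, b)
            rows.append({"A": levels[i], "B": levels[j], "t": float(t)})
            raw_ps.append(float(p))
    adj = bonferroni(raw_ps)
    for row, p_raw, p_adj in zip(rows, raw_ps, adj):
        row["p_unc"] = p_raw
        row["p_bonf"] = p_adj
    return pd.DataFrame(rows)


def significance_label(p: float) -> str:
    """Reporting convention: significant below 0.05, marginal below 0.08."""
    if p < 0.05:
        return "significant"
    if p < 0.08:
        return "marginal"
    return "ns"


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "F": r.F,
                "df1": r.df1,
                "df2": r.df2,
                "epsilon": r.epsilon,
                "p": r.p,
                "eta_p2": r.eta_p2,
                "pw": r.pw,
                "significance": significance_label(r.p),
            }
            for r in results
        ]
    )
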