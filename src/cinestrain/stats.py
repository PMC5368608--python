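"""Statistical battery: group comparisons, regressions, agreement suite.

* Normality by Shapiro-Wilk at alpha = 0.05 decides between the parametric
  and non-parametric branch of the repeated-measures comparison
  (one-way repeated-measures ANOVA with Tukey post-hoc vs Friedman).
* Two-group comparisons use the independent-samples t-test.
* Agreement between paired measurements: Bland-Altman bias and 95% limits
  of agreement, two-way mixed-effects absolute-agreement single-measurement
  ICC (the standard choice for intra-/inter-observer imaging studies),
  and a within-subject coefficient of variation
  CV = (SD(differences) / sqrt(2)) / grand mean of |measurements| x 100
  (systematic bias is reported by Bland-Altman, not CV).

The repeated-measures ANOVA, Tukey and ICC arithmetic is computed directly
from the two-way (subject x condition) mean squares — the hand-checkable
construction — and is vectorized over leading batch axes so that
simulation studies (e.g. type-I error at thousands of replicates) run at
desk scale.  Ordinary fits go through scipy / statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    pvalue: float
    df: tuple[float, ...] = ()
    normal: bool | None = None
    posthoc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.pvalue) and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class AgreementResult:
    """Paired-measurement agreement: bias +/- SD, limits, ICC, CV."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    icc: float
    cv_pct: float
    n: int
    means: np.ndarray = field(default=None, repr=False)  # Bland-Altman plot x
    diffs: np.ndarray = field(default=None, repr=False)  # Bland-Altman plot y


# ---------------------------------------------------------------------------
# repeated-measures ANOVA from mean squares (vectorized over leading axes)

def rm_anova(data: np.ndarray) -> tuple[np.ndarray, tuple[int, int], np.ndarray]:
    """One-way repeated-measures ANOVA on ``(..., n_subjects, k_conditions)``.

    Returns (F, (df_condition, df_error), p).  Decomposition:
    SS_total = SS_subjects + SS_conditions + SS_error with
    F = MS_conditions / MS_error on (k-1, (n-1)(k-1)) df.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim < 2:
        raise ValueError("data must be (..., subjects, conditions)")
    n, k = data.shape[-2], data.shape[-1]
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(data)):
        raise ValueError("repeated design is unbalanced: missing values present")
    grand = data.mean(axis=(-1, -2), keepdims=True)
    subj = data.mean(axis=-1, keepdims=True)
    cond = data.mean(axis=-2, keepdims=True)
    ss_cond = n * np.sum((cond - grand) ** 2, axis=(-1, -2))
    ss_subj = k * np.sum((subj - grand) ** 2, axis=(-1, -2))
    ss_tot = np.sum((data - grand) ** 2, axis=(-1, -2))
    ss_err = ss_tot - ss_cond - ss_subj
    df_c, df_e = k - 1, (n - 1) * (k - 1)
    ms_c = ss_cond / df_c
    ms_e = np.maximum(ss_err / df_e, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_c / ms_e
    p = sps.f.sf(F, df_c, df_e)
    return F, (df_c, df_e), p


def tukey_rm(data: np.ndarray, labels: list[str] | None = None) -> dict:
    """Tukey HSD on repeated-measures condition means.

    q = |mean_i - mean_j| / sqrt(MS_error / n), referred to the studentized
    range with (k, df_error).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    _, (df_c, df_e), _ = rm_anova(data)
    grand = data.mean()
    ss_err = ((data - data.mean(axis=1, keepdims=True)
               - data.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    ms_e = ss_err / df_e
    means = data.mean(axis=0)
    labels = labels or [f"c{i}" for i in range(k)]
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(means[i] - means[j]) / np.sqrt(ms_e / n)
            out[(labels[i], labels[j])] = float(sps.studentized_range.sf(q, k, df_e))
    return out


def compare_groups(
    data,
    design: str,
    labels: list[str] | None = None,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """The study's comparison rule.

    ``design="independent"``: two groups (sequence of two samples), compared
    with the independent-samples t-test.  ``design="repeated"``: an
    ``(n_subjects, k_conditions)`` matrix; Shapiro-Wilk on every condition
    decides repeated-measures ANOVA + Tukey (all normal) vs Friedman.
    """
    if design == "independent":
        a, b = (np.asarray(g, dtype=float) for g in data)
        if a.size < 3 or b.size < 3:
            raise ValueError("need >= 3 observations per group")
        normal = bool(
            sps.shapiro(a).pvalue > alpha and sps.shapiro(b).pvalue > alpha
        )
        t, p = sps.ttest_ind(a, b)
        return ComparisonResult(
            test="independent t-test", statistic=float(t), pvalue=float(p),
            df=(a.size + b.size - 2,), normal=normal,
        )
    if design == "repeated":
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("repeated design expects an (n_subjects, k_conditions) matrix")
        if not np.all(np.isfinite(arr)):
            raise ValueError("repeated design is unbalanced: missing condition values")
        if arr.shape[0] < 3:
            raise ValueError("need >= 3 subjects")
        normal = all(sps.shapiro(arr[:, j]).pvalue > alpha for j in range(arr.shape[1]))
        if normal:
            F, dfs, p = rm_anova(arr)
            return ComparisonResult(
                test="repeated-measures ANOVA",
                statistic=float(F), pvalue=float(p), df=dfs, normal=True,
                posthoc=tukey_rm(arr, labels),
            )
        stat, p = sps.friedmanchisquare(*[arr[:, j] for j in range(arr.shape[1])])
        return ComparisonResult(
            test="Friedman", statistic=float(stat), pvalue=float(p),
            df=(arr.shape[1] - 1,), normal=False,
        )
    raise ValueError(f"unknown design {design!r}; expected 'independent' or 'repeated'")


# ---------------------------------------------------------------------------
# regression

def fit_linear_models(
    table: pd.DataFrame, outcome: str, predictors: list[str]
) -> pd.DataFrame:
    """Univariable Pearson correlations/slopes plus a multivariable OLS fit.

    Returns one row per predictor with univariable ``r``, ``slope``,
    ``p_uni`` and multivariable ``coef``, ``p_multi``.  A rank-deficient
    design raises, naming the collinear columns.
    """
    y = table[outcome].to_numpy(dtype=float)
    n = y.size
    if n <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    X = table[predictors].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        bad = [p for p, s in zip(predictors, X.std(axis=0)) if s == 0]
        raise ValueError(f"constant predictor(s): {', '.join(bad)}")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        bad = sorted(
            {predictors[i] for i in range(len(predictors))
             for j in range(i + 1, len(predictors)) if abs(corr[i, j]) > 1 - 1e-10}
            | {predictors[j] for i in range(len(predictors))
               for j in range(i + 1, len(predictors)) if abs(corr[i, j]) > 1 - 1e-10}
        )
        raise ValueError(f"rank-deficient design; collinear columns: {', '.join(bad) or 'unknown'}")
    fit = sm.OLS(y, design).fit()
    rows = []
    for i, p in enumerate(predictors):
        r, p_uni = sps.pearsonr(X[:, i], y)
        slope = r * y.std(ddof=1) / X[:, i].std(ddof=1)
        rows.append({
            "predictor": p, "r": float(r), "slope": float(slope), "p_uni": float(p_uni),
            "coef": float(fit.params[i + 1]), "p_multi": float(fit.pvalues[i + 1]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# agreement suite

def _check_pairs(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("pairs must be (n_subjects, k>=2 raters/occasions)")
    return arr


def icc(pairs) -> float:
    """ICC(2,1): two-way mixed-effects, absolute agreement, single measurement.

    From the two-way ANOVA mean squares (MSR between subjects, MSC between
    raters, MSE residual):
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    arr = _check_pairs(pairs)
    n, k = arr.shape
    if n < 5:
        raise ValueError("need >= 5 subjects for a stable ICC")
    grand = arr.mean()
    if np.allclose(arr, grand):
        raise ValueError("zero total variance: ICC undefined")
    msr = k * ((arr.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((arr.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((arr - arr.mean(axis=1, keepdims=True)
            - arr.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def cv_agreement(pairs) -> float:
    """Within-subject CV (%): (SD of paired differences / sqrt(2)) over the
    grand mean of |measurements|.  Pure bias contributes to Bland-Altman,
    not to this CV (SD of a constant difference is zero)."""
    arr = _check_pairs(pairs)
    if arr.shape[1] != 2:
        raise ValueError("CV is defined here for paired (two-occasion) measurements")
    grand = np.abs(arr).mean()
    if grand == 0:
        raise ValueError("grand mean of |measurements| is zero: CV undefined")
    sd_within = np.std(arr[:, 0] - arr[:, 1], ddof=1) / np.sqrt(2.0)
    return float(sd_within / grand * 100.0)


def bland_altman(pairs) -> AgreementResult:
    """Bland-Altman agreement of two paired measurement series.

    bias = mean(first - second); 95% limits = bias +/- 1.96 SD(differences);
    ICC and within-subject CV are filled in alongside; ``means``/``diffs``
    are the plot coordinates.
    """
    arr = _check_pairs(pairs)
    if arr.shape[1] != 2:
        raise ValueError("Bland-Altman needs exactly two measurement series")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    try:
        icc_val = icc(arr)
    except ValueError:
        icc_val = float("nan")
    try:
        cv_val = cv_agreement(arr)
    except ValueError:
        cv_val = float("nan")
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        icc=icc_val,
        cv_pct=cv_val,
        n=arr.shape[0],
        means=arr.mean(axis=1),
        diffs=d,
    )


def bland_altman_plot(result: AgreementResult, ax=None, title: str = ""):
    """Render a Bland-Altman plot (matplotlib imported lazily)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.means, result.diffs, s=12, alpha=0.7)
    for yline, style in ((result.bias, "-"), (result.loa_lower, "--"), (result.loa_upper, "--")):
        ax.axhline(yline, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of measurements")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    return ax
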