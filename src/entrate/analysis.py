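"""Cohort analysis pipeline: screening, regressions, moderation, extreme groups.

Implements the analysis plan used in caregiving-unpredictability cohort
studies on any dyad table:

1. covariate screening against the child outcome (include a candidate if
   it shows at least a small effect, |r| > .10, or a significant
   association);
2. Pearson correlations with Fisher-z 95% intervals;
3. hierarchical ordinary-least-squares regression in ordered blocks,
   reporting standardized and unstandardized coefficients and adjusted R²
   per step;
4. sex-moderation analysis (exposure × sex interaction entered last,
   probed by sex-stratified correlations);
5. extreme-group comparison of the highest-unpredictability 15% against
   the rest (t-test, Cohen's d, covariate-adjusted linear model).

All p-values are two-sided; intervals are 95% unless configured.  Rows
with missing values are dropped listwise with a logged count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .markov import CutoffReport, classify_unpredictability

__all__ = [
    "CorrelationResult",
    "RegressionStep",
    "RegressionTable",
    "GroupComparison",
    "ScreeningReport",
    "ModerationResult",
    "ExtremeGroupResult",
    "pearson_ci",
    "apply_screening_rule",
    "screen_covariates",
    "hierarchical_regression",
    "moderation_analysis",
    "extreme_group_analysis",
    "CohortStudy",
    "CohortStudyResults",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with two-sided p and Fisher-z confidence bounds."""

    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int

    def __str__(self) -> str:
        return (
            f"r = {self.r:.3f}, p = {self.p:.3f}, "
            f"CI = {self.ci_low:.3f} – {self.ci_high:.3f}, n = {self.n}"
        )


@dataclass
class RegressionStep:
    """One cumulative block of a hierarchical regression."""

    terms: pd.DataFrame  # index: term; columns: std_beta, beta, ci_low, ci_high, p
    r2: float
    adj_r2: float
    n: int


@dataclass
class RegressionTable:
    """Ordered steps of a hierarchical regression."""

    steps: list[RegressionStep]
    outcome: str
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Hierarchical regression for {self.outcome}", "=" * 72]
        for i, step in enumerate(self.steps, start=1):
            lines.append(f"Step {i}  (n = {step.n}, adj. R² = {step.adj_r2:.3f})")
            lines.append(
                f"  {'term':<42}{'β_std':>8}{'β':>9}{'p':>8}  95% CI"
            )
            for term, row in step.terms.iterrows():
                lines.append(
                    f"  {term:<42}{row.std_beta:>8.3f}{row.beta:>9.3f}"
                    f"{row.p:>8.3f}  [{row.ci_low:.3f}, {row.ci_high:.3f}]"
                )
        return "\n".join(lines)


@dataclass
class GroupComparison:
    """Two-group comparison: means, t, df, p, Cohen's d, mean-difference CI."""

    group_names: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    t: float
    df: float
    p: float
    cohens_d: float
    diff_ci: tuple[float, float]

    def __str__(self) -> str:
        (g1, g2), (m1, m2), (s1, s2) = self.group_names, self.means, self.sds
        return (
            f"{g1}: M = {m1:.2f} (SD = {s1:.2f}, n = {self.ns[0]}) vs "
            f"{g2}: M = {m2:.2f} (SD = {s2:.2f}, n = {self.ns[1]}); "
            f"t({self.df:g}) = {self.t:.3f}, p = {self.p:.3f}, "
            f"d = {self.cohens_d:.2f}, "
            f"CI = {self.diff_ci[0]:.3f} – {self.diff_ci[1]:.3f}"
        )


@dataclass
class ScreeningReport:
    """Covariate screening outcome: per-candidate statistics and decision."""

    table: pd.DataFrame  # index: candidate; columns: kind, r, stat, p, included
    included: list[str]
    r_threshold: float
    alpha: float


@dataclass
class ModerationResult:
    regression: RegressionTable
    stratified: dict[str, CorrelationResult]


@dataclass
class ExtremeGroupResult:
    comparison: GroupComparison
    cutoffs: CutoffReport
    adjusted_model: RegressionStep | None
    interaction_p: float | None = None


def _drop_missing(df: pd.DataFrame, columns: list[str], context: str) -> pd.DataFrame:
    sub = df[columns]
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(
            f"{context}: dropped {n_dropped} row(s) with missing values "
            f"(listwise deletion)",
            UserWarning,
            stacklevel=3,
        )
    return df.loc[complete]


def pearson_ci(x, y, confidence: float = 0.95) -> CorrelationResult:
    """Pearson r with two-sided p and a Fisher-z confidence interval.

    The interval is ``tanh(arctanh(r) ± z* / sqrt(n - 3))`` with ``z*``
    the standard-normal critical value for the requested confidence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("at least 4 paired observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = zcrit / np.sqrt(n - 3)
    return CorrelationResult(
        r=float(r),
        p=float(p),
        ci_low=float(np.tanh(z - half)),
        ci_high=float(np.tanh(z + half)),
        n=n,
    )


def apply_screening_rule(
    r: float, p: float, r_threshold: float = 0.10, alpha: float = 0.05
) -> bool:
    """Inclusion rule for a continuous candidate confounder.

    Include if the candidate shows at least a small effect size
    (|r| strictly greater than ``r_threshold``) *or* a significant
    association (p < ``alpha``) with the outcome.
    """
    return abs(r) > r_threshold or p < alpha


def screen_covariates(
    cohort: pd.DataFrame,
    candidates: list[str],
    outcome: str,
    r_threshold: float = 0.10,
    alpha: float = 0.05,
) -> ScreeningReport:
    """Screen candidate confounders against the outcome.

    Continuous candidates use the Pearson rule (|r| > threshold or
    p < alpha); two-level categorical candidates are screened by the
    significance of a pooled-variance t-test on the outcome.  Constant
    candidates are excluded with a warning.
    """
    rows = []
    included = []
    for cand in candidates:
        if cand not in cohort.columns:
            raise KeyError(f"candidate {cand!r} not in cohort")
        data = _drop_missing(cohort, [cand, outcome], f"screen {cand}")
        x, y = data[cand], data[outcome]
        if x.nunique(dropna=True) <= 1:
            warnings.warn(
                f"candidate {cand!r} is constant; excluded from screening",
                UserWarning,
                stacklevel=2,
            )
            rows.append((cand, "constant", np.nan, np.nan, np.nan, False))
            continue
        if pd.api.types.is_numeric_dtype(x) and x.nunique() > 2:
            res = pearson_ci(x.to_numpy(float), y.to_numpy(float))
            ok = apply_screening_rule(res.r, res.p, r_threshold, alpha)
            rows.append((cand, "continuous", res.r, res.r, res.p, ok))
        else:
            levels = sorted(x.unique(), key=str)
            if len(levels) != 2:
                raise ValueError(
                    f"categorical candidate {cand!r} must have exactly 2 levels"
                )
            g0 = y[x == levels[0]].to_numpy(float)
            g1 = y[x == levels[1]].to_numpy(float)
            t, p = stats.ttest_ind(g0, g1, equal_var=True)
            ok = p < alpha
            rows.append((cand, "categorical", np.nan, float(t), float(p), ok))
        if ok:
            included.append(cand)
    table = pd.DataFrame(
        rows, columns=["candidate", "kind", "r", "stat", "p", "included"]
    ).set_index("candidate")
    return ScreeningReport(
        table=table, included=included, r_threshold=r_threshold, alpha=alpha
    )


def _design_matrix(
    cohort: pd.DataFrame, terms: list[str], reference: dict[str, str]
) -> pd.DataFrame:
    """Numeric design columns: categoricals dummy-coded vs their reference."""
    cols = {}
    for term in terms:
        x = cohort[term]
        if pd.api.types.is_numeric_dtype(x):
            cols[term] = x.to_numpy(float)
        else:
            levels = sorted(x.unique(), key=str)
            if len(levels) != 2:
                raise ValueError(f"term {term!r} must be numeric or two-level")
            ref = reference.get(term, levels[0])
            other = [lv for lv in levels if lv != ref]
            if not other:
                raise ValueError(f"reference level {ref!r} is the only level")
            cols[f"{term}[{other[0]}]"] = (x == other[0]).astype(float).to_numpy()
    return pd.DataFrame(cols, index=cohort.index)


def _fit_step(X: pd.DataFrame, y: np.ndarray, confidence: float) -> RegressionStep:
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError(
            f"rank-deficient design: collinearity among terms {list(X.columns)}"
        )
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=1 - confidence)
    sy = y.std(ddof=1)
    rows = {}
    for term in X.columns:
        sx = X[term].to_numpy().std(ddof=1)
        rows[term] = {
            "std_beta": fit.params[term] * sx / sy,
            "beta": fit.params[term],
            "ci_low": ci.loc[term, 0],
            "ci_high": ci.loc[term, 1],
            "p": fit.pvalues[term],
        }
    return RegressionStep(
        terms=pd.DataFrame.from_dict(rows, orient="index"),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
    )


def hierarchical_regression(
    cohort: pd.DataFrame,
    blocks: list[list[str]],
    outcome: str,
    reference: dict[str, str] | None = None,
    confidence: float = 0.95,
) -> RegressionTable:
    """OLS refit at each cumulative block of predictors.

    ``blocks`` is an ordered list of term lists; step *k* regresses the
    outcome on the union of blocks 1..k.  Standardized coefficients are
    ``beta * sd(x) / sd(y)`` (equivalent to z-scoring every column,
    dummies included); confidence intervals and p-values attach to the
    unstandardized coefficients.  Categorical terms are dummy-coded
    against a stated reference level (default: first level alphabetically;
    for ``child_sex``, female).
    """
    reference = {"child_sex": "female", **(reference or {})}
    all_terms = [t for block in blocks for t in block]
    data = _drop_missing(cohort, all_terms + [outcome], "hierarchical_regression")
    y = data[outcome].to_numpy(float)
    steps = []
    cumulative: list[str] = []
    for block in blocks:
        cumulative = cumulative + list(block)
        X = _design_matrix(data, cumulative, reference)
        steps.append(_fit_step(X, y, confidence))
    return RegressionTable(
        steps=steps,
        outcome=outcome,
        metadata={
            "reference_levels": reference,
            "standardization": "all columns z-scored, dummies included",
            "multiple_testing": "none",
        },
    )


def moderation_analysis(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    moderator: str = "child_sex",
    covariates: list[str] = (),
    reference: dict[str, str] | None = None,
    confidence: float = 0.95,
) -> ModerationResult:
    """Sex-moderation analysis of an exposure–outcome association.

    Fits three hierarchical steps — covariates; + exposure and moderator
    main effects; + interaction (mean-centered exposure × moderator
    dummy) — then probes the interaction with moderator-stratified
    Pearson correlations.  Strata with fewer than 4 complete pairs are
    omitted with a warning.
    """
    reference = {"child_sex": "female", **(reference or {})}
    cols = list(covariates) + [exposure, moderator, outcome]
    data = _drop_missing(cohort, cols, "moderation_analysis").copy()
    levels = sorted(data[moderator].unique(), key=str)
    if len(levels) != 2:
        raise ValueError(f"moderator {moderator!r} must be binary")
    ref = reference.get(moderator, levels[0])
    other = [lv for lv in levels if lv != str(ref) and lv != ref][0]
    centered = data[exposure] - data[exposure].mean()
    dummy = (data[moderator] == other).astype(float)
    inter = f"{exposure} x {moderator}[{other}]"
    data[inter] = centered * dummy
    blocks = [list(covariates), [exposure, moderator], [inter]]
    blocks = [b for b in blocks if b]
    table = hierarchical_regression(
        data, blocks, outcome, reference=reference, confidence=confidence
    )
    table.metadata["interaction_term"] = inter
    stratified: dict[str, CorrelationResult] = {}
    for level in levels:
        sub = data[data[moderator] == level]
        if len(sub) < 4:
            warnings.warn(
                f"stratum {moderator}={level!r} has n = {len(sub)} < 4; "
                "stratified correlation omitted",
                UserWarning,
                stacklevel=2,
            )
            continue
        try:
            stratified[str(level)] = pearson_ci(
                sub[exposure].to_numpy(float), sub[outcome].to_numpy(float),
                confidence=confidence,
            )
        except ValueError as err:
            warnings.warn(
                f"stratum {moderator}={level!r}: stratified correlation "
                f"omitted ({err})",
                UserWarning,
                stacklevel=2,
            )
    return ModerationResult(regression=table, stratified=stratified)


def _low_tail_indicator(x: np.ndarray, quantile: float = 0.15) -> np.ndarray:
    """1 for values strictly below the low-tail quantile cut, else 0."""
    cut = np.quantile(x, quantile, method="linear")
    return (x < cut).astype(float)


def extreme_group_analysis(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: list[str] = (),
    high_quantile: float = 0.85,
    low_dichotomize: list[str] = (),
    welch: bool = False,
    moderator: str | None = None,
    reference: dict[str, str] | None = None,
    confidence: float = 0.95,
) -> ExtremeGroupResult:
    """Compare the high-exposure extreme group against the rest.

    Dyads with exposure strictly above the ``high_quantile`` cut form the
    high-unpredictability group.  The unadjusted contrast is a pooled-
    variance Student's t-test (Welch by flag) with Cohen's d on the pooled
    SD and a CI for the mean difference (high − low/moderate).  The
    adjusted model regresses the outcome on the group indicator plus
    covariates; covariate names listed in ``low_dichotomize`` (e.g.
    maternal sensitivity) are replaced by a low-vs-rest indicator at their
    lowest 15th percentile, mirroring the exposure dichotomization at the
    other tail.  If ``moderator`` is given, a group × moderator
    interaction model is additionally fitted and its interaction p
    reported.
    """
    cols = list(covariates) + [exposure, outcome]
    if moderator:
        cols.append(moderator)
    data = _drop_missing(cohort, cols, "extreme_group_analysis").copy()
    cutoffs = classify_unpredictability(
        data[exposure].to_numpy(float), high_quantile=high_quantile
    )
    high = np.array(cutoffs.labels) == "high"
    if not high.any():
        raise ValueError("high-exposure group is empty; cannot compare groups")
    y_high = data.loc[high, outcome].to_numpy(float)
    y_low = data.loc[~high, outcome].to_numpy(float)
    n1, n2 = len(y_high), len(y_low)
    t, p = stats.ttest_ind(y_high, y_low, equal_var=not welch)
    if welch:
        df_ = stats.ttest_ind(y_high, y_low, equal_var=False).df
    else:
        df_ = n1 + n2 - 2
    sp = np.sqrt(
        ((n1 - 1) * y_high.var(ddof=1) + (n2 - 1) * y_low.var(ddof=1))
        / (n1 + n2 - 2)
    )
    diff = y_high.mean() - y_low.mean()
    d = diff / sp if sp > 0 else 0.0
    se = sp * np.sqrt(1 / n1 + 1 / n2)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df_)
    comparison = GroupComparison(
        group_names=("high", "low_moderate"),
        means=(float(y_high.mean()), float(y_low.mean())),
        sds=(float(y_high.std(ddof=1)), float(y_low.std(ddof=1))),
        ns=(n1, n2),
        t=float(t),
        df=float(df_),
        p=float(p),
        cohens_d=float(d),
        diff_ci=(float(diff - tcrit * se), float(diff + tcrit * se)),
    )
    group_col = f"{exposure}[high]"
    data[group_col] = high.astype(float)
    model_terms = [group_col]
    for cov in covariates:
        if cov in low_dichotomize:
            name = f"{cov}[low]"
            data[name] = _low_tail_indicator(data[cov].to_numpy(float))
            model_terms.append(name)
        else:
            model_terms.append(cov)
    adjusted = None
    if covariates:
        table = hierarchical_regression(
            data, [model_terms], outcome, reference=reference,
            confidence=confidence,
        )
        adjusted = table.steps[0]
    interaction_p = None
    if moderator:
        mod = moderation_analysis(
            data, group_col, outcome, moderator=moderator,
            covariates=[t_ for t_ in model_terms if t_ != group_col],
            reference=reference, confidence=confidence,
        )
        inter = mod.regression.metadata["interaction_term"]
        interaction_p = float(mod.regression.steps[-1].terms.loc[inter, "p"])
    return ExtremeGroupResult(
        comparison=comparison,
        cutoffs=cutoffs,
        adjusted_model=adjusted,
        interaction_p=interaction_p,
    )


class CohortStudy:
    """Full analysis plan for a dyad cohort, statsmodels-style.

    Construct from a cohort DataFrame (or CSV via :meth:`from_csv`), call
    :meth:`fit` to run screening, correlation, hierarchical adjustment,
    sex moderation and the extreme-group contrast in one pass.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        exposure: str = "entropy_rate",
        outcome: str = "child_ec",
        sex: str = "child_sex",
        candidates: list[str] | None = None,
        high_quantile: float = 0.85,
        low_dichotomize: list[str] = ("maternal_sensitivity",),
    ):
        self.cohort = cohort
        self.exposure = exposure
        self.outcome = outcome
        self.sex = sex
        if candidates is None:
            candidates = [
                c
                for c in cohort.columns
                if c not in {exposure, outcome, sex, "dyad_id"}
            ]
        self.candidates = candidates
        self.high_quantile = high_quantile
        self.low_dichotomize = [
            c for c in low_dichotomize if c in cohort.columns
        ]

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CohortStudy":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> "CohortStudyResults":
        screening = screen_covariates(
            self.cohort, self.candidates, self.outcome
        )
        sex_screen = screen_covariates(
            self.cohort, [self.sex], self.outcome
        )
        covariates = list(screening.included)
        data = _drop_missing(
            self.cohort,
            covariates + [self.exposure, self.outcome, self.sex],
            "CohortStudy.fit",
        )
        exposure_corr = pearson_ci(
            data[self.exposure].to_numpy(float),
            data[self.outcome].to_numpy(float),
        )
        sex_comp = _sex_comparison(data, self.sex, self.outcome)
        adjust_blocks = [[self.exposure]] + [[c] for c in covariates]
        if sex_screen.included:
            adjust_blocks.append([self.sex])
        adjusted = hierarchical_regression(data, adjust_blocks, self.outcome)
        moderation = moderation_analysis(
            data, self.exposure, self.outcome, moderator=self.sex,
            covariates=covariates,
        )
        extreme = extreme_group_analysis(
            data, self.exposure, self.outcome,
            covariates=covariates + ([self.sex] if sex_screen.included else []),
            high_quantile=self.high_quantile,
            low_dichotomize=self.low_dichotomize,
            moderator=self.sex,
        )
        return CohortStudyResults(
            model=self,
            screening=screening,
            sex_screening=sex_screen,
            exposure_correlation=exposure_corr,
            sex_comparison=sex_comp,
            adjusted=adjusted,
            moderation=moderation,
            extreme=extreme,
            n=len(data),
        )


def _sex_comparison(data: pd.DataFrame, sex: str, outcome: str) -> GroupComparison:
    levels = sorted(data[sex].unique(), key=str)
    g = [data.loc[data[sex] == lv, outcome].to_numpy(float) for lv in levels]
    n1, n2 = len(g[0]), len(g[1])
    t, p = stats.ttest_ind(g[0], g[1], equal_var=True)
    sp = np.sqrt(
        ((n1 - 1) * g[0].var(ddof=1) + (n2 - 1) * g[1].var(ddof=1))
        / (n1 + n2 - 2)
    )
    diff = g[0].mean() - g[1].mean()
    se = sp * np.sqrt(1 / n1 + 1 / n2)
    tcrit = stats.t.ppf(0.975, n1 + n2 - 2)
    return GroupComparison(
        group_names=(str(levels[0]), str(levels[1])),
        means=(float(g[0].mean()), float(g[1].mean())),
        sds=(float(g[0].std(ddof=1)), float(g[1].std(ddof=1))),
        ns=(n1, n2),
        t=float(t),
        df=float(n1 + n2 - 2),
        p=float(p),
        cohens_d=float(diff / sp) if sp > 0 else 0.0,
        diff_ci=(float(diff - tcrit * se), float(diff + tcrit * se)),
    )


class CohortStudyResults:
    """Results of the full cohort analysis plan."""

    def __init__(
        self, model, screening, sex_screening, exposure_correlation,
        sex_comparison, adjusted, moderation, extreme, n,
    ):
        self.model = model
        self.screening = screening
        self.sex_screening = sex_screening
        self.exposure_correlation = exposure_correlation
        self.sex_comparison = sex_comparison
        self.adjusted = adjusted
        self.moderation = moderation
        self.extreme = extreme
        self.n = n

    def plot_moderation(self, ax=None):
        """Exposure–outcome scatter with per-sex least-squares lines.

        The visual companion to the stratified correlations: one fitted
        line per moderator level, data points colored accordingly.
        Returns the matplotlib Axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4.5))
        m = self.model
        data = _drop_missing(
            m.cohort, [m.exposure, m.outcome, m.sex], "plot_moderation"
        )
        for level, color in zip(sorted(data[m.sex].unique(), key=str),
                                ("#1f77b4", "#d62728")):
            sub = data[data[m.sex] == level]
            x = sub[m.exposure].to_numpy(float)
            y = sub[m.outcome].to_numpy(float)
            ax.scatter(x, y, s=12, alpha=0.5, color=color, label=str(level))
            if len(sub) >= 2 and np.ptp(x) > 0:
                slope, intercept = np.polyfit(x, y, 1)
                grid = np.linspace(x.min(), x.max(), 50)
                ax.plot(grid, intercept + slope * grid, color=color, lw=2)
        ax.set_xlabel(f"{m.exposure} (bits)")
        ax.set_ylabel(m.outcome)
        ax.legend(title=m.sex, frameon=False)
        return ax

    def summary(self) -> str:
        m = self.model
        lines = [
            "Cohort unpredictability analysis",
            "=" * 72,
            f"n complete dyads: {self.n}",
            "",
            "Covariate screening (|r| > "
            f"{self.screening.r_threshold:g} or p < {self.screening.alpha:g}):",
            self.screening.table.to_string(
                float_format=lambda v: f"{v:.3f}"
            ),
            f"  included: {', '.join(self.screening.included) or 'none'}",
            f"  sex screened by t-test: "
            f"included = {bool(self.sex_screening.included)}",
            "",
            f"Exposure correlation ({m.exposure} vs {m.outcome}): "
            f"{self.exposure_correlation}",
            f"Sex comparison ({m.outcome}): {self.sex_comparison}",
            "",
            self.adjusted.summary(),
            "",
            self.moderation.regression.summary(),
            "Stratified correlations:",
        ]
        for level, res in self.moderation.stratified.items():
            lines.append(f"  {m.sex} = {level}: {res}")
        lines += [
            "",
            "Extreme-group contrast (highest "
            f"{1 - m.high_quantile:.0%} of {m.exposure}):",
            f"  {self.extreme.comparison}",
            f"  cut value: {self.extreme.cutoffs.cut_value:.3f}",
        ]
        if self.extreme.adjusted_model is not None:
            lines.append("  adjusted model:")
            for term, row in self.extreme.adjusted_model.terms.iterrows():
                lines.append(
                    f"    {term:<40}β = {row.beta:>7.3f}  p = {row.p:.3f}  "
                    f"[{row.ci_low:.3f}, {row.ci_high:.3f}]"
                )
        if self.extreme.interaction_p is not None:
            lines.append(
                f"  group × sex interaction p = {self.extreme.interaction_p:.3f}"
            )
        return "\n".join(lines)
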