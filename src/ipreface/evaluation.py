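"""Diagnostic-accuracy statistics for the acidemia-prediction analysis.

Covers the full statistical workflow of the study design: ROC curve and AUC
(Mann-Whitney estimate, ties counted one half) with a DeLong
normal-approximation confidence interval, Youden-index cutoff selection
(positivity rule: score >= cutoff; ties broken toward the smallest cutoff,
favoring sensitivity), confusion metrics, two-group and k-group comparison
tables, the exact 2x2 test for proportions, Hanley-McNeil sample-size
calculation for a one-sided AUC test, and a baseline-characteristics cohort
summary.

Standard tests are delegated to scipy/sklearn; the DeLong variance and the
Hanley-McNeil power solver are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.metrics import roc_curve

from .events import LaborCase
from .exceptions import AnalysisError, ComparisonError


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCAnalysis:
    thresholds: np.ndarray  # ascending candidate cutoffs (score >= t positive)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    auc_se: float
    p_value: float  # two-sided test of AUC = 0.5 (DeLong z)
    ci_method: str = "delong-logit-normal"
    n_pos: int = 0
    n_neg: int = 0


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC (Mann-Whitney, ties 1/2) and its DeLong variance via midranks."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    rank_all = stats.rankdata(all_scores)  # midranks
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    # structural components: V10_i = P(pos_i > neg) + P(pos_i == neg)/2
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_analysis(scores: Sequence[float], outcomes: Sequence[bool]) -> ROCAnalysis:
    """ROC curve and AUC with DeLong confidence interval.

    ``outcomes`` are the acidemia labels (True = positive).  Requires at
    least one positive and one negative; otherwise the ROC is undefined and
    an :class:`AnalysisError` is raised.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.shape != y.shape:
        raise AnalysisError("scores and outcomes must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise AnalysisError(
            f"roc_analysis requires both outcome classes (got {n_pos} positive, "
            f"{n_neg} negative)"
        )

    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    # orient as ascending thresholds with positivity rule score >= t
    order = np.argsort(thr)
    thresholds = thr[order]
    sensitivity = tpr[order]
    specificity = 1.0 - fpr[order]

    auc, var = _delong_variance(s[y], s[~y])
    se = math.sqrt(var)
    z = stats.norm.ppf(0.975)
    if 0.0 < auc < 1.0 and se > 0:
        # normal interval on the logit scale: better small-sample coverage
        # than the plain-scale interval, and bounded in (0, 1) by construction
        logit = math.log(auc / (1.0 - auc))
        se_logit = se / (auc * (1.0 - auc))
        lo = 1.0 / (1.0 + math.exp(-(logit - z * se_logit)))
        hi = 1.0 / (1.0 + math.exp(-(logit + z * se_logit)))
    else:
        lo = max(0.0, auc - z * se)
        hi = min(1.0, auc + z * se)
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return ROCAnalysis(
        thresholds=thresholds, sensitivity=sensitivity, specificity=specificity,
        auc=auc, auc_ci_low=lo, auc_ci_high=hi, auc_se=se, p_value=float(p),
        n_pos=n_pos, n_neg=n_neg,
    )


@dataclass(frozen=True)
class CutoffReport:
    """Operating point chosen on an ROC curve (positive: score >= cutoff)."""

    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fpr: float
    fnr: float
    youden_j: float


def youden_cutoff(roc: ROCAnalysis) -> CutoffReport:
    """Cutoff maximizing the Youden index J = sensitivity + specificity - 1.

    Among tied maximizers the smallest cutoff is returned (favoring
    sensitivity).  All six confusion metrics are evaluated at that cutoff.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    # smallest threshold among maximizers; tolerance guards against 1-ulp
    # differences between algebraically equal J values
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    cutoff = float(roc.thresholds[best])
    sens = float(roc.sensitivity[best])
    spec = float(roc.specificity[best])
    tp = sens * roc.n_pos
    fn = roc.n_pos - tp
    tn = spec * roc.n_neg
    fp = roc.n_neg - tn
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    return CutoffReport(
        cutoff=cutoff, sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        fpr=1.0 - spec, fnr=1.0 - sens, youden_j=sens + spec - 1.0,
    )


# ---------------------------------------------------------------------------
# exact and asymptotic tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    The two-sided p-value is the sum of hypergeometric point probabilities
    not exceeding that of the observed table, conditioning on both margins.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"cell counts must be non-negative integers, got {x!r}")
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _expected_counts(table: np.ndarray) -> np.ndarray:
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    return rowsum * colsum / table.sum()


def proportion_test(table: np.ndarray) -> tuple[str, float]:
    """Chi-square test for a 2xk count table, falling back to Fisher exact
    (2x2 only) when any expected cell count is below 5."""
    table = np.asarray(table, dtype=float)
    small = (_expected_counts(table) < 5).any()
    if small and table.shape == (2, 2):
        a, b = table[0]
        c, d = table[1]
        return "fisher", fisher_exact_2x2(int(a), int(b), int(c), int(d))
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi-square", float(p)


# ---------------------------------------------------------------------------
# group comparison (Table-2-shaped)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    variable: str
    kind: Literal["continuous", "binary"]
    group_summaries: tuple[str, ...]
    test: str
    p_value: float


def _is_parametric(groups: list[np.ndarray], alpha: float = 0.05) -> bool:
    """Normality screen: Shapiro-Wilk in every group (needs n >= 3)."""
    for g in groups:
        if len(g) < 3:
            return False
        if len(np.unique(g)) == 1:
            return False
        if stats.shapiro(g).pvalue < alpha:
            return False
    return True


def _summary(values: np.ndarray, parametric: bool) -> str:
    if parametric:
        return f"{values.mean():.1f} ± {values.std(ddof=1):.1f}"
    return f"{np.median(values):.1f} ({values.min():.1f}–{values.max():.1f})"


def continuous_group_test(groups: list[np.ndarray],
                          normality_alpha: float = 0.05) -> tuple[str, float]:
    """Documented selection rule for continuous variables: Shapiro-Wilk
    screen in every group chooses t / ANOVA versus Mann-Whitney U /
    Kruskal-Wallis.  Returns (test name, two-sided p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    return _continuous_test(groups, _is_parametric(groups, normality_alpha))


def _continuous_test(groups: list[np.ndarray], parametric: bool) -> tuple[str, float]:
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence of any difference
        return ("t" if parametric else "mann-whitney") if len(groups) == 2 else \
               ("anova" if parametric else "kruskal-wallis"), 1.0
    if len(groups) == 2:
        if parametric:
            return "t", float(stats.ttest_ind(groups[0], groups[1], equal_var=False).pvalue)
        return "mann-whitney", float(stats.mannwhitneyu(groups[0], groups[1],
                                                        alternative="two-sided").pvalue)
    if parametric:
        return "anova", float(stats.f_oneway(*groups).pvalue)
    return "kruskal-wallis", float(stats.kruskal(*groups).pvalue)


def compare_groups(
    cases: Sequence[LaborCase],
    grouping: Callable[[LaborCase], int],
    variables: Sequence[tuple[str, str, Callable[[LaborCase], object]]],
    normality_alpha: float = 0.05,
) -> list[GroupComparison]:
    """Per-variable between-group tests emitting a Table-2-shaped report.

    ``grouping`` maps a case to its group index; ``variables`` is a list of
    (name, kind, accessor) with kind ``continuous`` or ``binary``.  Test
    selection: for continuous variables a Shapiro-Wilk screen in every group
    chooses the t test / one-way ANOVA (parametric) versus the Mann-Whitney U
    / Kruskal-Wallis test; for binary variables the chi-square test, with
    Fisher's exact test when any expected cell count is below 5 (2x2).
    """
    labels = sorted({grouping(c) for c in cases})
    if len(labels) < 2:
        raise ComparisonError(f"need >= 2 groups, got {len(labels)}")
    grouped: dict[int, list[LaborCase]] = {g: [] for g in labels}
    for c in cases:
        grouped[grouping(c)].append(c)
    if any(len(v) == 0 for v in grouped.values()):
        raise ComparisonError("empty group")

    out: list[GroupComparison] = []
    for name, kind, accessor in variables:
        if kind == "continuous":
            gvals = [np.asarray([accessor(c) for c in grouped[g]
                                 if accessor(c) is not None], dtype=float)
                     for g in labels]
            if any(len(g) == 0 for g in gvals):
                raise ComparisonError(f"variable {name!r}: empty group after dropping missing")
            parametric = _is_parametric(gvals, normality_alpha)
            test, p = _continuous_test(gvals, parametric)
            summaries = tuple(_summary(g, parametric) for g in gvals)
        elif kind == "binary":
            counts = []
            summaries_l = []
            for g in labels:
                vals = [bool(accessor(c)) for c in grouped[g] if accessor(c) is not None]
                k, n = sum(vals), len(vals)
                counts.append([k, n - k])
                pct = 100.0 * k / n if n else float("nan")
                summaries_l.append(f"{pct:.1f} ({k}/{n})")
            test, p = proportion_test(np.asarray(counts).T)
            summaries = tuple(summaries_l)
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
        out.append(GroupComparison(variable=name, kind=kind,  # type: ignore[arg-type]
                                   group_summaries=summaries, test=test, p_value=p))
    return out


# ---------------------------------------------------------------------------
# Hanley-McNeil sample size for a one-sided AUC test
# ---------------------------------------------------------------------------

def _hanley_mcneil_variance(auc: float, n_pos: float, n_neg: float) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    return (auc * (1.0 - auc) + (n_pos - 1.0) * (q1 - auc * auc)
            + (n_neg - 1.0) * (q2 - auc * auc)) / (n_pos * n_neg)


def auc_sample_size(
    auc_alt: float,
    power: float = 0.90,
    alpha_one_sided: float = 0.05,
    ratio_neg_per_pos: float = 9.0,
) -> tuple[int, int, int]:
    """Sample size to detect ``auc_alt`` against a null AUC of 0.5.

    Solves the Hanley-McNeil power equation
    ``z_alpha * sqrt(V0) + z_beta * sqrt(V1) = auc_alt - 0.5`` for the
    continuous number of positives (with negatives = ratio x positives and
    the variances evaluated under the null and the alternative), rounds it
    to the nearest integer, and scales by the allocation ratio.

    Returns ``(n_pos, n_neg, n_total)``.
    """
    if not 0.5 < auc_alt < 1.0:
        raise ValueError("auc_alt must lie in (0.5, 1): no finite n otherwise")
    if not (0.0 < power < 1.0 and 0.0 < alpha_one_sided < 1.0):
        raise ValueError("power and alpha must lie in (0, 1)")
    if ratio_neg_per_pos <= 0:
        raise ValueError("allocation ratio must be positive")
    z_a = stats.norm.ppf(1.0 - alpha_one_sided)
    z_b = stats.norm.ppf(power)
    delta = auc_alt - 0.5

    def gap(m: float) -> float:
        v0 = _hanley_mcneil_variance(0.5, m, ratio_neg_per_pos * m)
        v1 = _hanley_mcneil_variance(auc_alt, m, ratio_neg_per_pos * m)
        return z_a * math.sqrt(v0) + z_b * math.sqrt(v1) - delta

    m_cont = optimize.brentq(gap, 1.0 + 1e-9, 1e7)
    n_pos = int(math.floor(m_cont + 0.5))
    n_neg = int(math.floor(ratio_neg_per_pos * n_pos + 0.5))
    return n_pos, n_neg, n_pos + n_neg


# ---------------------------------------------------------------------------
# cohort summary (Table-1-shaped)
# ---------------------------------------------------------------------------

def case_level(case: LaborCase) -> Optional[int]:
    """The case's five-tier level: the maximum level over its leveled events."""
    levels = [e.level for e in case.events if e.level is not None]
    return max(levels) if levels else None


def summarize_cohort(cases: Sequence[LaborCase]) -> pd.DataFrame:
    """Baseline-characteristics summary, overall and by five-tier level group.

    Continuous covariates report mean +/- sd, ordinal ones median (range),
    flags report % (n/N); acidemia rates are given at the nested pH
    thresholds 7.2 / 7.1 / 7.0 along with the NICU-for-asphyxia rate.
    """
    if not cases:
        raise ComparisonError("cannot summarize an empty cohort")

    groups: dict[str, list[LaborCase]] = {"all": list(cases)}
    for c in cases:
        lvl = case_level(c)
        if lvl is not None:
            groups.setdefault(f"level {lvl}", []).append(c)

    def mean_sd(vals):
        v = np.asarray([x for x in vals if x is not None], dtype=float)
        return f"{v.mean():.1f} ± {v.std(ddof=1):.1f}" if len(v) > 1 else (
            f"{v[0]:.1f}" if len(v) else "")

    def med_range(vals):
        v = np.asarray([x for x in vals if x is not None], dtype=float)
        return f"{np.median(v):.1f} ({v.min():.0f}–{v.max():.0f})" if len(v) else ""

    def rate(flags):
        v = [bool(x) for x in flags if x is not None]
        if not v:
            return ""
        return f"{100.0 * sum(v) / len(v):.1f} ({sum(v)}/{len(v)})"

    rows: dict[str, dict[str, str]] = {}

    def add(name: str, fn, accessor):
        rows[name] = {g: fn([accessor(c) for c in cs]) for g, cs in groups.items()}

    add("n", lambda vals: str(len(vals)), lambda c: c)
    add("maternal age (y)", mean_sd, lambda c: c.maternal_age)
    add("parity", med_range, lambda c: c.parity)
    add("gestational week", med_range, lambda c: c.gestational_week)
    add("induction of labor", rate, lambda c: c.induction)
    add("vacuum delivery", rate, lambda c: c.vacuum)
    add("decision to delivery (min)", med_range,
        lambda c: (c.delivery_time - c.decision_time) / 60.0)
    add("removal to delivery (min)", med_range,
        lambda c: (c.delivery_time - c.removal_time) / 60.0)
    add("Apgar 1 min", med_range, lambda c: c.apgar1)
    add("Apgar 5 min", med_range, lambda c: c.apgar5)
    for key, label in (("ph", "pH"), ("pco2", "PCO2 (mm Hg)"), ("po2", "PO2 (mm Hg)"),
                       ("hco3", "HCO3 (mmol/L)"), ("be", "BE (mEq/L)"),
                       ("lactate", "lactate (mmol/L)")):
        add(label, mean_sd,
            lambda c, k=key: getattr(c.blood_gas, k) if c.blood_gas else None)
    for thr in (7.2, 7.1, 7.0):
        add(f"pH < {thr}", rate,
            lambda c, t=thr: c.blood_gas.acidemia(t) if c.blood_gas else None)
    add("NICU for asphyxia", rate, lambda c: c.nicu_asphyxia)

    cols = ["all"] + sorted(g for g in groups if g != "all")
    return pd.DataFrame(rows).T.reindex(columns=cols).fillna("")


def acidemia_rates(cases: Sequence[LaborCase]) -> dict[float, float]:
    """Fraction of cases below each nested pH threshold (7.2, 7.1, 7.0)."""
    with_bg = [c for c in cases if c.blood_gas is not None]
    if not with_bg:
        raise ComparisonError("no blood-gas panels in cohort")
    return {thr: sum(c.blood_gas.acidemia(thr) for c in with_bg) / len(with_bg)
            for thr in (7.2, 7.1, 7.0)}
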