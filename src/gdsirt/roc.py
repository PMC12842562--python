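"""ROC machinery and the hypothesis tests the reduction pipeline relies on.

AUC is the Mann–Whitney probability that a random case outscores a random
control (ties half-weighted).  Variances come from DeLong placement values;
the paired DeLong test compares two correlated AUCs computed on the same
subjects, and the Hanley–McNeil z compares AUCs from independent samples.
Operating-point utilities (Youden cutoff, McNemar, two-proportion chi-square,
predictive values) round out the screening-performance toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, norm, rankdata
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "RocResult",
    "DelongComparison",
    "CutoffPerformance",
    "auc",
    "delong_paired",
    "hanley_mcneil_independent",
    "youden_cutoff",
    "mcnemar",
    "chisq_two_proportions",
    "predictive_values",
    "cutoff_table",
]


@dataclass
class RocResult:
    auc: float
    var: float
    ci: tuple[float, float]
    n_cases: int
    n_controls: int
    degenerate: bool = False

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var))


@dataclass
class DelongComparison:
    delta_auc: float
    z: float
    p: float
    var: float
    degenerate: bool = False


@dataclass
class CutoffPerformance:
    """Operating point: positive test means ``score >= cutoff``.

    Sensitivity/specificity are percentages; ``youden_j`` is on the [-1, 1]
    fraction scale (sens + spec - 1).
    """

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


def _split_cases(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have matching shapes")
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both diagnosis classes must be present")
    return cases, controls


def _placements(cases, controls):
    """DeLong placement values via midranks.

    ``v10[i]`` is the fraction of controls scored below case *i* (ties half),
    ``v01[j]`` the fraction of cases scored above control *j*.
    """
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    r_all = rankdata(combined)
    r_cases = rankdata(cases)
    r_controls = rankdata(controls)
    v10 = (r_all[:m] - r_cases) / n
    v01 = 1.0 - (r_all[m:] - r_controls) / m
    return v10, v01


def auc(scores, labels, level: float = 0.95) -> RocResult:
    """Mann–Whitney AUC with DeLong variance and a Wald CI clipped to [0, 1].

    Constant scores yield AUC 0.5 with zero variance and a degenerate flag.
    """
    cases, controls = _split_cases(scores, labels)
    degenerate = False
    if np.ptp(np.concatenate([cases, controls])) == 0:
        warnings.warn("constant scores: AUC degenerate at 0.5", stacklevel=2)
        degenerate = True
    v10, v01 = _placements(cases, controls)
    a = float(v10.mean())
    s10 = float(v10.var(ddof=1)) if len(v10) > 1 else 0.0
    s01 = float(v01.var(ddof=1)) if len(v01) > 1 else 0.0
    var = s10 / len(v10) + s01 / len(v01)
    zq = norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(var)
    ci = (max(0.0, a - half), min(1.0, a + half))
    return RocResult(a, var, ci, len(cases), len(controls), degenerate)


def delong_paired(scores_a, scores_b, labels) -> DelongComparison:
    """DeLong test for two correlated AUCs measured on the same subjects.

    Returns the AUC difference (A minus B), the normal z statistic and the
    two-sided p-value.  Identical score vectors (zero variance of the
    difference) are reported as delta 0, p 1 with a degenerate flag.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired scores must have identical shapes")
    cases_a, controls_a = _split_cases(scores_a, labels)
    cases_b, controls_b = _split_cases(scores_b, labels)
    v10a, v01a = _placements(cases_a, controls_a)
    v10b, v01b = _placements(cases_b, controls_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    delta = auc_a - auc_b
    m, n = len(v10a), len(v01a)
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 1e-14:
        return DelongComparison(
            0.0 if abs(delta) < 1e-12 else delta,
            0.0,
            1.0 if abs(delta) < 1e-12 else 0.0,
            0.0,
            degenerate=True,
        )
    z = delta / np.sqrt(var)
    p = 2 * norm.sf(abs(z))
    return DelongComparison(delta, float(z), float(p), float(var))


def hanley_mcneil_independent(auc_a, se_a, auc_b, se_b):
    """z-test for an AUC difference between two independent samples.

    ``z = (AUC_A - AUC_B) / sqrt(SE_A^2 + SE_B^2)``, two-sided normal p.
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    denom = np.sqrt(se_a**2 + se_b**2)
    if denom == 0:
        if auc_a == auc_b:
            return 0.0, 1.0
        raise ValueError("both standard errors are zero")
    z = (auc_a - auc_b) / denom
    return float(z), float(2 * norm.sf(abs(z)))


def youden_cutoff(scores, labels) -> CutoffPerformance:
    """Operating point maximizing Youden's J = sens + spec - 1.

    Every observed score value is tried as the threshold of the rule
    "positive if score >= t"; ties in J are broken toward the *higher*
    cutoff (favouring specificity).
    """
    cases, controls = _split_cases(scores, labels)
    thresholds = np.unique(np.concatenate([cases, controls]))
    sens = np.array([(cases >= t).mean() for t in thresholds])
    spec = np.array([(controls < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)[-1]
    return CutoffPerformance(
        cutoff=float(thresholds[best]),
        sensitivity=float(100 * sens[best]),
        specificity=float(100 * spec[best]),
        youden_j=float(j[best]),
    )


def mcnemar(a_correct, b_correct) -> float:
    """McNemar test for paired classification accuracy of two scales.

    Exact binomial on the discordant pairs when there are fewer than 25,
    otherwise the continuity-corrected chi-square.  No discordant pairs
    gives p = 1.
    """
    a_correct = np.asarray(a_correct, dtype=bool)
    b_correct = np.asarray(b_correct, dtype=bool)
    if a_correct.shape != b_correct.shape:
        raise ValueError("paired indicators must have identical shapes")
    b = int(np.sum(a_correct & ~b_correct))
    c = int(np.sum(~a_correct & b_correct))
    if b + c == 0:
        return 1.0
    table = [[0, b], [c, 0]]
    res = _sm_mcnemar(table, exact=(b + c < 25), correction=True)
    return float(min(res.pvalue, 1.0))


def chisq_two_proportions(x1, n1, x2, n2) -> float:
    """Continuity-corrected 2x2 chi-square comparing two independent
    proportions; degenerate margins give p = 1 with a warning."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 margin; returning p = 1", stacklevel=2)
        return 1.0
    stat, p, _, _ = chi2_contingency(table, correction=True)
    return float(p)


def predictive_values(sensitivity, specificity, prevalence):
    """PPV and NPV at a given prevalence (all fractions in [0, 1])."""
    for v in (sensitivity, specificity, prevalence):
        if not 0 <= v <= 1:
            raise ValueError("arguments must be fractions in [0, 1]")
    ppv_den = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    npv_den = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    if ppv_den == 0 or npv_den == 0:
        raise ValueError("predictive value undefined (zero denominator)")
    ppv = sensitivity * prevalence / ppv_den
    npv = specificity * (1 - prevalence) / npv_den
    return float(ppv), float(npv)


def cutoff_table(
    scores, labels, prevalences=(0.038, 0.13, 0.20)
) -> pd.DataFrame:
    """Sweep every threshold and tabulate sens/spec/J plus PPV/NPV under the
    given prevalence scenarios (community, clinic, nursing-home defaults)."""
    cases, controls = _split_cases(scores, labels)
    rows = []
    for t in np.unique(np.concatenate([cases, controls])):
        sens = float((cases >= t).mean())
        spec = float((controls < t).mean())
        row = {
            "cutoff": float(t),
            "sensitivity": 100 * sens,
            "specificity": 100 * spec,
            "youden_j": sens + spec - 1.0,
        }
        for prev in prevalences:
            try:
                ppv, npv = predictive_values(sens, spec, prev)
            except ValueError:
                ppv, npv = np.nan, np.nan
            row[f"ppv_{prev:g}"] = 100 * ppv
            row[f"npv_{prev:g}"] = 100 * npv
        rows.append(row)
    return pd.DataFrame(rows)
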