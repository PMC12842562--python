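"""Efficiency ratio (AUC per item) with bootstrap inference.

The efficiency ratio of a scale is its AUC divided by its number of items —
diagnostic accuracy achieved per item administered.  Two inference routes:

* within one sample, two scales are compared by resampling subjects with
  replacement (pairing preserved), recomputing both efficiency ratios per
  resample, and reading a percentile CI off the distribution of differences;
* across independent samples (development vs validation), a z-test on the
  two bootstrap standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .roc import _placements, _split_cases

__all__ = [
    "EfficiencyResult",
    "BootstrapComparison",
    "efficiency_ratio",
    "bootstrap_se",
    "bootstrap_compare_within",
    "cross_set_z",
]


@dataclass
class EfficiencyResult:
    scale: str
    auc: float
    n_items: int
    ratio: float
    se: float
    iterations: int
    seed: int


@dataclass
class BootstrapComparison:
    """Percentile-method comparison of two within-sample efficiency ratios."""

    diff: float
    ci: tuple[float, float]
    significant: bool
    p_boot: float
    iterations: int
    n_redrawn: int
    n_skipped: int


def efficiency_ratio(auc_value: float, n_items: int) -> float:
    """AUC divided by the number of items."""
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if not 0 <= auc_value <= 1:
        raise ValueError("auc must lie in [0, 1]")
    return float(auc_value) / int(n_items)


def _fast_auc(scores, labels01):
    cases = scores[labels01]
    controls = scores[~labels01]
    v10, _ = _placements(cases, controls)
    return float(v10.mean())


def _resample(rng, n, labels01, max_retry=100):
    """Subject resample with replacement; redraw if one class vanishes."""
    redraws = 0
    for _ in range(max_retry):
        idx = rng.integers(0, n, n)
        sel = labels01[idx]
        if sel.any() and (~sel).any():
            return idx, redraws
        redraws += 1
    return None, redraws


def bootstrap_se(
    scores, labels, n_items: int, B: int = 1000, seed: int = 0, scale: str = ""
) -> EfficiencyResult:
    """Point efficiency ratio plus its bootstrap standard error."""
    scores = np.asarray(scores, dtype=float)
    labels01 = np.asarray(labels).astype(bool)
    _split_cases(scores, labels01.astype(int))  # validates both classes present
    rng = np.random.default_rng(seed)
    n = len(scores)
    ratios = []
    for _ in range(B):
        idx, _ = _resample(rng, n, labels01)
        if idx is None:
            continue
        ratios.append(_fast_auc(scores[idx], labels01[idx]) / n_items)
    point = efficiency_ratio(_fast_auc(scores, labels01), n_items)
    return EfficiencyResult(
        scale=scale,
        auc=_fast_auc(scores, labels01),
        n_items=n_items,
        ratio=point,
        se=float(np.std(ratios, ddof=1)),
        iterations=len(ratios),
        seed=seed,
    )


def bootstrap_compare_within(
    scores_a,
    n_items_a: int,
    scores_b,
    n_items_b: int,
    labels,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapComparison:
    """Percentile bootstrap for the difference of two efficiency ratios.

    Scales A and B are scored on the *same* subjects; each of the ``B``
    resamples draws subjects with replacement, recomputes both AUCs and
    efficiency ratios and takes the difference (A minus B).  The comparison
    is significant iff the central 95% percentile interval excludes zero.
    A supplementary two-sided bootstrap p, ``2 min(F(0), 1-F(0))``, is
    reported; the CI rule remains the decision criterion.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels01 = np.asarray(labels).astype(bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels01.shape:
        raise ValueError("scores and labels must be aligned on the same subjects")
    rng = np.random.default_rng(seed)
    n = len(labels01)
    diffs = np.empty(B)
    got = 0
    redrawn = 0
    skipped = 0
    for _ in range(B):
        idx, r = _resample(rng, n, labels01)
        redrawn += r
        if idx is None:
            skipped += 1
            continue
        ra = _fast_auc(scores_a[idx], labels01[idx]) / n_items_a
        rb = _fast_auc(scores_b[idx], labels01[idx]) / n_items_b
        diffs[got] = ra - rb
        got += 1
    if skipped:
        warnings.warn(f"{skipped} degenerate bootstrap iterations skipped", stacklevel=2)
    diffs = diffs[:got]
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    point = (
        _fast_auc(scores_a, labels01) / n_items_a
        - _fast_auc(scores_b, labels01) / n_items_b
    )
    frac_below = float(np.mean(diffs < 0) + 0.5 * np.mean(diffs == 0))
    p_boot = float(min(1.0, 2 * min(frac_below, 1 - frac_below)))
    return BootstrapComparison(
        diff=float(point),
        ci=(float(lo), float(hi)),
        significant=bool(lo > 0 or hi < 0),
        p_boot=p_boot,
        iterations=got,
        n_redrawn=redrawn,
        n_skipped=skipped,
    )


def cross_set_z(eff_dev: float, se_dev: float, eff_val: float, se_val: float):
    """z-test for an efficiency difference between independent samples:
    ``z = (eff_dev - eff_val) / sqrt(se_dev^2 + se_val^2)``."""
    denom = np.sqrt(se_dev**2 + se_val**2)
    if denom == 0:
        if eff_dev == eff_val:
            return 0.0, 1.0
        raise ValueError("both bootstrap standard errors are zero")
    z = (eff_dev - eff_val) / denom
    return float(z), float(2 * norm.sf(abs(z)))
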