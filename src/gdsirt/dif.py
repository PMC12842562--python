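"""Differential item functioning (Mantel–Haenszel) and differential test
functioning (subgroup AUC).

Items are audited one at a time: subjects are stratified on the scale's
total score (including the studied item — the classical MH-DIF matcher),
per-stratum 2x2 tables of group x endorsement are pooled into the MH common
odds ratio, and the effect size is expressed on the ETS delta scale,
``delta_MH = -2.35 ln(alpha_MH)``, binned into the ETS A/B/C categories.
Scale-level impact is summarized by per-group AUCs (DTF).

Note: MH on a 2PL (non-Rasch) scale can flag artifactual DIF when the two
groups differ strongly in latent-trait distribution, because the total score
is then not a sufficient matcher; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .banks import ScaleDefinition
from .irt import _item_column, _subset_matrix
from .reduction import sum_score
from .roc import RocResult, auc

__all__ = ["DIFResult", "DTFResult", "mh_dif", "ets_classify", "dtf_auc", "dif_table"]

#: ETS delta-scale constant converting an MH log odds ratio to the delta metric.
ETS_DELTA_CONSTANT = 2.35


@dataclass
class DIFResult:
    item: int
    group_var: str
    groups: tuple[str, str]
    alpha_mh: float
    chi2: float
    p: float
    delta_mh: float
    category: str
    direction: str
    n_strata: int

    @property
    def abs_delta_mh(self) -> float:
        return abs(self.delta_mh)


@dataclass
class DTFResult:
    group_var: str
    groups: tuple[str, str]
    roc_1: RocResult
    roc_2: RocResult | None
    delta_auc: float | None


def ets_classify(abs_delta_mh: float, p: float) -> str:
    """ETS A/B/C effect-size category for an MH delta.

    A (negligible) if |delta| < 1.0 or the MH test is non-significant;
    B (moderate) if 1.0 <= |delta| < 1.5 with p < 0.05;
    C (large) if |delta| >= 1.5 with p < 0.05.
    """
    if abs_delta_mh < 0:
        raise ValueError("abs_delta_mh must be non-negative")
    if abs_delta_mh < 1.0 or p >= 0.05:
        return "A"
    if abs_delta_mh < 1.5:
        return "B"
    return "C"


def _merge_sparse_strata(stratum_ids: np.ndarray, min_size: int) -> np.ndarray:
    """Merge strata with fewer than ``min_size`` subjects into the nearest
    (by matching-score value) neighbouring stratum."""
    levels = np.sort(np.unique(stratum_ids))
    merged = {lv: lv for lv in levels}
    changed = True
    while changed:
        changed = False
        mapped = np.array([merged[s] for s in stratum_ids])
        counts = pd.Series(mapped).value_counts()
        current = np.sort(counts.index.to_numpy())
        if len(current) <= 1:
            break
        for lv in current:
            if counts[lv] < min_size:
                others = current[current != lv]
                nearest = others[np.argmin(np.abs(others - lv))]
                for key, val in list(merged.items()):
                    if val == lv:
                        merged[key] = nearest
                changed = True
                break
    return np.array([merged[s] for s in stratum_ids])


def mh_dif(
    responses,
    item: int,
    group,
    matching_score=None,
    scale: ScaleDefinition | None = None,
    group_var: str = "group",
    min_stratum: int = 5,
) -> DIFResult:
    """Mantel–Haenszel DIF test for one item between two groups.

    ``matching_score`` defaults to the total score on ``scale`` (including
    the studied item).  The common odds ratio applies a 0.5 continuity
    correction only to strata containing a zero cell; the MH chi-square uses
    the standard continuity correction.  ``alpha_mh > 1`` means the first
    group (alphabetically) endorses the item more readily at matched score.
    """
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    g1, g2 = str(levels[0]), str(levels[1])

    if isinstance(responses, pd.DataFrame):
        endorsed = responses[_item_column(item)].to_numpy(dtype=float)
    else:
        x = np.asarray(responses, dtype=float)
        endorsed = x[:, item - 1]
    if matching_score is None:
        if scale is None:
            raise ValueError("provide matching_score or a scale definition")
        matching_score = sum_score(responses, scale)
    matching_score = np.asarray(matching_score, dtype=float)

    strata = _merge_sparse_strata(matching_score, min_stratum)
    num_or = den_or = 0.0
    sum_a = sum_e = sum_v = 0.0
    n_used = 0
    for s in np.unique(strata):
        mask = strata == s
        in_g1 = group[mask] == levels[0]
        yes = endorsed[mask] == 1
        a = float(np.sum(in_g1 & yes))
        b = float(np.sum(in_g1 & ~yes))
        c = float(np.sum(~in_g1 & yes))
        d = float(np.sum(~in_g1 & ~yes))
        nt = a + b + c + d
        if nt < 2:
            continue
        row1, row2 = a + b, c + d
        col1, col2 = a + c, b + d
        if row1 > 0 and row2 > 0 and col1 > 0 and col2 > 0:
            sum_a += a
            sum_e += row1 * col1 / nt
            sum_v += row1 * row2 * col1 * col2 / (nt * nt * (nt - 1))
            n_used += 1
        # odds-ratio sums: continuity-correct only zero-cell strata
        if 0 in (a, b, c, d):
            a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            nt_ = nt + 2.0
        else:
            a_, b_, c_, d_, nt_ = a, b, c, d, nt
        num_or += a_ * d_ / nt_
        den_or += b_ * c_ / nt_

    if sum_v == 0 or den_or == 0 or num_or == 0:
        raise ValueError("all strata degenerate; MH odds ratio undefined")
    alpha_mh = num_or / den_or
    stat = (abs(sum_a - sum_e) - 0.5) ** 2 / sum_v
    p = float(chi2.sf(stat, df=1))
    delta = -ETS_DELTA_CONSTANT * np.log(alpha_mh)
    category = ets_classify(abs(delta), p)
    direction = g1 if alpha_mh > 1 else (g2 if alpha_mh < 1 else "none")
    return DIFResult(
        item=int(item),
        group_var=group_var,
        groups=(g1, g2),
        alpha_mh=float(alpha_mh),
        chi2=float(stat),
        p=p,
        delta_mh=float(delta),
        category=category,
        direction=direction,
        n_strata=n_used,
    )


def dtf_auc(scores, labels, group, group_var: str = "group") -> DTFResult:
    """Per-group AUC comparison (differential test functioning).

    A group lacking one diagnosis class gets a missing AUC and the difference
    is reported as missing.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    rocs = []
    for lv in levels:
        mask = group == lv
        try:
            rocs.append(auc(scores[mask], labels[mask]))
        except ValueError:
            rocs.append(None)
    delta = None
    if rocs[0] is not None and rocs[1] is not None:
        delta = rocs[0].auc - rocs[1].auc
    return DTFResult(
        group_var=group_var,
        groups=(str(levels[0]), str(levels[1])),
        roc_1=rocs[0],
        roc_2=rocs[1],
        delta_auc=delta,
    )


def dif_table(
    responses,
    scale: ScaleDefinition,
    groupings: dict[str, np.ndarray],
    labels=None,
    min_stratum: int = 5,
) -> pd.DataFrame:
    """Audit every item of a scale against each grouping variable.

    Returns one row per item x grouping with the signed MH delta, its
    magnitude, p-value, ETS category and favoured direction; when diagnosis
    ``labels`` are given a DTF block (per-group AUC) is appended with
    ``item = 0`` rows.
    """
    score = sum_score(responses, scale)
    rows = []
    for gname, gvals in groupings.items():
        for item in scale.items:
            try:
                r = mh_dif(
                    responses,
                    item,
                    gvals,
                    matching_score=score,
                    group_var=gname,
                    min_stratum=min_stratum,
                )
            except ValueError:
                continue
            rows.append(
                {
                    "item": item,
                    "group_var": gname,
                    "delta_mh": r.delta_mh,
                    "abs_delta_mh": r.abs_delta_mh,
                    "p": r.p,
                    "category": r.category,
                    "direction": r.direction,
                }
            )
        if labels is not None:
            d = dtf_auc(score, labels, gvals, group_var=gname)
            rows.append(
                {
                    "item": 0,
                    "group_var": gname,
                    "auc_group1": None if d.roc_1 is None else d.roc_1.auc,
                    "auc_group2": None if d.roc_2 is None else d.roc_2.auc,
                    "delta_auc": d.delta_auc,
                }
            )
    return pd.DataFrame(rows)
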