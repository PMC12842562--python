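"""Discrimination-ordered sequential scale reduction with equivalence testing.

The procedure: rank items by fitted 2PL discrimination, then for each k (from
the full pool down to ``k_min``) score the top-k scale as a unit-weighted
integer sum in both the development and validation cohorts, compare its AUC
against the full scale with the paired DeLong test within each cohort, and
compare dev-vs-val AUCs with the independent-samples Hanley–McNeil z.  The
selected minimum k* is the smallest k passing the stopping rule whose
predecessor (k*-1) fails it; the expected-test-information column additionally
supports an elbow diagnostic on marginal information gains.

Scale scores are deliberately unit-weighted sums, not latent-trait estimates:
the IRT model selects items, while scoring stays the integer count clinicians
actually use (cutoffs like "positive if >= 4 of 10").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .banks import ItemBank, ScaleDefinition
from .irt import LatentGrid, _subset_matrix, expected_test_information
from .roc import auc, delong_paired, hanley_mcneil_independent

__all__ = [
    "sum_score",
    "SequentialReduction",
    "ReductionResults",
    "select_minimum",
    "elbow_detection",
]


def sum_score(responses, scale: ScaleDefinition, return_missing: bool = False):
    """Unit-weighted integer sum over a scale's items.

    Missing responses are skipped (available-item sum); set
    ``return_missing=True`` to also receive a per-subject flag marking rows
    with at least one missing scale item.
    """
    x = _subset_matrix(responses, scale)
    missing = np.isnan(x)
    scores = np.nansum(x, axis=1)
    if return_missing:
        return scores, missing.any(axis=1)
    return scores


def select_minimum(trace: pd.DataFrame, alpha: float = 0.05, rule: str = "dual"):
    """Smallest k satisfying the stopping rule whose predecessor fails it.

    ``rule="dual"`` requires DeLong non-significance versus the full scale in
    *both* development and validation sets; ``rule="dev_only"`` uses the
    development set alone.  If no evaluated k passes, the full scale is
    returned with ``no_reduction=True``.
    """
    if len(trace) == 0:
        raise ValueError("empty reduction trace")
    if rule not in ("dual", "dev_only"):
        raise ValueError("rule must be 'dual' or 'dev_only'")
    t = trace.sort_values("k").reset_index(drop=True)
    if rule == "dual":
        passes = (t["p_dev"] > alpha) & (t["p_val"] > alpha)
    else:
        passes = t["p_dev"] > alpha
    ks = t["k"].to_numpy()
    ok = passes.to_numpy()
    for i, k in enumerate(ks):
        if not ok[i]:
            continue
        prev_evaluated = i > 0 and ks[i - 1] == k - 1
        if not prev_evaluated or not ok[i - 1]:
            return int(k), False
    return int(ks[-1]), True


def elbow_detection(trace: pd.DataFrame, tol: float = 1e-9):
    """k at which the marginal information gain drops the most.

    With I(k) the expected test information of the top-k scale and
    ``delta_k = I(k) - I(k-1)``, the elbow is the k maximizing
    ``delta_k - delta_{k+1}``.  Returns ``None`` (with a warning) when fewer
    than three consecutive k are available or all second differences vanish.
    """
    t = trace.sort_values("k").reset_index(drop=True)
    ks = t["k"].to_numpy()
    info = t["test_information"].to_numpy(dtype=float)
    consec = np.flatnonzero(np.diff(ks) != 1)
    if len(consec) or len(ks) < 3:
        if len(ks) < 3:
            warnings.warn("elbow undefined: fewer than 3 consecutive steps", stacklevel=2)
            return None
    delta = np.diff(info)  # delta[i] = I(k_{i+1}) - I(k_i), gain of step to k_{i+1}
    drop = delta[:-1] - delta[1:]  # indexed by the middle k
    if np.all(np.abs(drop) < tol):
        warnings.warn("no elbow: marginal gains are constant", stacklevel=2)
        return None
    return int(ks[1:-1][int(np.argmax(drop))])


@dataclass
class ReductionResults:
    """Trace plus the selected scale and elbow diagnostic."""

    trace: pd.DataFrame
    k_selected: int
    no_reduction: bool
    elbow: int | None
    ranking: np.ndarray
    alpha: float
    rule: str

    @property
    def selected_items(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.sort(self.ranking[: self.k_selected]))

    @property
    def selected_scale(self) -> ScaleDefinition:
        return ScaleDefinition(f"TOP{self.k_selected}", self.selected_items)

    def to_tsv(self, path) -> None:
        self.trace.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        head = (
            "Sequential discrimination-ordered reduction "
            f"(rule={self.rule}, alpha={self.alpha})\n"
            f"  selected k* = {self.k_selected}"
            + ("  [no reduction possible]" if self.no_reduction else "")
            + f"   elbow = {self.elbow}\n"
            f"  selected items: {list(self.selected_items)}\n"
        )
        cols = [
            "k", "auc_dev", "delta_dev", "p_dev",
            "auc_val", "delta_val", "p_val", "cross_delta", "cross_p",
            "test_information",
        ]
        with pd.option_context("display.float_format", "{:0.4f}".format):
            return head + self.trace[cols].to_string(index=False)


class SequentialReduction:
    """Backward reduction model over a fixed discrimination ranking.

    Parameters
    ----------
    dev, val : Cohort or (responses, diagnosis) pairs
        Development and validation samples; the ranking must come from a fit
        on the development sample only.
    ranking : sequence of int
        Item ids in descending discrimination order (from
        ``TwoPLResults.rank_items``).
    item_bank : ItemBank
        Fitted bank used for the information column.
    k_min : int
        Smallest evaluated scale length (>= 2).
    """

    def __init__(
        self,
        dev,
        val,
        ranking,
        item_bank: ItemBank,
        k_min: int = 4,
        alpha: float = 0.05,
        rule: str = "dual",
        grid: LatentGrid | None = None,
    ):
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if k_min < 2:
            raise ValueError("k_min must be at least 2")
        self.dev_responses, self.dev_diagnosis = _unpack(dev)
        self.val_responses, self.val_diagnosis = _unpack(val)
        self.ranking = np.asarray(ranking, dtype=int)
        if len(set(self.ranking.tolist())) != len(self.ranking):
            raise ValueError("ranking contains duplicate item ids")
        self.item_bank = item_bank
        self.k_min = int(k_min)
        self.alpha = float(alpha)
        self.rule = rule
        self.grid = grid or LatentGrid.standard_normal()

    def fit(self) -> ReductionResults:
        full = ScaleDefinition("FULL", tuple(int(i) for i in np.sort(self.ranking)))
        dev_full = sum_score(self.dev_responses, full)
        val_full = sum_score(self.val_responses, full)

        rows = []
        for k in range(len(self.ranking), self.k_min - 1, -1):
            scale = ScaleDefinition(
                f"TOP{k}", tuple(int(i) for i in np.sort(self.ranking[:k]))
            )
            dev_k = sum_score(self.dev_responses, scale)
            val_k = sum_score(self.val_responses, scale)
            roc_dev = auc(dev_k, self.dev_diagnosis)
            roc_val = auc(val_k, self.val_diagnosis)
            cmp_dev = delong_paired(dev_k, dev_full, self.dev_diagnosis)
            cmp_val = delong_paired(val_k, val_full, self.val_diagnosis)
            z_cross, p_cross = hanley_mcneil_independent(
                roc_dev.auc, roc_dev.se, roc_val.auc, roc_val.se
            )
            rows.append(
                {
                    "k": k,
                    "items": ",".join(str(i) for i in scale.items),
                    "auc_dev": roc_dev.auc,
                    "ci_dev_low": roc_dev.ci[0],
                    "ci_dev_high": roc_dev.ci[1],
                    "delta_dev": cmp_dev.delta_auc,
                    "p_dev": cmp_dev.p,
                    "auc_val": roc_val.auc,
                    "ci_val_low": roc_val.ci[0],
                    "ci_val_high": roc_val.ci[1],
                    "delta_val": cmp_val.delta_auc,
                    "p_val": cmp_val.p,
                    "cross_delta": roc_dev.auc - roc_val.auc,
                    "cross_z": z_cross,
                    "cross_p": p_cross,
                    "test_information": expected_test_information(
                        self.item_bank, scale, self.grid
                    ),
                }
            )
        trace = pd.DataFrame(rows)
        k_star, no_reduction = select_minimum(trace, self.alpha, self.rule)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            elbow = elbow_detection(trace)
        return ReductionResults(
            trace=trace,
            k_selected=k_star,
            no_reduction=no_reduction,
            elbow=elbow,
            ranking=self.ranking,
            alpha=self.alpha,
            rule=self.rule,
        )


def _unpack(cohort_or_pair):
    if hasattr(cohort_or_pair, "responses"):
        return cohort_or_pair.responses, cohort_or_pair.diagnosis
    responses, diagnosis = cohort_or_pair
    return responses, np.asarray(diagnosis, dtype=int)
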