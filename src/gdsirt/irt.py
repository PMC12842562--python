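"""Two-parameter logistic (2PL) IRT calibration by marginal maximum likelihood.

The model: a subject with latent severity ``theta`` endorses item *j* with
probability ``P_j(theta) = 1 / (1 + exp(-a_j (theta - b_j)))``.  ``a_j`` is the
item's discrimination and ``b_j`` the severity at which endorsement probability
is exactly 50%.  Calibration integrates the latent trait out against a standard
normal prior on a fixed quadrature grid (Bock–Aitkin EM): the E-step computes
each subject's posterior over the grid, the M-step refits each item's logistic
curve to the expected endorsement counts.

:class:`TwoPLModel` follows the statsmodels convention — construct from data,
call :meth:`~TwoPLModel.fit`, receive a :class:`TwoPLResults` carrying the
fitted :class:`~gdsirt.banks.ItemBank`, standard errors, the log-likelihood
path and convergence diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .banks import ItemBank, ScaleDefinition

__all__ = [
    "LatentGrid",
    "icc",
    "item_information",
    "expected_test_information",
    "rank_items",
    "item_auc",
    "cronbach_alpha",
    "TwoPLModel",
    "TwoPLResults",
]


@dataclass(frozen=True)
class LatentGrid:
    """Quadrature nodes and normalized standard-normal weights for theta."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if np.any(weights <= 0):
            raise ValueError("quadrature weights must be positive")
        weights = weights / weights.sum()
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def standard_normal(cls, n_nodes: int = 61, span: float = 6.0) -> "LatentGrid":
        """Equally spaced nodes on [-span, span] with N(0,1) density weights."""
        nodes = np.linspace(-span, span, n_nodes)
        return cls(nodes, norm.pdf(nodes))


def icc(theta, a, b):
    """2PL item characteristic curve: P(endorse | theta).

    Strictly increasing in ``theta``; equals 0.5 at ``theta == b``.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("discrimination a must be > 0")
    return expit(a * (np.asarray(theta, dtype=float) - np.asarray(b, dtype=float)))


def item_information(theta, a, b):
    """Fisher information of one 2PL item at ``theta``: ``a^2 P (1 - P)``.

    Non-negative, unimodal with its maximum ``a^2/4`` at ``theta == b``.
    """
    p = icc(theta, a, b)
    return np.asarray(a, dtype=float) ** 2 * p * (1.0 - p)


def expected_test_information(
    bank: ItemBank,
    subset: ScaleDefinition | None = None,
    grid: LatentGrid | None = None,
) -> float:
    """Test information of an item subset averaged over the latent prior.

    Sums item informations (additive across items) and integrates against the
    grid's standard-normal weights, giving a single scalar per scale that the
    reduction trace uses for elbow detection.
    """
    if grid is None:
        grid = LatentGrid.standard_normal()
    sub = bank if subset is None else bank.subset(list(subset.items))
    if len(sub) == 0:
        raise ValueError("subset must contain at least one item")
    info = item_information(
        grid.nodes[None, :], sub.a[:, None], sub.b[:, None]
    )  # (J, Q)
    return float(info.sum(axis=0) @ grid.weights)


def rank_items(bank: ItemBank) -> np.ndarray:
    """Item ids sorted by descending discrimination.

    Ties are broken by descending per-item AUC (when the bank carries one),
    then by ascending item index.
    """
    auc_key = bank.item_auc if bank.item_auc is not None else np.zeros(len(bank))
    # lexsort: last key is primary
    order = np.lexsort((bank.items, -auc_key, -bank.a))
    return bank.items[order]


def item_auc(responses, diagnosis) -> float:
    """Mann–Whitney AUC of a single binary item against the diagnosis.

    For a binary predictor this equals (sensitivity + specificity) / 2.
    """
    from .roc import auc  # local import to avoid a cycle

    return auc(np.asarray(responses, dtype=float), diagnosis).auc


def cronbach_alpha(responses, subset: ScaleDefinition | None = None) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    ``alpha = k/(k-1) * (1 - sum(item variances) / var(total score))`` with
    sample (ddof=1) variances.  ``responses`` is a subjects x items array or
    DataFrame with columns ``item_XX`` when ``subset`` is given.
    """
    x = _subset_matrix(responses, subset)
    if x.shape[1] < 2:
        raise ValueError("Cronbach's alpha requires at least 2 items")
    item_var = x.var(axis=0, ddof=1)
    if np.any(item_var == 0):
        raise ValueError("every item must have non-zero variance")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    k = x.shape[1]
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def _item_column(item_id: int) -> str:
    return f"item_{item_id:02d}"


def _subset_matrix(responses, subset: ScaleDefinition | None) -> np.ndarray:
    if isinstance(responses, pd.DataFrame):
        if subset is not None:
            cols = [_item_column(i) for i in subset.items]
            missing = [c for c in cols if c not in responses.columns]
            if missing:
                raise KeyError(f"response matrix lacks columns {missing}")
            responses = responses[cols]
        return responses.to_numpy(dtype=float)
    x = np.asarray(responses, dtype=float)
    if subset is not None:
        x = x[:, [i - 1 for i in subset.items]]
    return x


# ---------------------------------------------------------------------------
# Marginal maximum likelihood fitting
# ---------------------------------------------------------------------------


class TwoPLModel:
    """2PL IRT model for a subjects x items binary response matrix.

    Parameters
    ----------
    responses : DataFrame or (n, J) array
        Entries in {0, 1}; NaN marks a missing response (ignored in the
        likelihood under a missing-at-random assumption).  DataFrame columns
        are taken as item identifiers (``item_07`` -> 7).
    item_ids : sequence of int, optional
        1-based identifiers when ``responses`` is a bare array.
    """

    def __init__(self, responses, item_ids=None):
        if isinstance(responses, pd.DataFrame):
            if item_ids is None:
                item_ids = [
                    int(c.split("_")[-1]) if str(c).startswith("item_") else k + 1
                    for k, c in enumerate(responses.columns)
                ]
            x = responses.to_numpy(dtype=float)
        else:
            x = np.asarray(responses, dtype=float)
        if x.ndim != 2 or x.shape[1] < 2:
            raise ValueError("responses must be 2-D with at least 2 items")
        obs = ~np.isnan(x)
        vals = x[obs]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("responses must be binary (0/1, NaN for missing)")
        # drop subjects with no observed responses at all
        keep = obs.any(axis=1)
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} all-missing subject rows",
                stacklevel=2,
            )
            x, obs = x[keep], obs[keep]
        self.endog = x
        self.obs_mask = obs
        self.item_ids = (
            np.arange(1, x.shape[1] + 1)
            if item_ids is None
            else np.asarray(item_ids, dtype=int)
        )
        self.nobs = x.shape[0]

    def fit(
        self,
        grid: LatentGrid | None = None,
        tol: float = 1e-4,
        max_iter: int = 500,
        a_bounds: tuple[float, float] = (0.05, 6.0),
        b_bound: float = 8.0,
    ) -> "TwoPLResults":
        """Bock–Aitkin EM until max parameter change < ``tol``.

        Items endorsed by all or no subjects are excluded with a warning
        (their parameters are not identified).  Estimates are clipped to
        ``a_bounds`` / ``|b| <= b_bound``; hitting a bound raises a warning.
        """
        if grid is None:
            grid = LatentGrid.standard_normal()
        x, obs = self.endog, self.obs_mask
        rate = np.nansum(x, axis=0) / obs.sum(axis=0)
        degenerate = (rate == 0.0) | (rate == 1.0)
        item_ids = self.item_ids
        if degenerate.any():
            bad = item_ids[degenerate]
            warnings.warn(
                f"excluding items with constant responses: {bad.tolist()}",
                stacklevel=2,
            )
            x, obs = x[:, ~degenerate], obs[:, ~degenerate]
            item_ids = item_ids[~degenerate]
            rate = rate[~degenerate]

        theta, w = grid.nodes, grid.weights
        logw = np.log(w)
        xf = np.where(obs, x, 0.0)
        of = obs.astype(float)

        # slope-intercept parameterization z = c + d*theta (a = d, b = -c/d)
        d = np.ones(len(item_ids))
        c = np.log(np.clip(rate, 0.01, 0.99) / (1 - np.clip(rate, 0.01, 0.99)))

        ll_path: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            z = c[:, None] + d[:, None] * theta[None, :]  # (J, Q)
            p = expit(z)
            logp = np.log(np.clip(p, 1e-300, None))
            log1mp = np.log(np.clip(1.0 - p, 1e-300, None))
            loglik_iq = xf @ logp + (of - xf) @ log1mp  # (n, Q)
            aw = loglik_iq + logw
            m = logsumexp(aw, axis=1)
            ll_path.append(float(m.sum()))
            post = np.exp(aw - m[:, None])  # (n, Q) posterior weights

            n_jq = of.T @ post
            r_jq = xf.T @ post

            c_new, d_new = _mstep_newton(c.copy(), d.copy(), n_jq, r_jq, theta)
            a_new = d_new
            b_new = -c_new / d_new
            delta = max(
                np.max(np.abs(a_new - d)), np.max(np.abs(b_new - (-c / d)))
            )
            c, d = c_new, d_new
            if delta < tol:
                converged = True
                break

        a_hat = d.copy()
        b_hat = -c / d
        hit = (a_hat < a_bounds[0]) | (a_hat > a_bounds[1]) | (np.abs(b_hat) > b_bound)
        if hit.any():
            warnings.warn(
                f"parameter bounds hit for items {item_ids[hit].tolist()}",
                stacklevel=2,
            )
        a_hat = np.clip(a_hat, a_bounds[0], a_bounds[1])
        b_hat = np.clip(b_hat, -b_bound, b_bound)

        se_a, se_b = _approximate_se(a_hat, b_hat, n_jq, r_jq, theta)
        bank = ItemBank(
            items=item_ids,
            a=a_hat,
            b=b_hat,
            se_a=se_a,
            se_b=se_b,
            meta={
                "n_iter": n_iter,
                "converged": converged,
                "loglike": ll_path[-1],
                "bound_hit": item_ids[hit].tolist(),
            },
        )
        return TwoPLResults(self, bank, grid, np.asarray(ll_path), converged, n_iter)


def _mstep_newton(c, d, n_jq, r_jq, theta, max_steps=50, gtol=1e-10):
    """Per-item Newton maximization of the expected complete-data likelihood.

    Vectorized across items; updates are damped to +/-1.0 per step for
    stability on quasi-Guttman items.
    """
    for _ in range(max_steps):
        z = c[:, None] + d[:, None] * theta[None, :]
        p = expit(z)
        resid = r_jq - n_jq * p
        wgt = n_jq * p * (1.0 - p)
        g0 = resid.sum(axis=1)
        g1 = (resid * theta).sum(axis=1)
        h00 = wgt.sum(axis=1)
        h01 = (wgt * theta).sum(axis=1)
        h11 = (wgt * theta**2).sum(axis=1)
        det = np.maximum(h00 * h11 - h01**2, 1e-12)
        dc = np.clip((h11 * g0 - h01 * g1) / det, -1.0, 1.0)
        dd = np.clip((h00 * g1 - h01 * g0) / det, -1.0, 1.0)
        c += dc
        d += dd
        d = np.maximum(d, 1e-3)  # keep slope positive during iteration
        if max(np.max(np.abs(g0)), np.max(np.abs(g1))) < gtol:
            break
    return c, d


def _approximate_se(a, b, n_jq, r_jq, theta):
    """Delta-method SEs from the expected-counts information (per item).

    These condition on the final posterior weights, so they understate the
    full-marginal uncertainty slightly; adequate for ranking diagnostics.
    """
    c = -a * b
    z = c[:, None] + a[:, None] * theta[None, :]
    p = expit(z)
    wgt = n_jq * p * (1 - p)
    i00 = wgt.sum(axis=1)
    i01 = (wgt * theta).sum(axis=1)
    i11 = (wgt * theta**2).sum(axis=1)
    det = np.maximum(i00 * i11 - i01**2, 1e-12)
    v_cc = i11 / det
    v_cd = -i01 / det
    v_dd = i00 / det
    # a = d; b = -c/d -> grad_b = (-1/d, c/d^2)
    se_a = np.sqrt(np.maximum(v_dd, 0))
    gb_c = -1.0 / a
    gb_d = c / a**2
    var_b = gb_c**2 * v_cc + 2 * gb_c * gb_d * v_cd + gb_d**2 * v_dd
    se_b = np.sqrt(np.maximum(var_b, 0))
    return se_a, se_b


class TwoPLResults:
    """Fitted 2PL calibration: item bank, diagnostics, information functions."""

    def __init__(self, model, item_bank, grid, loglike_path, converged, n_iter):
        self.model = model
        self.item_bank: ItemBank = item_bank
        self.grid = grid
        self.loglike_path = loglike_path
        self.converged = converged
        self.n_iter = n_iter

    @property
    def params(self) -> pd.DataFrame:
        return self.item_bank.to_frame().set_index("item_id")

    @property
    def loglike(self) -> float:
        return float(self.loglike_path[-1])

    def attach_item_aucs(self, diagnosis) -> None:
        """Compute per-item AUCs against a diagnosis label (used as ranking
        tie-break) and store them on the bank."""
        x = self.model.endog
        ids = self.item_bank.items
        col = {it: k for k, it in enumerate(self.model.item_ids)}
        aucs = np.array(
            [item_auc(x[:, col[i]], diagnosis) for i in ids], dtype=float
        )
        self.item_bank.item_auc = aucs

    def rank_items(self) -> np.ndarray:
        return rank_items(self.item_bank)

    def test_information(self, theta, subset: ScaleDefinition | None = None):
        sub = (
            self.item_bank
            if subset is None
            else self.item_bank.subset(list(subset.items))
        )
        theta = np.asarray(theta, dtype=float)
        return item_information(theta[..., None], sub.a, sub.b).sum(axis=-1)

    def expected_test_information(self, subset: ScaleDefinition | None = None):
        return expected_test_information(self.item_bank, subset, self.grid)

    def summary(self) -> str:
        head = (
            "2PL marginal maximum likelihood (EM)\n"
            f"  subjects: {self.model.nobs}   items: {len(self.item_bank)}\n"
            f"  log-likelihood: {self.loglike:.2f}   EM cycles: {self.n_iter}"
            f"   converged: {self.converged}\n"
        )
        frame = self.params.copy()
        with pd.option_context("display.float_format", "{:0.3f}".format):
            return head + frame.to_string()
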