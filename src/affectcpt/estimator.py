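"""Maximum-likelihood CPT estimation as a scikit-learn style estimator.

``CPTChoiceModel`` fits cumulative prospect theory with a softmax/guessing
choice rule to one participant's binary choices in one domain.  Fitting
follows a two-stage scheme: a coarse grid search over the parameter space
identifies the 20 best-fitting combinations (by the deviance G^2), and each
is refined with Nelder-Mead simplex runs in a transformed space that
enforces the parameter bounds smoothly.

Trials are encoded as rows of a design matrix ``X`` with columns
``(outcome_a, prob_a, outcome_b, prob_b)`` — the loss branch of each
two-branch option — and a binary target ``y`` (1 = option A chosen).
Multi-branch prospects are supported through the record-level API in
:mod:`affectcpt.fitting`, which falls back to a generic (slower) valuation
path.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cpt import _CLIP, BOUNDS, ChoiceRule, CPTParams, softmax_choice_prob, valuation
from .lotteries import Lottery

__all__ = ["CPTChoiceModel", "DEFAULT_GRID", "chance_g2"]

# Default grid: covers the stated bounds with log-ish spacing for the
# elevation and sensitivity parameters.
DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "alpha": tuple(np.round(np.arange(0.1, 1.01, 0.1), 10)),
    "gamma": tuple(np.round(np.arange(0.1, 1.01, 0.1), 10)),
    "delta": (0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 10.0),
    "g": (0.02, 0.1, 0.3, 0.6, 0.9),
    "phi": (0.05, 0.2, 1.0, 5.0),
}

PROB_FLOOR = 1e-12


def chance_g2(n_trials: int) -> float:
    """Deviance of pure guessing: ``-2 * n * ln(1/2)`` (116.45 for n=84)."""
    return -2.0 * n_trials * math.log(0.5)


# ---------------------------------------------------------------------------
# trial data: valuation paths
# ---------------------------------------------------------------------------


class TrialData:
    """Per-trial choice data with a vectorized valuation path.

    Either ``X`` (two-branch loss arrays) or ``pairs`` (generic Lottery
    pairs) must be given.  Two-branch data vectorizes valuations across both
    trials and grid points; generic prospects are evaluated per trial.
    """

    def __init__(
        self,
        y: Sequence[int],
        X: Optional[np.ndarray] = None,
        pairs: Optional[Sequence[tuple[Lottery, Lottery]]] = None,
    ):
        self.y = np.asarray(y, dtype=bool)
        if (X is None) == (pairs is None):
            raise ValueError("provide exactly one of X or pairs")
        if X is not None:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != 4:
                raise ValueError("X must have columns (outcome_a, prob_a, outcome_b, prob_b)")
            if len(X) != len(self.y):
                raise ValueError("X and y length mismatch")
            if np.any(X[:, [0, 2]] > 0):
                raise ValueError("outcomes must be <= 0 (loss domain)")
            if np.any((X[:, [1, 3]] < 0) | (X[:, [1, 3]] > 1)):
                raise ValueError("probabilities must lie in [0, 1]")
            self.X = X
            self.pairs = None
            # the design reuses a handful of magnitudes and probabilities, so
            # value/weight transforms are evaluated on the unique values only
            self._x_unique, x_inv = np.unique(X[:, [0, 2]], return_inverse=True)
            self._xa_inv, self._xb_inv = x_inv.reshape(len(X), 2).T
            self._p_unique, p_inv = np.unique(X[:, [1, 3]], return_inverse=True)
            self._pa_inv, self._pb_inv = p_inv.reshape(len(X), 2).T
            # likelihood terms repeat when the same (problem, choice) pattern
            # recurs (two presentations, repeated designs): collapse to
            # weighted unique rows for the deviance computations
            patterns = np.column_stack([X, self.y])
            uniq, inv = np.unique(patterns, axis=0, return_inverse=True)
            self._c_w = np.bincount(inv).astype(float)
            self._c_y = uniq[:, 4].astype(bool)
            self._c_xa = np.searchsorted(self._x_unique, uniq[:, 0])
            self._c_xb = np.searchsorted(self._x_unique, uniq[:, 2])
            self._c_pa = np.searchsorted(self._p_unique, uniq[:, 1])
            self._c_pb = np.searchsorted(self._p_unique, uniq[:, 3])
        else:
            self.X = None
            self.pairs = list(pairs)
            if len(self.pairs) != len(self.y):
                raise ValueError("pairs and y length mismatch")

    def __len__(self) -> int:
        return len(self.y)

    def valuations_grid(
        self, alpha: np.ndarray, gamma: np.ndarray, delta: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """V(A), V(B) for each (alpha, gamma, delta) combo; shape (c, t)."""
        a = np.asarray(alpha, dtype=float)[:, None]
        gm = np.asarray(gamma, dtype=float)[:, None]
        d = np.asarray(delta, dtype=float)[:, None]
        if self.X is not None:
            v_u = -np.power(-self._x_unique[None, :], a)  # (c, n_unique_x)
            num = d * np.power(self._p_unique[None, :], gm)
            w_u = np.where(
                self._p_unique[None, :] == 0.0,
                0.0,
                num / (num + np.power(1.0 - self._p_unique[None, :], gm)),
            )
            va = v_u[:, self._xa_inv] * w_u[:, self._pa_inv]
            vb = v_u[:, self._xb_inv] * w_u[:, self._pb_inv]
            return va, vb
        va = np.empty((len(a), len(self)))
        vb = np.empty_like(va)
        for c in range(len(a)):
            params = CPTParams(alpha=float(a[c, 0]), gamma=float(gm[c, 0]), delta=float(d[c, 0]), g=1.0)
            for t, (lot_a, lot_b) in enumerate(self.pairs):
                va[c, t] = valuation(lot_a, params)
                vb[c, t] = valuation(lot_b, params)
        return va, vb

    def valuations(self, alpha: float, gamma: float, delta: float) -> tuple[np.ndarray, np.ndarray]:
        va, vb = self.valuations_grid([alpha], [gamma], [delta])
        return va[0], vb[0]

    def valuations_compressed(
        self, alpha: np.ndarray, gamma: np.ndarray, delta: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(V(A), V(B), y, weight) over unique weighted likelihood rows."""
        if self.X is None:
            va, vb = self.valuations_grid(alpha, gamma, delta)
            return va, vb, self.y, np.ones(len(self.y))
        a = np.asarray(alpha, dtype=float)[:, None]
        gm = np.asarray(gamma, dtype=float)[:, None]
        d = np.asarray(delta, dtype=float)[:, None]
        v_u = -np.power(-self._x_unique[None, :], a)
        num = d * np.power(self._p_unique[None, :], gm)
        w_u = num / (num + np.power(1.0 - self._p_unique[None, :], gm))
        va = v_u[:, self._c_xa] * w_u[:, self._c_pa]
        vb = v_u[:, self._c_xb] * w_u[:, self._c_pb]
        return va, vb, self._c_y, self._c_w


def _two_branch_value(x, p, alpha, gamma, delta):
    # V = v(x) * w(p): with branches (0 @ 1-p, x @ p) the loss is the worst
    # outcome, so its rank-dependent weight is w(p) and v(0)=0 drops out.
    num = delta * np.power(p, gamma)
    w = np.where(p == 0.0, 0.0, num / (num + np.power(1.0 - p, gamma)))
    return -np.power(-x, alpha) * w


def observed_choice_probs(
    va: np.ndarray, vb: np.ndarray, y: np.ndarray, g: float, phi: float
) -> np.ndarray:
    """Predicted probability of the observed choice per trial (last axis)."""
    p_a = softmax_choice_prob(va, vb, g=g, phi=phi)
    return np.where(y, p_a, 1.0 - p_a)


def g2_from_probs(p_obs: np.ndarray, floor: float = PROB_FLOOR) -> np.ndarray:
    """Deviance ``-2 * sum(ln p)`` along the last axis, with probability floor."""
    return -2.0 * np.sum(np.log(np.clip(p_obs, floor, 1.0)), axis=-1)


# ---------------------------------------------------------------------------
# grid search and simplex refinement over TrialData
# ---------------------------------------------------------------------------


def grid_g2(
    data: TrialData, rule: ChoiceRule, grid: dict[str, Sequence[float]]
) -> tuple[list[dict[str, float]], np.ndarray]:
    """G^2 at every grid point, in deterministic product order.

    Returns the list of parameter dicts (product order over the rule's free
    parameters, core CPT parameters outermost) and the matching G^2 array.
    """
    names = ChoiceRule(rule).free_params
    axes = [tuple(float(v) for v in grid[n]) for n in names]
    core_axes, tail_axes = axes[:3], axes[3:]
    core = list(itertools.product(*core_axes))
    tail = list(itertools.product(*tail_axes))
    alpha, gamma, delta = (np.array([c[i] for c in core]) for i in range(3))
    va, vb, y, w = data.valuations_compressed(alpha, gamma, delta)
    g2s = np.empty((len(core), len(tail)))
    for j, tail_vals in enumerate(tail):
        kw = dict(zip(names[3:], tail_vals))
        g = kw.get("g", 0.0)
        phi = kw.get("phi", 1.0)
        p_obs = observed_choice_probs(va, vb, y, g, phi)
        g2s[:, j] = -2.0 * (np.log(np.clip(p_obs, PROB_FLOOR, 1.0)) @ w)
    combos = [
        dict(zip(names, core_vals + tail_vals))
        for core_vals in core
        for tail_vals in tail
    ]
    return combos, g2s.reshape(-1)


def top_grid_points(
    data: TrialData,
    rule: ChoiceRule,
    grid: Optional[dict[str, Sequence[float]]] = None,
    n_top: int = 20,
) -> list[tuple[dict[str, float], float]]:
    """The ``n_top`` best grid points by ascending G^2 (ties: first-found).

    A grid with fewer than ``n_top`` points returns all of them, with a
    warning.
    """
    grid = dict(DEFAULT_GRID, **(grid or {}))
    combos, g2s = grid_g2(data, rule, grid)
    if len(combos) < n_top:
        warnings.warn(f"grid holds only {len(combos)} points (< {n_top}); using all")
    order = np.argsort(g2s, kind="stable")[:n_top]
    return [(combos[i], float(g2s[i])) for i in order]


def _to_unconstrained(params: dict[str, float]) -> np.ndarray:
    """Map parameters onto R via a scaled logit over each bound interval."""
    z = []
    for name, x in params.items():
        lo, hi = BOUNDS[name]
        frac = np.clip((x - lo) / (hi - lo), 1e-9, 1.0 - 1e-9)
        z.append(logit(frac))
    return np.array(z)


def _from_unconstrained(z: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    out = {}
    for name, zi in zip(names, z):
        lo, hi = BOUNDS[name]
        out[name] = float(lo + (hi - lo) * expit(zi))
    return out


def _objective(data: TrialData, rule: ChoiceRule, names: Sequence[str]):
    lo = np.array([BOUNDS[n][0] for n in names])
    span = np.array([BOUNDS[n][1] - BOUNDS[n][0] for n in names])
    idx = {n: i for i, n in enumerate(names)}
    i_g, i_phi = idx.get("g"), idx.get("phi")

    if data.X is not None:
        xu, pu = -data._x_unique, data._p_unique
        xa, xb = data._c_xa, data._c_xb
        pa, pb = data._c_pa, data._c_pb
        y, w = data._c_y, data._c_w
        one_m_pu = 1.0 - pu

        def f(z: np.ndarray) -> float:
            x = lo + span * expit(z)
            g = x[i_g] if i_g is not None else 0.0
            phi = x[i_phi] if i_phi is not None else 1.0
            v_u = -np.power(xu, x[0])
            num = x[2] * np.power(pu, x[1])
            w_u = num / (num + np.power(one_m_pu, x[1]))
            d = np.clip(phi * (v_u[xa] * w_u[pa] - v_u[xb] * w_u[pb]), -_CLIP, _CLIP)
            p_a = (1.0 - g) * expit(d) + g / 2.0
            p_obs = np.where(y, p_a, 1.0 - p_a)
            return float(-2.0 * np.dot(np.log(np.maximum(p_obs, PROB_FLOOR)), w))

        return f

    def f(z: np.ndarray) -> float:
        p = _from_unconstrained(z, names)
        va, vb = data.valuations(p["alpha"], p["gamma"], p["delta"])
        g2 = g2_from_probs(
            observed_choice_probs(va, vb, data.y, p.get("g", 0.0), p.get("phi", 1.0))
        )
        return float(g2)

    return f


def refine_start(
    data: TrialData,
    rule: ChoiceRule,
    start: dict[str, float],
    max_iter: int = 2000,
    fatol: float = 1e-8,
    xatol: float = 1e-6,
) -> tuple[dict[str, float], float, bool]:
    """Nelder-Mead refinement from one start; returns (params, g2, converged).

    The simplex runs in the scaled-logit space so every iterate respects the
    parameter bounds; the result never has a worse G^2 than the start.
    """
    names = ChoiceRule(rule).free_params
    obj = _objective(data, rule, names)
    z0 = _to_unconstrained({n: start[n] for n in names})
    res = minimize(
        obj,
        z0,
        method="Nelder-Mead",
        options={"maxiter": max_iter, "fatol": fatol, "xatol": xatol},
    )
    cand = [(z0, obj(z0)), (res.x, float(res.fun))]
    z_best, g2_best = min(cand, key=lambda c: c[1])
    return _from_unconstrained(z_best, names), g2_best, bool(res.success)


class CPTChoiceModel(BaseEstimator):
    """Cumulative prospect theory choice model for loss lotteries.

    Fits the CPT parameters (outcome sensitivity ``alpha``, probability
    sensitivity ``gamma``, weighting elevation ``delta``) together with the
    choice-rule parameters (guessing probability ``g`` and/or choice
    sensitivity ``phi``) to binary choices by minimizing the deviance
    G^2 = -2 log L, via grid search followed by simplex refinement.

    Parameters
    ----------
    rule : {"guess_only", "sensitivity_only", "both"}
        Choice-rule variant.  The guessing rule mixes a softmax of the raw
        valuations with uniform random choice; the sensitivity variants
        scale the valuation difference by ``phi``.
    grid : dict, optional
        Overrides for the default grid axes (name -> sequence of values).
    n_starts : int
        Number of best grid points carried into simplex refinement.
    max_iter, fatol, xatol : simplex stopping controls per start.

    Attributes
    ----------
    params_ : CPTParams — best-fitting parameter set.
    alpha_, gamma_, delta_, g_, phi_ : individual fitted values.
    g2_ : float — deviance of the best fit.
    bic_ : float — ``g2_ + k ln(n_trials_)`` with k free parameters.
    per_trial_prob_ : ndarray — predicted probability of each observed choice.
    grid_best_g2_ : float — best deviance found on the grid alone.
    start_points_used_ : int, converged_ : bool, n_trials_ : int.

    Examples
    --------
    >>> model = CPTChoiceModel(rule="guess_only")
    >>> model.fit(X, y).gamma_  # doctest: +SKIP
    """

    def __init__(
        self,
        rule: str = "guess_only",
        grid: Optional[dict] = None,
        n_starts: int = 20,
        max_iter: int = 2000,
        fatol: float = 1e-8,
        xatol: float = 1e-6,
    ):
        self.rule = rule
        self.grid = grid
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.fatol = fatol
        self.xatol = xatol

    # -- core fit on TrialData (shared with the record-level API) ----------

    def _fit_data(self, data: TrialData) -> "CPTChoiceModel":
        if len(data) == 0:
            raise ValueError("cannot fit an empty choice set")
        rule = ChoiceRule(self.rule)
        names = rule.free_params
        starts = top_grid_points(data, rule, self.grid, self.n_starts)
        candidates: list[tuple[dict[str, float], float, bool]] = []
        for start, _ in starts:
            candidates.append(
                refine_start(
                    data, rule, start,
                    max_iter=self.max_iter, fatol=self.fatol, xatol=self.xatol,
                )
            )
        if "g" in names:
            # Pure guessing (g = 1) is the closed endpoint of its interval,
            # which the logit transform only reaches asymptotically; evaluate
            # it explicitly so the fit can never be worse than chance.
            chance = dict(candidates[0][0])
            chance["g"] = 1.0
            candidates.append((chance, chance_g2(len(data)), True))
        best_i = min(range(len(candidates)), key=lambda i: candidates[i][1])
        best_params, best_g2, converged = candidates[best_i]

        self.rule_ = rule
        self.n_trials_ = len(data)
        self.start_points_used_ = len(starts)
        self.grid_best_g2_ = float(starts[0][1])
        self.alpha_ = best_params["alpha"]
        self.gamma_ = best_params["gamma"]
        self.delta_ = best_params["delta"]
        self.g_ = best_params.get("g")
        self.phi_ = best_params.get("phi")
        self.params_ = CPTParams(
            alpha=self.alpha_,
            gamma=self.gamma_,
            delta=self.delta_,
            g=self.g_ if self.g_ is not None else 1e-6,
            phi=self.phi_,
        )
        self.g2_ = float(best_g2)
        self.converged_ = converged
        k = len(names)
        self.bic_ = self.g2_ + k * math.log(self.n_trials_)
        self.n_free_params_ = k
        va, vb = data.valuations(self.alpha_, self.gamma_, self.delta_)
        self.per_trial_prob_ = observed_choice_probs(
            va, vb, data.y, self.g_ or 0.0, self.phi_ or 1.0
        )
        self.classes_ = np.array([0, 1])
        return self

    def fit(self, X, y) -> "CPTChoiceModel":
        """Fit to a two-branch design matrix.

        X : array-like (n_trials, 4) — columns (outcome_a, prob_a,
            outcome_b, prob_b), outcomes <= 0.  A pandas DataFrame with
            those columns is accepted.
        y : array-like (n_trials,) — 1 where option A was chosen.
        """
        X, y = _coerce_Xy(X, y)
        return self._fit_data(TrialData(y, X=X))

    def predict_proba(self, X) -> np.ndarray:
        """Probability of choosing each option, columns (B, A)."""
        check_is_fitted(self, "params_")
        X = _coerce_X(X)
        data = TrialData(np.zeros(len(X), dtype=bool), X=X)
        va, vb = data.valuations(self.alpha_, self.gamma_, self.delta_)
        p_a = softmax_choice_prob(va, vb, g=self.g_ or 0.0, phi=self.phi_ or 1.0)
        p_a = np.atleast_1d(p_a)
        return np.column_stack([1.0 - p_a, p_a])

    def predict(self, X) -> np.ndarray:
        """Most probable option per trial (1 = A)."""
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y) -> float:
        """Mean predicted probability of the observed choices."""
        X, y = _coerce_Xy(X, y)
        p = self.predict_proba(X)[:, 1]
        return float(np.mean(np.where(np.asarray(y, dtype=bool), p, 1 - p)))


_X_COLUMNS = ["outcome_a", "prob_a", "outcome_b", "prob_b"]


def _coerce_X(X) -> np.ndarray:
    if hasattr(X, "loc") and hasattr(X, "columns"):
        X = X[_X_COLUMNS].to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("X must be (n_trials, 4): outcome_a, prob_a, outcome_b, prob_b")
    return X


def _coerce_Xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = _coerce_X(X)
    y = np.asarray(y)
    if y.shape != (len(X),):
        raise ValueError("y must be one binary label per trial")
    if not np.isin(y, [0, 1, False, True]).all():
        raise ValueError("y must be binary (1 = option A chosen)")
    return X, y.astype(bool)
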