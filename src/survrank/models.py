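"""Three right-censored survival learners behind one contract.

Every fitted model exposes

* ``predict_risk(X)``  — one finite scalar per subject, higher = worse
  prognosis (earlier expected event);
* ``predict_survival(X)`` — one right-continuous survival StepFunction per
  subject.

The learners:

* **Cox proportional hazards** — Newton–Raphson maximisation of the Breslow
  partial log-likelihood (covariates standardised internally, coefficients
  reported on the original scale), Breslow baseline cumulative hazard.
* **Random survival forest** — bagged binary survival trees. Each node
  maximises the two-sample log-rank statistic over `mtry` randomly chosen
  features and all admissible midpoint thresholds; leaves store Nelson–Aalen
  cumulative hazards on the training event-time grid; the ensemble cumulative
  hazard is the pointwise tree mean and the risk score its sum over the grid.
* **DeepSurv-style network** — a feed-forward net whose single linear output
  estimates the log-risk; trained by full-batch gradient descent (with
  backtracking, so the recorded loss trajectory is non-increasing) on the
  negative Cox partial log-likelihood of the output scores.

Ties are handled Breslow-style throughout. Determinism: all stochastic
choices flow from the ``seed`` argument; tied split statistics break to the
lowest feature index, then the lowest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical_io import SurvivalTable
from .metrics import StepFunction, nelson_aalen

__all__ = [
    "CoxModel",
    "RandomSurvivalForestModel",
    "DeepSurvModel",
    "ConvergenceError",
    "fit_cox",
    "fit_rsf",
    "fit_deepsurv",
    "fit_model",
    "predict_risk",
    "predict_survival",
    "logrank_split_statistic",
    "cox_partial_loglik",
    "DEFAULT_RSF_PARAMS",
    "DEFAULT_DEEPSURV_PARAMS",
]

# Pinned defaults (the learners' reference configurations; all overridable).
DEFAULT_RSF_PARAMS = dict(n_trees=100, mtry=None, min_leaf=3, max_depth=None,
                          bootstrap=True)
DEFAULT_DEEPSURV_PARAMS = dict(hidden_sizes=(32,), learning_rate=0.1,
                               epochs=512, l2=1e-4)


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


def _as_matrix(X, feature_names: list[str]) -> np.ndarray:
    """Validate a prediction input against the training feature layout."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in feature_names if f not in X.columns]
        extra = [c for c in X.columns if c not in feature_names]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing {missing}, unexpected {extra}"
            )
        return X[feature_names].to_numpy(dtype=float)
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[None, :]
    if Xv.shape[1] != len(feature_names):
        raise ValueError(
            f"expected {len(feature_names)} features, got {Xv.shape[1]}"
        )
    return Xv


# ==========================================================================
# Cox proportional hazards
# ==========================================================================

def _breslow_quantities(Xs, time, event, beta, ridge=0.0, want_hessian=True):
    """Breslow partial log-likelihood, gradient and Hessian at ``beta``.

    Subjects sorted ascending in time; the risk set of an event at t is every
    subject with observed time >= t (ties share one risk set).
    """
    n, p = Xs.shape
    order = np.argsort(time, kind="mergesort")
    t, e, X = time[order], event[order], Xs[order]
    eta = X @ beta
    eta_max = eta.max()
    w = np.exp(eta - eta_max)
    # reverse-cumulative sums: S0[j] = sum_{i >= j} w_i, similarly S1, S2
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    first = np.searchsorted(t, t, side="left")  # risk set start per subject
    ev = e == 1
    n_ev = int(ev.sum())
    if n_ev == 0:
        raise ValueError("at least one observed event is required")
    f_ev = first[ev]
    s0_ev = s0[f_ev]
    loglik = float(np.sum(eta[ev] - (np.log(s0_ev) + eta_max)))
    grad = X[ev].sum(axis=0) - (s1[f_ev] / s0_ev[:, None]).sum(axis=0)
    hess = None
    if want_hessian:
        s2 = np.cumsum(np.einsum("ij,ik->ijk", w[:, None] * X, X)[::-1],
                       axis=0)[::-1]
        mu = s1[f_ev] / s0_ev[:, None]
        hess = -(s2[f_ev] / s0_ev[:, None, None]).sum(axis=0) \
            + np.einsum("ij,ik->jk", mu, mu)
    if ridge > 0.0:
        loglik -= 0.5 * ridge * float(beta @ beta)
        grad = grad - ridge * beta
        if want_hessian:
            hess = hess - ridge * np.eye(p)
    return loglik, grad, hess


def cox_partial_loglik(X, time, event, beta) -> float:
    """Breslow partial log-likelihood at an arbitrary coefficient vector."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    ll, _, _ = _breslow_quantities(
        X, np.asarray(time, float), np.asarray(event, int), beta,
        want_hessian=False,
    )
    return ll


def _breslow_baseline(X, time, event, beta) -> StepFunction:
    """Breslow estimate of the baseline cumulative hazard H0 (at x = 0)."""
    order = np.argsort(time, kind="mergesort")
    t, e = time[order], event[order]
    w = np.exp(X[order] @ beta)
    s0 = np.cumsum(w[::-1])[::-1]
    uniq, idx = np.unique(t, return_index=True)
    d = np.add.reduceat(e, idx)
    mask = d > 0
    h0 = np.cumsum(d[mask] / s0[idx][mask])
    return StepFunction(uniq[mask], h0, 0.0)


@dataclass
class CoxModel:
    kind = "cox"
    beta: np.ndarray
    baseline_chf: StepFunction
    feature_names: list[str]
    n_iter: int
    converged: bool
    loglik: float
    trace: list[float] = field(default_factory=list)

    def predict_risk(self, X) -> np.ndarray:
        return _as_matrix(X, self.feature_names) @ self.beta

    def predict_survival(self, X) -> list[StepFunction]:
        lp = self.predict_risk(X)
        grid = self.baseline_chf.times
        h0 = self.baseline_chf.values
        return [
            StepFunction(grid, np.exp(-h0 * np.exp(z)), 1.0) for z in lp
        ]

    def to_dict(self) -> dict:
        return {
            "kind": "cox",
            "beta": dict(zip(self.feature_names, self.beta.tolist())),
            "baseline_times": self.baseline_chf.times.tolist(),
            "baseline_chf": self.baseline_chf.values.tolist(),
        }


def fit_cox(table: SurvivalTable, ridge: float = 0.0, tol: float = 1e-8,
            max_iter: int = 100) -> CoxModel:
    """Newton–Raphson fit of the Cox model (Breslow ties, Breslow baseline).

    Covariates are standardised internally and the coefficients mapped back.
    Convergence requires the gradient max-norm (standardised scale) to fall
    below ``tol``; runaway coefficients raise with advice to use ``ridge``.
    """
    Xv = table.X.to_numpy(dtype=float)
    time, event = table.time, table.event
    if event.sum() == 0:
        raise ValueError("cannot fit a Cox model without observed events")
    mean = Xv.mean(axis=0)
    scale = Xv.std(axis=0)
    scale[scale == 0.0] = 1.0
    Xs = (Xv - mean) / scale

    p = Xs.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _breslow_quantities(Xs, time, event, beta, ridge)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        alpha = 1.0
        for _ in range(40):  # step-halving keeps the likelihood ascending
            cand = beta - alpha * step
            ll_new, grad_new, hess_new = _breslow_quantities(
                Xs, time, event, cand, ridge
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        else:
            raise ConvergenceError(
                "Cox Newton-Raphson: no ascent direction found", trace
            )
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        trace.append(ll)
        if np.max(np.abs(beta)) > 50.0:
            raise ConvergenceError(
                "coefficients diverging (likely complete separation); "
                "refit with ridge > 0", trace
            )
    else:
        if np.max(np.abs(grad)) >= tol:
            raise ConvergenceError(
                f"Cox Newton-Raphson did not converge in {max_iter} "
                f"iterations (|grad| = {np.max(np.abs(grad)):.3g})", trace
            )
        converged = True

    beta_orig = beta / scale
    baseline = _breslow_baseline(Xv, time, event, beta_orig)
    return CoxModel(
        beta=beta_orig,
        baseline_chf=baseline,
        feature_names=table.feature_names,
        n_iter=it,
        converged=converged,
        loglik=ll,
        trace=trace,
    )


# ==========================================================================
# Log-rank splitting and the random survival forest
# ==========================================================================

def logrank_split_statistic(time, event, group) -> float:
    """Squared standardised two-sample log-rank statistic (O - E)^2 / V.

    Larger values mean greater survival separation between the two groups;
    defined as 0 when there are no events or no variance. Symmetric in the
    group labels.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group).astype(bool)
    if group.all() or (~group).all():
        raise ValueError("both groups must be non-empty")
    uniq = np.unique(time[event == 1])
    if uniq.size == 0:
        return 0.0
    at_risk = time[:, None] >= uniq[None, :]
    death = (time[:, None] == uniq[None, :]) & (event[:, None] == 1)
    n_k = at_risk.sum(axis=0).astype(float)
    d_k = death.sum(axis=0).astype(float)
    n1_k = (at_risk & group[:, None]).sum(axis=0).astype(float)
    d1_k = (death & group[:, None]).sum(axis=0).astype(float)
    O = d1_k.sum()
    E = float(np.sum(d_k * n1_k / n_k))
    with np.errstate(divide="ignore", invalid="ignore"):
        var_k = np.where(
            n_k > 1,
            d_k * (n1_k / n_k) * (1.0 - n1_k / n_k) * (n_k - d_k) / (n_k - 1.0),
            0.0,
        )
    V = float(var_k.sum())
    if V <= 0.0:
        return 0.0
    return float((O - E) ** 2 / V)


def _best_threshold(x, time, event, min_leaf):
    """Best midpoint threshold for one feature by the log-rank criterion.

    Evaluates every admissible split (both daughters >= min_leaf, boundary
    values distinct) in one vectorised pass; returns (statistic, threshold)
    or None. Ties in the statistic resolve to the lowest threshold.
    """
    m = x.size
    order = np.argsort(x, kind="mergesort")
    xs, ts, es = x[order], time[order], event[order]
    ev_times = np.unique(ts[es == 1])
    if ev_times.size == 0:
        return None
    at_risk = ts[:, None] >= ev_times[None, :]
    death = (ts[:, None] == ev_times[None, :]) & (es[:, None] == 1)
    n1 = np.cumsum(at_risk, axis=0).astype(float)   # row s-1: left group size s
    d1 = np.cumsum(death, axis=0).astype(float)
    n_k = at_risk.sum(axis=0).astype(float)
    d_k = death.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(
            n_k > 1, d_k * (n_k - d_k) / (n_k - 1.0), 0.0
        )
    frac = n1 / n_k
    O = d1.sum(axis=1)
    E = (frac * d_k).sum(axis=1)
    V = (factor * frac * (1.0 - frac)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(V > 0.0, (O - E) ** 2 / V, 0.0)

    sizes = np.arange(1, m)                # left-group sizes for split rows 0..m-2
    valid = (sizes >= min_leaf) & (m - sizes >= min_leaf) & (xs[:-1] < xs[1:])
    if not valid.any():
        return None
    stat_v = stat[:-1][valid]
    best = int(np.argmax(stat_v))          # first max = lowest threshold
    if stat_v[best] <= 0.0:
        return None
    pos = np.nonzero(valid)[0][best]
    threshold = 0.5 * (xs[pos] + xs[pos + 1])
    return float(stat_v[best]), threshold


class _SurvivalTree:
    """Binary survival tree; leaves hold Nelson–Aalen CHFs on a shared grid."""

    __slots__ = ("feature", "threshold", "left", "right", "chf")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.chf: list = []

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.chf.append(None)
        return len(self.feature) - 1

    def finalize(self, grid_size: int):
        self.feature = np.asarray(self.feature, dtype=np.int64)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.left = np.asarray(self.left, dtype=np.int64)
        self.right = np.asarray(self.right, dtype=np.int64)
        chf = np.zeros((len(self.chf), grid_size))
        for i, row in enumerate(self.chf):
            if row is not None:
                chf[i] = row
        self.chf = chf

    def leaf_chf(self, Xv: np.ndarray) -> np.ndarray:
        cur = np.zeros(Xv.shape[0], dtype=np.int64)
        while True:
            feat = self.feature[cur]
            internal = feat >= 0
            if not internal.any():
                break
            idx = np.nonzero(internal)[0]
            nodes = cur[idx]
            go_left = Xv[idx, feat[internal]] <= self.threshold[nodes]
            cur[idx] = np.where(go_left, self.left[nodes], self.right[nodes])
        return self.chf[cur]

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "leaf_chf": self.chf.tolist(),
        }


def _grow_tree(Xv, time, event, grid, mtry, min_leaf, max_depth, bootstrap, rng):
    n, p = Xv.shape
    tree = _SurvivalTree()
    if bootstrap:
        sample = rng.integers(0, n, size=n)
    else:
        sample = np.arange(n)
    root = tree._new_node()
    stack = [(root, sample, 0)]
    while stack:
        node, idx, depth = stack.pop()
        t, e = time[idx], event[idx]
        can_split = (
            idx.size >= 2 * min_leaf
            and e.sum() > 0
            and (max_depth is None or depth < max_depth)
        )
        split = None
        if can_split:
            feats = np.sort(rng.choice(p, size=min(mtry, p), replace=False))
            best_stat = 0.0
            for f in feats:  # ascending order: ties break to lowest index
                res = _best_threshold(Xv[idx, f], t, e, min_leaf)
                if res is not None and res[0] > best_stat:
                    best_stat, split = res[0], (int(f), res[1])
        if split is None:
            na = nelson_aalen(t, e) if e.sum() > 0 else None
            tree.chf[node] = na(grid) if na is not None else np.zeros(grid.size)
            continue
        f, thr = split
        go_left = Xv[idx, f] <= thr
        left = tree._new_node()
        right = tree._new_node()
        tree.feature[node] = f
        tree.threshold[node] = thr
        tree.left[node] = left
        tree.right[node] = right
        stack.append((right, idx[~go_left], depth + 1))
        stack.append((left, idx[go_left], depth + 1))
    tree.finalize(grid.size)
    return tree


@dataclass
class RandomSurvivalForestModel:
    kind = "rsf"
    trees: list
    event_grid: np.ndarray
    feature_names: list[str]
    params: dict

    def predict_chf(self, X) -> np.ndarray:
        """Ensemble cumulative hazard: pointwise mean over trees (n x grid)."""
        Xv = _as_matrix(X, self.feature_names)
        total = np.zeros((Xv.shape[0], self.event_grid.size))
        for tree in self.trees:
            total += tree.leaf_chf(Xv)
        return total / len(self.trees)

    def predict_risk(self, X) -> np.ndarray:
        """Ensemble CHF summed over the training event-time grid."""
        return self.predict_chf(X).sum(axis=1)

    def predict_survival(self, X) -> list[StepFunction]:
        chf = self.predict_chf(X)
        return [StepFunction(self.event_grid, np.exp(-row), 1.0) for row in chf]

    def to_dict(self) -> dict:
        return {
            "kind": "rsf",
            "params": {k: v for k, v in self.params.items()},
            "event_grid": self.event_grid.tolist(),
            "trees": [t.to_dict() for t in self.trees],
        }


def fit_rsf(table: SurvivalTable, n_trees: int = 100, mtry: int | None = None,
            min_leaf: int = 3, max_depth: int | None = None,
            bootstrap: bool = True, seed: int = 0) -> RandomSurvivalForestModel:
    """Grow a random survival forest with log-rank splitting.

    ``mtry`` defaults to ceil(sqrt(p)). Each tree is grown on a bootstrap
    sample (switchable off); leaf cumulative hazards are Nelson–Aalen
    estimates evaluated on the grid of distinct training event times.
    """
    if n_trees < 1 or min_leaf < 1:
        raise ValueError("n_trees and min_leaf must be positive")
    if max_depth is not None and max_depth < 1:
        raise ValueError("max_depth must be positive or None")
    Xv = table.X.to_numpy(dtype=float)
    p = Xv.shape[1]
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must be in [1, {p}]")
    grid = np.unique(table.time[table.event == 1])
    if grid.size == 0:
        raise ValueError("cannot grow survival trees without observed events")
    seeds = np.random.SeedSequence(seed).spawn(n_trees)
    trees = [
        _grow_tree(Xv, table.time, table.event, grid, mtry, min_leaf,
                   max_depth, bootstrap, np.random.default_rng(s))
        for s in seeds
    ]
    return RandomSurvivalForestModel(
        trees=trees,
        event_grid=grid,
        feature_names=table.feature_names,
        params=dict(n_trees=n_trees, mtry=mtry, min_leaf=min_leaf,
                    max_depth=max_depth, bootstrap=bootstrap, seed=seed),
    )


# ==========================================================================
# DeepSurv-style network
# ==========================================================================

def _cox_score_loss_grad(scores, time, event):
    """Negative Breslow partial log-likelihood of raw scores and its gradient.

    Normalised by the number of events so the learning rate is size-free.
    """
    order = np.argsort(time, kind="mergesort")
    t, e, s = time[order], event[order], scores[order]
    n_ev = int(e.sum())
    if n_ev == 0:
        raise ValueError("no events in training data")
    smax = s.max()
    w = np.exp(s - smax)
    s0 = np.cumsum(w[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    ev = e == 1
    loss = -float(np.sum(s[ev] - (np.log(s0[first[ev]]) + smax))) / n_ev
    add = np.zeros(t.size)
    np.add.at(add, first[ev], 1.0 / s0[first[ev]])
    c = np.cumsum(add)
    grad_sorted = -(e - w * c) / n_ev
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return loss, grad


@dataclass
class DeepSurvModel:
    kind = "deepsurv"
    weights: list
    biases: list
    mean_: np.ndarray
    scale_: np.ndarray
    baseline_chf: StepFunction
    feature_names: list[str]
    loss_trajectory: list[float]
    params: dict

    def _forward(self, Xs: np.ndarray) -> np.ndarray:
        h = Xs
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return (h @ self.weights[-1] + self.biases[-1]).ravel()

    def predict_risk(self, X) -> np.ndarray:
        Xv = _as_matrix(X, self.feature_names)
        return self._forward((Xv - self.mean_) / self.scale_)

    def predict_survival(self, X) -> list[StepFunction]:
        scores = self.predict_risk(X)
        grid = self.baseline_chf.times
        h0 = self.baseline_chf.values
        return [StepFunction(grid, np.exp(-h0 * np.exp(z)), 1.0)
                for z in scores]


def fit_deepsurv(table: SurvivalTable, hidden_sizes=(32,),
                 learning_rate: float = 0.1, epochs: int = 512,
                 l2: float = 1e-4, seed: int = 0) -> DeepSurvModel:
    """Train the log-risk network by full-batch gradient descent.

    The loss is the event-normalised negative Cox partial log-likelihood of
    the network output plus an L2 penalty on the weights. A backtracking rule
    (halve the step when the loss would increase) keeps the recorded loss
    trajectory non-increasing and the fit deterministic given ``seed``.
    ``hidden_sizes=()`` degenerates to a linear Cox-type score trained by
    gradient descent.
    """
    Xv = table.X.to_numpy(dtype=float)
    time, event = table.time, table.event
    mean = Xv.mean(axis=0)
    scale = Xv.std(axis=0)
    scale[scale == 0.0] = 1.0
    Xs = (Xv - mean) / scale
    n, p = Xs.shape

    rng = np.random.default_rng(seed)
    sizes = [p, *hidden_sizes, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))

    def forward(Ws, bs):
        acts = [Xs]
        h = Xs
        for W, b in zip(Ws[:-1], bs[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        scores = (h @ Ws[-1] + bs[-1]).ravel()
        return scores, acts

    def total_loss(Ws, bs):
        scores, _ = forward(Ws, bs)
        loss, _ = _cox_score_loss_grad(scores, time, event)
        return loss + 0.5 * l2 * sum(float(np.sum(W * W)) for W in Ws)

    def gradients(Ws, bs):
        scores, acts = forward(Ws, bs)
        loss, dscores = _cox_score_loss_grad(scores, time, event)
        loss += 0.5 * l2 * sum(float(np.sum(W * W)) for W in Ws)
        gWs = [None] * len(Ws)
        gbs = [None] * len(bs)
        delta = dscores[:, None]
        for layer in range(len(Ws) - 1, -1, -1):
            gWs[layer] = acts[layer].T @ delta + l2 * Ws[layer]
            gbs[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ Ws[layer].T) * (acts[layer] > 0.0)
        return loss, gWs, gbs

    loss, gWs, gbs = gradients(weights, biases)
    if not np.isfinite(loss):
        raise ConvergenceError("non-finite loss at initialisation", [loss])
    trajectory = [loss]
    lr = float(learning_rate)
    for _ in range(epochs):
        accepted = False
        for _ in range(30):
            cand_W = [W - lr * g for W, g in zip(weights, gWs)]
            cand_b = [b - lr * g for b, g in zip(biases, gbs)]
            cand_loss = total_loss(cand_W, cand_b)
            if np.isfinite(cand_loss) and cand_loss <= loss + 1e-12:
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            break  # no descent possible at any step size: converged
        weights, biases = cand_W, cand_b
        loss, gWs, gbs = gradients(weights, biases)
        trajectory.append(loss)
        if not np.isfinite(loss):
            raise ConvergenceError("training loss diverged", trajectory)

    model = DeepSurvModel(
        weights=weights,
        biases=biases,
        mean_=mean,
        scale_=scale,
        baseline_chf=StepFunction([1.0], [0.0], 0.0),  # placeholder
        feature_names=table.feature_names,
        loss_trajectory=trajectory,
        params=dict(hidden_sizes=tuple(hidden_sizes),
                    learning_rate=learning_rate, epochs=epochs, l2=l2,
                    seed=seed),
    )
    # Breslow baseline at score 0, using the trained scores as offsets
    scores = model._forward(Xs)
    order = np.argsort(time, kind="mergesort")
    t, e = time[order], event[order]
    w = np.exp(scores[order] - scores.max())
    s0 = np.cumsum(w[::-1])[::-1]
    uniq, idx = np.unique(t, return_index=True)
    d = np.add.reduceat(e, idx)
    mask = d > 0
    h0 = np.cumsum(d[mask] / s0[idx][mask]) * np.exp(-scores.max())
    model.baseline_chf = StepFunction(uniq[mask], h0, 0.0)
    return model


# ==========================================================================
# Shared contract helpers
# ==========================================================================

MODEL_KINDS = ("cox", "rsf", "deepsurv")


def fit_model(table: SurvivalTable, kind: str, params: dict | None = None,
              seed: int = 0):
    """Fit any of the three learners by name with optional hyperparameters."""
    params = dict(params or {})
    if kind == "cox":
        return fit_cox(table, **params)
    if kind == "rsf":
        merged = {**DEFAULT_RSF_PARAMS, **params}
        return fit_rsf(table, seed=params.get("seed", seed),
                       **{k: v for k, v in merged.items() if k != "seed"})
    if kind == "deepsurv":
        merged = {**DEFAULT_DEEPSURV_PARAMS, **params}
        return fit_deepsurv(table, seed=params.get("seed", seed),
                            **{k: v for k, v in merged.items() if k != "seed"})
    raise ValueError(f"unknown model kind {kind!r}; valid: {MODEL_KINDS}")


def predict_risk(model, X) -> np.ndarray:
    """Scalar risk per subject; higher = worse prognosis."""
    return np.asarray(model.predict_risk(X), dtype=float)


def predict_survival(model, X) -> list[StepFunction]:
    """One survival StepFunction per subject."""
    return model.predict_survival(X)
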