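"""Neural propensity scoring with an explicit covariate-balance loss (BCAUS).

The propensity model is a one-hidden-layer neural network trained on the
joint objective

    L_total = L_bce + nu * mu * L_bias

where ``L_bce`` is the mean binary cross-entropy of treatment-arm
prediction, ``L_bias`` is the mean squared *inverse-probability-weighted*
standardized mean difference across covariates, ``nu`` is the user-facing
trade-off, and ``mu`` is a detached ratio ``L_bce / L_bias`` recomputed
each epoch so the two terms contribute at comparable magnitude. Minimizing
``L_bias`` directly pushes the induced IPTW pseudo-populations toward
covariate balance, removing the manual specification-check-respecify loop
of classical propensity modelling.

Training is full-batch Adam with analytic gradients (the balance term is
differentiable through the IPTW weights ``1/e`` and ``1/(1-e)``). The
returned model is the epoch checkpoint that balanced the most covariates,
with ties broken by the lower cross-entropy.

:class:`BcausClassifier` follows the scikit-learn estimator contract
(``fit`` / ``predict_proba`` / ``get_params``), so it drops into sklearn
model selection if desired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_X_y

__all__ = ["BcausClassifier", "compute_weights", "check_balance", "BalanceReport"]

_EPS = 1e-12


def compute_weights(propensity: np.ndarray, t: np.ndarray, clip=(0.01, 0.99)):
    """IPTW weights: 1/e for the case arm, 1/(1-e) for the comparator arm.

    Propensities are clipped to ``clip`` first to bound the weights.
    """
    lo, hi = clip
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("propensity clip must satisfy 0 < lo < hi < 1")
    e = np.clip(np.asarray(propensity, dtype=float), lo, hi)
    t = np.asarray(t)
    return np.where(t == 1, 1.0 / e, 1.0 / (1.0 - e))


def _weighted_smds(X, t, w, pooled_sd):
    """Weighted SMD per covariate; zero-variance covariates get 0."""
    t1, t0 = t == 1, t == 0
    w1, w0 = w[t1], w[t0]
    m1 = (w1[:, None] * X[t1]).sum(axis=0) / w1.sum()
    m0 = (w0[:, None] * X[t0]).sum(axis=0) / w0.sum()
    smd = np.zeros(X.shape[1])
    nz = pooled_sd > _EPS
    smd[nz] = (m1[nz] - m0[nz]) / pooled_sd[nz]
    return smd, m1, m0


def _pooled_sd(X, t):
    v1 = X[t == 1].var(axis=0, ddof=1) if (t == 1).sum() > 1 else np.zeros(X.shape[1])
    v0 = X[t == 0].var(axis=0, ddof=1) if (t == 0).sum() > 1 else np.zeros(X.shape[1])
    return np.sqrt((v1 + v0) / 2.0)


@dataclass
class BalanceReport:
    """Per-covariate weighted SMDs against a balance threshold."""

    table: pd.DataFrame  # covariate, unweighted_smd, weighted_smd, balanced
    threshold: float

    @property
    def all_balanced(self) -> bool:
        return bool(self.table.balanced.all())

    @property
    def n_balanced(self) -> int:
        return int(self.table.balanced.sum())


def check_balance(X, t, w, threshold: float = 0.1,
                  feature_names=None) -> BalanceReport:
    """Weighted standardized mean differences between arms.

    SMD_j = |weighted mean_case(X_j) - weighted mean_comp(X_j)| divided by
    the pooled *unweighted* SD of X_j; covariates with zero variance are
    reported as perfectly balanced (SMD 0).
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t)
    w = np.asarray(w, dtype=float)
    if not (len(X) == len(t) == len(w)):
        raise ValueError("X, t, w must have equal length")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sd = _pooled_sd(X, t)
    weighted, _, _ = _weighted_smds(X, t, w, sd)
    unweighted, _, _ = _weighted_smds(X, t, np.ones_like(w), sd)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j}" for j in range(X.shape[1])]
    )
    table = pd.DataFrame(
        {
            "covariate": names,
            "unweighted_smd": np.abs(unweighted),
            "weighted_smd": np.abs(weighted),
        }
    )
    table["balanced"] = table.weighted_smd < threshold
    return BalanceReport(table=table, threshold=threshold)


class BcausClassifier(BaseEstimator, ClassifierMixin):
    """Balance-regularized neural propensity model.

    Parameters
    ----------
    hidden_width : int
        Units in the single hidden layer.
    nu : float
        Weight of the balance loss; 0 reduces the model to a plain
        cross-entropy propensity classifier.
    learning_rate, max_epochs : Adam step size and epoch budget
        (full-batch).
    propensity_clip : (lo, hi)
        Propensities are clipped to this interval wherever IPTW weights
        are formed (both inside the balance loss and at prediction time).
    balance_threshold : float
        |weighted SMD| below which a covariate counts as balanced; drives
        checkpoint selection and the fitted balance report.
    min_arm_warn : int
        Arms smaller than this are flagged (``small_arm_``) but still fit;
        the evidence-network stage enforces its own node-size rule.
    random_state : int
        Seed for weight initialization.

    Attributes
    ----------
    propensities_ : clipped propensity per training snapshot
    weights_ : IPTW weight per training snapshot
    trace_ : per-epoch DataFrame (l_bce, l_bias, mu, n_balanced)
    balance_ : BalanceReport at the selected checkpoint
    best_epoch_ : index of the selected checkpoint
    """

    def __init__(
        self,
        hidden_width: int = 64,
        nu: float = 1.0,
        learning_rate: float = 0.01,
        max_epochs: int = 300,
        propensity_clip=(0.01, 0.99),
        balance_threshold: float = 0.1,
        min_arm_warn: int = 36,
        random_state: int = 0,
    ):
        self.hidden_width = hidden_width
        self.nu = nu
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.propensity_clip = propensity_clip
        self.balance_threshold = balance_threshold
        self.min_arm_warn = min_arm_warn
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _forward(self, Xs, params):
        W1, b1, W2, b2 = params
        a = Xs @ W1 + b1
        h = np.maximum(a, 0.0)
        z = h @ W2 + b2
        e = 1.0 / (1.0 + np.exp(-z))
        return a, h, z.ravel(), e.ravel()

    def fit(self, X, t):
        """Fit on a confounder matrix X and binary arm labels t (1 = case)."""
        X, t = check_X_y(X, t, dtype=float, ensure_min_samples=4)
        t = np.asarray(t)
        labels = np.unique(t)
        if not np.array_equal(labels, [0, 1]):
            raise ValueError("t must contain both arms coded 0/1")
        n1, n0 = int((t == 1).sum()), int((t == 0).sum())
        if min(n1, n0) < 2:
            raise ValueError("each arm needs at least 2 snapshots")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite covariates")
        self.classes_ = np.array([0, 1])
        self.small_arm_ = min(n1, n0) < self.min_arm_warn

        # Internal standardization; constant columns pass through untouched.
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd < _EPS, 1.0, sd)
        self.scale_mean_, self.scale_sd_ = mean, sd
        Xs = (X - mean) / sd

        n, p = Xs.shape
        lo, hi = self.propensity_clip
        rng = np.random.default_rng(self.random_state)
        W1 = rng.normal(0.0, np.sqrt(2.0 / p), size=(p, self.hidden_width))
        b1 = np.zeros(self.hidden_width)
        W2 = rng.normal(0.0, np.sqrt(2.0 / self.hidden_width), size=(self.hidden_width, 1))
        b2 = np.zeros(1)
        params = [W1, b1, W2, b2]
        m_adam = [np.zeros_like(q) for q in params]
        v_adam = [np.zeros_like(q) for q in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        pooled = _pooled_sd(Xs, t)
        t1mask, t0mask = t == 1, t == 0

        trace = []
        best = None  # (n_balanced, -l_bce, epoch, params)

        for epoch in range(self.max_epochs + 1):
            _, h, z, e_raw = self._forward(Xs, params)
            e_bce = np.clip(e_raw, _EPS, 1.0 - _EPS)
            l_bce = -np.mean(t * np.log(e_bce) + (1 - t) * np.log(1 - e_bce))

            e_w = np.clip(e_raw, lo, hi)
            w = np.where(t1mask, 1.0 / e_w, 1.0 / (1.0 - e_w))
            smd, m1, m0 = _weighted_smds(Xs, t, w, pooled)
            l_bias = float(np.mean(smd**2))
            n_balanced = int((np.abs(smd) < self.balance_threshold).sum())
            mu = l_bce / l_bias if l_bias > _EPS else 0.0

            trace.append(
                {
                    "epoch": epoch,
                    "l_bce": float(l_bce),
                    "l_bias": l_bias,
                    "mu": float(mu),
                    "n_balanced": n_balanced,
                }
            )
            cand = (n_balanced, -l_bce)
            if best is None or cand > best[0]:
                best = (cand, epoch, [q.copy() for q in params])

            if epoch == self.max_epochs:
                break

            # --- gradients -----------------------------------------------
            # BCE term: dL/dz = (e - t)/n.
            dz = (e_bce - t) / n

            # Balance term: through the weighted means and IPTW weights.
            if self.nu > 0 and mu > 0:
                g = np.zeros(p)
                nz = pooled > _EPS
                g[nz] = 2.0 * smd[nz] / (p * pooled[nz])
                W1sum = w[t1mask].sum()
                W0sum = w[t0mask].sum()
                dL_dw = np.zeros(n)
                dL_dw[t1mask] = ((Xs[t1mask] - m1) @ g) / W1sum
                dL_dw[t0mask] = -((Xs[t0mask] - m0) @ g) / W0sum
                dw_de = np.zeros(n)
                inside = (e_raw > lo) & (e_raw < hi)  # clip has zero grad outside
                dw_de[t1mask & inside] = -1.0 / e_w[t1mask & inside] ** 2
                dw_de[t0mask & inside] = 1.0 / (1.0 - e_w[t0mask & inside]) ** 2
                dbias_de = dL_dw * dw_de
                dz = dz + self.nu * mu * dbias_de * e_raw * (1.0 - e_raw)

            dz = dz[:, None]
            gW2 = h.T @ dz
            gb2 = dz.sum(axis=0)
            dh = (dz @ params[2].T) * (h > 0)
            gW1 = Xs.T @ dh
            gb1 = dh.sum(axis=0)

            grads = [gW1, gb1, gW2, gb2]
            step = epoch + 1
            for q, gq, mq, vq in zip(params, grads, m_adam, v_adam):
                mq *= beta1
                mq += (1 - beta1) * gq
                vq *= beta2
                vq += (1 - beta2) * gq**2
                mhat = mq / (1 - beta1**step)
                vhat = vq / (1 - beta2**step)
                q -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)

        self.trace_ = pd.DataFrame(trace)
        self.best_epoch_ = best[1]
        self.params_ = best[2]
        self.n_features_in_ = p

        e = self._propensity_standardized(Xs)
        self.propensities_ = e
        self.weights_ = np.where(t1mask, 1.0 / e, 1.0 / (1.0 - e))
        self.balance_ = check_balance(
            X, t, self.weights_, threshold=self.balance_threshold
        )
        return self

    def _propensity_standardized(self, Xs):
        lo, hi = self.propensity_clip
        _, _, _, e = self._forward(Xs, self.params_)
        return np.clip(e, lo, hi)

    def propensity(self, X) -> np.ndarray:
        """Clipped propensity e(x) = P(case arm | x)."""
        X = check_array(X, dtype=float)
        Xs = (X - self.scale_mean_) / self.scale_sd_
        return self._propensity_standardized(Xs)

    def predict_proba(self, X):
        e = self.propensity(X)
        return np.column_stack([1.0 - e, e])

    def predict(self, X):
        return (self.propensity(X) >= 0.5).astype(int)

    def iptw_weights(self, X, t) -> np.ndarray:
        """IPTW weights for arbitrary rows (uses the fitted clip)."""
        return compute_weights(self.propensity(X), t, clip=self.propensity_clip)
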