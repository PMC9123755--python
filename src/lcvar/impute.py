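"""Chained-equations single imputation of item-level missing values.

Missing cells are initialised with variable means and then updated by
sweeping variable-by-variable: each incomplete variable is regressed on all
other variables (pooled across occasions and participants, using the current
completed data), regression parameters are drawn from their approximate
posterior, and missing cells are re-drawn from the predictive distribution.
After a fixed number of sweeps the last draw is kept — a single imputation,
not a pooled multiple imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EmaPanel


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for the chained-equations sweep.

    n_iterations
        Number of full variable-by-variable sweeps (default 500).
    method
        'bayes' draws coefficients and noise from the posterior predictive;
        'pmm' does predictive-mean matching against the 5 nearest observed
        donors.
    clamp
        Clip imputed values to the 0-100 slider scale.
    """

    n_iterations: int = 500
    seed: int = 0
    clamp: bool = True
    method: str = "bayes"
    pmm_donors: int = 5

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.method not in ("bayes", "pmm"):
            raise ValueError(f"unknown imputation method {self.method!r}")


def impute_chained(panel: EmaPanel, config: ImputationConfig | None = None) -> EmaPanel:
    """Return a copy of the panel with every missing cell imputed.

    Observed cells are never altered; the result is deterministic under the
    config seed.  Fails if any variable is missing on every occasion, or if
    no variable is fully observed while overall missingness reaches 50%.
    """
    config = config or ImputationConfig()
    X = panel.values_matrix()
    miss = np.isnan(X)
    if not miss.any():
        return panel.copy()

    n, d = X.shape
    all_missing = miss.all(axis=0)
    if all_missing.any():
        name = panel.variable_names[int(np.flatnonzero(all_missing)[0])]
        raise ValueError(f"variable '{name}' is missing on every occasion")
    frac = miss.mean()
    if frac >= 0.5 and not (~miss).all(axis=0).any():
        raise ValueError(
            f"{frac:.0%} of cells missing and no fully observed variable; "
            "the chained equations would be anchored on imputations only"
        )

    rng = np.random.default_rng(config.seed)
    work = X.copy()
    col_means = np.nanmean(X, axis=0)
    for j in range(d):
        work[miss[:, j], j] = col_means[j]

    incomplete = [j for j in range(d) if miss[:, j].any()]
    lo, hi = (0.0, 100.0)
    for _ in range(config.n_iterations):
        for j in incomplete:
            obs = ~miss[:, j]
            mis = miss[:, j]
            others = [c for c in range(d) if c != j]
            Xo = np.column_stack([np.ones(obs.sum()), work[obs][:, others]])
            Xm = np.column_stack([np.ones(mis.sum()), work[mis][:, others]])
            y = work[obs, j]
            beta_hat, sigma2, XtX_inv = _ols_posterior(Xo, y, rng)
            if config.method == "bayes":
                try:
                    L = np.linalg.cholesky(XtX_inv * sigma2)
                    beta = beta_hat + L @ rng.standard_normal(len(beta_hat))
                except np.linalg.LinAlgError:
                    beta = beta_hat
                pred = Xm @ beta + rng.normal(0.0, np.sqrt(sigma2), size=mis.sum())
            else:  # predictive-mean matching
                pred_obs = Xo @ beta_hat
                pred_mis = Xm @ beta_hat
                pred = _pmm_draw(pred_obs, y, pred_mis, config.pmm_donors, rng)
            if config.clamp:
                pred = np.clip(pred, lo, hi)
            work[mis, j] = pred

    out = panel.copy()
    out.data.loc[:, panel.variable_names] = work
    return out


def _ols_posterior(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """OLS fit with a scaled-inverse-chi-squared noise draw (ridge-guarded)."""
    k = X.shape[1]
    G = X.T @ X + 1e-8 * np.eye(k)
    G_inv = np.linalg.inv(G)
    beta_hat = G_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    dof = max(len(y) - k, 1)
    s2 = float(resid @ resid) / dof
    sigma2 = s2 * dof / max(float(rng.chisquare(dof)), 1e-12)
    return beta_hat, sigma2, G_inv


def _pmm_draw(pred_obs, y_obs, pred_mis, donors, rng):
    out = np.empty(len(pred_mis))
    k = min(donors, len(y_obs))
    for i, p in enumerate(pred_mis):
        nearest = np.argsort(np.abs(pred_obs - p))[:k]
        out[i] = y_obs[nearest[rng.integers(k)]]
    return out
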