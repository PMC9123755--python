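"""Finite mixture of VAR(p) models with exogenous covariates, fitted by EM.

Each latent class k owns a lag order p_k, lagged coefficient matrices A_1..A_p
(autoregressive on the diagonal, cross-lagged off it), a covariate/intercept
coefficient matrix B, an innovation covariance Sigma, and a mixing proportion
pi_k.  Individuals — not occasions — are the units of classification: the
E-step computes posterior class responsibilities per participant from the
participant's whole conditional Gaussian likelihood, and the M-step refits
each class by responsibility-weighted multivariate least squares.

Model selection scans a grid of (number of clusters K) x (lag order) cells,
launches many EM starts per cell (pseudo-random centre-based starts, a
rational k-means start, and a warm start from the neighbouring cell), and
ranks cells by the Hannan-Quinn criterion.

Degeneracy handling follows the covariance-inflation rule: when a class
collapses (expected membership below the minimum or a non-PD Sigma), every
element of its Sigma is increased by a fixed increment (default 10) and its
responsibilities are re-drawn, after which EM continues.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .data import CovariateSpec, DesignPair, EmaPanel, build_design

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class VarClusterModel:
    """One latent class: VAR(p) dynamics plus covariate effects.

    A[l-1][i, j] is the lag-l effect of variable j at t-l on variable i at t
    (diagonal = autoregressive, off-diagonal = cross-lagged).  B maps
    [intercept, covariates] onto the outcome mean.  Sigma is the innovation
    covariance; pi the mixing proportion.
    """

    lag: int
    A: list[np.ndarray]
    B: np.ndarray
    Sigma: np.ndarray
    pi: float = 1.0

    @property
    def n_vars(self) -> int:
        return self.B.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.B.shape[1] - 1

    def coefficient_matrix(self) -> np.ndarray:
        """(n_predictors, n_vars) matrix C such that mean = X @ C.

        Predictor order matches DesignPair: intercept+covariates, then one
        block of all variables per lag.
        """
        blocks = [self.B.T] + [a.T for a in self.A]
        return np.vstack(blocks)

    @classmethod
    def from_coefficient_matrix(
        cls, C: np.ndarray, n_vars: int, n_covariates: int, lag: int,
        Sigma: np.ndarray, pi: float = 1.0,
    ) -> "VarClusterModel":
        base = 1 + n_covariates
        B = C[:base].T
        A = [
            C[base + l * n_vars: base + (l + 1) * n_vars].T
            for l in range(lag)
        ]
        return cls(lag=lag, A=A, B=B, Sigma=Sigma, pi=pi)

    def companion_matrix(self) -> np.ndarray:
        """Companion form of the lag polynomial (d*p x d*p)."""
        return companion_matrix(self.A)

    def spectral_radius(self) -> float:
        return spectral_radius(self.A)

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


def companion_matrix(A: Sequence[np.ndarray]) -> np.ndarray:
    A = [np.asarray(a, dtype=float) for a in A]
    d = A[0].shape[0]
    p = len(A)
    top = np.hstack(A)
    if p == 1:
        return top
    lower = np.hstack([np.eye(d * (p - 1)), np.zeros((d * (p - 1), d))])
    return np.vstack([top, lower])


def spectral_radius(A: Sequence[np.ndarray]) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(A)))))


@dataclass
class LcvarFit:
    """A fitted mixture: class models, posterior memberships, and fit metrics."""

    clusters: list[VarClusterModel]
    responsibilities: np.ndarray      # (n_participants, K)
    participant_ids: list
    loglik: float
    loglik_trace: list[float]
    n_modeled_rows: int
    n_params: int
    hqc: float
    aic: float
    converged: bool
    n_resets: int
    start_descriptor: str
    variable_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([m.pi for m in self.clusters])

    @property
    def hard_labels(self) -> dict:
        """Modal cluster per participant; ties go to the lowest index."""
        idx = np.argmax(self.responsibilities, axis=1)
        return dict(zip(self.participant_ids, idx.tolist()))

    def cluster_sizes(self) -> np.ndarray:
        idx = np.argmax(self.responsibilities, axis=1)
        return np.bincount(idx, minlength=self.n_clusters)

    def meets_min_members(self, min_members: int) -> bool:
        return bool(self.cluster_sizes().min() >= min_members)


@dataclass(frozen=True)
class FitConfig:
    """Estimation hyperparameters for the cluster-number x lag grid search."""

    k_min: int = 2
    k_max: int = 3
    lag_min: int = 1
    lag_max: int = 3
    min_members: int = 2
    n_pseudo_random_starts: int = 15
    use_rational_start: bool = True
    max_em_iterations: int = 50
    loglik_tol: float = 1e-07
    sigma_reset_increment: float = 10.0
    heterogeneous_lags: bool = False
    shared_sigma: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.lag_min < 1:
            raise ValueError("k_min and lag_min must be >= 1")
        if self.k_max < self.k_min or self.lag_max < self.lag_min:
            raise ValueError("grid bounds must satisfy k_min<=k_max, lag_min<=lag_max")
        if self.loglik_tol <= 0:
            raise ValueError("loglik_tol must be positive")


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _row_logliks(Y: np.ndarray, X: np.ndarray, model: VarClusterModel) -> np.ndarray:
    """Per-row conditional Gaussian log density under one class model."""
    d = Y.shape[1]
    resid = Y - X @ model.coefficient_matrix()
    try:
        chol, low = linalg.cho_factor(model.Sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise DegenerateSigmaError(str(exc)) from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    z = linalg.cho_solve((chol, low), resid.T)
    quad = np.einsum("ij,ji->i", resid, z)
    return -0.5 * (d * _LOG_2PI + logdet + quad)


class DegenerateSigmaError(RuntimeError):
    """Sigma not positive definite; caught by the EM reset path."""


def conditional_loglik(design: DesignPair, model: VarClusterModel) -> float:
    """Conditional log-likelihood of the design's rows under one class model.

    The mean is ``A . lagged values + B . [1, covariates]`` and the first p
    occasions per participant are conditioned on (they appear only as
    predictors).  Everything is evaluated in log space.
    """
    cols = design.column_slice(model.lag)
    ll = _row_logliks(design.outcomes, design.predictors[:, cols], model)
    return float(ll.sum())


def _participant_logliks(
    design: DesignPair, clusters: Sequence[VarClusterModel], codes: np.ndarray,
    n_participants: int,
) -> np.ndarray:
    """(n_participants, K) matrix of per-participant conditional log-likelihoods."""
    K = len(clusters)
    out = np.empty((n_participants, K))
    for k, model in enumerate(clusters):
        cols = design.column_slice(model.lag)
        rows = _row_logliks(design.outcomes, design.predictors[:, cols], model)
        out[:, k] = np.bincount(codes, weights=rows, minlength=n_participants)
    return out


def e_step(
    design: DesignPair,
    clusters: Sequence[VarClusterModel],
    proportions: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Posterior responsibilities and mixture log-likelihood.

    responsibility(i, k) is proportional to pi_k exp(loglik_ik), normalised per
    participant through log-sum-exp so that log-likelihood differences of
    several hundred nats neither overflow nor underflow.
    """
    if proportions is None:
        proportions = np.array([m.pi for m in clusters])
    codes = design.codes
    n = len(design.participant_ids)
    ll = _participant_logliks(design, clusters, codes, n)
    logpost = ll + np.log(proportions)[None, :]
    norm = logsumexp(logpost, axis=1)
    resp = np.exp(logpost - norm[:, None])
    return resp, float(norm.sum())


def m_step(
    design: DesignPair,
    responsibilities: np.ndarray,
    lags: Sequence[int],
    ridge: float = 1e-8,
    shared_sigma: bool = False,
) -> tuple[list[VarClusterModel], np.ndarray]:
    """Responsibility-weighted multivariate least squares per cluster.

    Coefficients solve the weighted normal equations; Sigma is the weighted
    residual covariance (with a tiny ridge if numerically singular); mixing
    proportions are mean responsibilities.
    """
    codes = design.codes
    K = responsibilities.shape[1]
    n_vars = design.n_vars
    proportions = responsibilities.mean(axis=0)
    clusters: list[VarClusterModel] = []
    pooled_sigma = np.zeros((n_vars, n_vars))
    pooled_weight = 0.0
    for k in range(K):
        w = responsibilities[codes, k]
        total = w.sum()
        if total <= 0:
            raise ValueError(f"cluster {k} has zero effective weight")
        cols = design.column_slice(lags[k])
        X = design.predictors[:, cols]
        Y = design.outcomes
        Xw = X * w[:, None]
        G = X.T @ Xw
        try:
            C = np.linalg.solve(G, Xw.T @ Y)
        except np.linalg.LinAlgError:
            G[np.diag_indices_from(G)] += ridge * (1.0 + np.trace(G) / len(G))
            C = np.linalg.solve(G, Xw.T @ Y)
        resid = Y - X @ C
        Sigma = (resid * w[:, None]).T @ resid / total
        Sigma = 0.5 * (Sigma + Sigma.T)
        evals = np.linalg.eigvalsh(Sigma)
        if evals.min() < 1e-10:
            Sigma = Sigma + (1e-10 - min(evals.min(), 0.0) + 1e-12) * np.eye(n_vars)
        pooled_sigma += Sigma * total
        pooled_weight += total
        clusters.append(
            VarClusterModel.from_coefficient_matrix(
                C, n_vars, design.n_covariates, lags[k], Sigma, float(proportions[k])
            )
        )
    if shared_sigma:
        shared = pooled_sigma / pooled_weight
        for model in clusters:
            model.Sigma = shared.copy()
    return clusters, proportions


# ---------------------------------------------------------------------------
# Starts
# ---------------------------------------------------------------------------

def _soften_onehot(assign: np.ndarray, K: int, eps: float = 1e-3) -> np.ndarray:
    n = len(assign)
    resp = np.full((n, K), eps / max(K - 1, 1))
    resp[np.arange(n), assign] = 1.0 - eps if K > 1 else 1.0
    return resp / resp.sum(axis=1, keepdims=True)


def _fit_single_var(
    Y: np.ndarray, X: np.ndarray, n_vars: int, n_cov: int, lag: int,
    ridge: float = 1e-6,
) -> VarClusterModel:
    """Ridge-stabilised per-participant (or per-subset) VAR fit."""
    G = X.T @ X
    G[np.diag_indices_from(G)] += ridge
    C = np.linalg.solve(G, X.T @ Y)
    resid = Y - X @ C
    Sigma = resid.T @ resid / max(len(Y), 1)
    Sigma = 0.5 * (Sigma + Sigma.T) + 1e-6 * np.eye(n_vars)
    return VarClusterModel.from_coefficient_matrix(C, n_vars, n_cov, lag, Sigma)


def pseudo_random_start(
    design: DesignPair, K: int, rng: np.random.Generator, lag: int | None = None,
) -> np.ndarray:
    """Centre-based random start: K random participants seed the classes.

    A VAR is fitted to each centre participant alone; every participant is
    then hard-assigned to the centre model giving it the highest conditional
    likelihood, and the one-hot assignment is softened by 1e-3.
    """
    n = len(design.participant_ids)
    if K > n:
        raise ValueError(f"K={K} exceeds the {n} available participants")
    lag = design.lag if lag is None else lag
    codes = design.codes
    centres = rng.choice(n, size=K, replace=False)
    cols = design.column_slice(lag)
    X = design.predictors[:, cols]
    models = []
    for c in centres:
        rows = codes == c
        models.append(
            _fit_single_var(
                design.outcomes[rows], X[rows], design.n_vars,
                design.n_covariates, lag,
            )
        )
    ll = _participant_logliks(design, models, codes, n)
    return _soften_onehot(np.argmax(ll, axis=1), K)


def rational_start(
    design: DesignPair, K: int, rng: np.random.Generator, lag: int | None = None,
) -> np.ndarray:
    """k-means start on per-participant VAR + covariate coefficient vectors."""
    n = len(design.participant_ids)
    if K > n:
        raise ValueError(f"K={K} exceeds the {n} available participants")
    lag = design.lag if lag is None else lag
    codes = design.codes
    cols = design.column_slice(lag)
    X = design.predictors[:, cols]
    feats = np.empty((n, len(cols) * design.n_vars))
    for i in range(n):
        rows = codes == i
        model = _fit_single_var(
            design.outcomes[rows], X[rows], design.n_vars, design.n_covariates, lag,
        )
        feats[i] = model.coefficient_matrix().ravel()
    if np.allclose(feats.std(axis=0), 0.0):
        warnings.warn(
            "all per-participant coefficient vectors identical; "
            "falling back to a pseudo-random start", stacklevel=2,
        )
        return pseudo_random_start(design, K, rng, lag)
    km = KMeans(
        n_clusters=K, n_init=10,
        random_state=int(rng.integers(0, 2**31 - 1)),
    ).fit(feats)
    return _soften_onehot(km.labels_, K)


# ---------------------------------------------------------------------------
# Degeneracy reset
# ---------------------------------------------------------------------------

def nearest_pd(S: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the PD cone by eigenvalue flooring."""
    S = 0.5 * (S + S.T)
    evals, evecs = np.linalg.eigh(S)
    if evals.min() >= floor:
        return S
    evals = np.clip(evals, floor, None)
    return (evecs * evals) @ evecs.T


def reset_degenerate(
    model: VarClusterModel, increment: float = 10.0,
) -> VarClusterModel:
    """Inflate Sigma by adding ``increment`` to every element.

    The result is symmetrised and, if necessary, projected to the nearest
    positive-definite matrix.  Responsibility re-randomisation for the
    affected cluster happens in the EM loop, which owns the random stream.
    """
    Sigma = nearest_pd(model.Sigma + increment)
    return replace(model, Sigma=Sigma)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def run_em(
    design: DesignPair,
    K: int,
    lags: Sequence[int],
    start_responsibilities: np.ndarray,
    config: FitConfig,
    rng: np.random.Generator | None = None,
    start_descriptor: str = "custom",
) -> LcvarFit:
    """Alternate M- and E-steps from an initial responsibility matrix.

    Stops when the log-likelihood improves by less than ``loglik_tol`` or
    after ``max_em_iterations``.  A class whose expected membership falls
    below ``min_members`` (or whose Sigma loses positive definiteness) is
    reset: its Sigma is inflated by ``sigma_reset_increment`` and its
    responsibilities are re-drawn uniformly at random, after which iteration
    continues.  Resets are counted and the trace records every accepted
    log-likelihood.
    """
    rng = rng or np.random.default_rng(config.seed)
    resp = np.asarray(start_responsibilities, dtype=float).copy()
    n = len(design.participant_ids)
    if resp.shape != (n, K):
        raise ValueError(f"start responsibilities must be {(n, K)}, got {resp.shape}")

    lags = list(lags)
    trace: list[float] = []
    clusters: list[VarClusterModel] = []
    proportions = np.full(K, 1.0 / K)
    n_resets = 0
    converged = False
    loglik = -np.inf

    for _ in range(config.max_em_iterations):
        try:
            clusters, proportions = m_step(
                design, resp, lags, shared_sigma=config.shared_sigma,
            )
            degenerate = [
                k for k in range(K)
                if resp[:, k].sum() < config.min_members
            ]
            if degenerate:
                raise _DegenerateCluster(degenerate)
            new_resp, new_loglik = e_step(design, clusters, proportions)
        except (DegenerateSigmaError, _DegenerateCluster, np.linalg.LinAlgError) as exc:
            bad = exc.clusters if isinstance(exc, _DegenerateCluster) else range(K)
            for k in bad:
                if clusters:
                    clusters[k] = reset_degenerate(
                        clusters[k], config.sigma_reset_increment
                    )
                resp[:, k] = rng.uniform(0.0, 1.0, size=n)
            resp /= resp.sum(axis=1, keepdims=True)
            n_resets += 1
            logger.info("EM reset %d (clusters %s)", n_resets, list(bad))
            continue

        delta = new_loglik - loglik
        resp, loglik = new_resp, new_loglik
        trace.append(loglik)
        if abs(delta) < config.loglik_tol:
            converged = True
            break

    q = count_parameters(clusters, K)
    hqc, aic = information_criteria(loglik, q, len(design.outcomes))
    return LcvarFit(
        clusters=clusters,
        responsibilities=resp,
        participant_ids=list(design.participant_ids),
        loglik=loglik,
        loglik_trace=trace,
        n_modeled_rows=len(design.outcomes),
        n_params=q,
        hqc=hqc,
        aic=aic,
        converged=converged,
        n_resets=n_resets,
        start_descriptor=start_descriptor,
        variable_names=list(design.variable_names),
        covariate_names=list(design.covariate_names),
    )


class _DegenerateCluster(RuntimeError):
    def __init__(self, clusters):
        super().__init__(f"degenerate clusters {clusters}")
        self.clusters = list(clusters)


# ---------------------------------------------------------------------------
# Information criteria
# ---------------------------------------------------------------------------

def count_parameters(clusters: Sequence[VarClusterModel], K: int | None = None) -> int:
    """Free-parameter count of a fitted mixture.

    Per cluster: n_vars^2 * p lagged coefficients, n_vars * (n_covariates+1)
    covariate/intercept coefficients, and n_vars(n_vars+1)/2 covariance
    entries; plus K-1 free mixing proportions.
    """
    K = len(clusters) if K is None else K
    q = 0
    for m in clusters:
        d = m.n_vars
        q += d * d * m.lag + d * (m.n_covariates + 1) + d * (d + 1) // 2
    return q + (K - 1)


def information_criteria(loglik: float, n_params: int, n_rows: int) -> tuple[float, float]:
    """Per-row Hannan-Quinn and Akaike criteria; lower is better.

    HQC = (-2 logL + 2 q ln ln N) / N and AIC = (-2 logL + 2 q) / N with
    N the number of modelled outcome rows.
    """
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood is not finite")
    if n_rows <= np.e:
        raise ValueError(f"N={n_rows} too small: ln(ln N) undefined or negative")
    hqc = (-2.0 * loglik + 2.0 * n_params * np.log(np.log(n_rows))) / n_rows
    aic = (-2.0 * loglik + 2.0 * n_params) / n_rows
    return float(hqc), float(aic)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclass
class GridCell:
    K: int
    lags: tuple[int, ...]
    fit: LcvarFit | None
    error: str | None = None

    @property
    def hqc(self) -> float:
        return self.fit.hqc if self.fit is not None else np.inf


@dataclass
class GridResult:
    cells: list[GridCell]
    selected: LcvarFit

    def summary(self):
        import pandas as pd

        rows = []
        for c in self.cells:
            rows.append(
                {
                    "K": c.K,
                    "lags": "/".join(map(str, c.lags)),
                    "loglik": c.fit.loglik if c.fit else np.nan,
                    "n_params": c.fit.n_params if c.fit else np.nan,
                    "hqc": c.fit.hqc if c.fit else np.nan,
                    "aic": c.fit.aic if c.fit else np.nan,
                    "converged": c.fit.converged if c.fit else False,
                    "n_resets": c.fit.n_resets if c.fit else np.nan,
                    "start": c.fit.start_descriptor if c.fit else c.error,
                }
            )
        return pd.DataFrame(rows).sort_values("hqc").reset_index(drop=True)


def _lag_vectors(K: int, config: FitConfig):
    if config.heterogeneous_lags:
        # non-decreasing per-cluster lag vectors; canonical form avoids
        # duplicate cells that differ only by cluster relabelling
        yield from combinations_with_replacement(
            range(config.lag_min, config.lag_max + 1), K
        )
    else:
        for p in range(config.lag_min, config.lag_max + 1):
            yield (p,) * K


def _cell_rng(seed: int, cell_index: int, start_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(cell_index, start_index))
    return np.random.default_rng(ss)


def fit_grid(
    panel: EmaPanel,
    config: FitConfig | None = None,
    covariates: CovariateSpec | None = None,
) -> GridResult:
    """Scan the K x lag grid, run all starts per cell, rank cells by HQC.

    Per cell the starts are ``n_pseudo_random_starts`` centre-based random
    starts, one rational k-means start, and a warm start from the previous
    cell with the same K.  The best-log-likelihood fit that respects the
    minimum cluster size wins the cell; the grid argmin by HQC (ties: fewer
    parameters, then smaller K, then lower lags) is the selected solution.
    """
    config = config or FitConfig()
    covariates = covariates or CovariateSpec()

    cells: list[GridCell] = []
    warm: dict[int, np.ndarray] = {}
    cell_index = 0
    for K in range(config.k_min, config.k_max + 1):
        for lags in _lag_vectors(K, config):
            design = build_design(panel, max(lags), covariates)
            starts: list[tuple[str, np.ndarray]] = []
            for s in range(config.n_pseudo_random_starts):
                rng = _cell_rng(config.seed, cell_index, s)
                try:
                    starts.append(
                        (f"pseudo-random-{s}", pseudo_random_start(design, K, rng))
                    )
                except Exception as exc:  # noqa: BLE001 - recorded per cell
                    logger.warning("pseudo-random start failed: %s", exc)
            if config.use_rational_start:
                rng = _cell_rng(config.seed, cell_index, 10_000)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        starts.append(("rational", rational_start(design, K, rng)))
                except Exception as exc:  # noqa: BLE001
                    logger.warning("rational start failed: %s", exc)
            if K in warm and warm[K].shape[0] == len(design.participant_ids):
                starts.append(("warm", warm[K]))

            best: LcvarFit | None = None
            for name, resp0 in starts:
                rng = _cell_rng(config.seed, cell_index, 20_000 + len(name))
                try:
                    fit = run_em(
                        design, K, lags, resp0, config, rng, start_descriptor=name
                    )
                except Exception as exc:  # noqa: BLE001
                    logger.warning("EM start %s failed: %s", name, exc)
                    continue
                if not fit.meets_min_members(config.min_members):
                    continue
                if best is None or fit.loglik > best.loglik or (
                    fit.loglik == best.loglik and fit.converged and not best.converged
                ):
                    best = fit
            if best is None:
                cells.append(GridCell(K, lags, None, error="all starts failed"))
                logger.warning("grid cell K=%d lags=%s failed", K, lags)
            else:
                cells.append(GridCell(K, lags, best))
                warm[K] = best.responsibilities
                logger.info(
                    "cell K=%d lags=%s: loglik=%.3f hqc=%.4f (%s, converged=%s)",
                    K, lags, best.loglik, best.hqc, best.start_descriptor,
                    best.converged,
                )
            cell_index += 1

    fitted = [c for c in cells if c.fit is not None]
    if not fitted:
        raise RuntimeError("every grid cell failed to produce a valid fit")
    selected = min(
        fitted,
        key=lambda c: (c.fit.hqc, c.fit.n_params, c.K, c.lags),
    )
    return GridResult(cells=cells, selected=selected.fit)
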