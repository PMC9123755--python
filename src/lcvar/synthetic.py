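"""Synthetic EMA panels with known latent-class VAR structure.

Generates slider-scale (0-100) momentary time series for a roster of
participants, each belonging to one latent class with its own stable VAR
dynamics and per-beep diurnal mean profile, plus item-level missingness and
class-linked trait tables.  Ground-truth labels make clustering recovery
measurable (adjusted Rand index) and feed the characterisation-stage tests.
A shuffled-null transform destroys temporal structure while preserving
marginal distributions, giving a randomised-data control for coefficient
shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import DEFAULT_BEEP_TIMES, EmaPanel, Schedule
from .model import VarClusterModel, spectral_radius

DEFAULT_VARIABLE_NAMES = [
    "craving", "hunger",
    "cheerful", "enthusiastic", "relaxed", "calm", "active",
    "irritated", "worried", "depressed", "bored", "nervous_stressed",
    "present_coping", "anticipated_coping",
]


@dataclass
class GroundTruth:
    """True cluster memberships and class-level trait structure."""

    labels: dict
    trait_means: np.ndarray | None = None      # (K, n_traits)
    trait_names: list[str] = field(default_factory=list)
    gender_probs: np.ndarray | None = None     # (K, n_gender_categories)
    gender_categories: list[str] = field(default_factory=lambda: ["female", "male"])

    @property
    def n_clusters(self) -> int:
        return int(max(self.labels.values())) + 1


@dataclass
class SimulationSpec:
    """Full description of one synthetic study.

    Defaults mirror the study design this package emulates: 14 days x 6 beeps
    of 14 slider items.  ``diurnal_profiles`` are per-cluster target means per
    (beep, variable) on the 0-100 scale; internally they are converted to
    beep-specific VAR intercepts so the stationary per-beep means match them
    exactly.  ``dropout_rule`` optionally draws a completed-prompt count per
    participant (whole prompts are then masked), on top of item-level MCAR
    masking at ``missing_rate``.
    """

    n_participants: int
    cluster_models: list[VarClusterModel]
    cluster_proportions: np.ndarray
    diurnal_profiles: np.ndarray               # (K, beeps_per_day, n_vars)
    n_days: int = 14
    beeps_per_day: int = 6
    missing_rate: float = 0.0
    beep_missing_rates: Sequence[float] | None = None   # optional MAR mechanism
    dropout_rule: Callable[[np.random.Generator, int], np.ndarray] | None = None
    seed: int = 0
    burn_in: int = 50
    variable_names: list[str] | None = None
    min_cluster_members: int = 2

    @property
    def n_vars(self) -> int:
        return self.cluster_models[0].n_vars

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_models)

    def schedule(self) -> Schedule:
        if self.beeps_per_day == 6:
            times = DEFAULT_BEEP_TIMES
        else:
            times = tuple(
                int(540 + i * 750 / max(self.beeps_per_day - 1, 1))
                for i in range(self.beeps_per_day)
            )
        return Schedule(self.n_days, self.beeps_per_day, times)

    def validate(self) -> None:
        props = np.asarray(self.cluster_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError(f"cluster proportions sum to {props.sum()}, not 1")
        if (props <= 0).any():
            raise ValueError("every cluster proportion must be positive")
        if len(props) != self.n_clusters:
            raise ValueError("proportions and cluster models disagree on K")
        for k, m in enumerate(self.cluster_models):
            rho = m.spectral_radius()
            if rho >= 1.0:
                raise ValueError(
                    f"cluster {k} is unstable (companion spectral radius {rho:.4f})"
                )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        prof = np.asarray(self.diurnal_profiles, dtype=float)
        if prof.shape != (self.n_clusters, self.beeps_per_day, self.n_vars):
            raise ValueError(
                f"diurnal_profiles must be (K, B, n_vars) = "
                f"({self.n_clusters}, {self.beeps_per_day}, {self.n_vars}), "
                f"got {prof.shape}"
            )


# ---------------------------------------------------------------------------
# Parameter construction
# ---------------------------------------------------------------------------

def make_var_params(
    n_vars: int,
    lag: int,
    cross_effect: float = 0.2,
    spectral_cap: float = 0.8,
    seed: int = 0,
    diag: float = 0.3,
    noise_scale: float = 0.03,
    cross_pairs: Sequence[tuple[int, int, float]] | None = None,
    innovation_sd: float = 8.0,
    max_attempts: int = 10,
) -> VarClusterModel:
    """Build a stable VAR(p) class model with designated cross-lagged effects.

    Lag-1 has autoregression ``diag`` on the diagonal; all matrices get small
    random entries; ``cross_pairs`` (predictor index, outcome index, sign)
    entries of the lag-1 matrix are set to ``sign * cross_effect``.  If the
    companion spectral radius exceeds ``spectral_cap`` the lag-l matrices are
    rescaled by s**l (which scales the companion eigenvalues by s) until the
    cap holds; after ``max_attempts`` failures the offending radius is
    reported.
    """
    if n_vars < 1 or lag < 1:
        raise ValueError("n_vars and lag must be >= 1")
    if not 0.0 < spectral_cap < 1.0:
        raise ValueError("spectral_cap must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    A = [rng.normal(0.0, noise_scale, size=(n_vars, n_vars)) for _ in range(lag)]
    A[0][np.diag_indices(n_vars)] = diag
    if cross_pairs is None and n_vars >= 2 and cross_effect:
        cross_pairs = [(0, 1, +1.0), (1, 0, -1.0)]
    for pred, out, sign in cross_pairs or []:
        A[0][out, pred] = sign * cross_effect

    for _ in range(max_attempts):
        rho = spectral_radius(A)
        if rho <= spectral_cap:
            break
        s = 0.98 * spectral_cap / rho
        A = [a * s ** (l + 1) for l, a in enumerate(A)]
    else:
        raise RuntimeError(
            f"could not stabilise VAR below cap {spectral_cap}; "
            f"last spectral radius {spectral_radius(A):.4f}"
        )
    Sigma = innovation_sd**2 * np.eye(n_vars)
    B = np.zeros((n_vars, 1))
    return VarClusterModel(lag=lag, A=[a.copy() for a in A], B=B, Sigma=Sigma)


def flat_profiles(
    n_clusters: int, beeps_per_day: int, n_vars: int, level: float = 50.0,
) -> np.ndarray:
    return np.full((n_clusters, beeps_per_day, n_vars), float(level))


def m_curve_profiles(
    n_clusters: int,
    beeps_per_day: int,
    n_vars: int,
    base: float = 45.0,
    amplitude: float = 15.0,
    appetite_indices: Sequence[int] = (0, 1),
) -> np.ndarray:
    """Mean profiles with the diurnal appetite 'M-curve'.

    Appetite variables (craving, hunger by default) peak mid-morning and
    late afternoon; all other items stay flat at ``base``.
    """
    shape = np.array([0.1, 1.0, 0.35, 1.0, 0.5, 0.0])
    if beeps_per_day != 6:
        x = np.linspace(0, 5, beeps_per_day)
        shape = np.interp(x, np.arange(6), shape)
    prof = np.full((n_clusters, beeps_per_day, n_vars), float(base))
    for j in appetite_indices:
        prof[:, :, j] = base + amplitude * shape[None, :]
    return prof


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_var_series(
    A: Sequence[np.ndarray],
    intercepts: np.ndarray,
    Sigma: np.ndarray,
    T: int,
    rng: np.random.Generator,
    burn_in: int = 50,
) -> np.ndarray:
    """Simulate x_t = c_t + sum_l A_l x_{t-l} + eps_t, eps ~ N(0, Sigma).

    ``intercepts`` is either one vector (constant c) or a (T, d) array of
    per-occasion intercepts; the burn-in recycles the first intercept.
    """
    A = [np.asarray(a, dtype=float) for a in A]
    d = A[0].shape[0]
    p = len(A)
    c = np.asarray(intercepts, dtype=float)
    if c.ndim == 1:
        c = np.broadcast_to(c, (T, d))
    chol = np.linalg.cholesky(Sigma) if np.any(Sigma) else np.zeros((d, d))
    total = burn_in + T
    eps = rng.standard_normal((total, d)) @ chol.T
    x = np.zeros((total, d))
    for t in range(total):
        ct = c[0] if t < burn_in else c[t - burn_in]
        acc = ct + eps[t]
        for l in range(1, p + 1):
            if t - l >= 0:
                acc = acc + A[l - 1] @ x[t - l]
        x[t] = acc
    return x[burn_in:]


def _profile_to_intercepts(
    profile: np.ndarray, A: Sequence[np.ndarray], n_days: int,
) -> np.ndarray:
    """Per-occasion intercepts whose stationary means equal the target profile.

    With mu_t the target mean at occasion t (cycling through beeps), taking
    c_t = mu_t - sum_l A_l mu_{t-l} makes E[x_t] = mu_t exactly.
    """
    B, d = profile.shape
    mus = np.tile(profile, (n_days + 1, 1))       # one leading cycle as history
    T = n_days * B
    offset = B
    c = np.empty((T, d))
    for t in range(T):
        acc = mus[offset + t].copy()
        for l, a in enumerate(A, start=1):
            acc -= a @ mus[offset + t - l]
        c[t] = acc
    return c


def simulate_panel(spec: SimulationSpec) -> tuple[EmaPanel, GroundTruth]:
    """Draw a full synthetic panel and its ground truth.

    Each participant is assigned a cluster from ``cluster_proportions``
    (re-sampled until every cluster has at least ``min_cluster_members``),
    their series follows the cluster's VAR recursion around the cluster's
    diurnal mean profile, recorded values are clamped to the 0-100 slider,
    and observations are masked missing per the configured mechanism.
    Identical specs (including seed) yield bit-identical panels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K = spec.n_clusters
    props = np.asarray(spec.cluster_proportions, dtype=float)

    for _ in range(200):
        labels = rng.choice(K, size=spec.n_participants, p=props)
        if np.bincount(labels, minlength=K).min() >= spec.min_cluster_members:
            break
    else:
        raise RuntimeError(
            f"could not draw >= {spec.min_cluster_members} members per cluster "
            f"for n={spec.n_participants}"
        )

    schedule = spec.schedule()
    T = schedule.n_prompts
    B = spec.beeps_per_day
    d = spec.n_vars
    var_names = list(spec.variable_names or _default_names(d))
    profiles = np.asarray(spec.diurnal_profiles, dtype=float)

    frames = []
    for i in range(spec.n_participants):
        k = int(labels[i])
        model = spec.cluster_models[k]
        c = _profile_to_intercepts(profiles[k], model.A, spec.n_days)
        series = simulate_var_series(
            model.A, c, model.Sigma, T, rng, burn_in=spec.burn_in
        )
        values = np.clip(series, 0.0, 100.0)

        mask = np.zeros((T, d), dtype=bool)
        if spec.beep_missing_rates is not None:
            rates = np.tile(
                np.asarray(spec.beep_missing_rates, dtype=float), spec.n_days
            )
            mask |= rng.uniform(size=(T, d)) < rates[:, None]
        elif spec.missing_rate > 0:
            mask |= rng.uniform(size=(T, d)) < spec.missing_rate
        if spec.dropout_rule is not None:
            completed = int(np.asarray(spec.dropout_rule(rng, 1)).ravel()[0])
            completed = int(np.clip(completed, 0, T))
            missed = rng.choice(T, size=T - completed, replace=False)
            mask[missed, :] = True
        values = values.astype(float)
        values[mask] = np.nan

        days = np.repeat(np.arange(1, spec.n_days + 1), B)
        beeps = np.tile(np.arange(1, B + 1), spec.n_days)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": f"p{i + 1:03d}",
                    "day": days,
                    "beep": beeps,
                    "clock_time": np.tile(schedule.beep_times, spec.n_days),
                    **{v: values[:, j] for j, v in enumerate(var_names)},
                }
            )
        )

    panel = EmaPanel(pd.concat(frames, ignore_index=True), schedule, var_names)
    truth = GroundTruth(
        labels={f"p{i + 1:03d}": int(labels[i]) for i in range(spec.n_participants)}
    )
    return panel, truth


def _default_names(d: int) -> list[str]:
    if d <= len(DEFAULT_VARIABLE_NAMES):
        return DEFAULT_VARIABLE_NAMES[:d]
    return DEFAULT_VARIABLE_NAMES + [
        f"item_{j + 1}" for j in range(len(DEFAULT_VARIABLE_NAMES), d)
    ]


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_traits(
    truth: GroundTruth, noise_sd: float, seed: int = 0,
) -> pd.DataFrame:
    """Per-participant trait table: cluster mean plus Gaussian noise.

    Gender is drawn per cluster from ``truth.gender_probs``.  The returned
    frame has one row per participant with the true cluster label attached,
    ready for the characterisation stage.
    """
    if truth.trait_means is None:
        raise ValueError("ground truth has no trait means")
    rng = np.random.default_rng(seed)
    means = np.asarray(truth.trait_means, dtype=float)
    K, n_traits = means.shape
    names = truth.trait_names or [f"trait_{j + 1}" for j in range(n_traits)]
    rows = []
    for pid, k in truth.labels.items():
        if not 0 <= k < K:
            raise ValueError(f"participant {pid} has unknown cluster label {k}")
        row = {"participant_id": pid, "cluster": k}
        vals = means[k] + rng.normal(0.0, noise_sd, size=n_traits)
        row.update(dict(zip(names, vals)))
        if truth.gender_probs is not None:
            g = rng.choice(len(truth.gender_categories), p=truth.gender_probs[k])
            row["gender"] = truth.gender_categories[g]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shuffled null
# ---------------------------------------------------------------------------

def shuffle_null(panel: EmaPanel, seed: int = 0) -> EmaPanel:
    """Permute each participant x variable series in time.

    Destroys all lagged structure while preserving each participant's
    marginal value multiset (missing cells travel with their values), giving
    a randomised-data control under which fitted lagged coefficients should
    shrink towards zero.
    """
    if not len(panel.data):
        raise ValueError("cannot shuffle an empty panel")
    rng = np.random.default_rng(seed)
    out = panel.copy()
    for _, idx in out.data.groupby("participant_id", sort=False).groups.items():
        idx = np.asarray(idx)
        for name in panel.variable_names:
            perm = rng.permutation(len(idx))
            col = out.data.loc[idx, name].to_numpy()
            out.data.loc[idx, name] = col[perm]
    return out
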