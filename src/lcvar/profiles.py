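"""Post-fit descriptive surfaces: coefficient heatmaps and daytime courses.

Heatmaps lay out each cluster's lagged coefficient matrices as one
predictor x (lag-block outcome) table, with the appetite items (craving,
hunger) leading the rows and closing each lag block's columns so their
cross-lagged effects are easy to scan.  Daytime courses are per-cluster
per-beep means of the raw 0-100 observations, computed on observed
(pre-imputation) values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import EmaPanel
from .model import LcvarFit


def _row_order(names: Sequence[str], lead: Sequence[str]) -> list[str]:
    lead_present = [v for v in lead if v in names]
    rest = [v for v in names if v not in lead_present]
    return lead_present + rest


def _col_order(names: Sequence[str], trail: Sequence[str]) -> list[str]:
    trail_present = [v for v in trail if v in names]
    rest = [v for v in names if v not in trail_present]
    return rest + trail_present


def heatmap_matrix(
    fit: LcvarFit,
    cluster: int,
    lead_vars: Sequence[str] = ("craving", "hunger"),
) -> pd.DataFrame:
    """Labelled predictor x outcome coefficient table for one cluster.

    Rows are predictor variables (appetite items first); columns come in one
    block per lag, each block ending with the appetite items reversed
    (..., hunger, craving).  Cell (predictor v, lag-l block outcome w) equals
    A_l[w, v] on the model (standardised) scale.
    """
    if not 0 <= cluster < fit.n_clusters:
        raise IndexError(f"cluster {cluster} not in 0..{fit.n_clusters - 1}")
    model = fit.clusters[cluster]
    names = fit.variable_names or [f"var_{j + 1}" for j in range(model.n_vars)]
    rows = _row_order(names, lead_vars)
    cols_per_lag = _col_order(names, list(lead_vars)[::-1])
    ridx = {v: names.index(v) for v in names}

    data = np.empty((len(rows), model.lag * len(names)))
    columns = []
    for l in range(1, model.lag + 1):
        A = model.A[l - 1]
        for c, w in enumerate(cols_per_lag):
            columns.append(f"lag{l}:{w}")
            for r, v in enumerate(rows):
                data[r, (l - 1) * len(names) + c] = A[ridx[w], ridx[v]]
    return pd.DataFrame(data, index=rows, columns=columns)


def heatmap_to_tensors(
    heatmap: pd.DataFrame, variable_names: Sequence[str],
) -> list[np.ndarray]:
    """Invert :func:`heatmap_matrix` back to the list of A matrices."""
    d = len(variable_names)
    ridx = {v: i for i, v in enumerate(variable_names)}
    lags = sorted({int(c.split(":")[0][3:]) for c in heatmap.columns})
    A = [np.empty((d, d)) for _ in lags]
    for col in heatmap.columns:
        lag_s, w = col.split(":")
        l = int(lag_s[3:])
        for v in heatmap.index:
            A[l - 1][ridx[w], ridx[v]] = heatmap.loc[v, col]
    return A


@dataclass
class DaytimeCourse:
    """Per-cluster, per-beep, per-variable means of raw observations."""

    values: np.ndarray       # (K, B, n_vars); NaN where no observation
    counts: np.ndarray       # matching observation counts
    clusters: list
    variable_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        K, B, d = self.values.shape
        for k in range(K):
            for b in range(B):
                row = {"cluster": self.clusters[k], "beep": b + 1}
                for j, v in enumerate(self.variable_names):
                    row[v] = self.values[k, b, j]
                    row[f"n_{v}"] = int(self.counts[k, b, j])
                rows.append(row)
        return pd.DataFrame(rows)


def daytime_means(panel: EmaPanel, labels: Mapping) -> DaytimeCourse:
    """Mean raw value per (cluster, beep, variable) over non-missing cells.

    ``labels`` must cover every participant in the panel.  Cells without any
    contributing observation stay NaN with count zero.
    """
    missing = [p for p in panel.participants if p not in labels]
    if missing:
        raise ValueError(f"labels missing for participants {missing[:5]}")
    clusters = sorted(set(labels[p] for p in panel.participants))
    B = panel.schedule.beeps_per_day
    d = panel.n_vars
    values = np.full((len(clusters), B, d), np.nan)
    counts = np.zeros((len(clusters), B, d), dtype=int)

    df = panel.data.copy()
    df["_cluster"] = df["participant_id"].map(dict(labels))
    grouped = df.groupby(["_cluster", "beep"], sort=True)
    means = grouped[panel.variable_names].mean()
    ns = grouped[panel.variable_names].count()
    for (k, b), row in means.iterrows():
        ki = clusters.index(k)
        values[ki, b - 1] = row.to_numpy()
        counts[ki, b - 1] = ns.loc[(k, b)].to_numpy()
    return DaytimeCourse(values, counts, clusters, list(panel.variable_names))


def plot_heatmap(heatmap: pd.DataFrame, path, title: str = "") -> None:
    """Save a simple diverging-colour coefficient heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.4 * heatmap.shape[1], 1 + 0.4 * len(heatmap)))
    vmax = max(float(np.abs(heatmap.to_numpy()).max()), 1e-6)
    im = ax.imshow(heatmap.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(heatmap.shape[1]), heatmap.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(heatmap)), heatmap.index, fontsize=6)
    n_vars = len(heatmap.index)
    for cut in range(n_vars, heatmap.shape[1], n_vars):
        ax.axvline(cut - 0.5, color="k", lw=1)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_daytime_courses(course: DaytimeCourse, path) -> None:
    """Save per-variable daytime-course line plots, one line per cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    K, B, d = course.values.shape
    ncol = min(d, 4)
    nrow = int(np.ceil(d / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False)
    for j, name in enumerate(course.variable_names):
        ax = axes[j // ncol][j % ncol]
        for k in range(K):
            ax.plot(range(1, B + 1), course.values[k, :, j],
                    marker="o", ms=3, label=f"cluster {course.clusters[k]}")
        ax.set_title(name, fontsize=8)
        ax.set_xlabel("beep")
    for j in range(d, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
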