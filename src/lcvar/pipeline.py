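"""End-to-end orchestration: simulate -> prepare -> impute -> fit -> profile
-> characterize, driven by one structured config with reproducible seeding.

A single top-level seed fans out to named per-stage sub-seeds so any stage
can be re-run in isolation; every stage logs its sub-seed, writes delimited
text outputs, and a JSON manifest records the config snapshot, timings and
output digests.  A stage is skipped on re-run when its recorded digest still
matches the config and its outputs exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characterize import characterize_clusters
from .data import (
    CovariateSpec, EmaPanel, filter_compliance, read_long_table, standardize,
    write_long_table,
)
from .impute import ImputationConfig, impute_chained
from .model import FitConfig, fit_grid
from .profiles import daytime_means, heatmap_matrix
from .synthetic import (
    GroundTruth, SimulationSpec, flat_profiles, m_curve_profiles, make_var_params,
    simulate_panel, simulate_traits,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "n_participants": 60,
        "n_days": 14,
        "beeps_per_day": 6,
        "n_vars": 4,
        "n_clusters": 3,
        "lag": 1,
        "cross_effect": 0.35,
        "missing_rate": 0.05,
        "profiles": "m_curve",
        "trait_separation": 1.0,
    },
    "prepare": {"min_completed": 50, "standardize": True, "trend": False},
    "impute": {"iterations": 20},
    "fit": {
        "k_min": 2, "k_max": 3, "lag_min": 1, "lag_max": 1,
        "n_pseudo_random_starts": 5,
    },
}


def _sub_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(source) -> dict:
    if isinstance(source, dict):
        cfg = source
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    validate_config(merged)
    return merged


def validate_config(cfg: dict) -> None:
    fit = cfg.get("fit", {})
    if fit.get("k_min", 2) > fit.get("k_max", 3):
        raise ValueError("fit.k_min must not exceed fit.k_max")
    if fit.get("lag_min", 1) > fit.get("lag_max", 1):
        raise ValueError("fit.lag_min must not exceed fit.lag_max")
    imp = cfg.get("impute", {})
    if imp.get("iterations", 1) < 1:
        raise ValueError("impute.iterations must be >= 1")
    sim = cfg.get("simulate", {})
    if sim and sim.get("n_participants", 1) < sim.get("n_clusters", 1) * 2:
        raise ValueError("simulate.n_participants too small for the cluster count")


def build_simulation_spec(cfg: dict, seed: int) -> tuple[SimulationSpec, GroundTruth]:
    """Translate the `simulate` config section into a SimulationSpec.

    Cluster dynamics differ in the sign/placement of the designated
    cross-lagged effects, the separation that the clustering stage is meant
    to recover.
    """
    sim = cfg["simulate"]
    K = sim["n_clusters"]
    d = sim["n_vars"]
    lag = sim.get("lag", 1)
    ce = sim.get("cross_effect", 0.35)
    pair_sets = [
        [(0, 1, +1.0), (1, 0, +1.0)],
        [(0, 1, -1.0), (1, 0, -1.0)],
        [(0, 1, -1.0), (1, 0, +1.0)],
        [(0, 1, +1.0), (1, 0, -1.0)],
    ]
    models = [
        make_var_params(
            d, lag, cross_effect=ce, seed=seed + k,
            cross_pairs=pair_sets[k % len(pair_sets)],
        )
        for k in range(K)
    ]
    if sim.get("profiles", "m_curve") == "m_curve":
        profiles = m_curve_profiles(K, sim["beeps_per_day"], d)
    else:
        profiles = flat_profiles(K, sim["beeps_per_day"], d)
    spec = SimulationSpec(
        n_participants=sim["n_participants"],
        cluster_models=models,
        cluster_proportions=np.full(K, 1.0 / K),
        diurnal_profiles=profiles,
        n_days=sim["n_days"],
        beeps_per_day=sim["beeps_per_day"],
        missing_rate=sim.get("missing_rate", 0.0),
        seed=seed,
    )
    sep = sim.get("trait_separation", 1.0)
    truth_proto = GroundTruth(
        labels={},
        trait_means=np.arange(K, dtype=float)[:, None] * sep + 3.0,
        trait_names=["trait_score"],
        gender_probs=np.tile([0.8, 0.2], (K, 1)),
    )
    return spec, truth_proto


class RunManifest(dict):
    """Config snapshot, per-stage seeds/timings, and output digests."""

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self, indent=2, default=str))


def run_pipeline(config, outdir) -> RunManifest:
    """Execute all stages in order and write every artifact under ``outdir``.

    Stage order: simulate (or load `input` panel), prepare (compliance filter
    + optional z-scoring), impute, fit (grid search), profile (daytime
    courses on raw observed values + per-cluster heatmaps), characterize
    (trait ANOVAs, Tukey, gender Fisher).  Failures abort with the stage
    named; earlier outputs are retained.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(
        config=cfg, seed=seed, version=__version__, stages={}, outputs={}
    )

    def stage(name):
        logger.info("stage %s (sub-seed %d)", name, _sub_seed(seed, name))

        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                manifest.save(outdir / "manifest.json")
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
                "sub_seed": _sub_seed(seed, name),
            }
            return result

        return wrap

    # -- simulate / load ---------------------------------------------------
    def _simulate():
        if "input" in cfg:
            return read_long_table(cfg["input"]), None
        spec, truth_proto = build_simulation_spec(cfg, _sub_seed(seed, "simulate"))
        panel, truth = simulate_panel(spec)
        truth.trait_means = truth_proto.trait_means
        truth.trait_names = truth_proto.trait_names
        truth.gender_probs = truth_proto.gender_probs
        write_long_table(panel, outdir / "panel_raw.csv")
        pd.DataFrame(
            {"participant_id": list(truth.labels), "cluster": list(truth.labels.values())}
        ).to_csv(outdir / "true_labels.csv", index=False)
        traits = simulate_traits(truth, noise_sd=1.0, seed=_sub_seed(seed, "traits"))
        traits.to_csv(outdir / "traits.csv", index=False)
        return panel, traits

    panel, traits = stage("simulate")(_simulate)

    # -- prepare -----------------------------------------------------------
    def _prepare():
        prep = cfg["prepare"]
        filtered = filter_compliance(panel, prep.get("min_completed", 50))
        return filtered

    filtered = stage("prepare")(_prepare)

    # -- impute ------------------------------------------------------------
    def _impute():
        imp = ImputationConfig(
            n_iterations=cfg["impute"].get("iterations", 20),
            seed=_sub_seed(seed, "impute"),
        )
        complete = impute_chained(filtered, imp)
        write_long_table(complete, outdir / "panel_imputed.csv")
        return complete

    complete = stage("impute")(_impute)

    # -- fit ---------------------------------------------------------------
    def _fit():
        if cfg["prepare"].get("standardize", True):
            scaled, record = standardize(complete)
            record.to_frame().to_csv(outdir / "scaling.csv", index=False)
        else:
            scaled = complete
        fcfg = FitConfig(
            seed=_sub_seed(seed, "fit"),
            **{k: v for k, v in cfg["fit"].items() if k != "seed"},
        )
        cov = CovariateSpec(day_trend=cfg["prepare"].get("trend", False))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = fit_grid(scaled, fcfg, cov)
        grid.summary().to_csv(outdir / "grid_summary.csv", index=False)
        fit = grid.selected
        members = pd.DataFrame(
            fit.responsibilities,
            columns=[f"posterior_{k}" for k in range(fit.n_clusters)],
        )
        members.insert(0, "participant_id", fit.participant_ids)
        members.insert(1, "cluster", [fit.hard_labels[p] for p in fit.participant_ids])
        members.to_csv(outdir / "membership.csv", index=False, float_format="%.10g")
        return grid

    grid = stage("fit")(_fit)
    fit = grid.selected

    # -- profile -----------------------------------------------------------
    def _profile():
        labels = fit.hard_labels
        course = daytime_means(filtered, labels)
        course.to_frame().to_csv(outdir / "daytime_courses.csv", index=False)
        for k in range(fit.n_clusters):
            heatmap_matrix(fit, k).to_csv(outdir / f"heatmap_cluster{k}.csv")
        return course

    stage("profile")(_profile)

    # -- characterize ------------------------------------------------------
    def _characterize():
        if traits is None:
            logger.info("no trait table; characterisation skipped")
            return None
        report = characterize_clusters(traits, fit.hard_labels)
        report["anova"].to_csv(outdir / "trait_anova.csv", index=False)
        rows = []
        for trait, contrasts in report["tukey"].items():
            for c in contrasts:
                rows.append(
                    {"trait": trait, "a": c.group_a, "b": c.group_b,
                     "delta": c.delta, "p": c.p,
                     "ci_low": c.ci_low, "ci_high": c.ci_high}
                )
        pd.DataFrame(rows).to_csv(outdir / "trait_contrasts.csv", index=False)
        if "gender_fisher_p" in report:
            (outdir / "gender_fisher.json").write_text(
                json.dumps({"p": report["gender_fisher_p"]})
            )
        return report

    stage("characterize")(_characterize)

    for f in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json")):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _digest(f)
    manifest.save(outdir / "manifest.json")
    return manifest
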