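"""One-command study driver: the full two-approach comparison.

Reproduces the study design end to end: generate (or load) a landscape
and occurrences; thin occurrences to a minimum inter-point distance;
build spatial folds; sample background; extract samples-with-data tables
for a fine ("targeted") and a coarse ("generalized") variable stack;
prefilter collinear variables; run nested forward-fold metric estimation
per approach; fit final models tuned by spatial CV on all folds; write
suitability and presence-absence maps; and compare the two approaches'
metrics and maps. Every stage writes its artifacts into the output
directory and is skipped on resume if its outputs already exist; the
manifest records the configuration, derived seeds, and stage decisions
so a run is exactly repeatable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ffme import compare_approaches, run_ffme
from .filtering import correlation_prefilter
from .maps import compare_maps
from .maxent import Maxent
from .metrics import max_tss_threshold
from .prep import assign_background_folds, make_folds, sample_background, thin
from .raster import write_stack
from .selection import ModelSettings, tune
from .swd import SWDTable, build_swd
from .synthetic import make_paired_stacks, sample_presences

__all__ = ["StudyConfig", "run_study"]


@dataclass
class StudyConfig:
    """All tunables of a study run; defaults mirror the reference design."""

    # synthetic landscape
    shape: tuple[int, int] = (128, 128)
    cell_size: float = 50.0
    corr_range: float = 300.0
    n_fine: int = 12
    n_coarse: int = 5
    n_true: int = 3
    n_presences: int = 1000
    clustering: int = 7
    # occurrence prep
    min_dist: float = 50.0
    k_folds: int = 7
    n_background: int = 50_000
    # filtering
    r_threshold: float = 0.7
    # evaluation
    n_test: int = 2
    settings: ModelSettings = field(default_factory=ModelSettings)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "settings" in d and isinstance(d["settings"], dict):
            d["settings"] = ModelSettings(**d["settings"])
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d


def _seed_stream(seed: int) -> dict[str, int]:
    """Named substream seeds, all below 2**31."""
    ss = np.random.SeedSequence(seed)
    names = ["landscape", "presences", "thin", "folds", "background", "ffme_fine", "ffme_coarse"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def run_study(config: StudyConfig, out_dir: str | Path, seed: int = 0, *, resume: bool = True) -> dict:
    """Execute the full two-approach study; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seed_stream(seed)
    manifest: dict = {
        "hsm_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "derived_seeds": seeds,
        "config": config.to_dict(),
        "stages": {},
    }

    # --- stage 1: landscape + occurrences -------------------------------
    fine, coarse, truth = make_paired_stacks(
        config.n_fine,
        config.n_coarse,
        shape=config.shape,
        cell_size=config.cell_size,
        corr_range=config.corr_range,
        seed=seeds["landscape"],
        n_true=config.n_true,
    )
    occ = sample_presences(
        truth, config.n_presences, clustering=config.clustering, seed=seeds["presences"]
    )
    manifest["stages"]["synth"] = {
        "n_fine": fine.n_layers,
        "n_coarse": coarse.n_layers,
        "valid_cells": fine.n_valid,
        "true_variables": sorted(truth.coefficients),
    }

    # --- stage 2: prep ---------------------------------------------------
    swd_paths = {a: out / f"swd_{a}.csv" for a in ("fine", "coarse")}
    if resume and all(p.exists() for p in swd_paths.values()):
        swds = {
            a: SWDTable.from_csv(p, categorical=stack.categorical)
            for (a, p), stack in zip(swd_paths.items(), (fine, coarse))
        }
        manifest["stages"]["prep"] = {"resumed": True}
    else:
        thinned = thin(occ, config.min_dist, seed=seeds["thin"])
        scheme = make_folds(thinned, config.k_folds, seed=seeds["folds"])
        occ_folded = thinned.with_fold(scheme.labels)
        bg = sample_background(fine, config.n_background, seed=seeds["background"])
        bg = assign_background_folds(bg, scheme)
        swds = {
            "fine": build_swd(fine, occ_folded, bg),
            "coarse": build_swd(coarse, occ_folded, bg),
        }
        for a, p in swd_paths.items():
            swds[a].to_csv(p)
        manifest["stages"]["prep"] = {
            "n_raw": len(occ),
            "n_thinned": len(thinned),
            "fold_sizes": scheme.sizes.tolist(),
            "n_background": config.n_background,
        }

    # --- stage 3: correlation prefilter ---------------------------------
    kept: dict[str, list[str]] = {}
    for a in ("fine", "coarse"):
        rep = correlation_prefilter(swds[a], config.r_threshold)
        kept[a] = rep.kept
        rep.to_csv(out / f"filter_{a}.csv")
        swds[a] = swds[a].subset_vars(rep.kept)
    manifest["stages"]["filter"] = {a: kept[a] for a in kept}

    # --- stage 4: ffme per approach --------------------------------------
    reports = {}
    for a in ("fine", "coarse"):
        csv_path = out / f"ffme_{a}.csv"
        report = run_ffme(
            swds[a], n_test=config.n_test, settings=config.settings, seed=seeds[f"ffme_{a}"]
        )
        report.to_csv(csv_path)
        reports[a] = report
        manifest["stages"][f"ffme_{a}"] = {
            "n_splits": len(report.rows),
            "mean": {k: float(v) for k, v in report.mean.items()},
        }

    comparison = compare_approaches(reports["fine"], reports["coarse"], names=("fine", "coarse"))
    comparison.to_csv(out / "ffme_comparison.csv", index=False)
    wins = {n: int((comparison["winner"] == n).sum()) for n in ("fine", "coarse")}
    manifest["stages"]["comparison"] = {
        "wins": wins,
        "deltas": dict(zip(comparison["metric"], comparison["delta"].astype(float))),
    }

    # --- stage 5: final maps ---------------------------------------------
    maps = {}
    thresholds = {}
    for a, stack in (("fine", fine), ("coarse", coarse)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = tune(swds[a], config.settings)
        model = Maxent(
            swds[a].subset_vars(result.variables),
            result.feature_classes,
            n_hinge_knots=config.settings.n_hinge_knots,
            n_threshold_knots=config.settings.n_threshold_knots,
        )
        fitted = model.fit(result.rm, max_iter=config.settings.max_iter,
                           tol=config.settings.tol, on_fail="warn")
        suit = fitted.predict(stack.subset(result.variables))
        pred = fitted.predict(swds[a])
        thresholds[a] = max_tss_threshold(pred, swds[a].is_presence)
        maps[a] = suit
        write_stack(suit, out / f"map_{a}", write_mask=False)
        fitted.to_json(out / f"model_{a}.json")
        manifest["stages"][f"final_{a}"] = {**result.as_dict(), "threshold": thresholds[a]}

    map_report = compare_maps(maps["fine"], maps["coarse"], thresholds["fine"], thresholds["coarse"])
    map_report.to_json(out / "map_comparison.json")
    manifest["stages"]["maps"] = json.loads(map_report.to_json())

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
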