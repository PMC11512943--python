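"""End-to-end experiment orchestration from a single configuration.

``run_experiment`` drives the whole chain — simulate → preprocess → folds →
train ensembles → predict → vote → uncertainty — across all five
cross-validation rotations and writes tidy CSV artifacts (fold-level
evaluation, CV summary, rejection curves, error-decrease table) plus a run
manifest with seeds and timings.  ``run_band_experiment`` repeats
band-restricted training over several runs and aggregates the three
per-band summaries (best fold, best run mean, overall mean).

Every stage seed derives deterministically from the experiment seed, so a
rerun with the same configuration reproduces all outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .bands import BAND_ORDER, BROADBAND
from .ensembles import (
    Ensemble,
    EnsembleSpec,
    build_depth_ensemble,
    build_frequency_ensemble,
    build_weight_ensemble,
    mcd_predict,
    pool_models,
)
from .evaluate import EvalResult, evaluate_tensor, make_folds, rotations, summarize_cv
from .models import (
    EpochClassifier,
    EpochDataset,
    ModelSpec,
    TrainingConfig,
)
from .preprocess import (
    DEFAULT_EXTRACT_SECONDS,
    DISCARD_INITIAL_SECONDS,
    preprocess_recording,
    segment_epochs,
    thin_training_epochs,
)
from .synthdata import CohortSpec, ConfigurationError, Recording, generate_cohort
from .uncertainty import DEFAULT_P_GRID, error_decrease, rejection_curve, summarize_table3

__all__ = ["ExperimentConfig", "run_experiment", "run_band_experiment", "band_report"]

log = logging.getLogger("eegens")


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    extract_seconds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXTRACT_SECONDS))
    discard_initial_s: float = DISCARD_INITIAL_SECONDS
    base_model: ModelSpec = field(default_factory=ModelSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    ensembles: tuple[EnsembleSpec, ...] = (
        EnsembleSpec(strategy="weights_uniform"),
    )
    schemes: tuple[str, ...] = ("ensemble_subject", "ensemble_epoch")
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    n_folds: int = 5
    n_repeat_runs: int = 3
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.base_model.validate()
        self.training.validate()
        for e in self.ensembles:
            e.validate()
        needed = self.discard_initial_s + max(self.extract_seconds.values())
        if self.cohort.duration < needed:
            raise ConfigurationError(
                f"cohort duration {self.cohort.duration}s cannot supply "
                f"{needed}s (discard + longest extraction)"
            )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "band_effects" in c:
                c["band_effects"] = {k: tuple(v) for k, v in c["band_effects"].items()}
            kwargs["cohort"] = CohortSpec(**c)
        if "base_model" in raw:
            m = dict(raw["base_model"])
            if "kernel_sizes" in m:
                m["kernel_sizes"] = tuple(m["kernel_sizes"])
            kwargs["base_model"] = ModelSpec(**m)
        if "training" in raw:
            kwargs["training"] = TrainingConfig(**raw["training"])
        if "ensembles" in raw:
            specs = []
            for e in raw["ensembles"]:
                e = dict(e)
                if "depths" in e:
                    e["depths"] = tuple(e["depths"])
                base = kwargs.get("base_model", ModelSpec())
                if e.pop("ads", None) or e.get("strategy") == "ads_mcd":
                    base = replace(base, ads=True)
                specs.append(EnsembleSpec(base=base, **e))
            kwargs["ensembles"] = tuple(specs)
        for key in ("extract_seconds", "discard_initial_s", "schemes", "p_grid",
                    "n_folds", "n_repeat_runs", "seed"):
            if key in raw:
                val = raw[key]
                kwargs[key] = tuple(val) if isinstance(val, list) else val
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _prepare_cohort(config: ExperimentConfig) -> list[Recording]:
    cohort = generate_cohort(replace(config.cohort, seed=config.cohort.seed))
    kept = []
    for rec in cohort:
        clean = preprocess_recording(rec)
        if clean is not None:
            kept.append(clean)
    n_rej = len(cohort) - len(kept)
    log.info("preprocess: kept %d/%d recordings (%d rejected by channel QC)",
             len(kept), len(cohort), n_rej)
    return kept


def _epoch_store(recordings: Mapping[str, Recording], subjects: Sequence[str],
                 role: str, config: ExperimentConfig,
                 band: str = BROADBAND) -> EpochDataset:
    arrays = []
    for s in subjects:
        ep = segment_epochs(recordings[s], config.extract_seconds[role], role,
                            discard_initial_s=config.discard_initial_s, band=band)
        if role == "train":
            ep = thin_training_epochs(ep)
        arrays.append(ep)
    return EpochDataset.from_epoch_arrays(arrays)


def _banded_stores(recordings: Mapping[str, Recording], subjects: Sequence[str],
                   role: str, config: ExperimentConfig,
                   bands: Sequence[str] = BAND_ORDER) -> dict[str, EpochDataset]:
    from .preprocess import bandpass
    from .bands import CANONICAL_BANDS

    per_band: dict[str, dict[str, Recording]] = {b: {} for b in bands}
    for s in subjects:
        for band in bands:
            bd = CANONICAL_BANDS[band]
            per_band[band][s] = bandpass(recordings[s], bd.low, bd.high)
    return {band: _epoch_store(per_band[band], subjects, role, config, band=band)
            for band in bands}


def _ensemble_name(spec: EnsembleSpec) -> str:
    return f"{spec.base.family}_{spec.strategy}"


def _build_ensemble(spec: EnsembleSpec, stores, banded, cfg: TrainingConfig,
                    prior_members) -> Ensemble:
    base = replace(spec.base, seed=cfg.seed)
    if spec.strategy in ("weights_uniform", "weights_normal"):
        dist = spec.strategy.split("_")[1]
        members = build_weight_ensemble(base, dist, stores["train"],
                                        stores["validation"], cfg, n=spec.n_members)
        return Ensemble(spec=spec, members=members, name=_ensemble_name(spec))
    if spec.strategy == "depth":
        members = build_depth_ensemble(base, stores["train"], stores["validation"],
                                       cfg, depths=spec.depths)
        return Ensemble(spec=spec, members=members, name=_ensemble_name(spec))
    if spec.strategy == "ads_mcd":
        member = EpochClassifier(replace(base, ads=True)).fit(
            stores["train"], stores["validation"], cfg)
        return Ensemble(spec=spec, members=[member], name=_ensemble_name(spec))
    if spec.strategy == "frequency":
        if banded is None:
            raise ConfigurationError("frequency ensemble needs banded epoch stores")
        members, report = build_frequency_ensemble(
            base, banded["train"], banded["validation"], cfg, top_k=spec.top_k)
        return Ensemble(spec=spec, members=members, name=_ensemble_name(spec),
                        selection_report=report)
    if spec.strategy == "model_pool":
        pool = list(prior_members)
        if len(pool) < 2:
            for fam, ads in (("inception", False), ("eegnet", False),
                             ("inception", True)):
                m = EpochClassifier(replace(base, family=fam, ads=ads)).fit(
                    stores["train"], stores["validation"], cfg)
                pool.append(m)
        pspec, members = pool_models(pool[:max(2, spec.n_members)])
        return Ensemble(spec=pspec, members=members, name=_ensemble_name(spec))
    raise ConfigurationError(f"unknown strategy {spec.strategy!r}")


def _assert_no_leakage(roles: Mapping[str, Sequence[str]], rotation: int) -> None:
    train, val, test = (set(roles[r]) for r in ("train", "validation", "test"))
    overlap = (train & val) | (train & test) | (val & test)
    if overlap:
        raise AssertionError(
            f"subject leakage in rotation {rotation}: {sorted(overlap)[:5]}"
        )


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig, outdir) -> Path:
    """Execute all rotations × ensembles × schemes; write result CSVs."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "simulate"
    try:
        recordings = {r.subject_id: r for r in _prepare_cohort(config)}
        subject_labels = {s: r.label for s, r in recordings.items()}
        stage = "folds"
        seeds = np.random.SeedSequence(config.seed).generate_state(2 + 10_000)
        split = make_folds(subject_labels, config.n_folds, seed=int(seeds[0] % 2**31))
        role_maps = rotations(split)
        needs_bands = any(e.strategy == "frequency" for e in config.ensembles)

        results: list[EvalResult] = []
        curves = []
        decreases = []
        for r, roles in enumerate(role_maps):
            stage = f"rotation {r}"
            _assert_no_leakage(roles, r)
            stores = {role: _epoch_store(recordings, roles[role], role, config)
                      for role in ("train", "validation", "test")}
            banded = None
            if needs_bands:
                banded = {role: _banded_stores(recordings, roles[role], role, config)
                          for role in ("train", "validation", "test")}
            prior_members = []
            test_labels = {s: subject_labels[s] for s in roles["test"]}
            for e_idx, espec in enumerate(config.ensembles):
                stage = f"rotation {r}, ensemble {espec.strategy}"
                t0 = time.time()
                cfg = replace(config.training,
                              seed=int(seeds[2 + r * 100 + e_idx] % 2**31))
                ens = _build_ensemble(espec, stores, banded, cfg, prior_members)
                if espec.strategy not in ("model_pool", "ads_mcd"):
                    prior_members.extend(ens.members[:2])
                if espec.strategy == "frequency":
                    tensor = ens.predict(banded["test"] | {BROADBAND: stores["test"]},
                                         seed=cfg.seed)
                else:
                    tensor = ens.predict(stores["test"], seed=cfg.seed)
                log.info("rotation %d %s: %d members trained+predicted in %.1fs",
                         r, ens.name, len(ens.members), time.time() - t0)
                for scheme in config.schemes:
                    res = evaluate_tensor(tensor, test_labels, scheme=scheme,
                                          fold=r, ensemble=ens.name)
                    results.append(res)
                    curve = rejection_curve(tensor, test_labels, scheme=scheme,
                                            p_grid=config.p_grid)
                    curve.insert(0, "fold", r)
                    curve.insert(0, "ensemble", ens.name)
                    curves.append(curve)
                    base_acc = curve.loc[curve.p_removed == 0,
                                         "per_subject_accuracy"]
                    acc0 = float(base_acc.iloc[0]) if len(base_acc) else \
                        res.per_subject_accuracy
                    for _, row in curve.iterrows():
                        if row.p_removed == 0:
                            continue
                        try:
                            dec = error_decrease(acc0, row.per_subject_accuracy)
                        except ZeroDivisionError:
                            dec = float("nan")
                        decreases.append({
                            "ensemble": ens.name, "scheme": scheme, "fold": r,
                            "p_removed": row.p_removed, "decrease": dec,
                        })
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage '{stage}': {exc}") from exc

    eval_df = pd.DataFrame([r.__dict__ for r in results])
    eval_df.to_csv(outdir / "evaluation.csv", index=False)
    summarize_cv(results).to_csv(outdir / "cv_summary.csv", index=False)
    curve_df = pd.concat(curves, ignore_index=True)
    curve_df.to_csv(outdir / "rejection_curve.csv", index=False)
    dec_df = pd.DataFrame(decreases)
    dec_df.to_csv(outdir / "error_decrease.csv", index=False)
    summarize_table3(dec_df).to_csv(outdir / "table3_summary.csv", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_subjects_kept": len(recordings),
        "n_folds": config.n_folds,
        "ensembles": [e.strategy for e in config.ensembles],
        "schemes": list(config.schemes),
        "p_grid": list(config.p_grid),
        "runtime_s": round(time.time() - t_start, 2),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def run_band_experiment(config: ExperimentConfig,
                        bands: Sequence[str] = BAND_ORDER,
                        n_folds_per_run: int | None = None) -> pd.DataFrame:
    """Per-band accuracies over ``n_repeat_runs`` runs × folds.

    Each run re-seeds model initialisation (fold assignment is generated
    once and shared, mirroring a fixed data split across runs).  Returns a
    tidy frame (band, run, fold, per_subject_accuracy).
    """
    config.validate()
    recordings = {r.subject_id: r for r in _prepare_cohort(config)}
    subject_labels = {s: r.label for s, r in recordings.items()}
    seeds = np.random.SeedSequence(config.seed).generate_state(1 + 10_000)
    split = make_folds(subject_labels, config.n_folds, seed=int(seeds[0] % 2**31))
    role_maps = rotations(split)
    if n_folds_per_run is not None:
        role_maps = role_maps[:n_folds_per_run]

    from .evaluate import subject_accuracy_from_probs

    rows = []
    for r, roles in enumerate(role_maps):
        _assert_no_leakage(roles, r)
        banded = {role: _banded_stores(recordings, roles[role], role, config, bands)
                  for role in ("train", "validation", "test")}
        for band in bands:
            for run in range(config.n_repeat_runs):
                model_seed = int(seeds[1 + r * 997 + run * 31] % 2**31)
                cfg = replace(config.training, seed=model_seed)
                base = replace(config.base_model, seed=model_seed)
                member = EpochClassifier(base, band=band).fit(
                    banded["train"][band], banded["validation"][band], cfg)
                te = banded["test"][band]
                probs = member.predict_proba(te)
                acc = subject_accuracy_from_probs(probs, te.subject_ids,
                                                  te.subject_labels)
                rows.append({"band": band, "run": run, "fold": r,
                             "per_subject_accuracy": acc})
    return pd.DataFrame(rows)


def band_report(accuracies: pd.DataFrame) -> pd.DataFrame:
    """The three per-band aggregates: best fold, best run mean, overall mean."""
    required = {"band", "run", "fold", "per_subject_accuracy"}
    if not required.issubset(accuracies.columns):
        raise ValueError(f"band accuracies need columns {sorted(required)}")
    rows = []
    for band, grp in accuracies.groupby("band", sort=False):
        run_means = grp.groupby("run")["per_subject_accuracy"].mean()
        rows.append({
            "band": band,
            "best_fold_accuracy": float(grp["per_subject_accuracy"].max()),
            "best_run_mean_accuracy": float(run_means.max()),
            "overall_mean_accuracy": float(grp["per_subject_accuracy"].mean()),
        })
    return pd.DataFrame(rows)
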