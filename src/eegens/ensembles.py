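"""Deep-ensemble construction strategies and the prediction tensor.

Five ways to obtain an ensemble of epoch classifiers:

* ``weights_uniform`` / ``weights_normal`` — the same architecture trained
  from 5 different random initial weights (uniform or normal initialiser);
* ``depth`` — one member per inception depth in (2, 4, 6, 8, 10);
* ``ads_mcd`` — a single ADS model whose Monte Carlo dropout forward passes
  act as implicit members (50 passes by default);
* ``model_pool`` — heterogeneous previously trained members pooled together;
* ``frequency`` — one member per canonical frequency band, with the top 3
  by validation performance composing the final ensemble.

Whatever the strategy, prediction produces the same object: a
members × epochs matrix of class-1 probabilities (:class:`PredictionTensor`)
that downstream voting and uncertainty code consumes without knowing how
the members were built.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BAND_ORDER, BROADBAND
from .models import (
    EpochClassifier,
    EpochDataset,
    ModelSpec,
    TrainedModel,
    TrainingConfig,
    _as_dataset,
)
from .synthdata import ConfigurationError

__all__ = [
    "EnsembleSpec",
    "PredictionTensor",
    "Ensemble",
    "build_weight_ensemble",
    "build_depth_ensemble",
    "build_frequency_ensemble",
    "mcd_predict",
    "pool_models",
    "ensemble_predict",
    "rank_bands",
]

STRATEGIES = ("weights_uniform", "weights_normal", "depth", "ads_mcd",
              "model_pool", "frequency")
DEFAULT_DEPTHS = (2, 4, 6, 8, 10)


@dataclass(frozen=True)
class EnsembleSpec:
    strategy: str
    n_members: int = 5
    depths: tuple[int, ...] = DEFAULT_DEPTHS
    n_forward: int = 50
    top_k: int = 3
    base: ModelSpec = field(default_factory=ModelSpec)

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(f"unknown ensemble strategy {self.strategy!r}")
        if self.strategy == "ads_mcd" and not self.base.ads:
            raise ConfigurationError("ads_mcd requires an ADS base model")
        if self.strategy == "depth" and not self.depths:
            raise ConfigurationError("depth ensemble needs a non-empty depth list")


@dataclass
class PredictionTensor:
    """Members × epochs matrix of class-1 probabilities."""

    probs: np.ndarray                 # [n_members, n_epochs]
    epoch_to_subject: np.ndarray      # [n_epochs] subject ids
    member_ids: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be a 2-D members × epochs matrix")
        if self.probs.shape[1] != len(self.epoch_to_subject):
            raise ValueError("epoch_to_subject length must match n_epochs")
        if self.probs.size and (self.probs.min() < 0 or self.probs.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_members(self) -> int:
        return self.probs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.probs.shape[1]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.epoch_to_subject:
            seen.setdefault(str(s), None)
        return list(seen)

    def epochs_of(self, subject: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.epoch_to_subject, dtype=object) == subject)

    def mean_probs(self) -> np.ndarray:
        """Per-epoch ensemble mean — the ensemble's point prediction."""
        return self.probs.mean(axis=0)


def _member_seeds(base_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(base_seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _fit_member(spec: ModelSpec, train_data, val_data, cfg, band, name):
    try:
        return EpochClassifier(spec, band=band).fit(train_data, val_data, cfg)
    except Exception as exc:
        raise RuntimeError(f"training of ensemble member {name!r} failed: {exc}") from exc


def build_weight_ensemble(base: ModelSpec, dist: str, train_data, val_data,
                          cfg: TrainingConfig = TrainingConfig(),
                          n: int = 5) -> list[TrainedModel]:
    """n architecturally identical members differing only in initial weights."""
    if n < 2:
        raise ConfigurationError("a weight ensemble needs at least 2 members")
    if dist not in ("uniform", "normal"):
        raise ConfigurationError("dist must be 'uniform' or 'normal'")
    scheme = f"random_{dist}"
    members = []
    for i, seed in enumerate(_member_seeds(base.seed, n)):
        spec = replace(base, init_scheme=scheme, seed=seed)
        members.append(_fit_member(spec, train_data, val_data, cfg, BROADBAND,
                                   f"weights_{dist}[{i}]"))
    return members


def build_depth_ensemble(base: ModelSpec, train_data, val_data,
                         cfg: TrainingConfig = TrainingConfig(),
                         depths: Sequence[int] = DEFAULT_DEPTHS) -> list[TrainedModel]:
    """One member per requested inception depth, in the given order."""
    if not depths:
        raise ConfigurationError("depth list must be non-empty")
    members = []
    for d in depths:
        spec = replace(base, depth=int(d))
        members.append(_fit_member(spec, train_data, val_data, cfg, BROADBAND,
                                   f"depth[{d}]"))
    return members


def rank_bands(scores: Mapping[str, float], top_k: int) -> list[str]:
    """Bands ordered by descending validation score; ties keep band order."""
    names = [b for b in BAND_ORDER if b in scores]
    names += [b for b in scores if b not in names]
    vals = np.array([scores[b] for b in names])
    order = np.argsort(-vals, kind="stable")
    return [names[i] for i in order[:top_k]]


def build_frequency_ensemble(base: ModelSpec, banded_train: Mapping[str, object],
                             banded_val: Mapping[str, object],
                             cfg: TrainingConfig = TrainingConfig(),
                             top_k: int = 3):
    """Train one member per canonical band; keep the ``top_k`` by validation.

    Validation performance is per-subject majority-vote accuracy on the
    member's own band-filtered validation epochs.  Returns the selected
    members plus a selection report with one row per band.
    """
    from .evaluate import subject_accuracy_from_probs

    for band in BAND_ORDER:
        if band not in banded_train or band not in banded_val:
            raise ValueError(f"missing epoch store for band {band!r}")
    scores: dict[str, float] = {}
    trained: dict[str, TrainedModel] = {}
    for band in BAND_ORDER:
        member = _fit_member(base, banded_train[band], banded_val[band], cfg,
                             band, f"frequency[{band}]")
        va = _as_dataset(banded_val[band])
        probs = member.predict_proba(va)
        scores[band] = subject_accuracy_from_probs(probs, va.subject_ids,
                                                   va.subject_labels)
        trained[band] = member
    selected = rank_bands(scores, top_k)
    report = pd.DataFrame({
        "band": list(BAND_ORDER),
        "val_subject_accuracy": [scores[b] for b in BAND_ORDER],
        "selected": [b in selected for b in BAND_ORDER],
    }).sort_values("val_subject_accuracy", ascending=False, kind="stable")
    report["rank"] = np.arange(1, len(report) + 1)
    return [trained[b] for b in selected], report.reset_index(drop=True)


def pool_models(members: Sequence[TrainedModel]) -> tuple[EnsembleSpec, list[TrainedModel]]:
    """Pool previously trained heterogeneous members into a model ensemble."""
    members = list(members)
    if len(members) < 2:
        raise ConfigurationError("a model pool needs at least 2 members")
    dims = {(m.n_channels, m.samples_per_epoch) for m in members}
    if len(dims) > 1:
        raise ConfigurationError(f"members disagree on input dimensions: {dims}")
    spec = EnsembleSpec(strategy="model_pool", n_members=len(members),
                        base=members[0].spec)
    return spec, members


def mcd_predict(trained: TrainedModel, epochs, n_forward: int = 50,
                seed: int = 0) -> PredictionTensor:
    """Monte Carlo dropout: stochastic forward passes as implicit members.

    Dropout in the ADS head stays active at prediction time; each forward
    pass is one row.  The per-epoch mean of the rows is the ensemble's
    point prediction downstream.
    """
    net = trained.network()
    if not net.has_mc_dropout:
        raise ConfigurationError("Monte Carlo dropout needs an ADS model "
                                 "(no dropout layer to sample)")
    if n_forward < 2:
        raise ConfigurationError("n_forward must be >= 2")
    ds = _as_dataset(epochs)
    rng = np.random.default_rng(seed)
    rows = np.empty((n_forward, ds.n_epochs))
    from ._nn import sigmoid
    for i in range(n_forward):
        out = []
        for j in range(0, ds.n_epochs, 1024):
            z = net.forward_logits(ds.X[j:j + 1024], mc=True, rng=rng)
            out.append(sigmoid(z))
        rows[i] = np.concatenate(out)
    return PredictionTensor(
        probs=rows,
        epoch_to_subject=np.asarray(ds.subject_ids, dtype=object),
        member_ids=[f"mc_pass[{i}]" for i in range(n_forward)],
    )


def _member_id(i: int, m: TrainedModel) -> str:
    s = m.spec
    tag = f"{s.family}_d{s.depth}" + ("_ads" if s.ads else "")
    if m.band != BROADBAND:
        tag += f"_{m.band}"
    return f"{tag}[{i}]"


def ensemble_predict(members: Sequence[TrainedModel], epochs) -> PredictionTensor:
    """Row i = member i's probabilities over all epochs.

    ``epochs`` is either one epoch store (every member sees the same input)
    or a mapping band → epoch store.  With a mapping, each member receives
    the store of its own band — the default route for frequency ensembles,
    where members trained on a band also see the test data filtered to that
    band — and broadband members receive the "broadband" store.  All stores
    must hold the same epochs of the same subjects in the same order.
    """
    members = list(members)
    if not members:
        raise ValueError("no ensemble members given")
    if isinstance(epochs, Mapping):
        stores = {k: _as_dataset(v) for k, v in epochs.items()}
        n_ep = {v.n_epochs for v in stores.values()}
        if len(n_ep) != 1:
            raise ValueError("banded epoch stores differ in epoch count")
        ref = next(iter(stores.values()))
    else:
        ds = _as_dataset(epochs)
        stores = None
        ref = ds
    rows = []
    for i, m in enumerate(members):
        data = stores[m.band if m.band in stores else BROADBAND] if stores else ref
        try:
            rows.append(m.predict_proba(data))
        except Exception as exc:
            raise RuntimeError(
                f"prediction failed for member {_member_id(i, m)}: {exc}"
            ) from exc
    return PredictionTensor(
        probs=np.vstack(rows),
        epoch_to_subject=np.asarray(ref.subject_ids, dtype=object),
        member_ids=[_member_id(i, m) for i, m in enumerate(members)],
    )


@dataclass
class Ensemble:
    """A built ensemble: strategy descriptor plus its trained members."""

    spec: EnsembleSpec
    members: list[TrainedModel]
    name: str = ""
    selection_report: pd.DataFrame | None = None

    def predict(self, epochs, seed: int = 0) -> PredictionTensor:
        if self.spec.strategy == "ads_mcd":
            return mcd_predict(self.members[0], epochs,
                               n_forward=self.spec.n_forward, seed=seed)
        return ensemble_predict(self.members, epochs)

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for i, m in enumerate(self.members):
            stem = f"member_{i:02d}"
            np.savez(directory / f"{stem}.npz",
                     **{f"w{j}": w for j, w in enumerate(m.weights)})
            meta = {
                "spec": {**m.spec.__dict__, "kernel_sizes": list(m.spec.kernel_sizes)},
                "band": m.band,
                "best_val_loss": m.best_val_loss,
                "n_channels": m.n_channels,
                "samples_per_epoch": m.samples_per_epoch,
                "stopped_at": m.stopped_at,
                "input_scale": m.input_scale,
            }
            (directory / f"{stem}.json").write_text(json.dumps(meta))
            entries.append(stem)
        manifest = {
            "strategy": self.spec.strategy,
            "name": self.name,
            "n_members": len(self.members),
            "members": entries,
        }
        path = directory / "ensemble.json"
        path.write_text(json.dumps(manifest, indent=1))
        return path

    @classmethod
    def load(cls, directory) -> "Ensemble":
        directory = Path(directory)
        manifest = json.loads((directory / "ensemble.json").read_text())
        members = []
        for stem in manifest["members"]:
            meta = json.loads((directory / f"{stem}.json").read_text())
            sd = meta["spec"]
            sd["kernel_sizes"] = tuple(sd["kernel_sizes"])
            spec = ModelSpec(**sd)
            with np.load(directory / f"{stem}.npz") as z:
                weights = [z[f"w{j}"] for j in range(len(z.files))]
            members.append(TrainedModel(
                spec=spec, weights=weights,
                best_val_loss=meta["best_val_loss"], history={},
                n_channels=meta["n_channels"],
                samples_per_epoch=meta["samples_per_epoch"],
                band=meta["band"], stopped_at=meta["stopped_at"],
                input_scale=meta.get("input_scale", 1.0),
            ))
        spec = EnsembleSpec(strategy=manifest["strategy"],
                            n_members=manifest["n_members"],
                            base=members[0].spec)
        return cls(spec=spec, members=members, name=manifest.get("name", ""))
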