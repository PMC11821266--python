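"""Bias-only baseline predictors for binding affinity.

Four baselines, each a tree-ensemble regressor over features that carry
no 3D interaction information, so anything they predict correctly is
attributable to dataset bias rather than learned biophysics:

* ``ligand`` view ("LigandBias"): 2D ligand descriptors only.  By
  construction it predicts the same pK for a ligand no matter which
  protein it is paired with.
* ``pocket`` view ("ProteinBias"): pocket amino-acid composition only.
* ``both`` view ("BothBias"): the concatenation of the two.
* "EnsembleBias": the (by default unweighted) mean of a ligand-view and
  a pocket-view model's predictions — see :func:`ensemble_predict`.

Hyperparameters are chosen over a small fixed grid of tree-ensemble
configurations by K-fold cross-validated RMSE, then the winner is refit
on all non-excluded records.  Everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold

from .featurize import (
    DescriptorSchema,
    build_descriptor_schema,
    concat_features,
    ligand_descriptors,
    pocket_residue_counts,
)
from .io import ComplexRecord

__all__ = [
    "VIEWS",
    "TrainConfig",
    "BiasModel",
    "train_bias_model",
    "predict",
    "ensemble_predict",
    "save_model",
    "load_model",
    "default_candidate_grid",
]

VIEWS = ("ligand", "pocket", "both")


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration for one bias model.

    ``excluded_ids`` are removed before fold assignment AND before the
    final refit (so a benchmark like a core set never leaks into
    training).  ``search_budget`` caps how many grid entries are tried;
    with a budget of 1 the single default configuration is fit directly
    without cross-validation.
    """

    cv_folds: int = 5
    excluded_ids: frozenset = frozenset()
    search_budget: int = 4
    seed: int = 0
    overflow_threshold: float = 1e8
    pocket_threshold_A: float = 15.0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.search_budget < 1:
            raise ValueError("search_budget must be >= 1")


def default_candidate_grid() -> list[tuple[str, dict]]:
    """The documented hyperparameter grid, in trial order."""
    return [
        ("rf", {"n_estimators": 200, "max_depth": None, "min_samples_leaf": 1}),
        ("rf", {"n_estimators": 200, "max_depth": 12, "min_samples_leaf": 2}),
        ("hgb", {"max_iter": 300, "learning_rate": 0.1}),
        ("hgb", {"max_iter": 300, "learning_rate": 0.05, "max_depth": 6}),
    ]


def _make_regressor(kind: str, params: dict, seed: int):
    if kind == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if kind == "hgb":
        return HistGradientBoostingRegressor(random_state=seed, **params)
    raise ValueError(f"unknown regressor kind {kind!r}")


@dataclass
class BiasModel:
    """A trained baseline predictor bound to its featurization recipe."""

    view: str
    regressor: object
    schema: DescriptorSchema | None
    pocket_threshold_A: float
    metadata: dict = field(default_factory=dict)
    _ligand_cache: dict = field(default_factory=dict, repr=False)

    def _ligand_vector(self, record: ComplexRecord) -> np.ndarray:
        key = record.ligand.inchikey
        if key not in self._ligand_cache:
            self._ligand_cache[key] = ligand_descriptors(record.ligand, self.schema)
        return self._ligand_cache[key]

    def featurize(self, record: ComplexRecord) -> np.ndarray:
        """One feature vector for one record, under this model's view.

        Ligand descriptors are cached by InChI-Key: they are functions of
        the 2D graph only, so all poses of a molecule share a vector.
        """
        if self.view == "ligand":
            return self._ligand_vector(record)
        pocket = pocket_residue_counts(
            record.protein, record.ligand, threshold_A=self.pocket_threshold_A
        )
        if self.view == "pocket":
            return pocket.as_vector()
        return concat_features(self._ligand_vector(record), pocket)

    def feature_matrix(self, records: Sequence[ComplexRecord]) -> np.ndarray:
        return np.vstack([self.featurize(r) for r in records])


def train_bias_model(
    records: Sequence[ComplexRecord],
    view: str,
    config: TrainConfig | None = None,
    candidates: list[tuple[str, dict]] | None = None,
) -> BiasModel:
    """Train one bias baseline.

    The grid (truncated to ``config.search_budget`` entries) is scored by
    ``cv_folds``-fold cross-validated RMSE; the best configuration is
    refit on every non-excluded record.  Requires at least
    ``10 * cv_folds`` records after exclusions.
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}, got {view!r}")
    config = config or TrainConfig()
    kept = [r for r in records if r.complex_id not in config.excluded_ids]
    if len(kept) < 10 * config.cv_folds:
        raise ValueError(
            f"need >= {10 * config.cv_folds} records after exclusions, have {len(kept)}"
        )
    y = np.array([r.label.pk for r in kept], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite pK label in training records")

    schema = None
    if view in ("ligand", "both"):
        by_key = {r.ligand.inchikey: r.ligand for r in kept}
        schema = build_descriptor_schema(
            list(by_key.values()), overflow_threshold=config.overflow_threshold
        )
    model = BiasModel(
        view=view,
        regressor=None,
        schema=schema,
        pocket_threshold_A=config.pocket_threshold_A,
    )
    X = model.feature_matrix(kept)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature after imputation")

    grid = (candidates or default_candidate_grid())[: config.search_budget]
    cv_scores: list[float] = []
    if len(grid) == 1:
        best_idx = 0
        cv_scores = [float("nan")]
    else:
        kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
        for kind, params in grid:
            sq_errs = []
            for train_ix, val_ix in kf.split(X):
                reg = _make_regressor(kind, params, config.seed)
                reg.fit(X[train_ix], y[train_ix])
                resid = reg.predict(X[val_ix]) - y[val_ix]
                sq_errs.append(np.mean(resid**2))
            cv_scores.append(float(np.sqrt(np.mean(sq_errs))))
        best_idx = int(np.argmin(cv_scores))
    kind, params = grid[best_idx]
    regressor = _make_regressor(kind, params, config.seed)
    regressor.fit(X, y)
    model.regressor = regressor
    model.metadata = {
        "view": view,
        "n_train": len(kept),
        "cv_folds": config.cv_folds,
        "seed": config.seed,
        "n_excluded": len(records) - len(kept),
        "chosen": {"kind": kind, "params": params},
        "grid_cv_rmse": cv_scores,
        "pocket_threshold_A": config.pocket_threshold_A,
    }
    return model


def predict(model: BiasModel, records: Sequence[ComplexRecord]) -> list[tuple[str, float]]:
    """Predicted pK per record, order preserved.

    A record that cannot be featurized yields NaN (with a warning) rather
    than silently disappearing.
    """
    out: list[tuple[str, float]] = []
    feats: list[np.ndarray] = []
    ids: list[str] = []
    statuses: list[bool] = []
    for rec in records:
        try:
            feats.append(model.featurize(rec))
            statuses.append(True)
        except Exception as exc:  # surfaced, never swallowed silently
            import warnings

            warnings.warn(f"featurization failed for {rec.complex_id}: {exc}", stacklevel=2)
            feats.append(None)
            statuses.append(False)
        ids.append(rec.complex_id)
    good = [i for i, ok in enumerate(statuses) if ok]
    preds = np.full(len(records), np.nan)
    if good:
        preds[good] = model.regressor.predict(np.vstack([feats[i] for i in good]))
    for cid, p in zip(ids, preds):
        out.append((cid, float(p)))
    return out


def ensemble_predict(
    model_a: BiasModel,
    model_b: BiasModel,
    records: Sequence[ComplexRecord],
    weights: tuple[float, float] = (0.5, 0.5),
) -> list[tuple[str, float]]:
    """Weighted mean of two members' predictions (default: unweighted).

    NaN from either member propagates with a warning.
    """
    wa, wb = weights
    total = wa + wb
    if total <= 0:
        raise ValueError("ensemble weights must sum to a positive number")
    pa = dict(predict(model_a, records))
    pb = dict(predict(model_b, records))
    out = []
    for rec in records:
        a, b = pa[rec.complex_id], pb[rec.complex_id]
        v = (wa * a + wb * b) / total
        if np.isnan(v):
            import warnings

            warnings.warn(f"NaN ensemble member prediction for {rec.complex_id}", stacklevel=2)
        out.append((rec.complex_id, float(v)))
    return out


def predictions_to_frame(preds: list[tuple[str, float]]) -> pd.DataFrame:
    return pd.DataFrame(preds, columns=["complex_id", "pred_pk"])


def save_model(model: BiasModel, path: str | Path) -> None:
    """Persist a model as a directory: metadata JSON + joblib'd regressor."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(model.metadata)
    meta["format_version"] = 1
    meta["view"] = model.view
    meta["pocket_threshold_A"] = model.pocket_threshold_A
    (path / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    if model.schema is not None:
        model.schema.save(path / "schema.json")
    joblib.dump(model.regressor, path / "regressor.joblib")


def load_model(path: str | Path) -> BiasModel:
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    schema = None
    if (path / "schema.json").exists():
        schema = DescriptorSchema.load(path / "schema.json")
    regressor = joblib.load(path / "regressor.joblib")
    return BiasModel(
        view=meta["view"],
        regressor=regressor,
        schema=schema,
        pocket_threshold_A=float(meta.get("pocket_threshold_A", 15.0)),
        metadata=meta,
    )
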