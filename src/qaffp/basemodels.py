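"""Per-target random-forest QSAR base models and their registry.

Each base model is trained on Morgan fingerprints against pIC50 with a seeded
70/30 train/test split.  Ten-fold cross-validation on the training portion
yields pooled out-of-fold predictions, from which we compute q² (squared
Pearson correlation of out-of-fold vs observed, by default) and the per-fold
absolute residuals that calibrate the model's cross-conformal predictor.  The
final regressor is refit on the whole training portion and scored on the
held-out 30% (R²_test).  Models enter the affinity-fingerprint panel only if
they clear both gates: q² > 0.5 and R²_test > 0.6.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, train_test_split

from qaffp.chemdata import CuratedDataset, DescriptorMatrix
from qaffp.conformal import ConformalCalibration, calibrate


@dataclass(frozen=True)
class ModelConfig:
    n_trees: int = 100
    cv_folds: int = 10
    test_fraction: float = 0.30
    seed: int = 0
    q2_variant: str = "pearson"  # or "press" (1 - PRESS/SS)
    confidence: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.q2_variant not in ("pearson", "press"):
            raise ValueError(f"unknown q2_variant {self.q2_variant!r}")


def rmse(observed, predicted) -> float:
    """Root mean squared error."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length and non-empty")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation; 0 when either vector is constant."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need >= 2 paired points")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return 0.0
    with warnings.catch_warnings():
        # guard against near-constant inputs where the correlation degenerates
        warnings.simplefilter("ignore")
        r = sps.pearsonr(obs, pred).statistic
    return float(r * r) if np.isfinite(r) else 0.0


def q_squared(observed, oof_predicted, variant: str = "pearson") -> float:
    """Cross-validation goodness-of-fit from pooled out-of-fold predictions."""
    if variant == "pearson":
        return r_squared(observed, oof_predicted)
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(oof_predicted, dtype=float)
    ss = float(np.sum((obs - obs.mean()) ** 2))
    if ss == 0:
        return 0.0
    press = float(np.sum((obs - pred) ** 2))
    return 1.0 - press / ss


@dataclass
class BaseModel:
    """A trained per-target regressor with its scores and conformal calibration."""

    model_id: str
    target_id: str
    endpoint: str
    regressor: RandomForestRegressor
    q2: float
    r2_test: float
    cv_oof: pd.DataFrame  # columns: compound_id, fold, observed, predicted
    calibration: ConformalCalibration
    config: ModelConfig
    selected: bool | None = None
    orthologue_group: str | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.regressor.predict(np.asarray(X, dtype=float))


def train_base_model(
    dataset: CuratedDataset,
    fingerprints: DescriptorMatrix,
    config: ModelConfig = ModelConfig(),
    model_id: str | None = None,
) -> BaseModel:
    """Train, cross-validate and conformally calibrate one base model."""
    n = len(dataset)
    minimum = config.cv_folds * 2
    if n < minimum:
        raise ValueError(
            f"dataset {dataset.dataset_id!r} has {n} compounds; "
            f"at least {minimum} required for {config.cv_folds}-fold CV"
        )
    ids = dataset.entries["compound_id"].tolist()
    X = fingerprints.subset_rows(ids).values
    y = dataset.entries["pIC50"].to_numpy(dtype=float)

    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=config.test_fraction, random_state=config.seed
    )
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]

    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    oof_rows = []
    fold_pairs = []
    for fold, (fit_i, val_i) in enumerate(kf.split(X_tr)):
        rf = RandomForestRegressor(
            n_estimators=config.n_trees, random_state=config.seed
        )
        rf.fit(X_tr[fit_i], y_tr[fit_i])
        pred = rf.predict(X_tr[val_i])
        fold_pairs.append((y_tr[val_i], pred))
        for local, p in zip(val_i, pred):
            oof_rows.append(
                {
                    "compound_id": ids[train_idx[local]],
                    "fold": fold,
                    "observed": float(y_tr[local]),
                    "predicted": float(p),
                }
            )
    oof = pd.DataFrame(oof_rows)
    q2 = q_squared(oof["observed"], oof["predicted"], config.q2_variant)
    calibration = calibrate(fold_pairs, confidence=config.confidence)

    final = RandomForestRegressor(
        n_estimators=config.n_trees, random_state=config.seed
    )
    final.fit(X_tr, y_tr)
    r2_test = r_squared(y_te, final.predict(X_te))

    return BaseModel(
        model_id=model_id or dataset.dataset_id,
        target_id=dataset.dataset_id,
        endpoint=dataset.endpoint,
        regressor=final,
        q2=q2,
        r2_test=r2_test,
        cv_oof=oof,
        calibration=calibration,
        config=config,
    )


@dataclass
class BaseModelRegistry:
    """Ordered collection of base models; order defines fingerprint bit order."""

    models: list[BaseModel] = field(default_factory=list)
    orthologue_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate model_ids in registry")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def get(self, model_id: str) -> BaseModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)

    @property
    def selected(self) -> list[BaseModel]:
        return [m for m in self.models if m.selected]

    def to_manifest(self) -> list[dict]:
        return [
            {
                "model_id": m.model_id,
                "target_id": m.target_id,
                "endpoint": m.endpoint,
                "q2": m.q2,
                "r2_test": m.r2_test,
                "selected": m.selected,
            }
            for m in self.models
        ]


def manifest_from_endpoint_counts(counts: dict[str, int]) -> list[dict]:
    """Stub registry manifest with one entry per dataset of each endpoint.

    Useful for sizing a panel before any model is trained: the ChEMBL-derived
    panel this framework was built around comprises EC50, IC50, Ki and Kd
    datasets whose per-endpoint counts sum to the fingerprint length.
    """
    manifest = []
    for endpoint, n in counts.items():
        for i in range(n):
            mid = f"{endpoint}_{i:04d}"
            manifest.append(
                {
                    "model_id": mid,
                    "target_id": mid,
                    "endpoint": endpoint,
                    "q2": None,
                    "r2_test": None,
                    "selected": None,
                }
            )
    return manifest


def select_models(
    registry: BaseModelRegistry, q2_min: float = 0.5, r2_min: float = 0.6
) -> BaseModelRegistry:
    """Flag models clearing both predictivity gates; order is unchanged."""
    for m in registry.models:
        if m.q2 is None or m.r2_test is None:
            raise ValueError(f"model {m.model_id!r} is unscored")
        m.selected = bool(m.q2 > q2_min and m.r2_test > r2_min)
    return registry


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_base_model(model: BaseModel, directory: Path | str) -> Path:
    """Persist regressor (joblib) plus a JSON sidecar of scores and calibration."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    artifact = directory / f"{model.model_id}.joblib"
    joblib.dump(model.regressor, artifact)
    sidecar = {
        "model_id": model.model_id,
        "target_id": model.target_id,
        "endpoint": model.endpoint,
        "q2": model.q2,
        "r2_test": model.r2_test,
        "selected": model.selected,
        "orthologue_group": model.orthologue_group,
        "config": {
            "n_trees": model.config.n_trees,
            "cv_folds": model.config.cv_folds,
            "test_fraction": model.config.test_fraction,
            "seed": model.config.seed,
            "q2_variant": model.config.q2_variant,
            "confidence": model.config.confidence,
        },
        "calibration": model.calibration.to_jsonable(),
        "cv_oof": model.cv_oof.to_dict(orient="list"),
        "artifact_path": artifact.name,
    }
    with open(directory / f"{model.model_id}.json", "w") as fh:
        json.dump(sidecar, fh)
    return artifact


def load_base_model(directory: Path | str, model_id: str) -> BaseModel:
    directory = Path(directory)
    with open(directory / f"{model_id}.json") as fh:
        sc = json.load(fh)
    regressor = joblib.load(directory / sc["artifact_path"])
    return BaseModel(
        model_id=sc["model_id"],
        target_id=sc["target_id"],
        endpoint=sc["endpoint"],
        regressor=regressor,
        q2=sc["q2"],
        r2_test=sc["r2_test"],
        cv_oof=pd.DataFrame(sc["cv_oof"]),
        calibration=ConformalCalibration.from_jsonable(sc["calibration"]),
        config=ModelConfig(**sc["config"]),
        selected=sc["selected"],
        orthologue_group=sc.get("orthologue_group"),
    )


def save_registry(registry: BaseModelRegistry, directory: Path | str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in registry.models:
        save_base_model(m, directory)
    manifest = directory / "registry.json"
    with open(manifest, "w") as fh:
        json.dump(
            {
                "models": [m.model_id for m in registry.models],
                "orthologue_groups": registry.orthologue_groups,
            },
            fh,
        )
    return manifest


def load_registry(directory: Path | str) -> BaseModelRegistry:
    directory = Path(directory)
    with open(directory / "registry.json") as fh:
        meta = json.load(fh)
    models = [load_base_model(directory, mid) for mid in meta["models"]]
    return BaseModelRegistry(models, meta.get("orthologue_groups", {}))
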