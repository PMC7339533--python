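"""Balanced full-factorial benchmark of descriptor sets.

Every (dataset, descriptor set, replicate) cell trains one random-forest
regressor on a seeded 70/30 split and records test-set RMSE and R².  The
split seed is derived from the master seed, dataset id and replicate index
only — never from the descriptor — so within a replicate all descriptor sets
see the identical train/test partition, which is what makes the downstream
factorial contrast between descriptors fair.

Y-scrambling permutes the *training* labels before fitting (test labels stay
untouched) as a chance-correlation control, and the test-fraction sweep
re-runs replicates at alternative held-out fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from qaffp._seeds import derive_seed
from qaffp.chemdata import CuratedDataset, DescriptorMatrix


@dataclass(frozen=True)
class ExperimentDesign:
    dataset_ids: tuple[str, ...]
    descriptor_names: tuple[str, ...]
    n_replicates: int = 50
    test_fraction: float = 0.30
    n_trees: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class Job:
    dataset_id: str
    descriptor_name: str
    replicate: int
    split_seed: int  # shared across descriptor sets by construction


@dataclass
class ReplicateResult:
    dataset_id: str
    descriptor_name: str
    replicate: int
    rmse_test: float
    r2_test: float
    per_compound: pd.DataFrame  # compound_id, observed, predicted
    feature_importances: pd.Series  # named, sums to 1 (or all-zero fallback)


def enumerate_jobs(design: ExperimentDesign) -> list[Job]:
    """Cartesian product dataset x descriptor x replicate with derived seeds."""
    jobs = []
    for ds in design.dataset_ids:
        for rep in range(design.n_replicates):
            seed = derive_seed(design.master_seed, ds, rep)
            for desc in design.descriptor_names:
                jobs.append(Job(ds, desc, rep, seed))
    return jobs


def split_seed(design: ExperimentDesign, dataset_id: str, replicate: int) -> int:
    """The replicate's split seed (descriptor-independent by construction)."""
    return derive_seed(design.master_seed, dataset_id, replicate)


def run_replicate(
    dataset: CuratedDataset,
    descriptors: DescriptorMatrix,
    seed: int,
    design: ExperimentDesign,
    replicate: int = 0,
    scramble_training_labels: bool = False,
    scramble_seed: int | None = None,
    test_fraction: float | None = None,
) -> ReplicateResult:
    """Train and score one benchmark cell on a seeded split."""
    ids = dataset.entries["compound_id"].tolist()
    X = descriptors.subset_rows(ids).values
    y = dataset.entries["pIC50"].to_numpy(dtype=float)
    frac = design.test_fraction if test_fraction is None else test_fraction
    idx = np.arange(len(ids))
    train_idx, test_idx = train_test_split(idx, test_size=frac, random_state=seed)
    if len(test_idx) < 2:
        raise ValueError(
            f"degenerate split: {len(test_idx)} test compounds for "
            f"dataset {dataset.dataset_id!r}"
        )
    y_train = y[train_idx]
    if scramble_training_labels:
        rng = np.random.default_rng(seed if scramble_seed is None else scramble_seed)
        y_train = rng.permutation(y_train)

    rf = RandomForestRegressor(n_estimators=design.n_trees, random_state=seed)
    rf.fit(X[train_idx], y_train)
    pred = rf.predict(X[test_idx])
    obs = y[test_idx]

    from qaffp.basemodels import r_squared, rmse

    importances = pd.Series(rf.feature_importances_, index=descriptors.col_ids)
    return ReplicateResult(
        dataset_id=dataset.dataset_id,
        descriptor_name=descriptors.kind,
        replicate=replicate,
        rmse_test=rmse(obs, pred),
        r2_test=r_squared(obs, pred),
        per_compound=pd.DataFrame(
            {
                "compound_id": [ids[i] for i in test_idx],
                "observed": obs,
                "predicted": pred,
            }
        ),
        feature_importances=importances,
    )


def run_benchmark(
    datasets: dict[str, CuratedDataset],
    descriptor_matrices: dict[str, dict[str, DescriptorMatrix]],
    design: ExperimentDesign,
) -> list[ReplicateResult]:
    """Run the whole balanced design.

    ``descriptor_matrices[dataset_id][descriptor_name]`` holds the descriptor
    matrix of that dataset's compounds for that descriptor set.
    """
    results = []
    for ds_id in design.dataset_ids:
        dataset = datasets[ds_id]
        for rep in range(design.n_replicates):
            seed = split_seed(design, ds_id, rep)
            for desc in design.descriptor_names:
                mat = descriptor_matrices[ds_id][desc]
                results.append(
                    run_replicate(dataset, mat, seed, design, replicate=rep)
                )
    return results


def results_table(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    """Long-format summary table (one row per benchmark cell replicate)."""
    return pd.DataFrame(
        {
            "dataset": [r.dataset_id for r in results],
            "descriptor": [r.descriptor_name for r in results],
            "replicate": [r.replicate for r in results],
            "rmse_test": [r.rmse_test for r in results],
            "r2_test": [r.r2_test for r in results],
        }
    )


def predictions_table(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    """Per-compound test-set predictions pooled over replicates (long format)."""
    frames = []
    for r in results:
        df = r.per_compound.copy()
        df.insert(0, "dataset", r.dataset_id)
        df.insert(1, "descriptor", r.descriptor_name)
        df.insert(2, "replicate", r.replicate)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def y_scramble(
    dataset: CuratedDataset,
    descriptors: DescriptorMatrix,
    seeds: Sequence[int],
    design: ExperimentDesign,
) -> list[float]:
    """R²_test after permuting training labels, one value per seed."""
    if len(dataset) < 20:
        raise ValueError("y-scrambling needs >= 20 compounds")
    out = []
    for s in seeds:
        res = run_replicate(
            dataset,
            descriptors,
            seed=split_seed(design, dataset.dataset_id, 0),
            design=design,
            scramble_training_labels=True,
            scramble_seed=s,
        )
        out.append(res.r2_test)
    return out


def fraction_sweep(
    dataset: CuratedDataset,
    descriptor_matrices: dict[str, DescriptorMatrix],
    fractions: Sequence[float],
    design: ExperimentDesign,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Benchmark each descriptor set at each test fraction.

    Returns a long table (fraction, descriptor, replicate, rmse_test, r2_test)
    plus a per-fraction descriptor ranking by mean RMSE (column ``rank``).
    """
    reps = design.n_replicates if n_replicates is None else n_replicates
    rows = []
    for frac in fractions:
        if not 0 < frac < 1:
            raise ValueError(f"test fraction {frac} outside (0, 1)")
        for rep in range(reps):
            seed = derive_seed(design.master_seed, dataset.dataset_id, rep, frac)
            for name, mat in descriptor_matrices.items():
                res = run_replicate(
                    dataset, mat, seed, design, replicate=rep, test_fraction=frac
                )
                rows.append(
                    {
                        "fraction": frac,
                        "descriptor": name,
                        "replicate": rep,
                        "rmse_test": res.rmse_test,
                        "r2_test": res.r2_test,
                    }
                )
    df = pd.DataFrame(
        rows, columns=["fraction", "descriptor", "replicate", "rmse_test", "r2_test"]
    )
    if df.empty:
        df["rank"] = pd.Series(dtype=float)
        return df
    means = df.groupby(["fraction", "descriptor"])["rmse_test"].transform("mean")
    df["rank"] = (
        df.assign(_m=means)
        .groupby("fraction")["_m"]
        .rank(method="dense")
        .astype(int)
    )
    return df
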