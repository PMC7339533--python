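"""Structured run configuration, provenance stamps and the staged pipeline.

The pipeline chains simulate -> curate -> train-base -> build -> benchmark
-> analyze.  Every stage writes its artifacts plus a JSON provenance stamp
(config hash, input-file hashes, derived seed, timestamp); a completed stage
whose stamp matches the current config is skipped on re-run unless forced.
A single master seed fans out into per-stage seeds via stable hashing, so no
two stages share an RNG stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from qaffp import basemodels, benchmark, chemdata, qaffp, stats, synthdata
from qaffp._seeds import derive_seed

log = logging.getLogger("qaffp")

STAGES = ("simulate", "curate", "train-base", "build", "benchmark", "analyze")
_STAGE_DEPS = {
    "simulate": (),
    "curate": ("simulate",),
    "train-base": ("curate",),
    "build": ("train-base",),
    "benchmark": ("build",),
    "analyze": ("benchmark",),
}


@dataclass
class RunConfig:
    out_dir: str = "qaffp_run"
    master_seed: int = 0
    synth: synthdata.SynthConfig = field(default_factory=synthdata.SynthConfig)
    curation: chemdata.CurationConfig = field(default_factory=chemdata.CurationConfig)
    model: basemodels.ModelConfig = field(default_factory=basemodels.ModelConfig)
    build: qaffp.QAFFPBuildConfig = field(default_factory=qaffp.QAFFPBuildConfig)
    n_replicates: int = 5
    n_trees: int = 100
    test_fraction: float = 0.30
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("synth", synthdata.SynthConfig),
            ("curation", chemdata.CurationConfig),
            ("model", basemodels.ModelConfig),
            ("build", qaffp.QAFFPBuildConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            return obj

        return enc(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stamp_path(out_dir: Path, stage: str) -> Path:
    return out_dir / f"{stage}.provenance.json"


def _write_stamp(out_dir: Path, stage: str, config: RunConfig, inputs: list[Path]) -> None:
    stamp = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "input_hashes": {str(p): _file_hash(p) for p in inputs if p.exists()},
        "seed": derive_seed(config.master_seed, stage),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(_stamp_path(out_dir, stage), "w") as fh:
        json.dump(stamp, fh, indent=1)


def _stage_done(out_dir: Path, stage: str, config: RunConfig) -> bool:
    p = _stamp_path(out_dir, stage)
    if not p.exists():
        return False
    try:
        stamp = json.loads(p.read_text())
    except json.JSONDecodeError:
        return False
    return stamp.get("config_hash") == config.config_hash()


class MissingDependencyError(RuntimeError):
    pass


def run_pipeline(config: RunConfig, stages: list[str], force: bool = False) -> Path:
    """Execute the requested stages in order; returns the output directory."""
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    stages = sorted(set(stages), key=STAGES.index)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config_echo.json", "w") as fh:
        json.dump(config.to_jsonable(), fh, indent=1)

    for stage in stages:
        for dep in _STAGE_DEPS[stage]:
            if dep not in stages and not _stage_done(out_dir, dep, config):
                raise MissingDependencyError(
                    f"stage {stage!r} requires completed stage {dep!r}; "
                    f"run it first"
                )
        if not force and _stage_done(out_dir, stage, config):
            log.info("stage %s already complete, skipping", stage)
            continue
        log.info("running stage %s", stage)
        _RUNNERS[stage](config, out_dir)
    return out_dir


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _run_simulate(config: RunConfig, out_dir: Path) -> None:
    synth = dataclasses.replace(
        config.synth, seed=derive_seed(config.master_seed, "simulate")
    )
    records, molecules, truth = synthdata.generate_target_datasets(synth)
    cell = synthdata.generate_cell_line_datasets(synth, molecules, truth)
    records.to_csv(out_dir / "target_records.csv", index=False)
    cell.to_csv(out_dir / "cell_line_records.csv", index=False)
    pd.DataFrame(molecules, columns=["compound_id", "smiles"]).to_csv(
        out_dir / "molecules.csv", index=False
    )
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_jsonable(), fh)
    _write_stamp(out_dir, "simulate", config, [])


def _run_curate(config: RunConfig, out_dir: Path) -> None:
    inputs = [out_dir / "target_records.csv", out_dir / "cell_line_records.csv"]
    targets = chemdata.read_bioactivity_csv(inputs[0])
    cell = chemdata.read_bioactivity_csv(inputs[1])
    molecules = chemdata.standardize_table(pd.concat([targets, cell]))
    curated_t = chemdata.curate_all(targets, molecules, config.curation)
    endpoint_cfg = dataclasses.replace(config.curation, mode="endpoint_dataset")
    curated_c = chemdata.curate_all(cell, molecules, endpoint_cfg)
    cur_dir = out_dir / "curated"
    cur_dir.mkdir(exist_ok=True)
    for name, ds in {**curated_t, **curated_c}.items():
        ds.to_csv(cur_dir / f"{name}.csv")
    with open(out_dir / "curation_provenance.json", "w") as fh:
        json.dump(
            {k: v.provenance for k, v in {**curated_t, **curated_c}.items()}, fh
        )
    _write_stamp(out_dir, "curate", config, inputs)


def _load_curated(out_dir: Path, prefix: str) -> dict[str, chemdata.CuratedDataset]:
    out = {}
    for p in sorted((out_dir / "curated").glob(f"{prefix}*.csv")):
        entries = pd.read_csv(p, dtype={"compound_id": str})
        out[p.stem] = chemdata.CuratedDataset(p.stem, "IC50", entries)
    return out


def _morgan_for(datasets: dict[str, chemdata.CuratedDataset]) -> dict[str, chemdata.DescriptorMatrix]:
    mats = {}
    for name, ds in datasets.items():
        mols = [
            chemdata.standardize_molecule(s, "smiles", c)
            for c, s in ds.entries[["compound_id", "std_smiles"]].itertuples(index=False)
        ]
        mats[name] = chemdata.morgan_fingerprints(mols)
    return mats


def _run_train_base(config: RunConfig, out_dir: Path) -> None:
    datasets = _load_curated(out_dir, "T")
    mats = _morgan_for(datasets)
    models = []
    for i, (name, ds) in enumerate(sorted(datasets.items())):
        cfg = dataclasses.replace(
            config.model, seed=derive_seed(config.master_seed, "train-base", name)
        )
        models.append(basemodels.train_base_model(ds, mats[name], cfg))
    registry = basemodels.BaseModelRegistry(models)
    basemodels.select_models(registry)
    basemodels.save_registry(registry, out_dir / "registry")
    with open(out_dir / "registry_manifest.json", "w") as fh:
        json.dump(registry.to_manifest(), fh, indent=1)
    _write_stamp(out_dir, "train-base", config, [])


def _run_build(config: RunConfig, out_dir: Path) -> None:
    registry = basemodels.load_registry(out_dir / "registry")
    cell = _load_curated(out_dir, "CL")
    mats = _morgan_for(cell)
    build_dir = out_dir / "qaffp"
    build_dir.mkdir(exist_ok=True)
    for name, mat in mats.items():
        rv = qaffp.build_rv_qaffp(mat, registry, config.build)
        rv.to_csv(build_dir / f"{name}_rv.csv")
        qaffp.binarize(rv, config.build).to_csv(build_dir / f"{name}_b.csv")
    _write_stamp(out_dir, "build", config, [])


def _run_benchmark(config: RunConfig, out_dir: Path) -> None:
    registry = basemodels.load_registry(out_dir / "registry")
    cell = _load_curated(out_dir, "CL")
    morgan = _morgan_for(cell)
    design = benchmark.ExperimentDesign(
        dataset_ids=tuple(sorted(cell)),
        descriptor_names=("rv_qaffp", "b_qaffp", "morgan2"),
        n_replicates=config.n_replicates,
        test_fraction=config.test_fraction,
        n_trees=config.n_trees,
        master_seed=derive_seed(config.master_seed, "benchmark"),
    )
    descriptor_matrices: dict[str, dict[str, chemdata.DescriptorMatrix]] = {}
    for name, mat in morgan.items():
        rv = qaffp.build_rv_qaffp(mat, registry, config.build)
        descriptor_matrices[name] = {
            "rv_qaffp": rv.to_descriptor_matrix(),
            "b_qaffp": qaffp.binarize(rv, config.build).to_descriptor_matrix(),
            "morgan2": mat,
        }
    results = benchmark.run_benchmark(cell, descriptor_matrices, design)
    table = benchmark.results_table(results)
    # stable descriptor names regardless of matrix kind strings
    table.to_csv(out_dir / "benchmark_results.csv", index=False)
    benchmark.predictions_table(results).to_csv(
        out_dir / "benchmark_predictions.csv", index=False
    )
    _write_stamp(out_dir, "benchmark", config, [])


def _run_analyze(config: RunConfig, out_dir: Path) -> None:
    table = pd.read_csv(out_dir / "benchmark_results.csv")
    ref = (sorted(table["dataset"].unique())[0], "morgan2")
    fit = stats.fit_factorial(table, ref)
    report = {
        "reference_levels": list(ref),
        "intercept": fit.intercept,
        "adjusted_r2": fit.adjusted_r2,
        "residual_se": fit.residual_se,
        "interaction_pvalue": fit.interaction_pvalue,
        "coefficients": {
            term: {
                "coef": float(row["coef"]),
                "std_err": float(row["std_err"]),
                "p_value": float(row["p_value"]),
            }
            for term, row in fit.coef_table.iterrows()
        },
    }
    with open(out_dir / "factorial_fit.json", "w") as fh:
        json.dump(report, fh, indent=1)
    diag = stats.diagnostics(fit)
    diag.residual_vs_fitted.to_csv(out_dir / "residual_vs_fitted.csv", index=False)
    diag.qq.to_csv(out_dir / "qq.csv", index=False)
    _write_stamp(out_dir, "analyze", config, [out_dir / "benchmark_results.csv"])


_RUNNERS = {
    "simulate": _run_simulate,
    "curate": _run_curate,
    "train-base": _run_train_base,
    "build": _run_build,
    "benchmark": _run_benchmark,
    "analyze": _run_analyze,
}
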