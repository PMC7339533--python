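"""Synthetic ChEMBL-like inputs with known ground truth.

Molecules come from a small scaffold-plus-substituent SMILES grammar, so
every structure parses, standardizes, and yields a diverse Morgan bit
pattern.  Per-target potencies are a sparse linear function of the
compound's Morgan bits plus Gaussian noise — by construction exactly
learnable by the fingerprint-based base models, which is the point: the
generator verifies the pipeline, it does not imitate medicinal chemistry.
Cell-line potencies are in turn a sparse linear function of the TRUE
per-target activities, so an affinity fingerprint built from well-trained
base models is predictive of them by construction.

The raw tables deliberately re-introduce the mess the curation stage must
handle: duplicate measurements with noise, non-"=" relation rows, and salt
counterions on a configurable fraction of structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qaffp._seeds import derive_seed
from qaffp.chemdata import (
    DescriptorMatrix,
    MoleculeRecord,
    morgan_fingerprints,
    standardize_molecule,
)

_SCAFFOLDS = (
    "c1cc({a})cc({b})c1{c}",
    "c1cc({a})ccc1{b}",
    "c1cc({a})cnc1{b}",
    "c1cc({a})no1",
    "C1CC({a})CCC1{b}",
    "c1ccc2c(c1)cc({a})cc2{b}",
    "O=C(N{a})c1ccc({b})cc1",
    "c1csc({a})c1{b}",
)

_SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "CO", "CCO", "OC", "OCC", "N", "NC",
    "NCC", "F", "Cl", "Br", "C#N", "C(F)(F)F", "C(=O)OC", "C(=O)NC",
    "SC", "CN(C)C", "O", "CCN", "C=C", "CC#N",
)

_COUNTERIONS = ("Cl", "Br", "OS(=O)(=O)O", "[Na+].[Cl-]", "CC(=O)O")


@dataclass(frozen=True)
class SynthConfig:
    n_targets: int = 5
    n_compounds_per_target: int = 300
    noise_sd: float = 0.0  # pIC50 units
    duplicate_rate: float = 0.1
    bad_relation_rate: float = 0.05
    salt_rate: float = 0.1
    n_cell_lines: int = 2
    cell_line_n_active_targets: int = 3  # sparsity of the latent map
    cell_line_weight_scale: float = 1.0
    cell_line_noise_sd: float = 0.0
    n_signal_bits: int = 8  # sparsity of the bit -> activity map
    coefficient_scale: float = 2.0  # pIC50 per active bit group
    baseline_pic50: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplicate_rate", "bad_relation_rate", "salt_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Serializable record of the generating coefficients."""

    signal_bits: dict[str, list[int]]  # target -> Morgan bit indices
    coefficients: dict[str, list[float]]  # target -> weights on those bits
    baseline: float
    true_activity: pd.DataFrame  # compounds x targets, noise-free pIC50
    cell_line_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    cell_line_true: pd.DataFrame | None = None

    def to_jsonable(self) -> dict:
        return {
            "signal_bits": self.signal_bits,
            "coefficients": self.coefficients,
            "baseline": self.baseline,
            "true_activity": self.true_activity.to_dict(orient="index"),
            "cell_line_weights": self.cell_line_weights,
            "cell_line_true": (
                None
                if self.cell_line_true is None
                else self.cell_line_true.to_dict(orient="index")
            ),
        }


def generate_molecules(
    n: int, seed: int, salt_rate: float = 0.0
) -> list[tuple[str, str]]:
    """Deterministically generate n distinct, parseable SMILES.

    A ``salt_rate`` fraction of the raw SMILES carry a counterion fragment
    that standardization must strip.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    i = 0
    while len(out) < n:
        scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
        subs = {
            key: _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
            for key in ("a", "b", "c")
        }
        smiles = scaffold.format(**subs)
        if smiles in seen:
            continue
        seen.add(smiles)
        if rng.random() < salt_rate:
            ion = _COUNTERIONS[rng.integers(len(_COUNTERIONS))]
            raw = f"{smiles}.{ion}"
        else:
            raw = smiles
        cid = f"CPD{i:06d}"
        rec = standardize_molecule(raw, "smiles", cid)
        if rec.rejected:  # pragma: no cover - grammar emits organics only
            continue
        out.append((cid, raw))
        i += 1
    return out


def _standardize_all(molecules: list[tuple[str, str]]) -> list[MoleculeRecord]:
    return [standardize_molecule(smi, "smiles", cid) for cid, smi in molecules]


def generate_target_datasets(
    config: SynthConfig,
) -> tuple[pd.DataFrame, list[tuple[str, str]], GroundTruth]:
    """Raw per-target bioactivity tables plus the generating ground truth.

    Returns ``(records, molecules, truth)`` where ``records`` is a raw
    bioactivity table in the chemdata CSV dialect (one block of
    ``n_compounds_per_target`` compounds per target, with duplicates, bad
    relations, and value noise applied), ``molecules`` the (compound_id,
    raw smiles) list, and ``truth`` the coefficient record.
    """
    n_total = config.n_targets * config.n_compounds_per_target
    molecules = generate_molecules(
        n_total, derive_seed(config.seed, "molecules"), config.salt_rate
    )
    records_mol = _standardize_all(molecules)
    fps = morgan_fingerprints(records_mol)

    rng = np.random.default_rng(derive_seed(config.seed, "targets"))
    signal_bits: dict[str, list[int]] = {}
    coefficients: dict[str, list[float]] = {}
    true_cols: dict[str, np.ndarray] = {}
    rows = []
    # pick signal bits among commonly-set bits so the signal is learnable
    bit_freq = fps.values.mean(axis=0)
    informative = np.where((bit_freq > 0.05) & (bit_freq < 0.95))[0]
    for t in range(config.n_targets):
        tid = f"T{t:03d}"
        bits = rng.choice(informative, size=config.n_signal_bits, replace=False)
        coefs = rng.normal(0.0, config.coefficient_scale, size=config.n_signal_bits)
        signal_bits[tid] = [int(b) for b in bits]
        coefficients[tid] = [float(c) for c in coefs]
        true = config.baseline_pic50 + fps.values[:, bits] @ coefs
        true_cols[tid] = true

        lo = t * config.n_compounds_per_target
        hi = lo + config.n_compounds_per_target
        for i in range(lo, hi):
            cid = molecules[i][0]
            pic50 = true[i] + rng.normal(0.0, config.noise_sd)
            n_meas = 2 if rng.random() < config.duplicate_rate else 1
            for _ in range(n_meas):
                meas = pic50 + rng.normal(0.0, min(config.noise_sd, 0.1))
                relation = ">" if rng.random() < config.bad_relation_rate else "="
                rows.append(
                    {
                        "compound_id": cid,
                        "smiles": molecules[i][1],
                        "target_id": tid,
                        "endpoint": "IC50",
                        "value_nM": 10 ** (9.0 - meas),
                        "unit": "nM",
                        "relation": relation,
                        "molecule_type": "Small molecule",
                    }
                )
    truth = GroundTruth(
        signal_bits=signal_bits,
        coefficients=coefficients,
        baseline=config.baseline_pic50,
        true_activity=pd.DataFrame(
            true_cols, index=[cid for cid, _ in molecules]
        ),
    )
    return pd.DataFrame(rows), molecules, truth


def generate_cell_line_datasets(
    config: SynthConfig,
    molecules: list[tuple[str, str]],
    truth: GroundTruth,
    permute_labels: bool = False,
) -> pd.DataFrame:
    """Cell-line tables whose activity is a latent map of true target activities.

    Each cell line's pIC50 is a sparse linear combination (plus noise) of the
    compound's TRUE per-target activities, centred back onto the baseline
    scale.  ``permute_labels`` shuffles the compound-to-activity assignment —
    a null control under which no descriptor should be predictive.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "cell_lines"))
    target_ids = list(truth.true_activity.columns)
    cids = [cid for cid, _ in molecules]
    smiles = {cid: smi for cid, smi in molecules}
    activity = truth.true_activity.loc[cids]
    rows = []
    cl_true: dict[str, np.ndarray] = {}
    for c in range(config.n_cell_lines):
        cl_id = f"CL{c:02d}"
        k = min(config.cell_line_n_active_targets, len(target_ids))
        chosen = rng.choice(len(target_ids), size=k, replace=False)
        weights = rng.normal(0.0, config.cell_line_weight_scale, size=k)
        centred = activity.to_numpy()[:, chosen] - config.baseline_pic50
        values = config.baseline_pic50 + centred @ weights
        values = values + rng.normal(0.0, config.cell_line_noise_sd, size=len(values))
        if permute_labels:
            values = rng.permutation(values)
        truth.cell_line_weights[cl_id] = {
            target_ids[int(t)]: float(w) for t, w in zip(chosen, weights)
        }
        cl_true[cl_id] = values
        for cid, v in zip(cids, values):
            rows.append(
                {
                    "compound_id": cid,
                    "smiles": smiles[cid],
                    "target_id": cl_id,
                    "endpoint": "IC50",
                    "value_nM": 10 ** (9.0 - v),
                    "unit": "nM",
                    "relation": "=",
                    "molecule_type": "Small molecule",
                }
            )
    truth.cell_line_true = pd.DataFrame(cl_true, index=cids)
    return pd.DataFrame(rows)
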