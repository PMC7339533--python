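"""Compound and bioactivity curation, plus structural/physicochemical descriptors.

Standardization follows the common ChEMBL-style preprocessing rules: keep the
largest organic fragment (stripping counterions), reject entirely inorganic
entries, neutralize simple protonated/deprotonated acid and base groups, and
emit a canonical SMILES.  Bioactivity curation keeps only exact ("=") nM
measurements on small molecules, converts to pIC50 = −log10(value [M]), and
aggregates duplicate (compound, dataset) measurements by their mean — in
base-model mode a duplicated pair is discarded outright when the pIC50
standard deviation of its measurements reaches 0.5, a conservative guard
against irreproducible public data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

VALID_ENDPOINTS = frozenset({"IC50", "EC50", "Ki", "Kd"})

# Atoms carrying a formal charge that can be neutralized by adding/removing
# protons, excluding charge-separated (zwitterion-adjacent) motifs that must
# keep their charges to stay valid (e.g. nitro groups).
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


class StructureParseError(ValueError):
    """Raised when a raw structure string cannot be parsed."""


class EmptyDatasetError(ValueError):
    """Raised when curation drops every input record."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized structure with provenance flags.

    ``std_smiles`` is ``None`` exactly when the molecule was rejected as
    entirely inorganic; otherwise it is a single-fragment canonical SMILES.
    """

    compound_id: str
    raw_structure: str
    std_smiles: str | None
    flags: frozenset[str] = frozenset()

    @property
    def rejected(self) -> bool:
        return "rejected_inorganic" in self.flags


@dataclass(frozen=True)
class BioactivityRecord:
    compound_id: str
    target_id: str
    endpoint: str
    value_nM: float
    relation: str = "="
    molecule_type: str = "Small molecule"
    assay_id: str | None = None

    def __post_init__(self) -> None:
        if self.endpoint not in VALID_ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if not self.value_nM > 0:
            raise ValueError(f"value_nM must be positive, got {self.value_nM}")


@dataclass(frozen=True)
class CurationConfig:
    required_relation: str = "="
    required_unit: str = "nM"
    required_molecule_type: str = "Small molecule"
    duplicate_sd_threshold: float = 0.5
    mode: str = "base_model"  # or "endpoint_dataset"

    def __post_init__(self) -> None:
        if self.duplicate_sd_threshold <= 0:
            raise ValueError("duplicate_sd_threshold must be > 0")
        if self.mode not in ("base_model", "endpoint_dataset"):
            raise ValueError(f"unknown curation mode {self.mode!r}")


@dataclass
class CuratedDataset:
    """Per-dataset curated activities on the pIC50 scale.

    ``entries`` has columns (compound_id, std_smiles, pIC50), one row per
    compound.  ``provenance`` counts records dropped per filter; kept rows
    (pre-aggregation) plus drops always reconcile with the input count.
    """

    dataset_id: str
    endpoint: str
    entries: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


@dataclass
class DescriptorMatrix:
    """A dense named descriptor matrix (compounds x descriptors)."""

    kind: str
    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} cols"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate column ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="compound_id")

    def subset_rows(self, row_ids: Sequence[str]) -> "DescriptorMatrix":
        index = {r: i for i, r in enumerate(self.row_ids)}
        rows = [index[r] for r in row_ids]
        return DescriptorMatrix(self.kind, list(row_ids), list(self.col_ids), self.values[rows])


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def _is_organic(frag: Chem.Mol) -> bool:
    # organic = contains a carbon bonded to hydrogen or to another carbon
    for atom in frag.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        if atom.GetTotalNumHs() > 0:
            return True
        if any(nb.GetAtomicNum() == 6 for nb in atom.GetNeighbors()):
            return True
    return False


def _neutralize(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    if not matches:
        return mol, False
    mol = Chem.RWMol(mol)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h_count = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(h_count - charge)
        atom.UpdatePropertyCache()
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out, True


def standardize_molecule(
    raw: str, fmt: str = "smiles", compound_id: str = "?"
) -> MoleculeRecord:
    """Standardize one structure to a canonical, neutral, single-fragment SMILES.

    Parameters
    ----------
    raw:
        SMILES string or SDF/mol block.
    fmt:
        ``"smiles"`` or ``"sdf"``.
    compound_id:
        Used only for error messages and the returned record.

    Entirely inorganic inputs (no fragment with a C–H or C–C bond) are flagged
    ``rejected_inorganic`` and carry no standardized SMILES.  Multi-fragment
    inputs keep the largest organic fragment (most heavy atoms; ties broken by
    canonical SMILES order) and are flagged ``salt_stripped``.
    """
    if fmt == "smiles":
        mol = Chem.MolFromSmiles(raw)
    elif fmt == "sdf":
        mol = Chem.MolFromMolBlock(raw)
    else:
        raise ValueError(f"unknown structure format {fmt!r}")
    if mol is None:
        raise StructureParseError(f"cannot parse structure for record {compound_id!r}")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [f for f in frags if _is_organic(f)]
    if not organic:
        return MoleculeRecord(
            compound_id, raw, None, frozenset({"rejected_inorganic"})
        )

    flags: set[str] = set()
    if len(frags) > 1:
        flags.add("salt_stripped")
    # largest organic fragment; deterministic tie-break on canonical SMILES
    keep = max(
        organic,
        key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)),
    )
    keep, changed = _neutralize(keep)
    if changed:
        flags.add("neutralized")
    return MoleculeRecord(compound_id, raw, Chem.MolToSmiles(keep), frozenset(flags))


def standardize_table(
    table: pd.DataFrame,
    smiles_col: str = "smiles",
    id_col: str = "compound_id",
) -> dict[str, MoleculeRecord]:
    """Standardize every unique (compound_id, smiles) pair in a table."""
    records: dict[str, MoleculeRecord] = {}
    for cid, smi in (
        table[[id_col, smiles_col]].drop_duplicates(id_col).itertuples(index=False)
    ):
        records[str(cid)] = standardize_molecule(str(smi), "smiles", str(cid))
    return records


# ---------------------------------------------------------------------------
# Bioactivity curation
# ---------------------------------------------------------------------------

def to_pic50(value_nM: float) -> float:
    """Convert a potency in nM to pIC50 = −log10(value [M])."""
    if not value_nM > 0:
        raise ValueError(f"potency must be positive, got {value_nM}")
    return 9.0 - math.log10(value_nM)


def curate(
    records: Iterable[BioactivityRecord] | pd.DataFrame,
    molecules: dict[str, MoleculeRecord],
    config: CurationConfig = CurationConfig(),
    dataset_id: str | None = None,
) -> CuratedDataset:
    """Filter, convert, and aggregate bioactivity records for one dataset.

    Records failing the relation / unit / molecule-type filters, or whose
    molecule was rejected at standardization, are dropped and counted in
    ``provenance``.  Surviving values are converted to pIC50 and duplicate
    (compound, dataset) measurements replaced by their mean; in ``base_model``
    mode the compound is dropped entirely when the sample standard deviation
    of its duplicate pIC50 values is >= ``duplicate_sd_threshold``.
    """
    df = _records_frame(records)
    if df.empty:
        raise EmptyDatasetError("no input records")
    targets = df["target_id"].unique()
    if dataset_id is None:
        if len(targets) != 1:
            raise ValueError(
                f"records span {len(targets)} datasets; pass dataset_id or "
                "use curate_all"
            )
        dataset_id = str(targets[0])
    else:
        df = df[df["target_id"] == dataset_id]

    n_in = len(df)
    provenance = {
        "input": n_in,
        "bad_relation": 0,
        "bad_unit": 0,
        "bad_molecule_type": 0,
        "bad_endpoint": 0,
        "rejected_molecule": 0,
        "unstable_duplicates": 0,
    }

    mask_rel = df["relation"] == config.required_relation
    provenance["bad_relation"] = int((~mask_rel).sum())
    df = df[mask_rel]
    if "unit" in df.columns:
        mask_unit = df["unit"] == config.required_unit
        provenance["bad_unit"] = int((~mask_unit).sum())
        df = df[mask_unit]
    mask_type = df["molecule_type"] == config.required_molecule_type
    provenance["bad_molecule_type"] = int((~mask_type).sum())
    df = df[mask_type]
    mask_ep = df["endpoint"].isin(VALID_ENDPOINTS)
    provenance["bad_endpoint"] = int((~mask_ep).sum())
    df = df[mask_ep]

    def _resolvable(cid: str) -> bool:
        if cid not in molecules:
            raise KeyError(f"compound {cid!r} has no molecule record")
        return not molecules[cid].rejected

    mask_mol = df["compound_id"].map(_resolvable)
    provenance["rejected_molecule"] = int((~mask_mol).sum())
    df = df[mask_mol].copy()

    if df.empty:
        raise EmptyDatasetError(
            f"no records survive curation for dataset {dataset_id!r}: {provenance}"
        )

    df["pIC50"] = df["value_nM"].map(to_pic50)
    grouped = df.groupby("compound_id")["pIC50"]
    agg = grouped.agg(["mean", "std", "count"]).reset_index()
    if config.mode == "base_model":
        unstable = (agg["count"] > 1) & (
            agg["std"] >= config.duplicate_sd_threshold
        )
        provenance["unstable_duplicates"] = int(
            agg.loc[unstable, "count"].sum()
        )
        agg = agg[~unstable]
    if agg.empty:
        raise EmptyDatasetError(
            f"all compounds removed by duplicate filtering for {dataset_id!r}"
        )

    endpoint = df["endpoint"].iloc[0]
    entries = pd.DataFrame(
        {
            "compound_id": agg["compound_id"].astype(str),
            "std_smiles": [
                molecules[c].std_smiles for c in agg["compound_id"].astype(str)
            ],
            "pIC50": agg["mean"].astype(float),
        }
    ).reset_index(drop=True)
    provenance["kept"] = int(agg["count"].sum())
    return CuratedDataset(dataset_id, endpoint, entries, provenance)


def curate_all(
    records: Iterable[BioactivityRecord] | pd.DataFrame,
    molecules: dict[str, MoleculeRecord],
    config: CurationConfig = CurationConfig(),
) -> dict[str, CuratedDataset]:
    """Curate a multi-dataset table, one :class:`CuratedDataset` per target."""
    df = _records_frame(records)
    out: dict[str, CuratedDataset] = {}
    for tid in df["target_id"].unique():
        out[str(tid)] = curate(df, molecules, config, dataset_id=str(tid))
    return out


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = [
        {
            "compound_id": r.compound_id,
            "target_id": r.target_id,
            "endpoint": r.endpoint,
            "value_nM": r.value_nM,
            "relation": r.relation,
            "molecule_type": r.molecule_type,
            "assay_id": r.assay_id,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def read_bioactivity_csv(path) -> pd.DataFrame:
    """Read a bioactivity CSV/TSV in the package's standard dialect."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    rename = {
        "standard_value": "value_nM",
        "standard_units": "unit",
        "standard_relation": "relation",
    }
    return df.rename(columns=rename)


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def _require_standardized(molecules: Sequence[MoleculeRecord]) -> None:
    for m in molecules:
        if m.std_smiles is None:
            raise ValueError(
                f"compound {m.compound_id!r} was rejected at standardization "
                "and has no structure to featurize"
            )


def morgan_fingerprints(
    molecules: Sequence[MoleculeRecord], radius: int = 2, n_bits: int = 1024
) -> DescriptorMatrix:
    """Hashed circular (Morgan) fingerprints from standardized structures."""
    _require_standardized(molecules)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = np.zeros((len(molecules), n_bits), dtype=float)
    for i, m in enumerate(molecules):
        mol = Chem.MolFromSmiles(m.std_smiles)
        if mol is None:  # pragma: no cover - std_smiles is always parseable
            raise StructureParseError(
                f"standardized SMILES for {m.compound_id!r} failed to re-parse"
            )
        rows[i] = np.array(gen.GetFingerprint(mol), dtype=float)
    return DescriptorMatrix(
        kind=f"morgan{radius}",
        row_ids=[m.compound_id for m in molecules],
        col_ids=[f"morgan{radius}_{j}" for j in range(n_bits)],
        values=rows,
    )


def physchem_descriptor_names() -> list[str]:
    """The fixed, ordered list of 1-D/2-D physicochemical descriptor names."""
    return [name for name, _ in Descriptors._descList]


def physchem_descriptors(molecules: Sequence[MoleculeRecord]) -> DescriptorMatrix:
    """RDKit 1-D and 2-D physicochemical descriptors with median imputation.

    Non-finite descriptor values are imputed with the column median over the
    given set of molecules (zero when the whole column is non-finite); constant
    columns are retained, which is harmless for tree learners.
    """
    _require_standardized(molecules)
    names = physchem_descriptor_names()
    funcs = dict(Descriptors._descList)
    rows = np.empty((len(molecules), len(names)), dtype=float)
    for i, m in enumerate(molecules):
        mol = Chem.MolFromSmiles(m.std_smiles)
        for j, name in enumerate(names):
            try:
                rows[i, j] = float(funcs[name](mol))
            except Exception:
                rows[i, j] = np.nan
    # column-median imputation of NaN/inf
    rows[~np.isfinite(rows)] = np.nan
    for j in range(rows.shape[1]):
        col = rows[:, j]
        bad = np.isnan(col)
        if bad.any():
            med = np.nanmedian(col) if not bad.all() else 0.0
            col[bad] = med
    return DescriptorMatrix(
        kind="physchem",
        row_ids=[m.compound_id for m in molecules],
        col_ids=names,
        values=rows,
    )
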