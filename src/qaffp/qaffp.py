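"""Assembly of QSAR-derived affinity fingerprint (QAFFP) descriptor matrices.

The real-valued fingerprint (rv-QAFFP) of a compound is the vector of point
predictions across the base-model panel, with a companion matrix of conformal
interval half-widths.  The binary variant (b-QAFFP) sets a bit to 1 only when
the prediction exceeds the activity cutoff (default 5 pIC50, i.e. 10 µM) AND
the prediction lies inside the model's applicability domain — conformal
half-width strictly below the threshold (default 2 pIC50).  Out-of-domain
predictions become 0 under the assumption that an arbitrary compound is more
likely inactive than active on an arbitrary target.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from qaffp.basemodels import BaseModelRegistry
from qaffp.chemdata import DescriptorMatrix
from qaffp.conformal import half_width


@dataclass(frozen=True)
class QAFFPBuildConfig:
    variant: str = "rv"  # "rv" or "b"
    model_subset: str = "selected_only"  # "selected_only", "all", "r2_cutoff:<x>"
    activity_cutoff: float = 5.0  # pIC50
    ad_half_width_max: float = 2.0  # pIC50
    confidence: float = 0.90
    exclude_target: str | None = None
    use_orthologues: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("rv", "b"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not math.isfinite(self.activity_cutoff):
            raise ValueError("activity_cutoff must be finite")
        if not self.ad_half_width_max > 0:
            raise ValueError("ad_half_width_max must be > 0")


@dataclass
class QAFFPMatrix:
    """Compounds x base-models prediction matrix with interval half-widths."""

    variant: str
    row_ids: list[str]
    col_ids: list[str]  # base-model ids, registry order
    values: np.ndarray
    errors: np.ndarray | None = None  # conformal half-widths, same shape
    confidence: float = 0.90

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.row_ids), len(self.col_ids))
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != {shape}")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != shape:
                raise ValueError(f"errors shape {self.errors.shape} != {shape}")
            if np.nanmin(self.errors, initial=0.0) < 0:
                raise ValueError("half-widths must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_descriptor_matrix(self) -> DescriptorMatrix:
        suffix = "_bin" if self.variant == "b" else ""
        return DescriptorMatrix(
            kind=f"{self.variant}_qaffp",
            row_ids=list(self.row_ids),
            col_ids=[f"{c}{suffix}" for c in self.col_ids],
            values=self.values.copy(),
        )

    def to_csv(self, path) -> None:
        self.to_descriptor_matrix().to_csv(path)
        if self.errors is not None:
            err = DescriptorMatrix(
                kind="half_width",
                row_ids=list(self.row_ids),
                col_ids=[f"{c}_hw" for c in self.col_ids],
                values=self.errors,
            )
            p = str(path)
            err.to_csv(re.sub(r"(\.\w+)?$", r"_hw\1", p, count=1))


def subset_by_r2(registry: BaseModelRegistry, r2_cutoff: float) -> list[str]:
    """Model ids with R²_test >= cutoff, in registry order."""
    out = []
    for m in registry:
        if m.r2_test is None:
            raise ValueError(f"model {m.model_id!r} is unscored")
        if m.r2_test >= r2_cutoff:
            out.append(m.model_id)
    return out


def exclude_target(
    registry: BaseModelRegistry,
    target_id: str | None,
    orthologue_map: dict[str, str] | None = None,
) -> list[str]:
    """Model ids after removing a modeled target and its orthologues.

    ``target_id`` of ``None`` (a cell-line endpoint, which has no protein
    target) is a no-op.  With an orthologue map (target -> group), all targets
    sharing the excluded target's group are removed; without one, only exact
    matches are.
    """
    if target_id is None:
        return [m.model_id for m in registry]
    omap = orthologue_map or registry.orthologue_groups or {}
    group = omap.get(target_id)
    if group is None and target_id not in {m.target_id for m in registry}:
        import warnings

        warnings.warn(
            f"target {target_id!r} unknown to the registry; "
            "falling back to exact-match exclusion",
            stacklevel=2,
        )
    keep = []
    for m in registry:
        if m.target_id == target_id:
            continue
        if group is not None and omap.get(m.target_id) == group:
            continue
        keep.append(m.model_id)
    return keep


def _resolve_subset(registry: BaseModelRegistry, config: QAFFPBuildConfig) -> list[str]:
    if config.model_subset == "selected_only":
        ids = [m.model_id for m in registry if m.selected]
        reason = "selection gates (q2/r2)"
    elif config.model_subset == "all":
        ids = [m.model_id for m in registry]
        reason = "registry is empty"
    elif config.model_subset.startswith("r2_cutoff:"):
        cutoff = float(config.model_subset.split(":", 1)[1])
        ids = subset_by_r2(registry, cutoff)
        reason = f"r2_test cutoff {cutoff}"
    else:
        raise ValueError(f"unknown model_subset {config.model_subset!r}")
    if config.exclude_target is not None:
        omap = registry.orthologue_groups if config.use_orthologues else {}
        allowed = set(exclude_target(registry, config.exclude_target, omap))
        ids = [i for i in ids if i in allowed]
        reason += f" + exclusion of target {config.exclude_target!r}"
    if not ids:
        raise ValueError(f"no base models remain after {reason}")
    return ids


def build_rv_qaffp(
    fingerprints: DescriptorMatrix,
    registry: BaseModelRegistry,
    config: QAFFPBuildConfig = QAFFPBuildConfig(),
) -> QAFFPMatrix:
    """Predict every compound with every panel model; attach interval widths.

    ``fingerprints`` must be the same descriptor kind the base models were
    trained on (Morgan fingerprints of the standardized compounds).
    """
    model_ids = _resolve_subset(registry, config)
    n, k = len(fingerprints.row_ids), len(model_ids)
    values = np.zeros((n, k))
    errors = np.zeros((n, k))
    X = fingerprints.values
    for j, mid in enumerate(model_ids):
        model = registry.get(mid)
        if n:
            values[:, j] = model.predict(X)
        errors[:, j] = half_width(model.calibration, config.confidence)
    return QAFFPMatrix(
        variant="rv",
        row_ids=list(fingerprints.row_ids),
        col_ids=model_ids,
        values=values,
        errors=errors,
        confidence=config.confidence,
    )


def binarize(rv: QAFFPMatrix, config: QAFFPBuildConfig = QAFFPBuildConfig()) -> QAFFPMatrix:
    """Threshold an rv-QAFFP into the binary variant.

    bit = 1  iff  prediction > activity_cutoff  and  half-width < AD threshold
    (infinite half-widths are always outside the applicability domain).
    """
    if rv.errors is None:
        raise ValueError("rv-QAFFP has no interval half-width companion")
    in_ad = rv.errors < config.ad_half_width_max
    active = rv.values > config.activity_cutoff
    bits = (active & in_ad).astype(float)
    return QAFFPMatrix(
        variant="b",
        row_ids=list(rv.row_ids),
        col_ids=list(rv.col_ids),
        values=bits,
        errors=rv.errors.copy(),
        confidence=rv.confidence,
    )


def combine(a: DescriptorMatrix, b: DescriptorMatrix) -> DescriptorMatrix:
    """Horizontally concatenate two descriptor matrices over the same rows."""
    if list(a.row_ids) != list(b.row_ids):
        raise ValueError("row ids differ between the matrices being combined")
    if len(b.col_ids) == 0:
        return DescriptorMatrix(a.kind, list(a.row_ids), list(a.col_ids), a.values.copy())
    if len(a.col_ids) == 0:
        return DescriptorMatrix(b.kind, list(b.row_ids), list(b.col_ids), b.values.copy())
    return DescriptorMatrix(
        kind=f"combined:{a.kind}+{b.kind}",
        row_ids=list(a.row_ids),
        col_ids=list(a.col_ids) + list(b.col_ids),
        values=np.hstack([a.values, b.values]),
    )


@dataclass(frozen=True)
class DescriptorSetSpec:
    """One entry of the benchmark descriptor menu."""

    name: str
    parts: tuple[str, ...]  # primitive descriptor names to concatenate


QAFFP_PRIMITIVES = ("rv_qaffp_440", "b_qaffp_440", "rv_qaffp_1360")
BASELINE_PRIMITIVES = ("morgan2", "physchem")


def enumerate_descriptor_sets(include_qaffp: bool = True) -> list[DescriptorSetSpec]:
    """The full benchmark menu of descriptor sets.

    Three QAFFP variants and two structure-based baselines, plus every
    QAFFP x baseline combination: 11 descriptor sets in total (2 when the
    QAFFP variants are disabled).
    """
    specs = []
    if include_qaffp:
        for p in QAFFP_PRIMITIVES:
            specs.append(DescriptorSetSpec(p, (p,)))
    for b in BASELINE_PRIMITIVES:
        specs.append(DescriptorSetSpec(b, (b,)))
    if include_qaffp:
        for p in QAFFP_PRIMITIVES:
            for b in BASELINE_PRIMITIVES:
                specs.append(DescriptorSetSpec(f"{p}+{b}", (p, b)))
    return specs


def materialize_descriptor_set(
    spec: DescriptorSetSpec, primitives: dict[str, DescriptorMatrix]
) -> DescriptorMatrix:
    """Concatenate a spec's primitive matrices (given by name) into one."""
    missing = [p for p in spec.parts if p not in primitives]
    if missing:
        raise KeyError(f"descriptor set {spec.name!r} needs missing primitives {missing}")
    mat = primitives[spec.parts[0]]
    for p in spec.parts[1:]:
        mat = combine(mat, primitives[p])
    return DescriptorMatrix(spec.name, list(mat.row_ids), list(mat.col_ids), mat.values)
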