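"""QAFFP matrix assembly, binarization, subsetting and combination."""

import math

import numpy as np
import pytest

from qaffp.chemdata import DescriptorMatrix
from qaffp.qaffp import (
    QAFFPBuildConfig,
    QAFFPMatrix,
    binarize,
    build_rv_qaffp,
    combine,
    enumerate_descriptor_sets,
    exclude_target,
    materialize_descriptor_set,
    subset_by_r2,
)


class _Stub:
    """Minimal stand-in base model with a constant prediction."""

    def __init__(self, mid, r2=0.7, target=None, value=6.0, hw=1.0, selected=True):
        self.model_id = mid
        self.target_id = target or mid
        self.r2_test = r2
        self.q2 = 0.7
        self.selected = selected
        self._value = value
        self._hw = hw
        self.calibration = None

    def predict(self, X):
        return np.full(len(X), self._value)


class _StubRegistry:
    def __init__(self, models, orthologue_groups=None):
        self.models = models
        self.orthologue_groups = orthologue_groups or {}

    def __iter__(self):
        return iter(self.models)

    def get(self, mid):
        return next(m for m in self.models if m.model_id == mid)


def _registry(r2s=(0.65, 0.75, 0.85)):
    return _StubRegistry([_Stub(f"M{i}", r2=r) for i, r in enumerate(r2s)])


def _rv(values, errors):
    values = np.atleast_2d(values)
    return QAFFPMatrix(
        variant="rv",
        row_ids=[f"c{i}" for i in range(values.shape[0])],
        col_ids=[f"M{j}" for j in range(values.shape[1])],
        values=values,
        errors=np.atleast_2d(errors),
    )


class TestSubsetByR2:
    def test_zero_cutoff_keeps_all(self):
        assert subset_by_r2(_registry(), 0.0) == ["M0", "M1", "M2"]

    def test_impossible_cutoff_empty(self):
        assert subset_by_r2(_registry(), 1.01) == []

    def test_cutoff_08_keeps_one(self):
        assert subset_by_r2(_registry(), 0.8) == ["M2"]

    def test_nested(self):
        reg = _registry((0.1, 0.5, 0.7, 0.9))
        subsets = [set(subset_by_r2(reg, c)) for c in (0.0, 0.4, 0.6, 0.8)]
        for lo, hi in zip(subsets[1:], subsets[:-1]):
            assert lo <= hi


class TestExcludeTarget:
    def test_orthologue_group_removed(self):
        reg = _StubRegistry(
            [_Stub("T1"), _Stub("T1_ortho"), _Stub("T2")],
            {"T1": "G", "T1_ortho": "G"},
        )
        assert exclude_target(reg, "T1") == ["T2"]

    def test_exact_match_only_without_map(self):
        reg = _StubRegistry([_Stub("T1"), _Stub("T1_ortho"), _Stub("T2")])
        assert exclude_target(reg, "T1") == ["T1_ortho", "T2"]

    def test_cell_line_no_target_is_noop(self):
        reg = _StubRegistry([_Stub("T1"), _Stub("T2")])
        assert exclude_target(reg, None) == ["T1", "T2"]

    def test_unknown_target_warns(self):
        reg = _StubRegistry([_Stub("T1")])
        with pytest.warns(UserWarning, match="unknown"):
            assert exclude_target(reg, "Tx") == ["T1"]


class TestBuild:
    def _fps(self, n=3):
        return DescriptorMatrix(
            "morgan2", [f"c{i}" for i in range(n)], ["b0", "b1"], np.zeros((n, 2))
        )

    def test_subset_all_column_count(self, trained_base_model):
        model, _, fps = trained_base_model
        from qaffp.basemodels import BaseModelRegistry

        reg = BaseModelRegistry([model])
        rv = build_rv_qaffp(fps, reg, QAFFPBuildConfig(model_subset="all"))
        assert rv.shape == (len(fps.row_ids), 1)
        assert rv.col_ids == [model.model_id]
        assert np.isfinite(rv.values).all()

    def test_empty_compound_list_keeps_header(self, trained_base_model):
        model, _, fps = trained_base_model
        from qaffp.basemodels import BaseModelRegistry

        reg = BaseModelRegistry([model])
        empty = DescriptorMatrix("morgan2", [], fps.col_ids, np.zeros((0, 1024)))
        rv = build_rv_qaffp(empty, reg, QAFFPBuildConfig(model_subset="all"))
        assert rv.shape == (0, 1)
        assert rv.col_ids == [model.model_id]

    def test_empty_subset_raises(self):
        reg = _registry()
        for m in reg.models:
            m.selected = False
        with pytest.raises(ValueError, match="no base models"):
            build_rv_qaffp(self._fps(), reg, QAFFPBuildConfig())


class TestBinarize:
    # all eight (prediction vs cutoff) x (half-width vs AD) x (finite/inf) cases
    @pytest.mark.parametrize(
        "pred, hw, expected",
        [
            (6.0, 1.5, 1.0),  # active, inside AD
            (6.0, 2.5, 0.0),  # active, outside AD
            (6.0, math.inf, 0.0),  # active, infinite interval
            (6.0, 2.0, 0.0),  # active, boundary half-width (strict <)
            (4.0, 0.5, 0.0),  # inactive, inside AD
            (4.0, 2.5, 0.0),  # inactive, outside AD
            (4.0, math.inf, 0.0),  # inactive, infinite interval
            (5.0, 0.5, 0.0),  # boundary prediction (strict >)
        ],
    )
    def test_truth_table(self, pred, hw, expected):
        b = binarize(_rv([[pred]], [[hw]]))
        assert b.values[0, 0] == expected

    def test_missing_errors_companion(self):
        rv = QAFFPMatrix("rv", ["c0"], ["M0"], np.array([[6.0]]), errors=None)
        with pytest.raises(ValueError, match="half-width"):
            binarize(rv)

    def test_raising_cutoff_never_adds_bits(self, rng):
        values = rng.uniform(3, 8, size=(10, 6))
        errors = rng.uniform(0, 3, size=(10, 6))
        rv = _rv(values, errors)
        low = binarize(rv, QAFFPBuildConfig(activity_cutoff=4.0))
        high = binarize(rv, QAFFPBuildConfig(activity_cutoff=6.0))
        assert np.all(high.values <= low.values)

    def test_one_bits_only_above_cutoff(self, rng):
        rv = _rv(rng.uniform(3, 8, size=(8, 5)), rng.uniform(0, 3, size=(8, 5)))
        b = binarize(rv)
        assert np.all(rv.values[b.values == 1] > 5.0)


class TestCombine:
    def _mat(self, kind, cols, n=3, fill=1.0):
        return DescriptorMatrix(
            kind,
            [f"c{i}" for i in range(n)],
            [f"{kind}_{j}" for j in range(cols)],
            np.full((n, cols), fill),
        )

    def test_widths_add(self):
        c = combine(self._mat("a", 440), self._mat("b", 1024))
        assert len(c.col_ids) == 1464
        assert c.kind == "combined:a+b"

    def test_empty_identity(self):
        a = self._mat("a", 4)
        c = combine(a, self._mat("b", 0))
        assert c.col_ids == a.col_ids
        assert np.array_equal(c.values, a.values)

    def test_row_mismatch_raises(self):
        a = self._mat("a", 2)
        b = DescriptorMatrix("b", ["x", "y", "z"], ["b_0"], np.zeros((3, 1)))
        with pytest.raises(ValueError, match="row ids"):
            combine(a, b)


class TestDescriptorMenu:
    def test_eleven_specs(self):
        specs = enumerate_descriptor_sets()
        assert len(specs) == 11
        assert len({s.name for s in specs}) == 11

    def test_baselines_only(self):
        assert len(enumerate_descriptor_sets(include_qaffp=False)) == 2

    def test_combined_width_is_sum_of_parts(self):
        prims = {
            "rv_qaffp_440": DescriptorMatrix(
                "rv_qaffp_440", ["c0"], [f"m{i}" for i in range(5)], np.zeros((1, 5))
            ),
            "b_qaffp_440": DescriptorMatrix(
                "b_qaffp_440", ["c0"], [f"bm{i}" for i in range(5)], np.zeros((1, 5))
            ),
            "rv_qaffp_1360": DescriptorMatrix(
                "rv_qaffp_1360", ["c0"], [f"a{i}" for i in range(8)], np.zeros((1, 8))
            ),
            "morgan2": DescriptorMatrix(
                "morgan2", ["c0"], [f"f{i}" for i in range(16)], np.zeros((1, 16))
            ),
            "physchem": DescriptorMatrix(
                "physchem", ["c0"], [f"p{i}" for i in range(3)], np.zeros((1, 3))
            ),
        }
        for spec in enumerate_descriptor_sets():
            mat = materialize_descriptor_set(spec, prims)
            assert len(mat.col_ids) == sum(
                len(prims[p].col_ids) for p in spec.parts
            )


def test_exclusion_commutes_with_build(trained_base_model):
    """Excluding then building equals building then dropping the column."""
    model, _, fps = trained_base_model
    from qaffp.basemodels import BaseModel, BaseModelRegistry

    import copy

    other = copy.copy(model)
    other.model_id = "OTHER"
    other.target_id = "OTHER"
    reg = BaseModelRegistry([model, other])
    full = build_rv_qaffp(fps, reg, QAFFPBuildConfig(model_subset="all"))
    excl = build_rv_qaffp(
        fps,
        reg,
        QAFFPBuildConfig(model_subset="all", exclude_target=model.target_id),
    )
    keep = [j for j, c in enumerate(full.col_ids) if c != model.model_id]
    assert excl.col_ids == [full.col_ids[j] for j in keep]
    assert np.array_equal(excl.values, full.values[:, keep])
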