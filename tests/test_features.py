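import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rknet.errors import (
    AdapterUnavailableError,
    DimensionMismatchError,
    DuplicateSliceError,
    InvalidInputError,
)
from rknet.features import (
    EDGE_SLICE,
    GRID_SLICE,
    HIST_SLICE,
    REFERENCE_DIM,
    VAR_SLICE,
    ExtractorConfig,
    assemble_and_normalize,
    extract_cnn,
    extract_matrix,
    extract_reference,
    extract_slice,
    register_adapter,
    unregister_adapter,
    zscore_columns,
)

from conftest import make_slice


class TestReferenceExtractor:
    def test_dimension(self):
        row = extract_reference(make_slice(np.zeros((64, 64))))
        assert row.shape == (REFERENCE_DIM,)

    def test_all_zero_slice(self):
        row = extract_reference(make_slice(np.zeros((64, 64))))
        hist = row[HIST_SLICE]
        assert hist[0] == pytest.approx(1.0)
        assert np.all(hist[1:] == 0.0)
        np.testing.assert_allclose(row[GRID_SLICE], 0.0)
        np.testing.assert_allclose(row[EDGE_SLICE], 0.0, atol=1e-12)
        np.testing.assert_allclose(row[VAR_SLICE], 0.0, atol=1e-12)

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(3)
        pixels = rng.uniform(0, 1, size=(50, 50))
        a = extract_reference(make_slice(pixels))
        b = extract_reference(make_slice(pixels.copy()))
        np.testing.assert_array_equal(a, b)

    def test_variance_cells_oracle(self):
        # oracle: direct variance of the two grids. A half-0/half-1 image has
        # per-window variance up to 0.25; a uniform 0.5 image has none.
        half = np.zeros((64, 64))
        half[32:] = 1.0
        uniform = np.full((64, 64), 0.5)
        v_half = extract_reference(make_slice(half))[VAR_SLICE]
        v_uniform = extract_reference(make_slice(uniform))[VAR_SLICE]
        assert v_half.sum() > v_uniform.sum()
        # straddling window oracle: rows 11..42 hold 11 ones of 32 rows, so
        # the binary-image variance is p(1-p) with p = 11/32
        p = 11.0 / 32.0
        assert v_half.max() == pytest.approx(p * (1 - p), abs=1e-9)
        np.testing.assert_allclose(v_uniform, 0.0, atol=1e-12)

    def test_histogram_fractions_sum_to_one(self):
        rng = np.random.default_rng(11)
        row = extract_reference(make_slice(rng.uniform(0, 1, (64, 64))))
        assert row[HIST_SLICE].sum() == pytest.approx(1.0)

    def test_non_finite_rejected(self):
        pixels = np.zeros((16, 16))
        pixels[0, 0] = np.nan
        with pytest.raises(InvalidInputError, match="invalid input"):
            extract_reference(make_slice(pixels))

    def test_input_size_floor(self):
        with pytest.raises(InvalidInputError):
            ExtractorConfig(input_size=(4, 64))


class TestCnnAdapter:
    def test_mock_adapter_contract(self):
        # mock: per-channel sums; oracle = hand computation on a tiny image
        register_adapter("sums", lambda img: img.sum(axis=(0, 1)))
        try:
            pixels = np.full((16, 16), 0.25)
            cfg = ExtractorConfig(name="cnn-adapter", input_size=(16, 16),
                                  adapter_options={"adapter": "sums"})
            row = extract_cnn(make_slice(pixels), cfg)
            np.testing.assert_allclose(row, 0.25 * 16 * 16 * np.ones(3))
        finally:
            unregister_adapter("sums")

    def test_inference_determinism(self):
        register_adapter("mean", lambda img: np.array([img.mean(), img.std()]))
        try:
            cfg = ExtractorConfig(name="cnn-adapter", input_size=(16, 16),
                                  adapter_options={"adapter": "mean"})
            s = make_slice(np.random.default_rng(0).uniform(0, 1, (20, 20)))
            np.testing.assert_array_equal(extract_cnn(s, cfg), extract_cnn(s, cfg))
        finally:
            unregister_adapter("mean")

    def test_no_adapter_registered(self):
        cfg = ExtractorConfig(name="cnn-adapter", adapter_options={"adapter": "ghost"})
        with pytest.raises(AdapterUnavailableError, match="adapter unavailable"):
            extract_cnn(make_slice(np.zeros((16, 16))), cfg)

    def test_nan_embedding_surfaced_with_key(self):
        register_adapter("nan", lambda img: np.array([np.nan]))
        try:
            cfg = ExtractorConfig(name="cnn-adapter", adapter_options={"adapter": "nan"})
            s = make_slice(np.zeros((16, 16)), patient="PX", index=5)
            with pytest.raises(AdapterUnavailableError, match="PX"):
                extract_cnn(s, cfg)
        finally:
            unregister_adapter("nan")

    def test_fallback_to_reference(self):
        cfg = ExtractorConfig(name="cnn-adapter", input_size=(64, 64),
                              adapter_options={"adapter": "missing"})
        s = make_slice(np.zeros((64, 64)))
        row = extract_slice(s, cfg)
        assert row.shape == (REFERENCE_DIM,)


class TestAssembleAndNormalize:
    def test_two_point_zscore(self):
        m = assemble_and_normalize([np.array([0.0]), np.array([2.0])],
                                   [("P", "S", 0), ("P", "S", 1)])
        np.testing.assert_allclose(m.values, [[-1.0], [1.0]])

    def test_constant_column_zeroed(self):
        m = assemble_and_normalize([np.array([5.0, 1.0]), np.array([5.0, 3.0])],
                                   [("P", "S", 0), ("P", "S", 1)])
        np.testing.assert_allclose(m.values[:, 0], 0.0)

    def test_mean_sd_oracle(self):
        # oracle: direct mean/sd arithmetic on [[1,10],[2,20],[3,30]]
        rows = [np.array([1.0, 10.0]), np.array([2.0, 20.0]), np.array([3.0, 30.0])]
        m = assemble_and_normalize(rows, [("P", "S", i) for i in range(3)])
        np.testing.assert_allclose(m.values.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(m.values.std(axis=0), 1.0, atol=1e-6)

    def test_ragged_rows(self):
        with pytest.raises(DimensionMismatchError, match="dimension mismatch"):
            assemble_and_normalize([np.zeros(2), np.zeros(3)],
                                   [("P", "S", 0), ("P", "S", 1)])

    def test_duplicate_keys(self):
        with pytest.raises(DuplicateSliceError, match="duplicate slice"):
            assemble_and_normalize([np.zeros(2), np.zeros(2)],
                                   [("P", "S", 0), ("P", "S", 0)])

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(20, 6))
        once = zscore_columns(values)
        twice = zscore_columns(once)
        assert np.max(np.abs(twice - once)) <= 1e-8

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_normalized_invariant_holds(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(scale=rng.uniform(0.1, 50), size=(8, 4))
        out = zscore_columns(values)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-8)
        sd = out.std(axis=0)
        assert np.all((np.abs(sd - 1.0) < 1e-6) | (sd == 0.0))


class TestSeparability:
    def test_phantom_classes_separate(self, small_spec):
        # between-class mean distance must exceed within-class at s >= 2
        from rknet.pipeline import PipelineConfig
        from rknet.synthetic import generate_volume, truth_table

        cfg = ExtractorConfig()
        pc = PipelineConfig()
        lo = pc.window_center - pc.window_width / 2
        truth = truth_table(small_spec)
        relevant = {(r.patient_id, r.series_id, r.slice_index): r.relevant
                    for r in truth.slices.itertuples(index=False)}
        rows, labels = [], []
        for i in range(small_spec.n_patients):
            vol = generate_volume(small_spec, i)
            pid = f"P{i:03d}"
            for z in range(vol.shape[0]):
                pixels = np.clip((vol[z] - lo) / pc.window_width, 0, 1)
                rows.append(extract_reference(make_slice(pixels, patient=pid, index=z), cfg))
                labels.append(relevant[(pid, pid, z)])
        X = zscore_columns(np.asarray(rows))
        labels = np.asarray(labels)
        tumor, other = X[labels], X[~labels]

        def mean_dist(A, B):
            return np.mean(np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2))

        between = mean_dist(tumor, other)
        within = 0.5 * (mean_dist(tumor, tumor) + mean_dist(other, other))
        assert between > within


def test_extract_matrix_end_to_end(small_spec):
    from rknet.synthetic import generate_volume

    vol = generate_volume(small_spec, 0)
    slices = [make_slice(np.clip(vol[z] / 400 + 0.4, 0, 1), index=z)
              for z in range(vol.shape[0])]
    m = extract_matrix(slices)
    assert m.values.shape == (small_spec.n_slices, REFERENCE_DIM)
    assert m.normalized
    assert m.extractor_name == "reference"
    frame = m.to_frame()
    assert len(frame) == small_spec.n_slices
    assert "f000" in frame.columns
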