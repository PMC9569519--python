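"""Convolutional model: architecture contracts, training protocol, persistence."""

import numpy as np
import pytest

from neoimm.alphabet import DEFAULT_ALPHABET
from neoimm.cnn import (
    IncompatibleModelError,
    ModelConfig,
    ModelLoadError,
    TrainedModel,
    alphabet_hash,
    build_model,
    load_model,
    predict,
    save_model,
    train,
)
from neoimm.curation import assign_splits, curate_dataframe
from neoimm.dataset import build_encoded_dataset
from neoimm.features import EmptyClassError

FAST = dict(max_epochs=6, n_members=1, branch_warmup_epochs=2,
            conv_filters=(8, 8), branch_dense_units=(32, 32, 256),
            fusion_dense_units=(16, 8))


@pytest.fixture(scope="module")
def small_encoded():
    from neoimm.simulate import SimulationConfig, simulate_assays
    assays, feats, _, pseudo = simulate_assays(
        SimulationConfig(n_records=200, n_alleles=3, seed=9))
    ds = assign_splits(curate_dataframe(assays), seed=9)
    enc = build_encoded_dataset(ds.rows, feats, pseudo)
    return enc, pseudo


@pytest.fixture(scope="module")
def trained(small_encoded):
    enc, pseudo = small_encoded
    checksum = alphabet_hash(DEFAULT_ALPHABET, pseudo)
    model = train(enc.arrays, ModelConfig(seed=3, **FAST), enc.norm_constants,
                  alphabet_checksum=checksum)
    return model, enc, pseudo, checksum


class TestArchitecture:
    def test_branch_flatten_output_is_256_dimensional(self):
        net = build_model(ModelConfig(seed=0))
        pep = np.zeros((2, 11, 21))
        pep[:, :, 0] = 1
        mhc = np.zeros((2, 33, 21))
        mhc[:, :, 0] = 1
        p_out, m_out = net.branch_outputs(pep, mhc)
        assert p_out.shape == (2, 256)
        assert m_out.shape == (2, 256)

    def test_untrained_model_outputs_probability(self):
        net = build_model(ModelConfig(seed=0))
        pep = np.zeros((1, 11, 21))
        pep[:, :, 2] = 1
        mhc = np.zeros((1, 33, 21))
        mhc[:, :, 3] = 1
        out = net.forward(pep, mhc, np.array([[0.4, 0.6]]))
        assert out.shape == (1,)
        assert np.isfinite(out[0]) and 0.0 <= out[0] <= 1.0

    def test_same_seed_identical_initial_weights(self):
        a = build_model(ModelConfig(seed=5))
        b = build_model(ModelConfig(seed=5))
        for k, v in a.parameters().items():
            np.testing.assert_array_equal(v, b.parameters()[k])

    def test_different_seed_differs(self):
        a = build_model(ModelConfig(seed=5))
        b = build_model(ModelConfig(seed=6))
        assert any(not np.array_equal(v, b.parameters()[k])
                   for k, v in a.parameters().items())

    def test_branch_output_must_be_256(self):
        with pytest.raises(ValueError):
            ModelConfig(branch_dense_units=(64, 64, 128))

    def test_output_range_on_fuzzed_inputs(self):
        rng = np.random.default_rng(0)
        net = build_model(ModelConfig(seed=1))
        for _ in range(5):
            pep = np.eye(21)[rng.integers(0, 21, size=(4, 11))]
            mhc = np.eye(21)[rng.integers(0, 21, size=(4, 33))]
            sc = rng.random((4, 2))
            out = net.forward(pep, mhc, sc)
            assert np.all((out >= 0) & (out <= 1))


class TestTraining:
    def test_same_seed_identical_history(self, small_encoded):
        enc, _ = small_encoded
        m1 = train(enc.arrays, ModelConfig(seed=7, **FAST), enc.norm_constants)
        m2 = train(enc.arrays, ModelConfig(seed=7, **FAST), enc.norm_constants)
        assert m1.history == m2.history

    def test_history_has_both_losses(self, trained):
        model, *_ = trained
        assert len(model.history["train_loss"]) == len(model.history["val_loss"])
        assert all(np.isfinite(v) for v in model.history["train_loss"])

    def test_missing_validation_split_rejected(self, small_encoded):
        enc, _ = small_encoded
        arrays = dict(enc.arrays)
        arrays["split"] = np.where(arrays["split"] == "validation", "train",
                                   arrays["split"])
        with pytest.raises(ValueError, match="validation"):
            train(arrays, ModelConfig(seed=0, **FAST))

    def test_single_class_training_set_rejected(self, small_encoded):
        enc, _ = small_encoded
        arrays = dict(enc.arrays)
        arrays["label"] = np.ones_like(arrays["label"])
        with pytest.raises(EmptyClassError):
            train(arrays, ModelConfig(seed=0, **FAST))

    def test_class_weights_recorded(self, trained):
        model, enc, *_ = trained
        cw = model.weights_used
        assert cw is not None
        assert cw.w_pos * cw.s_pos + cw.w_neg * cw.s_neg == pytest.approx(cw.total)


class TestPredict:
    def test_scores_in_unit_interval(self, trained):
        model, enc, *_ = trained
        scores = predict(model, enc.arrays)
        assert np.all((scores >= 0) & (scores <= 1))
        assert len(scores) == len(enc.table)

    def test_order_equivariance(self, trained):
        model, enc, *_ = trained
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(enc.table))
        base = predict(model, enc.arrays)
        permuted = predict(model, {k: enc.arrays[k][perm]
                                   for k in ("peptide", "mhc", "scalars")})
        np.testing.assert_allclose(permuted, base[perm], atol=1e-12)

    def test_singleton_matches_batched(self, trained):
        model, enc, *_ = trained
        batched = predict(model, enc.arrays)
        singles = np.concatenate([
            predict(model, {k: enc.arrays[k][i:i + 1]
                            for k in ("peptide", "mhc", "scalars")})
            for i in range(10)
        ])
        np.testing.assert_allclose(singles, batched[:10], atol=1e-5)

    def test_checksum_mismatch_rejected(self, trained):
        model, enc, *_ = trained
        with pytest.raises(IncompatibleModelError):
            predict(model, enc.arrays, alphabet_checksum="deadbeef")


class TestPersistence:
    def test_round_trip_predicts_identically(self, trained, tmp_path):
        model, enc, *_ = trained
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        probe = {k: enc.arrays[k][:100] for k in ("peptide", "mhc", "scalars")}
        np.testing.assert_allclose(predict(loaded, probe), predict(model, probe),
                                   atol=1e-6)

    def test_round_trip_preserves_norm_constants(self, trained, tmp_path):
        model, *_ = trained
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.norm_constants.keys() == model.norm_constants.keys()
        for k, c in model.norm_constants.items():
            assert loaded.norm_constants[k] == c
        assert loaded.alphabet_checksum == model.alphabet_checksum

    def test_corrupt_file_rejected_with_checksum_detail(self, trained, tmp_path):
        model, *_ = trained
        path = tmp_path / "model.npz"
        save_model(model, path)
        raw = bytearray(path.read_bytes())
        raw[len(raw) // 2] ^= 0xFF
        path.write_bytes(bytes(raw))
        with pytest.raises(ModelLoadError):
            load_model(path)

    def test_garbage_file_rejected(self, tmp_path):
        path = tmp_path / "model.npz"
        path.write_bytes(b"not a model at all")
        with pytest.raises(ModelLoadError):
            load_model(path)

    def test_unwritable_path_raises_io_error(self, trained):
        model, *_ = trained
        with pytest.raises(OSError):
            save_model(model, "/nonexistent-dir/model.npz")

    def test_loaded_model_enforces_checksum(self, trained, tmp_path):
        model, enc, pseudo, checksum = trained
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        with pytest.raises(IncompatibleModelError):
            predict(loaded, enc.arrays, alphabet_checksum="other")
        scores = predict(loaded, enc.arrays, alphabet_checksum=checksum)
        assert len(scores) == len(enc.table)
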