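import numpy as np
import pytest

from methyldiag.io import ValidationError
from methyldiag.model import (
    DiagnosisModel,
    DynamicResidualParams,
    TrainConfig,
    dynamic_residual_forward,
    init_model,
    model_forward,
    predict,
    predict_matrix,
    train_model,
)
from methyldiag.simulate import SyntheticCohortConfig, generate_cohort


# ------------------------------------------------------------ initialization
def test_init_deterministic_and_head_arithmetic():
    a = init_model(d=16, heads=4, seed=7)
    b = init_model(d=16, heads=4, seed=7)
    for k in a.parameters():
        np.testing.assert_array_equal(a.parameters()[k].data, b.parameters()[k].data)
    assert a.width // a.heads == 4  # per-head dimension
    c = init_model(d=16, heads=4, seed=8)
    assert any(
        not np.array_equal(c.parameters()[k].data, a.parameters()[k].data)
        for k in a.parameters()
    )


def test_init_rejects_indivisible_heads():
    with pytest.raises(ValidationError, match="divisible"):
        init_model(d=400, heads=7)


# --------------------------------------------------------- dynamic residual
def _residual(d, W_fc, b_fc, W_gate, b_gate):
    return DynamicResidualParams(
        W_fc=np.asarray(W_fc, dtype=float),
        b_fc=np.asarray(b_fc, dtype=float),
        W_gate=np.asarray(W_gate, dtype=float),
        b_gate=np.asarray(b_gate, dtype=float),
    )


def test_residual_hand_example():
    """d=2, H=(1,1), T=2H, zero gate logits: G=0.5 so O=(H+T)/2=(1.5,1.5)."""
    p = _residual(2, 2 * np.eye(2), np.zeros(2), np.zeros((2, 2)), np.zeros(2))
    out = dynamic_residual_forward(np.array([1.0, 1.0]), p)
    np.testing.assert_allclose(out, [1.5, 1.5], atol=1e-15)


def test_residual_gate_closed_is_identity():
    rng = np.random.default_rng(0)
    W = rng.standard_normal((4, 4))
    p = _residual(4, W, rng.standard_normal(4), np.zeros((4, 4)), -1e9 * np.ones(4))
    H = rng.standard_normal(4)
    np.testing.assert_array_equal(dynamic_residual_forward(H, p), H)


def test_residual_gate_open_is_affine_transform():
    rng = np.random.default_rng(1)
    W, b = rng.standard_normal((4, 4)), rng.standard_normal(4)
    p = _residual(4, W, b, np.zeros((4, 4)), 1e9 * np.ones(4))
    H = rng.standard_normal(4)
    np.testing.assert_array_equal(dynamic_residual_forward(H, p), H @ W + b)


def test_residual_shape_mismatch_rejected():
    p = _residual(3, np.eye(3), np.zeros(3), np.eye(3), np.zeros(3))
    with pytest.raises(ValidationError, match="width"):
        dynamic_residual_forward(np.ones(4), p)


def test_gate_closed_model_equals_baseline():
    """Residual model with a saturated-closed gate matches the no-residual
    baseline given shared encoder and classifier weights."""
    full = DiagnosisModel(d=8, heads=2, seed=3, dropout=0.0)
    base = DiagnosisModel(d=8, heads=2, seed=3, dropout=0.0,
                          use_dynamic_residual=False)
    for k, t in base.parameters().items():
        t.data = full.parameters()[k].data.copy()
    full.parameters()["res_b_gate"].data = -1e9 * np.ones(8)
    X = np.random.default_rng(4).random((6, 8))
    np.testing.assert_allclose(
        full.predict_proba(X), base.predict_proba(X), atol=1e-6
    )


# ------------------------------------------------------------------ forward
def test_probabilities_normalized_and_uniform_logits():
    model = DiagnosisModel(d=8, heads=2, seed=0)
    X = np.random.default_rng(0).random((10, 8))
    probs = predict(model, X)
    assert probs.shape == (10, 2)
    assert np.all(probs >= 0)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    model.parameters()["W_class"].data[:] = 0.0
    model.parameters()["b_class"].data[:] = 0.0
    np.testing.assert_allclose(predict(model, X), 0.5, atol=1e-12)


def test_forward_deterministic_in_eval_mode():
    model = DiagnosisModel(d=8, heads=2, seed=5)
    C = np.random.default_rng(1).random(8)
    p1 = model_forward(C, model)
    p2 = model_forward(C, model)
    np.testing.assert_array_equal(p1, p2)


def test_forward_rejects_wrong_length():
    model = DiagnosisModel(d=8, heads=2, seed=0)
    with pytest.raises(ValidationError, match="8"):
        model_forward(np.ones(5), model)


def test_predict_row_equivariance():
    model = DiagnosisModel(d=6, heads=2, seed=2)
    X = np.random.default_rng(2).random((7, 6))
    perm = np.random.default_rng(3).permutation(7)
    np.testing.assert_allclose(predict(model, X)[perm], predict(model, X[perm]),
                               atol=1e-12)


# ----------------------------------------------------------------- training
def _separable(n=30, d=8, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.uniform(0.3, 0.7, (n, d))
    X[y == 1, 0] = rng.uniform(0.8, 0.95, n // 2)
    X[y == 0, 0] = rng.uniform(0.05, 0.2, n // 2)
    return X, y


def test_training_reduces_loss_and_is_deterministic():
    X, y = _separable()
    cfg = TrainConfig(epochs=15, batch_size=8, seed=1, val_fraction=0.0)
    m1, h1 = train_model(X, y, cfg, heads=2)
    m2, h2 = train_model(X, y, cfg, heads=2)
    assert h1["train_loss"][-1] < h1["train_loss"][0]
    assert h1 == h2
    for k in m1.parameters():
        np.testing.assert_array_equal(m1.parameters()[k].data,
                                      m2.parameters()[k].data)


def test_training_records_validation_and_early_stops():
    X, y = _separable(n=60)
    cfg = TrainConfig(epochs=200, batch_size=16, seed=2, val_fraction=0.2,
                      patience=3, min_delta=1e-2)
    _, hist = train_model(X, y, cfg, heads=2)
    assert "val_loss" in hist
    assert len(hist["train_loss"]) < 200  # early stopping engaged


def test_training_rejects_single_class():
    X = np.random.default_rng(0).random((10, 4))
    with pytest.raises(ValidationError, match="single class"):
        train_model(X, np.zeros(10, dtype=int), TrainConfig(epochs=1), heads=2)


def test_trained_model_separates_training_set():
    X, y = _separable(n=40)
    cfg = TrainConfig(epochs=60, batch_size=8, seed=3, val_fraction=0.0,
                      dropout=0.0)
    model, _ = train_model(X, y, cfg, heads=2)
    pred = (model.predict_proba(X)[:, 1] >= 0.5).astype(int)
    assert (pred == y).mean() >= 0.95


# -------------------------------------------------------------- persistence
def test_save_load_round_trip(tmp_path):
    model = DiagnosisModel(d=6, heads=2, seed=9, site_ids=[f"cg{i}" for i in range(6)])
    model.save(tmp_path / "model")
    back = DiagnosisModel.load(tmp_path / "model")
    X = np.random.default_rng(5).random((4, 6))
    np.testing.assert_array_equal(model.predict_proba(X), back.predict_proba(X))
    assert back.site_ids == model.site_ids


def test_predict_matrix_enforces_site_order(tmp_path):
    cfg = SyntheticCohortConfig(
        tissues=("lung",), n_healthy_per_tissue=3, n_disease_per_tissue=3,
        n_sites=6, n_tissue_specific=2, n_disease_specific_per_tissue=2, seed=0,
    )
    matrix, _, _ = generate_cohort(cfg)
    model = DiagnosisModel(d=6, heads=2, seed=0, site_ids=list(matrix.site_ids))
    probs = predict_matrix(model, matrix)
    assert probs.shape == (6, 2)
    shuffled = matrix.subset_sites(list(reversed(matrix.site_ids)))
    with pytest.raises(ValidationError, match="cg00000005"):
        predict_matrix(model, shuffled)
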