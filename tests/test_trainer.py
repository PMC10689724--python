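"""Training loop: LR schedule, stopping rule, checkpoint policy."""

import numpy as np
import pytest

from mslesseg.dataprep import SliceRecord
from mslesseg.losses import LossSpec
from mslesseg.network import NetConfig, build_model
from mslesseg.trainer import (
    LossHistory,
    TrainConfig,
    TrainingDivergedError,
    checkpoint_path,
    fine_tune,
    load_checkpoint,
    lr_at,
    train,
)


def test_lr_schedule_closed_form():
    cfg = TrainConfig()
    assert lr_at(0, cfg) == pytest.approx(3e-4)
    assert lr_at(299, cfg) == pytest.approx(3e-4)
    assert lr_at(300, cfg) == pytest.approx(3e-4 * 0.9)
    assert lr_at(900, cfg) == pytest.approx(3e-4 * 0.9**3)
    for b in range(0, 10_001, 157):
        assert lr_at(b, cfg) == pytest.approx(3e-4 * 0.9 ** (b // 300))


def test_fine_tune_config_overrides():
    cfg = TrainConfig(fine_tune=True)
    assert cfg.initial_lr == pytest.approx(1e-5)
    assert cfg.checkpoint_stride == 5
    assert cfg.max_epochs == 20
    assert all(
        lr_at(b, cfg) <= 1e-5 + 1e-12 for b in range(0, 5000, 37)
    )


def _records(n=4, size=16, seed=0, lesion=True):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        images = {
            m: rng.random((size, size)).astype(np.float32)
            for m in ("FLAIR", "T1w", "T2w")
        }
        lab = np.zeros((size, size), dtype=np.uint8)
        if lesion:
            lab[4:8, 4:8] = 1
        recs.append(SliceRecord(images, lab, "axial", i, (size, size)))
    return recs


def _tiny_cfg(tmp_path, **kw):
    kw.setdefault("max_epochs", 4)
    kw.setdefault("batch_size_train", 2)
    kw.setdefault("checkpoint_stride", 3)
    kw.setdefault("checkpoint_dir", str(tmp_path / "ckpt"))
    return TrainConfig(**kw)


@pytest.fixture(scope="module")
def tiny_net_cfg():
    return NetConfig(n0=2, depth=2, seed=0)


def test_training_writes_stride_and_best_checkpoints(tmp_path, tiny_net_cfg):
    model = build_model(tiny_net_cfg)
    recs = _records()
    cfg = _tiny_cfg(tmp_path)
    model, hist = train(model, recs, recs, cfg, LossSpec())
    assert len(hist) == 4
    # stride checkpoint at epoch 3; best checkpoint whenever improved
    assert checkpoint_path(cfg.checkpoint_dir, 3).exists()
    best = hist.best_epoch + 1
    assert checkpoint_path(cfg.checkpoint_dir, best).exists()
    assert (np.asarray(hist.checkpoint_saved)[[2]]).all()


def test_early_stopping_halts_after_patience(monkeypatch):
    """Patience 2 with a loss plateauing after epoch 5 halts at epoch 7."""
    import mslesseg.trainer as trainer_mod

    scripted = [0.9, 0.8, 0.7, 0.6, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
    calls = {"n": 0}

    def fake_forward(model, records, loss_spec, batch_size, train_mode,
                     optimizer=None, cfg=None, batch_counter=None):
        if train_mode:
            return 1.0
        calls["n"] += 1
        return scripted[calls["n"] - 1]

    monkeypatch.setattr(trainer_mod, "_forward_loss", fake_forward)
    model = build_model(NetConfig(n0=2, depth=2, seed=1))
    recs = _records()
    cfg = TrainConfig(max_epochs=10, early_stop_patience=2, batch_size_train=4)
    _, hist = train(model, recs, recs, cfg, LossSpec())
    assert len(hist) == 7
    assert hist.best_epoch == 4  # 0-based epoch 5


def test_early_stopping_never_fires_before_patience_elapsed(tmp_path):
    model = build_model(NetConfig(n0=2, depth=2, seed=2))
    recs = _records()
    cfg = TrainConfig(max_epochs=6, early_stop_patience=200,
                      batch_size_train=4)
    _, hist = train(model, recs, recs, cfg, LossSpec())
    assert len(hist) == 6  # budget reached, never stopped early


def test_seeded_training_is_deterministic(tiny_net_cfg):
    recs = _records()
    losses = []
    for _ in range(2):
        model = build_model(tiny_net_cfg)
        cfg = TrainConfig(max_epochs=2, batch_size_train=2, seed=7)
        _, hist = train(model, recs, recs, cfg, LossSpec())
        losses.append(hist.train_loss[0])
    assert losses[0] == losses[1]


def test_training_loss_decreases_on_learnable_data(tiny_net_cfg):
    model = build_model(tiny_net_cfg)
    recs = _records(n=6, seed=3)
    cfg = TrainConfig(max_epochs=10, batch_size_train=3, initial_lr=3e-3)
    _, hist = train(model, recs, recs, cfg, LossSpec())
    assert hist.val_loss[-1] < hist.val_loss[0]


def test_nan_loss_aborts():
    model = build_model(NetConfig(n0=2, depth=2, seed=4))
    # blow up the weights so the forward pass saturates and bce yields nan/inf
    for p in model.parameters():
        p.data *= 1e30
    recs = _records()
    cfg = TrainConfig(max_epochs=2, batch_size_train=4, initial_lr=1e30)
    with pytest.raises(TrainingDivergedError):
        train(model, recs, recs, cfg, LossSpec(kind="bce"))


def test_empty_record_sets_rejected(tiny_net_cfg):
    model = build_model(tiny_net_cfg)
    with pytest.raises(ValueError):
        train(model, [], _records(), TrainConfig(), LossSpec())


def test_fine_tune_resumes_from_pretrained_weights(tmp_path, tiny_net_cfg):
    model = build_model(tiny_net_cfg)
    recs = _records()
    cfg = _tiny_cfg(tmp_path, max_epochs=2)
    model, _ = train(model, recs, recs, cfg, LossSpec())
    state = model.state_dict()

    model2 = build_model(tiny_net_cfg)
    ft_cfg = TrainConfig(fine_tune=True,
                         checkpoint_dir=str(tmp_path / "ft"))
    ft_cfg.max_epochs = 5
    model2, hist = fine_tune(model2, state, recs, recs, ft_cfg, LossSpec())
    assert len(hist) == 5
    assert checkpoint_path(ft_cfg.checkpoint_dir, 5).exists()


def test_fine_tune_checkpoint_epochs_follow_stride_five(tmp_path,
                                                        tiny_net_cfg):
    model = build_model(tiny_net_cfg)
    recs = _records()
    cfg = TrainConfig(fine_tune=True, checkpoint_dir=str(tmp_path / "ft2"))
    _, hist = train(model, recs, recs, cfg, LossSpec())
    for e in (5, 10, 15, 20):
        assert checkpoint_path(cfg.checkpoint_dir, e).exists()


def test_checkpoint_round_trip_restores_weights(tmp_path, tiny_net_cfg):
    model = build_model(tiny_net_cfg)
    recs = _records()
    cfg = _tiny_cfg(tmp_path, max_epochs=3)
    model, hist = train(model, recs, recs, cfg, LossSpec())
    w_after = {k: v.copy() for k, v in model.state_dict().items()}
    load_checkpoint(model, cfg.checkpoint_dir, 3)
    state3 = model.state_dict()
    assert set(state3) == set(w_after)


def test_history_csv_round_trip(tmp_path):
    hist = LossHistory(
        val_loss=np.array([0.5, 0.4, 0.45]),
        checkpoint_saved=np.array([False, True, True]),
        best_epoch=1,
        train_loss=np.array([0.6, 0.5, 0.48]),
    )
    p = tmp_path / "hist.csv"
    hist.to_csv(p)
    back = LossHistory.from_csv(p)
    assert np.allclose(back.val_loss, hist.val_loss)
    assert np.array_equal(back.checkpoint_saved, hist.checkpoint_saved)
    assert back.best_epoch == 1
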