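"""Training loops: loss closed forms, convergence, transfer, freezing."""

import numpy as np
import pytest

import retina_em as r
from retina_em import nn
from retina_em.augment import AugmentationConfig, AugmentedPair, \
    CorruptionRecord, GeometricRecord
from retina_em.train import (TrainConfig, dice_loss, mse_loss, pretrain_step,
                             segmentation_loss)


def _pair(inp, tgt):
    return AugmentedPair(input_image=inp, target_image=tgt,
                         geometric=GeometricRecord(),
                         corruption=CorruptionRecord())


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(iterations=0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainConfig(loss="hinge")
    with pytest.raises(ValueError):
        TrainConfig(freeze=("transformer", "bogus"))


def test_mse_closed_form():
    pred = nn.Tensor(np.zeros((1, 1, 2, 2), dtype=np.float32))
    target = np.array([[[[1, 0], [0, 0]]]], dtype=np.float32)
    assert float(mse_loss(pred, target).data) == pytest.approx(0.25)


def test_pretrain_step_zero_loss_when_output_matches_target(tiny_model):
    """A model stubbed to emit the target exactly gives loss 0."""

    class Stub:
        def reconstruct(self, x):
            return x

    imgs = np.random.default_rng(0).uniform(0, 1, (2, 16, 16)).astype(np.float32)
    batch = [_pair(i, i) for i in imgs]
    opt = nn.SGD({}, lr=0.1)
    loss = pretrain_step(Stub(), batch, opt)
    assert loss == pytest.approx(0.0)


def test_pretrain_step_rejects_empty_batch(tiny_model):
    opt = nn.SGD(tiny_model.params, lr=0.01)
    with pytest.raises(ValueError):
        pretrain_step(tiny_model, [], opt)


def test_fixed_batch_loss_decreases(tiny_config):
    model = r.build_model(tiny_config)
    rng = np.random.default_rng(1)
    imgs = rng.uniform(0, 1, (2, 64, 64)).astype(np.float32)
    batch = [_pair(i, i) for i in imgs]
    opt = nn.SGD(model.params, lr=0.01, momentum=0.9)
    first = pretrain_step(model, batch, opt)
    for _ in range(19):
        last = pretrain_step(model, batch, opt)
    assert last < first


def test_run_pretraining_contracts(small_corpus, tiny_config):
    model = r.build_model(tiny_config)
    cfg = TrainConfig(iterations=10, batch_size=2, learning_rate=0.02,
                      loss="mse", seed=4)
    ckpt = r.run_pretraining(small_corpus, model, cfg)
    assert len(ckpt.loss_history) == 10
    assert set(ckpt.families) == {"conv_encoder", "transformer", "decoder",
                                  "head"}
    assert ckpt.iteration == 10


def test_run_pretraining_rejects_empty_corpus(tiny_model):
    with pytest.raises(ValueError):
        r.run_pretraining([], tiny_model, TrainConfig(iterations=1, loss="mse"))


def test_run_pretraining_seeded_histories_identical(small_corpus, tiny_config):
    cfg = TrainConfig(iterations=5, batch_size=2, learning_rate=0.02,
                      loss="mse", seed=9)
    h1 = r.run_pretraining(small_corpus, r.build_model(tiny_config), cfg)
    h2 = r.run_pretraining(small_corpus, r.build_model(tiny_config), cfg)
    assert h1.loss_history == h2.loss_history


# -- transfer ----------------------------------------------------------------

def _quick_checkpoint(tiny_config, corpus, iterations=3):
    model = r.build_model(tiny_config)
    cfg = TrainConfig(iterations=iterations, batch_size=2, learning_rate=0.02,
                      loss="mse", seed=2)
    return r.run_pretraining(corpus, model, cfg)


def test_transfer_copies_transformer_only(small_corpus, tiny_config):
    src = _quick_checkpoint(tiny_config, small_corpus)
    fresh_cfg = r.ModelConfig.tiny(n_classes=3, seed=99)
    target = r.build_model(fresh_cfg)
    before = target.state_arrays()
    r.transfer_transformer_params(src, target)
    fams = target.parameter_families()
    for name in fams["transformer"]:
        np.testing.assert_array_equal(target.params[name].data,
                                      src.arrays[name])
    for fam in ("conv_encoder", "decoder", "head"):
        for name in fams[fam]:
            np.testing.assert_array_equal(target.params[name].data,
                                          before[name])


def test_transfer_shape_mismatch_names_parameter(small_corpus, tiny_config):
    src = _quick_checkpoint(tiny_config, small_corpus)
    other = r.build_model(r.ModelConfig(
        input_size=64, conv_channels=(16, 32), patch_size=2, embed_dim=16,
        n_layers=2, n_heads=2, mlp_dim=64, decoder_channels=(32, 16, 16),
        n_classes=3))
    with pytest.raises(ValueError, match="transformer"):
        r.transfer_transformer_params(src, other)


# -- freezing ----------------------------------------------------------------

def test_set_trainable_rejects_unknown_family(tiny_model):
    with pytest.raises(ValueError):
        r.set_trainable(tiny_model, ["attention"])


def test_freeze_all_families_keeps_loss_constant(labeled_image, tiny_config):
    model = r.build_model(tiny_config)
    img, lab = labeled_image
    cfg = TrainConfig(iterations=5, batch_size=1, learning_rate=0.1,
                      loss="ce", seed=0,
                      freeze=("conv_encoder", "transformer", "decoder",
                              "head"),
                      augment_finetune=False)
    ckpt = r.run_finetuning([(img, lab)], model, cfg)
    assert len(set(np.round(ckpt.loss_history, 10))) == 1


def test_freeze_transformer_keeps_it_bit_identical(labeled_image, tiny_config,
                                                   small_corpus):
    src = _quick_checkpoint(tiny_config, small_corpus)
    model = r.build_model(r.ModelConfig.tiny(n_classes=3, seed=42))
    before = model.state_arrays()  # conv_encoder untouched by transfer
    img, lab = labeled_image
    cfg = TrainConfig(iterations=10, batch_size=1, learning_rate=0.05,
                      loss="ce_dice", seed=1, freeze=("transformer",))
    ckpt = r.run_finetuning([(img, lab)], model, cfg, source=src)
    fams = model.parameter_families()
    for name in fams["transformer"]:
        np.testing.assert_array_equal(ckpt.arrays[name], src.arrays[name])
    changed = [n for n in fams["conv_encoder"]
               if not np.array_equal(ckpt.arrays[n], before[n])]
    assert changed, "conv encoder should train while transformer is frozen"


def test_no_freeze_updates_every_family(labeled_image, tiny_config):
    model = r.build_model(tiny_config)
    before = model.state_arrays()
    img, lab = labeled_image
    cfg = TrainConfig(iterations=10, batch_size=1, learning_rate=0.05,
                      loss="ce_dice", seed=3, freeze=())
    ckpt = r.run_finetuning([(img, lab)], model, cfg)
    fams = model.parameter_families()
    for fam in ("conv_encoder", "transformer", "decoder", "head"):
        moved = any(not np.array_equal(ckpt.arrays[n], before[n])
                    for n in fams[fam])
        assert moved, f"family {fam} did not update"


# -- fine-tuning -------------------------------------------------------------

def test_finetune_history_length(labeled_image, tiny_config):
    model = r.build_model(tiny_config)
    img, lab = labeled_image
    cfg = TrainConfig(iterations=7, batch_size=1, learning_rate=0.02,
                      loss="ce", seed=0)
    ckpt = r.run_finetuning([(img, lab)], model, cfg)
    assert len(ckpt.loss_history) == 7


def test_finetune_rejects_out_of_range_labels(tiny_config):
    model = r.build_model(tiny_config)  # n_classes = 3
    img = np.zeros((64, 64), dtype=np.float32)
    lab = np.full((64, 64), 7, dtype=np.int64)
    with pytest.raises(ValueError, match="slice 0"):
        r.run_finetuning([(img, lab)], model,
                         TrainConfig(iterations=1, loss="ce"))


def test_finetune_rejects_shape_mismatch(tiny_config):
    model = r.build_model(tiny_config)
    img = np.zeros((64, 64), dtype=np.float32)
    lab = np.zeros((32, 32), dtype=np.int64)
    with pytest.raises(ValueError, match="slice 0"):
        r.run_finetuning([(img, lab)], model,
                         TrainConfig(iterations=1, loss="ce"))


def test_dice_loss_zero_for_perfect_confident_prediction():
    labels = np.zeros((1, 4, 4), dtype=np.int64)
    labels[0, :2] = 1
    logits = np.full((1, 2, 4, 4), -50.0, dtype=np.float32)
    logits[0, 0][labels[0] == 0] = 50.0
    logits[0, 1][labels[0] == 1] = 50.0
    loss = dice_loss(nn.Tensor(logits), labels)
    assert float(loss.data) == pytest.approx(0.0, abs=1e-4)
    ce = segmentation_loss(nn.Tensor(logits), labels, "ce")
    assert float(ce.data) == pytest.approx(0.0, abs=1e-4)
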