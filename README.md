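# retina-em

Self-supervised reconstruction pre-training and fine-tuning of a hybrid
CNN–transformer network for semantic segmentation of electron-microscopy
(EM) images, with volumetric inference and a full segmentation-metric
layer — all runnable at desk scale on one CPU via a built-in synthetic
EM-image generator.

## Who this is for

EM image-analysis practitioners who want an end-to-end, dependency-light
pipeline for the pre-train → transfer → fine-tune → predict → evaluate
workflow: pre-training a segmentation encoder on unlabeled 2-D EM patches
by image reconstruction, transferring and freezing the transformer layers,
fine-tuning on labeled data, and evaluating with the field's standard
semantic metrics (IoU, precision/recall/F, Mean False Distance, and the
CREMI synaptic-cleft distances ADGT/ADF).

## The method

**Architecture (TransUNet-style).** Stride-2 convolutional stages extract a
high-resolution feature map from a grayscale image; a patch embedding
tokenises the feature map; pre-norm transformer blocks (multi-head
self-attention + MLP) refine the tokens globally; the tokens are reshaped
to a spatial grid and progressively upsampled with U-Net-style skip
connections from the convolutional stages. Interchangeable heads produce
either a single-channel reconstruction or per-pixel class scores.

**Pre-training.** Each unlabeled patch x is augmented twice from one
sampled record: a geometric transform g (flips, right-angle rotations, each
with probability ½) gives the clean target g(x), and photometric
corruptions c (brightness/contrast, Gaussian noise, Gaussian blur, and 1–32
masked 16-px patches) give the network input c(g(x)). The network is
trained to minimise

    L = mean‖f(c(g(x))) − g(x)‖²

so input and target are geometrically aligned and the encoder must undo
the corruption, including inpainting the masked patches.

**Fine-tuning.** The pre-trained transformer family (patch embedding,
positional embedding, all blocks, final norm) is transferred into a fresh
model and frozen; the convolutional encoder, decoder and segmentation head
remain trainable and are optimised with pixel-wise cross-entropy + soft
Dice (SGD, momentum 0.9, polynomial learning-rate decay per iteration).
3-D volumes are sliced into 2-D images for training.

**Inference.** Volumes (axis order z, y, x) are predicted slice-wise.
Isotropic volumes use orthoplane inference — the xy, xz and yz probability
volumes are averaged voxel-wise; anisotropic volumes are predicted on xy
slices only. Labels are the per-voxel argmax.

## Worked example

```python
import numpy as np
import retina_em as r
from retina_em.train import TrainConfig

# synthetic EM-like corpus and a labeled volume
corpus = r.generate_pretrain_corpus(8, r.SyntheticSpec(image_size=64, seed=3))
vol, lab = r.generate_labeled_volume(
    r.SyntheticSpec(image_size=64, volume_shape=(1, 64, 64),
                    n_classes=2, objects_per_class=(2, 3), seed=5))

# reconstruction pre-training (tiny config: 64 px, 2 conv stages, 2 blocks)
model = r.build_model(r.ModelConfig.tiny(n_classes=2, seed=7))
ckpt = r.run_pretraining(corpus, model,
                         TrainConfig(iterations=500, batch_size=4,
                                     learning_rate=0.05, loss="mse", seed=11))
print(f"MSE {ckpt.loss_history[0]:.3f} -> {np.mean(ckpt.loss_history[-20:]):.4f}")

# transfer the transformer, freeze it, fine-tune the rest
seg = r.build_model(r.ModelConfig.tiny(n_classes=3, seed=1))
dataset = [(vol[0], lab.data[0].astype(np.int64))]
r.run_finetuning(dataset, seg,
                 TrainConfig(iterations=300, batch_size=2, learning_rate=0.05,
                             loss="ce_dice", seed=0, freeze=("transformer",)),
                 source=ckpt)

from retina_em import infer
pred = np.argmax(infer.predict_slice(seg, vol[0]), axis=0)
print(f"train IoU {r.evaluate_segmentation(pred, dataset[0][1], 3).mean_iou:.3f}")
```

Output:

```
MSE 1.119 -> 0.0143
train IoU 0.990
```

The pre-training loss falls by ~98% as the network learns to invert the
corruptions; the fine-tuned model then overfits the single training image
almost perfectly (foreground mean IoU 0.990), demonstrating capacity and a
working transfer/freeze path.

The same chain is available from the shell:

```bash
retina synth    --config run.yaml --out runs/demo
retina pretrain --config run.yaml --out runs/demo
retina finetune --config run.yaml --out runs/demo --pretrained runs/demo/pretrained.h5
retina predict  --config run.yaml --out runs/demo \
                --checkpoint runs/demo/finetuned.h5 --volume runs/demo/test.h5
retina evaluate --pred runs/demo/prediction.h5 --gt runs/demo/test.h5 --out runs/demo
```

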