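# dgtta

Domain-generalized pre-training and source-free test-time adaptation for
3D medical image segmentation.

## The problem

A segmentation network trained on one imaging domain (say, abdominal CT)
often fails on another (say, MR): anatomy is unchanged, but absolute
intensities and contrasts are remapped, sometimes non-monotonically.
Re-labeling the new domain is expensive, and the training data may not be
shareable at all.  This package implements a compact two-stage answer for
3D volumes:

1. **Domain-generalized pre-training.**  The network is fed inputs that
   are stable across domains:
   - *GIN augmentation*: `GIN(x) = α·g_ρ(x) + (1−α)·x`, blending the
     input with the output of a shallow convolutional network `g_ρ` whose
     weights ρ are re-randomized every iteration (α ~ U[0,1]);
   - *SSC descriptor*: a 12-channel self-similarity context field,
     `SSC(x, p, d) = exp(−SSD(x, p, d)/σ_N²)`, built from the sums of
     squared differences between diagonally adjacent patches in each
     voxel's 6-neighborhood, normalized by the mean patch distance σ_N².
     Both SSD and σ_N² scale with a² under `x → a·x + b`, so the
     descriptor is invariant to affine intensity changes.

2. **Test-time adaptation (TTA).**  For a single unseen target scan x_t
   (no source data, no labels), two random affine views `A(x_t)`,
   `B(x_t)` of each patch pass through the network f_θ, predictions are
   warped back by the exact inverses and masked to commonly valid voxels
   m_c, and θ is nudged to make them agree:

       L_TTA = ℓ(A⁻¹∘f_θ(A(x_t)), B⁻¹∘f_θ(B(x_t)))

   where ℓ is a Dice-form loss with squared denominator terms (exponent
   d = 2), which is exactly zero for identical predictions.  AdamW at
   η = 1e-5 (weight decay 0.01) runs 12 steps, each accumulating the
   gradients of 16 random patches; only branch A backpropagates.

A paired-domain phantom generator (shared label geometry, CT-like vs
MR-like intensity lookups, noise, bias field) makes the whole pipeline
runnable and testable end-to-end without any external dataset.

## Who it is for

Researchers who need cross-domain 3D segmentation with strict data
constraints (source-free, single-sample adaptation), and anyone who wants
a desk-scale, fully inspectable reference implementation of the
augmentation-descriptor-consistency recipe: every stage — descriptor,
augmentation, invertible warps, consistency loss, adaptation loop — is a
small, tested numpy/scipy module.

## Worked example

```python
from dgtta import (PhantomSpec, generate_phantoms, FeaturePipeline,
                   TrainConfig, TTAConfig, pretrain, predict, adapt,
                   mean_foreground_dice)

phantoms = generate_phantoms(PhantomSpec(), 9, seed=0)      # (label, CT-like, MR-like)
train_set = [(src, lm) for lm, src, _ in phantoms[:8]]
model, _ = pretrain(train_set, FeaturePipeline("none"), TrainConfig(seed=0))

label, _, target = phantoms[8]                               # unseen MR-like scan
pre = mean_foreground_dice(predict(model, target).argmax_labels(), label)
adapted, trace = adapt(model, target, TTAConfig(seed=0))     # source-free
post = mean_foreground_dice(predict(adapted, target).argmax_labels(), label)
print(pre, post, trace[0], trace[-1])
```

Running `python examples/04_test_time_adaptation.py` (this script with
printing) gives:

```
consistency loss: step 1 0.2780 -> step 12 0.1989
target Dice before adaptation: 35.6%
target Dice after adaptation:  35.5%
```

The consistency loss falls as the two augmented branches are pulled into
agreement; the per-sample Dice movement at the method's 12-step budget on
this compact backbone is marginal — cross-domain conclusions are drawn at
cohort level.  `examples/03_pretrain_and_predict.py` runs that cohort
comparison and prints:

```
[none] epoch loss 1.899 -> 0.768
  source-domain mean Dice: 75.7%
  target-domain mean Dice: 41.7%
[gin+ssc] epoch loss 2.153 -> 0.956
  source-domain mean Dice: 80.8%
  target-domain mean Dice: 81.6%
cross-domain drop of the raw-intensity model: 34.0 Dice points
```

The raw-intensity model loses 34 Dice points on the remapped domain; the
GIN+SSC pipeline keeps essentially identical accuracy in both domains.

The other scripts in `examples/` walk through one capability each:
phantom simulation, the SSC descriptor and its affine invariance,
pre-training with and without the generalizing features, adaptation, and
the evaluation metrics (Dice, HD95, signed-rank testing).

There is also a thin CLI for shell use:

```bash
dgtta simulate --out data/ --n-train 8 --n-test 4 --seed 7
dgtta pretrain --data data/ --features gin+ssc --out model.ckpt
dgtta tta --model model.ckpt --input data/target/test/img_s7_012.nii --out seg.nii.gz
dgtta evaluate --pred preds/ --gt gts/ --classes 1,2,3,4 --out scores.csv
```

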