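"""Adapt a pre-trained model to one unseen target scan, source-free.

Runs the two-branch consistency scheme on a single target phantom: both
branches see affinely distorted views of random patches, predictions are
inverse-warped, masked, and pulled toward agreement with the d=2 Dice
loss; only branch A backpropagates.  Prints the consistency-loss trace
and the Dice before/after adaptation.
"""
from dgtta import (FeaturePipeline, PhantomSpec, TTAConfig, TrainConfig,
                   adapt, generate_phantoms, mean_foreground_dice, predict,
                   pretrain)

phantoms = generate_phantoms(PhantomSpec(), 9, seed=0)
train_set = [(src, lm) for lm, src, _ in phantoms[:8]]
model, _ = pretrain(train_set, FeaturePipeline("none"), TrainConfig(seed=0))

label, _, target = phantoms[8]
pre = mean_foreground_dice(predict(model, target).argmax_labels(), label)

cfg = TTAConfig(seed=2)  # 12 steps x 16 patches, AdamW 1e-5, branch-A grads
adapted, trace = adapt(model, target, cfg)
post = mean_foreground_dice(predict(adapted, target).argmax_labels(), label)

print(f"consistency loss: step 1 {trace[0]:.4f} -> step {len(trace)} {trace[-1]:.4f}")
print(f"target Dice before adaptation: {pre:.1f}%")
print(f"target Dice after adaptation:  {post:.1f}%")
print("The loss trace shows the two branches agreeing more; the Dice shift")
print("per sample is small at this scale and is judged across a cohort.")
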