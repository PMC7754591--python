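"""Train the random-forest voxel classifier and segment a held-out phantom.

Training chains preprocessing, CSA extraction and feature computation per
dataset, then fits the forest (30 trees, depth 30 by default) on a random
subset of the feature-label pairs. Segmentation applies the model inside
the hand mask and post-processes the raw mask (dilation, island filter,
Gaussian-fit intensity trim).
"""

from handmuscle import (
    PhantomSpec,
    PipelineConfig,
    dice,
    make_t1_phantom,
    run_segmentation_workflow,
    run_training_workflow,
)

cfg = PipelineConfig(seed=0)
phantoms = [make_t1_phantom(PhantomSpec(shape=(8, 64, 64), seed=s)) for s in range(5)]
train_data = [(t1, muscle) for t1, _, muscle in phantoms[:4]]

model, _, manifest = run_training_workflow(cfg, train_data, train_fraction=0.2)
print(f"trained on {len(train_data)} phantoms "
      f"({manifest.stage_seconds['prepare']:.1f}s prepare, "
      f"{manifest.stage_seconds['final_fit']:.1f}s fit)")

t1_test, _, muscle_test = phantoms[4]
result = run_segmentation_workflow(cfg, model, t1_test)
print(f"held-out raw Dice:            {dice(result['raw_muscle'], muscle_test):.4f}")
print(f"held-out post-processed Dice: {dice(result['muscle_auto'], muscle_test):.4f}")
print("-> Dice near 1 means the voxel classifier recovered the muscle of a")
print("   phantom it never saw during training.")
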