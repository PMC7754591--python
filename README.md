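# handmuscle

Semi-automated segmentation of hand muscle in T1-weighted MR volumes and
quantification of intramuscular fat from paired two-point Dixon scans.

## Who this is for

Quantifying hand muscle volume and fat content matters for studying muscle
loss and fat infiltration in rheumatoid arthritis and related conditions,
but manual slice-by-slice outlining of hand muscle takes hours per scan.
This package implements a pipeline that produces an automatic muscle mask
for expert review (corrected masks re-enter the workflow as files), then
transfers the mask to the Dixon fat-fraction image and reports fat content
— cutting interaction time to minutes while keeping the expert in the loop.

## The method

1. **Pre-processing.** The T1 volume is corrected for the smooth
   multiplicative bias field (either an N4 wrapper or a self-contained
   robust polynomial fit), the hand cross-sectional area (CSA) is
   extracted by thresholding at 70 intensity units (background ≈ 10, hand
   ≈ 500), a 3D morphological opening, and largest-component selection,
   and intensities are normalized against the two peak maxima of the
   in-hand grey-value histogram:

   V_norm = (V − V_cort) / (V_muscle − V_cort) · 100

   so cortical bone maps to 0 and muscle to 100 in every scan.

2. **Voxel classification.** Each hand voxel gets a 21-channel feature
   vector — mean/SD over city-block neighborhoods (radii 1–3 in 2D, 4–6
   in 3D), Sobel gradient magnitude, four extended local binary pattern
   codes (ELBP_CI, ELBP_NI, ELBP_RD, ELBP_AD) with bilinearly interpolated
   circle samples, and a 4-orientation Gabor bank (0°/45°/90°/135°) — and
   a random forest labels it muscle or background. The forest and texture
   hyperparameters Ƥ = Ƥ_RF ∪ Ƥ_GF ∪ Ƥ_ELBP are selected by k-fold
   cross-validation maximizing the mean Dice ratio; the shipped defaults
   are the optimal set (30 trees, depth 30, 0.0001 % samples per node,
   21×21 Gabor kernel with σ = λ = 1 mm, ELBP radius 3 with 8 samples).
   The raw mask is post-processed: dilation, island filtering (< 10
   voxels dropped), and a Gaussian-fit intensity trim at μ ± 3σ.

3. **Fat quantification.** The Dixon pair gives a per-voxel fat fraction

   V_ff = V_fat / (V_water + V_fat) · 1000‰,

   the T1 masks are transferred onto the FF grid by rigid registration
   (Mattes mutual information, regular-step gradient descent), and mean
   fat fraction (‰) and absolute fat content (fat-equivalent volume, mm³)
   are reported inside the operator-chosen metacarpal VOI.

4. **Evaluation.** Dice ratio, average surface distance and (directed or
   symmetric) Hausdorff distance between masks in physical millimetres;
   reanalysis precision as RMS_SD and CV over repeated analyses.

A synthetic phantom generator produces paired T1/Dixon volumes with
ground-truth CSA, muscle and fat-fraction maps, so the whole pipeline is
testable without patient data.

## Worked example

```bash
python examples/04_train_and_segment.py
```

prints (on this machine):

```
trained on 4 phantoms (0.1s prepare, 1.1s fit)
held-out raw Dice:            0.9954
held-out post-processed Dice: 0.9999
```

The classifier was trained on four phantoms and applied to a fifth it
never saw; Dice near 1 against the construction truth means essentially
every muscle voxel was recovered. `examples/05_fat_quantification.py`
continues to the Dixon stage:

```
muscle volume:   12102.0 mm^3
mean fat fraction:  200.0 permille (20.0%)
absolute fat:    2420.4 mm^3 (fat-equivalent volume)
ground-truth mean over all muscle: 200.0 permille
```

i.e. the reported mean fat fraction matches the fat map the phantom was
built from. The other examples walk through simulation, preprocessing,
the feature bank, and the evaluation/precision statistics.

A thin CLI mirrors the workflows (`handmuscle simulate | preprocess |
segment-csa | features | train | segment | quantify-fat | evaluate |
precision`); run `handmuscle --help` for the options.

## Layout

```
src/handmuscle/   volume/io, config, phantom, preprocess, csa, features,
                  rf (classifier + CV search + postprocess), fatquant,
                  metrics, pipeline, cli
examples/         one short narrative script per capability
tests/            unit + property tests, brute-force oracles, acceptance
docs/methods.md   models, assumptions, parameter choices, limitations
```
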