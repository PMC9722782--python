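# Methods

This note documents the models, conventions and design choices behind
`gliofed`, in the spirit of a methods appendix: what is simulated, what
is deliberately not, and which knobs matter.

## Label algebra

Label maps use the BraTS convention {0 background, 1 NCR, 2 ED, 4 ET};
code 3 (a legacy "non-enhancing" class) is rejected rather than
remapped, since the annotation protocol simulated here defines only
1/2/4. The three predicted regions are nested unions — ET = (label 4),
TC = (labels 1∪4), WT = (labels 1∪2∪4) — and the inverse mapping first
enforces nesting upward (TC := TC ∨ ET, WT := WT ∨ TC) before decoding
ET→4, TC∖ET→1, WT∖TC→2. Upward enforcement preserves every positive
ET/TC prediction, matching the containment semantics; the round trip
derive ∘ decode is exact on valid label maps (property-tested).

## Phantom generator

Each case is a brain ellipsoid (non-zero intensity on an exactly-zero
background) with a concentric tumor: NCR core inside an ET shell inside
an ED envelope, radii drawn per case from strictly increasing ranges.
Default contrast places ET brightest and NCR darkest on T1Gd, and ED
brightest on T2-FLAIR — the clinical signatures radiologists use —
with additive Gaussian noise (σ = 4 intensity units against tissue
contrasts of 30–80) confined to the brain so background stays exactly
zero, as cropping assumes. Site effects are per-channel affine
shifts/scales; per-site case counts can be drawn log-normally to mimic
the heavy skew of real federations. Annotation corruption modes: ET↔ED
code swap, morphological dilation/erosion of the whole tumor, and random
per-voxel code reassignment.

What the phantoms do *not* emulate: MR physics, bias fields, anatomy,
deformable tumor shapes, rater disagreement. Passing tests therefore
demonstrate the correctness and dynamics of the *federation machinery*,
not segmentation accuracy on real brains.

Determinism: all per-site randomness derives from
`blake2s(seed, "site", site_id)`, so a federation is bit-identical for a
given (seed, config) and independent of site iteration order.

## Preprocessing and augmentation

Per case, once: all-zero border planes are removed on each axis (interior
planes never — registration-aligned brains are contiguous) with a crop
record for exact un-cropping, then non-zero intensities are z-scored per
channel (zeros stay zero; a constant channel maps to zero). Normalizing
whole volumes once, rather than per patch per round, is cheaper and
deterministic; patch statistics differ negligibly on brain-sized crops.

Per round, per case: one uniform random patch (volumes smaller than the
patch are zero-padded symmetrically), then augmentation in the fixed
order flip → rotations → noise: an axis flip at p = 1.0 (axis uniform),
90° and 180° rotations each at p = 0.5 with the rotation plane re-drawn
independently per event, and additive Gaussian noise (μ = 0, σ = 0.1) at
p = 0.2 on image channels only. Geometric transforms hit image and
reference identically, so reference channels stay binary and their
per-channel voxel counts are conserved (property-tested).

Splits are 4:1 with n_val = floor(n/5) (minimum 1) — forced by the
reference protocol's 231 → 185/46 split — drawn once from a stored seed
and preserved for the entire run.

## Network and training

A 3D residual U-Net: stem convolution, `depth` encoder levels of
{residual block, stride-2 downsampling conv doubling the filters},
mirrored decoder with 2×2×2 stride-2 transposed convolutions and skip
concatenation, and a 1×1×1 head to three sigmoid channels. Residual
blocks are two 3×3×3 convolutions with instance normalization and leaky
ReLU and an identity (or 1×1×1 projection) shortcut. This composition is
one standard 3D-ResUNet variant among several; it is configurable so the
normalization/upsampling choices can be swapped.

Training is batch size 1, Adam (β = 0.9/0.999, ε = 1e-8), one optimizer
step per case per epoch on a fresh random augmented patch. The loss is
the mirrored soft Dice: mean over regions of 1 − DSC(1 − ref, 1 − pred)
with floating-point predictions; no per-region weights or penalties. A
channel whose complements are both empty contributes 0 (no smoothing
epsilon is needed — complements of sub-compartments are never empty in
practice). Evaluation binarizes at a strict > 0.5 threshold (fixed tie
behavior; exact 0.5 outputs are measure-zero).

The network, autograd and Adam are implemented in numpy (float32
training; the gradients are verified against central finite differences
in float64). Everything is bit-reproducible on CPU, which makes the
one-site-federation ≡ centralized-training identity testable exactly.

Reference-scale hyperparameters are 30 base filters, depth 4, 128³
patches, lr = 5e-5. The `tiny_config` used in tests and studies is
4 filters, depth 2, 16³ patches on 32³ phantoms, lr = 5e-3 — chosen so
that a federation converges within tens of rounds on one CPU core. At
the reference lr the tiny regime cannot converge inside any desk-scale
round budget; 5e-3 is the package's calibrated default for this regime.

**Known limitation — region-collapse stalls.** The mirrored loss has a
local minimum at "predict the region empty" (the complement Dice of an
empty prediction is already high for small regions). With batch-1 Adam,
a collapsed channel's escape is delayed by the second-moment history and
can exceed a 20-round budget; whether ET escapes is deterministic in
(data seed, init seed). Both federated and centralized training stall
identically under shared data/init, so comparative conclusions are
unaffected; absolute small-region scores within short budgets are.
`ModelConfig.grad_clip_norm` offers global-norm clipping (default off;
it does not affect this stall, as Adam is scale-normalized).

Per-site Adam moments persist across federated rounds and are never
aggregated — only model parameters are averaged; a flag resets them per
round for comparison.

## Federation protocol

One round: broadcast consensus → each training site trains one local
epoch → FedAvg with weights equal to *training-split* case counts (the
update reflects only the data actually trained on) → the new consensus
is evaluated on every site's validation split. Rounds are synchronous; a
site failure aborts the round rather than aggregating partially. Weights
are normalized before averaging, so FedAvg is invariant to their scale.
Per-(site, round) RNG streams derive from a stable hash, making runs
resumable bit-exactly from any checkpoint plus the stored optimizer
states. Stopping is max-rounds, with optional plateau detection: stop
when the best pooled collective score of the last W rounds improves on
the best before them by less than ε.

Validation is whole-volume (padded to a depth-compatible size, un-padded
after) rather than patch-based: phantoms are small and whole-volume
scoring removes patch-sampling noise from the round curves.

## Model selection

Every round's consensus is a candidate. Rankings use the validation
aggregates recomputed from per-case scores: *collective* (per-case
3-region mean, then across all cases of all sites) for singlets, pooled
per-region means for triplet specialists; ties break toward the earlier
round (deterministic, and earlier models are less exposed to late-round
noise). A triplet assembles region r from specialist r's sigmoid output
and then binarizes — voxelwise equivalent to binarizing per specialist,
stated once for determinism. Ensembles average member sigmoids voxelwise
before the 0.5 threshold.

## Evaluation and anomaly monitoring

Paired model comparison reports per-region mean DSC, *relative*
improvement (Δ/mean_baseline × 100 — a 0.62 → 0.8246 change reads as
+33%), and a two-sided Wilcoxon signed-rank p per region; a zero
baseline yields an undefined (not infinite) improvement.

The signed-rank test drops zero differences, uses the exact null
distribution for ≤ 25 remaining pairs (dynamic programming over doubled
midranks, so ties are exact too) and a normal approximation with
continuity and tie corrections beyond; it matches exhaustive
sign-assignment enumeration to 1e-12 for n ≤ 12 (tested).

Site anomaly scanning pairs each site's per-round validation means with
the federation-wide means and flags a site when the two-sided p < α
(default 0.05) *and* the site sits at least `min_deficit` (default 0.05
DSC) below the federation mean. The margin is a practical-significance
guard: site and federation curves score the same consensus model each
round and co-move, so any persistent case-difficulty offset — however
tiny — becomes statistically significant over enough rounds. Annotation
corruption produces deficits an order of magnitude larger (~0.4 DSC on
the phantoms) than ordinary difficulty offsets (~0.04), which the margin
separates; `min_deficit=0` recovers the purely statistical rule.
Multiple testing across sites is reported raw, with an optional
Bonferroni column.

## Study protocols and problem sizes

The two built-in studies (`gliofed.protocols`) run on 32³ phantoms with
the tiny network: the convergence study (6 IID sites × 8 cases,
20 rounds, federated vs centralized at equal step count — 840 optimizer
steps each) and the robustness study (5 × 12 clean cases plus one
3-case site with swapped ET/ED labels, 15 rounds, clean-vs-corrupted
runs at identical seeds plus the anomaly scan). These sizes keep each
study to roughly a minute per training arm on a single CPU core while
leaving all three regions learnable.
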