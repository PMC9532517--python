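# synquant

Quantification pipeline for excitatory synapse and dendritic-spine studies
in fluorescence microscopy, with a synthetic ground-truth simulator.

Neuroscience labs routinely score synapse formation by counting
colocalized pre-/post-synaptic marker puncta (e.g. Synapsin I and PSD95)
along dendrites, profiling arbor complexity by Sholl analysis, classifying
dendritic spines, scoring spatial-object-recognition behavior, and
normalizing western-blot densitometry — usually with a mix of closed-source
tools and ad-hoc scripts. `synquant` reimplements that entire measurement
chain as a tested, reusable Python package, and pairs it with a simulator
that renders confocal-like images, trajectories and band tables with known
ground truth, so every stage can be validated quantitatively.

## What it computes

**Synapse density.** Each channel of a (projected) multi-channel image is
binarized at a per-image adaptive threshold

&nbsp;&nbsp;&nbsp;&nbsp;T = μ + k·σ

over all pixels (k = 2 for puncta channels, k = 1 for the cell-fill
channel). The binary masks are conjoined pixelwise (triple colocalization:
puncta A ∧ puncta B ∧ cell fill; a dual mode conjoins the two puncta masks
only), 8-connected components with area-equivalent diameter < 10 μm are
counted as synaptic puncta, and density = count / dendrite length (per μm),
with the length taken from a dendrite trace (SWC import or a
skeletonization-based tracer).

**Sholl profiles.** Intersections of the vectorized trace with concentric
circles every 10 μm from the soma centre, counted exactly as
segment–circle crossings; groups are compared with the two-sample
Kolmogorov–Smirnov test.

**Spine morphometry.** Protrusions along a traced dendrite are segmented,
measured (length, head width, neck width) and classified
thin / stubby / mushroom / filopodium by a configurable geometric rule set;
densities are reported per μm overall and per class.

**Behavior.** Nose-point trajectories are scored against an object layout:
a sample counts as exploration when the nose is strictly closer than 2 cm
to an object's boundary; the readout is the percentage of exploration time
per object, compared across sessions by one-way ANOVA with Fisher's LSD.

**Statistics.** Welch's unpaired t, one-way ANOVA with Dunnett's T3
(unequal variances; studentized-maximum-modulus critical values with
per-pair Welch df, implemented here and Monte-Carlo validated), Tukey's
HSD, Fisher's LSD, the two-sample K–S test, and loading-control
densitometry normalization with fold changes relative to a control group.

## Worked example

```python
from synquant import simulate as sim, puncta as pnc, dendrite as den

# render a 1024x1024 three-channel neuron image with known ground truth
cfg = sim.SimConfig(true_density=0.25, seed=42)   # 0.25 synapses per μm
image_set, truth = sim.generate_neuron_image(cfg)
print(truth.skeleton_length, len(truth.synapse_centers))
# 377.4 94        -> 94 = round(0.25 x 377.4) colocalized puncta placed

# threshold -> colocalize -> count -> density
result = pnc.quantify_image(image_set, truth.to_trace())
print(result.count, round(result.density, 3))
# 94 0.249        -> every punctum recovered; density within 1% of truth

# Sholl profile of the same arbor
profile = den.sholl(truth.to_trace(), step=10.0)
print(profile.radii[:5], profile.intersections[:5])
# [10. 20. 30. 40. 50.] [5 5 7 8 5]
```

The same pipeline is scriptable from the shell:

```bash
synquant simulate --out-dir run/ --n-images 10 --true-density 0.25 --seed 1
synquant quantify --image-dir run/ --out run/quantify.csv --pixel-size 0.2
synquant sholl    --trace-dir run/ --out run/sholl.csv
synquant report   --result-dir run/
```

Every output CSV/JSON embeds a hash of the resolved configuration, and
identical configuration + seed reproduces byte-identical result tables.

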