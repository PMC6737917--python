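# Methods

This note records the models, the numerical choices, and the limits of what
the test suite demonstrates. It is written for a reader who wants to know
what the package actually computes and why, not as a user guide.

## Problem setting

A *field* is an area of land under one crop, crop mixture, or management
regime; boundaries mark changes in crop or practice, or natural disruptions
(roads, ditches). In smallholder landscapes at 0.5 m resolution, boundaries
are frequently texture transitions rather than intensity edges, with tree
canopies and shadows as occluders. The pipeline is: semantic boundary
detection (FCN) → oriented contour cues and globalization → oriented
watershed + ultrametric contour map (UCM) → combinatorial grouping → boundary
precision-recall assessment with positional tolerance.

## Boundary FCN

Encoder-decoder architecture: encoder blocks of 3×3 conv + batch-norm +
ReLU followed by 2×2 max-pooling that records argmax indices; the decoder
mirrors the encoder block-for-block and upsamples by placing values at the
recorded indices (index unpooling) before densifying convolutions; a final
3×3 conv and softmax give per-pixel class probabilities. The full layout is
13 convolutions / 5 pooling stages (64–512 filters); the `tiny` preset
(2 blocks, 16/32 filters) is the desk-scale default — the full layout is a
configuration choice, not a code change. Weights are He-normal initialized;
there is a checkpoint load hook, so externally pre-trained encoder weights
can be injected, but no download is performed or required.

Training: patches sampled uniformly at random, fully inside the tile;
imbalance is handled only by the loss — mean cross-entropy with weight 10 on
boundary pixels (weight 1 reduces it to plain cross-entropy; the mean is over
the pixel count, so a uniform (½, ½) prediction gives ln 2). Optimizer is
Adam, α = 0.001, β₁ = 0.9, β₂ = 0.999, batch 32, 300 epochs in the
reference schedule — ceil(6000/32) × 300 = 56,400 iterations. The engine is
a small numpy implementation (im2col convolution, explicit backprop) —
sufficient because the desk-scale network is tiny and single-CPU.

Inference is tiled with feathered (linear-ramp) overlap blending; on an
image that fits one tile the blended path equals a direct whole-image
forward pass to ~1e-7, and the tiled-vs-direct contract is tested at 1e-5.

## Oriented cues

The local cue is the χ² distance between value histograms (12 equal-width
bins over the channel range, so the cue is invariant to affine rescaling of
a channel) of two half-discs split by a diameter at orientation θ, computed
by convolution per histogram bin. Orientation bins index the **boundary
tangent**: a vertical step edge peaks at θ = π/2. Half-discs falling
(almost) entirely outside the image carry no evidence and are zeroed.

Scales: disc radii (4, 8, 16) px. The lower radius is deliberately at the
crop-row stripe period (4–10 px): smaller discs fire on every stripe edge
inside a field, flooding the signal with clutter; at radius ≥ period the
stripe phases average out of both half-disc histograms while genuine
between-field transitions still respond. An optional texture channel (a
small even/odd oriented filter bank plus seeded k-means into 32 textons,
χ² over texton histograms at radius 10) adds orientation/period contrast
where mean intensities are similar.

Globalization (sPb): the max-over-orientations signal is downsampled ×4 by
block max; affinities between coarse pixels within radius 5 follow the
intervening-contour rule w = exp(−max-signal-on-line / 0.1); the smallest
generalized eigenvectors of (D−W)v = λDv (16, solved per connected
component via the normalized Laplacian with shift-invert) are upsampled,
smoothed (σ=1), and their directional derivatives along each orientation's
normal are summed with 1/√λ weights. Because a uniform affinity graph
yields eigenvectors that reflect only the grid's shape, the globalized
signal is gated by the input's own contrast (×max of input): a zero input
gives exactly zero oriented contrast. gPb = mPb + sPb, rescaled to [0, 1]
(global max by default; a percentile scale is available to clip rare
extreme responses, but did not help on the synthetic scenes and is off).

Combination with the FCN: the scalar probability is lifted to an oriented
signal — `replicate` copies it across orientations; the default
`structure-tensor` mode modulates it by cos² of the angle to the local
tangent (from the smoothed probability map's structure tensor), weighted by
the tensor's coherence so isotropic regions stay isotropic. Output =
α · lifted + (1−α) · gPb with α = 0.5 (the combination weight is not fixed
by prior art; equal weighting after normalizing both parents is the neutral
choice).

## OWT-UCM

The watershed floods the max-over-orientations surface from its regional
minima. Two numerical guards keep the finest partition an over-segmentation
of contour ridges rather than of per-pixel noise: a light pre-smoothing
(σ = 0.5) and h-minima suppression of minima shallower than 0.02 (both can
be disabled; a constant surface yields one region). Boundaries live on the
interpixel grid; maximal same-region-pair chains of edges, split at
junction corners (corners meeting ≥ 3 boundary edges), are arcs.

Arc re-weighting: arcs are cut into chains of ≤ 5 edges; the chain's
endpoint corners define its direction; each edge takes the oriented signal
(mean of its two flanking pixels) at the nearest orientation bin. Arc
strength is the mean over its edges.

UCM construction: repeatedly merge the pair of adjacent regions whose
common boundary (all shared edges) has the lowest average strength, with
ties broken by region ids; each merge is recorded at the running maximum of
averages, which enforces the ultrametric (averages can decrease after
merging). Pair averages are exact (sums/counts combined on merge, never
approximated); a lazy heap keyed by (average, pair) gives O(E log E)
overall. n finest regions always produce exactly n−1 merges. Thresholding
at k keeps edges with value > k; k = 0 preserves the full
over-segmentation and partitions at increasing k are nested.

The exported UCM raster assigns each pixel the max value of its incident
interpixel edges. The scene outline is a boundary of every partition at
every threshold and is written at strength 1.0 — reference boundary sets
include the scene frame, so detected/reference comparisons stay symmetric.

## Combinatorial grouping

Candidates are all hierarchy nodes plus connected pairs/triplets of
adjacent regions sampled at 12 levels along the merge sequence,
deduplicated by leaf set, capped at 2000 by score. The score is **UCM
persistence**: min over outer leaf-pair mean strengths (the level at which
the region would merge outward — image-frame sides count as 1.0) minus max
over interior ones (the level at which it became one piece), clipped at 0.
Complete fields persist longest; fragments die at their weakest ridge and
over-merged regions are born late. Two simpler scores were rejected during
design: mean-outer − mean-interior lets the root region dominate under
heavy over-segmentation (interior mean dilutes to ~0), and
mean-outer − max-interior lets late-merging single-cell fragments dominate.

Selection is greedy in decreasing score (ties: smaller area, then
lexicographic leaf order); a candidate is accepted if < 5% of its area is
already covered; candidates smaller than 0.4% of the scene are not
selectable (thin boundary-sliver watershed cells persist as long as their
surrounding ridge but are not fields, and neither are occluder-scale blobs such as tree canopies). Uncovered finest regions join the
adjacent accepted segment across the weakest separating boundary. The
output boundary set is always a subset of the finest partition's arcs plus
the frame; no boundary is invented, and no threshold parameter is needed.

## Evaluation

Detected strength maps are reduced to edgels by oriented non-maximum
suppression (local maximum along the gradient direction of the smoothed
map, bilinear ±1 px) before thresholding — morphological thinning of a
binarized wide band drifts and sprouts spurs, which measurably inflates
false detections; UCM rasters are already thin and skip NMS. Each skeleton
pixel becomes an edgel with orientation from PCA of skeleton points in its
5×5 neighbourhood.

Matching: a pair is admissible only within d_max pixels; cost =
distance/d_max + 0.1·Δθ/(π/2) with Δθ the acute orientation difference.
Cardinality is maximized before cost, implemented as a one-sided sparse
assignment: rows are the smaller edgel side, each with a private
"unmatched" dummy column at penalty s·max_cost + 1 (provably
cardinality-first; a uniform +1 shift keeps stored weights positive and is
neutral because every full matching has the same edge count). Large
instances are sparsified to the 10 nearest admissible partners per edgel
per side; the matching is exact whenever degrees are ≤ 10 (all small
instances, including the exhaustive-enumeration property test at ≤ 8
edgels per side) and a distance-dominated approximation otherwise.
P = matched/|detected|, R = matched/|reference| (0 conventions at empty
sets), F is their harmonic mean. d_max × resolution gives the ground
tolerance: 10 px = 5 m, 5 px = 2.5 m at 0.5 m. PR curves sweep evenly
spaced thresholds; error maps classify correct / missed / false edgels.

## Synthetic scenes

The generator emulates the smallholder mosaic the method assumes: Voronoi
cells of uniform seeds (one Lloyd step, then a 15% fraction of
adjacent-cell merges for irregular multi-edge fields), mean field area
0.22 ha at 0.5 m (~8800 px; the `sougoumba` preset is ~6× larger);
per-field base spectra from six crop archetypes (base level 0.32–0.74 with
a spectral tilt and N(0, 0.04) per-field jitter), assigned by greedy
coloring of the field adjacency so adjacent fields always differ — a
boundary marks a change of cultivation, so identical adjacent fields would
be a contradiction in terms; oriented sinusoidal crop-row stripes (period
4–10 px, relative amplitude 0.15, random per-field orientation); tree
discs (3 per ha, radius 3–8 px, dark canopy with offset shadow) whose
placement ignores field edges so canopies straddle boundaries; optional
bright road corridors (3–8 px wide) carved out of the field polygons; and
i.i.d. Gaussian noise (σ = 0.02) per band. All randomness flows through
one seeded generator; (params, seed) determine every output bit.

What the generator does **not** emulate: sensor PSF and atmospheric
effects, mixed cropping within a field, gradual boundary transition zones,
seasonal variability, and geolocation error in the reference. Passing the
end-to-end tests therefore shows the machinery is correct and that the
method solves scenes with the assumed statistical structure — it does not
certify accuracy on real WorldView imagery.

## Study conditions of the scaled-down experiment

The end-to-end experiment trains the tiny detector on 6 synthetic training
scenes (256×256 px) with 1536 patches of 48 px, batch 8, 12 epochs
(2304 iterations, ~9 minutes on one CPU), and evaluates on 3 held-out
scenes: best-threshold boundary F at d_max = 10 px over a 25-threshold UCM
sweep. Measured at these conditions (seed 7/101/202): mean best F ≈ 0.95
with the frame included on both sides (the generator's truth contract puts
the scene outline in the boundary set), and ≈ 0.92 when the frame is
excluded from both detection and reference — the score is carried by the
interior boundaries, not the frame.

## Known limitations

- The FCN engine is single-threaded numpy; the full 13-conv layout is
  expressible but impractical to train here.
- The matching's candidate pruning makes very large degenerate instances
  approximate (documented above); P/R differences are negligible in
  practice because costs are distance-dominated.
- Greedy UCM agglomeration with exact re-averaging is O(E log E) but the
  arc tracing is pure Python; tiles much beyond 1000×1000 px will be slow.
- The grouping score uses UCM persistence only; no learned region features
  (area, shape, spectral homogeneity) are used for ranking.
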