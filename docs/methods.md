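# Methods

This note records the models behind each `replikit` module, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a user may want to override.

## Coordinate conventions

All 3D grids are `(z, y, x)` with a per-axis voxel size in µm, default
`(0.29, 0.125, 0.125)` — the pitch of a typical high-NA confocal acquisition
with 290 nm z-steps. Every physical quantity (spot σ, distances, volumes,
thresholds fitted over radius) is computed in µm so results are invariant to
the grid anisotropy; voxel units appear only in array indexing and in the
"centroid error < 1 voxel" convention (per-axis µm error divided by that
axis's voxel size).

## Cell-cycle profiling

Model: a 15-min EdU pulse marks replicating cells; DAPI sum intensity is
proportional to DNA content (1x in G1, 2x in G2, in between during S).
Gating is two thresholds: EdU-positive → S; remaining cells split at a DAPI
cutoff between the 1x and 2x modes.

* Automatic EdU threshold: Otsu on `log(1+EdU)`. The log stabilizes the
  positive/negative separation under multiplicative intensity spread; a
  manual threshold overrides it (the split is ultimately an acquisition
  choice).
* Automatic DAPI cutoff: midpoint of the two most prominent histogram modes
  of the non-S cells (64 bins, lightly smoothed, peak prominence >= 10% of
  the tallest bin). If fewer than two modes are found, or the two modes are
  closer than a factor 1.3 (G2 carries ~2x the G1 content, so anything
  closer is one mode), the caller is told to supply a manual cutoff.
* Durations: `dt = ln2 * Δt / (ln N2 − ln N1)` (base-independent), and
  `duration_i = fraction_i * dt`. Sub-stage fractions (S I/S II/S III) are
  accepted as inputs — scoring the spatial patterns that define the
  sub-stages is a manual step and not automated here.
* EdU per nucleus defaults to the sum intensity; mean intensity is a column
  choice left to the caller (whether sum or mean is used upstream is an
  acquisition-dependent decision).

## 3D nucleus segmentation

Pipeline: Gaussian blur (xy radius 2 px; the z radius is divided by the
z/xy voxel ratio so the blur is isotropic in µm) → min–max normalization →
global threshold (Otsu by default) → keep largest 26-connected component →
2 dilations → 3D hole filling → 2 erosions. The symmetric dilate/erode pair
is a morphological closing that bridges small intensity dips at the rim; the
exact structuring iterations are exposed because the optimum depends on
nucleus size and noise. Because of the normalization the mask is exactly
invariant to affine intensity rescaling. A QC table (volume, surface,
sphericity, component count) replaces interactive mask inspection;
irregular, low-sphericity masks are the cases a user should review.

## 3D spot segmentation (replication foci / replicons / FISH spots)

1. **Preprocess**: per-slice 2D mean filter (radius 1 px) + min–max
   normalization. The filter is 2D deliberately: stack rank filters are
   conventionally per-plane, and on a grid whose z pitch is ~2.3x the xy
   pitch, averaging across planes flattens the intensity saddle between
   axially adjacent spots and merges their maxima.
2. **Seeds**: regional 3D maxima with prominence >= `h` (26-neighborhood,
   h-maxima transform). Default `h` = 5x the robust noise sd of the
   processed volume, with the raw-noise sd estimated from the MAD of first
   differences along x (structure cancels to first order) and propagated
   through the mean filter and normalization. Five sd keeps the expected
   number of false maxima across a ~10⁵-voxel nucleus well below one while
   remaining several-fold below the amplitude of any resolvable spot; at 3 sd
   roughly one noise maximum per nucleus survives, which is incompatible
   with exact counting. A per-slice 2D-maxima compatibility mode exists.
3. **Threshold**: per seed, least squares fit of `I(r) = A exp(−r²/2σ²) + B`
   to the radial mean profile (0.5-voxel bins out to 10 σ₀, out-of-mask
   voxels excluded); growth threshold `A exp(−k²/2) + B`. `k = 2` by default
   (~13.5% of amplitude above background), exposed as the one free parameter
   of the stopping rule. Fits that do not converge, give σ <= 0, or land at
   or below the in-mask noise floor (median + 2 sd) fall back to the
   half-height threshold `B + (A−B)/2` and are flagged.
4. **Growth and splitting**: each seed claims the connected component of
   voxels above its threshold inside a local window (4 σ_fit half-extent —
   an isolated spot reaches only k σ at its threshold); overlapping claims
   are resolved by marker-based 3D watershed on the inverted processed
   intensity. Objects under 5 voxels are discarded as shot noise.
5. **Features**: volumes (voxel count x voxel volume), intensity-weighted
   centroids, all-pairs Euclidean distances, and centroid-to-border
   distances (nearest background-adjacent mask voxel center; an edge-to-edge
   option exists). All in µm.

## Repli-FISH "AND" logic

Colocalization is the voxelwise conjunction of two binary masks; 26-connected
components of the intersection are the colocalizing objects, consistent with
the foci connectivity. "Associated" in the triple analysis (replicating rDNA
vs RPA 194) means >= 1 shared voxel; a dilation tolerance (default 0) can
absorb registration slack between sequential hybridizations, which are
otherwise assumed perfectly registered. Timing profiles divide each cell's
probe-in-RFi sum intensity by the median over early-S (S I) cells of the same
probe (and cell line), so the S I median fold change is 1 by construction;
cells with zero probe-in-RFi signal are kept (a zero is informative — the
repeat is not replicating), with a flag to drop them.

## Fork-speed proxy

`R = Σ EdU / Σ PCNA` over nucleus voxels, background-subtracted per channel
(background = histogram mode of in-mask, outside-foci voxels). PCNA counts
active replisomes; EdU integrates nucleotides incorporated during the pulse;
their ratio tracks synthesis per replisome, i.e. relative fork speed. The
ratio is only meaningful after dividing by a normalization-group median
(default: per cell line, pooling stages, so stage-to-stage comparisons remain
honest); the normalized statistic is invariant to global channel gains. A
volume-ratio mode (segmented EdU volume / segmented PCNA volume) is provided
for the spatial overlap reading of the statistic; both can be reported.

## Chromatin compaction classes

Gaussian-emission hidden Markov random field on in-mask DAPI intensities:
K = 7 classes, Potts prior on the 6-neighborhood with coupling β (default
1.0), fitted per nucleus — never pooled across cells, so staining variation
between samples cancels. Inference is EM for the class means/variances
alternating with checkerboard ICM label updates; iteration stops when fewer
than 0.1% of labels change (max 50 iterations; non-convergence returns the
best labeling with a warning). Initialization places class means linearly
between the 1st and 99th intensity percentiles and assigns voxels to the
nearest mean — affine-equivariant, and free of the tie problems quantile
binning has on near-discrete histograms. Classes are relabeled by ascending
mean, so class 1 (dimmest) is the IC, 2–4 the ANC and 5–7 the CDC/INC.
With β = 0 the procedure is classification-EM on a plain Gaussian mixture
(the test suite cross-checks this against an independent mixture
implementation). ICM is deterministic by design: identical inputs give
identical labelings without a sampler seed. Signal mapping is intensity
weighted: `fraction_c = Σ I(v) over (class c ∩ signal mask) / Σ I(v) over
signal mask`, so bright spots dominate and dim tails contribute little.

## Origin interval analytics

Intervals are 0-based half-open with `mid = floor((start+end)/2)`. Merging
follows distance-`d` semantics (same-chromosome gap <= window → coalesce
into the span), matching the behavior of the standard interval-merge tool;
the test suite checks equivalence against an independent O(n²) union-find
oracle and against `bedtools merge -d` itself. IODs are strictly
intra-chromosomal mid-to-mid gaps, pooled across chromosomes for the summary
mean/median (a per-chromosome table is also emitted). Overlap counts an
interval as shared on >= 1 bp intersection with no reciprocal-fraction
requirement; because the percentage depends on the reference set, both
directional percentages and a union-based percentage are reported.

Upstream peak generation is documented, not implemented: trim reads
(Trimmomatic), align to hg38 (`bowtie2 --very-sensitive --end-to-end`),
then `macs2 callpeak -t <sample> --gsize 2.7e9 -q 0.001 --min-length 200`
without control, or use deposited peak files where available. Those steps
require the public SNS-seq accessions and hours of compute, so the package
consumes their BED/narrowPeak outputs.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the
benchmark conditions and were fixed once, on realism grounds:

* **Geometry**: ellipsoidal nucleus, semi-axes (3.5, 6, 6) µm in a
  32 x 128 x 128 grid at (0.29, 0.125, 0.125) µm voxels — a ~520 µm³
  nucleus, typical for cultured human cells.
* **DAPI texture**: Potts-coupled label field (6-neighborhood, β = 1,
  50 checkerboard Gibbs sweeps — approximate sampling is sufficient for
  recovery benchmarks) with class means 100, 130, …, 280 over a background
  of 10. The base is set well above background because real DAPI-stained
  chromatin is everywhere much brighter than the outside of the nucleus;
  the 30-unit step against 10-unit read noise gives 3 sd class separation.
* **Spots**: isotropic 3D Gaussians in µm (σ = 0.25 µm), rendered onto the
  anisotropic grid; amplitude 100 over background 10 with Gaussian read
  noise sd 10 (SNR 10) plus Poisson shot noise on the clean signal — the
  standard fluorescence noise model. Placement is rejection sampling with a
  4 σ minimum separation (dispersed mode; peripheral and clustered modes
  emulate the mid- and late-S spatial patterns). When a colocalization pair
  is planted the default separation is 6 σ: a segmented mask extends ~2 σ at
  the k = 2 threshold, so 4 σ spacing would let non-partner masks touch and
  make the planted colocalization count ambiguous.
* **Colocalization / ratio controls**: a stated fraction of probe spots
  reuses target centroids exactly; the EdU channel is rescaled so the
  background-subtracted EdU:PCNA total-signal ratio equals the requested
  value before noise.
* **Populations**: exact class counts (largest-remainder rounding) with
  G1 DAPI ~ N(1000, 5% cv), G2 at 2x, S uniform in between; EdU 500 ± 50
  for S cells vs 20 ± 5 otherwise.
* **Origins**: mid-to-mid gaps from a lognormal with ~34 kb mean by default
  (a typical unclustered inter-origin spacing) or any user-supplied gap
  sampler; truth records the planted mids and gaps.

What the generator does **not** emulate: point-spread-function anisotropy
and deconvolution artifacts, intensity falloff with depth, chromatic
misregistration, nucleoli and other subnuclear intensity structure,
spot-size and amplitude heterogeneity, and cell-to-cell variability in all
of the above. Passing the recovery benchmarks therefore demonstrates the
correctness of the algorithms under the stated noise model, not performance
on real acquisitions, where parameters (h, k, β, morphology iterations) may
need tuning and masks deserve QC review.

## Problem sizes and determinism

The test suite and the acceptance script run simulations at the sizes above
(20 nuclei for spot-recovery, 10 replicate nuclei for the compaction
benchmark, 100 random interval sets for the merge oracle), which the whole
suite completes in a couple of minutes on one CPU. Every stochastic step
consumes a `numpy` `default_rng` seeded from the caller; identical seeds
give bit-identical volumes, tables and CSVs (the pipeline manifest records
the config hash and seed for provenance).

## Known limitations

* Single-nucleus frames only; multi-nucleus scenes must be cropped upstream
  (the 2D screen segmentation handles crowded fields, the 3D path does not).
* The Gaussian radial model assumes approximately isotropic spots in µm;
  strongly elongated objects get conservative thresholds via the fallback.
* ICM finds a local optimum of the HMRF posterior; with weak class
  separation (< 2 sd) accuracy degrades and the β prior dominates.
* The fork-speed statistic is a proxy — it does not measure kb/min and is
  only comparable within a normalization group.
* No drift/registration correction across sequential hybridizations.
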