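# replikit

Single-cell image and interval analytics for genome-replication progression.

DNA replication in human nuclei is organized in microscopically resolvable
**replication foci (RFi)** — clusters of active replisomes labeled by EdU
pulse incorporation or by PCNA immunostaining. How foci counts, sizes,
spatial arrangement, underlying chromatin compaction, and the replication
timing of repeat elements (rDNA, centromeres, Alu, LINE1) change between
pluripotent and somatic cells is a quantitative-imaging question: it takes
3D spot segmentation on anisotropic confocal/super-resolution stacks,
mask-logic colocalization, voxel-level chromatin classification, and
interval analytics on sequencing-derived replication-origin maps. `replikit`
packages those operations as a tested, reusable pipeline for microscopists
and computational biologists, together with a synthetic-data generator that
plants known ground truth so every step can be benchmarked.

## What it computes

* **Cell-cycle profiling** (`replikit.cellcycle`) — gate cells into G1/S/G2
  from DAPI sum intensity (DNA content) and EdU level, then convert fractions
  to absolute durations via the doubling time
  *dt = (log 2 · Δt) / (log N₂ − log N₁)* and *duration = fraction × dt*.
* **3D nucleus masks** (`replikit.nucleus3d`) — Gaussian blur → normalization
  → Otsu → largest component → dilate/fill/erode; channels are masked by
  voxelwise minimum with the nucleus mask.
* **3D spot segmentation** (`replikit.foci3d`) — per-slice mean filter and
  normalization; 3D maxima with prominence *h* as seeds; for each seed a
  least-squares fit of *I(r) = A·exp(−r²/2σ²) + B* to the radial mean profile
  sets the growth threshold *A·e^(−k²/2) + B* (default *k = 2*); seeded
  region growth with marker-based 3D watershed splits touching foci. Features
  (volumes, all-pairs distances, distance to nuclear border) come out in µm
  honoring the anisotropic voxel size (default 0.125 × 0.125 × 0.29 µm).
* **Repli-FISH "AND" logic** (`replikit.replifish`) — voxelwise conjunction
  of probe and RFi binary masks; connected components of the intersection are
  the repeats replicating at fixation time. Probe-intensity fold changes are
  normalized to the early-S (S I) median; a third mask (RPA 194) gives the
  replication–transcription association fraction of rDNA.
* **Fork-speed proxy** (`replikit.forkspeed`) — R = Σ EdU / Σ PCNA per
  nucleus: nucleotides incorporated per active replisome; ratios are
  normalized by group medians so channel gains cancel.
* **Chromatin compaction classes** (`replikit.compaction`) — a Gaussian-
  emission hidden Markov random field (Potts spatial prior, EM + ICM) assigns
  each nuclear voxel to one of 7 DAPI-intensity classes: class 1 =
  interchromatin compartment (IC), 2–4 = active nuclear compartment (ANC),
  5–7 = chromatin domain clusters / inactive compartment (INC). Signals are
  mapped onto classes with intensity weighting.
* **Origin analytics** (`replikit.origins`) — BED/narrowPeak parsing,
  bedtools-style distance-window merging, inter-origin distances (IOD,
  mid-to-mid within chromosomes), cluster-count profiles at 10/20/30 kb, and
  between-set overlap percentages.
* **Synthetic data** (`replikit.simulate`) — ellipsoidal nuclei with
  Potts-textured 7-class DAPI, planted Gaussian spots (dispersed /
  peripheral / clustered), controllable colocalization fraction and EdU:PCNA
  ratio, planted cell populations and origin interval sets — all
  bit-reproducible under a seed.

## Worked example

```python
import numpy as np
from replikit.simulate import NucleusSimSpec, generate_nucleus_volume
from replikit import nucleus3d, foci3d

spec = NucleusSimSpec(seed=42, n_spots={"pcna": 50})   # SNR 10, sep >= 4 sigma
channels, truth = generate_nucleus_volume(spec)
mask = nucleus3d.segment_nucleus_3d(channels["dapi"])
pcna = nucleus3d.mask_channel(channels["pcna"], mask)
spots = foci3d.segment_spots(pcna, mask=mask.data)
feats = foci3d.spot_features(spots, mask)
print(f"nucleus volume: {mask.volume_um3:.1f} um^3")
print(f"replication foci detected: {feats.n_spots} (planted: 50)")
print(f"median focus volume: {np.median(feats.volumes_um3):.3f} um^3")
print(f"median inter-foci distance: {np.median(feats.pair_distances_um):.2f} um")
print(f"median distance to nuclear border: {np.median(feats.border_distances_um):.2f} um")
```

prints

```
nucleus volume: 519.8 um^3
replication foci detected: 50 (planted: 50)
median focus volume: 0.614 um^3
median inter-foci distance: 4.93 um
median distance to nuclear border: 0.99 um
```

— all 50 planted foci are recovered inside the ~520 µm³ nucleus; the
~0.6 µm³ focus volume corresponds to the planted 0.25 µm spot width at the
*k = 2* threshold, and the distance features quantify the dispersed spatial
pattern typical of early S phase. The same applies to origin sets:

```python
from replikit.simulate import generate_origin_bed
from replikit.origins import cluster_count_profile, inter_origin_distances

origins, truth = generate_origin_bed({f"chr{i}": 200 for i in (1, 2)}, seed=42)
print(cluster_count_profile(origins).to_string(index=False))
print(f"mean IOD: {inter_origin_distances(origins).mean/1000:.1f} kb")
```

```
 window  n_origins
      0        400
  10000        396
  20000        311
  30000        201
mean IOD: 33.6 kb
```

Merging at growing windows collapses closely spaced origins into clusters —
the count drops from 400 to 201 at 30 kb — and the ~34 kb mean IOD matches
the planted gap distribution.

A `replikit` command-line tool wraps the same operations
(`replikit simulate|cellcycle|segment|foci|replifish|forkspeed|compaction|origins|run`);
see `replikit --help`.

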