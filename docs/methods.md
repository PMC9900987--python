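# Methods

This note documents the models and procedures implemented in `scmst`, the
assumptions behind them, the parameters that matter, and what the synthetic
benchmark does and does not demonstrate.

## Acquisition model and conventions

The pipeline targets serial-hybridization smFISH: in each round, a small set
of genes (five by default) is read out on separate fluorescence channels,
signal is stripped, and the next probe set is hybridized on the same
section. Gene identity is therefore a plain `(round, channel) → gene`
codebook lookup — there is no combinatorial barcode and no error-correcting
decoding. Reference channels (membrane immunostain and DAPI) ride along for
segmentation and registration.

Conventions used everywhere: 0-based voxel indices in `(z, y, x)` order,
half-open bounding boxes, label 0 = background, voxel size in µm per axis
(default `(0.5, 0.2, 0.2)`: 0.5 µm optical sectioning, ~0.2 µm pixels at
63× on a 13 µm-pixel camera).

## Pre-filtering

**Flat-field estimation** (`imageprep.estimate_flatfield`) is retrospective:
the per-pixel median over many z-planes of one channel is robust to the
sparse spot content and retains the smooth multiplicative shading, which is
then regularized either by a least-squares polynomial surface fit (order 2,
the default — exact for the low-order shading a microscope produces and
free of the edge bias a large-kernel smoother introduces) or by heavy
Gaussian smoothing (`method="median-smooth"`). Fields are normalized to
spatial mean 1; correction is `(I − darkfield)/F`, clipped at 0. Darkfield
estimation (1st percentile across planes) is off by default. At least 2
planes are required, ≥ 8 recommended.

**Denoising** is a 3×3×3 median filter (`scipy.ndimage.median_filter`,
reflected borders), applied to gene channels only, after flat-field
correction and before detection.

**Registration** (`imageprep.register_rounds`) is integer-voxel translation
only — rounds are imaged on the same mounted coverslip, so residual motion
is translational stage drift; rotation, scaling and nonrigid motion are out
of scope. The shift maximizing cross-correlation (FFT on mean-subtracted
volumes, restricted to a ±`max_shift` window) is returned with the exact
Pearson correlation of the overlapping region as a confidence score; scores
below 0.2 are flagged low-confidence. The pipeline registers each round's
DAPI channel to round 0 and applies the negated shift to all channels with
constant fill. The strips invalidated by the fill are tracked as a validity
mask: candidate spots inside them are discarded, because filter responses
at a fill edge are artifacts and the underlying tissue was never imaged in
that round.

## Segmentation

The learned 3D segmenter of the original workflow is deliberately replaced
by a classical seeded watershed (and by ingestion of externally produced
label masks, which are first-class input). Seeds are local maxima of the
Gaussian-smoothed DAPI channel above its Otsu threshold, separated by at
least 3 µm; local maxima rather than threshold components, so adjacent
nuclei whose smoothed tails touch still seed separate cells. Because cell
interiors are as dark as the outside of the tissue, background cannot be
identified by intensity — enclosure by the membrane ring is the cue. A
generous tissue mask is built by filling the thresholded membrane ring
plane-wise (a cell clipped by the stack border is open in 3D but still
ringed in every xy section); the complement of that mask seeds a background
basin, and flooding the membrane elevation from nuclei plus background
markers places each cell/background boundary on the ridge crest. Labels are
relabeled `1..K` by centroid lexicographic order (deterministic output);
cells under `min_cell_volume` (µm³) are dropped; cells touching the xy
border are kept but flagged.

On simulated fields this recovers ≥ 90% of cells 1:1 at IoU ≥ 0.5 (median
IoU ≈ 0.99) when cells lie within the frame; cells clipped by the xy image
border lose their membrane enclosure and may be flooded by the background
basin, which is why the segmentation benchmark scenes place centroids at
least one cell radius from the border. Real tiles do contain clipped cells;
those are exactly the cells the border flag marks for exclusion or
cross-tile handling.

## Spot calling and gating

**Detection** is scale-normalized Laplacian-of-Gaussian filtering at the
PSF scale (default σ = (0.5, 0.25, 0.25) µm → (1.0, 1.25, 1.25) voxels)
followed by local-maximum extraction (`min_distance=1`, i.e. a 3³
neighborhood — larger suppression boxes veto genuine neighbors at ~3σ
separation) above an absolute response threshold (`min_peak=30` a.u. for
the default intensity scale; set relative to the camera noise floor, not to
the signal level, so dim unspecific dots are still detected and left for
the gate to classify).

**Gating** runs 2-means per `(fov, round, channel)` group on log10 peak
intensity. Grouping per channel is essential: exposure times and laser
powers differ per fluorophore, so intensities are not comparable across
channels. The higher-mean cluster is labeled `signal`, the rest
`unspecific`; the decision depends only on cluster means, never on label
ids, so it is invariant to any relabeling of the clusters. For the default
k = 2 on a single feature the partition is computed exactly: the global
2-means optimum in 1-D is a contiguous split of the sorted values, found by
prefix-sum enumeration of all n−1 splits (ties broken toward the higher
threshold). k > 2 or multi-feature gating falls back to seeded
k-means++ (`sklearn`). Groups with fewer than k spots or zero variance are
labeled all-signal with a warning. Spots are labeled, never deleted;
downstream counting uses `class == "signal"` only.

## Counting

A spot belongs to the cell whose label contains its rounded voxel; spots on
label 0 or out of bounds are unassigned and excluded. Counts are tallied per
gene per cell over all fields of view, with global cell ids
`fov * 100000 + local_label`. FOVs are treated as disjoint after an optional
overlap trim (`fov_trim` x-columns of every FOV after the first; cells with
centroids inside the trim are dropped) — a simple, testable double-counting
rule; the default trim is 0 (tiles assumed pre-cropped to disjoint regions).
QC filters (`min_spots_per_cell`, `min_cell_volume`) default to off: the
reference workflow applies no count-level filters. The gene axis always
carries the full panel in codebook order, even for all-zero genes.

## Normalization, clustering, gating

**z-scores** are per gene within normalization groups:
`per_stage` pools all fields of view of one developmental stage into one
group (so "high"/"low" calls are consistent across a cross-section);
`cross_stage` pools every cell into a single group for between-stage
comparison, optionally followed by `zscore_through_genes`, a second
standardization of each cell's profile across the panel. The standard
deviation is the population convention (divide by n), so a two-cell group
with counts [1, 3] gives exactly z = ±1. Zero-variance gene/group pairs are
set to 0 and flagged rather than propagating NaN. Input is raw counts by
default (`log1p` optional); the z-score itself already removes per-gene
scale, and the NB counts at this panel's expression levels are not so
skewed that the gate or clustering changes qualitatively under log1p.

**Clustering** is agglomerative on cell z-profiles via
`scipy.cluster.hierarchy`; defaults are correlation distance with average
linkage (the common choice for expression heatmaps, insensitive to a cell's
overall detection efficiency), with euclidean/ward and complete linkage
available (ward restricted to euclidean). Flat clusters come from cutting
at a user-chosen `n_clusters` — cluster number is a deliberate user choice,
matching how stage-specific heatmaps are cut by inspection; no automatic
model selection is attempted. Display order is dendrogram leaf order.

**Co-expression gating** is a strict intersection: cell ∈ gate ⇔ z > 0
(strictly above the gene mean) for *every* gene of the module. Named
modules: pluripotency (*PouV/Oct4, Nanog, Klf4*), pan-ectoderm (those plus
*Tfap2A, Sox2*), neural crest (*Foxd3, cMyc, Pax7, Snai2, Sox10, Sox9*),
neural (*Nestin, MycN, Msi1*). Adding a gene can only shrink the gate.

**Back-mapping** paints each cell's projected footprint (max-label
z-projection by default, matching how 2D figures summarize a 20 µm section;
single-plane mode available) with its subpopulation or gate color; uncolored
cells are neutral gray, background black, with an optional grayscale
underlay. Rasterization is a pure per-pixel label→color lookup and is
independent of cell iteration order.

## The synthetic-data generator

`synth.simulate_section` emulates the acquisition end to end: cells are
clipped 3D Voronoi territories around random centroids in a slab (minimum
centroid separation 1.5× the 3.6–4.5 µm cell radius, placed by rejection
sampling; committed programs confined to medio-lateral x-bands of the
footprint, the stem program full-width); the membrane channel is the
smoothed ridge image of territory boundaries and DAPI a Gaussian blob per
nucleus; per-cell, per-gene transcript counts are negative-binomial (mean
µ_g, dispersion r = 8 — overdispersed, giving clustering realistic
within-program variance); spots are 3D Gaussians at the PSF σ with
intensities N(900, 120²) a.u. for signal; unspecific background dots are
uniform in the volume at 12 per 1000 µm³ with intensities N(250, 60²) —
about 3.6× dimmer than signal, the "low intensity" population the gate
removes; each (round, channel) gets a random multiplicative quadratic
illumination field of ±30% amplitude; each round after the first gets an
integer drift (±1 z, ±3 xy voxels by default), applied before illumination;
the camera adds a 100 a.u. baseline and N(0, 25²) read noise, on a 12-bit
intensity scale. The paper-fixed geometry — 0.5 µm z-spacing, five genes
per round, six rounds, a 30-gene panel, three fields of view — is the
default; volume extent and cell number are desk-scale choices.

Two idealizations matter for interpreting results:

- **Placement is authoritative.** NB draws are targets; a spot that cannot
  be placed at the minimum PSF-normalized separation (3.2σ by default, 4σ
  in the noiseless preset) within the retry budget is dropped, and
  `true_counts` always equal the spots actually rendered. Spots are also
  kept ≥ 2 voxels from cell boundaries and volume faces. Ground truth is
  therefore resolvable by construction. Real transcripts co-locate below
  the diffraction limit; a real pipeline undercounts dense cells, and
  passing the exact-conservation tests here says nothing about that regime.
- **No optics beyond a Gaussian PSF.** No photobleaching, no stripping
  chemistry residue, no chromatic aberration, no autofluorescence texture;
  background is spatially uniform. Passing tests demonstrate the pipeline's
  logic and numerics, not robustness to every real-world artifact.

All randomness flows from `SimConfig.seed` through named substreams
(`numpy` `SeedSequence` spawn keys per field of view and purpose), so
identical configs give bit-identical outputs, and the counts-only path
(`simulate_counts`) is independent of image rendering.

Preset summary (chosen once at generator design time):

| preset | use | key values |
|---|---|---|
| `SimConfig()` / `counts_config()` | clustering & gating benchmarks (no images) | 4 programs, high µ = 20, stem baseline 3, low 0.8, r = 8; 2000 cells on a 120×120 µm footprint |
| `default_config()` | image-mode benchmarks at default SNR | same programs moderated (high µ = 8, stem 1.5, low 0.5) and 4.5 µm cells, so per-channel spot density stays below the random-packing limit of the PSF exclusion volume; 54 cells / 3 FOVs of 24×24×10 µm |
| `noiseless_config()` | degenerate exactness regime | 10 genes / 2 rounds, 16 cells, high µ = 4, no background dots, flat field, zero drift, zero noise, zero jitter, 4σ spot separation |

## Pipeline composition and reproducibility

`run_pipeline` executes simulate → preprocess → segment → detect → gate →
quantify → cluster → gate-modules → render, each stage consuming the
previous stage's outputs; segmentation can be swapped for ground-truth
labels or an external mask. Every output file's SHA-256 goes into
`manifest.json` together with the fully resolved configuration and seed;
wall-clock timings go to the log, never the manifest, so two runs with the
same config and seed produce byte-identical manifests and outputs (TIFFs
are written without timestamps or UUIDs for the same reason). The k-means
gate and the simulator draw from named substreams of the run seed, so
stages can be rerun independently with identical results.

In the noiseless preset the gate stage is disabled: with no unspecific dots
there is no second intensity population, and 2-means on a unimodal sample
would split it arbitrarily. The gate exists to remove a population that
this preset deliberately does not generate.

## Problem sizes used by the test-bench and acceptance script

Registration: 20 stacks of 24×64×64 with shifts uniform in [−8, 8]³.
Median-filter oracle: 50 random 8³ volumes. Flat-field: 10 planted ±30%
quadratic fields, 20 planes of 64². Detection/counting at default SNR: the
`default_config` SNR and density at a reduced readout (2 rounds / 10 genes,
1 FOV, 18 cells) so repeated full-pipeline runs stay fast; noiseless
exactness on the full `noiseless_config`. Segmentation: 50 cells in a
64×64×10 µm field. Clustering/gating: 2000 cells × 30 genes per seed;
merge-sequence oracle at n = 5. Gate equivalence: 100 random 8×25
matrices. Back-mapping: 10 random label fixtures. Determinism: two full
runs of the reduced noisy preset.

## Known limitations

- Integer-voxel registration only; subvoxel drift becomes localization
  error (< 1 voxel) that the 2-voxel match radius absorbs.
- The watershed stand-in needs a membrane-enclosed geometry; it is not a
  replacement for a learned segmenter on real tissue, and xy-border-clipped
  cells are unreliable (flagged, not fixed).
- No spot-shape scoring, no subpixel Gaussian fitting, no deduplication
  across rounds (sequential readout makes the latter unnecessary).
- Per-optical-plane counting is not offered; counts are over 3D cell
  volumes.
- The per-stage heatmap cut (`n_clusters`) is user-chosen; ARI benchmarks
  use the planted number of programs.
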