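# scmst

A tested, reusable pipeline for **single-cell multiplex spatial
transcriptomics by serial smFISH**: multi-round, multi-channel 3D image
stacks in; a gene × cell transcript count matrix with preserved spatial
positions out — plus the downstream normalization, subpopulation
clustering, co-expression gating, and tissue back-mapping that turn that
matrix into biology.

It is written for labs doing sequential-hybridization imaging (one gene per
round × channel pair, e.g. five HCR-amplified genes per round over six
rounds for a 30-gene panel, three fields of view per cryosection), and for
anyone who wants a fully ground-truthed synthetic benchmark for such
pipelines: every stage here can be scored against a simulator that knows
the answer.

## The pipeline

For each field of view, with stacks $I_{r,c}(z, y, x)$ for round $r$ and
channel $c$:

1. **Illumination correction** — a retrospective flat-field $F_{r,c}(y,x)$
   (smooth, multiplicative, mean 1) is estimated from the per-pixel median
   over z-planes and divided out: $I' = (I - D)/F$.
2. **Denoising** — 3×3×3 median filter ahead of spot detection.
3. **Round registration** — the integer translation $\hat{s}_r =
   \arg\max_s \mathrm{NCC}(I_0, T_s I_r)$ over a ±`max_shift` window,
   estimated on the DAPI reference channel and applied to all channels;
   strips invalidated by the translation are masked out downstream.
4. **Segmentation** — seeded 3D watershed: DAPI maxima seed basins, the
   membrane stain is the elevation map, a background basin keeps label 0
   outside the tissue. Precomputed label masks are accepted as first-class
   input instead.
5. **Spot detection** — scale-normalized Laplacian-of-Gaussian maxima at
   the PSF scale; one candidate spot per maximum above threshold.
6. **Intensity gating** — per (FOV, round, channel), 2-means clustering of
   $\log_{10}$ peak intensity; the higher-mean cluster is *signal*, the
   lower is *unspecific* (non-specifically bound probe shows up as dim
   dots). For $k=2$ on one feature the partition is computed exactly as
   the optimal contiguous split of the sorted values.
7. **Decoding & counting** — gene identity is the codebook lookup
   $(r, c) \mapsto g$; each signal spot is assigned to the cell whose 3D
   label contains its voxel; counts $X_{gc}$ are tallied per gene per cell.
8. **Normalization** — gene-wise z-scores
   $z_{gc} = (X_{gc} - \mu_g)/\sigma_g$ within normalization groups:
   per stage (pooling its fields of view) or across all pooled stages,
   with population-σ convention and an optional second standardization
   through genes.
9. **Clustering & gating** — agglomerative clustering of cells on their z
   profiles (correlation distance, average linkage by default) into
   subpopulations; named gene modules (pluripotency = *PouV/Oct4, Nanog,
   Klf4*; pan-ectoderm adds *Tfap2A, Sox2*; neural crest; neural) are
   gated by strict co-expression: a cell passes iff $z_{gc} > 0$ for every
   module gene.
10. **Back-mapping** — each cell in the original section image is painted
    with its subpopulation or gate color on a z-projection of the label
    volume.

## The simulator

`scmst.synth` generates complete sections with ground truth for every
stage: cells as clipped 3D Voronoi territories in a slab (membrane ridge +
DAPI blob reference channels), per-cell negative-binomial expression from
planted subpopulation programs with spatial domains, diffraction-limited
3D Gaussian spots plus low-intensity unspecific background dots, smooth
quadratic illumination fields, camera noise, and inter-round drift. Ground
truth (label volume, spot table, count matrix, program labels, applied
shifts and flat-fields) is exact by construction.

## Worked example

End-to-end on a simulated section (three FOVs, 30 genes over 6 rounds,
watershed segmentation, K-means gating):

```python
from scmst import RunConfig, run_pipeline, default_config

cfg = RunConfig(out_dir="runs/demo", sim=default_config(seed=1), seed=1)
result = run_pipeline(cfg)
counts = result.counts
print(f"count matrix: {counts.n_genes} genes x {counts.n_cells} cells, "
      f"{counts.counts.sum()} transcripts")
print(f"estimated round shifts (FOV 0): {[s.shift for s in result.shifts[0]]}")
gate = result.gates["pluripotency"]
print(f"pluripotency gate (Nanog+PouV+Klf4, all z>0): "
      f"{len(gate.cell_ids)}/{counts.n_cells} cells "
      f"({100*len(gate.cell_ids)/counts.n_cells:.1f}%)")
```

prints

```
count matrix: 30 genes x 48 cells, 1738 transcripts
estimated round shifts (FOV 0): [(0, 0, 0), (1, 1, 2), (0, 0, 2), (0, 2, 2), (-1, -3, -2), (0, -3, -2)]
pluripotency gate (Nanog+PouV+Klf4, all z>0): 6/48 cells (12.5%)
```

The 48 cells are the watershed's recovery of the 54 simulated cells; the
shift estimates are the simulator's planted drift, recovered exactly. The
gate reports the cells above the mean for all three pluripotency genes.

Clustering at scale runs on the counts-only simulator (no images):

```python
from sklearn.metrics import adjusted_rand_score
from scmst import counts_config, simulate_counts
from scmst.clustermap import GeneModule, gate_coexpression, hierarchical_cluster, zscore

cm, subpop, _ = simulate_counts(counts_config(seed=1, n_cells=2000))
zm = zscore(cm, mode="cross_stage")
assignment = hierarchical_cluster(zm, n_clusters=4)
print("ARI vs planted programs:",
      round(adjusted_rand_score(subpop.loc[assignment.assignment.index],
                                assignment.assignment), 3))
gate = gate_coexpression(zm, GeneModule.named("pan_ecto"))
print(f"pan-ectoderm gate: {len(gate.cell_ids)}/{cm.n_cells} cells "
      f"({100*len(gate.cell_ids)/cm.n_cells:.1f}%)")
```

prints

```
ARI vs planted programs: 1.0
pan-ectoderm gate: 369/2000 cells (18.4%)
```

— the four planted programs (three committed, one uncommitted stem group)
are recovered perfectly, and the 5-gene pan-ectoderm gate selects a subset
dominated by the planted stem cells.

A `scmst` command-line interface wraps every stage
(`simulate`, `preprocess`, `segment`, `detect`, `gate`, `quantify`,
`cluster`, `gate-modules`, `render`, `run`); see `scmst --help`.

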