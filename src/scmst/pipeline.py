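"""End-to-end pipeline composition and the run manifest.

``run_pipeline`` executes the enabled stages in their documented order —
simulate -> preprocess (flat-field, median filter, round registration) ->
segment -> detect -> gate -> quantify -> cluster -> gate_modules -> render —
with each stage consuming the previous stage's declared outputs.  Every
output file is hashed into ``manifest.json`` so that reruns with the same
configuration and seed can be verified byte-identical.  All stochastic
stages draw from named substreams of the run seed and no wall-clock data
enters the manifest (timings go to the log), so manifests are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .clustermap import (
    GENE_MODULES,
    GeneModule,
    gate_coexpression,
    hierarchical_cluster,
    plot_heatmap,
    zscore,
)
from .errors import ConfigurationError
from .imageprep import (
    RoundShift,
    correct_illumination,
    estimate_flatfield,
    median_filter_3d,
    register_rounds,
    translate,
)
from .quantify import assign_spots_to_cells, build_count_matrix
from .render import backmap, save_backmap
from .segment import LabelVolume, load_labels, save_labels, segment_cells
from .spots import decode_gene, detect_spots, kmeans_signal_gate
from .synth import SimConfig, simulate_section

logger = logging.getLogger("scmst")

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

PALETTE = [
    (0.9, 0.1, 0.1), (0.1, 0.4, 0.9), (0.1, 0.7, 0.2), (1.0, 0.8, 0.1),
    (0.7, 0.2, 0.8), (0.9, 0.5, 0.1), (0.2, 0.8, 0.8), (0.6, 0.4, 0.2),
    (0.9, 0.4, 0.6), (0.4, 0.6, 0.1), (0.3, 0.3, 0.9), (0.5, 0.5, 0.5),
]


@dataclass
class RunConfig:
    """Every stage parameter of one pipeline run, fully serializable."""

    out_dir: str
    sim: SimConfig | None = None
    mask_paths: dict[int, str] | None = None   # precomputed label masks
    use_true_labels: bool = False              # ground-truth segmentation
    # preprocess
    median_kernel: int = 3
    max_shift: int = 6
    flatfield_method: str = "median-poly"
    # detect
    detect_sigma: tuple[float, float, float] | None = None  # voxels
    detect_min_distance: int = 1
    detect_min_peak: float = 30.0
    # gate
    gate_enabled: bool = True
    kmeans_k: int = 2
    # quantify
    min_spots_per_cell: int = 0
    min_cell_volume: float = 0.0
    # cluster / modules
    zscore_mode: str = "per_stage"
    n_clusters: int = 4
    cluster_metric: str = "correlation"
    cluster_linkage: str = "average"
    modules: list[str] = field(
        default_factory=lambda: ["pluripotency", "pan_ecto", "nc", "neural"]
    )
    # render
    render_projection: str = "max_z"
    seed: int = 0

    def effective(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunResult:
    """Key objects of a finished run, plus where everything was written."""

    run_dir: Path
    manifest: dict
    counts = None
    zmat = None
    assignment = None
    gates: dict = field(default_factory=dict)
    shifts: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)
    spots = None


def _valid_box(
    shape: np.ndarray, shift: np.ndarray, margin: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open voxel box still valid after undoing ``shift``.

    Undoing a round shift fills a strip of width |shift| at one border per
    axis; an extra ``margin`` absorbs filter edge effects next to it.
    """
    lo = np.maximum(-shift, 0)
    hi = shape - np.maximum(shift, 0)
    lo = np.where(lo > 0, lo + margin, lo)
    hi = np.where(hi < shape, hi - margin, hi)
    return lo, hi


def _hash_outputs(run_dir: Path, paths: list[Path]) -> dict[str, str]:
    return {
        str(p.relative_to(run_dir)): sio.file_sha256(p)
        for p in sorted(paths)
    }


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the pipeline per ``config`` and write a hashed manifest.

    Currently the first stage is the simulator (raw-microscope ingestion
    uses the same downstream path via the library API); segmentation can be
    replaced by ground-truth labels or precomputed masks.
    """
    if config.sim is None:
        raise ConfigurationError(
            "run_pipeline requires a simulation config as its input stage"
        )
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "scmst",
        "seed": config.seed,
        "config": config.effective(),
        "stages": {},
    }
    result = RunResult(run_dir, manifest)
    t0 = time.time()

    def done(stage: str, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "status": "complete",
            "outputs": _hash_outputs(run_dir, outputs),
        }
        logger.info("stage %s complete (%.1fs)", stage, time.time() - t0)

    # ---- simulate -------------------------------------------------------
    sim = config.sim
    images, gt = simulate_section(sim)
    codebook = sim.codebook
    out: list[Path] = []
    sim_dir = run_dir / "simulate"
    sim_dir.mkdir(exist_ok=True)
    for fov, rounds in images.stacks.items():
        for r, stack in enumerate(rounds):
            p = sim_dir / f"fov{fov}_round{r}.tif"
            sio.write_stack(p, stack)
            out.append(p)
        p = sim_dir / f"fov{fov}_truth_labels.tif"
        save_labels(p, gt.label_volumes[fov])
        out.append(p)
    sio.write_spot_table(sim_dir / "true_spots.csv", gt.true_spots)
    sio.write_count_matrix(sim_dir / "true_counts", gt.true_counts)
    sio.write_codebook(sim_dir / "codebook.yaml", codebook)
    (sim_dir / "config.json").write_text(
        json.dumps(dataclasses.asdict(sim), indent=2, sort_keys=True, default=list)
    )
    out += [
        sim_dir / "true_spots.csv", sim_dir / "codebook.yaml",
        sim_dir / "config.json",
        *sorted((sim_dir / "true_counts").iterdir()),
    ]
    done("simulate", out)

    # ---- preprocess -----------------------------------------------------
    n_ch = images.channels_per_round
    mem_ch, dapi_ch = images.membrane_channel, images.dapi_channel
    pre_dir = run_dir / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    corrected: dict[int, list[np.ndarray]] = {}
    for fov, rounds in images.stacks.items():
        corrected[fov] = [np.empty_like(s) for s in rounds]
    for r in range(sim.n_rounds):
        for c in range(n_ch + 2):
            planes = [images.stacks[fov][r][c] for fov in images.stacks]
            ff = estimate_flatfield(planes, method=config.flatfield_method)
            for fov in images.stacks:
                vol = correct_illumination(images.stacks[fov][r][c], ff)
                if c < n_ch:
                    vol = median_filter_3d(vol, config.median_kernel)
                corrected[fov][r][c] = vol
    # register each round to round 0 via the DAPI reference channel
    shifts_out: list[Path] = []
    registered = corrected
    for fov in registered:
        fov_shifts: list[RoundShift] = []
        ref = registered[fov][0][dapi_ch]
        for r in range(sim.n_rounds):
            if r == 0:
                rs = RoundShift(0, (0, 0, 0), 1.0)
            else:
                rs = register_rounds(
                    ref, registered[fov][r][dapi_ch],
                    max_shift=config.max_shift, round_=r,
                )
            fov_shifts.append(rs)
            if rs.shift != (0, 0, 0):
                back = tuple(-s for s in rs.shift)
                for c in range(n_ch + 2):
                    registered[fov][r][c] = translate(
                        registered[fov][r][c], back, fill=0.0
                    )
        result.shifts[fov] = fov_shifts
        p = pre_dir / f"fov{fov}_shifts.csv"
        sio.write_shift_table(p, fov_shifts)
        shifts_out.append(p)
    done("preprocess", shifts_out)

    # ---- segment --------------------------------------------------------
    seg_dir = run_dir / "segment"
    seg_dir.mkdir(exist_ok=True)
    labels: dict[int, LabelVolume] = {}
    seg_out: list[Path] = []
    for fov in registered:
        if config.use_true_labels:
            labels[fov] = gt.label_volumes[fov]
        elif config.mask_paths and fov in config.mask_paths:
            labels[fov] = load_labels(
                config.mask_paths[fov], voxel_size=sim.voxel_size
            )
        else:
            labels[fov] = segment_cells(
                registered[fov][sim.n_rounds - 1][mem_ch],
                registered[fov][0][dapi_ch],
                min_cell_volume=config.min_cell_volume,
                voxel_size=sim.voxel_size,
            )
        p = seg_dir / f"fov{fov}_labels.tif"
        save_labels(p, labels[fov])
        seg_out.append(p)
        cpath = seg_dir / f"fov{fov}_centroids.csv"
        labels[fov].centroids().to_csv(cpath, index=False)
        seg_out.append(cpath)
    result.labels = labels
    done("segment", seg_out)

    # ---- detect ---------------------------------------------------------
    sigma = (
        tuple(config.detect_sigma)
        if config.detect_sigma is not None
        else tuple(sim.sigma_voxels)
    )
    shape = np.array(sim.volume_shape)
    tables = []
    for fov in registered:
        for r in range(sim.n_rounds):
            for c in range(n_ch):
                if (r, c) not in codebook.entries:
                    continue
                det = detect_spots(
                    registered[fov][r][c], sigma,
                    min_distance=config.detect_min_distance,
                    min_peak=config.detect_min_peak,
                    fov=fov, round_=r, channel=c,
                )
                # validity mask from registration: strips filled by the
                # back-translation never carry data; peaks there are edge
                # artifacts of the filters (margin = filter support)
                sh = np.array(result.shifts[fov][r].shift)
                lo, hi = _valid_box(shape, sh, margin=2)
                zyx = det[["z", "y", "x"]].to_numpy()
                keep = np.all((zyx >= lo) & (zyx < hi), axis=1)
                tables.append(det[keep])
    spots = pd.concat(tables, ignore_index=True) if tables else tables
    spots["spot_id"] = np.arange(len(spots))
    det_path = run_dir / "spots_raw.csv"
    sio.write_spot_table(det_path, spots)
    done("detect", [det_path])

    # ---- gate -----------------------------------------------------------
    if config.gate_enabled:
        spots = kmeans_signal_gate(spots, k=config.kmeans_k, seed=config.seed)
    else:
        spots = spots.assign(**{"class": "signal"})
    gate_path = run_dir / "spots_gated.csv"
    sio.write_spot_table(gate_path, spots)
    done("gate", [gate_path])

    # ---- quantify -------------------------------------------------------
    spots = decode_gene(spots, codebook)
    for fov in labels:
        spots = assign_spots_to_cells(spots, labels[fov], fov=fov)
    counts = build_count_matrix(
        spots, codebook, labels,
        min_spots_per_cell=config.min_spots_per_cell,
        min_cell_volume=config.min_cell_volume,
        section=sim.section, stage=sim.stage,
    )
    result.spots = spots
    result.counts = counts
    q_dir = run_dir / "counts"
    sio.write_count_matrix(q_dir, counts)
    sio.write_spot_table(run_dir / "spots_assigned.csv", spots)
    done("quantify", [run_dir / "spots_assigned.csv", *sorted(q_dir.iterdir())])

    # ---- cluster --------------------------------------------------------
    zmat = zscore(counts, mode=config.zscore_mode)
    n_k = min(config.n_clusters, max(counts.n_cells, 1))
    assignment = hierarchical_cluster(
        zmat, n_k, metric=config.cluster_metric, linkage=config.cluster_linkage
    )
    result.zmat = zmat
    result.assignment = assignment
    cl_dir = run_dir / "cluster"
    cl_dir.mkdir(exist_ok=True)
    sio.write_zscore_matrix(cl_dir / "zscores.csv", zmat)
    pd.DataFrame(
        {
            "cell_id": assignment.assignment.index,
            "cluster": assignment.assignment.to_numpy(),
        }
    ).to_csv(cl_dir / "clusters.csv", index=False)
    (cl_dir / "dendrogram.json").write_text(
        json.dumps(assignment.linkage_matrix.tolist())
    )
    plot_heatmap(zmat, assignment, cl_dir / "heatmap.png")
    (cl_dir / "leaf_order.json").write_text(
        json.dumps([int(c) for c in assignment.leaf_order])
    )
    done(
        "cluster",
        [cl_dir / "zscores.csv", cl_dir / "clusters.csv",
         cl_dir / "dendrogram.json", cl_dir / "heatmap.png",
         cl_dir / "leaf_order.json"],
    )

    # ---- gate_modules ---------------------------------------------------
    mod_dir = run_dir / "modules"
    mod_dir.mkdir(exist_ok=True)
    mod_out: list[Path] = []
    panel = set(counts.genes)
    for name in config.modules:
        genes = GENE_MODULES.get(name)
        if genes is None or not set(genes) <= panel:
            logger.warning("module %s not fully in panel; skipped", name)
            continue
        res = gate_coexpression(zmat, GeneModule(name, list(genes)))
        result.gates[name] = res
        p = mod_dir / f"{name}.json"
        p.write_text(
            json.dumps(
                {
                    "module": name,
                    "genes": res.module.genes,
                    "cell_ids": sorted(int(c) for c in res.cell_ids),
                    "per_stage": res.per_stage.to_dict(orient="records"),
                },
                indent=2, sort_keys=True,
            )
        )
        mod_out.append(p)
    done("gate_modules", mod_out)

    # ---- render ---------------------------------------------------------
    ren_dir = run_dir / "render"
    ren_dir.mkdir(exist_ok=True)
    ren_out: list[Path] = []
    cluster_color = {
        cid: PALETTE[(cid - 1) % len(PALETTE)]
        for cid in assignment.cluster_ids
    }
    cells = counts.cells
    for fov in labels:
        sel = cells["fov"] == fov
        coloring = {}
        for gid in cells.loc[sel, "cell_id"]:
            local = int(gid) - fov * 100_000
            coloring[local] = cluster_color[int(assignment.assignment.loc[gid])]
        img = backmap(
            labels[fov], coloring, projection=config.render_projection,
            legend={f"cluster {k}": v for k, v in cluster_color.items()},
            provenance="cluster assignment",
        )
        p = ren_dir / f"fov{fov}_clusters.png"
        save_backmap(p, img)
        ren_out.append(p)
        lp = ren_dir / f"fov{fov}_legend.json"
        lp.write_text(json.dumps({k: list(v) for k, v in img.legend.items()},
                                 indent=2, sort_keys=True))
        ren_out.append(lp)
    done("render", ren_out)

    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return result
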