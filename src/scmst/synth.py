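"""Synthetic serial-smFISH datasets with complete ground truth.

The generator emulates the acquisition this pipeline assumes: a gene panel
read out sequentially (five genes per hybridization round by default, 30
genes over six rounds), three fields of view per cross-section, z-stacks at
0.5 µm spacing, a membrane stain and DAPI as reference channels,
diffraction-limited 3D Gaussian spots plus low-intensity unspecific
background dots, a smooth multiplicative illumination field per (round,
channel), camera read noise, and translational drift between rounds.

Cells are modeled as clipped 3D Voronoi territories around random centroids
in a tissue slab; each cell belongs to a transcriptional program
(subpopulation) that fixes per-gene negative-binomial count distributions
and a medio-lateral spatial domain, so that clustering, gating and
back-mapping stages all have planted truth to be scored against.

Every random draw flows from ``SimConfig.seed`` through named substreams,
so identical configs yield bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .errors import ConfigurationError
from .imageprep import translate
from .quantify import CELL_COLUMNS, CountMatrix, global_cell_id
from .segment import LabelVolume
from .spots import SPOT_COLUMNS, Codebook

__all__ = [
    "SimConfig",
    "SubpopProgram",
    "GroundTruth",
    "SectionImages",
    "DEFAULT_PANEL",
    "default_programs",
    "default_config",
    "noiseless_config",
    "counts_config",
    "simulate_section",
    "simulate_counts",
]

#: 30-gene ectoderm panel: pluripotency trio, pan-ectoderm, neural crest,
#: neural, and non-neural-ectoderm / border markers.
DEFAULT_PANEL = [
    "PouV", "Nanog", "Klf4", "Tfap2A", "Sox2",
    "Foxd3", "cMyc", "Pax7", "Snai2", "Sox10",
    "Sox9", "Nestin", "MycN", "Msi1", "Sox21",
    "Hes5", "Dlx5", "Dlx6", "Gata2", "Gata3",
    "Msx1", "Krt19", "Pax3", "Zic1", "Six1",
    "Eya2", "Wnt6", "Bmp4", "Notch1", "Epha4",
]


@dataclass
class SubpopProgram:
    """A planted transcriptional subpopulation.

    ``expression`` maps gene -> (NB mean, NB dispersion); genes absent from
    the mapping fall back to ``baseline_expression``.  ``spatial_domain`` is
    the fractional x-band (medio-lateral) of the section footprint where
    member cells are placed; bands may overlap and together must cover the
    footprint.
    """

    name: str
    color: tuple[float, float, float] = (0.5, 0.5, 0.5)
    spatial_domain: tuple[float, float] = (0.0, 1.0)
    expression: dict[str, tuple[float, float]] = field(default_factory=dict)
    baseline_expression: tuple[float, float] = (1.0, 8.0)
    fraction: float | None = None

    def params(self, gene: str) -> tuple[float, float]:
        return self.expression.get(gene, self.baseline_expression)


@dataclass
class SimConfig:
    """Full parameterization of one simulated cross-section."""

    volume_shape: tuple[int, int, int] = (20, 120, 120)
    voxel_size: tuple[float, float, float] = (0.5, 0.2, 0.2)
    n_rounds: int = 6
    channels_per_round: int = 5
    gene_panel: list[str] = field(default_factory=lambda: list(DEFAULT_PANEL))
    n_fovs: int = 3
    n_cells: int = 90
    subpopulations: list[SubpopProgram] | None = None
    background_spot_rate: float = 12.0       # unspecific dots per 1000 µm³
    spot_sigma: tuple[float, float, float] = (0.5, 0.25, 0.25)  # µm (z, y, x)
    signal_intensity: tuple[float, float] = (900.0, 120.0)      # a.u. mean, sd
    background_intensity: tuple[float, float] = (250.0, 60.0)
    illumination_order: int = 2
    illumination_amplitude: float = 0.3
    round_shifts: list[tuple[int, int, int]] | None = None
    max_drift: tuple[int, int, int] = (1, 3, 3)
    noise_sd: float = 25.0
    baseline: float = 100.0
    cell_radius_um: float = 3.6
    centroid_margin_um: float | None = None  # None -> 0.7 * cell radius
    spot_jitter: float = 0.25
    min_spot_separation: float = 3.2         # units of PSF sigma, per channel
    stage: str = "stage1"
    section: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.volume_shape):
            raise ConfigurationError("volume_shape must be strictly positive")
        if self.n_rounds <= 0 or self.channels_per_round <= 0:
            raise ConfigurationError("rounds and channels must be positive")
        if len(self.gene_panel) > self.n_rounds * self.channels_per_round:
            raise ConfigurationError(
                f"panel of {len(self.gene_panel)} genes exceeds codebook "
                f"capacity {self.n_rounds} x {self.channels_per_round}"
            )
        if self.n_fovs <= 0:
            raise ConfigurationError("n_fovs must be positive")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be non-negative")
        if self.signal_intensity[0] <= self.background_intensity[0]:
            raise ConfigurationError(
                "signal intensity mean must exceed background intensity mean"
            )
        if self.round_shifts is not None:
            for s in self.round_shifts:
                for comp, dim in zip(s, self.volume_shape):
                    if abs(comp) > dim // 4:
                        raise ConfigurationError(
                            f"round shift {s} exceeds volume_shape/4"
                        )
        for p in self.programs:
            for gene in self.gene_panel:
                if p.params(gene)[0] < 0:
                    raise ConfigurationError(
                        f"program {p.name}: negative mean for {gene}"
                    )

    @property
    def programs(self) -> list[SubpopProgram]:
        if self.subpopulations:
            return self.subpopulations
        return default_programs(self.gene_panel)

    @property
    def codebook(self) -> Codebook:
        return Codebook.from_panel(
            self.gene_panel, self.n_rounds, self.channels_per_round
        )

    @property
    def sigma_voxels(self) -> np.ndarray:
        return np.array(self.spot_sigma) / np.array(self.voxel_size)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SectionImages:
    """Rendered stacks: ``stacks[fov][round]`` is (C+2, Z, Y, X) float32.

    Channels 0..C-1 are the round's gene readouts, channel C the membrane
    stain, channel C+1 DAPI (both references rendered every round).
    """

    stacks: dict[int, list[np.ndarray]]
    channels_per_round: int

    @property
    def membrane_channel(self) -> int:
        return self.channels_per_round

    @property
    def dapi_channel(self) -> int:
        return self.channels_per_round + 1


@dataclass
class GroundTruth:
    """Everything the simulator knows: the answer key for every stage."""

    label_volumes: dict[int, LabelVolume]
    true_spots: pd.DataFrame
    true_counts: CountMatrix
    cell_subpop: pd.Series            # global cell_id -> program name
    applied_shifts: dict[int, tuple[int, int, int]]
    applied_flatfields: dict[tuple[int, int], np.ndarray]


def default_programs(
    panel: list[str],
    high: float = 20.0,
    dispersion: float = 8.0,
    stem_baseline: float = 3.0,
    low_mean: float = 0.8,
) -> list[SubpopProgram]:
    """Four planted programs: three committed groups plus an uncommitted
    stem group that spans the whole footprint and co-expresses the
    pluripotency trio with the pan-ectoderm markers."""
    hi, disp = high, dispersion
    low = (low_mean, dispersion)

    def expr(genes: list[str]) -> dict[str, tuple[float, float]]:
        return {g: (hi, disp) for g in genes if g in panel}

    return [
        SubpopProgram(
            "stem", color=(1.0, 0.85, 0.1), spatial_domain=(0.0, 1.0),
            expression=expr(["PouV", "Nanog", "Klf4", "Tfap2A", "Sox2"]),
            baseline_expression=(stem_baseline, dispersion),
        ),
        SubpopProgram(
            "neural", color=(0.2, 0.4, 0.9), spatial_domain=(0.0, 0.45),
            expression=expr(["Sox2", "Nestin", "MycN", "Msi1", "Sox21", "Hes5"]),
            baseline_expression=low,
        ),
        SubpopProgram(
            "neural_crest", color=(0.1, 0.7, 0.3), spatial_domain=(0.35, 0.7),
            expression=expr(["Foxd3", "cMyc", "Pax7", "Snai2", "Sox10", "Sox9"]),
            baseline_expression=low,
        ),
        SubpopProgram(
            "non_neural_ectoderm", color=(0.9, 0.3, 0.3), spatial_domain=(0.6, 1.0),
            expression=expr(["Tfap2A", "Dlx5", "Gata2", "Gata3", "Msx1", "Krt19"]),
            baseline_expression=low,
        ),
    ]


def default_config(seed: int = 0, **kw) -> SimConfig:
    """The reference acquisition geometry at desk scale (images rendered).

    Expression means are moderated relative to the counts-only preset so
    that per-channel spot density stays resolvable for a diffraction-limited
    detector (transcripts per cell per gene low enough that spots rarely sit
    within one PSF width of each other).
    """
    defaults = dict(
        n_cells=54,
        cell_radius_um=4.5,
        subpopulations=default_programs(
            kw.get("gene_panel", list(DEFAULT_PANEL)),
            high=8.0, stem_baseline=1.5, low_mean=0.5,
        ),
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def noiseless_config(seed: int = 0, **kw) -> SimConfig:
    """Degenerate preset: no background dots, no noise, flat illumination,
    zero drift, spots on voxel centers — the exact-conservation regime."""
    panel = kw.get("gene_panel", list(DEFAULT_PANEL[:10]))
    n_rounds = kw.get("n_rounds", 2)
    defaults = dict(
        volume_shape=(16, 96, 96),
        n_rounds=n_rounds,
        channels_per_round=5,
        gene_panel=panel,
        n_fovs=1,
        n_cells=16,
        cell_radius_um=4.5,
        subpopulations=default_programs(
            panel, high=4.0, stem_baseline=1.0, low_mean=0.3
        ),
        min_spot_separation=4.0,
        background_spot_rate=0.0,
        illumination_amplitude=0.0,
        round_shifts=[(0, 0, 0)] * n_rounds,
        noise_sd=0.0,
        spot_jitter=0.0,
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def counts_config(seed: int = 0, n_cells: int = 2000, **kw) -> SimConfig:
    """Counts-only preset for the clustering/gating stages.

    The footprint is section-scale (120 x 120 µm per FOV) so the requested
    cell number fits at realistic packing; no images are rendered from it.
    """
    defaults = dict(volume_shape=(20, 600, 600), n_cells=n_cells, seed=seed)
    defaults.update(kw)
    return SimConfig(**defaults)


# ---------------------------------------------------------------------------
# internals

def _rng(seed: int, *key: int) -> np.random.Generator:
    """Named substream: independent generator per (seed, purpose key)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _draw_nb(rng: np.random.Generator, mean: float, dispersion: float, size) :
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _assign_programs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    programs = config.programs
    fracs = np.array(
        [p.fraction if p.fraction is not None else np.nan for p in programs]
    )
    if np.isnan(fracs).all():
        fracs = np.full(len(programs), 1.0 / len(programs))
    else:
        fracs = np.nan_to_num(fracs, nan=(1 - np.nansum(fracs)) / max(np.isnan(fracs).sum(), 1))
    fracs = fracs / fracs.sum()
    return rng.choice(len(programs), size=config.n_cells, p=fracs)


def _split_cells(n_cells: int, n_fovs: int) -> list[int]:
    base = n_cells // n_fovs
    rem = n_cells % n_fovs
    return [base + (1 if f < rem else 0) for f in range(n_fovs)]


def _place_centroids(
    config: SimConfig,
    programs_idx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson-disk-ish centroid placement honoring program x-bands (µm)."""
    zdim, ydim, xdim = config.volume_shape
    vs = np.array(config.voxel_size)
    extent = np.array([zdim, ydim, xdim]) * vs
    base_margin = (
        config.centroid_margin_um
        if config.centroid_margin_um is not None
        else config.cell_radius_um * 0.7
    )
    margin = np.minimum(base_margin, extent / 4)
    min_sep = 1.5 * config.cell_radius_um
    buf = np.empty((len(programs_idx), 3))
    n_placed = 0
    progs = config.programs
    for idx in programs_idx:
        lo, hi = progs[idx].spatial_domain
        min_sep2 = min_sep**2
        for _ in range(80):
            z = rng.uniform(margin[0], extent[0] - margin[0])
            y = rng.uniform(margin[1], extent[1] - margin[1])
            xlo = max(lo * extent[2], margin[2])
            xhi = min(hi * extent[2], extent[2] - margin[2])
            x = rng.uniform(min(xlo, xhi), max(xlo, xhi))
            pos = np.array([z, y, x])
            if n_placed == 0 or (
                ((buf[:n_placed] - pos) ** 2).sum(axis=1).min() >= min_sep2
            ):
                break
        buf[n_placed] = pos
        n_placed += 1
    return buf / vs  # back to voxel units


def _voronoi_labels(config: SimConfig, centroids_vox: np.ndarray) -> np.ndarray:
    """Clipped Voronoi territories: voxels within cell_radius_um of their
    nearest centroid (distances in µm, so anisotropy is respected)."""
    shape = config.volume_shape
    labels = np.zeros(shape, dtype=np.int32)
    if len(centroids_vox) == 0:
        return labels
    vs = np.array(config.voxel_size)
    grid = np.indices(shape).reshape(3, -1).T * vs
    tree = cKDTree(centroids_vox * vs)
    dist, idx = tree.query(grid, workers=-1)
    lab = np.where(dist <= config.cell_radius_um, idx + 1, 0)
    return lab.reshape(shape).astype(np.int32)


def _render_gaussian_spots(
    canvas: np.ndarray, positions: np.ndarray, amplitudes: np.ndarray,
    sigma_vox: np.ndarray,
) -> None:
    """Add 3D Gaussians in place, each over a local ±3σ patch."""
    half = np.maximum(np.ceil(3 * sigma_vox).astype(int), 1)
    shape = np.array(canvas.shape)
    for pos, amp in zip(positions, amplitudes):
        lo = np.maximum(np.round(pos).astype(int) - half, 0)
        hi = np.minimum(np.round(pos).astype(int) + half + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]), indexing="ij",
        )
        d2 = (
            ((zz - pos[0]) / sigma_vox[0]) ** 2
            + ((yy - pos[1]) / sigma_vox[1]) ** 2
            + ((xx - pos[2]) / sigma_vox[2]) ** 2
        )
        canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.exp(-0.5 * d2)


def _quadratic_field(
    shape_yx: tuple[int, int], amplitude: float, rng: np.random.Generator,
    order: int = 2,
) -> np.ndarray:
    """Random smooth low-order polynomial field, mean 1, strictly positive."""
    ny, nx = shape_yx
    y = np.linspace(-1, 1, ny)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    surf = np.zeros((ny, nx))
    for i in range(order + 1):
        for j in range(order + 1 - i):
            if i == j == 0:
                continue
            surf = surf + rng.normal(0, 1) * (y**i) * (x**j)
    if amplitude == 0 or np.ptp(surf) == 0:
        return np.ones((ny, nx))
    surf = surf / np.max(np.abs(surf)) * amplitude
    field = 1.0 + surf
    return np.maximum(field, 0.05) / np.maximum(field, 0.05).mean()


def _interior_offsets(
    labels: np.ndarray, margin: float = 2.0, edge: int = 2
) -> dict[int, np.ndarray]:
    """Per-cell voxel coordinates at least ``margin`` voxels from any
    boundary and ``edge`` voxels from the volume faces (so no rendered spot
    is truncated by the stack border), falling back to the full region for
    thin cells."""
    boundary = find_boundaries(labels, mode="thick") | (labels == 0)
    if edge > 0:
        for ax in range(3):
            sl = [slice(None)] * 3
            sl[ax] = slice(0, edge)
            boundary[tuple(sl)] = True
            sl[ax] = slice(-edge, None)
            boundary[tuple(sl)] = True
    dist = ndi.distance_transform_edt(~boundary)
    out: dict[int, np.ndarray] = {}
    for k in np.unique(labels):
        if k == 0:
            continue
        mask = (labels == k) & (dist >= margin)
        if not mask.any():
            mask = labels == k
        out[int(k)] = np.argwhere(mask)
    return out


def _draw_round_shifts(config: SimConfig, rng: np.random.Generator):
    if config.round_shifts is not None:
        shifts = list(config.round_shifts)
        if len(shifts) != config.n_rounds:
            raise ConfigurationError("round_shifts must have n_rounds entries")
        return {r: tuple(int(c) for c in s) for r, s in enumerate(shifts)}
    out = {0: (0, 0, 0)}
    for r in range(1, config.n_rounds):
        out[r] = tuple(
            int(rng.integers(-m, m + 1)) for m in config.max_drift
        )
    return out


def _separated_placement(
    rng: np.random.Generator,
    interior: np.ndarray,
    n: int,
    occupied: list[np.ndarray],
    min_sep_sigma: float,
    sigma_vox: np.ndarray,
    jitter: float,
) -> np.ndarray:
    """Draw up to n spot positions from a cell's interior voxels, keeping a
    minimum PSF-normalized separation (||Δ/σ|| in sigma units) from spots
    already placed in the same channel.

    Placement is authoritative: a draw that cannot be separated within the
    retry budget is dropped (the realized count, not the NB target, defines
    ground truth), so rendered spots are resolvable by construction.
    """
    chosen = []
    min_sep2 = min_sep_sigma**2
    for _ in range(n):
        for _ in range(150):
            cand = interior[rng.integers(len(interior))].astype(float)
            if jitter > 0:
                cand = cand + rng.uniform(-jitter, jitter, 3)
            if not occupied or np.min(
                (((np.array(occupied) - cand) / sigma_vox) ** 2).sum(axis=1)
            ) >= min_sep2:
                occupied.append(cand)
                chosen.append(cand)
                break
    return np.array(chosen).reshape(-1, 3)


# ---------------------------------------------------------------------------
# public operations

def simulate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, pd.Series, pd.DataFrame]:
    """Draw the gene x cell matrix directly from the planted programs.

    Skips image rendering entirely: negative-binomial counts per cell per
    gene, centroids placed inside each program's spatial domain.  Returns
    ``(counts, cell -> program name, centroid table)``.
    """
    rng_assign = _rng(config.seed, 1)
    rng_place = _rng(config.seed, 2)
    rng_counts = _rng(config.seed, 3)
    progs = config.programs
    prog_idx = _assign_programs(config, rng_assign)
    per_fov = _split_cells(config.n_cells, config.n_fovs)

    rows, subpop = [], {}
    cell_no = 0
    for fov, n_f in enumerate(per_fov):
        idx_f = prog_idx[cell_no:cell_no + n_f]
        cents = _place_centroids(config, idx_f, rng_place)
        for local, (pidx, cent) in enumerate(zip(idx_f, cents), start=1):
            gid = global_cell_id(fov, local)
            rows.append(
                {
                    "cell_id": gid, "fov": fov, "section": config.section,
                    "stage": config.stage, "z": cent[0], "y": cent[1],
                    "x": cent[2], "volume_voxels": 0,
                }
            )
            subpop[gid] = progs[pidx].name
        cell_no += n_f

    cells = pd.DataFrame(rows, columns=CELL_COLUMNS)
    # vectorized NB draws: per program, per gene, over member cells
    counts = np.zeros((len(config.gene_panel), config.n_cells), dtype=int)
    for pidx, prog in enumerate(progs):
        members = np.flatnonzero(prog_idx == pidx)
        if members.size == 0:
            continue
        for gi, gene in enumerate(config.gene_panel):
            counts[gi, members] = _draw_nb(
                rng_counts, *prog.params(gene), size=members.size
            )
    cm = CountMatrix(counts, list(config.gene_panel), cells)
    return cm, pd.Series(subpop, dtype=object), cells[["cell_id", "z", "y", "x"]]


def simulate_section(config: SimConfig) -> tuple[SectionImages, GroundTruth]:
    """Render the full multi-round acquisition plus its answer key.

    See the module docstring for the generative model.  The returned spot
    table holds true positions in the *reference* (unshifted) frame;
    rendered images of round r show each spot at position + shift_r.
    """
    codebook = config.codebook
    progs = config.programs
    n_ch = config.channels_per_round
    mem_ch, dapi_ch = n_ch, n_ch + 1
    sigma_vox = config.sigma_voxels

    prog_idx_all = _assign_programs(config, _rng(config.seed, 1))
    per_fov = _split_cells(config.n_cells, config.n_fovs)
    shifts = _draw_round_shifts(config, _rng(config.seed, 4))

    # one illumination field per (round, channel incl. references): optics,
    # shared across stage positions (FOVs)
    rng_illum = _rng(config.seed, 5)
    flatfields = {
        (r, c): _quadratic_field(
            config.volume_shape[1:], config.illumination_amplitude, rng_illum,
            config.illumination_order,
        )
        for r in range(config.n_rounds)
        for c in range(n_ch + 2)
    }

    stacks: dict[int, list[np.ndarray]] = {}
    label_volumes: dict[int, LabelVolume] = {}
    spot_records: list[dict] = []
    cell_rows: list[dict] = []
    subpop: dict[int, str] = {}
    count_cols: dict[int, np.ndarray] = {}
    spot_id = 0
    cell_no = 0

    for fov in range(config.n_fovs):
        idx_f = prog_idx_all[cell_no:cell_no + per_fov[fov]]
        rng_place = _rng(config.seed, 10, fov)
        rng_counts = _rng(config.seed, 11, fov)
        rng_spots = _rng(config.seed, 12, fov)
        rng_noise = _rng(config.seed, 13, fov)
        rng_bg = _rng(config.seed, 14, fov)

        cents = _place_centroids(config, idx_f, rng_place)
        labels = _voronoi_labels(config, cents)
        lv = LabelVolume(labels, config.voxel_size)
        label_volumes[fov] = lv
        interior = _interior_offsets(labels)

        # per-cell metadata + NB counts
        vols = {
            int(k): int(v)
            for k, v in zip(*np.unique(labels[labels > 0], return_counts=True))
        }
        n_genes = len(config.gene_panel)
        for local, (pidx, cent) in enumerate(zip(idx_f, cents), start=1):
            gid = global_cell_id(fov, local)
            subpop[gid] = progs[pidx].name
            cell_rows.append(
                {
                    "cell_id": gid, "fov": fov, "section": config.section,
                    "stage": config.stage, "z": cent[0], "y": cent[1],
                    "x": cent[2], "volume_voxels": vols.get(local, 0),
                }
            )
            count_cols[gid] = np.array(
                [
                    _draw_nb(rng_counts, *progs[pidx].params(g), size=1)[0]
                    if local in interior else 0
                    for g in config.gene_panel
                ]
            )

        # place + render, round by round
        rounds = []
        vol_um3 = float(
            np.prod(np.array(config.volume_shape) * np.array(config.voxel_size))
        )
        for r in range(config.n_rounds):
            stack = np.zeros((n_ch + 2,) + tuple(config.volume_shape), np.float32)
            for c in range(n_ch):
                if (r, c) not in codebook.entries:
                    continue
                gene = codebook.entries[(r, c)]
                g_row = config.gene_panel.index(gene)
                occupied: list[np.ndarray] = []
                canvas = np.zeros(config.volume_shape, dtype=float)
                for local in range(1, len(idx_f) + 1):
                    gid = global_cell_id(fov, local)
                    n_spots = int(count_cols[gid][g_row])
                    if n_spots == 0 or local not in interior:
                        continue
                    pos = _separated_placement(
                        rng_spots, interior[local], n_spots, occupied,
                        config.min_spot_separation, sigma_vox,
                        config.spot_jitter,
                    )
                    # realized count is ground truth (placement may drop
                    # draws that cannot be separated in a crowded cell)
                    count_cols[gid][g_row] = len(pos)
                    amps = np.maximum(
                        rng_spots.normal(*config.signal_intensity, len(pos)), 1.0
                    )
                    _render_gaussian_spots(canvas, pos, amps, sigma_vox)
                    for p, a in zip(pos, amps):
                        spot_records.append(
                            {
                                "spot_id": spot_id, "fov": fov, "round": r,
                                "channel": c, "gene": gene, "z": p[0],
                                "y": p[1], "x": p[2], "intensity": float(a),
                                "class": "signal", "cell_id": local,
                            }
                        )
                        spot_id += 1
                # unspecific background dots
                n_bg = (
                    rng_bg.poisson(config.background_spot_rate * vol_um3 / 1000.0)
                    if config.background_spot_rate > 0
                    else 0
                )
                if n_bg:
                    # unspecific dots are physical spots too: keep the same
                    # PSF-normalized separation so ground truth is resolvable
                    pos_list = []
                    min_sep2 = config.min_spot_separation**2
                    for _ in range(n_bg):
                        for _ in range(60):
                            cand = rng_bg.uniform(
                                0, np.array(config.volume_shape) - 1, 3
                            )
                            if not occupied or np.min(
                                (((np.array(occupied) - cand) / sigma_vox) ** 2)
                                .sum(axis=1)
                            ) >= min_sep2:
                                break
                        occupied.append(cand)
                        pos_list.append(cand)
                    pos = np.array(pos_list)
                    amps = np.maximum(
                        rng_bg.normal(*config.background_intensity, n_bg), 1.0
                    )
                    _render_gaussian_spots(canvas, pos, amps, sigma_vox)
                    for p, a in zip(pos, amps):
                        vox = np.round(p).astype(int)
                        spot_records.append(
                            {
                                "spot_id": spot_id, "fov": fov, "round": r,
                                "channel": c, "gene": gene, "z": p[0],
                                "y": p[1], "x": p[2], "intensity": float(a),
                                "class": "unspecific",
                                "cell_id": int(labels[tuple(vox)]),
                            }
                        )
                        spot_id += 1
                stack[c] = canvas

            # reference channels: membrane ridge + nuclear blobs
            mem = find_boundaries(labels, mode="thick").astype(float)
            mem = ndi.gaussian_filter(mem * config.signal_intensity[0], 0.6)
            stack[mem_ch] = mem
            dapi = np.zeros(config.volume_shape, dtype=float)
            _render_gaussian_spots(
                dapi, cents,
                np.full(len(cents), config.signal_intensity[0]),
                np.array([2.0, 3.5, 3.5]),
            )
            stack[dapi_ch] = dapi

            # drift -> illumination -> camera
            for c in range(n_ch + 2):
                scene = translate(stack[c], shifts[r], fill=0.0)
                img = flatfields[(r, c)][None] * (scene + config.baseline)
                if config.noise_sd > 0:
                    img = img + rng_noise.normal(0, config.noise_sd, img.shape)
                stack[c] = np.clip(img, 0, None)
            rounds.append(stack)
        stacks[fov] = rounds
        cell_no += per_fov[fov]

    cells = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)
    counts = (
        np.stack([count_cols[g] for g in cells["cell_id"]], axis=1)
        if len(cells)
        else np.zeros((len(config.gene_panel), 0), dtype=int)
    )
    true_counts = CountMatrix(counts, list(config.gene_panel), cells)
    true_spots = pd.DataFrame(spot_records, columns=SPOT_COLUMNS)
    gt = GroundTruth(
        label_volumes=label_volumes,
        true_spots=true_spots,
        true_counts=true_counts,
        cell_subpop=pd.Series(subpop, dtype=object),
        applied_shifts=shifts,
        applied_flatfields=flatfields,
    )
    return SectionImages(stacks, n_ch), gt
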