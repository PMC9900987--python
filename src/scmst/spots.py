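"""Spot detection, K-means intensity gating, and codebook decoding.

Each hybridization round reads out one gene per fluorescence channel, so a
spot's gene identity is a plain codebook lookup — there is no combinatorial
barcode.  Candidate spots are detected as local maxima of a
Laplacian-of-Gaussian response (the standard detector for diffraction-limited
smFISH dots).  True signal is separated from unspecifically bound probe —
which shows up as low-intensity dots — by 2-means clustering of the spot
intensities within each (round, channel) group; the higher-mean cluster is
called signal.  Gated spots are labeled, never deleted, so the decision is
auditable downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from sklearn.cluster import KMeans

from .errors import DecodingError, ValidationError

__all__ = [
    "Codebook",
    "SPOT_COLUMNS",
    "detect_spots",
    "kmeans_signal_gate",
    "optimal_1d_two_means",
    "decode_gene",
]

#: Canonical SpotTable column set (CSV schema).
SPOT_COLUMNS = [
    "spot_id",
    "fov",
    "round",
    "channel",
    "gene",
    "z",
    "y",
    "x",
    "intensity",
    "class",
    "cell_id",
]


@dataclass
class Codebook:
    """Mapping from (round, channel) to gene name.

    Readout is sequential — five genes per round on a six-channel microscope
    in the reference acquisition — so the mapping must be injective over
    genes and fit within ``n_rounds * channels_per_round`` slots.
    """

    entries: dict[tuple[int, int], str]
    n_rounds: int
    channels_per_round: int
    reference_channels: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        genes = list(self.entries.values())
        if len(set(genes)) != len(genes):
            dupes = {g for g in genes if genes.count(g) > 1}
            raise ValidationError(f"codebook not injective over genes: {sorted(dupes)}")
        if len(self.entries) > self.n_rounds * self.channels_per_round:
            raise ValidationError(
                "codebook has more entries than rounds x channels slots"
            )
        for r, c in self.entries:
            if not (0 <= r < self.n_rounds and 0 <= c < self.channels_per_round):
                raise ValidationError(f"codebook entry ({r}, {c}) out of range")

    @property
    def genes(self) -> list[str]:
        """Panel genes in (round, channel) order."""
        return [self.entries[k] for k in sorted(self.entries)]

    @classmethod
    def from_panel(
        cls, gene_panel: list[str], n_rounds: int, channels_per_round: int
    ) -> "Codebook":
        """Lay a gene panel out sequentially: round-major, channel-minor."""
        if len(gene_panel) > n_rounds * channels_per_round:
            raise ValidationError(
                f"panel of {len(gene_panel)} genes exceeds "
                f"{n_rounds} x {channels_per_round} codebook capacity"
            )
        entries = {
            (i // channels_per_round, i % channels_per_round): g
            for i, g in enumerate(gene_panel)
        }
        return cls(entries, n_rounds, channels_per_round)

    def lookup(self, round_: int, channel: int) -> str:
        try:
            return self.entries[(round_, channel)]
        except KeyError:
            raise DecodingError(
                f"no codebook entry for (round={round_}, channel={channel})"
            ) from None


def empty_spot_table() -> pd.DataFrame:
    df = pd.DataFrame(columns=SPOT_COLUMNS)
    return df.astype(
        {
            "spot_id": int, "fov": int, "round": int, "channel": int,
            "z": float, "y": float, "x": float, "intensity": float,
            "cell_id": int,
        }
    )


def detect_spots(
    volume: np.ndarray,
    sigma: float | tuple[float, float, float],
    min_distance: int = 1,
    min_peak: float = 0.0,
    fov: int = 0,
    round_: int = 0,
    channel: int = 0,
) -> pd.DataFrame:
    """Detect candidate spots as LoG local maxima.

    Parameters
    ----------
    volume
        Preprocessed (flat-field corrected, median filtered) 3D volume.
    sigma
        LoG scale in voxels, per axis or isotropic; should match the spot
        size (σ of the effective PSF).
    min_distance
        Minimum separation between reported maxima (voxels).
    min_peak
        Absolute response threshold on the (negated) LoG response.

    Returns
    -------
    A candidate SpotTable: gene undecoded (""), class unassigned ("").
    """
    if np.isscalar(sigma):
        sigma = (float(sigma),) * 3  # type: ignore[assignment]
    if any(s <= 0 for s in sigma):  # type: ignore[union-attr]
        raise ValidationError("sigma must be strictly positive")
    volume = np.asarray(volume, dtype=float)
    # Negated LoG: bright blobs become positive peaks; scale-normalized.
    response = -ndi.gaussian_laplace(volume, sigma) * float(np.mean(sigma)) ** 2
    peaks = peak_local_max(
        response,
        min_distance=int(min_distance),
        threshold_abs=float(min_peak) if min_peak > 0 else None,
        exclude_border=False,
    )
    df = empty_spot_table()
    if peaks.size == 0:
        return df
    df = pd.DataFrame(
        {
            "spot_id": np.arange(len(peaks)),
            "fov": fov,
            "round": round_,
            "channel": channel,
            "gene": "",
            "z": peaks[:, 0].astype(float),
            "y": peaks[:, 1].astype(float),
            "x": peaks[:, 2].astype(float),
            "intensity": response[tuple(peaks.T)],
            "class": "",
            "cell_id": 0,
        }
    )[SPOT_COLUMNS]
    return df


def optimal_1d_two_means(values: np.ndarray) -> np.ndarray:
    """Exact 2-means partition of 1-D data.

    The global optimum of 2-means on a line is a contiguous split of the
    sorted values; enumerate all n-1 splits with prefix sums and return a
    boolean mask marking the higher-mean cluster.  Ties in the objective are
    broken toward the smaller high cluster (i.e. the higher threshold).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2 or np.ptp(values) == 0:
        return np.ones(n, dtype=bool)
    order = np.argsort(values, kind="stable")
    s = values[order]
    csum = np.cumsum(s)
    total = csum[-1]
    k = np.arange(1, n)  # split: low cluster = s[:k]
    mean_lo = csum[:-1] / k
    mean_hi = (total - csum[:-1]) / (n - k)
    # WCSS = sum(x^2) - k*mean_lo^2 - (n-k)*mean_hi^2; sum(x^2) constant.
    objective = -(k * mean_lo**2 + (n - k) * mean_hi**2)
    best = int(np.argmax(-objective[::-1]))  # last argmin -> higher threshold
    split = n - 1 - best
    high = np.zeros(n, dtype=bool)
    high[order[split:]] = True
    return high


def kmeans_signal_gate(
    spot_table: pd.DataFrame,
    k: int = 2,
    log_intensity: bool = True,
    seed: int = 0,
    group_by: tuple[str, ...] = ("fov", "round", "channel"),
) -> pd.DataFrame:
    """Label each spot signal vs unspecific by K-means on intensity.

    Clustering runs independently per (fov, round, channel) group because
    exposure and laser power differ between fluorophores, so absolute
    intensities are not comparable across channels.  Within a group the
    cluster with the highest mean intensity is labeled ``signal`` and the
    rest ``unspecific``; which spots are called signal is therefore invariant
    to any relabeling of the K-means clusters.  Groups with fewer than ``k``
    spots or zero intensity variance are labeled all-signal with a warning.

    For the default ``k=2`` on the single intensity feature the partition is
    computed exactly (optimal contiguous split of the sorted values); larger
    ``k`` uses seeded k-means++.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    out = spot_table.copy()
    if out.empty:
        return out
    classes = np.empty(len(out), dtype=object)
    feat_all = out["intensity"].to_numpy(dtype=float)
    if log_intensity:
        feat_all = np.log10(np.maximum(feat_all, 1e-12))
    for _, idx in out.groupby(list(group_by), sort=False).indices.items():
        feats = feat_all[idx]
        if len(idx) < k or np.ptp(feats) == 0:
            warnings.warn(
                "spot group too small or degenerate for k-means; "
                "labeling all spots signal"
            )
            classes[idx] = "signal"
            continue
        if k == 2:
            high = optimal_1d_two_means(feats)
        else:
            km = KMeans(n_clusters=k, n_init=min(50, 10), random_state=seed)
            lab = km.fit_predict(feats.reshape(-1, 1))
            means = [feats[lab == j].mean() for j in range(k)]
            high = lab == int(np.argmax(means))
        classes[idx] = np.where(high, "signal", "unspecific")
    out["class"] = classes
    return out


def decode_gene(spot_table: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Populate the gene column from (round, channel) via the codebook.

    Spots from designated reference channels (membrane/DAPI) are dropped and
    the dropped count reported in a warning.  An unknown (round, channel)
    pair raises :class:`DecodingError` naming the pair.
    """
    out = spot_table.copy()
    if out.empty:
        return out
    keep = np.ones(len(out), dtype=bool)
    genes = np.empty(len(out), dtype=object)
    pairs = list(zip(out["round"].astype(int), out["channel"].astype(int)))
    for i, pair in enumerate(pairs):
        if pair in codebook.reference_channels:
            keep[i] = False
            genes[i] = ""
        else:
            genes[i] = codebook.lookup(*pair)
    out["gene"] = genes
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} spots from reference channels")
        out = out[keep].reset_index(drop=True)
    return out
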