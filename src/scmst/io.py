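"""Readers and writers for every pipeline artifact.

Plain, lossless interchange formats throughout: TIFF for volumes, CSV for
tables, MatrixMarket (plus gene/cell sidecar CSVs) for count matrices,
YAML/JSON for codebooks and run metadata.  All readers validate schemas and
raise :class:`FormatError` naming the offending file and field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .clustermap import ZScoreMatrix
from .errors import FormatError
from .imageprep import RoundShift
from .quantify import CELL_COLUMNS, CountMatrix
from .spots import SPOT_COLUMNS, Codebook

__all__ = [
    "write_spot_table", "read_spot_table",
    "write_count_matrix", "read_count_matrix",
    "write_codebook", "read_codebook",
    "write_stack", "read_stack",
    "write_shift_table", "read_shift_table",
    "write_zscore_matrix",
    "file_sha256",
]


def write_spot_table(path, spots: pd.DataFrame) -> None:
    spots.to_csv(path, index=False, columns=SPOT_COLUMNS)


def read_spot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: spot table missing columns {missing}")
    return df[SPOT_COLUMNS]


def write_count_matrix(path_dir, cm: CountMatrix, dense_csv: bool = True) -> None:
    """MTX + gene/cell sidecars; optionally also one dense CSV."""
    d = Path(path_dir)
    d.mkdir(parents=True, exist_ok=True)
    mmwrite(str(d / "counts.mtx"), coo_matrix(cm.counts))
    pd.DataFrame({"gene": cm.genes}).to_csv(d / "genes.csv", index=False)
    cm.cells.to_csv(d / "cells.csv", index=False)
    if dense_csv:
        cm.to_frame().to_csv(d / "counts_dense.csv")


def read_count_matrix(path_dir) -> CountMatrix:
    d = Path(path_dir)
    try:
        counts = np.asarray(mmread(str(d / "counts.mtx")).todense()).astype(int)
        genes = pd.read_csv(d / "genes.csv")["gene"].tolist()
        cells = pd.read_csv(d / "cells.csv", keep_default_na=False)
    except FileNotFoundError as e:
        raise FormatError(f"{path_dir}: missing count-matrix artifact: {e}") from e
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise FormatError(f"{d / 'cells.csv'}: missing columns {missing}")
    return CountMatrix(counts, genes, cells[CELL_COLUMNS])


def write_codebook(path, codebook: Codebook) -> None:
    payload = {
        "n_rounds": codebook.n_rounds,
        "channels_per_round": codebook.channels_per_round,
        "rounds": {
            int(r): {int(c): g for (rr, c), g in codebook.entries.items() if rr == r}
            for r in sorted({r for r, _ in codebook.entries})
        },
        "reference_channels": sorted(list(p) for p in codebook.reference_channels),
    }
    text = (
        json.dumps(payload, indent=2, sort_keys=True)
        if str(path).endswith(".json")
        else yaml.safe_dump(payload, sort_keys=True)
    )
    Path(path).write_text(text)


def read_codebook(path) -> Codebook:
    text = Path(path).read_text()
    payload = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    for key in ("n_rounds", "channels_per_round", "rounds"):
        if key not in payload:
            raise FormatError(f"{path}: codebook missing field {key!r}")
    entries = {
        (int(r), int(c)): g
        for r, chans in payload["rounds"].items()
        for c, g in chans.items()
    }
    refs = {tuple(p) for p in payload.get("reference_channels", [])}
    return Codebook(
        entries, int(payload["n_rounds"]), int(payload["channels_per_round"]),
        reference_channels=refs,
    )


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (C, Z, Y, X) or (Z, Y, X) float stack as TIFF.

    Plain TIFF with an axes annotation; no timestamps or UUIDs are written,
    so identical arrays produce identical bytes.
    """
    axes = "CZYX" if stack.ndim == 4 else "ZYX"
    tifffile.imwrite(
        str(path), np.asarray(stack, dtype=np.float32), metadata={"axes": axes}
    )


def read_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_shift_table(path, shifts: list[RoundShift]) -> None:
    pd.DataFrame(
        [
            {
                "round": s.round, "dz": s.shift[0], "dy": s.shift[1],
                "dx": s.shift[2], "score": s.score,
                "low_confidence": s.low_confidence,
            }
            for s in shifts
        ]
    ).to_csv(path, index=False)


def read_shift_table(path) -> list[RoundShift]:
    df = pd.read_csv(path)
    needed = ["round", "dz", "dy", "dx", "score"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: shift table missing columns {missing}")
    return [
        RoundShift(
            int(r.round), (int(r.dz), int(r.dy), int(r.dx)), float(r.score),
            bool(getattr(r, "low_confidence", False)),
        )
        for r in df.itertuples(index=False)
    ]


def write_zscore_matrix(path, zmat: ZScoreMatrix) -> None:
    zmat.to_frame().to_csv(path)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
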