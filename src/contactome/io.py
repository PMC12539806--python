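"""Readers and writers for label stacks, adjacency tables and run configs."""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from imageio.v3 import imread, imwrite

from contactome.adjacency import AdjacencyMatrix, LabelVolume

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Dataset calibration plus the pipeline parameter defaults.

    Defaults follow the published protocol: 45 nm contact threshold,
    condensation merge divisor 10,000, connectivity lag weights (100, 30),
    embedding diffusion time 50 and seed 1.
    """

    dataset: str = "dataset"
    pixel_size_nm: float = 4.5
    z_spacing_nm: float = 30.0
    region: tuple[int, int] | None = None
    threshold_nm: float = 45.0
    epsilon_divisor: float = 10_000.0
    max_iterations: int = 1000
    w1: float = 100.0
    w2: float = 30.0
    diffusion_time: int = 50
    seed: int = 1
    out_dir: str = "out"

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "z_spacing_nm", "threshold_nm",
                     "epsilon_divisor", "w1", "w2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.diffusion_time < 1 or self.max_iterations < 1:
            raise ValueError("diffusion_time and max_iterations must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
        if data.get("region") is not None:
            data["region"] = tuple(data["region"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Label stacks
# ---------------------------------------------------------------------------

def read_label_stack(
    path,
    pixel_size_nm: float,
    z_spacing_nm: float,
    region: tuple[int, int] | None = None,
) -> LabelVolume:
    """Load a multi-page TIFF or a directory of PNG slices.

    PNG slices are ordered by the integer embedded in their zero-padded
    filenames and must form a contiguous index sequence.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.png"))
        if not files:
            raise ValueError(f"{p}: no PNG slices found")
        indices = []
        for f in files:
            m = re.search(r"(\d+)", f.stem)
            if m is None:
                raise ValueError(f"{f.name}: no slice index in filename")
            indices.append(int(m.group(1)))
        order = np.argsort(indices)
        sorted_idx = [indices[i] for i in order]
        expected = list(range(sorted_idx[0], sorted_idx[0] + len(files)))
        if sorted_idx != expected:
            missing = sorted(set(expected) - set(sorted_idx))
            raise ValueError(f"{p}: missing slice index {missing}")
        slices = [np.asarray(imread(files[i])).astype(np.int32) for i in order]
    elif p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        slices = [a.astype(np.int32) for a in arr]
    else:
        raise ValueError(f"{p}: expected a TIFF file or a PNG directory")

    shape = slices[0].shape
    for i, s in enumerate(slices):
        if s.shape != shape:
            raise ValueError(f"slice {i} shape {s.shape} != slice 0 shape {shape}")
    return LabelVolume(
        slices=slices, pixel_size=pixel_size_nm, z_spacing=z_spacing_nm,
        region=region,
    )


def write_label_stack(vol: LabelVolume, path, fmt: str = "tiff") -> None:
    """Write a volume as a multi-page TIFF or a directory of PNG slices."""
    p = Path(path)
    if fmt == "tiff":
        tifffile.imwrite(
            p, np.stack(vol.slices).astype(np.uint16), photometric="minisblack"
        )
    elif fmt == "png":
        p.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(vol.slices):
            imwrite(p / f"slice_{i:04d}.png", s.astype(np.uint16))
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Adjacency tables
# ---------------------------------------------------------------------------

def read_adjacency(path) -> AdjacencyMatrix:
    """Load a square labeled CSV/XLSX contact table.

    Rows and columns are matched by label, not position.  Asymmetries above
    1e-6 relative are rejected; smaller ones are symmetrized by the mean with
    a logged notice.
    """
    p = Path(path)
    if p.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(p, index_col=0)
    else:
        df = pd.read_csv(p, index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if len(set(df.index)) != len(df.index) or len(set(df.columns)) != len(df.columns):
        raise ValueError(f"{p}: duplicate labels")
    if set(df.index) != set(df.columns):
        raise ValueError(f"{p}: row and column label sets differ")
    df = df.loc[df.index, df.index]  # realign columns by label
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError(f"{p}: negative contact quantities")
    scale = max(np.abs(vals).max(), 1.0)
    asym = np.abs(vals - vals.T).max() / scale
    if asym > 1e-6:
        raise ValueError(f"{p}: matrix asymmetric (relative deviation {asym:.3g})")
    if asym > 0:
        log.warning("ADJ_SYMMETRIZED tiny asymmetry %.3g symmetrized by mean", asym)
        vals = (vals + vals.T) / 2.0
    return AdjacencyMatrix(labels=list(df.index), values=vals)


def write_adjacency(matrix: AdjacencyMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path)


def write_trace_json(trace, path) -> None:
    """Condensation trace as JSON: per-iteration assignments and modularity."""
    payload = {
        "labels": [str(l) for l in trace.labels],
        "epsilon": trace.epsilon,
        "converged": trace.converged,
        "iterations": [
            {
                "n_clusters": rec.n_clusters,
                "modularity": rec.modularity,
                "sigma": None if rec.sigma != rec.sigma else rec.sigma,
                "assignment": {str(k): int(v) for k, v in rec.assignment.items()},
            }
            for rec in trace.iterations
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_manifest(path, **entries) -> None:
    """JSON run manifest: inputs, parameters, package version."""
    import contactome

    manifest = {"contactome_version": contactome.__version__, **entries}
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
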