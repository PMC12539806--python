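"""Synthetic inputs with known ground truth.

Tube phantoms emulate segmented neurite stacks with analytically known
contact geometry; planted-block matrices emulate adjacency matrices with a
known stratum structure; Gaussian point clouds exercise the condensation
loop directly.  All generation is seeded per call — no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from contactome.adjacency import AdjacencyMatrix, LabelVolume


@dataclass(frozen=True)
class TubePhantomSpec:
    """Straight- or curved-tube phantom: one disk cross-section per slice.

    ``tubes`` is a list of ``(label, centers, radius)`` where ``centers`` is
    either a single ``(row, col)`` used on every slice or a per-slice list.
    """

    n_slices: int
    image_shape: tuple[int, int]
    tubes: list[tuple[int, object, float]]
    pixel_size: float = 4.5
    z_spacing: float = 30.0

    def centers_of(self, tube_idx: int) -> list[tuple[float, float]]:
        _, centers, _ = self.tubes[tube_idx]
        first = centers[0] if isinstance(centers, (list, tuple)) else None
        if isinstance(first, (list, tuple, np.ndarray)):
            if len(centers) != self.n_slices:
                raise ValueError("per-slice center list length != n_slices")
            return [tuple(c) for c in centers]
        return [tuple(centers)] * self.n_slices


@dataclass(frozen=True)
class PlantedAdjacencySpec:
    """Block-structured adjacency: strong within-block, weak between-block."""

    block_sizes: tuple[int, ...] = (10, 10, 10, 10)
    within_weight: tuple[float, float] = (100.0, 10.0)  # (mean, sd)
    between_weight: tuple[float, float] = (1.0, 1.0)
    seed: int = 0


def make_tube_phantom(spec: TubePhantomSpec) -> LabelVolume:
    """Render the phantom as a label stack; disks must not overlap.

    Pixel (z, r, c) takes the label of the tube whose disk contains it
    (center distance <= radius), else 0.
    """
    labels = [lab for lab, _, _ in spec.tubes]
    if len(set(labels)) != len(labels) or any(l <= 0 for l in labels):
        raise ValueError("tube labels must be unique and > 0")
    if any(r <= 0 for _, _, r in spec.tubes):
        raise ValueError("tube radii must be > 0")

    h, w = spec.image_shape
    rr, cc = np.mgrid[0:h, 0:w]
    slices = []
    for z in range(spec.n_slices):
        img = np.zeros((h, w), dtype=np.int32)
        for t, (lab, _, radius) in enumerate(spec.tubes):
            cr, ccol = spec.centers_of(t)[z]
            disk = (rr - cr) ** 2 + (cc - ccol) ** 2 <= radius ** 2
            clash = disk & (img != 0)
            if clash.any():
                other = int(img[clash][0])
                raise ValueError(
                    f"overlapping disks on slice {z}: labels {other} and {lab}"
                )
            img[disk] = lab
        slices.append(img)
    return LabelVolume(
        slices=slices, pixel_size=spec.pixel_size, z_spacing=spec.z_spacing
    )


def make_planted_adjacency(
    spec: PlantedAdjacencySpec,
) -> tuple[AdjacencyMatrix, np.ndarray]:
    """Planted-block adjacency matrix and its ground-truth block labels.

    Entries within a block are drawn from the within-weight distribution and
    entries across blocks from the between-weight distribution; negatives are
    clipped to 0 (contact quantities are counts).  Deterministic under seed.
    """
    if len(spec.block_sizes) < 2 or any(b < 2 for b in spec.block_sizes):
        raise ValueError("need at least 2 blocks of size >= 2")
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.block_sizes)
    truth = np.concatenate(
        [np.full(b, k, dtype=int) for k, b in enumerate(spec.block_sizes)]
    )
    wm, ws = spec.within_weight
    bm, bs = spec.between_weight
    vals = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    same = truth[iu] == truth[ju]
    draws = np.where(
        same,
        rng.normal(wm, ws, size=iu.size),
        rng.normal(bm, bs, size=iu.size),
    )
    draws = np.clip(draws, 0.0, None)
    vals[iu, ju] = draws
    vals[ju, iu] = draws
    labels = [f"n{i:03d}" for i in range(n)]
    return AdjacencyMatrix(labels=labels, values=vals), truth


def make_point_cloud(
    blob_centers: np.ndarray,
    n_per_blob: int,
    sd: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian blobs around the given centers; rows labeled by blob index."""
    centers = np.atleast_2d(np.asarray(blob_centers, dtype=float))
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    pts = []
    labels = []
    for k, c in enumerate(centers):
        pts.append(c + rng.normal(0.0, sd, size=(n_per_blob, centers.shape[1])))
        labels.extend([k] * n_per_blob)
    return np.vstack(pts), np.array(labels, dtype=int)


def phantom_oracle_adjacency(
    vol: LabelVolume, distance_px: int
) -> tuple[list[int], np.ndarray]:
    """Exhaustive pixel-pair oracle for phantom adjacency.

    For every ordered label pair (a, b) counts, slice by slice, the pixels of
    b lying within Euclidean distance ``distance_px`` of some pixel of a,
    then symmetrizes directed totals by their mean.  Quadratic in pixel count
    — intended only as an independent check on small phantoms.
    """
    labels = vol.labels(in_region=False).tolist()
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    directed = np.zeros((n, n))
    for z in vol.region_slices():
        img = vol.slices[z]
        coords = {
            lab: np.argwhere(img == lab).astype(float)
            for lab in labels
            if (img == lab).any()
        }
        for a in coords:
            for b in coords:
                if a == b:
                    continue
                diff = coords[b][:, None, :] - coords[a][None, :, :]
                d2 = (diff ** 2).sum(axis=2)
                hit = (d2.min(axis=1) <= distance_px ** 2).sum()
                directed[index[a], index[b]] += int(hit)
    return labels, (directed + directed.T) / 2.0
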