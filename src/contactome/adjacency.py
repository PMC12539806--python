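"""Pairwise neuron-neuron contact quantification from segmented label volumes.

Contact ("adjacency") between two segmented neurons is measured as the number
of shared pixels within a calibrated distance threshold: the outline of one
cell is expanded by the threshold distance and the pixels of the partner cell
covered by that expansion are counted, per slice, and summed over the analyzed
neuropil region.  The two directed counts are symmetrized by their arithmetic
mean to form the entries of a symmetric adjacency matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """Ordered stack of 2-D integer label images with physical calibration.

    Parameters
    ----------
    slices
        List of 2-D integer arrays of identical shape.  0 is background;
        positive values are neuron labels.
    pixel_size
        In-plane resolution in nm per pixel (isotropic in x-y).
    z_spacing
        Section thickness / spacing between consecutive slices, in nm.
    region
        Optional inclusive ``(first_slice, last_slice)`` index range defining
        the analyzed neuropil; coordinates are 0-based.  ``None`` means the
        whole stack.
    """

    slices: list[np.ndarray]
    pixel_size: float
    z_spacing: float
    region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("LabelVolume requires at least one slice")
        shape = self.slices[0].shape
        for i, s in enumerate(self.slices):
            if s.ndim != 2:
                raise ValueError(f"slice {i} is not 2-D")
            if s.shape != shape:
                raise ValueError(
                    f"slice {i} shape {s.shape} differs from slice 0 shape {shape}"
                )
            if np.any(s < 0):
                raise ValueError(f"slice {i} contains negative labels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.z_spacing <= 0:
            raise ValueError("z_spacing must be > 0")
        if self.region is not None:
            lo, hi = self.region
            if not (0 <= lo <= hi < len(self.slices)):
                raise ValueError(
                    f"region {self.region} outside slice range 0..{len(self.slices) - 1}"
                )

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    def region_slices(self) -> range:
        """Indices of the slices inside the analyzed region (inclusive)."""
        if self.region is None:
            return range(len(self.slices))
        return range(self.region[0], self.region[1] + 1)

    def labels(self, in_region: bool = True) -> np.ndarray:
        """Sorted nonzero labels present (within the region by default)."""
        idx = self.region_slices() if in_region else range(len(self.slices))
        out: set[int] = set()
        for i in idx:
            out.update(np.unique(self.slices[i]).tolist())
        out.discard(0)
        return np.array(sorted(out), dtype=int)

    def as_array(self) -> np.ndarray:
        """The stack as a single (z, rows, cols) array."""
        return np.stack(self.slices, axis=0)


@dataclass(frozen=True)
class ThresholdSpec:
    """Distance threshold for adjacency, carried in both nm and pixels.

    ``distance_px`` is derived by round-half-up from ``distance_nm`` and the
    pixel size, matching the convention of quoting thresholds in mixed units
    (e.g. 45 nm = 10 px at 4.5 nm/px).
    """

    distance_nm: float
    distance_px: int

    def __post_init__(self) -> None:
        if self.distance_nm <= 0:
            raise ValueError("distance_nm must be > 0")
        if self.distance_px < 0:
            raise ValueError("distance_px must be >= 0")

    @classmethod
    def from_nm(cls, distance_nm: float, pixel_size: float) -> "ThresholdSpec":
        px = int(np.floor(distance_nm / pixel_size + 0.5))  # round half up
        return cls(distance_nm=distance_nm, distance_px=px)


@dataclass
class ContactRecord:
    """Per-pair contact bookkeeping: directed counts and patch geometry."""

    pair: tuple[int, int]
    directed_pixels: tuple[int, int]  # (count a->b, count b->a)
    per_slice_outline_length_nm: list[float] = field(default_factory=list)
    total_area_nm2: float = 0.0

    def set_area(self, z_spacing: float) -> None:
        """Contact surface area: summed outline lengths x z-spacing."""
        self.total_area_nm2 = float(sum(self.per_slice_outline_length_nm)) * z_spacing


@dataclass
class AdjacencyMatrix:
    """Square symmetric nonnegative matrix of contact quantities."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix is not symmetric")
        if np.any(self.values < 0):
            raise ValueError("negative contact quantities")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label) -> int:
        return self.labels.index(label)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def expand_region(mask: np.ndarray, distance_px: int) -> np.ndarray:
    """Euclidean dilation of a binary region by ``distance_px`` pixels.

    Every pixel within Euclidean distance <= distance_px of the input region
    is set; input pixels are retained.  An empty mask is returned unchanged
    with a logged notice.
    """
    mask = np.asarray(mask).astype(bool)
    if distance_px < 0:
        raise ValueError("distance_px must be >= 0")
    if not mask.any():
        log.warning("CONTACT_EMPTY_MASK expansion of an empty region requested")
        return mask.copy()
    if distance_px == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= distance_px


def pairwise_contact_slice(
    label_image: np.ndarray,
    label_a: int,
    label_b: int,
    threshold: ThresholdSpec,
) -> tuple[int, int, np.ndarray]:
    """Directed shared-pixel counts and the 2-D contact overlap on one slice.

    count a->b = pixels of b covered by the expansion of a by the threshold
    distance; count b->a symmetric in roles.  The overlap mask is the union of
    the two directed overlaps and is the 2-D contact region used for patch
    meshing.
    """
    if label_a == label_b:
        raise ValueError("contact requires two distinct labels")
    mask_a = label_image == label_a
    mask_b = label_image == label_b
    if not mask_a.any() or not mask_b.any():
        return 0, 0, np.zeros_like(mask_a, dtype=bool)
    exp_a = expand_region(mask_a, threshold.distance_px)
    exp_b = expand_region(mask_b, threshold.distance_px)
    overlap_ab = exp_a & mask_b
    overlap_ba = exp_b & mask_a
    return int(overlap_ab.sum()), int(overlap_ba.sum()), overlap_ab | overlap_ba


def outline_length_nm(mask: np.ndarray, pixel_size: float) -> float:
    """Perimeter of a binary region in nm by boundary-segment counting.

    Counts unit pixel edges exposed to background (4-connectivity), i.e. the
    length of the rasterized contour, times the pixel size.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    padded = np.pad(mask, 1)
    edges = 0
    for axis in (0, 1):
        d = np.diff(padded.astype(np.int8), axis=axis)
        edges += int(np.abs(d).sum())
    return edges * pixel_size


def compute_adjacency_matrix(
    vol: LabelVolume, threshold: ThresholdSpec
) -> tuple[AdjacencyMatrix, list[ContactRecord]]:
    """Adjacency matrix and contact records over the analyzed region.

    Directed counts are summed over in-region slices; each matrix entry is
    the arithmetic mean of the two directed totals.  Labels present only
    outside the region contribute zero rows.
    """
    labels = vol.labels(in_region=False)
    if labels.size == 0:
        raise ValueError("volume contains no nonzero labels")
    label_list = labels.tolist()
    index = {lab: i for i, lab in enumerate(label_list)}
    n = len(label_list)
    directed = np.zeros((n, n), dtype=float)  # directed[i, j] = count i->j
    outline: dict[tuple[int, int], list[float]] = {}

    for z in vol.region_slices():
        img = vol.slices[z]
        present = [int(v) for v in np.unique(img) if v != 0]
        # expand each present label once per slice
        expansions = {
            lab: expand_region(img == lab, threshold.distance_px) for lab in present
        }
        masks = {lab: img == lab for lab in present}
        for ai, a in enumerate(present):
            for b in present[ai + 1:]:
                ab = int((expansions[a] & masks[b]).sum())
                ba = int((expansions[b] & masks[a]).sum())
                if ab == 0 and ba == 0:
                    continue
                i, j = index[a], index[b]
                directed[i, j] += ab
                directed[j, i] += ba
                ov = (expansions[a] & masks[b]) | (expansions[b] & masks[a])
                outline.setdefault((a, b), []).append(
                    outline_length_nm(ov, vol.pixel_size)
                )

    values = (directed + directed.T) / 2.0
    matrix = AdjacencyMatrix(labels=label_list, values=values)

    records: list[ContactRecord] = []
    for (a, b), lengths in sorted(outline.items()):
        i, j = index[a], index[b]
        rec = ContactRecord(
            pair=(a, b),
            directed_pixels=(int(directed[i, j]), int(directed[j, i])),
            per_slice_outline_length_nm=lengths,
        )
        rec.set_area(vol.z_spacing)
        records.append(rec)
    return matrix, records


def _pair_gap_px(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Edge-to-edge gap between two regions in pixels.

    Measured as the minimum center-to-center distance minus one pixel, so
    membrane-apposed regions (no background between them) have gap 0 and g
    background pixels between parallel edges give gap g.
    """
    dist = ndimage.distance_transform_edt(~mask_a)
    return max(0.0, float(dist[mask_b].min()) - 1.0)


def calibrate_threshold(
    vol: LabelVolume,
    reference_expansion_nm: float = 45.0,
    target_overlap_nm: float = 30.0,
    candidates_nm: list[float] | None = None,
    direct_gap_px: float = 3.0,
) -> tuple[float, float]:
    """Calibrate the per-dataset distance threshold against a target overlap.

    For each candidate distance, each cell outline is expanded by the
    candidate into its directly contacting partners and the mean penetration
    depth (candidate minus inter-membrane gap, in nm) is measured across
    contacting pairs.  Returns ``(distance_nm, achieved_depth_nm)`` for the
    smallest candidate whose mean depth reaches ``target_overlap_nm``.

    Directly contacting pairs are those whose minimum inter-region distance is
    at most ``direct_gap_px`` pixels on some slice.
    """
    if candidates_nm is None:
        candidates_nm = [reference_expansion_nm]
    candidates = sorted(candidates_nm)

    # collect per-pair minimum gaps (nm) over in-region slices
    gaps: dict[tuple[int, int], float] = {}
    for z in vol.region_slices():
        img = vol.slices[z]
        present = [int(v) for v in np.unique(img) if v != 0]
        for ai, a in enumerate(present):
            for b in present[ai + 1:]:
                g = _pair_gap_px(img == a, img == b)
                key = (a, b)
                gaps[key] = min(gaps.get(key, np.inf), g)
    contacting = {k: g for k, g in gaps.items() if g <= direct_gap_px}
    if not contacting:
        raise ValueError("no directly contacting pair found in the volume")

    gap_nm = np.array(list(contacting.values())) * vol.pixel_size
    achieved: list[float] = []
    for cand in candidates:
        depths = np.maximum(0.0, cand - gap_nm)
        achieved.append(float(depths.mean()))
    for cand, depth in zip(candidates, achieved):
        if depth >= target_overlap_nm:
            return cand, depth
    raise ValueError(
        "no candidate reaches the target overlap of "
        f"{target_overlap_nm} nm; achieved depths: "
        + ", ".join(f"{c} nm -> {d:.1f} nm" for c, d in zip(candidates, achieved))
    )


def contact_stats(
    records: list[ContactRecord],
    primary_label: int,
    neuron_surface_nm2: float,
    ring_surface_nm2: float,
) -> list[dict]:
    """Per-partner contact statistics for one primary neuron.

    For each partner: total contact area (nm^2), dense rank by area
    (1 = largest; ties share a rank), and area as a percentage of the
    neuron's surface and of the nerve-ring surface.
    """
    if neuron_surface_nm2 <= 0 or ring_surface_nm2 <= 0:
        raise ValueError("surface areas must be > 0")
    mine = [r for r in records if primary_label in r.pair]
    if not mine:
        raise ValueError(f"label {primary_label} has no contact records")
    areas = np.array([r.total_area_nm2 for r in mine])
    # dense rank: 1 = largest, equal areas share a rank, no gaps
    distinct = np.sort(np.unique(areas))[::-1]
    rank_of = {a: i + 1 for i, a in enumerate(distinct)}
    out = []
    for r, a in zip(mine, areas):
        partner = r.pair[0] if r.pair[1] == primary_label else r.pair[1]
        out.append(
            {
                "partner": partner,
                "total_area_nm2": float(a),
                "rank": rank_of[a],
                "pct_of_neuron_surface": float(a / neuron_surface_nm2 * 100.0),
                "pct_of_ring_surface": float(a / ring_surface_nm2 * 100.0),
            }
        )
    return out


def neuron_stats(vol: LabelVolume, label: int) -> tuple[float, float]:
    """(volume nm^3, surface area nm^2) of one neuron within the region.

    Volume is voxel count x pixel_size^2 x z_spacing; surface area is
    measured on the marching-cubes isosurface of the label's mask.
    """
    from contactome.meshing import isosurface, mesh_surface_area

    idx = list(vol.region_slices())
    stack = np.stack([vol.slices[z] == label for z in idx], axis=0)
    count = int(stack.sum())
    if count == 0:
        raise ValueError(f"label {label} absent from the analyzed region")
    volume = count * vol.pixel_size ** 2 * vol.z_spacing
    mesh = isosurface(stack, vol.pixel_size, vol.z_spacing)
    return volume, mesh_surface_area(mesh)
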