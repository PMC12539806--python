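"""Triangle meshes for morphologies, contact patches and synapse glyphs.

Surfaces are triangulated with marching cubes at the 0.5 level of binary
masks, with vertex coordinates scaled anisotropically into physical nm.  No
smoothing is applied anywhere so the rendered surface reflects the raw
segmentation.  Meshes align across specimens via a rigid rotation plus a
scale factor and travel as Wavefront OBJ files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from skimage.measure import block_reduce, marching_cubes

log = logging.getLogger(__name__)


@dataclass
class Mesh:
    """Triangle surface: vertices in nm, faces as vertex-index triples."""

    vertices: np.ndarray  # (V, 3) float, columns (x, y, z)
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinates")
        for f in self.faces:
            if len(set(f.tolist())) != 3:
                raise ValueError(f"degenerate face {f.tolist()}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass(frozen=True)
class TransformSpec:
    """Rigid rotation followed by uniform scaling."""

    rotation: np.ndarray  # 3x3 orthonormal
    scale: float = 1.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal (R^T R = I)")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def compose(self, other: "TransformSpec") -> "TransformSpec":
        """self after other: apply(self, apply(other, m))."""
        return TransformSpec(
            rotation=self.rotation @ other.rotation, scale=self.scale * other.scale
        )


@dataclass(frozen=True)
class SynapseAnnotation:
    partner_a: str
    partner_b: str
    kind: str  # pre | post | electrical
    position: tuple[float, float, float]
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("pre", "post", "electrical"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite synapse position")


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------

def isosurface(
    mask_stack: np.ndarray,
    pixel_size: float,
    z_spacing: float,
    downsample: int = 1,
) -> Mesh:
    """Marching-cubes surface of a binary (z, rows, cols) volume in nm.

    ``downsample`` block-reduces the in-plane resolution of the 2-D masks
    before triangulation (max-pooling, so thin structures survive); the
    effective pixel size grows by the same factor.  Vertices come out as
    (x, y, z) = (col, row, slice) in physical nm; no smoothing is applied.
    """
    vol = np.asarray(mask_stack).astype(bool)
    if vol.ndim != 3:
        raise ValueError("mask stack must be 3-D (z, rows, cols)")
    if not vol.any():
        raise ValueError("empty mask")
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    if downsample > 1:
        vol = block_reduce(vol, (1, downsample, downsample), np.max)
        pixel_size = pixel_size * downsample
    padded = np.pad(vol.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(
        padded, level=0.5, spacing=(z_spacing, pixel_size, pixel_size)
    )
    # un-pad and reorder (z, row, col) -> (x, y, z)
    verts -= np.array([z_spacing, pixel_size, pixel_size])
    xyz = verts[:, [2, 1, 0]]
    return Mesh(vertices=xyz, faces=faces)


def contact_patch_mesh(
    overlap_masks: list[np.ndarray],
    pixel_size: float,
    z_spacing: float,
) -> Mesh | None:
    """3-D contact-patch surface from the stacked 2-D overlap masks.

    Returns ``None`` with a logged warning when the overlap region is empty
    or too small to triangulate reliably — an expected outcome for tiny
    contacts, not an error.
    """
    stack = np.stack([np.asarray(m, dtype=bool) for m in overlap_masks], axis=0)
    if not stack.any():
        log.warning("CONTACT_PATCH_TOO_SMALL empty overlap; no mesh produced")
        return None
    try:
        mesh = isosurface(stack, pixel_size, z_spacing)
    except (ValueError, RuntimeError) as exc:
        log.warning("CONTACT_PATCH_TOO_SMALL triangulation failed: %s", exc)
        return None
    if mesh.n_faces == 0:
        log.warning("CONTACT_PATCH_TOO_SMALL zero faces; no mesh produced")
        return None
    return mesh


def apply_transform(mesh: Mesh, T: TransformSpec) -> Mesh:
    """v' = scale x (R v) for every vertex; faces unchanged."""
    verts = (T.rotation @ mesh.vertices.T).T * T.scale
    return Mesh(vertices=verts, faces=mesh.faces.copy())


def mesh_surface_area(mesh: Mesh) -> float:
    """Total triangle area (nm^2)."""
    v = mesh.vertices
    a = v[mesh.faces[:, 1]] - v[mesh.faces[:, 0]]
    b = v[mesh.faces[:, 2]] - v[mesh.faces[:, 0]]
    return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())


def is_watertight(mesh: Mesh) -> bool:
    """Every edge shared by exactly two faces."""
    edges = {}
    for f in mesh.faces:
        for i in range(3):
            e = tuple(sorted((int(f[i]), int(f[(i + 1) % 3]))))
            edges[e] = edges.get(e, 0) + 1
    return all(c == 2 for c in edges.values())


# ---------------------------------------------------------------------------
# Synapse glyphs
# ---------------------------------------------------------------------------

def _star_mesh() -> Mesh:
    """Six-spike octahedral star of unit tip radius centered at the origin."""
    w = 0.35
    cube = np.array(
        [[sx * w, sy * w, sz * w] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    tips = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    verts = np.vstack([cube, tips])
    faces = []
    for t, tip in enumerate(tips):
        axis = int(np.argmax(np.abs(tip)))
        sign = np.sign(tip[axis])
        ring = [i for i, v in enumerate(cube) if np.sign(v[axis]) == sign]
        center = cube[ring].mean(axis=0)
        # order the 4 ring vertices around the tip axis
        rest = [a for a in range(3) if a != axis]
        ang = np.arctan2(cube[ring][:, rest[1]] - center[rest[1]],
                         cube[ring][:, rest[0]] - center[rest[0]])
        ring = [ring[i] for i in np.argsort(ang)]
        for i in range(4):
            a, b = ring[i], ring[(i + 1) % 4]
            tri = [8 + t, a, b]
            # orient outward: normal should point away from the origin
            n = np.cross(verts[tri[1]] - verts[tri[0]], verts[tri[2]] - verts[tri[0]])
            if np.dot(n, verts[tri].mean(axis=0)) < 0:
                tri = [8 + t, b, a]
            faces.append(tri)
    return Mesh(vertices=verts, faces=np.array(faces))


def _unit_glyph(kind: str) -> Mesh:
    if kind == "pre":  # block
        tm = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        return Mesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
    if kind == "post":  # sphere
        tm = trimesh.creation.icosphere(subdivisions=1, radius=0.5)
        return Mesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
    if kind == "electrical":  # star
        m = _star_mesh()
        return Mesh(vertices=m.vertices * 0.5, faces=m.faces)
    raise ValueError(f"unknown synapse kind {kind!r}")


def place_synapse_glyphs(
    annotations: list[SynapseAnnotation], base_size_nm: float = 100.0
) -> list[Mesh]:
    """One glyph mesh per annotation, centered at the annotated position.

    Shape by kind — pre: block, post: sphere, electrical: star — with the
    glyph's extent ``base_size_nm`` times the annotation's scale factor.
    """
    glyphs = []
    for ann in annotations:
        unit = _unit_glyph(ann.kind)
        size = base_size_nm * ann.scale
        verts = unit.vertices * size
        verts = verts - verts.mean(axis=0) + np.asarray(ann.position, dtype=float)
        glyphs.append(Mesh(vertices=verts, faces=unit.faces.copy()))
    return glyphs


# ---------------------------------------------------------------------------
# Wavefront OBJ I/O
# ---------------------------------------------------------------------------

def write_obj(mesh: Mesh, path) -> None:
    """Write v/f records, face indices 1-based per the OBJ convention."""
    with open(path, "w") as fh:
        fh.write("# contactome mesh\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def read_obj(path) -> Mesh:
    """Read v/f records; malformed lines raise with their line number."""
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            try:
                if tok[0] == "v":
                    verts.append([float(t) for t in tok[1:4]])
                elif tok[0] == "f":
                    idx = [int(t.split("/")[0]) - 1 for t in tok[1:4]]
                    faces.append(idx)
                # other record types (vn, vt, o, g, ...) are ignored
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: parse error at line {lineno}: {raw!r}") from exc
    if not verts:
        raise ValueError(f"{path}: no vertex records")
    return Mesh(vertices=np.array(verts), faces=np.array(faces, dtype=int).reshape(-1, 3))
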