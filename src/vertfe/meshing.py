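"""Voxel mask → conforming linear tetrahedral mesh.

The labeled region is block-coarsened to cubic cells of side ≈ the target
edge length (a cell is kept when at least half of its voxels are
foreground), and each kept cell is split into the 6 Freudenthal (Kuhn)
tetrahedra sharing the cell's main diagonal.  Using the same split in every
cell makes shared faces conforming without any parity bookkeeping.  Element
labels (body vs posterior) are inherited by majority vote over the cell's
foreground voxels, ties to the body.

No surface smoothing is applied: the stair-step boundary is deterministic
and all failure-load comparisons in this package are relative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .image import ImageVolume, LabelMask

__all__ = [
    "TetMesh",
    "voxel_to_tet",
    "extract_boundary_sets",
    "tet_volumes",
    "export_abaqus_inp",
]

# Freudenthal split: for each permutation of the unit steps (ex, ey, ez) the
# tet walks 0 -> e_p0 -> e_p0+e_p1 -> (1,1,1); all 6 share the main diagonal.
_PERMS = list(itertools.permutations((0, 1, 2)))


def _freudenthal_offsets() -> np.ndarray:
    """(6, 4, 3) corner offsets of the 6 tets of a unit cell, positively oriented."""
    tets = []
    eye = np.eye(3, dtype=np.int64)
    for perm in _PERMS:
        p0 = np.zeros(3, dtype=np.int64)
        p1 = p0 + eye[perm[0]]
        p2 = p1 + eye[perm[1]]
        p3 = np.ones(3, dtype=np.int64)
        verts = np.stack([p0, p1, p2, p3])
        if np.linalg.det((verts[1:] - verts[0]).astype(float)) < 0:
            verts = verts[[0, 2, 1, 3]]
        tets.append(verts)
    return np.stack(tets)


_TET_OFFSETS = _freudenthal_offsets()


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with named boundary node sets.

    nodes : (M, 3) float, mm.  tets : (N, 4) int, positively oriented.
    element_label : (N,) int — 1 body, 2 posterior.
    node_sets : e.g. {"inferior_body": array, "superior_body": array}.
    """

    nodes: np.ndarray
    tets: np.ndarray
    element_label: np.ndarray
    node_sets: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def volume(self) -> float:
        return float(tet_volumes(self).sum())


def tet_volumes(mesh: TetMesh) -> np.ndarray:
    """Signed volumes of all elements (positive under the ordering convention)."""
    v = mesh.nodes[mesh.tets]
    d = v[:, 1:] - v[:, :1]
    return np.linalg.det(d) / 6.0


def voxel_to_tet(mask: LabelMask, img: ImageVolume, target_edge_mm: float) -> TetMesh:
    """Structured 6-tet-per-cell mesh of the labeled region.

    Cubic cells of side exactly ``target_edge_mm`` are laid on a lattice
    anchored at the grid origin; each voxel is assigned to the cell holding
    its center, and a cell is kept when the foreground voxel volume inside
    it is at least half the cell volume.  When the edge equals the (uniform)
    voxel spacing the cells coincide with the voxels and the mesh volume
    equals the voxel-counted mask volume exactly.
    """
    mask.check_grid(img)
    spacing = np.asarray(mask.spacing)
    edge = float(target_edge_mm)
    if edge < max(spacing) * (1 - 1e-9):
        raise ValueError(
            f"target_edge_mm={edge} is below the voxel spacing {tuple(spacing)}"
        )
    labels = mask.labels
    if not (labels > 0).any():
        raise ValueError("mask is empty: no foreground voxels to mesh")

    shape = np.asarray(labels.shape)
    # cell index of each voxel center along each axis
    axis_cells = [
        np.floor(((np.arange(shape[a]) + 0.5) * spacing[a]) / edge * (1 + 1e-12)).astype(
            np.int64
        )
        for a in range(3)
    ]
    ncell = np.asarray([int(c[-1]) + 1 for c in axis_cells])
    ci = axis_cells[0][:, None, None]
    cj = axis_cells[1][None, :, None]
    ck = axis_cells[2][None, None, :]
    flat_cell = (ci * ncell[1] + cj) * ncell[2] + ck
    ncell_total = int(np.prod(ncell))
    n_tot = np.bincount(flat_cell.ravel(), minlength=ncell_total)
    n1 = np.bincount(flat_cell.ravel()[(labels == 1).ravel()], minlength=ncell_total)
    n2 = np.bincount(flat_cell.ravel()[(labels == 2).ravel()], minlength=ncell_total)

    # >= half of the voxels assigned to the cell are foreground, ties kept
    keep = (n_tot > 0) & (2 * (n1 + n2) >= n_tot)
    if not keep.any():
        raise ValueError("no cell is at least half foreground at this edge length")
    cell_label = np.where(n2 > n1, 2, 1).astype(np.uint8)

    kept = np.nonzero(keep)[0]
    cells = np.stack(
        [kept // (ncell[1] * ncell[2]), (kept // ncell[2]) % ncell[1], kept % ncell[2]],
        axis=1,
    )
    k = len(cells)

    # corner lattice ids: corner (i, j, k) -> flat id on (ncell+1) grid
    corners = cells[:, None, None, :] + _TET_OFFSETS[None]  # (K, 6, 4, 3)
    dims = ncell + 1
    flat = (
        corners[..., 0] * dims[1] * dims[2] + corners[..., 1] * dims[2] + corners[..., 2]
    )
    used, inv = np.unique(flat, return_inverse=True)
    tets = inv.reshape(k * 6, 4)

    gi = used // (dims[1] * dims[2])
    gj = (used // dims[2]) % dims[1]
    gk = used % dims[2]
    origin = np.asarray(mask.origin)
    nodes = origin + np.stack([gi, gj, gk], axis=1) * edge

    element_label = np.repeat(cell_label[kept], 6)
    return TetMesh(nodes.astype(np.float64), tets.astype(np.int64), element_label)


def extract_boundary_sets(mesh: TetMesh, band_fraction: float = 0.02) -> TetMesh:
    """Fill ``inferior_body`` / ``superior_body`` node sets in place.

    Each set holds the nodes of body-labeled elements whose z lies within
    ``band_fraction`` of the body's z-extent from its min (max); nodes shared
    with posterior elements are excluded, so the platens never touch the
    posterior arch.
    """
    if not (0 < band_fraction < 1):
        raise ValueError("band_fraction must be in (0, 1)")
    body_elems = mesh.element_label == 1
    if not body_elems.any():
        raise ValueError("mesh has no body-labeled elements")
    body_nodes = np.unique(mesh.tets[body_elems])
    post_nodes = np.unique(mesh.tets[mesh.element_label == 2])
    z = mesh.nodes[body_nodes, 2]
    zmin, zmax = z.min(), z.max()
    band = band_fraction * (zmax - zmin)
    shared = np.isin(body_nodes, post_nodes)
    inferior = body_nodes[(z <= zmin + band) & ~shared]
    superior = body_nodes[(z >= zmax - band) & ~shared]
    if len(inferior) == 0 or len(superior) == 0:
        raise ValueError(
            "boundary band produced an empty node set (geometry too thin for band)"
        )
    mesh.node_sets["inferior_body"] = inferior
    mesh.node_sets["superior_body"] = superior
    return mesh


def export_abaqus_inp(mesh: TetMesh, materials, path, n_bins: int = 100) -> None:
    """Minimal Abaqus-dialect .inp export: nodes, C3D4 elements, binned sections.

    Elements are grouped into ``n_bins`` equal-width bins of Ez; each bin
    gets an element set, a *SOLID SECTION and an isotropic-equivalent
    *ELASTIC block (engineering constants for the transversely isotropic
    material).  Intended as a cross-validation export, not a full deck.
    """
    ez = np.asarray(materials.Ez)
    lo, hi = ez.min(), ez.max()
    if hi <= lo:
        bins = np.zeros(len(ez), dtype=int)
        n_bins = 1
    else:
        bins = np.minimum(((ez - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
    with open(path, "w") as f:
        f.write("*HEADING\nvertfe voxel tetra model\n")
        f.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i}, {x:.6g}, {y:.6g}, {z:.6g}\n")
        f.write("*ELEMENT, TYPE=C3D4\n")
        for e, tet in enumerate(mesh.tets, start=1):
            a, b, c, d = tet + 1
            f.write(f"{e}, {a}, {b}, {c}, {d}\n")
        for name, nodes in mesh.node_sets.items():
            f.write(f"*NSET, NSET={name.upper()}\n")
            ids = nodes + 1
            for chunk in np.array_split(ids, max(1, len(ids) // 12)):
                f.write(", ".join(str(int(i)) for i in chunk) + "\n")
        for b in np.unique(bins):
            elems = np.nonzero(bins == b)[0] + 1
            f.write(f"*ELSET, ELSET=MAT{b}\n")
            for chunk in np.array_split(elems, max(1, len(elems) // 12)):
                f.write(", ".join(str(int(i)) for i in chunk) + "\n")
            ez_bin = float(ez[bins == b].mean())
            f.write(f"*SOLID SECTION, ELSET=MAT{b}, MATERIAL=MAT{b}\n")
            f.write(f"*MATERIAL, NAME=MAT{b}\n*ELASTIC, TYPE=ENGINEERING CONSTANTS\n")
            ex = 0.333 * ez_bin
            f.write(
                f"{ex:.6g}, {ex:.6g}, {ez_bin:.6g}, "
                f"{materials.nu_xy}, {materials.nu_xz}, {materials.nu_xz}, "
                f"{0.121 * ez_bin:.6g}, {0.157 * ez_bin:.6g}\n{0.157 * ez_bin:.6g}\n"
            )
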