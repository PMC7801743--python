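"""Triangulated cortical surface patches and ROI definitions.

Meshes are plain vertex/face arrays read and written as OFF-format
text; an optional GIFTI loader delegates to nibabel when available.
ROI border vertex lists are stored one 0-based index per line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SurfacePatch", "RoiMap", "read_off", "write_off", "read_vertex_list", "write_vertex_list", "load_gifti_surface"]


@dataclass(frozen=True)
class SurfacePatch:
    """Triangulated surface: (n, 3) vertex coordinates in mm, (m, 3) triangle indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        if np.any(areas < 1e-12):
            raise ValueError("mesh contains degenerate (zero-area) triangles")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (k, 2) index array."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)


@dataclass(frozen=True)
class RoiMap:
    """ROI membership with designated low- and high-preference end borders."""

    members: np.ndarray
    low_border: np.ndarray
    high_border: np.ndarray

    def __post_init__(self) -> None:
        m = np.unique(np.asarray(self.members, dtype=int))
        lo = np.unique(np.asarray(self.low_border, dtype=int))
        hi = np.unique(np.asarray(self.high_border, dtype=int))
        if lo.size == 0 or hi.size == 0:
            raise ValueError("border vertex sets must be non-empty")
        if np.intersect1d(lo, hi).size:
            raise ValueError("low and high borders must be disjoint")
        if not (np.isin(lo, m).all() and np.isin(hi, m).all()):
            raise ValueError("borders must be subsets of the ROI members")
        object.__setattr__(self, "members", m)
        object.__setattr__(self, "low_border", lo)
        object.__setattr__(self, "high_border", hi)

    def swapped(self) -> "RoiMap":
        """Same ROI with the two end borders exchanged."""
        return RoiMap(members=self.members, low_border=self.high_border, high_border=self.low_border)


def write_off(patch: SurfacePatch, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(patch.vertices)} {len(patch.faces)} 0\n")
        for v in patch.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in patch.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_off(path: str | Path) -> SurfacePatch:
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    body = tokens[4:]
    verts = np.array(body[: 3 * nv], dtype=float).reshape(nv, 3)
    faces = []
    i = 3 * nv
    for _ in range(nf):
        k = int(body[i])
        if k != 3:
            raise ValueError("only triangle meshes are supported")
        faces.append([int(body[i + 1]), int(body[i + 2]), int(body[i + 3])])
        i += k + 1
    return SurfacePatch(vertices=verts, faces=np.asarray(faces))


def write_vertex_list(indices: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(indices, dtype=int), fmt="%d")


def read_vertex_list(path: str | Path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path, dtype=int))


def load_gifti_surface(path: str | Path) -> SurfacePatch:
    """Load a GIFTI surface file (requires nibabel)."""
    import nibabel as nib

    img = nib.load(str(path))
    verts = img.agg_data("NIFTI_INTENT_POINTSET")
    faces = img.agg_data("NIFTI_INTENT_TRIANGLE")
    return SurfacePatch(vertices=np.asarray(verts, dtype=float), faces=np.asarray(faces, dtype=int))
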