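"""Triangulated-surface utilities shared by the cohort generator and the
shape-association pipeline.

All coordinates are in millimetres. A surface is a pair ``(vertices, faces)``
with ``vertices`` an (n, 3) float array and ``faces`` an (m, 3) int array.
Triangulations built here are consistently outward-oriented so that
area-weighted vertex normals point away from the enclosed cavity.
"""

from __future__ import annotations

import numpy as np
import trimesh

__all__ = [
    "fibonacci_sphere",
    "ellipsoid_surface",
    "vertex_normals",
    "triangle_areas",
    "write_surface",
    "read_surface",
    "write_vtk_pointdata",
    "write_scalar_csv",
]


def fibonacci_sphere(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` points on the unit sphere with a Fibonacci lattice and
    triangulate them by their convex hull.

    The lattice places points in convex position, so every point is a hull
    vertex and the hull facets form a valid closed triangulation with no
    degenerate (zero-area) triangles. This gives a closed-at-apex surface
    with an *exact*, arbitrary vertex count, which is what the cohort
    generator needs to honour per-substructure point budgets.
    """
    if n < 4:
        raise ValueError(f"need at least 4 points for a closed surface, got {n}")
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    phi = 2.0 * np.pi * i / golden
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    if len(hull.vertices) != n:  # pragma: no cover - lattice is convex by design
        raise RuntimeError("Fibonacci lattice produced non-convex configuration")
    faces = _orient_outward(pts, hull.simplices)
    return pts, faces


def _orient_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip triangles whose normal points toward the centroid."""
    centroid = vertices.mean(axis=0)
    tri = vertices[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    outward = tri.mean(axis=1) - centroid
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    faces = faces.copy()
    faces[flip] = faces[flip][:, ::-1]
    return faces


def ellipsoid_surface(
    n: int,
    semi_axes: tuple[float, float, float],
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Closed ellipsoid with exactly ``n`` vertices (Fibonacci lattice)."""
    pts, faces = fibonacci_sphere(n)
    v = pts * np.asarray(semi_axes, dtype=float) + np.asarray(center, dtype=float)
    return v, faces


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unit vertex normals as the area-weighted average of incident triangle
    normals.

    The raw triangle cross product has magnitude 2x the triangle area, so
    accumulating it per incident vertex weights each face by its area.
    """
    tri = vertices[faces]
    face_n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normals = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(normals, faces[:, k], face_n)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("vertex with zero accumulated normal (degenerate star)")
    return normals / norm


# ---------------------------------------------------------------------------
# I/O — OFF / PLY through trimesh, legacy-VTK point scalars by hand
# ---------------------------------------------------------------------------

def write_surface(path, vertices: np.ndarray, faces: np.ndarray) -> None:
    """Write OFF or PLY (chosen by extension), ASCII encoding."""
    path = str(path)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if path.endswith(".off"):
        mesh.export(path, file_type="off")
    elif path.endswith(".ply"):
        mesh.export(path, file_type="ply", encoding="ascii")
    else:
        raise ValueError(f"unsupported mesh extension for {path!r} (use .off or .ply)")


def read_surface(path) -> tuple[np.ndarray, np.ndarray]:
    mesh = trimesh.load_mesh(str(path), process=False)
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=int)


def write_vtk_pointdata(path, vertices, faces, scalars: dict[str, np.ndarray]) -> None:
    """Legacy ASCII VTK PolyData file with one or more POINT_DATA scalar
    fields — viewable in ParaView etc. without extra dependencies."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlipidshape vertex map\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} float\n")
        for x, y, z in vertices:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for a, b, c in faces:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"POINT_DATA {len(vertices)}\n")
        for name, values in scalars.items():
            values = np.asarray(values, dtype=float)
            if len(values) != len(vertices):
                raise ValueError(f"scalar field {name!r} length mismatch")
            fh.write(f"SCALARS {name.replace(' ', '_')} float 1\nLOOKUP_TABLE default\n")
            for v in values:
                fh.write("nan\n" if not np.isfinite(v) else f"{v:.6f}\n")


def write_scalar_csv(path, values: np.ndarray) -> None:
    """Viewer-agnostic per-vertex scalar export: ``vertex_id,value``."""
    with open(path, "w") as fh:
        fh.write("vertex_id,value\n")
        for i, v in enumerate(np.asarray(values, dtype=float)):
            fh.write(f"{i},{'' if not np.isfinite(v) else repr(float(v))}\n")
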