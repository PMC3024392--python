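"""Association of a lipid with heart shape via surface-normal regression.

The pipeline: rigidly align corresponded heart surfaces, average the control
group into a mean two-phase model carrying a vertex normal field, code each
subject as signed deviations from the mean along those normals, regress the
per-vertex deviation on a lipid value across subjects, reconstruct synthetic
hearts at chosen lipid values, and map the consequences as per-vertex wall
thickening and wall motion differences.

Conventions
-----------
* coordinates in millimetres; phases are ``"ED"`` (end-diastole) and
  ``"ES"`` (end-systole);
* normals are computed once on the mean model per phase (area-weighted) and
  reused for deviation coding, reconstruction, and motion; ED normals anchor
  motion;
* deviation of subject j at vertex i: d_ji = (x_ji - mean_i) . n_i;
* per-vertex regression: d_ji = a_i + b_i * l_j (ordinary least squares over
  subjects), so a reconstructed surface at lipid value l is
  mean_i + (a_i + b_i * l) * n_i;
* wall thickness at an LV-endocardial vertex is the distance along its
  outward normal to the first epicardial triangle hit; wall thickening is
  thickness(ES) - thickness(ED); wall motion is the ED->ES displacement
  projected on the inward ED normal, so that systolic contraction is
  positive and a *negative* difference map means reduced function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .meshes import (
    read_surface,
    vertex_normals,
    write_scalar_csv,
    write_surface,
    write_vtk_pointdata,
)

PHASES = ("ED", "ES")
SURFACES = ("lv_endo", "rv_endo", "epicardium")

__all__ = [
    "HeartSurfaceCohort",
    "MeanModel",
    "VertexRegressionField",
    "rigid_align",
    "kabsch",
    "mean_model",
    "shape_deviations",
    "fit_vertex_regression",
    "reconstruct_shape",
    "wall_thickness",
    "thickening_and_motion_maps",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class HeartSurfaceCohort:
    """Corresponded heart surfaces for a cohort.

    ``coords[phase]`` is an (n_subjects, n_vertices, 3) array; every subject
    and phase shares ``faces`` and the per-vertex ``labels`` (one of
    ``lv_endo``, ``rv_endo``, ``epicardium``), which is what point
    correspondence means here.
    """

    coords: dict[str, np.ndarray]
    faces: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame  # index subject_id, column "group"

    def __post_init__(self):
        shapes = {self.coords[p].shape for p in self.coords}
        if len(shapes) != 1:
            raise ValueError("phases disagree on array shape")
        (n_subj, n_vert, three), = shapes
        if three != 3 or n_vert != len(self.labels):
            raise ValueError("coords / labels mismatch")
        if n_subj != len(self.meta):
            raise ValueError("coords / meta subject count mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.meta)

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    def surface_mask(self, surface: str) -> np.ndarray:
        if surface not in SURFACES:
            raise ValueError(f"unknown surface {surface!r}")
        return self.labels == surface

    def subject_index(self, groups) -> np.ndarray:
        return np.flatnonzero(self.meta["group"].isin(groups).values)

    # -- persistence ---------------------------------------------------

    def write(self, outdir, fmt: str = "off") -> None:
        """One mesh file per subject per phase plus a ``cohort.json``
        manifest recording files, groups, and label ranges."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "subjects": [],
            "phases": list(self.coords),
            "labels": _label_ranges(self.labels),
            "format": fmt,
        }
        for j, sid in enumerate(self.meta.index):
            entry = {"subject_id": str(sid), "group": int(self.meta["group"].iloc[j]),
                     "files": {}}
            for phase in self.coords:
                fname = f"{sid}_{phase}.{fmt}"
                write_surface(outdir / fname, self.coords[phase][j], self.faces)
                entry["files"][phase] = fname
            manifest["subjects"].append(entry)
        with open(outdir / "cohort.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def read(cls, outdir) -> "HeartSurfaceCohort":
        outdir = Path(outdir)
        with open(outdir / "cohort.json") as fh:
            manifest = json.load(fh)
        labels = _expand_label_ranges(manifest["labels"])
        coords = {p: [] for p in manifest["phases"]}
        meta_rows = []
        faces = None
        for entry in manifest["subjects"]:
            meta_rows.append(dict(subject_id=entry["subject_id"], group=entry["group"]))
            for phase in manifest["phases"]:
                v, f = read_surface(outdir / entry["files"][phase])
                faces = f if faces is None else faces
                coords[phase].append(v)
        meta = pd.DataFrame(meta_rows).set_index("subject_id")
        return cls(coords={p: np.asarray(v) for p, v in coords.items()},
                   faces=faces, labels=labels, meta=meta)


def _label_ranges(labels: np.ndarray) -> dict[str, list[int]]:
    out = {}
    for s in SURFACES:
        idx = np.flatnonzero(labels == s)
        if len(idx):
            out[s] = [int(idx[0]), int(idx[-1]) + 1]
    return out


def _expand_label_ranges(ranges: dict[str, list[int]]) -> np.ndarray:
    n = max(b for _, b in ranges.values())
    labels = np.empty(n, dtype=object)
    for s, (a, b) in ranges.items():
        labels[a:b] = s
    return labels.astype(str)


@dataclass
class MeanModel:
    """Vertex-wise average surface of a reference (control) group, with the
    unit normal field used throughout the shape coding."""

    coords: dict[str, np.ndarray]      # phase -> (n_vertices, 3)
    normals: dict[str, np.ndarray]     # phase -> (n_vertices, 3), unit
    faces: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        for p in self.coords:
            norm = np.linalg.norm(self.normals[p], axis=1)
            if not np.allclose(norm, 1.0, atol=1e-8):
                raise ValueError(f"normals not unit length in phase {p!r}")


@dataclass
class VertexRegressionField:
    """Per-vertex OLS of normal deviation on a lipid: d = a + b * l.

    ``intercept`` and ``slope`` are (n_vertices,) arrays per phase, in mm
    and mm per lipid unit. ``lipid_mean`` / ``lipid_sd`` are the reference
    (control) group's lipid statistics used for reconstruction at perturbed
    values.
    """

    lipid: str
    intercept: dict[str, np.ndarray]
    slope: dict[str, np.ndarray]
    lipid_mean: float
    lipid_sd: float


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimising ||R@moving + t - target||.

    SVD solution with the determinant sign fix so reflections are never
    returned.
    """
    mu_m = moving.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (moving - mu_m).T @ (target - mu_t)
    U, S, Vt = np.linalg.svd(H)
    if S[-1] <= 0 and S[-2] <= 0:
        raise ValueError("degenerate (rank-deficient) configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_m
    return R, t


def rigid_align(cohort: HeartSurfaceCohort, reference: np.ndarray | None = None) -> HeartSurfaceCohort:
    """Rigidly align every subject to a reference vertex set (no scaling).

    One transform per subject, estimated on the ED phase over all vertices
    and applied to both phases so intra-subject motion is preserved. The
    default reference is the first subject's ED surface.
    """
    if reference is None:
        reference = cohort.coords["ED"][0]
    new_coords = {p: np.empty_like(cohort.coords[p]) for p in cohort.coords}
    for j in range(cohort.n_subjects):
        R, t = kabsch(cohort.coords["ED"][j], reference)
        for p in cohort.coords:
            new_coords[p][j] = cohort.coords[p][j] @ R.T + t
    return HeartSurfaceCohort(coords=new_coords, faces=cohort.faces.copy(),
                              labels=cohort.labels.copy(), meta=cohort.meta.copy())


# ---------------------------------------------------------------------------
# Mean model, deviations, regression, reconstruction
# ---------------------------------------------------------------------------

def mean_model(cohort: HeartSurfaceCohort, groups=(2,)) -> MeanModel:
    """Vertex-wise mean of the reference group (default the matched
    controls, group 2) per phase, with per-surface area-weighted normals."""
    idx = cohort.subject_index(groups)
    if len(idx) < 1:
        raise ValueError("reference group is empty")
    coords = {p: cohort.coords[p][idx].mean(axis=0) for p in cohort.coords}
    normals = {}
    for p, v in coords.items():
        n = np.empty_like(v)
        for s in SURFACES:
            mask = cohort.labels == s
            if not mask.any():
                continue
            # each substructure is its own closed surface: restrict the
            # triangulation so normals do not bleed across structures
            n[mask] = _surface_normals(v, cohort.faces, mask)
        normals[p] = n
    return MeanModel(coords=coords, normals=normals,
                     faces=cohort.faces.copy(), labels=cohort.labels.copy())


def _surface_normals(vertices: np.ndarray, faces: np.ndarray, mask: np.ndarray) -> np.ndarray:
    keep = mask[faces].all(axis=1)
    sub_faces = faces[keep]
    old_to_new = -np.ones(len(vertices), dtype=int)
    ids = np.flatnonzero(mask)
    old_to_new[ids] = np.arange(len(ids))
    return vertex_normals(vertices[ids], old_to_new[sub_faces])


def shape_deviations(cohort: HeartSurfaceCohort, mean: MeanModel) -> dict[str, np.ndarray]:
    """Signed deviation of each subject from the mean along the mean-model
    normals: d[phase][j, i] = (x_ji - mean_i) . n_i."""
    out = {}
    for p in cohort.coords:
        diff = cohort.coords[p] - mean.coords[p][None, :, :]
        out[p] = np.einsum("jik,ik->ji", diff, mean.normals[p])
    return out


def fit_vertex_regression(
    deviations: dict[str, np.ndarray],
    lipid_values: np.ndarray,
    *,
    lipid: str = "lipid",
    reference_values: np.ndarray | None = None,
) -> VertexRegressionField:
    """Ordinary least squares of d_ji on l_j at every vertex, per phase.

    ``lipid_values`` has one entry per cohort subject (the pooled case +
    control sample); ``reference_values`` are the control-group lipid values
    whose mean/SD parameterise reconstruction (defaults to all values).
    """
    l = np.asarray(lipid_values, dtype=float)
    var = l.var()
    if var == 0:
        raise ValueError("lipid has zero variance across subjects; slope undefined")
    if len(l) < 3:
        raise ValueError("need at least 3 subjects for a meaningful fit")
    ref = l if reference_values is None else np.asarray(reference_values, dtype=float)
    intercept, slope = {}, {}
    lc = l - l.mean()
    for p, d in deviations.items():
        if d.shape[0] != len(l):
            raise ValueError("one lipid value per subject required")
        b = (lc @ d) / (lc @ lc)
        a = d.mean(axis=0) - b * l.mean()
        intercept[p], slope[p] = a, b
    return VertexRegressionField(lipid=lipid, intercept=intercept, slope=slope,
                                 lipid_mean=float(ref.mean()), lipid_sd=float(ref.std()))


def reconstruct_shape(
    field: VertexRegressionField,
    mean: MeanModel,
    lipid_value: float,
) -> dict[str, np.ndarray]:
    """Surface at a given lipid value: x_i = mean_i + (a_i + b_i*l) * n_i,
    both phases."""
    out = {}
    for p in mean.coords:
        d = field.intercept[p] + field.slope[p] * lipid_value
        out[p] = mean.coords[p] + d[:, None] * mean.normals[p]
    return out


def perturbed_lipid_value(field: VertexRegressionField, direction: float = -1.0,
                          n_sd: float = 2.0) -> float:
    """Reference mean shifted by ``n_sd`` control-group SDs; the default
    direction (negative) follows a lipid found diminished in cases."""
    return field.lipid_mean + direction * n_sd * field.lipid_sd


# ---------------------------------------------------------------------------
# Wall thickness / thickening / motion
# ---------------------------------------------------------------------------

def _ray_triangle_first_hit(
    origins: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    eps: float = 1e-9,
) -> np.ndarray:
    """Vectorised Moller-Trumbore: smallest positive ray parameter t per ray
    over all triangles, NaN where nothing is hit. ``triangles`` is
    (m, 3, 3); directions need not be unit length (t is then in direction
    units, so pass unit normals for millimetres)."""
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    best = np.full(len(origins), np.inf)
    # chunk over rays to bound the (rays x triangles) intermediates
    chunk = max(1, int(4e6 // max(len(triangles), 1)))
    for s in range(0, len(origins), chunk):
        O = origins[s:s + chunk][:, None, :]    # (r, 1, 3)
        D = directions[s:s + chunk][:, None, :]
        P = np.cross(D, e2[None, :, :])
        det = np.einsum("rmk,mk->rm", P, e1)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        T = O - v0[None, :, :]
        u = np.einsum("rmk,rmk->rm", T, P) * inv
        Q = np.cross(T, e1[None, :, :])
        v = np.einsum("rmk,rmk->rm", Q, np.broadcast_to(D, Q.shape)) * inv
        t = np.einsum("rmk,mk->rm", Q, e2) * inv
        # t >= -eps keeps zero-distance hits so coincident surfaces get
        # thickness 0 (rays from endocardial vertices never start on the
        # epicardium otherwise)
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t >= -eps)
        t = np.where(hit, np.maximum(t, 0.0), np.inf)
        best[s:s + chunk] = t.min(axis=1)
    best[~np.isfinite(best)] = np.nan
    return best


def wall_thickness(
    endo_vertices: np.ndarray,
    endo_normals: np.ndarray,
    epi_vertices: np.ndarray,
    epi_faces: np.ndarray,
    cutoff: float = 50.0,
) -> np.ndarray:
    """Per-vertex myocardial thickness: distance from each endocardial
    vertex along its outward unit normal to the first epicardial triangle.

    Vertices whose ray misses the epicardium within ``cutoff`` mm come back
    NaN (flagged, excluded from maps) rather than silently substituted.
    """
    triangles = np.asarray(epi_vertices, dtype=float)[np.asarray(epi_faces, dtype=int)]
    thickness = _ray_triangle_first_hit(
        np.asarray(endo_vertices, dtype=float),
        np.asarray(endo_normals, dtype=float),
        triangles,
    )
    thickness[thickness > cutoff] = np.nan
    return thickness


def thickening_and_motion_maps(
    model_low: dict[str, np.ndarray],
    model_high: dict[str, np.ndarray],
    mean: MeanModel,
    surface: str = "lv_endo",
) -> tuple[np.ndarray, np.ndarray]:
    """Difference maps (low-lipid minus high-lipid) of wall thickening and
    wall motion on one surface (default LV endocardium).

    thickening = thickness(ES) - thickness(ED);
    motion = (x_ED - x_ES) . n_ED  (contraction positive).
    Negative map values mean the quantity decreased at the low lipid value.
    """
    mask = mean.labels == surface
    epi_mask = mean.labels == "epicardium"
    keep = epi_mask[mean.faces].all(axis=1)
    epi_faces_l = mean.faces[keep]
    ids = np.flatnonzero(epi_mask)
    remap = -np.ones(len(mean.labels), dtype=int)
    remap[ids] = np.arange(len(ids))
    epi_faces_local = remap[epi_faces_l]

    def measures(model):
        thick = {}
        for p in PHASES:
            thick[p] = wall_thickness(
                model[p][mask], mean.normals[p][mask],
                model[p][epi_mask], epi_faces_local,
            )
        thickening = thick["ES"] - thick["ED"]
        motion = np.einsum(
            "ik,ik->i", model["ED"][mask] - model["ES"][mask], mean.normals["ED"][mask]
        )
        return thickening, motion

    th_low, mo_low = measures(model_low)
    th_high, mo_high = measures(model_high)
    return th_low - th_high, mo_low - mo_high


def export_maps(outdir, mean: MeanModel, thickening: np.ndarray, motion: np.ndarray,
                surface: str = "lv_endo") -> None:
    """Write the LV maps as legacy-VTK point scalars and plain CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = mean.labels == surface
    ids = np.flatnonzero(mask)
    remap = -np.ones(len(mean.labels), dtype=int)
    remap[ids] = np.arange(len(ids))
    keep = mask[mean.faces].all(axis=1)
    faces_local = remap[mean.faces[keep]]
    write_vtk_pointdata(
        outdir / f"{surface}_maps.vtk", mean.coords["ED"][mask], faces_local,
        {"thickening_diff_mm": thickening, "motion_diff_mm": motion},
    )
    write_scalar_csv(outdir / f"{surface}_thickening_diff.csv", thickening)
    write_scalar_csv(outdir / f"{surface}_motion_diff.csv", motion)
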