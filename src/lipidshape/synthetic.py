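"""Synthetic lipid studies and heart-surface cohorts with known ground truth.

Two case-control serum lipidomics studies are emulated: a discovery study
(11 mutation carriers at risk of dilated cardiomyopathy vs 11 matched
controls, groups 1/2) and an independent study (8 diagnosed DCM patients vs
8 controls, groups 3/4). Concentrations are log-normal; a planted effect is
an additive shift of the case-group log-mean, so the planted fold equals the
case/control median ratio of the generating distribution exactly.

The default panel has 286 species laid out on contiguous (class, carbons,
double-bond) grids so that exhaustive desaturation + elongation enumeration
yields exactly 267 ratio variables (553 variables in total), and contains
the seven species/ratios whose between-group folds the default effect maps
plant (0.4-0.9 on the median).

Heart cohorts are built from an a-priori two-phase geometry: closed
ellipsoidal LV endocardium and epicardium and a laterally displaced
ellipsoidal RV endocardium, 906 + 1516 + 906 = 3328 corresponded vertices by
default. End-systole is the end-diastolic surface contracted inward about
its own center, the endocardium more than the epicardium, so wall thickening
is positive by construction. Each subject deviates from the base geometry
along the base normal field by a_i + b_i * l_j + noise, with the planted
slope field b concentrated in a septal patch of the LV endocardium at
end-systole (contraction-coupled), and a chosen so the control-group mean
surface equals the base geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .meshes import fibonacci_sphere, triangle_areas
from .prep import LipidSpecies, LipidTable
from .shape import SURFACES, HeartSurfaceCohort, MeanModel, _surface_normals

__all__ = [
    "LipidPanelSpec",
    "HeartCohortSpec",
    "GroundTruth",
    "default_lipid_panel",
    "generate_lipid_study",
    "generate_heart_cohort",
    "LAMIN_PLUS_EFFECTS",
    "LAMIN_MINUS_EFFECTS",
]


# ---------------------------------------------------------------------------
# Lipid panel
# ---------------------------------------------------------------------------

@dataclass
class LipidPanelSpec:
    """Generative description of a lipid panel.

    ``planted_effects`` maps species names to fold changes (case median /
    control median); ``base_log_mean`` / ``base_log_sd`` are the log-normal
    location and scale per species.
    """

    species: list[LipidSpecies]
    planted_effects: dict[str, float] = field(default_factory=dict)
    base_log_mean: dict[str, float] = field(default_factory=dict)
    base_log_sd: dict[str, float] = field(default_factory=dict)
    default_log_sd: float = 0.4

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(self.species) < 1:
            raise ValueError("panel must contain at least one species")
        if len(set(names)) != len(names):
            raise ValueError("duplicate species in panel")
        known = set(names)
        for name, fold in self.planted_effects.items():
            if name not in known:
                raise ValueError(f"planted effect on unknown lipid {name!r}")
            if not fold > 0:
                raise ValueError(f"fold change for {name!r} must be positive")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def log_mean(self, name: str) -> float:
        return self.base_log_mean.get(name, 0.0)

    def log_sd(self, name: str) -> float:
        return self.base_log_sd.get(name, self.default_log_sd)

    def with_effects(self, effects: dict[str, float]) -> "LipidPanelSpec":
        return replace(self, planted_effects=dict(effects))


# Between-group fold changes planted by default, one map per study. Effects
# on ratio variables are planted on the numerator species (the ratio of two
# log-normals inherits the numerator's median shift when the denominator is
# untouched): TG(49:2) carries TG(49:2)/TG(49:1), TG(50:2) carries
# TG(50:2)/TG(50:1), TG(54:3) carries TG(54:3)/TG(54:2).
LAMIN_PLUS_EFFECTS = {
    "PC(38:5e)": 0.7,
    "PS(38:2)": 0.6,
    "TG(49:2)": 0.9,
    "TG(49:3)": 0.5,
    "TG(50:10)": 0.8,
    "TG(50:2)": 0.5,
    "TG(54:3)": 0.8,
}
LAMIN_MINUS_EFFECTS = {
    "PC(38:5e)": 0.7,
    "PS(38:2)": 0.7,
    "TG(49:2)": 0.6,
    "TG(49:3)": 0.6,
    "TG(50:10)": 0.6,
    "TG(50:2)": 0.1,
    "TG(54:3)": 0.4,
}

# Control-group median concentrations (arbitrary units) for the species the
# default effect maps touch; the remaining species get reproducible
# pseudo-random medians. Values chosen to sit in a serum-lipidome-like range.
_CONTROL_MEDIANS = {
    "PC(38:5e)": 0.85,
    "PS(38:2)": 4.38,
    "TG(49:1)": 2.00,
    "TG(49:2)": 1.72,
    "TG(49:3)": 4.08,
    "TG(50:1)": 1.00,
    "TG(50:2)": 0.06,
    "TG(50:10)": 1.69,
    "TG(54:2)": 1.00,
    "TG(54:3)": 5.87,
}

# Log-scale dispersion for the same species, back-solved from printed
# case/control interquartile ranges (log-normal IQR: sd = ln(q75/q25)/1.349,
# averaged over the two groups). A ratio of two independent log-normals has
# sqrt(2) times the species sd, so species feeding a ratio variable carry
# the ratio-implied sd / sqrt(2).
_CONTROL_LOG_SD = {
    "PC(38:5e)": 0.25,
    "PS(38:2)": 0.32,
    "TG(49:1)": 0.095,
    "TG(49:2)": 0.095,
    "TG(49:3)": 0.24,
    "TG(50:1)": 0.35,
    "TG(50:2)": 0.35,
    "TG(50:10)": 0.47,
    "TG(54:2)": 0.23,
    "TG(54:3)": 0.23,
}

# (class, ether, carbons, double-bond values): contiguous grids whose
# desaturation + elongation pair counts sum to 267 over the whole panel.
_PANEL_BLOCKS = [
    ("TG", False, list(range(44, 56)), [1, 2, 3]),
    ("PC", False, list(range(30, 41, 2)), [0, 1, 2, 3, 4, 5]),
    ("PC", True, list(range(34, 41, 2)), [2, 3, 4, 5, 6]),
    ("PE", False, list(range(34, 41, 2)), [1, 2, 3, 4, 5, 6]),
    ("PS", False, list(range(36, 41, 2)), [1, 2, 3, 4]),
    ("SM", False, list(range(34, 43, 2)), [1, 2, 3]),
    ("LPC", False, list(range(16, 23, 2)), [0, 1, 2]),
    ("CE", False, list(range(16, 21, 2)), [0, 1, 2]),
    ("PI", False, [36, 38], [2, 3, 4]),
    ("PG", False, [34, 36], [1, 2, 3]),
    ("Cer", False, [34], [1, 2]),
    ("PA", False, [34, 36], [2]),
]
_FILLER_CLASSES = ["DG", "MG", "LPE", "LPA", "GlcCer", "LacCer", "ChoE"]


def default_lipid_panel(effects: dict[str, float] | None = None) -> LipidPanelSpec:
    """The 286-species default panel. ``effects`` defaults to the discovery
    study's seven planted folds (:data:`LAMIN_PLUS_EFFECTS`)."""
    species: list[LipidSpecies] = []
    for cls, eth, carbons, dbs in _PANEL_BLOCKS:
        for c in carbons:
            for d in dbs:
                species.append(LipidSpecies(cls, c, d, ether=eth))
    species.append(LipidSpecies("TG", 50, 10))  # isolated, ratio-free
    # 105 singleton species on sparse grids (no desaturation/elongation
    # partners), emulating identified lipids without enzymatic neighbours
    for k in range(105):
        cls = _FILLER_CLASSES[k % len(_FILLER_CLASSES)]
        m = k // len(_FILLER_CLASSES)
        species.append(LipidSpecies(cls, 18 + 3 * m, m % 5))
    rng = np.random.default_rng(68105)  # fixed: panel is a constant
    base_log_mean = {}
    for s in species:
        if s.name in _CONTROL_MEDIANS:
            base_log_mean[s.name] = float(np.log(_CONTROL_MEDIANS[s.name]))
        else:
            base_log_mean[s.name] = float(rng.uniform(np.log(0.05), np.log(20.0)))
    return LipidPanelSpec(
        species=species,
        planted_effects=dict(LAMIN_PLUS_EFFECTS if effects is None else effects),
        base_log_mean=base_log_mean,
        base_log_sd=dict(_CONTROL_LOG_SD),
    )


def generate_lipid_study(
    spec: LipidPanelSpec,
    n_case: int,
    n_control: int,
    seed: int,
    *,
    study: str = "Lamin+",
    case_group: int = 1,
    control_group: int = 2,
) -> LipidTable:
    """Draw a case-control concentration table from the panel.

    Cases get the planted fold as an additive log-shift, so the generating
    median ratio equals the fold; all concentrations are positive.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("subject counts must be positive")
    rng = np.random.default_rng(seed)
    names = spec.names()
    mu = np.array([spec.log_mean(n) for n in names])
    sd = np.array([spec.log_sd(n) for n in names])
    shift = np.array([np.log(spec.planted_effects.get(n, 1.0)) for n in names])
    n_total = n_case + n_control
    z = rng.standard_normal((n_total, len(names)))
    log_conc = mu + sd * z
    log_conc[:n_case] += shift
    prefix = study.replace("+", "p").replace("-", "m").replace("−", "m")
    ids = [f"{prefix}_{j + 1:02d}" for j in range(n_total)]
    meta = pd.DataFrame(
        {"study": study,
         "group": [case_group] * n_case + [control_group] * n_control},
        index=pd.Index(ids, name="subject_id"),
    )
    data = pd.DataFrame(np.exp(log_conc), index=meta.index, columns=names)
    return LipidTable(data=data, meta=meta)


def write_study(table: LipidTable, spec: LipidPanelSpec, outdir, seed: int) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "lipid_table.csv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump({"planted_folds": spec.planted_effects, "seed": seed}, fh, indent=1)


# ---------------------------------------------------------------------------
# Heart cohorts
# ---------------------------------------------------------------------------

@dataclass
class HeartCohortSpec:
    """Generative description of a two-phase heart-surface cohort.

    Geometry is in millimetres. ``slope_magnitude`` is the peak of the
    planted per-vertex slope field (mm of normal deviation per lipid unit),
    concentrated in the LV septal patch at end-systole; ``noise_sd`` is the
    per-vertex normal-direction noise (segmentation-error surrogate).
    """

    n_cases: int = 11
    n_controls: int = 11
    points_per_surface: dict[str, int] = field(
        default_factory=lambda: {"lv_endo": 906, "rv_endo": 1516, "epicardium": 906}
    )
    coupled_lipid: str = "TG(49:3)"
    slope_magnitude: float = 3.0
    noise_sd: float = 0.8
    lv_semi_axes: tuple[float, float, float] = (25.0, 25.0, 38.0)
    wall_thickness: float = 9.0
    rv_semi_axes: tuple[float, float, float] = (10.0, 24.0, 32.0)
    rv_center: tuple[float, float, float] = (28.0, 0.0, -3.0)
    endo_es_scale: tuple[float, float, float] = (0.80, 0.80, 0.93)
    epi_es_scale: tuple[float, float, float] = (0.93, 0.93, 0.97)
    rv_es_scale: tuple[float, float, float] = (0.85, 0.85, 0.95)
    septal_threshold: float = 0.55  # start of the patch along +x, unit-sphere frame

    def __post_init__(self):
        if set(self.points_per_surface) != set(SURFACES):
            raise ValueError(f"points_per_surface must have keys {SURFACES}")
        if any(n < 4 for n in self.points_per_surface.values()):
            raise ValueError("each surface needs at least 4 points")
        if not self.wall_thickness > 0:
            raise ValueError("wall thickness must be positive")
        if not np.prod(self.endo_es_scale) < 1.0:
            raise ValueError("end-systolic cavity must be smaller than end-diastolic")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("subject counts must be non-negative")

    @property
    def total_points(self) -> int:
        return sum(self.points_per_surface.values())

    @property
    def epi_semi_axes(self) -> tuple[float, float, float]:
        return tuple(a + self.wall_thickness for a in self.lv_semi_axes)


@dataclass
class GroundTruth:
    """Planted generating parameters stored alongside a generated cohort."""

    intercept: dict[str, np.ndarray]   # phase -> (n_vertices,)
    slope: dict[str, np.ndarray]
    lipid: str
    seed: int
    base_model: MeanModel

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"lipid": self.lipid, "seed": self.seed,
                 "intercept": {p: v.tolist() for p, v in self.intercept.items()},
                 "slope": {p: v.tolist() for p, v in self.slope.items()}},
                fh,
            )


def _base_geometry(spec: HeartCohortSpec) -> tuple[MeanModel, np.ndarray]:
    """A-priori two-phase model and the unit-sphere parameter points of the
    LV endocardium (used to place the septal patch)."""
    parts = {}
    unit_lv = None
    for s in SURFACES:
        n = spec.points_per_surface[s]
        pts, faces = fibonacci_sphere(n)
        if s == "lv_endo":
            unit_lv = pts
            ed = pts * np.asarray(spec.lv_semi_axes)
            es = ed * np.asarray(spec.endo_es_scale)
        elif s == "epicardium":
            ed = pts * np.asarray(spec.epi_semi_axes)
            es = ed * np.asarray(spec.epi_es_scale)
        else:  # rv_endo
            c = np.asarray(spec.rv_center)
            ed = pts * np.asarray(spec.rv_semi_axes) + c
            es = (ed - c) * np.asarray(spec.rv_es_scale) + c
        parts[s] = (ed, es, faces)
    labels = np.concatenate(
        [np.full(spec.points_per_surface[s], s, dtype=object) for s in SURFACES]
    ).astype(str)
    offsets = np.cumsum([0] + [spec.points_per_surface[s] for s in SURFACES[:-1]])
    faces = np.vstack(
        [parts[s][2] + off for s, off in zip(SURFACES, offsets)]
    )
    coords = {
        "ED": np.vstack([parts[s][0] for s in SURFACES]),
        "ES": np.vstack([parts[s][1] for s in SURFACES]),
    }
    if np.any(triangle_areas(coords["ED"], faces) <= 0):
        raise ValueError("degenerate (zero-area) triangle in base geometry")
    normals = {}
    for p, v in coords.items():
        n = np.empty_like(v)
        for s in SURFACES:
            mask = labels == s
            n[mask] = _surface_normals(v, faces, mask)
        normals[p] = n
    model = MeanModel(coords=coords, normals=normals, faces=faces, labels=labels)
    return model, unit_lv


def _septal_slope_field(spec: HeartCohortSpec, labels: np.ndarray,
                        unit_lv: np.ndarray) -> dict[str, np.ndarray]:
    """Planted slope field: smoothstep patch on the LV endocardium facing
    the RV (+x), active at end-systole with a negative (inward) sign so a
    higher lipid value deepens systolic contraction there."""
    n = len(labels)
    w = np.clip((unit_lv[:, 0] - spec.septal_threshold) / 0.25, 0.0, 1.0)
    w = w * w * (3.0 - 2.0 * w)
    b_es = np.zeros(n)
    b_es[labels == "lv_endo"] = -spec.slope_magnitude * w
    return {"ED": np.zeros(n), "ES": b_es}


def generate_heart_cohort(
    spec: HeartCohortSpec,
    lipid_values: np.ndarray,
    seed: int,
    *,
    groups: np.ndarray | None = None,
    subject_ids: list[str] | None = None,
    center_on_control_mean: bool = True,
) -> tuple[HeartSurfaceCohort, GroundTruth]:
    """Generate a corresponded two-phase cohort coupled to a lipid.

    Vertex i of subject j is base_i + (a_i + b_i * l_j + eps) * n_i per
    phase. With ``center_on_control_mean`` (default) the intercept is
    a_i = -b_i * mean(l over controls), so the control-group mean surface
    equals the base geometry and a noiseless cohort round-trips exactly
    through the mean-model / deviation / per-vertex-regression pipeline.
    """
    l = np.asarray(lipid_values, dtype=float)
    n_subj = spec.n_cases + spec.n_controls
    if len(l) != n_subj:
        raise ValueError(f"expected {n_subj} lipid values, got {len(l)}")
    if groups is None:
        groups = np.array([1] * spec.n_cases + [2] * spec.n_controls)
    groups = np.asarray(groups)
    if len(groups) != n_subj:
        raise ValueError("one group label per subject required")
    rng = np.random.default_rng(seed)
    base, unit_lv = _base_geometry(spec)
    slope = _septal_slope_field(spec, base.labels, unit_lv)
    control_mean = float(l[groups % 2 == 0].mean()) if (groups % 2 == 0).any() else float(l.mean())
    if center_on_control_mean:
        intercept = {p: -slope[p] * control_mean for p in slope}
    else:
        intercept = {p: np.zeros_like(slope[p]) for p in slope}
    coords = {}
    for p in ("ED", "ES"):
        dev = intercept[p][None, :] + slope[p][None, :] * l[:, None]
        if spec.noise_sd > 0:
            dev = dev + rng.normal(0.0, spec.noise_sd, size=dev.shape)
        coords[p] = base.coords[p][None, :, :] + dev[:, :, None] * base.normals[p][None, :, :]
    if subject_ids is None:
        subject_ids = [f"H{j + 1:02d}" for j in range(n_subj)]
    meta = pd.DataFrame({"group": groups},
                        index=pd.Index(subject_ids, name="subject_id"))
    cohort = HeartSurfaceCohort(coords=coords, faces=base.faces.copy(),
                                labels=base.labels.copy(), meta=meta)
    truth = GroundTruth(intercept=intercept, slope=slope, lipid=spec.coupled_lipid,
                        seed=seed, base_model=base)
    return cohort, truth
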