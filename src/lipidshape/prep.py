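"""Lipidomics dataset preparation and group-comparison statistics.

The analysis dataset couples a subjects x variables concentration matrix
with per-subject metadata (study, case/control group) and per-variable
annotations parsed from lipid shorthand names such as ``TG(49:3)`` or
``PC(38:5e)``. Two derived-variable families proxy enzyme activities:

* desaturation ratios — same class, same acyl carbons, double bonds
  differing by one, e.g. ``TG(49:2)/TG(49:1)``;
* elongation ratios — same class, same double bonds, carbons differing
  by two, e.g. ``TG(54:2)/TG(52:2)``.

Group comparisons follow the two-sided t-test on log-transformed values,
with fold changes and quantiles reported on the raw concentration scale
(fold = median(case) / median(control)).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LipidSpecies",
    "LipidTable",
    "GroupComparison",
    "RatioRule",
    "parse_lipid_name",
    "enumerate_ratio_variables",
    "log_transform",
    "compare_groups",
    "wilcoxon_screen",
]


# ---------------------------------------------------------------------------
# Species annotation
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"^([A-Za-z0-9]+)\((\d+):(\d+)(e?)\)$")


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid species: headgroup class, total acyl carbons, total double
    bonds, and whether it is an ether (alkyl/alkenyl-linked) lipid."""

    lipid_class: str
    carbons: int
    double_bonds: int
    ether: bool = False

    @property
    def name(self) -> str:
        tag = "e" if self.ether else ""
        return f"{self.lipid_class}({self.carbons}:{self.double_bonds}{tag})"


def parse_lipid_name(name: str) -> LipidSpecies | None:
    """Parse shorthand like ``PC(38:5e)``; return None if not parseable."""
    m = _NAME_RE.match(name)
    if m is None:
        return None
    cls, c, d, tag = m.groups()
    return LipidSpecies(cls, int(c), int(d), ether=(tag == "e"))


def annotate_variables(names: list[str]) -> pd.DataFrame:
    """Per-variable annotation frame. Ratio columns (``A/B``) are flagged and
    carry their parent species pair; unparseable names get null annotation."""
    rows = []
    for name in names:
        if "/" in name:
            num, den = name.split("/", 1)
            rows.append(
                dict(variable=name, lipid_class=_cls(num), carbons=_car(num),
                     double_bonds=_db(num), ether=_eth(num), is_ratio=True,
                     numerator=num, denominator=den)
            )
        else:
            sp = parse_lipid_name(name)
            rows.append(
                dict(variable=name,
                     lipid_class=sp.lipid_class if sp else None,
                     carbons=sp.carbons if sp else None,
                     double_bonds=sp.double_bonds if sp else None,
                     ether=sp.ether if sp else False,
                     is_ratio=False, numerator=None, denominator=None)
            )
    return pd.DataFrame(rows).set_index("variable")


def _cls(n):
    sp = parse_lipid_name(n)
    return sp.lipid_class if sp else None


def _car(n):
    sp = parse_lipid_name(n)
    return sp.carbons if sp else None


def _db(n):
    sp = parse_lipid_name(n)
    return sp.double_bonds if sp else None


def _eth(n):
    sp = parse_lipid_name(n)
    return sp.ether if sp else False


# ---------------------------------------------------------------------------
# LipidTable container
# ---------------------------------------------------------------------------

@dataclass
class LipidTable:
    """Subjects x variables concentration table with metadata.

    Attributes
    ----------
    data:
        DataFrame indexed by subject id; columns are lipid variables
        (raw positive concentrations, derived ratios, or log values after
        :func:`log_transform`).
    meta:
        DataFrame indexed by subject id with columns ``study`` and ``group``
        (group in {1, 2, 3, 4}: odd = cases, even = matched controls).
    annotations:
        per-variable annotation, see :func:`annotate_variables`.
    log_scale:
        True once :func:`log_transform` has been applied.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    annotations: pd.DataFrame = None
    log_scale: bool = False

    def __post_init__(self):
        if self.annotations is None:
            self.annotations = annotate_variables(list(self.data.columns))
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the subject index")
        if self.meta["group"].isna().any():
            raise ValueError("missing group labels")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    def subjects_in_group(self, *groups: int) -> pd.Index:
        return self.meta.index[self.meta["group"].isin(groups)]

    def to_csv(self, path) -> None:
        out = pd.concat([self.meta[["study", "group"]], self.data], axis=1)
        out.index.name = "subject_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, log_scale: bool = False) -> "LipidTable":
        raw = pd.read_csv(path, index_col="subject_id")
        meta = raw[["study", "group"]].copy()
        meta["group"] = meta["group"].astype(int)
        data = raw.drop(columns=["study", "group"]).astype(float)
        return cls(data=data, meta=meta, log_scale=log_scale)


# ---------------------------------------------------------------------------
# Ratio enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioRule:
    """Which enzyme-activity ratios to enumerate.

    Desaturation: numerator has one more double bond; elongation: numerator
    has two more carbons. Pairs must share lipid class and ether linkage.
    """

    desaturation: bool = True
    elongation: bool = True
    carbon_step: int = 2
    double_bond_step: int = 1


def enumerate_ratio_variables(table: LipidTable, rule: RatioRule = RatioRule()) -> LipidTable:
    """Append desaturation/elongation ratio columns to a raw-scale table.

    Each ratio column is numerator / denominator per subject. Enumeration is
    exhaustive over annotated species pairs under the rule; the numerator is
    the more-desaturated (resp. longer) species.
    """
    if table.log_scale:
        raise ValueError("enumerate ratios on the raw scale, before log transform")
    ann = table.annotations
    species = ann[~ann["is_ratio"] & ann["lipid_class"].notna()]
    # index species by (class, ether, carbons, double_bonds) for O(1) partner lookup
    key_to_name = {
        (r.lipid_class, bool(r.ether), int(r.carbons), int(r.double_bonds)): name
        for name, r in species.iterrows()
    }
    new_cols: dict[str, pd.Series] = {}
    for name, r in species.iterrows():
        key = (r.lipid_class, bool(r.ether), int(r.carbons), int(r.double_bonds))
        partners = []
        if rule.desaturation:
            partners.append((key[0], key[1], key[2], key[3] - rule.double_bond_step))
        if rule.elongation:
            partners.append((key[0], key[1], key[2] - rule.carbon_step, key[3]))
        for pk in partners:
            den = key_to_name.get(pk)
            if den is None:
                continue
            col = f"{name}/{den}"
            denom = table.data[den]
            if (denom <= 0).any():
                raise ValueError(f"non-positive denominator in ratio {col}")
            new_cols[col] = table.data[name] / denom
    if not new_cols:
        augmented = table.data.copy()
    else:
        augmented = pd.concat([table.data, pd.DataFrame(new_cols)], axis=1)
    if augmented.columns.duplicated().any():
        raise ValueError("duplicate variable names after ratio enumeration")
    return LipidTable(data=augmented, meta=table.meta.copy())


# ---------------------------------------------------------------------------
# Transforms and group statistics
# ---------------------------------------------------------------------------

def log_transform(table: LipidTable) -> LipidTable:
    """Natural log of every variable (concentrations are log-normal-ish;
    the test statistics downstream assume approximate Gaussianity)."""
    bad = table.data <= 0
    if bad.any().any():
        j = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-positive value for subject {table.data.index[j[0]]!r}, "
            f"variable {table.data.columns[j[1]]!r}"
        )
    return LipidTable(
        data=np.log(table.data),
        meta=table.meta.copy(),
        annotations=table.annotations.copy(),
        log_scale=True,
    )


@dataclass
class GroupComparison:
    """Per-variable between-group record: two-sided t-test p on log values,
    fold = raw-scale median(case)/median(control), and raw-scale quartiles."""

    variable: str
    p_value: float
    fold: float
    t_statistic: float
    quantiles_case: tuple[float, float, float]
    quantiles_control: tuple[float, float, float]

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compare_groups(
    table: LipidTable,
    group_case: int,
    group_control: int,
    *,
    equal_var: bool = False,
) -> list[GroupComparison]:
    """Compare every variable between a case and a control group.

    ``table`` must be on the raw scale: the t-test is run on log values
    internally while folds and quantiles use the raw concentrations
    (the reporting convention for concentration tables). Welch's t-test by
    default; ``equal_var=True`` for Student's.
    """
    if table.log_scale:
        raise ValueError("compare_groups expects the raw-scale table")
    idx_a = table.subjects_in_group(group_case)
    idx_b = table.subjects_in_group(group_control)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs at least 2 subjects for the t-test")
    raw_a = table.data.loc[idx_a]
    raw_b = table.data.loc[idx_b]
    log_a = np.log(raw_a.values)
    log_b = np.log(raw_b.values)
    t, p = stats.ttest_ind(log_a, log_b, axis=0, equal_var=equal_var)
    qa = np.quantile(raw_a.values, [0.25, 0.5, 0.75], axis=0)  # type-7 interpolation
    qb = np.quantile(raw_b.values, [0.25, 0.5, 0.75], axis=0)
    out = []
    for j, name in enumerate(table.data.columns):
        # identical groups give 0/0 in the t statistic; define t=0, p=1
        tj, pj = (0.0, 1.0) if np.isnan(t[j]) else (float(t[j]), float(p[j]))
        out.append(
            GroupComparison(
                variable=name,
                p_value=pj,
                fold=float(qa[1, j] / qb[1, j]),
                t_statistic=tj,
                quantiles_case=tuple(float(v) for v in qa[:, j]),
                quantiles_control=tuple(float(v) for v in qb[:, j]),
            )
        )
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten comparison records into a table mirroring the usual summary
    layout (p, fold, per-group quartiles)."""
    rows = []
    for c in comparisons:
        rows.append(
            dict(variable=c.variable, p_value=c.p_value, fold=c.fold,
                 case_q25=c.quantiles_case[0], case_q50=c.quantiles_case[1],
                 case_q75=c.quantiles_case[2],
                 control_q25=c.quantiles_control[0],
                 control_q50=c.quantiles_control[1],
                 control_q75=c.quantiles_control[2])
        )
    return pd.DataFrame(rows).set_index("variable")


def wilcoxon_screen(
    image_params: pd.DataFrame,
    groups: pd.Series,
    group_a: int,
    group_b: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) screen of image parameters.

    Returns the full per-parameter p-value frame with a ``significant``
    column (p < alpha). Exact null distribution where SciPy can use it
    (no ties, small n); all-tied parameters get p = 1 with a warning.
    """
    a = image_params.loc[groups[groups == group_a].index]
    b = image_params.loc[groups[groups == group_b].index]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for name in image_params.columns:
        xa, xb = a[name].values, b[name].values
        if np.all(xa == xa[0]) and np.all(xb == xa[0]):
            warnings.warn(f"parameter {name!r} is constant across both groups; p = 1")
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append(dict(parameter=name, p_value=p, significant=p < alpha))
    return pd.DataFrame(rows).set_index("parameter")
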