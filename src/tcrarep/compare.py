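"""Cohort-level comparisons: genotype grouping, within- vs between-genotype
overlap summaries, per-TRAV/TRAJ-pair N-region comparisons, and shared-sequence
reports.

Samples are grouped by genotype = (selecting MHCII allele, fixed TCR-beta).
Unordered sample pairs fall into four comparison classes depending on whether
the two genotypes share the MHC allele and/or the TCR-beta.  Standard errors
are taken across unordered pairs, with no correction for pairs sharing a mouse
(a documented limitation).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import OverlapResult, chao_jaccard, jaccard
from .keys import KEY_COLUMNS, KeyScheme
from .repertoire import Repertoire

__all__ = [
    "CohortDesign",
    "GroupSummary",
    "COMPARISON_CLASSES",
    "comparison_class",
    "pairwise_matrix",
    "summarize_by_class",
    "restrict_repertoire",
    "admissible_vj_pairs",
    "nregion_comparison",
    "shared_sequence_report",
    "cohort_mean_sem",
]

COMPARISON_CLASSES = (
    "same_MHC_same_beta",
    "same_MHC_diff_beta",
    "diff_MHC_same_beta",
    "diff_MHC_diff_beta",
)

_METRICS = {"jaccard": jaccard, "chao_jaccard": chao_jaccard}


@dataclass
class CohortDesign:
    """A cohort of repertoires with a sample -> genotype grouping."""

    samples: list[Repertoire]
    grouping: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.grouping:
            self.grouping = {r.sample_id: r.metadata.genotype for r in self.samples}
        ids = [r.sample_id for r in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in cohort")
        if len(ids) < 2:
            raise ValueError("a cohort needs at least 2 samples")
        unassigned = [i for i in ids if i not in self.grouping]
        if unassigned:
            raise ValueError(f"samples without a genotype group: {unassigned}")

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.samples]

    def repertoire(self, sample_id: str) -> Repertoire:
        for r in self.samples:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def groups(self) -> dict[tuple[str, str], list[str]]:
        out: dict[tuple[str, str], list[str]] = {}
        for sid in self.sample_ids:
            out.setdefault(self.grouping[sid], []).append(sid)
        return out


@dataclass(frozen=True)
class GroupSummary:
    comparison_class: str
    metric: str
    mean: float
    sem: float | None
    n_pairs: int


def comparison_class(design: CohortDesign, sample_a: str, sample_b: str) -> str:
    mhc_a, beta_a = design.grouping[sample_a]
    mhc_b, beta_b = design.grouping[sample_b]
    mhc = "same_MHC" if mhc_a == mhc_b else "diff_MHC"
    beta = "same_beta" if beta_a == beta_b else "diff_beta"
    return f"{mhc}_{beta}"


def pairwise_matrix(
    design: CohortDesign, metric: str = "jaccard"
) -> tuple[pd.DataFrame, list[OverlapResult]]:
    """Symmetric matrix of the overlap metric over all unordered sample pairs.

    The diagonal holds metric(self, self).  Returns the matrix and the flat
    list of off-diagonal :class:`OverlapResult` s.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    fn = _METRICS[metric]
    ids = design.sample_ids
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    results: list[OverlapResult] = []
    for a in ids:
        mat.loc[a, a] = fn(design.repertoire(a), design.repertoire(a)).value
    for a, b in itertools.combinations(ids, 2):
        res = fn(design.repertoire(a), design.repertoire(b))
        mat.loc[a, b] = mat.loc[b, a] = res.value
        results.append(res)
    return mat, results


def summarize_by_class(
    matrix: pd.DataFrame, design: CohortDesign, metric: str = "jaccard"
) -> list[GroupSummary]:
    """Partition unordered pairs into the four comparison classes; mean and SEM
    per class.  Self-pairs are excluded; classes with zero pairs are omitted.
    """
    values: dict[str, list[float]] = {c: [] for c in COMPARISON_CLASSES}
    for a, b in itertools.combinations(design.sample_ids, 2):
        values[comparison_class(design, a, b)].append(float(matrix.loc[a, b]))
    out: list[GroupSummary] = []
    for cls in COMPARISON_CLASSES:
        vals = values[cls]
        if not vals:
            continue
        mean, sem = cohort_mean_sem(vals)
        out.append(GroupSummary(cls, metric, mean, sem, len(vals)))
    return out


def cohort_mean_sem(values: list[float]) -> tuple[float, float | None]:
    """Mean and standard error of the mean; SEM is None for a single value."""
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if len(arr) < 2:
        return mean, None
    return mean, float(arr.std(ddof=1) / math.sqrt(len(arr)))


def restrict_repertoire(rep: Repertoire, v_group: str, j_group: str) -> Repertoire:
    """CDR3-only repertoire restricted to clonotypes of one (V, J) pair."""
    if rep.key_scheme is not KeyScheme.FULL_TCRA:
        raise ValueError("restriction requires full TCR-alpha keys")
    sub = rep.table[(rep.table["v_group"] == v_group) & (rep.table["j_group"] == j_group)]
    cols = KEY_COLUMNS[KeyScheme.CDR3_ONLY]
    keep = [c for c in cols + ["count", "n_bases"] if c in sub.columns]
    table = sub[keep].reset_index(drop=True)
    return Repertoire(rep.sample_id, rep.metadata, KeyScheme.CDR3_ONLY, table)


def admissible_vj_pairs(design: CohortDesign, min_unique: int = 5) -> list[tuple[str, str]]:
    """(V, J) pairs for which *every* sample has >= ``min_unique`` distinct CDR3s."""
    per_sample: list[set[tuple[str, str]]] = []
    for rep in design.samples:
        if rep.key_scheme is not KeyScheme.FULL_TCRA:
            raise ValueError("admissibility requires full TCR-alpha keys")
        counts = rep.table.groupby(["v_group", "j_group"])["cdr3_aa"].nunique()
        per_sample.append(set(counts[counts >= min_unique].index))
    common = set.intersection(*per_sample) if per_sample else set()
    return sorted(common)


def nregion_comparison(
    design: CohortDesign,
    trav_group: str,
    traj: str,
    min_unique: int = 5,
    metric: str = "jaccard",
) -> tuple[list[GroupSummary], pd.DataFrame, dict[str, int]]:
    """Compare CDR3 (junction/N-region) sequences for one TRAV/TRAJ pair.

    Every sample must carry at least ``min_unique`` distinct CDR3s for the
    pair; otherwise the comparison is excluded and the per-sample distinct
    counts are returned as the exclusion log.  Because the V and J are fixed,
    differences between the restricted CDR3 sets reflect the junctions.
    """
    restricted = [restrict_repertoire(r, trav_group, traj) for r in design.samples]
    distinct = {r.sample_id: r.n_clonotypes for r in restricted}
    if any(d < min_unique for d in distinct.values()):
        return [], pd.DataFrame(), distinct
    sub_design = CohortDesign(restricted, dict(design.grouping))
    mat, _ = pairwise_matrix(sub_design, metric)
    return summarize_by_class(mat, sub_design, metric), mat, distinct


def shared_sequence_report(
    design: CohortDesign, groups: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Clonotypes present in at least one sample of *every* requested group.

    Returns one row per such public clonotype with per-sample counts (0 where
    absent).  ``groups`` defaults to all genotype groups in the design.
    """
    group_map = design.groups()
    if groups is None:
        groups = sorted(group_map)
    if len(groups) < 2:
        raise ValueError("shared-sequence report needs at least 2 groups")
    missing = [g for g in groups if g not in group_map]
    if missing:
        raise ValueError(f"groups not in design: {missing}")
    schemes = {r.key_scheme for r in design.samples}
    if len(schemes) != 1:
        raise ValueError("samples must share one key scheme")
    key_cols = KEY_COLUMNS[schemes.pop()]

    counts = {r.sample_id: r.counts() for r in design.samples}
    present_per_group = []
    for g in groups:
        keys: set[tuple] = set()
        for sid in group_map[g]:
            keys |= set(counts[sid])
        present_per_group.append(keys)
    public = sorted(set.intersection(*present_per_group))
    rows = []
    for key in public:
        row = dict(zip(key_cols, key))
        for sid in design.sample_ids:
            row[sid] = counts[sid].get(key, 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=key_cols + design.sample_ids)
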