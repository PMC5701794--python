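"""Richness and overlap statistics for clonotype repertoires.

* species accumulation curves (seeded subsampling without replacement),
* Chao1 total-richness estimation,
* presence/absence Jaccard over clonotype keys,
* the Chao et al. (2005) abundance-based Jaccard index, which corrects the
  shared-relative-abundance probabilities U and V for shared clonotypes that
  went unseen, using the rare shared classes (singletons/doubletons in the
  other sample),
* Euclidean distances between segment-usage profiles expressed as
  log2-transformed counts per 10^4 sequences, and
* average-linkage (UPGMA) hierarchical ordering of samples for heatmaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform

from .keys import KeyScheme
from .repertoire import Repertoire

__all__ = [
    "AccumulationCurve",
    "OverlapResult",
    "accumulation_curve",
    "chao1",
    "estimate_richness",
    "jaccard",
    "chao_jaccard",
    "euclidean_usage_distance",
    "usage_distance_matrix",
    "hierarchical_order",
]

COUNTS_PER = 10_000.0  # usage normalisation: counts per 10^4 sequences


@dataclass(frozen=True)
class AccumulationCurve:
    depths: tuple[int, ...]
    mean_unique: tuple[float, ...]
    sd_unique: tuple[float, ...]
    permutations: int
    seed: int


@dataclass(frozen=True)
class OverlapResult:
    sample_a: str
    sample_b: str
    metric: str
    value: float
    key_scheme: str
    defined: bool = True


def accumulation_curve(
    rep: Repertoire,
    depths: list[int] | None = None,
    permutations: int = 100,
    seed: int = 0,
) -> AccumulationCurve:
    """Mean and sd of unique clonotypes in random subsamples without replacement.

    ``depths`` defaults to 20 evenly spaced depths up to the total read count.
    At full depth the mean equals the observed richness exactly and the sd is 0.
    """
    counts = rep.table["count"].to_numpy(dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        raise ValueError(f"{rep.sample_id}: empty repertoire")
    if depths is None:
        depths = sorted({max(1, round(total * i / 20)) for i in range(1, 21)})
    depths = sorted(int(d) for d in depths)
    if depths[0] < 1 or depths[-1] > total:
        raise ValueError(f"depths must lie in [1, {total}]")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    reads = np.repeat(np.arange(len(counts)), counts)
    rng = np.random.default_rng(seed)
    uniques = np.empty((permutations, len(depths)), dtype=np.int64)
    n_clono = len(counts)
    for p in range(permutations):
        shuffled = rng.permutation(reads)
        first_seen = np.full(n_clono, total, dtype=np.int64)
        np.minimum.at(first_seen, shuffled, np.arange(total))
        for k, d in enumerate(depths):
            uniques[p, k] = int(np.count_nonzero(first_seen < d))
    return AccumulationCurve(
        depths=tuple(depths),
        mean_unique=tuple(uniques.mean(axis=0)),
        sd_unique=tuple(uniques.std(axis=0, ddof=0)),
        permutations=permutations,
        seed=seed,
    )


def chao1(counts: np.ndarray | list[int]) -> float:
    """Chao1 lower-bound richness from singleton/doubleton clonotype counts.

    ``S_obs + f1^2 / (2 f2)``, or the bias-corrected
    ``S_obs + f1 (f1 - 1) / (2 (f2 + 1))`` when no doubletons exist.
    """
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def estimate_richness(rep: Repertoire) -> float:
    """Chao1 estimate of the total number of distinct clonotypes in the sample."""
    if rep.table.empty:
        raise ValueError(f"{rep.sample_id}: empty repertoire")
    return chao1(rep.table["count"].to_numpy())


def _check_schemes(rep_a: Repertoire, rep_b: Repertoire) -> KeyScheme:
    if rep_a.key_scheme != rep_b.key_scheme:
        raise ValueError(
            f"key schemes differ: {rep_a.key_scheme.value} vs {rep_b.key_scheme.value}"
        )
    return rep_a.key_scheme


def jaccard(rep_a: Repertoire, rep_b: Repertoire) -> OverlapResult:
    """Presence/absence Jaccard |A n B| / |A u B| over unique clonotype keys."""
    scheme = _check_schemes(rep_a, rep_b)
    a, b = rep_a.keys(), rep_b.keys()
    union = a | b
    if not union:
        return OverlapResult(
            rep_a.sample_id, rep_b.sample_id, "jaccard", math.nan, scheme.value, defined=False
        )
    value = len(a & b) / len(union)
    return OverlapResult(rep_a.sample_id, rep_b.sample_id, "jaccard", value, scheme.value)


def _chao_u(
    shared: list[tuple],
    counts_self: dict[tuple, int],
    counts_other: dict[tuple, int],
    n_self: int,
    m_other: int,
) -> float:
    """Chao 2005 estimated total relative abundance in `self` of shared species.

    U = sum(x_i/n) + ((m-1)/m) * f_plus1/(2 f_plus2) * sum(x_i/n : y_i = 1)
    where f_plus1 / f_plus2 count shared species that are singletons /
    doubletons in the *other* sample; f_plus2 = 0 is replaced by 1 and the
    estimate is clamped to 1.
    """
    obs = sum(counts_self[k] for k in shared) / n_self
    f_plus1 = sum(1 for k in shared if counts_other[k] == 1)
    f_plus2 = sum(1 for k in shared if counts_other[k] == 2)
    rare = sum(counts_self[k] for k in shared if counts_other[k] == 1) / n_self
    correction = ((m_other - 1) / m_other) * f_plus1 / (2.0 * max(f_plus2, 1)) * rare
    return min(obs + correction, 1.0)


def chao_jaccard(rep_a: Repertoire, rep_b: Repertoire) -> OverlapResult:
    """Chao et al. (2005) abundance-based Jaccard index UV / (U + V - UV).

    Unlike the presence/absence index, shared clonotypes contribute their
    relative abundance, and rare shared classes are used to correct for shared
    clonotypes missed by sampling.  No shared clonotypes gives 0.
    """
    scheme = _check_schemes(rep_a, rep_b)
    ca, cb = rep_a.counts(), rep_b.counts()
    n, m = sum(ca.values()), sum(cb.values())
    if n == 0 or m == 0:
        return OverlapResult(
            rep_a.sample_id, rep_b.sample_id, "chao_jaccard", math.nan, scheme.value, defined=False
        )
    shared = sorted(set(ca) & set(cb))
    if not shared:
        return OverlapResult(rep_a.sample_id, rep_b.sample_id, "chao_jaccard", 0.0, scheme.value)
    u = _chao_u(shared, ca, cb, n, m)
    v = _chao_u(shared, cb, ca, m, n)
    if u == 0.0 or v == 0.0:
        value = 0.0
    else:
        value = (u * v) / (u + v - u * v)
    return OverlapResult(rep_a.sample_id, rep_b.sample_id, "chao_jaccard", value, scheme.value)


def euclidean_usage_distance(
    counts_a: pd.Series,
    counts_b: pd.Series,
    pseudocount: float = 1.0,
) -> float:
    """Euclidean distance between two segment-usage profiles.

    Each profile is scaled to counts per 10^4 total sequences, incremented by
    ``pseudocount`` (in the same counts-per-10^4 unit, to admit zeros), and
    log2-transformed; the distance is the Euclidean norm of the difference.
    Label sets must match exactly.
    """
    if list(counts_a.index) != list(counts_b.index):
        raise ValueError("usage label sets differ")
    a = counts_a.to_numpy(dtype=float)
    b = counts_b.to_numpy(dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("usage profiles must have positive totals")
    la = np.log2(a / a.sum() * COUNTS_PER + pseudocount)
    lb = np.log2(b / b.sum() * COUNTS_PER + pseudocount)
    return float(np.linalg.norm(la - lb))


def usage_distance_matrix(
    usage_counts: dict[str, pd.Series], pseudocount: float = 1.0
) -> pd.DataFrame:
    """Pairwise log2 counts-per-10^4 distances over samples.

    Profiles are harmonised to the union of labels (absent segments count 0)
    before the pairwise distances are taken.
    """
    labels: list[str] = []
    for s in usage_counts.values():
        for lab in s.index:
            if lab not in labels:
                labels.append(lab)
    aligned = {k: s.reindex(labels, fill_value=0.0) for k, s in usage_counts.items()}
    names = list(aligned)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = euclidean_usage_distance(aligned[a], aligned[b], pseudocount)
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def _newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def hierarchical_order(
    distance_matrix: pd.DataFrame,
) -> tuple[list[str], np.ndarray, str]:
    """Average-linkage (UPGMA) ordering of samples for heatmap rendering.

    Returns the leaf order, the scipy linkage matrix, and the tree in Newick
    form (ultrametric branch lengths from the cophenetic heights).
    """
    mat = distance_matrix.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    labels = list(distance_matrix.index)
    if len(labels) == 1:
        return labels, np.empty((0, 4)), f"{labels[0]};"
    z = linkage(squareform(mat, checks=False), method="average")
    order = [labels[i] for i in leaves_list(z)]
    tree = to_tree(z)
    return order, z, _newick(tree, labels) + ";"
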