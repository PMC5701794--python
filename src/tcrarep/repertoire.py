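"""Per-sample clonotype abundance tables and descriptive summaries.

A :class:`Repertoire` is the central container: a clonotype table (key columns
per the chosen key scheme, a read count, and the mean estimated N-region bases
per clonotype) plus sample metadata (mouse id, selecting MHCII allele, fixed
TCR-beta, compartment).

Weighting conventions: segment-usage tables default to read (abundance)
weighting, since percent use is a statement about cells; CDR3-length, N-base and
positional amino-acid summaries default to unique-clonotype weighting, since
they are comparisons of *different sequences*.  Both modes are exposed.
Standard errors across mice are a cohort-level quantity (see
:func:`tcrarep.compare.cohort_mean_sem`), never computed across clonotypes
within one mouse.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import AnnotatedSequence
from .keys import KEY_COLUMNS, KeyScheme

__all__ = [
    "SampleMetadata",
    "Repertoire",
    "UsageVector",
    "build_repertoire",
    "coarsen",
    "usage_table",
    "cdr3_length_distribution",
    "mean_cdr3_length",
    "mean_n_bases",
    "positional_aa_frequency",
]

MHC_ALLELES = ("b", "f", "s", "other")
TCRB_GENOTYPES = ("DObWT", "DOb48A", "polyclonal")
COMPARTMENTS = ("preselection_thymocyte", "naive_CD4")


@dataclass(frozen=True)
class SampleMetadata:
    mouse_id: str
    mhc_allele: str = "other"
    tcrb: str = "polyclonal"
    compartment: str = "naive_CD4"

    def __post_init__(self) -> None:
        if self.mhc_allele not in MHC_ALLELES:
            raise ValueError(f"mhc_allele must be one of {MHC_ALLELES}")
        if self.tcrb not in TCRB_GENOTYPES:
            raise ValueError(f"tcrb must be one of {TCRB_GENOTYPES}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")

    @property
    def genotype(self) -> tuple[str, str]:
        return (self.mhc_allele, self.tcrb)


@dataclass
class Repertoire:
    """Clonotype abundance table for one sample under one key scheme."""

    sample_id: str
    metadata: SampleMetadata
    key_scheme: KeyScheme
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.key_scheme = KeyScheme(self.key_scheme)
        cols = KEY_COLUMNS[self.key_scheme]
        missing = [c for c in cols + ["count"] if c not in self.table.columns]
        if missing:
            raise ValueError(f"{self.sample_id}: repertoire table missing columns {missing}")
        if len(self.table) and (self.table["count"] <= 0).any():
            raise ValueError(f"{self.sample_id}: clonotype counts must be strictly positive")

    @property
    def key_columns(self) -> list[str]:
        return KEY_COLUMNS[self.key_scheme]

    @property
    def total_reads(self) -> int:
        return int(self.table["count"].sum())

    @property
    def n_clonotypes(self) -> int:
        return len(self.table)

    def keys(self) -> set[tuple]:
        return set(map(tuple, self.table[self.key_columns].itertuples(index=False)))

    def counts(self) -> dict[tuple, int]:
        return {
            tuple(k): int(c)
            for *k, c in self.table[self.key_columns + ["count"]].itertuples(index=False)
        }


def build_repertoire(
    annotated: list[AnnotatedSequence],
    key_scheme: KeyScheme,
    sample_id: str,
    metadata: SampleMetadata,
) -> Repertoire:
    """Aggregate productive, singleton-filtered sequences of one sample.

    Non-productive sequences are rejected (they do not encode a chain and the
    analysis is of protein sequences); mixed sample ids are a hard error.
    """
    key_scheme = KeyScheme(key_scheme)
    cols = KEY_COLUMNS[key_scheme]
    for a in annotated:
        if a.sample_id and a.sample_id != sample_id:
            raise ValueError(
                f"mixed sample ids: building {sample_id!r} but found {a.sample_id!r}"
            )
        if not a.productive:
            raise ValueError(f"{a.read_id}: non-productive sequences cannot enter a repertoire")
    if not annotated:
        table = pd.DataFrame(columns=cols + ["count", "n_bases"])
        return Repertoire(sample_id, metadata, key_scheme, table)
    rows = pd.DataFrame(
        {
            "v_group": [a.v_group for a in annotated],
            "j_group": [a.j_group for a in annotated],
            "cdr3_aa": [a.cdr3_aa for a in annotated],
            "n_bases": [a.n_bases for a in annotated],
        }
    )
    grouped = (
        rows.groupby(cols, as_index=False)
        .agg(count=("n_bases", "size"), n_bases=("n_bases", "mean"))
        .sort_values(cols, kind="mergesort")
        .reset_index(drop=True)
    )
    return Repertoire(sample_id, metadata, key_scheme, grouped)


def coarsen(rep: Repertoire, new_scheme: KeyScheme) -> Repertoire:
    """Re-key a repertoire under a coarser scheme (e.g. full TCR-alpha -> CDR3-only).

    Clonotype count is non-increasing and total reads are conserved.
    """
    new_scheme = KeyScheme(new_scheme)
    new_cols = KEY_COLUMNS[new_scheme]
    missing = [c for c in new_cols if c not in rep.table.columns]
    if missing:
        raise ValueError(f"cannot coarsen {rep.key_scheme.value} -> {new_scheme.value}")
    if rep.table.empty:
        table = pd.DataFrame(columns=new_cols + ["count", "n_bases"])
        return Repertoire(rep.sample_id, rep.metadata, new_scheme, table)
    df = rep.table.copy()
    has_n = "n_bases" in df.columns
    if has_n:
        df["_nw"] = df["n_bases"] * df["count"]
        agg = df.groupby(new_cols, as_index=False).agg(
            count=("count", "sum"), _nw=("_nw", "sum")
        )
        agg["n_bases"] = agg["_nw"] / agg["count"]
        agg = agg.drop(columns="_nw")
    else:
        agg = df.groupby(new_cols, as_index=False).agg(count=("count", "sum"))
    agg = agg.sort_values(new_cols, kind="mergesort").reset_index(drop=True)
    return Repertoire(rep.sample_id, rep.metadata, new_scheme, agg)


@dataclass(frozen=True)
class UsageVector:
    """Percent use of each segment group on one axis; sums to 100."""

    axis: str  # "TRAV" or "TRAJ"
    labels: tuple[str, ...]
    percents: tuple[float, ...]
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        total = sum(self.percents)
        if self.labels and abs(total - 100.0) > 1e-9:
            raise ValueError(f"usage percents sum to {total}, expected 100")


_TRAV_RE = re.compile(r"TRAV(\d+)-(\d+)")
_TRAJ_RE = re.compile(r"TRAJ(\d+)")


def _axis_sort_key(axis: str, label: str):
    if axis == "TRAV":
        m = _TRAV_RE.match(label)
        if m:  # ordered by family, then subfamily, not by locus position
            return (0, int(m.group(1)), int(m.group(2)), label)
    else:
        m = _TRAJ_RE.match(label)
        if m:  # ordered by position on the chromosome (id number = position rank)
            return (0, int(m.group(1)), 0, label)
    return (1, 0, 0, label)


def usage_table(
    rep: Repertoire,
    axis: str,
    weighting: str = "reads",
    labels: list[str] | None = None,
) -> UsageVector:
    """Percent use of each TRAV group or TRAJ on the given axis.

    ``weighting='reads'`` (default) weights by clonotype abundance;
    ``'unique'`` counts each clonotype once.  ``labels`` may supply the full
    axis (absent segments get 0%), e.g. for comparing samples.
    """
    if axis not in ("TRAV", "TRAJ"):
        raise ValueError("axis must be 'TRAV' or 'TRAJ'")
    col = "v_group" if axis == "TRAV" else "j_group"
    if col not in rep.table.columns:
        raise ValueError(f"axis {axis} unavailable under key scheme {rep.key_scheme.value}")
    if rep.table.empty:
        raise ValueError(f"{rep.sample_id}: empty repertoire has no usage table")
    w = rep.table["count"] if weighting == "reads" else pd.Series(1.0, index=rep.table.index)
    sums = rep.table.assign(_w=w).groupby(col)["_w"].sum()
    if labels is not None:
        unknown = set(sums.index) - set(labels)
        if unknown:
            raise ValueError(f"labels missing observed segments: {sorted(unknown)}")
        sums = sums.reindex(labels, fill_value=0.0)
    ordered = sorted(sums.index, key=lambda s: _axis_sort_key(axis, s))
    sums = sums.loc[ordered]
    percents = 100.0 * sums / sums.sum()
    return UsageVector(axis, tuple(sums.index), tuple(percents), tuple(float(x) for x in sums))


def _require_cdr3(rep: Repertoire) -> None:
    if "cdr3_aa" not in rep.table.columns:
        raise ValueError(f"CDR3 summaries unavailable under key scheme {rep.key_scheme.value}")
    if rep.table.empty:
        raise ValueError(f"{rep.sample_id}: empty repertoire")


def _weights(rep: Repertoire, weighting: str) -> np.ndarray:
    if weighting == "reads":
        return rep.table["count"].to_numpy(dtype=float)
    if weighting == "unique":
        return np.ones(len(rep.table))
    raise ValueError("weighting must be 'reads' or 'unique'")


def cdr3_length_distribution(rep: Repertoire, weighting: str = "unique") -> pd.Series:
    """Histogram of CDR3 amino-acid lengths (index: length, values: weight)."""
    _require_cdr3(rep)
    lengths = rep.table["cdr3_aa"].str.len()
    w = pd.Series(_weights(rep, weighting), index=rep.table.index)
    hist = w.groupby(lengths).sum().sort_index()
    hist.index.name = "cdr3_length"
    return hist


def mean_cdr3_length(rep: Repertoire, weighting: str = "unique") -> float:
    _require_cdr3(rep)
    lengths = rep.table["cdr3_aa"].str.len().to_numpy(dtype=float)
    w = _weights(rep, weighting)
    return float(np.average(lengths, weights=w))


def mean_n_bases(rep: Repertoire, weighting: str = "unique") -> float:
    """Mean estimated N-region bases over clonotypes (or reads)."""
    if "n_bases" not in rep.table.columns or rep.table.empty:
        raise ValueError(f"{rep.sample_id}: no N-base information")
    n = rep.table["n_bases"].to_numpy(dtype=float)
    return float(np.average(n, weights=_weights(rep, weighting)))


_AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")


def positional_aa_frequency(
    rep: Repertoire, cdr3_length: int, weighting: str = "unique"
) -> pd.DataFrame:
    """Position x amino-acid frequency matrix for CDR3s of one length.

    Positions are 1-based counting the anchor Cys as position 1; each row is a
    probability vector.  Returns an empty frame (with a warning) when no
    clonotype has the requested length.
    """
    _require_cdr3(rep)
    sub = rep.table[rep.table["cdr3_aa"].str.len() == cdr3_length]
    if sub.empty:
        warnings.warn(
            f"{rep.sample_id}: no clonotypes of CDR3 length {cdr3_length}", stacklevel=2
        )
        return pd.DataFrame(columns=list(_AA_ALPHABET))
    w = (
        sub["count"].to_numpy(dtype=float)
        if weighting == "reads"
        else np.ones(len(sub))
    )
    mat = np.zeros((cdr3_length, len(_AA_ALPHABET)))
    aa_index = {aa: i for i, aa in enumerate(_AA_ALPHABET)}
    for seq, weight in zip(sub["cdr3_aa"], w):
        for pos, aa in enumerate(seq):
            mat[pos, aa_index[aa]] += weight
    mat /= mat.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        mat, index=pd.RangeIndex(1, cdr3_length + 1, name="position"), columns=list(_AA_ALPHABET)
    )
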