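"""Synthetic TCR-alpha cohort generator with full ground truth.

The generator emulates the statistical structure the analysis assumes:

* a germline pool of V and J segments (with optional identical duplicated V
  subfamily trios, to exercise ambiguity-group collapsing),
* V-J rearrangement with geometric exonuclease trimming of the V 3' end and
  J 5' end and geometric numbers of untemplated N additions,
* a distal-TRAJ usage tilt (one exponential bias parameter over the positional
  index of the J segment),
* positive selection modelled as deterministic hash acceptance: a candidate
  CDR3 is accepted iff a hash of (CDR3 protein, genotype key) falls below the
  acceptance rate.  Identical CDR3s are therefore accepted identically in all
  mice of one genotype, and accepted across genotypes only with probability
  about the acceptance rate — which plants within-genotype clonotype sharing
  exceeding between-genotype sharing without inventing an affinity model,
* uneven clonal abundances: each selected cell draws a lognormal peripheral
  expansion factor, and convergently generated clonotypes pool their cells,
* per-base substitution sequencing errors.

Everything is a pure function of (config, seed); reads, reference, design and
ground truth can be written as plain FASTA/TSV/YAML.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .germline import AmbiguityGroup, GermlineSegment, collapse_indistinguishable, write_reference
from .keys import KeyScheme
from .repertoire import Repertoire, SampleMetadata

__all__ = [
    "Genotype",
    "PositionPreference",
    "SimulationConfig",
    "Rearrangement",
    "MouseSample",
    "SimulatedCohort",
    "simulate_reference",
    "simulate_rearrangement",
    "apply_selection",
    "simulate_repertoires",
    "simulate_cohort",
    "write_cohort",
    "capped_geometric_mean",
    "config_from_yaml",
    "config_to_yaml",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_V_ANCHOR_BACK = 9  # Cys codon starts 9 nt before the V 3' end
_J_ANCHOR_OFFSET = 18  # F/W/L codon offset within J (G codon follows)
_J_ANCHOR_CODONS = ("TTT", "TTC", "TGG", "TTG")
_G_CODONS = ("GGA", "GGT", "GGC", "GGG")


@dataclass(frozen=True)
class Genotype:
    mhc_allele: str
    tcrb: str

    @property
    def key(self) -> str:
        return f"{self.mhc_allele}:{self.tcrb}"


@dataclass(frozen=True)
class PositionPreference:
    """Selection preference for one amino acid at one CDR3 position (1-based,
    Cys = 1), optionally restricted to one CDR3 length."""

    position: int
    amino_acid: str
    weight: float
    cdr3_length: int | None = None


@dataclass
class SimulationConfig:
    seed: int
    # germline pool
    n_v_segments: int = 12  # distinct V sequences (a duplicated trio counts once)
    n_duplicate_v_trios: int = 1
    n_j_segments: int = 10
    v_length: int = 60
    j_length: int = 45
    # rearrangement
    v_accessibility_weights: tuple[float, ...] | None = None
    j_positional_bias: float = 1.0  # distal preference; 0 = uniform
    max_trim_v: int = 3
    trim_p_v: float = 0.5
    max_trim_j: int = 3
    trim_p_j: float = 0.5
    max_n: int = 12
    n_addition_p: float = 0.25
    # selection
    selection_mode: str = "hash_acceptance"  # neutral | hash_acceptance | aa_preference
    acceptance_rate: float = 0.1
    aa_preferences: tuple[PositionPreference, ...] = ()
    max_attempts_per_cell: int = 200
    # cohort
    genotypes: tuple[Genotype, ...] = (
        Genotype("b", "DObWT"),
        Genotype("f", "DObWT"),
        Genotype("s", "DObWT"),
        Genotype("b", "DOb48A"),
        Genotype("f", "DOb48A"),
        Genotype("s", "DOb48A"),
    )
    n_mice_per_genotype: int = 3
    n_cells: int = 1500  # selected cells per mouse
    compartment: str = "naive_CD4"
    # abundance and sequencing
    abundance_distribution: str = "lognormal"  # or uniform
    abundance_sigma: float = 1.5
    depth: int = 10_000
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_v_segments < 2 or self.n_j_segments < 2:
            raise ValueError("need at least 2 V and 2 J segments")
        if self.n_duplicate_v_trios > self.n_v_segments:
            raise ValueError("more duplicate trios than V segments")
        if self.v_accessibility_weights is not None:
            w = np.asarray(self.v_accessibility_weights, dtype=float)
            if len(w) != self.n_v_segments:
                raise ValueError("v_accessibility_weights length must equal n_v_segments")
            if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
                raise ValueError("v_accessibility_weights must be a probability vector")
        for rate in (self.acceptance_rate, self.error_rate, self.trim_p_v, self.trim_p_j,
                     self.n_addition_p):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates and probabilities must lie in [0, 1]")
        if self.max_trim_v > _V_ANCHOR_BACK - 3:
            raise ValueError(f"max_trim_v must be <= {_V_ANCHOR_BACK - 3} to keep the V anchor")
        if self.max_trim_j > _J_ANCHOR_OFFSET:
            raise ValueError(f"max_trim_j must be <= {_J_ANCHOR_OFFSET} to keep the J anchor")
        if self.selection_mode not in ("neutral", "hash_acceptance", "aa_preference"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.abundance_distribution not in ("uniform", "lognormal"):
            raise ValueError(f"unknown abundance_distribution {self.abundance_distribution!r}")
        self.genotypes = tuple(
            g if isinstance(g, Genotype) else Genotype(**g) for g in self.genotypes
        )
        self.aa_preferences = tuple(
            p if isinstance(p, PositionPreference) else PositionPreference(**p)
            for p in self.aa_preferences
        )

    def v_weights(self) -> np.ndarray:
        if self.v_accessibility_weights is not None:
            return np.asarray(self.v_accessibility_weights, dtype=float)
        w = 0.85 ** np.arange(self.n_v_segments)  # uneven accessibility by default
        return w / w.sum()

    def j_weights(self) -> np.ndarray:
        idx = np.arange(self.n_j_segments, dtype=float)
        pos = idx / max(self.n_j_segments - 1, 1)  # higher index = more distal
        w = np.exp(self.j_positional_bias * pos)
        return w / w.sum()


def capped_geometric_mean(p: float, cap: int) -> float:
    """Mean of min(G, cap) with P(G=k) = p (1-p)^k on {0, 1, ...}."""
    q = 1.0 - p
    if p == 0.0:
        return float(cap)
    return q * (1.0 - q**cap) / (1.0 - q)


def _random_seq(rng: np.random.Generator, k: int) -> str:
    return _BASES[rng.integers(0, 4, size=k)].tobytes().decode("ascii")


def simulate_reference(config: SimulationConfig, rng: np.random.Generator | None = None
                       ) -> list[GermlineSegment]:
    """Random germline pool honouring the anchor invariants.

    The first ``n_duplicate_v_trios`` V families are emitted as identical
    A/D/N triplets, so collapsing finds planted ambiguity groups.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    segments: list[GermlineSegment] = []
    seen: set[str] = set()
    for fam in range(1, config.n_v_segments + 1):
        while True:
            seq = _random_seq(rng, config.v_length)
            anchor = config.v_length - _V_ANCHOR_BACK
            seq = seq[:anchor] + "TGT" + seq[anchor + 3 :]
            if seq not in seen:
                seen.add(seq)
                break
        dup_classes = ["A", "D", "N"] if fam <= config.n_duplicate_v_trios else ["A"]
        for dup in dup_classes:
            segments.append(
                GermlineSegment(
                    segment_id=f"TRAV{fam:02d}-1{dup}",
                    kind="V",
                    family=fam,
                    subfamily=1,
                    dup_class=dup,
                    nt_sequence=seq,
                    anchor_offset=anchor,
                )
            )
    for num in range(1, config.n_j_segments + 1):
        while True:
            seq = _random_seq(rng, config.j_length)
            anchor_codon = _J_ANCHOR_CODONS[rng.integers(0, len(_J_ANCHOR_CODONS))]
            g_codon = _G_CODONS[rng.integers(0, len(_G_CODONS))]
            seq = seq[:_J_ANCHOR_OFFSET] + anchor_codon + g_codon + seq[_J_ANCHOR_OFFSET + 6 :]
            if seq not in seen:
                seen.add(seq)
                break
        segments.append(
            GermlineSegment(
                segment_id=f"TRAJ{num:02d}",
                kind="J",
                family=num,
                subfamily=1,
                dup_class="none",
                nt_sequence=seq,
                anchor_offset=_J_ANCHOR_OFFSET,
            )
        )
    return segments


@dataclass(frozen=True)
class Rearrangement:
    """One candidate V-J joining with its full ground truth."""

    v_id: str
    j_id: str
    v_group: str
    j_group: str
    trim_v: int
    trim_j: int
    n_seq: str  # the drawn untemplated bases
    nt_sequence: str  # pre-error read sequence
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    n_identifiable: int  # N bases under the maximal-extension convention

    @property
    def n_drawn(self) -> int:
        return len(self.n_seq)


def _identifiable_n(seq: str, v_seq: str, j_seq: str, cdr3_len: int) -> int:
    k, mv = 0, min(len(seq), len(v_seq))
    while k < mv and seq[k] == v_seq[k]:
        k += 1
    lj = len(j_seq)
    j_ext, mj = 0, min(lj, len(seq) - k)
    while j_ext < mj and seq[len(seq) - 1 - j_ext] == j_seq[lj - 1 - j_ext]:
        j_ext += 1
    return min(max(len(seq) - k - j_ext, 0), cdr3_len)


_STOP = "*"
_J_AA = ("F", "W", "L")


def _make_rearrangement(
    v: GermlineSegment,
    j: GermlineSegment,
    v_group: str,
    j_group: str,
    trim_v: int,
    trim_j: int,
    n_seq: str,
) -> Rearrangement:
    v_part = v.nt_sequence[: len(v.nt_sequence) - trim_v]
    j_part = j.nt_sequence[trim_j:]
    seq = v_part + n_seq + j_part
    av = v.anchor_offset
    jpos = len(seq) - (len(j.nt_sequence) - j.anchor_offset)
    cdr3_nt = seq[av : jpos + 3]
    usable = len(cdr3_nt) - len(cdr3_nt) % 3
    cdr3_aa = str(Seq(cdr3_nt[:usable]).translate()) if usable else ""
    productive = (
        len(cdr3_nt) % 3 == 0
        and len(cdr3_aa) >= 2
        and cdr3_aa[0] == "C"
        and cdr3_aa[-1] in _J_AA
        and _STOP not in cdr3_aa
    )
    return Rearrangement(
        v_id=v.segment_id,
        j_id=j.segment_id,
        v_group=v_group,
        j_group=j_group,
        trim_v=trim_v,
        trim_j=trim_j,
        n_seq=n_seq,
        nt_sequence=seq,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        productive=productive,
        n_identifiable=_identifiable_n(seq, v.nt_sequence, j.nt_sequence, len(cdr3_nt)),
    )


class _Locus:
    """Reference bundled for generation: V units (one per distinct sequence,
    with their duplicated members) and positionally ordered J segments."""

    def __init__(self, segments: list[GermlineSegment], config: SimulationConfig):
        self.segments = segments
        groups = collapse_indistinguishable(segments)
        self.groups = groups
        v_groups = [g for g in groups if g.kind == "V"]
        v_groups.sort(key=lambda g: g.representative.family)
        by_id = {s.segment_id: s for s in segments}
        self.v_units = [
            (g.group_id, [by_id[m] for m in sorted(g.members)]) for g in v_groups
        ]
        j_groups = [g for g in groups if g.kind == "J"]
        j_groups.sort(key=lambda g: g.representative.family)  # chromosomal order
        self.j_units = [(g.group_id, g.representative) for g in j_groups]
        if len(self.v_units) != config.n_v_segments:
            raise ValueError("reference does not match config (distinct V count)")
        if len(self.j_units) != config.n_j_segments:
            raise ValueError("reference does not match config (J count)")


def simulate_rearrangement(
    locus: _Locus, config: SimulationConfig, rng: np.random.Generator
) -> Rearrangement:
    """Draw a single candidate rearrangement (no selection applied)."""
    vi = rng.choice(len(locus.v_units), p=config.v_weights())
    jj = rng.choice(len(locus.j_units), p=config.j_weights())
    v_gid, members = locus.v_units[vi]
    v = members[rng.integers(len(members))]
    j_gid, j = locus.j_units[jj]
    trim_v = int(min(rng.geometric(config.trim_p_v) - 1, config.max_trim_v))
    trim_j = int(min(rng.geometric(config.trim_p_j) - 1, config.max_trim_j))
    n_len = int(min(rng.geometric(config.n_addition_p) - 1, config.max_n))
    n_seq = _random_seq(rng, n_len)
    return _make_rearrangement(v, j, v_gid, j_gid, trim_v, trim_j, n_seq)


def _aa_factor(cdr3_aa: str, prefs: tuple[PositionPreference, ...]) -> float:
    factor = 1.0
    for p in prefs:
        if p.cdr3_length is not None and len(cdr3_aa) != p.cdr3_length:
            continue
        if p.position <= len(cdr3_aa) and cdr3_aa[p.position - 1] == p.amino_acid:
            factor *= p.weight
    return factor


def apply_selection(cdr3_aa: str, genotype_key: str, config: SimulationConfig) -> bool:
    """Deterministic positive-selection filter on a productive CDR3.

    ``hash_acceptance``: accept iff a 64-bit hash of (CDR3, genotype key),
    mapped to [0, 1), is below the acceptance rate.  ``aa_preference``
    multiplies the threshold by the preference weight of each matching
    position.  ``neutral`` accepts everything.
    """
    if config.selection_mode == "neutral":
        return True
    threshold = config.acceptance_rate
    if config.selection_mode == "aa_preference":
        threshold = min(threshold * _aa_factor(cdr3_aa, config.aa_preferences), 1.0)
    digest = hashlib.sha256(f"{cdr3_aa}|{genotype_key}".encode()).digest()
    u = int.from_bytes(digest[:8], "big") / 2**64
    return u < threshold


@dataclass
class MouseSample:
    sample_id: str
    metadata: SampleMetadata
    genotype: Genotype
    clonotypes: pd.DataFrame  # one row per distinct pre-error read sequence
    discarded_cells: int


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    reference: list[GermlineSegment]
    groups: list[AmbiguityGroup]
    mice: list[MouseSample]
    reads: dict[str, list[tuple[str, str]]]  # sample_id -> [(read_id, sequence)]
    read_truth: pd.DataFrame  # read_id, sample_id, clonotype_index, n_errors

    @property
    def design_grouping(self) -> dict[str, tuple[str, str]]:
        return {m.sample_id: (m.genotype.mhc_allele, m.genotype.tcrb) for m in self.mice}


def _simulate_mouse_cells(
    locus: _Locus,
    config: SimulationConfig,
    genotype: Genotype,
    rng: np.random.Generator,
) -> tuple[list[Rearrangement], int]:
    """Rearrange-and-select until n_cells selected cells (bounded attempts).

    A thymocyte whose candidate is non-productive or rejected re-rearranges;
    a cell exhausting its attempt budget is discarded (logged).
    """
    v_weights, j_weights = config.v_weights(), config.j_weights()
    n_v, n_j = len(locus.v_units), len(locus.j_units)
    cells: list[Rearrangement] = []
    attempts = 0
    budget = config.n_cells * config.max_attempts_per_cell
    while len(cells) < config.n_cells and attempts < budget:
        batch = int(min(4096, budget - attempts))
        vi = rng.choice(n_v, size=batch, p=v_weights)
        jj = rng.choice(n_j, size=batch, p=j_weights)
        tv = np.minimum(rng.geometric(config.trim_p_v, size=batch) - 1, config.max_trim_v)
        tj = np.minimum(rng.geometric(config.trim_p_j, size=batch) - 1, config.max_trim_j)
        nlen = np.minimum(rng.geometric(config.n_addition_p, size=batch) - 1, config.max_n)
        flat_n = _BASES[rng.integers(0, 4, size=int(nlen.sum()))].tobytes().decode("ascii")
        member_u = rng.random(batch)
        offsets = np.concatenate([[0], np.cumsum(nlen)])
        for k in range(batch):
            if len(cells) >= config.n_cells:
                break
            attempts += 1
            v_gid, members = locus.v_units[int(vi[k])]
            v = members[int(member_u[k] * len(members))]
            j_gid, j = locus.j_units[int(jj[k])]
            n_seq = flat_n[offsets[k] : offsets[k + 1]]
            r = _make_rearrangement(v, j, v_gid, j_gid, int(tv[k]), int(tj[k]), n_seq)
            if not r.productive:
                continue
            if not apply_selection(r.cdr3_aa, genotype.key, config):
                continue
            cells.append(r)
    discarded = max(config.n_cells - len(cells), 0)
    return cells, discarded


def _aggregate_clonotypes(
    cells: list[Rearrangement], config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Pool cells by pre-error sequence; weight = summed expansion factors."""
    if config.abundance_distribution == "lognormal":
        factors = rng.lognormal(0.0, config.abundance_sigma, size=len(cells))
    else:
        factors = np.ones(len(cells))
    index: dict[str, int] = {}
    rows: list[dict] = []
    for cell, f in zip(cells, factors):
        i = index.get(cell.nt_sequence)
        if i is None:
            index[cell.nt_sequence] = len(rows)
            rows.append(
                {
                    "v_id": cell.v_id,
                    "j_id": cell.j_id,
                    "v_group": cell.v_group,
                    "j_group": cell.j_group,
                    "sequence": cell.nt_sequence,
                    "cdr3_nt": cell.cdr3_nt,
                    "cdr3_aa": cell.cdr3_aa,
                    "trim_v": cell.trim_v,
                    "trim_j": cell.trim_j,
                    "n_drawn": cell.n_drawn,
                    "n_identifiable": cell.n_identifiable,
                    "cells": 1,
                    "weight": float(f),
                }
            )
        else:
            rows[i]["cells"] += 1
            rows[i]["weight"] += float(f)
    df = pd.DataFrame(rows)
    df.index.name = "clonotype_index"
    return df


def _mouse_repertoire(mouse: MouseSample, depth_counts: np.ndarray) -> Repertoire:
    df = mouse.clonotypes.assign(count=depth_counts)
    df = df[df["count"] > 0]
    grouped = (
        df.assign(_nw=df["n_identifiable"] * df["count"])
        .groupby(["v_group", "j_group", "cdr3_aa"], as_index=False)
        .agg(count=("count", "sum"), _nw=("_nw", "sum"))
    )
    grouped["n_bases"] = grouped["_nw"] / grouped["count"]
    grouped = (
        grouped.drop(columns="_nw")
        .sort_values(["v_group", "j_group", "cdr3_aa"], kind="mergesort")
        .reset_index(drop=True)
    )
    return Repertoire(mouse.sample_id, mouse.metadata, KeyScheme.FULL_TCRA, grouped)


def _iter_mice(config: SimulationConfig):
    for gi, genotype in enumerate(config.genotypes):
        for mi in range(config.n_mice_per_genotype):
            sample_id = f"{genotype.mhc_allele}_{genotype.tcrb}_m{mi + 1}"
            yield gi, mi, genotype, sample_id


def _build_mice(config: SimulationConfig, locus: _Locus) -> list[MouseSample]:
    mice = []
    for gi, mi, genotype, sample_id in _iter_mice(config):
        rng = np.random.default_rng([config.seed, 2, gi, mi])
        cells, discarded = _simulate_mouse_cells(locus, config, genotype, rng)
        if not cells:
            raise RuntimeError(f"{sample_id}: no cells selected; acceptance rate too low?")
        clonotypes = _aggregate_clonotypes(cells, config, rng)
        metadata = SampleMetadata(
            mouse_id=sample_id,
            mhc_allele=genotype.mhc_allele,
            tcrb=genotype.tcrb,
            compartment=config.compartment,
        )
        mice.append(MouseSample(sample_id, metadata, genotype, clonotypes, discarded))
    return mice


def simulate_repertoires(config: SimulationConfig) -> tuple[list[Repertoire], list[MouseSample]]:
    """Fast path: per-mouse repertoires sampled to depth, skipping read emission.

    Identical to :func:`simulate_cohort` up to (and including) the multinomial
    read sampling, but no per-read sequences or errors are generated.
    """
    locus = _Locus(simulate_reference(config), config)
    mice = _build_mice(config, locus)
    reps = []
    for gi, mi, _genotype, sample_id in _iter_mice(config):
        mouse = mice[gi * config.n_mice_per_genotype + mi]
        rng = np.random.default_rng([config.seed, 3, gi, mi])
        w = mouse.clonotypes["weight"].to_numpy()
        counts = rng.multinomial(config.depth, w / w.sum())
        reps.append(_mouse_repertoire(mouse, counts))
    return reps, mice


_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


def _apply_errors(seq: str, k: int, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=k, replace=False)
    # substitute with one of the three other bases
    shift = rng.integers(1, 4, size=k)
    for p, s in zip(pos, shift):
        arr[p] = _BASES[(_BASE_INDEX[arr[p]] + s) % 4]
    return arr.tobytes().decode("ascii")


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full cohort: per-mouse read sets with sequencing errors and ground truth."""
    reference = simulate_reference(config)
    locus = _Locus(reference, config)
    mice = _build_mice(config, locus)
    reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows: list[tuple[str, str, int, int]] = []
    for gi, mi, _genotype, sample_id in _iter_mice(config):
        mouse = mice[gi * config.n_mice_per_genotype + mi]
        rng = np.random.default_rng([config.seed, 3, gi, mi])
        w = mouse.clonotypes["weight"].to_numpy()
        counts = rng.multinomial(config.depth, w / w.sum())
        err_rng = np.random.default_rng([config.seed, 4, gi, mi])
        sample_reads: list[tuple[str, str]] = []
        read_no = 0
        for ci, (seq, c) in enumerate(zip(mouse.clonotypes["sequence"], counts)):
            if c == 0:
                continue
            n_errors = err_rng.binomial(len(seq), config.error_rate, size=int(c))
            for k in n_errors:
                read_no += 1
                rid = f"{sample_id}_r{read_no:06d}"
                out = _apply_errors(seq, int(k), err_rng) if k else seq
                sample_reads.append((rid, out))
                truth_rows.append((rid, sample_id, ci, int(k)))
        reads[sample_id] = sample_reads
    read_truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample_id", "clonotype_index", "n_errors"]
    )
    return SimulatedCohort(
        config=config,
        reference=reference,
        groups=locus.groups,
        mice=mice,
        reads=reads,
        read_truth=read_truth,
    )


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    d = asdict(config)
    d["genotypes"] = [asdict(g) for g in config.genotypes]
    d["aa_preferences"] = [asdict(p) for p in config.aa_preferences]
    if d["v_accessibility_weights"] is not None:
        d["v_accessibility_weights"] = list(d["v_accessibility_weights"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("v_accessibility_weights") is not None:
        d["v_accessibility_weights"] = tuple(d["v_accessibility_weights"])
    return SimulationConfig(**d)


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write reads (FASTA), reference (FASTA+TSV), design YAML and ground truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_reference(cohort.reference, outdir / "reference.fasta", outdir / "reference.tsv")
    config_to_yaml(cohort.config, outdir / "config.yaml")
    design = {
        "samples": {
            m.sample_id: {
                "mouse_id": m.metadata.mouse_id,
                "mhc_allele": m.metadata.mhc_allele,
                "tcrb": m.metadata.tcrb,
                "compartment": m.metadata.compartment,
            }
            for m in cohort.mice
        }
    }
    with open(outdir / "design.yaml", "w") as fh:
        yaml.safe_dump(design, fh, sort_keys=True)
    for sample_id, sample_reads in cohort.reads.items():
        with open(outdir / f"{sample_id}.fasta", "w") as fh:
            for rid, seq in sample_reads:
                fh.write(f">{rid}\n{seq}\n")
    clono = pd.concat(
        [m.clonotypes.assign(sample_id=m.sample_id) for m in cohort.mice],
        ignore_index=False,
    )
    clono.to_csv(outdir / "ground_truth_clonotypes.tsv", sep="\t", float_format="%.10g")
    cohort.read_truth.to_csv(outdir / "ground_truth_reads.tsv", sep="\t", index=False)
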