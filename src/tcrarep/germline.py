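"""Germline TRAV/TRAJ reference handling.

A reference is a FASTA of segment alleles plus a tab-separated sidecar with one
row per allele (``segment_id, kind, family, subfamily, dup_class, anchor_offset``).
Each V segment carries the position of its conserved CDR3-anchor cysteine codon;
each J segment the position of the conserved F/W/L of the F/W/L-G motif.

The mouse Trav locus contains duplicated subfamily members ('A' originals, 'D'
duplicated, 'N' new genes) whose stored sequences can be byte-identical and are
therefore indistinguishable by sequence analysis.  Such members are collapsed
into :class:`AmbiguityGroup` s whose ids concatenate the duplication-class
letters (e.g. ``TRAV06-3ADN``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GermlineSegment",
    "AmbiguityGroup",
    "ReferenceError",
    "load_reference",
    "write_reference",
    "collapse_indistinguishable",
    "groups_by_kind",
]

_DUP_CLASSES = ("A", "D", "N", "none")
_V_ANCHOR_AA = "C"
_J_ANCHOR_AA = ("F", "W", "L")


class ReferenceError(ValueError):
    """Raised when a germline reference fails validation."""


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class GermlineSegment:
    """One TRAV or TRAJ allele.

    ``anchor_offset`` is the 0-based offset of the first nucleotide of the
    conserved anchor codon: Cys for V segments, F/W/L (followed by Gly) for J.
    """

    segment_id: str
    kind: str  # "V" or "J"
    family: int
    subfamily: int
    dup_class: str  # "A", "D", "N" or "none"
    nt_sequence: str
    anchor_offset: int

    def __post_init__(self) -> None:
        if self.kind not in ("V", "J"):
            raise ReferenceError(f"{self.segment_id}: kind must be 'V' or 'J', got {self.kind!r}")
        if self.dup_class not in _DUP_CLASSES:
            raise ReferenceError(
                f"{self.segment_id}: dup_class must be one of {_DUP_CLASSES}, got {self.dup_class!r}"
            )
        seq = self.nt_sequence
        if not seq or set(seq) - set("ACGT"):
            raise ReferenceError(f"{self.segment_id}: sequence must be non-empty A/C/G/T")
        if not 0 <= self.anchor_offset <= len(seq) - 3:
            raise ReferenceError(
                f"{self.segment_id}: anchor_offset {self.anchor_offset} outside sequence "
                f"(length {len(seq)})"
            )
        anchor_aa = _translate_codon(seq[self.anchor_offset : self.anchor_offset + 3])
        if self.kind == "V":
            if anchor_aa != _V_ANCHOR_AA:
                raise ReferenceError(
                    f"{self.segment_id}: V anchor codon at offset {self.anchor_offset} "
                    f"translates to {anchor_aa!r}, expected C"
                )
        else:
            if anchor_aa not in _J_ANCHOR_AA:
                raise ReferenceError(
                    f"{self.segment_id}: J anchor codon translates to {anchor_aa!r}, "
                    "expected F, W or L"
                )
            if self.anchor_offset + 6 > len(seq):
                raise ReferenceError(f"{self.segment_id}: no codon after the J anchor")
            next_aa = _translate_codon(seq[self.anchor_offset + 3 : self.anchor_offset + 6])
            if next_aa != "G":
                raise ReferenceError(
                    f"{self.segment_id}: codon after the J anchor translates to "
                    f"{next_aa!r}, expected G (F/W/L-G motif)"
                )

    @property
    def stem(self) -> str:
        """Family-subfamily stem shared by duplicated subfamily members."""
        if self.kind == "V":
            return f"TRAV{self.family:02d}-{self.subfamily}"
        return f"TRAJ{self.family:02d}"


@dataclass(frozen=True)
class AmbiguityGroup:
    """A set of germline segments indistinguishable over the assignment region.

    ``group_id`` is the common stem plus the sorted duplication-class letters of
    the members (``TRAV06-3ADN``); singleton groups keep their plain id.
    """

    group_id: str
    kind: str
    members: frozenset[str]
    representative: GermlineSegment = field(compare=False)

    @property
    def nt_sequence(self) -> str:
        return self.representative.nt_sequence

    @property
    def anchor_offset(self) -> int:
        return self.representative.anchor_offset


_META_COLUMNS = ["segment_id", "kind", "family", "subfamily", "dup_class", "anchor_offset"]


def load_reference(fasta_path: str | Path, metadata_path: str | Path) -> list[GermlineSegment]:
    """Load and validate a germline reference (FASTA + TSV sidecar).

    FASTA record ids must match metadata ``segment_id`` rows one-to-one.
    Anchor-codon invariants are checked on load; any violation raises
    :class:`ReferenceError` naming the offending segment.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = set(_META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ReferenceError(f"metadata is missing columns: {sorted(missing_cols)}")
    if meta["segment_id"].duplicated().any():
        dups = meta.loc[meta["segment_id"].duplicated(), "segment_id"].tolist()
        raise ReferenceError(f"duplicate segment_id in metadata: {dups}")
    meta_by_id = meta.set_index("segment_id")

    segments: list[GermlineSegment] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        sid = record.id
        if sid in seen:
            raise ReferenceError(f"duplicate segment_id in FASTA: {sid}")
        seen.add(sid)
        if sid not in meta_by_id.index:
            raise ReferenceError(f"no metadata row for FASTA record {sid}")
        row = meta_by_id.loc[sid]
        segments.append(
            GermlineSegment(
                segment_id=sid,
                kind=str(row["kind"]),
                family=int(row["family"]),
                subfamily=int(row["subfamily"]),
                dup_class=str(row["dup_class"]),
                nt_sequence=str(record.seq).upper(),
                anchor_offset=int(row["anchor_offset"]),
            )
        )
    unseen = set(meta_by_id.index) - seen
    if unseen:
        raise ReferenceError(f"metadata rows without FASTA records: {sorted(unseen)}")
    return segments


def write_reference(
    segments: list[GermlineSegment], fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Serialize a reference back to FASTA + TSV (round-trips with load_reference)."""
    with open(fasta_path, "w") as fh:
        for seg in segments:
            fh.write(f">{seg.segment_id}\n{seg.nt_sequence}\n")
    rows = [
        {
            "segment_id": s.segment_id,
            "kind": s.kind,
            "family": s.family,
            "subfamily": s.subfamily,
            "dup_class": s.dup_class,
            "anchor_offset": s.anchor_offset,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(metadata_path, sep="\t", index=False)


def collapse_indistinguishable(segments: list[GermlineSegment]) -> list[AmbiguityGroup]:
    """Merge segments with identical assignment-region sequence and stem.

    The assignment region is the full stored sequence.  Only subfamily members
    (same family-subfamily stem) are merged; identical sequences across
    different stems are kept separate with a warning.  The result partitions
    the input: every segment belongs to exactly one group.
    """
    by_key: dict[tuple[str, str, str], list[GermlineSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.kind, seg.stem, seg.nt_sequence), []).append(seg)

    # warn on identical sequences crossing stems
    seq_to_stems: dict[tuple[str, str], set[str]] = {}
    for kind, stem, seq in by_key:
        seq_to_stems.setdefault((kind, seq), set()).add(stem)
    for (kind, _seq), stems in seq_to_stems.items():
        if len(stems) > 1:
            warnings.warn(
                f"identical {kind} sequences across different stems kept separate: "
                f"{sorted(stems)}",
                stacklevel=2,
            )

    groups: list[AmbiguityGroup] = []
    for (kind, stem, _seq), members in by_key.items():
        members = sorted(members, key=lambda s: s.segment_id)
        if len(members) == 1 and members[0].dup_class == "none":
            gid = members[0].segment_id
        else:
            letters = "".join(sorted(m.dup_class for m in members if m.dup_class != "none"))
            gid = stem + letters
        groups.append(
            AmbiguityGroup(
                group_id=gid,
                kind=kind,
                members=frozenset(m.segment_id for m in members),
                representative=members[0],
            )
        )
    groups.sort(key=lambda g: (g.kind, g.group_id))
    return groups


def groups_by_kind(groups: list[AmbiguityGroup], kind: str) -> list[AmbiguityGroup]:
    return [g for g in groups if g.kind == kind]
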