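"""Readers and writers for the pipeline's standard formats.

Reads come in as FASTA or FASTQ (qualities ignored).  Annotated sequences go
out as an AIRR-style rearrangement TSV; repertoires as clonotype TSVs with the
sample metadata in ``#key=value`` header lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

from .annotate import AnnotatedSequence, RawRead
from .keys import KEY_COLUMNS, KeyScheme, clonotype_key
from .repertoire import Repertoire, SampleMetadata

__all__ = [
    "read_sequences",
    "write_airr",
    "read_airr",
    "airr_to_annotated",
    "write_repertoire",
    "read_repertoire",
]

AIRR_COLUMNS = [
    "sequence_id",
    "v_call",
    "j_call",
    "sequence",
    "junction",
    "junction_aa",
    "n_bases",
    "productive",
    "corrections_applied",
    "duplicate_count",
]


def read_sequences(path: str | Path, sample_id: str = "") -> Iterator[RawRead]:
    """Yield reads from FASTA or FASTQ (format sniffed from the extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    for record in SeqIO.parse(str(path), fmt):
        yield RawRead(record.id, str(record.seq).upper(), sample_id)


def write_airr(annotated: list[AnnotatedSequence], path: str | Path) -> None:
    """AIRR-style rearrangement TSV, one row per read.

    ``duplicate_count`` is the number of reads in the sample sharing the full
    TCR-alpha clonotype key.
    """
    from collections import Counter

    dup = Counter(clonotype_key(a, KeyScheme.FULL_TCRA) for a in annotated)
    rows = [
        {
            "sequence_id": a.read_id,
            "v_call": a.v_group,
            "j_call": a.j_group,
            "sequence": a.corrected_nt,
            "junction": a.cdr3_nt,
            "junction_aa": a.cdr3_aa,
            "n_bases": a.n_bases,
            "productive": "T" if a.productive else "F",
            "corrections_applied": a.corrections_applied,
            "duplicate_count": dup[clonotype_key(a, KeyScheme.FULL_TCRA)],
        }
        for a in annotated
    ]
    pd.DataFrame(rows, columns=AIRR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"junction_aa": str, "junction": str})


def airr_to_annotated(df: pd.DataFrame, sample_id: str = "") -> list[AnnotatedSequence]:
    return [
        AnnotatedSequence(
            read_id=str(r.sequence_id),
            sample_id=sample_id,
            v_group=str(r.v_call),
            j_group=str(r.j_call),
            corrected_nt=str(r.sequence),
            cdr3_nt=str(r.junction),
            cdr3_aa=str(r.junction_aa),
            n_bases=int(r.n_bases),
            productive=(str(r.productive) == "T"),
            corrections_applied=int(r.corrections_applied),
        )
        for r in df.itertuples(index=False)
    ]


def write_repertoire(rep: Repertoire, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample_id={rep.sample_id}\n")
        fh.write(f"#key_scheme={rep.key_scheme.value}\n")
        m = rep.metadata
        fh.write(f"#mouse_id={m.mouse_id}\n#mhc_allele={m.mhc_allele}\n")
        fh.write(f"#tcrb={m.tcrb}\n#compartment={m.compartment}\n")
        rep.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_repertoire(path: str | Path) -> Repertoire:
    header: dict[str, str] = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].rstrip("\n").partition("=")
            header[key] = value
        table = pd.read_csv(fh, sep="\t")
    scheme = KeyScheme(header["key_scheme"])
    for col in KEY_COLUMNS[scheme]:
        if col in table.columns:
            table[col] = table[col].astype(str)
    metadata = SampleMetadata(
        mouse_id=header.get("mouse_id", header["sample_id"]),
        mhc_allele=header.get("mhc_allele", "other"),
        tcrb=header.get("tcrb", "polyclonal"),
        compartment=header.get("compartment", "naive_CD4"),
    )
    return Repertoire(header["sample_id"], metadata, scheme, table)
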