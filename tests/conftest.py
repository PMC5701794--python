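import pandas as pd
import pytest

from tcrarep.germline import GermlineSegment, collapse_indistinguishable
from tcrarep.keys import KeyScheme
from tcrarep.repertoire import Repertoire, SampleMetadata

# Hand-built toy reference: 2 V and 2 J segments with valid anchors.
# V anchor (TGT, Cys) sits 9 nt before the 3' end; J anchor (TTT/TGG, F/W)
# at offset 6 with a Gly codon following.
TOY_V1 = "ATGACCGATCTGAAGGCAGCA" + "TGT" + "GCTGCA"  # len 30, anchor 21
TOY_V2 = "CCGTTAGGCATAGACCTTAGC" + "TGT" + "AGTCAA"
TOY_J1 = "GGAACT" + "TTT" + "GGA" + "AAGCTGACC"  # len 21, anchor 6
TOY_J2 = "CTTCAG" + "TGG" + "GGT" + "CTGAAAACC"


def _seg(sid, kind, family, subfamily, dup, seq, anchor):
    return GermlineSegment(sid, kind, family, subfamily, dup, seq, anchor)


@pytest.fixture
def toy_segments():
    return [
        _seg("TRAV01-1A", "V", 1, 1, "A", TOY_V1, 21),
        _seg("TRAV02-1A", "V", 2, 1, "A", TOY_V2, 21),
        _seg("TRAJ01", "J", 1, 1, "none", TOY_J1, 6),
        _seg("TRAJ02", "J", 2, 1, "none", TOY_J2, 6),
    ]


@pytest.fixture
def toy_groups(toy_segments):
    return collapse_indistinguishable(toy_segments)


def make_repertoire(
    sample_id,
    counts,
    key_scheme=KeyScheme.FULL_TCRA,
    metadata=None,
    n_bases=None,
):
    """Repertoire from a dict of clonotype-key tuples (or strings) -> count."""
    scheme = KeyScheme(key_scheme)
    if metadata is None:
        metadata = SampleMetadata(mouse_id=sample_id)
    key_cols = {
        KeyScheme.FULL_TCRA: ["v_group", "j_group", "cdr3_aa"],
        KeyScheme.CDR3_ONLY: ["cdr3_aa"],
        KeyScheme.VJ_PAIR: ["v_group", "j_group"],
    }[scheme]
    if not counts:
        table = pd.DataFrame(columns=key_cols + ["count"])
        return Repertoire(sample_id, metadata, scheme, table)
    rows = []
    for i, (key, count) in enumerate(counts.items()):
        if isinstance(key, str):
            key = (key,)
        if scheme is KeyScheme.FULL_TCRA:
            row = {"v_group": key[0], "j_group": key[1], "cdr3_aa": key[2]}
        elif scheme is KeyScheme.CDR3_ONLY:
            row = {"cdr3_aa": key[0]}
        else:
            row = {"v_group": key[0], "j_group": key[1]}
        row["count"] = count
        if n_bases is not None:
            row["n_bases"] = n_bases[i]
        rows.append(row)
    table = pd.DataFrame(rows)
    return Repertoire(sample_id, metadata, scheme, table)
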