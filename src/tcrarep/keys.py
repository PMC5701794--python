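"""Clonotype key schemes.

A clonotype is identified either by its full TCR-alpha protein identity
(V group, J group, CDR3 amino-acid sequence), by the CDR3 alone, or by the
bare V-J pair.  The scheme chosen changes what "the same sequence" means in
every downstream overlap and filtering step.
"""

from __future__ import annotations

from enum import Enum

__all__ = ["KeyScheme", "KEY_COLUMNS", "clonotype_key"]


class KeyScheme(str, Enum):
    FULL_TCRA = "full_tcra"
    CDR3_ONLY = "cdr3_only"
    VJ_PAIR = "vj_pair"


KEY_COLUMNS: dict[KeyScheme, list[str]] = {
    KeyScheme.FULL_TCRA: ["v_group", "j_group", "cdr3_aa"],
    KeyScheme.CDR3_ONLY: ["cdr3_aa"],
    KeyScheme.VJ_PAIR: ["v_group", "j_group"],
}


def clonotype_key(annotated, scheme: KeyScheme) -> tuple:
    """Key tuple for an annotated sequence under ``scheme``."""
    scheme = KeyScheme(scheme)
    if scheme is KeyScheme.FULL_TCRA:
        return (annotated.v_group, annotated.j_group, annotated.cdr3_aa)
    if scheme is KeyScheme.CDR3_ONLY:
        return (annotated.cdr3_aa,)
    return (annotated.v_group, annotated.j_group)
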